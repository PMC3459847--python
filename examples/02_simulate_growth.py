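"""A label-and-chase growth simulation: 15 min light, 75 min dark.

Runs the stochastic patch-insertion model at the headline kinetics and
prints the area ledger and the patch census at both snapshot times.
"""

from omgrowth import LabelSchedule, SimulationConfig, run_simulation

cfg = SimulationConfig(
    k_on=0.004,
    k_ins=0.00064,
    tau=50.0,
    t_double=None,
    seed=42,
    t_end=5400.0,
    snapshot_times=(900.0, 5400.0),
    schedule=LabelSchedule(((900.0, "light"), (4500.0, "dark"))),
)
snaps = run_simulation(cfg)

for s in snaps:
    n_light = sum(p.label == "light" for p in s.patches)
    n_dark = sum(p.label == "dark" for p in s.patches)
    print(
        f"t = {s.t / 60:5.1f} min | cylinder {s.geom.x_left:+.2f}..{s.geom.x_right:+.2f} um"
        f" | area {s.area:6.3f} um^2 (initial {s.initial_area:.3f}"
        f" + inserted {s.inserted_area:.3f})"
        f" | patches: {n_light} light, {n_dark} dark"
    )
print(
    "\nThe domain area equals initial + inserted area exactly (flux ledger);\n"
    "light patches are created only in the first 15 minutes and are then\n"
    "dispersed toward the poles by dark insertion."
)
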