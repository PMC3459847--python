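"""Render a simulated cell into widefield micrographs and save a TIFF stack.

The light-labelled patches are wrapped onto the 3D cylinder, blurred with a
defocus-dependent Gaussian PSF (100X / 1.4 NA at 575 nm, 68 nm pixels) and
read out with shot + read noise.
"""

import numpy as np

from omgrowth import (
    LabelSchedule,
    OpticsConfig,
    SimulationConfig,
    render_micrograph,
    run_simulation,
    save_tiff,
)

times = tuple(np.arange(0.0, 5401.0, 900.0))
cfg = SimulationConfig(
    k_on=0.004, k_ins=0.00064, tau=50.0, t_double=None, seed=7,
    t_end=5400.0, snapshot_times=times,
    schedule=LabelSchedule(((900.0, "light"), (4500.0, "dark"))),
)
snaps = run_simulation(cfg)

optics = OpticsConfig()
rng = np.random.default_rng(7)
frames = [render_micrograph(s, optics, rng=rng) for s in snaps]
path = save_tiff(frames, "scratch_micrographs.tif")

from omgrowth import detect_spots

print(f"wrote {len(frames)} frames to {path}")
for m in frames:
    sig = m.data.max() - np.median(m.data)
    n = len(detect_spots(m))
    print(
        f"t = {m.t / 60:5.1f} min | {m.data.shape[0]}x{m.data.shape[1]} px"
        f" @ {m.pixel_nm:.0f} nm | peak {sig:6.1f} counts over background"
        f" | {n} puncta"
    )
print(
    "\nThe image widens as the cell elongates; after labeling ends, unlabeled\n"
    "growth concentrates the light material into discrete diffraction-limited\n"
    "puncta drifting toward the inert poles."
)
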