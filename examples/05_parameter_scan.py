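"""A miniature parameter screen over mean insertion size at fixed doubling time.

Each pair runs the full simulate -> render -> detect -> sigmoid pipeline;
pairs are then classified against metric intervals (stand-ins for
experiment-derived bounds, centred on the headline pair here).
"""

import numpy as np

from omgrowth import ScanGrid, classify_consistent, run_scan

T_DOUBLE = 5400.0
lam = np.log(2) / T_DOUBLE

# headline pair plus a 20x spread of mean insertion sizes at tau = 50 s
pairs = [(0.004, 0.00064)]
for tau, m in ((50.0, 0.16), (50.0, 0.008)):
    k_ins = m / tau
    pairs.append(((lam * lam + lam / tau) / k_ins, k_ins))

grid = ScanGrid(tuple(pairs), t_double=T_DOUBLE, replicates=2, base_seed=5)
df = run_scan(grid, t_end=1200.0, frame_interval=150.0)
cols = ["k_on", "k_ins", "tau", "mean_insertion_area",
        "appearance_rate_per_um", "max_puncta_per_um"]
print(df[cols].to_string(index=False, float_format=lambda x: f"{x:.4g}"))

head = df.iloc[0]
rate_iv = (0.75 * head["appearance_rate_per_um"], 1.25 * head["appearance_rate_per_um"])
count_iv = (0.75 * head["max_puncta_per_um"], 1.25 * head["max_puncta_per_um"])
labelled, summary = classify_consistent(df, rate_iv, count_iv)
print("\nlabels:", list(labelled["label"]))
print("consistency region:", summary)
print(
    "\nLarger insertion events produce fewer resolvable puncta per um of\n"
    "perimeter; bounds around the headline metrics single out its (k_on,\n"
    "tau*k_ins) region, the screen's mechanism for constraining the kinetics."
)
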