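"""Run the full RolDE pipeline on a simulated dataset.

Scores every protein with the three modules (RegROTS, DiffROTS, PolyReg),
combines them by rank product, estimates significance against the simulated
null rank-product distribution and prints the top detections.
"""

from rolde import generate_dataset, inject_missing, run_rolde
from rolde.rots import RotsSettings

ds = generate_dataset(n_background=300, n_spikein=20, trend_pair=("Sigmoid", "Stable"), seed=11)
ds = inject_missing(ds, overall_rate=0.10, mechanism="MNAR", seed=12)

res = run_rolde(ds.expr, ds.design, settings=RotsSettings(b=100), n_sim=100_000, seed=13)

top = res.table.sort_values("S_RolDE").head(10)
print(top[["S_RolDE", "rank_RegROTS", "rank_DiffROTS", "rank_PolyReg", "estimated_p", "adjusted_p"]])
n_spike_top = sum(p.startswith("SPIKE") for p in top.index)
print(f"\n{n_spike_top}/10 of the top-10 proteins are true spike-ins.")
print("S_RolDE is the geometric mean of the three module ranks: 1 means a")
print("protein ranked first in every module; estimated_p is the fraction of")
print("simulated null rank products at least as small.")
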