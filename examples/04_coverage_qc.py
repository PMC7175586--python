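"""Transcript-coverage QC: poly(A) selection on degraded RNA skews coverage
toward the 3' end; random-primed (rRNA-depleted) libraries stay even.
"""

import numpy as np

from mgpde import coverage_metrics, metrics_frame, qc_regressions, simulate_coverage

rins = {f"s{i:02d}": float(r) for i, r in enumerate(np.linspace(3.0, 7.2, 8))}
pa = simulate_coverage(40, (500, 1500), "polyA", rins, seed=1)
rp = simulate_coverage(40, (500, 1500), "random_primed", rins, seed=1)

metrics = [coverage_metrics(c) for c in pa + rp]
table = metrics_frame(metrics)
print(table.groupby("cohort")[["bias5", "bias3", "median_cv"]].median().round(3))

regs = qc_regressions(metrics)
print("\nper-cohort regression of each metric on RIN (slope, F-test p):")
print(regs["rin"].round(4).to_string(index=False))
print(
    "\nbias5/bias3 = mean coverage of the terminal 100 bases over the "
    "transcript mean (1 = unbiased).  In the poly(A) cohort bias3 rises and "
    "bias5 falls as RIN drops; the random-primed cohort is flat near 1."
)
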