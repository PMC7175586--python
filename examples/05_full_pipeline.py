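"""Run the whole pipeline from one config dict: simulate, preprocess,
MGPs, covariate diagnostics, DE with and without composition adjustment,
enrichment and delta scoring — with every output written under out/.
"""

import json
from pathlib import Path

from mgpde import run_all

config = {
    "seed": 7,
    "simulate": {
        "composition_shift": {"oligodendrocyte": 1.3},
        "n_regulatory_de": 100,
        "regulatory_lfc": 1.5,
    },
    "enrichment": {"n_resample": 2000},
}

out = Path("scratch/example_run")
manifest = run_all(config, out)
comparison = json.loads((out / "de_comparison.json").read_text())

print(f"pipeline wrote {len(manifest.files)} files under {out}/")
print(f"DE genes without MGP adjustment: {comparison['n_sig_0']}")
print(f"DE genes with MGP adjustment:    {comparison['n_sig_ct']}")
print(f"significant in both models:      {comparison['n_both']}")
print(
    "\nThe drop in discoveries under adjustment measures how much of the "
    "apparent differential expression was carried by cell-composition "
    "differences between cases and controls."
)
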