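#!/usr/bin/env python
"""Generate every synthetic input the analysis consumes.

Writes four datasets with planted, recorded truth under results/data/:
a germplasm IP6 panel (two 2-fold pairs, one 1.2-fold decoy pair), a
two-group count table with 10% planted 4-fold genes, a miRNA/transcript
set with planted target sites, and the full network dataset (3 planted
co-expression modules, 24 samples, metabolites tied to module factors, a
guide gene and a planted candidate inside the first module).
"""

from pathlib import Path

from phytonet.presets import simulate_preset

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"

if __name__ == "__main__":
    for preset in ("germplasm", "counts", "mirna", "full"):
        paths = simulate_preset(preset, seed=SEED, out_dir=DATA / preset)
        print(f"[{preset}] wrote {len(paths)} files -> {DATA / preset}")
    print("done: all synthetic inputs carry their planted truth as JSON")
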