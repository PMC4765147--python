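#!/usr/bin/env python
"""Screen the germplasm panel for stable IP6-content line pairs.

Applies the Q = |log2(x_i/x_j)| contrast with the Q > 0.58 gate in every
environment plus the one-sided stability t-test, and checks the retained
set against the planted truth.
"""

import json
from pathlib import Path

from phytonet.germplasm import GermplasmPanel, evaluate_all_pairs

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data" / "germplasm"
OUT = ROOT / "results" / "tables"

if __name__ == "__main__":
    panel = GermplasmPanel.from_tsv(DATA / "germplasm_panel.tsv")
    truth = json.loads((DATA / "truth_germplasm.json").read_text())
    pairs = evaluate_all_pairs(panel)
    OUT.mkdir(parents=True, exist_ok=True)
    pairs.to_csv(OUT / "germplasm_pairs.tsv", sep="\t", index=False)

    stable = {frozenset((a, b)) for a, b in
              pairs.loc[pairs.stable, ["line_i", "line_j"]].itertuples(index=False)}
    for hi, lo, ratio in truth["germplasm_pairs"]:
        status = "retained" if frozenset((hi, lo)) in stable else "rejected"
        print(f"planted pair {hi}/{lo} (ratio {ratio}): {status}")
    print(f"{len(stable)} stable pairs of {len(pairs)} evaluated "
          f"-> {OUT / 'germplasm_pairs.tsv'}")
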