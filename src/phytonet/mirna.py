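"""Plant-style miRNA target scoring.

Duplexes are scored with additive penalties in the plant target-prediction
tradition: 0 for a Watson-Crick pair, 0.5 for a G:U wobble, 1 for any
other mismatch, with every penalty doubled over miRNA positions 2-13 (the
functionally critical core). A site is called a predicted target when its
total score is strictly below 4. Only ungapped miRNA-length windows are
scored. Predicted targets are reported together with the Pearson
correlation of miRNA and target expression (no gate is applied to it —
anticorrelation is supporting evidence, not a filter).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

SCORE_MAX = 4.0  # exclusive: predicted targets score strictly below this
CORE_START, CORE_END = 2, 13  # 1-based miRNA positions with doubled penalties

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {("G", "U"), ("U", "G")}


@dataclass
class DuplexScore:
    mirna_id: str
    target_id: str
    score: float
    site_start: int  # 0-based on the target transcript
    site_end: int  # half-open
    predicted: bool


def _clean(seq: str, what: str) -> str:
    if not seq:
        raise ValueError(f"{what} sequence is empty")
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"{what} sequence contains invalid characters: {sorted(bad)}")
    return s


def score_duplex(mirna_seq: str, site_seq: str) -> float:
    """Penalty score of a miRNA against a same-length target site.

    Both sequences run 5'->3'; miRNA position i pairs with site position
    L - i (the site is read antiparallel). T and U are treated identically.
    """
    m = _clean(mirna_seq, "miRNA")
    s = _clean(site_seq, "site")
    if len(m) != len(s):
        raise ValueError(f"sequence lengths differ ({len(m)} vs {len(s)})")
    total = 0.0
    L = len(m)
    for i in range(L):
        mb, tb = m[i], s[L - 1 - i]
        if _COMPLEMENT[mb] == tb:
            penalty = 0.0
        elif (mb, tb) in _WOBBLE:
            penalty = 0.5
        else:
            penalty = 1.0
        if CORE_START <= i + 1 <= CORE_END:
            penalty *= 2.0
        total += penalty
    return total


def scan_targets(
    mirna_seq: str,
    transcript_seq: str,
    mirna_id: str = "mirna",
    target_id: str = "target",
    threshold: float = SCORE_MAX,
) -> list[DuplexScore]:
    """Score every ungapped miRNA-length window of a transcript.

    Windows scoring strictly below ``threshold`` are returned best first
    (ties by position); coordinates are 0-based half-open on the
    transcript.
    """
    m = _clean(mirna_seq, "miRNA")
    t = _clean(transcript_seq, "transcript")
    if len(t) < len(m):
        raise ValueError("transcript is shorter than the miRNA")
    hits = []
    for start in range(len(t) - len(m) + 1):
        window = t[start:start + len(m)]
        score = score_duplex(m, window)
        if score < threshold:
            hits.append(DuplexScore(
                mirna_id=mirna_id, target_id=target_id, score=score,
                site_start=start, site_end=start + len(m),
                predicted=score < SCORE_MAX,
            ))
    hits.sort(key=lambda h: (h.score, h.site_start))
    return hits


def expression_anticorrelation(mirna_profile, target_profile) -> float:
    """Pearson correlation of miRNA and target expression across samples.

    Returns NaN (with a warning) when either profile has zero variance.
    """
    x = np.asarray(mirna_profile, dtype=float)
    y = np.asarray(target_profile, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must cover the same samples")
    if x.size < 3:
        raise ValueError("at least 3 samples are required")
    if x.std() == 0 or y.std() == 0:
        log.warning("zero-variance expression profile; correlation undefined")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
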