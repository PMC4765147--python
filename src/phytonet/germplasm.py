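"""Germplasm screening for stable seed IP6 (phytic acid) content contrasts.

Inbred-line pairs are contrasted with the Q statistic, the absolute log2
ratio of seed phytic-acid-phosphorus content (mg/g) between two lines.
A pair is kept when the contrast clears a threshold in every environment
where both lines were measured *and* the per-environment Q values are
significantly above the threshold (one-sided one-sample t-test), i.e. the
contrast is large and environmentally stable.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: default contrast threshold: log2(1.5), a 1.5-fold content difference
Q_THRESHOLD = 0.58


@dataclass
class GermplasmPanel:
    """Lines x environments table of seed IP6 content (mg/g); NaN = missing."""

    content: pd.DataFrame  # index: line_id, columns: env_id

    def __post_init__(self) -> None:
        if self.content.shape[1] < 2:
            raise ValueError("a germplasm panel needs at least 2 environments")
        vals = self.content.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise ValueError("IP6 content values must be strictly positive")

    @property
    def line_ids(self) -> list[str]:
        return list(self.content.index)

    @property
    def env_ids(self) -> list[str]:
        return list(self.content.columns)

    @classmethod
    def from_tsv(cls, path) -> "GermplasmPanel":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(content=df.astype(float))

    def to_tsv(self, path) -> None:
        self.content.to_csv(path, sep="\t")


@dataclass
class LinePair:
    """One evaluated line pair with per-environment Q values."""

    line_i: str
    line_j: str
    q_per_env: dict[str, float] = field(default_factory=dict)
    mean_q: float = float("nan")
    stability_p: float = float("nan")
    stable: bool = False


def compute_q(x_i: float, x_j: float) -> float:
    """Absolute log2 content ratio Q = |log2(x_i / x_j)|.

    Symmetric in its arguments and invariant to rescaling both contents.
    """
    if x_i <= 0 or x_j <= 0:
        raise ValueError(f"content values must be positive, got ({x_i}, {x_j})")
    return abs(float(np.log2(x_i / x_j)))


def _stability_p(q_values: np.ndarray, q_threshold: float) -> float:
    """One-sided p for H1: mean Q > q_threshold (one-sample t-test)."""
    if q_values.std(ddof=1) == 0.0:
        # degenerate: identical Q in all environments
        return 0.0 if q_values.mean() > q_threshold else 1.0
    t, p_two = stats.ttest_1samp(q_values, q_threshold)
    return p_two / 2.0 if t > 0 else 1.0 - p_two / 2.0


def evaluate_pair(
    panel: GermplasmPanel,
    line_i: str,
    line_j: str,
    q_threshold: float = Q_THRESHOLD,
    alpha: float = 0.05,
) -> LinePair | None:
    """Evaluate one pair; None when fewer than 2 shared environments."""
    xi = panel.content.loc[line_i]
    xj = panel.content.loc[line_j]
    both = xi.notna() & xj.notna()
    if both.sum() < 2:
        log.warning("pair (%s, %s) has <2 shared environments; skipped", line_i, line_j)
        return None
    q = {env: compute_q(xi[env], xj[env]) for env in panel.env_ids if both[env]}
    qv = np.array(list(q.values()))
    p = _stability_p(qv, q_threshold)
    stable = bool(np.all(qv > q_threshold) and p < alpha)
    return LinePair(line_i, line_j, q, float(qv.mean()), float(p), stable)


def screen_stable_pairs(
    panel: GermplasmPanel,
    q_threshold: float = Q_THRESHOLD,
    alpha: float = 0.05,
    pairs: list[tuple[str, str]] | None = None,
    high_group: list[str] | None = None,
    low_group: list[str] | None = None,
) -> list[LinePair]:
    """Return the stable line pairs of a panel.

    Pairs are enumerated across ``high_group`` x ``low_group`` when given,
    from ``pairs`` when given, else over all unordered pairs (quadratic —
    fine at desk scale, a warning is emitted above 1000 lines).

    A pair is stable when (a) Q > ``q_threshold`` in every environment where
    both lines are measured, and (b) the per-environment Q values exceed the
    threshold significantly (one-sided one-sample t-test, p < ``alpha``).
    """
    if pairs is None:
        if high_group is not None and low_group is not None:
            pairs = [(h, l) for h in high_group for l in low_group if h != l]
        else:
            if len(panel.line_ids) > 1000:
                log.warning(
                    "enumerating all pairs of %d lines is quadratic", len(panel.line_ids)
                )
            pairs = list(itertools.combinations(panel.line_ids, 2))
    out = []
    for li, lj in pairs:
        lp = evaluate_pair(panel, li, lj, q_threshold, alpha)
        if lp is not None and lp.stable:
            out.append(lp)
    return out


def evaluate_all_pairs(
    panel: GermplasmPanel,
    q_threshold: float = Q_THRESHOLD,
    alpha: float = 0.05,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Evaluate pairs and return every evaluated record (stable or not)."""
    if pairs is None:
        pairs = list(itertools.combinations(panel.line_ids, 2))
    rows = []
    for li, lj in pairs:
        lp = evaluate_pair(panel, li, lj, q_threshold, alpha)
        if lp is None:
            continue
        row = {"line_i": lp.line_i, "line_j": lp.line_j}
        row.update({f"q_{env}": q for env, q in lp.q_per_env.items()})
        row.update(
            {"mean_q": lp.mean_q, "stability_p": lp.stability_p, "stable": lp.stable}
        )
        rows.append(row)
    return pd.DataFrame(rows)
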