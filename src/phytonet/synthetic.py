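"""Synthetic-data generators with planted, recorded structure.

Every input the pipeline consumes can be generated here: an expression
matrix over a genotype x stage x replicate embryo design with planted
co-expression modules (single latent factor per module — the minimal
generator of block-correlated expression), metabolite profiles with a
chosen correlation to a module factor, negative-binomial count tables with
planted fold changes, a multi-environment germplasm panel with planted
content-ratio line pairs, miRNA/target-site duplexes with a planned number
of mismatches, and a hand-built candidate-screening benchmark network.

All generators are pure functions of their arguments including the seed,
and each returns its ground truth alongside the data so recovery tests
never have to re-derive what was planted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .expression import CountTable, ExpressionMatrix
from .germplasm import GermplasmPanel

RNA = "ACGU"
COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
#: positions on the miRNA (1-based from the 5' end) where pairing penalties double
CORE_POSITIONS = range(2, 14)
MIRNA_LENGTH = 21

# expression emission: affine map of the latent Gaussian into positive
# arbitrary units; preserves both Pearson and Spearman structure exactly
EXPR_OFFSET = 10.0
EXPR_SCALE = 2.0
EXPR_FLOOR = 1e-3


@dataclass
class ModuleSpec:
    """One planted co-expression module: its size, how tightly the member
    genes follow the latent factor (loading in (0, 1]), and optionally a
    fixed per-sample factor profile (drawn N(0,1) when absent)."""

    module_id: str
    n_genes: int
    loading: float = 0.85
    factor_profile: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("a module needs at least one gene")
        if not 0 < self.loading <= 1:
            raise ValueError("loading must lie in (0, 1]")


@dataclass
class SyntheticDesign:
    """Genotype x stage x replicate expression design plus planted modules."""

    genotypes: tuple = ("HPA", "LPA")
    stages: tuple = ("12DAP", "21DAP", "30DAP")
    replicates: int = 2
    n_background_genes: int = 350
    modules: list[ModuleSpec] = field(default_factory=list)
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return len(self.genotypes) * len(self.stages) * self.replicates

    def sample_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": f"{g}_{s}_r{r}", "genotype": g, "stage": s, "replicate": r}
            for g in self.genotypes for s in self.stages
            for r in range(1, self.replicates + 1)
        ]
        return pd.DataFrame(rows).set_index("sample_id")


def default_design(seed: int = 0, replicates: int = 2, n_modules: int = 5,
                   genes_per_module: int = 50, loading: float = 0.85,
                   n_background: int = 350) -> SyntheticDesign:
    mods = [ModuleSpec(f"M{i + 1}", genes_per_module, loading) for i in range(n_modules)]
    return SyntheticDesign(replicates=replicates, n_background_genes=n_background,
                           modules=mods, seed=seed)


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside generated data."""

    module_of: dict = field(default_factory=dict)  # gene -> module_id
    factors: dict = field(default_factory=dict)  # module_id -> per-sample vector
    sample_ids: list = field(default_factory=list)
    metabolite_targets: dict = field(default_factory=dict)  # metabolite -> (module, r0)
    de_genes: dict = field(default_factory=dict)  # gene -> planted fold change
    germplasm_pairs: list = field(default_factory=list)  # (line_hi, line_lo, ratio)
    duplex_scores: dict = field(default_factory=dict)  # mirna_id -> truth score
    candidate_roles: dict = field(default_factory=dict)  # gene -> role string
    expected_top_candidate: str | None = None

    def to_json(self, path) -> None:
        data = asdict(self)
        data["factors"] = {m: list(map(float, v)) for m, v in self.factors.items()}
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)


# ---------------------------------------------------------------- expression

def gen_expression_with_modules(design: SyntheticDesign) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Expression matrix with planted block-correlated modules.

    Each module gene's latent profile is loading * factor + sqrt(1 -
    loading^2) * noise with i.i.d. standard-normal noise; background genes
    are pure noise. The latent values are mapped affinely into positive
    arbitrary expression units (correlation structure is untouched).
    """
    n = design.n_samples
    if n < 4:
        raise ValueError("at least 4 samples are required (correlation degenerates below)")
    rng = np.random.default_rng(design.seed)
    meta = design.sample_frame()
    samples = list(meta.index)

    truth = PlantedTruth(sample_ids=samples)

    # Draw factors for modules without an explicit profile, mutually
    # orthogonalized and standardized: planted modules are distinct latent
    # programs, and truth labels must stay recoverable in principle — two
    # factors overlapping by chance would confound the planted membership.
    drawn = [s for s in design.modules if s.factor_profile is None]
    if drawn:
        raw = rng.standard_normal((n, len(drawn)))
        if len(drawn) <= n:
            raw, _ = np.linalg.qr(raw - raw.mean(axis=0, keepdims=True))
        drawn_factors = {
            s.module_id: (raw[:, j] - raw[:, j].mean()) / raw[:, j].std()
            for j, s in enumerate(drawn)
        }

    rows, gene_ids = [], []
    for spec in design.modules:
        if spec.factor_profile is not None:
            f = np.asarray(spec.factor_profile, dtype=float)
            if len(f) != n:
                raise ValueError(
                    f"factor profile of {spec.module_id} has length {len(f)}, expected {n}")
        else:
            f = drawn_factors[spec.module_id]
        truth.factors[spec.module_id] = f
        resid = math.sqrt(1.0 - spec.loading**2)
        for k in range(spec.n_genes):
            gid = f"{spec.module_id}_g{k + 1:04d}"
            rows.append(spec.loading * f + resid * rng.standard_normal(n))
            gene_ids.append(gid)
            truth.module_of[gid] = spec.module_id
    for k in range(design.n_background_genes):
        gid = f"bg_g{k + 1:05d}"
        rows.append(rng.standard_normal(n))
        gene_ids.append(gid)
        truth.module_of[gid] = "background"

    latent = np.vstack(rows) if rows else np.empty((0, n))
    values = np.maximum(EXPR_OFFSET + EXPR_SCALE * latent, EXPR_FLOOR)
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=samples),
        sample_meta=meta,
    )
    return expr, truth


def gen_metabolite_profiles(truth: PlantedTruth, targets: dict, seed: int = 0) -> pd.DataFrame:
    """Metabolite x sample profiles with planted factor correlations.

    ``targets`` maps metabolite name -> (module_id, r0); each metabolite is
    r0 * factor + sqrt(1 - r0^2) * noise over samples (factor standardized
    first). Negative r0 plants an anticorrelated metabolite; r0 = 0 an
    independent one. Recorded in ``truth.metabolite_targets``.
    """
    rng = np.random.default_rng(seed)
    n = len(truth.sample_ids)
    rows = {}
    for met, (module_id, r0) in targets.items():
        if module_id not in truth.factors:
            raise ValueError(f"metabolite {met!r} targets unknown module {module_id!r}")
        if abs(r0) > 1:
            raise ValueError(f"|r0| must be <= 1, got {r0}")
        f = np.asarray(truth.factors[module_id], dtype=float)
        fz = (f - f.mean()) / f.std()
        rows[met] = r0 * fz + math.sqrt(1.0 - r0 * r0) * rng.standard_normal(n)
        truth.metabolite_targets[met] = (module_id, float(r0))
    return pd.DataFrame(rows, index=truth.sample_ids).T


def default_metabolite_targets(module_ids) -> dict:
    """IP1..IP6 against the first five modules, alternating sign, with IP6
    left independent (r0 = 0) as a negative control."""
    mods = list(module_ids)
    targets = {}
    signs = [0.9, -0.9, 0.9, -0.9, 0.9]
    for i in range(min(5, len(mods))):
        targets[f"IP{i + 1}"] = (mods[i], signs[i])
    targets["IP6"] = (mods[0], 0.0)
    return targets


# -------------------------------------------------------------------- counts

def gen_count_table(
    n_genes: int,
    n_per_group: int,
    de_fraction: float = 0.0,
    fold_change: float = 2.0,
    dispersion: float = 0.05,
    seed: int = 0,
) -> tuple[CountTable, PlantedTruth]:
    """Negative-binomial count table for a two-group comparison.

    Gene-wise baseline means are drawn log-uniform over [10, 1000]; a
    ``de_fraction`` of genes gets a group-2 mean of ``fold_change`` times
    its group-1 mean. ``dispersion`` is the NB alpha (variance = mu +
    alpha mu^2); alpha = 0 degenerates to Poisson.
    """
    if n_per_group < 2:
        raise ValueError("at least 2 samples per group are required")
    if fold_change <= 0:
        raise ValueError("fold_change must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:05d}" for i in range(n_genes)]
    base = 10.0 ** rng.uniform(1.0, 3.0, size=n_genes)
    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.array([], dtype=int)

    mu = np.tile(base[:, None], (1, 2 * n_per_group))
    mu[de_idx, n_per_group:] *= fold_change

    if dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu))

    cols = [f"A_r{i + 1}" for i in range(n_per_group)] + [f"B_r{i + 1}" for i in range(n_per_group)]
    df = pd.DataFrame(counts, index=genes, columns=cols)
    table = CountTable(
        counts=df,
        exon_length_kb=pd.Series(rng.uniform(0.5, 5.0, size=n_genes), index=genes),
        mapped_reads_millions=df.sum(axis=0) / 1e6,
    )
    truth = PlantedTruth(de_genes={genes[i]: float(fold_change) for i in de_idx})
    return table, truth


def count_group_labels(table: CountTable) -> pd.Series:
    return pd.Series([c.split("_")[0] for c in table.counts.columns],
                     index=table.counts.columns)


# ----------------------------------------------------------------- germplasm

def gen_germplasm_panel(
    n_lines: int,
    n_envs: int,
    planted_pairs: list[tuple[float, float]],
    seed: int = 0,
) -> tuple[GermplasmPanel, PlantedTruth]:
    """Multi-environment IP6 content panel (mg/g) with planted line pairs.

    Each planted (ratio, noise_sd) adds a high/low line pair whose
    per-environment log2 content difference is log2(ratio) plus N(0,
    sqrt(2) * noise_sd) noise. Background lines sit in a narrow band around
    3 mg/g so unplanted pairs stay well under the screening threshold.
    """
    if n_envs < 2:
        raise ValueError("at least 2 environments are required")
    rng = np.random.default_rng(seed)
    envs = [f"env{e + 1}" for e in range(n_envs)]
    rows, truth = {}, PlantedTruth()
    for k, (ratio, noise_sd) in enumerate(planted_pairs):
        if ratio <= 0:
            raise ValueError(f"planted ratio must be positive, got {ratio}")
        lo_base = 3.0 / math.sqrt(ratio)
        hi, lo = f"hi_{k + 1}", f"lo_{k + 1}"
        rows[lo] = lo_base * 2.0 ** rng.normal(0.0, noise_sd, n_envs)
        rows[hi] = lo_base * ratio * 2.0 ** rng.normal(0.0, noise_sd, n_envs)
        truth.germplasm_pairs.append((hi, lo, float(ratio)))
    for k in range(n_lines - 2 * len(planted_pairs)):
        base = 3.0 * 2.0 ** rng.normal(0.0, 0.05)
        rows[f"line_{k + 1:03d}"] = base * 2.0 ** rng.normal(0.0, 0.02, n_envs)
    panel = GermplasmPanel(content=pd.DataFrame(rows, index=envs).T)
    return panel, truth


# --------------------------------------------------------------------- miRNA

def _mismatch_choices(m: str) -> list[str]:
    """Target bases that pair with miRNA base ``m`` as a plain mismatch
    (neither Watson-Crick nor G:U wobble)."""
    bad = {COMPLEMENT[m]}
    if m == "G":
        bad.add("U")
    if m == "U":
        bad.add("G")
    return [b for b in RNA if b not in bad]


def gen_mirna_duplexes(
    n_pairs: int,
    mismatch_plan: list[tuple[int, int, int]],
    seed: int = 0,
) -> tuple[list[dict], PlantedTruth]:
    """miRNA / target-site duplexes with a planned number of edits.

    Each plan entry is (core mismatches, tail mismatches, tail G:U wobbles);
    core = miRNA positions 2-13 where penalties double. The site is the
    reverse complement of the miRNA carrying exactly the planned edits, so
    the truth score is 2*core + 1*tail + 0.5*gu. A single plan entry is
    broadcast over all pairs.
    """
    if len(mismatch_plan) == 1:
        mismatch_plan = list(mismatch_plan) * n_pairs
    if len(mismatch_plan) != n_pairs:
        raise ValueError("mismatch_plan must have 1 or n_pairs entries")
    rng = np.random.default_rng(seed)
    core = list(CORE_POSITIONS)
    tail = [p for p in range(1, MIRNA_LENGTH + 1) if p not in CORE_POSITIONS]
    records, truth = [], PlantedTruth()
    for k, (n_core, n_tail, n_gu) in enumerate(mismatch_plan):
        if n_core > len(core) or n_tail + n_gu > len(tail) or min(n_core, n_tail, n_gu) < 0:
            raise ValueError(f"mismatch plan {(n_core, n_tail, n_gu)} is not realizable "
                             f"on a {MIRNA_LENGTH}-nt duplex")
        mirna = [RNA[i] for i in rng.integers(0, 4, MIRNA_LENGTH)]
        core_pos = sorted(rng.choice(core, size=n_core, replace=False))
        tail_pos = sorted(rng.choice(tail, size=n_tail + n_gu, replace=False))
        tail_mm, gu_pos = tail_pos[:n_tail], tail_pos[n_tail:]
        for p in gu_pos:  # wobble needs a G or U on the miRNA side
            mirna[p - 1] = "G" if rng.integers(0, 2) else "U"
        site = [COMPLEMENT[b] for b in reversed(mirna)]

        def site_idx(p: int) -> int:
            return MIRNA_LENGTH - p  # miRNA position p pairs with this site index

        for p in core_pos + tail_mm:
            choices = _mismatch_choices(mirna[p - 1])
            site[site_idx(p)] = choices[rng.integers(0, len(choices))]
        for p in gu_pos:
            site[site_idx(p)] = "U" if mirna[p - 1] == "G" else "G"
        score = 2.0 * n_core + 1.0 * n_tail + 0.5 * n_gu
        mid = f"mir_{k + 1:03d}"
        records.append({
            "mirna_id": mid, "target_id": f"target_{k + 1:03d}",
            "mirna_seq": "".join(mirna), "site_seq": "".join(site),
            "truth_score": score,
        })
        truth.duplex_scores[mid] = score
    return records, truth


def embed_site(site_seq: str, flank: int = 40, seed: int = 0) -> tuple[str, int]:
    """Plant a target site inside a random transcript; returns (transcript,
    0-based site offset)."""
    rng = np.random.default_rng(seed)
    left = "".join(RNA[i] for i in rng.integers(0, 4, flank))
    right = "".join(RNA[i] for i in rng.integers(0, 4, flank))
    return left + site_seq + right, flank


# --------------------------------------------------- candidate-screen benchmark

def gen_candidate_benchmark(seed: int = 0):
    """Benchmark network for the candidate-screening rules.

    One guide gene, one true candidate satisfying all three mandatory
    principles (shared top hub, guide distance < 4, power-node co-membership
    with a guide-correlated gene) plus both bonus criteria (preferred domain,
    differential expression), and ten decoys built to fail screening:
    four lack the shared hub, three lack the power-node co-membership, and
    three sit at guide distance >= 4 (which, on a graph metric, also costs
    them the shared hub — hub adjacency to gene and guide forces distance
    <= 2, so a pure distance violation cannot exist in isolation).

    The seed permutes gene identifiers (exercising tie-breaking); the
    topology itself is fixed. Returns (edges frame, guides dict, domain
    annotations dict, de flags dict, PlantedTruth).
    """
    rng = np.random.default_rng(seed)
    roles: dict[str, str] = {}

    def node(role: str, tag: str) -> str:
        roles[tag] = role
        return tag

    G = node("guide", "GUIDE")
    H = node("hub", "H")
    edges: list[tuple[str, str, float]] = [(H, G, 0.4)]  # hub touches the guide weakly
    C = node("true_candidate", "C")
    edges.append((H, C, 0.8))
    # biclique {C, X1, X2} x {Y, Y2}; X1 strongly correlated with the guide
    X1, X2 = node("guide_correlate", "X1"), node("filler", "X2")
    Y, Y2 = node("filler", "Y"), node("filler", "Y2")
    for a in (C, X1, X2):
        for b in (Y, Y2):
            edges.append((a, b, 0.8))
    edges.append((X1, G, 0.9))
    # decoys missing only the power-node co-membership: plain spokes of H
    for i in range(3):
        d = node("decoy_no_powernode", f"DP{i + 1}")
        edges.append((H, d, 0.8))
    for i in range(6):
        f = node("filler", f"F{i + 1}")
        edges.append((H, f, 0.8))
    # decoys missing only the shared hub: same local structure as C but
    # attached to the guide through a low-degree node N
    N = node("filler", "N")
    edges.append((N, G, 0.8))
    for i in range(4):
        d = node("decoy_no_hub", f"DH{i + 1}")
        z1 = node("guide_correlate", f"Z{i + 1}")
        z2 = node("filler", f"Zb{i + 1}")
        w, v = node("filler", f"W{i + 1}"), node("filler", f"V{i + 1}")
        edges.append((N, d, 0.8))
        for a in (d, z1, z2):
            for b in (w, v):
                edges.append((a, b, 0.8))
        edges.append((z1, G, 0.9))
    # decoys beyond the distance gate: a 4-step chain from the guide
    chain = [G] + [node("filler", t) for t in ("ca", "cb", "cc", "cd")]
    for a, b in zip(chain, chain[1:]):
        edges.append((a, b, 0.8))
    for i in range(3):
        d = node("decoy_too_far", f"DD{i + 1}")
        edges.append((chain[-1], d, 0.8))
    # two big guide-free star hubs so the top-degree list is saturated by
    # hubs, only one of which (H) touches the guide
    for hub, n_leaves in (("H2", 12), ("H3", 13)):
        h = node("hub", hub)
        for i in range(n_leaves):
            edges.append((h, node("filler", f"{hub}L{i + 1}"), 0.8))

    # seed-dependent relabeling
    tags = sorted(roles)
    ids = [f"gene_{i + 1:03d}" for i in range(len(tags))]
    rng.shuffle(ids)
    rename = dict(zip(tags, ids))
    edges_df = pd.DataFrame(
        [(rename[a], rename[b], w) for a, b, w in edges],
        columns=["gene_a", "gene_b", "weight"],
    )
    guides = {rename[G]: "MIK"}
    annotations = {rename[C]: {"IPR027417"}}
    de_flags = {rename[C]: True}
    truth = PlantedTruth(
        candidate_roles={rename[t]: r for t, r in roles.items()},
        expected_top_candidate=rename[C],
    )
    return edges_df, guides, annotations, de_flags, truth
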