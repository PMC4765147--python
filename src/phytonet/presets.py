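"""Ready-made synthetic datasets written to disk for CLI and pipeline runs.

Presets: ``network`` (expression + metabolites + design metadata),
``germplasm`` (multi-environment IP6 panel), ``counts`` (two-group count
table), ``mirna`` (miRNA/transcript FASTA pairs), ``full`` (a complete
pipeline input set with a guide gene and a planted candidate inside the
first co-expression module). Every preset also writes the planted truth as
JSON.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import synthetic as syn

PRESETS = ("network", "germplasm", "counts", "mirna", "full")

#: planted guide/candidate ids used by the ``full`` preset
FULL_GUIDE = "GRMZM2G361593"  # MIK analog, first gene of module M1
FULL_CANDIDATE = "GRMZM2G999001"


def _write_fasta(records: dict, path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")


def simulate_preset(preset: str, seed: int, out_dir) -> dict:
    """Write one preset's files under ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if preset == "network":
        return _network(seed, out)
    if preset == "germplasm":
        return _germplasm(seed, out)
    if preset == "counts":
        return _counts(seed, out)
    if preset == "mirna":
        return _mirna(seed, out)
    if preset == "full":
        return _full(seed, out)
    raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")


def _network(seed: int, out: Path, design=None) -> dict:
    design = design or syn.default_design(seed=seed)
    expr, truth = syn.gen_expression_with_modules(design)
    targets = syn.default_metabolite_targets(truth.factors)
    metabolites = syn.gen_metabolite_profiles(truth, targets, seed=seed + 1)
    paths = {
        "expression_tsv": out / "expression.tsv",
        "sample_meta_tsv": out / "sample_meta.tsv",
        "metabolites_tsv": out / "metabolites.tsv",
        "truth_json": out / "truth_network.json",
    }
    expr.to_tsv(paths["expression_tsv"])
    expr.sample_meta.to_csv(paths["sample_meta_tsv"], sep="\t")
    metabolites.to_csv(paths["metabolites_tsv"], sep="\t")
    truth.to_json(paths["truth_json"])
    return {k: str(v) for k, v in paths.items()}


def _germplasm(seed: int, out: Path) -> dict:
    panel, truth = syn.gen_germplasm_panel(
        n_lines=20, n_envs=3,
        planted_pairs=[(2.0, 0.02), (2.0, 0.02), (1.2, 0.02)], seed=seed)
    paths = {"panel_tsv": out / "germplasm_panel.tsv",
             "truth_json": out / "truth_germplasm.json"}
    panel.to_tsv(paths["panel_tsv"])
    truth.to_json(paths["truth_json"])
    return {k: str(v) for k, v in paths.items()}


def _counts(seed: int, out: Path) -> dict:
    table, truth = syn.gen_count_table(
        n_genes=2000, n_per_group=3, de_fraction=0.1,
        fold_change=4.0, dispersion=0.05, seed=seed)
    paths = {"counts_tsv": out / "counts.tsv", "truth_json": out / "truth_counts.json"}
    table.to_tsv(paths["counts_tsv"])
    truth.to_json(paths["truth_json"])
    return {k: str(v) for k, v in paths.items()}


def _mirna(seed: int, out: Path) -> dict:
    records, truth = syn.gen_mirna_duplexes(
        n_pairs=6, mismatch_plan=[(0, 0, 0), (1, 0, 0), (0, 2, 1),
                                  (2, 0, 0), (0, 1, 2), (1, 1, 0)], seed=seed)
    mirnas, transcripts = {}, {}
    for i, rec in enumerate(records):
        mirnas[rec["mirna_id"]] = rec["mirna_seq"]
        transcript, _ = syn.embed_site(rec["site_seq"], flank=40, seed=seed + i)
        transcripts[rec["target_id"]] = transcript
    paths = {"mirnas_fasta": out / "mirnas.fa",
             "transcripts_fasta": out / "transcripts.fa",
             "truth_json": out / "truth_mirna.json"}
    _write_fasta(mirnas, paths["mirnas_fasta"])
    _write_fasta(transcripts, paths["transcripts_fasta"])
    truth.to_json(paths["truth_json"])
    return {k: str(v) for k, v in paths.items()}


def _full(seed: int, out: Path) -> dict:
    """Complete pipeline inputs: 3 planted modules of 35 genes (loading
    0.9), 24 samples, with the first module carrying the guide gene and a
    planted candidate that is differentially expressed and P-loop
    (IPR027417) annotated."""
    design = syn.default_design(seed=seed, replicates=4, n_modules=3,
                                genes_per_module=35, loading=0.9,
                                n_background=150)
    expr, truth = syn.gen_expression_with_modules(design)
    rename = {"M1_g0001": FULL_GUIDE, "M1_g0002": FULL_CANDIDATE}
    expr.values.rename(index=rename, inplace=True)
    truth.module_of = {rename.get(g, g): m for g, m in truth.module_of.items()}
    truth.candidate_roles = {FULL_GUIDE: "guide", FULL_CANDIDATE: "true_candidate"}
    truth.expected_top_candidate = FULL_CANDIDATE

    targets = syn.default_metabolite_targets(truth.factors)
    metabolites = syn.gen_metabolite_profiles(truth, targets, seed=seed + 1)

    guides = pd.DataFrame({"gene_id": [FULL_GUIDE], "role": ["MIK"]})
    annotations = pd.DataFrame({
        "gene_id": [FULL_CANDIDATE],
        "interpro_ids": ["IPR027417"],
        "tf_family": [""],
        "description": ["P-loop containing nucleoside triphosphate hydrolase"],
    })
    de = pd.DataFrame({
        "gene_id": list(expr.values.index),
        "log2_fc": 0.0, "p_value": 1.0, "fdr": 1.0, "is_de": False,
    }).set_index("gene_id")
    de.loc[FULL_CANDIDATE, ["log2_fc", "p_value", "fdr", "is_de"]] = [2.1, 1e-8, 1e-6, True]

    paths = {
        "expression_tsv": out / "expression.tsv",
        "sample_meta_tsv": out / "sample_meta.tsv",
        "metabolites_tsv": out / "metabolites.tsv",
        "guides_tsv": out / "guides.tsv",
        "annotations_tsv": out / "annotations.tsv",
        "de_tsv": out / "de.tsv",
        "truth_json": out / "truth_full.json",
    }
    expr.to_tsv(paths["expression_tsv"])
    expr.sample_meta.to_csv(paths["sample_meta_tsv"], sep="\t")
    metabolites.to_csv(paths["metabolites_tsv"], sep="\t")
    guides.to_csv(paths["guides_tsv"], sep="\t", index=False)
    annotations.to_csv(paths["annotations_tsv"], sep="\t", index=False)
    de.to_csv(paths["de_tsv"], sep="\t")
    truth.to_json(paths["truth_json"])
    return {k: str(v) for k, v in paths.items()}
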