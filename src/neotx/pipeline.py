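"""End-to-end orchestration: configuration, stages, manifest.

A run proceeds: input acquisition (synthetic simulation, a user count
matrix, or per-species sequences for the orthology stage) -> normalization
-> the four fixed contrasts (each parasite vs the adult non-parasite, the
two parasites against each other, juveniles vs adults of the non-parasite)
-> concordant-DE intersection -> neoteny classification and enrichment
chi-squared -> PCA with ANOVA on component scores -> candidate-gene report.
Every output is written as TSV/JSON under the run directory together with a
manifest recording the configuration, per-stage row counts and output
checksums; identical configuration and seed reproduce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expression import (
    estimate_dispersion,
    log_normalized_matrix,
    nb_wald_test,
    size_factors_median_of_ratios,
    tmm_factors,
)
from .io import (
    read_blast_tab,
    read_count_matrix,
    read_fasta,
    read_sample_table,
    write_tsv,
)
from .neoteny import (
    anova_pc_scores,
    candidate_gene_report,
    classify_neoteny_table,
    concordant_de,
    neoteny_enrichment_test,
    pca_expression,
    significant_set,
)
from .orthology import orthologs_from_contigs, reciprocal_best_hits, three_way_orthologs
from .simulate import SimulationSpec, generate_count_matrix

logger = logging.getLogger("neotx")

__all__ = ["PipelineConfig", "run_pipeline", "derive_groups", "CONTRASTS"]

#: The four fixed contrasts, as (test group, reference group).  The second-
#: named group is the reference: log2fc > 0 means higher in the first.
CONTRASTS = (
    ("parasite1", "nonparasite_adult"),
    ("parasite2", "nonparasite_adult"),
    ("parasite1", "parasite2"),
    ("nonparasite_juvenile", "nonparasite_adult"),
)


@dataclass
class PipelineConfig:
    """Run configuration; defaults are the analysis' published thresholds."""

    mode: str = "synthetic"  # synthetic | counts | sequences
    counts_path: str | None = None
    samples_path: str | None = None
    fasta_paths: dict[str, str] = field(default_factory=dict)
    hits_paths: dict[str, str] = field(default_factory=dict)
    alpha_de: float = 0.05
    alpha_candidates: float = 0.1
    evalue_cutoff: float = 1e-20
    min_contig_length: int = 250
    background: str = "complement"  # complement | all
    yates: bool = False
    seed: int = 0
    outdir: str = "neotx_run"
    candidates: list[str] = field(default_factory=list)
    simulation: dict = field(default_factory=dict)
    pseudo_reference: bool = False
    n_pcs: int = 4

    def validate(self) -> None:
        if self.mode not in ("synthetic", "counts", "sequences"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.alpha_de < 1:
            raise ValueError("alpha_de must lie in (0, 1)")
        if not 0 < self.alpha_candidates < 1:
            raise ValueError("alpha_candidates must lie in (0, 1)")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")
        if self.min_contig_length < 1:
            raise ValueError("min_contig_length must be >= 1")
        if self.background not in ("complement", "all"):
            raise ValueError("background must be 'complement' or 'all'")
        if self.mode == "counts" and not (self.counts_path and self.samples_path):
            raise ValueError("counts mode requires counts_path and samples_path")
        if self.mode == "sequences" and len(self.fasta_paths) != 3:
            raise ValueError("sequences mode requires exactly three fasta_paths")
        for name in ("counts_path", "samples_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{name} does not exist: {p}")
        for p in list(self.fasta_paths.values()) + list(self.hits_paths.values()):
            if not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def derive_groups(samples: pd.DataFrame) -> pd.Series:
    """Map samples to the four canonical group labels.

    Uses an explicit ``group`` column when present; otherwise derives the
    label from species (``parasite1``/``parasite2``/``nonparasite``) and age.
    """
    samples = samples.set_index("sample_id") if "sample_id" in samples.columns else samples
    if "group" in samples.columns:
        return samples["group"]
    known = {"parasite1", "parasite2", "nonparasite"}
    bad = set(samples["species"]) - known
    if bad:
        raise ValueError(
            f"cannot derive groups: unknown species {sorted(bad)}; "
            "add an explicit 'group' column"
        )
    out = samples.apply(
        lambda r: r["species"]
        if r["species"] != "nonparasite"
        else ("nonparasite_juvenile" if r["age"] == "juvenile" else "nonparasite_adult"),
        axis=1,
    )
    out.name = "group"
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _parasite_direction(lfc_p1: pd.Series, lfc_p2: pd.Series) -> pd.Series:
    """Consensus parasite direction for CDE-style labelling: the sign of the
    mean log2 fold change of the two parasite contrasts."""
    return 0.5 * (lfc_p1 + lfc_p2)


def run_expression_stage(
    counts: pd.DataFrame,
    groups: pd.Series,
    pseudo_reference: bool = False,
) -> dict:
    """Normalization, dispersion estimation and the four fixed contrasts."""
    sf = size_factors_median_of_ratios(counts, pseudo_reference=pseudo_reference)
    group_map = {g: list(groups.index[groups == g]) for g in groups.unique()}
    disp = estimate_dispersion(counts, groups, size_factors=sf)
    contrasts = {}
    for test, ref in CONTRASTS:
        name = f"{test}_vs_{ref}"
        contrasts[name] = nb_wald_test(
            counts, group_map[ref], group_map[test], sf, disp
        )
        logger.info("contrast %s: %d genes", name, len(contrasts[name]))
    tmm = tmm_factors(counts)
    tmm_matrix = counts / tmm
    return {
        "size_factors": sf,
        "dispersions": disp,
        "contrasts": contrasts,
        "tmm_factors": tmm,
        "tmm_matrix": tmm_matrix,
    }


def run_neoteny_stage(
    contrasts: dict[str, pd.DataFrame],
    alpha_de: float = 0.05,
    background: str = "complement",
    yates: bool = False,
) -> dict:
    """CDE intersection, neoteny labels and the three enrichment tests."""
    c_p1 = contrasts["parasite1_vs_nonparasite_adult"]
    c_p2 = contrasts["parasite2_vs_nonparasite_adult"]
    c_juv = contrasts["nonparasite_juvenile_vs_nonparasite_adult"]

    cde, discordant = concordant_de(c_p1, c_p2, alpha=alpha_de)
    labels = pd.DataFrame(
        {
            "parasite1": classify_neoteny_table(c_p1["log2fc"], c_juv["log2fc"]),
            "parasite2": classify_neoteny_table(c_p2["log2fc"], c_juv["log2fc"]),
            "cde_consensus": classify_neoteny_table(
                _parasite_direction(c_p1["log2fc"], c_p2["log2fc"]), c_juv["log2fc"]
            ),
        },
        index=c_p1.index,
    )

    tests = {}
    de_sets = {
        "parasite1": significant_set(c_p1, alpha_de),
        "parasite2": significant_set(c_p2, alpha_de),
        "cde_consensus": set(cde.index),
    }
    for key, de_set in de_sets.items():
        de_genes = labels.index.intersection(sorted(de_set))
        de_labels = labels.loc[de_genes, key]
        if background == "complement":
            bg_genes = labels.index.difference(de_genes)
        else:
            bg_genes = labels.index
        bg_labels = labels.loc[bg_genes, key]
        try:
            tests[key] = neoteny_enrichment_test(de_labels, bg_labels, yates=yates)
        except ValueError as exc:
            logger.warning("enrichment test %s undefined: %s", key, exc)
            tests[key] = None
    return {"cde": cde, "discordant": discordant, "labels": labels, "tests": tests}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages and write outputs plus a manifest.

    Returns the manifest dictionary (also written to ``manifest.json``).
    The manifest's config echo omits the output directory so re-runs into
    different directories remain byte-identical.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts_stage = {"row_counts": {}}
    outputs: list[Path] = []

    def emit(name: str, table: pd.DataFrame, index: bool = True) -> None:
        path = outdir / name
        write_tsv(table, path, index=index)
        outputs.append(path)
        counts_stage["row_counts"][name] = int(len(table))

    truth = None
    counts = samples = None
    # --- stage: inputs ----------------------------------------------------
    if config.mode == "synthetic":
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", config.seed)
        spec = SimulationSpec(**sim_kwargs)
        logger.info("simulating counts: %d genes, seed %d", spec.n_genes, spec.seed)
        counts, samples, truth = generate_count_matrix(spec)
        emit("counts.tsv", counts)
        emit("samples.tsv", samples, index=False)
        emit("truth.tsv", truth)
    elif config.mode == "counts":
        counts = read_count_matrix(config.counts_path)
        samples = read_sample_table(config.samples_path)
        missing = set(samples["sample_id"]) - set(counts.columns)
        if missing:
            raise ValueError(
                f"samples in metadata but not in count matrix: {sorted(missing)}"
            )
        extra = set(counts.columns) - set(samples["sample_id"])
        if extra:
            raise ValueError(
                f"samples in count matrix but not in metadata: {sorted(extra)}"
            )
    else:  # sequences
        contigs = {sp: read_fasta(p) for sp, p in sorted(config.fasta_paths.items())}
        if config.hits_paths:
            species = sorted(contigs)
            pairs = {}
            for (a, b) in [(0, 1), (0, 2), (1, 2)]:
                ab = read_blast_tab(config.hits_paths[f"{species[a]}_{species[b]}"])
                ba = read_blast_tab(config.hits_paths[f"{species[b]}_{species[a]}"])
                pairs[(a, b)] = reciprocal_best_hits(ab, ba, config.evalue_cutoff)
            triplets = three_way_orthologs(pairs[(0, 1)], pairs[(0, 2)], pairs[(1, 2)])
        else:
            triplets, _ = orthologs_from_contigs(
                contigs,
                min_length=config.min_contig_length,
                evalue_cutoff=config.evalue_cutoff,
            )
        trip_df = pd.DataFrame(
            [(t.id_species1, t.id_species2, t.id_species3) for t in triplets],
            columns=[f"id_{sp}" for sp in sorted(contigs)],
        )
        emit("ortholog_triplets.tsv", trip_df, index=False)
        if config.counts_path:
            counts = read_count_matrix(config.counts_path)
            samples = read_sample_table(config.samples_path)

    manifest: dict = {
        "tool": "neotx",
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in config.to_dict().items() if k != "outdir"},
        "thresholds": {
            "alpha_de": config.alpha_de,
            "alpha_candidates": config.alpha_candidates,
            "evalue_cutoff": config.evalue_cutoff,
            "min_contig_length": config.min_contig_length,
        },
    }

    if counts is not None:
        groups = derive_groups(samples)
        groups = groups.reindex(counts.columns)
        # --- stage: expression -------------------------------------------
        expr = run_expression_stage(
            counts, groups, pseudo_reference=config.pseudo_reference
        )
        emit("size_factors.tsv", expr["size_factors"].to_frame())
        emit("tmm_factors.tsv", expr["tmm_factors"].to_frame())
        emit("dispersions.tsv", expr["dispersions"].to_frame())
        for name, table in expr["contrasts"].items():
            emit(f"contrast_{name}.tsv", table)

        # --- stage: comparative neoteny ----------------------------------
        neo = run_neoteny_stage(
            expr["contrasts"],
            alpha_de=config.alpha_de,
            background=config.background,
            yates=config.yates,
        )
        emit("cde.tsv", neo["cde"])
        emit("cde_discordant.tsv", neo["discordant"])
        emit("neoteny_labels.tsv", neo["labels"])
        summary_rows = []
        for key, res in neo["tests"].items():
            if res is None:
                continue
            summary_rows.append(
                {
                    "de_set": key,
                    "n_de_juvenile_like": res.table[0, 0],
                    "n_de_adult_like": res.table[0, 1],
                    "n_bg_juvenile_like": res.table[1, 0],
                    "n_bg_adult_like": res.table[1, 1],
                    "chi2": res.chi2,
                    "df": res.df,
                    "p": res.p,
                    "percent_de_neotenic": res.percent_de_neotenic,
                    "percent_background_neotenic": res.percent_background_neotenic,
                }
            )
        emit("neoteny_tests.tsv", pd.DataFrame(summary_rows), index=False)

        # --- stage: PCA / ANOVA ------------------------------------------
        logmat = log_normalized_matrix(counts, expr["size_factors"])
        pca = pca_expression(logmat)
        emit("pca_scores.tsv", pca.scores)
        emit(
            "pca_variance.tsv",
            pd.DataFrame(
                {
                    "component": [f"PC{i+1}" for i in range(len(pca.variance_fraction))],
                    "variance_fraction": pca.variance_fraction,
                }
            ),
            index=False,
        )
        anova_rows = []
        for pc in pca.scores.columns[: config.n_pcs]:
            res = anova_pc_scores(pca.scores[pc], groups)
            anova_rows.append(
                {
                    "component": pc,
                    "F": res.F,
                    "df_between": res.df_between,
                    "df_within": res.df_within,
                    "p": res.p,
                }
            )
        emit("pca_anova.tsv", pd.DataFrame(anova_rows), index=False)

        # --- stage: candidate report -------------------------------------
        if config.candidates:
            report, missing_ids = candidate_gene_report(
                expr["contrasts"],
                config.candidates,
                alpha=config.alpha_candidates,
                tmm_matrix=expr["tmm_matrix"],
            )
            emit("candidate_report.tsv", report, index=False)
            manifest["missing_candidates"] = sorted(missing_ids)

        summary = {}
        for key, res in neo["tests"].items():
            if res is not None:
                summary[key] = {
                    "chi2": res.chi2,
                    "p": res.p,
                    "percent_de_neotenic": res.percent_de_neotenic,
                    "percent_background_neotenic": res.percent_background_neotenic,
                }
        manifest["neoteny_summary"] = summary
        manifest["n_cde"] = int(len(neo["cde"]))
        if truth is not None:
            manifest["n_true_de"] = int(truth["is_de"].sum())

    manifest["row_counts"] = counts_stage["row_counts"]
    manifest["checksums"] = {p.name: _sha256(p) for p in sorted(outputs)}
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("wrote manifest to %s", manifest_path)
    return manifest
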