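"""Synthetic data generation for the comparative neoteny pipeline.

Two generators live here:

* :func:`generate_count_matrix` draws a gene x sample matrix of negative-
  binomial counts structured like the comparative study the pipeline targets:
  two brood-parasitic species groups, one non-parasitic species with adult and
  juvenile samples, a configurable fraction of genes differentially expressed
  in both parasites relative to the adult non-parasite, and a configurable
  fraction of those DE genes whose juvenile-contrast direction matches the
  parasite direction (the neotenic fraction).  Ground-truth labels are
  returned alongside the counts so every downstream statistical stage can be
  validated against truth.

* :func:`generate_ortholog_trios` builds three species-specific transcript
  sets that share mutated copies of common ancestral coding sequences, plus
  unrelated decoy transcripts, as a fixture for the orthology stage.

Counts are generated directly at the gene level; read-level simulation adds
nothing to testing the statistics and is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "SimulationSpec",
    "SequenceTrioSpec",
    "SimulationSpecError",
    "generate_count_matrix",
    "generate_ortholog_trios",
]

#: Canonical sample-group labels, in column order of the simulated matrix.
GROUPS = ("parasite1", "parasite2", "nonparasite_adult", "nonparasite_juvenile")

#: Default group sizes: 14 and 17 parasitic females, 4 adult and 5 juvenile
#: non-parasitic females — the field sample sizes the design emulates.
DEFAULT_SAMPLES_PER_GROUP = {
    "parasite1": 14,
    "parasite2": 17,
    "nonparasite_adult": 4,
    "nonparasite_juvenile": 5,
}

#: Prolactin/vehicle split carried as metadata only (the study pooled
#: treatments after finding almost no treatment-responsive transcripts).
_TREATMENT_SPLIT = {
    "parasite1": 9,  # prolactin; remainder vehicle
    "parasite2": 11,
    "nonparasite_adult": 4,
    "nonparasite_juvenile": 5,
}


class SimulationSpecError(ValueError):
    """A simulation spec field failed validation; the message names it."""


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the synthetic count-matrix generator.

    Parameters
    ----------
    n_genes
        Number of simulated genes (ortholog rows).
    samples_per_group
        Samples per group label; keys must be exactly ``GROUPS``.
    baseline_log_mean_range
        Low/high of the natural-log baseline mean expression; per-gene
        baselines are drawn log-uniformly in this range.
    dispersion
        NB dispersion alpha, with variance = mu + alpha * mu**2.  Zero gives
        Poisson counts.
    de_fraction
        Fraction of genes differentially expressed in both parasite groups
        relative to the adult non-parasite.
    neotenic_fraction
        Fraction of DE genes whose juvenile-vs-adult direction matches the
        parasite-vs-adult direction.
    lfc_magnitude
        Absolute log2 effect size applied to parasite groups of DE genes.
    juvenile_lfc_magnitude
        Absolute log2 effect size of the juvenile contrast for DE genes;
        defaults to ``lfc_magnitude``.  Set it below the detection limit to
        emulate informative-but-insignificant juvenile effects.
    decouple_parasites
        If True, the two parasite groups receive independent DE directions,
        exercising the concordance logic downstream; neoteny truth labels then
        refer to parasite group 1.
    library_size_range
        Low/high of per-sample library-scale multipliers, drawn log-uniformly.
    seed
        Root seed; all sub-generators are split from it deterministically.
    """

    n_genes: int = 12_000
    samples_per_group: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SAMPLES_PER_GROUP)
    )
    baseline_log_mean_range: tuple[float, float] = (math.log(5.0), math.log(500.0))
    dispersion: float = 0.2
    de_fraction: float = 0.05
    neotenic_fraction: float = 0.78
    lfc_magnitude: float = 1.0
    juvenile_lfc_magnitude: float | None = None
    decouple_parasites: bool = False
    library_size_range: tuple[float, float] = (0.7, 1.4)
    seed: int = 0

    def validate(self) -> None:
        if not (isinstance(self.n_genes, (int, np.integer)) and self.n_genes > 0):
            raise SimulationSpecError("n_genes must be a positive integer")
        if set(self.samples_per_group) != set(GROUPS):
            raise SimulationSpecError(
                f"samples_per_group keys must be exactly {GROUPS}"
            )
        for g, n in self.samples_per_group.items():
            if not (isinstance(n, (int, np.integer)) and n > 0):
                raise SimulationSpecError(
                    f"samples_per_group[{g!r}] must be a positive integer"
                )
        lo, hi = self.baseline_log_mean_range
        if not lo <= hi:
            raise SimulationSpecError("baseline_log_mean_range must have low <= high")
        if self.dispersion < 0:
            raise SimulationSpecError("dispersion must be >= 0")
        for name in ("de_fraction", "neotenic_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationSpecError(f"{name} must lie in [0, 1]")
        if self.lfc_magnitude <= 0:
            raise SimulationSpecError("lfc_magnitude must be positive")
        if self.juvenile_lfc_magnitude is not None and self.juvenile_lfc_magnitude <= 0:
            raise SimulationSpecError("juvenile_lfc_magnitude must be positive")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise SimulationSpecError(
                "library_size_range must be positive with low <= high"
            )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Draw NB(mu, alpha) counts with variance mu + alpha*mu**2 (Poisson at 0)."""
    if alpha == 0:
        return rng.poisson(mean)
    size = 1.0 / alpha
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_count_matrix(
    spec: SimulationSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a structured count matrix with ground-truth DE/neoteny labels.

    Returns
    -------
    counts : DataFrame
        Genes x samples non-negative integer counts, index ``gene_id``.
    samples : DataFrame
        One row per sample with columns ``sample_id``, ``species``, ``age``,
        ``treatment`` and ``group``.
    truth : DataFrame
        Per gene: ``is_de``, ``direction_parasite``, ``direction_juvenile``,
        ``is_neotenic`` (and both per-parasite directions when the parasites
        are decoupled).
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    rng_truth, rng_lib, rng_counts = (
        np.random.default_rng(s) for s in root.spawn(3)
    )

    n = spec.n_genes
    gene_ids = np.array([f"g{i:05d}" for i in range(n)])

    # --- ground truth ----------------------------------------------------
    n_de = round(n * spec.de_fraction)
    n_neo = round(n_de * spec.neotenic_fraction)
    de_idx = rng_truth.choice(n, size=n_de, replace=False)
    neo_idx = de_idx[:n_neo]  # de_idx already in random order

    dir_p1 = np.zeros(n, dtype=int)
    dir_p1[de_idx] = rng_truth.choice([-1, 1], size=n_de)
    if spec.decouple_parasites:
        dir_p2 = np.zeros(n, dtype=int)
        dir_p2[de_idx] = rng_truth.choice([-1, 1], size=n_de)
    else:
        dir_p2 = dir_p1

    # Every gene carries a true juvenile-vs-adult direction: developmental
    # expression change is pervasive even where parasite status has no
    # effect.  Background directions are random and independent of DE
    # status; among DE genes the neotenic fraction share the parasite
    # direction and the rest oppose it.
    dir_juv = rng_truth.choice([-1, 1], size=n)
    dir_juv[de_idx] = -dir_p1[de_idx]
    dir_juv[neo_idx] = dir_p1[neo_idx]

    is_de = np.zeros(n, dtype=bool)
    is_de[de_idx] = True
    is_neo = np.zeros(n, dtype=bool)
    is_neo[neo_idx] = True

    truth = pd.DataFrame(
        {
            "is_de": is_de,
            "direction_parasite": dir_p1,
            "direction_juvenile": dir_juv,
            "is_neotenic": is_neo,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    if spec.decouple_parasites:
        truth["direction_parasite2"] = dir_p2

    # --- expected means --------------------------------------------------
    lo, hi = spec.baseline_log_mean_range
    baseline = np.exp(rng_truth.uniform(lo, hi, size=n))
    juv_lfc = (
        spec.lfc_magnitude
        if spec.juvenile_lfc_magnitude is None
        else spec.juvenile_lfc_magnitude
    )
    group_mult = {
        "parasite1": 2.0 ** (dir_p1 * spec.lfc_magnitude),
        "parasite2": 2.0 ** (dir_p2 * spec.lfc_magnitude),
        "nonparasite_adult": np.ones(n),
        "nonparasite_juvenile": 2.0 ** (dir_juv * juv_lfc),
    }

    # --- samples and counts ----------------------------------------------
    rows = []
    for group in GROUPS:
        n_prl = min(_TREATMENT_SPLIT[group], spec.samples_per_group[group])
        for k in range(spec.samples_per_group[group]):
            rows.append(
                {
                    "sample_id": f"{group}_s{k + 1:02d}",
                    "species": (
                        "nonparasite" if group.startswith("nonparasite") else group
                    ),
                    "age": "juvenile" if group.endswith("juvenile") else "adult",
                    "treatment": "prolactin" if k < n_prl else "vehicle",
                    "group": group,
                }
            )
    samples = pd.DataFrame(rows)

    log_lo, log_hi = np.log(spec.library_size_range)
    lib = np.exp(rng_lib.uniform(log_lo, log_hi, size=len(samples)))

    counts = np.empty((n, len(samples)), dtype=np.int64)
    for j, (_, row) in enumerate(samples.iterrows()):
        mu = baseline * group_mult[row["group"]] * lib[j]
        counts[:, j] = _nb_draw(rng_counts, mu, spec.dispersion)

    counts_df = pd.DataFrame(
        counts,
        index=pd.Index(gene_ids, name="gene_id"),
        columns=samples["sample_id"].to_numpy(),
    )
    return counts_df, samples, truth


# ---------------------------------------------------------------------------
# Ortholog trio sequences
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass(frozen=True)
class SequenceTrioSpec:
    """Parameters for the ortholog-trio sequence fixture.

    Each trio derives from one ancestral coding sequence (ATG ... stop)
    embedded in per-species random UTRs and independently mutated per species
    at ``substitution_rate`` per site.  Decoys are unrelated random sequences.
    """

    n_trios: int = 50
    # defaults keep every contig >= 250 bp so the pipeline's length filter
    # never discards a true ortholog
    orf_aa_length_range: tuple[int, int] = (80, 150)
    utr_length_range: tuple[int, int] = (30, 100)
    substitution_rate: float = 0.02
    n_decoys: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_trios < 0:
            raise SimulationSpecError("n_trios must be non-negative")
        lo, hi = self.orf_aa_length_range
        if not (2 <= lo <= hi):
            raise SimulationSpecError(
                "orf_aa_length_range must satisfy 2 <= low <= high"
            )
        lo, hi = self.utr_length_range
        if not (0 <= lo <= hi):
            raise SimulationSpecError("utr_length_range must have 0 <= low <= high")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise SimulationSpecError("substitution_rate must lie in [0, 1)")
        if self.n_decoys < 0:
            raise SimulationSpecError("n_decoys must be non-negative")


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        # substitute with a uniformly chosen different base
        for i in np.nonzero(hit)[0]:
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _mutate_cds(cds: str, rate: float, rng: np.random.Generator) -> str:
    """Mutate a coding sequence under purifying selection against nonsense.

    The start codon and terminal stop are conserved and substitutions that
    would create an in-frame stop are rejected (the codon reverts), so the
    open reading frame survives, as it does in real orthologs.
    """
    if rate == 0:
        return cds
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for k in range(1, len(codons) - 1):
        mutated = _mutate(codons[k], rate, rng)
        if mutated not in _STOPS:
            codons[k] = mutated
    return "".join(codons)


def generate_ortholog_trios(
    spec: SequenceTrioSpec,
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Generate three species-specific transcript sets with known orthology.

    Returns
    -------
    sequences : dict
        Keys ``species1``/``species2``/``species3``; each value is a list of
        ``(contig_id, sequence)`` pairs (true orthologs then decoys).
    truth : DataFrame
        One row per trio with columns ``id_species1``/``id_species2``/
        ``id_species3`` naming the true triplet, plus ``ancestral_cds``,
        the unmutated coding sequence the trio derives from.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    species = ("species1", "species2", "species3")
    seqs: dict[str, list[tuple[str, str]]] = {sp: [] for sp in species}
    truth_rows = []

    for t in range(spec.n_trios):
        aa_len = int(rng.integers(spec.orf_aa_length_range[0], spec.orf_aa_length_range[1] + 1))
        cds = "ATG" + "".join(
            _SENSE_CODONS[i]
            for i in rng.integers(len(_SENSE_CODONS), size=aa_len - 1)
        ) + ("TAA", "TAG", "TGA")[rng.integers(3)]
        row = {}
        for sp in species:
            utr5 = "".join(_BASES[rng.integers(4, size=rng.integers(
                spec.utr_length_range[0], spec.utr_length_range[1] + 1))])
            utr3 = "".join(_BASES[rng.integers(4, size=rng.integers(
                spec.utr_length_range[0], spec.utr_length_range[1] + 1))])
            body = _mutate_cds(cds, spec.substitution_rate, rng)
            cid = f"{sp}_trio{t:04d}"
            seqs[sp].append((cid, utr5 + body + utr3))
            row[f"id_{sp}"] = cid
        row["ancestral_cds"] = cds
        truth_rows.append(row)

    for sp in species:
        for d in range(spec.n_decoys):
            length = int(rng.integers(200, 600))
            seqs[sp].append(
                (f"{sp}_decoy{d:04d}", "".join(_BASES[rng.integers(4, size=length)]))
            )

    truth = pd.DataFrame(
        truth_rows, columns=[f"id_{sp}" for sp in species] + ["ancestral_cds"]
    )
    return seqs, truth
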