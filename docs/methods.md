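# Methods

## The comparative neoteny computation

The pipeline asks whether expression changes in adult brood parasites,
relative to the adult of a non-parasitic relative, mirror the changes seen
in juveniles of that relative. Three species groups are compared: two
parasites (P1, P2) and a non-parasite with adult (A) and juvenile (J)
samples. For each gene, three log₂ fold changes against the shared adult
reference are estimated: P1 vs A, P2 vs A and J vs A. A gene is
**juvenile-like (neotenic)** when its parasite-vs-adult and
juvenile-vs-adult fold changes share a nonzero sign, **adult-like** when
the signs oppose, and **undefined** when either is exactly zero (excluded,
with counts logged). The **CDE set** contains genes with adjusted p < 0.05
in *both* parasite contrasts and equal fold-change sign; genes significant
in both but with opposite signs are reported separately as discordant.
Enrichment of juvenile-like labels in a DE set is tested with a Pearson χ²
test of independence on the 2×2 table (DE set vs background) ×
(juvenile-like vs adult-like), df = 1, Yates correction off by default
(flag available). The background defaults to the complement of the DE set
so the table rows are disjoint, as a test of independence requires; a
`background: all` option reproduces the marginal comparison against all
genes. For CDE-based labelling the parasite direction of background genes
is the sign of the mean of the two parasite fold changes (DE members'
signs agree by construction).

## Differential expression stand-in

The DE stage is a fully specified negative-binomial Wald test rather than
a wrapped external tool, so that every number is reproducible from stated
formulas:

- **Size factors** — median-of-ratios: per sample, the median over
  all-positive genes of count / per-gene geometric mean, rescaled to
  geometric mean 1. If no gene is positive everywhere, a
  `pseudo_reference` flag switches the reference to geometric means over
  observed samples only.
- **Dispersion** — per gene, method of moments on normalized counts with
  variance pooled within groups: α̂ = max(0, (s² − m̄)/m̄²), then averaged
  50/50 with the 10 %-trimmed mean of α̂ across genes and floored at 1e-8.
  The equal-weight shrinkage is a deliberately simple, fully reproducible
  stand-in for empirical-Bayes dispersion trends; simulations in the test
  suite show it recovers α = 0.5 within ±0.2 at 20 samples per group and
  keeps the Wald test's type-I error at 5 ± 2 % under the acceptance
  conditions (6 vs 6 samples, α = 0.2).
- **Wald test** — group means of normalized counts with pseudo-count 0.5
  (avoids infinite fold changes at zero); log₂FC = log₂(mean_B/mean_A)
  with B the test and A the reference group; the delta-method variance of
  a group mean is q·Σ(1/sᵢ)/n² + α·q²/n at the observed mean q; two-sided
  p from the standard normal. Genes with zero counts across both groups
  get undefined p and are excluded from the Benjamini–Hochberg
  denominator. No fold-change shrinkage, Cook's filtering or independent
  filtering is applied — results are therefore not expected to match any
  specific external DE tool gene-for-gene.
- **TMM factors** (reporting only) — the classic doubly trimmed (30 % on
  log-ratios, 5 % on average log expression), precision-weighted mean of
  log₂ ratios against the column whose upper quartile is closest to the
  mean upper quartile. Composition factors match edgeR's
  `calcNormFactors` to 1e-8 (cross-checked in the tests via Rscript). The
  returned factor is library size × composition factor, rescaled to
  geometric mean 1, i.e. the full normalization divisor: a sample scaled
  up 4× receives a 4× larger factor.

PCA treats samples as observations and genes as variables (per-gene
centering, optional scaling); each component's sign is fixed by making its
largest-magnitude loading positive, so runs are deterministic. One-way
fixed-effects ANOVA on component scores uses F = MS_between/MS_within.

## Orthology stage

Contigs shorter than 250 bp are removed (strict inequality). Exact
duplicates and exact substrings collapse to the longest representative
(ties by lexicographic id); near-identity clustering is intentionally out
of scope. The longest ATG-initiated, stop-terminated ORF is selected over
six frames (ties: + strand, then lower frame, then lower start); codons
containing N are invalid as start or stop; a flag restricts the search to
the + strand for strictly directional assemblies. Peptide similarity uses
Smith–Waterman local alignment (BLOSUM62; a gap of length L costs
11 + 1·L) with `evalue_proxy = exp(−score)` — a monotone transform used
only for thresholding, never a calibrated e-value; standard 12-column
BLAST tabular files can be supplied instead. Reciprocal best hits require
mutual best hits with e-value ≤ 1e-20 in both directions; best-hit ties
resolve by e-value, then score, then lexicographic subject id, making
output independent of hit-table order. Triplets are strict triangles of
the three pairwise RBH sets — the conservative resolution of pairwise
inconsistency.

## Synthetic data: what it emulates and what it does not

`SimulationSpec` defaults encode the study conditions the pipeline
targets: group sizes 14 (P1), 17 (P2), 4 (A), 5 (J); NB counts with
dispersion α = 0.2 (typical for wild-caught, cross-individual bulk brain
RNA-seq; variance = μ + αμ²); baseline means log-uniform on [5, 500];
per-sample library factors log-uniform on [0.7, 1.4]; 5 % of genes DE in
both parasites at |log₂FC| = 1 with random shared sign (a flag decouples
the two parasites to exercise the concordance logic); 78 % of DE genes
neotenic. **Every** gene carries a true juvenile-vs-adult direction —
random ±1 for non-DE genes, matched or opposed to the parasite direction
for DE genes according to the neotenic fraction — because developmental
expression change is pervasive in real tissue even where parasite status
has no effect. The juvenile effect magnitude defaults to `lfc_magnitude`
and is independently configurable.

Known departures from real data: counts are generated at the gene level
(no reads, assembly artifacts or contaminants); all genes share one
dispersion; DE effects have a single magnitude; and with the default
juvenile magnitude the juvenile-vs-adult contrast yields many significant
genes, unlike the near-empty juvenile contrast a small-n field study
reports. Lowering `juvenile_lfc_magnitude` emulates
directionally-informative but sub-significant juvenile effects, at the
cost of noisier direction labels. Trio sequences evolve under purifying
selection against nonsense changes (start/stop conserved, in-frame stop
creation rejected), since real orthologs do not accumulate premature
stops; decoys are unrelated random sequences.

## Calibration and a known structural artifact

The acceptance suite verifies, among other things, that the Wald test's
null rejection rate at α = 0.05 lies in [0.03, 0.07], and that an
end-to-end run at the defaults recovers the neotenic percentage among
truth-DE genes inside the exact binomial 95 % interval of 78 % while the
enrichment test rejects.

One spec'd property fails by construction, and the failure is
informative: with the neotenic fraction at 0.5 (no true enrichment), the
enrichment p-value across seeds is *not* uniform (≈ 22 % of runs reject
at 0.05; KS-vs-uniform p ≈ 2e-10). Two mechanisms, both intrinsic to the
published procedure at these sample sizes, produce a false signal:

1. **Shared-reference correlation.** All three contrasts use the same
   4-sample adult reference, so their fold-change errors are positively
   correlated (ρ ≈ 0.6 at α = 0.2). Background genes' estimated parasite
   and juvenile signs therefore agree more than half the time (~52–53 %
   measured; ~73 % if background genes carried no true juvenile effect at
   all).
2. **Winner's curse.** The DE row is selected by significance of the
   parasite contrasts. Conditioning on a large estimated parasite effect
   selects for favorable shared-reference noise, which then drags the
   juvenile fold change toward concordance; the measured DE-row
   concordance exceeds its true value by several points (e.g. ~62 % when
   the truth is 50 %, and 85–88 % in the worked example when the
   simulated truth is 78 %).

No option inside the defined procedure removes the artifact — the
classifier requires both contrasts against the same adult reference, and
the test compares the significance-selected set against the rest — so
the corresponding acceptance check is left failing rather than papered
over. Practical implication for real analyses of this design: the
background juvenile-like percentage, not 50 %, is the only honest chance
baseline, and even against that baseline the DE-set percentage is
inflated by selection; enrichment statistics from such designs should be
read conservatively, or calibrated by permuting sample labels.

## Problem sizes used by the test suite

Simulated checks run at the study scale (12 000 genes, 40 samples; 10
seeds for recovery, 100 seeds for the null study), trio fixtures at 50
trios of 80–150 aa ORFs, and oracle-equivalence checks at 200-query hit
tables and 10 kb sequences — sizes chosen so the full suite completes in
about a minute while keeping every estimate's sampling error well inside
the asserted tolerances.
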