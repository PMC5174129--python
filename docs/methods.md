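# Methods

This note documents the models, the numerical choices and the synthetic
study behind `droughtmine`, in the spirit of a package's statistical
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design assumed by the pipeline

Two genotypes of contrasting drought tolerance ("tolerant",
"susceptible"), each grown under drought and well-watered conditions,
sampled at six ordered timepoints A–F with biological replicates.
Timepoints are assigned to drought periods from drought-plot soil water
content (SWC): period I (mild) while SWC ≥ 18%, period II (severe) once
SWC < 15%, period III for re-watered timepoints (flagged in the sample
metadata, since SWC alone cannot distinguish re-watering from pre-drought
wetness). SWC between the two thresholds is assigned to period II with a
logged warning: a drying field crosses that band quickly, and severe is
the conservative call. Thresholds live in `AnalysisConfig`
(`swc_mild_threshold` 18.0%, `swc_severe_threshold` 15.0%).

## Physiology

RWC = (fresh − dry)/(saturated − dry) on leaf weights; drought-tolerance
coefficient = grain yield under drought / well-watered; per-timepoint
trait fold changes and relative gas exchange are ratios of replicate
means (replicate-mean pairing chosen because plot pairing across the two
fields is not defined; flagged here as a convention). All two-sample
comparisons default to the Welch (unequal-variance) t-test — "independent
t-test" leaves the variance assumption open, and Welch is the safer
general choice; a Student variant is available via
`AnalysisConfig.ttest_variant`. Soil-water CV uses the sample (n − 1)
standard deviation, appropriate for small numbers of field plots.

## Differential expression

FPKM fold changes are log2[(FPKM_D + c)/(FPKM_W + c)] with pseudocount
c = 10⁻⁵, finite for zero expression and exactly 0 when both means are 0.

**Replicated mode.** Per timepoint, a Welch t-test on
log2(FPKM + c) per gene, Benjamini–Hochberg adjustment across genes
*within* that timepoint (per-timepoint DEG counts are the unit of
reporting, so multiple testing is not pooled across timepoints), DEG iff
q < 0.05 and |log2FC| ≥ 1. This is a matrix-level stand-in for read-level
differential tests: raw reads are outside this package's scope, and a
variance-aware test on the log scale is the closest analogue available
from an FPKM matrix.

**Unreplicated mode.** With one library per condition no per-gene test
exists. The stand-in assumes most genes are null and estimates the null
spread of log2FC as a function of abundance: genes are grouped into up to
20 equal-count bins over mean log2 abundance and the null variance per
bin is median(log2FC²)/median(χ²₁) (≈ /0.4549). The median-based local
estimate is deliberately robust: a loess on squared log2FC would be
inflated by the minority of genes with real effects. Each gene's log2FC
is z-scored against its bin's SD, giving a two-sided normal p; DEG iff
p < 0.05 and |log2FC| ≥ 1. The acceptance suite verifies the null
false-positive rate of this stand-in stays within 1.5× nominal.

**Development-dependent exclusion.** Drought delays development, so a
drought-vs-control difference may reflect developmental stage, not
drought. Any gene called differential between *any* of the C(T,2) pairs
of well-watered timepoints (same test machinery and thresholds per pair,
no extra correction — a literal reading of "any two timepoints") is
flagged and stripped of DEG status. Flagging and exclusion are
per-genotype by default (`dev_dependent_scope`), since the two genotypes'
developmental programs need not coincide; a global mode pools the flags.

Log2FC profiles destined for heatmaps are clamped to ±6 (genes) and ±10
(metabolites); clamping is idempotent and does not affect any statistics.

## Metabolomics

Peak tables are normalized to the summed intensity of each sample
(computed over detected peaks; missing peaks stay missing), making calls
invariant to per-sample global intensity drift — a property the test
suite asserts directly. Variables are then mean-centered and scaled to
unit sample variance; zero-variance variables are dropped with a warning.

**Missing peaks.** No imputation is performed, because none can be
justified from a peak table alone. Under the default "propagate" policy,
NA survives normalization and scaling statistics are computed over
available values; univariate tests use available values, and the
multivariate model drops metabolites that are incomplete over its fitted
samples (with a warning). The "drop" policy removes any metabolite with a
missing value up front. Cross-genotype analyses are restricted to
metabolites detected in both genotypes (any non-missing peak), so
platform detection bias cannot masquerade as regulation.

**OPLS-DA.** Class coding is centered ±1 (symmetric, which makes the
orthogonality checks exact). For each of `n_orthogonal` components
(default 1 — the standard O-PLS setup for a two-class contrast), the part
of the X-loading not aligned with the predictive weight defines an
orthogonal weight; its component is deflated from X. The final predictive
component is fitted by NIPALS (tolerance 10⁻¹⁰ on the score change,
maximum 500 iterations, convergence failure is an error reporting the
iteration count; with a single response the fixed point is reached in one
pass). Orthogonal scores are uncorrelated with the class vector by
construction. With `n_orthogonal=0` the model is plain PLS-DA, verified
against an independent NIPALS implementation in the tests.

**VIP.** VIP_j = √(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a) over
predictive components; with one predictive component this is
√p·|w_j|, so Σ VIP² = p exactly. The identity is asserted at every fit.

**DM calls.** Per drought period (all its timepoints pooled, both
conditions): a metabolite is differential iff VIP > 1.0 and the
univariate Welch p on normalized intensities < 0.05. Fitting per period
rather than per timepoint or globally balances sample size against
stationarity of the drought response; the period map is configurable.
Note one behaviour visible in the near-noise-free worked fixture:
sum normalization is compositional, so when planted metabolites rise, all
other metabolites' normalized values shift slightly in the opposite
direction, and at vanishing noise these shifts become "significant".
The divergence criterion of the key-metabolite step is what keeps such
closure artefacts out of the mining.

## Integration and mining

Pearson correlations use the t-transform for two-sided p; pairs with
missing values are dropped; zero-variance features are skipped with a log
entry; edges are retained iff |r| > 0.6 and p < 0.05 (two-sided on |r|).
Feature values enter correlations on the log2 scale (log2(FPKM + c),
log2 normalized intensity): FPKM and peak intensities are heavily
right-skewed, and Pearson on raw values is dominated by the few largest
observations.

Two trait-pairing modes are shipped because the exact vectors correlated
in such designs are a genuine free choice: the default "replicate" mode
correlates drought-sample feature values against replicate-level trait
values (n = timepoints × replicates; chosen for statistical power), and
"profile" mode correlates per-timepoint log2FC against the trait's
drought/watered fold change (n = timepoints).

Enrichment is the upper-tail hypergeometric test with the expression
matrix as universe (the tested population here, not the genome),
annotation sets intersected with the universe, and BH control within each
annotation namespace (KEGG-style ids vs GO: ids) separately. Energy-
related DEGs are those annotated to the five photosynthesis/energy KEGG
pathways (ko00196, ko00710, ko00720, ko00195, ko00190).

**Key metabolites** must satisfy all of: (a) detected in both genotypes;
(b) DM in ≥ 1 genotype; (c) osmolality- or AOC-correlated in ≥ 1
genotype; (d) divergently regulated — |difference of the genotypes' mean
log2FC| ≥ `divergence_lfc_threshold` (default 1.0 log2 unit) in at least
one period. The explicit divergence parameter replaces an otherwise
qualitative "different regulation" judgement.

**Candidate genes** must satisfy all of: (i) surviving DEG; (ii)
annotated to ≥ 1 pathway containing a key metabolite's compound id
(compound ids must match the metabolite table's ids — mapping instrument
annotations to compound ids is the user's responsibility); (iii)
osmolality- or AOC-correlated; (iv) correlated with that key metabolite
over the full drought series (a period-restricted variant is available).
The reported fold change is the gene's median log2FC over drought-period
timepoints. Candidates are mined per genotype; tightening the correlation
threshold can only shrink the candidate set (asserted in tests).
Profile clustering uses average-linkage agglomeration on Euclidean
distances over capped log2FC profiles — a common default, configurable.

## The synthetic study

The generator is the package's stand-in for the unavailable raw study
data; its defaults are the study conditions: 2 genotypes × 2 conditions ×
6 timepoints (A,B = I; C,D,E = II; F = III) × 3 replicates, 2000 genes,
120 metabolites, planted effect 2.0 log2 units, expression noise SD 0.25
on the log2 scale, 5% drought-responsive and 5% development-dependent
genes, 6 key metabolites and 12 candidate genes (the counts a drought
multi-omics screen of this shape plausibly yields), 10 metabolites
detected in only one genotype per genotype.

* Expression noise is log-normal (normal on log2 FPKM): FPKM is positive
  and the analysis scale is log2.
* Drought-responsive genes shift by ±effect only under drought during
  periods I–II. Development-dependent genes drift linearly across
  timepoints under both conditions (total drift = the planted effect), so
  they are invisible to the drought contrast but caught by the
  well-watered pair tests.
* Traits are simulated at replicate level (so both correlation modes are
  exercisable): osmolality rises strongly during severe drought in the
  tolerant genotype and weakly in the susceptible one; AOC likewise; SWC
  follows the mild→severe→re-watered trajectory; grain-yield anchors give
  tolerance coefficients near 0.74 (tolerant) and 0.21 (susceptible).
* Key metabolites are linearly coupled on the log2 scale to a trait's
  replicate-level value (coupling 1.5 log2 per scaled trait unit), which
  simultaneously makes them differential, trait-correlated and
  divergent (~2 log2 units between genotypes in the severe period —
  an unambiguous planted divergence relative to its ≥ 1.0 criterion).
  Key metabolites are drawn as moderate-abundance peaks: a dominating
  peak that rises under drought would drag the per-sample sum with it,
  and closure after sum normalization would erase the planted divergence.
* Candidate genes are responsive genes whose drought effect follows the
  anchor trait's trajectory (full planted strength at the trait's peak)
  plus a replicate-level coupling (0.5 log2 per trait SD) to the same
  trait signal that drives their anchor metabolite — hence gene–trait,
  gene–metabolite and metabolite–trait correlations all arise from one
  latent physiological signal, as they would in a real stress response.
  Each candidate shares a planted pathway (containing both the gene and
  the metabolite id) with its anchor; anchor pathways are padded with
  null genes.
* Metabolite intensities are log-normal (positive, right-skewed, and the
  planted couplings are exact on the log2 scale) and each sample carries
  a random global intensity factor in [0.5, 2] that sum normalization
  must remove.

What the generator does **not** emulate: read-count sampling noise and
its mean–variance relation, isoform structure, batch effects, retention-
time drift or co-elution in GC/MS, spatial field effects, and real
pathway topology. Passing recovery tests therefore demonstrates that the
pipeline's logic recovers the structure it is specified to find under
its stated noise model — not that the thresholds are optimal for any
particular real dataset.

A hand-auditable worked fixture (20 genes, 10 metabolites, 2 replicates,
noise SDs 0.01, fixed seed) is shipped under `tests/data/worked_fixture/`
and regenerated bit-for-bit by `make_worked_fixture()`; the tests trace
it through every stage and require the exact planted candidate set.

## Problem sizes used in the checks

The acceptance suite runs the full default study over 10 seeds for
parameter recovery; null calibrations use 200 repeats of a 500-gene
unreplicated contrast and 200 repeats of a 30-metabolite, 12-sample
two-class design; the hypergeometric oracle sweep enumerates all
universes up to size 12; BH is checked against a sorting oracle on 1000
random p-vectors. These sizes make the whole suite run in well under a
minute while keeping Monte-Carlo error small relative to the tested
bounds.

## Known limitations

* The unreplicated-mode p-value is a calibrated stand-in, not a read-level
  model; its p-values are meaningful only relative to the assumed
  log-normal noise.
* Welch t-tests with 3 replicates have ~4 degrees of freedom; borderline
  effects (≈ the 1.0 log2 threshold) are recovered unreliably — visible
  in the recovery-vs-noise grid of the tests.
* Sum normalization is compositional; strong regulation concentrated in
  high-abundance peaks biases all other metabolites' fold changes.
* Pearson layers assume (log-scale) linear coupling; rank-based
  alternatives are not implemented.
* The pipeline treats annotation sets as given; no live pathway retrieval.
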