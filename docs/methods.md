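# Methods

This note documents the statistical models, parameter choices and known
limitations of each pipeline stage. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Differential BioID scoring

**Input model.** A spectral-count matrix: non-negative integer counts per
prey protein per sample, with samples grouped by bait (wild-type AID, two
RR-domain mutants, the APOBEC2 specificity control) and a dedicated row
for BirA* self-biotinylation. Counts are normalised per sample by the
BirA* count, which proxies bait abundance and labelling efficiency; a
zero BirA* count is a hard error because normalisation is then undefined.

**Fold.** Per-prey fold enrichment of pseudocounted mean normalised
counts, `(mean_A + c)/(mean_B + c)`. The pseudocount defaults to half the
smallest nonzero normalised value in the matrix (configurable): zeros are
common in spectral-count data and the ratio must stay finite. A prey is
called when enrichment of wild type is ≥2.5-fold over *each* mutant and
≥5-fold over APOBEC2; thresholds are inclusive.

**Normz.** Z-score of log₂ fold enrichments against one mutant, using the
sample standard deviation (n−1) — appropriate at the small prey counts of
targeted runs. Flag at Z ≥ 2 in the wild-type-enriched direction. Log
base 2 is used for every log-transformed quantity and stated in output
headers. A zero-variance vector yields all-zero Z-scores, no flags, and a
warning rather than an error.

**Maz.** Local Z-score on the ratio–intensity plane: ratio = log₂ fold
enrichment, intensity = log₂ pseudocounted mean normalised abundance of
the two baits compared. The window for a candidate is the
`w = max(5, ceil(0.10·n))` preys *nearest in intensity* (candidate
included; distance ties broken by input order). Nearest-in-intensity was
chosen over rank-adjacency after sorting because a "window around the
candidate" is a neighbourhood in intensity; the floor of 5 prevents
degenerate standard deviations. With `window_frac=1` the local Z equals
the global Z exactly — this identity is tested.

**Deseq (negative-binomial Wald test).** Counts are modelled
NB(μ, α) with variance μ + αμ², the same parameterisation the generator
uses. Size factors come from the median-of-ratios over preys with
all-nonzero counts. The design has two conditions — wild type versus the
two mutants pooled, mutants as the reference level — so the GLM reduces
to two group means on the size-factor scale, fitted per prey by Newton
iteration of the score equation.

*Dispersion.* With three replicates per condition a per-prey dispersion
estimate is unavoidably noisy, and that noise propagates into the Wald
denominator: simulations in the test suite show a plain per-prey estimate
with a normal reference roughly doubles the nominal type-I error, while
switching to a heavy-tailed small-sample reference sacrifices essentially
all Benjamini–Hochberg power at stringent thresholds. The implementation
therefore estimates dispersion by maximising the Cox–Reid adjusted
profile likelihood (the count-data analogue of REML, removing the bias
from the two fitted means) plus `prior_n` times the dataset-average
adjusted profile likelihood — weighted-likelihood moderation toward the
*common* dispersion, the classic tagwise scheme of count-based
differential-expression analysis. The default prior weight corresponds to
10 prior degrees of freedom (`prior_n = 10/residual df`), the
long-standing field default. No mean–dispersion trend is fitted and no
per-prey estimate is replaced by a trend value; genuinely discrepant
preys remain free to move. The optimiser uses a log-spaced grid
(floor 10⁻⁸, the degenerate-Poisson limit) refined by parabolic
interpolation; accuracy beyond that resolution does not measurably affect
the Wald statistic.

*Test.* Wald statistic on the log wild-type/mutant ratio with its
information-based standard error, referred to the normal distribution;
two-sided p-values, Benjamini–Hochberg adjustment (via statsmodels)
across tested preys, flag at adjusted p < 0.1 *and* positive wild-type
coefficient (one-sided flagging: the consensus of interest is loss in the
mutants; the opposite direction is reported but never enters the
consensus). All-zero preys are excluded from testing and reported as
untested. Measured on null simulations at the study conditions
(mean 50, dispersion 0.05, 3+3), the raw-p<0.05 fraction sits near
0.05–0.06 (the acceptance suite checks this), and a planted 8-fold
reduction is flagged essentially always.

**Consensus.** A method "calls" a prey only when its both-mutant
criterion passes (Fold: the joint rule; Normz/Maz: flag against each
mutant separately; Deseq: the pooled-mutant contrast). Union = ≥1
calling method, core = ≥2. Prey identifiers are compared
case-insensitively after trimming; duplicates are an error, as are
mismatched prey universes between methods.

## SHM spectrum

Clones are aligned to the reference globally (match +1, mismatch −2, gap
open −5, gap extend −1, via Biopython's PairwiseAligner; scores
configurable). Alignments under 80% identity (matches over reference
length) reject the clone with a report — a mismatched amplicon, not a
mutated one. Columns with gaps or N are excluded from substitution
calling; gap runs are counted as indel *events* and reported separately
but excluded from the mutations-per-bp frequency, which summarises the
substitution profile. Every sequenced clone counts independently — no
clonal-duplicate collapsing.

Classification uses 1-based coordinates on the reference top strand: a
mutated C is a hotspot mutation when positions (p−2, p−1, p) read W,R,C
(W = A/T, R = A/G); a mutated G when (p, p+1, p+2) read G,Y,W (Y = C/T),
the bottom-strand mirror of WRC; A/T sites form the third class. Contexts
running off the sequence end classify as non-hotspot with a warning. The
same classifier drives the clone generator's hotspot rates, so generated
truth sets round-trip exactly — and the whole pipeline output is invariant
under reverse-complementing all inputs (tested).

Frequency = substitutions / (clones × reference length), with a clone's
N-masked and deleted sites removed from the denominator when they exceed
1% of the reference (below that the correction is negligible and plate
noise dominates). The analysed length is the trimmed reference length.

## Fluctuation assay

Per culture, frequency = Rif-R cfu / Amp-R cfu × 10⁹ (plating dilution
factors, if any, multiply raw cfu first). The per-construct statistic is
the median over cultures (mean of the central pair for even n), which
damps the jackpot cultures inherent to fluctuation designs. Construct
values are normalised to the reference construct *within* each
experiment, then averaged across experiments — matching how such assays
are reported (each experiment normalised to its own wild-type median).
Only frequencies are computed; Luria–Delbrück mutation-*rate* estimation
is out of scope.

## Reporter statistics

Background subtraction floors at zero with a flag (a negative
class-switching percentage is measurement noise, not signal).
Competitive-growth series divide by the day-0 ratio or the series
maximum. Nuclear fraction = 100 × nuclear/total signal; foci positivity =
percentage of cells with ≥k foci (k = 5 by default).

## ChIP-qPCR

Per amplicon, the standard curve Ct = a + b·log₁₀(quantity) is fitted by
least squares to a ≥3-point input dilution series; quantities live on an
arbitrary per-plate scale anchored at the undiluted input (= 1). The
implied efficiency is 10^(−1/b) − 1 (so b = −3.3219 means perfect
doubling); efficiencies outside [0.8, 1.1] and r² < 0.98 raise warnings,
not errors — the procedure defines no hard QC thresholds. Percent input
= 100 × q_IP × input_fraction / q_undiluted, where `input_fraction` (the
fraction of IP chromatin the input standard represents) is a required
user parameter. IP Ct values beyond ±3 cycles of the standard range warn
of extrapolation. IgG-control percent input is subtracted per amplicon;
negative differences are retained and flagged, never clamped.

## Synthetic-data generators

All generators draw from `numpy.random.default_rng(seed)` with explicit
seeds — identical seeds give byte-identical outputs, and no global RNG
state is touched.

* **BioID** (`gen_bioid`): per-prey baseline means are log-normal around
  `base_mean` (median-anchored, `mean_sdlog` = 1.0 by default) so the R-I
  plane has the dynamic range real interactomes show; counts are NB draws
  with the shared variance parameterisation. Planted preys have means
  divided by `effect_size` in both mutant baits; APOBEC2 carries
  `a2_background_frac` (default 0.1) of each wild-type mean; the BirA*
  row is drawn around `birA_mean` (default 200 — the ligase fusion is
  typically among the strongest signals) and resampled on zero, since the
  real bait always self-biotinylates. Defaults (500 preys, 20 planted,
  8-fold effect, base mean 50, dispersion 0.05, 3 replicates) are the
  planted-recovery study conditions used throughout the tests. Replicate
  number is configurable and is a simulation choice, not a property of
  any particular experiment.
* **SHM clones** (`gen_shm_clones`): independent per-site substitution at
  `per_base_rate`, multiplied at hotspot C/G sites by
  `hotspot_multiplier`; substituted base uniform over the three
  alternatives; effective rates above 1 are rejected.
* **Fluctuation** (`gen_fluctuation`): Amp-R counts Poisson around
  `ampR_mean`, Rif-R counts Poisson(freq × ampR/10⁹) — plate-count noise
  on top of a fixed per-construct frequency.
* **qPCR** (`gen_qpcr`): Ct = a − log(q)/log(efficiency) + N(0, noise_sd)
  with a 3-point, 2-log dilution series per amplicon plus IP and IgG
  wells; the generator's `efficiency` is the per-cycle amplification
  factor (2 = doubling, i.e. fitted-curve efficiency 1.0).

**What the generators do not emulate** — and hence what passing tests do
not show about real data: peptide-to-protein inference and shared-peptide
ambiguity, between-replicate correlation from batch structure,
contaminant preys, sequencing chromatogram errors and clonal lineage
structure in SHM data, plate-position effects in qPCR, and cell-to-cell
correlation in imaging statistics. Recovery results on synthetic data are
upper bounds on real-data performance.

## Problem sizes

Simulation-based checks run at: 200 null datasets of 2000 preys (NB
calibration), 25 datasets of 1000 preys (NB power), 20 seeds of the
500-prey consensus recovery, 50–600 clones for SHM properties, 100–200
random vectors for exact identities. These sizes put Monte-Carlo error
well below the tested tolerances while keeping the default suite fast.

## Known limitations

* The NB test is a reimplementation, not a DESeq2 wrapper: no
  mean–dispersion trend, no LFC shrinkage, normal-reference Wald only.
  Agreement with DESeq2 is therefore behavioural (calibration and power
  on simulations), not numeric.
* The Maz window definition (nearest-in-intensity) is one reading of "a
  sliding window around the candidate"; rank-window variants would differ
  in dense ties.
* Alignment-based mutation calling assumes point substitutions dominate;
  clones with heavy structural changes are rejected rather than
  interpreted.
* `input_fraction` in ChIP quantification must be supplied by the user;
  it is experiment bookkeeping the data files do not carry.
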