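# Methods

This note documents the models behind each module, the defaults and why,
what the simulators do and do not emulate, and the numerical choices that a
user extending the package should know about.

## Coordinate system

All likelihoods work in genetic units (Morgans internally, centimorgans in
interfaces); physical coordinates are 0-based half-open bp. The default
test-bed layout has 22 autosomes totalling 35 Morgans at a uniform 1 cM/Mb,
with per-chromosome lengths tapering roughly like human autosomes (weight
∝ 30 − i). Real-data runs must supply their own genetic map and total
genetic length r: nothing downstream assumes the toy layout.

## Synthetic data

The simulators use renewal (Markov) approximations along the genome instead
of full ancestral-recombination-graph machinery. This is adequate for
segment-length and segment-count statistics — the quantities every
estimator here consumes — and keeps all experiments desk-scale. They do
not reproduce long-range correlations in coalescence times between distant
loci, linked selection, crossover interference, non-constant population
size within the horizon, or ancient-DNA damage profiles (the read simulator
has a single symmetric error rate; damage handling belongs upstream of this
package's scope). Passing tests therefore validate the estimators under
their own model assumptions, not robustness to these real-data features.

* **Ancestry mosaics** alternate archaic/modern tracts per haplotype:
  archaic lengths Exp((1−m)t), modern Exp(mt), initial state archaic with
  the stationary probability m. The extended-pulse variant draws a
  per-tract admixture time T ~ Gamma(k, k/t_m) and a length Exp(T) (Lomax
  marginal); the two-pulse variant assigns tracts to the pulses with weight
  π.
* **Panel frequencies** follow a Balding–Nichols model per source
  (ancestral p ~ U(0.05, 0.95), source frequency Beta(p(1−F)/F,
  (1−p)(1−F)/F)), with an archaic-admixture-style ascertainment keeping
  sites with |f_AFR − f_NEA| ≥ 0.3 by default. Drift defaults F_AFR = 0.15,
  F_NEA = F_DEN = 0.35 express the deeper drift of the archaic panels; the
  contaminant frequency defaults to f_AFR.
* **Reads**: depth ~ Poisson(coverage); each read is a contaminant with the
  given probability, otherwise copies a random haplotype allele; symmetric
  base flip with the error rate. `coverage=inf` emits true genotypes.
* **Pedigree IBD** simulates transmission explicitly: per common ancestor,
  each meiosis lays Poisson(1/Morgan) crossovers without interference, and
  IBD is where both descent paths carry the same ancestral haplotype.
  Closed forms for the mean total (a·r/2^(m−1) Morgans) and segment count
  (a·(rm + c_chr)/2^(m−1)) are exported for testing.
* **Coalescent IBD/ROH** walk each chromosome as a stationary renewal
  process: tract times are geometric with the length-biased tilt
  Q(g) ∝ (2g+Δ)P(g) (sampled exactly as a sum of two geometrics), so the
  locus-wise marginal time is exactly geometric; the tract covering the
  chromosome start uses the plain marginal with a memoryless residual
  length. Only tracts with g ≤ G and length ≥ the cutoff are emitted. For
  very large N (expected tracts > 5·10⁶) a thinned Poisson construction
  with the same marginal intensity is used instead.

## Finite-chromosome end correction

The textbook segment-count intensity
λ(N) = Σ_g n_pairs·P(g)·(2g·r + c_chr)·e^(−2g·ℓ₀) assumes chromosomes much
longer than the cutoff ℓ₀. On 22 chromosomes averaging 1.6 Morgans with
ℓ₀ = 0.12 Morgans that is not true: a segment starting within ℓ₀ of a
chromosome end is truncated below the cutoff and never observed, which
removes an ℓ₀-length window per chromosome. All intensity functions
(`ibd_intensity`, `roh_bin_intensity`, `expected_ibd_count`,
`expected_segment_count`) therefore use r_eff = r − c_chr·ℓ₀ by default
(for ROH bins, the bin's lower edge). Monte Carlo from the renewal
simulator confirms the correction (e.g. 13.07 observed segments per
replicate at N = 160 vs 13.06 corrected vs 14.12 uncorrected); the
uncorrected form remains available via `end_corrected=False`. Without the
correction the N_e MLE is biased upward by roughly the same ~7%. A
second-order effect — truncated runs migrating between ROH length bins —
is not corrected and is visible only as a ≲2% residual in bin-level
comparisons.

## Ancestry HMM

Six unordered diploid states decoded on the ordered 3×3 product space of
two independent per-haplotype chains, each reverting to the stationary
source weights q at rate ρ per Morgan (for a single pulse t generations
ago, ρ = t and q_NEA = m). Emissions marginalize the latent haplotype
alleles (Bernoulli in the source panel frequencies) through a binomial
read model with fixed error and contamination; contamination is an input,
not co-estimated. Forward–backward runs in a compiled (numba) kernel with
per-site scaling; emissions are floored at e⁻⁶⁹⁰ to keep logs finite.

Defaults for segment calling — posterior threshold 0.8 on P(state contains
NEA), merge gap 0.05 cM, minimum length 0.05 cM, boundaries at genetic
midpoints between flanking sites — are package choices (config-exposed).
At 28 ascertained sites per cM and 20× coverage this caller recovers
roughly 83% of true tracts ≥ 0.5 cM with ~0.1 cM median boundary error;
the misses are genuinely weak-signal tracts whose peak posterior never
reaches the threshold, so users chasing recall at the cost of precision
should lower the threshold (0.5 gives ~93% recall here). Genome-wide
ancestry uses the mean NEA dosage with a moving-block bootstrap
(5 cM blocks, 1,000 resamples) for the 95% CI.

`fit_hmm_params` fits (q_NEA, ρ) by a coarse grid plus Nelder–Mead on the
forward likelihood; it is deterministic given its grids and is intended for
real-data runs where the truth is unknown.

## Admixture dating

Lengths enter likelihoods in Morgans; the default cutoff is 0.2 cM. The
(1−m) correction to t̂ (a ≤3% effect at m ≈ 0.03) is not applied by
default. The two-pulse EM uses 5 seeded restarts, convergence at
Δloglik < 1e-8 or 500 iterations, and flags component collapse (rates
within 1%, or mixture weight at the boundary) as degenerate. The extended
pulse is maximized over (log t_m, log k) by Nelder–Mead from three k
starting points with k capped at 10⁴ (a fit at the cap is flagged as
indistinguishable from a single pulse); the t_m CI is a profile-likelihood
interval. Model selection is by BIC with ties (ΔBIC < 2) going to the
simpler model; a parametric-bootstrap LRT of single vs two is available.
The longest-100 route sets the cutoff at the 100th-longest length, valid by
memorylessness. Covariance dating grids the dosage onto 0.05 cM bins,
computes lagged products by FFT per chromosome, fits A·e^(−td) + B by
weighted least squares (weights = pair counts, lags ≤ 20 cM), requires a
genuinely decaying curve (correlation of covariance with distance
< −0.05, A > 0) and bootstraps chromosomes for its CI. On a single
diploid (~170 tracts) its point estimate scatters ±15% around the truth.

Calendar propagation is interval arithmetic: [r_low + g_low·τ,
r_high + g_high·τ] for generation interval g, generation time τ (default
29 years) and radiocarbon interval r, reported in years cal BP and rounded
to ka. CIs from several methods combine by interval union.

## Kinship and N_e

Close-kin classification compares six class-specific HMMs over local IBD
state {0, 1, 2} with stationary weights at the canonical (k0, k1, k2) per
class, persistence e^(−spacing/10 cM) between 20 cM windows, and binomial
mismatch emissions with rates (p_background, mean, p_self). The output is
the ML class and the log-likelihood ratio to the runner-up. Contamination
adjustment is not implemented; mismatch rates are supplied by the caller.

Distant degrees maximize Poisson(count | a·(r_eff·m + c_chr)/2^(m−1)·
e^(−m·ℓ₀)) × Exp(m excess lengths) over m ∈ {1..13}, a ∈ {1, 2};
degree = m − log₂ a (so parent–offspring and full siblings both sit at
degree 1 and cannot be separated by this likelihood — segment lengths
bounded by chromosomes carry no extra information there). With ~7
observable ≥12 cM segments at the fifth degree, Poisson noise alone spreads
the MAP over ±1 degree in ~20% of cases; the 95% credible set over degrees
(from the normalized likelihood) covers the truth at its nominal rate.

Recent N_e from IBD maximizes the same Poisson + length-mixture likelihood
over N (log grid 2–50,000, bounded refinement); it reports the MLE, a 95%
credible interval under a log-uniform prior (matching a "with 95%
probability" reading), and the profile-likelihood interval. The MLE's
small-sample skew (few segments → heavy right tail) leaves its mean ~7%
above the truth at λ ≈ 13 expected segments; the median is nearly unbiased.
Zero segments yield a flagged lower bound. The ROH-based estimator
multiplies Poisson bin likelihoods ([4,8), [8,12), [12,20), [20,∞) cM,
hapROH-style bins, config-exposed) across individuals — a composite
likelihood that treats individuals as independent. The age-gap posterior
scores observed total IBD against simulated totals per candidate gap
(point mass at zero plus a Gaussian kernel over positive totals) under a
uniform prior over gaps.

## Diversity and age

Heterozygosity is hets per 10⁴ callable sites with a weighted 5-Mb block
jackknife SE. The ROH caller is a two-state Viterbi over 0.25 cM windows of
het counts (Poisson emissions; inside-ROH rate 5% of the background as an
error floor; entry probability 10⁻³ per window, mean ROH 10 cM in the exit
rate), emitting runs ≥ 4 cM; its parameters are declared defaults,
config-exposed. Branch shortening estimates age = T_cal·(1 − n_anc/n_mod)
from derived-transversion counts, with the Wilson interval of the branch
proportion propagated through the formula; the calibration span T_cal is an
explicit input. Negative ages truncate to 0 with a flag.

## f-statistics

Frequencies (or seeded pseudo-haploid 0/1 draws) per population per site;
complete-case per statistic. D, f3, f4 and the f4-ratio use a weighted
delete-one block jackknife (Busing et al. 1999) in 5-Mb physical blocks
(block weight = site count). The f4-ratio refuses denominators within 3 SE
of zero. MDS is classical Torgerson scaling of 1 − f3 (double-centering +
eigendecomposition, deterministic up to axis sign).

## Shared introgression

Edge sharing counts focal segment boundaries with a panel boundary within
0.1 cM (circular genetic distance), against a null that circularly rotates
each panel genome per chromosome by an independent uniform offset
(n_perm = 999 by default; P = (1 + #null ≥ obs)/(n_perm + 1)). Rotation
preserves each genome's segment count and length distribution, so the test
is about positions only. Bin correlation uses 0.1 cM presence/absence
indicators and Pearson r, with panel-vs-panel pairs as the background;
constant indicators give a missing r. Both tolerances exceed the HMM's
~0.1 cM boundary noise and are config-exposed.

## Pipeline

`run_demo` chains simulate → decode → call → date → calendar with
per-stage seeds derived from the master seed by a counter scheme
(`derive_seed`), defaults of 30,000 sites at 10× (a ~1-minute run), and a
deterministic JSON report; a stage failure aborts with the stage name and
preserves partial outputs. The generation interval entering the calendar
step is the fitted single-pulse CI unless overridden in the config.

## Test scale

Stochastic suites run at fixed seeds with tolerances of 3 Monte Carlo SEs
at the replicate counts used (hundreds to a few thousand replicates per
property; the CI-coverage check uses 1,000 replicates). The acceptance
script uses 50–100 replicates per experiment and ~10⁵-site genomes —
sizes chosen so each experiment completes in minutes on one CPU while
holding the tolerances stated in its docstring.
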