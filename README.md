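# paleopulse

Demographic inference for the earliest modern humans out of Africa, built
around the analyses that connect archaic (Neanderthal) ancestry in ancient
genomes to calendar-scale history: local-ancestry segment calling, admixture
dating from tract lengths, kinship and recent effective population size from
identity-by-descent (IBD) and runs of homozygosity (ROH), allele-sharing
statistics, and molecular age estimation — all exercised on synthetic data
with known ground truth.

It is aimed at population geneticists who want desk-scale, testable
re-implementations of these estimators: every input the pipeline consumes
(ascertained site panels, low-coverage reads, ancestry mosaics, pedigree and
coalescent IBD/ROH) can be generated by the built-in simulators, so every
estimator ships with a closed-form or simulation oracle.

## The models

**Tract-length dating.** A single admixture pulse t generations ago leaves
archaic tracts with exponentially distributed genetic lengths,
ℓ ~ Exp(t) (lengths in Morgans). With a cutoff c against incomplete lineage
sorting, the truncated MLE is t̂ = n / Σ(ℓᵢ − c), with a chi-squared 95% CI
[χ²₀.₀₂₅,₂ₙ, χ²₀.₉₇₅,₂ₙ] / (2Σ(ℓᵢ − c)). Alternatives: a two-exponential
mixture (two pulses, fitted by EM) and an extended pulse in which the
admixture time is Gamma(k, k/t_m)-distributed, giving a Lomax tract-length
marginal f(ℓ) = kβᵏ/(β+ℓ)ᵏ⁺¹ with β = k/t_m. A segment-free route fits the
exponential decay A·e^(−t·d) + B of the ancestry-dosage autocovariance with
genetic distance d.

**Diploid local ancestry.** A six-state HMM over unordered source pairs
(AFR, NEA, DEN homozygous; AFRNEA, AFRDEN, NEADEN heterozygous): the two
haplotypes follow independent Markov chains with switch rate ρ per Morgan
toward stationary weights q, and emissions marginalize the latent diploid
genotype over binomial read counts with error and contamination.

**IBD/ROH and recent N_e.** In a constant-size population of N diploids, a
haplotype pair coalescing g generations back leaves segments of length
~ Exp(2g) Morgans. The expected number of segments above ℓ₀ within a
G-generation horizon is

    λ(N) = Σ_{g=1..G} n_pairs · (1/2N)(1−1/2N)^(g−1) · (2g·r_eff + c_chr) · e^(−2g·ℓ₀),

with r_eff the genome length in Morgans reduced for chromosome-end
truncation (see `docs/methods.md`) and c_chr the chromosome count. A joint
Poisson(count) + Exp-mixture(lengths) likelihood yields the recent-N_e MLE
from IBD between two genomes (4 haplotype pairs); the same intensity binned
by length does so from per-individual ROH. Pedigree relatives separated by
m meioses through a common ancestors share a·(r_eff·m + c_chr)/2^(m−1)
segments in expectation, the basis of distant-degree inference
(degree d = m − log₂ a).

**f-statistics.** D = (BABA − ABBA)/(ABBA + BABA), outgroup
f3(O; X, Y) = E[(o−x)(o−y)], f4 and the direct f4-ratio ancestry
proportion, all with weighted 5-Mb block-jackknife standard errors, plus
classical 2-D scaling of the 1−f3 distance matrix.

## Worked example

The demo runs the whole chain — simulate a 35-Morgan diploid genome with
2.9% archaic ancestry from a pulse 85 generations back, sample 10× reads at
30,000 ascertained sites, decode the HMM, call segments, fit all three
tract-length models, pick one by BIC, and propagate to calendar years:

```python
import paleopulse as pp
report = pp.run_demo(pp.RunConfig(seed=1))
```

or `paleopulse demo --seed 1 --out run1/`. With seed 1 the report reads
(abridged):

```
truth      archaic_fraction 2.92%   admixture_time 85
ancestry   proportion 2.83%  (95% CI 2.41–3.30%)   n_sites 29,999
segments   n 50   total 77.7 cM
dating     single  t̂ 73.9  (95% CI 54.8–95.7)
           two     degenerate to single pulse
model      single  (BIC)
calendar   44,990–49,356 cal BP  →  45–49 ka
```

Reading it: the decoded genome-wide archaic proportion (2.83%) brackets the
simulated truth (2.92%); the 50 called segments date the pulse to ~74
generations with a CI covering the true 85; the mixture fit collapses onto
the single pulse, so BIC keeps the one-pulse model; and combining the
generation CI with a 29-year generation time and a radiocarbon window of
43,400–46,580 cal BP places the admixture at 45–49 ka. The same seed always
reproduces this report byte for byte.

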