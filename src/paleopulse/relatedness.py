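"""Kinship classification, distant-degree inference and recent N_e from IBD.

Close kin (up to third degree) are classified from windowed pairwise
mismatch rates of pseudo-haploid data with a small HMM over the local
IBD-sharing state (0, 1 or 2 shared haplotypes), one HMM per candidate
relationship class; the output is the maximum-likelihood class and the
log-likelihood ratio to the runner-up.

More distant relationships are read off long IBD segments: a relative pair
separated by m meioses through a ancestors shares
a·(r·m + c_chr)/2^(m-1)·exp(-m·l0) long segments in expectation (r genome
length in Morgans, c_chr chromosomes, l0 the length cutoff in Morgans), with
Exp(m) excess lengths.  The same Poisson-plus-lengths construction over a
geometric coalescence-time prior yields the recent effective population
size from IBD between two unrelated genomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import binom

from .core_genome import GenomeLayout, PaleopulseError, SegmentSet
from .synthdata import CoalescentScenario, simulate_pairwise_coalescent_segments

logger = logging.getLogger("paleopulse")

#: Canonical IBD-state fractions (k0, k1, k2) per relationship class.
KINSHIP_CLASSES: dict[str, tuple[float, float, float]] = {
    "identical": (0.0, 0.0, 1.0),
    "parent-offspring": (0.0, 1.0, 0.0),
    "siblings": (0.25, 0.5, 0.25),
    "second-degree": (0.5, 0.5, 0.0),
    "third-degree": (0.75, 0.25, 0.0),
    "unrelated": (1.0, 0.0, 0.0),
}

#: Window persistence: windows are 20 cM of genetic length and the IBD state
#: decorrelates as exp(-spacing / 10 cM) between window midpoints.
DEFAULT_PERSISTENCE = float(np.exp(-2.0))


@dataclass
class DegreeFit:
    """Meioses/ancestor fit for a distant relative pair."""

    m: int
    a: int
    degree: float
    surface: pd.DataFrame          # columns m, a, degree, loglik, posterior
    credible_degrees: list[float]  # 95% credible set of degrees
    flags: list = field(default_factory=list)


@dataclass
class NeEstimate:
    """Recent effective population size from long IBD/ROH segments."""

    n_hat: float
    interval: tuple[float, float]          # 95% posterior (log-uniform prior)
    profile_interval: tuple[float, float]  # 95% profile-likelihood
    horizon_G: int
    min_len_cM: float
    n_segments: int
    lengths_cM: np.ndarray
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_hat < 2:
            raise PaleopulseError("N_e estimate below 2")
        if not (self.interval[0] <= self.n_hat <= self.interval[1]):
            raise PaleopulseError("interval does not contain the estimate")


# ---------------------------------------------------------------------------
# Close-kin classification
# ---------------------------------------------------------------------------

def _class_loglik(n_obs: np.ndarray, n_mis: np.ndarray, k: np.ndarray,
                  mu: np.ndarray, persistence: float) -> float:
    """Scaled forward pass of the 3-state windowed IBD HMM for one class."""
    em = binom.pmf(n_mis[:, None], n_obs[:, None], mu[None, :])  # (W, 3)
    alpha = k * em[0]
    s = alpha.sum()
    if s <= 0:
        return -np.inf
    ll = np.log(s)
    alpha /= s
    p = persistence
    for w in range(1, len(n_obs)):
        pred = p * alpha + (1 - p) * k * alpha.sum()
        alpha = pred * em[w]
        s = alpha.sum()
        if s <= 0:
            return -np.inf
        ll += np.log(s)
        alpha /= s
    return float(ll)


def classify_kinship_pair(window_counts: pd.DataFrame | tuple,
                          p_background: float, p_self: float,
                          persistence: float = DEFAULT_PERSISTENCE) -> dict:
    """Classify a pair of genomes into a kinship class.

    ``window_counts`` carries per-window observed comparisons ``n_obs`` and
    mismatches ``n_mismatch`` from pairwise pseudo-haploid comparison
    (a DataFrame with those columns or an ``(n_obs, n_mismatch)`` tuple of
    arrays).  ``p_background`` is the mismatch rate of unrelated genomes and
    ``p_self`` that of two samplings of one genome; the one-shared-haplotype
    state mismatches at their mean.  Returns the best class, the LLR to the
    runner-up, and per-class log-likelihoods.
    """
    if isinstance(window_counts, pd.DataFrame):
        n_obs = window_counts["n_obs"].to_numpy(int)
        n_mis = window_counts["n_mismatch"].to_numpy(int)
    else:
        n_obs, n_mis = (np.asarray(a, int) for a in window_counts)
    if not (0 < p_self < p_background < 1):
        raise PaleopulseError(
            "need 0 < p_self < p_background < 1 (uninformative configuration)")
    keep = n_obs > 0
    if keep.sum() < 20:
        raise PaleopulseError(
            f"only {int(keep.sum())} non-empty windows (need >= 20)")
    n_obs, n_mis = n_obs[keep], n_mis[keep]
    mu = np.array([p_background, (p_background + p_self) / 2.0, p_self])

    logliks = {
        label: _class_loglik(n_obs, n_mis, np.asarray(k, float), mu, persistence)
        for label, k in KINSHIP_CLASSES.items()
    }
    ranked = sorted(logliks, key=logliks.get, reverse=True)
    best, second = ranked[0], ranked[1]
    return {
        "class": best,
        "k": KINSHIP_CLASSES[best],
        "llr": logliks[best] - logliks[second],
        "runner_up": second,
        "logliks": logliks,
    }


def simulate_kinship_windows(label: str, n_windows: int, mean_obs: float,
                             p_background: float, p_self: float, seed: int,
                             persistence: float = DEFAULT_PERSISTENCE
                             ) -> pd.DataFrame:
    """Simulate windowed mismatch counts for a known kinship class."""
    if label not in KINSHIP_CLASSES:
        raise PaleopulseError(f"unknown kinship class {label!r}")
    rng = np.random.default_rng(seed)
    k = np.asarray(KINSHIP_CLASSES[label], float)
    mu = np.array([p_background, (p_background + p_self) / 2.0, p_self])
    states = np.empty(n_windows, int)
    states[0] = rng.choice(3, p=k)
    for w in range(1, n_windows):
        if rng.random() < persistence:
            states[w] = states[w - 1]
        else:
            states[w] = rng.choice(3, p=k)
    n_obs = rng.poisson(mean_obs, n_windows)
    n_mis = rng.binomial(n_obs, mu[states])
    return pd.DataFrame({"n_obs": n_obs, "n_mismatch": n_mis, "state": states})


# ---------------------------------------------------------------------------
# Distant degree
# ---------------------------------------------------------------------------

def expected_ibd_count(m: int, a: int, layout: GenomeLayout,
                       min_len_cM: float, end_corrected: bool = True) -> float:
    """Expected number of IBD segments >= min_len for an (m, a) relative pair.

    a·(r_eff·m + c_chr)/2^(m-1)·exp(-m·l0), with r_eff = r - c_chr·l0 when
    ``end_corrected``: a segment starting within l0 of a chromosome end is
    truncated below the cutoff and never observed, which removes an
    l0-length window per chromosome from the usable genome (r is the genome
    length in Morgans, l0 the cutoff in Morgans).
    """
    r, c = layout.r_total, layout.c_chr
    l0 = min_len_cM / 100.0
    r_eff = max(r - c * l0, 0.0) if end_corrected else r
    return a * (r_eff * m + c) / 2.0 ** (m - 1) * np.exp(-m * l0)


def fit_distant_degree(ibd: SegmentSet, layout: GenomeLayout,
                       min_len_cM: float = 12.0,
                       m_grid=range(1, 14)) -> DegreeFit:
    """Infer the degree of a distant relative pair from long IBD segments.

    Likelihood over the (m, a) grid: the segment count is
    Poisson(expected_ibd_count) and the excess lengths are Exp(m) Morgans.
    Degree is d = m - log2(a) (parent-offspring 1, siblings 1, avuncular 2,
    first cousins 3).  The credible set collects degrees until 95% of the
    normalized likelihood mass is covered.
    """
    lengths = ibd.lengths_cM
    lengths = lengths[lengths >= min_len_cM]
    rows = []
    if lengths.size == 0:
        m_max = max(m_grid)
        return DegreeFit(m_max, 1, float(m_max), pd.DataFrame(),
                         [], flags=[f"no detectable relationship (>= m={m_max})"])
    e = (lengths - min_len_cM) / 100.0
    n = lengths.size
    for m in m_grid:
        for a in (1, 2):
            lam = expected_ibd_count(m, a, layout, min_len_cM)
            ll = n * np.log(lam) - lam + np.sum(np.log(m) - m * e)
            rows.append({"m": m, "a": a, "degree": m - np.log2(a), "loglik": ll})
    surf = pd.DataFrame(rows)
    w = np.exp(surf["loglik"] - surf["loglik"].max())
    surf["posterior"] = w / w.sum()
    best = surf.loc[surf["loglik"].idxmax()]

    by_degree = surf.groupby("degree")["posterior"].sum().sort_values(ascending=False)
    credible, acc = [], 0.0
    for deg, p in by_degree.items():
        credible.append(float(deg))
        acc += p
        if acc >= 0.95:
            break
    return DegreeFit(int(best["m"]), int(best["a"]), float(best["degree"]),
                     surf, sorted(credible))


# ---------------------------------------------------------------------------
# Recent N_e from IBD
# ---------------------------------------------------------------------------

def ibd_intensity(N: float, G: int, n_pairs: int, layout: GenomeLayout,
                  min_len_cM: float, end_corrected: bool = True) -> float:
    """Expected count of recent IBD segments longer than the cutoff.

    lambda(N) = sum_{g<=G} n_pairs·P_N(g)·(2g·r_eff + c_chr)·exp(-2g·l0)
    with r_eff = r - c_chr·l0 when ``end_corrected`` (segments starting
    within l0 of a chromosome end are truncated below the cutoff); the
    uncorrected infinite-chromosome form uses r_eff = r.
    """
    p = 1.0 / (2.0 * N)
    g = np.arange(1, G + 1)
    pmf = p * (1 - p) ** (g - 1)
    l0 = min_len_cM / 100.0
    r, c = layout.r_total, layout.c_chr
    r_eff = max(r - c * l0, 0.0) if end_corrected else r
    return float(n_pairs * np.sum(pmf * (2 * g * r_eff + c) * np.exp(-2 * g * l0)))


def _ne_loglik(N: float, n_seg: int, excess: np.ndarray, G: int, n_pairs: int,
               layout: GenomeLayout, min_len_cM: float) -> float:
    lam = ibd_intensity(N, G, n_pairs, layout, min_len_cM)
    ll = n_seg * np.log(max(lam, 1e-300)) - lam
    if n_seg:
        p = 1.0 / (2.0 * N)
        g = np.arange(1, G + 1)
        l0 = min_len_cM / 100.0
        r_eff = max(layout.r_total - layout.c_chr * l0, 0.0)
        w = p * (1 - p) ** (g - 1) * (2 * g * r_eff + layout.c_chr) \
            * np.exp(-2 * g * l0)
        w = w / w.sum()
        dens = (w[None, :] * 2 * g[None, :]
                * np.exp(-2 * g[None, :] * excess[:, None])).sum(axis=1)
        ll += float(np.log(np.maximum(dens, 1e-300)).sum())
    return float(ll)


def estimate_recent_ne_ibd(ibd: SegmentSet, layout: GenomeLayout,
                           horizon_G: int = 15, min_len_cM: float = 12.0,
                           n_pairs: int = 4,
                           n_grid: np.ndarray | None = None) -> NeEstimate:
    """Recent effective population size from long IBD between two genomes.

    Maximizes the Poisson likelihood of the segment count (intensity
    ``ibd_intensity``) joint with the Exp-mixture likelihood of excess
    lengths.  Reports both a 95% credible interval under a log-uniform N
    prior and the 95% profile-likelihood interval.
    """
    if horizon_G < 1:
        raise PaleopulseError("horizon must be >= 1 generation")
    lengths = ibd.lengths_cM
    lengths = lengths[lengths >= min_len_cM]
    excess = (lengths - min_len_cM) / 100.0
    n_seg = lengths.size
    if n_grid is None:
        n_grid = np.exp(np.linspace(np.log(2.0), np.log(50_000.0), 400))

    flags = []
    ll = np.array([_ne_loglik(N, n_seg, excess, horizon_G, n_pairs,
                              layout, min_len_cM) for N in n_grid])
    if n_seg == 0:
        # likelihood is exp(-lambda(N)): monotone in N -> lower bound only
        ok = ll >= ll.max() - np.log(20.0)
        lo = float(n_grid[ok].min())
        return NeEstimate(float(n_grid[-1]), (lo, float(n_grid[-1])),
                          (lo, float(n_grid[-1])), horizon_G, min_len_cM, 0,
                          lengths, flags=["zero segments; lower bound on N only"])

    i_best = int(np.argmax(ll))
    lo_b = n_grid[max(i_best - 2, 0)]
    hi_b = n_grid[min(i_best + 2, len(n_grid) - 1)]
    res = minimize_scalar(
        lambda N: -_ne_loglik(N, n_seg, excess, horizon_G, n_pairs,
                              layout, min_len_cM),
        bounds=(lo_b, hi_b), method="bounded")
    n_hat = float(res.x)
    ll_max = -res.fun

    # posterior under log-uniform prior (uniform weight on the log grid)
    post = np.exp(ll - ll.max())
    post /= post.sum()
    cdf = np.cumsum(post)
    lo = float(n_grid[np.searchsorted(cdf, 0.025)])
    hi = float(n_grid[min(np.searchsorted(cdf, 0.975), len(n_grid) - 1)])
    lo, hi = min(lo, n_hat), max(hi, n_hat)

    ok = ll >= ll_max - 1.920729  # chi2(0.95, 1) / 2
    prof = (min(float(n_grid[ok].min()), n_hat),
            max(float(n_grid[ok].max()), n_hat))
    return NeEstimate(n_hat, (lo, hi), prof, horizon_G, min_len_cM,
                      int(n_seg), lengths, flags=flags)


# ---------------------------------------------------------------------------
# Age-gap posterior
# ---------------------------------------------------------------------------

def estimate_separation_posterior(observed_total_cM: float, Ne: float,
                                  layout: GenomeLayout,
                                  candidate_gaps=range(0, 16),
                                  horizon_G: int = 15,
                                  min_len_cM: float = 12.0, n_pairs: int = 4,
                                  n_sims: int = 200, seed: int = 0
                                  ) -> pd.DataFrame:
    """Posterior over the generation gap between two samples.

    For each candidate gap the distribution of total long-IBD sharing is
    simulated under the renewal coalescent with the samples' ages offset by
    the gap; the observed total is scored against it (zero totals by the
    simulated point mass at zero, positive totals by a Gaussian kernel
    density over the positive simulated totals).  A uniform prior over the
    candidate gaps is assumed.
    """
    if Ne is None or Ne < 2:
        raise PaleopulseError("a valid Ne estimate is required")
    rng = np.random.default_rng(seed)
    rows = []
    for gap in candidate_gaps:
        sc = CoalescentScenario(N_e=Ne, G=horizon_G, n_pairs=n_pairs, delta=gap)
        totals = np.empty(n_sims)
        for s in range(n_sims):
            seg = simulate_pairwise_coalescent_segments(
                sc, layout, min_len_cM, seed=int(rng.integers(2 ** 31)))
            totals[s] = seg.total_cM
        floor = 0.5 / n_sims
        if observed_total_cM <= 0:
            like = max(float(np.mean(totals == 0)), floor)
        else:
            pos = totals[totals > 0]
            if pos.size < 2:
                like = floor
            else:
                bw = max(1.06 * pos.std(ddof=1) * pos.size ** -0.2, 1.0)
                kern = np.exp(-0.5 * ((observed_total_cM - pos) / bw) ** 2) \
                    / (bw * np.sqrt(2 * np.pi))
                like = max(float(pos.size / n_sims * kern.mean()), floor * 1e-3)
        rows.append({"gap": int(gap), "likelihood": like})
    out = pd.DataFrame(rows)
    out["posterior"] = out["likelihood"] / out["likelihood"].sum()
    return out
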