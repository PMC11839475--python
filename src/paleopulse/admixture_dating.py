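"""Dating archaic admixture from tract lengths and ancestry covariance.

After a single admixture pulse t generations ago, archaic tract lengths are
exponentially distributed with rate t per Morgan (recombination breaks one
tract per Morgan per generation).  A length cutoff (default 0.2 cM) removes
short tracts that incomplete lineage sorting could mimic; by memorylessness
the excesses above the cutoff remain Exp(t).  Three tract-length models are
fitted:

* single pulse — closed-form truncated-exponential MLE, chi-squared CI;
* two-pulse mixture — EM on a two-component truncated exponential mixture;
* extended pulse — admixture time Gamma(k, k/t_m) distributed, giving a
  Lomax marginal for tract lengths; k -> infinity recovers the single pulse.

A segment-free alternative fits the exponential decay of the ancestry-dosage
autocovariance with genetic distance.  Generation-scale estimates propagate
to calendar dates via a generation time and the sample's radiocarbon
interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize, minimize_scalar
from scipy.stats import chi2

from .core_genome import PaleopulseError, SegmentSet

logger = logging.getLogger("paleopulse")

_K_MAX = 1e4
_MIN_N_SINGLE = 10
_MIN_N_MIX = 50


@dataclass
class PulseFit:
    """A fitted admixture-time model.

    ``t_hat`` is in generations; ``ci`` the 95% CI; ``params`` holds extra
    model parameters (t1/t2/pi for the mixture, k for the extended pulse).
    """

    kind: str
    t_hat: float
    ci: tuple[float, float]
    loglik: float
    n: int
    cutoff_cM: float
    n_params: int
    params: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.ci[0] <= self.t_hat <= self.ci[1]):
            raise PaleopulseError("CI does not bracket the point estimate")
        if not np.isfinite(self.loglik):
            raise PaleopulseError("non-finite log-likelihood")


@dataclass(frozen=True)
class CalendarInterval:
    """Calendar date interval in years cal BP with its components."""

    low: float
    high: float
    g_interval: tuple[float, float]
    generation_time: float
    radiocarbon_interval: tuple[float, float]

    @property
    def ka(self) -> tuple[int, int]:
        """Interval rounded to the nearest millennium (ka)."""
        return (int(round(self.low / 1000.0)), int(round(self.high / 1000.0)))


def _excess_morgans(lengths_cM: np.ndarray, cutoff_cM: float) -> np.ndarray:
    lengths_cM = np.asarray(lengths_cM, float)
    if np.any(lengths_cM < cutoff_cM - 1e-12):
        raise PaleopulseError(
            f"{np.sum(lengths_cM < cutoff_cM)} segment(s) below the "
            f"{cutoff_cM} cM cutoff; filter first")
    return (lengths_cM - cutoff_cM) / 100.0


# ---------------------------------------------------------------------------
# Single pulse
# ---------------------------------------------------------------------------

def fit_single_pulse(lengths_cM, cutoff_cM: float = 0.2) -> PulseFit:
    """Truncated-exponential MLE of the admixture time.

    With excesses e_i = (l_i - c)/100 Morgans, t-hat = n / sum(e_i); the 95%
    CI is [chi2(0.025, 2n), chi2(0.975, 2n)] / (2 sum(e_i)).
    """
    e = _excess_morgans(lengths_cM, cutoff_cM)
    n = e.size
    if n < _MIN_N_SINGLE:
        raise PaleopulseError(
            f"only {n} segments (need >= {_MIN_N_SINGLE}); for sparse data "
            "use the longest-segment decay-curve mode")
    s = e.sum()
    if s <= 0:
        raise PaleopulseError("all excess lengths are zero; cannot estimate a rate")
    t_hat = n / s
    ci = (chi2.ppf(0.025, 2 * n) / (2 * s), chi2.ppf(0.975, 2 * n) / (2 * s))
    loglik = n * np.log(t_hat) - t_hat * s
    return PulseFit("single", float(t_hat), (float(ci[0]), float(ci[1])),
                    float(loglik), n, cutoff_cM, n_params=1)


# ---------------------------------------------------------------------------
# Two-pulse mixture
# ---------------------------------------------------------------------------

def _em_two_exp(e: np.ndarray, t1: float, t2: float, pi: float,
                tol: float = 1e-8, max_iter: int = 500):
    """EM for a two-component exponential mixture on excess lengths."""
    n = e.size
    trace = []
    ll_old = -np.inf
    for _ in range(max_iter):
        d1 = pi * t1 * np.exp(-t1 * e)
        d2 = (1 - pi) * t2 * np.exp(-t2 * e)
        tot = d1 + d2
        ll = float(np.log(np.maximum(tot, 1e-300)).sum())
        trace.append(ll)
        r = d1 / np.maximum(tot, 1e-300)
        pi = float(r.mean())
        pi = min(max(pi, 1e-6), 1 - 1e-6)
        t1 = float(r.sum() / max((r * e).sum(), 1e-300))
        t2 = float((1 - r).sum() / max(((1 - r) * e).sum(), 1e-300))
        if ll - ll_old < tol and ll_old > -np.inf:
            break
        ll_old = ll
    return t1, t2, pi, trace[-1], trace


def fit_two_pulse_mixture(lengths_cM, cutoff_cM: float = 0.2,
                          n_restarts: int = 5, seed: int = 0) -> PulseFit:
    """EM fit of a two-exponential mixture (two admixture pulses).

    Runs ``n_restarts`` seeded restarts and keeps the best likelihood.
    Components within 1% of each other raise the ``degenerate`` flag.
    """
    e = _excess_morgans(lengths_cM, cutoff_cM)
    n = e.size
    if n < _MIN_N_MIX:
        raise PaleopulseError(f"only {n} segments (need >= {_MIN_N_MIX})")
    rng = np.random.default_rng(seed)
    t0 = n / e.sum()
    best = None
    for _ in range(n_restarts):
        t1 = t0 * rng.uniform(0.2, 0.9)
        t2 = t0 * rng.uniform(1.1, 5.0)
        pi = rng.uniform(0.2, 0.8)
        res = _em_two_exp(e, t1, t2, pi)
        if best is None or res[3] > best[3]:
            best = res
    t1, t2, pi, ll, trace = best
    if t1 > t2:
        t1, t2, pi = t2, t1, 1 - pi
    flags = []
    if abs(t2 - t1) / max(t2, 1e-12) < 0.01 or pi < 1e-3 or pi > 1 - 1e-3:
        flags.append("degenerate to single pulse")
    t_mean = pi * t1 + (1 - pi) * t2
    return PulseFit("two", float(t_mean),
                    (min(t1, t_mean), max(t2, t_mean)), float(ll), n,
                    cutoff_cM, n_params=3,
                    params={"t1": t1, "t2": t2, "pi": pi,
                            "loglik_trace": trace},
                    flags=flags)


# ---------------------------------------------------------------------------
# Extended pulse
# ---------------------------------------------------------------------------

def extended_pulse_logpdf(l_morgans, t_m: float, k: float,
                          cutoff_morgans: float = 0.0) -> np.ndarray:
    """Log density of the Lomax tract-length marginal, truncated at a cutoff.

    f(l) = k beta^k / (beta + l)^(k+1) with beta = k / t_m; truncation at c
    divides by the survival (beta / (beta + c))^k.
    """
    l = np.asarray(l_morgans, float)
    beta = k / t_m
    logf = np.log(k) + k * np.log(beta) - (k + 1) * np.log(beta + l)
    log_surv = k * (np.log(beta) - np.log(beta + cutoff_morgans))
    return logf - log_surv


def fit_extended_pulse(lengths_cM, cutoff_cM: float = 0.2) -> PulseFit:
    """Numeric MLE of the extended-pulse (Lomax) tract-length model.

    Optimizes over (log t_m, log k); the 95% CI for t_m comes from the
    profile likelihood.  A shape estimate at the upper bound (k = 1e4) is
    flagged as indistinguishable from a single pulse.
    """
    lengths_cM = np.asarray(lengths_cM, float)
    if np.any(lengths_cM < cutoff_cM - 1e-12):
        raise PaleopulseError("segments below the cutoff; filter first")
    n = lengths_cM.size
    if n < _MIN_N_MIX:
        raise PaleopulseError(f"only {n} segments (need >= {_MIN_N_MIX})")
    l = lengths_cM / 100.0
    c = cutoff_cM / 100.0

    def nll(x):
        t_m, k = np.exp(x)
        if not (1e-3 < t_m < 1e6) or not (1e-3 < k < _K_MAX * 10):
            return 1e12
        return -float(extended_pulse_logpdf(l, t_m, min(k, _K_MAX), c).sum())

    t0 = n / max((l - c).sum(), 1e-300)
    best = None
    for k0 in (1.0, 5.0, 100.0):
        res = minimize(nll, [np.log(t0), np.log(k0)], method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    t_m, k = np.exp(best.x)
    k = min(k, _K_MAX)
    ll = -best.fun
    flags = []
    if k >= _K_MAX * 0.99:
        flags.append("indistinguishable from single pulse")

    # profile-likelihood CI for t_m
    def prof(log_tm: float) -> float:
        r = minimize_scalar(
            lambda lk: -float(extended_pulse_logpdf(
                l, np.exp(log_tm), np.exp(lk), c).sum()),
            bounds=(np.log(1e-2), np.log(_K_MAX)), method="bounded")
        return -r.fun

    thr = ll - chi2.ppf(0.95, 1) / 2.0
    lo, hi = t_m, t_m
    for sign in (-1, 1):
        step = 0.02
        x = np.log(t_m)
        while step > 1e-4:
            if prof(x + sign * step) >= thr:
                x += sign * step
                if abs(x - np.log(t_m)) > 3:  # runaway: flat profile
                    break
            else:
                step /= 2
        if sign < 0:
            lo = float(np.exp(x))
        else:
            hi = float(np.exp(x))
    return PulseFit("extended", float(t_m), (lo, hi), float(ll), n, cutoff_cM,
                    n_params=2, params={"k": float(k)}, flags=flags)


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def select_pulse_model(fits: list[PulseFit], lengths_cM=None,
                       n_boot: int = 0, seed: int = 0) -> dict:
    """Pick a tract-length model by BIC (ties within 2 go to the simpler).

    With ``n_boot`` > 0 and the data supplied, also runs a parametric-
    bootstrap likelihood-ratio test of single vs two-pulse.
    """
    ns = {f.n for f in fits}
    cs = {f.cutoff_cM for f in fits}
    if len(ns) != 1 or len(cs) != 1:
        raise PaleopulseError("fits compare different data or cutoffs")
    n = ns.pop()
    bic = {f.kind: -2 * f.loglik + f.n_params * np.log(n) for f in fits}
    order = sorted(fits, key=lambda f: (bic[f.kind], f.n_params))
    chosen = order[0]
    for f in order[1:]:
        if bic[f.kind] - bic[chosen.kind] < 2 and f.n_params < chosen.n_params:
            chosen = f
    out = {"model": chosen.kind, "bic": bic}

    if n_boot and lengths_cM is not None:
        by_kind = {f.kind: f for f in fits}
        if "single" in by_kind and "two" in by_kind:
            f1, f2 = by_kind["single"], by_kind["two"]
            obs = 2 * (f2.loglik - f1.loglik)
            rng = np.random.default_rng(seed)
            cutoff = f1.cutoff_cM
            null = np.empty(n_boot)
            for b in range(n_boot):
                sim = cutoff + rng.exponential(100.0 / f1.t_hat, n)
                s1 = fit_single_pulse(sim, cutoff)
                s2 = fit_two_pulse_mixture(sim, cutoff, seed=int(rng.integers(2 ** 31)))
                null[b] = 2 * (s2.loglik - s1.loglik)
            out["lrt_p"] = float((1 + np.sum(null >= obs)) / (n_boot + 1))
    return out


# ---------------------------------------------------------------------------
# Longest-segment decay curve
# ---------------------------------------------------------------------------

def decay_curve_longest(segments: SegmentSet | np.ndarray,
                        n_top: int = 100) -> tuple[PulseFit, pd.DataFrame]:
    """Date from the ``n_top`` longest segments only.

    The cutoff is set at the shortest of the selected segments; by
    exponential memorylessness the excesses above it are again Exp(t).
    Also returns the empirical survival curve of the selected lengths.
    """
    lengths = (segments.lengths_cM if isinstance(segments, SegmentSet)
               else np.asarray(segments, float))
    if lengths.size < n_top:
        raise PaleopulseError(
            f"only {lengths.size} segments (< n_top={n_top}); lower n_top")
    top = np.sort(lengths)[-n_top:]
    c_star = float(top[0])
    if np.allclose(top, c_star):
        raise PaleopulseError("all selected lengths equal; zero excess mass")
    fit = fit_single_pulse(top, cutoff_cM=c_star)
    fit.kind = "longest"
    srt = np.sort(top)
    curve = pd.DataFrame({
        "length_cM": srt,
        "survival": 1.0 - np.arange(n_top) / n_top,
    })
    return fit, curve


# ---------------------------------------------------------------------------
# Segment-free covariance dating
# ---------------------------------------------------------------------------

def date_by_ancestry_covariance(track, bin_cM: float = 0.05,
                                max_cM: float = 20.0, min_cM: float = 0.05,
                                n_boot: int = 200, seed: int = 0,
                                min_sites: int = 10_000) -> PulseFit:
    """Date admixture from the decay of ancestry-dosage autocovariance.

    The dosage track is averaged onto a uniform ``bin_cM`` grid per
    chromosome; the autocovariance at genetic distance d is fitted as
    A exp(-t d) + B (d in Morgans) by weighted least squares, with the
    affine term B absorbing background ancestry structure.  The CI is a
    chromosome-resampling bootstrap.
    """
    df = track.df[track.df["informative"]] if hasattr(track, "df") else track
    if len(df) < min_sites:
        raise PaleopulseError(f"need >= {min_sites} decoded sites, got {len(df)}")
    max_lag = int(round(max_cM / bin_cM))
    min_lag = max(1, int(round(min_cM / bin_cM)))
    grand_mean = float(df["dosage"].mean())

    # per-chromosome lagged products and pair counts, once, via FFT
    # (missing bins enter as zeros with a 0/1 mask)
    chrom_stats = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        cm = grp["cM"].to_numpy(float)
        dos = grp["dosage"].to_numpy(float)
        idx = np.floor(cm / bin_cM).astype(int)
        nb = idx.max() + 1
        s = np.bincount(idx, weights=dos, minlength=nb)
        cnt = np.bincount(idx, minlength=nb)
        mask = (cnt > 0).astype(float)
        grid = np.zeros(nb)
        grid[cnt > 0] = s[cnt > 0] / cnt[cnt > 0] - grand_mean
        nfft = 1 << int(np.ceil(np.log2(2 * nb)))
        fx = np.fft.rfft(grid, nfft)
        fm = np.fft.rfft(mask, nfft)
        num = np.fft.irfft(fx * np.conj(fx), nfft)[: max_lag + 1]
        den = np.fft.irfft(fm * np.conj(fm), nfft)[: max_lag + 1]
        chrom_stats[chrom] = (num, np.round(den))

    def cov_curve(chroms) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        num = np.zeros(max_lag + 1)
        cnt = np.zeros(max_lag + 1)
        for ch in chroms:
            n, c = chrom_stats[ch]
            num[: n.size] += n
            cnt[: c.size] += c
        lags = np.nonzero(cnt)[0]
        lags = lags[lags >= min_lag]
        return lags, num[lags] / cnt[lags], cnt[lags]

    def fit_t(chroms):
        lags, cov, w = cov_curve(chroms)
        d = lags * bin_cM / 100.0
        # signal check: covariance must actually decay with distance
        r = np.corrcoef(d, cov)[0, 1]
        A0 = max(cov[: max(3, len(cov) // 20)].mean(), 1e-8)
        try:
            popt, _ = curve_fit(
                lambda x, A, t, B: A * np.exp(-t * x) + B, d, cov,
                p0=[A0, 80.0, 0.0], sigma=1.0 / np.sqrt(w), maxfev=20000)
        except RuntimeError as err:
            raise PaleopulseError(f"no datable signal: fit failed ({err})")
        A, t, B = popt
        if A <= 0 or t <= 0 or r > -0.05:
            raise PaleopulseError("no datable signal: covariance curve is flat")
        return float(t), (d, cov)

    chroms = list(chrom_stats)
    t_hat, _ = fit_t(chroms)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        pick = rng.choice(len(chroms), len(chroms), replace=True)
        try:
            tb, _ = fit_t([chroms[i] for i in pick])
            boots.append(tb)
        except PaleopulseError:
            continue
    if len(boots) >= 20:
        lo, hi = np.percentile(boots, [2.5, 97.5])
        lo, hi = min(lo, t_hat), max(hi, t_hat)
    else:
        lo, hi = t_hat, t_hat
    return PulseFit("covariance", t_hat, (float(lo), float(hi)), 0.0,
                    int(len(df)), 0.0, n_params=3)


# ---------------------------------------------------------------------------
# Calendar propagation
# ---------------------------------------------------------------------------

def generations_to_calendar(g_interval: tuple[float, float],
                            generation_time_years: float = 29.0,
                            radiocarbon_interval: tuple[float, float] = (43_400.0, 46_580.0),
                            ) -> CalendarInterval:
    """Propagate a generation interval to a calendar date in years cal BP.

    low = r_low + g_low * gt and high = r_high + g_high * gt: the admixture
    happened between ``g`` generations before the older and younger bounds
    of the sample's radiocarbon date.
    """
    g_lo, g_hi = g_interval
    r_lo, r_hi = radiocarbon_interval
    if g_lo < 0 or g_hi < 0:
        raise PaleopulseError("generation counts must be non-negative")
    if g_lo > g_hi or r_lo > r_hi or generation_time_years <= 0:
        raise PaleopulseError("intervals must be ordered and gt positive")
    return CalendarInterval(
        low=r_lo + g_lo * generation_time_years,
        high=r_hi + g_hi * generation_time_years,
        g_interval=(g_lo, g_hi),
        generation_time=generation_time_years,
        radiocarbon_interval=(r_lo, r_hi),
    )


def union_of_intervals(intervals: list[tuple[float, float]]) -> tuple[float, float]:
    """Union (min low, max high) of CIs from several dating methods."""
    if not intervals:
        raise PaleopulseError("empty interval list")
    return (min(i[0] for i in intervals), max(i[1] for i in intervals))
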