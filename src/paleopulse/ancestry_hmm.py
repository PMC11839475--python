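"""Diploid three-source local-ancestry HMM.

Decodes low-coverage read counts (or genotypes) at ascertained sites into the
six unordered diploid ancestry states AFR, NEA, DEN, AFRNEA, AFRDEN and
NEADEN.  The two haplotypes follow independent continuous-time Markov chains
along the genetic map, each reverting toward the stationary source weights
``q`` at switch rate ``rho`` per Morgan; the diploid process is their
composition, decoded on the ordered 3x3 state space and collapsed to the six
unordered states.

Emissions marginalize the latent diploid genotype: each haplotype's allele is
Bernoulli in its source's panel frequency, and each read is a contaminant
with fixed probability (drawing from the contaminant frequency ``f_c``) or an
endogenous copy of a random haplotype allele, with a symmetric base-error
flip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize
from scipy.stats import binom

from .core_genome import ANCESTRY_STATES, GeneticMap, PaleopulseError, SegmentSet, SiteTable

logger = logging.getLogger("paleopulse")

_SOURCES = ("AFR", "NEA", "DEN")
_FREQ_COLS = ("f_AFR", "f_NEA", "f_DEN")
# unordered-state -> ordered index pairs in the 3x3 representation
_UNORDERED = {
    "AFR": [(0, 0)], "NEA": [(1, 1)], "DEN": [(2, 2)],
    "AFRNEA": [(0, 1), (1, 0)], "AFRDEN": [(0, 2), (2, 0)],
    "NEADEN": [(1, 2), (2, 1)],
}


@dataclass
class HmmParams:
    """Stationary source weights, switch rate and nuisance parameters.

    ``q`` orders as (AFR, NEA, DEN) and must sum to 1; ``rho`` is the
    per-haplotype switch rate toward ``q`` per Morgan (for a single admixture
    pulse t generations ago, rho = t).
    """

    q: tuple[float, float, float] = (0.97, 0.03, 0.0)
    rho: float = 80.0
    error_rate: float = 0.001
    contamination: float = 0.0

    def __post_init__(self) -> None:
        q = np.asarray(self.q, float)
        if q.min() < 0 or abs(q.sum() - 1) > 1e-8:
            raise PaleopulseError("q must be non-negative and sum to 1")
        if self.rho <= 0:
            raise PaleopulseError("switch rate rho must be positive")
        if not (0 <= self.contamination < 1):
            raise PaleopulseError("contamination must be in [0, 1)")


@dataclass
class PosteriorTrack:
    """Per-site posterior over the six states plus the NEA dosage.

    ``df`` has columns chrom, pos, cM, informative, the six state labels and
    ``dosage`` = P(NEA) + (P(AFRNEA) + P(NEADEN))/2.
    """

    df: pd.DataFrame
    loglik: float
    params: HmmParams

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# Emissions
# ---------------------------------------------------------------------------

def _genotype_likelihoods(sites: SiteTable, params: HmmParams) -> np.ndarray:
    """Per-site likelihood of the data given diploid source-genotype g=0,1,2.

    Shape (n, 3); missing sites get 1 for every g.
    """
    n = len(sites)
    df = sites.df
    e = params.error_rate
    c = params.contamination
    out = np.ones((n, 3))
    if sites.has_reads:
        n_tot = df["n_total"].to_numpy(int)
        n_der = df["n_der"].to_numpy(int)
        has = n_tot > 0
        f_c = df["f_c"].to_numpy(float)
        for g in range(3):
            p_read = (1 - c) * ((g / 2) * (1 - e) + (1 - g / 2) * e) \
                + c * (f_c * (1 - e) + (1 - f_c) * e)
            out[has, g] = binom.pmf(n_der[has], n_tot[has], p_read[has])
    elif sites.has_genotypes:
        gt = df["gt"].to_numpy(int)
        has = gt >= 0
        for g in range(3):
            out[has, g] = np.where(gt[has] == g, 1.0, 1e-12)
    else:
        raise PaleopulseError("site table carries neither read counts nor genotypes")
    if (~np.isfinite(out)).any():
        raise PaleopulseError("non-finite genotype likelihood encountered")
    return out


def _ordered_emissions(sites: SiteTable, params: HmmParams) -> np.ndarray:
    """Linear-scale emission likelihoods on the ordered 3x3 state space.

    For ordered sources (a, b) the latent haplotype alleles are independent
    Bernoulli(f_a), Bernoulli(f_b); the genotype-level likelihood is mixed
    over the implied genotype distribution.
    """
    df = sites.df
    for col in _FREQ_COLS:
        bad = df[col].isna().to_numpy()
        if sites.has_reads:
            bad &= df["n_total"].to_numpy() > 0
        if bad.any():
            i = int(np.nonzero(bad)[0][0])
            raise PaleopulseError(
                f"site {df['chrom'].iloc[i]}:{df['pos'].iloc[i]} has data but "
                f"missing panel frequency {col}")
    F = df[list(_FREQ_COLS)].to_numpy(float)          # (n, 3)
    Lg = _genotype_likelihoods(sites, params)          # (n, 3)
    fa = F[:, :, None]                                 # (n, 3, 1)
    fb = F[:, None, :]                                 # (n, 1, 3)
    w0 = (1 - fa) * (1 - fb)
    w1 = fa * (1 - fb) + (1 - fa) * fb
    w2 = fa * fb
    em = (w0 * Lg[:, None, None, 0]
          + w1 * Lg[:, None, None, 1]
          + w2 * Lg[:, None, None, 2])
    return em


def emission_loglik(sites: SiteTable, params: HmmParams) -> pd.DataFrame:
    """Per-site x per-state (six unordered states) log-likelihood table."""
    em = _ordered_emissions(sites, params)
    out = sites.df[["chrom", "pos", "cM"]].copy()
    for state in ANCESTRY_STATES:
        # emission is symmetric in the ordering, so any representative works
        i, j = _UNORDERED[state][0]
        out[state] = np.log(np.maximum(em[:, i, j], 1e-300))
    return out


# ---------------------------------------------------------------------------
# Forward-backward (numba)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fb_core(em, decay, q):  # pragma: no cover - exercised via decode_posterior
    """Scaled forward-backward on the factorized 3x3 chain.

    em: (n,3,3) linear emissions (pre-scaled); decay[i] = exp(-rho*d_i) is the
    self-retention probability from site i-1 to site i (decay[0] unused).
    Returns (posterior (n,3,3), log-likelihood of the scaled emissions).
    """
    n = em.shape[0]
    alpha = np.empty((n, 3, 3))
    scales = np.empty(n)

    a0 = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            a0[i, j] = q[i] * q[j] * em[0, i, j]
    s = a0.sum()
    scales[0] = s
    alpha[0] = a0 / s

    P = np.empty((3, 3))
    for t in range(1, n):
        dc = decay[t]
        for i in range(3):
            for j in range(3):
                P[i, j] = (1 - dc) * q[j]
                if i == j:
                    P[i, j] += dc
        # pred = P^T @ alpha[t-1] @ P
        tmp = P.T @ alpha[t - 1] @ P
        at = tmp * em[t]
        s = at.sum()
        scales[t] = s
        alpha[t] = at / s

    beta = np.ones((3, 3))
    post = np.empty((n, 3, 3))
    post[n - 1] = alpha[n - 1] * beta
    post[n - 1] /= post[n - 1].sum()
    for t in range(n - 2, -1, -1):
        dc = decay[t + 1]
        for i in range(3):
            for j in range(3):
                P[i, j] = (1 - dc) * q[j]
                if i == j:
                    P[i, j] += dc
        eb = em[t + 1] * beta
        beta = (P @ eb @ P.T) / scales[t + 1]
        pt = alpha[t] * beta
        post[t] = pt / pt.sum()

    ll = 0.0
    for t in range(n):
        ll += np.log(scales[t])
    return post, ll


@njit(cache=True)
def _viterbi_core(logem, decay, logq):  # pragma: no cover
    """Max log-probability of any state path (9 ordered states)."""
    n = logem.shape[0]
    v = np.empty(9)
    for i in range(3):
        for j in range(3):
            v[3 * i + j] = logq[i] + logq[j] + logem[0, i, j]
    lp = np.empty((9, 9))
    for t in range(1, n):
        dc = decay[t]
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    for l in range(3):
                        p1 = (1 - dc) * np.exp(logq[k]) + (dc if i == k else 0.0)
                        p2 = (1 - dc) * np.exp(logq[l]) + (dc if j == l else 0.0)
                        lp[3 * i + j, 3 * k + l] = (
                            np.log(max(p1 * p2, 1e-300)))
        vn = np.full(9, -np.inf)
        for s2 in range(9):
            best = -np.inf
            for s1 in range(9):
                cand = v[s1] + lp[s1, s2]
                if cand > best:
                    best = cand
            vn[s2] = best + logem[t, s2 // 3, s2 % 3]
        v = vn
    return v.max()


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def decode_posterior(sites: SiteTable, params: HmmParams) -> PosteriorTrack:
    """Forward-backward posterior decoding of the six-state diploid HMM."""
    em = _ordered_emissions(sites, params)
    scale = em.reshape(len(em), -1).max(axis=1)
    if np.any(scale <= 0) or not np.all(np.isfinite(scale)):
        i = int(np.nonzero(~((scale > 0) & np.isfinite(scale)))[0][0])
        raise PaleopulseError(
            f"non-finite emission at site "
            f"{sites.df['chrom'].iloc[i]}:{sites.df['pos'].iloc[i]}")
    em_scaled = em / scale[:, None, None]
    q = np.asarray(params.q, float)

    df = sites.df
    posts = []
    loglik = 0.0
    for chrom, idx in df.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        cm = df.loc[idx, "cM"].to_numpy(float)
        d = np.diff(cm, prepend=cm[0]) / 100.0  # Morgans
        decay = np.exp(-params.rho * np.maximum(d, 0.0))
        post, ll = _fb_core(em_scaled[idx], decay, q)
        loglik += ll + np.log(scale[idx]).sum()
        posts.append(post)
    post = np.concatenate(posts, axis=0)

    out = df[["chrom", "pos", "cM"]].copy()
    if sites.has_reads:
        out["informative"] = df["n_total"].to_numpy() > 0
    else:
        out["informative"] = df["gt"].to_numpy() >= 0
    for state, pairs in _UNORDERED.items():
        out[state] = sum(post[:, i, j] for i, j in pairs)
    out["dosage"] = out["NEA"] + 0.5 * (out["AFRNEA"] + out["NEADEN"])
    return PosteriorTrack(out, float(loglik), params)


def viterbi_loglik(sites: SiteTable, params: HmmParams) -> float:
    """Log-probability of the best single state path (for diagnostics)."""
    em = _ordered_emissions(sites, params)
    logem = np.log(np.maximum(em, 1e-300))
    q = np.asarray(params.q, float)
    logq = np.log(np.maximum(q, 1e-300))
    df = sites.df
    total = 0.0
    for chrom, idx in df.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        cm = df.loc[idx, "cM"].to_numpy(float)
        d = np.diff(cm, prepend=cm[0]) / 100.0
        decay = np.exp(-params.rho * np.maximum(d, 0.0))
        total += _viterbi_core(logem[idx], decay, logq)
    return float(total)


# ---------------------------------------------------------------------------
# Segment calling
# ---------------------------------------------------------------------------

def call_segments(track: PosteriorTrack, threshold: float = 0.8,
                  min_len_cM: float = 0.05, max_gap_cM: float = 0.05,
                  sample: str = "sample0") -> SegmentSet:
    """Call NEA-containing segments from the posterior track.

    Maximal runs of sites where P(state contains NEA) > ``threshold`` become
    segments; runs separated by gaps <= ``max_gap_cM`` merge; segments
    shorter than ``min_len_cM`` are dropped.  Segment boundaries sit at the
    genetic midpoints between the flanking sites; the label is the modal
    argmax state within the run and the posterior is the mean NEA-containing
    probability.
    """
    df = track.df
    recs = []
    state_cols = list(ANCESTRY_STATES)
    for chrom, grp in df.groupby("chrom", sort=False):
        cm = grp["cM"].to_numpy(float)
        pos = grp["pos"].to_numpy(float)
        p_nea = (grp["NEA"] + grp["AFRNEA"] + grp["NEADEN"]).to_numpy(float)
        hot = p_nea > threshold
        if not hot.any():
            continue
        # run boundaries (midpoints between flanking sites, clamped at ends)
        edges = np.nonzero(np.diff(np.concatenate([[0], hot.view(np.int8), [0]])))[0]
        starts_i, ends_i = edges[0::2], edges[1::2] - 1
        runs = []
        for si, ei in zip(starts_i, ends_i):
            s_cm = cm[si] if si == 0 else (cm[si - 1] + cm[si]) / 2
            e_cm = cm[ei] if ei == len(cm) - 1 else (cm[ei] + cm[ei + 1]) / 2
            s_bp = pos[si] if si == 0 else (pos[si - 1] + pos[si]) / 2
            e_bp = pos[ei] if ei == len(cm) - 1 else (pos[ei] + pos[ei + 1]) / 2
            runs.append([s_cm, e_cm, s_bp, e_bp, si, ei])
        merged = [runs[0]]
        for r in runs[1:]:
            if r[0] - merged[-1][1] <= max_gap_cM:
                merged[-1][1], merged[-1][3], merged[-1][5] = r[1], r[3], r[5]
            else:
                merged.append(r)
        sub = grp[state_cols].to_numpy(float)
        for s_cm, e_cm, s_bp, e_bp, si, ei in merged:
            if e_cm - s_cm < min_len_cM:
                continue
            states = np.asarray(state_cols)[np.argmax(sub[si:ei + 1], axis=1)]
            nea_states = states[np.isin(states, ["NEA", "AFRNEA", "NEADEN"])]
            label = (pd.Series(nea_states).mode().iloc[0]
                     if nea_states.size else "AFRNEA")
            recs.append((chrom, int(s_bp), max(int(e_bp), int(s_bp) + 1),
                         s_cm, e_cm, label, sample,
                         float(p_nea[si:ei + 1].mean())))
    cols = ["chrom", "start_bp", "end_bp", "start_cM", "end_cM",
            "state", "sample", "posterior"]
    return SegmentSet(pd.DataFrame(recs, columns=cols), "ancestry")


# ---------------------------------------------------------------------------
# Genome-wide proportion
# ---------------------------------------------------------------------------

def ancestry_proportion(track: PosteriorTrack, block_cM: float = 5.0,
                        n_boot: int = 1000, seed: int = 0,
                        min_sites: int = 100) -> dict:
    """Genome-wide mean NEA dosage with a moving-block bootstrap 95% CI.

    Sites are grouped into contiguous ``block_cM`` blocks along each
    chromosome; blocks are resampled with replacement ``n_boot`` times.
    """
    df = track.df[track.df["informative"]]
    if len(df) < min_sites:
        raise PaleopulseError(
            f"only {len(df)} informative sites (need >= {min_sites})")
    est = float(df["dosage"].mean())

    blocks = []
    for chrom, grp in df.groupby("chrom", sort=False):
        cm = grp["cM"].to_numpy(float)
        bidx = np.floor((cm - cm[0]) / block_cM).astype(int)
        for b in np.unique(bidx):
            blocks.append(grp["dosage"].to_numpy(float)[bidx == b])
    rng = np.random.default_rng(seed)
    n_blocks = len(blocks)
    means = np.empty(n_boot)
    for i in range(n_boot):
        pick = rng.integers(0, n_blocks, n_blocks)
        cat = np.concatenate([blocks[j] for j in pick])
        means[i] = cat.mean()
    lo, hi = np.percentile(means, [2.5, 97.5])
    return {"proportion": est, "ci": (float(lo), float(hi)),
            "n_sites": int(len(df)), "n_blocks": n_blocks}


# ---------------------------------------------------------------------------
# Desert overlap
# ---------------------------------------------------------------------------

def desert_overlap(segments: SegmentSet, deserts: list[tuple],
                   gmap: GeneticMap | None = None) -> pd.DataFrame:
    """Overlap of NEA-containing segments with archaic-ancestry deserts.

    ``deserts`` is a list of ``(chrom, start_bp, end_bp)`` intervals (from
    external catalogues).  Returns one row per desert with the total
    overlapping segment length (bp and, if a map is given, cM) and the
    number of overlapping records.
    """
    rows = []
    seg = segments.df[segments.df["state"].isin(["NEA", "AFRNEA", "NEADEN"])]
    for k, desert in enumerate(deserts):
        if len(desert) != 3 or desert[1] >= desert[2]:
            raise PaleopulseError(f"malformed desert interval {desert!r}")
        chrom, d_s, d_e = desert
        sub = seg[seg["chrom"] == chrom]
        s = np.maximum(sub["start_bp"].to_numpy(float), d_s)
        e = np.minimum(sub["end_bp"].to_numpy(float), d_e)
        ov = np.maximum(e - s, 0.0)
        hit = ov > 0
        ov_cm = np.nan
        if gmap is not None and hit.any():
            ov_cm = float(np.sum(
                np.asarray(gmap.bp_to_cM(chrom, e[hit]))
                - np.asarray(gmap.bp_to_cM(chrom, s[hit]))))
        elif gmap is not None:
            ov_cm = 0.0
        rows.append({"desert": k, "chrom": chrom, "start_bp": d_s, "end_bp": d_e,
                     "overlap_bp": float(ov.sum()), "overlap_cM": ov_cm,
                     "n_segments": int(hit.sum())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Parameter fitting
# ---------------------------------------------------------------------------

def fit_hmm_params(sites: SiteTable, error_rate: float = 0.001,
                   contamination: float = 0.0,
                   q_nea_grid=(0.01, 0.02, 0.03, 0.05),
                   rho_grid=(40.0, 80.0, 160.0)) -> HmmParams:
    """Fit (q_NEA, rho) by coarse grid search plus Nelder-Mead refinement.

    q_DEN is held at 0 (single archaic source); for a three-source fit,
    extend the grid.  Deterministic given the grids.
    """
    def ll(qn: float, rho: float) -> float:
        p = HmmParams(q=(1 - qn, qn, 0.0), rho=rho,
                      error_rate=error_rate, contamination=contamination)
        return decode_posterior(sites, p).loglik

    best = max(((ll(qn, r), qn, r) for qn in q_nea_grid for r in rho_grid))
    _, qn0, r0 = best

    def neg(x):
        qn = 1 / (1 + np.exp(-x[0]))
        rho = np.exp(x[1])
        return -ll(qn, rho)

    res = minimize(neg, [np.log(qn0 / (1 - qn0)), np.log(r0)],
                   method="Nelder-Mead",
                   options={"xatol": 1e-3, "fatol": 1e-3, "maxiter": 200})
    qn = float(1 / (1 + np.exp(-res.x[0])))
    rho = float(np.exp(res.x[1]))
    return HmmParams(q=(1 - qn, qn, 0.0), rho=rho,
                     error_rate=error_rate, contamination=contamination)
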