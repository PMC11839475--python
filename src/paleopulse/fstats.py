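"""f3/f4/D statistics with weighted block jackknife, f4-ratio, and 1-f3 MDS.

All statistics act on a site x population allele-frequency table (a
DataFrame with ``chrom`` and ``pos`` columns plus one column per
population; pseudo-haploid data are frequencies in {0, 1}).  Standard
errors come from a weighted delete-one block jackknife in physical blocks
(default 5 Mb), weights proportional to per-block site counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_genome import PaleopulseError

logger = logging.getLogger("paleopulse")


@dataclass(frozen=True)
class StatResult:
    """An f/D statistic with jackknife SE and Z score."""

    label: str
    pops: tuple
    value: float
    se: float
    z: float
    n_blocks: int
    n_sites: int


# ---------------------------------------------------------------------------
# Jackknife machinery
# ---------------------------------------------------------------------------

def weighted_block_jackknife(full: float, loo: np.ndarray,
                             m_j: np.ndarray) -> float:
    """Weighted delete-one-block jackknife SE (Busing et al. 1999).

    ``full`` is the all-data estimate, ``loo[j]`` the estimate with block j
    removed, and ``m_j`` the block weights (site counts).
    """
    loo = np.asarray(loo, float)
    m_j = np.asarray(m_j, float)
    g = len(loo)
    if g < 2:
        raise PaleopulseError("need at least 2 blocks for a jackknife SE")
    n = m_j.sum()
    h = n / m_j
    theta_j = g * full - np.sum((1 - m_j / n) * loo)
    tau = h * full - (h - 1) * loo
    var = np.sum((tau - theta_j) ** 2 / (h - 1)) / g
    return float(np.sqrt(var))


def _block_index(df: pd.DataFrame, block_bp: float) -> np.ndarray:
    key = df["chrom"].astype(str) + ":" + \
        (df["pos"] // int(block_bp)).astype(int).astype(str)
    _, idx = np.unique(key.to_numpy(), return_inverse=True)
    return idx


def _ratio_of_sums_jackknife(num: np.ndarray, den: np.ndarray,
                             blocks: np.ndarray) -> tuple[float, float, int]:
    """Full estimate and jackknife SE of sum(num)/sum(den) over blocks."""
    nb = blocks.max() + 1
    num_b = np.bincount(blocks, weights=num, minlength=nb)
    den_b = np.bincount(blocks, weights=den, minlength=nb)
    m_b = np.bincount(blocks, minlength=nb).astype(float)
    tot_n, tot_d = num_b.sum(), den_b.sum()
    if tot_d == 0:
        raise PaleopulseError("no informative sites")
    full = tot_n / tot_d
    keep = den_b != tot_d  # guard against a single all-mass block
    loo = (tot_n - num_b[keep]) / (tot_d - den_b[keep])
    se = weighted_block_jackknife(full, loo, m_b[keep]) if keep.sum() >= 2 \
        else float("nan")
    return float(full), se, int(nb)


def _check_pops(freqs: pd.DataFrame, pops) -> None:
    missing = [p for p in pops if p not in freqs.columns]
    if missing:
        raise PaleopulseError(f"populations absent from table: {missing}")


# ---------------------------------------------------------------------------
# D statistic
# ---------------------------------------------------------------------------

def compute_d(freqs: pd.DataFrame, pops: tuple, block_bp: float = 5e6
              ) -> StatResult:
    """D(P1, P2; P3, P4) = sum(BABA - ABBA) / sum(ABBA + BABA).

    Sites with missing data in any of the four populations are dropped.
    """
    _check_pops(freqs, pops)
    sub = freqs.dropna(subset=list(pops))
    p1, p2, p3, p4 = (sub[p].to_numpy(float) for p in pops)
    num = (p1 - p2) * (p3 - p4)
    den = (p1 * (1 - p2) + (1 - p1) * p2) * (p3 * (1 - p4) + (1 - p3) * p4)
    blocks = _block_index(sub, block_bp)
    d, se, nb = _ratio_of_sums_jackknife(num, den, blocks)
    z = d / se if se and se > 0 else float("nan")
    return StatResult("D", tuple(pops), d, se, z, nb, len(sub))


# ---------------------------------------------------------------------------
# f3 / f4
# ---------------------------------------------------------------------------

def _mean_stat_jackknife(vals: np.ndarray, blocks: np.ndarray
                         ) -> tuple[float, float, int]:
    den = np.ones_like(vals)
    return _ratio_of_sums_jackknife(vals, den, blocks)


def compute_f3(freqs: pd.DataFrame, outgroup: str, x: str, y: str,
               block_bp: float = 5e6) -> StatResult:
    """Outgroup f3(O; X, Y) = mean over sites of (o - x)(o - y)."""
    _check_pops(freqs, (outgroup, x, y))
    sub = freqs.dropna(subset=[outgroup, x, y])
    vals = (sub[outgroup].to_numpy(float) - sub[x].to_numpy(float)) * \
           (sub[outgroup].to_numpy(float) - sub[y].to_numpy(float))
    f3, se, nb = _mean_stat_jackknife(vals, _block_index(sub, block_bp))
    z = f3 / se if se and se > 0 else float("nan")
    return StatResult("f3", (outgroup, x, y), f3, se, z, nb, len(sub))


def f3_matrix(freqs: pd.DataFrame, pops: list[str], outgroup: str,
              block_bp: float = 5e6) -> pd.DataFrame:
    """Symmetric outgroup-f3 matrix over all population pairs."""
    mat = pd.DataFrame(np.nan, index=pops, columns=pops, dtype=float)
    for i, x in enumerate(pops):
        for y in pops[i:]:
            val = compute_f3(freqs, outgroup, x, y, block_bp).value
            mat.loc[x, y] = val
            mat.loc[y, x] = val
    return mat


def compute_f4(freqs: pd.DataFrame, pops: tuple, block_bp: float = 5e6
               ) -> StatResult:
    """f4(A, B; C, D) = mean over sites of (a - b)(c - d)."""
    _check_pops(freqs, pops)
    sub = freqs.dropna(subset=list(pops))
    a, b, c, d = (sub[p].to_numpy(float) for p in pops)
    vals = (a - b) * (c - d)
    f4, se, nb = _mean_stat_jackknife(vals, _block_index(sub, block_bp))
    z = f4 / se if se and se > 0 else float("nan")
    return StatResult("f4", tuple(pops), f4, se, z, nb, len(sub))


def f4_ratio(freqs: pd.DataFrame, num_pops: tuple, den_pops: tuple,
             block_bp: float = 5e6) -> StatResult:
    """Ancestry proportion alpha = f4(num) / f4(den), jackknifed as a ratio.

    Errors out when the denominator f4 is within 3 SE of zero.
    """
    den_stat = compute_f4(freqs, den_pops, block_bp)
    if not np.isfinite(den_stat.z) or abs(den_stat.z) < 3:
        raise PaleopulseError(
            f"ratio undefined: denominator f4 Z = {den_stat.z:.2f} (|Z| < 3)")
    _check_pops(freqs, num_pops)
    sub = freqs.dropna(subset=list(set(num_pops) | set(den_pops)))
    a, b, c, d = (sub[p].to_numpy(float) for p in num_pops)
    num = (a - b) * (c - d)
    a, b, c, d = (sub[p].to_numpy(float) for p in den_pops)
    den = (a - b) * (c - d)
    blocks = _block_index(sub, block_bp)
    alpha, se, nb = _ratio_of_sums_jackknife(num, den, blocks)
    z = alpha / se if se and se > 0 else float("nan")
    return StatResult("f4-ratio", (num_pops, den_pops), alpha, se, z, nb, len(sub))


# ---------------------------------------------------------------------------
# Pseudo-haploid sampling
# ---------------------------------------------------------------------------

def pseudo_haploid(gt: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Draw one random allele per individual at heterozygous calls.

    ``gt`` holds diploid genotypes {0, 1, 2} (NaN missing) per individual
    column; returns 0/1 pseudo-haploid calls, seeded for reproducibility.
    """
    rng = np.random.default_rng(seed)
    out = gt.copy()
    for col in gt.columns:
        v = gt[col].to_numpy(float)
        draw = rng.random(len(v))
        out[col] = np.where(np.isnan(v), np.nan,
                            np.where(v == 1, (draw < 0.5).astype(float), v / 2))
    return out


# ---------------------------------------------------------------------------
# MDS on 1 - f3
# ---------------------------------------------------------------------------

def mds_from_f3(f3_mat: pd.DataFrame) -> pd.DataFrame:
    """Classical (Torgerson) 2-D scaling of the 1 - f3 distance matrix.

    Deterministic up to the sign of each axis.
    """
    M = f3_mat.to_numpy(float)
    if not np.allclose(M, M.T, atol=1e-8):
        raise PaleopulseError("f3 matrix is not symmetric")
    D = 1.0 - M
    np.fill_diagonal(D, 0.0)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:2]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    return pd.DataFrame(coords, index=f3_mat.index, columns=["dim1", "dim2"])
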