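"""Tests for a shared introgression pulse between genomes.

Archaic segments inherited from the same admixture event sit on correlated
genomic backgrounds across carriers, because recombination has had the same
number of generations to break up the founding haplotypes.  Two
complementary statistics quantify this:

* edge sharing — the proportion of focal-segment boundaries that coincide
  (within a genetic-distance tolerance) with a segment boundary in any panel
  genome, against a circular-rotation permutation null;
* binned-indicator correlation — Pearson correlation of per-bin archaic
  presence/absence between the focal genome and each panel genome.

The rotation null preserves each panel genome's segment count and length
distribution and destroys only positional information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_genome import GenomeLayout, PaleopulseError, SegmentSet

logger = logging.getLogger("paleopulse")

_NEA_STATES = ("NEA", "AFRNEA", "NEADEN")


@dataclass
class SharingResult:
    """Sharing evidence between a focal genome and a panel."""

    proportion: float | None = None
    null_mean: float | None = None
    p_value: float | None = None
    r_focal: dict = field(default_factory=dict)     # panel genome -> r
    r_background: list = field(default_factory=list)


def _edges_by_chrom(segs: SegmentSet) -> dict[str, np.ndarray]:
    df = segs.df[segs.df["state"].isin(_NEA_STATES)]
    return {
        str(chrom): np.sort(np.concatenate([
            grp["start_cM"].to_numpy(float), grp["end_cM"].to_numpy(float)]))
        for chrom, grp in df.groupby("chrom", sort=False)
    }


def _circular_min_dist(query: np.ndarray, ref: np.ndarray, L: float
                       ) -> np.ndarray:
    """Min circular distance from each query edge to any reference edge."""
    if ref.size == 0:
        return np.full(query.size, np.inf)
    ref = np.sort(ref)
    idx = np.searchsorted(ref, query)
    cand = np.stack([
        np.abs(query - ref[np.clip(idx - 1, 0, ref.size - 1)]),
        np.abs(query - ref[np.clip(idx, 0, ref.size - 1)]),
    ])
    lin = cand.min(axis=0)
    wrap = np.minimum(query + (L - ref[-1]), (L - query) + ref[0])
    return np.minimum(lin, np.minimum(wrap, L - lin))


def edge_sharing(focal: SegmentSet, panel: list[SegmentSet],
                 layout: GenomeLayout, tol_cM: float = 0.1,
                 n_perm: int = 999, seed: int = 0) -> SharingResult:
    """Proportion of focal segment edges matched by any panel genome.

    An edge (segment start or end, in cM) counts as shared when some panel
    genome has an edge within ``tol_cM`` (circular genetic distance on the
    chromosome).  The null rotates every panel genome's segments by an
    independent uniform circular offset per chromosome, ``n_perm`` times;
    P = (1 + #null >= observed) / (n_perm + 1).
    """
    if tol_cM < 0:
        raise PaleopulseError("tolerance must be non-negative")
    focal_edges = _edges_by_chrom(focal)
    n_edges = sum(v.size for v in focal_edges.values())
    if n_edges == 0:
        raise PaleopulseError("focal segment set has no archaic segments")
    panel_edges = [_edges_by_chrom(p) for p in panel]
    cm_len = layout.cM_lengths

    def proportion(offsets=None) -> float:
        hit = 0
        for chrom, q in focal_edges.items():
            L = cm_len[chrom]
            matched = np.zeros(q.size, bool)
            for gi, pe in enumerate(panel_edges):
                ref = pe.get(chrom)
                if ref is None or ref.size == 0:
                    continue
                if offsets is not None:
                    ref = np.sort((ref + offsets[gi][chrom]) % L)
                matched |= _circular_min_dist(q, ref, L) <= tol_cM
            hit += int(matched.sum())
        return hit / n_edges

    obs = proportion()
    if n_perm == 0:
        return SharingResult(proportion=float(obs))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        offsets = [
            {chrom: rng.uniform(0, cm_len[chrom]) for chrom in cm_len}
            for _ in panel
        ]
        null[b] = proportion(offsets)
    p = (1 + np.sum(null >= obs)) / (n_perm + 1)
    return SharingResult(proportion=float(obs), null_mean=float(null.mean()),
                         p_value=float(p))


def _indicator(segs: SegmentSet, layout: GenomeLayout, bin_cM: float
               ) -> np.ndarray:
    parts = []
    df = segs.df[segs.df["state"].isin(_NEA_STATES)]
    for name, _bp, cm_len in layout.chromosomes:
        nb = int(np.ceil(cm_len / bin_cM))
        ind = np.zeros(nb, bool)
        grp = df[df["chrom"] == name]
        for s, e in zip(grp["start_cM"].to_numpy(float),
                        grp["end_cM"].to_numpy(float)):
            ind[int(s / bin_cM): int(np.ceil(e / bin_cM))] = True
        parts.append(ind)
    return np.concatenate(parts)


def segment_correlation(focal: SegmentSet, panel: list[SegmentSet],
                        layout: GenomeLayout, bin_cM: float = 0.1
                        ) -> SharingResult:
    """Per-bin archaic-indicator correlation of the focal genome vs a panel.

    The genome is discretized into ``bin_cM`` bins; Pearson r is computed
    between the focal indicator and each panel genome's, plus a background
    distribution from all panel-vs-panel pairs.  Constant indicators give an
    undefined r, recorded as missing (NaN).
    """
    if bin_cM <= 0:
        raise PaleopulseError("bin width must be positive")
    f_ind = _indicator(focal, layout, bin_cM).astype(float)
    p_inds = [_indicator(p, layout, bin_cM).astype(float) for p in panel]

    def corr(a, b):
        if a.std() == 0 or b.std() == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])

    r_focal = {i: corr(f_ind, p) for i, p in enumerate(p_inds)}
    r_bg = [corr(p_inds[i], p_inds[j])
            for i in range(len(p_inds)) for j in range(i + 1, len(p_inds))]
    return SharingResult(r_focal=r_focal, r_background=r_bg)
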