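"""Forward simulators with known ground truth.

Every input the pipeline consumes can be generated here: archaic-ancestry
mosaics along a genetic map, three-source reference-panel allele frequencies,
Poisson-coverage read sampling with error and contamination, pedigree-
transmitted IBD between two relatives, and pairwise-coalescent IBD/ROH in a
small constant-size population.

The simulators use a renewal (Markov) approximation along the genome rather
than a full ancestral-recombination-graph simulation: tract boundaries are
laid down as a renewal process whose rates match the marginal expectations
used by the downstream estimators.  Crossovers are Poisson without
interference.  All simulators are deterministic given (seed, parameters).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_genome import (
    GeneticMap,
    GenomeLayout,
    PaleopulseError,
    SegmentSet,
    SiteTable,
)

logger = logging.getLogger("paleopulse")


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseModel:
    """Archaic-admixture pulse model.

    kind ``single``: one admixture generation ``t_m`` ago with fraction ``m``;
    archaic tract lengths are Exp((1-m)·t_m) Morgans.  kind ``two``: tracts
    come from pulse 1 (time t1) with weight ``pi`` else pulse 2 (time t2).
    kind ``extended``: the admixture generation is Gamma(shape k, rate k/t_m)
    distributed, giving Lomax-marginal tract lengths.
    """

    kind: str = "single"
    t_m: float = 80.0
    m: float = 0.03
    t1: float | None = None
    t2: float | None = None
    pi: float | None = None
    k: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("single", "two", "extended"):
            raise PaleopulseError(f"unknown pulse kind {self.kind!r}")
        if self.t_m <= 0:
            raise PaleopulseError("t_m must be positive")
        if not (0 <= self.m < 1):
            raise PaleopulseError("admixture fraction m must be in [0, 1)")
        if self.kind == "two":
            if self.t1 is None or self.t2 is None or self.pi is None:
                raise PaleopulseError("two-pulse model needs t1, t2 and pi")
            if not (0 < self.pi < 1):
                raise PaleopulseError("pi must be in (0, 1)")
        if self.kind == "extended":
            if self.k is None or self.k <= 0:
                raise PaleopulseError("extended pulse needs shape k > 0")

    @property
    def mean_time(self) -> float:
        if self.kind == "two":
            return self.pi * self.t1 + (1 - self.pi) * self.t2
        return self.t_m


@dataclass(frozen=True)
class CoalescentScenario:
    """Constant-size pairwise-coalescent scenario over a recent horizon.

    ``n_pairs`` is 4 for two diploid genomes (all haplotype pairs) and 1 for
    within-individual ROH.  ``delta`` is the age gap in generations between
    the two samples (0 for contemporaries).
    """

    N_e: float
    G: int
    n_pairs: int = 4
    delta: int = 0

    def __post_init__(self) -> None:
        if self.N_e < 2:
            raise PaleopulseError("N_e must be at least 2")
        if self.G < 1:
            raise PaleopulseError("horizon G must be at least 1")
        if self.n_pairs not in (1, 4):
            raise PaleopulseError("n_pairs must be 1 or 4")
        if self.delta < 0:
            raise PaleopulseError("sample age gap delta must be non-negative")


# ---------------------------------------------------------------------------
# Ancestry mosaics
# ---------------------------------------------------------------------------

def _archaic_lengths(rng: np.random.Generator, model: PulseModel,
                     shape: tuple[int, int]) -> np.ndarray:
    """Draw archaic tract lengths in Morgans (one array element per tract)."""
    if model.kind == "single":
        rate = (1 - model.m) * model.t_m
        return rng.exponential(1.0 / rate, shape)
    if model.kind == "two":
        r1 = (1 - model.m) * model.t1
        r2 = (1 - model.m) * model.t2
        from1 = rng.random(shape) < model.pi
        return np.where(from1, rng.exponential(1.0 / r1, shape),
                        rng.exponential(1.0 / r2, shape))
    # extended: T ~ Gamma(k, rate k/t_m), length | T ~ Exp(T)  (Lomax marginal)
    T = rng.gamma(model.k, model.t_m / model.k, shape)
    return rng.exponential(1.0 / T)


def simulate_ancestry_mosaic(model: PulseModel, layout: GenomeLayout,
                             n_haplotypes: int, seed: int,
                             hap_prefix: str = "hap") -> SegmentSet:
    """Simulate archaic-tract mosaics for ``n_haplotypes`` haplotypes.

    Along each chromosome an alternating renewal process switches between
    modern tracts (Exp(m·t) Morgans) and archaic tracts (pulse-model
    lengths); the initial state is archaic with the stationary probability
    ``m``.  Returns the archaic tracts as an ancestry SegmentSet with state
    label ``NEA``, sample ids ``{hap_prefix}{i}``.
    """
    rng = np.random.default_rng(seed)
    gmap = GeneticMap.from_layout(layout)
    rows: list[pd.DataFrame] = []

    if model.m == 0:
        return SegmentSet(pd.DataFrame(columns=[
            "chrom", "start_bp", "end_bp", "start_cM", "end_cM",
            "state", "sample", "posterior"]), "ancestry")

    t = model.mean_time
    exp_tracts = layout.r_total * model.m * (1 - model.m) * t
    if exp_tracts < 1:
        warnings.warn(
            f"expected archaic tracts per genome is {exp_tracts:.3g} (< 1); "
            "mosaic will be mostly empty", stacklevel=2)

    mod_mean = 1.0 / (model.m * t)
    for name, _bp_len, cm_len in layout.chromosomes:
        L = cm_len / 100.0  # Morgans
        # expected pairs per chromosome, with headroom; redraw rare shortfalls
        n = n_haplotypes
        K = max(4, int(np.ceil(L / mod_mean * 1.8 + 8)))
        start_archaic = rng.random(n) < model.m
        while True:
            la = _archaic_lengths(rng, model, (n, K))
            lm = rng.exponential(mod_mean, (n, K))
            seq = np.empty((n, 2 * K))
            arch_mask = np.zeros((n, 2 * K), bool)
            sa = start_archaic[:, None]
            seq[:, 0::2] = np.where(sa, la, lm)
            seq[:, 1::2] = np.where(sa, lm, la)
            arch_mask[:, 0::2] = sa
            arch_mask[:, 1::2] = ~sa
            ends = np.cumsum(seq, axis=1)
            if ends[:, -1].min() >= L:
                break
            K *= 2  # not enough tracts drawn; retry with more
        starts = ends - seq
        keep = arch_mask & (starts < L)
        hap_idx, _ = np.nonzero(keep)
        s_cm = np.minimum(starts[keep], L) * 100.0
        e_cm = np.minimum(ends[keep], L) * 100.0
        ok = e_cm > s_cm
        rows.append(pd.DataFrame({
            "chrom": name,
            "start_cM": s_cm[ok],
            "end_cM": e_cm[ok],
            "sample": np.array([f"{hap_prefix}{i}" for i in hap_idx[ok]]),
        }))

    df = pd.concat(rows, ignore_index=True)
    df["state"] = "NEA"
    df["posterior"] = 1.0
    if not len(df):
        df["start_bp"] = pd.Series(dtype=np.int64)
        df["end_bp"] = pd.Series(dtype=np.int64)
        return SegmentSet(df, "ancestry")
    parts = []
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.copy()
        grp["start_bp"] = np.floor(gmap.cM_to_bp(chrom, grp["start_cM"].to_numpy())).astype(np.int64)
        grp["end_bp"] = np.ceil(gmap.cM_to_bp(chrom, grp["end_cM"].to_numpy())).astype(np.int64)
        parts.append(grp)
    df = pd.concat(parts, ignore_index=True)
    df = df.sort_values(["sample", "chrom", "start_bp"]).reset_index(drop=True)
    return SegmentSet(df, "ancestry")


# ---------------------------------------------------------------------------
# Panel frequencies
# ---------------------------------------------------------------------------

def simulate_panel_frequencies(n_sites: int, layout: GenomeLayout, seed: int,
                               F_AFR: float = 0.15, F_NEA: float = 0.35,
                               F_DEN: float = 0.35,
                               ascertainment_min_diff: float = 0.3) -> SiteTable:
    """Balding–Nichols panel frequencies for the three sources.

    Each site draws an ancestral frequency p ~ Uniform(0.05, 0.95) and then,
    per source s with drift parameter F_s, a frequency from
    Beta(p(1-F_s)/F_s, (1-p)(1-F_s)/F_s).  Only sites with
    ``|f_AFR - f_NEA| >= ascertainment_min_diff`` are retained, emulating an
    archaic-admixture ascertainment scheme.  Sites are placed uniformly per
    cM along the genome.  The contaminant frequency ``f_c`` defaults to the
    African panel frequency.
    """
    for name, F in (("F_AFR", F_AFR), ("F_NEA", F_NEA), ("F_DEN", F_DEN)):
        if not (0 < F < 1):
            raise PaleopulseError(f"{name} must be in (0, 1)")
    if not (0 <= ascertainment_min_diff < 1):
        raise PaleopulseError("ascertainment_min_diff must be in [0, 1)")

    rng = np.random.default_rng(seed)
    gmap = GeneticMap.from_layout(layout)

    def draw(n: int) -> pd.DataFrame:
        p = rng.uniform(0.05, 0.95, n)
        freqs = {}
        for name, F in (("f_AFR", F_AFR), ("f_NEA", F_NEA), ("f_DEN", F_DEN)):
            freqs[name] = rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F)
        df = pd.DataFrame(freqs)
        return df[np.abs(df["f_AFR"] - df["f_NEA"]) >= ascertainment_min_diff]

    first = draw(max(n_sites, 2000))
    if len(first) == 0:
        raise PaleopulseError(
            "no sites survive ascertainment; lower ascertainment_min_diff")
    rate = max(len(first) / max(n_sites, 2000), 1e-4)
    kept = [first]
    total = len(first)
    while total < n_sites:
        batch = draw(int((n_sites - total) / rate * 1.3) + 100)
        kept.append(batch)
        total += len(batch)
    df = pd.concat(kept, ignore_index=True).iloc[:n_sites].reset_index(drop=True)

    # uniform placement on the genetic map
    cm_lengths = np.array([c[2] for c in layout.chromosomes])
    chrom_idx = rng.choice(len(cm_lengths), n_sites, p=cm_lengths / cm_lengths.sum())
    cm_pos = rng.uniform(0, cm_lengths[chrom_idx])
    names = np.array(layout.names)
    df["chrom"] = names[chrom_idx]
    df["cM"] = cm_pos
    pos = np.empty(n_sites, dtype=np.int64)
    for i, name in enumerate(names):
        sel = chrom_idx == i
        if sel.any():
            pos[sel] = np.asarray(gmap.cM_to_bp(name, cm_pos[sel])).astype(np.int64)
    df["pos"] = pos
    df["anc"] = "A"
    df["der"] = "G"
    df["f_c"] = df["f_AFR"]
    df = df.drop_duplicates(["chrom", "pos"])
    return SiteTable(df)


# ---------------------------------------------------------------------------
# Read sampling
# ---------------------------------------------------------------------------

def _site_sources(sites: SiteTable, truth: SegmentSet, hap_id: str) -> np.ndarray:
    """Per-site source indicator for one haplotype: True where archaic."""
    out = np.zeros(len(sites), bool)
    seg = truth.df[truth.df["sample"] == hap_id]
    for chrom, grp in seg.groupby("chrom", sort=False):
        sel = sites.df["chrom"].to_numpy() == chrom
        if not sel.any():
            continue
        cm = sites.df.loc[sel, "cM"].to_numpy()
        starts = np.sort(grp["start_cM"].to_numpy())
        ends = np.sort(grp["end_cM"].to_numpy())
        # inside a segment iff more starts than ends at or before the site
        inside = np.searchsorted(starts, cm, "right") > np.searchsorted(ends, cm, "right")
        out[sel] = inside
    return out


def simulate_reads(sites: SiteTable, truth: SegmentSet,
                   coverage: float, error_rate: float, contamination: float,
                   seed: int, hap_ids: tuple[str, str] = ("hap0", "hap1"),
                   archaic_panel: str = "f_NEA") -> SiteTable:
    """Sample sequencing reads for one diploid over an ancestry mosaic.

    Per site the depth is Poisson(``coverage``); each read is a contaminant
    with probability ``contamination`` (derived allele with probability
    ``f_c``) and otherwise copies one of the two haplotype alleles at random;
    every read's base is flipped with probability ``error_rate``.  The two
    haplotype alleles are Bernoulli draws from the archaic panel frequency
    inside a truth tract and from ``f_AFR`` outside.  ``coverage=inf``
    switches to genotype mode and emits the true diploid genotype instead of
    reads.  Truth columns ``g_true`` (diploid source-allele genotype) and
    ``dosage_true`` (archaic haplotype dosage in [0, 1]) are carried along.
    """
    if coverage <= 0:
        raise PaleopulseError("coverage must be positive")
    if not (0 <= contamination < 1):
        raise PaleopulseError("contamination must be in [0, 1)")
    rng = np.random.default_rng(seed)
    df = sites.df.copy()
    n = len(df)

    arch = np.column_stack([_site_sources(sites, truth, h) for h in hap_ids])
    f_afr = df["f_AFR"].to_numpy()
    f_arch = df[archaic_panel].to_numpy()
    alleles = np.empty((n, 2), dtype=np.int8)
    for h in range(2):
        f = np.where(arch[:, h], f_arch, f_afr)
        alleles[:, h] = rng.random(n) < f
    g = alleles.sum(axis=1)
    df["g_true"] = g
    df["dosage_true"] = arch.mean(axis=1)

    if np.isinf(coverage):
        df["gt"] = g
        return SiteTable(df)

    depth = rng.poisson(coverage, n)
    n_cont = rng.binomial(depth, contamination)
    n_endo = depth - n_cont
    e = error_rate
    f_c = df["f_c"].to_numpy()
    p_cont = f_c * (1 - e) + (1 - f_c) * e
    p_endo = (g / 2.0) * (1 - e) + (1 - g / 2.0) * e
    df["n_der"] = rng.binomial(n_cont, p_cont) + rng.binomial(n_endo, p_endo)
    df["n_total"] = depth
    return SiteTable(df)


# ---------------------------------------------------------------------------
# Pedigree IBD
# ---------------------------------------------------------------------------

def _descend_labels(rng: np.random.Generator, L: float, n_meioses: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Trace one ancestor's material through ``n_meioses`` meioses.

    Returns breakpoints (Morgans, starting at 0, ending at L) and per-interval
    labels: 0/1 for the ancestor's two haplotypes, -1 for non-ancestral
    material.  Crossovers are Poisson(1/Morgan) per meiosis, no interference.
    """
    def crossover_mosaic() -> tuple[np.ndarray, np.ndarray]:
        k = rng.poisson(L)
        pts = np.sort(rng.uniform(0, L, k))
        breaks = np.concatenate([[0.0], pts, [L]])
        chooser = (np.arange(breaks.size - 1) + rng.integers(2)) % 2
        return breaks, chooser

    # meiosis 1: gamete is a mosaic of the ancestor's two haplotypes
    breaks, labels = crossover_mosaic()
    labels = labels.astype(np.int64)

    for _ in range(n_meioses - 1):
        cb, choose = crossover_mosaic()
        # merge breakpoints of carrier labels and the new crossover mosaic
        allb = np.union1d(breaks, cb)
        mid = (allb[:-1] + allb[1:]) / 2
        lab = labels[np.searchsorted(breaks, mid) - 1]
        ch = choose[np.searchsorted(cb, mid) - 1]
        lab = np.where(ch == 1, lab, -1)  # chooser==1 keeps the carrier
        # compress equal neighbours
        keep = np.concatenate([[True], lab[1:] != lab[:-1]])
        breaks = np.concatenate([allb[:-1][keep], [L]])
        labels = lab[keep]
    return breaks, labels


def simulate_pedigree_ibd(m: int, a: int, layout: GenomeLayout, seed: int,
                          sample: str = "pair0") -> SegmentSet:
    """IBD segments between two relatives separated by ``m`` meioses.

    The relatives are connected through ``a`` common ancestors (1 or 2); the
    path is split as evenly as possible between the two descendants and each
    ancestor's transmission is simulated explicitly.  For ``m=1`` one
    endpoint *is* the ancestor (parent–offspring): the offspring's whole
    genome is IBD, split into segments at crossovers.
    """
    if m < 1:
        raise PaleopulseError("meioses m must be >= 1")
    if a not in (1, 2):
        raise PaleopulseError("number of common ancestors a must be 1 or 2")
    rng = np.random.default_rng(seed)
    gmap = GeneticMap.from_layout(layout)
    m1, m2 = m // 2, m - m // 2
    recs: list[tuple] = []

    for name, _bp_len, cm_len in layout.chromosomes:
        L = cm_len / 100.0
        for _anc in range(a):
            b2, l2 = _descend_labels(rng, L, m2)
            if m1 == 0:
                # descendant 1 is the ancestor: IBD wherever l2 != -1,
                # broken at every label change
                starts, ends = [], []
                for i in range(l2.size):
                    if l2[i] >= 0:
                        starts.append(b2[i])
                        ends.append(b2[i + 1])
            else:
                b1, l1 = _descend_labels(rng, L, m1)
                allb = np.union1d(b1, b2)
                mid = (allb[:-1] + allb[1:]) / 2
                x1 = l1[np.searchsorted(b1, mid) - 1]
                x2 = l2[np.searchsorted(b2, mid) - 1]
                shared = (x1 == x2) & (x1 >= 0)
                starts, ends = [], []
                for i in range(shared.size):
                    if shared[i]:
                        if starts and np.isclose(ends[-1], allb[i]):
                            ends[-1] = allb[i + 1]
                        else:
                            starts.append(allb[i])
                            ends.append(allb[i + 1])
            for s, e in zip(starts, ends):
                if e > s:
                    recs.append((name, s * 100.0, e * 100.0))

    df = pd.DataFrame(recs, columns=["chrom", "start_cM", "end_cM"])
    if len(df):
        parts = []
        for chrom, grp in df.groupby("chrom", sort=False):
            grp = grp.copy()
            grp["start_bp"] = np.floor(gmap.cM_to_bp(chrom, grp["start_cM"].to_numpy())).astype(np.int64)
            grp["end_bp"] = np.ceil(gmap.cM_to_bp(chrom, grp["end_cM"].to_numpy())).astype(np.int64)
            parts.append(grp)
        df = pd.concat(parts, ignore_index=True)
    else:
        df["start_bp"] = pd.Series(dtype=np.int64)
        df["end_bp"] = pd.Series(dtype=np.int64)
    df["state"] = "IBD"
    df["sample"] = sample
    df["posterior"] = 1.0
    return SegmentSet(df, "ibd")


def expected_pedigree_ibd(m: int, a: int, layout: GenomeLayout) -> dict[str, float]:
    """Closed-form pedigree-IBD expectations.

    Total shared length a·r/2^(m-1) Morgans and segment count
    a·(r·m + c_chr)/2^(m-1), with r the genome length in Morgans and c_chr
    the chromosome count.
    """
    r, c = layout.r_total, layout.c_chr
    return {
        "total_morgans": a * r / 2 ** (m - 1),
        "count": a * (r * m + c) / 2 ** (m - 1),
    }


# ---------------------------------------------------------------------------
# Pairwise-coalescent IBD / ROH
# ---------------------------------------------------------------------------

def _draw_tilted_times(rng: np.random.Generator, n: int, p: float,
                       delta: int) -> np.ndarray:
    """Draw tract coalescence times from the length-biased tilt.

    Q(g) proportional to (2g+delta)·P(g) with P geometric(p); the g·P(g)
    component is a negative binomial (sum of two geometrics minus one).
    """
    g_nb = rng.geometric(p, n) + rng.geometric(p, n) - 1
    if delta == 0:
        return g_nb
    w_nb = (2.0 / p) / (2.0 / p + delta)
    g_plain = rng.geometric(p, n)
    return np.where(rng.random(n) < w_nb, g_nb, g_plain)


def simulate_pairwise_coalescent_segments(sc: CoalescentScenario,
                                          layout: GenomeLayout,
                                          min_len_cM: float, seed: int,
                                          sample_prefix: str = "pair"
                                          ) -> SegmentSet:
    """Recent-IBD (or ROH) segments under a constant-size renewal coalescent.

    Each haplotype pair walks every chromosome as a renewal process: a tract
    has coalescence generation g with tract-rate proportional to
    (2g+delta)·P(g) (the length-biased tilt of the geometric P(g), so the
    locus-wise marginal time is exactly geometric) and length
    Exp(2g+delta) Morgans.  Tracts with g <= G and genetic length
    >= ``min_len_cM`` are emitted; older tracts only occupy space.
    The segment kind is ``roh`` for n_pairs=1 and ``ibd`` otherwise.
    """
    if min_len_cM < 0:
        raise PaleopulseError("min_len_cM must be non-negative")
    rng = np.random.default_rng(seed)
    gmap = GeneticMap.from_layout(layout)

    p = 1.0 / (2.0 * sc.N_e)
    Z = 2.0 / p + sc.delta  # expected tracts per Morgan, E[2g + delta]
    # dense walk is infeasible for very large N: recent segments are then
    # vanishingly sparse and a thinned Poisson construction is exact enough
    sparse = Z * layout.r_total > 5e6

    kind = "roh" if sc.n_pairs == 1 else "ibd"
    state = "ROH" if kind == "roh" else "IBD"
    recs = []
    for pair in range(sc.n_pairs):
        sample = f"{sample_prefix}{pair}"
        for name, _bp, cm_len in layout.chromosomes:
            L = cm_len / 100.0
            if sparse:
                gg = np.arange(1, sc.G + 1)
                pmf = p * (1 - p) ** (gg - 1)
                lam_g = pmf * ((2 * gg + sc.delta) * L + 1)
                n_g = rng.poisson(lam_g)
                g = np.repeat(gg, n_g)
                starts = rng.uniform(0, L, g.size)
                lens = rng.exponential(1.0 / (2.0 * g + sc.delta))
                ends = np.minimum(starts + lens, L)
                emit = (ends - starts) * 100.0 >= min_len_cM
            else:
                n_draw = int(L * Z * 1.25) + 40
                # the tract covering the chromosome start is locus-marginal
                # (plain geometric time, memoryless residual length);
                # interior tracts follow the length-biased tilt
                g = np.concatenate([[rng.geometric(p)],
                                    _draw_tilted_times(rng, n_draw, p, sc.delta)])
                lens = rng.exponential(1.0 / (2.0 * g + sc.delta))
                while lens.sum() < L:  # rare shortfall
                    g2 = _draw_tilted_times(rng, n_draw, p, sc.delta)
                    g = np.concatenate([g, g2])
                    lens = np.concatenate(
                        [lens, rng.exponential(1.0 / (2.0 * g2 + sc.delta))])
                ends = np.cumsum(lens)
                starts = ends - lens
                keep = starts < L
                g, starts = g[keep], starts[keep]
                ends = np.minimum(ends[keep], L)
                emit = (g <= sc.G) & ((ends - starts) * 100.0 >= min_len_cM)
            for s, e in zip(starts[emit], ends[emit]):
                recs.append((name, s * 100.0, e * 100.0, sample))

    df = pd.DataFrame(recs, columns=["chrom", "start_cM", "end_cM", "sample"])
    if len(df):
        parts = []
        for chrom, grp in df.groupby("chrom", sort=False):
            grp = grp.copy()
            grp["start_bp"] = np.floor(gmap.cM_to_bp(chrom, grp["start_cM"].to_numpy())).astype(np.int64)
            grp["end_bp"] = np.ceil(gmap.cM_to_bp(chrom, grp["end_cM"].to_numpy())).astype(np.int64)
            parts.append(grp)
        df = pd.concat(parts, ignore_index=True)
    else:
        df["start_bp"] = pd.Series(dtype=np.int64)
        df["end_bp"] = pd.Series(dtype=np.int64)
    df["state"] = state
    df["posterior"] = 1.0
    return SegmentSet(df, kind)


def expected_segment_count(N_e: float, G: int, n_pairs: int, layout: GenomeLayout,
                           min_len_cM: float, delta: int = 0,
                           end_corrected: bool = True) -> float:
    """Closed-form expected number of emitted recent segments.

    lambda(N) = sum_{g=1..G} n_pairs · P_N(g) · ((2g+delta)·r_eff + c_chr)
                · exp(-(2g+delta)·l0)
    with r the genome length in Morgans, c_chr the chromosome count and l0
    the length cutoff in Morgans.  ``end_corrected`` uses
    r_eff = r - c_chr·l0: a tract starting within l0 of a chromosome end is
    truncated below the cutoff and never emitted.
    """
    p = 1.0 / (2.0 * N_e)
    g = np.arange(1, G + 1)
    pmf = p * (1 - p) ** (g - 1)
    rate = 2.0 * g + delta
    l0 = min_len_cM / 100.0
    r, c = layout.r_total, layout.c_chr
    r_eff = max(r - c * l0, 0.0) if end_corrected else r
    return float(n_pairs * np.sum(pmf * (rate * r_eff + c) * np.exp(-rate * l0)))
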