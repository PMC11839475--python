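"""Genome coordinate backbone: layouts, genetic maps, site tables and segment sets.

All genetic lengths are stored in centimorgans (cM) and converted to Morgans
only inside likelihood computations.  Physical coordinates are 0-based,
half-open.  Every downstream module (simulators, HMM, dating, kinship,
diversity) works on the three containers defined here:

* :class:`GenomeLayout` — the chromosomes and their physical/genetic lengths;
* :class:`SiteTable`    — ascertained biallelic sites with panel frequencies
  and per-sample read counts or genotypes;
* :class:`SegmentSet`   — typed genomic intervals (local-ancestry calls, IBD,
  ROH) with genetic lengths and posterior support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("paleopulse")

#: Diploid local-ancestry state labels: three homozygous sources and the
#: three unordered heterozygous combinations.
ANCESTRY_STATES = ("AFR", "NEA", "DEN", "AFRNEA", "AFRDEN", "NEADEN")

#: Labels allowed per segment kind.
ALLOWED_STATES = {
    "ancestry": set(ANCESTRY_STATES),
    "ibd": {"IBD"},
    "roh": {"ROH"},
}

SEGMENT_COLUMNS = [
    "chrom", "start_bp", "end_bp", "start_cM", "end_cM",
    "state", "sample", "posterior",
]


class PaleopulseError(ValueError):
    """Input-validation failure anywhere in the pipeline."""


# ---------------------------------------------------------------------------
# GenomeLayout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeLayout:
    """Ordered autosomes with physical and genetic lengths.

    Attributes
    ----------
    chromosomes:
        Ordered ``(name, bp_length, cM_length)`` triples.
    """

    chromosomes: tuple[tuple[str, int, float], ...]

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise PaleopulseError("duplicate chromosome names in layout")
        for name, bp, cm in self.chromosomes:
            if bp <= 0 or cm <= 0:
                raise PaleopulseError(
                    f"chromosome {name}: lengths must be positive (bp={bp}, cM={cm})"
                )

    @property
    def names(self) -> list[str]:
        return [c[0] for c in self.chromosomes]

    @property
    def c_chr(self) -> int:
        """Number of chromosomes."""
        return len(self.chromosomes)

    @property
    def cM_lengths(self) -> dict[str, float]:
        return {c[0]: c[2] for c in self.chromosomes}

    @property
    def bp_lengths(self) -> dict[str, int]:
        return {c[0]: c[1] for c in self.chromosomes}

    @property
    def r_total(self) -> float:
        """Total genetic length of the genome in Morgans."""
        return sum(c[2] for c in self.chromosomes) / 100.0

    @property
    def total_cM(self) -> float:
        return sum(c[2] for c in self.chromosomes)


def default_layout(n_chrom: int = 22, total_morgans: float = 35.0,
                   cm_per_mb: float = 1.0) -> GenomeLayout:
    """Toy autosomal layout used throughout the test-bed.

    22 chromosomes totalling 35 Morgans with a uniform 1 cM/Mb map; per
    chromosome lengths taper roughly like human autosomes (the i-th
    chromosome gets weight ``n_chrom + 8 - i``).
    """
    weights = np.array([n_chrom + 8 - i for i in range(1, n_chrom + 1)], float)
    cm = total_morgans * 100.0 * weights / weights.sum()
    chroms = tuple(
        (f"chr{i + 1}", int(round(cm[i] * 1e6 / cm_per_mb)), float(cm[i]))
        for i in range(n_chrom)
    )
    return GenomeLayout(chroms)


# ---------------------------------------------------------------------------
# GeneticMap
# ---------------------------------------------------------------------------

class GeneticMap:
    """Piecewise-linear bp<->cM interpolation per chromosome.

    Breakpoints are monotone in both coordinates; queries outside the mapped
    range clamp to the first/last breakpoint.
    """

    def __init__(self, breakpoints: dict[str, tuple[np.ndarray, np.ndarray]]):
        self._bp: dict[str, np.ndarray] = {}
        self._cm: dict[str, np.ndarray] = {}
        for chrom, (bp, cm) in breakpoints.items():
            bp = np.asarray(bp, float)
            cm = np.asarray(cm, float)
            if bp.size < 2:
                raise PaleopulseError(f"{chrom}: need at least two map breakpoints")
            if np.any(np.diff(bp) <= 0):
                raise PaleopulseError(f"{chrom}: bp positions not strictly increasing")
            if np.any(np.diff(cm) < 0):
                bad = int(np.where(np.diff(cm) < 0)[0][0]) + 1
                raise PaleopulseError(
                    f"{chrom}: cM not non-decreasing at breakpoint {bad} "
                    f"(bp={bp[bad]:.0f}, cM={cm[bad]})"
                )
            self._bp[chrom] = bp
            self._cm[chrom] = cm

    @classmethod
    def from_layout(cls, layout: GenomeLayout) -> "GeneticMap":
        """Uniform-rate map implied by a layout (linear bp<->cM)."""
        return cls({
            name: (np.array([0.0, bp]), np.array([0.0, cm]))
            for name, bp, cm in layout.chromosomes
        })

    @property
    def chromosomes(self) -> list[str]:
        return list(self._bp)

    def _check(self, chrom: str) -> None:
        if chrom not in self._bp:
            raise PaleopulseError(f"chromosome {chrom!r} not in genetic map")

    def bp_to_cM(self, chrom: str, bp) -> np.ndarray | float:
        self._check(chrom)
        out = np.interp(np.asarray(bp, float), self._bp[chrom], self._cm[chrom])
        return float(out) if np.isscalar(bp) or np.ndim(bp) == 0 else out

    def cM_to_bp(self, chrom: str, cm) -> np.ndarray | float:
        # np.interp needs strictly increasing x; collapse flat cM stretches.
        self._check(chrom)
        cm_arr, bp_arr = self._cm[chrom], self._bp[chrom]
        keep = np.concatenate([[True], np.diff(cm_arr) > 0])
        out = np.interp(np.asarray(cm, float), cm_arr[keep], bp_arr[keep])
        return float(out) if np.isscalar(cm) or np.ndim(cm) == 0 else out


def load_genetic_map(path: str | Path) -> GeneticMap:
    """Read a PLINK-style ``.map`` file.

    Accepts the 4-column dialect ``chrom id cM bp`` or a bare 3-column
    ``chrom bp cM``.  Chromosome blocks must be contiguous.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 4:
                chrom, _snp, cm, bp = parts
            elif len(parts) == 3:
                chrom, bp, cm = parts
            else:
                raise PaleopulseError(
                    f"{path}:{lineno}: expected 3 or 4 columns, got {len(parts)}"
                )
            rows.append((chrom, float(bp), float(cm), lineno))

    seen: list[str] = []
    for chrom, _, _, _ in rows:
        if not seen or seen[-1] != chrom:
            if chrom in seen:
                raise PaleopulseError(
                    f"{path}: chromosome {chrom} appears in non-contiguous blocks"
                )
            seen.append(chrom)

    breakpoints = {}
    for chrom in seen:
        block = [(bp, cm, ln) for c, bp, cm, ln in rows if c == chrom]
        block.sort(key=lambda r: r[0])
        bp = np.array([r[0] for r in block])
        cm = np.array([r[1] for r in block])
        dec = np.where(np.diff(cm) < 0)[0]
        if dec.size:
            ln = block[int(dec[0]) + 1][2]
            raise PaleopulseError(
                f"{path}: non-monotone cM on {chrom} at line {ln}"
            )
        breakpoints[chrom] = (bp, cm)
    return GeneticMap(breakpoints)


# ---------------------------------------------------------------------------
# SiteTable
# ---------------------------------------------------------------------------

SITE_COLUMNS = ["chrom", "pos", "cM", "anc", "der", "f_AFR", "f_NEA", "f_DEN", "f_c"]


class SiteTable:
    """Ascertained biallelic sites with panel frequencies and sample data.

    Wraps a :class:`pandas.DataFrame` with columns ``chrom, pos (0-based bp),
    cM, anc, der, f_AFR, f_NEA, f_DEN, f_c`` plus, per sample, either read
    counts ``n_der, n_total`` or a called genotype ``gt`` in {0, 1, 2} with
    -1 for missing.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in SITE_COLUMNS if c not in df.columns]
        if missing:
            raise PaleopulseError(f"site table missing columns: {missing}")
        for col in ("f_AFR", "f_NEA", "f_DEN", "f_c"):
            vals = df[col].to_numpy(float)
            if np.any((vals < 0) | (vals > 1)):
                raise PaleopulseError(f"{col} outside [0, 1]")
        if {"n_der", "n_total"} <= set(df.columns):
            if np.any(df["n_der"].to_numpy() > df["n_total"].to_numpy()):
                raise PaleopulseError("n_der exceeds n_total")
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def has_reads(self) -> bool:
        return {"n_der", "n_total"} <= set(self.df.columns)

    @property
    def has_genotypes(self) -> bool:
        return "gt" in self.df.columns

    def attach_cM(self, gmap: GeneticMap) -> "SiteTable":
        df = self.df.copy()
        for chrom, idx in df.groupby("chrom", sort=False).groups.items():
            df.loc[idx, "cM"] = gmap.bp_to_cM(str(chrom), df.loc[idx, "pos"].to_numpy())
        return SiteTable(df)

    def write_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SiteTable":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def from_vcf(cls, path: str | Path, gmap: GeneticMap,
                 panel_freqs: pd.DataFrame | None = None,
                 sample: str | int = 0) -> "SiteTable":
        """Read biallelic SNPs from a VCF as called genotypes.

        ``panel_freqs`` (indexed like the resulting table) supplies the
        source frequencies; absent that, frequency columns are NaN-free
        zeros and must be filled before likelihood work.
        """
        from cyvcf2 import VCF  # local import: optional dependency

        recs = []
        vcf = VCF(str(path))
        sidx = sample if isinstance(sample, int) else vcf.samples.index(sample)
        for v in vcf:
            if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
                continue
            g = v.genotypes[sidx]
            gt = -1 if g[0] < 0 or g[1] < 0 else int(g[0] > 0) + int(g[1] > 0)
            recs.append((v.CHROM, v.POS - 1, v.REF, v.ALT[0], gt))
        df = pd.DataFrame(recs, columns=["chrom", "pos", "anc", "der", "gt"])
        for col in ("f_AFR", "f_NEA", "f_DEN", "f_c"):
            df[col] = panel_freqs[col].to_numpy() if panel_freqs is not None else 0.0
        df["cM"] = 0.0
        return cls(df).attach_cM(gmap)


# ---------------------------------------------------------------------------
# SegmentSet
# ---------------------------------------------------------------------------

class SegmentSet:
    """Typed genomic intervals of one kind (``ancestry``, ``ibd`` or ``roh``)."""

    def __init__(self, df: pd.DataFrame, kind: str):
        if kind not in ALLOWED_STATES:
            raise PaleopulseError(
                f"unknown segment kind {kind!r}; allowed: {sorted(ALLOWED_STATES)}"
            )
        df = df.copy()
        for col, default in (("posterior", 1.0), ("sample", "sample0")):
            if col not in df.columns:
                df[col] = default
        missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
        if missing:
            raise PaleopulseError(f"segment table missing columns: {missing}")
        if len(df):
            bad = df["start_bp"].to_numpy() >= df["end_bp"].to_numpy()
            if np.any(bad):
                row = df[bad].iloc[0]
                raise PaleopulseError(
                    f"degenerate interval {row['chrom']}:{row['start_bp']}-{row['end_bp']}"
                )
            unknown = set(df["state"]) - ALLOWED_STATES[kind]
            if unknown:
                raise PaleopulseError(
                    f"unknown state labels {sorted(unknown)} for kind {kind!r}; "
                    f"allowed: {sorted(ALLOWED_STATES[kind])}"
                )
        self.df = df[SEGMENT_COLUMNS].reset_index(drop=True)
        self.kind = kind

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lengths_cM(self) -> np.ndarray:
        return (self.df["end_cM"] - self.df["start_cM"]).to_numpy(float)

    @property
    def total_cM(self) -> float:
        return float(self.lengths_cM.sum())

    def for_sample(self, sample: str) -> "SegmentSet":
        return SegmentSet(self.df[self.df["sample"] == sample], self.kind)

    def subset_state(self, *states: str) -> "SegmentSet":
        return SegmentSet(self.df[self.df["state"].isin(states)], self.kind)

    def attach_cM(self, gmap: GeneticMap) -> "SegmentSet":
        df = self.df.copy()
        for chrom, idx in df.groupby("chrom", sort=False).groups.items():
            df.loc[idx, "start_cM"] = gmap.bp_to_cM(str(chrom), df.loc[idx, "start_bp"].to_numpy())
            df.loc[idx, "end_cM"] = gmap.bp_to_cM(str(chrom), df.loc[idx, "end_bp"].to_numpy())
        return SegmentSet(df, self.kind)

    def merged(self) -> "SegmentSet":
        """Merge overlapping/adjacent records of the same sample+state+chrom.

        Conserves total covered bp; the merged record's posterior is the
        length-weighted mean of its parts.
        """
        if not len(self.df):
            return SegmentSet(self.df, self.kind)
        out = []
        for (samp, state, chrom), grp in self.df.groupby(
                ["sample", "state", "chrom"], sort=True):
            grp = grp.sort_values("start_bp")
            cur = None
            for row in grp.itertuples(index=False):
                if cur is None or row.start_bp > cur["end_bp"]:
                    if cur is not None:
                        out.append(cur)
                    cur = {
                        "chrom": chrom, "start_bp": row.start_bp, "end_bp": row.end_bp,
                        "start_cM": row.start_cM, "end_cM": row.end_cM,
                        "state": state, "sample": samp,
                        "_wp": row.posterior * (row.end_bp - row.start_bp),
                    }
                else:
                    if row.end_bp > cur["end_bp"]:
                        cur["end_bp"] = row.end_bp
                        cur["end_cM"] = max(cur["end_cM"], row.end_cM)
                    cur["_wp"] += row.posterior * (row.end_bp - row.start_bp)
            if cur is not None:
                out.append(cur)
        df = pd.DataFrame(out)
        df["posterior"] = df.pop("_wp") / (df["end_bp"] - df["start_bp"])
        return SegmentSet(df, self.kind)

    # -- I/O ----------------------------------------------------------------

    def write(self, path: str | Path) -> None:
        df = self.df.copy()
        df.insert(0, "#kind", self.kind)
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read(cls, path: str | Path, kind: str | None = None,
             gmap: GeneticMap | None = None) -> "SegmentSet":
        df = pd.read_csv(path, sep="\t")
        if "#kind" in df.columns:
            file_kind = str(df["#kind"].iloc[0]) if len(df) else "ancestry"
            df = df.drop(columns="#kind")
            kind = kind or file_kind
        if kind is None:
            raise PaleopulseError("segment kind not given and not stored in file")
        if "start_cM" not in df.columns or "end_cM" not in df.columns:
            if gmap is None:
                raise PaleopulseError("segment file lacks cM columns; pass a genetic map")
            df["start_cM"] = 0.0
            df["end_cM"] = 0.0
            return cls(df, kind).attach_cM(gmap)
        return cls(df, kind)


def read_segments(path: str | Path, kind: str | None = None,
                  gmap: GeneticMap | None = None) -> SegmentSet:
    """Read a BED-like TSV of segments (see :meth:`SegmentSet.read`)."""
    return SegmentSet.read(path, kind=kind, gmap=gmap)


def write_segments(segments: SegmentSet, path: str | Path) -> None:
    segments.write(path)


def concat_segments(sets: Iterable[SegmentSet]) -> SegmentSet:
    sets = list(sets)
    kinds = {s.kind for s in sets}
    if len(kinds) != 1:
        raise PaleopulseError(f"cannot concatenate mixed kinds {kinds}")
    return SegmentSet(pd.concat([s.df for s in sets], ignore_index=True), kinds.pop())
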