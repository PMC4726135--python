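"""Linkage-map representation, physical-to-genetic projection, and binning.

The genome model used by the meiosis simulator is a linkage map discretised
into 0.1-cM bins: each chromosome's genetic length in Morgans doubles as the
Poisson rate for crossover counts, and markers are attached to the bin whose
midpoint is nearest their genetic position.

Physical (bp) positions are projected onto the genetic (cM) scale by local
polynomial regression (degree 2, tricube weights) on an anchor table of
(bp, cM) pairs, with the conventional span parameter controlling smoothness
(default 0.189).  Because a smoothed projection can locally invert marker
order, any non-positive successive genetic gap is replaced by 1e-6 cM and
positions re-accumulated so the output is strictly increasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ChromosomeMap",
    "LinkageMap",
    "BinnedGenome",
    "LoessCurve",
    "fit_physical_to_genetic",
    "project_markers",
    "build_bins",
    "NEGATIVE_GAP_CM",
]

#: replacement for a non-positive successive genetic gap, in cM
NEGATIVE_GAP_CM: float = 1.0e-6


@dataclass
class ChromosomeMap:
    name: str
    length_morgan: float
    markers: pd.DataFrame  # columns: marker_id, pos_cm, (optional) pos_bp

    def __post_init__(self) -> None:
        req = {"marker_id", "pos_cm"}
        if not req.issubset(self.markers.columns):
            raise ValueError("markers must have marker_id and pos_cm columns")
        pos = self.markers["pos_cm"].to_numpy(dtype=float)
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"{self.name}: genetic positions must be non-decreasing")
        if self.length_morgan < 0:
            raise ValueError("chromosome length must be non-negative")
        if len(pos) and self.length_morgan * 100.0 < pos[-1] - 1e-9:
            raise ValueError(
                f"{self.name}: length_morgan smaller than last marker position"
            )

    @property
    def length_cm(self) -> float:
        return self.length_morgan * 100.0


@dataclass
class LinkageMap:
    """Ordered chromosomes; chromosome genetic length (Morgan) is the Poisson rate."""

    chromosomes: list[ChromosomeMap]

    @property
    def n_markers(self) -> int:
        return sum(len(c.markers) for c in self.chromosomes)

    @property
    def marker_ids(self) -> list[str]:
        out: list[str] = []
        for c in self.chromosomes:
            out.extend(c.markers["marker_id"].tolist())
        return out

    def marker_positions(self) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
        """Flat (pos_cm, pos_bp or None, chromosome index) over all markers."""
        cm, bp, ch = [], [], []
        has_bp = all("pos_bp" in c.markers.columns for c in self.chromosomes)
        for ci, c in enumerate(self.chromosomes):
            cm.append(c.markers["pos_cm"].to_numpy(dtype=float))
            if has_bp:
                bp.append(c.markers["pos_bp"].to_numpy(dtype=float))
            ch.append(np.full(len(c.markers), ci))
        return (
            np.concatenate(cm) if cm else np.array([]),
            np.concatenate(bp) if has_bp and bp else None,
            np.concatenate(ch) if ch else np.array([], dtype=int),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, length_morgan: dict[str, float] | None = None) -> "LinkageMap":
        """Build from a long table with columns chrom, marker_id, pos_cm[, pos_bp].

        When a chromosome's genetic length is not supplied it is taken as the
        last marker position (rounded up to the bin above zero length).
        """
        chroms = []
        for name, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("pos_cm", kind="stable").reset_index(drop=True)
            if length_morgan and name in length_morgan:
                lm = length_morgan[name]
            else:
                lm = float(sub["pos_cm"].max()) / 100.0 if len(sub) else 0.0
            cols = ["marker_id", "pos_cm"] + (["pos_bp"] if "pos_bp" in sub.columns else [])
            chroms.append(ChromosomeMap(name=str(name), length_morgan=lm, markers=sub[cols]))
        return cls(chromosomes=chroms)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.chromosomes:
            sub = c.markers.copy()
            sub.insert(0, "chrom", c.name)
            rows.append(sub)
        return pd.concat(rows, ignore_index=True)


@dataclass
class BinnedGenome:
    """0.1-cM discretisation of a linkage map.

    Bins tile [0, length_cm) per chromosome as half-open intervals of width
    ``bin_size_cm``; markers are assigned to the bin whose midpoint is nearest
    (ties to the lower-index bin).
    """

    bin_size_cm: float
    chrom_names: list[str]
    n_bins: np.ndarray  # per chromosome
    marker_bins: np.ndarray  # global flat bin index per marker (map order)
    marker_chrom: np.ndarray  # chromosome index per marker
    lengths_morgan: np.ndarray  # per chromosome

    @property
    def total_bins(self) -> int:
        return int(self.n_bins.sum())

    @property
    def offsets(self) -> np.ndarray:
        """Global index of the first bin of each chromosome."""
        return np.concatenate([[0], np.cumsum(self.n_bins)[:-1]]).astype(int)

    def bin_midpoints_cm(self, chrom_index: int) -> np.ndarray:
        nb = int(self.n_bins[chrom_index])
        return (np.arange(nb) + 0.5) * self.bin_size_cm


class LoessCurve:
    """Local polynomial regression curve (degree 2, tricube weights).

    At each query point the ``span`` fraction of nearest anchors is fitted by
    weighted least squares and the fit evaluated at the query — the
    conventional definition of loess.  Falls back to a lower degree when the
    local window is rank-deficient.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray, span: float = 0.189, degree: int = 2):
        order = np.argsort(x, kind="stable")
        self.x = np.asarray(x, dtype=float)[order]
        self.y = np.asarray(y, dtype=float)[order]
        if not 0 < span <= 1:
            raise ValueError("span must be in (0, 1]")
        self.span = span
        self.degree = degree
        self._k = max(degree + 1, int(math.ceil(span * len(self.x))))
        if len(self.x) < degree + 1:
            raise ValueError("too few anchors for the local fit")

    def __call__(self, xq) -> np.ndarray:
        xq_arr = np.atleast_1d(np.asarray(xq, dtype=float))
        out = np.empty_like(xq_arr)
        for i, q in enumerate(xq_arr):
            out[i] = self._fit_at(q)
        return out if np.ndim(xq) else float(out[0])

    def _fit_at(self, q: float) -> float:
        d = np.abs(self.x - q)
        idx = np.argsort(d, kind="stable")[: self._k]
        xs, ys, ds = self.x[idx], self.y[idx], d[idx]
        dmax = ds.max()
        if dmax == 0:
            return float(ys.mean())
        w = (1.0 - np.minimum(ds / dmax, 1.0) ** 3) ** 3
        w = np.maximum(w, 1e-12)
        for deg in range(self.degree, -1, -1):
            xc = xs - q  # centre so the intercept is the fitted value
            basis = np.vander(xc, deg + 1, increasing=True)
            sw = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(basis * sw[:, None], ys * sw, rcond=None)
            if np.all(np.isfinite(coef)):
                return float(coef[0])
        return float(np.average(ys, weights=w))


def fit_physical_to_genetic(
    anchors_bp: np.ndarray,
    anchors_cm: np.ndarray,
    span: float = 0.189,
    min_anchors: int = 10,
) -> LoessCurve:
    """Fit the bp -> cM projection for one chromosome from anchor pairs."""
    bp = np.asarray(anchors_bp, dtype=float)
    cm = np.asarray(anchors_cm, dtype=float)
    if bp.shape != cm.shape or bp.ndim != 1:
        raise ValueError("anchor arrays must be 1-D and of equal length")
    if len(bp) < min_anchors:
        raise ValueError(
            f"chromosome rejected: {len(bp)} anchors < required {min_anchors}"
        )
    return LoessCurve(bp, cm, span=span)


def project_markers(mapping, pos_bp: np.ndarray) -> np.ndarray:
    """Project bp positions to strictly increasing cM positions.

    Markers must be sorted by bp.  Raw projected positions may locally
    decrease; every non-positive successive gap is replaced by
    ``NEGATIVE_GAP_CM`` and the positions re-accumulated cumulatively so the
    result is strictly increasing.  Positive gaps smaller than the
    replacement are raised to it as well, so the accumulated positions
    remain strictly increasing in floating point.
    """
    bp = np.asarray(pos_bp, dtype=float)
    if np.any(np.diff(bp) < 0):
        raise ValueError("markers must be sorted by physical position")
    raw = np.asarray(mapping(bp), dtype=float)
    if raw.size == 0:
        return raw
    gaps = np.diff(raw)
    gaps[gaps < NEGATIVE_GAP_CM] = NEGATIVE_GAP_CM
    start = max(raw[0], 0.0)
    return np.concatenate([[start], start + np.cumsum(gaps)])


def assign_bins(pos_cm: np.ndarray, bin_size_cm: float, n_bins: int) -> np.ndarray:
    """Nearest-midpoint bin assignment; ties go to the lower-index bin."""
    pos = np.asarray(pos_cm, dtype=float)
    # nearest midpoint (k+0.5)*bin  <=>  ceil(pos/bin) - 1, ties at boundaries
    # resolving to the lower bin; guard float noise with a tiny epsilon
    idx = np.ceil(pos / bin_size_cm - 1e-9).astype(int) - 1
    return np.clip(idx, 0, max(n_bins - 1, 0))


def build_bins(lmap: LinkageMap, bin_size_cm: float = 0.1) -> BinnedGenome:
    """Discretise a linkage map into fixed-width genetic bins."""
    if bin_size_cm <= 0:
        raise ValueError("bin_size_cm must be positive")
    names, nbins, lens = [], [], []
    marker_bins, marker_chrom = [], []
    offset = 0
    for ci, c in enumerate(lmap.chromosomes):
        nb = max(1, int(math.ceil(c.length_cm / bin_size_cm - 1e-9)))
        names.append(c.name)
        nbins.append(nb)
        lens.append(c.length_morgan)
        pos = c.markers["pos_cm"].to_numpy(dtype=float)
        local = assign_bins(pos, bin_size_cm, nb)
        marker_bins.append(local + offset)
        marker_chrom.append(np.full(len(pos), ci))
        offset += nb
    return BinnedGenome(
        bin_size_cm=bin_size_cm,
        chrom_names=names,
        n_bins=np.asarray(nbins, dtype=int),
        marker_bins=np.concatenate(marker_bins) if marker_bins else np.array([], dtype=int),
        marker_chrom=np.concatenate(marker_chrom) if marker_chrom else np.array([], dtype=int),
        lengths_morgan=np.asarray(lens, dtype=float),
    )
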