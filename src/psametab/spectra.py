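"""Spectral bucketing: multi-sample 1D NMR spectra to a feature matrix.

The feature-extraction scheme is "intelligent" (minima-snapped) bucketing:
nominal bucket boundaries are laid out every ``nominal_width`` ppm across
the integration region, and each interior boundary is then relocated to the
local minimum of a reference spectrum (the point-wise mean across samples)
within a window of half-width ``looseness * nominal_width / 2`` around its
nominal position.  A peak whose position jitters from sample to sample
(e.g. the pH effect on chemical shift) therefore tends to stay inside one
bucket instead of being split across two.  With the default 0.04 ppm width
and 50% looseness every bucket width is guaranteed to lie in [0.02, 0.06]
ppm.

The residual-water region is excluded bucket-wise after integration, and
each sample row is finally normalized to unit total area so that global
concentration differences between samples cancel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumSet",
    "BucketTable",
    "intelligent_bucket",
    "exclude_region",
    "normalize_total_area",
]


@dataclass
class SpectrumSet:
    """A shared ppm axis plus one intensity vector per sample.

    The axis is stored ascending; all samples share it.
    """

    ppm: np.ndarray
    intensities: np.ndarray  # (n_samples, n_points)
    sample_ids: list[str]

    def __post_init__(self):
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if np.any(np.diff(self.ppm) <= 0):
            # accept descending input but store ascending
            if np.all(np.diff(self.ppm) < 0):
                self.ppm = self.ppm[::-1].copy()
                self.intensities = self.intensities[:, ::-1].copy()
            else:
                raise ValueError("ppm axis must be strictly monotone")
        if self.intensities.shape != (len(self.sample_ids), self.ppm.size):
            raise ValueError("intensities must be (n_samples, n_points)")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("spectra contain non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intensities.T, index=pd.Index(self.ppm, name="ppm"),
                            columns=self.sample_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "SpectrumSet":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ppm=df.index.to_numpy(float),
                   intensities=df.to_numpy(float).T,
                   sample_ids=[str(c) for c in df.columns])


@dataclass
class BucketTable:
    """Samples x buckets integral matrix with explicit ppm boundaries."""

    intervals: np.ndarray          # (n_buckets, 2) ordered [lo, hi)
    values: np.ndarray             # (n_samples, n_buckets)
    sample_ids: list[str]
    normalized: bool = False
    excluded_regions: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(self.intervals[:, 1] <= self.intervals[:, 0]):
            raise ValueError("bucket intervals must have hi > lo")
        if np.any(np.diff(self.intervals[:, 0]) <= 0):
            raise ValueError("bucket intervals must be ordered")

    @property
    def widths(self) -> np.ndarray:
        return self.intervals[:, 1] - self.intervals[:, 0]

    @property
    def centers(self) -> np.ndarray:
        return self.intervals.mean(axis=1)

    @property
    def n_buckets(self) -> int:
        return self.intervals.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{lo:.4f}-{hi:.4f}" for lo, hi in self.intervals]
        return pd.DataFrame(self.values, index=self.sample_ids, columns=cols)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for k, (lo, hi) in enumerate(self.intervals):
                fh.write(f"# bucket {k} {lo:.6f} {hi:.6f}\n")
            for lo, hi in self.excluded_regions:
                fh.write(f"# excluded {lo:.6f} {hi:.6f}\n")
            fh.write(f"# normalized {int(self.normalized)}\n")
            self.to_frame().to_csv(fh, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "BucketTable":
        intervals, excluded, normalized = [], [], False
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                parts = line[1:].split()
                if parts[0] == "bucket":
                    intervals.append((float(parts[2]), float(parts[3])))
                elif parts[0] == "excluded":
                    excluded.append((float(parts[1]), float(parts[2])))
                elif parts[0] == "normalized":
                    normalized = bool(int(parts[1]))
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, sep="\t", index_col=0)
        return cls(intervals=np.array(intervals), values=df.to_numpy(float),
                   sample_ids=[str(i) for i in df.index],
                   normalized=normalized, excluded_regions=excluded)


def _cumulative_integral(ppm: np.ndarray, y: np.ndarray):
    """Exact integral of the piecewise-linear interpolant up to arbitrary ppm.

    Returns a callable F with F(b) - F(a) the trapezoidal integral over
    [a, b], exact even when a, b fall between grid points.
    """
    from scipy.integrate import cumulative_trapezoid

    C = np.concatenate([[0.0], cumulative_trapezoid(y, ppm)])

    def F(p):
        p = np.asarray(p, dtype=float)
        i = np.clip(np.searchsorted(ppm, p, side="right") - 1, 0, ppm.size - 2)
        x0, x1 = ppm[i], ppm[i + 1]
        y0, y1 = y[i], y[i + 1]
        d = p - x0
        # integral of linear segment from x0 to p
        return C[i] + y0 * d + 0.5 * (y1 - y0) / (x1 - x0) * d * d

    return F


def _plan_boundaries(lo: float, hi: float, nominal_width: float, looseness: float):
    """Nominal boundary positions plus a relocatable flag per boundary.

    Boundaries sit at lo + k*nominal_width.  A trailing remainder at least
    nominal_width*(1-looseness) wide becomes its own bucket whose left
    boundary is fixed; a smaller remainder is merged into the previous
    bucket, whose left boundary is then fixed.  Together with the search
    half-window looseness*nominal_width/2 this guarantees every bucket
    width lies in [nominal*(1-looseness), nominal*(1+looseness)].
    """
    n_full = int(np.floor((hi - lo) / nominal_width + 1e-9))
    remainder = (hi - lo) - n_full * nominal_width
    bounds = [lo + k * nominal_width for k in range(n_full + 1)]
    if remainder > 1e-12:
        if remainder >= nominal_width * (1.0 - looseness) - 1e-12:
            bounds.append(hi)          # remainder is its own bucket
            fixed_tail = 2             # hi and the boundary before it
        else:
            bounds[-1] = hi            # merge remainder into last bucket
            fixed_tail = 2             # hi and the (moved) boundary's left one
    else:
        bounds[-1] = hi
        fixed_tail = 1
    bounds = np.asarray(bounds)
    relocatable = np.ones(bounds.size, dtype=bool)
    relocatable[0] = False
    relocatable[-fixed_tail:] = False
    return bounds, relocatable


def intelligent_bucket(spectra: SpectrumSet, nominal_width: float = 0.04,
                       looseness: float = 0.5,
                       region: tuple[float, float] = (0.80, 8.50)) -> BucketTable:
    """Minima-snapped bucketing of a spectrum set.

    Each interior boundary moves to the minimum of the mean spectrum within
    +/- looseness*nominal_width/2 of its nominal position (argmin ties are
    broken toward the nominal position; a flat window keeps the nominal
    boundary).  Bucket values are trapezoidal integrals of each sample over
    [lo, hi); region endpoints stay fixed.
    """
    lo, hi = region
    if not (0.0 <= looseness < 1.0):
        raise ValueError("looseness must be in [0, 1)")
    if hi - lo < nominal_width:
        raise ValueError("region narrower than one nominal bucket width")
    if lo < spectra.ppm[0] - 1e-9 or hi > spectra.ppm[-1] + 1e-9:
        raise ValueError("integration region outside the ppm axis")

    reference = spectra.intensities.mean(axis=0)
    bounds, relocatable = _plan_boundaries(lo, hi, nominal_width, looseness)
    half = looseness * nominal_width / 2.0

    final = bounds.copy()
    for i in np.nonzero(relocatable)[0]:
        b = bounds[i]
        j0 = np.searchsorted(spectra.ppm, b - half, side="left")
        j1 = np.searchsorted(spectra.ppm, b + half, side="right")
        if j1 - j0 < 1:
            continue
        window = reference[j0:j1]
        m = window.min()
        cand = np.nonzero(window <= m)[0] + j0
        if window.max() - m <= 0.0:      # flat window: keep nominal
            continue
        final[i] = spectra.ppm[cand[np.argmin(np.abs(spectra.ppm[cand] - b))]]

    intervals = np.column_stack([final[:-1], final[1:]])
    values = np.empty((spectra.n_samples, intervals.shape[0]))
    for s in range(spectra.n_samples):
        F = _cumulative_integral(spectra.ppm, spectra.intensities[s])
        values[s] = F(intervals[:, 1]) - F(intervals[:, 0])
    return BucketTable(intervals=intervals, values=values,
                       sample_ids=list(spectra.sample_ids))


def exclude_region(buckets: BucketTable, lo: float = 4.70,
                   hi: float = 5.20) -> BucketTable:
    """Drop every bucket whose interval overlaps the open interval (lo, hi).

    Any overlap removes the bucket (applied literally: a bucket spanning
    the region edge is dropped).  The default removes the residual-water
    presaturation region.
    """
    if lo >= hi:
        raise ValueError("exclusion region requires lo < hi")
    keep = (buckets.intervals[:, 1] <= lo) | (buckets.intervals[:, 0] >= hi)
    return BucketTable(intervals=buckets.intervals[keep],
                       values=buckets.values[:, keep],
                       sample_ids=list(buckets.sample_ids),
                       normalized=buckets.normalized,
                       excluded_regions=buckets.excluded_regions + [(lo, hi)])


def normalize_total_area(buckets: BucketTable) -> BucketTable:
    """Divide each sample row by its own total so rows sum to one."""
    totals = buckets.values.sum(axis=1)
    bad = np.nonzero(totals <= 0)[0]
    if bad.size:
        names = ", ".join(buckets.sample_ids[i] for i in bad)
        raise ValueError(f"non-positive total area for sample(s): {names}")
    return replace(buckets, values=buckets.values / totals[:, None],
                   normalized=True)
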