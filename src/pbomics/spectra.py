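"""Spectral bucketing and normalization for 1D NMR and GC-MS peak tables.

A raw 1H-NMR spectrum arrives as a (ppm, intensity) series that has already
been phased, baseline-corrected and referenced upstream.  To turn spectra
into a feature matrix comparable across samples, each spectrum is integrated
over fixed-width chemical-shift intervals ("buckets"), solvent regions are
discarded, and every row is normalized to a common total integral so that
each bucket represents a fraction of total observed signal rather than an
absolute concentration.

Three bucket schemes are provided as presets, matching the acquisition
protocols for aqueous liver extracts, plasma CPMG spectra and intact-tissue
HRMAS spectra respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BucketScheme",
    "BucketTable",
    "SCHEME_PRESETS",
    "build_buckets",
    "bucket_spectrum",
    "bucket_spectra",
    "normalize_total",
    "renormalize_excluding",
    "normalize_peak_table",
]

#: Tolerance used when comparing bucket edges against exclusion-region
#: boundaries; bucket edges are reconstructed from integer multiples of the
#: width so only float representation error needs absorbing.
_EDGE_TOL = 1e-9

#: Glucose and glycogen resonance regions (ppm) removed when liver-extract
#: bucket tables are renormalized to reveal lower-concentration metabolites.
GLUCOSE_GLYCOGEN_REGIONS = ((3.35, 4.05), (4.60, 4.72), (5.20, 5.55))


@dataclass(frozen=True)
class BucketScheme:
    """A fixed-width binning specification over a chemical-shift range.

    Buckets are left-closed, right-open intervals ``[lo, hi)`` tiling
    ``[start_ppm, end_ppm)``; a trailing partial bucket (when the range is
    not an integer number of widths) is dropped.  Any bucket whose interval
    overlaps an exclusion region with positive length is removed entirely.
    """

    start_ppm: float
    end_ppm: float
    width_ppm: float
    exclusions: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.width_ppm <= 0:
            raise ValueError(f"bucket width must be positive, got {self.width_ppm}")
        if not self.start_ppm < self.end_ppm:
            raise ValueError(
                f"scheme range is empty: start {self.start_ppm} >= end {self.end_ppm}"
            )
        excl = tuple(tuple(map(float, e)) for e in self.exclusions)
        for lo, hi in excl:
            if not (lo < hi):
                raise ValueError(f"exclusion region ({lo}, {hi}) is empty")
            if lo < self.start_ppm - _EDGE_TOL or hi > self.end_ppm + _EDGE_TOL:
                raise ValueError(
                    f"exclusion region ({lo}, {hi}) lies outside the scheme "
                    f"range [{self.start_ppm}, {self.end_ppm}]"
                )
        for (lo1, hi1), (lo2, hi2) in zip(excl, excl[1:]):
            if hi1 > lo2:
                raise ValueError(
                    f"exclusion regions ({lo1}, {hi1}) and ({lo2}, {hi2}) overlap"
                )
        object.__setattr__(self, "exclusions", excl)


#: Bucket-scheme presets for the three acquisition protocols.
SCHEME_PRESETS: dict[str, BucketScheme] = {
    # aqueous liver extracts: 0.01 ppm buckets, water region excluded
    "liver_extract": BucketScheme(0.20, 9.95, 0.01, ((4.72, 5.05),)),
    # plasma CPMG: 0.02 ppm buckets, water region excluded
    "plasma_cpmg": BucketScheme(0.60, 8.00, 0.02, ((4.68, 5.15),)),
    # intact-tissue HRMAS: 0.04 ppm buckets, water region excluded
    "hrmas": BucketScheme(0.50, 5.60, 0.04, ((4.75, 5.00),)),
}

#: Normalization states a BucketTable can be in.
_STATES = ("raw", "total_10000", "renormalized")


@dataclass
class BucketTable:
    """Samples x buckets matrix of non-negative integrals.

    ``data`` columns are labelled ``"lo-hi"`` in ascending ppm;
    ``intervals`` carries the numeric (lo, hi) pairs in column order.
    """

    data: pd.DataFrame
    intervals: tuple[tuple[float, float], ...]
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in _STATES:
            raise ValueError(f"unknown normalization state {self.state!r}")
        if len(self.intervals) != self.data.shape[1]:
            raise ValueError("intervals do not match table columns")
        for (lo1, hi1), (lo2, hi2) in zip(self.intervals, self.intervals[1:]):
            if hi1 > lo2 + _EDGE_TOL:
                raise ValueError("bucket intervals must be disjoint and ascending")


def _interval_label(lo: float, hi: float) -> str:
    return f"{lo:.4g}-{hi:.4g}"


def _overlaps(lo: float, hi: float, rlo: float, rhi: float) -> bool:
    """Positive-length overlap between bucket [lo, hi) and region [rlo, rhi]."""
    return hi > rlo + _EDGE_TOL and lo < rhi - _EDGE_TOL


def build_buckets(scheme: BucketScheme) -> list[tuple[float, float]]:
    """Enumerate the bucket intervals of a scheme, exclusions removed.

    Edges are computed as ``start + i * width`` with the index arithmetic
    done in integers, so repeated widths do not accumulate float drift.
    """
    span = scheme.end_ppm - scheme.start_ppm
    n_full = int(np.floor(span / scheme.width_ppm + _EDGE_TOL))
    out: list[tuple[float, float]] = []
    for i in range(n_full):
        lo = scheme.start_ppm + i * scheme.width_ppm
        hi = scheme.start_ppm + (i + 1) * scheme.width_ppm
        if any(_overlaps(lo, hi, rlo, rhi) for rlo, rhi in scheme.exclusions):
            continue
        out.append((lo, hi))
    return out


def _augmented_cumulative_integral(
    ppm: np.ndarray, intensity: np.ndarray, edges: np.ndarray
) -> np.ndarray:
    """Trapezoidal cumulative integral of the spectrum evaluated at ``edges``.

    The piecewise-linear signal is integrated exactly by inserting the bucket
    edges into the native grid before accumulating, so bucket integrals sum
    to the full-range integral without discretisation loss.
    """
    grid = np.union1d(ppm, edges)
    vals = np.interp(grid, ppm, intensity)
    cum = np.concatenate(
        [[0.0], np.cumsum(0.5 * (vals[1:] + vals[:-1]) * np.diff(grid))]
    )
    idx = np.searchsorted(grid, edges)
    return cum[idx]


def bucket_spectrum(
    ppm: np.ndarray, intensity: np.ndarray, scheme: BucketScheme
) -> pd.Series:
    """Integrate one spectrum over the scheme's buckets (trapezoidal rule).

    Parameters
    ----------
    ppm, intensity
        The spectrum; the ppm axis must be strictly monotone and span the
        scheme range.

    Returns
    -------
    pandas.Series indexed by ``"lo-hi"`` bucket labels, ascending ppm.
    """
    ppm = np.asarray(ppm, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if ppm.ndim != 1 or ppm.shape != intensity.shape:
        raise ValueError("ppm and intensity must be 1-D arrays of equal length")
    d = np.diff(ppm)
    if np.all(d < 0):  # spectra are often stored high-to-low ppm
        ppm, intensity = ppm[::-1], intensity[::-1]
    elif not np.all(d > 0):
        raise ValueError("ppm axis must be strictly monotone")
    if not np.all(np.isfinite(intensity)):
        raise ValueError("intensities must be finite")
    if ppm[0] > scheme.start_ppm + _EDGE_TOL or ppm[-1] < scheme.end_ppm - _EDGE_TOL:
        lo_gap = (scheme.start_ppm, min(ppm[0], scheme.end_ppm))
        hi_gap = (max(ppm[-1], scheme.start_ppm), scheme.end_ppm)
        uncovered = lo_gap if ppm[0] > scheme.start_ppm + _EDGE_TOL else hi_gap
        raise ValueError(
            f"spectrum [{ppm[0]:g}, {ppm[-1]:g}] does not cover the scheme "
            f"range; uncovered interval ({uncovered[0]:g}, {uncovered[1]:g})"
        )
    intervals = build_buckets(scheme)
    edges = np.unique(np.array(intervals, dtype=float).ravel())
    cum = _augmented_cumulative_integral(ppm, intensity, edges)
    pos = {e: i for i, e in enumerate(edges)}
    values = [cum[pos[hi]] - cum[pos[lo]] for lo, hi in intervals]
    return pd.Series(
        values, index=[_interval_label(lo, hi) for lo, hi in intervals], dtype=float
    )


def bucket_spectra(
    spectra: dict[str, tuple[np.ndarray, np.ndarray]], scheme: BucketScheme
) -> BucketTable:
    """Bucket a set of named spectra into one raw BucketTable."""
    if not spectra:
        raise ValueError("no spectra supplied")
    rows = {sid: bucket_spectrum(p, y, scheme) for sid, (p, y) in spectra.items()}
    data = pd.DataFrame(rows).T
    data.index.name = "sample_id"
    return BucketTable(data=data, intervals=tuple(build_buckets(scheme)), state="raw")


def _row_normalize(data: pd.DataFrame, target: float, what: str) -> pd.DataFrame:
    sums = data.sum(axis=1)
    bad = sums.index[sums <= 0]
    if len(bad):
        raise ValueError(f"cannot normalize {what} with non-positive total: {bad[0]!r}")
    return data.mul(target / sums, axis=0)


def normalize_total(table: BucketTable, target: float = 10_000.0) -> BucketTable:
    """Scale each row so its total integral equals ``target`` (default 10000).

    Between-bucket ratios within a row are unchanged; each bucket thereafter
    represents its share of the total spectral integral.
    """
    data = _row_normalize(table.data, target, "spectrum row")
    return BucketTable(data=data, intervals=table.intervals, state="total_10000")


def renormalize_excluding(
    table: BucketTable, regions: tuple[tuple[float, float], ...]
) -> BucketTable:
    """Drop buckets overlapping ``regions`` and renormalize rows to 10000.

    Used when a few dominant resonances (e.g. glucose and glycogen in liver
    extracts) swamp the constant-sum normalization: removing them and
    renormalizing reveals dose responses of lower-concentration metabolites.
    """
    if table.state != "total_10000":
        raise ValueError("renormalization expects a table normalized to 10000")
    if not regions:
        return BucketTable(
            data=table.data.copy(), intervals=table.intervals, state="renormalized"
        )
    keep = [
        i
        for i, (lo, hi) in enumerate(table.intervals)
        if not any(_overlaps(lo, hi, rlo, rhi) for rlo, rhi in regions)
    ]
    if not keep:
        raise ValueError("exclusion regions would remove every bucket")
    data = table.data.iloc[:, keep]
    data = _row_normalize(data, 10_000.0, "spectrum row")
    return BucketTable(
        data=data,
        intervals=tuple(table.intervals[i] for i in keep),
        state="renormalized",
    )


def normalize_peak_table(peaks: pd.DataFrame, target: float = 10_000.0) -> pd.DataFrame:
    """Normalize a samples x peaks GC-MS peak-area table to a constant total.

    Shares :func:`normalize_total`'s contract; peak tables have named peaks
    rather than ppm-interval buckets.
    """
    return _row_normalize(peaks, target, "peak-table row")
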