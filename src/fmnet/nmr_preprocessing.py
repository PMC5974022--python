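"""1-D NMR preprocessing: baseline removal, alignment, bucketing, normalization.

The metabolomics side of the pipeline. Raw spectra (ppm, intensity) are
baseline-corrected with a morphological rolling-ball filter, aligned to the
median spectrum, integrated into fixed-width buckets (default 0.02 ppm) with
exclusion regions (water, reference compound, spectrum extremes), normalized
to a constant total integral (default 1000), and finally dilution-corrected by
probabilistic quotient normalization (PQN).

The stage order baseline -> align -> bucket -> total integral -> PQN is
recorded in each bucket matrix's provenance and enforced where a stage
requires its predecessor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import grey_dilation, grey_erosion, uniform_filter1d

from fmnet._utils import write_table

#: conventional exclusion windows: residual water, TSP reference, extremes
DEFAULT_EXCLUSIONS: tuple[tuple[float, float], ...] = (
    (-np.inf, 0.50),   # upfield extreme + TSP reference region
    (4.50, 5.20),      # residual water resonance
    (9.00, np.inf),    # downfield extreme
)

Normalization = Literal["raw", "total1000", "pqn"]


@dataclass
class Spectrum:
    """A 1-D spectrum: strictly monotone ppm axis + intensities.

    Descending axes (the native NMR display order) are accepted and stored
    ascending.
    """

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = "spectrum"

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D arrays of equal length")
        d = np.diff(self.ppm)
        if (d > 0).all():
            pass
        elif (d < 0).all():
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        else:
            raise ValueError("ppm axis must be strictly monotone")


@dataclass
class NmrBucketMatrix:
    """Samples x buckets matrix of integrated intensities."""

    df: pd.DataFrame
    bucket_edges: list[tuple[float, float]]
    normalization: Normalization = "raw"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.bucket_edges) != self.df.shape[1]:
            raise ValueError("bucket_edges must match the number of columns")
        edges = sorted(self.bucket_edges)
        for (lo1, hi1), (lo2, _) in zip(edges, edges[1:]):
            if hi1 > lo2 + 1e-12:
                raise ValueError("buckets must be non-overlapping")
        if (self.df.to_numpy(dtype=float) < -1e-9).any():
            raise ValueError("bucket intensities must be non-negative")
        if self.normalization == "total1000":
            sums = self.df.to_numpy(dtype=float).sum(axis=1)
            if not np.allclose(sums, sums[0], rtol=1e-6):
                raise ValueError("total-normalized rows must share one total")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    def write(self, path, header_comments: list[str] | None = None) -> None:
        comments = [f"normalization={self.normalization}"]
        comments += [f"stage={s}" for s in self.provenance]
        write_table(self.df, path, comments + (header_comments or []))


def rolling_ball_baseline(spec: Spectrum, radius_points: int = 50) -> Spectrum:
    """Subtract a morphological rolling-ball baseline.

    The baseline is a grey-scale opening (erosion then dilation with a flat
    window of 2*radius+1 points) smoothed with a moving average of the same
    width; the opening lies pointwise at or below the signal, so broad trends
    are removed while narrow peaks survive.
    """
    if radius_points < 1:
        raise ValueError("radius_points must be >= 1")
    n = len(spec.intensity)
    if radius_points >= n:
        raise ValueError("radius_points must be smaller than the spectrum length")
    size = 2 * radius_points + 1
    opened = grey_dilation(
        grey_erosion(spec.intensity, size=size, mode="nearest"),
        size=size,
        mode="nearest",
    )
    baseline = uniform_filter1d(opened, size=size, mode="nearest")
    return Spectrum(spec.ppm.copy(), spec.intensity - baseline, spec.sample_id)


def _integrate(ppm: np.ndarray, y: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of the piecewise-linear spectrum over [lo, hi]."""
    inside = (ppm > lo) & (ppm < hi)
    xs = np.concatenate(([lo], ppm[inside], [hi]))
    ys = np.interp(xs, ppm, y, left=0.0, right=0.0)
    return float(np.trapezoid(ys, xs))


def bucket_spectrum(
    spec: Spectrum,
    width_ppm: float = 0.02,
    exclusions: Sequence[tuple[float, float]] = DEFAULT_EXCLUSIONS,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Integrate the spectrum into half-open buckets [lo, lo + width).

    Bucket edges are aligned to multiples of ``width_ppm``. Any bucket that
    overlaps an exclusion interval is dropped entirely.
    """
    if width_ppm <= 0:
        raise ValueError("width_ppm must be positive")
    lo0 = np.floor(spec.ppm[0] / width_ppm) * width_ppm
    n_buckets = int(np.ceil((spec.ppm[-1] - lo0) / width_ppm))
    edges, vals = [], []
    for i in range(n_buckets):
        lo = lo0 + i * width_ppm
        hi = lo + width_ppm
        if any(lo < ex_hi and hi > ex_lo for ex_lo, ex_hi in exclusions):
            continue
        edges.append((lo, hi))
        vals.append(_integrate(spec.ppm, spec.intensity, lo, hi))
    if not edges:
        raise ValueError("exclusions cover the whole spectral range")
    return np.asarray(vals), edges


def bucket_spectra(
    spectra: Sequence[Spectrum],
    width_ppm: float = 0.02,
    exclusions: Sequence[tuple[float, float]] = DEFAULT_EXCLUSIONS,
) -> NmrBucketMatrix:
    """Bucket several spectra sharing a ppm range into one matrix."""
    rows, edges0 = [], None
    for spec in spectra:
        vals, edges = bucket_spectrum(spec, width_ppm, exclusions)
        if edges0 is None:
            edges0 = edges
        elif edges != edges0:
            raise ValueError("spectra produced differing bucket grids")
        rows.append(np.clip(vals, 0.0, None))
    cols = [f"B{(lo + hi) / 2:.3f}" for lo, hi in edges0]
    df = pd.DataFrame(rows, index=[s.sample_id for s in spectra], columns=cols)
    return NmrBucketMatrix(df, edges0, "raw", provenance=["bucket"])


def total_integral_normalize(m: NmrBucketMatrix, total: float = 1000.0) -> NmrBucketMatrix:
    """Scale each row so its bucket sum equals ``total`` (default 1000)."""
    sums = m.values.sum(axis=1)
    zero = np.asarray(m.sample_ids)[sums == 0]
    if len(zero):
        raise ValueError(f"zero-integral samples: {list(zero)}")
    scaled = m.values * (total / sums[:, None])
    return NmrBucketMatrix(
        pd.DataFrame(scaled, index=m.df.index, columns=m.df.columns),
        m.bucket_edges,
        "total1000",
        provenance=m.provenance + [f"total_integral={total:g}"],
    )


def pqn_normalize(
    m: NmrBucketMatrix,
    reference: Literal["median_all", "median_of_group"] = "median_all",
    groups: dict[str, str] | None = None,
    reference_group: str | None = None,
    enforce_total: bool = True,
) -> tuple[NmrBucketMatrix, pd.Series]:
    """Probabilistic quotient normalization.

    The reference spectrum is the per-bucket median (over all samples, or over
    one group). Each sample's quotient is the median of its bucket-wise ratios
    to the reference (buckets where the reference is zero are skipped), and
    the row is divided by that quotient. Quotients are returned so planted or
    instrumental dilution factors can be inspected.

    ``enforce_total`` asserts the conventional stage order (total-integral
    normalization first); pass ``False`` to estimate dilution directly from a
    raw matrix.
    """
    if enforce_total and m.normalization != "total1000":
        raise ValueError("pqn_normalize expects a total-integral-normalized matrix")
    if m.df.shape[0] < 3:
        raise ValueError("PQN needs at least 3 samples")
    vals = m.values
    if reference == "median_all":
        ref = np.median(vals, axis=0)
    elif reference == "median_of_group":
        if groups is None or reference_group is None:
            raise ValueError("median_of_group requires groups and reference_group")
        members = [s for s in m.sample_ids if groups.get(s) == reference_group]
        if not members:
            raise ValueError(f"no samples in group {reference_group!r}")
        ref = np.median(m.df.loc[members].to_numpy(dtype=float), axis=0)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    ok = ref > 0
    if not ok.any():
        raise ValueError("reference spectrum is all zero")
    quot = np.median(vals[:, ok] / ref[ok], axis=1)
    out = NmrBucketMatrix(
        pd.DataFrame(vals / quot[:, None], index=m.df.index, columns=m.df.columns),
        m.bucket_edges,
        "pqn",
        provenance=m.provenance + [f"pqn_reference={reference}"],
    )
    return out, pd.Series(quot, index=m.df.index, name="pqn_quotient")


def align_buckets(
    spectra: Sequence[Spectrum],
    max_shift_ppm: float,
    return_shifts: bool = False,
) -> list[Spectrum] | tuple[list[Spectrum], np.ndarray]:
    """Shift each spectrum onto the cohort median by integer grid steps.

    The lag (at most ``max_shift_ppm``) maximizing the Pearson correlation
    with the median spectrum over the overlapping segment is applied; edges
    are padded with the boundary value. Correlation is scale-free, so global
    intensity differences do not bias the estimate.
    """
    if not spectra:
        return []
    grid = spectra[0].ppm
    for s in spectra[1:]:
        if s.ppm.shape != grid.shape or not np.allclose(s.ppm, grid):
            raise ValueError("align_buckets requires a common ppm grid")
    dppm = float(np.mean(np.diff(grid)))
    span = float(grid[-1] - grid[0])
    if max_shift_ppm >= span:
        raise ValueError("max_shift_ppm must be smaller than the grid span")
    max_lag = int(round(max_shift_ppm / dppm))
    ref = np.median([s.intensity for s in spectra], axis=0)
    out, shifts = [], []
    for s in spectra:
        best_lag, best_r = 0, -np.inf
        for lag in range(-max_lag, max_lag + 1):
            if lag >= 0:
                a, b = s.intensity[lag:], ref[: len(ref) - lag]
            else:
                a, b = s.intensity[:lag], ref[-lag:]
            if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            if r > best_r + 1e-12:
                best_lag, best_r = lag, r
        shifted = np.interp(
            np.arange(len(grid)) + best_lag,
            np.arange(len(grid)),
            s.intensity,
            left=s.intensity[0],
            right=s.intensity[-1],
        )
        out.append(Spectrum(grid.copy(), shifted, s.sample_id))
        shifts.append(-best_lag * dppm)
    if return_shifts:
        return out, np.asarray(shifts)
    return out
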