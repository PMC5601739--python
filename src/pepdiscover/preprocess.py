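"""Spectral preprocessing: smoothing, baseline, noise, normalisation, peaks.

The canonical processing chain, applied in a fixed, logged order by
:func:`preprocess_spectrum`:

1. crop to the acquisition range,
2. moving-average smoothing (5-point window by default, truncated at the
   edges so no data are invented),
3. baseline estimation -- within each mass window the dominant local
   maxima are located and the lowest points between consecutive dominant
   maxima become baseline anchors, linearly interpolated across the grid
   -- followed by subtraction (clamped at zero),
4. local noise estimation by a sliding-window median absolute deviation
   scaled to the Gaussian standard deviation (1.4826 x MAD),
5. total-ion-current (TIC) normalisation: every point divided by the sum
   of all intensities in the spectrum,
6. peak detection at a signal-to-noise cut-off (5.0 by default), with
   centroid m/z computed as the intensity-weighted mean over the
   contiguous region above half the apex height.

S/N is invariant under the global TIC division, so detection behaves
identically whether it runs before or after normalisation; reported peak
intensities are on the normalised scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from pepdiscover.spectra import Spectrum

__all__ = [
    "Peak",
    "PeakList",
    "PreprocessParams",
    "smooth",
    "estimate_baseline",
    "subtract_baseline",
    "estimate_noise",
    "detect_peaks",
    "normalize_tic",
    "preprocess_spectrum",
]


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class Peak:
    """One detected peak: centroid m/z, height above baseline, and S/N."""

    mz: float
    intensity: float
    snr: float

    def __post_init__(self) -> None:
        if self.intensity < 0 or self.snr < 0:
            raise PreprocessError("peak intensity and snr must be >= 0")


@dataclass
class PeakList:
    sample_id: str
    peaks: list[Peak]

    def __post_init__(self) -> None:
        mzs = [p.mz for p in self.peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise PreprocessError("peaks must be sorted strictly by m/z")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mzs(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])


@dataclass(frozen=True)
class PreprocessParams:
    """Tunable parameters of the preprocessing chain.

    ``align_tol_rel`` is carried here because the downstream cross-sample
    alignment assumes per-spectrum mass shifts of no more than this
    relative tolerance (0.1% by default).
    """

    smooth_window: int = 5
    snr_cutoff: float = 5.0
    baseline_mass_window: float = 100.0
    noise_mass_window: float = 100.0
    align_tol_rel: float = 0.001
    mz_min: float = 1000.0
    mz_max: float = 10000.0

    def __post_init__(self) -> None:
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise PreprocessError(f"smooth_window must be odd >= 1, got {self.smooth_window}")
        if self.snr_cutoff <= 0:
            raise PreprocessError("snr_cutoff must be > 0")
        if not 0 < self.align_tol_rel <= 0.01:
            raise PreprocessError("align_tol_rel must be in (0, 0.01]")
        if self.baseline_mass_window <= 0 or self.noise_mass_window <= 0:
            raise PreprocessError("mass windows must be > 0")


def smooth(s: Spectrum, window: int = 5) -> Spectrum:
    """Moving-average smoothing with edge-truncated windows.

    Each point becomes the mean of the intensities within a centered
    ``window``-point window; at the edges the window shrinks to the
    available points (no reflected or zero-padded data).
    """
    if window < 1 or window % 2 == 0:
        raise PreprocessError(f"smoothing window must be odd >= 1, got {window}")
    if window > len(s):
        raise PreprocessError(f"smoothing window {window} exceeds spectrum length {len(s)}")
    if window == 1:
        out = s.copy()
    else:
        kernel = np.ones(window)
        sums = np.convolve(s.intensity, kernel, mode="same")
        counts = np.convolve(np.ones_like(s.intensity), kernel, mode="same")
        out = Spectrum(s.mz.copy(), sums / counts, s.sample_id, list(s.processing_log))
    out.processing_log.append(f"smooth(window={window})")
    return out


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of local maxima; plateaus resolve to their leftmost point."""
    n = len(x)
    if n < 3:
        return np.array([], dtype=int)
    maxima = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j + 1 < n and x[j + 1] < x[i]:
                maxima.append(i)  # leftmost point of the plateau
            i = j + 1
        else:
            i += 1
    return np.array(maxima, dtype=int)


def _mad_sigma(x: np.ndarray) -> float:
    """Robust Gaussian-consistent scale: 1.4826 x median absolute deviation."""
    med = np.median(x)
    return 1.4826 * float(np.median(np.abs(x - med)))


def estimate_baseline(s: Spectrum, mass_window: float = 100.0) -> np.ndarray:
    """Estimate the slowly varying background of a smoothed spectrum.

    The spectrum is partitioned into consecutive windows of ``mass_window``
    Th.  Within each window, dominant local maxima (prominence above three
    times the window's robust noise scale) are located and the minimum
    intensity between each pair of consecutive dominant maxima becomes a
    baseline anchor; windows without two dominant maxima (no peak
    structure) contribute their median, the unbiased location of a
    signal-free stretch -- anchoring such windows at their minimum would
    sit one noise excursion below the true background and shift every
    residual upward.  Anchors are linearly interpolated (and constant-
    extrapolated at the ends) over the full m/z grid.
    """
    if mass_window <= 0:
        raise PreprocessError("mass_window must be > 0")
    mz, y = s.mz, s.intensity
    span = mz[-1] - mz[0]
    if mass_window >= span:
        warnings.warn(
            "baseline mass window wider than the spectrum span; using a flat "
            "global-minimum baseline",
            stacklevel=2,
        )
        return np.full_like(y, float(np.min(y)))

    edges = np.arange(mz[0], mz[-1] + mass_window, mass_window)
    anchor_x: list[float] = []
    anchor_y: list[float] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        i0, i1 = np.searchsorted(mz, lo), np.searchsorted(mz, hi)
        if i1 - i0 < 1:
            continue
        seg = y[i0:i1]
        noise = _mad_sigma(seg)
        maxima = _local_maxima(seg)
        dominant = [m for m in maxima if seg[m] - np.min(seg) > 3 * noise] if noise > 0 else []
        if len(dominant) >= 2:
            for a, b in zip(dominant[:-1], dominant[1:]):
                k = a + int(np.argmin(seg[a : b + 1]))
                anchor_x.append(mz[i0 + k])
                anchor_y.append(seg[k])
        else:
            anchor_x.append(float((mz[i0] + mz[i1 - 1]) / 2.0))
            anchor_y.append(float(np.median(seg)))
    baseline = np.interp(mz, anchor_x, anchor_y)
    return baseline


def subtract_baseline(s: Spectrum, baseline: np.ndarray) -> Spectrum:
    """Subtract a baseline series, clamping the result at zero."""
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != s.intensity.shape:
        raise PreprocessError(
            f"baseline length {len(baseline)} != spectrum length {len(s)}"
        )
    out = Spectrum(
        s.mz.copy(),
        np.maximum(s.intensity - baseline, 0.0),
        s.sample_id,
        list(s.processing_log),
    )
    out.processing_log.append("subtract_baseline")
    return out


def estimate_noise(s: Spectrum, mass_window: float = 100.0) -> np.ndarray:
    """Local noise level by sliding-window MAD, interpolated to every point.

    Windows of ``mass_window`` Th advance by half a window; each
    contributes 1.4826 x MAD at its center.  A spectrum with no variation
    yields zero noise everywhere (with a warning); downstream S/N for a
    positive peak is then infinite.
    """
    if mass_window <= 0:
        raise PreprocessError("mass_window must be > 0")
    mz, y = s.mz, s.intensity
    step = mass_window / 2.0
    centers: list[float] = []
    levels: list[float] = []
    lo = mz[0]
    while lo < mz[-1]:
        hi = lo + mass_window
        i0, i1 = np.searchsorted(mz, lo), np.searchsorted(mz, hi)
        if i1 - i0 >= 3:
            centers.append((lo + min(hi, mz[-1])) / 2.0)
            levels.append(_mad_sigma(y[i0:i1]))
        lo += step
    if not centers:
        centers, levels = [mz[0]], [_mad_sigma(y)]
    noise = np.interp(mz, centers, levels)
    if np.all(noise == 0):
        warnings.warn("spectrum has no local variation; noise level is 0", stacklevel=2)
    return noise


def detect_peaks(
    s: Spectrum, noise: np.ndarray, snr_cutoff: float = 5.0
) -> PeakList:
    """Detect peaks as local maxima with apex S/N at or above the cut-off.

    A point qualifies when it is strictly greater than both neighbours
    (plateaus count once, at their leftmost point) and its intensity over
    the local noise level reaches ``snr_cutoff``.  The centroid m/z is the
    intensity-weighted mean over the contiguous run of points above half
    the apex height.
    """
    noise = np.asarray(noise, dtype=float)
    if noise.shape != s.intensity.shape:
        raise PreprocessError("noise series length must match the spectrum")
    y = s.intensity
    peaks: list[Peak] = []
    for idx in _local_maxima(y):
        apex = y[idx]
        local_noise = noise[idx]
        snr = np.inf if local_noise == 0 else apex / local_noise
        if snr < snr_cutoff:
            continue
        half = apex / 2.0
        lo = idx
        while lo > 0 and y[lo - 1] > half:
            lo -= 1
        hi = idx
        while hi < len(y) - 1 and y[hi + 1] > half:
            hi += 1
        seg = slice(lo, hi + 1)
        weight = y[seg].sum()
        centroid = float(np.dot(s.mz[seg], y[seg]) / weight) if weight > 0 else float(s.mz[idx])
        peaks.append(Peak(centroid, float(apex), float(snr)))
    # merge pathological duplicates (two apices sharing a centroid): keep the taller
    peaks.sort(key=lambda p: (p.mz, -p.intensity))
    deduped: list[Peak] = []
    for p in peaks:
        if deduped and p.mz <= deduped[-1].mz:
            continue
        deduped.append(p)
    return PeakList(s.sample_id, deduped)


def normalize_tic(s: Spectrum) -> Spectrum:
    """Divide every intensity by the spectrum's total intensity sum."""
    total = float(s.intensity.sum())
    if total <= 0:
        raise PreprocessError(
            f"cannot TIC-normalize spectrum {s.sample_id!r}: non-positive total intensity"
        )
    out = Spectrum(s.mz.copy(), s.intensity / total, s.sample_id, list(s.processing_log))
    out.processing_log.append("normalize_tic")
    return out


def crop(s: Spectrum, mz_min: float, mz_max: float) -> Spectrum:
    i0, i1 = np.searchsorted(s.mz, mz_min), np.searchsorted(s.mz, mz_max, side="right")
    if i1 - i0 < 2:
        raise PreprocessError(
            f"spectrum {s.sample_id!r} has fewer than 2 points in [{mz_min}, {mz_max}]"
        )
    out = Spectrum(s.mz[i0:i1].copy(), s.intensity[i0:i1].copy(), s.sample_id, list(s.processing_log))
    out.processing_log.append(f"crop({mz_min:g}, {mz_max:g})")
    return out


def preprocess_spectrum(
    s: Spectrum, params: PreprocessParams | None = None
) -> tuple[Spectrum, PeakList]:
    """Run the full canonical chain on one raw spectrum.

    Returns the processed (smoothed, baseline-subtracted, TIC-normalised)
    spectrum and its detected peak list; every step is appended to the
    spectrum's processing log.  The function is pure: identical input and
    parameters give identical output.
    """
    params = params or PreprocessParams()
    out = crop(s, params.mz_min, params.mz_max)
    out = smooth(out, params.smooth_window)
    baseline = estimate_baseline(out, params.baseline_mass_window)
    # noise is estimated on the raw residual: the zero-clamp of the
    # subtraction step would otherwise collapse the MAD in signal-free
    # regions where about half the residuals are negative
    residual = Spectrum(out.mz, out.intensity - baseline, out.sample_id)
    noise = estimate_noise(residual, params.noise_mass_window)
    out = subtract_baseline(out, baseline)
    total = float(out.intensity.sum())
    out = normalize_tic(out)
    # S/N is invariant under the global division; scale noise to match
    peaks = detect_peaks(out, noise / total, params.snr_cutoff)
    out.processing_log.append(
        f"detect_peaks(snr_cutoff={params.snr_cutoff:g}, n={len(peaks)})"
    )
    return out, peaks
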