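"""Sliding-window Hanning-taper alpha power estimation.

Power is estimated in 0.5 s windows advanced in 0.05 s steps; within each
window the signal is Hann-tapered and Fourier transformed, and power at
the alpha-band bin centers (8, 10, 12, 14 Hz by default -- the native bins
of a 0.5 s window) is averaged.  Power is normalized by the squared sum of
the taper so that a unit tone at a bin center yields power 1/2 regardless
of window length.  Time stamps refer to window centers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dataset import T_START

__all__ = [
    "AlphaPowerTimecourse",
    "AlphaPowerSummary",
    "sliding_alpha_power",
    "combine_planar_power",
    "window_average",
    "baseline_zscore",
    "band_bins",
]


@dataclass
class AlphaPowerTimecourse:
    """Trial x sensor x time-step alpha power.

    ``power`` is NaN where a window extends past a trial's own length;
    ``times`` holds window-center times, s relative to cue onset.
    """

    power: np.ndarray
    times: np.ndarray
    band: tuple = (8.0, 14.0)
    window: float = 0.5
    step: float = 0.05
    freqs: tuple = (8.0, 10.0, 12.0, 14.0)

    @property
    def n_steps(self) -> int:
        return len(self.times)


@dataclass
class AlphaPowerSummary:
    """Trial x sensor alpha power averaged over an analysis window."""

    power: np.ndarray
    window: tuple = (1.0, 2.5)


def band_bins(band: tuple, bin_width: float, window: float, fs: float):
    """Bin centers and DFT bin indices for ``band`` sampled every
    ``bin_width`` Hz; centers must fall on the window's native frequency
    grid (resolution ``1 / window``)."""
    centers = np.arange(band[0], band[1] + 1e-9, bin_width)
    nwin = int(round(window * fs))
    k = centers * nwin / fs
    k_idx = np.round(k).astype(int)
    if np.any(np.abs(k - k_idx) > 1e-6):
        raise ValueError(
            f"bin centers {centers.tolist()} are not native frequencies of a "
            f"{window} s window at {fs} Hz"
        )
    if np.any(k_idx > nwin // 2):
        raise ValueError("band extends beyond the Nyquist frequency")
    return centers, k_idx


def sliding_alpha_power(
    data: np.ndarray,
    fs: float,
    t_start: float = T_START,
    window: float = 0.5,
    step: float = 0.05,
    band: tuple = (8.0, 14.0),
    bin_width: float = 2.0,
) -> AlphaPowerTimecourse:
    """Hanning-taper sliding-window band power along the last axis.

    Parameters
    ----------
    data : ndarray (..., n_samples)
        Trial segments (NaN-padded beyond each trial's length; any window
        touching padding yields NaN power).
    fs : float
        Sampling rate, Hz.
    t_start : float
        Time of the first sample relative to cue onset.

    Returns
    -------
    AlphaPowerTimecourse
        Power per window, averaged over the band's bin centers with equal
        weights.  A window holding a unit-amplitude tone at a bin center
        contributes power 1/2 at that bin.
    """
    nwin = int(round(window * fs))
    nstep = int(round(step * fs))
    n = data.shape[-1]
    if nwin > n:
        raise ValueError("window longer than the data segment")
    centers, k_idx = band_bins(band, bin_width, window, fs)
    taper = np.hanning(nwin)
    norm = taper.sum() ** 2
    t = np.arange(nwin)
    # DFT basis restricted to the band's bins, taper folded in
    basis = (taper[:, None] * np.exp(-2j * np.pi * k_idx[None, :] * t[:, None] / nwin))
    basis = basis.astype(np.complex64)

    n_steps = (n - nwin) // nstep + 1
    out = np.empty(data.shape[:-1] + (n_steps,), dtype=np.float32)
    for m in range(n_steps):
        seg = data[..., m * nstep : m * nstep + nwin]
        X = seg @ basis  # (..., n_bins)
        out[..., m] = (2.0 * (np.abs(X) ** 2) / norm).mean(axis=-1)
    times = t_start + nstep * np.arange(n_steps) / fs + window / 2
    return AlphaPowerTimecourse(
        power=out,
        times=times,
        band=tuple(band),
        window=window,
        step=step,
        freqs=tuple(centers),
    )


def combine_planar_power(
    tc_x: AlphaPowerTimecourse, tc_y: AlphaPowerTimecourse
) -> AlphaPowerTimecourse:
    """Elementwise sum of the two planar components' power (the standard
    convention for combining planar gradient channels)."""
    if tc_x.power.shape != tc_y.power.shape:
        raise ValueError("planar components have mismatching shapes")
    if not np.allclose(tc_x.times, tc_y.times):
        raise ValueError("planar components have mismatching time axes")
    return replace(tc_x, power=tc_x.power + tc_y.power)


def window_average(
    tc: AlphaPowerTimecourse, window: tuple = (1.0, 2.5)
) -> AlphaPowerSummary:
    """Mean power over time steps whose centers fall in the closed window."""
    mask = (tc.times >= window[0]) & (tc.times <= window[1])
    if not mask.any():
        raise ValueError(f"no window centers inside {window}")
    return AlphaPowerSummary(power=tc.power[..., mask].mean(axis=-1), window=tuple(window))


def baseline_zscore(
    series: np.ndarray, times: np.ndarray, baseline: tuple = (-0.75, -0.25)
) -> np.ndarray:
    """Standardize ROI-averaged power timecourses to a pre-cue baseline.

    ``series`` has shape (n_trials, n_series, n_steps) -- typically the two
    hemispheric ROI averages of one subject.  A single affine transform
    (mean/SD pooled over all trials, both series and the baseline steps)
    is applied to every time point, so after the transform the pooled
    baseline has mean 0 and SD 1.  Invariant under positive rescaling and
    shifts of the raw power.
    """
    if series.ndim != 3:
        raise ValueError("series must be (n_trials, n_series, n_steps)")
    if series.shape[0] < 2:
        raise ValueError("baseline standardization needs at least 2 trials")
    mask = (times >= baseline[0]) & (times <= baseline[1])
    if not mask.any():
        raise ValueError(f"no time steps inside baseline {baseline}")
    base = series[..., mask]
    mu = np.nanmean(base)
    sd = np.nanstd(base)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero baseline variance")
    return (series - mu) / sd
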