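"""Gradient-echo relaxometry: BOLD signal to ΔR2* concentration curves.

A sinusoidal end-tidal CO₂ challenge modulates cerebral deoxyhemoglobin and
hence the effective transverse relaxation rate R2*.  For a gradient-echo
signal S(t) = S0·exp(−TE·ΔR2*(t)), the relaxation change is recovered from
the log-ratio of the signal to its temporal mean (single echo), or from the
log-ratio of two echoes, which cancels inflow and receive-field effects
(dual echo).  ΔR2*(t) is treated as proportional to the deoxyhemoglobin
tracer concentration C(t) with unit proportionality in tissue and blood.

Sign convention: an oxygenation (signal) increase maps to a ΔR2* decrease.
The downstream estimators use fundamental-frequency magnitudes and wrapped
phases only, so this sign never needs to be flipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EchoSeries",
    "ConcentrationSeries",
    "QualityMaps",
    "SinusoidFit",
    "single_echo_delta_r2star",
    "dual_echo_delta_r2star",
    "suppress_high_amplitude_voxels",
    "fit_sinusoid",
    "fit_sinusoid_volume",
    "temporal_snr",
    "crop_to_cycles",
]

MIN_TIMEPOINTS = 8


class InvalidSignalError(ValueError):
    """Raised when a masked voxel contains non-positive samples."""


@dataclass
class EchoSeries:
    """One echo of a 4D gradient-echo BOLD acquisition.

    Parameters
    ----------
    data
        Signal intensities, shape (x, y, z, t), arbitrary units.
    te
        Echo time in seconds (e.g. 0.035).
    tr
        Repetition interval in seconds.
    t0
        Acquisition time of the first sample, seconds.
    """

    data: np.ndarray
    te: float
    tr: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D (x,y,z,t) data, got {self.data.ndim}D")
        if self.data.shape[-1] < MIN_TIMEPOINTS:
            raise ValueError(f"need at least {MIN_TIMEPOINTS} time points")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("signal contains non-finite samples")
        if np.any(self.data < 0):
            raise ValueError("signal contains negative samples")
        if self.te <= 0:
            raise ValueError("echo time must be positive")
        if self.tr <= 0:
            raise ValueError("repetition time must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.tr * np.arange(self.n_frames)

    def cropped_to_cycles(self, period: float) -> "EchoSeries":
        """Return a copy truncated to the largest whole number of stimulus cycles."""
        n = crop_to_cycles(self.n_frames, self.tr, period)
        return EchoSeries(self.data[..., :n], te=self.te, tr=self.tr, t0=self.t0)


@dataclass
class ConcentrationSeries:
    """Voxelwise ΔR2*(t) ≡ tracer concentration curves, units 1/s.

    Curves have (near-)zero temporal mean by construction because the
    baseline S0 is the per-voxel temporal mean of the signal.
    """

    data: np.ndarray
    tr: float
    t0: float = 0.0
    r_y_tissue: float = 1.0
    r_y_blood: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("expected 4D (x,y,z,t) concentration data")
        if self.r_y_tissue <= 0 or self.r_y_blood <= 0:
            raise ValueError("r_Y proportionality coefficients must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.tr * np.arange(self.n_frames)

    def cropped_to_cycles(self, period: float) -> "ConcentrationSeries":
        n = crop_to_cycles(self.n_frames, self.tr, period)
        return ConcentrationSeries(
            self.data[..., :n], tr=self.tr, t0=self.t0,
            r_y_tissue=self.r_y_tissue, r_y_blood=self.r_y_blood,
        )


@dataclass
class QualityMaps:
    """Per-voxel sinusoid-fit summaries of the raw BOLD signal.

    amplitude : fitted peak-to-peak amplitude, percent of the voxel baseline
    phase     : fitted phase in [−π, π), atan2(cos-coef, sin-coef) convention
    tsnr      : peak-to-peak amplitude over residual standard deviation
    vein_mask : voxels suppressed from tissue statistics (high amplitude)
    """

    amplitude: np.ndarray
    phase: np.ndarray
    tsnr: np.ndarray
    vein_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.vein_mask is None:
            self.vein_mask = np.zeros(self.amplitude.shape, dtype=bool)


def crop_to_cycles(n_frames: int, tr: float, period: float) -> int:
    """Number of frames spanning the largest whole number of stimulus cycles.

    Integer-cycle cropping removes spectral leakage and makes per-cycle
    integrals well defined.
    """
    frames_per_cycle = period / tr
    n_cycles = int(np.floor(n_frames / frames_per_cycle))
    if n_cycles < 1:
        raise ValueError("series shorter than one stimulus cycle")
    # keep an integer frame count closest to (but not exceeding) n_cycles
    n = int(round(n_cycles * frames_per_cycle))
    return min(n, n_frames)


def single_echo_delta_r2star(
    series: EchoSeries, mask: np.ndarray | None = None
) -> ConcentrationSeries:
    """ΔR2*(t) = −(1/TE)·ln(S(t)/S0) with S0 the per-voxel temporal mean.

    Parameters
    ----------
    series
        Single-echo BOLD data.
    mask
        Optional 3D boolean brain mask.  Outside the mask the output is zero;
        inside, any non-positive sample raises :class:`InvalidSignalError`.
    """
    data = series.data
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    bad = np.any(data[mask] <= 0, axis=-1)
    if np.any(bad):
        idx = tuple(int(i) for i in np.argwhere(mask)[bad][0])
        raise InvalidSignalError(
            f"non-positive signal sample inside mask at voxel {idx}"
        )
    out = np.zeros_like(data)
    s = data[mask]
    s0 = s.mean(axis=-1, keepdims=True)
    out[mask] = -np.log(s / s0) / series.te
    return ConcentrationSeries(out, tr=series.tr, t0=series.t0)


def dual_echo_delta_r2star(
    series1: EchoSeries, series2: EchoSeries, mask: np.ndarray | None = None
) -> ConcentrationSeries:
    """Dual-echo ΔR2* from the echo-ratio log, cancelling S0 modulations.

    ΔR2*(t) = [ln(S1/S0,1) − ln(S2/S0,2)] / (TE2 − TE1), TE2 > TE1.
    """
    if series1.data.shape != series2.data.shape:
        raise ValueError("echo series must share grid and time-point count")
    if (series1.tr != series2.tr) or (series1.t0 != series2.t0):
        raise ValueError("echo series must share timing")
    if series2.te <= series1.te:
        raise ValueError("second echo time must exceed the first")
    if mask is None:
        mask = np.ones(series1.data.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(series1.data)
    for s in (series1, series2):
        if np.any(s.data[mask] <= 0):
            raise InvalidSignalError("non-positive signal sample inside mask")
    s1 = series1.data[mask]
    s2 = series2.data[mask]
    l1 = np.log(s1 / s1.mean(axis=-1, keepdims=True))
    l2 = np.log(s2 / s2.mean(axis=-1, keepdims=True))
    out[mask] = (l1 - l2) / (series2.te - series1.te)
    return ConcentrationSeries(out, tr=series1.tr, t0=series1.t0)


@dataclass
class SinusoidFit:
    """Least-squares fit of offset + drift + sinusoid at a fixed frequency.

    Model: y(t) = a + d·(t − t̄) + b·sin(2πf t) + c·cos(2πf t).
    phase = atan2(c, b), so a pure sin(2πf t) has phase 0; amplitude_pp is
    the raw peak-to-peak 2√(b²+c²); amplitude_pp_percent divides by the
    offset a (NaN when the offset is not positive, e.g. zero-mean ΔR2*).
    """

    offset: float
    drift: float
    b: float
    c: float

    @property
    def amplitude_pp(self) -> float:
        return 2.0 * float(np.hypot(self.b, self.c))

    @property
    def amplitude_pp_percent(self) -> float:
        if self.offset <= 0:
            return float("nan")
        return self.amplitude_pp / self.offset * 100.0

    @property
    def phase(self) -> float:
        ph = float(np.arctan2(self.c, self.b))
        return float((ph + np.pi) % (2 * np.pi) - np.pi)


def _design_matrix(t: np.ndarray, f_c: float) -> np.ndarray:
    w = 2 * np.pi * f_c
    return np.column_stack(
        [np.ones_like(t), t - t.mean(), np.sin(w * t), np.cos(w * t)]
    )


def _check_fit_preconditions(n: int, tr: float, f_c: float) -> None:
    if f_c <= 0:
        raise ValueError("fundamental frequency must be positive")
    if f_c >= 0.5 / tr:
        raise ValueError("fundamental frequency at or above Nyquist")
    if n * tr < 2.0 / f_c:
        raise ValueError("need at least two stimulus cycles for a sinusoid fit")


def fit_sinusoid(signal: np.ndarray, tr: float, f_c: float, t0: float = 0.0) -> SinusoidFit:
    """Fit offset + linear drift + sinusoid at ``f_c`` to a 1D series."""
    y = np.asarray(signal, dtype=float)
    _check_fit_preconditions(y.size, tr, f_c)
    t = t0 + tr * np.arange(y.size)
    X = _design_matrix(t, f_c)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return SinusoidFit(offset=beta[0], drift=beta[1], b=beta[2], c=beta[3])


def fit_sinusoid_volume(
    data: np.ndarray, tr: float, f_c: float, t0: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised sinusoid fit over a 4D volume.

    Returns (offset, b, c, residual_sd) as 3D maps; residual_sd is the
    standard deviation of the series after removing all four regressors.
    """
    data = np.asarray(data, dtype=float)
    nt = data.shape[-1]
    _check_fit_preconditions(nt, tr, f_c)
    t = t0 + tr * np.arange(nt)
    X = _design_matrix(t, f_c)
    flat = data.reshape(-1, nt).T  # (t, vox)
    beta, *_ = np.linalg.lstsq(X, flat, rcond=None)
    resid = flat - X @ beta
    resid_sd = resid.std(axis=0, ddof=0)
    shape3 = data.shape[:3]
    return (
        beta[0].reshape(shape3),
        beta[2].reshape(shape3),
        beta[3].reshape(shape3),
        resid_sd.reshape(shape3),
    )


def temporal_snr(signal: np.ndarray, tr: float, f_c: float, t0: float = 0.0) -> float:
    """Peak-to-peak fitted amplitude over the residual standard deviation.

    The residual is the signal after removing offset, linear trend, and the
    fundamental sinusoid.  A zero-variance residual (pure sinusoid) returns
    the +inf sentinel.
    """
    y = np.asarray(signal, dtype=float)
    fit = fit_sinusoid(y, tr, f_c, t0=t0)
    t = t0 + tr * np.arange(y.size)
    X = _design_matrix(t, f_c)
    resid = y - X @ np.array([fit.offset, fit.drift, fit.b, fit.c])
    sd = float(resid.std())
    scale = max(1.0, float(np.abs(y).max()))
    if sd <= 1e-12 * scale:
        return float("inf")
    return fit.amplitude_pp / sd


def quality_maps(
    series: EchoSeries, f_c: float, mask: np.ndarray | None = None
) -> QualityMaps:
    """Amplitude (% of baseline), phase and tSNR maps of a BOLD echo."""
    offset, b, c, resid_sd = fit_sinusoid_volume(series.data, series.tr, f_c, series.t0)
    pp = 2.0 * np.hypot(b, c)
    with np.errstate(divide="ignore", invalid="ignore"):
        amplitude = np.where(offset > 0, pp / offset * 100.0, np.nan)
        tsnr = np.where(resid_sd > 0, pp / resid_sd, np.inf)
    phase = (np.arctan2(c, b) + np.pi) % (2 * np.pi) - np.pi
    if mask is not None:
        outside = ~np.asarray(mask, dtype=bool)
        amplitude = amplitude.copy()
        amplitude[outside] = np.nan
        tsnr = tsnr.copy()
        tsnr[outside] = np.nan
    return QualityMaps(amplitude=amplitude, phase=phase, tsnr=tsnr)


def suppress_high_amplitude_voxels(
    quality: QualityMaps | np.ndarray,
    brain_mask: np.ndarray,
    percentile: float = 0.98,
) -> np.ndarray:
    """Mask of pial-vein-like voxels to EXCLUDE from tissue statistics.

    A voxel is excluded when its fitted amplitude strictly exceeds the given
    percentile (linear interpolation between order statistics) of in-brain
    amplitudes.
    """
    if not 0.0 < percentile < 1.0:
        raise ValueError("percentile must lie in (0, 1)")
    amplitude = quality.amplitude if isinstance(quality, QualityMaps) else np.asarray(quality)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    vals = amplitude[brain_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("empty brain mask (no finite amplitudes)")
    cut = np.percentile(vals, percentile * 100.0)
    return brain_mask & (np.nan_to_num(amplitude, nan=-np.inf) > cut)
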