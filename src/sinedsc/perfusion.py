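"""Frequency-domain tracer-kinetics perfusion estimators.

The tracer-kinetics convolution C_tissue = C_blood ⊗ (CBF·R) becomes a
per-frequency product in the Fourier domain.  With a single-frequency
sinusoidal drive the estimation collapses to the fundamental f_c:

    CBF_raw = |C_tissue(f_c)| / (|C_VOF(f_c)| · |R(f_c)|)        [1/s]

with the residue function modeled as a decaying exponential R(t)=e^{−t/τ},
|R(f)| = 1/sqrt(1/τ² + (2πf)²), and the time constant identified with the
tissue-to-vein phase delay, τ = TD.  Working with magnitudes makes the
estimate independent of the tissue/VOF relative delay, which is what lets
an anti-causal (venous-referenced) system be quantified at all.

Scaling to physiological units uses 6000·κ/ρ with the small-vessel
hematocrit correction κ = 1/0.69 (the deoxygenation contrast lives in red
cells) and brain density ρ = 1.05 g/mL.  Applying the same κ/ρ factor to
CBF and CBV keeps the central-volume theorem MTT = CBV/CBF consistent; the
factor is toggleable for CBF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import circulant

from typing import TYPE_CHECKING

from .relaxometry import ConcentrationSeries, EchoSeries
from .spectral import (
    SpectralSummary,
    VOF,
    _demodulate_rows,
    demodulate_curve,
    wrap_delay,
)

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import GasTrace

__all__ = [
    "KineticsConfig",
    "ResidueModel",
    "PerfusionMaps",
    "CVRResult",
    "residue_magnitude",
    "time_delay_map",
    "clip_tau",
    "cbf_frequency_domain",
    "cbv_map",
    "cbv_map_auc",
    "mtt_map",
    "cvr_map",
    "flow_timecourse",
    "svd_deconvolution_oracle",
]

SECONDS_PER_MINUTE = 60.0


@dataclass
class KineticsConfig:
    """Constants and switches of the tracer-kinetics quantification.

    kappa : small-vessel-to-large-vessel hematocrit correction (default 1/0.69)
    rho   : brain density, g/mL (default 1.05)
    tau_floor / tau_cap : bounds on the residue time constant, seconds;
        ``None`` defers to TR/2 and period/2 at use time
    apply_kappa_to_cbf : apply the κ/ρ scaling to CBF as well as CBV so
        that MTT = CBV/CBF is unit-consistent
    etco2_reference : mmHg, operating point of the CBF(t) linear model
    """

    kappa: float = 1.0 / 0.69
    rho: float = 1.05
    tau_floor: float | None = None
    tau_cap: float | None = None
    apply_kappa_to_cbf: bool = True
    etco2_reference: float = 40.0

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.rho <= 0:
            raise ValueError("kappa and rho must be positive")

    @property
    def kappa_over_rho(self) -> float:
        return self.kappa / self.rho


@dataclass
class ResidueModel:
    """Decaying-exponential residue function R(t) = e^{−t/τ}."""

    tau: float
    form: str = "decaying exponential"

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("residue time constant must be positive")

    def magnitude(self, f: np.ndarray | float) -> np.ndarray | float:
        return residue_magnitude(self.tau, f)


def residue_magnitude(tau: np.ndarray | float, f: np.ndarray | float):
    """|R(f)| = 1/sqrt(1/τ² + (2πf)²), seconds.

    Equals τ at DC, decreasing towards 1/(2πf) at high frequency.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau[np.isfinite(tau)] <= 0):
        raise ValueError("residue time constant must be positive")
    out = 1.0 / np.sqrt(1.0 / tau**2 + (2 * np.pi * np.asarray(f, dtype=float)) ** 2)
    return out if out.ndim else float(out)


def time_delay_map(
    phase: np.ndarray | float,
    phase_venous: float,
    f_c: float,
) -> np.ndarray | float:
    """TD = (φ_tissue − φ_venous)/(2π f_c), wrapped into [0, period).

    With the sin/cos phase convention (a delayed sinusoid has phase
    −2πf_c·delay), this is the non-negative tissue-to-vein interval; the
    vein itself maps to 0 and undefined (NaN) phases propagate.
    """
    period = 1.0 / f_c
    td = (np.asarray(phase, dtype=float) - phase_venous) / (2 * np.pi * f_c)
    td = np.where(np.isnan(td), np.nan, wrap_delay(td, period))
    return td if np.ndim(td) else float(td)


def clip_tau(
    td: np.ndarray, f_c: float, tr: float, cfg: KineticsConfig
) -> tuple[np.ndarray, int, int]:
    """Bound τ=TD into [tau_floor, tau_cap]; returns (tau, n_floored, n_capped).

    The floor (default TR/2) keeps |R(f_c)| finite and well conditioned; the
    cap (default period/2) keeps the first-order phase-delay≈τ identification
    meaningful.
    """
    floor = cfg.tau_floor if cfg.tau_floor is not None else tr / 2.0
    cap = cfg.tau_cap if cfg.tau_cap is not None else 0.5 / f_c
    td = np.asarray(td, dtype=float)
    finite = np.isfinite(td)
    n_floored = int(np.sum(finite & (td < floor)))
    n_capped = int(np.sum(finite & (td > cap)))
    return np.clip(td, floor, cap), n_floored, n_capped


def cbf_frequency_domain(
    spec_tissue: SpectralSummary,
    vof: VOF | complex,
    td_map: np.ndarray,
    cfg: KineticsConfig | None = None,
    tr: float = 1.5,
) -> np.ndarray:
    """Single-frequency CBF map, mL/100 g/min.

    Per voxel: raw flow = |C_t(f_c)| / (|C_VOF(f_c)|·|R(f_c; τ=TD)|), the
    least-squares solution of the magnitude-spectrum fit when only the
    fundamental is used; scaled by 6000·κ/ρ (κ/ρ optional via config).
    """
    cfg = cfg or KineticsConfig()
    vof_coeff = vof.coeff if isinstance(vof, VOF) else vof
    vof_mag = abs(vof_coeff)
    if vof_mag <= 0:
        raise ValueError("VOF fundamental magnitude must be strictly positive")
    tau, n_floored, n_capped = clip_tau(td_map, spec_tissue.f_c, tr, cfg)
    if n_floored or n_capped:
        warnings.warn(
            f"residue time constant bounded in {n_floored} (floor) / "
            f"{n_capped} (cap) voxels",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r_mag = 1.0 / np.sqrt(1.0 / tau**2 + (2 * np.pi * spec_tissue.f_c) ** 2)
        raw = spec_tissue.magnitude / (vof_mag * r_mag)
    scale = SECONDS_PER_MINUTE * 100.0
    if cfg.apply_kappa_to_cbf:
        scale *= cfg.kappa_over_rho
    return raw * scale


def cbf_band_fit(
    conc_tissue: ConcentrationSeries,
    vof_curve: np.ndarray,
    td_map: np.ndarray,
    f_c: float,
    cfg: KineticsConfig | None = None,
    band_bins: int = 2,
) -> np.ndarray:
    """Multi-bin magnitude-spectrum CBF fit over f_c ± ``band_bins`` DFT bins.

    Robustness variant of the single-frequency estimator: the least-squares
    flow is Σ|C_t||C_b||R| / Σ(|C_b||R|)² over the band.  Units as
    :func:`cbf_frequency_domain`.
    """
    cfg = cfg or KineticsConfig()
    conc = conc_tissue.cropped_to_cycles(1.0 / f_c)
    nt = conc.n_frames
    freqs = np.fft.rfftfreq(nt, conc.tr)
    k_c = int(np.argmin(np.abs(freqs - f_c)))
    lo, hi = max(1, k_c - band_bins), min(len(freqs) - 1, k_c + band_bins)
    band = np.arange(lo, hi + 1)
    f_band = freqs[band]
    vof_mag = np.abs(np.fft.rfft(vof_curve[:nt] - np.mean(vof_curve[:nt]))[band])
    if not np.all(vof_mag > 0):
        raise ValueError("VOF magnitude vanishes inside the fit band")
    tau, _, _ = clip_tau(td_map, f_c, conc.tr, cfg)
    r_mag = 1.0 / np.sqrt(1.0 / tau[..., None] ** 2 + (2 * np.pi * f_band) ** 2)
    flat = conc.data.reshape(-1, nt)
    t_mag = np.abs(np.fft.rfft(flat - flat.mean(axis=-1, keepdims=True), axis=-1)[:, band])
    t_mag = t_mag.reshape(conc.data.shape[:3] + (len(band),))
    denom = (vof_mag * r_mag) ** 2
    raw = (t_mag * vof_mag * r_mag).sum(axis=-1) / denom.sum(axis=-1)
    scale = SECONDS_PER_MINUTE * 100.0
    if cfg.apply_kappa_to_cbf:
        scale *= cfg.kappa_over_rho
    return raw * scale


def cbv_map(
    spec_tissue: SpectralSummary,
    vof: VOF | complex,
    cfg: KineticsConfig | None = None,
) -> np.ndarray:
    """CBV = (κ/ρ)·100·|C_tissue(f_c)|/|C_VOF(f_c)|, mL/100 g.

    For zero-mean periodic curves the literal ratio of curve integrals is
    0/0; over whole cycles the ratio of rectified areas equals the ratio of
    fundamental magnitudes, which is used here as the steady-state
    equivalent (see :func:`cbv_map_auc` for the rectified-AUC variant).
    """
    cfg = cfg or KineticsConfig()
    vof_coeff = vof.coeff if isinstance(vof, VOF) else vof
    vof_mag = abs(vof_coeff)
    if vof_mag <= 0:
        raise ValueError("VOF fundamental magnitude must be strictly positive")
    return cfg.kappa_over_rho * 100.0 * spec_tissue.magnitude / vof_mag


def cbv_map_auc(
    conc_tissue: ConcentrationSeries,
    vof_curve: np.ndarray,
    f_c: float,
    cfg: KineticsConfig | None = None,
) -> np.ndarray:
    """Rectified-AUC CBV variant: (κ/ρ)·100·∫|C_t−C̄_t|dt / ∫|C_b−C̄_b|dt.

    Mirrors the integral-ratio definition directly; on noiseless
    integer-cycle sinusoids it equals the magnitude-ratio variant.
    """
    cfg = cfg or KineticsConfig()
    conc = conc_tissue.cropped_to_cycles(1.0 / f_c)
    nt = conc.n_frames
    v = np.asarray(vof_curve, dtype=float)[:nt]
    v_auc = np.abs(v - v.mean()).sum() * conc.tr
    if v_auc <= 0:
        raise ValueError("VOF rectified area must be strictly positive")
    dev = conc.data - conc.data.mean(axis=-1, keepdims=True)
    t_auc = np.abs(dev).sum(axis=-1) * conc.tr
    return cfg.kappa_over_rho * 100.0 * t_auc / v_auc


def mtt_map(cbv: np.ndarray, cbf: np.ndarray) -> np.ndarray:
    """Central volume theorem: MTT = CBV/CBF, converted min→s (×60).

    Voxels with zero/undefined CBF get NaN.
    """
    cbv = np.asarray(cbv, dtype=float)
    cbf = np.asarray(cbf, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mtt = np.where(cbf > 0, cbv / cbf * SECONDS_PER_MINUTE, np.nan)
    return mtt


def flow_timecourse(
    cbf0: float,
    cvr: float,
    etco2: np.ndarray,
    etco2_reference: float = 40.0,
) -> np.ndarray:
    """Linear CBF response model: CBF(t) = CBF0·(1 + CVR·(EtCO₂(t) − ref)/100).

    ``cvr`` is in %/mmHg.  A typical grey-matter CVR of 0.2 %/mmHg with a
    5 mmHg peak-to-peak drive oscillates flow by only ~1% of baseline, which
    is why the sinusoidal estimate can be read as average (baseline) flow.
    """
    etco2 = np.asarray(etco2, dtype=float)
    return cbf0 * (1.0 + cvr * (etco2 - etco2_reference) / 100.0)


@dataclass
class CVRResult:
    """Voxelwise cerebrovascular reactivity estimates.

    cvr          : slope of percent BOLD on aligned EtCO₂, %/mmHg
    cvr_delay    : per-voxel BOLD-to-EtCO₂ lag, seconds, in [−period/2, period/2)
    global_lag   : brain-mean lag from cross-correlation, seconds
    cbf_cvr_ratio: CBF/CVR map when a CBF map was supplied, else None
    """

    cvr: np.ndarray
    cvr_delay: np.ndarray
    global_lag: float
    cbf_cvr_ratio: np.ndarray | None = None


def _percent_signal(data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.full(data.shape, np.nan)
    s = data[mask]
    out[mask] = 100.0 * (s / s.mean(axis=-1, keepdims=True) - 1.0)
    return out


def cvr_map(
    bold: EchoSeries,
    gas: "GasTrace",
    brain_mask: np.ndarray,
    f_c: float,
    cbf: np.ndarray | None = None,
    per_voxel_alignment: bool = True,
) -> CVRResult:
    """CVR from percent BOLD regressed on temporally aligned EtCO₂.

    Alignment is two-stage: a global lag maximising the cross-correlation
    between the brain-mean percent-signal series and EtCO₂ over lags within
    ±period/2 (warned when the search hits the boundary), then a per-voxel
    refinement from the phase difference at f_c (reported as ``cvr_delay``).
    Each voxel's EtCO₂ regressor is the trace linearly interpolated at
    t − lag; frames whose shifted time falls outside the recorded trace are
    dropped from that voxel's ordinary least squares.
    """
    period = 1.0 / f_c
    brain_mask = np.asarray(brain_mask, dtype=bool)
    t_frames = bold.times
    co2 = np.interp(t_frames, gas.t, gas.etco2)
    if np.std(co2) <= 0:
        raise ValueError("EtCO2 trace has zero variance on the frame grid")
    psc = _percent_signal(bold.data, brain_mask)
    mean_psc = np.nanmean(psc[brain_mask], axis=0)

    # global lag: discrete cross-correlation on the TR grid within ±period/2
    max_shift = int(np.floor(0.5 * period / bold.tr))
    lags = np.arange(-max_shift, max_shift + 1)
    y = mean_psc - mean_psc.mean()
    z = co2 - co2.mean()
    cc = np.array([
        np.dot(y[max(0, k):len(y) + min(0, k)], z[max(0, -k):len(z) - max(0, k)])
        / max(1, len(y) - abs(k))
        for k in lags
    ])
    k_best = int(lags[np.argmax(cc)])
    global_lag = k_best * bold.tr
    if abs(k_best) == max_shift:
        warnings.warn("global lag search hit the ±period/2 boundary", stacklevel=2)

    nt = bold.n_frames
    if per_voxel_alignment:
        # phase-based per-voxel lag at the fundamental (wrapped to ±period/2)
        phi_co2 = np.angle(demodulate_curve(co2, bold.tr, f_c, bold.t0))
        coeff = _demodulate_rows(psc[brain_mask], bold.tr, f_c, bold.t0)
        phi_vox = np.angle(coeff)
        d = (phi_co2 - phi_vox) / (2 * np.pi * f_c)
        d = np.mod(d + period / 2.0, period) - period / 2.0
        delays = d
    else:
        delays = np.full(int(brain_mask.sum()), global_lag)

    # per-voxel OLS of percent signal on EtCO2 evaluated at t − lag
    shifted_t = t_frames[None, :] - delays[:, None]
    valid = (shifted_t >= gas.t[0]) & (shifted_t <= gas.t[-1])
    z_mat = np.interp(shifted_t.ravel(), gas.t, gas.etco2).reshape(shifted_t.shape)
    y_mat = psc[brain_mask]
    w = valid.astype(float)
    n = w.sum(axis=1)
    sy = (w * y_mat).sum(axis=1)
    sz = (w * z_mat).sum(axis=1)
    syz = (w * y_mat * z_mat).sum(axis=1)
    szz = (w * z_mat**2).sum(axis=1)
    denom = szz - sz**2 / n
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(denom > 0, (syz - sy * sz / n) / denom, np.nan)

    cvr = np.full(bold.data.shape[:3], np.nan)
    cvr[brain_mask] = slope
    delay_map = np.full(bold.data.shape[:3], np.nan)
    delay_map[brain_mask] = delays
    ratio = None
    if cbf is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(np.abs(cvr) > 0, cbf / cvr, np.nan)
    return CVRResult(cvr=cvr, cvr_delay=delay_map, global_lag=global_lag,
                     cbf_cvr_ratio=ratio)


def svd_deconvolution_oracle(
    conc_tissue: ConcentrationSeries | np.ndarray,
    vof_curve: np.ndarray,
    tr: float | None = None,
    threshold: float = 0.1,
) -> np.ndarray:
    """Time-domain truncated-SVD deconvolution comparator, raw flow in 1/s.

    Discretises C_tissue = C_VOF ⊛ (CBF·R) as a circulant (periodic, hence
    delay-insensitive) system A x = c_t with A = TR·circ(c_VOF), zeroes
    singular values below ``threshold``·max, and reports CBF as the maximum
    of the recovered flow-scaled residue per voxel.  Serves as the internal
    cross-check of the frequency-domain estimator; like all truncated-SVD
    DSC solvers it underestimates when the VOF lacks high-frequency content.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if isinstance(conc_tissue, ConcentrationSeries):
        data = conc_tissue.data.reshape(-1, conc_tissue.n_frames)
        tr = conc_tissue.tr
        out_shape = conc_tissue.data.shape[:3]
    else:
        data = np.atleast_2d(np.asarray(conc_tissue, dtype=float))
        if tr is None:
            raise ValueError("tr is required for raw-array input")
        out_shape = data.shape[:-1] if data.ndim > 2 else (data.shape[0],)
        data = data.reshape(-1, data.shape[-1])
    vof_curve = np.asarray(vof_curve, dtype=float)
    if vof_curve.size != data.shape[-1]:
        raise ValueError("tissue curves and VOF must share the time grid")
    a = tr * circulant(vof_curve)
    u, s, vt = np.linalg.svd(a)
    keep = s >= threshold * s.max()
    s_inv = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
    x = (vt.T * s_inv) @ (u.T @ data.T)  # (t, vox)
    return x.max(axis=0).reshape(out_shape)


@dataclass
class PerfusionMaps:
    """Bundle of perfusion/reactivity volumes with unit metadata."""

    cbf: np.ndarray          # mL/100 g/min
    cbv: np.ndarray          # mL/100 g
    td: np.ndarray           # s
    mtt: np.ndarray          # s
    cvr: np.ndarray | None = None        # %/mmHg
    cvr_delay: np.ndarray | None = None  # s
    cbf_cvr_ratio: np.ndarray | None = None
    tsnr: np.ndarray | None = None
    units: dict = field(default_factory=lambda: {
        "cbf": "mL/100g/min", "cbv": "mL/100g", "td": "s", "mtt": "s",
        "cvr": "%/mmHg", "cvr_delay": "s", "cbf_cvr_ratio": "(mL/100g/min)/(%/mmHg)",
        "tsnr": "dimensionless",
    })
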