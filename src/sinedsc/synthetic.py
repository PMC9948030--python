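"""Digital phantoms for sinusoidal-CO₂ deoxygenation DSC.

The generator renders multi-echo gradient-echo BOLD volumes from the same
frequency-domain tracer-kinetics model the estimators invert, with known
ground truth, so the whole pipeline is testable without acquired data.

Forward model (steady-state, per voxel):

* the EtCO₂ drive is a sinusoid (default 35–45 mmHg, 60 s period);
* vein voxels carry the blood concentration C_b(t) = −A_v·sin(2πf_c(t−d_v)),
  the sign chosen so that a CO₂ (signal) increase lowers ΔR2*;
* tissue voxels carry the steady-state response of the exponential-residue
  kinetics: amplitude A_v·CBF_raw·|R(f_c; τ=TD)| and phase LEADING the vein
  by exactly TD seconds (the contrast drains to the veins, so the system is
  anti-causal and the vein is latest);
* each echo is rendered as S(t) = S0·exp(−TE·C(t)) plus white Gaussian
  noise calibrated to a whole-brain temporal-SNR target.

Because the single-frequency model ties the tissue/vein amplitude ratio to
CBF_raw·|R(f_c; TD)|, the ground-truth CBV (= CBF·|R|/60) and CVR (∝ the
rendered BOLD amplitude) are DERIVED from CBF and TD rather than set
independently; this keeps the phantom exactly self-consistent with the
estimators' model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0, i1

from .perfusion import KineticsConfig, residue_magnitude, SECONDS_PER_MINUTE
from .relaxometry import EchoSeries

__all__ = [
    "GasTrace",
    "PhantomSpec",
    "GroundTruth",
    "Phantom",
    "generate_etco2_trace",
    "generate_phantom",
    "convolve_residue",
    "generate_deconvolution_curves",
]

LABEL_BACKGROUND = 0
LABEL_GM = 1
LABEL_WM = 2
LABEL_VEIN = 3


@dataclass
class GasTrace:
    """Timestamped end-tidal gas recordings (mmHg)."""

    t: np.ndarray
    etco2: np.ndarray
    eto2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.etco2 = np.asarray(self.etco2, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.etco2.shape:
            raise ValueError("t and etco2 must be 1D arrays of equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.etco2 <= 0) or np.any(self.etco2 > 100):
            raise ValueError("EtCO2 outside the (0, 100] mmHg plausibility range")
        if self.eto2 is not None:
            self.eto2 = np.asarray(self.eto2, dtype=float)


def generate_etco2_trace(
    period: float = 60.0,
    baseline: float = 40.0,
    peak_to_peak: float = 10.0,
    duration: float = 330.0,
    dt: float = 0.5,
    jitter_sd: float = 0.0,
    seed: int | None = None,
    eto2: float = 110.0,
) -> GasTrace:
    """Sinusoidal EtCO₂ target trace: baseline + (pp/2)·sin(2πt/period).

    Defaults swing between 35 and 45 mmHg with a 60 s period.  Optional
    zero-mean Gaussian jitter emulates breath-to-breath targeting error.
    """
    if peak_to_peak < 0:
        raise ValueError("peak_to_peak must be non-negative")
    if duration < 2 * period:
        raise ValueError("trace must span at least two stimulus periods")
    t = np.arange(0.0, duration, dt)
    co2 = baseline + 0.5 * peak_to_peak * np.sin(2 * np.pi * t / period)
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        co2 = co2 + rng.normal(0.0, jitter_sd, size=t.shape)
    return GasTrace(t=t, etco2=co2, eto2=np.full_like(t, eto2))


@dataclass
class PhantomSpec:
    """Forward-model parameters of the digital phantom.

    Compartment ground truth mirrors in-vivo grey/white-matter magnitudes
    (CBF ≈ 48 / 25 mL/100 g/min, tissue-to-vein delays ≈ 6.6 / 6.3 s).  The
    vein compartment spans slightly more than 2% of the brain at one common
    delay so the 98th-percentile venous-phase rule recovers the true venous
    phase exactly.  ``tsnr_target`` calibrates the additive noise to the
    whole-brain temporal SNR observed with this stimulus (≈1.36); ``None``
    renders a noiseless phantom.
    """

    shape: tuple[int, int, int] = (32, 32, 8)
    tr: float = 1.5
    te: tuple[float, ...] = (0.035, 0.090)
    n_frames: int = 220
    period: float = 60.0
    etco2_baseline: float = 40.0
    etco2_peak_to_peak: float = 10.0
    gm_cbf: float = 48.0
    gm_td: float = 6.6
    wm_cbf: float = 25.0
    wm_td: float = 6.3
    n_vein: int = 120
    vein_amplitude: float = 6.0   # ΔR2* half-amplitude of pure blood, 1/s
    vein_delay: float = 10.0      # seconds after the stimulus reference
    s0: float = 1000.0
    tsnr_target: float | None = 1.36
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period < 2 * self.tr:
            raise ValueError("stimulus period below Nyquist (period < 2·TR)")
        for v in (self.gm_cbf, self.gm_td, self.wm_cbf, self.wm_td,
                  self.vein_amplitude, self.vein_delay, self.s0):
            if v <= 0:
                raise ValueError("all ground-truth parameters must be positive")
        if self.n_vein < 20:
            raise ValueError("need at least n_vof (20) vein voxels")

    @property
    def f_c(self) -> float:
        return 1.0 / self.period

    @property
    def duration(self) -> float:
        return self.n_frames * self.tr

    def cbf_raw(self, cbf: float) -> float:
        """mL/100 g/min → raw flow in 1/s under the configured κ/ρ scaling."""
        scale = SECONDS_PER_MINUTE * 100.0
        if self.kinetics.apply_kappa_to_cbf:
            scale *= self.kinetics.kappa_over_rho
        return cbf / scale


@dataclass
class GroundTruth:
    """True parameter maps aligned to the phantom grid.

    labels: 0 background, 1 grey-matter-like, 2 white-matter-like, 3 vein.
    CBF/CBV/CVR are NaN outside tissue (CBF also in veins, where the notion
    of flow per tissue mass does not apply).
    """

    cbf: np.ndarray
    cbv: np.ndarray
    td: np.ndarray
    cvr: np.ndarray
    labels: np.ndarray

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def gm_mask(self) -> np.ndarray:
        return self.labels == LABEL_GM

    @property
    def wm_mask(self) -> np.ndarray:
        return self.labels == LABEL_WM

    @property
    def vein_mask(self) -> np.ndarray:
        return self.labels == LABEL_VEIN


@dataclass
class Phantom:
    echoes: list[EchoSeries]
    gas: GasTrace
    truth: GroundTruth
    spec: PhantomSpec
    concentration: np.ndarray  # noiseless ΔR2*(t), for debugging/cross-checks


def _phantom_labels(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.shape
    labels = np.zeros(spec.shape, dtype=np.int16)
    mx = max(1, nx // 8)
    my = max(1, ny // 8)
    brain = np.zeros(spec.shape, dtype=bool)
    brain[mx:nx - mx, my:ny - my, :] = True
    labels[brain] = LABEL_GM
    wx = max(2, nx // 3)
    wy = max(2, ny // 3)
    cx, cy = nx // 2, ny // 2
    labels[cx - wx // 2:cx + wx // 2, cy - wy // 2:cy + wy // 2, :] = LABEL_WM
    # veins: evenly spread over the GM compartment, deterministic
    gm_flat = np.flatnonzero((labels == LABEL_GM).ravel())
    if spec.n_vein > gm_flat.size // 4:
        raise ValueError("too many vein voxels for this grid")
    step = max(1, gm_flat.size // spec.n_vein)
    vein_flat = gm_flat[::step][: spec.n_vein]
    lab = labels.ravel()
    lab[vein_flat] = LABEL_VEIN
    return lab.reshape(spec.shape)


def generate_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Render the phantom: one EchoSeries per TE, gas trace and ground truth.

    All randomness flows through ``spec.seed``; calling twice with the same
    spec is bit-identical.
    """
    spec = spec or PhantomSpec()
    labels = _phantom_labels(spec)
    f_c = spec.f_c
    t = spec.tr * np.arange(spec.n_frames)

    # per-voxel concentration amplitude (1/s) and absolute delay (s)
    amp = np.zeros(spec.shape)
    delay = np.full(spec.shape, np.nan)
    cbf = np.full(spec.shape, np.nan)
    td = np.full(spec.shape, np.nan)
    for lab, cbf_i, td_i in ((LABEL_GM, spec.gm_cbf, spec.gm_td),
                             (LABEL_WM, spec.wm_cbf, spec.wm_td)):
        m = labels == lab
        r_mag = residue_magnitude(td_i, f_c)
        amp[m] = spec.vein_amplitude * spec.cbf_raw(cbf_i) * r_mag
        delay[m] = spec.vein_delay - td_i
        cbf[m] = cbf_i
        td[m] = td_i
    veins = labels == LABEL_VEIN
    amp[veins] = spec.vein_amplitude
    delay[veins] = spec.vein_delay
    td[veins] = 0.0

    # derived ground truth: CBV from the central-volume-consistent ratio,
    # CVR from the exact regression slope of the rendered exponential signal
    cbv = cbf * residue_magnitude(np.where(np.isnan(td) | (td <= 0), 1.0, td), f_c)
    cbv = np.where(np.isfinite(cbf), cbv / SECONDS_PER_MINUTE, np.nan)
    kcfg = spec.kinetics
    cbv[veins] = kcfg.kappa_over_rho * 100.0
    x = spec.te[0] * amp
    with np.errstate(invalid="ignore"):
        # exact OLS slope of 100·(S/S̄−1) on the aligned EtCO₂ sinusoid:
        # S ∝ e^{x·sinθ} has mean I0(x) and fundamental 2·I1(x)·sinθ
        cvr = np.where(
            labels > 0,
            200.0 * i1(x) / (i0(x) * (0.5 * spec.etco2_peak_to_peak)),
            np.nan,
        )

    # steady-state concentration curves; CO2 up → ΔR2* down
    phase_t = 2 * np.pi * f_c * (t[None, :] - np.nan_to_num(delay).ravel()[:, None])
    conc = -amp.ravel()[:, None] * np.sin(phase_t)
    conc[labels.ravel() == LABEL_BACKGROUND] = 0.0
    conc = conc.reshape(spec.shape + (spec.n_frames,))

    # noise calibrated so GM-like voxels (the brain's median amplitude) hit
    # the temporal-SNR target at the first echo
    if spec.tsnr_target is not None:
        a_gm = spec.vein_amplitude * spec.cbf_raw(spec.gm_cbf) * residue_magnitude(spec.gm_td, f_c)
        sigma = 2.0 * spec.s0 * np.sinh(spec.te[0] * a_gm) / spec.tsnr_target
    else:
        sigma = 0.0
    rng = np.random.default_rng(spec.seed)

    echoes = []
    background = labels == LABEL_BACKGROUND
    for te in spec.te:
        s = spec.s0 * np.exp(-te * conc)
        s[background] = 0.05 * spec.s0
        if sigma > 0:
            s = s + rng.normal(0.0, sigma, size=s.shape)
            s = np.clip(s, 1e-3 * spec.s0, None)  # keep log-safe
        echoes.append(EchoSeries(s, te=te, tr=spec.tr, t0=0.0))

    gas = generate_etco2_trace(
        period=spec.period,
        baseline=spec.etco2_baseline,
        peak_to_peak=spec.etco2_peak_to_peak,
        duration=spec.duration + spec.tr,
        dt=0.5,
        seed=spec.seed,
    )
    truth = GroundTruth(cbf=cbf, cbv=cbv, td=td, cvr=cvr, labels=labels)
    return Phantom(echoes=echoes, gas=gas, truth=truth, spec=spec,
                   concentration=conc)


def convolve_residue(
    curve: np.ndarray,
    cbf_raw: float,
    tau: float,
    tr: float,
    midpoint: bool = True,
) -> np.ndarray:
    """Circular (periodic) convolution of a curve with CBF·e^{−t/τ}.

    ``midpoint=True`` samples the kernel at (k+½)·TR, which cancels the
    leading discretisation error of the rectangle rule (the kernel is
    exponential, so node sampling overestimates the transfer magnitude by
    ≈Δt/(2τ)); node sampling is available for solver cross-checks that
    require kernel(0) = CBF exactly.
    """
    curve = np.asarray(curve, dtype=float)
    n = curve.size
    k = np.arange(n) + (0.5 if midpoint else 0.0)
    kernel = tr * cbf_raw * np.exp(-k * tr / tau)
    return np.real(np.fft.ifft(np.fft.fft(curve) * np.fft.fft(kernel)))


def generate_deconvolution_curves(
    n_voxels: int = 64,
    period: float = 60.0,
    dt: float = 0.25,
    n_cycles: int = 2,
    cbf_raw_range: tuple[float, float] = (0.003, 0.008),
    tau_range: tuple[float, float] = (5.0, 10.0),
    seed: int = 0,
) -> dict:
    """Broadband deconvolution phantom for the SVD comparator.

    The sinusoidal steady-state phantom is spectrally rank-2 (stimulus
    fundamental only), which leaves the maximum of the residue unconstrained
    for a time-domain deconvolver.  This variant drives the same kinetics
    with a periodic bolus train plus a full-spectrum periodic perturbation,
    so both the frequency-domain estimator (at f_c, with the true τ) and the
    truncated-SVD comparator are well posed.  Tissue curves are exact
    circular convolutions of the VOF with node-sampled CBF·e^{−t/τ}.

    Returns a dict with t, vof, tissue (n_voxels × n_t), cbf_raw, tau, f_c.
    """
    rng = np.random.default_rng(seed)
    n_t = int(round(n_cycles * period / dt))
    t = dt * np.arange(n_t)
    bolus = np.exp(10.0 * (np.cos(2 * np.pi * t / period) - 1.0))
    vof = bolus + 0.5 + 0.2 * rng.standard_normal(n_t)
    side = int(np.ceil(np.sqrt(n_voxels)))
    cbf_raw = np.linspace(*cbf_raw_range, side)
    tau = np.linspace(*tau_range, side)
    cbf_grid, tau_grid = [a.ravel()[:n_voxels] for a in np.meshgrid(cbf_raw, tau)]
    tissue = np.stack([
        convolve_residue(vof, f, tv, dt, midpoint=False)
        for f, tv in zip(cbf_grid, tau_grid)
    ])
    return {
        "t": t, "vof": vof, "tissue": tissue,
        "cbf_raw": cbf_grid, "tau": tau_grid,
        "f_c": 1.0 / period, "dt": dt,
    }
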