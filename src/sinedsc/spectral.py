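"""Fundamental-frequency demodulation and venous output function selection.

With a sinusoidal gas drive, every voxel's concentration curve is (to first
order) a sinusoid at the stimulus fundamental f_c.  The complex coefficient
at f_c carries all the information the tracer-kinetics estimators need:
its magnitude feeds CBF/CBV, its phase feeds delay/TD maps.

The venous output function (VOF) plays the role the arterial input function
has in bolus DSC: because CO₂-driven deoxygenation contrast arises in
exchanging vessels and drains to veins, the system is anti-causal and the
latest, largest responses are venous.  The VOF is selected automatically as
the voxels with the highest integrated rectified concentration among those
with delays at the top of the in-brain delay histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .relaxometry import ConcentrationSeries, _design_matrix, _check_fit_preconditions

__all__ = [
    "SpectralSummary",
    "VOF",
    "VenousReference",
    "demodulate_fundamental",
    "demodulate_curve",
    "phase_delay_map",
    "venous_reference_phase",
    "select_vof",
    "wrap_delay",
]


@dataclass
class SpectralSummary:
    """Per-voxel complex fundamental-frequency coefficient.

    ``coeff = b + i·c`` where the voxel series is b·sin(2πf_c t)+c·cos(2πf_c t)
    (after offset/trend removal), so a pure A·sin(2πf_c t) voxel has
    magnitude A and phase 0.
    """

    f_c: float
    coeff: np.ndarray  # 3D complex

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.coeff)

    @property
    def phase(self) -> np.ndarray:
        return (np.angle(self.coeff) + np.pi) % (2 * np.pi) - np.pi

    @property
    def period(self) -> float:
        return 1.0 / self.f_c


@dataclass
class VenousReference:
    """Venous reference delay/phase from the tail of the delay histogram."""

    delay: float        # seconds, relative to the pipeline reference phase
    phase: float        # radians, absolute (same convention as SpectralSummary)
    percentile: float
    f_c: float


@dataclass
class VOF:
    """Automatically selected venous output function.

    voxel_indices : (n_vof, 3) integer array of grid coordinates
    curve         : mean concentration series over the selected voxels (1/s)
    coeff         : complex fundamental coefficient of ``curve``
    phase_venous  : radians, phase of ``curve`` at f_c
    """

    voxel_indices: np.ndarray
    curve: np.ndarray
    coeff: complex
    phase_venous: float
    n_vof: int


def wrap_delay(delay: np.ndarray | float, period: float) -> np.ndarray | float:
    """Wrap a delay (seconds) into [0, period)."""
    return np.mod(delay, period)


def recenter_delays(
    delay_map: np.ndarray, period: float, mask: np.ndarray | None = None
) -> np.ndarray:
    """Re-wrap delays into a period-wide window centred on their circular mean.

    Delays live on a circle, so a voxel responding just BEFORE the reference
    wraps from ≈0 to ≈period and would masquerade as the latest voxel,
    corrupting the venous tail of the delay histogram.  Re-centring on the
    circular mean puts such voxels at small negative delays instead, which
    keeps the early/late ordering monotone as long as the true delays span
    less than one period (they do: transit spreads are a few seconds).
    """
    delay = np.asarray(delay_map, dtype=float)
    sel = delay[np.asarray(mask, dtype=bool)] if mask is not None else delay
    sel = sel[np.isfinite(sel)]
    if sel.size == 0:
        return delay.copy()
    ang = 2 * np.pi * sel / period
    mu = period * np.angle(np.exp(1j * ang).mean()) / (2 * np.pi)
    return np.mod(delay - mu + period / 2.0, period) + mu - period / 2.0


def _demodulate_rows(rows: np.ndarray, tr: float, f_c: float, t0: float) -> np.ndarray:
    """Demodulate (n, t) series at f_c; returns complex b + i·c per row.

    Drift is removed via a line fitted to per-cycle means.  Because the
    cycle mean of every integer-cycle harmonic is exactly zero, this leaves
    harmonic content untouched, and the subsequent 2/N sin/cos projection
    is exactly orthogonal to the offset and to all other integer-cycle
    frequencies — so a linear drift and any out-of-band harmonic contribute
    exactly nothing to the fundamental coefficient.  Falls back to a joint
    OLS with a trend column when the cycle length is not a whole number of
    frames.
    """
    nt = rows.shape[-1]
    _check_fit_preconditions(nt, tr, f_c)
    t = t0 + tr * np.arange(nt)
    fpc = 1.0 / (f_c * tr)  # frames per cycle
    if abs(fpc - round(fpc)) < 1e-9 and nt % round(fpc) == 0:
        fpc = int(round(fpc))
        n_cyc = nt // fpc
        cyc_means = rows.reshape(-1, n_cyc, fpc).mean(axis=-1)  # (n, cycles)
        cyc_t = t.reshape(n_cyc, fpc).mean(axis=-1)
        A = np.column_stack([np.ones(n_cyc), cyc_t - cyc_t.mean()])
        beta, *_ = np.linalg.lstsq(A, cyc_means.T, rcond=None)
        trend = beta[0][:, None] + beta[1][:, None] * (t - cyc_t.mean())[None, :]
        resid = rows - trend
        w = 2 * np.pi * f_c
        b = (2.0 / nt) * resid @ np.sin(w * t)
        c = (2.0 / nt) * resid @ np.cos(w * t)
        return b + 1j * c
    X = _design_matrix(t, f_c)
    beta, *_ = np.linalg.lstsq(X, rows.T, rcond=None)
    return beta[2] + 1j * beta[3]


def demodulate_curve(signal: np.ndarray, tr: float, f_c: float, t0: float = 0.0) -> complex:
    """Complex fundamental coefficient of a 1D series (drift-immune).

    On an integer number of cycles this equals the (scaled) DFT bin at f_c.
    """
    y = np.asarray(signal, dtype=float)
    return complex(_demodulate_rows(y[None, :], tr, f_c, t0)[0])


def demodulate_fundamental(conc: ConcentrationSeries, f_c: float) -> SpectralSummary:
    """Demodulate every voxel of a concentration series at f_c.

    The series is cropped to the largest whole number of cycles first, so
    the sin/cos pair is exactly orthogonal to the offset, the (cycle-mean)
    drift estimate, and any other integer-cycle frequency.
    """
    cropped = conc.cropped_to_cycles(1.0 / f_c)
    data = cropped.data
    nt = data.shape[-1]
    coeff = _demodulate_rows(data.reshape(-1, nt), cropped.tr, f_c, cropped.t0)
    return SpectralSummary(f_c=f_c, coeff=coeff.reshape(data.shape[:3]))


def phase_delay_map(
    spec: SpectralSummary,
    reference_phase: float,
    magnitude_floor: float = 0.0,
) -> np.ndarray:
    """Per-voxel lag (seconds) relative to a reference phase, in [0, period).

    Later responses get larger delays.  Voxels with magnitude at or below
    ``magnitude_floor`` have undefined phase and return NaN (excluded from
    downstream percentiles).
    """
    delay = (reference_phase - spec.phase) / (2 * np.pi * spec.f_c)
    delay = wrap_delay(delay, spec.period)
    out = np.where(spec.magnitude > magnitude_floor, delay, np.nan)
    return out


def venous_reference_phase(
    delay_map: np.ndarray,
    brain_mask: np.ndarray,
    f_c: float,
    reference_phase: float = 0.0,
    percentile: float = 0.98,
    min_defined: int = 50,
) -> VenousReference:
    """Venous delay/phase as a high percentile of the in-brain delay histogram.

    Selecting the tail of the histogram instead of hand-picking a vein
    removes observer bias.  Percentiles use linear interpolation between
    order statistics.
    """
    if not 0.0 < percentile < 1.0:
        raise ValueError("percentile must lie in (0, 1)")
    vals = np.asarray(delay_map)[np.asarray(brain_mask, dtype=bool)]
    vals = vals[np.isfinite(vals)]
    if vals.size < min_defined:
        raise ValueError(
            f"only {vals.size} defined delays in mask (need >= {min_defined})"
        )
    d = float(np.percentile(vals, percentile * 100.0))
    phase = reference_phase - 2 * np.pi * f_c * d
    phase = (phase + np.pi) % (2 * np.pi) - np.pi
    return VenousReference(delay=d, phase=phase, percentile=percentile, f_c=f_c)


def rectified_integral(conc: ConcentrationSeries) -> np.ndarray:
    """Time integral of the rectified, demeaned concentration, per voxel.

    ∫|C(t) − C̄| dt over whole cycles: a response-size score that is immune
    to baseline brightness.
    """
    data = conc.data
    dev = data - data.mean(axis=-1, keepdims=True)
    return conc.tr * np.abs(dev).sum(axis=-1)


def select_vof(
    conc: ConcentrationSeries,
    delay_map: np.ndarray,
    brain_mask: np.ndarray,
    f_c: float,
    n_vof: int = 20,
    delay_percentile: float = 0.98,
) -> VOF:
    """Select the venous output function voxels.

    Candidates are in-brain voxels whose delay is at or above the
    ``delay_percentile`` of in-brain delays (inclusive, so that a cohort of
    veins sharing the exact percentile value remains eligible); among them
    the ``n_vof`` with the highest integrated rectified concentration are
    kept.  Ties are broken by score then lexicographic voxel index, making
    the selection bit-reproducible and invariant to traversal order and to
    positive rescaling of the data.
    """
    conc = conc.cropped_to_cycles(1.0 / f_c)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    delay = np.asarray(delay_map, dtype=float)
    vals = delay[brain_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no defined delays inside the brain mask")
    cut = np.percentile(vals, delay_percentile * 100.0)
    cand = brain_mask & np.isfinite(delay) & (delay >= cut)
    n_cand = int(cand.sum())
    if n_cand < n_vof:
        raise ValueError(
            f"only {n_cand} voxels exceed the delay percentile; "
            f"need {n_vof} — lower delay_percentile"
        )
    score = rectified_integral(conc)
    flat_idx = np.flatnonzero(cand.ravel())
    flat_score = score.ravel()[flat_idx]
    # sort by descending score, ties by ascending flat index (lexicographic)
    order = np.lexsort((flat_idx, -flat_score))
    chosen = flat_idx[order[:n_vof]]
    chosen.sort()
    coords = np.column_stack(np.unravel_index(chosen, conc.data.shape[:3]))
    curve = conc.data.reshape(-1, conc.n_frames)[chosen].mean(axis=0)
    coeff = demodulate_curve(curve, conc.tr, f_c, conc.t0)
    phase = (np.angle(coeff) + np.pi) % (2 * np.pi) - np.pi
    return VOF(
        voxel_indices=coords,
        curve=curve,
        coeff=coeff,
        phase_venous=float(phase),
        n_vof=n_vof,
    )
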