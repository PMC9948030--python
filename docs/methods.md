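# Methods

## Signal model

A sinusoidal end-tidal CO₂ drive (baseline 40 mmHg, 10 mmHg peak-to-peak,
period 60 s) modulates cerebral vasodilation and hence deoxyhemoglobin.
The gradient-echo signal is modeled as S(t) = S₀·exp(−TE·ΔR2*(t)); a CO₂
(and signal) increase corresponds to a ΔR2* decrease.  ΔR2* is treated as
proportional to the tracer (deoxyhemoglobin) concentration with unit
proportionality in tissue and blood, so tissue/blood ratios are the only
quantities that matter and the proportionality cancels from CBF.

Single-echo relaxometry uses the per-voxel temporal mean as S₀: in a
continuous sinusoidal protocol there is no pre-stimulus baseline window, and
over whole cycles the temporal mean is the natural operating point.  The
Jensen bias of a temporal-mean baseline is a pure DC offset in ΔR2*
(exactly so for the dual-echo log-ratio), which the fundamental-frequency
analysis ignores.

All series are cropped to the largest whole number of stimulus cycles
before spectral work.  This removes leakage and makes per-cycle integrals
well defined.

## Demodulation and drift

Each voxel's fundamental coefficient is b + i·c with
x(t) ≈ b·sin(2πf_c t) + c·cos(2πf_c t).  Drift is estimated from a line
fitted to per-cycle means; because the cycle mean of every integer-cycle
harmonic is exactly zero, this trend estimate is blind to the stimulus
response and its harmonics, and the subsequent 2/N sin/cos projection is
exactly orthogonal to the offset, the removed trend and all other
integer-cycle frequencies.  (A joint OLS with a raw linear-trend column
would leak ~1% of out-of-band harmonics into the fundamental through the
discrete non-orthogonality of a sampled ramp; the fallback for non-integer
frames-per-cycle accepts this.)  Raw-signal sinusoid fits (amplitude %,
phase, temporal SNR) use the joint offset+trend+sin/cos OLS, with phase
= atan2(c, b) so a pure sine has phase 0.

Temporal SNR is the fitted peak-to-peak amplitude over the residual
standard deviation after removing offset, trend and the fundamental; a
zero-variance residual returns +inf.

## Delay maps, venous reference, VOF

Phases are converted to delays relative to a reference: the EtCO₂
fundamental phase (sign-flipped, since ΔR2* anti-correlates with CO₂) when
a gas trace is available, otherwise the brain-mean concentration curve.
Delays are then re-wrapped into a period-wide window centred on their
circular mean.  Delays live on a circle: without re-centring, a voxel
responding just *before* the reference wraps to ≈period and masquerades as
the latest voxel, contaminating the venous tail of the delay histogram —
under noise this single effect can redirect the VOF onto tissue voxels.

The venous reference delay/phase is the 98th percentile of the in-brain
delay histogram (linear interpolation between order statistics — no
percentile convention is standard, so one is fixed and documented).  The
VOF comprises the 20 voxels with the highest integrated rectified
concentration ∫|C−C̄|dt among those with delays at or above that percentile
(inclusive, so a cohort of veins sharing the exact percentile value remains
eligible); ties break by score then lexicographic index, making selection
deterministic and invariant to traversal order and positive rescaling.
Pial-vein suppression for tissue statistics (amplitude strictly above the
98th in-brain percentile) runs *after* VOF selection, which needs exactly
those bright voxels.

## Kinetics

TD = (φ_tissue − φ_venous)/(2πf_c) wrapped to [0, period): the printed
formula alone goes negative whenever the vein is latest, and the
non-negative tissue-to-vein interval is the physically meaningful reading.
The residue function is R(t) = e^(−t/τ) with τ identified with TD (the
first-order low-frequency approximation of a single-pole system), giving
|R(f)| = 1/√(1/τ² + (2πf)²).  τ is bounded to [TR/2, period/2]: the floor
keeps |R(f_c)| well conditioned, the cap keeps the τ≈phase-delay
identification meaningful; bounded voxels are counted and logged.

CBF_raw = |C_t(f_c)|/(|C_VOF(f_c)|·|R(f_c)|) is the least-squares magnitude
fit restricted to the fundamental (a ±2-bin band variant exists for
robustness experiments).  Physiological scaling is 6000·κ/ρ with κ = 1/0.69
(the contrast resides in red cells, and capillary hematocrit is lower than
large-vessel hematocrit) and ρ = 1.05 g/mL.  The same κ/ρ factor is applied
to CBF as well as CBV — the bare frequency-domain relation carries no
scaling at all, and only the common factor keeps MTT = CBV/CBF consistent;
it is toggleable (`apply_kappa_to_cbf`).

CBV uses the fundamental-magnitude ratio ×(κ/ρ)·100.  The literal ratio of
curve integrals is 0/0 for zero-mean periodic curves; over whole cycles the
ratio of rectified areas equals the magnitude ratio, and a rectified-AUC
variant is provided and tested for agreement.  MTT converts min→s (×60).
Working with magnitudes and wrapped delays is what makes the anti-causal
(venous-referenced) system quantifiable: no causality constraint is ever
imposed.

CVR is the voxelwise OLS slope of percent BOLD on the aligned EtCO₂ trace
(%/mmHg).  Alignment is two-stage: a global cross-correlation lag on the TR
grid within ±period/2 (warned at the boundary), then a per-voxel lag from
the phase difference at f_c, reported as the `cvr_delay` map.  A single
global lag would attenuate the slope by cos(2πΔd/period) wherever a voxel's
delay differs from the global one — ≈2% at Δd = 2 s — so per-voxel
alignment is required for sub-percent recovery.  EtCO₂ is resampled by
linear interpolation onto frame times (breath-sampled traces carry no
canonical resampling rule); frames whose shifted time falls outside the
recorded trace are dropped from that voxel's regression.

## SVD comparator

The traditional time-domain route discretises the convolution as
A = TR·circ(C_VOF) (circulant, hence delay-insensitive — appropriate for
periodic integer-cycle data), zeroes singular values below a threshold
fraction of the maximum, and reports max of the recovered flow-scaled
residue.  It is a comparator, not the estimator.  One structural caveat: a
pure single-frequency drive makes A rank-2, so the maximum of the residue
(its value at lag zero) is unconstrained and the comparator cannot agree
with the frequency-domain estimate on the steady-state sinusoidal phantom
in principle.  Cross-estimator checks therefore use the broadband
deconvolution phantom (below), where both routes are well posed; there they
agree within a few percent, limited by the rectangle-rule discretisation of
the exponential kernel (≈Δt/(2τ)).

## Digital phantom

Geometry: a rectangular brain (margin ⅛ of the grid) containing a central
white-matter-like block, grey-matter-like tissue elsewhere, and 120 vein
voxels spread deterministically through the grey matter (~2.6% of the 4608
brain voxels, so the veins span the top 2% of the delay histogram and the
98th-percentile rule recovers the venous phase exactly).  Defaults mirror
the acquisition design: 32×32×8 voxels, TR 1.5 s, TE 35/90 ms, 220 frames,
60 s period.

Vein voxels carry C_b(t) = −A_v·sin(2πf_c(t−d_v)) with A_v = 6 s⁻¹ and
d_v = 10 s.  Tissue voxels carry the steady-state kinetics response:
amplitude A_v·CBF_raw·|R(f_c; τ=TD)| and phase *leading* the vein by
exactly TD (anti-causal direction; the τ = TD identification is adopted as
generative truth, so the estimators' model is exactly invertible).
Compartment values are physiologically anchored — grey matter CBF 48 and
white matter 25 mL/100 g/min, TD 6.6/6.3 s — without claiming to reproduce
any cohort.  A_v = 6 s⁻¹ puts the grey-matter BOLD swing at ≈1.3%
peak-to-peak at TE 35 ms, inside the observed 1.2–1.5% band; vein voxels,
being pure blood, swing ≈40% — larger than real veins show, but it is the
value the model itself implies for a partial-volume-free blood voxel.

In this single-frequency model the tissue/vein amplitude ratio *is*
CBF_raw·|R|, so CBV and CVR are not free knobs: ground-truth
CBV = CBF·|R(f_c; TD)|/60 and ground-truth CVR is the exact regression
slope of the rendered exponential signal on the CO₂ sinusoid,
200·I₁(x)/(I₀(x)·A_CO₂) with x = TE·(tissue amplitude) (modified Bessel
functions from the e^{x·sinθ} expansion).  Specifying independent CBV/CVR
would contradict the forward model and break exact round-tripping.

Noise is white Gaussian, calibrated so grey matter (the brain's median
amplitude compartment) hits a whole-brain temporal-SNR target of 1.36 at
the first echo; `tsnr_target=None` renders noiseless data.  All randomness
flows through one seed.  The phantom emulates steady-state periodic
responses only: no transient onset, no hyperpneic asymmetry of the negative
CO₂ half-cycle, no motion, no spatially correlated noise, no partial-volume
veins.  Passing tests therefore demonstrate correctness of the inversion
chain under the method's own model, not robustness to those real-data
effects.

The broadband deconvolution phantom drives the same kinetics with a
periodic bolus train exp(10(cos(2πf_c t)−1)) plus a full-spectrum periodic
perturbation, sampled at dt = 0.25 s over two cycles with τ ∈ [5, 10] s;
tissue curves are exact circular convolutions of the VOF with a
node-sampled exponential kernel, so the SVD route recovers the generating
flow to machine precision and the frequency route to the discretisation
bound above.

## Pipeline defaults and problem sizes

Single-echo quantification is the default (dual-echo is noisier and is
opt-in), the delay and suppression percentiles are 0.98, n_VOF = 20, and
the EtCO₂ reference is 40 mmHg.  The shipped test-suite and acceptance runs
use the default 32×32×8×220 phantom (≈4.6k brain voxels) and 64-voxel
deconvolution fixtures; every stage is vectorised, so a full run completes
in seconds.

## Agreement statistics

ROI summaries exclude suppressed and undefined voxels and drop emptied ROIs
with a warning.  Limits of agreement: d = A−B, bias ± 1.96·sd(d) (sample
sd), all normalised by the single grand mean of the pairwise averages — the
most literal reading of "the average of the two methods" — and reported in
percent.  Intersubject CoV is sd/mean×100; test–retest CoV is the RMS of
within-subject standard deviations over the grand mean (the formula is
named but never defined in the protocol this mirrors; the RMS convention is
ours).  Pearson correlation over shared ROI means requires ≥3 ROIs and
flags zero-variance inputs.

## Known limitations

Values are semi-quantitative: absolute calibration of the
ΔR2*–concentration relationship (via SpO₂/hematocrit) is out of scope, the
VOF is assumed partial-volume-free, and the exponential residue with
τ = TD is a first-order approximation whose phase delay differs from τ by
τ − atan(2πf_c·τ)/(2πf_c) (≈0.8 s at τ = 6.6 s).  MTT in this
single-frequency model is fully determined by TD (MTT = |R(f_c; TD)| in
seconds), so it adds no independent information at f_c.  The CVR lag is
identified only modulo the stimulus period and is reported in
[−period/2, period/2).
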