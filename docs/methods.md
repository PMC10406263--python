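# Methods

`dscsim` simulates dynamic susceptibility contrast (DSC) MRI signals for
two paramagnetic contrast agents — gadolinium (Gd) and deoxyhemoglobin
(dOHb) — at 3T, and inverts them with the standard DSC quantification
pipeline. Its purpose is to expose, under controlled conditions, how
perfusion estimates (rCBV, rCBF, MTT) depend on contrast susceptibility,
bolus magnitude and duration, baseline oxygen saturation, reference-voxel
partial volume, and singular-value thresholding.

## Forward signal model

A voxel is a mixture of extravascular extracellular space (EES) and up to
five intravascular (IVS) compartments (artery, arteriole, capillary,
venule, vein), each with a fractional blood volume `pCBV_i` (percent), a
baseline oxygen saturation `Y0_i`, and a vessel-radius class. The
T2*-weighted gradient-echo signal is

    S = (1 - CBV) * exp(-TE * (R2*_0,EES + R2*_con,EES))
        + sum_i CBV_i * exp(-TE * (R2*_0,IVS + R2*_con,IVS,i))

with `TE = 30 ms`, `R2*_0,EES = 20.99 1/s` and `R2*_0,IVS = 13.8 1/s`
(fully oxygenated blood). The EES contribution is a single exponential
whose contrast rate is the sum over compartments; each IVS compartment is
its own exponential.

Intravascular paramagnetic content produces an angular frequency shift at
the vessel surface,

    dv = 0.264e-6 * Hct * (1 - Y0 - dY) * gamma * B0  +  0.026e-6 * [Gd] * gamma * B0

with `gamma = 2*pi*42.6e6 rad/s/T`, `B0 = 3 T`, `Hct = 0.4`. The
extravascular contrast rate is linear in the shift,
`R2*_con,EES = sum_i pCBV_i * c_i * dv_i` with radius-class coefficients
`c = 0.0387` (5 um capillaries), `0.0433` (16–200 um), `0.0798`
(200 um at 90 degrees) per percent CBV — Monte-Carlo-derived constants
taken as given. The intravascular rate is quadratic in total effective
deoxygenation:

    R2*_con,IVS = 181 * (1 - Y0 - dY + 0.246*[Gd])^2

The factor 0.246 = 0.026/(0.264*Hct) converts Gd concentration into the
saturation drop with the same susceptibility effect ("pseudo-oxygenation":
1 mM of Gd is equivalent to a 24.6 % drop at Hct 0.4). It is recomputed
from the configured constants so a non-default hematocrit stays
self-consistent.

Two deliberate conventions:

* **Baseline deoxygenation contributes to the contrast terms.** A vein at
  `Y0 = 0.60` relaxes faster than an artery before any bolus, so baseline
  signals order artery > tissue > vein, and the quadratic cross-term
  `2*(1-Y0)*|dY|` makes venous responses to a given bolus much larger than
  arterial ones. This cross-term is the root of most quantification biases
  the package demonstrates.
* **Frequency shifts are angular (rad/s)** and the Table of radius-class
  coefficients is treated as seconds. Whether the source calibration meant
  rad/s or Hz is not decidable from the available description; the choice
  lives in `PhysicsConstants` and can be flipped in one place.

Hyperoxic overshoot (negative effective deoxygenation) is clipped to zero
rather than squared into a spurious positive rate; the squared form is
symmetric, which would be unphysical for overshoot.

## Contrast inputs and transport

The Gd arterial inlet is a gamma variate
`a*(t/b)^c*exp(c*(1-t/b))` with defaults `a = 2 mM`, `b = 2.5 s` (time to
peak), `c = 3`. The dOHb inlet is a rectangular SaO2 drop convolved with a
unit-area decaying exponential (default time constant 5 s — not given
numerically by the source; chosen to produce the observed 30–40 s bolus
widths) with ~30 s plateau; the return edge uses the same exponential by
default, or an abrupt step mimicking single-breath resaturation. Named
paradigms: 98–90 %, 98–84 %, 98–75 %, 88–80 % SaO2, and standard Gd.

Tissue and venous voxels receive the inlet convolved with a residue
function: biexponential `R(t) = f*exp(-t*t1) + (1-f)*exp(-t*t2)`
(`f = 0.92`, `t1 = 0.68`, `t2 = 0.05`; MTT = f/t1 + (1-f)/t2 = 2.953 s)
for tissue, monoexponential with MTT 4 s for the vein, plus pure delays of
1 s and 2 s. The transport kernel is the **unit-area** normalization
`k = R / integral(R)`, so steady-state concentration is conserved (a long
plateau emerges at full amplitude). This choice is what reproduces the
printed vein/artery peak-relaxation ratios (~4 for dOHb, ~1.1 for Gd);
convolving with raw `R(t)` would scale amplitudes by MTT and break both.
The kernel support extends until `R < 1e-9` so the slow compartment's long
tail (time constant 20 s) is fully represented; the discrete kernel is
trapezoid-weighted and renormalized to unit area. Delays are whole-sample
shifts on the fine grid (default `dt = 0.1 s`), applied after convolution.

All kinetics run on the fine grid and are decimated to the acquisition TR
(default 1.5 s) afterwards, because 1–2 s delays and the 2.5 s
time-to-peak are not representable at TR.

The tissue voxel mixes compartments in the 1:2:2 ratio
(artery/arteriole : capillary : vein/venule), with the arterial fifth
split equally between artery (`Y0 = 1.00`) and arteriole (0.95), the
venous two fifths equally between vein and venule (0.60), and capillaries
at 0.775. For hypoxic paradigms the dedicated arterial voxel's baseline is
the paradigm's base-SaO2 (e.g. 0.98) rather than 1.00: the paradigm
defines the subject's arterial baseline, and this is what reproduces the
vein/artery ratio near 4.

## Inversion pipeline

Signal is converted with `dR2*(t) = -(1/TE) * ln(S(t)/S0)`, `S0` the
baseline-window mean. Series are truncated to the bolus window: from the
first AIF sample above 10 % of the AIF peak to the last VOF sample above
2 % of the VOF peak. The end criterion is deliberately looser than the
onset criterion — a 10 % end cut amputates the venous and tissue washout
(the slow tissue compartment decays with a 20 s time constant) and biases
areas and MTT.

rCBV is the kappa-scaled area ratio `kappa * 100 * area(tissue)/area(ref)`
(mL/100g at unit brain density), with the reference either the arterial or
the venous curve. The hematocrit correction is
`kappa_Gd = (1-Hct)/(1-0.69*Hct)` (plasma-borne) and
`kappa_dOHb = 1/0.69` (red-cell-borne; the hematocrit cancels).

rCBF comes from SVD deconvolution of the tissue curve by the AIF only
(normalizing a deconvolution to the vein would violate indicator-dilution
scaling, since the venous curve is not rescaled to arterial area): the
lower-triangular convolution matrix `A[j,k] = TR * aif[j-k]` is inverted
with singular values below a fraction (clinical default 0.20) of the
largest zeroed. `rCBF = kappa * max(b) * 100 * 60` and
`MTT = rCBV/rCBF * 60` by the central volume principle; the residue-based
`area(b)/max(b)` is exposed as a diagnostic. Negative tail values of the
estimate are kept — thresholding is the only regularization. Voxels with
negative rCBV are excluded and reported.

### Deconvolution sampling caveat

Zero-threshold SVD recovery of the true MTT is only meaningful when the
sampling interval resolves the AIF. The default gamma-variate inlet has a
full width at half maximum of ~3.7 s — about 2.5 samples at TR 1.5 s — and
at that spacing the simple-discretization SVD gives 4.5–6 s for a true
2.95 s regardless of window phase or quadrature, the well-known
coarse-sampling bias of standard SVD deconvolution. The
`mtt_recovery_experiment` driver therefore validates the machinery on the
fine simulation grid (dt 0.1 s, window onset at 1 % of the AIF peak) with
concentration-proportional curves (the low-susceptibility linear limit,
where measured relaxation is proportional to concentration): threshold 0
recovers 3.24 s (within 10 % of 2.953 s) and threshold 0.2 inflates it to
6.3 s. Through the full nonlinear signal model the quadratic intravascular
term reshapes the measured arterial curve (at 2 mM the arterial response
is ~90 % quadratic), and the threshold-0 estimate converges to ~4.7 s even
at fine sampling — itself a demonstration of why quantification with a
high-susceptibility AIF voxel is biased. The bolus-duration experiment
runs the full nonlinear pipeline at TR 1.5 s, where all the
duration/threshold orderings hold.

## Digital phantom

The default phantom is a 32x32x8 grid: a 2-voxel CSF rim, a 3-voxel
cortical GM ribbon (CBV 4 %), a WM core (CBV 2 %), and single-column
artery and vein (CBV 90 %) traversing all slices. Each region carries one
voxel model, so the noiseless 4D dataset has one distinct time course per
region; Gaussian noise (per-region standard deviation as a fraction of the
regional baseline signal) can be added, seeded and byte-reproducible.
Ground-truth label, CBV and MTT maps accompany the data.

What the phantom emulates — and what it does not: it captures
compartmental signal physics, transport delays, partial-volume dependence
of the reference voxels and noise-driven exclusions, but has no vascular
trees, no spatial partial-volume mixing beyond the compartment model, no
motion, no T1/inflow effects, and no contrast leakage. Tests passing on
the phantom therefore validate the quantification logic, not robustness to
real-data artifacts.

The segmentation preset (`segmentation_phantom_spec`) mirrors the two
facts the threshold segmentation relies on in real data: vessels carry
strong physiological noise (5 % of baseline here), so the noise mask
(voxels within the lowest 10 % of the epsilon_t range) removes them; and
CSF-adjacent voxels show a long apparent transit time because they
partial-volume with slow pial/dural venous structures (modeled as a 1 %
venous compartment drained with MTT 12 s, delay 3 s), so the MTT mask
(lowest 70 % of the [2nd, 98th]-percentile robust range) removes them.
After those two masks, WM is the lowest 20 % of the remaining
signal-change range and GM the highest 75 %. The range is computed after
masking: in a phantom the unmasked range is dominated by vessel voxels,
which real continuous data tolerates better than a five-level phantom.

## Numerical choices

* Fine grid dt 0.1 s; simulations span 120 s; experiment drivers use TR
  1.5 s except where noted above.
* Convolution by direct summation (`numpy.convolve`) — time courses are
  short, no FFT needed.
* Onset detection at 10 % of series peak (configurable); deconvolution
  windows must not start with near-zero AIF samples at threshold 0, which
  is why the recovery driver uses the 1 % criterion on the fine grid.
* The temporal filter is a 5-tap unit-sum Gaussian (sigma = 1 sample) with
  edge renormalization; the map smoother is the separable 3x3 binomial
  kernel applied per slice.
* mL/100g scaling assumes brain density 1 g/mL.
* The same kappa is applied to rCBF as to rCBV so MTT is
  hematocrit-free.

## Known limitations

* The quantitative rCBV scale is biased high by construction: tissue
  (EES-linear) relaxivity per unit CBV is about three times the venous
  intravascular linear relaxivity, so even venous-normalized Gd rCBV
  overestimates the simulated 4 % GM volume — this mirrors the
  overestimation the package exists to demonstrate, and is why the
  experiment drivers report values relative to Gd rather than absolute
  accuracy.
* Tissue compartments share a single transported bolus; no per-compartment
  dispersion.
* No noise model beyond additive Gaussian on signal; physiological noise
  is emulated only as a larger Gaussian amplitude in vessels.
* The block-circulant (delay-insensitive) deconvolution variant is not
  implemented; delays are handled by the causal lower-triangular form.
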