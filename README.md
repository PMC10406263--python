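# dscsim

Forward simulation and perfusion quantification for dual-agent dynamic
susceptibility contrast (DSC) MRI at 3T.

DSC MRI tracks a paramagnetic bolus through the brain and converts the
transient T2*-weighted signal drop into cerebral blood volume (rCBV),
blood flow (rCBF) and mean transit time (MTT). The classic agent is a
gadolinium (Gd) chelate; a transient drop in arterial oxygen saturation
creates the same kind of bolus from endogenous deoxyhemoglobin (dOHb) at
roughly a tenth of the susceptibility. Because the intravascular
relaxation rate is *quadratic* in paramagnetic content while the
extravascular rate is linear, the measured response of a reference artery
or vein depends on its baseline oxygenation, its partial volume, and the
bolus amplitude — and so do the perfusion numbers computed from it.
`dscsim` exists to quantify those biases under controlled conditions: it
is aimed at perfusion-MRI researchers designing or interpreting dOHb/Gd
DSC protocols.

## Model

A voxel mixes extravascular (EES) and intravascular (IVS) compartments:

    S = (1 - CBV) e^{-TE (R2*_0,EES + Σ_i pCBV_i c_i Δν_i)}
        + Σ_i CBV_i e^{-TE (R2*_0,IVS + 181 (1 - Y0_i - ΔY + 0.246 [Gd])²}

where Δν is the susceptibility-induced frequency shift
`0.264·10⁻⁶·Hct·(1−Y0−ΔY)·γB0 + 0.026·10⁻⁶·[Gd]·γB0`, the c_i are
vessel-radius-class coefficients, and 0.246 converts mM of Gd into the
equivalent saturation drop (the "pseudo-oxygenation": 1 mM ≡ 24.6 % at
Hct 0.4). Boluses propagate to tissue and vein by convolution with
unit-area residue-function kernels (biexponential tissue kernel,
MTT = f/t1 + (1−f)/t2 = 2.95 s; monoexponential venous kernel, 4 s).
The inversion pipeline is the standard one: ΔR2*(t) = −ln(S/S0)/TE,
κ-corrected area-ratio rCBV against an arterial or venous reference, and
truncated-SVD deconvolution by the AIF for rCBF, with MTT = rCBV/rCBF.
See `docs/methods.md` for the full account.

## Worked example

Simulate the reference voxel trio (artery and vein at 100 % CBV, mixed
tissue at 4 %) for a large hypoxic bolus (98→75 % SaO2) and a standard
2 mM Gd bolus, and compare peak relaxation changes:

```python
from dscsim.experiments import simulate_reference_voxels, peak_delta_r2
from dscsim.paradigms import PARADIGMS

for name in ("dohb_large_high", "gd_standard"):
    c = simulate_reference_voxels(PARADIGMS[name], arterial_cbv=100, venous_cbv=100)
    pa, pv, pt = (peak_delta_r2(c[k]) for k in ("artery", "vein", "tissue"))
    print(f"{name}: artery {pa:.2f} 1/s  tissue {pt:.2f} 1/s  "
          f"vein {pv:.2f} 1/s  vein/artery {pv/pa:.2f}")
```

prints

```
dohb_large_high: artery 11.18 1/s  tissue 3.20 1/s  vein 42.35 1/s  vein/artery 3.79
gd_standard: artery 41.52 1/s  tissue 3.34 1/s  vein 43.79 1/s  vein/artery 1.05
```

The vein responds ~3.8× more strongly than the artery to the same hypoxic
bolus (its lower baseline saturation feeds the quadratic cross-term),
while Gd's higher susceptibility nearly equalizes the two (ratio ~1.1).
The downstream consequence for quantification:

```python
from dscsim import paradigm_comparison_experiment
t = paradigm_comparison_experiment().table
print(t[["paradigm", "rcbv_arterial", "rcbv_venous", "mtt"]].round(2).to_string(index=False))
```

```
        paradigm  rcbv_arterial  rcbv_venous   mtt
     gd_standard          20.47         6.26  7.14
 dohb_small_high         112.25        13.83 13.48
dohb_medium_high          76.68        13.18 13.75
 dohb_large_high          51.56        12.19 13.21
  dohb_small_low          39.19        13.83 12.67
```

Arterial-normalized rCBV of the same 4 %-CBV tissue voxel varies more
than fivefold across hypoxic paradigms, shrinking monotonically as the
bolus gets larger or the baseline saturation lower, and is smallest for
Gd; normalizing to the vein compresses that spread by an order of
magnitude. MTT values (computed with the clinical 20 % singular-value
threshold and a long dOHb bolus) are inflated well above the true 2.95 s —
shortening the bolus or dropping the threshold moves them back down
(`bolus_duration_mtt_experiment`, `mtt_recovery_experiment`).

## Command line

```
dscsim simulate  --config cfg.yaml --out out/           # time courses / phantom
dscsim analyze   --in vol4d.nii.gz --aif x,y,z --vof x,y,z --agent gd --out maps/
dscsim experiment {cbv-sweep,paradigms,mtt-duration,ds-ratio} --out out/
```

Configuration is YAML or JSON; outputs are CSV/JSON plus optional NIfTI.

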