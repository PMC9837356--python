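# simepet

Minimally invasive quantification of TSPO PET tracer binding (e.g.
[¹⁸F]FEPPA) by **simultaneous estimation (SIME)** of a brain-wide
non-displaceable distribution volume, with blood-based input-function
correction and a Monte Carlo error-analysis toolkit.

## The problem

TSPO tracers have no reference region, so quantifying their uptake normally
requires a two-tissue compartment model (2TCM) driven by a
metabolite-corrected **arterial** input function and 2–3 h of scanning.
`simepet` implements the less invasive alternative: fit all regional
time–activity curves (TACs) *jointly*, assuming the non-displaceable
distribution volume V<sub>ND</sub> is uniform across the brain. Sharing
V<sub>ND</sub> removes one free parameter per region, stabilises the fit
enough to shorten the scan to 90 min, and makes the binding potential
insensitive to a scaling error in the input — which is what makes
image-derived input functions (IDIFs), anchored to a few **venous** blood
samples, usable in place of arterial lines.

## The model

Each region follows the 2TCM with rate constants K₁ (ml·cm⁻³·min⁻¹) and
k₂, k₃, k₄ (min⁻¹). Its impulse response is the biexponential

    IRF(t) = φ₁ e^(−θ₁ t) + φ₂ e^(−θ₂ t),
    θ₁,₂ = ½ [ (k₂+k₃+k₄) ± √((k₂+k₃+k₄)² − 4 k₂k₄) ],

and the modelled PET signal in a region is

    C(t) = (1 − v_B) · (C_p ⊛ IRF)(t) + v_B · C_wb(t),

time-averaged over each frame, with the fractional blood volume fixed at
v_B = 5%. C_p is the metabolite-corrected plasma-parent input, built from the
whole-blood curve via a biexponential blood-to-plasma ratio BPR(t) and a
Hill-type parent fraction f(t): C_p = C_wb / BPR · f.

Macro-parameters: V<sub>ND</sub> = K₁/k₂, V<sub>T</sub> = V<sub>ND</sub>(1 + k₃/k₄),
V<sub>S</sub> = V<sub>T</sub> − V<sub>ND</sub>, BP<sub>ND</sub> = V<sub>S</sub>/V<sub>ND</sub>.

SIME minimises the summed squared residual over all regions with per-region
(k₂, k₃, k₄) plus one common V<sub>ND</sub>, coupling K₁ = k₂·V<sub>ND</sub>.
Three routes are available: a bounded trust-region least-squares optimizer
(default), a bounded Nelder–Mead simplex, and a profile grid search over
V<sub>ND</sub> candidates that serves as an independent cross-check.

## Worked example

Simulate a noisy six-region 90-min study (true V<sub>ND</sub> = 2.35 ml/cm³,
regional V<sub>T</sub> between 11.69 and 15.16 ml/cm³, 5% mean-scaled
Gaussian noise) and run SIME:

```python
import numpy as np
from simepet import (synth_input, reference_truth, make_frame_schedule,
                     model_tac, NoiseProfile, add_noise, sime_joint_fit)

schedule = make_frame_schedule("mmr_90")          # 52 frames, 5399 s
inp = synth_input(t_end_min=95.0)                 # whole-blood + plasma-parent
truth = reference_truth()                         # six regions, V_ND = 2.35
tacs = [model_tac(r, inp, schedule, region=n) for n, r in truth.items()]
profile = NoiseProfile.flat(0.05, schedule, list(truth))
rng = np.random.default_rng(42)
noisy = [add_noise(t, profile, rng) for t in tacs]

res = sime_joint_fit(noisy, inp, seed=42)
print(res.summary())
```

```
Simultaneous estimation (shared V_ND) results
==============================================
method:     optimizer
V_ND:       2.2258 ml/cm^3
total cost: 90.4323
converged:  True   failed: False

               K1     k2     k3     k4   V_ND     V_T     V_S  BP_ND    cost converged at_bounds
region
frontal    0.2373 0.1066 0.2551 0.0459 2.2258 14.5864 12.3606 5.5533 10.1921      True     False
temporal   0.2353 0.1057 0.2669 0.0469 2.2258 14.8926 12.6668 5.6909 11.5243      True     False
cerebellum 0.2368 0.1064 0.1989 0.0474 2.2258 11.5582  9.3324 4.1928 17.0744      True     False
thalamus   0.2360 0.1060 0.2232 0.0542 2.2258 11.3849  9.1591 4.1150 14.4114      True     False
insula     0.2382 0.1070 0.2422 0.0409 2.2258 15.4081 13.1823 5.9224 22.8805      True     False
caudate    0.2399 0.1078 0.2118 0.0382 2.2258 14.5771 12.3513 5.5491 14.3496      True     False
```

One noisy realisation recovers the common V<sub>ND</sub> within ~5% and every
regional V<sub>T</sub> within a few percent; averaging over replicates (see
`monte_carlo_recovery`) shows the estimator is essentially unbiased in
V<sub>ND</sub> and V<sub>T</sub>, with BP<sub>ND</sub> precision of ~12% COV
under this noise level. On noiseless data the fit returns the generating
parameters to optimizer precision.

## Command line

```bash
simepet simulate  --preset mmr_90 --noise 0.05 --seed 1 --out study/
simepet blood-fit --blood blood.csv --out blood_models.json
simepet idif-scale --input idif.csv --blood blood.csv --out idif_scaled.csv
simepet sime      --config run.json            # full chain, writes parameters.csv
simepet mc-error  --n-reps 200 --seed 1 --out mc/
simepet agreement --pairs pairs.csv            # venous-vs-arterial regression
```

Exit codes: 0 success, 2 parse/config error, 3 fit failure.

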