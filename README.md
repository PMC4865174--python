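# oisi — intrinsic-signal imaging analysis for mouse V1

`oisi` analyzes intrinsic-signal optical imaging recordings of mouse primary
visual cortex to measure **visual acuity** and **ocular dominance**, the two
standard physiological readouts of binocular-vision plasticity (e.g. after
monocular deprivation).  It is written for systems-neuroscience labs that
acquire widefield reflectance movies under ~700 nm light while drifting
gratings of increasing spatial frequency (SF) are shown to each eye, and for
methodologists who want every stage of that analysis verifiable: the package
ships a synthetic-data generator with analytically known ground truth, so the
whole pipeline is validated by parameter recovery without any animal data.

## The analysis

For each trial (5 stored frames of 1 s), the response map is the frame ratio

&nbsp;&nbsp;&nbsp;&nbsp;R = mean(last three frames) / first frame,

since the last three frames carry the strongest intrinsic signal and the
first precedes the hemodynamic response.  Trials are averaged per eye × SF
condition.  Stimulus-locked spatial patterns are then extracted with a
generalized-indicator-function decomposition: with C_S the pixel covariance
of the condition-mean maps and C_N that of the per-trial residuals, solve

&nbsp;&nbsp;&nbsp;&nbsp;C_S v = λ (C_N + εI) v,

keep components whose stimulus-locked variance exceeds what trial-shuffled
data produce, and rebuild each map from the retained patterns; a Gaussian
low-pass (3 px SD) smooths the result.  Inside the binocular-zone ROI the SF
tuning curve is the mean response magnitude per SF.  After normalization by
the maximal amplitude among SFs, **visual acuity** is the x-intercept of a
least-squares line through the descending limb in (log10 SF, magnitude)
coordinates.  For each eye the **response integral** over SFs above a
threshold is computed by trapezoidal approximation on the log10-SF axis, and
the **ocular dominance index** at that threshold is the contrast formula

&nbsp;&nbsp;&nbsp;&nbsp;ODI = (C − I) / (C + I) ∈ [−1, 1],

positive for contralateral preference (+1 and −1 are the contra-only and
ipsi-only extremes).  Companion utilities implement the quantification
formulas used alongside such experiments: 2^−ΔΔCt relative qPCR expression,
percent-of-control summaries (mean ± SEM), and the pooled-variance Student
t-test.

## Worked example

Simulate one default recording session (10 SFs from 0.0303 to 1 cpd, 16
trials per eye and SF, realistic white/vascular/drift noise; true acuities
0.5 cpd contralateral, 0.35 cpd ipsilateral) and analyze it:

```bash
oisi analyze --outdir demo_run --seed 1
```

prints

```
acuity[contra] = 0.4523 cpd
acuity[ipsi] = 0.3734 cpd
ODI at lowest threshold = +0.2349
report written to demo_run/report.json
```

and `oisi report --outdir demo_run` summarizes the stored report:

```
mode=simulation seed=1 roi=84 px
acuity[contra] = 0.4523 cpd (R^2=0.989)
acuity[ipsi] = 0.3734 cpd (R^2=0.961)
ODI by threshold (cpd): 0.030:+0.235  0.045:+0.251  0.066:+0.269  0.097:+0.323  0.143:+0.431  0.211:+0.444  0.312:+0.135  0.460:-0.018  0.678:-0.008
```

The recovered acuities sit within one SF grid step of the ground truth
(0.45 vs 0.5 and 0.37 vs 0.35 cpd), the fitted descending limbs are nearly
straight (R² ≈ 0.95–0.99), and the ODI profile is positive — the
contralateral eye dominates — most strongly at mid spatial frequencies where
the ipsilateral response has already fallen off.  On noiseless data the same
pipeline recovers both acuities to machine-level accuracy, because the
generator's tuning model (plateau, then a limb linear in log10 SF hitting
zero exactly at the acuity) makes the x-intercept estimator exact.

The same analysis runs on recorded data (`oisi analyze --input-dir DIR`,
HDF5 stacks as written by `oisi simulate`), and
`examples/scenario_nacl_vs_cretat.json` holds a two-cohort scenario (treated
cohort with raised ipsilateral acuity, contralateral unchanged) for use with
`oisi.compare_cohorts`.

From Python:

```python
import oisi

report = oisi.run_pipeline(oisi.RunConfig(seed=1))
print(report["acuity"]["ipsi"]["acuity_cpd"])
```

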