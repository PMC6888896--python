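# vflatent

Latent-space modelling of longitudinal visual fields for glaucoma
progression: an MMD-regularized variational autoencoder for 24-2 standard
automated perimetry, global progression-rate statistics computed in the
learned latent space, and two-stage prediction of future visual fields.

## The problem

Glaucoma management rests on detecting *progression* — true deterioration of
the visual field — against heavy test-retest noise. The standard tools are
one-dimensional: the slope of mean deviation (MD) over time, or independent
per-location ("pointwise", PW) regressions. Both discard the spatial
structure of glaucomatous loss. This package models the whole field: each
24-2 test (52 informative total-deviation values, in dB) is embedded as a
zero-padded 12×12 image, normalized to [0, 1], and compressed to a few
latent features by a convolutional autoencoder whose aggregate latent
distribution is pulled toward a standard-normal prior with the maximum mean
discrepancy (MMD) — the InfoVAE formulation, in which the encoder is
deterministic and only the decoder is a (Gaussian-mean) probabilistic map.

On top of the latent space the package provides:

* **Rates of progression.** A patient's encoded trajectory z_il (visit i,
  feature l) is fitted by one stacked OLS model with a zero-sum constraint,

      z_il = a_l + (β + δ_l) t_i + ε_il,   Σ_l δ_l = 0,

  so β is the *mean rate of change across features*; a two-sided t-test on
  β (or, with a quadratic term, a joint F test on the global linear and
  quadratic rates) flags progression at α = 0.05. The comparator is the MD
  slope, flagged when significantly negative (one-sided, α = 0.05). Since
  every method is a 0.05-level p-value, hit rates on glaucoma eyes compare
  methods at a matched ~95% specificity.
* **Prediction of future fields.** Per-dimension OLS extrapolation of the
  first k visits' latent features, decoded into a future field; accuracy is
  MAE over the 52 informative locations, compared with PW regression by
  one-sided Wilcoxon signed-rank tests at the Bonferroni level 0.05/900.
* **A synthetic cohort simulator** (the study's clinical data is not
  public): a 17%/58%/25% normal/suspect/glaucoma mixture, ~7.6 visits over
  ~5 years, baseline MD ≈ −3.55 dB, arcuate/nasal-step/paracentral defect
  archetypes, per-status progression rates, and 2 dB test-retest noise —
  with per-patient ground truth for recovery experiments.

The autoencoder (convolutions, transposed convolutions, Adam, MMD gradient)
is implemented in numpy with hand-written backpropagation; it is small
enough (12×12 inputs) that this trains in minutes on one CPU core.

## Worked example

`examples/04_predict_fields.py` simulates 1,000 patients, trains an L = 8
model for 30 epochs, and compares future-field prediction against pointwise
regression on the held-out test patients:

```
 k_input  horizon  n_patients  mae_vae_mean  mae_pw_mean  wilcoxon_p  significant
       3        1          64          2.35         2.95    9.64e-08         True
       3        3          41          2.89         5.02       4e-11         True
       3        5          33          3.75         7.18    3.57e-08         True
       5        1          41          2.21         2.31      0.0281        False
       5        3          33          2.47         3.17    1.11e-05         True
       5        5          28          2.59            4    7.57e-06         True
```

Reading the table: with only three input visits and a five-visit horizon the
latent two-stage method predicts the held-out field with a mean absolute
error of 3.75 dB versus 7.18 dB for pointwise regression — extrapolated
per-location slopes are wild with three points, while decoded fields remain
smooth and bounded — and the paired signed-rank p-value (3.6e−08) is far
below the Bonferroni threshold 0.05/900 ≈ 6e−05. The advantage shrinks as
more input visits become available, the same qualitative pattern across the
scenario grid.

The other examples cover cohort simulation (`01`), training diagnostics and
the latent-dimension sweep (`02`), progression hit rates and the 95%
specificity calibration (`03`), and decoding a 2-D latent lattice into a
field mosaic (`05`). A thin CLI wraps the same pipeline:

```sh
vflatent simulate --n-patients 500 --seed 0 --out cohort.csv
vflatent train --data cohort.csv --latent-dim 8 --epochs 30 --seed 0 --out model.npz
vflatent progress --model model.npz --data cohort.csv --seed 0 --out progression.csv
vflatent predict --model model.npz --data cohort.csv --seed 0 --out predictions.csv
vflatent viz --model model2d.npz --out grid.png          # needs latent_dim=2
vflatent all --n-patients 200 --outdir demo/             # end to end
```

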