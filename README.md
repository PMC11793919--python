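# tfbigain

Missing-value imputation for multivariate time series with irregular
sampling, using a bidirectional, time-decay-aware recurrent GAN trained with
f-divergence adversarial losses (tf-BiGAIN).

Clinical records, air-quality monitors and similar sensor streams are
sampled irregularly and riddled with gaps; downstream models (mortality
prediction, pollution classification) need complete sequences. This package
imputes those gaps with a generative model rather than summary statistics,
so the filled values respect both cross-feature correlation and temporal
dynamics — in both time directions.

## Model

A sequence is a matrix **X** ∈ ℝ^(D×T) with mask **M** (1 = observed) and
timestamps t₁ < … < t_T, t₁ = 0. Per feature, forward/backward time-lag
matrices δᶠ, δᵇ accumulate the elapsed time since (resp. until) the nearest
observation. The recurrent unit is a GRU whose previous hidden state is
attenuated by a learned decay before gating (GRUI):

    β_t = exp(−max(0, W_β δ_t + b_β)),      H_{t−1} ← H_{t−1} ⊙ β_t

run independently forward (with δᶠ) and backward (with δᵇ); the two hidden
trajectories are averaged per timestep.

The generator receives M⊙X + (1−M)⊙Z (observed entries plus noise in the
gaps) and produces a full matrix Ĝ; the completed data is
X̂ = M⊙X + (1−M)⊙Ĝ, so observed entries are preserved exactly. A
discriminator scores every entry of X̂; scores at observed/imputed positions
feed the f-GAN variational objective

    L_D = E_real[g_f(S)] − E_fake[f*(g_f(S))],      L_G = L_GA + λ‖(X−Ĝ)⊙M‖²,

where f* is the convex conjugate of the divergence's generator function and
g_f its domain-guarding output activation (forward/reverse KL,
Jensen–Shannon, Pearson χ²; a weight-clipped Wasserstein critic is included
as a special case). After training, the noise filling the gaps is refined
per sequence by gradient descent on the imputation loss.

## Worked example

```python
import numpy as np
import tfbigain as tb

# irregular sampling: 3 features, 5 timestamps, '?' entries missing
X = np.array([[2, np.nan, np.nan, 5, 9],
              [3, 8, np.nan, np.nan, np.nan],
              [np.nan, 6, np.nan, 10, 1]], float)
t = np.array([0., 3., 5., 8., 12.])
M = tb.build_mask(X)
print(tb.forward_time_lag(M, t))
print(tb.backward_time_lag(M, t))
```

```
[[0. 3. 5. 8. 4.]
 [0. 3. 2. 5. 9.]
 [0. 3. 2. 5. 4.]]
[[8. 5. 3. 4. 0.]
 [3. 9. 7. 4. 0.]
 [3. 5. 3. 4. 0.]]
```

Row 1 of the forward matrix reads: at t₃ = 5 the first feature was last seen
at t₁ = 0, so its lag is 5; the backward matrix records the wait until the
next observation instead.

End-to-end on synthetic data (20 sequences, 5 features, 48 steps, 20%
missing completely at random):

```python
cfg = tb.SimConfig(seed=1)
incomplete, truth, masks, _ = tb.simulate(cfg)
imputer = tb.FDivGANImputer(divergence="forward_kl", direction="bi",
                            batch_size=4, pretrain_epochs=5, epochs=15,
                            refine_iterations=50, random_state=1)
completed = imputer.fit(incomplete).transform(incomplete)
print(tb.masked_rmse(truth, completed, masks))                       # 1.229
print(tb.masked_rmse(truth, [tb.baseline_impute(s, "mean")
                             for s in incomplete], masks))           # 1.571
```

The GAN imputer recovers the hidden entries with RMSE 1.23 versus 1.57 for
per-feature-mean imputation: the recurrent decay model exploits each
sequence's own temporal context. `FDivGANImputer` and `GRUClassifier`
follow the scikit-learn estimator API (`get_params`, `clone`, pipelines).

A CLI mirrors the library:

```bash
tbigain simulate --out data/ --missing-rate 0.3 --seed 1
tbigain impute --input data/incomplete.csv --output imputed.csv \
               --divergence js --seed 7
tbigain evaluate --input data/incomplete.csv --truth data/truth.csv \
                 --imputed imputed.csv
tbigain sweep --out sweep.csv --rates 0.1,0.3,0.5
```

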