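# dsmm — robust non-rigid point-set registration

`dsmm` aligns two point sets — a fixed **target** X (M×D) and a moving
**template** Y (N×D), D ∈ {2, 3} — without any pre-alignment, landmarks or
feature descriptors. It is aimed at biomedical point data: contours traced
from MR slices, landmark clouds picked in thoracic CT, surface samples —
settings where many points have no true partner (occlusion) and clutter
points have no anatomical meaning (outliers).

## The model

The template points act as the centroids of a heavy-tailed mixture: the
target points are modeled as draws from

    f(x_m) = Σ_n  w_mn · S(x_m | y_n, σ²I, γ_n),

where S is the multivariate Student's-t density with per-component degrees
of freedom γ_n (initialized at 1, i.e. Cauchy, for maximal robustness) and
shared isotropic scale σ². Two ingredients distinguish the method from
Gaussian-mixture registration of the coherent-point-drift family:

1. **Per-pair Dirichlet mixture proportions.** The component labels are
   treated as random variables with a Dirichlet prior whose concentration
   parameters are an exponentiated moving average of the posteriors over
   each template point's k nearest neighbors:

       w_mn = softmax_n( (ᾱ/N_n) Σ_{i∈∂y_n} p_mi ).

   Neighboring template points therefore vote together for their
   correspondences, and the single concentration coefficient ᾱ is
   re-estimated each EM iteration by a 1-D root solve — one extra scalar
   parameter, not M×N of them.

2. **Student's-t robustness.** In the scale-mixture representation each
   pair carries a latent weight u_mn = (γ_n + D)/(γ_n + d_mn) that
   down-weights distant pairs in every M-step; γ_n itself is re-estimated
   from a digamma stationarity equation, so the tail weight adapts to the
   contamination actually present.

The template moves by a Gaussian-RBF displacement field Y ← Y + GW with
kernel g_ij = exp(−‖y_i−y_j‖²/(2β²)), fitted from a regularized weighted
least-squares solve; β (default 2 on normalized coordinates) sets the
coherence scale of the motion and λ (default 2) the regularization
strength. As γ → ∞ and ᾱ → 0 the whole scheme reduces to a plain
Gaussian-mixture coherent-drift iteration (exposed as the `cpd_limit` test
mode).

## Worked example

```python
import dsmm

# a 300-point lung-like 3-D cloud, smoothly deformed by 10% of its
# bounding-box diagonal (coordinates in mm), ground truth known
sc = dsmm.make_scenario("cloud_deform", 0.10, seed=7)

pre, pre_sd = dsmm.pre_registration_error(sc)
res = dsmm.register(sc.X, sc.Y)          # defaults: beta=2, lam=2, k=5
post, post_sd = dsmm.mean_correspondence_error(res, sc)

print(f"pre-registration error : {pre:.2f} +/- {pre_sd:.2f} mm")
print(f"post-registration error: {post:.4f} +/- {post_sd:.4f} mm")
print(f"iterations: {res.n_iter}, converged: {res.converged}")
```

prints

```
pre-registration error : 17.59 +/- 1.05 mm
post-registration error: 0.0017 +/- 0.0013 mm
iterations: 7, converged: True
```

i.e. the mean Euclidean distance between each warped template point and
its ground-truth partner drops from 17.6 mm to essentially zero; the
`trace` attribute records the negative log-likelihood, σ², mean γ and ᾱ at
every iteration, and `res.correspondence` gives each template point's
maximum-posterior target index with its probability.

The same pipeline is available from the shell:

```
dsmm synth --kind cloud_deform --level 0.1 --seed 7 --out-dir fixtures/
dsmm register --target fixtures/X.txt --template fixtures/Y.txt \
              --out Yreg.txt --trace trace.csv --correspondence corr.csv
```

Point sets are plain delimited text (one point per row, `#` comments) or
ASCII PLY vertex lists.

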