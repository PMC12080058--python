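# Methods

This note documents the models, the synthetic study design, the
numerical choices, and the limitations of `neuronorm`. It states no
empirical claims beyond what the test suite and `scripts/acceptance.py`
compute.

## Confound adjustment

Each imaging feature is modelled on a control cohort as

    y = β₀ + f(age) + β_sex · sex + β_icv · ICV + ε

with `f` a penalized natural cubic regression spline. In one dimension
the thin-plate spline of order 2 coincides with the natural cubic
smoothing spline, so a natural cubic basis is the exact low-rank
analogue of thin-plate regression splines; it is also linear beyond the
boundary knots, which gives principled linear extrapolation for ages
outside the fitted range (applied with a warning). Knots (default
`basis_dim = 10`) sit at age quantiles. The spline block is
orthogonalized against {1, age} so the parametric age slope stays
identified; the curvature penalty ∫f″² is evaluated by quadrature and
the smoothing parameter is chosen per feature by GCV over a fixed
25-point log-spaced grid. Because the design matrix is shared across
features, all features are fitted simultaneously per grid point.

Adjustment replaces each feature by `(y − ŷ − μ_res) / σ_res` with the
residual mean and (n−1) standard deviation taken from the fitting
cohort: control-referenced z-scores. One confound model is fitted per
site/cohort (`fit_cohort_id`) and never shared across sites; for the
target site the fine-tuning controls are the fitting cohort and the
holdout/at-risk cohorts are transformed with those fixed coefficients.
Constant features are excluded with a warning; residuals are exactly
orthogonal to the unpenalized columns (intercept, age, sex, ICV) by the
normal equations, which the tests verify. Applying a fitted model is a
fixed affine map — it refits nothing, so only the single-application
contract is guaranteed.

## The multi-modal normative model

The DMVAE has, per modality m, an encoder producing Gaussian posteriors
over a shared code z_s (default k_s = 10) and a private code z_p^m
(default k_p = 2), and a decoder mapping [z_s, z_p^m] back to the
feature block with a learned per-feature observation variance. The
training objective sums, over every (source n, target m) modality pair,
the Gaussian reconstruction negative log-likelihood of block m decoded
from modality n's shared code and modality m's private code —
cross-modality reconstruction is what forces z_s to carry information
common to all blocks — plus β-weighted KL terms (β = 1 by default)
pulling every shared and private posterior toward N(0, I). The M²
reconstruction terms are averaged over M so the reconstruction/KL
balance matches a single-view VAE.

Networks are two-layer MLPs (hidden width 64) with ELU activations and
a linear skip connection from the input into the posterior means.
Both choices are deliberate, not incidental: disease effects enter as
coordinated mean shifts across many regions, and with bounded
activations such shifts saturate hidden units and shrink
out-of-distribution latent codes toward the prior — which would make
latent deviation *decrease* with severity. ELU keeps roughly half the
units in their linear regime for any shift direction and the skip path
keeps the latent response monotone, so the Mahalanobis deviation grows
with abnormality as intended. The out-of-distribution behaviour of an
autoencoder trained only on healthy data is otherwise unidentified;
this is a known caveat of autoencoder-based normative models.

Optimization is Adam (pretraining lr 1e−3, fine-tuning lr 1e−4, batch
256 by default; the bundled experiments use batch 64 at their smaller
cohort sizes), implemented with analytic gradients in NumPy and
verified against central finite differences. Training is deterministic
given the seed: initialization, batch order and reparameterization
noise all derive from it. Posterior log-variances are clipped to ±8 and
observation log-variances to ±6 for numerical safety; a non-finite loss
aborts with a diagnostic. Fine-tuning continues optimization of *all*
weights from the pretrained state on target-site controls and appends
to the training history; it never re-initializes.

Inference uses posterior means only (no sampling), so latents,
reconstructions and all deviation metrics are deterministic. The
cross-modality shared code combines the per-modality shared posteriors
by precision weighting. Checkpoints round-trip bit-exactly through
`.npz` containers that embed the architecture, history and seed.

## Deviation metrics

The holdout reference stores the holdout cohort's shared-latent mean
μ_z and covariance Σ_z (ddof = 1, ridge-regularized by
`1e−6 · trace/k_s` on the diagonal; a covariance that is still not
positive definite raises), plus per-feature reconstruction-residual
mean μ_r and SD σ_r. `D_ml` is the Mahalanobis distance of a subject's
shared code from (μ_z, Σ_z), computed via Cholesky factorization; the
tests check it against the explicit matrix inverse to 1e−8 and verify
its affine invariance and the in-sample χ²(k_s) behaviour of D_ml².
`D_uf` is the signed z-score `(r − μ_r)/σ_r` of the residual
`r = x − x̂`, so regional loss (atrophy, FA reduction) that the
normative reconstruction does not track appears as negative D_uf, and
MD elevation as positive. Deviations are computed per subject-visit
row; aggregation across visits (baseline vs latest) is the caller's
choice and an explicit pipeline flag.

Referencing against the holdout — not the training or fine-tuning
controls — absorbs residual model misfit into the reference so the
metrics measure abnormality relative to how the model treats healthy
data it has never seen.

## Outlier and permutation analysis

A region is an outlier when D_uf < −1.96 (T1, FA) or D_uf > +1.96 (MD);
the boundary value itself is not an outlier (strict inequality). By
construction this flags 2.5% of healthy-like scores per tail, which the
acceptance script verifies on 100,000 null scores. Outlier maps are
per-feature flagged fractions within a stratum; the 0.025 display floor
used when rendering maps is presentation-only and never enters any
statistic.

Cortical regions map to the seven Yeo functional networks and
subcortical grey matter to medial temporal lobe (hippocampus,
amygdala), thalamus, and basal ganglia (accumbens, pallidum, putamen,
caudate); the ventral diencephalon has no canonical assignment and is
excluded from network analyses. The bundled Desikan-Killiany → Yeo
assignment is a coarse majority-overlap mapping authored for this
package; users with a preferred mapping can supply their own
two-column file. A network's rate counts each subject once — the
fraction of subjects with at least one flagged region in the network.

The permutation test permutes case/control labels (default 10,000
draws), recomputes network rates, and reports
`p = (1 + #{null ≥ observed}) / (n_perm + 1)`: add-one smoothing avoids
p = 0 and counting ties as exceeding is conservative. Per-region
empirical p-values, when requested, reuse the same permutation draws
for coherence and speed. Because the null statistic is discrete
(multiples of 1/n_cases), p-values are mildly super-uniform; the
acceptance script measures the realized rejection rate at α = 0.05
under an exchangeable null (≈3–4% across 400 datasets with 2,000
permutations — conservative, never anti-conservative). FDR control is
Benjamini–Hochberg step-up (via statsmodels), tested against a
hand-implemented oracle on all subsets of 8 p-values.

## Downstream statistics

Biomarker age adjustment fits `biomarker ~ age` by least squares on
controls only and residualizes all rows with those fixed coefficients —
cases with a different age slope deliberately retain residual age
association. Correlations are Pearson with pairwise deletion, always
reporting the n used. Cohen's d uses the pooled (n−1-weighted) SD with
the convention that positive d means the subgroup exceeds controls.
Group contrasts use Welch's unequal-variance t-test
(Welch–Satterthwaite df); longitudinal change uses a two-sided paired
t-test. A degenerate paired sample with identical pairs returns t = 0,
p = 1; a constant non-zero difference (zero variance, undefined t)
raises. All tests are two-sided. The Bonferroni threshold for the
six-test biomarker/cognition family is α/6 = 0.0083.

## Synthetic study design

The generator emulates the study structure end-to-end. Defaults mirror
the target design: 169 fine-tuning / 168 holdout "super healthy"
controls (MMSE > 28, CDR = 0, no ApoE ε4) and 592 at-risk subjects,
with a desk-scale 1,000-subject pretraining cohort; ICV ~ N(1.50, 0.15)
and CSF marginals anchored to published cohort demographics (p-tau
≈ 16.7 healthy / ≈ 20 at-risk pg/mL, etc.).

Features = shared-factor loadings × subject factors (variance share
0.5) + private-factor contribution (0.2) + smooth age effect + linear
sex effect + linear ICV effect (T1 only; ICV does not plausibly drive
tract FA/MD) + Gaussian noise (sd 0.5). The age curve is a linear trend
plus a logistic "accelerating decline after 60", negative for T1/FA and
positive for MD; its recoverability by the spline fit is tested
(R² > 0.9). The target-site cohorts (fine-tune, holdout, at-risk)
receive a fixed per-feature additive offset (sd `site_shift = 0.3`
control-sd) emulating the scanner/processing domain gap that makes
fine-tuning testable.

Severity is `(2·CDR + (30 − MMSE)/10) / 9 ∈ [0, 1]`, a monotone blend
of both clinical stratifications, zero for CDR = 0 / MMSE = 30. CDR and
MMSE are drawn from categorical distributions shaped like the published
at-risk stratum sizes (62% CDR = 0, 35% CDR = 0.5, 3% CDR = 1). Disease
shifts act on `affected_regions` (default: bilateral hippocampus,
amygdala, entorhinal, parahippocampal volumes and ILF/UNC/fornix-ST
FA + MD) with sign −/−/+ for T1/FA/MD, magnitude
`effect_size · w_i · control-sd`, where `w_i = severity_i/E[severity]`
is normalized by the exact expectation under the label distribution so
the *at-risk group mean* shift equals `effect_size` (default 2.0
control-sd at the group level; individual shifts scale with severity).
Visit v > 0 adds `progression_rate · v · w_i` (default 0.5) in the same
regions for at-risk subjects only — progression scales with severity
because a flat shift would be first-order orthogonal to the deviation
of the low-severity majority and because cognitively normal at-risk
members progressing as fast as CDR = 1 members would be implausible.
CSF p-tau/t-tau rise and abeta42 falls linearly in severity with
Gaussian noise. Identical seeds give bit-identical tables.

What the generator does **not** emulate: voxel-level structure, scanner
physics, non-Gaussian feature marginals, missing data, dropout between
visits, or correlated confound distributions across sites. Passing
tests therefore demonstrate correctness and sensitivity of the
machinery under a known linear-Gaussian world, not performance on real
cohorts.

## Problem sizes and experiment settings

The bundled experiments (tests and acceptance script) use cohorts of
500 pretraining / 200 fine-tuning / 200–400 holdout / 500 at-risk
subjects, k_s = 6, 30-epoch training with batch 64 — sizes at which the
full pipeline runs in seconds while leaving all qualitative signatures
(severity ordering, longitudinal detection, fine-tuning benefit)
clearly measurable. Longitudinal experiments generate an enlarged
holdout and split it: one half fits the reference, the other half is
scored at both visits, so the paired control contrast is not biased by
comparing in-sample (reference) rows at baseline against out-of-sample
rows at follow-up. Permutation calibration uses 400 datasets × 2,000
permutations; all other analyses use the 10,000-permutation default.

## Known limitations

- The latent response to deviations far outside the healthy manifold is
  intrinsically unidentified from healthy training data; the ELU + skip
  architecture keeps it monotone but its scale is not calibrated.
- D_ml uses the shared latents only; private codes are excluded, so
  strictly modality-private abnormality surfaces in D_uf but is muted
  in D_ml.
- GCV smoothing selection is per feature but shares one knot set; very
  small control cohorts (< basis_dim + 3) are rejected rather than
  downscaled.
- Site harmonization beyond fine-tuning (e.g. ComBat-style location /
  scale adjustment) is out of scope.
- The permutation p-value is conservative under heavy ties (small case
  groups); use larger case strata or more permutations when rates are
  coarse.
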