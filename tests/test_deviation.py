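import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from neuronorm import deviation
from neuronorm.deviation import (
    HoldoutReference,
    compute_dml,
    compute_duf,
    deviation_table,
    fit_holdout_reference,
)
from neuronorm.stats import welch_t
from neuronorm.synthetic_data import SimulationConfig, generate_cohort
from neuronorm.confound import apply_confound_model, fit_confound_model


def _ref_from(Z, feats=("f",)):
    mu = Z.mean(axis=0)
    cov = np.cov(Z, rowvar=False, ddof=1)
    return HoldoutReference(
        latent_mean=mu, latent_cov=np.atleast_2d(cov),
        residual_mean=np.zeros(len(feats)), residual_sd=np.ones(len(feats)),
        feature_names=list(feats), n_holdout=len(Z),
    )


class TestMahalanobis:
    def test_zero_at_reference_mean(self):
        ref = _ref_from(np.random.default_rng(0).normal(size=(50, 3)))
        assert ref.mahalanobis(ref.latent_mean[None, :])[0] == pytest.approx(0.0)

    def test_identity_covariance_reduces_to_euclidean(self):
        ref = HoldoutReference(
            latent_mean=np.zeros(3), latent_cov=np.eye(3),
            residual_mean=np.zeros(1), residual_sd=np.ones(1),
            feature_names=["f"],
        )
        assert ref.mahalanobis(np.array([[1.0, 0, 0]]))[0] == pytest.approx(1.0)

    def test_diagonal_two_covariance_hand_case(self):
        # explicit (z-mu)^T Sigma^-1 (z-mu) = 1/2 + 1/2 = 1 -> distance 1
        ref = HoldoutReference(
            latent_mean=np.zeros(2), latent_cov=np.diag([2.0, 2.0]),
            residual_mean=np.zeros(1), residual_sd=np.ones(1),
            feature_names=["f"],
        )
        assert ref.mahalanobis(np.array([[1.0, 1.0]]))[0] == pytest.approx(1.0)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_affine_invariance(self, seed):
        """Mahalanobis distance is invariant under any invertible linear
        re-parameterization applied to latents and reference alike."""
        rng = np.random.default_rng(seed)
        Z = rng.normal(size=(60, 4))
        Q = rng.normal(size=(30, 4))
        A = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        ref = _ref_from(Z)
        ref_t = _ref_from(Z @ A.T)
        d0 = ref.mahalanobis(Q)
        d1 = ref_t.mahalanobis(Q @ A.T)
        assert np.allclose(d0, d1, rtol=1e-7, atol=1e-8)

    def test_in_sample_median_matches_chi_square(self):
        rng = np.random.default_rng(1)
        k = 6
        Z = rng.normal(size=(300, k))
        ref = _ref_from(Z)
        med = np.median(ref.mahalanobis(Z) ** 2)
        expected = sps.chi2(df=k).median()
        assert abs(med - expected) / expected < 0.25


class TestHoldoutReference:
    def test_identical_subjects_rejected(self, fitted_study):
        ho = fitted_study["adj_holdout"]
        ho0 = ho[ho.visit == 0]
        degenerate = pd.concat([ho0.iloc[[0]]] * 40, ignore_index=True)
        with pytest.raises(ValueError):
            fit_holdout_reference(fitted_study["model"], degenerate)

    def test_too_small_holdout_rejected(self, fitted_study):
        ho = fitted_study["adj_holdout"]
        with pytest.raises(ValueError, match="holdout too small"):
            fit_holdout_reference(fitted_study["model"], ho.iloc[:5])

    def test_reference_is_deterministic(self, fitted_study):
        ho = fitted_study["adj_holdout"]
        ho0 = ho[ho.visit == 0]
        r1 = fit_holdout_reference(fitted_study["model"], ho0)
        r2 = fit_holdout_reference(fitted_study["model"], ho0)
        assert (r1.latent_mean == r2.latent_mean).all()
        assert (r1.latent_cov == r2.latent_cov).all()
        assert (r1.residual_sd == r2.residual_sd).all()

    def test_self_referenced_duf_standardized(self, fitted_study):
        model = fitted_study["model"]
        ho0 = fitted_study["adj_holdout"].query("visit == 0")
        ref = fit_holdout_reference(model, ho0)
        duf = compute_duf(model, ref, ho0)
        assert np.allclose(duf.mean(), 0.0, atol=1e-10)
        assert np.allclose(duf.std(ddof=1), 1.0, atol=1e-10)


class TestDeviationMetrics:
    def test_dml_nonnegative_and_deterministic(self, fitted_study):
        model = fitted_study["model"]
        ho0 = fitted_study["adj_holdout"].query("visit == 0")
        ar0 = fitted_study["adj_at_risk"].query("visit == 0")
        ref = fit_holdout_reference(model, ho0)
        d1 = compute_dml(model, ref, ar0)
        d2 = compute_dml(model, ref, ar0)
        assert (d1 >= 0).all()
        assert (d1 == d2).all()

    def test_duf_zero_and_unit_anchors(self):
        """Residual at the holdout mean gives 0; one sd below gives -1."""
        ref = HoldoutReference(
            latent_mean=np.zeros(2), latent_cov=np.eye(2),
            residual_mean=np.array([0.5]), residual_sd=np.array([2.0]),
            feature_names=["f"],
        )
        z = (np.array([0.5, -1.5]) - ref.residual_mean) / ref.residual_sd
        assert z[0] == pytest.approx(0.0)
        assert z[1] == pytest.approx(-1.0)

    def test_atrophy_shows_negative_duf_in_affected_region(self, modalities,
                                                           feature_names):
        """Strong simulated hippocampal atrophy drives the at-risk group
        median d_uf below -1 (5 generator seeds)."""
        from neuronorm import dmvae
        medians = []
        for seed in range(5):
            cfg = SimulationConfig(
                n_healthy_train=400, n_finetune=150, n_holdout=150,
                n_at_risk=200, k_shared=6, effect_size=2.0, seed=200 + seed,
            )
            t = generate_cohort(cfg)
            cm_tr = fit_confound_model(
                t[t.cohort_label == "healthy_train"], feature_names)
            cm_s = fit_confound_model(
                t[t.cohort_label == "finetune"], feature_names)
            adj_tr = apply_confound_model(cm_tr, t[t.cohort_label == "healthy_train"])
            adj_ho = apply_confound_model(cm_s, t[t.cohort_label == "holdout"])
            adj_ar = apply_confound_model(cm_s, t[t.cohort_label == "at_risk"])
            m = dmvae.train(adj_tr, modalities,
                            dmvae.Hyperparams(epochs=20, batch_size=64),
                            k_shared=6, seed=seed)
            ref = fit_holdout_reference(m, adj_ho)
            duf = compute_duf(m, ref, adj_ar)
            medians.append(duf["Left-Hippocampus"].median())
        assert np.median(medians) < -1.0

    def test_severity_strata_orderings_monotone(self, fitted_study):
        """Mean d_ml increases across severity strata (Spearman rho > 0.9
        over >= 4 strata)."""
        model = fitted_study["model"]
        ho0 = fitted_study["adj_holdout"].query("visit == 0")
        ar0 = fitted_study["adj_at_risk"].query("visit == 0")
        ref = fit_holdout_reference(model, ho0)
        dml = compute_dml(model, ref, ar0)
        sev_bins = pd.cut(
            2 * ar0["cdr"].to_numpy() + (30 - ar0["mmse"].to_numpy()) / 10,
            bins=[-0.01, 0.15, 0.5, 1.2, 10], labels=False,
        )
        means = [dml[sev_bins == b].mean() for b in range(4)]
        rho = sps.spearmanr(range(4), means).statistic
        assert rho > 0.9

    def test_deviation_table_layout(self, fitted_study):
        model = fitted_study["model"]
        ho0 = fitted_study["adj_holdout"].query("visit == 0")
        ref = fit_holdout_reference(model, ho0)
        tab = deviation_table(model, ref, ho0)
        assert list(tab.columns[:3]) == ["subject_id", "visit", "d_ml"]
        assert list(tab.columns[3:]) == model.feature_names

    def test_severity_label_ordering_via_dml(self, fitted_study):
        """Group means reproduce holdout <= CDR=0 < CDR=0.5."""
        model = fitted_study["model"]
        ho0 = fitted_study["adj_holdout"].query("visit == 0")
        ar0 = fitted_study["adj_at_risk"].query("visit == 0")
        ref = fit_holdout_reference(model, ho0)
        d_ho = compute_dml(model, ref, ho0)
        d_ar = compute_dml(model, ref, ar0)
        cdr = ar0["cdr"].to_numpy()
        assert d_ar[cdr == 0.5].mean() > d_ar[cdr == 0].mean()
        assert welch_t(d_ar[cdr == 0.5], d_ar[cdr == 0]).p < 0.01
        assert d_ar[cdr == 0].mean() >= d_ho.mean() - 0.1
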