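import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import CCA

from neuronorm import dmvae
from neuronorm.dmvae import (
    Hyperparams,
    NormativeModel,
    _decode_one,
    _loss_and_grads,
    encode,
    fine_tune,
    init_model,
    reconstruct,
    train,
)
from neuronorm.synthetic_data import SimulationConfig, generate_cohort

TINY_MODS = {"A": [f"a{i}" for i in range(5)], "B": [f"b{i}" for i in range(4)]}


def _tiny_batch(seed=0, n=7):
    rng = np.random.default_rng(seed)
    return {m: rng.normal(size=(n, len(f))) for m, f in TINY_MODS.items()}


def test_analytic_gradients_match_finite_differences():
    """Backprop gradients agree with central finite differences of the
    deterministic (zero-noise) objective."""
    model = init_model(TINY_MODS, k_shared=2, k_private=1, hidden=6, seed=3)
    # move away from zero-initialized biases/skips so every path is active
    rng = np.random.default_rng(4)
    for k, v in model.params.items():
        model.params[k] = v + rng.normal(0, 0.05, size=v.shape)
    Xs = _tiny_batch()
    eps = {m: (np.zeros((7, 2)), np.zeros((7, 1))) for m in TINY_MODS}
    loss, grads = _loss_and_grads(model.params, Xs, 2, 1, 1.0, eps)

    h = 1e-6
    rng = np.random.default_rng(5)
    for key in sorted(model.params):
        flat = model.params[key].ravel()
        for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
            orig = flat[idx]
            flat[idx] = orig + h
            lp, _ = _loss_and_grads(model.params, Xs, 2, 1, 1.0, eps)
            flat[idx] = orig - h
            lm, _ = _loss_and_grads(model.params, Xs, 2, 1, 1.0, eps)
            flat[idx] = orig
            fd = (lp - lm) / (2 * h)
            an = grads[key].ravel()[idx]
            assert an == pytest.approx(fd, rel=1e-4, abs=1e-7), key


def _frame(Xs):
    return pd.concat(
        [pd.DataFrame(Xs[m], columns=TINY_MODS[m]) for m in TINY_MODS], axis=1
    )


def test_zero_epochs_returns_initialization():
    df = _frame(_tiny_batch())
    model = train(df, TINY_MODS, Hyperparams(epochs=0), k_shared=2,
                  k_private=1, hidden=6, seed=1)
    ref = init_model(TINY_MODS, k_shared=2, k_private=1, hidden=6, seed=1)
    for k in ref.params:
        assert (model.params[k] == ref.params[k]).all()


def test_zero_epoch_finetune_is_identity():
    df = _frame(_tiny_batch())
    model = train(df, TINY_MODS, Hyperparams(epochs=3, batch_size=4),
                  k_shared=2, k_private=1, hidden=6, seed=1)
    tuned = fine_tune(model, df, Hyperparams(epochs=0))
    for k in model.params:
        assert (tuned.params[k] == model.params[k]).all()


def test_encode_is_deterministic_with_contracted_shapes():
    df = _frame(_tiny_batch())
    model = train(df, TINY_MODS, Hyperparams(epochs=5, batch_size=4),
                  k_shared=2, k_private=1, hidden=6, seed=2)
    c1 = encode(model, df)
    c2 = encode(model, df)
    assert (c1.shared == c2.shared).all()
    assert c1.shared.shape == (len(df), 2)
    for m in TINY_MODS:
        assert c1.private[m].shape == (len(df), 1)
    rec = reconstruct(model, df)
    assert list(rec.columns) == model.feature_names
    assert np.isfinite(rec.to_numpy()).all()


def test_untrained_model_finite_on_zero_input():
    model = init_model(TINY_MODS, k_shared=2, k_private=1, hidden=6, seed=0)
    df = _frame({m: np.zeros((3, len(f))) for m, f in TINY_MODS.items()})
    rec = reconstruct(model, df)
    assert np.isfinite(rec.to_numpy()).all()


def test_feature_permutation_equivariance():
    """Permuting one modality's feature columns together with the
    corresponding encoder input weights and decoder output weights leaves
    latent codes identical and permutes reconstructions accordingly."""
    df = _frame(_tiny_batch())
    model = train(df, TINY_MODS, Hyperparams(epochs=5, batch_size=4),
                  k_shared=2, k_private=1, hidden=6, seed=2)
    perm = np.array([3, 1, 4, 0, 2])
    permuted = model.copy()
    permuted.modalities["A"] = [model.modalities["A"][i] for i in perm]
    permuted.params["enc_A_W1"] = model.params["enc_A_W1"][:, perm]
    permuted.params["enc_A_S"] = model.params["enc_A_S"][:, perm]
    permuted.params["dec_A_V2"] = model.params["dec_A_V2"][perm]
    permuted.params["dec_A_c2"] = model.params["dec_A_c2"][perm]
    permuted.params["dec_A_logvar"] = model.params["dec_A_logvar"][perm]
    c0 = encode(model, df)
    c1 = encode(permuted, df)
    assert np.allclose(c0.shared, c1.shared)
    r0 = reconstruct(model, df)
    r1 = reconstruct(permuted, df)
    assert np.allclose(r0[model.modalities["A"]], r1[model.modalities["A"]])


def test_checkpoint_round_trip_bit_exact(tmp_path):
    df = _frame(_tiny_batch())
    model = train(df, TINY_MODS, Hyperparams(epochs=3, batch_size=4),
                  k_shared=2, k_private=1, hidden=6, seed=9)
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = NormativeModel.load(path)
    assert loaded.modalities == model.modalities
    assert loaded.history == model.history
    for k in model.params:
        assert (loaded.params[k] == model.params[k]).all()


def test_training_loss_trends_downward(fitted_study):
    hist = [h["loss"] for h in fitted_study["pretrained"].history]
    assert np.isfinite(hist).all()
    # median over the first vs last 10-epoch window
    assert np.median(hist[-10:]) < np.median(hist[:10])


def test_validation_error_reaches_noise_floor():
    """On linear-Gaussian data the model reconstructs held-out healthy
    subjects close to the generative noise floor (per-feature MSE below
    1.2x the noise variance, median over 5 seeds)."""
    ratios = []
    for seed in range(5):
        cfg = SimulationConfig(
            n_healthy_train=1500, n_finetune=0, n_holdout=500, n_at_risk=0,
            beta_age=0, beta_sex=0, beta_icv=0, site_shift=0,
            k_shared=4, noise_sd=0.5, seed=seed,
        )
        t = generate_cohort(cfg)
        mods = _mods_from(t)
        feats = [f for fs in mods.values() for f in fs]
        tr = t[t.cohort_label == "healthy_train"]
        va = t[t.cohort_label == "holdout"]
        m = train(tr, mods, Hyperparams(epochs=200, batch_size=256),
                  k_shared=4, seed=seed)
        rec = reconstruct(m, va)
        mse = ((va[feats].to_numpy() - rec[feats].to_numpy()) ** 2).mean()
        ratios.append(mse / cfg.noise_sd**2)
    assert np.median(ratios) < 1.2


def _mods_from(t):
    from neuronorm.features import default_modality_specs
    return {s.name: [f for f in s.features if f in t.columns]
            for s in default_modality_specs()}


def test_shared_code_recovers_generative_factors():
    """Canonical correlation between shared posterior means and the true
    shared factors exceeds 0.8 on held-out linear-Gaussian data."""
    cfg = SimulationConfig(
        n_healthy_train=2000, n_finetune=0, n_holdout=500, n_at_risk=0,
        beta_age=0, beta_sex=0, beta_icv=0, site_shift=0,
        k_shared=4, noise_sd=0.5, seed=0,
    )
    t, gt = generate_cohort(cfg, return_truth=True)
    mods = _mods_from(t)
    tr = t[t.cohort_label == "healthy_train"]
    va = t[t.cohort_label == "holdout"]
    m = train(tr, mods, Hyperparams(epochs=120, batch_size=256),
              k_shared=4, seed=0)
    code = encode(m, va)
    U = gt.shared_factors[(t.cohort_label == "holdout").to_numpy()]
    cca = CCA(n_components=4).fit(code.shared, U)
    Xc, Yc = cca.transform(code.shared, U)
    cc = [abs(np.corrcoef(Xc[:, i], Yc[:, i])[0, 1]) for i in range(4)]
    assert min(cc) > 0.8


def test_at_risk_reconstruction_error_exceeds_healthy(fitted_study, feature_names):
    model = fitted_study["model"]
    ho = fitted_study["adj_holdout"]
    ar = fitted_study["adj_at_risk"]
    ho0, ar0 = ho[ho.visit == 0], ar[ar.visit == 0]

    def err(d):
        r = reconstruct(model, d)
        return ((d[feature_names].to_numpy() - r[feature_names].to_numpy()) ** 2).mean()

    assert err(ar0) > err(ho0)


def test_private_code_supports_own_modality_reconstruction(fitted_study,
                                                           feature_names):
    """Ablating a modality's private code degrades that modality's
    reconstruction more than the other modalities' (weak
    disentanglement)."""
    model = fitted_study["model"]
    ho = fitted_study["adj_holdout"]
    ho0 = ho[ho.visit == 0]
    code = encode(model, ho0)

    def mse_per_modality(ablate=None):
        out = {}
        for m, feats in model.modalities.items():
            zp = code.private[m].copy()
            if m == ablate:
                zp[:] = 0.0
            Z = np.concatenate([code.shared, zp], axis=1)
            _, xhat = _decode_one(model.params, m, Z)
            out[m] = ((ho0[feats].to_numpy() - xhat) ** 2).mean()
        return out

    base = mse_per_modality()
    for m in model.modalities:
        abl = mse_per_modality(ablate=m)
        own_increase = abl[m] - base[m]
        other_increase = max(abl[o] - base[o] for o in model.modalities if o != m)
        assert own_increase >= other_increase  # others unchanged by construction
        assert own_increase > 0


def test_modality_mismatch_raises(fitted_study):
    model = fitted_study["model"]
    bad = pd.DataFrame(np.zeros((2, 3)), columns=["x", "y", "z"])
    with pytest.raises(ValueError, match="missing features"):
        encode(model, bad)
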