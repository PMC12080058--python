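import warnings

import pytest

from neuronorm.confound import apply_confound_model, fit_confound_model
from neuronorm import dmvae
from neuronorm.features import default_modality_specs
from neuronorm.synthetic_data import SimulationConfig, generate_cohort

warnings.filterwarnings("ignore", message="ages outside the fitted range")


@pytest.fixture(scope="session")
def feature_names():
    return [f for s in default_modality_specs() for f in s.features]


@pytest.fixture(scope="session")
def modalities():
    return {s.name: list(s.features) for s in default_modality_specs()}


@pytest.fixture(scope="session")
def fitted_study(feature_names, modalities):
    """A complete small synthetic study: site-shifted two-visit cohorts,
    per-site confound models, and a pretrained + fine-tuned normative
    model.  Shared across tests that exercise the full deviation path."""
    cfg = SimulationConfig(
        n_healthy_train=500, n_finetune=200, n_holdout=200, n_at_risk=500,
        k_shared=6, n_visits=2, seed=100,
    )
    cohort = generate_cohort(cfg)

    def rows(label, baseline_only=True):
        df = cohort[cohort["cohort_label"] == label]
        return df[df["visit"] == 0] if baseline_only else df

    cm_train = fit_confound_model(rows("healthy_train"), feature_names)
    cm_site = fit_confound_model(rows("finetune"), feature_names)
    adj_train = apply_confound_model(cm_train, rows("healthy_train"))
    adj_finetune = apply_confound_model(cm_site, rows("finetune"))
    adj_holdout = apply_confound_model(cm_site, rows("holdout", False))
    adj_at_risk = apply_confound_model(cm_site, rows("at_risk", False))

    pretrained = dmvae.train(
        adj_train, modalities,
        dmvae.Hyperparams(epochs=30, batch_size=64),
        k_shared=cfg.k_shared, seed=0,
    )
    model = dmvae.fine_tune(
        pretrained, adj_finetune,
        dmvae.Hyperparams(epochs=30, batch_size=64, learning_rate=1e-4),
    )
    return {
        "config": cfg,
        "cohort": cohort,
        "confound_site": cm_site,
        "adj_train": adj_train,
        "adj_finetune": adj_finetune,
        "adj_holdout": adj_holdout,
        "adj_at_risk": adj_at_risk,
        "pretrained": pretrained,
        "model": model,
    }
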