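"""Synthetic multi-modal cohort generator with known ground truth.

Emulates the study design the package targets: a large healthy training
cohort from one site, plus fine-tuning / holdout / at-risk cohorts from a
second site with an additive domain shift.  Features for three modality
blocks (T1 grey-matter volumes, FA and MD tract values) share latent
factor structure, carry smooth nonlinear age effects plus linear sex/ICV
effects, and at-risk subjects receive regionally focused deviations that
scale with their cognitive-severity labels (CDR, MMSE).  Two-visit data
adds progression in the at-risk arm only.

Disease-shift sign convention: grey-matter volume and FA decrease,
MD increases.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import fa_features, md_features, t1_features

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_cohort",
    "severity_from_labels",
]

COHORT_LABELS = ("healthy_train", "finetune", "holdout", "at_risk")

# CDR / MMSE sampling distribution for the at-risk arm (categorical).
_CDR_PROBS = {0.0: 0.62, 0.5: 0.35, 1.0: 0.03}
_MMSE_GIVEN_CDR = {
    0.0: {30: 0.30, 29: 0.30, 28: 0.20, 27: 0.12, 26: 0.08},
    0.5: {29: 0.10, 28: 0.20, 27: 0.25, 26: 0.20, 25: 0.15, 24: 0.10},
    1.0: {26: 0.20, 25: 0.20, 24: 0.20, 23: 0.15, 22: 0.15, 21: 0.10},
}
_APOE_PROBS = (0.48, 0.46, 0.06)

_VALID_CDR = (0.0, 0.5, 1.0, 2.0, 3.0)


def severity_from_labels(cdr, mmse):
    """Scalar disease severity in [0, 1] from CDR and MMSE labels.

    Defined as ``(2 * CDR + (30 - MMSE) / 10) / 9`` — a monotone blend of
    the two clinical stratifications, anchored at 0 for a cognitively
    normal subject (CDR = 0, MMSE = 30) and 1 at the scale maximum
    (CDR = 3, MMSE = 0).
    """
    cdr = np.asarray(cdr, dtype=float)
    mmse = np.asarray(mmse, dtype=float)
    if not np.isin(cdr, _VALID_CDR).all():
        raise ValueError("CDR values must be in {0, 0.5, 1, 2, 3}")
    if ((mmse < 0) | (mmse > 30)).any():
        raise ValueError("MMSE values must be in 0..30")
    sev = (2.0 * cdr + (30.0 - mmse) / 10.0) / 9.0
    return sev if sev.ndim else float(sev)


def _expected_at_risk_severity() -> float:
    """Exact E[severity] under the at-risk CDR/MMSE sampling distribution."""
    e = 0.0
    for cdr, pc in _CDR_PROBS.items():
        for mmse, pm in _MMSE_GIVEN_CDR[cdr].items():
            e += pc * pm * severity_from_labels(cdr, mmse)
    return e


def _default_affected_regions() -> list[str]:
    regions = []
    for h in ("Left", "Right"):
        regions += [f"{h}-Hippocampus", f"{h}-Amygdala"]
    for h in ("lh", "rh"):
        regions += [f"{h}_entorhinal", f"{h}_parahippocampal"]
    for t in ("ILF-L", "ILF-R", "UNC-L", "UNC-R", "FX/ST-L", "FX/ST-R"):
        regions += [f"{t}_FA", f"{t}_MD"]
    return regions


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Effect sizes (``effect_size``, ``progression_rate``, ``site_shift``)
    are expressed in control-standard-deviation units of each feature.
    ``effect_size`` is the *expected at-risk group mean* shift; individual
    subjects deviate proportionally to their severity scalar.
    """

    n_healthy_train: int = 1000
    n_finetune: int = 169
    n_holdout: int = 168
    n_at_risk: int = 592
    n_features: dict[str, int] = field(
        default_factory=lambda: {"T1": 82, "FA": 32, "MD": 32}
    )
    k_shared: int = 6
    k_private: int = 2
    age_range: tuple[float, float] = (50.0, 80.0)
    beta_age: float = 0.5
    beta_sex: float = 0.3
    beta_icv: float = 0.5
    noise_sd: float = 0.5
    affected_regions: list[str] = field(default_factory=_default_affected_regions)
    effect_size: float = 2.0
    progression_rate: float = 0.5
    site_shift: float = 0.3
    n_visits: int = 1
    seed: int = 0

    def feature_names(self) -> dict[str, list[str]]:
        pools = {"T1": t1_features(), "FA": fa_features(), "MD": md_features()}
        out = {}
        for mod, n in self.n_features.items():
            if mod not in pools:
                raise ValueError(f"unknown modality {mod!r}")
            if n > len(pools[mod]):
                raise ValueError(f"at most {len(pools[mod])} {mod} features available")
            out[mod] = pools[mod][:n]
        return out

    def validate(self) -> None:
        for name in ("n_healthy_train", "n_finetune", "n_holdout", "n_at_risk"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_visits < 1:
            raise ValueError("n_visits must be >= 1")
        declared = [f for feats in self.feature_names().values() for f in feats]
        missing = set(self.affected_regions) - set(declared)
        if missing:
            raise ValueError(f"affected_regions not in feature list: {sorted(missing)}")


@dataclass
class GroundTruth:
    """Generative quantities stored for validation of downstream stages."""

    shared_factors: np.ndarray          # rows aligned with the table
    private_factors: dict[str, np.ndarray]
    loadings: dict[str, np.ndarray]     # modality -> (d_m, k_shared)
    age_amplitude: np.ndarray           # per feature, signed
    age_curve: "np.ufunc | object"      # centred g(age), callable
    sex_coef: np.ndarray
    icv_coef: np.ndarray
    feature_sd: np.ndarray              # theoretical marginal sd per feature
    site_offset: np.ndarray
    severity: np.ndarray                # per row


def _age_curve_factory(age_range):
    lo, hi = age_range
    mid = 0.5 * (lo + hi)

    def g_raw(a):
        a = np.asarray(a, dtype=float)
        return (a - mid) / 15.0 + 1.0 / (1.0 + np.exp(-(a - 60.0) / 3.0))

    grid = np.linspace(lo, hi, 2001)
    offset = g_raw(grid).mean()
    var = g_raw(grid).var()

    def g(a):
        return g_raw(a) - offset

    return g, var


def generate_cohort(
    config: SimulationConfig, return_truth: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, GroundTruth]:
    """Generate a subject-by-visit cohort table with multi-modal features.

    Returns a DataFrame with one row per subject-visit: identifiers,
    covariates (age, sex, ICV), cohort label, clinical labels
    (CDR, MMSE, ApoE e4 count), CSF biomarkers, and one column per
    declared feature.  With ``return_truth=True`` also returns the
    generative ground truth for validation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    feats = config.feature_names()
    mods = list(feats)
    names = [f for m in mods for f in feats[m]]
    d = len(names)
    ks, kp = config.k_shared, config.k_private

    # fixed generative structure (deterministic given seed)
    loadings = {m: rng.normal(size=(len(feats[m]), ks)) * np.sqrt(0.5 / ks) for m in mods}
    private = {m: rng.normal(size=(len(feats[m]), kp)) * np.sqrt(0.2 / max(kp, 1)) for m in mods}
    g, var_g = _age_curve_factory(config.age_range)
    direction = np.array([1.0 if n.endswith("_MD") else -1.0 for n in names])
    age_amp = config.beta_age * rng.uniform(0.5, 1.5, size=d) * direction
    sex_coef = config.beta_sex * rng.normal(size=d)
    is_t1 = np.array([m == "T1" for m in mods for _ in feats[m]])
    icv_coef = config.beta_icv * rng.uniform(0.5, 1.5, size=d) * is_t1
    site_offset = rng.normal(size=d) * config.site_shift

    L_all = np.vstack([loadings[m] for m in mods])
    P_sq = np.concatenate([np.square(private[m]).sum(axis=1) for m in mods])
    feature_sd = np.sqrt(
        np.square(L_all).sum(axis=1)
        + P_sq
        + config.noise_sd**2
        + np.square(age_amp) * var_g
        + np.square(sex_coef) * 0.25
        + np.square(icv_coef)
    )

    affected = np.isin(names, config.affected_regions)
    e_sev = _expected_at_risk_severity()

    sizes = {
        "healthy_train": config.n_healthy_train,
        "finetune": config.n_finetune,
        "holdout": config.n_holdout,
        "at_risk": config.n_at_risk,
    }

    rows = []
    feat_blocks = []
    truth_u, truth_v, truth_sev = [], {m: [] for m in mods}, []
    sid = 0
    for label, n in sizes.items():
        if n == 0:
            continue
        age0 = rng.uniform(*config.age_range, size=n)
        sex = rng.integers(0, 2, size=n).astype(float)
        icv = rng.normal(1.50, 0.15, size=n)
        u = rng.normal(size=(n, ks))
        v = {m: rng.normal(size=(n, kp)) for m in mods}

        if label == "at_risk":
            cdr_levels = np.array(list(_CDR_PROBS))
            cdr = rng.choice(cdr_levels, size=n, p=list(_CDR_PROBS.values()))
            mmse = np.empty(n, dtype=int)
            for lvl in cdr_levels:
                mask = cdr == lvl
                tbl = _MMSE_GIVEN_CDR[lvl]
                mmse[mask] = rng.choice(
                    list(tbl), size=int(mask.sum()), p=list(tbl.values())
                )
            apoe = rng.choice([0, 1, 2], size=n, p=_APOE_PROBS)
        else:
            cdr = np.zeros(n)
            mmse = rng.integers(29, 31, size=n)
            apoe = np.zeros(n, dtype=int)
        sev = np.asarray(severity_from_labels(cdr, mmse))

        ptau = 16.7 + 50.0 * sev + rng.normal(0, 5.0, size=n)
        ttau = 198.0 + 470.0 * sev + rng.normal(0, 60.0, size=n)
        abeta = np.clip(1555.0 - 3500.0 * sev + rng.normal(0, 500.0, size=n), 50.0, None)
        ptau = np.clip(ptau, 1.0, None)
        ttau = np.clip(ttau, 10.0, None)

        base = (
            u @ L_all.T
            + np.hstack([v[m] @ private[m].T for m in mods])
            + sex[:, None] * sex_coef[None, :]
            + ((icv - 1.50) / 0.15)[:, None] * icv_coef[None, :]
        )
        if label != "healthy_train":
            base = base + site_offset[None, :]
        if label == "at_risk":
            w = sev / e_sev
            base = base + (
                w[:, None] * (config.effect_size * direction * feature_sd * affected)[None, :]
            )

        for visit in range(config.n_visits):
            age = age0 + visit * 1.0
            x = (
                base
                + g(age)[:, None] * age_amp[None, :]
                + rng.normal(0, config.noise_sd, size=(n, d))
            )
            if label == "at_risk" and visit > 0:
                # progression scales with subject severity: decliners decline
                x = x + visit * w[:, None] * (
                    config.progression_rate * direction * feature_sd * affected
                )[None, :]
            tab = pd.DataFrame(
                {
                    "subject_id": [f"S{sid + i:05d}" for i in range(n)],
                    "visit": visit,
                    "age": age,
                    "sex": sex,
                    "icv": icv,
                    "cohort_label": label,
                    "cdr": cdr,
                    "mmse": mmse,
                    "apoe_e4_count": apoe,
                    "csf_ptau": ptau,
                    "csf_ttau": ttau,
                    "csf_abeta42": abeta,
                }
            )
            rows.append(tab)
            feat_blocks.append(x)
            truth_u.append(u)
            for m in mods:
                truth_v[m].append(v[m])
            truth_sev.append(sev)
        sid += n

    table = pd.concat(rows, ignore_index=True)
    X = np.vstack(feat_blocks)
    table = pd.concat([table, pd.DataFrame(X, columns=names)], axis=1)
    table = table.sort_values(["subject_id", "visit"], kind="stable").reset_index(drop=True)

    if not return_truth:
        return table

    # rows were re-sorted; align truth arrays with the sorted table
    pre_sort = pd.concat(rows, ignore_index=True)
    sort_idx = pre_sort.sort_values(["subject_id", "visit"], kind="stable").index.values
    truth = GroundTruth(
        shared_factors=np.vstack(truth_u)[sort_idx],
        private_factors={m: np.vstack(truth_v[m])[sort_idx] for m in mods},
        loadings=loadings,
        age_amplitude=age_amp,
        age_curve=g,
        sex_coef=sex_coef,
        icv_coef=icv_coef,
        feature_sd=feature_sd,
        site_offset=site_offset,
        severity=np.concatenate(truth_sev)[sort_idx],
    )
    return table, truth


def config_to_yaml(config: SimulationConfig, path) -> None:
    import yaml

    data = dataclasses.asdict(config)
    data["age_range"] = list(config.age_range)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def config_from_yaml(path) -> SimulationConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if "age_range" in data:
        data["age_range"] = tuple(data["age_range"])
    return SimulationConfig(**data)
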