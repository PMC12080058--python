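"""End-to-end orchestration of the three-stage normative workflow.

Stages: (optional) simulate -> per-site confound fit/apply -> pretrain on
healthy controls -> fine-tune on target-site controls -> holdout
reference -> deviation scores -> outlier / network / statistical
reports.  Every run writes a manifest with the config hash, seed, stage
durations and produced files; reruns with an identical config and seed
reproduce all deterministic outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import confound, deviation, dmvae, outliers, stats, synthetic_data
from .features import NetworkParcellation, default_modality_specs

log = logging.getLogger("neuronorm")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    output_dir: str = "neuronorm_run"
    cohort_table: str | None = None       # CSV path; None -> simulate
    parcellation: str | None = None       # TSV path; None -> built-in default
    simulation: dict = field(default_factory=dict)   # SimulationConfig overrides
    basis_dim: int = 10
    k_shared: int = 10
    k_private: int = 2
    hidden: int = 64
    epochs: int = 200
    finetune_epochs: int = 100
    batch_size: int = 256
    learning_rate: float = 1e-3
    finetune_learning_rate: float = 1e-4
    kl_beta: float = 1.0
    outlier_z: float = 1.96
    alpha: float = 0.05
    n_perm: int = 10_000
    visit: str = "baseline"               # "baseline" or "latest" for D_ml analyses
    seed: int = 0

    def validate(self) -> None:
        if self.outlier_z <= 0 or self.alpha <= 0 or self.n_perm <= 0:
            raise ValueError("thresholds must be positive")
        if self.visit not in ("baseline", "latest"):
            raise ValueError("visit must be 'baseline' or 'latest'")
        for path in (self.cohort_table, self.parcellation):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _select_visit(df: pd.DataFrame, which: str) -> pd.DataFrame:
    agg = "min" if which == "baseline" else "max"
    pick = df.groupby("subject_id")["visit"].transform(agg)
    return df[df["visit"] == pick]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow; returns the artifact directory."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
        "outputs": [],
        "inputs": {},
    }

    def _write(df: pd.DataFrame, name: str, index=False) -> None:
        path = out / name
        df.to_csv(path, index=index)
        manifest["outputs"].append(name)

    def _stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, *exc):
                manifest["stages"][name] = round(time.perf_counter() - self.t0, 3)
                log.info("stage %s: done (%.2fs)", name, manifest["stages"][name])

        return _Timer()

    try:
        # --- inputs --------------------------------------------------
        with _stage("load"):
            if config.cohort_table is None:
                sim = synthetic_data.SimulationConfig(
                    **{"seed": config.seed, **config.simulation}
                )
                cohort = synthetic_data.generate_cohort(sim)
                _write(cohort, "cohort.csv")
            else:
                cohort = pd.read_csv(config.cohort_table)
                manifest["inputs"]["cohort_table"] = _file_hash(config.cohort_table)
            if config.parcellation is None:
                parc = NetworkParcellation.default()
            else:
                parc = NetworkParcellation.from_file(config.parcellation)
                manifest["inputs"]["parcellation"] = _file_hash(config.parcellation)

        specs = default_modality_specs()
        modalities = {
            s.name: [f for f in s.features if f in cohort.columns] for s in specs
        }
        all_feats = [f for feats in modalities.values() for f in feats]

        def rows(label, baseline_only=True):
            df = cohort[cohort["cohort_label"] == label]
            return df[df["visit"] == 0] if baseline_only else df

        # --- confound adjustment, one model per site ------------------
        with _stage("adjust"):
            cm_train = confound.fit_confound_model(
                rows("healthy_train"), all_feats,
                basis_dim=config.basis_dim, fit_cohort_id="healthy_train",
            )
            cm_site = confound.fit_confound_model(
                rows("finetune"), all_feats,
                basis_dim=config.basis_dim, fit_cohort_id="finetune",
            )
            cm_train.save(out / "confound_train_site.json")
            cm_site.save(out / "confound_target_site.json")
            manifest["outputs"] += [
                "confound_train_site.json", "confound_target_site.json",
            ]
            adj_train = confound.apply_confound_model(cm_train, rows("healthy_train"))
            adj_ft = confound.apply_confound_model(cm_site, rows("finetune"))
            adj_holdout = confound.apply_confound_model(
                cm_site, rows("holdout", baseline_only=False)
            )
            adj_risk = confound.apply_confound_model(
                cm_site, rows("at_risk", baseline_only=False)
            )

        # --- model ----------------------------------------------------
        with _stage("train"):
            model = dmvae.train(
                adj_train, modalities,
                dmvae.Hyperparams(config.epochs, config.batch_size,
                                  config.learning_rate, config.kl_beta),
                k_shared=config.k_shared, k_private=config.k_private,
                hidden=config.hidden, seed=config.seed,
            )
        with _stage("finetune"):
            model = dmvae.fine_tune(
                model, adj_ft,
                dmvae.Hyperparams(config.finetune_epochs, config.batch_size,
                                  config.finetune_learning_rate, config.kl_beta),
            )
            model.save(out / "model.npz")
            manifest["outputs"].append("model.npz")

        # --- deviations -----------------------------------------------
        with _stage("deviate"):
            ref = deviation.fit_holdout_reference(
                model, adj_holdout[adj_holdout["visit"] == 0], holdout_id="holdout"
            )
            dev_holdout = deviation.deviation_table(model, ref, adj_holdout)
            dev_risk = deviation.deviation_table(model, ref, adj_risk)
            dev_holdout.insert(2, "cohort_label", "holdout")
            dev_risk.insert(2, "cohort_label", "at_risk")
            dev = pd.concat([dev_holdout, dev_risk], ignore_index=True)
            _write(dev, "deviations.csv")

        # --- outlier maps and network tests ---------------------------
        with _stage("outliers"):
            meta_cols = ["subject_id", "visit", "cohort_label"]
            hold_sel = _select_visit(dev_holdout, config.visit)
            risk_sel = _select_visit(dev_risk, config.visit)
            risk_meta = _select_visit(
                cohort[cohort["cohort_label"] == "at_risk"], config.visit
            )
            flags_hold = outliers.flag_outliers(
                hold_sel.drop(columns=meta_cols + ["d_ml"]), specs
            )
            flags_risk = outliers.flag_outliers(
                risk_sel.drop(columns=meta_cols + ["d_ml"]), specs
            )
            maps = [outliers.outlier_proportions(flags_hold, "holdout")]
            strata = {"cdr=0": risk_meta["cdr"] == 0,
                      "cdr=0.5": risk_meta["cdr"] == 0.5,
                      "mmse=30": risk_meta["mmse"] == 30,
                      "mmse=28-29": risk_meta["mmse"].between(28, 29),
                      "mmse=26-27": risk_meta["mmse"].between(26, 27),
                      "mmse=21-25": risk_meta["mmse"].between(21, 25)}
            net_rows = []
            for name, mask in strata.items():
                sub = flags_risk[mask.to_numpy()]
                if len(sub) == 0:
                    continue
                maps.append(outliers.outlier_proportions(sub, name))
                p_net = outliers.permutation_test(
                    sub, flags_hold, parc, n_perm=config.n_perm, seed=config.seed
                )
                net_rows.append(pd.DataFrame({
                    "stratum": name, "network": p_net.index,
                    "rate": outliers.network_outlier_rate(sub, parc).reindex(p_net.index),
                    "p": p_net.values,
                    "p_fdr": outliers.fdr_correct(p_net).values,
                }))
            _write(
                pd.DataFrame({m.stratum: m.proportions for m in maps}).T
                .rename_axis("stratum"), "outlier_maps.csv", index=True,
            )
            if net_rows:
                _write(pd.concat(net_rows, ignore_index=True), "network_tests.csv")

        # --- downstream statistics ------------------------------------
        with _stage("stats"):
            rows_out = []
            # Welch t on d_ml across CDR strata vs holdout
            groups = {"holdout": hold_sel["d_ml"].to_numpy()}
            for name, mask in strata.items():
                vals = risk_sel["d_ml"].to_numpy()[mask.to_numpy()]
                if len(vals) >= 2:
                    groups[name] = vals
            names = list(groups)
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    res = stats.welch_t(groups[a], groups[b])
                    rows_out.append(("welch_dml", f"{a} vs {b}",
                                     res.t, res.t, res.p, sum(res.n)))
            # biomarker correlations with d_ml (age-adjusted, controls = holdout)
            risk_tab = stats.add_ptau_abeta_ratio(risk_meta.copy())
            hold_tab = stats.add_ptau_abeta_ratio(
                _select_visit(cohort[cohort["cohort_label"] == "holdout"], config.visit)
            )
            risk_adj = stats.age_adjust(
                risk_tab, hold_tab,
                columns=[c for c in stats.BIOMARKER_COLUMNS if c in risk_tab],
            )
            dml_by_subj = risk_sel.set_index("subject_id")["d_ml"]
            for col in stats.BIOMARKER_COLUMNS + ["cdr", "mmse"]:
                if col not in risk_adj.columns:
                    continue
                y = risk_adj.set_index("subject_id")[col].reindex(dml_by_subj.index)
                res = stats.correlate(dml_by_subj.to_numpy(), y.to_numpy())
                rows_out.append(("pearson_dml", col, res.r, res.r, res.p, res.n))
            # Cohen's d per region for ApoE strata at baseline
            risk_base = _select_visit(dev_risk, "baseline").set_index("subject_id")
            apoe = risk_meta.set_index("subject_id")["apoe_e4_count"].reindex(
                risk_base.index
            )
            hold_duf = hold_sel
            d_rows = {}
            for n_e4 in (0, 1, 2):
                sub = risk_base[apoe.to_numpy() == n_e4]
                if len(sub) < 2:
                    continue
                d_rows[f"apoe_e4={n_e4}"] = {
                    f: stats.cohens_d(sub[f], hold_duf[f]) for f in all_feats
                }
            if d_rows:
                _write(pd.DataFrame(d_rows).T.rename_axis("stratum"),
                       "cohens_d_apoe.csv", index=True)
            # paired baseline vs followup d_ml per cohort
            for label, devtab in (("holdout", dev_holdout), ("at_risk", dev_risk)):
                wide = devtab.pivot_table(index="subject_id", columns="visit",
                                          values="d_ml")
                if wide.shape[1] >= 2:
                    v0, v1 = sorted(wide.columns)[:2]
                    pair = wide[[v0, v1]].dropna()
                    if len(pair) >= 2:
                        res = stats.paired_t(pair[v0], pair[v1])
                        rows_out.append(("paired_dml", label,
                                         res.t, res.t, res.p, res.n[0]))
            _write(pd.DataFrame(
                rows_out,
                columns=["analysis", "variable", "estimate", "statistic", "p", "n"],
            ), "stats.csv")

    except Exception:
        manifest["status"] = "failed"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    manifest["status"] = "ok"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]
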