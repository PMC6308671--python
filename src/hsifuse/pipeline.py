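"""End-to-end orchestration: simulate -> train -> select -> fuse -> evaluate.

Every run is driven by a :class:`RunConfig` (flat key-value file or
keyword arguments), is fully seeded, and writes its artifacts plus a
manifest to an output directory.  Identical configs produce byte-identical
outputs.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import asdict, dataclass, fields

import numpy as np
import pandas as pd

from . import __version__
from .chemometrics import (PlsdaClassifier, RbfClassifier, crossval_perf)
from .datatypes import LABEL_NAMES, SpectrumTable
from .evaluation import agreement_partition, roc_auc, score
from .featsel import format_wavelengths, select_features
from .fusion import (bayes_fuse, decision_profiles, fuse_data_level,
                     fuse_feature_separate, fuzzy_template_fit,
                     fuzzy_template_predict, weighted_majority_vote,
                     wmv_weights)
from .synth import SyntheticConfig, generate_mean_spectra

FUSION_LEVELS = ("data", "feature-separate", "feature-joint", "decision")
DECISION_RULES = ("wmv", "bayes", "fuzzy")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "run"
    # synthetic data
    n_healthy: int = 120
    n_bruised: int = 120
    n_test_healthy: int = 80
    n_test_bruised: int = 96
    effect_size: float = 0.065
    noise_sd_pb: float = 0.005
    noise_sd_lctf: float = 0.004
    scatter_sd: float = 0.02
    complementarity: float = 0.5
    calyx_fraction: float = 0.25
    # the prediction session has drifted clutter, as acquisition sessions do
    test_nuisance_scale: float = 1.8
    test_session: int = 1
    # optional external inputs (CSV paths); override simulation when set
    table_pb: str = ""
    table_lctf: str = ""
    test_table_pb: str = ""
    test_table_lctf: str = ""
    # modeling
    classifier: str = "plsda"  # plsda | rbf
    folds: int = 10
    max_lv: int = 15
    # feature selection
    frog_iters: int = 300
    max_features: int = 80
    # fusion
    level: str = "decision"
    decision_rule: str = "all"  # wmv | bayes | fuzzy | all
    decision_on: str = "features"  # features | full

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.level not in FUSION_LEVELS:
            raise ValueError(f"level must be one of {FUSION_LEVELS}")
        if self.decision_rule not in DECISION_RULES + ("all",):
            raise ValueError(f"unknown decision rule {self.decision_rule!r}")
        if self.classifier not in ("plsda", "rbf"):
            raise ValueError("classifier must be 'plsda' or 'rbf'")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Flat ``key = value`` config file; '#' starts a comment."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key = value")
                key, val = (s.strip() for s in line.split("=", 1))
                if key not in known:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                default = getattr(cls, key, None)
                for f in fields(cls):
                    if f.name == key:
                        default = f.default
                if isinstance(default, bool):
                    kwargs[key] = val.lower() in ("1", "true", "yes")
                elif isinstance(default, int):
                    kwargs[key] = int(val)
                elif isinstance(default, float):
                    kwargs[key] = float(val)
                else:
                    kwargs[key] = val
        return cls(**kwargs)


def _make_classifier(cfg: RunConfig, seed: int):
    if cfg.classifier == "rbf":
        # compact grid keeps the demo fast; widen via chemometrics.RbfClassifier
        return RbfClassifier(c_grid=(1.0, 10.0, 100.0),
                             g_grid=(0.001, 0.01, 0.1),
                             folds=cfg.folds, seed=seed)
    return PlsdaClassifier(max_lv=cfg.max_lv, folds=cfg.folds, seed=seed)


def _simulate(cfg: RunConfig):
    base = dict(
        effect_size=cfg.effect_size, noise_sd_pb=cfg.noise_sd_pb,
        noise_sd_lctf=cfg.noise_sd_lctf, scatter_sd=cfg.scatter_sd,
        complementarity=cfg.complementarity,
        calyx_fraction=cfg.calyx_fraction,
    )
    train_cfg = SyntheticConfig(n_healthy=cfg.n_healthy,
                                n_bruised=cfg.n_bruised,
                                seed=cfg.seed, **base)
    test_cfg = SyntheticConfig(n_healthy=cfg.n_test_healthy,
                               n_bruised=cfg.n_test_bruised,
                               seed=cfg.seed + 100_003,
                               nuisance_scale=cfg.test_nuisance_scale,
                               session=cfg.test_session, **base)
    trA, trB, tr_truth = generate_mean_spectra(train_cfg)
    teA, teB, te_truth = generate_mean_spectra(test_cfg)
    # distinct id spaces for train and test
    for tab, truth in ((teA, te_truth), (teB, te_truth)):
        tab.sample_ids = ["T" + s for s in tab.sample_ids]
    for t in te_truth:
        t.sample_id = "T" + t.sample_id
    return trA, trB, teA, teB, tr_truth, te_truth


def _load_tables(cfg: RunConfig):
    trA = SpectrumTable.from_csv(cfg.table_pb)
    trB = SpectrumTable.from_csv(cfg.table_lctf)
    teA = SpectrumTable.from_csv(cfg.test_table_pb)
    teB = SpectrumTable.from_csv(cfg.test_table_lctf)
    for name, tab in (("table_pb", trA), ("table_lctf", trB),
                      ("test_table_pb", teA), ("test_table_lctf", teB)):
        if tab.labels is None:
            raise ValueError(f"stage simulate/load: {name} is missing labels")
    return trA, trB, teA, teB


def _report(pred_labels, score_b, truth) -> dict:
    rep = score(pred_labels, truth).to_dict()
    _, auc = roc_auc(score_b, truth)
    rep["auc"] = auc
    return rep


def _fusion_rows(result, truth):
    return pd.DataFrame({
        "sample_id": result.sample_ids,
        "score_h": result.score_h,
        "score_b": result.score_b,
        "label_A": [LABEL_NAMES[l] for l in result.labels_a],
        "label_B": [LABEL_NAMES[l] for l in result.labels_b],
        "label_fused": [LABEL_NAMES[l] for l in result.labels],
        "agreed": result.agreed,
        "truth": [LABEL_NAMES[l] for l in truth],
    })


def run_pipeline(cfg: RunConfig, log=print) -> dict:
    """Execute the configured pipeline; returns the metrics dictionary."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    stage = "simulate"
    try:
        if cfg.table_pb:
            trA, trB, teA, teB = _load_tables(cfg)
        else:
            trA, trB, teA, teB, _, _ = _simulate(cfg)
        trA.to_csv(os.path.join(cfg.out_dir, "train_pb.csv"))
        trB.to_csv(os.path.join(cfg.out_dir, "train_lctf.csv"))
        teA.to_csv(os.path.join(cfg.out_dir, "test_pb.csv"))
        teB.to_csv(os.path.join(cfg.out_dir, "test_lctf.csv"))
        truth = teA.labels

        cfg_doc = asdict(cfg)
        cfg_doc.pop("out_dir")  # keep outputs byte-identical across run dirs
        metrics: dict = {"config": cfg_doc, "version": __version__}

        stage = "train"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clfA = _make_classifier(cfg, cfg.seed).fit(trA)
            clfB = _make_classifier(cfg, cfg.seed + 1).fit(trB)
            perfA = crossval_perf(_make_classifier(cfg, cfg.seed), trA,
                                  folds=cfg.folds, seed=cfg.seed)
            perfB = crossval_perf(_make_classifier(cfg, cfg.seed + 1), trB,
                                  folds=cfg.folds, seed=cfg.seed)
            probA = clfA.predict_proba(teA)
            probB = clfB.predict_proba(teB)
        metrics["single_pb"] = _report(probA.labels, probA.p_bruised, truth)
        metrics["single_lctf"] = _report(probB.labels, probB.p_bruised, truth)
        metrics["cv_pb"] = {"sensitivity": perfA.sensitivity,
                            "specificity": perfA.specificity}
        metrics["cv_lctf"] = {"sensitivity": perfB.sensitivity,
                              "specificity": perfB.specificity}

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if cfg.level == "data":
                _run_data_level(cfg, trA, trB, teA, teB, truth, metrics)
            elif cfg.level in ("feature-separate", "feature-joint"):
                _run_feature_level(cfg, trA, trB, teA, teB, truth, metrics, log)
            else:
                _run_decision_level(cfg, trA, trB, teA, teB, truth,
                                    metrics, log)

        stage = "evaluate"
        payload = json.dumps(metrics, indent=2, sort_keys=True)
        with open(os.path.join(cfg.out_dir, "metrics.json"), "w") as fh:
            fh.write(payload)
        manifest = {
            "tool": "hsifuse",
            "version": __version__,
            "seed": cfg.seed,
            "config": cfg_doc,
            "artifacts": sorted(os.listdir(cfg.out_dir)),
        }
        with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
            fh.write(json.dumps(manifest, indent=2, sort_keys=True))
        return metrics
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc


def _run_data_level(cfg, trA, trB, teA, teB, truth, metrics):
    from .chemometrics import fit_scaler

    scalers = (fit_scaler(trA), fit_scaler(trB))
    fused_tr = fuse_data_level(trA, trB, scalers=scalers)
    fused_te = fuse_data_level(teA, teB, scalers=scalers)
    clf = _make_classifier(cfg, cfg.seed + 2).fit(fused_tr)
    prob = clf.predict_proba(fused_te)
    metrics["data_level"] = _report(prob.labels, prob.p_bruised, truth)
    return fused_tr, fused_te, prob


def _select_per_instrument(cfg, trA, trB):
    selA = select_features(trA, n_iter=cfg.frog_iters, max_n=cfg.max_features,
                           folds=cfg.folds, seed=cfg.seed)
    selB = select_features(trB, n_iter=cfg.frog_iters, max_n=cfg.max_features,
                           folds=cfg.folds, seed=cfg.seed + 1)
    return selA, selB


def _write_selection(cfg, name, sel):
    pd.DataFrame({
        "wavelength": sel.wavelengths,
        "probability": sel.probabilities,
        "rank": np.argsort(np.argsort(-sel.probabilities, kind="stable")) + 1,
        "selected": [i in set(sel.subset) for i in range(len(sel.columns))],
    }).to_csv(os.path.join(cfg.out_dir, f"selection_{name}.csv"), index=False)
    pd.DataFrame({
        "n_features": np.arange(1, len(sel.cv_error_curve) + 1),
        "cv_error": sel.cv_error_curve,
    }).to_csv(os.path.join(cfg.out_dir, f"cv_curve_{name}.csv"), index=False)


def _run_feature_level(cfg, trA, trB, teA, teB, truth, metrics, log):
    from .fusion import fuse_feature_joint

    if cfg.level == "feature-separate":
        selA, selB = _select_per_instrument(cfg, trA, trB)
        _write_selection(cfg, "pb", selA)
        _write_selection(cfg, "lctf", selB)
        log("PB " + format_wavelengths(selA))
        log("LCTF " + format_wavelengths(selB))
        fused_tr = fuse_feature_separate(selA, selB, trA, trB)
        fused_te = fuse_feature_separate(selA, selB, teA, teB)
        key = "feature_separate"
    else:
        from .chemometrics import fit_scaler

        scalers = (fit_scaler(trA), fit_scaler(trB))
        joint_tr = fuse_data_level(trA, trB, scalers=scalers)
        joint_te = fuse_data_level(teA, teB, scalers=scalers)
        fused_tr, sel = fuse_feature_joint(joint_tr, n_iter=cfg.frog_iters,
                                           max_n=cfg.max_features,
                                           folds=cfg.folds, seed=cfg.seed + 2)
        _write_selection(cfg, "joint", sel)
        log("joint " + format_wavelengths(sel))
        fused_te = joint_te.select_columns(sel.subset)
        key = "feature_joint"
    clf = _make_classifier(cfg, cfg.seed + 3).fit(fused_tr)
    prob = clf.predict_proba(fused_te)
    metrics[key] = _report(prob.labels, prob.p_bruised, truth)


def _run_decision_level(cfg, trA, trB, teA, teB, truth, metrics, log):
    if cfg.decision_on == "features":
        selA, selB = _select_per_instrument(cfg, trA, trB)
        _write_selection(cfg, "pb", selA)
        _write_selection(cfg, "lctf", selB)
        log("PB " + format_wavelengths(selA))
        log("LCTF " + format_wavelengths(selB))
        trA = trA.select_columns(selA.subset)
        trB = trB.select_columns(selB.subset)
        teA = teA.select_columns(selA.subset)
        teB = teB.select_columns(selB.subset)
    clfA = _make_classifier(cfg, cfg.seed + 4).fit(trA)
    clfB = _make_classifier(cfg, cfg.seed + 5).fit(trB)
    perfA = crossval_perf(_make_classifier(cfg, cfg.seed + 4), trA,
                          folds=cfg.folds, seed=cfg.seed)
    perfB = crossval_perf(_make_classifier(cfg, cfg.seed + 5), trB,
                          folds=cfg.folds, seed=cfg.seed)
    probA = clfA.predict_proba(teA)
    probB = clfB.predict_proba(teB)
    tr_probA = clfA.predict_proba(trA)
    tr_probB = clfB.predict_proba(trB)

    rules = (DECISION_RULES if cfg.decision_rule == "all"
             else (cfg.decision_rule,))
    for rule in rules:
        if rule == "wmv":
            result = weighted_majority_vote(wmv_weights(perfA, perfB),
                                            probA, probB)
        elif rule == "bayes":
            result = bayes_fuse(perfA, perfB, probA, probB)
        else:
            templates = fuzzy_template_fit(
                decision_profiles(tr_probA, tr_probB), trA.labels)
            result = fuzzy_template_predict(templates, probA, probB)
        rep = _report(result.labels, result.score_b, truth)
        rep["agreement"] = agreement_partition(
            result.labels_a, result.labels_b, result.labels, truth).to_dict()
        metrics[f"decision_{rule}"] = rep
        _fusion_rows(result, truth).to_csv(
            os.path.join(cfg.out_dir, f"fusion_{rule}.csv"), index=False)
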