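"""Reproducible benchmark experiments on the synthetic generator.

These drive the acceptance checks: per-seed accuracy of every fusion route
(single instruments, data level, feature level separate/joint, and the
three decision rules on feature-selected classifiers), plus the
informative-band recovery experiment for the wavelength selector.
"""

from __future__ import annotations

import warnings

import numpy as np

from .chemometrics import PlsdaClassifier, crossval_perf, fit_scaler
from .evaluation import score
from .featsel import choose_n_features, random_frog, select_features
from .fusion import (bayes_fuse, decision_profiles, fuse_data_level,
                     fuse_feature_joint, fuse_feature_separate,
                     fuzzy_template_fit, fuzzy_template_predict,
                     weighted_majority_vote, wmv_weights)
from .synth import SyntheticConfig, generate_mean_spectra, sparse_band_table

TEST_SEED_OFFSET = 100_003


def fusion_comparison(seed: int, n_test: tuple[int, int] = (200, 240),
                      frog_iters_single: int = 450,
                      frog_iters_joint: int = 900,
                      max_n: int = 40) -> dict:
    """Accuracy of every fusion route for one seeded draw.

    Training set is the default synthetic config; the test set is a second
    acquisition session with drifted clutter, as the pipeline default uses.
    """
    tr_cfg = SyntheticConfig(seed=seed)
    te_cfg = SyntheticConfig(seed=seed + TEST_SEED_OFFSET,
                             n_healthy=n_test[0], n_bruised=n_test[1],
                             nuisance_scale=1.8, session=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        A, B, _ = generate_mean_spectra(tr_cfg)
        A2, B2, _ = generate_mean_spectra(te_cfg)
        out: dict = {}

        clfA = PlsdaClassifier(seed=0).fit(A)
        clfB = PlsdaClassifier(seed=1).fit(B)
        out["single_pb"] = score(clfA.predict_proba(A2).labels,
                                 A2.labels).accuracy
        out["single_lctf"] = score(clfB.predict_proba(B2).labels,
                                   B2.labels).accuracy

        scalers = (fit_scaler(A), fit_scaler(B))
        dtr = fuse_data_level(A, B, scalers=scalers)
        dte = fuse_data_level(A2, B2, scalers=scalers)
        out["data"] = score(
            PlsdaClassifier(seed=2).fit(dtr).predict_proba(dte).labels,
            A2.labels).accuracy

        jtr, sel_joint = fuse_feature_joint(dtr, n_iter=frog_iters_joint,
                                            max_n=max_n, seed=seed + 2)
        jte = dte.select_columns(sel_joint.subset)
        out["feature_joint"] = score(
            PlsdaClassifier(seed=4).fit(jtr).predict_proba(jte).labels,
            A2.labels).accuracy

        selA = select_features(A, n_iter=frog_iters_single, max_n=max_n,
                               seed=seed)
        selB = select_features(B, n_iter=frog_iters_single, max_n=max_n,
                               seed=seed + 1)
        ftr = fuse_feature_separate(selA, selB, A, B)
        fte = fuse_feature_separate(selA, selB, A2, B2)
        out["feature_separate"] = score(
            PlsdaClassifier(seed=3).fit(ftr).predict_proba(fte).labels,
            A2.labels).accuracy

        sA = A.select_columns(selA.subset)
        sB = B.select_columns(selB.subset)
        sA2 = A2.select_columns(selA.subset)
        sB2 = B2.select_columns(selB.subset)
        cA = PlsdaClassifier(seed=5).fit(sA)
        cB = PlsdaClassifier(seed=6).fit(sB)
        qA = cA.predict_proba(sA2)
        qB = cB.predict_proba(sB2)
        perfA = crossval_perf(PlsdaClassifier(seed=5), sA, seed=seed)
        perfB = crossval_perf(PlsdaClassifier(seed=6), sB, seed=seed)

        out["decision_wmv"] = score(
            weighted_majority_vote(wmv_weights(perfA, perfB), qA, qB).labels,
            A2.labels).accuracy
        out["decision_bayes"] = score(
            bayes_fuse(perfA, perfB, qA, qB).labels, A2.labels).accuracy
        templates = fuzzy_template_fit(
            decision_profiles(cA.predict_proba(sA), cB.predict_proba(sB)),
            sA.labels)
        out["decision_fuzzy"] = score(
            fuzzy_template_predict(templates, qA, qB).labels,
            A2.labels).accuracy
    return out


def recovery_trial(grid, seed: int, n_informative: int = 5,
                   effect: float = 0.08, noise_sd: float = 0.03,
                   nuisance_sd: float = 0.15, n_iter: int = 300,
                   max_n: int = 20) -> tuple[float, int]:
    """Informative-band recovery on one instrument grid.

    Returns (fraction of informative bands in the top-ranked set, chosen
    subset size).  n = 240 samples as in the calibration cohort.
    """
    grid = np.asarray(grid, float)
    p = len(grid)
    informative = set(np.linspace(5, p - 6, n_informative).astype(int))
    tab = sparse_band_table(120, 120, grid, sorted(informative),
                            effect=effect, noise_sd=noise_sd, seed=seed,
                            nuisance_sd=nuisance_sd)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        probs = random_frog(tab, n_iter=n_iter, seed=seed)
        top = set(np.argsort(-probs)[:n_informative])
        sel = choose_n_features(probs, tab, max_n=max_n, seed=seed)
    return len(top & informative) / n_informative, sel.n_selected
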