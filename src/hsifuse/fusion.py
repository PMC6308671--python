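"""Fusion of the two instruments at data, feature, and decision level.

Data level: each instrument's table is autoscaled on the training rows and
the columns are concatenated (instrument-namespaced).  Feature level: either
the per-instrument random-frog selections are combined, or selection is run
jointly on the concatenated matrix.  Decision level combines two
probabilistic classifiers' outputs with one of three rules: weighted
majority vote, a Bayesian sensor model using cross-validated
sensitivity/specificity as conditional probabilities, or fuzzy-template
matching of decision profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemometrics import (ClassifierPerformance, ProbOutput, Scaler,
                           fit_scaler)
from .datatypes import BRUISED, HEALTHY, SpectrumTable
from .featsel import SelectionResult, select_features


def _namespaced(table: SpectrumTable, tag: str) -> list:
    return [c if ":" in c else f"{tag}:{c}" for c in table.columns]


def _check_alignment(tableA: SpectrumTable, tableB: SpectrumTable) -> None:
    if tableA.sample_ids != tableB.sample_ids:
        raise ValueError("sample ids/order differ between the two tables")


# ---------------------------------------------------------------------------
# data & feature level


def fuse_data_level(tableA: SpectrumTable, tableB: SpectrumTable,
                    tagA: str = "PB", tagB: str = "LCTF",
                    scalers: tuple[Scaler, Scaler] | None = None
                    ) -> SpectrumTable:
    """Autoscale each table, then concatenate columns (A first).

    ``scalers`` fitted on training tables may be supplied to transform a
    prediction set consistently; by default scalers are fitted on the
    tables themselves.
    """
    _check_alignment(tableA, tableB)
    if scalers is None:
        scalers = (fit_scaler(tableA), fit_scaler(tableB))
    sA, sB = scalers
    colsA = _namespaced(tableA, tagA)
    colsB = _namespaced(tableB, tagB)
    if set(colsA) & set(colsB):
        raise ValueError("duplicate column names across instruments")
    labels = tableA.labels
    if labels is None:
        labels = tableB.labels
    return SpectrumTable(
        np.hstack([sA.transform(tableA.values), sB.transform(tableB.values)]),
        np.concatenate([tableA.wavelengths, tableB.wavelengths]),
        list(tableA.sample_ids),
        labels=None if labels is None else labels.copy(),
        columns=colsA + colsB,
        fused=True,
    )


def fuse_feature_separate(selA: SelectionResult, selB: SelectionResult,
                          tableA: SpectrumTable, tableB: SpectrumTable,
                          tagA: str = "PB", tagB: str = "LCTF"
                          ) -> SpectrumTable:
    """Combine the per-instrument selected wavelengths into one table."""
    _check_alignment(tableA, tableB)
    if selA.n_selected == 0 or selB.n_selected == 0:
        raise ValueError("empty feature selection")
    subA = tableA.select_columns(np.unique(selA.subset))
    subB = tableB.select_columns(np.unique(selB.subset))
    labels = tableA.labels if tableA.labels is not None else tableB.labels
    return SpectrumTable(
        np.hstack([subA.values, subB.values]),
        np.concatenate([subA.wavelengths, subB.wavelengths]),
        list(tableA.sample_ids),
        labels=None if labels is None else labels.copy(),
        columns=_namespaced(subA, tagA) + _namespaced(subB, tagB),
        fused=True,
    )


def fuse_feature_joint(fused: SpectrumTable, n_iter: int = 1000,
                       max_n: int = 80, folds: int = 10, seed: int = 0
                       ) -> tuple[SpectrumTable, SelectionResult]:
    """Random-frog selection run jointly on the data-level fused matrix."""
    sel = select_features(fused, n_iter=n_iter, max_n=max_n, folds=folds,
                          seed=seed)
    return fused.select_columns(sel.subset), sel


# ---------------------------------------------------------------------------
# decision level


@dataclass
class FusionWeights:
    """Per-classifier, per-class weights; each class's weights sum to 1."""

    w_a_h: float
    w_b_h: float
    w_a_b: float
    w_b_b: float

    def __post_init__(self):
        for v in (self.w_a_h, self.w_b_h, self.w_a_b, self.w_b_b):
            if not 0.0 <= v <= 1.0:
                raise ValueError("weights must be in [0, 1]")
        if abs(self.w_a_h + self.w_b_h - 1.0) > 1e-9:
            raise ValueError("healthy-class weights must sum to 1")
        if abs(self.w_a_b + self.w_b_b - 1.0) > 1e-9:
            raise ValueError("bruised-class weights must sum to 1")


@dataclass
class FusionResult:
    sample_ids: list
    score_h: np.ndarray
    score_b: np.ndarray
    labels: np.ndarray  # fused +1/-1
    labels_a: np.ndarray
    labels_b: np.ndarray

    @property
    def agreed(self) -> np.ndarray:
        return self.labels_a == self.labels_b


def _finalize(probA: ProbOutput, probB: ProbOutput, score_h, score_b
              ) -> FusionResult:
    score_h = np.asarray(score_h, float)
    score_b = np.asarray(score_b, float)
    # tie breaks to bruised, the detection-positive class
    labels = np.where(score_h > score_b, HEALTHY, BRUISED)
    return FusionResult(list(probA.sample_ids), score_h, score_b, labels,
                        probA.labels.copy(), probB.labels.copy())


def _check_prob_pair(probA: ProbOutput, probB: ProbOutput) -> None:
    if probA.sample_ids != probB.sample_ids:
        raise ValueError("classifier outputs are not aligned")
    for prob in (probA, probB):
        if np.max(np.abs(prob.proba.sum(axis=1) - 1.0)) > 1e-6:
            raise ValueError("probability rows must sum to 1")


def wmv_weights(perfA: ClassifierPerformance, perfB: ClassifierPerformance
                ) -> FusionWeights:
    """w(l)(i) = alpha_l(i) / (alpha_A(i) + alpha_B(i))."""
    den_h = perfA.alpha_h + perfB.alpha_h
    den_b = perfA.alpha_b + perfB.alpha_b
    if den_h <= 0 or den_b <= 0:
        raise ValueError("per-class accuracies are all zero for a class")
    return FusionWeights(
        w_a_h=perfA.alpha_h / den_h, w_b_h=perfB.alpha_h / den_h,
        w_a_b=perfA.alpha_b / den_b, w_b_b=perfB.alpha_b / den_b,
    )


def weighted_majority_vote(w: FusionWeights, probA: ProbOutput,
                           probB: ProbOutput) -> FusionResult:
    """S(i,x) = w_A(i) p_A(i,x) + w_B(i) p_B(i,x); label = argmax score."""
    _check_prob_pair(probA, probB)
    score_h = w.w_a_h * probA.p_healthy + w.w_b_h * probB.p_healthy
    score_b = w.w_a_b * probA.p_bruised + w.w_b_b * probB.p_bruised
    return _finalize(probA, probB, score_h, score_b)


def bayes_fuse(perfA: ClassifierPerformance, perfB: ClassifierPerformance,
               probA: ProbOutput, probB: ProbOutput,
               priors: tuple[float, float] = (0.5, 0.5)) -> FusionResult:
    """Bayesian sensor fusion with CV sensitivity/specificity as the
    per-instrument conditional decision probabilities.

    For each true state the likelihood sums the four (decision_A,
    decision_B) combinations of conditional probability x soft classifier
    output; the posterior normalizes over the two states.
    """
    _check_prob_pair(probA, probB)
    for perf in (perfA, perfB):
        if not (0 <= perf.sensitivity <= 1 and 0 <= perf.specificity <= 1):
            raise ValueError("sensitivity/specificity must be in [0, 1]")
    pa_h, pa_b = probA.p_healthy, probA.p_bruised
    pb_h, pb_b = probB.p_healthy, probB.p_bruised
    # P(instrument decides h | healthy) = specificity, etc.
    lik_h = (
        perfA.specificity * pa_h * perfB.specificity * pb_h
        + (1 - perfA.specificity) * pa_b * perfB.specificity * pb_h
        + perfA.specificity * pa_h * (1 - perfB.specificity) * pb_b
        + (1 - perfA.specificity) * pa_b * (1 - perfB.specificity) * pb_b
    )
    lik_b = (
        perfA.sensitivity * pa_b * perfB.sensitivity * pb_b
        + (1 - perfA.sensitivity) * pa_h * perfB.sensitivity * pb_b
        + perfA.sensitivity * pa_b * (1 - perfB.sensitivity) * pb_h
        + (1 - perfA.sensitivity) * pa_h * (1 - perfB.sensitivity) * pb_h
    )
    num_h = priors[0] * lik_h
    num_b = priors[1] * lik_b
    denom = num_h + num_b
    if np.any(denom <= 0):
        raise ValueError("degenerate likelihoods: both states have mass 0")
    return _finalize(probA, probB, num_h / denom, num_b / denom)


def decision_profiles(probA: ProbOutput, probB: ProbOutput) -> np.ndarray:
    """Stacked per-sample decision profiles, shape (n, L=2, c=2)."""
    _check_prob_pair(probA, probB)
    return np.stack([probA.proba, probB.proba], axis=1)


@dataclass
class FuzzyTemplates:
    """Class-wise mean training decision profiles (similarity prototypes)."""

    template_h: np.ndarray  # (L, c)
    template_b: np.ndarray

    def __post_init__(self):
        self.template_h = np.asarray(self.template_h, float)
        self.template_b = np.asarray(self.template_b, float)
        for t in (self.template_h, self.template_b):
            if np.any(t < -1e-9) or np.any(t > 1 + 1e-9):
                raise ValueError("template entries must be in [0, 1]")


def fuzzy_template_fit(train_dp: np.ndarray, labels) -> FuzzyTemplates:
    """Templates = elementwise mean of each class's training profiles."""
    train_dp = np.asarray(train_dp, float)
    labels = np.asarray(labels, int)
    if train_dp.ndim != 3 or len(labels) != train_dp.shape[0]:
        raise ValueError("decision profiles must be (n, L, c) aligned to labels")
    sel_h = labels == HEALTHY
    sel_b = labels == BRUISED
    if not sel_h.any() or not sel_b.any():
        raise ValueError("each class needs at least one training sample")
    return FuzzyTemplates(train_dp[sel_h].mean(axis=0),
                          train_dp[sel_b].mean(axis=0))


def fuzzy_similarity(template: np.ndarray, dp: np.ndarray) -> np.ndarray:
    """mu = 1 - mean squared elementwise difference (in [0, 1])."""
    template = np.asarray(template, float)
    dp = np.asarray(dp, float)
    if dp.shape[-2:] != template.shape:
        raise ValueError("decision profile shape does not match template")
    diff = dp - template
    return 1.0 - np.mean(diff * diff, axis=(-2, -1))


def fuzzy_template_predict(templates: FuzzyTemplates, probA: ProbOutput,
                           probB: ProbOutput) -> FusionResult:
    dp = decision_profiles(probA, probB)
    mu_h = fuzzy_similarity(templates.template_h, dp)
    mu_b = fuzzy_similarity(templates.template_b, dp)
    return _finalize(probA, probB, mu_h, mu_b)
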