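"""Probability-calibrated two-class discrimination from spectra.

PLS-DA regresses the spectra onto class codes +1 (healthy) / -1 (bruised)
and converts the continuous prediction ``y`` into posterior probabilities by
fitting one Gaussian density per class to the training-set predictions.  The
cut-off ``y*`` is the point where both class densities are equal, so the
posterior there is exactly 0.5 (with equal priors).

The same probabilistic-classifier contract is offered by an RBF kernel
machine backed by scikit-learn, tuned by grid search.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .datatypes import BRUISED, HEALTHY, SpectrumTable

SIGMA_FLOOR = 1e-6
SCALE_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# autoscaling


@dataclass
class Scaler:
    """Per-column mean/sd learned on a training table (sd uses n-1)."""

    mean: np.ndarray
    std: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) / self.std


def fit_scaler(train: SpectrumTable) -> Scaler:
    if train.n_samples < 2:
        raise ValueError("scaler needs at least 2 training rows")
    mean = train.values.mean(axis=0)
    std = train.values.std(axis=0, ddof=1)
    if np.any(std < SCALE_FLOOR):
        warnings.warn(
            f"{int((std < SCALE_FLOOR).sum())} constant column(s); "
            "sd clamped to floor",
            stacklevel=2,
        )
        std = np.maximum(std, SCALE_FLOOR)
    return Scaler(mean, std)


def apply_scaler(scaler: Scaler, table: SpectrumTable) -> SpectrumTable:
    return table.with_values(scaler.transform(table.values))


# ---------------------------------------------------------------------------
# PLS (SIMPLS) on numpy — kept dependency-free for speed in inner CV loops


def _simpls_path(X: np.ndarray, y: np.ndarray, max_lv: int):
    """Univariate-response SIMPLS coefficient path.

    Returns ``(coefs, x_mean, y_mean)`` where ``coefs[:, a]`` is the
    regression vector using ``a + 1`` latent variables; prediction is
    ``(X - x_mean) @ coefs[:, a] + y_mean``.  If the predictive directions
    are exhausted early the path is extended by repetition, so every column
    is usable.  With LV count equal to the rank of centered X the last
    column coincides with ordinary least squares.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean

    s = Xc.T @ yc
    V = np.zeros((p, max_lv))
    coefs = np.zeros((p, max_lv))
    coef = np.zeros(p)
    for a in range(max_lv):
        r = s
        t = Xc @ r
        tnorm = np.linalg.norm(t)
        if tnorm < 1e-12:
            # predictive directions exhausted; freeze the path
            coefs[:, a:] = coef[:, None]
            break
        t = t / tnorm
        r = r / tnorm
        pa = Xc.T @ t
        qa = yc @ t
        coef = coef + r * qa
        coefs[:, a] = coef
        v = pa
        if a > 0:
            v = v - V[:, :a] @ (V[:, :a].T @ pa)
        vnorm = np.linalg.norm(v)
        if vnorm < 1e-12:
            coefs[:, a:] = coef[:, None]
            break
        V[:, a] = v / vnorm
        s = s - V[:, a] * (V[:, a] @ s)
    return coefs, x_mean, y_mean


def _simpls(X: np.ndarray, y: np.ndarray, n_lv: int):
    """Univariate-response SIMPLS; returns (coef, x_mean, y_mean)."""
    coefs, x_mean, y_mean = _simpls_path(X, y, n_lv)
    return coefs[:, -1], x_mean, y_mean


@dataclass
class PlsdaModel:
    """Fitted PLS-DA regression: spectrum -> scalar score y."""

    n_lv: int
    coef: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    wavelengths: np.ndarray
    columns: list

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.x_mean) @ self.coef + self.y_mean


def fit_plsda(train: SpectrumTable, n_lv: int) -> PlsdaModel:
    if train.labels is None:
        raise ValueError("training table must be labeled")
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training set contains a single class")
    n, p = train.values.shape
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(f"n_lv must be in [1, {min(n - 1, p)}], got {n_lv}")
    coef, x_mean, y_mean = _simpls(train.values, train.labels.astype(float), n_lv)
    return PlsdaModel(
        n_lv=n_lv,
        coef=coef,
        x_mean=x_mean,
        y_mean=y_mean,
        wavelengths=train.wavelengths.copy(),
        columns=list(train.columns),
    )


# ---------------------------------------------------------------------------
# Gaussian class PDFs and posterior probabilities


@dataclass
class GaussianClassPDF:
    mu_h: float
    sigma_h: float
    mu_b: float
    sigma_b: float
    cutoff: float


def _density_crossing(mu_h, sigma_h, mu_b, sigma_b):
    """Root of p(y|h) = p(y|b) lying between the class means."""
    lo, hi = min(mu_h, mu_b), max(mu_h, mu_b)
    if abs(sigma_h - sigma_b) < 1e-12:
        return 0.5 * (mu_h + mu_b)
    # equate log densities: quadratic A y^2 + B y + C = 0
    A = 1.0 / sigma_b**2 - 1.0 / sigma_h**2
    B = 2.0 * (mu_h / sigma_h**2 - mu_b / sigma_b**2)
    C = (
        mu_b**2 / sigma_b**2
        - mu_h**2 / sigma_h**2
        + 2.0 * np.log(sigma_b / sigma_h)
    )
    disc = B * B - 4.0 * A * C
    disc = max(disc, 0.0)
    roots = ((-B - np.sqrt(disc)) / (2 * A), (-B + np.sqrt(disc)) / (2 * A))
    inside = [r for r in roots if lo <= r <= hi]
    if inside:
        return float(inside[0])
    # numerically degenerate (means almost equal): nearest root to midpoint
    mid = 0.5 * (lo + hi)
    return float(min(roots, key=lambda r: abs(r - mid)))


def calibrate_pdf(scores, labels) -> GaussianClassPDF:
    scores = np.asarray(scores, float).ravel()
    labels = np.asarray(labels, int).ravel()
    sh = scores[labels == HEALTHY]
    sb = scores[labels == BRUISED]
    if len(sh) < 2 or len(sb) < 2:
        raise ValueError("each class needs at least 2 samples to fit a PDF")
    mu_h, mu_b = float(sh.mean()), float(sb.mean())
    sigma_h = float(sh.std(ddof=1))
    sigma_b = float(sb.std(ddof=1))
    if sigma_h < SIGMA_FLOOR or sigma_b < SIGMA_FLOOR:
        warnings.warn("class score sd below floor; clamped", stacklevel=2)
        sigma_h = max(sigma_h, SIGMA_FLOOR)
        sigma_b = max(sigma_b, SIGMA_FLOOR)
    cutoff = _density_crossing(mu_h, sigma_h, mu_b, sigma_b)
    return GaussianClassPDF(mu_h, sigma_h, mu_b, sigma_b, cutoff)


def _normal_logpdf(y, mu, sigma):
    return -0.5 * ((y - mu) / sigma) ** 2 - np.log(sigma)


def posterior_healthy(pdf: GaussianClassPDF, y) -> np.ndarray:
    """p(h|y) with equal priors, computed stably in log space."""
    y = np.asarray(y, float)
    lh = _normal_logpdf(y, pdf.mu_h, pdf.sigma_h)
    lb = _normal_logpdf(y, pdf.mu_b, pdf.sigma_b)
    m = np.maximum(lh, lb)
    eh = np.exp(lh - m)
    eb = np.exp(lb - m)
    return eh / (eh + eb)


@dataclass
class ProbOutput:
    """Per-sample (p_healthy, p_bruised) pairs with hard labels."""

    sample_ids: list
    proba: np.ndarray  # (n, 2) columns [healthy, bruised]
    labels: np.ndarray  # +1 / -1, ties (p=0.5) break to bruised

    def __post_init__(self):
        self.proba = np.asarray(self.proba, float)
        if self.proba.ndim != 2 or self.proba.shape[1] != 2:
            raise ValueError("proba must be (n, 2)")
        if np.any(self.proba < -1e-9) or np.any(self.proba > 1 + 1e-9):
            raise ValueError("probabilities outside [0, 1]")
        if np.max(np.abs(self.proba.sum(axis=1) - 1.0)) > 1e-6:
            raise ValueError("probability rows must sum to 1")
        self.labels = np.asarray(self.labels, int)

    @property
    def p_healthy(self) -> np.ndarray:
        return self.proba[:, 0]

    @property
    def p_bruised(self) -> np.ndarray:
        return self.proba[:, 1]


def _labels_from_p_healthy(ph: np.ndarray) -> np.ndarray:
    # tie at 0.5 -> bruised (detection-positive class)
    return np.where(ph > 0.5, HEALTHY, BRUISED)


def predict_proba(
    model: PlsdaModel, pdf: GaussianClassPDF, X: SpectrumTable
) -> ProbOutput:
    if list(X.columns) != list(model.columns):
        raise ValueError("wavelength grid does not match the fitted model")
    y = model.predict_score(X.values)
    ph = posterior_healthy(pdf, y)
    proba = np.column_stack([ph, 1.0 - ph])
    return ProbOutput(list(X.sample_ids), proba, _labels_from_p_healthy(ph))


# ---------------------------------------------------------------------------
# classifier contract


class PlsdaClassifier:
    """Autoscale -> PLS-DA -> Gaussian-PDF probability calibration."""

    def __init__(self, n_lv: int | None = None, max_lv: int = 15,
                 autoscale: bool = True, folds: int = 10, seed: int = 0):
        self.n_lv = n_lv
        self.max_lv = max_lv
        self.autoscale = autoscale
        self.folds = folds
        self.seed = seed
        self.scaler_ = None
        self.model_ = None
        self.pdf_ = None

    def clone(self) -> "PlsdaClassifier":
        return PlsdaClassifier(self.n_lv, self.max_lv, self.autoscale,
                               self.folds, self.seed)

    def fit(self, train: SpectrumTable) -> "PlsdaClassifier":
        if train.labels is None:
            raise ValueError("training table must be labeled")
        work = train
        if self.autoscale:
            self.scaler_ = fit_scaler(train)
            work = apply_scaler(self.scaler_, train)
        n_lv = self.n_lv
        if n_lv is None:
            cap = min(self.max_lv, work.n_samples - 1, work.n_bands)
            n_lv = select_lv(work, cap, folds=self.folds, seed=self.seed)
        self.model_ = fit_plsda(work, n_lv)
        scores = self.model_.predict_score(work.values)
        self.pdf_ = calibrate_pdf(scores, work.labels)
        return self

    def predict_proba(self, X: SpectrumTable) -> ProbOutput:
        if self.model_ is None:
            raise ValueError("classifier not fitted")
        if list(X.columns) != list(self.model_.columns):
            raise ValueError("wavelength grid does not match the fitted model")
        work = apply_scaler(self.scaler_, X) if self.autoscale else X
        return predict_proba(self.model_, self.pdf_, work)


def _stratified_folds(labels: np.ndarray, folds: int, seed: int):
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(labels)), labels))


def _plsda_cv_errors(X, y, max_lv, folds, seed):
    """Misclassification rate per LV count over stratified CV folds."""
    n = len(y)
    errors = np.zeros(max_lv)
    for tr, te in _stratified_folds(y, folds, seed):
        Xtr, ytr = X[tr], y[tr]
        Xte, yte = X[te], y[te]
        cap = min(max_lv, len(tr) - 1, X.shape[1])
        coefs, xm, ym = _simpls_path(Xtr, ytr.astype(float), cap)
        str_ = (Xtr - xm) @ coefs + ym  # (n_tr, cap) scores per LV count
        ste = (Xte - xm) @ coefs + ym
        for lv in range(1, max_lv + 1):
            col = min(lv, cap) - 1
            try:
                cut = calibrate_pdf(str_[:, col], ytr).cutoff
            except ValueError:
                cut = 0.0
            pred = np.where(ste[:, col] > cut, HEALTHY, BRUISED)
            errors[lv - 1] += np.sum(pred != yte)
    return errors / n


def select_lv(train: SpectrumTable, max_lv: int, folds: int = 10,
              seed: int = 0) -> int:
    """LV count minimizing 10-fold CV misclassification; ties -> fewest."""
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    if train.labels is None:
        raise ValueError("training table must be labeled")
    if train.n_samples < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV")
    max_lv = min(max_lv, train.n_samples - 1, train.n_bands)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        err = _plsda_cv_errors(train.values, train.labels, max_lv, folds, seed)
    return int(np.argmin(err)) + 1


# ---------------------------------------------------------------------------
# cross-validated performance


@dataclass
class ClassifierPerformance:
    """Pooled out-of-fold sensitivity/specificity.

    Convention (fixed throughout): sensitivity = recall of the bruised
    class, specificity = recall of the healthy class; the per-class
    accuracies are alpha(h) = specificity and alpha(b) = sensitivity.
    """

    sensitivity: float
    specificity: float
    seed: int = 0

    @property
    def alpha_h(self) -> float:
        return self.specificity

    @property
    def alpha_b(self) -> float:
        return self.sensitivity


def crossval_perf(classifier, train: SpectrumTable, folds: int = 10,
                  seed: int = 0) -> ClassifierPerformance:
    """Pooled out-of-fold performance of ``classifier`` (anything with
    ``clone``/``fit``/``predict_proba``)."""
    if train.labels is None:
        raise ValueError("training table must be labeled")
    y = train.labels
    if min(np.sum(y == HEALTHY), np.sum(y == BRUISED)) < folds:
        raise ValueError("too few samples per class for stratified CV")
    pred = np.zeros(train.n_samples, dtype=int)
    for tr, te in _stratified_folds(y, folds, seed):
        tr_tab = SpectrumTable(
            train.values[tr], train.wavelengths,
            [train.sample_ids[i] for i in tr], labels=y[tr],
            columns=list(train.columns), fused=train.fused,
        )
        te_tab = SpectrumTable(
            train.values[te], train.wavelengths,
            [train.sample_ids[i] for i in te],
            columns=list(train.columns), fused=train.fused,
        )
        clf = classifier.clone().fit(tr_tab)
        pred[te] = clf.predict_proba(te_tab).labels
    sens = float(np.mean(pred[y == BRUISED] == BRUISED))
    spec = float(np.mean(pred[y == HEALTHY] == HEALTHY))
    return ClassifierPerformance(sensitivity=sens, specificity=spec, seed=seed)


# ---------------------------------------------------------------------------
# RBF kernel machine (contract slot; internals delegated to scikit-learn)


class RbfClassifier:
    """SVM with RBF kernel and probability outputs, tuned by grid search.

    Grid search maximizes 10-fold CV accuracy; ties break to smaller c,
    then smaller g.
    """

    DEFAULT_C = tuple(2.0 ** k for k in range(-5, 16, 4))
    DEFAULT_G = tuple(2.0 ** k for k in range(-15, 4, 4))

    def __init__(self, c_grid=None, g_grid=None, autoscale: bool = True,
                 folds: int = 10, seed: int = 0):
        self.c_grid = tuple(c_grid) if c_grid is not None else self.DEFAULT_C
        self.g_grid = tuple(g_grid) if g_grid is not None else self.DEFAULT_G
        if not self.c_grid or not self.g_grid:
            raise ValueError("empty hyperparameter grid")
        if any(v <= 0 for v in self.c_grid) or any(v <= 0 for v in self.g_grid):
            raise ValueError("c and g must be positive")
        self.autoscale = autoscale
        self.folds = folds
        self.seed = seed
        self.scaler_ = None
        self.svc_ = None
        self.best_c_ = None
        self.best_g_ = None

    def clone(self) -> "RbfClassifier":
        return RbfClassifier(self.c_grid, self.g_grid, self.autoscale,
                             self.folds, self.seed)

    def _grid_search(self, X, y):
        best = None
        folds = min(self.folds, np.min(np.bincount((y == HEALTHY).astype(int))))
        folds = max(2, folds)
        splits = _stratified_folds(y, folds, self.seed)
        for c in sorted(self.c_grid):
            for g in sorted(self.g_grid):
                correct = 0
                for tr, te in splits:
                    svc = SVC(C=c, gamma=g, kernel="rbf")
                    svc.fit(X[tr], y[tr])
                    correct += np.sum(svc.predict(X[te]) == y[te])
                acc = correct / len(y)
                if best is None or acc > best[0] + 1e-12:
                    best = (acc, c, g)
        return best[1], best[2]

    def fit(self, train: SpectrumTable) -> "RbfClassifier":
        if train.labels is None:
            raise ValueError("training table must be labeled")
        X, y = train.values, train.labels
        if self.autoscale:
            self.scaler_ = fit_scaler(train)
            X = self.scaler_.transform(X)
        self.best_c_, self.best_g_ = self._grid_search(X, y)
        self.svc_ = SVC(C=self.best_c_, gamma=self.best_g_, kernel="rbf",
                        probability=True, random_state=self.seed)
        self.svc_.fit(X, y)
        return self

    def predict_proba(self, X: SpectrumTable) -> ProbOutput:
        if self.svc_ is None:
            raise ValueError("classifier not fitted")
        vals = self.scaler_.transform(X.values) if self.autoscale else X.values
        raw = self.svc_.predict_proba(vals)
        col_h = list(self.svc_.classes_).index(HEALTHY)
        ph = raw[:, col_h]
        proba = np.column_stack([ph, 1.0 - ph])
        return ProbOutput(list(X.sample_ids), proba, _labels_from_p_healthy(ph))


def rbf_classifier(train: SpectrumTable, c_grid=None, g_grid=None,
                   folds: int = 10, seed: int = 0) -> RbfClassifier:
    """Fit a grid-searched RBF kernel classifier on ``train``."""
    return RbfClassifier(c_grid, g_grid, folds=folds, seed=seed).fit(train)


# ---------------------------------------------------------------------------
# model persistence


def save_plsda(path, classifier: PlsdaClassifier) -> None:
    if classifier.model_ is None:
        raise ValueError("classifier not fitted")
    doc = {
        "format": "hsifuse-plsda",
        "version": 1,
        "n_lv": classifier.model_.n_lv,
        "coef": classifier.model_.coef.tolist(),
        "x_mean": classifier.model_.x_mean.tolist(),
        "y_mean": classifier.model_.y_mean,
        "wavelengths": classifier.model_.wavelengths.tolist(),
        "columns": classifier.model_.columns,
        "pdf": vars(classifier.pdf_),
        "autoscale": classifier.autoscale,
        "scaler": None
        if classifier.scaler_ is None
        else {"mean": classifier.scaler_.mean.tolist(),
              "std": classifier.scaler_.std.tolist()},
        "seed": classifier.seed,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_plsda(path) -> PlsdaClassifier:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "hsifuse-plsda":
        raise ValueError("not a PLS-DA model document")
    clf = PlsdaClassifier(n_lv=doc["n_lv"], autoscale=doc["autoscale"],
                          seed=doc.get("seed", 0))
    clf.model_ = PlsdaModel(
        n_lv=doc["n_lv"],
        coef=np.array(doc["coef"]),
        x_mean=np.array(doc["x_mean"]),
        y_mean=doc["y_mean"],
        wavelengths=np.array(doc["wavelengths"]),
        columns=list(doc["columns"]),
    )
    clf.pdf_ = GaussianClassPDF(**doc["pdf"])
    if doc["scaler"] is not None:
        clf.scaler_ = Scaler(np.array(doc["scaler"]["mean"]),
                             np.array(doc["scaler"]["std"]))
    return clf
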