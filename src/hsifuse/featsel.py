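"""Random-frog wavelength selection.

An iterative stochastic subset search: from the current subset a candidate
of perturbed size is proposed (shrunk by dropping the weakest-coefficient
variables, grown by importance-weighted draws from outside the subset) and
accepted depending on the ratio of cross-validated PLS-DA accuracies.  The
per-wavelength selection probability is the fraction of chain states
containing that wavelength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .chemometrics import _plsda_cv_errors, _simpls
from .datatypes import SpectrumTable


@dataclass
class SelectionResult:
    wavelengths: np.ndarray
    columns: list
    probabilities: np.ndarray  # selection probability per wavelength
    ranking: np.ndarray  # column indices, descending importance
    subset: np.ndarray  # chosen column indices (top-k of ranking)
    cv_error_curve: np.ndarray  # misclassification error for k = 1..max

    @property
    def n_selected(self) -> int:
        return len(self.subset)

    def subset_columns(self) -> list:
        return [self.columns[i] for i in self.subset]


def _cv_accuracy(X, y, cols, folds, seed, max_lv=10):
    """10-fold CV accuracy of PLS-DA restricted to ``cols`` (best LV <= cap)."""
    Xs = X[:, cols]
    cap = min(max_lv, len(cols), len(y) - 1)
    err = _plsda_cv_errors(Xs, y, cap, folds, seed)
    return 1.0 - float(np.min(err))


def random_frog(train: SpectrumTable, n_iter: int = 1000, q0: int | None = None,
                seed: int = 0, folds: int = 10, eta: float = 0.1,
                dim_sd_frac: float = 0.3, max_lv: int = 10,
                grow_weights: str = "corr") -> np.ndarray:
    """Per-wavelength selection probabilities from the subset chain."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if train.labels is None:
        raise ValueError("training table must be labeled")
    X, y = train.values, train.labels
    n, p = X.shape
    if q0 is None:
        q0 = min(p, max(2, p // 10))
    if not 1 <= q0 <= p:
        raise ValueError(f"q0 must be in [1, {p}]")
    rng = np.random.default_rng(seed)

    if p == 1:
        return np.ones(1)

    # global importance weights for the grow step, independent of the
    # current subset: per-variable |correlation with the class code| by
    # default, or |coefficient| of a full-spectrum model
    if grow_weights == "corr":
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        denom = np.linalg.norm(Xc, axis=0) * np.linalg.norm(yc)
        global_w = np.abs(Xc.T @ yc) / np.maximum(denom, 1e-12)
    elif grow_weights == "coef":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coef_full, _, _ = _simpls(X, y.astype(float),
                                      min(max_lv, n - 1, p))
        global_w = np.abs(coef_full)
    else:
        raise ValueError("grow_weights must be 'corr' or 'coef'")
    global_w = global_w + 1e-12

    subset = np.sort(rng.choice(p, size=q0, replace=False))
    cv_seed = int(rng.integers(0, 2**31 - 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        perf = _cv_accuracy(X, y, subset, folds, cv_seed, max_lv)
    counts = np.zeros(p)

    for _ in range(n_iter):
        q = len(subset)
        q_star = int(np.clip(round(rng.normal(q, dim_sd_frac * q)), 1, p))
        if q_star < q:
            # drop the lowest-|coefficient| variables of the current model
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                coef, _, _ = _simpls(X[:, subset], y.astype(float),
                                     min(max_lv, q, n - 1))
            keep = np.argsort(-np.abs(coef))[:q_star]
            candidate = np.sort(subset[keep])
        elif q_star > q:
            outside = np.setdiff1d(np.arange(p), subset)
            w = global_w[outside]
            w = w / w.sum()
            extra = rng.choice(outside, size=min(q_star - q, len(outside)),
                               replace=False, p=w)
            candidate = np.sort(np.concatenate([subset, extra]))
        else:
            candidate = subset
        if candidate is subset:
            new_perf = perf
            accept = True
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                new_perf = _cv_accuracy(X, y, candidate, folds, cv_seed, max_lv)
            if new_perf >= perf:
                accept = True
            else:
                ratio = new_perf / perf if perf > 0 else 1.0
                accept = rng.random() < eta * ratio
        if accept:
            subset = candidate
            perf = new_perf
        counts[subset] += 1.0
    return counts / n_iter


def choose_n_features(probabilities, train: SpectrumTable, max_n: int = 80,
                      folds: int = 10, seed: int = 0,
                      max_lv: int = 10, repeats: int = 3) -> SelectionResult:
    """Size the subset by CV error over top-1..top-max_n ranked variables.

    The error at each size is averaged over ``repeats`` independent fold
    splits to stabilize the curve; the chosen size is the argmin (ties go
    to the smaller size).
    """
    probabilities = np.asarray(probabilities, float)
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    if train.labels is None:
        raise ValueError("training table must be labeled")
    if train.n_samples < folds:
        raise ValueError("fewer samples than folds")
    p = train.n_bands
    if len(probabilities) != p:
        raise ValueError("probability vector length mismatch")
    # stable ranking: probability desc, index asc on ties
    ranking = np.lexsort((np.arange(p), -probabilities))
    kmax = min(max_n, p)
    X, y = train.values, train.labels
    curve = np.zeros(kmax)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(1, kmax + 1):
            cols = ranking[:k]
            cap = min(max_lv, k, train.n_samples - 1)
            errs = [np.min(_plsda_cv_errors(X[:, cols], y, cap, folds,
                                            seed + 7919 * r))
                    for r in range(repeats)]
            curve[k - 1] = float(np.mean(errs))
    best_k = int(np.argmin(curve)) + 1  # argmin returns the smallest index on ties
    return SelectionResult(
        wavelengths=train.wavelengths.copy(),
        columns=list(train.columns),
        probabilities=probabilities,
        ranking=ranking,
        subset=np.sort(ranking[:best_k]),
        cv_error_curve=curve,
    )


def select_features(train: SpectrumTable, n_iter: int = 1000,
                    q0: int | None = None, max_n: int = 80, folds: int = 10,
                    seed: int = 0, max_lv: int = 10,
                    n_chains: int = 3) -> SelectionResult:
    """random_frog + choose_n_features in one call.

    Selection probabilities are averaged over ``n_chains`` independent
    chains (splitting ``n_iter`` between them) to stabilize the ranking.
    """
    per = max(1, n_iter // n_chains)
    probs = np.mean([
        random_frog(train, n_iter=per, q0=q0, seed=seed + 10_007 * c,
                    folds=folds, max_lv=max_lv)
        for c in range(n_chains)
    ], axis=0)
    return choose_n_features(probs, train, max_n=max_n, folds=folds,
                             seed=seed, max_lv=max_lv)


def format_wavelengths(result: SelectionResult) -> str:
    """Log line in the style 'following K wavelengths: w1, w2, ... nm'."""
    wls = sorted(result.wavelengths[i] for i in result.subset)
    body = ", ".join(f"{w:.1f}" for w in wls)
    return f"following {len(wls)} wavelengths: {body} nm"
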