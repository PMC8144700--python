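"""Classification: LDA, the two validation schemes, and feature selection.

The predictor is two-class linear discriminant analysis on the eight
relative-power features: Gaussian class-conditional densities with a
pooled within-class covariance, so the decision boundary is the hyperplane
``w = Sigma^-1 (mu_pos - mu_neg)``.  Validation mirrors the two published
schemes: a single classifier trained on all n training subjects, and a
majority-vote ensemble of the n leave-one-out fold models.

The selection procedure that originally produced the eight features —
forward-backward stepwise logistic regression run inside every
leave-one-out fold, keeping predictors chosen in a majority of folds — is
reconstructed here (:func:`stepwise_select_loo`) as a reproducible,
explicitly separate procedure; the shipped feature set is never silently
replaced by it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    ClassError,
    ConditioningError,
    InputError,
    ParameterError,
    SeparationError,
)
from .features import FEATURE_NAMES_V1, FeatureMatrix

POSITIVE = "responder"
NEGATIVE = "non-responder"


@dataclass
class LDAModel:
    """Two-class LDA with pooled covariance.

    ``priors`` is (pi_pos, pi_neg); ``ridge`` is the diagonal loading that
    was added to the pooled covariance before inversion.
    """

    mean_pos: np.ndarray
    mean_neg: np.ndarray
    pooled_cov: np.ndarray
    priors: tuple[float, float]
    ridge: float = 0.0
    feature_names: tuple[str, ...] = FEATURE_NAMES_V1

    def __post_init__(self):
        self.mean_pos = np.asarray(self.mean_pos, dtype=float)
        self.mean_neg = np.asarray(self.mean_neg, dtype=float)
        self.pooled_cov = np.asarray(self.pooled_cov, dtype=float)
        p = self.mean_pos.shape[0]
        if self.pooled_cov.shape != (p, p):
            raise ParameterError("covariance shape does not match the means")
        if not np.allclose(self.pooled_cov, self.pooled_cov.T, atol=1e-10):
            raise ParameterError("pooled covariance must be symmetric")
        if abs(sum(self.priors) - 1.0) > 1e-9:
            raise ParameterError("priors must sum to 1")
        cov = self.pooled_cov + self.ridge * np.eye(p)
        eigmin = float(np.linalg.eigvalsh(cov).min())
        if eigmin <= 0:
            raise ConditioningError(
                f"pooled covariance not positive definite (min eigenvalue "
                f"{eigmin:.3g}); increase ridge"
            )
        self._cov_inv = np.linalg.inv(cov)
        self._w = self._cov_inv @ (self.mean_pos - self.mean_neg)

    @property
    def weights(self) -> np.ndarray:
        """Discriminant direction Sigma^-1 (mu_pos - mu_neg)."""
        return self._w

    def discriminant(self, x: np.ndarray) -> float:
        """Log posterior-odds of the positive class at *x*."""
        x = np.asarray(x, dtype=float)
        mid = (self.mean_pos + self.mean_neg) / 2.0
        return float(
            self._w @ (x - mid) + np.log(self.priors[0] / self.priors[1])
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "lda",
                "feature_names": list(self.feature_names),
                "mean_pos": self.mean_pos.tolist(),
                "mean_neg": self.mean_neg.tolist(),
                "pooled_cov": self.pooled_cov.tolist(),
                "priors": list(self.priors),
                "ridge": self.ridge,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "LDAModel":
        doc = json.loads(text)
        if doc.get("model") != "lda":
            raise InputError("not a serialized LDA model")
        return cls(
            mean_pos=np.array(doc["mean_pos"]),
            mean_neg=np.array(doc["mean_neg"]),
            pooled_cov=np.array(doc["pooled_cov"]),
            priors=tuple(doc["priors"]),
            ridge=float(doc["ridge"]),
            feature_names=tuple(doc["feature_names"]),
        )


@dataclass
class PredictionResult:
    """Prediction for one subject, with the audit trail for voting mode."""

    subject_id: str
    label: str
    posterior_pos: float
    votes: list[str] | None = None

    @property
    def vote_count_pos(self) -> int | None:
        if self.votes is None:
            return None
        return sum(v == POSITIVE for v in self.votes)


def _check_xy(X: np.ndarray, y: np.ndarray):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise InputError("X must be n x p with matching labels")
    if not np.all(np.isfinite(X)):
        raise InputError("feature matrix contains non-finite values")
    if set(np.unique(y)) != {0, 1}:
        raise ClassError("both classes must be present (labels 0 and 1)")
    return X, y


def fit_lda(
    X: np.ndarray,
    y: np.ndarray,
    priors: str | tuple[float, float] = "empirical",
    ridge: float = 0.0,
    feature_names: tuple[str, ...] = FEATURE_NAMES_V1,
) -> LDAModel:
    """Fit two-class LDA; y uses 1 = responder (positive class).

    The pooled covariance uses the unbiased n-2 denominator.  If the
    covariance is numerically singular and no ridge was given, a fallback
    loading of ``1e-6 * trace(S)/p`` is applied.
    """
    X, y = _check_xy(X, y)
    n, p = X.shape
    if n < p + 2:
        raise InputError(f"need n >= p+2 subjects to pool covariance (n={n}, p={p})")
    pos, neg = X[y == 1], X[y == 0]
    mu_pos, mu_neg = pos.mean(axis=0), neg.mean(axis=0)
    scatter = (pos - mu_pos).T @ (pos - mu_pos) + (neg - mu_neg).T @ (neg - mu_neg)
    cov = scatter / (n - 2)
    if priors == "empirical":
        pri = (len(pos) / n, len(neg) / n)
    elif priors == "equal":
        pri = (0.5, 0.5)
    else:
        pri = (float(priors[0]), float(priors[1]))
    try:
        return LDAModel(mu_pos, mu_neg, cov, pri, ridge=ridge,
                        feature_names=feature_names)
    except ConditioningError:
        if ridge > 0:
            raise
        fallback = 1e-6 * float(np.trace(cov)) / p
        if fallback <= 0:
            raise
        return LDAModel(mu_pos, mu_neg, cov, pri, ridge=fallback,
                        feature_names=feature_names)


def predict_lda(model: LDAModel, x: np.ndarray) -> tuple[str, float]:
    """Label and positive-class posterior for one feature vector.

    A posterior of exactly 0.5 predicts non-responder — the conservative
    choice of not promising treatment benefit on a coin flip.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InputError("feature vector contains non-finite values")
    score = model.discriminant(x)
    posterior = 1.0 / (1.0 + np.exp(-np.clip(score, -700, 700)))
    label = POSITIVE if posterior > 0.5 else NEGATIVE
    return label, float(posterior)


def _subject_ids(val_X, ids):
    if ids is not None:
        return list(ids)
    return [f"S{i + 1}" for i in range(len(val_X))]


def classify_single(
    train_X: np.ndarray,
    train_y: np.ndarray,
    val_X: np.ndarray,
    subject_ids: list[str] | None = None,
    **fit_kwargs,
) -> list[PredictionResult]:
    """Validation scheme A: one model trained on all n training subjects."""
    model = fit_lda(train_X, train_y, **fit_kwargs)
    val_X = np.atleast_2d(np.asarray(val_X, dtype=float))
    results = []
    for sid, x in zip(_subject_ids(val_X, subject_ids), val_X):
        label, post = predict_lda(model, x)
        results.append(PredictionResult(sid, label, post))
    return results


def classify_voting(
    train_X: np.ndarray,
    train_y: np.ndarray,
    val_X: np.ndarray,
    subject_ids: list[str] | None = None,
    **fit_kwargs,
) -> list[PredictionResult]:
    """Validation scheme B: majority vote of the n leave-one-out models.

    Each of the n fold models (trained with one training subject withheld)
    votes on every validation subject.  Ties — possible when n is even —
    are broken by the sign of the mean fold discriminant score, i.e. by the
    ensemble's pooled evidence.  The reported posterior is the mean fold
    posterior.
    """
    X, y = _check_xy(train_X, train_y)
    n = len(y)
    models = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            raise ClassError(
                f"leave-one-out fold {i} loses a class; cannot form the ensemble"
            )
        models.append(fit_lda(X[mask], y[mask], **fit_kwargs))
    val_X = np.atleast_2d(np.asarray(val_X, dtype=float))
    results = []
    for sid, x in zip(_subject_ids(val_X, subject_ids), val_X):
        votes, posts, scores = [], [], []
        for m in models:
            label, post = predict_lda(m, x)
            votes.append(label)
            posts.append(post)
            scores.append(m.discriminant(x))
        n_pos = sum(v == POSITIVE for v in votes)
        if n_pos * 2 > n:
            label = POSITIVE
        elif n_pos * 2 < n:
            label = NEGATIVE
        else:  # tie: pooled discriminant evidence decides
            label = POSITIVE if float(np.mean(scores)) > 0 else NEGATIVE
        results.append(
            PredictionResult(sid, label, float(np.mean(posts)), votes=votes)
        )
    return results


# --- logistic regression and stepwise selection -------------------------


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic regression (intercept first)."""

    coef: np.ndarray
    se: np.ndarray
    deviance: float
    n_iter: int
    converged: bool


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """IRLS fit of logit P(y=1) = b0 + X b; detects complete separation.

    Separation is flagged when fitted probabilities approach 0/1 on the
    correct side for every observation while coefficients diverge.
    """
    X, y = _check_xy(X, y) if X.size else (np.asarray(X, float), np.asarray(y, int))
    n, p = X.shape
    if n <= p + 1:
        raise InputError(f"need n > p+1 for logistic fit (n={n}, p={p})")
    design = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    deviance = np.inf
    sign = 2 * y - 1

    def check_separation(eta_now: np.ndarray):
        # Diverging coefficients with every observation on its own side of
        # the boundary mean the MLE does not exist.
        if np.max(np.abs(beta)) > 25 and np.min(sign * eta_now) >= 0:
            raise SeparationError("perfect separation: logistic MLE does not exist")

    for it in range(1, max_iter + 1):
        eta = np.clip(design @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        check_separation(eta)
        wsafe = np.maximum(w, 1e-10)
        z = eta + (y - mu) / wsafe
        wd = design * wsafe[:, None]
        try:
            beta_new = np.linalg.solve(design.T @ wd, wd.T @ z)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "singular weighted design (separation or collinearity)"
            ) from None
        eta_new = np.clip(design @ beta_new, -35, 35)
        mu_new = np.clip(1.0 / (1.0 + np.exp(-eta_new)), 1e-12, 1 - 1e-12)
        dev_new = -2.0 * float(
            np.sum(y * np.log(mu_new) + (1 - y) * np.log(1 - mu_new))
        )
        beta = beta_new
        if abs(deviance - dev_new) < tol:
            deviance = dev_new
            break
        deviance = dev_new
    else:
        it = max_iter
    eta = design @ beta
    if np.max(np.abs(beta)) > 25 and np.min(sign * eta) >= 0:
        raise SeparationError("perfect separation: logistic MLE does not exist")
    eta = np.clip(eta, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1 - mu), 1e-12)
    info = design.T @ (design * w[:, None])
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return LogisticFit(
        coef=beta, se=se, deviance=deviance, n_iter=it,
        converged=abs(deviance) < np.inf,
    )


def _null_deviance(y: np.ndarray) -> float:
    mu = np.clip(np.mean(y), 1e-12, 1 - 1e-12)
    return -2.0 * float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def _stepwise_once(
    X: np.ndarray,
    y: np.ndarray,
    alpha_enter: float,
    alpha_remove: float,
    max_steps: int = 50,
) -> list[int]:
    """Forward-backward stepwise by likelihood-ratio p-values.

    Returns the selected column indices.  Candidates whose fit hits
    separation are treated as unselectable in that step (unstable MLE).
    """
    n, k = X.shape
    selected: list[int] = []
    deviances = {(): _null_deviance(y)}

    def dev_of(cols: tuple[int, ...]) -> float | None:
        if cols not in deviances:
            try:
                deviances[cols] = fit_logistic(X[:, list(cols)], y).deviance
            except SeparationError:
                deviances[cols] = None
        return deviances[cols]

    for _ in range(max_steps):
        changed = False
        # forward
        current = dev_of(tuple(selected))
        if current is not None:
            best_p, best_j = None, None
            for j in range(k):
                if j in selected:
                    continue
                cand = dev_of(tuple(sorted(selected + [j])))
                if cand is None:
                    continue
                lr = max(current - cand, 0.0)
                pval = float(stats.chi2.sf(lr, df=1))
                if best_p is None or pval < best_p:
                    best_p, best_j = pval, j
            if best_p is not None and best_p < alpha_enter:
                selected.append(best_j)
                selected.sort()
                changed = True
        # backward
        if selected:
            current = dev_of(tuple(selected))
            worst_p, worst_j = None, None
            for j in selected:
                reduced = tuple(c for c in selected if c != j)
                red_dev = dev_of(reduced)
                if current is None or red_dev is None:
                    continue
                lr = max(red_dev - current, 0.0)
                pval = float(stats.chi2.sf(lr, df=1))
                if worst_p is None or pval > worst_p:
                    worst_p, worst_j = pval, j
            if worst_p is not None and worst_p > alpha_remove:
                selected.remove(worst_j)
                changed = True
        if not changed:
            break
    return selected


@dataclass
class SelectionResult:
    """Outcome of leave-one-out stepwise selection."""

    selected: list[int]  # candidate indices chosen in > vote_threshold of folds
    frequency: np.ndarray  # per-candidate fraction of folds selecting it
    trace: list[list[int]] = field(repr=False, default_factory=list)


def stepwise_select_loo(
    X: np.ndarray,
    y: np.ndarray,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
    vote_threshold: float = 0.5,
) -> SelectionResult:
    """Stepwise logistic selection repeated over all leave-one-out folds.

    Within each of the n folds, forward-backward stepwise logistic
    regression (likelihood-ratio criterion) picks a predictor subset; a
    candidate is retained overall when selected in more than
    ``vote_threshold`` of the folds.  Returned candidates are ranked by
    selection frequency.
    """
    X, y = _check_xy(X, y)
    n, k = X.shape
    if n < 20:
        raise InputError("leave-one-out stepwise selection needs n >= 20")
    counts = np.zeros(k)
    trace = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            raise ClassError(f"fold {i} loses a class")
        chosen = _stepwise_once(X[mask], y[mask], alpha_enter, alpha_remove)
        trace.append(chosen)
        for j in chosen:
            counts[j] += 1
    freq = counts / n
    selected = [int(j) for j in np.argsort(-freq) if freq[j] > vote_threshold]
    return SelectionResult(selected=selected, frequency=freq, trace=trace)


def evaluate_feature_matrix(
    train: FeatureMatrix,
    validation: FeatureMatrix,
    mode: str = "voting",
    **fit_kwargs,
) -> list[PredictionResult]:
    """Classify a validation table with a training table (header-checked)."""
    if train.feature_names != validation.feature_names:
        raise InputError(
            "training and validation feature tables have different headers"
        )
    if train.labels is None:
        raise InputError("training table has no labels")
    fit_kwargs.setdefault("feature_names", train.feature_names)
    classify = {"single": classify_single, "voting": classify_voting}.get(mode)
    if classify is None:
        raise ParameterError(f"unknown validation mode {mode!r}")
    return classify(
        train.values, train.labels, validation.values,
        subject_ids=list(validation.subject_ids), **fit_kwargs,
    )
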