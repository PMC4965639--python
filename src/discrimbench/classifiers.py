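"""The two competing classifiers: binary logistic regression and two-group
linear discriminant analysis.

Both models consume the same design matrix built from a :class:`Cohort`:
binary predictors enter as their 0/1 codes, continuous predictors as-is, and
k-level categoricals as k-1 dummy indicators with the first level as the
reference.  This is the classical device of scoring a categorical
characteristic 1 when present and 0 when absent and then treating the
indicator like any continuous variable.

Logistic regression is fitted by iteratively reweighted least squares (IRLS)
to the maximum-likelihood estimates; convergence is declared when the largest
coefficient update falls below 1e-8, with a 100-iteration cap.  Complete
separation — a real possibility in subsamples of 50 — is reported through the
``converged`` flag and a warning rather than an exception, and the model
still emits (extreme but finite) probabilities.

LDA is fitted in closed form.  With group means mu_i, pooled within-group
covariance S (denominator n - 2 for two groups) and priors pi_i, each case
gets a linear classification score

    Z_i = a_i + w_i' x,   w_i = S^{-1} mu_i,
    a_i = -(1/2) mu_i' S^{-1} mu_i + log(pi_i),

and is assigned to the group with the highest score.  The posterior
probability of group 1 implied by the same Gaussian shared-covariance model
is logit^{-1}(Z_1 - Z_0); the B and Q indices consume these posteriors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .cohort import Cohort, CohortError

INTERCEPT = "(intercept)"


class FitError(ValueError):
    """The requested fit is impossible on this cohort."""


class SeparationWarning(UserWarning):
    """Logistic coefficients diverged (complete or quasi-complete separation)."""


def design_matrix(cohort: Cohort) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Build the (intercept-free) design matrix for a cohort.

    Returns the matrix, its column names, and a map from design column back
    to the source predictor (dummies of one categorical share a source).
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    source: dict[str, str] = {}
    for p in cohort.schema:
        v = cohort.data[p.name].to_numpy(dtype=float)
        if p.kind == "categorical":
            # reference level dropped to keep the design full rank
            for code in range(1, len(p.levels)):
                names.append(f"{p.name}[{p.levels[code]}]")
                source[names[-1]] = p.name
                cols.append((v == code).astype(float))
        else:
            names.append(p.name)
            source[p.name] = p.name
            cols.append(v)
    if not cols:
        raise FitError("cohort has no predictors")
    return np.column_stack(cols), names, source


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise FitError("outcome has a single class; both groups must be present")


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood: -log(1+exp(-(2y-1)eta))
    s = (2 * y - 1) * eta
    return float(-np.logaddexp(0.0, -s).sum())


@dataclass(frozen=True)
class LogisticModel:
    """Fitted binary logistic regression on the logit scale."""

    intercept: float
    coefficients: dict[str, float]
    converged: bool
    n_iterations: int
    log_likelihood: float
    standard_errors: dict[str, float]
    loglik_path: tuple[float, ...]
    design_columns: tuple[str, ...]
    column_source: dict[str, str]

    def wald_p_values(self) -> dict[str, float]:
        """Two-sided Wald p-value per design column (intercept included)."""
        from scipy.stats import norm

        out = {}
        for name in (INTERCEPT, *self.design_columns):
            beta = self.intercept if name == INTERCEPT else self.coefficients[name]
            se = self.standard_errors[name]
            z = beta / se if se > 0 and np.isfinite(se) else np.inf
            out[name] = float(2 * norm.sf(abs(z)))
        return out


@dataclass(frozen=True)
class Prediction:
    """Per-record probability of group 1 and hard 0/1 label.

    The label is 1 exactly when the group-1 criterion wins; a tie
    (probability exactly 0.5, or equal classification scores) also goes to
    group 1 so that classification error is deterministic.
    """

    probabilities: np.ndarray
    labels: np.ndarray


def fit_logistic(cohort: Cohort, tol: float = 1e-8, max_iter: int = 100) -> LogisticModel:
    """Maximum-likelihood logistic fit by IRLS.

    Raises :class:`FitError` on a single-class outcome or a rank-deficient
    design.  On separation the coefficient path diverges; the fit stops at
    the iteration cap, flags ``converged=False``, and warns.
    """
    y = cohort.outcome
    _check_two_classes(y)
    X0, names, source = design_matrix(cohort)
    X = np.column_stack([np.ones(len(y)), X0])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError(f"design matrix is rank-deficient (columns: {names})")

    beta = np.zeros(X.shape[1])
    path: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        # weighted least-squares step on the working response
        z = eta + (y - mu) / w
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        path.append(_log_likelihood(y, X @ beta))
        if step < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            "logistic fit did not converge within "
            f"{max_iter} iterations; coefficients may be diverging "
            "(complete or quasi-complete separation)",
            SeparationWarning,
            stacklevel=2,
        )

    mu = expit(X @ beta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
        ses = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        ses = np.full(X.shape[1], np.nan)
    return LogisticModel(
        intercept=float(beta[0]),
        coefficients={n: float(b) for n, b in zip(names, beta[1:])},
        converged=converged,
        n_iterations=it,
        log_likelihood=path[-1],
        standard_errors={n: float(s) for n, s in zip([INTERCEPT, *names], ses)},
        loglik_path=tuple(path),
        design_columns=tuple(names),
        column_source=source,
    )


def _aligned_design(model_columns: tuple[str, ...], cohort: Cohort) -> np.ndarray:
    X, names, _ = design_matrix(cohort)
    if tuple(names) != tuple(model_columns):
        unknown = set(names) ^ set(model_columns)
        raise FitError(
            f"cohort columns do not match the fitted model (mismatch: {sorted(unknown)})"
        )
    return X


def predict_logistic(model: LogisticModel, cohort: Cohort) -> Prediction:
    """probabilities = logit^{-1}(b0 + sum b_j x_j); labels by the 0.5 rule."""
    X = _aligned_design(model.design_columns, cohort)
    beta = np.array([model.coefficients[n] for n in model.design_columns])
    p = expit(model.intercept + X @ beta)
    return Prediction(probabilities=p, labels=(p >= 0.5).astype(int))


@dataclass(frozen=True)
class LDAModel:
    """Fitted two-group linear discriminant: per-group score coefficients."""

    group_constants: tuple[float, float]
    group_weights: tuple[np.ndarray, np.ndarray]
    priors: tuple[float, float]
    pooled_covariance: np.ndarray
    group_means: tuple[np.ndarray, np.ndarray]
    design_columns: tuple[str, ...]
    column_source: dict[str, str]


def fit_lda(cohort: Cohort, equal_priors: bool = False) -> LDAModel:
    """Closed-form two-group LDA with pooled within-group covariance.

    Priors default to the empirical class proportions; ``equal_priors``
    forces 1/2 each.  A singular pooled covariance (e.g. a constant or
    aliased predictor after categorization) raises :class:`FitError` naming
    the predictor set.
    """
    y = cohort.outcome
    _check_two_classes(y)
    X, names, source = design_matrix(cohort)
    n = len(y)
    means = []
    scatter = np.zeros((X.shape[1], X.shape[1]))
    for cls in (0, 1):
        Xc = X[y == cls]
        m = Xc.mean(axis=0)
        means.append(m)
        d = Xc - m
        scatter += d.T @ d
    S = scatter / (n - 2)
    try:
        Si = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        raise FitError(f"pooled covariance is singular (predictors: {names})") from None
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > 1e12:
        raise FitError(f"pooled covariance is singular (predictors: {names})")
    if equal_priors:
        priors = (0.5, 0.5)
    else:
        p1 = float(y.mean())
        priors = (1 - p1, p1)
    weights = tuple(Si @ m for m in means)
    consts = tuple(
        float(-0.5 * m @ Si @ m + np.log(pi)) for m, pi in zip(means, priors)
    )
    return LDAModel(
        group_constants=consts,
        group_weights=weights,
        priors=priors,
        pooled_covariance=S,
        group_means=(means[0], means[1]),
        design_columns=tuple(names),
        column_source=source,
    )


def lda_scores(model: LDAModel, cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    """Per-record classification scores (Z_0, Z_1)."""
    X = _aligned_design(model.design_columns, cohort)
    z0 = model.group_constants[0] + X @ model.group_weights[0]
    z1 = model.group_constants[1] + X @ model.group_weights[1]
    return z0, z1


def predict_lda(model: LDAModel, cohort: Cohort) -> Prediction:
    """Highest-score assignment plus the Gaussian-Bayes posterior.

    Under the shared-covariance Gaussian model the posterior log-odds of
    group 1 equal Z_1 - Z_0 exactly, so the 0.5 probability rule and the
    highest-score rule give the same labels (ties to group 1).
    """
    z0, z1 = lda_scores(model, cohort)
    p = expit(z1 - z0)
    return Prediction(probabilities=p, labels=(z1 >= z0).astype(int))


# ---------------------------------------------------------------------------
# model persistence (auditable structured text)


def save_model(model: LogisticModel | LDAModel, path) -> None:
    if isinstance(model, LogisticModel):
        doc = {
            "type": "lr",
            "intercept": model.intercept,
            "coefficients": model.coefficients,
            "converged": model.converged,
            "n_iterations": model.n_iterations,
            "log_likelihood": model.log_likelihood,
            "standard_errors": model.standard_errors,
            "loglik_path": list(model.loglik_path),
            "design_columns": list(model.design_columns),
            "column_source": model.column_source,
        }
    else:
        doc = {
            "type": "lda",
            "group_constants": list(model.group_constants),
            "group_weights": [w.tolist() for w in model.group_weights],
            "priors": list(model.priors),
            "pooled_covariance": model.pooled_covariance.tolist(),
            "group_means": [m.tolist() for m in model.group_means],
            "design_columns": list(model.design_columns),
            "column_source": model.column_source,
        }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_model(path) -> LogisticModel | LDAModel:
    with open(path) as fh:
        doc = json.load(fh)
    kind = doc.get("type")
    if kind == "lr":
        return LogisticModel(
            intercept=doc["intercept"],
            coefficients=doc["coefficients"],
            converged=doc["converged"],
            n_iterations=doc["n_iterations"],
            log_likelihood=doc["log_likelihood"],
            standard_errors=doc["standard_errors"],
            loglik_path=tuple(doc["loglik_path"]),
            design_columns=tuple(doc["design_columns"]),
            column_source=doc["column_source"],
        )
    if kind == "lda":
        return LDAModel(
            group_constants=tuple(doc["group_constants"]),
            group_weights=tuple(np.array(w) for w in doc["group_weights"]),
            priors=tuple(doc["priors"]),
            pooled_covariance=np.array(doc["pooled_covariance"]),
            group_means=tuple(np.array(m) for m in doc["group_means"]),
            design_columns=tuple(doc["design_columns"]),
            column_source=doc["column_source"],
        )
    raise CohortError(f"{path}: unknown model type {kind!r}")
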