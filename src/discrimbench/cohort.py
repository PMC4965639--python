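"""Synthetic cohort generation and cohort I/O.

The study population this package emulates is a clinical cross-section of
cancer patients (n = 243) with a binary depression outcome and three
predictors retained by a screening logistic fit: satisfaction with one's
condition (binary), family history of depression (binary), and duration of
cancer in years (continuous, positive).  The original data were never
deposited, so every analysis here runs on synthetic cohorts drawn from one
of two explicit generating regimes:

``logistic``
    Predictors are drawn from their marginal distributions and the outcome
    from a Bernoulli whose probability is the inverse-logit of a linear
    predictor.  Logistic regression is the true model; LDA is misspecified.

``lda_gaussian``
    Class membership is drawn first, then continuous predictors from
    class-conditional Gaussians sharing one covariance matrix and binary
    predictors from class-conditional Bernoullis.  LDA's assumptions hold
    for the continuous block; logistic regression remains well-specified
    because the class log-posterior ratio is linear in the predictors.

All randomness flows from a single integer seed, making every cohort (and
everything fitted to it downstream) bit-reproducible.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

OUTCOME = "outcome"

_KINDS = ("binary", "categorical", "continuous")


class CohortError(ValueError):
    """Invalid cohort configuration, schema, or file content."""


@dataclass(frozen=True)
class Predictor:
    """One column of the predictor schema.

    ``levels`` is required for (and restricted to) categorical predictors;
    binary predictors are encoded 0/1 and treated as continuous inputs by
    both classifiers, following the standard dummy-variable convention.
    """

    name: str
    kind: str
    levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise CohortError(f"predictor {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "categorical":
            if self.levels is None or len(self.levels) < 2:
                raise CohortError(
                    f"predictor {self.name!r}: categorical needs >= 2 levels"
                )
        elif self.levels is not None:
            raise CohortError(
                f"predictor {self.name!r}: {self.kind} predictors carry no levels"
            )


def _check_schema(schema: tuple[Predictor, ...]) -> None:
    names = [p.name for p in schema]
    if len(set(names)) != len(names):
        raise CohortError("predictor names must be unique")
    if OUTCOME in names:
        raise CohortError(f"{OUTCOME!r} is reserved for the outcome column")


@dataclass(frozen=True)
class Cohort:
    """A complete-case cohort: schema plus aligned data.

    ``data`` holds one row per subject with the binary outcome in the
    ``outcome`` column and one column per schema predictor.  Missing values
    are rejected at construction (the study excluded incomplete records).
    """

    schema: tuple[Predictor, ...]
    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_schema(self.schema)
        if OUTCOME not in self.data.columns:
            raise CohortError(f"cohort data lacks the {OUTCOME!r} column")
        for p in self.schema:
            if p.name not in self.data.columns:
                raise CohortError(f"cohort data lacks predictor column {p.name!r}")
        if self.data.isna().any().any():
            raise CohortError("cohort contains missing values")
        y = self.data[OUTCOME].to_numpy()
        if not np.isin(y, (0, 1)).all():
            raise CohortError("outcome must be coded 0/1")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def outcome(self) -> np.ndarray:
        return self.data[OUTCOME].to_numpy(dtype=int)

    def predictor(self, name: str) -> Predictor:
        for p in self.schema:
            if p.name == name:
                return p
        raise CohortError(f"no predictor named {name!r}")

    @property
    def predictor_names(self) -> list[str]:
        return [p.name for p in self.schema]

    def with_predictors(self, names: list[str]) -> "Cohort":
        """Restrict the cohort to a subset of predictors (outcome kept)."""
        keep = tuple(p for p in self.schema if p.name in set(names))
        missing = set(names) - {p.name for p in keep}
        if missing:
            raise CohortError(f"no predictor named {sorted(missing)!r}")
        cols = [OUTCOME] + [p.name for p in keep]
        return Cohort(schema=keep, data=self.data[cols].reset_index(drop=True))

    def take(self, idx: np.ndarray) -> "Cohort":
        return Cohort(schema=self.schema, data=self.data.iloc[idx].reset_index(drop=True))


@dataclass(frozen=True)
class DurationSpec:
    """Marginal distribution of the positive continuous duration predictor."""

    dist: str = "lognormal"  # or "gamma"
    params: tuple[float, float] = (1.0, 0.6)  # (mu, sigma) or (shape, scale)

    def __post_init__(self) -> None:
        if self.dist not in ("lognormal", "gamma"):
            raise CohortError(f"duration_distribution: unknown dist {self.dist!r}")
        if any(p <= 0 for p in self.params[1:]) or (
            self.dist == "gamma" and self.params[0] <= 0
        ):
            raise CohortError("duration_distribution: parameters must be positive")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.dist == "lognormal":
            return rng.lognormal(self.params[0], self.params[1], n)
        return rng.gamma(self.params[0], self.params[1], n)


@dataclass(frozen=True)
class CohortConfig:
    """Full recipe for one synthetic cohort.

    For the ``logistic`` regime: ``binary_probs`` give the marginal success
    probabilities of the binary predictors, ``duration`` the marginal of the
    continuous duration, and ``intercept``/``coefficients`` the generating
    logit-scale parameters.

    For the ``lda_gaussian`` regime: ``class_prevalence`` is P(outcome = 1);
    ``class_means`` / ``shared_covariance`` parameterise the class-conditional
    Gaussians of the continuous predictors (shared covariance across classes,
    the homogeneity LDA assumes); ``class_binary_probs`` give per-class
    Bernoulli probabilities of the binary predictors.
    """

    n: int = 243
    regime: str = "logistic"
    seed: int = 0
    # logistic regime
    binary_probs: dict[str, float] = field(
        default_factory=lambda: {"satisfaction": 0.5, "family_history": 0.25}
    )
    duration: DurationSpec | None = field(default_factory=DurationSpec)
    intercept: float = -0.6
    coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "satisfaction": -1.3,
            "family_history": 1.5,
            "duration": 0.18,
        }
    )
    # lda_gaussian regime
    class_prevalence: float = 0.4
    class_means: dict[int, dict[str, float]] = field(
        default_factory=lambda: {0: {"duration": 2.8}, 1: {"duration": 3.6}}
    )
    shared_covariance: tuple[tuple[float, ...], ...] = ((2.0,),)
    class_binary_probs: dict[int, dict[str, float]] = field(
        default_factory=lambda: {
            0: {"satisfaction": 0.55, "family_history": 0.20},
            1: {"satisfaction": 0.40, "family_history": 0.32},
        }
    )

    def __post_init__(self) -> None:
        if not isinstance(self.n, numbers.Integral) or self.n <= 0:
            raise CohortError("n: must be a positive integer")
        if self.regime not in ("logistic", "lda_gaussian"):
            raise CohortError(f"regime: unknown regime {self.regime!r}")
        for name, p in self.binary_probs.items():
            if not 0 < p < 1:
                raise CohortError(f"binary_probs[{name!r}]: must lie in (0, 1)")
        if self.regime == "lda_gaussian":
            if not 0 < self.class_prevalence < 1:
                raise CohortError("class_prevalence: must lie in (0, 1)")
            cov = np.asarray(self.shared_covariance, dtype=float)
            if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
                raise CohortError("shared_covariance: must be a square matrix")
            if not np.allclose(cov, cov.T):
                raise CohortError("shared_covariance: must be symmetric")
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise CohortError("shared_covariance: must be positive-definite")
            for cls in (0, 1):
                for name, p in self.class_binary_probs.get(cls, {}).items():
                    if not 0 < p < 1:
                        raise CohortError(
                            f"class_binary_probs[{cls}][{name!r}]: must lie in (0, 1)"
                        )
            cont = sorted(self.class_means.get(0, {}))
            if cont != sorted(self.class_means.get(1, {})):
                raise CohortError("class_means: both classes need the same predictors")
            if len(cont) != cov.shape[0]:
                raise CohortError(
                    "shared_covariance: dimension must match the continuous predictors"
                )

    def schema(self) -> tuple[Predictor, ...]:
        if self.regime == "logistic":
            binary = sorted(self.binary_probs)
            cont = ["duration"] if self.duration is not None else []
        else:
            binary = sorted(self.class_binary_probs.get(0, {}))
            cont = sorted(self.class_means.get(0, {}))
        return tuple(
            [Predictor(b, "binary") for b in binary]
            + [Predictor(c, "continuous") for c in cont]
        )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw one cohort from the configured generating regime.

    Deterministic given ``config`` (the seed included): re-running with the
    same configuration yields a bit-identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    schema = config.schema()
    if config.regime == "logistic":
        cols: dict[str, np.ndarray] = {}
        for name in sorted(config.binary_probs):
            cols[name] = (rng.random(config.n) < config.binary_probs[name]).astype(int)
        if config.duration is not None:
            cols["duration"] = config.duration.draw(rng, config.n)
        eta = np.full(config.n, config.intercept, dtype=float)
        for name, beta in config.coefficients.items():
            if name not in cols:
                raise CohortError(f"coefficients[{name!r}]: no such generated predictor")
            eta += beta * cols[name]
        y = (rng.random(config.n) < expit(eta)).astype(int)
    else:
        y = (rng.random(config.n) < config.class_prevalence).astype(int)
        cols = {}
        cont = sorted(config.class_means[0])
        if cont:
            cov = np.asarray(config.shared_covariance, dtype=float)
            means = np.array(
                [[config.class_means[c][v] for v in cont] for c in (0, 1)]
            )
            draws = rng.multivariate_normal(
                np.zeros(len(cont)), cov, size=config.n, method="cholesky"
            )
            draws += means[y]
            for j, v in enumerate(cont):
                cols[v] = draws[:, j]
        for name in sorted(config.class_binary_probs.get(0, {})):
            p = np.where(
                y == 1,
                config.class_binary_probs[1][name],
                config.class_binary_probs[0][name],
            )
            cols[name] = (rng.random(config.n) < p).astype(int)
    data = pd.DataFrame({OUTCOME: y, **{p.name: cols[p.name] for p in schema}})
    return Cohort(schema=schema, data=data)


def paper_like(seed: int = 0, n: int = 243) -> CohortConfig:
    """The default study-like preset: three predictors, total-sample
    misclassification near one third under the generating model."""
    return CohortConfig(n=n, seed=seed, regime="logistic")


def lda_paper_like(seed: int = 0, n: int = 243) -> CohortConfig:
    """Same predictors, but generated under LDA's own assumptions."""
    return CohortConfig(n=n, seed=seed, regime="lda_gaussian")


def categorize_duration(
    cohort: Cohort, cutpoints: list[float], column: str = "duration"
) -> Cohort:
    """Replace a continuous column by an ordinal categorical.

    Intervals are left-closed/right-open: level k covers
    [cutpoints[k-1], cutpoints[k]).  The input cohort is not modified.
    """
    if not cutpoints:
        raise CohortError("cutpoints: must be a nonempty strictly increasing list")
    cuts = [float(c) for c in cutpoints]
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise CohortError("cutpoints: must be strictly increasing")
    pred = cohort.predictor(column)
    if pred.kind != "continuous":
        raise CohortError(f"predictor {column!r} is {pred.kind}, not continuous")
    values = cohort.data[column].to_numpy(dtype=float)
    codes = np.digitize(values, cuts, right=False)
    levels = tuple(str(k) for k in range(len(cuts) + 1))
    new_pred = Predictor(column, "categorical", levels)
    schema = tuple(new_pred if p.name == column else p for p in cohort.schema)
    data = cohort.data.copy()
    data[column] = codes
    return Cohort(schema=schema, data=data)


def empirical_tertiles(cohort: Cohort, column: str = "duration") -> list[float]:
    """Default categorization cutpoints: the empirical tertiles."""
    values = cohort.data[column].to_numpy(dtype=float)
    return list(np.quantile(values, [1 / 3, 2 / 3]))


# ---------------------------------------------------------------------------
# CSV + YAML-sidecar I/O


def write_cohort(cohort: Cohort, path) -> None:
    cohort.data.to_csv(path, index=False)


def write_schema(schema: tuple[Predictor, ...], path) -> None:
    doc = {
        p.name: (
            {"kind": p.kind, "levels": list(p.levels)}
            if p.kind == "categorical"
            else {"kind": p.kind}
        )
        for p in schema
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_schema(path) -> tuple[Predictor, ...]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise CohortError(f"schema file {path}: expected a mapping of predictors")
    preds = []
    for name, spec in doc.items():
        kind = spec.get("kind")
        levels = tuple(str(l) for l in spec["levels"]) if "levels" in spec else None
        preds.append(Predictor(str(name), kind, levels))
    return tuple(preds)


def read_cohort(path, schema: tuple[Predictor, ...]) -> Cohort:
    """Read a cohort CSV against a known schema.

    Schema/file mismatches (missing columns, non-numeric continuous values,
    out-of-range categorical codes) are reported with the offending column
    and data row number (1-based, excluding the header).
    """
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if OUTCOME not in raw.columns:
        raise CohortError(f"{path}: missing required column {OUTCOME!r}")
    for p in schema:
        if p.name not in raw.columns:
            raise CohortError(f"{path}: missing predictor column {p.name!r}")
    unknown = set(raw.columns) - {OUTCOME} - {p.name for p in schema}
    if unknown:
        raise CohortError(f"{path}: unknown column {sorted(unknown)[0]!r}")

    def _numeric(col: str, integer: bool) -> np.ndarray:
        # exact round-trip parsing (pandas' fast string parser drops ulps)
        out = np.empty(len(raw), dtype=int if integer else float)
        for i, v in enumerate(raw[col].tolist()):
            try:
                out[i] = int(v) if integer else float(v)
            except (TypeError, ValueError):
                raise CohortError(
                    f"{path}: non-numeric value in column {col!r}, row {i + 1}"
                ) from None
        return out

    cols = {OUTCOME: _numeric(OUTCOME, integer=True)}
    for p in schema:
        if p.kind == "continuous":
            cols[p.name] = _numeric(p.name, integer=False)
        else:
            vals = _numeric(p.name, integer=True)
            hi = 1 if p.kind == "binary" else len(p.levels) - 1
            bad = (vals < 0) | (vals > hi)
            if bad.any():
                row = int(np.flatnonzero(bad)[0]) + 1
                raise CohortError(
                    f"{path}: value out of range for {p.kind} column {p.name!r}, row {row}"
                )
            cols[p.name] = vals
    return Cohort(schema=schema, data=pd.DataFrame(cols))
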