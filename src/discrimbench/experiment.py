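"""The subsampling comparison design.

The study design this module reproduces: starting from a base cohort
(n = 243 in the default preset), a screening logistic fit on the full cohort
selects the predictors that matter; then, for each of two independent series,
simple random subsamples WITHOUT replacement are drawn at sizes 50, 100, 150,
200 and 220; on each subsample both classifiers are fitted and scored — by
resubstitution, on that same subsample — with the CE, B and Q indices; a
total-sample row (the full base cohort) closes each series.  A variant
repeats the whole design after categorizing the continuous duration
predictor, isolating the effect of categorization.

Scoring is by resubstitution because the design reports one index triple per
subsample with no hold-out: the total-sample rows are then identical across
series, which is the signature of evaluating on the fixed full cohort.

Subsample index sets are derived deterministically from (seed, series, size)
alone — not from the cohort's values — so a categorized run with the same
seed reuses exactly the same subjects as the uncategorized run, making the
two tables row-for-row comparable.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .classifiers import (
    FitError,
    SeparationWarning,
    fit_lda,
    fit_logistic,
    predict_lda,
    predict_logistic,
)
from .cohort import Cohort, CohortError, categorize_duration, empirical_tertiles
from .indices import IndexReport, index_report

MODELS = ("LR", "LDA")
TOTAL = "total"


class ExperimentError(ValueError):
    """Invalid experiment configuration or unusable base cohort."""


@dataclass(frozen=True)
class ExperimentConfig:
    """Knobs of the comparison design (defaults mirror the study)."""

    sizes: tuple[int, ...] = (50, 100, 150, 200, 220)
    n_series: int = 2
    include_total_row: bool = True
    selection_alpha: float = 0.05
    select: bool = True
    seed: int = 0
    equal_priors: bool = False
    q_mode: str = "strict"
    replicates: int = 1  # >1 averages each cell over independent subsamples
    cutpoints: tuple[float, ...] | None = None  # categorized variant; None = tertiles

    def __post_init__(self) -> None:
        if self.n_series < 1:
            raise ExperimentError("n_series: must be >= 1")
        if self.replicates < 1:
            raise ExperimentError("replicates: must be >= 1")
        if any(s <= 0 for s in self.sizes):
            raise ExperimentError("sizes: must be positive")
        if not 0 < self.selection_alpha <= 1:
            raise ExperimentError("selection_alpha: must lie in (0, 1]")


@dataclass(frozen=True)
class Cell:
    """One (series, size, model) slot: an index report or a failure marker."""

    report: IndexReport | None = None
    failure: str | None = None

    @property
    def ok(self) -> bool:
        return self.report is not None


@dataclass
class ComparisonTable:
    """Rows keyed by (series, size-or-'total'); one LR and one LDA cell each."""

    rows: dict[tuple[int, int | str], dict[str, Cell]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def row_keys(self) -> list[tuple[int, int | str]]:
        return list(self.rows.keys())


def select_predictors(cohort: Cohort, alpha: float = 0.05) -> list[str]:
    """Screen predictors with the full-cohort logistic fit.

    A predictor is retained when any of its design columns has a two-sided
    Wald p-value below ``alpha`` (for a k-level categorical, any of its
    dummies).  The underlying study states no selection criterion, only that
    a logistic fit picked the influential variables; the Wald screen is this
    package's concrete rule.  Deterministic given the cohort.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("error", SeparationWarning)
        try:
            model = fit_logistic(cohort)
        except SeparationWarning as w:
            raise ExperimentError(
                f"predictor selection aborted: full logistic fit did not converge ({w})"
            ) from None
    pvals = model.wald_p_values()
    selected = []
    for p in cohort.schema:
        cols = [c for c in model.design_columns if model.column_source[c] == p.name]
        if any(pvals[c] < alpha for c in cols):
            selected.append(p.name)
    return selected


def subsample(cohort: Cohort, n: int, rng: np.random.Generator) -> Cohort:
    """Simple random sample without replacement, both classes guaranteed.

    Draws are retried (fresh indices from the same stream) up to 100 times
    if one outcome class is absent, then an error is raised.
    """
    if n > cohort.n:
        raise ExperimentError(f"subsample size {n} exceeds base cohort size {cohort.n}")
    for _ in range(100):
        idx = rng.choice(cohort.n, size=n, replace=False)
        sub = cohort.take(idx)
        if len(np.unique(sub.outcome)) == 2:
            return sub
    raise ExperimentError(
        f"could not draw a subsample of {n} containing both classes in 100 attempts"
    )


def _cell_pair(sub: Cohort, config: ExperimentConfig) -> dict[str, Cell]:
    """Fit LR and LDA on one subsample and score both by resubstitution."""
    y = sub.outcome
    out: dict[str, Cell] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SeparationWarning)
        try:
            lr = fit_logistic(sub)
            out["LR"] = Cell(report=index_report(predict_logistic(lr, sub), y, config.q_mode))
        except FitError as e:
            out["LR"] = Cell(failure=str(e))
    try:
        lda = fit_lda(sub, equal_priors=config.equal_priors)
        out["LDA"] = Cell(report=index_report(predict_lda(lda, sub), y, config.q_mode))
    except FitError as e:
        out["LDA"] = Cell(failure=str(e))
    return out


def _mean_cells(cells: list[dict[str, Cell]]) -> dict[str, Cell]:
    """Average replicate cells per model; any failure or undefined Q propagates."""
    out: dict[str, Cell] = {}
    for m in MODELS:
        reps = [c[m] for c in cells]
        bad = next((c for c in reps if not c.ok), None)
        if bad is not None:
            out[m] = bad
            continue
        qs = [c.report.q for c in reps]
        out[m] = Cell(
            report=IndexReport(
                ce=float(np.mean([c.report.ce for c in reps])),
                b=float(np.mean([c.report.b for c in reps])),
                q=None if any(q is None for q in qs) else float(np.mean(qs)),
                n=reps[0].report.n,
            )
        )
    return out


def _subsample_rng(seed: int, series: int, size_index: int, replicate: int):
    return np.random.default_rng([seed & 0x7FFFFFFF, series, size_index, replicate])


def _run(work: Cohort, config: ExperimentConfig, selected: list[str]) -> ComparisonTable:
    for s in config.sizes:
        if s > work.n:
            raise ExperimentError(
                f"sizes: subsample size {s} exceeds base cohort size {work.n}"
            )
    table = ComparisonTable()
    for series in range(1, config.n_series + 1):
        for k, size in enumerate(config.sizes):
            reps = []
            for r in range(config.replicates):
                rng = _subsample_rng(config.seed, series, k, r)
                try:
                    sub = subsample(work, size, rng)
                except ExperimentError as e:
                    reps.append({m: Cell(failure=str(e)) for m in MODELS})
                    continue
                reps.append(_cell_pair(sub, config))
            table.rows[(series, size)] = _mean_cells(reps)
        if config.include_total_row:
            table.rows[(series, TOTAL)] = _cell_pair(work, config)
    cfg_doc = json.dumps(
        {
            "sizes": list(config.sizes),
            "n_series": config.n_series,
            "selection_alpha": config.selection_alpha,
            "seed": config.seed,
            "equal_priors": config.equal_priors,
            "q_mode": config.q_mode,
            "replicates": config.replicates,
            "cutpoints": list(config.cutpoints) if config.cutpoints else None,
            "selected": selected,
        },
        sort_keys=True,
    )
    table.metadata = {
        "seed": config.seed,
        "selected_predictors": selected,
        "config_hash": hashlib.sha256(cfg_doc.encode()).hexdigest()[:16],
    }
    return table


def run_comparison(base: Cohort, config: ExperimentConfig) -> ComparisonTable:
    """The full design on the base cohort (duration kept continuous)."""
    if config.select:
        selected = select_predictors(base, config.selection_alpha)
        if not selected:
            raise ExperimentError(
                f"no predictor passed the Wald screen at alpha={config.selection_alpha}"
            )
    else:
        selected = base.predictor_names
    return _run(base.with_predictors(selected), config, selected)


def run_categorized_comparison(base: Cohort, config: ExperimentConfig) -> ComparisonTable:
    """The same design after categorizing duration.

    Cutpoints default to the empirical tertiles of the base cohort's
    duration.  Degenerate cutpoints that collapse duration to a single
    observed level drop the predictor with a warning rather than failing.
    Run with the same seed as :func:`run_comparison`, the subsample index
    sets are identical, so the two tables are paired row-for-row.
    """
    cuts = list(config.cutpoints) if config.cutpoints else empirical_tertiles(base)
    cat = categorize_duration(base, cuts)
    if len(np.unique(cat.data["duration"])) < 2:
        warnings.warn(
            "cutpoints collapse 'duration' to a single level; dropping it",
            UserWarning,
            stacklevel=2,
        )
        keep = [p.name for p in cat.schema if p.name != "duration"]
        if not keep:
            raise ExperimentError("no predictors left after dropping 'duration'")
        cat = cat.with_predictors(keep)
    if config.select:
        selected = select_predictors(cat, config.selection_alpha)
        if not selected:
            raise ExperimentError(
                f"no predictor passed the Wald screen at alpha={config.selection_alpha}"
            )
    else:
        selected = cat.predictor_names
    return _run(cat.with_predictors(selected), config, selected)


# ---------------------------------------------------------------------------
# rendering


def _fmt_q(cell: Cell) -> str:
    if not cell.ok:
        return f"NA({_short_reason(cell.failure)})"
    if cell.report.q is None:
        return "NA(q-undefined)"
    return f"{cell.report.q:.5f}"


def _fmt_b(cell: Cell) -> str:
    return f"{cell.report.b:.5f}" if cell.ok else f"NA({_short_reason(cell.failure)})"


def _fmt_ce(cell: Cell) -> str:
    return f"{100 * cell.report.ce:.1f}" if cell.ok else f"NA({_short_reason(cell.failure)})"


def _short_reason(msg: str) -> str:
    msg = msg or "failed"
    if "singular" in msg:
        return "singular-covariance"
    if "converge" in msg or "separation" in msg:
        return "separation"
    if "both classes" in msg or "single class" in msg:
        return "degenerate-classes"
    return msg.split(";")[0][:40].replace(",", " ")


HEADER = ["n", "Q(LR)", "Q(LDA)", "B(LR)", "B(LDA)", "%CE(LR)", "%CE(LDA)", "series"]


def render_table(table: ComparisonTable, fmt: str = "csv") -> str:
    """Render in the study's table layout.

    Columns: n, Q(LR), Q(LDA), B(LR), B(LDA), %CE(LR), %CE(LDA) (plus a
    trailing series column); Q and B to 5 decimals, CE as percent to 1
    decimal.  Failed cells render as ``NA(reason)``.
    """
    if fmt not in ("csv", "tsv", "markdown"):
        raise ExperimentError(f"unknown table format {fmt!r}")
    rows = [list(HEADER)]
    for (series, size), cells in table.rows.items():
        lr, lda = cells["LR"], cells["LDA"]
        rows.append(
            [
                "Total sample" if size == TOTAL else str(size),
                _fmt_q(lr),
                _fmt_q(lda),
                _fmt_b(lr),
                _fmt_b(lda),
                _fmt_ce(lr),
                _fmt_ce(lda),
                str(series),
            ]
        )
    if fmt == "csv":
        return "\n".join(",".join(r) for r in rows) + "\n"
    if fmt == "tsv":
        return "\n".join("\t".join(r) for r in rows) + "\n"
    out = ["| " + " | ".join(rows[0]) + " |", "|" + "---|" * len(HEADER)]
    out += ["| " + " | ".join(r) + " |" for r in rows[1:]]
    return "\n".join(out) + "\n"
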