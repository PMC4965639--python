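"""Classification indices: CE, the B index, and the Q index.

Classification error (CE) is one minus overall accuracy — the fraction of
records whose hard label disagrees with the true group.  It is the common
yardstick but a blunt one: a predicted probability of 0.51 and one of 0.99
classify a positive case identically, so CE cannot see how accurate the
probabilities themselves are.

The B index is the Brier-complement: with p_i the predicted probability of
group 1 and y_i the actual membership (1 or 0),

    B = 1 - (1/n) * sum_i (y_i - p_i)^2.

B = 1 means perfect prediction; random prediction (p = 1/2) on two equally
sized groups gives B = 0.75.

The Q index is the base-2 logarithmic score,

    Q = 1 + (1/n) * sum_i [ y_i log2(p_i) + (1 - y_i) log2(1 - p_i) ],

with Q = 1 perfect, Q = 0 random (p = 1/2), and Q < 0 worse than random.
If any predicted probability is exactly 0 or 1 the logarithm degenerates and
Q is undefined; the strict mode (default) returns the undefined marker
``None`` whenever any p_i is 0 or 1, while the lenient mode applies the
0*log(0) = 0 convention so that a perfect prediction scores Q = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifiers import Prediction

Q_MODES = ("strict", "lenient")


class IndexError_(ValueError):
    """Invalid index input (length mismatch, empty, out-of-range p)."""


def _validate(p: np.ndarray | None, labels_or_y: np.ndarray, y: np.ndarray) -> None:
    if len(labels_or_y) != len(y):
        raise IndexError_(
            f"length mismatch: {len(labels_or_y)} predictions vs {len(y)} outcomes"
        )
    if len(y) == 0:
        raise IndexError_("empty input")
    if p is not None and ((p < 0) | (p > 1)).any():
        raise IndexError_("probabilities must lie in [0, 1]")


def classification_error(labels, y) -> float:
    """Fraction of records misclassified (a proportion; tables print %)."""
    labels = np.asarray(labels)
    y = np.asarray(y)
    _validate(None, labels, y)
    return float(np.mean(labels != y))


def b_index(p, y) -> float:
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate(p, p, y)
    return float(1.0 - np.mean((y - p) ** 2))


def q_index(p, y, mode: str = "strict") -> float | None:
    """Base-2 logarithmic accuracy index, or ``None`` when undefined.

    strict: any p_i in {0, 1} makes Q undefined, even when the offending
    log term is multiplied by zero.  lenient: zero-weighted log terms
    contribute zero, so only a p_i of 0 for an actual 1 (or 1 for an actual
    0) leaves Q undefined (at -inf, also reported as ``None``).
    """
    if mode not in Q_MODES:
        raise IndexError_(f"unknown Q mode {mode!r}; expected one of {Q_MODES}")
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate(p, p, y)
    boundary = (p == 0.0) | (p == 1.0)
    if mode == "strict" and boundary.any():
        return None
    p_used = np.where(y == 1, p, 1.0 - p)  # probability assigned to the truth
    if (p_used == 0.0).any():
        return None  # a certainly-wrong prediction: -inf even leniently
    with np.errstate(divide="ignore"):
        terms = np.log2(p_used)
    return float(1.0 + terms.mean())


@dataclass(frozen=True)
class IndexReport:
    """The (CE, B, Q, n) bundle for one fitted model on one dataset.

    ``q`` is ``None`` when the Q index is undefined for the supplied
    probabilities; the marker propagates into rendered tables and is never
    silently imputed.
    """

    ce: float
    b: float
    q: float | None
    n: int


def index_report(prediction: Prediction, y, q_mode: str = "strict") -> IndexReport:
    y = np.asarray(y)
    return IndexReport(
        ce=classification_error(prediction.labels, y),
        b=b_index(prediction.probabilities, y),
        q=q_index(prediction.probabilities, y, mode=q_mode),
        n=len(y),
    )
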