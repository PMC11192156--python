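"""Classifier evaluation statistics.

Confusion matrix (actual species in rows, predicted in columns), accuracy
with an exact two-sided binomial confidence interval, Cohen's kappa, the
no-information rate, and per-class sensitivity/precision.  The exact
(Clopper-Pearson) interval is the default because it reproduces, from
(successes, n) alone, the CI digits reported by the R toolchain this
pipeline mirrors; Wilson and Wald are available behind a flag.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Dict, List, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "EvaluationReport",
    "confusion_matrix",
    "accuracy_ci",
    "cohen_kappa",
    "no_information_rate",
    "evaluate",
]


def confusion_matrix(
    actual: Sequence, predicted: Sequence, class_labels: Sequence
) -> np.ndarray:
    """Entry (i, j) counts rows with actual class i predicted as class j."""
    if len(actual) != len(predicted):
        raise ValueError(
            f"length mismatch: {len(actual)} actual vs {len(predicted)} predicted"
        )
    pos = {lab: k for k, lab in enumerate(class_labels)}
    mat = np.zeros((len(class_labels), len(class_labels)), dtype=int)
    for a, p in zip(actual, predicted):
        if a not in pos or p not in pos:
            unknown = a if a not in pos else p
            raise ValueError(f"label {unknown!r} not in class_labels")
        mat[pos[a], pos[p]] += 1
    return mat


def accuracy_ci(
    successes: int, n: int, level: float = 0.95, method: str = "clopper-pearson"
) -> tuple[float, float]:
    """Two-sided binomial confidence interval for a proportion.

    Exact bounds come from beta quantiles; the degenerate edges are closed
    form (successes = n gives upper = 1 and lower = (alpha/2)^(1/n)).
    """
    if n < 1 or not 0 <= successes <= n:
        raise ValueError(f"invalid counts: {successes}/{n}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    if method == "clopper-pearson":
        lower = 0.0 if successes == 0 else float(
            stats.beta.ppf(alpha / 2, successes, n - successes + 1)
        )
        upper = 1.0 if successes == n else float(
            stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes)
        )
        return lower, upper
    phat = successes / n
    z = float(stats.norm.ppf(1 - alpha / 2))
    if method == "wald":
        half = z * math.sqrt(phat * (1 - phat) / n)
        return max(0.0, phat - half), min(1.0, phat + half)
    if method == "wilson":
        denom = 1 + z * z / n
        centre = (phat + z * z / (2 * n)) / denom
        half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
        return centre - half, centre + half
    raise ValueError(f"unknown CI method {method!r}")


def cohen_kappa(confusion: np.ndarray) -> float:
    """kappa = (p_o - p_e) / (1 - p_e) with marginal chance agreement p_e.

    Degenerate p_e = 1 (all mass in one cell row/column product) is defined
    as 1 when observed agreement is also perfect, else 0.
    """
    mat = np.asarray(confusion, dtype=float)
    n = mat.sum()
    if mat.size == 0 or n < 1:
        raise ValueError("confusion matrix must contain at least one count")
    p_o = np.trace(mat) / n
    p_e = float((mat.sum(axis=1) * mat.sum(axis=0)).sum()) / (n * n)
    if p_e >= 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def no_information_rate(actual: Sequence) -> float:
    """Accuracy of always predicting the most frequent actual class."""
    if len(actual) == 0:
        raise ValueError("empty label list")
    _, counts = np.unique(np.asarray(actual, dtype=object), return_counts=True)
    return float(counts.max() / counts.sum())


@dataclass
class EvaluationReport:
    class_labels: List[str]
    confusion: List[List[int]]
    n: int
    accuracy: float
    ci_low: float
    ci_high: float
    ci_level: float
    kappa: float
    nir: float
    per_class: Dict[str, Dict[str, float]]

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        return cls(**json.loads(text))

    def summary_table(self) -> str:
        """Human-readable statistics block, one row per statistic."""
        lines = [
            f"Number of observations        {self.n}",
            f"Accuracy                      {self.accuracy:.4f}",
            f"{int(self.ci_level * 100)}% CI of accuracy            "
            f"({self.ci_low:.4f}, {self.ci_high:.4f})",
            f"No information rate           {self.nir:.4f}",
            f"Kappa                         {self.kappa:.4f}",
        ]
        return "\n".join(lines)


def evaluate(
    actual: Sequence,
    predicted: Sequence,
    class_labels: Sequence[str],
    ci_level: float = 0.95,
    ci_method: str = "clopper-pearson",
) -> EvaluationReport:
    """Assemble the full statistics report for one prediction set."""
    mat = confusion_matrix(actual, predicted, class_labels)
    n = int(mat.sum())
    correct = int(np.trace(mat))
    accuracy = correct / n
    lo, hi = accuracy_ci(correct, n, level=ci_level, method=ci_method)
    per_class = {}
    for k, lab in enumerate(class_labels):
        row = mat[k].sum()
        col = mat[:, k].sum()
        per_class[str(lab)] = {
            "sensitivity": float(mat[k, k] / row) if row else float("nan"),
            "precision": float(mat[k, k] / col) if col else float("nan"),
            "n_actual": int(row),
        }
    return EvaluationReport(
        class_labels=[str(c) for c in class_labels],
        confusion=mat.tolist(),
        n=n,
        accuracy=float(accuracy),
        ci_low=lo,
        ci_high=hi,
        ci_level=ci_level,
        kappa=cohen_kappa(mat),
        nir=no_information_rate(actual),
        per_class=per_class,
    )
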