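"""Evaluation metrics: top-L/k long-range contact precision, 16 Å-filtered
distance MSE, and Pearson correlation between predicted and true distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np

LONG_RANGE_SEP = 24
CONTACT_THRESHOLD = 8.0
DISTANCE_FILTER = 16.0

logger = logging.getLogger(__name__)

#: Sentinel for metrics that are undefined on the given input.
UNDEFINED = float("nan")


@dataclass
class EvaluationReport:
    precision_topL5: float
    precision_topL2: float
    precision_topL: float
    mse: float
    pearson: float
    n_pairs_evaluated: int
    min_sep: int = LONG_RANGE_SEP
    contact_threshold: float = CONTACT_THRESHOLD
    distance_filter: float = DISTANCE_FILTER
    filter_on: str = "predicted"

    def as_row(self) -> str:
        d = asdict(self)
        return "\t".join(f"{v:.4f}" if isinstance(v, float) else str(v)
                         for v in d.values())

    def summary(self) -> str:
        return ("top-L/5 {precision_topL5:.3f}  top-L/2 {precision_topL2:.3f}"
                "  top-L {precision_topL:.3f}  MSE {mse:.3f}  "
                "Pearson {pearson:.3f}  (n={n_pairs_evaluated})"
                ).format(**asdict(self))


def _long_range_pairs(L: int, min_sep: int) -> tuple[np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(L, k=min_sep)
    return iu, ju


def contact_precision(scores: np.ndarray, truth: np.ndarray, k: float,
                      min_sep: int = LONG_RANGE_SEP,
                      contact_threshold: float = CONTACT_THRESHOLD) -> float:
    """Precision of the top floor(k) long-range pairs ranked by score.

    ``k`` is the number of pairs to select (callers pass L/5, L/2 or L).
    Ties break lexicographically on (i, j) for determinism. Returns NaN
    (undefined) if no eligible pair exists.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=float)
    L = scores.shape[0]
    iu, ju = _long_range_pairs(L, min_sep)
    if iu.size == 0:
        logger.warning("no pairs with separation >= %d for L=%d", min_sep, L)
        return UNDEFINED
    n_top = min(int(k), iu.size)
    if n_top < 1:
        return UNDEFINED
    s = scores[iu, ju]
    # stable sort on (-score, i, j): lexsort with last key most significant
    order = np.lexsort((ju, iu, -s))[:n_top]
    hits = truth[iu[order], ju[order]] <= contact_threshold
    return float(hits.mean())


def _filtered_pairs(pred: np.ndarray, truth: np.ndarray, filter_on: str,
                    cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth shape mismatch")
    L = pred.shape[0]
    iu, ju = np.triu_indices(L, k=1)
    p, t = pred[iu, ju], truth[iu, ju]
    if filter_on == "predicted":
        keep = p < cutoff
    elif filter_on == "true":
        keep = t < cutoff
    else:
        raise ValueError("filter_on must be 'predicted' or 'true'")
    return p[keep], t[keep]


def filtered_mse(pred: np.ndarray, truth: np.ndarray,
                 filter_on: str = "predicted",
                 cutoff: float = DISTANCE_FILTER) -> float:
    """Mean squared Å error over upper-triangle pairs passing the filter."""
    p, t = _filtered_pairs(np.asarray(pred, float), np.asarray(truth, float),
                           filter_on, cutoff)
    if p.size == 0:
        logger.warning("filtered_mse: empty filtered pair set")
        return UNDEFINED
    return float(np.mean((p - t) ** 2))


def distance_pearson(pred: np.ndarray, truth: np.ndarray,
                     filter_on: str = "predicted",
                     cutoff: float = DISTANCE_FILTER) -> float:
    """Sample Pearson correlation over the same filtered pair set."""
    p, t = _filtered_pairs(np.asarray(pred, float), np.asarray(truth, float),
                           filter_on, cutoff)
    if p.size < 2 or p.std() == 0 or t.std() == 0:
        logger.warning("distance_pearson: undefined (n<2 or zero variance)")
        return UNDEFINED
    return float(np.corrcoef(p, t)[0, 1])


def evaluate(scores: np.ndarray, pred_dist: np.ndarray, truth: np.ndarray,
             min_sep: int = LONG_RANGE_SEP, filter_on: str = "predicted",
             cutoff: float = DISTANCE_FILTER) -> EvaluationReport:
    """Full report: top-L/5, L/2, L precision + filtered MSE + Pearson."""
    L = truth.shape[0]
    p, t = _filtered_pairs(np.asarray(pred_dist, float),
                           np.asarray(truth, float), filter_on, cutoff)
    return EvaluationReport(
        precision_topL5=contact_precision(scores, truth, L / 5, min_sep),
        precision_topL2=contact_precision(scores, truth, L / 2, min_sep),
        precision_topL=contact_precision(scores, truth, L, min_sep),
        mse=filtered_mse(pred_dist, truth, filter_on, cutoff),
        pearson=distance_pearson(pred_dist, truth, filter_on, cutoff),
        n_pairs_evaluated=int(p.size),
        min_sep=min_sep,
        distance_filter=cutoff,
        filter_on=filter_on,
    )


def aggregate_reports(reports: list[EvaluationReport]) -> EvaluationReport:
    """Mean row across per-target reports (NaN-aware)."""
    if not reports:
        raise ValueError("no reports to aggregate")
    fields = ["precision_topL5", "precision_topL2", "precision_topL",
              "mse", "pearson"]
    means = {f: float(np.nanmean([getattr(r, f) for r in reports]))
             for f in fields}
    return EvaluationReport(
        **means,
        n_pairs_evaluated=int(sum(r.n_pairs_evaluated for r in reports)),
        min_sep=reports[0].min_sep,
        distance_filter=reports[0].distance_filter,
        filter_on=reports[0].filter_on,
    )
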