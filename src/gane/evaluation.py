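"""Matching-based and clustering-wise metrics for predicted complexes.

A predicted complex p matches a reference complex b when the neighborhood
affinity score

    NA(p, b) = |V_p ∩ V_b|^2 / (|V_p| * |V_b|)

reaches the threshold omega (0.25 by convention).  From the match counts
N_cp (predictions matching >= 1 reference) and N_cb (references matching
>= 1 prediction):

    Precision = N_cp / |P|,  Recall = N_cb / |B|,
    F-score   = 2 * Precision * Recall / (Precision + Recall).

The clustering-wise view uses the overlap matrix T_ij = |b_i ∩ p_j|:

    Sn  = sum_i max_j T_ij / sum_i |b_i|
    PPV = sum_j max_i T_ij / sum_j sum_i T_ij
    Acc = sqrt(Sn * PPV)

and the composite score for overall comparison is F-score + Acc.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from math import sqrt

import numpy as np

from .io_formats import ComplexSet

logger = logging.getLogger(__name__)

DEFAULT_OMEGA = 0.25


def na_score(p, b) -> float:
    """Neighborhood affinity |p ∩ b|^2 / (|p| |b|) between two protein sets."""
    p, b = frozenset(p), frozenset(b)
    if not p or not b:
        raise ValueError("NA is undefined for empty complexes")
    inter = len(p & b)
    return inter * inter / (len(p) * len(b))


def match_counts(
    predicted: ComplexSet, reference: ComplexSet, omega: float = DEFAULT_OMEGA
) -> tuple[int, int]:
    """(N_cp, N_cb): predictions / references with an NA >= omega partner."""
    if not 0.0 < omega <= 1.0:
        raise ValueError("omega must be in (0, 1]")
    P = predicted.member_sets()
    B = reference.member_sets()
    n_cp = sum(1 for p in P if any(na_score(p, b) >= omega for b in B))
    n_cb = sum(1 for b in B if any(na_score(p, b) >= omega for p in P))
    return n_cp, n_cb


def precision_recall_f(
    n_cp: int, n_cb: int, n_pred: int, n_ref: int
) -> tuple[float, float, float]:
    """Precision, Recall, F-score from match counts.

    Degenerate conventions: an empty prediction set has Precision 0, and
    F is 0 when Precision + Recall = 0.
    """
    if n_ref < 1:
        raise ValueError("reference set must be nonempty")
    precision = n_cp / n_pred if n_pred > 0 else 0.0
    recall = n_cb / n_ref
    denom = precision + recall
    f = 2.0 * precision * recall / denom if denom > 0 else 0.0
    return precision, recall, f


def sn_ppv_acc(
    predicted: ComplexSet, reference: ComplexSet
) -> tuple[float, float, float]:
    """Clustering-wise sensitivity, positive predictive value, accuracy."""
    B = [frozenset(b) for b in reference.member_sets()]
    P = [frozenset(p) for p in predicted.member_sets()]
    if not B or not P:
        raise ValueError("both complex sets must be nonempty")
    T = np.array([[len(b & p) for p in P] for b in B], dtype=float)
    sn = float(T.max(axis=1).sum()) / float(sum(len(b) for b in B))
    t_total = float(T.sum())
    if t_total == 0.0:
        logger.warning("no overlap between predictions and references; PPV set to 0")
        return sn, 0.0, 0.0
    ppv = float(T.max(axis=0).sum()) / t_total
    return sn, ppv, sqrt(sn * ppv)


def composite(f_score: float, acc: float) -> float:
    """Overall comparison statistic: F-score + Acc."""
    return f_score + acc


@dataclass(frozen=True)
class EvaluationReport:
    n_predicted: int
    n_reference: int
    n_cp: int
    n_cb: int
    precision: float
    recall: float
    f_score: float
    sn: float
    ppv: float
    acc: float
    composite: float
    omega: float

    def to_dict(self) -> dict:
        return asdict(self)

    def format(self) -> str:
        d = self.to_dict()
        width = max(len(k) for k in d)
        lines = []
        for k, v in d.items():
            if isinstance(v, float):
                lines.append(f"{k:<{width}}  {v:.4f}")
            else:
                lines.append(f"{k:<{width}}  {v}")
        return "\n".join(lines)


def evaluate(
    predicted: ComplexSet,
    reference: ComplexSet,
    omega: float = DEFAULT_OMEGA,
    min_size: int = 3,
) -> EvaluationReport:
    """Size-filter both sets (>= *min_size*) and compute the full report."""
    if min_size > 1:
        predicted = predicted.filter_min_size(min_size)
        reference = reference.filter_min_size(min_size)
    n_cp, n_cb = match_counts(predicted, reference, omega)
    precision, recall, f = precision_recall_f(
        n_cp, n_cb, len(predicted), len(reference)
    )
    if len(predicted) and len(reference):
        sn, ppv, acc = sn_ppv_acc(predicted, reference)
    else:
        sn = ppv = acc = 0.0
    return EvaluationReport(
        n_predicted=len(predicted),
        n_reference=len(reference),
        n_cp=n_cp,
        n_cb=n_cb,
        precision=precision,
        recall=recall,
        f_score=f,
        sn=sn,
        ppv=ppv,
        acc=acc,
        composite=composite(f, acc),
        omega=omega,
    )
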