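"""Quality scores for predicted versus reference complex sets.

Given ``n`` reference complexes and ``m`` predicted complexes, all scores
derive from the confusion matrix ``T = [t_ij]`` of pairwise intersection
sizes and from the overlap score

    ω(A, B) = |A ∩ B|² / (|A| · |B|),

which is 1 exactly for identical sets and conventionally counted as a match
when it exceeds 0.25.

* clustering-wise sensitivity   Sn  = Σ_i max_j t_ij / Σ_i n_i
* clustering-wise PPV           PPV = Σ_j max_i t_ij / Σ_j Σ_i t_ij
* geometric accuracy            Acc = √(Sn · PPV)
* maximum matching ratio        MMR = (total ω-weight of the maximum-weight
  bipartite matching between reference and predicted complexes) / n

PPV rewards predictions that split proteins finely — a dummy predictor
emitting one singleton per protein scores PPV = 1 — so Acc must be read
with care; MMR does not suffer from this pathology.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import linear_sum_assignment

from .network import ComplexSet

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "overlap_score",
    "confusion",
    "sn_ppv_acc",
    "mmr",
    "matched_counts",
    "evaluate",
]

#: Conventional match threshold on the overlap score ω.
DEFAULT_OMEGA = 0.25


def overlap_score(a, b) -> float:
    """ω(A, B) = |A∩B|²/(|A|·|B|); symmetric, in [0, 1], 1 iff A == B."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("overlap score of an empty set is undefined")
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


@dataclass
class ConfusionMatrix:
    """Reference × predicted intersection-size matrix with reference sizes."""

    t: np.ndarray  # (n, m) nonnegative integers
    reference_sizes: np.ndarray  # (n,) sizes n_i

    @property
    def n(self) -> int:
        return self.t.shape[0]

    @property
    def m(self) -> int:
        return self.t.shape[1]


def confusion(reference: ComplexSet, predicted: ComplexSet) -> ConfusionMatrix:
    """Build ``t_ij = |reference_i ∩ predicted_j|``; both sets must be non-empty."""
    if len(reference) == 0 or len(predicted) == 0:
        raise ValueError("confusion matrix requires non-empty complex sets")
    refs = [c.members for c in reference]
    preds = [c.members for c in predicted]
    t = np.array(
        [[len(r & p) for p in preds] for r in refs], dtype=np.int64
    )
    sizes = np.array([len(r) for r in refs], dtype=np.int64)
    return ConfusionMatrix(t=t, reference_sizes=sizes)


def sn_ppv_acc(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """Clustering-wise sensitivity, positive predictive value and their
    geometric mean.  PPV is defined as 0 when no protein is shared at all.
    """
    sn = float(cm.t.max(axis=1).sum() / cm.reference_sizes.sum())
    col_total = cm.t.sum()
    ppv = float(cm.t.max(axis=0).sum() / col_total) if col_total > 0 else 0.0
    acc = float(np.sqrt(sn * ppv))
    return sn, ppv, acc


def _omega_matrix(reference: ComplexSet, predicted: ComplexSet) -> np.ndarray:
    refs = [c.members for c in reference]
    preds = [c.members for c in predicted]
    w = np.zeros((len(refs), len(preds)))
    for i, r in enumerate(refs):
        for j, p in enumerate(preds):
            inter = len(r & p)
            if inter:
                w[i, j] = inter * inter / (len(r) * len(p))
    return w


def mmr(
    reference: ComplexSet,
    predicted: ComplexSet,
    edge_threshold: float = 0.0,
) -> float:
    """Maximum matching ratio.

    Solves the maximum-weight bipartite matching on the reference × predicted
    graph with ω edge weights (each complex used at most once) and divides
    the matched weight by the number of reference complexes.  ``edge_threshold``
    optionally drops ω-edges at or below the given value before matching
    (default keeps every ω > 0 edge).
    """
    if len(reference) == 0 or len(predicted) == 0:
        raise ValueError("MMR requires non-empty complex sets")
    w = _omega_matrix(reference, predicted)
    if edge_threshold > 0:
        w = np.where(w > edge_threshold, w, 0.0)
    row, col = linear_sum_assignment(w, maximize=True)
    return float(w[row, col].sum() / len(reference))


def matched_counts(
    reference: ComplexSet,
    predicted: ComplexSet,
    omega_threshold: float = DEFAULT_OMEGA,
) -> tuple[int, int]:
    """Complexes on each side matched by some counterpart with ω strictly
    above the threshold: (matched reference count, matched predicted count).
    """
    if not 0.0 <= omega_threshold < 1.0:
        raise ValueError("omega_threshold must be in [0, 1)")
    w = _omega_matrix(reference, predicted)
    matched_ref = int((w.max(axis=1) > omega_threshold).sum()) if w.size else 0
    matched_pred = int((w.max(axis=0) > omega_threshold).sum()) if w.size else 0
    return matched_ref, matched_pred


@dataclass
class EvaluationReport:
    """All quality scores of a predicted set against a reference catalog."""

    sn: float
    ppv: float
    acc: float
    mmr: float
    matched_reference: int
    matched_predicted: int
    n_reference: int
    n_predicted: int
    omega_threshold: float = DEFAULT_OMEGA

    def to_dict(self) -> dict:
        return asdict(self)

    def to_tsv(self) -> str:
        d = self.to_dict()
        keys = list(d)
        return (
            "\t".join(keys)
            + "\n"
            + "\t".join(
                f"{d[k]:.6f}" if isinstance(d[k], float) else str(d[k]) for k in keys
            )
            + "\n"
        )


def evaluate(
    reference: ComplexSet,
    predicted: ComplexSet,
    omega_threshold: float = DEFAULT_OMEGA,
) -> EvaluationReport:
    """Compute Sn, PPV, Acc, MMR and matched counts in one pass."""
    cm = confusion(reference, predicted)
    sn, ppv, acc = sn_ppv_acc(cm)
    ratio = mmr(reference, predicted)
    mref, mpred = matched_counts(reference, predicted, omega_threshold)
    return EvaluationReport(
        sn=sn,
        ppv=ppv,
        acc=acc,
        mmr=ratio,
        matched_reference=mref,
        matched_predicted=mpred,
        n_reference=len(reference),
        n_predicted=len(predicted),
        omega_threshold=omega_threshold,
    )
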