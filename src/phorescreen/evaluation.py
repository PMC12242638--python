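"""ROC/AUC and enrichment validation of screening protocols.

A screening protocol is judged by how well its scores rank known actives
above decoys. The ROC curve sweeps a threshold over the unique scores
(equal scores are grouped into single curve steps, giving diagonal
segments rather than order-dependent staircases) and the AUC is the
trapezoidal area, which equals the tie-corrected Mann-Whitney U statistic
normalized by n_actives * n_decoys.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np


@dataclass(frozen=True)
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    n_actives: int
    n_decoys: int


def _validate_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("degenerate labels: both classes must be present")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """ROC curve and trapezoidal AUC for an active(1)/decoy(0) ranking.

    Ties are grouped: compounds sharing a score enter the curve together,
    so the result does not depend on input order.
    """
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    _validate_classes(labels)
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        auc=auc,
        n_actives=int(labels.sum()),
        n_decoys=int((1 - labels).sum()),
    )


def enrichment_factor(
    scores: Sequence[float], labels: Sequence[int], top_fraction: float
) -> float:
    """Actives concentration in the top-scored fraction relative to baseline.

    EF(f) = (actives in top f / compounds in top f) / (actives / total).
    The top set is defined by score: all compounds tied with the boundary
    score are included, so the realized top set may exceed ``f * n``.
    EF(1) is exactly 1.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    _validate_classes(labels)
    n = len(scores)
    n_top_nominal = max(1, int(np.ceil(top_fraction * n)))
    order = np.argsort(-scores, kind="stable")
    boundary_score = scores[order[n_top_nominal - 1]]
    top_mask = scores >= boundary_score
    n_top = int(top_mask.sum())
    actives_top = int(labels[top_mask].sum())
    return (actives_top / n_top) / (labels.sum() / n)


def compare_protocols(
    runs: Mapping[str, tuple[Sequence[float], Sequence[int]]],
    ef_fractions: Sequence[float] = (0.01, 0.05, 0.1),
):
    """Tabulate AUC and enrichment factors per named run, plus AUC deltas.

    Every run must cover the same compound set size with the same labels
    (runs are alternative scorings of one library); a mismatch raises with
    the offending run names.

    Returns a pandas DataFrame indexed by run name with columns
    ``auc`` and ``ef_<f>``, carrying the pairwise AUC differences in
    ``df.attrs["auc_differences"]``.
    """
    import pandas as pd

    if not runs:
        raise ValueError("at least one run required")
    names = list(runs)
    ref_labels = np.asarray(runs[names[0]][1], int)
    for name in names[1:]:
        lab = np.asarray(runs[name][1], int)
        if lab.shape != ref_labels.shape or not np.array_equal(lab, ref_labels):
            raise ValueError(
                f"label mismatch between runs {names[0]!r} and {name!r}"
            )
    rows = {}
    for name in names:
        scores, labels = runs[name]
        res = roc_auc(scores, labels)
        row = {"auc": res.auc}
        for f in ef_fractions:
            row[f"ef_{f}"] = enrichment_factor(scores, labels, f)
        rows[name] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.attrs["auc_differences"] = {
        (a, b): rows[a]["auc"] - rows[b]["auc"]
        for i, a in enumerate(names)
        for b in names[i + 1:]
    }
    return df
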