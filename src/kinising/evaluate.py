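"""Reconstruction-quality metrics: ROC over connected/unconnected pairs,
identity-line R^2 for delays and efficacies, and per-class histogram summaries.

Scores and truth are always taken over ordered off-diagonal pairs; the
diagonal is excluded because the simulator forbids autapses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ROCResult", "roc_curve", "r2_identity", "histogram_report",
           "offdiag", "sign_accuracy"]


def offdiag(mat: np.ndarray) -> np.ndarray:
    """Flatten the off-diagonal entries of a square matrix."""
    mat = np.asarray(mat)
    n = mat.shape[0]
    return mat[~np.eye(n, dtype=bool)]


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tp_fraction: np.ndarray   # correctly identified existing synapses
    tn_fraction: np.ndarray   # correctly identified unconnected pairs
    auc: float


def roc_curve(scores: np.ndarray, truth: np.ndarray) -> ROCResult:
    """Sweep a discrimination threshold over the scores.

    A pair is declared a synapse when its score exceeds the threshold;
    ``truth`` marks the existing synapses.  The AUC equals the probability
    that a random existing synapse outscores a random unconnected pair
    (ties counted half).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(truth, dtype=bool).ravel()
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must be congruent")
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both existing synapses and unconnected pairs")

    order = np.argsort(-scores, kind="stable")
    sorted_truth = truth[order]
    tp = np.concatenate([[0], np.cumsum(sorted_truth)])
    fp = np.concatenate([[0], np.cumsum(~sorted_truth)])
    thresholds = np.concatenate([[np.inf], scores[order]])
    tpf = tp / n_pos
    tnf = 1.0 - fp / n_neg
    auc = float(np.trapezoid(tpf, 1.0 - tnf))
    return ROCResult(thresholds=thresholds, tp_fraction=tpf,
                     tn_fraction=tnf, auc=auc)


def r2_identity(estimates: np.ndarray, truths: np.ndarray) -> float:
    """R^2 of the estimates against the identity line y = x:
    1 - sum (est - true)^2 / sum (true - mean(true))^2."""
    est = np.asarray(estimates, dtype=float).ravel()
    tru = np.asarray(truths, dtype=float).ravel()
    if est.size != tru.size or est.size < 2:
        raise ValueError("need >= 2 congruent estimate/truth pairs")
    denom = float(np.sum((tru - tru.mean()) ** 2))
    if denom == 0.0:
        raise ValueError("truths have zero variance; identity R^2 undefined")
    return 1.0 - float(np.sum((est - tru) ** 2)) / denom


def _overlap(a: np.ndarray, b: np.ndarray, bins: np.ndarray) -> float:
    """Overlap coefficient of two samples' normalized histograms."""
    ha, _ = np.histogram(a, bins=bins, density=False)
    hb, _ = np.histogram(b, bins=bins, density=False)
    ha = ha / max(ha.sum(), 1)
    hb = hb / max(hb.sum(), 1)
    return float(np.minimum(ha, hb).sum())


def histogram_report(values: np.ndarray, classes: np.ndarray, n_bins: int = 60) -> dict:
    """Per-class counts/means/medians and pairwise histogram overlaps.

    ``classes`` assigns each value a label (e.g. 'excitatory', 'inhibitory',
    'unconnected'); empty classes are omitted with a note.
    """
    values = np.asarray(values, dtype=float).ravel()
    classes = np.asarray(classes).ravel()
    finite = np.isfinite(values)
    report = {"classes": {}, "overlap": {}, "notes": []}
    labels = [lab for lab in np.unique(classes)]
    samples = {}
    for lab in labels:
        sel = (classes == lab) & finite
        if not sel.any():
            report["notes"].append(f"class {lab!r} empty; omitted")
            continue
        v = values[sel]
        samples[str(lab)] = v
        report["classes"][str(lab)] = {
            "count": int(v.size),
            "mean": float(v.mean()),
            "median": float(np.median(v)),
            "std": float(v.std()),
        }
    if len(samples) >= 2 and np.isfinite(values[finite]).any():
        lo = min(v.min() for v in samples.values())
        hi = max(v.max() for v in samples.values())
        if lo == hi:
            hi = lo + 1.0
        bins = np.linspace(lo, hi, n_bins + 1)
        keys = sorted(samples)
        for a_i, ka in enumerate(keys):
            for kb in keys[a_i + 1:]:
                report["overlap"][f"{ka}|{kb}"] = _overlap(samples[ka], samples[kb], bins)
    return report


def sign_accuracy(sign_est: np.ndarray, j_true: np.ndarray) -> float:
    """Fraction of existing synapses whose estimated interaction sign matches
    the sign of the true efficacy."""
    mask = offdiag(j_true) != 0
    se = offdiag(sign_est)[mask]
    st = np.sign(offdiag(j_true))[mask]
    if mask.sum() == 0:
        raise ValueError("no existing synapses")
    return float(np.mean(se == st))
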