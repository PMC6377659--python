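"""ROC utilities and AUC-maximising linear marker combination (mROC).

A panel of k isoform proportions is combined into a single virtual
marker ``Z = a*Isoform1 + b*Isoform2 + c*Isoform3 + ...`` whose
coefficients are chosen to maximise the empirical ROC AUC of Z between
the two diagnostic groups.  The empirical AUC is the Mann-Whitney
concordance probability (ties count one half) and is invariant to
positive rescaling of the coefficient vector, so coefficients are
reported with unit Euclidean norm.

The empirical AUC is piecewise constant in the coefficients, which rules
out gradient ascent.  The optimiser is a deterministic multi-start
search: signed axis directions (so the fitted panel can never do worse
than its best single marker), the standardised class-mean difference,
a Fisher-discriminant direction, and a coarse direction grid, each
refined by Nelder-Mead on the empirical AUC; the best evaluated
direction wins, with ties broken toward the earliest candidate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import rankdata


class RocError(ValueError):
    """Raised when a ROC quantity is undefined for the given input."""


@dataclass
class RocCurve:
    """Empirical ROC step curve with its AUC.

    ``fpr``/``tpr`` trace the curve from (0, 0) to (1, 1) as the
    decision threshold decreases through the observed scores; higher
    score means more case-like.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise RocError("labels must be binary (0 = control, 1 = case)")
    if labels.min() == labels.max():
        raise RocError("AUC undefined: only one class present")
    return labels


def auc_score(scores, labels) -> float:
    """Tie-aware empirical AUC via mid-ranks (Mann-Whitney convention)."""
    labels = _check_labels(np.asarray(labels))
    scores = np.asarray(scores, dtype=float)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    ranks = rankdata(scores)
    u = float(ranks[labels == 1].sum()) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def roc_auc(scores, labels) -> RocCurve:
    """Empirical ROC curve and AUC, oriented so higher score => case."""
    labels = _check_labels(np.asarray(labels))
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    n1 = int(y.sum())
    n0 = y.size - n1
    # collapse tied scores into single steps
    thresholds, tps, fps = [], [], []
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            tp += y[j]
            fp += 1 - y[j]
            j += 1
        thresholds.append(s[i])
        tps.append(tp)
        fps.append(fp)
        i = j
    tpr = np.concatenate([[0.0], np.array(tps) / n1])
    fpr = np.concatenate([[0.0], np.array(fps) / n0])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(np.asarray(thresholds), fpr, tpr, auc)


@dataclass
class MarkerPanel:
    """A fitted marker combination: names, unit-norm coefficients, AUC, scores."""

    isoforms: list[str]
    coefficients: np.ndarray
    auc: float
    scores: np.ndarray


def _candidate_directions(X: np.ndarray, labels: np.ndarray) -> list[np.ndarray]:
    k = X.shape[1]
    dirs: list[np.ndarray] = []
    for i in range(k):
        e = np.zeros(k)
        e[i] = 1.0
        dirs.append(e.copy())
        dirs.append(-e)
    mu_diff = X[labels == 1].mean(axis=0) - X[labels == 0].mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    for d in (mu_diff, mu_diff / sd):
        n = np.linalg.norm(d)
        if n > 0:
            dirs.append(d / n)
            dirs.append(-d / n)
    # Fisher discriminant direction (regularised pooled covariance)
    cov = np.cov(X[labels == 0], rowvar=False) + np.cov(X[labels == 1], rowvar=False)
    cov = np.atleast_2d(cov) + 1e-6 * np.eye(k) * max(np.trace(np.atleast_2d(cov)), 1.0)
    fisher = np.linalg.solve(cov, mu_diff)
    n = np.linalg.norm(fisher)
    if n > 0:
        dirs.append(fisher / n)
        dirs.append(-fisher / n)
    # coarse deterministic direction grid
    if k == 2:
        ang = np.linspace(0.0, 2.0 * np.pi, 72, endpoint=False)
        dirs.extend(np.column_stack([np.cos(ang), np.sin(ang)]))
    elif k >= 3:
        m = 200
        golden = np.pi * (3.0 - np.sqrt(5.0))
        z = 1.0 - 2.0 * (np.arange(m) + 0.5) / m
        r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
        phi = golden * np.arange(m)
        sphere = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
        if k == 3:
            dirs.extend(sphere)
        else:
            rng = np.random.default_rng(12345)  # fixed: deterministic fit
            extra = rng.standard_normal((400, k))
            extra /= np.linalg.norm(extra, axis=1, keepdims=True)
            dirs.extend(extra)
    return dirs


def mroc_fit(marker_matrix, labels, isoforms: list[str] | None = None) -> MarkerPanel:
    """Fit the AUC-maximising linear combination of up to 5 markers.

    Constant marker columns are dropped with a warning (their
    coefficient is reported as 0); an all-constant matrix cannot rank
    samples and raises.  The returned coefficient vector has unit norm
    and is oriented so higher Z indicates the positive class.
    """
    X = np.asarray(marker_matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = _check_labels(np.asarray(labels))
    if X.shape[1] > 5:
        raise RocError("panels larger than 5 markers are not supported")
    names = isoforms if isoforms is not None else [f"marker{i+1}" for i in range(X.shape[1])]

    keep = np.ptp(X, axis=0) > 0
    if not keep.any():
        raise RocError("all marker columns are constant; no combination can rank samples")
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping constant marker column(s): {dropped}", stacklevel=2)
    # the search runs on standardised columns so the achieved AUC is
    # invariant to marker rescaling; coefficients are mapped back after
    scale = X[:, keep].std(axis=0)
    Xa = X[:, keep] / scale
    k = Xa.shape[1]

    def neg_auc(w: np.ndarray) -> float:
        n = np.linalg.norm(w)
        if n == 0:
            return -0.5
        return -auc_score(Xa @ (w / n), labels)

    if k == 1:
        best_w = np.array([1.0])
        if auc_score(-Xa[:, 0], labels) > auc_score(Xa[:, 0], labels):
            best_w = np.array([-1.0])
        best_auc = auc_score(Xa @ best_w, labels)
    else:
        candidates = _candidate_directions(Xa, labels)
        scored = [(-neg_auc(w), i, w) for i, w in enumerate(candidates)]
        scored.sort(key=lambda t: (-t[0], t[1]))
        best_auc, _, best_w = scored[0]
        for _, _, w0 in scored[:5]:
            res = minimize(
                neg_auc, w0, method="Nelder-Mead",
                options={"xatol": 1e-3, "fatol": 1e-9, "maxiter": 300},
            )
            cand = res.x / np.linalg.norm(res.x) if np.linalg.norm(res.x) else w0
            a = -neg_auc(cand)
            if a > best_auc:
                best_auc, best_w = a, cand
        best_w = best_w / np.linalg.norm(best_w)

    coef = np.zeros(X.shape[1])
    coef[keep] = best_w / scale  # undo the internal standardisation
    coef = coef / np.linalg.norm(coef)
    scores = X @ coef
    return MarkerPanel(
        isoforms=list(names),
        coefficients=coef,
        auc=float(auc_score(scores, labels)),
        scores=scores,
    )


def panel_report(panel: MarkerPanel, labels) -> dict:
    """Summarise a fitted panel: group-wise Z distribution, AUC, and
    sensitivity at 100% specificity."""
    labels = _check_labels(np.asarray(labels))
    z = panel.scores
    out = {"isoforms": panel.isoforms,
           "coefficients": [float(c) for c in panel.coefficients],
           "auc": panel.auc}
    for cls, name in ((0, "control"), (1, "case")):
        zz = z[labels == cls]
        out[name] = {
            "n": int(zz.size),
            "median": float(np.median(zz)),
            "q1": float(np.percentile(zz, 25)),
            "q3": float(np.percentile(zz, 75)),
        }
    cutoff = float(z[labels == 0].max())
    out["sensitivity_at_full_specificity"] = float(np.mean(z[labels == 1] > cutoff))
    return out
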