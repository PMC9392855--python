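"""ROC analysis: empirical curves, DeLong AUC inference, Youden cutoffs.

The empirical AUC is the Mann-Whitney two-sample statistic rescaled:
the fraction of (event, non-event) pairs ranked correctly, ties counting
one half.  Standard errors and covariances between AUCs of different
markers scored on the same subjects use the DeLong structural-components
(placement-value) estimator, which supports a Wald chi-square test of the
joint null that all AUCs are equal.  Optimal cutoffs maximise the Youden
index J = sensitivity + specificity - 1 over the observed score values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .bloodgas import Polarity


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC curve with AUC inference and the Youden operating point.

    ``thresholds`` are the distinct observed scores (original scale) in the
    order the curve is swept; the classification rule at the optimal cutoff
    is "predict the event when the score is at or beyond the cutoff in the
    event-predicting direction".
    """

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    auc_se: float
    auc_ci: tuple[float, float]
    p_vs_half: float
    optimal_cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    polarity: Polarity
    n_events: int
    n_nonevents: int

    def __post_init__(self) -> None:
        assert 0.0 <= self.auc <= 1.0
        assert self.auc_ci[0] <= self.auc + 1e-12 and self.auc - 1e-12 <= self.auc_ci[1]


def _validate(scores, labels, polarity) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-d arrays of equal length")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be 0/1 event indicators")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("ROC needs both classes present")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    polarity = Polarity(polarity)
    if polarity is Polarity.LOWER_PREDICTS_EVENT:
        s = -s
    return s, y


def _placements(oriented: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values: V10 (per event), V01 (per non-event), AUC."""
    x = oriented[y == 1]
    z = oriented[y == 0]
    # P(z < x) + 0.5 P(z == x), vectorised via broadcasting
    cmp = (x[:, None] > z[None, :]).astype(float) + 0.5 * (x[:, None] == z[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return v10, v01, float(cmp.mean())


def auc_delong(scores, labels, polarity=Polarity.HIGHER_PREDICTS_EVENT):
    """Empirical AUC with DeLong standard error and Wald 95% CI.

    Returns ``(auc, se, (lo, hi))`` with the CI clipped to [0, 1], plus the
    two-sided p against AUC = 0.5 available via :func:`empirical_roc`.
    """
    s, y = _validate(scores, labels, polarity)
    v10, v01, auc = _placements(s, y)
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = math.sqrt(s10 / m + s01 / n)
    lo = max(0.0, auc - 1.959963984540054 * se)
    hi = min(1.0, auc + 1.959963984540054 * se)
    return auc, se, (lo, hi)


def delong_covariance(score_matrix, labels, polarities) -> tuple[np.ndarray, np.ndarray]:
    """AUCs and their DeLong covariance for k markers on the same subjects.

    ``score_matrix`` is (n_subjects, k).  Returns ``(aucs, cov)`` with
    ``cov`` the k x k covariance matrix S10/m + S01/n of the AUC vector.
    """
    sm = np.asarray(score_matrix, dtype=float)
    if sm.ndim != 2:
        raise ValueError("score_matrix must be 2-d (subjects x markers)")
    k = sm.shape[1]
    if isinstance(polarities, (str, Polarity)):
        polarities = [polarities] * k
    if len(polarities) != k:
        raise ValueError("one polarity per marker required")
    v10s, v01s, aucs = [], [], []
    for j in range(k):
        s, y = _validate(sm[:, j], labels, polarities[j])
        v10, v01, auc = _placements(s, y)
        v10s.append(v10)
        v01s.append(v01)
        aucs.append(auc)
    v10m = np.array(v10s)  # k x m
    v01m = np.array(v01s)  # k x n
    m, n = v10m.shape[1], v01m.shape[1]
    s10 = np.cov(v10m, ddof=1) if m > 1 else np.zeros((k, k))
    s01 = np.cov(v01m, ddof=1) if n > 1 else np.zeros((k, k))
    cov = np.atleast_2d(s10) / m + np.atleast_2d(s01) / n
    return np.array(aucs), cov


def auc_equality_wald(score_matrix, labels, polarities) -> tuple[float, int, float]:
    """Wald chi-square test that all k AUCs are equal (paired design).

    Contrasts each AUC against the first; the statistic is
    (L a)' (L S L')^{-1} (L a) with S the DeLong covariance, on k-1 df.
    A numerically singular contrast covariance (e.g. duplicated markers)
    degenerates to the test on the maximal non-singular contrast space;
    identical markers therefore give p = 1.
    """
    aucs, cov = delong_covariance(score_matrix, labels, polarities)
    k = len(aucs)
    if k < 2:
        raise ValueError("need at least two markers to compare")
    L = np.hstack([-np.ones((k - 1, 1)), np.eye(k - 1)])
    diffs = L @ aucs
    v = L @ cov @ L.T
    # rank-aware inverse: duplicated markers make v singular with zero diffs
    u, sing, _ = np.linalg.svd(v)
    tol = sing[0] * max(v.shape) * np.finfo(float).eps if sing.size else 0.0
    rank = int((sing > tol).sum())
    if rank == 0:
        if np.allclose(diffs, 0):
            return 0.0, k - 1, 1.0
        raise np.linalg.LinAlgError(
            "singular AUC-contrast covariance with nonzero contrasts; "
            "markers may be degenerate"
        )
    vinv = (u[:, :rank] / sing[:rank]) @ u[:, :rank].T
    chi2 = float(diffs @ vinv @ diffs)
    df = k - 1
    return chi2, df, float(_sps.chi2.sf(chi2, df))


def youden_optimal_cutoff(scores, labels, polarity=Polarity.HIGHER_PREDICTS_EVENT):
    """Cutoff maximising J = sens + spec - 1 over observed score values.

    Ties in J are broken toward the smallest oriented threshold (the most
    sensitive rule).  Returns ``(cutoff, sens, spec, ppv, npv)`` with the
    cutoff on the original score scale; predict the event when the score
    is >= cutoff (higher-predicts-event) or <= cutoff (lower-).
    """
    s, y = _validate(scores, labels, polarity)
    cands = np.unique(s)  # ascending oriented scale
    best = None
    for thr in cands:
        pred = s >= thr
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        fn = int((~pred & (y == 1)).sum())
        tn = int((~pred & (y == 0)).sum())
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, thr, sens, spec, tp, fp, fn, tn)
    _, thr, sens, spec, tp, fp, fn, tn = best
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    if Polarity(polarity) is Polarity.LOWER_PREDICTS_EVENT:
        thr = -thr
    return float(thr), sens, spec, ppv, npv


def empirical_roc(scores, labels, polarity=Polarity.HIGHER_PREDICTS_EVENT) -> RocResult:
    """Full ROC analysis for one marker: curve, DeLong AUC inference,
    p-value against the chance line, and the Youden operating point."""
    polarity = Polarity(polarity)
    s, y = _validate(scores, labels, polarity)
    order = np.argsort(-s, kind="stable")
    ss, yy = s[order], y[order]
    n_ev, n_non = int(y.sum()), int(len(y) - y.sum())
    # sweep from +inf (predict none) down through each distinct observed value
    distinct = np.concatenate([[np.inf], np.unique(ss)[::-1]])
    sens = np.empty(len(distinct))
    spec = np.empty(len(distinct))
    tp = fp = 0
    i = 0
    for j, thr in enumerate(distinct):
        while i < len(ss) and ss[i] >= thr:
            tp += yy[i]
            fp += 1 - yy[i]
            i += 1
        sens[j] = tp / n_ev
        spec[j] = 1 - fp / n_non

    auc, se, ci = auc_delong(scores, labels, polarity)
    if se > 0:
        z = (auc - 0.5) / se
        p_half = float(2 * _sps.norm.sf(abs(z)))
    else:
        p_half = 1.0 if auc == 0.5 else 0.0
    cutoff, sn, sp, ppv, npv = youden_optimal_cutoff(scores, labels, polarity)

    thresholds = distinct if polarity is Polarity.HIGHER_PREDICTS_EVENT else -distinct
    return RocResult(
        thresholds=thresholds,
        sensitivities=sens,
        specificities=spec,
        auc=auc,
        auc_se=se,
        auc_ci=ci,
        p_vs_half=p_half,
        optimal_cutoff=cutoff,
        sensitivity=sn,
        specificity=sp,
        ppv=ppv,
        npv=npv,
        polarity=polarity,
        n_events=n_ev,
        n_nonevents=n_non,
    )
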