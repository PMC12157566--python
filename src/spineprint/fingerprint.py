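"""Connectome fingerprinting: identifiability matrix and derived metrics.

Given two runs per subject, the identifiability matrix I (Ns x Ns,
asymmetric) holds the Pearson correlation between each subject's run-1 FC
vector and every subject's run-2 FC vector.  From it follow:

* Iself   — mean of the diagonal (test-retest self-similarity),
* Iothers — mean of ALL off-diagonal entries (between-subject similarity),
* Idiff   — Iself - Iothers, the differential identifiability,
* Cohen's d — (Iself - Iothers) / sqrt((var_self + var_others) / 2),
* top-K identification accuracy — percentage of subjects whose diagonal
  entry ranks within the top K of their row (chance level 100 / Ns at K=1),
* the PCA sweep — Idiff recomputed after reconstructing all 2*Ns FC vectors
  from their top-m principal components, maximized over m.

Identification is row-wise (run 1 queries run 2); a tie between the diagonal
and an off-diagonal entry counts as a failed identification, which is
deterministic and conservative (probability zero for continuous data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .connectivity import FCVector

__all__ = [
    "IdentifiabilityResult",
    "DifferentialIdentifiabilityResult",
    "identifiability_matrix",
    "idiff",
    "cohens_d",
    "success_rate",
    "chance_level",
    "pca_differential_identifiability",
    "fingerprint_analysis",
    "FingerprintAnalysis",
]


@dataclass
class IdentifiabilityResult:
    """All fingerprint metrics for one pair of runs."""

    I: np.ndarray  # noqa: E741 - field name matches the field's convention
    iself: float
    iothers: float
    idiff: float
    var_self: float
    var_others: float
    cohens_d: float
    accuracy_topk: dict[int, float]
    chance_level: float
    subject_ids: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "iself": self.iself,
            "iothers": self.iothers,
            "idiff": self.idiff,
            "var_self": self.var_self,
            "var_others": self.var_others,
            "cohens_d": self.cohens_d,
            "accuracy_topk": {str(k): v for k, v in self.accuracy_topk.items()},
            "chance_level": round(self.chance_level, 1),
            "n_subjects": int(self.I.shape[0]),
        }


@dataclass
class DifferentialIdentifiabilityResult:
    """Idiff as a function of the number of retained components."""

    idiff_by_components: dict[int, float]
    m_star: int
    idiff_star: float


def _as_matrix(vectors: Sequence[FCVector] | np.ndarray) -> np.ndarray:
    if isinstance(vectors, np.ndarray):
        return np.atleast_2d(np.asarray(vectors, dtype=float))
    return np.vstack([np.asarray(v.values, dtype=float) for v in vectors])


def identifiability_matrix(
    run1: Sequence[FCVector] | np.ndarray,
    run2: Sequence[FCVector] | np.ndarray,
) -> np.ndarray:
    """Pearson correlation of every run-1 FC vector with every run-2 vector.

    Rows index run-1 subjects, columns run-2 subjects; subjects must be in
    the same order in both runs.
    """
    a = _as_matrix(run1)
    b = _as_matrix(run2)
    if a.shape != b.shape:
        raise ValueError(f"run shapes differ: {a.shape} vs {b.shape}")
    if a.shape[1] < 3:
        raise ValueError("FC vectors must have length >= 3")
    for tag, m in (("run 1", a), ("run 2", b)):
        sd = m.std(axis=1)
        if np.any(sd == 0):
            bad = np.flatnonzero(sd == 0).tolist()
            raise ValueError(f"constant FC vector for subject index {bad} in {tag}")
    az = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
    bz = (b - b.mean(axis=1, keepdims=True)) / b.std(axis=1, keepdims=True)
    out = az @ bz.T / a.shape[1]
    return np.clip(out, -1.0, 1.0)


def idiff(I: np.ndarray) -> tuple[float, float, float]:  # noqa: E741
    """(Iself, Iothers, Idiff) on the raw correlation scale."""
    I = np.asarray(I, dtype=float)  # noqa: E741
    ns = I.shape[0]
    if I.ndim != 2 or I.shape[1] != ns:
        raise ValueError("identifiability matrix must be square")
    if ns < 2:
        raise ValueError("need at least 2 subjects (Iothers undefined for Ns<2)")
    diag = np.diag(I)
    off = I[~np.eye(ns, dtype=bool)]
    iself = float(diag.mean())
    iothers = float(off.mean())
    return iself, iothers, iself - iothers


def cohens_d(I: np.ndarray) -> float:  # noqa: E741
    """Pooled-variance effect size between self and other similarities."""
    I = np.asarray(I, dtype=float)  # noqa: E741
    ns = I.shape[0]
    iself, iothers, _ = idiff(I)
    diag = np.diag(I)
    off = I[~np.eye(ns, dtype=bool)]
    pooled = (diag.var(ddof=1) + off.var(ddof=1)) / 2.0
    if pooled == 0:
        raise ValueError("zero pooled variance: effect size undefined")
    return float((iself - iothers) / np.sqrt(pooled))


def success_rate(I: np.ndarray, k: int = 1) -> tuple[float, list[int]]:  # noqa: E741
    """Top-K identification accuracy (percent) and identified subject indices.

    Subject i counts as identified at level K iff I[i, i] is strictly
    greater than all but at most K-1 off-diagonal entries of row i; ties with
    the diagonal count against identification.
    """
    I = np.asarray(I, dtype=float)  # noqa: E741
    ns = I.shape[0]
    if not 1 <= k < max(ns, 2):
        raise ValueError(f"K must satisfy 1 <= K < Ns, got K={k}, Ns={ns}")
    identified = []
    for i in range(ns):
        row = I[i]
        others = np.delete(row, i)
        n_not_beaten = int(np.sum(others >= row[i]))
        if n_not_beaten <= k - 1:
            identified.append(i)
    return 100.0 * len(identified) / ns, identified


def chance_level(ns: int) -> float:
    """Chance identification rate in percent: 100 / Ns."""
    if ns < 1:
        raise ValueError("Ns must be >= 1")
    return 100.0 / ns


def pca_differential_identifiability(
    run1: Sequence[FCVector] | np.ndarray,
    run2: Sequence[FCVector] | np.ndarray,
    m_values: Optional[Sequence[int]] = None,
) -> DifferentialIdentifiabilityResult:
    """Idiff after rank-m PCA reconstruction of the pooled FC vectors.

    The 2*Ns FC vectors are stacked as columns of an M x 2*Ns matrix, each
    edge (row) is centered across columns, and the columns are reconstructed
    from their top-m principal components plus the mean.  Idiff is recomputed
    for every m in ``m_values`` (default 2..2*Ns); at m = 2*Ns the
    reconstruction is exact, so that entry reproduces the raw Idiff.
    """
    a = _as_matrix(run1)
    b = _as_matrix(run2)
    if a.shape != b.shape:
        raise ValueError(f"run shapes differ: {a.shape} vs {b.shape}")
    ns = a.shape[0]
    n_cols = 2 * ns
    if m_values is None:
        m_values = range(2, n_cols + 1)
    m_values = [int(m) for m in m_values]
    for m in m_values:
        if not 1 <= m <= n_cols:
            raise ValueError(f"m={m} out of range [1, {n_cols}]")
    x = np.vstack([a, b]).T  # M x 2Ns, run-1 columns first
    mean = x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(x - mean, full_matrices=False)
    curve: dict[int, float] = {}
    for m in m_values:
        recon = (u[:, :m] * s[:m]) @ vt[:m] + mean
        r1 = recon[:, :ns].T
        r2 = recon[:, ns:].T
        _, _, d = idiff(identifiability_matrix(r1, r2))
        curve[m] = d
    m_star = max(curve, key=lambda m: (curve[m], -m))
    return DifferentialIdentifiabilityResult(
        idiff_by_components=curve, m_star=m_star, idiff_star=curve[m_star]
    )


def fingerprint_analysis(
    run1: Sequence[FCVector] | np.ndarray,
    run2: Sequence[FCVector] | np.ndarray,
    max_k: int = 5,
    subject_ids: Sequence[str] = (),
) -> IdentifiabilityResult:
    """Full fingerprint report for one pair of runs (function form)."""
    I = identifiability_matrix(run1, run2)  # noqa: E741
    ns = I.shape[0]
    iself, iothers, d_idiff = idiff(I)
    diag = np.diag(I)
    off = I[~np.eye(ns, dtype=bool)]
    accuracy = {
        k: success_rate(I, k)[0] for k in range(1, min(max_k, ns - 1) + 1)
    }
    return IdentifiabilityResult(
        I=I,
        iself=iself,
        iothers=iothers,
        idiff=d_idiff,
        var_self=float(diag.var(ddof=1)),
        var_others=float(off.var(ddof=1)),
        cohens_d=cohens_d(I),
        accuracy_topk=accuracy,
        chance_level=chance_level(ns),
        subject_ids=tuple(subject_ids),
    )


class FingerprintAnalysis(BaseEstimator):
    """Estimator form of the fingerprint pipeline.

    ``fit(X, y)`` takes run-1 FC vectors as ``X`` (Ns x M array or list of
    :class:`~spineprint.connectivity.FCVector`) and run-2 vectors as ``y``,
    with subjects in the same order, and exposes the metrics as fitted
    attributes.

    Parameters
    ----------
    max_k : int, default 5
        Largest K for the top-K accuracy curve (capped at Ns - 1).
    pca_sweep : bool, default False
        If True, also run the PCA differential-identifiability sweep.

    Attributes
    ----------
    I_ : ndarray of shape (Ns, Ns)
        Identifiability matrix (rows: run-1 subjects, columns: run-2).
    iself_, iothers_, idiff_, cohens_d_ : float
    accuracy_topk_ : dict mapping K to percent accuracy
    chance_level_ : float
    result_ : IdentifiabilityResult
    pca_result_ : DifferentialIdentifiabilityResult (if ``pca_sweep``)
    """

    def __init__(self, max_k: int = 5, pca_sweep: bool = False):
        self.max_k = max_k
        self.pca_sweep = pca_sweep

    def fit(self, X, y):
        res = fingerprint_analysis(X, y, max_k=self.max_k)
        self.result_ = res
        self.I_ = res.I
        self.iself_ = res.iself
        self.iothers_ = res.iothers
        self.idiff_ = res.idiff
        self.cohens_d_ = res.cohens_d
        self.accuracy_topk_ = res.accuracy_topk
        self.chance_level_ = res.chance_level
        if self.pca_sweep:
            self.pca_result_ = pca_differential_identifiability(X, y)
        return self

    def score(self, X=None, y=None) -> float:
        """Differential identifiability of the fitted run pair."""
        return self.idiff_
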