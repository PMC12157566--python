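"""Edge-wise test-retest reliability via ICC(1,1).

For every FC edge, subjects are treated as groups in a one-way random-effects
ANOVA with the k=2 runs as repeated measurements:

    ICC(1,1) = (MSR - MSW) / (MSR + (k - 1) * MSW)

where MSR is the between-subject mean square and MSW the within-subject
(error) mean square.  The edge-wise values are folded back into a symmetric
N x N map (diagonal undefined), thresholded at a percentile to keep the most
reliable edges, and summarized per region as nodal strength.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .connectivity import FCVector, devectorize, vectorize_upper
from .parcellation import ParcellationScheme

__all__ = [
    "ICCMap",
    "edge_icc",
    "threshold_percentile",
    "nodal_strength",
    "average_within_level_blocks",
    "ICCAnalysis",
]


@dataclass
class ICCMap:
    """Symmetric N x N map of per-edge ICC values (diagonal NaN)."""

    values: np.ndarray
    scheme: Optional[ParcellationScheme] = None
    k: int = 2

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"ICC map must be square, got {v.shape}")
        if not np.allclose(np.nan_to_num(v), np.nan_to_num(v.T), atol=1e-10):
            raise ValueError("ICC map must be symmetric")
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def edge_values(self) -> np.ndarray:
        """Upper-triangle edge values in canonical order (may contain NaN)."""
        return vectorize_upper(self.values).values


def edge_icc(
    run1: Sequence[FCVector] | np.ndarray,
    run2: Sequence[FCVector] | np.ndarray,
    scheme: Optional[ParcellationScheme] = None,
) -> ICCMap:
    """ICC(1,1) per edge across subjects, folded into a symmetric map.

    ``run1`` and ``run2`` hold one FC vector per subject (same order).  At
    edges where both mean squares vanish (identical values for every subject
    and run) the coefficient is undefined and NaN is stored; downstream
    percentile operations ignore those edges.
    """
    a = _stack(run1)
    b = _stack(run2)
    if a.shape != b.shape:
        raise ValueError(f"run shapes differ: {a.shape} vs {b.shape}")
    ns = a.shape[0]
    if ns < 2:
        raise ValueError("need at least 2 subjects for ICC")
    k = 2
    subj_mean = (a + b) / 2.0  # Ns x M
    grand = subj_mean.mean(axis=0)
    msr = k * np.sum((subj_mean - grand) ** 2, axis=0) / (ns - 1)
    msw = (np.sum((a - subj_mean) ** 2, axis=0) + np.sum((b - subj_mean) ** 2, axis=0)) / (
        ns * (k - 1)
    )
    denom = msr + (k - 1) * msw
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = np.where(denom > 0, (msr - msw) / denom, np.nan)
    n = int(round((1 + np.sqrt(1 + 8 * icc.size)) / 2))
    values = devectorize(icc, n)
    np.fill_diagonal(values, np.nan)
    if scheme is None:
        first = run1[0] if not isinstance(run1, np.ndarray) else None
        scheme = getattr(first, "scheme", None)
    return ICCMap(values=values, scheme=scheme, k=k)


def _stack(vectors: Sequence[FCVector] | np.ndarray) -> np.ndarray:
    if isinstance(vectors, np.ndarray):
        return np.atleast_2d(np.asarray(vectors, dtype=float))
    return np.vstack([np.asarray(v.values, dtype=float) for v in vectors])


def threshold_percentile(
    icc_map: ICCMap, q: float = 0.95
) -> tuple[float, ICCMap]:
    """Keep only edges at or above the q-quantile of the finite edge values.

    Returns the threshold (linear-interpolation quantile over the finite
    upper-triangle values, each edge counted once) and a copy of the map with
    sub-threshold edges zeroed; NaN edges stay NaN.
    """
    if not 0 <= q <= 1:
        raise ValueError(f"quantile must be in [0, 1], got {q}")
    edges = icc_map.edge_values()
    finite = edges[np.isfinite(edges)]
    if finite.size == 0:
        raise ValueError("all edge values are NaN; cannot threshold")
    thr = float(np.quantile(finite, q))
    filtered = icc_map.values.copy()
    with np.errstate(invalid="ignore"):
        filtered[filtered < thr] = 0.0
    return thr, ICCMap(values=filtered, scheme=icc_map.scheme, k=icc_map.k)


def nodal_strength(icc_map: ICCMap, mode: str = "sum") -> np.ndarray:
    """Per-region aggregate of the (filtered) map's rows.

    ``sum`` (default) treats NaN as 0; ``mean`` excludes NaN entries and the
    diagonal.
    """
    v = icc_map.values
    if mode == "sum":
        return np.nansum(np.where(np.isnan(v), 0.0, v), axis=1)
    if mode == "mean":
        with np.errstate(invalid="ignore"):
            return np.nanmean(v, axis=1)
    raise ValueError(f"mode must be 'sum' or 'mean', got {mode!r}")


def average_within_level_blocks(maps: Sequence[ICCMap]) -> ICCMap:
    """Collapse level-replicated spinal ICC maps to one 14 x 14 cross-section.

    For each map the L within-level 14 x 14 diagonal blocks are extracted and
    all blocks from all maps are averaged elementwise, ignoring NaN.  Edges
    between different spinal levels are not included.
    """
    if not maps:
        raise ValueError("need at least one ICC map")
    blocks = []
    scheme0 = None
    for m in maps:
        if m.scheme is None or m.scheme.kind != "spinal":
            raise ValueError("within-level averaging requires spinal schemes")
        n_levels = len(m.scheme.levels)
        if m.n_regions != 14 * n_levels:
            raise ValueError(
                f"spinal map has {m.n_regions} regions for {n_levels} levels"
            )
        for lv in range(n_levels):
            sl = slice(14 * lv, 14 * (lv + 1))
            blocks.append(m.values[sl, sl])
        if scheme0 is None:
            scheme0 = m.scheme
    stack = np.stack(blocks)
    import warnings

    with warnings.catch_warnings():
        # the diagonal is NaN in every block by construction
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        avg = np.nanmean(stack, axis=0)
    from .parcellation import build_spinal_scheme

    cross = build_spinal_scheme([scheme0.levels[0]])
    return ICCMap(values=avg, scheme=cross, k=maps[0].k)


class ICCAnalysis(BaseEstimator):
    """Estimator form of the edge-wise reliability analysis.

    ``fit(X, y)`` takes run-1 FC vectors as ``X`` and run-2 vectors as ``y``
    (Ns x M arrays or FCVector lists, same subject order).

    Parameters
    ----------
    quantile : float, default 0.95
        Percentile threshold applied to the edge ICC distribution.
    strength_mode : {"sum", "mean"}, default "sum"
        Nodal-strength aggregation over the filtered map.

    Attributes
    ----------
    icc_map_ : ICCMap
    threshold_ : float
    filtered_map_ : ICCMap
    nodal_strength_ : ndarray of shape (N,)
    """

    def __init__(self, quantile: float = 0.95, strength_mode: str = "sum"):
        self.quantile = quantile
        self.strength_mode = strength_mode

    def fit(self, X, y, scheme: Optional[ParcellationScheme] = None):
        self.icc_map_ = edge_icc(X, y, scheme=scheme)
        self.threshold_, self.filtered_map_ = threshold_percentile(
            self.icc_map_, self.quantile
        )
        self.nodal_strength_ = nodal_strength(self.filtered_map_, self.strength_mode)
        return self
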