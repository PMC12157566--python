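"""Functional connectivity: Pearson FC matrices and their vectorized forms.

The FC profile of one subject-run is the N x N matrix of Pearson
correlations between region-averaged time series.  For fingerprinting the
upper triangle (excluding the diagonal) is unfolded row-major into a vector
of length M = N(N-1)/2; that edge order is canonical across the package
(FC vectors, ICC maps, PCA reconstruction all use it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .parcellation import ParcellationScheme

__all__ = [
    "RunTimeSeries",
    "FCMatrix",
    "FCVector",
    "compute_fc",
    "vectorize_upper",
    "devectorize",
    "extract_block",
]


@dataclass
class RunTimeSeries:
    """One subject-run matrix of regions x time.

    ``scheme`` may be None for anonymous simulated regions; when present its
    region count must match the data.
    """

    data: np.ndarray  # (N, T)
    tr: float
    scheme: Optional[ParcellationScheme] = None
    subject_id: str = ""
    run_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"time series must be 2-D, got shape {self.data.shape}")
        if self.scheme is not None and self.scheme.n_regions != self.data.shape[0]:
            raise ValueError(
                f"scheme has {self.scheme.n_regions} regions but data has "
                f"{self.data.shape[0]} rows"
            )
        if self.tr <= 0:
            raise ValueError("TR must be positive")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def region_names(self) -> tuple[str, ...]:
        if self.scheme is not None:
            return self.scheme.names
        return tuple(f"r{i}" for i in range(self.n_regions))


@dataclass
class FCMatrix:
    """Symmetric N x N Pearson correlation matrix with unit diagonal."""

    values: np.ndarray
    scheme: Optional[ParcellationScheme] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"FC matrix must be square, got shape {v.shape}")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("FC matrix must be symmetric")
        if np.nanmax(np.abs(v)) > 1 + 1e-8:
            raise ValueError("FC entries must lie in [-1, 1]")
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class FCVector:
    """Length-M upper-triangle unfolding of an FC matrix, M = N(N-1)/2."""

    values: np.ndarray
    edge_index: tuple[tuple[int, int], ...]
    scheme: Optional[ParcellationScheme] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.edge_index) != self.values.size:
            raise ValueError("edge_index length must match vector length")


def compute_fc(ts: RunTimeSeries) -> FCMatrix:
    """Pearson correlation between every pair of region time series.

    The diagonal is set to exactly 1.  A constant region series makes the
    correlation undefined and raises, naming the region.
    """
    data = ts.data
    if data.shape[1] < 3:
        raise ValueError("need at least 3 time points for FC")
    sd = data.std(axis=1)
    if np.any(sd == 0):
        names = [ts.region_names()[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant time series for region(s) {names}; FC undefined")
    fc = np.corrcoef(data)
    np.clip(fc, -1.0, 1.0, out=fc)
    np.fill_diagonal(fc, 1.0)
    return FCMatrix(values=fc, scheme=ts.scheme)


def vectorize_upper(fc: FCMatrix | np.ndarray) -> FCVector:
    """Unfold the upper triangle (i < j, row-major) into a vector."""
    values = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    scheme = fc.scheme if isinstance(fc, FCMatrix) else None
    n = values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    return FCVector(
        values=values[iu, ju],
        edge_index=tuple(zip(iu.tolist(), ju.tolist())),
        scheme=scheme,
    )


def devectorize(vec: FCVector | np.ndarray, n: Optional[int] = None) -> np.ndarray:
    """Rebuild the symmetric matrix (unit diagonal) from an upper-triangle vector."""
    values = vec.values if isinstance(vec, FCVector) else np.asarray(vec, dtype=float)
    if n is None:
        m = values.size
        n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if n * (n - 1) // 2 != values.size:
        raise ValueError(f"vector length {values.size} is not N(N-1)/2 for N={n}")
    out = np.eye(n)
    iu, ju = np.triu_indices(n, k=1)
    out[iu, ju] = values
    out[ju, iu] = values
    return out


def extract_block(
    fc: FCMatrix,
    rows: Sequence[str] | Sequence[int],
    cols: Sequence[str] | Sequence[int],
) -> np.ndarray:
    """Flatten a sub-block of an FC matrix into a feature vector.

    If ``rows`` and ``cols`` name the same region set (same order) the block
    is square symmetric and its upper triangle is returned (within-structure
    profile, e.g. brain-only).  If the sets are disjoint the full rectangular
    block is returned row-major (between-structure profile, e.g. brain x
    spine).  Partially overlapping sets are ambiguous and rejected.
    """
    ridx = _resolve(fc, rows)
    cidx = _resolve(fc, cols)
    if ridx == cidx:
        sub = fc.values[np.ix_(ridx, cidx)]
        iu, ju = np.triu_indices(len(ridx), k=1)
        return sub[iu, ju]
    if set(ridx) & set(cidx):
        raise ValueError(
            "row and column region sets overlap but are not identical; "
            "use identical sets (within-block) or disjoint sets (between-block)"
        )
    return fc.values[np.ix_(ridx, cidx)].ravel()


def _resolve(fc: FCMatrix, regions: Sequence[str] | Sequence[int]) -> list[int]:
    regions = list(regions)
    if not regions:
        raise ValueError("region subset must be non-empty")
    if all(isinstance(r, (int, np.integer)) for r in regions):
        idx = [int(r) for r in regions]
        if min(idx) < 0 or max(idx) >= fc.n_regions:
            raise IndexError("region index out of range")
        return idx
    if fc.scheme is None:
        raise ValueError("FC matrix has no scheme; select regions by index")
    return fc.scheme.index_of([str(r) for r in regions])
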