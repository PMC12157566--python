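"""Synthetic multi-subject fMRI cohorts with controllable fingerprint strength.

Every subject-run time series is drawn from a zero-mean multivariate normal
whose correlation structure mixes three components:

    Sigma(i, r) = (1 - alpha - gamma) * C_group
                  + alpha * C_subj(i)          (the fingerprint)
                  + gamma * C_run(i, r)        (run-specific state)

with an optional iid observation-noise floor.  ``alpha`` controls how much
of each subject's correlation structure is stable across runs — the quantity
the fingerprinting pipeline tries to detect — and ``gamma`` how much changes
between runs.  All component matrices are low-rank-plus-diagonal random
correlation matrices; the convex mixture keeps the marginal scale comparable
across parameter settings.

Defaults mirror a single-site two-run resting-state study: 15 subjects,
98 regions (7 cervical levels x 14 cross-section regions), 230 volumes at
TR = 2.31 s.

The module also generates the auxiliary inputs the denoising stage consumes:
cardiac peak times and a respiratory waveform, and voxel blocks with
labelled regions and injected outliers.  Everything is reproducible
bit-for-bit from the spec's seed (child generators are spawned
deterministically).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .connectivity import RunTimeSeries
from .denoise import VoxelBlock
from .parcellation import ParcellationScheme, build_spinal_scheme

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "random_correlation",
    "nearest_correlation",
    "generate_cohort",
    "generate_driven_pair",
    "generate_physio",
    "generate_voxel_block",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic two-run cohort."""

    n_subjects: int = 15
    n_regions: int = 98
    n_timepoints: int = 230
    tr: float = 2.31
    alpha: float = 0.4  # subject-stable (fingerprint) weight
    gamma: float = 0.2  # run-specific weight
    latent_rank: int = 10
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_regions, self.n_timepoints) < 1:
            raise ValueError("counts must be positive")
        if not (0 <= self.alpha <= 1 and 0 <= self.gamma <= 1):
            raise ValueError("alpha and gamma must be in [0, 1]")
        if self.alpha + self.gamma > 1:
            raise ValueError(
                f"alpha + gamma = {self.alpha + self.gamma} exceeds 1"
            )


@dataclass
class SyntheticCohort:
    """Generated series plus the ground-truth per-subject structure."""

    series: dict[tuple[int, int], RunTimeSeries]  # (subject, run) -> series
    true_subject_fc: list[np.ndarray]
    spec: CohortSpec
    scheme: Optional[ParcellationScheme] = None

    def run_matrix(self, run: int) -> list[RunTimeSeries]:
        """All subjects' series for one run (0 or 1), subject order."""
        return [self.series[(i, run)] for i in range(self.spec.n_subjects)]


def random_correlation(
    n: int, q: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Random correlation matrix from a rank-q factor model.

    C = normalize(W W^T + delta I) with W an n x q standard-normal matrix;
    the diagonal is exactly 1 and the matrix is positive definite.  Large q
    concentrates the off-diagonals near zero.
    """
    if q < 1:
        raise ValueError("latent rank q must be >= 1")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    w = rng.standard_normal((n, q))
    c = w @ w.T + 1e-3 * np.eye(n)
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return c


def nearest_correlation(c: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Project to the positive-definite cone by eigenvalue clipping.

    Eigenvalues below ``floor`` are raised to it and the result is
    re-normalized to unit diagonal.  Cheap and adequate at these sizes.
    """
    c = (c + c.T) / 2.0
    vals, vecs = np.linalg.eigh(c)
    if vals.min() >= floor:
        return c
    vals = np.clip(vals, floor, None)
    out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def generate_cohort(
    spec: CohortSpec, scheme: Optional[ParcellationScheme] = None
) -> SyntheticCohort:
    """Draw a full two-run cohort from the mixture model.

    If ``scheme`` is omitted and ``n_regions`` is a multiple of 14 covering
    at most the C2-C8 levels, a spinal scheme is attached; otherwise the
    series carry anonymous region labels.
    """
    if scheme is None and spec.n_regions % 14 == 0 and 1 <= spec.n_regions // 14 <= 7:
        n_levels = spec.n_regions // 14
        scheme = build_spinal_scheme([f"C{i}" for i in range(2, 2 + n_levels)])
    if scheme is not None and scheme.n_regions != spec.n_regions:
        raise ValueError(
            f"scheme has {scheme.n_regions} regions, spec says {spec.n_regions}"
        )
    ss = np.random.SeedSequence(spec.seed)
    rng_group, rng_subj, rng_run, rng_noise = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    n, q = spec.n_regions, spec.latent_rank
    c_group = random_correlation(n, q, rng_group)
    base = 1.0 - spec.alpha - spec.gamma
    series: dict[tuple[int, int], RunTimeSeries] = {}
    true_fc: list[np.ndarray] = []
    for i in range(spec.n_subjects):
        c_subj = random_correlation(n, q, rng_subj)
        stable = base * c_group + spec.alpha * c_subj
        true_fc.append(nearest_correlation(stable / max(base + spec.alpha, 1e-12)))
        for r in range(2):
            c_run = random_correlation(n, q, rng_run)
            sigma = nearest_correlation(stable + spec.gamma * c_run)
            chol = np.linalg.cholesky(sigma)
            z = rng_noise.standard_normal((spec.n_timepoints, n))
            data = (z @ chol.T).T
            if spec.noise_sd > 0:
                data = data + spec.noise_sd * rng_noise.standard_normal(data.shape)
            series[(i, r)] = RunTimeSeries(
                data=data,
                tr=spec.tr,
                scheme=scheme,
                subject_id=f"sub-{i + 1:02d}",
                run_id=f"run-{r + 1}",
            )
    return SyntheticCohort(
        series=series, true_subject_fc=true_fc, spec=spec, scheme=scheme
    )


def generate_driven_pair(
    spec: CohortSpec,
    n_target: int = 28,
    mixing_density: float = 0.3,
    target_noise_sd: float = 0.5,
    target_scheme: Optional[ParcellationScheme] = None,
) -> tuple[SyntheticCohort, SyntheticCohort, list[np.ndarray]]:
    """Paired cohorts where the target structure is driven by the source.

    The source cohort X follows :func:`generate_cohort`; each target series
    is Y(i, r) = A_i X(i, r) + noise with A_i a sparse subject-specific
    mixing matrix fixed across runs.  Any identifiable structure in Y is
    therefore inherited from X — regressing X out of Y should destroy Y's
    fingerprint, while regressing Y out of X should leave X's mostly intact.

    ``mixing_density`` in [0, 1] is the expected fraction of nonzero entries
    of A_i; density 0 makes Y pure noise.
    """
    if not 0 <= mixing_density <= 1:
        raise ValueError("mixing_density must be in [0, 1]")
    x_cohort = generate_cohort(spec)
    ss = np.random.SeedSequence((spec.seed, 0x5EED))
    rng_mix, rng_noise = [np.random.default_rng(s) for s in ss.spawn(2)]
    series: dict[tuple[int, int], RunTimeSeries] = {}
    mixings: list[np.ndarray] = []
    for i in range(spec.n_subjects):
        mask = rng_mix.random((n_target, spec.n_regions)) < mixing_density
        a = rng_mix.standard_normal((n_target, spec.n_regions)) * mask
        mixings.append(a)
        for r in range(2):
            x = x_cohort.series[(i, r)]
            y = a @ x.data + target_noise_sd * rng_noise.standard_normal(
                (n_target, spec.n_timepoints)
            )
            series[(i, r)] = RunTimeSeries(
                data=y,
                tr=spec.tr,
                scheme=target_scheme,
                subject_id=x.subject_id,
                run_id=x.run_id,
            )
    y_spec = replace(spec, n_regions=n_target, alpha=0.0, gamma=0.0)
    y_cohort = SyntheticCohort(
        series=series,
        true_subject_fc=[],
        spec=y_spec,
        scheme=target_scheme,
    )
    return x_cohort, y_cohort, mixings


def generate_physio(
    duration_s: float,
    heart_rate_hz: float = 1.0,
    resp_rate_hz: float = 0.25,
    jitter_sd: float = 0.05,
    seed: int = 0,
    resp_fs: float = 10.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cardiac peak times and a respiratory waveform for one acquisition.

    Returns ``(peak_times, waveform, waveform_times)``: heartbeat peaks at
    jittered multiples of 1 / heart_rate covering the scan, and a sinusoidal
    respiratory trace at ``resp_rate_hz`` sampled at ``resp_fs`` Hz with
    small amplitude noise.
    """
    if heart_rate_hz <= 0 or resp_rate_hz <= 0:
        raise ValueError("physiological rates must be positive")
    rng = np.random.default_rng(seed)
    mean_ibi = 1.0 / heart_rate_hz
    n_beats = int(np.ceil(duration_s / mean_ibi)) + 2
    intervals = mean_ibi + jitter_sd * rng.standard_normal(n_beats)
    intervals = np.clip(intervals, 0.2 * mean_ibi, None)
    peaks = np.concatenate([[0.0], np.cumsum(intervals)])
    peaks = peaks[peaks <= duration_s + mean_ibi]
    t = np.arange(0.0, duration_s, 1.0 / resp_fs)
    waveform = np.sin(2 * np.pi * resp_rate_hz * t)
    if jitter_sd > 0:
        waveform = waveform + 0.05 * rng.standard_normal(t.size)
    return peaks, waveform, t


def generate_voxel_block(
    scheme: ParcellationScheme,
    voxels_per_region: int = 10,
    outlier_fraction: float = 0.0,
    seed: int = 0,
    n_timepoints: int = 200,
    tr: float = 2.31,
    noise_sd: float = 0.5,
    outlier_scale: float = 1e6,
) -> tuple[VoxelBlock, np.ndarray]:
    """Voxel block around known region ground truth, with optional outliers.

    Each region gets a smooth random ground-truth series; its voxels are
    that series plus iid noise, and a fraction of voxel-time points is
    replaced by ``outlier_scale``-magnitude spikes.  Returns the block and
    the regions x T ground-truth matrix.
    """
    if voxels_per_region < 1:
        raise ValueError("voxels_per_region must be >= 1")
    rng = np.random.default_rng(seed)
    n = scheme.n_regions
    # smooth ground truth: random walk, de-trended
    truth = np.cumsum(rng.standard_normal((n, n_timepoints)), axis=1)
    truth -= truth.mean(axis=1, keepdims=True)
    data = np.repeat(truth, voxels_per_region, axis=0)
    data = data + noise_sd * rng.standard_normal(data.shape)
    labels = [name for name in scheme.names for _ in range(voxels_per_region)]
    if outlier_fraction > 0:
        mask = rng.random(data.shape) < outlier_fraction
        spikes = outlier_scale * rng.choice([-1.0, 1.0], size=data.shape)
        data = np.where(mask, spikes, data)
    return VoxelBlock(data=data, tr=tr, labels=labels), truth
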