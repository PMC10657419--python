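"""Synthetic multi-subject fMRI benchmark generator.

Emulates a Simtb-style experiment: HRF-convolved event trains as temporal
sources, anisotropic Gaussian blobs on a 50x50 voxel grid as spatial maps,
and a noisy linear mixture Y = sum_i (tc_i + psi_i)(sm_i + phi_i) per
subject.  The default configuration is the four-subject design used
throughout this package's evaluation harness: 300 scans (TR = 1 s), 2500
voxels, nine spatiotemporal sources per subject drawn from a pool of 18
temporal and 12 spatial sources, with a 6 / 2 / 1 sharing pattern:

* sources 1-6: common time courses (up to HRF jitter) and common maps,
* sources 7-8: common maps but subject-unique time courses,
* source 9: both map and time course unique to each subject.

Inter-subject spatial variability is controlled by random translation
(sigma = 1.5 voxels), rotation (sigma = 0.9 degrees) and scaling drawn
from N(rho, 0.05^2); rho, the mean spread, sets the degree of overlap
between neighbouring blobs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hrf import CANONICAL_HRF, HrfParams, convolve_events, jitter_hrf

__all__ = [
    "BlobSpec",
    "VariabilityParams",
    "NoiseParams",
    "GroundTruth",
    "SynthConfig",
    "SyntheticDataset",
    "default_catalog",
    "make_event_train",
    "make_temporal_sources",
    "make_spatial_sources",
    "mix_subject",
    "make_dataset",
]

# design seeds fixed so the planted sources are identical across trials;
# only noise and inter-subject variability are redrawn per trial seed
_DESIGN_SEED_BASE = 180_000
_N_TEMPORAL_DESIGNS = 18
_EVENT_PROB = 0.06

LABEL_COMMON = "common-TC-common-SM"
LABEL_UNIQUE_TC = "unique-TC-common-SM"
LABEL_UNIQUE = "unique-TC-unique-SM"


@dataclass(frozen=True)
class BlobSpec:
    """One Gaussian-blob spatial source on the voxel grid."""

    source_id: int
    center: tuple[float, float]  # (x, y) grid units
    base_scale: float  # multiplies the sampled spread
    amplitude: float = 1.0
    aspect: float = 1.0  # sy / sx anisotropy
    theta0: float = 0.0  # base orientation, degrees

    def __post_init__(self) -> None:
        if self.base_scale <= 0:
            raise ValueError("base_scale must be positive")


@dataclass(frozen=True)
class VariabilityParams:
    """Inter-subject spatial variability (grid units / degrees)."""

    translation_sigma: float = 1.5
    rotation_sigma: float = 0.9
    scale_mean: float = 5.0  # rho, the spread parameter
    scale_sigma: float = 0.05

    def __post_init__(self) -> None:
        if min(self.translation_sigma, self.rotation_sigma, self.scale_sigma) < 0:
            raise ValueError("variability sigmas must be >= 0")
        if self.scale_mean <= 0:
            raise ValueError("scale_mean (rho) must be positive")


@dataclass(frozen=True)
class NoiseParams:
    """Variances of the additive temporal / spatial Gaussian noise."""

    temporal_variance: float = 0.3  # n_t
    spatial_variance: float = 0.01

    def __post_init__(self) -> None:
        if self.temporal_variance < 0 or self.spatial_variance < 0:
            raise ValueError("noise variances must be >= 0")


@dataclass
class GroundTruth:
    """Planted sources: time courses (N x P) and spatial maps (P x V)."""

    tcs: np.ndarray
    sms: np.ndarray
    sharing_labels: list[str]

    def __post_init__(self) -> None:
        if self.tcs.shape[1] != self.sms.shape[0]:
            raise ValueError("tcs columns must match sms rows")
        if len(self.sharing_labels) != self.sms.shape[0]:
            raise ValueError("one sharing label per source required")

    @property
    def n_sources(self) -> int:
        return self.sms.shape[0]


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the multi-subject synthetic benchmark."""

    n_subjects: int = 4
    n_scans: int = 300
    tr: float = 1.0
    grid: tuple[int, int] = (50, 50)
    n_sources: int = 9
    rho: float = 5.0
    noise: NoiseParams = field(default_factory=NoiseParams)
    translation_sigma: float = 1.5
    rotation_sigma: float = 0.9
    scale_sigma: float = 0.05
    hrf_jitter_sigma: float = 0.5
    hrf: HrfParams = field(default_factory=lambda: CANONICAL_HRF)

    @property
    def n_voxels(self) -> int:
        return self.grid[0] * self.grid[1]

    def variability(self) -> VariabilityParams:
        return VariabilityParams(
            translation_sigma=self.translation_sigma,
            rotation_sigma=self.rotation_sigma,
            scale_mean=self.rho,
            scale_sigma=self.scale_sigma,
        )


@dataclass
class SyntheticDataset:
    """One realisation of the benchmark: data, per-subject and group truth."""

    subjects: list  # list[SubjectMatrix]
    truths: list[GroundTruth]
    group_truth: GroundTruth
    config: SynthConfig
    seed: int
    metadata: dict = field(default_factory=dict)


def default_catalog(grid: tuple[int, int] = (50, 50)) -> list[BlobSpec]:
    """Twelve distinct, overlappable blobs on the grid.

    Stands in for the Simtb source-ID shapes: what matters for the benchmark
    is a set of distinct activation foci whose mutual overlap grows with the
    spread parameter rho.
    """
    gx, gy = grid
    sx, sy = gx / 50.0, gy / 50.0
    raw = [
        # (cx, cy, base_scale, aspect, theta0)
        (10, 10, 0.80, 1.00, 0.0),
        (25, 8, 0.70, 1.30, 20.0),
        (40, 11, 0.90, 0.75, -30.0),
        (8, 26, 0.75, 1.20, 45.0),
        (24, 22, 1.00, 1.00, 0.0),
        (41, 25, 0.70, 0.80, 60.0),
        (11, 40, 0.85, 1.25, -15.0),
        (26, 41, 0.75, 0.70, 30.0),
        (40, 40, 0.90, 1.10, 10.0),
        (17, 32, 0.65, 0.85, -45.0),
        (33, 33, 0.70, 1.15, 70.0),
        (32, 15, 0.65, 0.90, -60.0),
    ]
    return [
        BlobSpec(
            source_id=i + 1,
            center=(cx * sx, cy * sy),
            base_scale=s,
            aspect=a,
            theta0=t,
        )
        for i, (cx, cy, s, a, t) in enumerate(raw)
    ]


def make_event_train(
    n_scans: int, design_seed: int, event_prob: float = _EVENT_PROB
) -> np.ndarray:
    """Bernoulli event train on the TR grid from a fixed design seed."""
    rng = np.random.default_rng(design_seed)
    train = (rng.random(n_scans) < event_prob).astype(float)
    if not train.any():  # pathological seed: force one event
        train[rng.integers(n_scans)] = 1.0
    return train


def make_temporal_sources(
    n_scans: int,
    tr: float,
    onsets: list[np.ndarray],
    hrf: HrfParams = CANONICAL_HRF,
    rng: np.random.Generator | None = None,
    jitter_sigma: float = 0.0,
    allow_empty: bool = False,
) -> np.ndarray:
    """Build an N x P matrix of HRF-convolved event time courses.

    Parameters
    ----------
    onsets
        One array of event onset times (seconds) per source.
    jitter_sigma
        If positive, each source's HRF parameters are jittered with this
        standard deviation (requires ``rng``), modelling hemodynamic
        variability.
    allow_empty
        Permit empty onset lists (producing an all-zero column).
    """
    if n_scans * tr < hrf.kernel_length:
        raise ValueError("scan window shorter than the HRF kernel")
    cols = []
    for p, ons in enumerate(onsets):
        ons = np.asarray(ons, dtype=float)
        if ons.size == 0 and not allow_empty:
            raise ValueError(f"source {p} has an empty onset list")
        if ons.size and (ons.min() < 0 or ons.max() >= n_scans * tr):
            raise ValueError(f"source {p} has onsets outside [0, {n_scans * tr})")
        train = np.zeros(n_scans)
        idx = np.round(ons / tr).astype(int)
        np.add.at(train, np.clip(idx, 0, n_scans - 1), 1.0)
        params = hrf
        if jitter_sigma > 0:
            if rng is None:
                raise ValueError("jitter_sigma > 0 requires an rng")
            params = jitter_hrf(hrf, rng, jitter_sigma)
        cols.append(convolve_events(train, params, tr))
    return np.column_stack(cols)


def _render_blob(
    grid: tuple[int, int],
    center: tuple[float, float],
    sx: float,
    sy: float,
    theta_deg: float,
    amplitude: float,
) -> np.ndarray:
    gx, gy = grid
    xs = np.arange(gx, dtype=float)
    ys = np.arange(gy, dtype=float)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    dx = X - center[0]
    dy = Y - center[1]
    th = np.deg2rad(theta_deg)
    xr = np.cos(th) * dx + np.sin(th) * dy
    yr = -np.sin(th) * dx + np.cos(th) * dy
    img = amplitude * np.exp(-0.5 * ((xr / sx) ** 2 + (yr / sy) ** 2))
    return img.ravel()


def make_spatial_sources(
    grid: tuple[int, int],
    catalog: list[BlobSpec],
    var: VariabilityParams,
    rng: np.random.Generator,
    max_retries: int = 50,
) -> np.ndarray:
    """Render one subject's P x V spatial source maps.

    Each catalog blob is perturbed with a random translation, rotation and
    scale draw; the sampled scale multiplies the blob's ``base_scale`` to
    give the Gaussian spread in voxels.  Rows are the (x, y) image raveled
    in C order (y varies fastest), matching the NIfTI export layout.
    """
    if not catalog:
        raise ValueError("catalog must be nonempty")
    if grid[0] <= 0 or grid[1] <= 0:
        raise ValueError("grid must be positive")
    rows = []
    for spec in catalog:
        cx, cy = spec.center
        if not (0 <= cx < grid[0] and 0 <= cy < grid[1]):
            raise ValueError(f"blob {spec.source_id} center outside the grid")
        shift = var.translation_sigma * rng.standard_normal(2)
        theta = spec.theta0 + var.rotation_sigma * rng.standard_normal()
        scale = var.scale_mean + var.scale_sigma * rng.standard_normal()
        tries = 0
        while scale <= 0 and tries < max_retries:
            scale = var.scale_mean + var.scale_sigma * rng.standard_normal()
            tries += 1
        if scale <= 0:
            raise ValueError(f"could not sample a positive scale for blob {spec.source_id}")
        sx = scale * spec.base_scale
        sy = scale * spec.base_scale * spec.aspect
        rows.append(
            _render_blob(grid, (cx + shift[0], cy + shift[1]), sx, sy, theta, spec.amplitude)
        )
    return np.vstack(rows)


def mix_subject(
    tcs: np.ndarray,
    sms: np.ndarray,
    noise: NoiseParams,
    rng: np.random.Generator,
):
    """Noisy linear mixture Y = sum_i (tc_i + psi_i)(sm_i + phi_i).

    psi columns are N(0, temporal_variance), phi rows N(0, spatial_variance).
    Because the sum of outer products of the noisy pairs equals the matrix
    product of the noisy factors, this is computed as (T + Psi)(S + Phi).
    Returns (Y, Psi, Phi).
    """
    tcs = np.asarray(tcs, dtype=float)
    sms = np.asarray(sms, dtype=float)
    if tcs.shape[1] != sms.shape[0]:
        raise ValueError("tcs / sms shapes not conformable")
    psi = np.sqrt(noise.temporal_variance) * rng.standard_normal(tcs.shape)
    phi = np.sqrt(noise.spatial_variance) * rng.standard_normal(sms.shape)
    Y = (tcs + psi) @ (sms + phi)
    return Y, psi, phi


def _standardize_columns(T: np.ndarray) -> np.ndarray:
    T = T - T.mean(axis=0, keepdims=True)
    sd = T.std(axis=0, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return T / sd


def _design_indices(subject: int) -> list[int]:
    """Temporal design index per source for one subject.

    Designs 0-5 are the six common time courses; designs 6-9 / 10-13 hold
    the four subject-unique patterns of sources 7 / 8; designs 14-17 are the
    unique ninth-source patterns.
    """
    return list(range(6)) + [6 + subject, 10 + subject, 14 + subject]


def _catalog_indices(subject: int) -> list[int]:
    """Spatial catalog index per source for one subject (8 shared + 1 unique)."""
    return list(range(8)) + [8 + subject]


def make_dataset(config: SynthConfig = SynthConfig(), seed: int = 0) -> SyntheticDataset:
    """Generate the full multi-subject benchmark realisation for one seed.

    Returns per-subject data matrices with their nine-source ground truths
    and the twelve-source group ground truth (subject 1's nine sources plus
    the other subjects' unique ninth sources).
    """
    from .preprocess import SubjectMatrix  # local import to avoid a cycle

    catalog = default_catalog(config.grid)
    if config.n_sources > 9 or config.n_subjects > 4:
        raise ValueError(
            "default design supports at most 4 subjects with 9 sources each"
        )
    rng = np.random.default_rng(seed)
    var = config.variability()

    # fixed designs (event trains) shared across trials
    trains = [
        make_event_train(config.n_scans, _DESIGN_SEED_BASE + d)
        for d in range(_N_TEMPORAL_DESIGNS)
    ]

    subjects: list = []
    truths: list[GroundTruth] = []
    labels = (
        [LABEL_COMMON] * 6 + [LABEL_UNIQUE_TC] * 2 + [LABEL_UNIQUE]
    )[: config.n_sources]

    for m in range(config.n_subjects):
        hrf_m = jitter_hrf(config.hrf, rng, config.hrf_jitter_sigma)
        d_idx = _design_indices(m)[: config.n_sources]
        T = np.column_stack(
            [convolve_events(trains[d], hrf_m, config.tr) for d in d_idx]
        )
        T = _standardize_columns(T)
        c_idx = _catalog_indices(m)[: config.n_sources]
        S = make_spatial_sources(config.grid, [catalog[i] for i in c_idx], var, rng)
        Y, _, _ = mix_subject(T, S, config.noise, rng)
        subjects.append(
            SubjectMatrix(data=Y, tr=config.tr, subject_id=f"sub-{m + 1:02d}")
        )
        truths.append(GroundTruth(tcs=T, sms=S, sharing_labels=list(labels)))

    # group references: subject 1's nine sources + other subjects' ninth source
    g_tcs = [truths[0].tcs]
    g_sms = [truths[0].sms]
    g_labels = list(labels)
    for m in range(1, config.n_subjects):
        g_tcs.append(truths[m].tcs[:, -1:])
        g_sms.append(truths[m].sms[-1:, :])
        g_labels.append(LABEL_UNIQUE)
    group_truth = GroundTruth(
        tcs=np.column_stack(g_tcs), sms=np.vstack(g_sms), sharing_labels=g_labels
    )

    meta = {
        "seed": seed,
        "rho": config.rho,
        "noise_temporal_variance": config.noise.temporal_variance,
        "noise_spatial_variance": config.noise.spatial_variance,
        "mixture_sources": config.n_sources,
        "mixture_note": (
            "mixture sums over all 9 planted sources per subject; temporal "
            "sources standardised to zero mean / unit variance"
        ),
    }
    return SyntheticDataset(
        subjects=subjects,
        truths=truths,
        group_truth=group_truth,
        config=config,
        seed=seed,
        metadata=meta,
    )


def mean_pairwise_overlap(sms: np.ndarray) -> float:
    """Mean inner product between distinct l2-normalised map rows."""
    norms = np.linalg.norm(sms, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    U = sms / norms
    G = U @ U.T
    P = G.shape[0]
    off = G[~np.eye(P, dtype=bool)]
    return float(off.mean())
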