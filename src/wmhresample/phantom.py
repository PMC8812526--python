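"""Synthetic cohort generation.

Builds co-registered 3D phantom image pairs (FLAIR-like and T1-like) with
binary ground-truth lesion masks whose population statistics emulate a
normal-aging cohort with a low white-matter-hyperintensity (WMH) load:
right-skewed lesion volumes with a point mass at zero, paired baseline
(BL) / follow-up (FU) scans with intra-individual lesion growth, and a
fixed external partition never used for training.

The lesion-volume law is a zero-inflated log-normal.  The default
``(log_mu, log_sigma)`` were obtained once by quantile matching so that
the mixture median is 0.34 ml and the interquartile range 1.6 ml, the
summary statistics of the cohort being emulated; the zero-mass default is
21/160.  The anatomy is a nested-ellipsoid head phantom: a brain mask, a
GM-like shell, a WM-eligible shell and a CSF-like core.  Lesions are
quasi-spherical blobs grown voxel-by-voxel inside the WM-eligible region
until the realized mask hits the target voxel count exactly (or the
configured capacity, whichever is smaller).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import GenerationError, ParameterError
from .rng import spawn_rng

__all__ = [
    "LesionVolumeModel",
    "PhantomParams",
    "SubjectImage",
    "Cohort",
    "sample_lesion_volume",
    "generate_subject",
    "make_followup",
    "generate_cohort",
    "wm_capacity_voxels",
]

# Calibrated once by quantile matching (median 0.34 ml, IQR 1.6 ml at the
# default zero mass); do not retune per run.
_DEFAULT_LOG_MU = -0.6777304147031015
_DEFAULT_LOG_SIGMA = 2.105452522992593

# De-novo FU lesions are small: log-normal with median 0.1 ml.
_NEW_LESION_LOG_MU = math.log(0.1)
_NEW_LESION_LOG_SIGMA = 0.7


@dataclass(frozen=True)
class LesionVolumeModel:
    """Two-part lesion-volume law plus longitudinal progression.

    Parameters
    ----------
    p_zero
        Probability that a subject has no lesion at all.
    log_mu, log_sigma
        Log-normal parameters (log-ml) of the volume for lesioned subjects.
    growth_factor_mean, growth_factor_sd
        Multiplicative BL->FU volume growth; factors are truncated at 1 so
        lesions never shrink (monotone construction).
    new_lesion_rate
        Expected number of de-novo lesions appearing at FU (Poisson).
    """

    p_zero: float = 21.0 / 160.0
    log_mu: float = _DEFAULT_LOG_MU
    log_sigma: float = _DEFAULT_LOG_SIGMA
    growth_factor_mean: float = 1.6
    growth_factor_sd: float = 0.3
    new_lesion_rate: float = 0.2

    def validate(self) -> None:
        if not 0.0 <= self.p_zero <= 1.0:
            raise ParameterError(f"p_zero must be in [0, 1], got {self.p_zero}")
        if self.log_sigma < 0:
            raise ParameterError(f"log_sigma must be >= 0, got {self.log_sigma}")
        if self.growth_factor_mean < 0 or self.growth_factor_sd < 0:
            raise ParameterError("growth factor parameters must be >= 0")
        if self.new_lesion_rate < 0:
            raise ParameterError("new_lesion_rate must be >= 0")


# (FLAIR, T1) intensity means per tissue, arbitrary units.  Lesions are
# hyperintense on FLAIR and mildly hypointense on T1; CSF is suppressed on
# FLAIR (fluid attenuation) and dark on T1.
_DEFAULT_TISSUE_MEANS = {
    "background": (0.0, 0.0),
    "csf": (30.0, 40.0),
    "wm": (100.0, 120.0),
    "gm": (115.0, 90.0),
    "lesion": (150.0, 100.0),
}
_DEFAULT_TISSUE_SDS = {
    "background": (1.0, 1.0),
    "csf": (4.0, 4.0),
    "wm": (5.0, 5.0),
    "gm": (5.0, 5.0),
    "lesion": (6.0, 6.0),
}


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, intensity and cohort-size parameters of the phantom."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tissue_means: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_TISSUE_MEANS)
    )
    tissue_sds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_TISSUE_SDS)
    )
    noise_sd: float = 8.0
    n_paired: int = 80
    n_external: int = 41
    seed: int = 0
    # ellipsoid semi-axis fractions of the grid extent
    brain_frac: float = 0.42
    gm_frac: float = 0.36
    csf_frac: float = 0.10
    # largest lesion target allowed, as a fraction of the WM-eligible region
    capacity_frac: float = 0.5
    blob_mean_voxels: int = 150

    def validate(self) -> None:
        if any(s < 16 for s in self.grid_shape):
            raise ParameterError(f"grid_shape axes must all be >= 16, got {self.grid_shape}")
        if any(d <= 0 for d in self.voxel_dims):
            raise ParameterError(f"voxel_dims must all be > 0, got {self.voxel_dims}")
        if self.tissue_means["lesion"][0] <= self.tissue_means["wm"][0]:
            raise ParameterError("lesion FLAIR mean must exceed WM FLAIR mean")
        if self.n_paired < 0 or self.n_external < 0:
            raise ParameterError("cohort counts must be >= 0")
        if not 0 < self.csf_frac < self.gm_frac < self.brain_frac <= 0.5:
            raise ParameterError("ellipsoid fractions must satisfy 0 < csf < gm < brain <= 0.5")
        if not 0 < self.capacity_frac <= 1:
            raise ParameterError("capacity_frac must be in (0, 1]")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_dims)) / 1000.0


@dataclass
class SubjectImage:
    """One observation: co-registered volumes plus ground-truth masks."""

    participant_id: str
    timepoint: str  # "BL" | "FU"
    flair: np.ndarray
    t1: np.ndarray
    brain_mask: np.ndarray
    manual_mask: np.ndarray
    voxel_dims: tuple[float, float, float]

    def __post_init__(self) -> None:
        shapes = {self.flair.shape, self.t1.shape, self.brain_mask.shape, self.manual_mask.shape}
        if len(shapes) != 1:
            raise ParameterError(f"volumes must share one grid, got shapes {shapes}")
        if np.any(self.manual_mask & ~self.brain_mask):
            raise ParameterError("manual_mask must lie inside brain_mask")

    @property
    def manual_volume_ml(self) -> float:
        return float(self.manual_mask.sum()) * float(np.prod(self.voxel_dims)) / 1000.0


@dataclass
class Cohort:
    """The study dataset: paired resampling partition plus the external set."""

    resampling_subjects: list[SubjectImage]
    external_subjects: list[SubjectImage]
    params: PhantomParams
    model: LesionVolumeModel

    @property
    def participant_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.resampling_subjects:
            seen.setdefault(s.participant_id, None)
        return list(seen)

    @property
    def n_paired(self) -> int:
        return len(self.participant_ids)

    def get(self, participant_id: str, timepoint: str) -> SubjectImage:
        for s in self.resampling_subjects + self.external_subjects:
            if s.participant_id == participant_id and s.timepoint == timepoint:
                return s
        raise KeyError((participant_id, timepoint))

    def observations(self) -> Iterator[tuple[str, SubjectImage]]:
        """Yield (partition, subject) for every observation."""
        for s in self.resampling_subjects:
            yield "resampling", s
        for s in self.external_subjects:
            yield "external", s


def sample_lesion_volume(
    model: LesionVolumeModel,
    rng: np.random.Generator,
    size: int | None = None,
) -> float | np.ndarray:
    """Draw target lesion volumes (ml) from the two-part mixture.

    Returns 0 with probability ``p_zero``, otherwise a log-normal draw.
    A vector of draws is returned when ``size`` is given.
    """
    model.validate()
    n = 1 if size is None else int(size)
    zero = rng.random(n) < model.p_zero
    vols = np.where(zero, 0.0, rng.lognormal(model.log_mu, model.log_sigma, n))
    if size is None:
        return float(vols[0])
    return vols


# ---------------------------------------------------------------------------
# anatomy


def _ellipsoid(shape: tuple[int, int, int], frac: float) -> np.ndarray:
    """Filled ellipsoid mask with semi-axes frac*shape, centered."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = np.zeros(shape, dtype=float)
    for g, s in zip(grids, shape):
        c = (s - 1) / 2.0
        a = frac * s
        r2 = r2 + ((g - c) / a) ** 2
    return r2 <= 1.0


def _anatomy(params: PhantomParams) -> dict[str, np.ndarray]:
    brain = _ellipsoid(params.grid_shape, params.brain_frac)
    gm_inner = _ellipsoid(params.grid_shape, params.gm_frac)
    csf = _ellipsoid(params.grid_shape, params.csf_frac)
    wm = gm_inner & ~csf
    gm = brain & ~gm_inner
    return {"brain": brain, "gm": gm, "wm": wm, "csf": csf}


def wm_capacity_voxels(params: PhantomParams) -> int:
    """Number of WM-eligible voxels lesions may occupy."""
    return int(_anatomy(params)["wm"].sum())


# ---------------------------------------------------------------------------
# lesion growth

_NEIGHBOR_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def _grow_blob(
    lesion: np.ndarray,
    eligible: np.ndarray,
    seed_voxel: tuple[int, int, int],
    n_voxels: int,
    voxel_dims: tuple[float, float, float],
    rng: np.random.Generator,
) -> int:
    """Grow one quasi-spherical blob of ``n_voxels`` from ``seed_voxel``.

    Voxels are added nearest-to-seed first (mm metric) with a small random
    jitter on the priority so blobs are irregular.  Returns the number of
    voxels actually added (may fall short if the frontier is exhausted).
    """
    if n_voxels <= 0:
        return 0
    shape = lesion.shape
    sz = np.asarray(seed_voxel, dtype=float)
    dims = np.asarray(voxel_dims, dtype=float)
    heap: list[tuple[float, int, tuple[int, int, int]]] = []
    counter = 0
    added = 0
    in_heap = set()

    def push(v: tuple[int, int, int]) -> None:
        nonlocal counter
        if v in in_heap:
            return
        d = float(np.linalg.norm((np.asarray(v, dtype=float) - sz) * dims))
        jitter = 1.0 + 0.25 * rng.random()
        heapq.heappush(heap, (d * jitter, counter, v))
        in_heap.add(v)
        counter += 1

    push(tuple(seed_voxel))
    while heap and added < n_voxels:
        _, _, v = heapq.heappop(heap)
        if lesion[v] or not eligible[v]:
            continue
        lesion[v] = True
        added += 1
        for off in _NEIGHBOR_OFFSETS:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if all(0 <= w[i] < shape[i] for i in range(3)) and eligible[w] and not lesion[w]:
                push(w)
    return added


def _grow_from_mask(
    lesion: np.ndarray,
    eligible: np.ndarray,
    n_voxels: int,
    rng: np.random.Generator,
) -> int:
    """Dilate the existing lesion mask by ``n_voxels`` voxels, frontier-first.

    Used both as the FU growth mechanism and as the top-up pass that makes
    realized blob volumes exact.
    """
    if n_voxels <= 0 or not lesion.any():
        return 0
    shape = lesion.shape
    heap: list[tuple[float, int, tuple[int, int, int]]] = []
    counter = 0
    in_heap = set()

    def push(v: tuple[int, int, int], depth: float) -> None:
        nonlocal counter
        if v in in_heap:
            return
        heapq.heappush(heap, (depth + 0.25 * rng.random(), counter, v))
        in_heap.add(v)
        counter += 1

    idx = np.argwhere(lesion)
    for v in map(tuple, idx):
        for off in _NEIGHBOR_OFFSETS:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if all(0 <= w[i] < shape[i] for i in range(3)) and eligible[w] and not lesion[w]:
                push(w, 1.0)
    added = 0
    while heap and added < n_voxels:
        depth, _, v = heapq.heappop(heap)
        if lesion[v] or not eligible[v]:
            continue
        lesion[v] = True
        added += 1
        for off in _NEIGHBOR_OFFSETS:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if all(0 <= w[i] < shape[i] for i in range(3)) and eligible[w] and not lesion[w]:
                push(w, depth + 1.0)
    return added


def _build_lesion_mask(
    params: PhantomParams,
    wm: np.ndarray,
    n_target: int,
    rng: np.random.Generator,
) -> np.ndarray:
    lesion = np.zeros(params.grid_shape, dtype=bool)
    if n_target <= 0:
        return lesion
    capacity = int(wm.sum())
    if n_target > capacity:
        raise GenerationError(
            f"lesion target of {n_target} voxels exceeds WM capacity of {capacity}"
        )
    n_blobs = max(1, round(n_target / params.blob_mean_voxels))
    parts = rng.multinomial(n_target, np.full(n_blobs, 1.0 / n_blobs))
    wm_idx = np.argwhere(wm)
    for part in parts:
        if part <= 0:
            continue
        free = ~lesion
        # rejection-sample a seed voxel not already lesioned
        for _ in range(100):
            v = tuple(wm_idx[rng.integers(len(wm_idx))])
            if free[v]:
                break
        else:
            continue
        _grow_blob(lesion, wm, v, int(part), params.voxel_dims, rng)
    # exactness top-up: the WM region is connected, so frontier growth can
    # always reach the target while it is within capacity
    deficit = n_target - int(lesion.sum())
    if deficit > 0:
        _grow_from_mask(lesion, wm, deficit, rng)
    return lesion


def _render(
    params: PhantomParams,
    anatomy: dict[str, np.ndarray],
    lesion: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Paint FLAIR and T1 volumes from the tissue label map plus noise."""
    flair = np.zeros(params.grid_shape, dtype=np.float32)
    t1 = np.zeros(params.grid_shape, dtype=np.float32)
    regions = {
        "csf": anatomy["csf"],
        "wm": anatomy["wm"] & ~lesion,
        "gm": anatomy["gm"],
        "lesion": lesion,
    }
    for tissue, region in regions.items():
        n = int(region.sum())
        if n == 0:
            continue
        fm, tm = params.tissue_means[tissue]
        fs, ts = params.tissue_sds[tissue]
        flair[region] = fm + fs * rng.standard_normal(n)
        t1[region] = tm + ts * rng.standard_normal(n)
    if params.noise_sd > 0:
        brain = anatomy["brain"]
        n = int(brain.sum())
        flair[brain] += params.noise_sd * rng.standard_normal(n)
        t1[brain] += params.noise_sd * rng.standard_normal(n)
    return flair, t1


def generate_subject(
    params: PhantomParams,
    target_volume_ml: float,
    participant_id: str,
    timepoint: str,
    rng: np.random.Generator,
) -> SubjectImage:
    """Generate one phantom observation with the given target lesion volume.

    The realized mask volume equals the target rounded to whole voxels
    exactly, provided the target fits in the WM-eligible region; otherwise
    a :class:`GenerationError` is raised.
    """
    params.validate()
    if target_volume_ml < 0:
        raise ParameterError(f"target volume must be >= 0, got {target_volume_ml}")
    anatomy = _anatomy(params)
    n_target = round(target_volume_ml / params.voxel_volume_ml)
    lesion = _build_lesion_mask(params, anatomy["wm"], n_target, rng)
    flair, t1 = _render(params, anatomy, lesion, rng)
    return SubjectImage(
        participant_id=participant_id,
        timepoint=timepoint,
        flair=flair,
        t1=t1,
        brain_mask=anatomy["brain"],
        manual_mask=lesion,
        voxel_dims=params.voxel_dims,
    )


def make_followup(
    bl: SubjectImage,
    model: LesionVolumeModel,
    rng: np.random.Generator,
    params: PhantomParams,
) -> SubjectImage:
    """Generate the FU observation of a BL subject on the same anatomy.

    Existing lesions are dilated by a sampled multiplicative growth factor
    (truncated at 1) and de-novo lesions are added with Poisson rate
    ``new_lesion_rate``, so the FU manual volume is always >= the BL one.
    Growth beyond the WM-eligible capacity is truncated.
    """
    if bl.timepoint != "BL":
        raise ParameterError("make_followup expects a BL subject")
    model.validate()
    anatomy = _anatomy(params)
    wm = anatomy["wm"]
    capacity = int(wm.sum())
    lesion = bl.manual_mask.copy()
    n_bl = int(lesion.sum())

    g = max(1.0, float(rng.normal(model.growth_factor_mean, model.growth_factor_sd)))
    grow_by = min(round(n_bl * g), capacity) - n_bl
    _grow_from_mask(lesion, wm, grow_by, rng)

    n_new = int(rng.poisson(model.new_lesion_rate))
    if n_new > 0:
        wm_idx = np.argwhere(wm)
        for _ in range(n_new):
            vol_ml = float(rng.lognormal(_NEW_LESION_LOG_MU, _NEW_LESION_LOG_SIGMA))
            n_vox = min(round(vol_ml / params.voxel_volume_ml), capacity - int(lesion.sum()))
            if n_vox <= 0:
                continue
            for _ in range(100):
                v = tuple(wm_idx[rng.integers(len(wm_idx))])
                if not lesion[v]:
                    break
            else:
                continue
            _grow_blob(lesion, wm, v, n_vox, params.voxel_dims, rng)

    flair, t1 = _render(params, anatomy, lesion, rng)
    return SubjectImage(
        participant_id=bl.participant_id,
        timepoint="FU",
        flair=flair,
        t1=t1,
        brain_mask=anatomy["brain"],
        manual_mask=lesion,
        voxel_dims=params.voxel_dims,
    )


def generate_cohort(params: PhantomParams, model: LesionVolumeModel | None = None) -> Cohort:
    """Generate the full study cohort, reproducibly from ``params.seed``.

    Each participant consumes its own named random substream, so the
    cohort is stable under changes to ``n_paired``/``n_external`` for the
    participants that remain.  Lesion targets beyond ``capacity_frac`` of
    the WM-eligible region are clipped (the log-normal tail is heavier
    than the phantom can hold on small grids).
    """
    params.validate()
    model = model if model is not None else LesionVolumeModel()
    model.validate()
    cap_ml = params.capacity_frac * wm_capacity_voxels(params) * params.voxel_volume_ml

    resampling: list[SubjectImage] = []
    for i in range(params.n_paired):
        pid = f"sub-{i + 1:04d}"
        rng = spawn_rng(params.seed, "participant", i)
        target = min(float(sample_lesion_volume(model, rng)), cap_ml)
        bl = generate_subject(params, target, pid, "BL", rng)
        fu = make_followup(bl, model, rng, params)
        resampling.extend([bl, fu])

    external: list[SubjectImage] = []
    for j in range(params.n_external):
        pid = f"ext-{j + 1:04d}"
        rng = spawn_rng(params.seed, "external", j)
        target = min(float(sample_lesion_volume(model, rng)), cap_ml)
        external.append(generate_subject(params, target, pid, "FU", rng))

    return Cohort(
        resampling_subjects=resampling,
        external_subjects=external,
        params=params,
        model=model,
    )
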