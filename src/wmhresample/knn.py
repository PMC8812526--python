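"""Voxel-wise k-nearest-neighbour lesion classifier.

A minimal re-implementation of the trainable probabilistic segmenter
family used for WMH volumetry: per-voxel features are the standardized
FLAIR and T1 intensities (within the brain mask) plus grid-normalized
spatial coordinates scaled by a spatial weight, and the lesion
probability of a voxel is the fraction of lesion-labelled points among
its k nearest reference points in feature space (Euclidean metric).

Defaults follow the published recommendations for this family of tools:
k = 40 neighbours and per-draw reference sets capped at 2000 lesion /
10000 non-lesion points sampled uniformly without replacement.  Exact
distance ties at the k-th neighbour are broken by stable reference-point
order (lowest index first); the fast path detects boundary ties and
falls back to an exact stable sort for the affected voxels only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.neighbors import KDTree, NearestNeighbors

from .errors import InputError, ParameterError
from .phantom import SubjectImage

__all__ = [
    "FeatureConfig",
    "TrainingPointPolicy",
    "TrainedClassifier",
    "ProbabilityMap",
    "extract_features",
    "fit",
    "predict_probability",
    "binarize",
    "knn_lesion_fraction",
    "KnnIndex",
    "save_classifier",
    "load_classifier",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-space definition for the voxel classifier."""

    use_modalities: tuple[str, ...] = ("flair", "t1")
    spatial_weight: float = 1.0

    def validate(self) -> None:
        if self.spatial_weight < 0:
            raise ParameterError("spatial_weight must be >= 0")
        if not self.use_modalities:
            raise ParameterError("at least one modality is required")


@dataclass(frozen=True)
class TrainingPointPolicy:
    """Per-class caps on the pooled reference set."""

    max_lesion_points: int = 2000
    max_nonlesion_points: int = 10000

    def validate(self) -> None:
        if self.max_lesion_points < 1 or self.max_nonlesion_points < 1:
            raise ParameterError("point caps must be >= 1")


@dataclass
class TrainedClassifier:
    """The saved per-draw model: reference points, labels and settings."""

    features: np.ndarray  # (points, n_modalities + 3)
    labels: np.ndarray  # (points,) uint8
    k: int
    normalization_stats: dict[str, list[tuple[float, float]]]  # per training subject
    config: FeatureConfig
    draw_id: str = ""

    @property
    def is_degenerate(self) -> bool:
        return self.labels.sum() == 0

    def validate(self) -> None:
        if len(self.features) and self.k > len(self.features):
            raise ParameterError(f"k={self.k} exceeds {len(self.features)} reference points")


@dataclass
class ProbabilityMap:
    """Per-voxel lesion probability, zero outside the brain mask."""

    values: np.ndarray
    participant_id: str
    timepoint: str
    draw_id: str = ""


def _extract(
    subject: SubjectImage, config: FeatureConfig
) -> tuple[np.ndarray, np.ndarray, list[tuple[float, float]]]:
    config.validate()
    mask = subject.brain_mask.astype(bool)
    n = int(mask.sum())
    if n == 0:
        raise InputError("empty brain mask")
    idx = np.argwhere(mask)
    cols = []
    stats = []
    for name in config.use_modalities:
        vol = getattr(subject, name)
        vals = np.asarray(vol, dtype=np.float64)[mask]
        mu, sd = float(vals.mean()), float(vals.std())
        stats.append((mu, sd))
        cols.append((vals - mu) / sd if sd > 0 else np.zeros(n))
    shape = np.asarray(subject.brain_mask.shape, dtype=np.float64)
    denom = np.maximum(shape - 1.0, 1.0)
    coords = idx / denom * config.spatial_weight
    features = np.column_stack(cols + [coords]).astype(np.float32)
    return features, idx, stats


def extract_features(
    subject: SubjectImage, config: FeatureConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Feature rows for every brain-mask voxel, plus their voxel indices.

    Intensities are standardized to mean 0 / SD 1 within the mask per
    modality (SD-zero guard: constant images map to all-zero columns);
    the 3 spatial columns are voxel indices normalized to [0, 1] per axis
    and multiplied by the spatial weight.
    """
    features, idx, _ = _extract(subject, config)
    return features, idx


def fit(
    subjects: list[SubjectImage],
    policy: TrainingPointPolicy,
    config: FeatureConfig,
    k: int = 40,
    rng: np.random.Generator | None = None,
    draw_id: str = "",
) -> TrainedClassifier:
    """Pool labelled voxels across training subjects into a classifier.

    Lesion voxels (label 1) come from the manual masks, non-lesion voxels
    (label 0) from the rest of the brain mask; each class is subsampled
    uniformly without replacement to the policy caps.  A training set
    with zero lesion voxels yields a degenerate classifier that predicts
    0 everywhere (with a warning).
    """
    if not subjects:
        raise InputError("at least one training subject is required")
    policy.validate()
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(0)

    lesion_rows, nonlesion_rows = [], []
    stats: dict[str, list[tuple[float, float]]] = {}
    for s in subjects:
        feats, idx, subject_stats = _extract(s, config)
        stats[f"{s.participant_id}_{s.timepoint}"] = subject_stats
        lesion_at = s.manual_mask[tuple(idx.T)].astype(bool)
        lesion_rows.append(feats[lesion_at])
        nonlesion_rows.append(feats[~lesion_at])
    lesion = np.concatenate(lesion_rows)
    nonlesion = np.concatenate(nonlesion_rows)

    def subsample(arr: np.ndarray, cap: int) -> np.ndarray:
        if len(arr) <= cap:
            return arr
        keep = np.sort(rng.choice(len(arr), size=cap, replace=False))
        return arr[keep]

    lesion = subsample(lesion, policy.max_lesion_points)
    nonlesion = subsample(nonlesion, policy.max_nonlesion_points)
    if len(lesion) == 0:
        warnings.warn(
            "training set has no lesion voxels; classifier will predict 0 everywhere",
            stacklevel=2,
        )
    # non-lesion points first: at an exact distance tie the stable order
    # favours the non-lesion point (conservative lesion calls)
    features = np.concatenate([nonlesion, lesion])
    labels = np.concatenate(
        [np.zeros(len(nonlesion), dtype=np.uint8), np.ones(len(lesion), dtype=np.uint8)]
    )
    k_eff = min(k, len(features))
    clf = TrainedClassifier(
        features=features,
        labels=labels,
        k=k_eff,
        normalization_stats=stats,
        config=config,
        draw_id=draw_id,
    )
    clf.validate()
    return clf


def knn_lesion_fraction(
    reference: np.ndarray,
    labels: np.ndarray,
    query: np.ndarray,
    k: int,
    index: "KnnIndex | None" = None,
) -> np.ndarray:
    """Fraction of lesion labels among the k nearest reference points.

    Euclidean metric; exact ties at the k-th distance are resolved in
    stable reference order (lowest index wins).  Voxels that provably
    have probability 0 — at least k non-lesion references strictly closer
    than the nearest lesion reference — are certified by two cheap tree
    queries; the full k-NN search runs only on the remaining voxels,
    with an exact stable-sort fallback on rows where a boundary
    distance tie is detected.
    """
    reference = np.asarray(reference, dtype=np.float32)
    query = np.asarray(query, dtype=np.float32)
    labels = np.asarray(labels)
    n_ref = len(reference)
    if k < 1 or k > n_ref:
        raise ParameterError(f"k={k} must be in [1, {n_ref}]")
    if query.shape[1] != reference.shape[1]:
        raise InputError("query/reference feature arity mismatch")
    if len(query) == 0:
        return np.zeros(0, dtype=np.float32)

    index = index if index is not None else KnnIndex(reference, labels)
    les_idx, non_idx = index.les_idx, index.non_idx
    if len(les_idx) == 0:
        return np.zeros(len(query), dtype=np.float32)
    if len(non_idx) >= k and len(query) > 512:
        d1les = index.lesion_tree.query(query, k=1)[0][:, 0]
        # strictly-closer count: shrink the radius by one ulp so exact
        # ties fall through to the full (stable-order) search
        r = np.nextafter(d1les, -np.inf)
        cnt = index.nonlesion_tree.query_radius(query, r=r, count_only=True)
        active = cnt < k
        prob = np.zeros(len(query), dtype=np.float32)
        if active.any():
            prob[active] = _knn_fraction_full(reference, labels, query[active], k, index)
        return prob
    return _knn_fraction_full(reference, labels, query, k, index)


class KnnIndex:
    """Prebuilt search trees over one reference set (reused across queries)."""

    def __init__(self, reference: np.ndarray, labels: np.ndarray, leaf_size: int = 40):
        self.les_idx = np.flatnonzero(labels == 1)
        self.non_idx = np.flatnonzero(labels == 0)
        self.lesion_tree = (
            KDTree(reference[self.les_idx], leaf_size=leaf_size) if len(self.les_idx) else None
        )
        self.nonlesion_tree = (
            KDTree(reference[self.non_idx], leaf_size=leaf_size) if len(self.non_idx) else None
        )
        self.full = NearestNeighbors(n_neighbors=1, algorithm="kd_tree", leaf_size=leaf_size)
        self.full.fit(reference)


def _knn_fraction_full(
    reference: np.ndarray,
    labels: np.ndarray,
    query: np.ndarray,
    k: int,
    index: "KnnIndex",
) -> np.ndarray:
    """Full k-NN lesion fraction with stable tie-breaking."""
    n_ref = len(reference)
    lookahead = min(k + 1, n_ref)
    dist, idx = index.full.kneighbors(query, n_neighbors=lookahead)
    prob = labels[idx[:, :k]].mean(axis=1).astype(np.float32)

    if lookahead > k:
        tie_rows = np.flatnonzero(dist[:, k - 1] == dist[:, k])
        if len(tie_rows):
            # exact path: full stable sort of the affected rows
            d2 = ((query[tie_rows, None, :].astype(np.float64)
                   - reference[None, :, :].astype(np.float64)) ** 2).sum(axis=2)
            order = np.argsort(d2, axis=1, kind="stable")
            prob[tie_rows] = labels[order[:, :k]].mean(axis=1).astype(np.float32)
    return prob


def predict_probability(
    classifier: TrainedClassifier,
    subject: SubjectImage,
    config: FeatureConfig | None = None,
) -> ProbabilityMap:
    """Predict the per-voxel lesion probability map of a subject.

    The subject's intensities are standardized with its *own* brain-mask
    statistics.  Outside the brain mask the probability is 0.
    """
    config = config if config is not None else classifier.config
    feats, idx = extract_features(subject, config)
    if classifier.features.shape[0] and feats.shape[1] != classifier.features.shape[1]:
        raise InputError(
            f"feature arity mismatch: subject {feats.shape[1]} vs "
            f"model {classifier.features.shape[1]}"
        )
    values = np.zeros(subject.brain_mask.shape, dtype=np.float32)
    if not classifier.is_degenerate:
        prob = knn_lesion_fraction(classifier.features, classifier.labels, feats, classifier.k)
        values[tuple(idx.T)] = prob
    return ProbabilityMap(
        values=values,
        participant_id=subject.participant_id,
        timepoint=subject.timepoint,
        draw_id=classifier.draw_id,
    )


def binarize(prob: ProbabilityMap | np.ndarray, t: float) -> np.ndarray:
    """Threshold a probability map to a binary lesion mask.

    Voxels with probability >= t are kept for t > 0; t = 0 keeps voxels
    with probability strictly > 0 (so the zero threshold does not return
    the entire brain mask).
    """
    if not 0.0 <= t <= 1.0:
        raise ParameterError(f"threshold must be in [0, 1], got {t}")
    values = prob.values if isinstance(prob, ProbabilityMap) else np.asarray(prob)
    if t == 0.0:
        return values > 0.0
    return values >= t


def save_classifier(classifier: TrainedClassifier, path: Path) -> Path:
    """Save a per-draw model archive (portable npz, bit-exact round-trip)."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    stats_keys = list(classifier.normalization_stats)
    stats_vals = np.asarray(
        [classifier.normalization_stats[s] for s in stats_keys], dtype=np.float64
    )
    np.savez_compressed(
        path,
        features=classifier.features,
        labels=classifier.labels,
        k=np.int64(classifier.k),
        stats_keys=np.asarray(stats_keys),
        stats_vals=stats_vals,
        modalities=np.asarray(classifier.config.use_modalities),
        spatial_weight=np.float64(classifier.config.spatial_weight),
        draw_id=np.asarray(classifier.draw_id),
    )
    return path


def load_classifier(path: Path) -> TrainedClassifier:
    with np.load(path, allow_pickle=False) as z:
        stats = {
            str(key): [tuple(map(float, pair)) for pair in vals]
            for key, vals in zip(z["stats_keys"], z["stats_vals"])
        }
        return TrainedClassifier(
            features=z["features"],
            labels=z["labels"],
            k=int(z["k"]),
            normalization_stats=stats,
            config=FeatureConfig(
                use_modalities=tuple(str(m) for m in z["modalities"]),
                spatial_weight=float(z["spatial_weight"]),
            ),
            draw_id=str(z["draw_id"]),
        )
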