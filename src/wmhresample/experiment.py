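"""End-to-end experiment orchestration.

generate -> draw -> fit -> predict -> evaluate, fully reproducible from a
single master seed.  The unit of work is one (sample size, replicate)
pair; each unit writes its own raw-records CSV so an interrupted run can
be resumed without recomputing finished units.  Identical configuration
and seed give byte-identical CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import DesignParams, build_split, draw_training_set, enumerate_design
from .errors import InputError
from .knn import FeatureConfig, KnnIndex, TrainingPointPolicy, fit, knn_lesion_fraction
from .metrics import (
    RECORD_COLUMNS,
    dice_si,
    select_threshold,
    summarize_models,
)
from .phantom import Cohort, LesionVolumeModel, PhantomParams, generate_cohort
from .rng import spawn_rng

__all__ = ["ExperimentConfig", "run_experiment", "evaluate_run", "PROFILES"]

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))


@dataclass(frozen=True)
class ExperimentConfig:
    """Every knob of one experiment, in one place."""

    phantom: PhantomParams = field(default_factory=PhantomParams)
    lesion_model: LesionVolumeModel = field(default_factory=LesionVolumeModel)
    design: DesignParams = field(default_factory=DesignParams)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    policy: TrainingPointPolicy = field(default_factory=TrainingPointPolicy)
    k: int = 40
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    seed: int = 0

    def validate(self) -> None:
        self.phantom.validate()
        self.lesion_model.validate()
        self.design.validate(self.phantom.n_paired)
        self.features.validate()
        self.policy.validate()
        if len(self.thresholds) < 2 or any(not 0 <= t <= 1 for t in self.thresholds):
            raise InputError("thresholds must be a grid within [0, 1]")

    def reseeded(self, seed: int) -> "ExperimentConfig":
        """Copy of the config with all substreams re-rooted at ``seed``."""
        return replace(
            self,
            seed=seed,
            phantom=replace(self.phantom, seed=seed),
            design=replace(self.design, seed=seed),
        )

    @classmethod
    def from_yaml(cls, path: Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "phantom" in raw:
            p = raw["phantom"]
            for key in ("grid_shape", "voxel_dims"):
                if key in p:
                    p[key] = tuple(p[key])
            for key in ("tissue_means", "tissue_sds"):
                if key in p:
                    p[key] = {k2: tuple(v) for k2, v in p[key].items()}
            kwargs["phantom"] = PhantomParams(**p)
        if "lesion_model" in raw:
            kwargs["lesion_model"] = LesionVolumeModel(**raw["lesion_model"])
        if "design" in raw:
            d = raw["design"]
            if "sample_sizes" in d:
                d["sample_sizes"] = tuple(d["sample_sizes"])
            kwargs["design"] = DesignParams(**d)
        if "features" in raw:
            f = raw["features"]
            if "use_modalities" in f:
                f["use_modalities"] = tuple(f["use_modalities"])
            kwargs["features"] = FeatureConfig(**f)
        if "policy" in raw:
            kwargs["policy"] = TrainingPointPolicy(**raw["policy"])
        for key in ("k", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "thresholds" in raw:
            kwargs["thresholds"] = tuple(raw["thresholds"])
        config = cls(**kwargs)
        if "seed" in raw:
            config = config.reseeded(raw["seed"])
        return config


def _toy_profile(seed: int = 0) -> ExperimentConfig:
    return ExperimentConfig(
        phantom=PhantomParams(
            grid_shape=(24, 24, 24), voxel_dims=(2.0, 2.0, 2.0),
            n_paired=8, n_external=4, seed=seed,
        ),
        design=DesignParams(sample_sizes=(2, 4), n_draws=5, seed=seed),
        policy=TrainingPointPolicy(max_lesion_points=200, max_nonlesion_points=1000),
        k=10,
        seed=seed,
    )


def _scaled_profile(seed: int = 0) -> ExperimentConfig:
    """Desk-scale version of the full study: same structure, smaller sizes."""
    return ExperimentConfig(
        phantom=PhantomParams(
            grid_shape=(32, 32, 32), voxel_dims=(1.5, 1.5, 1.5),
            n_paired=40, n_external=20, seed=seed,
        ),
        design=DesignParams(sample_sizes=(5, 10, 20), n_draws=20, seed=seed),
        policy=TrainingPointPolicy(max_lesion_points=400, max_nonlesion_points=2000),
        k=40,
        seed=seed,
    )


def _full_profile(seed: int = 0) -> ExperimentConfig:
    return ExperimentConfig(
        phantom=PhantomParams(n_paired=80, n_external=41, seed=seed),
        design=DesignParams(seed=seed),
        seed=seed,
    )


PROFILES = {
    "toy": _toy_profile,
    "scaled": _scaled_profile,
    "full": _full_profile,
}


# ---------------------------------------------------------------------------


def _unit_path(outdir: Path, n: int, r: int) -> Path:
    return outdir / "units" / f"n{n:03d}_r{r:03d}.csv"


class _FeatureCache:
    """Per-observation feature rows, extracted once per run."""

    def __init__(self, cohort: Cohort, config: FeatureConfig):
        self.cohort = cohort
        self.config = config
        self._cache: dict[tuple[str, str], dict] = {}

    def get(self, pid: str, tp: str) -> dict:
        key = (pid, tp)
        if key not in self._cache:
            from .knn import extract_features

            subject = self.cohort.get(pid, tp)
            feats, idx = extract_features(subject, self.config)
            manual_at = subject.manual_mask[tuple(idx.T)].astype(bool)
            self._cache[key] = {
                "subject": subject,
                "features": feats,
                "manual_at_mask": manual_at,
                "manual_ml": subject.manual_volume_ml,
            }
        return self._cache[key]


def _predicted_volume_and_dice(
    prob_at_mask: np.ndarray,
    manual_at_mask: np.ndarray,
    thresholds: tuple[float, ...],
    voxel_volume_ml: float,
) -> list[tuple[float, float, float]]:
    """(threshold, predicted ml, dice) per threshold, from mask-voxel arrays."""
    out = []
    n_manual = int(manual_at_mask.sum())
    for t in thresholds:
        pred = prob_at_mask > 0.0 if t == 0.0 else prob_at_mask >= t
        n_pred = int(pred.sum())
        vol = n_pred * voxel_volume_ml
        inter = int((pred & manual_at_mask).sum())
        dice = float("nan") if n_manual + n_pred == 0 else 2.0 * inter / (n_manual + n_pred)
        out.append((float(t), vol, dice))
    return out


def _run_unit(
    config: ExperimentConfig,
    cohort: Cohort,
    cache: _FeatureCache,
    n: int,
    r: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One (sample size, replicate): draw, fit, predict, record."""
    rng_draw = spawn_rng(config.design.seed, "draw", n, r)
    draw = draw_training_set(cohort, n, rng_draw, replicate=r)
    split = build_split(draw, cohort)

    train_subjects = [cohort.get(pid, tp) for pid, tp in draw.members]
    rng_fit = spawn_rng(config.design.seed, "fit", n, r)
    clf = fit(
        train_subjects, config.policy, config.features,
        k=config.k, rng=rng_fit, draw_id=draw.draw_id,
    )

    members = pd.DataFrame(
        {
            "draw_id": draw.draw_id,
            "sample_size": n,
            "replicate": r,
            "participant_id": [pid for pid, _ in draw.members],
            "timepoint": [tp for _, tp in draw.members],
            "manual_ml": [cache.get(pid, tp)["manual_ml"] for pid, tp in draw.members],
        }
    )

    vox_ml = config.phantom.voxel_volume_ml
    index = None if clf.is_degenerate else KnnIndex(clf.features, clf.labels)
    rows = []
    for set_name, observations in split.sets().items():
        for pid, tp in observations:
            entry = cache.get(pid, tp)
            if clf.is_degenerate:
                prob = np.zeros(len(entry["features"]), dtype=np.float32)
            else:
                prob = knn_lesion_fraction(
                    clf.features, clf.labels, entry["features"], clf.k, index=index
                )
            for t, vol, dice in _predicted_volume_and_dice(
                prob, entry["manual_at_mask"], config.thresholds, vox_ml
            ):
                rows.append(
                    (
                        draw.draw_id, n, r, pid, tp, set_name, t,
                        entry["manual_ml"], vol, vol - entry["manual_ml"], dice,
                    )
                )
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return records, members


def run_experiment(
    config: ExperimentConfig,
    outdir: Path,
    resume: bool = False,
    progress: bool = False,
) -> Path:
    """Execute all stages; returns the output directory.

    Outputs: ``design_table.csv``, per-unit CSVs under ``units/``,
    ``raw_records.csv``, ``draw_members.csv``, ``summaries.csv`` and a
    ``manifest.json`` with config echo, version, seeds and checksums.
    With ``resume=True``, finished units (their CSV exists) are skipped.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "units").mkdir(exist_ok=True)
    t0 = time.time()

    design_table = enumerate_design(
        config.design, config.phantom.n_paired, config.phantom.n_external
    )
    design_table.to_csv(outdir / "design_table.csv", index=False)

    cohort = generate_cohort(config.phantom, config.lesion_model)
    cache = _FeatureCache(cohort, config.features)
    t_gen = time.time()

    units = [(n, r) for n in config.design.sample_sizes for r in range(config.design.n_draws)]
    for n, r in units:
        upath = _unit_path(outdir, n, r)
        mpath = upath.with_name(upath.stem + "_members.csv")
        if resume and upath.exists() and mpath.exists():
            continue
        records, members = _run_unit(config, cohort, cache, n, r)
        records.to_csv(upath, index=False)
        members.to_csv(mpath, index=False)
        if progress:
            print(f"  unit n={n} r={r} done ({time.time() - t0:.1f}s elapsed)")
    t_units = time.time()

    raw = pd.concat(
        [pd.read_csv(_unit_path(outdir, n, r)) for n, r in units], ignore_index=True
    )
    raw.to_csv(outdir / "raw_records.csv", index=False)
    members = pd.concat(
        [
            pd.read_csv(_unit_path(outdir, n, r).with_name(f"n{n:03d}_r{r:03d}_members.csv"))
            for n, r in units
        ],
        ignore_index=True,
    )
    members.to_csv(outdir / "draw_members.csv", index=False)

    summaries = summarize_models(raw)
    summaries.to_csv(outdir / "summaries.csv", index=False)
    t_star, _ = select_threshold(summaries, threshold_grid=config.thresholds)

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "selected_threshold": t_star,
        "substreams": {
            "cohort": "participant/<i>, external/<j>",
            "units": "draw/<n>/<r>, fit/<n>/<r>",
        },
        "files": {
            p.name: _sha256(p)
            for p in sorted(outdir.glob("*.csv"))
        },
        "timing_s": {
            "generate": round(t_gen - t0, 3),
            "units": round(t_units - t_gen, 3),
            "total": round(time.time() - t0, 3),
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def evaluate_run(outdir: Path, thresholds: tuple[float, ...] | None = None) -> dict:
    """Recompute summaries and the selected threshold from raw records.

    Stage isolation: this reads only ``raw_records.csv``, so deleting the
    summary outputs and re-running reproduces them exactly.
    """
    outdir = Path(outdir)
    raw_path = outdir / "raw_records.csv"
    if not raw_path.exists():
        raise InputError(f"no raw records at {raw_path}; run the experiment first")
    raw = pd.read_csv(raw_path)
    summaries = summarize_models(raw)
    summaries.to_csv(outdir / "summaries.csv", index=False)
    t_star, selection = select_threshold(summaries, threshold_grid=thresholds)
    return {"summaries": summaries, "selected_threshold": t_star, "selection": selection}
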