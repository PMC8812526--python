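"""Leakage-aware resampling design.

Training sets of 7 sizes (10..40 by 5 at defaults) are drawn 100 times
each, without replacement within a draw and with at most one observation
(BL or FU) per participant.  For each draw the three validation sets are
derived: internal-BL and internal-FU (all non-training participants, one
observation each) and the fixed external partition that is never trained
on.  A participant that contributes either scan to a training set is
excluded from both internal validation sets of that draw — the design's
data-leakage rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError
from .phantom import Cohort
from .rng import spawn_rng

__all__ = [
    "DesignParams",
    "TrainingDraw",
    "ValidationSplit",
    "draw_training_set",
    "build_split",
    "verify_no_leakage",
    "enumerate_design",
    "iter_draws",
    "find_duplicate_draws",
]

TIMEPOINTS = ("BL", "FU")


@dataclass(frozen=True)
class DesignParams:
    """Sample sizes, replicate count and master seed of the design."""

    sample_sizes: tuple[int, ...] = (10, 15, 20, 25, 30, 35, 40)
    n_draws: int = 100
    seed: int = 0

    def validate(self, n_paired: int | None = None) -> None:
        if any(n < 1 for n in self.sample_sizes):
            raise DesignError("all sample sizes must be >= 1")
        if self.n_draws < 1:
            raise DesignError("n_draws must be >= 1")
        if n_paired is not None and any(n > n_paired for n in self.sample_sizes):
            raise DesignError(
                f"sample sizes {self.sample_sizes} exceed the {n_paired} paired participants"
            )


@dataclass(frozen=True)
class TrainingDraw:
    """One random training set: (sample size, replicate) plus its members."""

    sample_size: int
    replicate: int
    members: tuple[tuple[str, str], ...]  # (participant_id, timepoint)

    @property
    def draw_id(self) -> str:
        return f"n{self.sample_size:03d}_r{self.replicate:03d}"

    @property
    def participant_ids(self) -> frozenset[str]:
        return frozenset(pid for pid, _ in self.members)


@dataclass(frozen=True)
class ValidationSplit:
    """The three leakage-consistent validation sets of one draw."""

    internal_bl: tuple[tuple[str, str], ...]
    internal_fu: tuple[tuple[str, str], ...]
    external: tuple[tuple[str, str], ...]

    def sets(self) -> dict[str, tuple[tuple[str, str], ...]]:
        return {
            "internal_bl": self.internal_bl,
            "internal_fu": self.internal_fu,
            "external": self.external,
        }


def draw_training_set(
    cohort: Cohort,
    n: int,
    rng: np.random.Generator,
    replicate: int = 0,
) -> TrainingDraw:
    """Draw ``n`` distinct participants, one observation (BL or FU) each.

    Participants are chosen uniformly without replacement from the paired
    resampling partition; the timepoint of each chosen participant is then
    uniform over BL/FU.
    """
    pids = cohort.participant_ids
    if n > len(pids):
        raise DesignError(f"cannot draw {n} from {len(pids)} paired participants")
    chosen = rng.choice(len(pids), size=n, replace=False)
    timepoints = rng.integers(0, 2, size=n)
    members = tuple(
        (pids[i], TIMEPOINTS[t]) for i, t in zip(sorted(chosen), timepoints)
    )
    return TrainingDraw(sample_size=n, replicate=replicate, members=members)


def build_split(draw: TrainingDraw, cohort: Cohort) -> ValidationSplit:
    """Derive the three validation sets for a draw.

    Internal sets hold one observation per *non-training* participant
    (their BL scans and their FU scans respectively), so each has
    ``n_paired - n`` observations; the external set is the fixed external
    partition.
    """
    pids = set(cohort.participant_ids)
    foreign = draw.participant_ids - pids
    if foreign:
        raise DesignError(f"draw contains participants not in this cohort: {sorted(foreign)}")
    held_out = [pid for pid in cohort.participant_ids if pid not in draw.participant_ids]
    return ValidationSplit(
        internal_bl=tuple((pid, "BL") for pid in held_out),
        internal_fu=tuple((pid, "FU") for pid in held_out),
        external=tuple((s.participant_id, s.timepoint) for s in cohort.external_subjects),
    )


def verify_no_leakage(
    draw: TrainingDraw,
    split: ValidationSplit,
    resampling_ids: frozenset[str] | None = None,
) -> tuple[bool, list[str]]:
    """Check the leakage rule; returns (pass, violating participant ids).

    A violation is any participant contributing to both the training draw
    and an internal validation set, or any external observation whose
    participant belongs to the resampling partition.
    """
    internal_ids = {pid for pid, _ in split.internal_bl} | {pid for pid, _ in split.internal_fu}
    violations = sorted(draw.participant_ids & internal_ids)
    if resampling_ids is not None:
        violations += sorted({pid for pid, _ in split.external} & resampling_ids)
    return (len(violations) == 0, violations)


def iter_draws(params: DesignParams, cohort: Cohort):
    """Yield every (draw, split) of the design, each on its own substream."""
    params.validate(cohort.n_paired)
    for n in params.sample_sizes:
        for r in range(params.n_draws):
            rng = spawn_rng(params.seed, "draw", n, r)
            draw = draw_training_set(cohort, n, rng, replicate=r)
            yield draw, build_split(draw, cohort)


def enumerate_design(
    params: DesignParams,
    n_paired: int = 80,
    n_external: int = 41,
) -> pd.DataFrame:
    """The design table: observation counts per sample size, plus totals.

    Columns follow the training/validation bookkeeping of the study:
    training size, internal BL and FU counts, external count, predictions
    per model and overall (per-model x replicates).  The final row holds
    the grand totals; ``models_total`` is sizes x replicates.
    """
    params.validate(n_paired)
    rows = []
    for n in params.sample_sizes:
        internal = n_paired - n
        per_model = 2 * internal + n_external
        rows.append(
            {
                "sample_size": n,
                "internal_bl": internal,
                "internal_fu": internal,
                "external": n_external,
                "per_model": per_model,
                "overall": per_model * params.n_draws,
            }
        )
    table = pd.DataFrame(rows)
    totals = {
        "sample_size": -1,
        "internal_bl": table["internal_bl"].sum(),
        "internal_fu": table["internal_fu"].sum(),
        "external": table["external"].sum(),
        "per_model": table["per_model"].sum(),
        "overall": table["overall"].sum(),
    }
    full = pd.concat([table, pd.DataFrame([totals])], ignore_index=True)
    full.attrs["models_total"] = len(params.sample_sizes) * params.n_draws
    full.attrs["grand_total_predictions"] = int(totals["overall"])
    return full


def find_duplicate_draws(draws: list[TrainingDraw]) -> list[tuple[str, str]]:
    """Report replicate pairs with identical member sets (not forbidden,
    merely reported, mirroring the duplicate-set check of the design)."""
    seen: dict[frozenset, str] = {}
    dupes = []
    for d in draws:
        key = frozenset(d.members)
        if key in seen:
            dupes.append((seen[key], d.draw_id))
        else:
            seen[key] = d.draw_id
    return dupes
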