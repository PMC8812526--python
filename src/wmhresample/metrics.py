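"""Volume, error, Dice and composition metrics.

The central quantity is the signed volume error, predicted minus manual
lesion volume in ml: positive values are overestimation by the
segmenter, negative values underestimation.  Per trained model
(= per draw), validation set and threshold, the signed errors are
aggregated into mean, sample SD, median and IQR; the working threshold
is the one whose across-model mean error has the smallest magnitude.
Spatial overlap is measured by the Dice similarity index
2|A∩B| / (|A|+|B|).

Quartile convention: median and IQR use linear interpolation
(numpy's default percentile method); reported medians/IQRs depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError

__all__ = [
    "ModelSummary",
    "mask_volume_ml",
    "signed_error",
    "summarize_model",
    "summarize_models",
    "select_threshold",
    "dice_si",
    "composition_analysis",
    "composition_error_correlation",
    "stratified_errors",
    "DEFAULT_VOLUME_BINS",
]

RECORD_COLUMNS = [
    "draw_id",
    "sample_size",
    "replicate",
    "participant_id",
    "timepoint",
    "validation_set",
    "threshold",
    "manual_ml",
    "predicted_ml",
    "error_ml",
    "dice",
]

# volume strata (ml): zero, very low, low, moderate, high
DEFAULT_VOLUME_BINS = (0.0, 0.1, 0.5, 2.0)


def mask_volume_ml(mask: np.ndarray, voxel_dims: tuple[float, float, float]) -> float:
    """Lesion volume in ml: voxel count x voxel volume (mm^3) / 1000."""
    arr = np.asarray(mask)
    if arr.dtype != bool and not np.isin(arr, (0, 1)).all():
        raise InputError("mask must be binary")
    return float(arr.astype(bool).sum()) * float(np.prod(voxel_dims)) / 1000.0


def signed_error(predicted_ml: float, manual_ml: float) -> float:
    """Predicted minus manual volume; >0 over-, <0 underestimation."""
    return predicted_ml - manual_ml


@dataclass(frozen=True)
class ModelSummary:
    """Aggregate of the signed errors of one model x set x threshold."""

    draw_id: str
    validation_set: str
    threshold: float
    mean_error: float
    sd_error: float
    median_error: float
    iqr_error: float
    n_observations: int
    sd_defined: bool = True


def summarize_model(
    errors: np.ndarray,
    draw_id: str = "",
    validation_set: str = "",
    threshold: float = float("nan"),
) -> ModelSummary:
    """Mean, sample SD (n-1), median and IQR of one model's signed errors.

    With a single observation the SD is undefined and reported as 0 with
    ``sd_defined=False``.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise InputError("cannot summarize an empty record set")
    single = errors.size == 1
    return ModelSummary(
        draw_id=draw_id,
        validation_set=validation_set,
        threshold=threshold,
        mean_error=float(errors.mean()),
        sd_error=0.0 if single else float(errors.std(ddof=1)),
        median_error=float(np.median(errors)),
        iqr_error=float(np.percentile(errors, 75) - np.percentile(errors, 25)),
        n_observations=int(errors.size),
        sd_defined=not single,
    )


def summarize_models(records: pd.DataFrame) -> pd.DataFrame:
    """Per (draw, validation set, threshold) summary table of raw records."""
    def agg(g: pd.DataFrame) -> pd.Series:
        e = g["error_ml"].to_numpy()
        s = summarize_model(e)
        return pd.Series(
            {
                "sample_size": g["sample_size"].iloc[0],
                "replicate": g["replicate"].iloc[0],
                "mean_error": s.mean_error,
                "sd_error": s.sd_error,
                "median_error": s.median_error,
                "iqr_error": s.iqr_error,
                "n_observations": s.n_observations,
            }
        )

    out = (
        records.groupby(["draw_id", "validation_set", "threshold"])
        .apply(agg, include_groups=False)
        .reset_index()
    )
    return out


def select_threshold(
    summaries: pd.DataFrame,
    validation_sets: tuple[str, ...] = ("internal_bl", "internal_fu"),
    threshold_grid: tuple[float, ...] | None = None,
    use_magnitude: bool = True,
) -> tuple[float, pd.DataFrame]:
    """Pick the working threshold t*.

    t* minimizes the magnitude of the across-model mean signed error,
    aggregated over the designated validation sets (set
    ``use_magnitude=False`` to minimize the signed value itself).  Exact
    ties break toward the larger threshold (more conservative masks).
    Returns (t*, per-threshold selection table).
    """
    sub = summaries[summaries["validation_set"].isin(validation_sets)]
    if sub.empty:
        raise InputError(f"no summaries for validation sets {validation_sets}")
    table = (
        sub.groupby("threshold")["mean_error"]
        .agg(mean_of_means="mean", sd_of_means="std", n_models="count")
        .reset_index()
    )
    if threshold_grid is not None:
        have = set(np.round(table["threshold"], 6))
        want = set(np.round(threshold_grid, 6))
        if not want <= have:
            raise InputError(f"incomplete threshold grid: missing {sorted(want - have)}")
    objective = table["mean_of_means"].abs() if use_magnitude else table["mean_of_means"]
    table = table.assign(objective=objective)
    best = table["objective"].min()
    t_star = float(table.loc[table["objective"] == best, "threshold"].max())
    return t_star, table.drop(columns="objective")


def dice_si(manual: np.ndarray, predicted: np.ndarray) -> float:
    """Dice similarity index 2|A∩B| / (|A|+|B|).

    Empty manual with non-empty prediction gives 0 (a zero-volume subject
    cannot be underestimated, only overestimated); both masks empty is
    undefined and returned as NaN so averages can exclude it.
    """
    a = np.asarray(manual).astype(bool)
    b = np.asarray(predicted).astype(bool)
    if a.shape != b.shape:
        raise InputError(f"grid mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return float("nan")
    return 2.0 * int((a & b).sum()) / (na + nb)


def composition_analysis(
    draw_volumes: pd.DataFrame,
    summaries: pd.DataFrame,
    threshold: float,
    validation_sets: tuple[str, ...] = ("internal_bl", "internal_fu", "external"),
    n_bins: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relate training-set composition to model-level error.

    ``draw_volumes`` has one row per training member with columns
    ``draw_id`` and ``manual_ml``.  Per draw, the proportions of members
    below 0.1 ml and below 0.5 ml are computed and joined with the
    model's mean signed error at the given threshold (averaged over the
    designated validation sets).  Returns (per-draw records, summary of
    mean error binned by the <0.5 ml proportion).
    """
    props = (
        draw_volumes.groupby("draw_id")["manual_ml"]
        .agg(
            prop_below_01=lambda v: float((v < 0.1).mean()),
            prop_below_05=lambda v: float((v < 0.5).mean()),
            n_members="count",
        )
        .reset_index()
    )
    at_t = summaries[
        (np.isclose(summaries["threshold"], threshold))
        & (summaries["validation_set"].isin(validation_sets))
    ]
    err = at_t.groupby("draw_id")["mean_error"].mean().rename("mean_error").reset_index()
    records = props.merge(err, on="draw_id", how="inner")

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    records = records.assign(
        prop_bin=pd.cut(records["prop_below_05"], edges, include_lowest=True)
    )
    binned = (
        records.groupby("prop_bin", observed=True)["mean_error"]
        .agg(mean_error="mean", n_draws="count")
        .reset_index()
    )
    return records.drop(columns="prop_bin"), binned


def composition_error_correlation(records: pd.DataFrame) -> tuple[float, float]:
    """Spearman rank correlation of <0.5 ml proportion vs mean error."""
    rho, p = sps.spearmanr(records["prop_below_05"], records["mean_error"])
    return float(rho), float(p)


def stratified_errors(
    records: pd.DataFrame,
    bins: tuple[float, ...] = DEFAULT_VOLUME_BINS,
) -> pd.DataFrame:
    """Mean signed error and Dice per manual-volume stratum.

    Records must be at one threshold.  Bins: exactly 0, then half-open
    intervals over ``bins``, then above the last edge.
    """
    if records["threshold"].nunique() > 1:
        raise InputError("stratified_errors expects records at a single threshold")
    v = records["manual_ml"].to_numpy()
    labels = np.empty(len(v), dtype=object)
    labels[v == 0] = "0 ml"
    lower = 0.0
    for hi in bins[1:]:
        sel = (v > lower) & (v <= hi)
        labels[sel] = f"({lower:g}, {hi:g}] ml"
        lower = hi
    labels[v > lower] = f"> {lower:g} ml"
    out = (
        records.assign(volume_bin=labels)
        .groupby("volume_bin", sort=False)
        .agg(
            mean_error=("error_ml", "mean"),
            mean_dice=("dice", "mean"),
            n_observations=("error_ml", "count"),
            bin_order=("manual_ml", "min"),
        )
        .sort_values("bin_order")
        .drop(columns="bin_order")
        .reset_index()
    )
    return out
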