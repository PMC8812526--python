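"""Human-readable reporting of a finished run.

Emits the summary tables — the mean (SD) of per-model mean signed errors
by sample size and validation set at the working threshold, the
threshold-selection table, the training-set composition analysis and the
volume-stratified errors — plus plain matplotlib figures: box plots of
per-model mean error versus sample size, and manual-versus-predicted
volume scatter with per-model linear fits.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import InputError
from .metrics import (
    composition_analysis,
    composition_error_correlation,
    select_threshold,
    stratified_errors,
    summarize_models,
)

__all__ = ["report", "error_matrix"]


def error_matrix(summaries: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Mean (SD) of per-model mean errors by sample size x validation set."""
    at_t = summaries[np.isclose(summaries["threshold"], threshold)]
    rows = []
    for n, g in at_t.groupby("sample_size"):
        row: dict = {"sample_size": int(n)}
        for set_name, gg in g.groupby("validation_set"):
            mean = gg["mean_error"].mean()
            sd = gg["mean_error"].std(ddof=1)
            row[f"{set_name}_mean"] = mean
            row[f"{set_name}_sd"] = sd
            row[f"{set_name}"] = f"{mean:.2f} ({sd:.2f})"
        rows.append(row)
    return pd.DataFrame(rows).sort_values("sample_size").reset_index(drop=True)


def report(outdir: Path, thresholds: tuple[float, ...] | None = None) -> dict:
    """Build all report tables and plots from a completed run directory."""
    outdir = Path(outdir)
    raw_path = outdir / "raw_records.csv"
    members_path = outdir / "draw_members.csv"
    if not raw_path.exists() or not members_path.exists():
        raise InputError(f"incomplete run in {outdir}: raw records or draw members missing")
    raw = pd.read_csv(raw_path)
    members = pd.read_csv(members_path)

    summaries = summarize_models(raw)
    t_star, selection = select_threshold(summaries, threshold_grid=thresholds)
    selection.to_csv(outdir / "threshold_selection.csv", index=False)

    matrix = error_matrix(summaries, t_star)
    matrix.to_csv(outdir / "table_mean_errors.csv", index=False)

    comp_records, comp_binned = composition_analysis(members, summaries, t_star)
    comp_records.to_csv(outdir / "composition.csv", index=False)
    comp_binned.to_csv(outdir / "composition_binned.csv", index=False)
    rho, rho_p = composition_error_correlation(comp_records)

    at_t = raw[np.isclose(raw["threshold"], t_star)]
    strata = stratified_errors(at_t)
    strata.to_csv(outdir / "stratified_errors.csv", index=False)

    plots = outdir / "plots"
    plots.mkdir(exist_ok=True)
    _plot_error_by_size(summaries, t_star, plots / "error_by_sample_size.png")
    _plot_volume_scatter(at_t, plots / "manual_vs_predicted.png")

    return {
        "selected_threshold": t_star,
        "selection": selection,
        "error_matrix": matrix,
        "composition": comp_records,
        "composition_binned": comp_binned,
        "composition_spearman": (rho, rho_p),
        "stratified": strata,
    }


def _plot_error_by_size(summaries: pd.DataFrame, t_star: float, path: Path) -> None:
    at_t = summaries[np.isclose(summaries["threshold"], t_star)]
    sets = sorted(at_t["validation_set"].unique())
    fig, axes = plt.subplots(1, len(sets), figsize=(4 * len(sets), 4), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, set_name in zip(axes, sets):
        g = at_t[at_t["validation_set"] == set_name]
        sizes = sorted(g["sample_size"].unique())
        data = [g.loc[g["sample_size"] == n, "mean_error"] for n in sizes]
        ax.boxplot(data, tick_labels=[str(int(n)) for n in sizes])
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_title(set_name)
        ax.set_xlabel("training sample size")
    axes[0].set_ylabel(f"per-model mean signed error (ml) at t={t_star:g}")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _plot_volume_scatter(at_t: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(at_t["manual_ml"], at_t["predicted_ml"], s=4, alpha=0.2, lw=0)
    # per-model linear fits
    for _, g in at_t.groupby("draw_id"):
        if g["manual_ml"].nunique() < 2:
            continue
        b, a = np.polyfit(g["manual_ml"], g["predicted_ml"], 1)
        x = np.array([g["manual_ml"].min(), g["manual_ml"].max()])
        ax.plot(x, a + b * x, color="steelblue", alpha=0.1, lw=0.7)
    lim = max(at_t["manual_ml"].max(), at_t["predicted_ml"].max(), 1.0)
    ax.plot([0, lim], [0, lim], color="red", lw=1.0, label="identity")
    ax.set_xlabel("manual volume (ml)")
    ax.set_ylabel("predicted volume (ml)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
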