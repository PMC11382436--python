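"""Study-shaped reporting: reliability and angle-comparison tables, and
Bland–Altman plots.

Two report shapes are produced.  The reliability table lists, per axis
(bone x variant x image kind x observer group), the inter-observer ICC and
the across-observer summary of intra-observer ICCs as ``mean (SD; range)``.
The angle-comparison table lists, per radiocarpal angle and axis variant,
the observer and software distributions as ``mean (SD; range)`` in integer
degrees with the paired t-test p-value, plus the axial-versus-tangential
comparison per bone — the same layout the measurement protocol reports.

Observer values entering the comparison are per-wrist means over the
instructed observers' stripped-image radiocarpal measurements (both
sessions), the setting in which manual measurement is most reliable.
"""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .observers import MeasurementTable
from .stats import (
    BlandAltmanResult,
    bland_altman,
    classify_reliability,
    compare_variants,
    inter_observer_icc,
    intra_observer_icc,
    paired_t_test,
)
from .volume import BoneLabel

__all__ = [
    "format_mean_sd_range",
    "format_p",
    "reliability_report",
    "observer_mean_angles",
    "angle_comparison_report",
    "bland_altman_by_angle",
    "plot_bland_altman",
]


def format_mean_sd_range(values) -> str:
    """Render a sample as ``mean (SD; min to max)`` in integer degrees."""
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1) if len(v) > 1 else 0.0
    return f"{v.mean():.0f} ({sd:.0f}; {v.min():.0f} to {v.max():.0f})"


def format_p(p: float) -> str:
    """p-values to three decimals; tiny ones rendered as ``<0.001``."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def reliability_report(table: MeasurementTable) -> pd.DataFrame:
    """Combined inter-/intra-observer reliability per axis and group."""
    intra = intra_observer_icc(table)
    inter = inter_observer_icc(table)
    merged = inter.merge(
        intra,
        on=["instructed", "image_kind", "bone", "variant"],
        suffixes=("_inter", "_intra"),
    )
    merged["group"] = np.where(merged["instructed"], "instructed", "uninstructed")
    merged["inter_category"] = merged["icc"].map(lambda v: classify_reliability(v).value)
    merged["intra_summary"] = [
        f"{r.icc_mean:.2f} ({r.icc_sd:.2f}; {r.icc_min:.2f} to {r.icc_max:.2f})"
        for r in merged.itertuples()
    ]
    cols = [
        "group",
        "image_kind",
        "bone",
        "variant",
        "icc",
        "inter_category",
        "icc_mean",
        "icc_sd",
        "icc_min",
        "icc_max",
        "intra_summary",
    ]
    return merged[cols].rename(columns={"icc": "inter_icc", "icc_mean": "intra_icc_mean"})


def observer_mean_angles(
    table: MeasurementTable, image_kind: str = "stripped", instructed: bool = True
) -> pd.DataFrame:
    """Per-wrist radiocarpal angles averaged over observers and sessions.

    Returns long format (wrist_id, bone, variant, angle_deg) comparable to
    the software's angle table.
    """
    rc = table.radiocarpal()
    sel = rc[(rc["image_kind"] == image_kind) & (rc["instructed"] == instructed)]
    if sel.empty:
        raise ValueError(f"no {image_kind!r} measurements for that observer group")
    out = (
        sel.groupby(["wrist_id", "bone", "variant"], as_index=False)["radiocarpal_deg"]
        .mean()
        .rename(columns={"radiocarpal_deg": "angle_deg"})
    )
    return out


def angle_comparison_report(
    observer_angles: pd.DataFrame, software_angles: pd.DataFrame
) -> pd.DataFrame:
    """Observer-versus-software angle comparison per bone and variant.

    Both inputs are long format (wrist_id, bone, variant, angle_deg); rows
    are matched per wrist.  The result carries ``mean (SD; range)`` strings
    for both sources, the paired t-test p-value, and appended rows with the
    per-bone axial-versus-tangential p-values for each source.
    """
    rows = []
    key = ["bone", "variant"]
    for (bone, variant), obs in observer_angles.groupby(key, sort=True):
        sw = software_angles[
            (software_angles["bone"] == bone) & (software_angles["variant"] == variant)
        ]
        merged = obs.merge(sw, on="wrist_id", suffixes=("_obs", "_sw"))
        if merged.empty:
            raise ValueError(f"no paired wrists for {bone}/{variant}")
        t, p = paired_t_test(merged["angle_deg_obs"], merged["angle_deg_sw"])
        rows.append(
            {
                "bone": bone,
                "variant": variant,
                "n": len(merged),
                "observers": format_mean_sd_range(merged["angle_deg_obs"]),
                "software": format_mean_sd_range(merged["angle_deg_sw"]),
                "mean_difference": float(
                    (merged["angle_deg_obs"] - merged["angle_deg_sw"]).mean()
                ),
                "p": format_p(p),
            }
        )
    body = pd.DataFrame(rows)
    variant_rows = []
    for source, angles in (("observers", observer_angles), ("software", software_angles)):
        cv = compare_variants(angles)
        for r in cv.itertuples():
            variant_rows.append(
                {
                    "bone": r.bone,
                    "variant": "axial vs tangential",
                    "n": r.n,
                    "observers": format_p(r.p) if source == "observers" else "",
                    "software": format_p(r.p) if source == "software" else "",
                    "mean_difference": r.mean_offset,
                    "p": "",
                }
            )
    return pd.concat([body, pd.DataFrame(variant_rows)], ignore_index=True)


def bland_altman_by_angle(
    observer_angles: pd.DataFrame,
    software_angles: pd.DataFrame,
    outlier_threshold: float = 20.0,
) -> dict[tuple[str, str], tuple[BlandAltmanResult, pd.DataFrame]]:
    """Bland–Altman agreement per (bone, variant), observer minus software.

    Returns for each angle the result object plus the merged per-wrist pair
    table (for plotting and outlier lookup)."""
    out = {}
    for (bone, variant), obs in observer_angles.groupby(["bone", "variant"], sort=True):
        sw = software_angles[
            (software_angles["bone"] == bone) & (software_angles["variant"] == variant)
        ]
        merged = obs.merge(sw, on="wrist_id", suffixes=("_obs", "_sw"))
        pairs = merged[["angle_deg_obs", "angle_deg_sw"]].to_numpy()
        out[(bone, variant)] = (bland_altman(pairs, outlier_threshold), merged)
    return out


def plot_bland_altman(
    result: BlandAltmanResult, merged: pd.DataFrame, title: str, path: str | Path
) -> Path:
    """Difference-versus-mean scatter with limits of agreement."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    a = merged["angle_deg_obs"].to_numpy()
    b = merged["angle_deg_sw"].to_numpy()
    mean = (a + b) / 2.0
    diff = a - b
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, diff, s=18, color="tab:blue")
    ax.axhline(result.mean_diff, color="k", lw=1)
    for y in result.limits:
        ax.axhline(y, color="k", lw=1, ls="--")
    flagged = np.abs(diff) > result.outlier_threshold
    if flagged.any():
        ax.scatter(mean[flagged], diff[flagged], s=40, facecolor="none", edgecolor="red")
    ax.set_xlabel("mean of observer and software (deg)")
    ax.set_ylabel("observer - software (deg)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
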