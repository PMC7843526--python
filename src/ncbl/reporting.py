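"""CSV/PNG report writers for scenario runs.

Every figure has a CSV twin holding exactly the numbers plotted, so figures
can be re-rendered from the CSVs alone (``ncbl report``).  All files use
period decimals and a fixed column order regardless of locale.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "write_s1",
    "write_s2",
    "write_s3",
    "write_s4",
    "render_from_csvs",
]


def _save_bar(df: pd.DataFrame, x: str, y: str, title: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(df[x].astype(str), df[y], color="steelblue")
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _save_heatmap(matrix: np.ndarray, title: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(matrix, vmin=-1, vmax=1, cmap="RdBu_r")
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(title)
    ax.set_xlabel("neuron")
    ax.set_ylabel("neuron")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_s1(res: dict[str, Any], out: Path) -> None:
    profile = pd.DataFrame(
        {"class": res["profile_class_ids"], "mean_activation": res["profile_means"]}
    )
    profile.to_csv(out / "s1_selectivity_profile.csv", index=False)
    _save_bar(
        profile, "class", "mean_activation",
        f"selectivity profile, unit {res['unit_id']}",
        out / "s1_selectivity_profile.png",
    )
    full = pd.DataFrame(
        {
            "class": res["profile_class_ids"],
            "coefficient": res["full_coefficients"],
            "p_value": res["full_p_values"],
            "explained_variance": res["full_explained_variance"],
        }
    )
    full.to_csv(out / "s1_regression_full.csv", index=False)
    reduced = pd.DataFrame(
        {"class": res["reduced_class_ids"], "coefficient": res["reduced_coefficients"]}
    )
    reduced.to_csv(out / "s1_regression_reduced.csv", index=False)


def write_s2(res: dict[str, Any], out: Path) -> None:
    rows = [
        {"model": "clean", "pair_accuracy": res["pair_accuracy_clean"]},
        {"model": "logo", "pair_accuracy": res["pair_accuracy_logo"]},
    ]
    df = pd.DataFrame(rows)
    df.to_csv(out / "s2_pair_accuracy.csv", index=False)
    _save_bar(df, "model", "pair_accuracy", "pair accuracy: clean vs logo",
              out / "s2_pair_accuracy.png")
    sal = pd.DataFrame(
        [{"condition": k, "logo_footprint_saliency": v} for k, v in res["saliency"].items()]
    )
    sal.to_csv(out / "s2_saliency.csv", index=False)


def write_s3(res: dict[str, Any], out: Path) -> None:
    df = pd.DataFrame(
        [
            {
                "model": "network (K-way)",
                "accuracy": res["network_accuracy"],
                "baseline_accuracy": res["network_chance"],
            },
            {
                "model": "linear SVM (binary)",
                "accuracy": res["decoder_accuracy"],
                "baseline_accuracy": res["decoder_chance"],
            },
        ]
    )
    df.to_csv(out / "s3_baselines.csv", index=False)
    _save_bar(df, "model", "accuracy", "accuracy vs its own chance level",
              out / "s3_baselines.png")


def write_s4(res: dict[str, Any], out: Path, tag: str, variants: tuple[str, str]) -> None:
    rows = [
        {
            "model": v,
            "avg_total": res[f"{v}_avg_total"],
            "avg_within_focus_unit": res[f"{v}_avg_within_unit"],
        }
        for v in variants
    ]
    pd.DataFrame(rows).to_csv(out / f"{tag}_summary.csv", index=False)
    for v in variants:
        key = f"{v}_matrix"
        if key in res:
            m = np.asarray(res[key])
            pd.DataFrame(m).to_csv(out / f"{tag}_{v}_matrix.csv", index=False)
            _save_heatmap(m, f"{tag}: {v}", out / f"{tag}_{v}_matrix.png")


def render_from_csvs(directory: str | Path) -> list[Path]:
    """Re-render every figure from its CSV twin; returns the written paths."""
    directory = Path(directory)
    written: list[Path] = []
    p = directory / "s1_selectivity_profile.csv"
    if p.exists():
        df = pd.read_csv(p)
        out = directory / "s1_selectivity_profile.png"
        _save_bar(df, "class", "mean_activation", "selectivity profile", out)
        written.append(out)
    p = directory / "s2_pair_accuracy.csv"
    if p.exists():
        df = pd.read_csv(p)
        out = directory / "s2_pair_accuracy.png"
        _save_bar(df, "model", "pair_accuracy", "pair accuracy: clean vs logo", out)
        written.append(out)
    p = directory / "s3_baselines.csv"
    if p.exists():
        df = pd.read_csv(p)
        out = directory / "s3_baselines.png"
        _save_bar(df, "model", "accuracy", "accuracy vs its own chance level", out)
        written.append(out)
    for tag in ("s4_grain", "s4_rhythm"):
        for mat in directory.glob(f"{tag}_*_matrix.csv"):
            m = pd.read_csv(mat).to_numpy()
            out = mat.with_suffix(".png")
            _save_heatmap(m, mat.stem, out)
            written.append(out)
    return written
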