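"""Min–max normalisation and the summed normalised triage score.

Each descriptor column x is rescaled over the panel to
NDV = (x − x_min)/(x_max − x_min); the score of a variant sums NDV for
descriptors that correlate positively with elevated viscosity and (1 − NDV)
for descriptors that correlate negatively, each times an optional weight
(default 1, evenly weighted). Lower score = lower hypothetical viscosity,
so the panel is ranked ascending.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: default direction of correlation with elevated viscosity
DEFAULT_DIRECTIONS: dict[str, str] = {
    "HI": "positive",
    "TANGO": "positive",
    "Tomar": "positive",
    "Sharma": "positive",
    "norm_hyd_score": "positive",
    "zeta": "negative",
    "BSA": "negative",
    "ens_charge": "negative",
}


@dataclass(frozen=True)
class NormalizedPanel:
    ndv: pd.DataFrame                       # variants x descriptors, in [0,1]
    column_bounds: dict[str, tuple[float, float]]  # provenance: (x_min, x_max)
    dropped: tuple[str, ...] = ()


def min_max_normalize(values) -> np.ndarray:
    """Elementwise (x − min)/(max − min). Raises on fewer than 2 values or a
    constant column (undefined denominator)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("min-max normalisation needs at least 2 values")
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        raise ZeroDivisionError("constant column: min-max normalisation undefined")
    return (x - lo) / (hi - lo)


def normalize_panel(table: pd.DataFrame, columns: list[str]) -> NormalizedPanel:
    """Normalise the requested descriptor columns over the panel.

    Columns that are constant, or that have missing values for some variant,
    are dropped panel-wide with a warning so every variant's score stays on
    one scale.
    """
    ndv = {}
    bounds = {}
    dropped = []
    for col in columns:
        x = table[col].to_numpy(dtype=float)
        if np.isnan(x).any():
            warnings.warn(
                f"descriptor {col!r} has missing values; excluded from scoring",
                stacklevel=2,
            )
            dropped.append(col)
            continue
        try:
            ndv[col] = min_max_normalize(x)
        except ZeroDivisionError:
            warnings.warn(
                f"descriptor {col!r} is constant across the panel; dropped",
                stacklevel=2,
            )
            dropped.append(col)
            continue
        bounds[col] = (float(np.min(x)), float(np.max(x)))
    return NormalizedPanel(
        ndv=pd.DataFrame(ndv, index=table.index),
        column_bounds=bounds,
        dropped=tuple(dropped),
    )


def normalized_score(
    panel: NormalizedPanel,
    directions: dict[str, str],
    weights: dict[str, float] | None = None,
) -> pd.Series:
    """Summed normalised score per variant (lower = more developable)."""
    weights = weights or {}
    score = pd.Series(0.0, index=panel.ndv.index)
    for col in panel.ndv.columns:
        if col not in directions:
            raise KeyError(f"descriptor {col!r} has no correlation direction")
        w = weights.get(col, 1.0)
        ndv = panel.ndv[col]
        if directions[col] == "positive":
            score = score + w * ndv
        elif directions[col] == "negative":
            score = score + w * (1.0 - ndv)
        else:
            raise ValueError(f"direction must be positive/negative, got {directions[col]!r}")
    score.name = "score"
    return score


def rank_panel(
    table: pd.DataFrame,
    directions: dict[str, str] | None = None,
    weights: dict[str, float] | None = None,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Normalise, score and rank a descriptor panel.

    ``columns`` defaults to the intersection of the table's columns with the
    keys of ``directions``. Output is sorted by ascending score with ties
    sharing a rank and ordered by variant_id; per-descriptor NDV columns are
    carried along as ``NDV_<name>``.
    """
    if len(table) < 2:
        raise ValueError("ranking needs at least 2 variants")
    directions = directions or DEFAULT_DIRECTIONS
    if columns is None:
        columns = [c for c in table.columns if c in directions]
    if not columns:
        raise ValueError("no scoreable descriptor columns found")
    panel = normalize_panel(table, columns)
    score = normalized_score(panel, directions, weights)
    out = pd.DataFrame({"score": score}).join(panel.ndv.add_prefix("NDV_"))
    # ties share a rank (competition ranking); tied rows order by variant_id
    order = sorted(out.index, key=lambda vid: (out.at[vid, "score"], str(vid)))
    out = out.loc[order]
    out["rank"] = out["score"].rank(method="min").astype(int)
    return out


def save_ranking_heatmap(ranked: pd.DataFrame, path) -> None:
    """Render the per-descriptor NDV matrix of a ranked panel as a heatmap."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ndv_cols = [c for c in ranked.columns if c.startswith("NDV_")]
    data = ranked[ndv_cols].to_numpy(dtype=float)
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.6 * len(ndv_cols), 0.8 + 0.3 * len(ranked))
    )
    im = ax.imshow(data, vmin=0.0, vmax=1.0, cmap="viridis", aspect="auto")
    ax.set_xticks(range(len(ndv_cols)), [c[4:] for c in ndv_cols], rotation=45, ha="right")
    ax.set_yticks(range(len(ranked)), ranked.index)
    fig.colorbar(im, ax=ax, label="normalised descriptor value")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
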