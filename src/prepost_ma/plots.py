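"""Forest and funnel plots.

Every figure is written together with a sidecar CSV (``<figure>.data.csv``)
holding the exact coordinates of all plotted elements, so tests and users
can assert numbers rather than pixels.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .effects_ad import TrialEffect
from .pooling import PoolingResult

__all__ = ["forest_plot", "funnel_plot"]


def _annotation(pooled: PoolingResult) -> str:
    label = "Random-effects (REML)" if pooled.model == "RE" else "Common-effect"
    if pooled.hk:
        label += ", Hartung-Knapp"
    return label


def _check_path(path: Path, format: str) -> Path:
    if format not in ("pdf", "png"):
        raise ValueError(f"format must be 'pdf' or 'png', got {format!r}")
    if path.suffix.lower() != f".{format}":
        path = path.with_suffix(f".{format}")
    return path


def forest_plot(
    effects: Sequence[TrialEffect],
    pooled: PoolingResult,
    path: str | Path,
    format: str = "png",
) -> pd.DataFrame:
    """Forest plot: one row per trial, summary diamond for the pooled effect.

    Returns the plot-data frame that is also written to ``<path>.data.csv``.
    """
    if not effects:
        raise ValueError("need at least one effect")
    path = _check_path(Path(path), format)
    z = stats.norm.ppf(0.5 + pooled.level / 2.0)
    records = []
    for eff in effects:
        records.append(
            {
                "element": "study", "label": eff.trial_id,
                "estimate": eff.estimate,
                "ci_low": eff.estimate - z * eff.se,
                "ci_high": eff.estimate + z * eff.se,
                "weight": 1.0 / eff.variance,
            }
        )
    records.append(
        {
            "element": "summary", "label": _annotation(pooled),
            "estimate": pooled.estimate,
            "ci_low": pooled.ci_low, "ci_high": pooled.ci_high,
            "weight": float("nan"),
        }
    )
    data = pd.DataFrame.from_records(records)

    n = len(effects)
    fig, ax = plt.subplots(figsize=(7.0, 1.0 + 0.45 * (n + 2)))
    weights = data.loc[data["element"] == "study", "weight"]
    wmax = float(weights.max())
    for i, rec in enumerate(records[:-1]):
        ypos = n - i
        ax.plot([rec["ci_low"], rec["ci_high"]], [ypos, ypos], color="black", lw=1.2)
        size = 4.0 + 8.0 * math.sqrt(rec["weight"] / wmax)
        ax.plot(rec["estimate"], ypos, marker="s", color="black", markersize=size)
        ax.text(
            ax.get_xlim()[0], ypos, "", va="center"
        )
    # summary diamond spanning the pooled CI
    ax.fill(
        [pooled.ci_low, pooled.estimate, pooled.ci_high, pooled.estimate],
        [0, 0.25, 0, -0.25],
        color="dimgray",
    )
    ax.axvline(0.0, color="gray", lw=0.8, ls=":")
    ax.set_yticks([n - i for i in range(n)] + [0])
    ax.set_yticklabels([e.trial_id for e in effects] + ["Summary"])
    ax.set_xlabel("Mean difference (treatment - control)")
    ax.set_title(_annotation(pooled))
    ax.set_ylim(-1, n + 1)
    fig.tight_layout()
    fig.savefig(path, format=format)
    plt.close(fig)
    data.to_csv(Path(str(path) + ".data.csv"), index=False, float_format="%.17g")
    return data


def funnel_plot(
    effects: Sequence[TrialEffect],
    pooled: PoolingResult,
    path: str | Path,
    format: str = "png",
) -> pd.DataFrame:
    """Funnel plot: estimate vs SE (inverted axis) with a 95% pseudo-CI funnel.

    The funnel is centred on the pooled estimate with bounds
    ``centre +/- z * SE`` at each vertical position.  Returns the plot-data
    frame, also written to ``<path>.data.csv``.
    """
    if len(effects) < 2:
        raise ValueError("need at least two effects for a funnel plot")
    path = _check_path(Path(path), format)
    z = stats.norm.ppf(0.975)
    se = np.array([e.se for e in effects])
    est = np.array([e.estimate for e in effects])
    se_grid = np.linspace(0.0, float(se.max()) * 1.05, 50)
    records = [
        {"element": "study", "label": e.trial_id, "estimate": e.estimate, "se": e.se}
        for e in effects
    ]
    records.append(
        {"element": "centre", "label": "", "estimate": pooled.estimate, "se": 0.0}
    )
    for s in se_grid:
        records.append(
            {"element": "funnel_low", "label": "", "estimate": pooled.estimate - z * s, "se": s}
        )
        records.append(
            {"element": "funnel_high", "label": "", "estimate": pooled.estimate + z * s, "se": s}
        )
    data = pd.DataFrame.from_records(records)

    fig, ax = plt.subplots(figsize=(6.0, 5.0))
    ax.plot(est, se, "o", color="black", ms=5)
    ax.plot(pooled.estimate - z * se_grid, se_grid, color="gray", lw=0.9, ls="--")
    ax.plot(pooled.estimate + z * se_grid, se_grid, color="gray", lw=0.9, ls="--")
    ax.axvline(pooled.estimate, color="gray", lw=0.9)
    ax.invert_yaxis()
    ax.set_xlabel("Mean difference (treatment - control)")
    ax.set_ylabel("Standard error")
    ax.set_title(_annotation(pooled))
    fig.tight_layout()
    fig.savefig(path, format=format)
    plt.close(fig)
    data.to_csv(Path(str(path) + ".data.csv"), index=False, float_format="%.17g")
    return data
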