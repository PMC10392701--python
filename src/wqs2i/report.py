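"""Serialization of results to JSON summaries and CSV weight tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def weights_table(summary: dict, component_names=None) -> pd.DataFrame:
    """Long-format weight table (component, direction, weight, selected)
    from a holdout summary."""
    rows = []
    cutoff = summary.get("cutoff")
    for direction in ("positive", "negative"):
        w = summary["weights"].get(direction)
        if w is None:
            continue
        for name, val in w.items():
            rows.append({"component": name, "direction": direction,
                         "weight": float(val),
                         "selected": bool(val > cutoff)})
    return pd.DataFrame(rows)


def write_weights_csv(summary: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    weights_table(summary).to_csv(path, index=False)


def plot_weight_distributions(dist, path=None):
    """Box-plots of the per-split weight distributions, one panel per
    direction, with a dashed line at the 1/c selection cutoff.

    ``dist`` is a HoldoutDistribution; returns the matplotlib figure
    (saved to ``path`` when given).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    panels = [(name, W) for name, W in
              (("positive", dist.weights_positive),
               ("negative", dist.weights_negative))
              if W.size and np.isfinite(W).all(axis=1).any()]
    c = len(dist.component_names)
    fig, axes = plt.subplots(len(panels), 1, squeeze=False,
                             figsize=(max(6, 0.25 * c), 3.2 * len(panels)))
    for ax, (name, W) in zip(axes.ravel(), panels):
        rows = W[np.isfinite(W).all(axis=1)]
        ax.boxplot(rows, tick_labels=dist.component_names)
        ax.axhline(1.0 / c, linestyle="--", color="grey")
        ax.set_ylabel(f"{name} weight")
        ax.tick_params(axis="x", rotation=90, labelsize=7)
    fig.tight_layout()
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(path, dpi=120)
    return fig
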