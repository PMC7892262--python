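"""Overview plot of gene-tag association results."""

from __future__ import annotations

import numpy as np
import pandas as pd

_MOI_MARKERS = {"dominant": "o", "recessive": "^"}
_CLASS_COLOURS = {
    "high": "#d62728",
    "moderate_deleterious": "#ff7f0e",
    "pooled": "#1f77b4",
}


def plot_associations(results: pd.DataFrame, pp_min: float = 0.75, ax=None):
    """Scatter of posterior probability by tag.

    One point per (gene, tag); marker shape encodes the winning mode of
    inheritance, colour the winning impact class.  Points above ``pp_min``
    are labelled with the gene symbol.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    res = results.dropna(subset=["pp"]).copy()
    tags = list(dict.fromkeys(res["tag"]))
    xpos = {t: i for i, t in enumerate(tags)}
    rng = np.random.default_rng(0)  # fixed jitter so plots reproduce
    for _, row in res.iterrows():
        moi, impact = (row.get("best_model") or "dominant:pooled").split(":", 1)
        x = xpos[row["tag"]] + rng.uniform(-0.15, 0.15)
        ax.scatter(
            x, row["pp"],
            marker=_MOI_MARKERS.get(moi, "s"),
            color=_CLASS_COLOURS.get(impact, "grey"),
            edgecolor="black", linewidth=0.3, zorder=3,
        )
        if row["pp"] > pp_min:
            ax.annotate(row["gene"], (x, row["pp"]), fontsize=7,
                        xytext=(2, 2), textcoords="offset points")
    ax.axhline(pp_min, color="grey", linestyle="--", linewidth=0.8)
    ax.set_xticks(range(len(tags)))
    ax.set_xticklabels(tags, rotation=45, ha="right")
    ax.set_ylabel("posterior probability of association")
    ax.set_ylim(-0.02, 1.05)
    return ax
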