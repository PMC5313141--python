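"""Bar-chart summaries of the phase-stratified permeability analysis."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def _axes(figsize):
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt.subplots(figsize=figsize)


def plot_kps_by_region(kps_by_region, path) -> Path:
    """Infarct vs contralateral KPS per phase, SEM error bars."""
    fig, ax = _axes((5, 4))
    phases = list(dict.fromkeys(kps_by_region["phase"]))
    width = 0.35
    xs = np.arange(len(phases))
    for k, region in enumerate(("infarct", "contralateral")):
        sub = kps_by_region[kps_by_region["region"] == region]
        sub = sub.set_index("phase").reindex(phases)
        ax.bar(xs + (k - 0.5) * width, sub["mean"], width,
               yerr=sub["sem"], capsize=3, label=region)
    ax.set_xticks(xs, phases)
    ax.set_ylabel("KPS (mL/100 g/min)")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    return path


def plot_kps_ratio(kps_ratio, path) -> Path:
    """Normalized permeability KPS_i/c per phase, SEM error bars."""
    fig, ax = _axes((4, 4))
    ax.bar(kps_ratio["phase"], kps_ratio["mean"], yerr=kps_ratio["sem"],
           capsize=3, color="tab:gray")
    ax.set_ylabel("KPS$_{i/c}$")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    return path
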