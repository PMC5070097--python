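"""Optional strip plots of per-SNV contamination estimates."""

from __future__ import annotations

from typing import Sequence

from .contamination import SampleContamination

__all__ = ["plot_contamination_strip"]


def plot_contamination_strip(samples: Sequence[SampleContamination], path) -> None:
    """One strip of per-SNV c values per sample, median as a bar.

    Values are plotted in percent; requires matplotlib (the ``plot``
    extra).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    fig, ax = plt.subplots(figsize=(1.6 * max(len(samples), 2) + 1, 4))
    rng = np.random.default_rng(0)  # jitter only, cosmetic
    for i, sc in enumerate(samples):
        ys = [100 * e.c for e in sc.per_snv]
        xs = i + rng.uniform(-0.12, 0.12, size=len(ys))
        ax.plot(xs, ys, "o", color="firebrick", alpha=0.6, markersize=4)
        ax.hlines(100 * sc.median_c, i - 0.25, i + 0.25, color="black", lw=2)
        ax.annotate(
            f"{100 * sc.median_c:.1f}",
            (i + 0.28, 100 * sc.median_c),
            fontsize=8,
            va="center",
        )
    ax.set_xticks(range(len(samples)))
    ax.set_xticklabels([sc.sample_id for sc in samples], rotation=30, ha="right", fontsize=8)
    ax.set_ylabel("estimated contamination (%)")
    ax.axhline(0, color="grey", lw=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
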