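"""Spatial consistency of significant findings across splits.

For each score and sample size, the per-split significance masks are
summed into an overlap map: a vertex with value 10 was significant in 10
of the discovery samples.  Density summaries describe the distribution of
these frequencies over the vertices that were significant at least once —
the analytical core of the study's consistency-map and density-plot
figures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


@dataclass
class OverlapMap:
    """Per-vertex count of splits in which the vertex was significant."""

    counts: np.ndarray
    n_splits: int
    score_name: str = ""
    sample_size: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.min(initial=0) < 0 or self.counts.max(initial=0) > self.n_splits:
            raise ValueError("counts must lie in [0, n_splits]")


@dataclass
class DensitySummary:
    """Distribution of significance frequencies over the ever-significant
    vertices.  Frequencies are percentages of ``n_splits``; an empty
    support yields the explicit empty summary."""

    n_support: int
    frequencies_pct: np.ndarray = field(default_factory=lambda: np.empty(0))
    median_pct: float | None = None
    max_pct: float | None = None

    @property
    def empty(self) -> bool:
        return self.n_support == 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_support": self.n_support,
                "median_pct": self.median_pct,
                "max_pct": self.max_pct,
            }
        )


def aggregate_overlap(
    masks: list[np.ndarray], score_name: str = "", sample_size: int | None = None
) -> OverlapMap:
    """Sum boolean significance masks (one per split) into an overlap map."""
    if not masks:
        raise ValueError("need at least one mask")
    arrs = [np.asarray(m, dtype=bool) for m in masks]
    n_v = arrs[0].shape[0]
    if any(a.shape != (n_v,) for a in arrs):
        raise ValueError("masks do not share a mesh")
    counts = np.sum(arrs, axis=0).astype(np.int64)
    return OverlapMap(
        counts=counts, n_splits=len(arrs), score_name=score_name, sample_size=sample_size
    )


def density_summary(overlap: OverlapMap) -> DensitySummary:
    """Frequencies (in % of splits) over vertices significant at least once."""
    support = overlap.counts[overlap.counts > 0]
    if support.size == 0:
        return DensitySummary(n_support=0)
    freq = support / overlap.n_splits * 100.0
    return DensitySummary(
        n_support=int(support.size),
        frequencies_pct=freq,
        median_pct=float(np.median(freq)),
        max_pct=float(freq.max()),
    )


def plot_density(summaries: dict[str, DensitySummary], path) -> None:
    """Kernel-density plot of overlap frequencies, one curve per label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, s in summaries.items():
        if s.empty:
            continue
        ax.hist(
            s.frequencies_pct, bins=20, range=(0, 100), density=True,
            histtype="step", label=label,
        )
    ax.set_xlabel("frequency of significance (% of splits)")
    ax.set_ylabel("density over significant vertices")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
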