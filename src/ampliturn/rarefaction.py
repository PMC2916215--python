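"""Analytic (expectation-exact) rarefaction.

The expected number of OTUs in a uniform without-replacement subsample of
g reads from an abundance vector (c_1, ..., c_S), T = sum c_i, is the
hypergeometric (Hurlbert) expectation

    E[S_g] = sum_i [ 1 - C(T - c_i, g) / C(T, g) ],

computed here in log-gamma space because T can be large enough to
overflow direct binomial coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .otu import OtuTable


def _log_binom(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def expected_richness(counts, g: int) -> float:
    """Hurlbert rarefaction E[S_g] for one abundance vector.

    ``counts`` must be positive integers; ``0 <= g <= T``.  Exact
    expectation under sampling without replacement; g = T returns the
    observed richness, g <= 1 returns g.
    """
    c = np.asarray(counts, dtype=np.int64)
    if c.ndim != 1 or len(c) == 0:
        raise ValueError("counts must be a non-empty 1-D vector")
    if (c < 1).any():
        raise ValueError("all abundances must be >= 1")
    total = int(c.sum())
    if not 0 <= g <= total:
        raise ValueError(f"subsample size g={g} outside [0, {total}]")
    if g == 0:
        return 0.0
    # C(T - c_i, g) = 0 whenever T - c_i < g
    keep = total - c >= g
    ratio = np.zeros(len(c))
    if keep.any():
        log_ratio = _log_binom((total - c[keep]).astype(float), float(g)) - _log_binom(
            np.array(float(total)), float(g)
        )
        ratio[keep] = np.clip(np.exp(log_ratio), 0.0, 1.0)
    return float(np.sum(1.0 - ratio))


@dataclass
class RarefactionCurve:
    """Expected richness over a grid of subsample sizes for one sample."""

    label: str
    sizes: np.ndarray
    expected: np.ndarray
    observed_richness: int
    total_reads: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"curve": self.label, "g": self.sizes, "expected_richness": self.expected}
        )


def rarefy_counts(counts, label: str, n_points: int = 50) -> RarefactionCurve:
    """Rarefaction curve on an evenly spaced grid from 0 to the total."""
    c = np.asarray(counts, dtype=np.int64)
    c = c[c > 0]
    total = int(c.sum())
    sizes = np.unique(np.linspace(0, total, n_points + 1).round().astype(np.int64))
    expected = np.array([expected_richness(c, int(g)) for g in sizes])
    return RarefactionCurve(
        label=label, sizes=sizes, expected=expected,
        observed_richness=int(len(c)), total_reads=total,
    )


def rarefaction_curves(
    table: OtuTable, n_points: int = 50, include_pooled: bool = True
) -> list[RarefactionCurve]:
    """One curve per sample, plus one for the pooled (column-summed) data."""
    curves = [
        rarefy_counts(table.counts[sample].to_numpy(), sample, n_points=n_points)
        for sample in table.samples
    ]
    if include_pooled:
        pooled = table.counts.sum(axis=1).to_numpy()
        curves.append(rarefy_counts(pooled, "all samples", n_points=n_points))
    return curves


def curves_to_tsv(curves: list[RarefactionCurve], path) -> None:
    pd.concat([c.to_frame() for c in curves]).to_csv(path, sep="\t", index=False)


def plot_curves(curves: list[RarefactionCurve], path) -> None:
    """Single-panel plot of all rarefaction curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for curve in curves:
        style = {"lw": 2.5, "color": "black"} if curve.label == "all samples" else {"lw": 1}
        ax.plot(curve.sizes, curve.expected, label=curve.label, **style)
    ax.set_xlabel("reads sampled")
    ax.set_ylabel("expected OTU richness")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
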