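"""Cross-method agreement diagnostics.

Different shell definitions shift the instantaneous coordination number
systematically; whether they see the *same* fluctuations is measured by
the CN distribution of each method and by Pearson / Spearman rank
correlation between per-frame CN series of the same trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .shells import ShellSeries

__all__ = ["CNDistribution", "cn_distribution", "correlate_methods", "correlation_matrix"]


@dataclass
class CNDistribution:
    """Normalized histogram of instantaneous CN, probabilities in percent."""

    method: str
    probabilities: dict[int, float]

    @property
    def mean(self) -> float:
        return sum(cn * p for cn, p in self.probabilities.items()) / 100.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"CN": list(self.probabilities), "probability_percent": list(self.probabilities.values())}
        )


def cn_distribution(shells: ShellSeries) -> CNDistribution:
    """CN value -> probability (%) over all frames of one shell series."""
    cn = shells.cn.astype(int)
    if len(cn) == 0:
        raise ValueError("empty shell series")
    values, counts = np.unique(cn, return_counts=True)
    probs = {int(v): 100.0 * c / len(cn) for v, c in zip(values, counts)}
    return CNDistribution(method=shells.method, probabilities=probs)


def correlate_methods(series_a: np.ndarray, series_b: np.ndarray) -> tuple[float, float]:
    """Pearson and Spearman (mid-rank) correlation of two CN series."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("series must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 frames to correlate")
    if np.var(a) == 0.0 or np.var(b) == 0.0:
        raise ValueError("zero-variance series: correlation undefined")
    pearson = float(stats.pearsonr(a, b).statistic)
    spearman = float(stats.spearmanr(a, b).statistic)
    return pearson, spearman


def correlation_matrix(series: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise method correlations as a tidy table (method_a, method_b, pearson, spearman)."""
    rows = []
    for (ma, sa), (mb, sb) in combinations(series.items(), 2):
        p, s = correlate_methods(sa, sb)
        rows.append({"method_a": ma, "method_b": mb, "pearson": p, "spearman": s})
    return pd.DataFrame(rows)
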