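"""Expression stratification and survival comparison.

Cohorts are stratified by the ranked expression of one gene into high /
middle / low groups (top and bottom fractions, default a quarter each);
metastasis-free survival of the extreme groups is then compared with the
Kaplan-Meier product-limit estimator and the two-group log-rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test


@dataclass
class StratifiedCohort:
    groups: pd.Series  # sample -> "high" | "middle" | "low"
    gene: str
    top_frac: float
    bottom_frac: float

    def samples(self, group: str) -> list:
        return list(self.groups.index[self.groups == group])


def stratify(
    expr: pd.Series,
    top_frac: float = 0.25,
    bottom_frac: float = 0.25,
    gene: str = "",
) -> StratifiedCohort:
    """Split samples into high/middle/low by ranked expression.

    Exactly floor(n * top_frac) samples go to ``high`` and
    floor(n * bottom_frac) to ``low``; ties are broken by the stable input
    sample order.
    """
    if top_frac <= 0 or bottom_frac <= 0 or top_frac + bottom_frac >= 1:
        raise ValueError("fractions must be positive and sum to < 1")
    n = len(expr)
    n_top = math.floor(n * top_frac)
    n_bot = math.floor(n * bottom_frac)
    if n_top < 1 or n_bot < 1:
        raise ValueError(f"cohort of {n} too small for non-empty high and low groups")
    order = np.argsort(-expr.to_numpy(), kind="stable")
    groups = pd.Series("middle", index=expr.index, name="group")
    groups.iloc[order[:n_top]] = "high"
    groups.iloc[order[n - n_bot:]] = "low"
    return StratifiedCohort(groups, gene, top_frac, bottom_frac)


def km_curve(times, events, groups) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimates per group.

    Returns, per group label, a DataFrame with columns ``time`` and
    ``survival``: S(t) = prod over event times <= t of (1 - d_i/n_i), with
    censored samples leaving the risk set without an event factor.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    out: dict[str, pd.DataFrame] = {}
    for g in pd.unique(groups):
        sel = groups == g
        if not sel.any():
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        sf = kmf.survival_function_
        out[str(g)] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return out


def logrank(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test: chi-square statistic (1 df) and p-value."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank requires exactly two groups, got {list(labels)}")
    if events.sum() < 1:
        raise ValueError("log-rank requires at least one event")
    a = groups == labels[0]
    res = logrank_test(times[a], times[~a], events[a], events[~a])
    return float(res.test_statistic), float(res.p_value)


def plot_km(curves: dict[str, pd.DataFrame], path: str | Path, title: str = "") -> None:
    """Optional step-plot of the survival curves (PNG/PDF by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, df in curves.items():
        ax.step(df["time"], df["survival"], where="post", label=name)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("metastasis-free survival")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
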