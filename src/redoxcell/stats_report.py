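"""Group statistics: one-way ANOVA, Dunnett's many-to-one test, z-scores.

Treatment-versus-control comparisons use the classical chain: a one-way
ANOVA across all groups, then Dunnett's multiple-comparison test of
each treatment against the shared control with a single pooled
variance, two-sided, significant at alpha = 0.01. The summary heatmap
statistic is the control-referenced z-score
z = (mu_treatment - mu_control) / sigma_control.

Dunnett's adjusted p-value is the tail probability of max_j |T_j| in
the joint null distribution of the treatment-vs-control t statistics
(which are correlated through the shared control mean and pooled
variance). It is evaluated here by seeded Monte Carlo sampling of that
joint distribution — transparent, easily cross-checked, and accurate
to well under the alpha scale at the default 100,000 draws. The null
sample depends only on the group sizes, so it is cached and reused
across calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSample",
    "DunnettResult",
    "anova_oneway",
    "dunnett_test",
    "z_score_summary",
    "groups_from_frame",
]


@dataclass
class GroupSample:
    """A condition label with its observed values (per cell or per well)."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 1:
            raise ValueError(f"group {self.label!r} is empty")


@dataclass
class DunnettResult:
    """Per-treatment comparisons against the control.

    ``table`` columns: treatment, diff (mean difference), se (from the
    single pooled variance), statistic, p_adjusted, significant.
    """

    control: str
    alpha: float
    df: int
    pooled_variance: float
    table: pd.DataFrame


def anova_oneway(groups: Sequence[GroupSample]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    for g in groups:
        if g.values.size < 2:
            raise ValueError(f"group {g.label!r} needs n >= 2")
    f, p = stats.f_oneway(*[g.values for g in groups])
    if np.isnan(f):  # all observations identical: no variance anywhere
        return 0.0, 1.0
    return float(f), float(p)


_NULL_CACHE: dict[tuple, np.ndarray] = {}


def _null_max_abs_t(
    sizes: tuple[int, ...], n_draws: int, seed: int
) -> np.ndarray:
    """Monte-Carlo sample of max_j |T_j| under the global null.

    sizes = (n_control, n_1, ..., n_k). Group means are sampled as
    N(0, 1/n_i) and the pooled variance as chi2(df)/df, reproducing the
    exact joint distribution of the Dunnett statistics.
    """
    key = (sizes, n_draws, seed)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(seed)
        n = np.asarray(sizes, dtype=float)
        df = int(n.sum()) - len(sizes)
        means = rng.standard_normal((n_draws, len(sizes))) / np.sqrt(n)
        s2 = rng.chisquare(df, size=n_draws) / df
        se = np.sqrt(1.0 / n[1:] + 1.0 / n[0])
        t = (means[:, 1:] - means[:, [0]]) / (np.sqrt(s2)[:, None] * se[None, :])
        _NULL_CACHE[key] = np.abs(t).max(axis=1)
    return _NULL_CACHE[key]


def dunnett_test(
    groups: Sequence[GroupSample],
    control: str,
    alpha: float = 0.01,
    n_draws: int = 100_000,
    seed: int = 0,
) -> DunnettResult:
    """Dunnett's many-to-one comparison with a single pooled variance.

    Two-sided. The adjusted p for treatment i is
    P(max_j |T_j| >= |t_i|) under the joint null, from a seeded
    Monte-Carlo sample shared across treatments (and cached across
    calls with the same group sizes).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    labels = [g.label for g in groups]
    if control not in labels:
        raise ValueError(f"control group {control!r} not present")
    for g in groups:
        if g.values.size < 2:
            raise ValueError(f"group {g.label!r} needs n >= 2 for a pooled variance")
    ctrl = next(g for g in groups if g.label == control)
    treatments = [g for g in groups if g.label != control]
    if not treatments:
        raise ValueError("need at least one treatment group")

    n_all = [ctrl.values.size] + [g.values.size for g in treatments]
    df = sum(n_all) - len(n_all)
    pooled = sum(
        ((g.values.size - 1) * g.values.var(ddof=1) for g in [ctrl, *treatments])
    ) / df

    null_max = _null_max_abs_t(tuple(n_all), n_draws, seed)
    sorted_null = np.sort(null_max)

    rows = []
    for g in treatments:
        diff = g.values.mean() - ctrl.values.mean()
        se = np.sqrt(pooled * (1.0 / g.values.size + 1.0 / ctrl.values.size))
        t = diff / se if se > 0 else np.inf * np.sign(diff)
        # tail fraction of the null max-|t| sample at |t|
        p_adj = 1.0 - np.searchsorted(sorted_null, abs(t), side="left") / n_draws
        rows.append(
            {
                "treatment": g.label,
                "diff": diff,
                "se": se,
                "statistic": t,
                "p_adjusted": float(p_adj),
                "significant": bool(p_adj < alpha),
            }
        )
    return DunnettResult(
        control=control,
        alpha=alpha,
        df=df,
        pooled_variance=float(pooled),
        table=pd.DataFrame(rows),
    )


def z_score_summary(
    groups_by_variable: Mapping[str, Sequence[GroupSample]],
    control: str,
) -> pd.DataFrame:
    """Control-referenced z-score per (variable, treatment).

    z = (mu_treatment - mu_control) / sigma_control with the control's
    sample SD (ddof=1). Output is a variables x treatments matrix.
    """
    rows = []
    for variable, groups in groups_by_variable.items():
        labels = [g.label for g in groups]
        if control not in labels:
            raise ValueError(f"control {control!r} missing for variable {variable!r}")
        ctrl = next(g for g in groups if g.label == control)
        if ctrl.values.size < 2:
            raise ValueError(f"control needs n >= 2 for variable {variable!r}")
        sigma = ctrl.values.std(ddof=1)
        if sigma <= 0:
            raise ValueError(f"control variance is zero for variable {variable!r}")
        mu_c = ctrl.values.mean()
        for g in groups:
            if g.label == control:
                continue
            rows.append(
                {
                    "variable": variable,
                    "treatment": g.label,
                    "z": (g.values.mean() - mu_c) / sigma,
                }
            )
    long = pd.DataFrame(rows)
    return long.pivot(index="variable", columns="treatment", values="z")


def groups_from_frame(df: pd.DataFrame) -> dict[str, list[GroupSample]]:
    """Read (condition, variable, value) rows into per-variable groups."""
    out: dict[str, list[GroupSample]] = {}
    for (variable, condition), sub in df.groupby(["variable", "condition"], sort=False):
        out.setdefault(str(variable), []).append(
            GroupSample(label=str(condition), values=sub["value"].to_numpy())
        )
    return out
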