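"""Feature screening: one-way ANOVA and Fisher LSD post-hoc pairs.

Each feature is tested for equality of means across the six stages
with a one-way ANOVA at 95% confidence; features are ranked by
descending F statistic (the p-values on large cohorts underflow to
zero and cannot order features).  Fisher's least significant
difference then compares every stage pair using the pooled
within-group mean square -- unprotected by design, so results are
flagged when the omnibus test did not reject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import META_COLUMNS
from .stages import STAGES


def _group_arrays(values, groups) -> list[np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = [g for g in STAGES if g in groups] or list(pd.unique(groups))
    arrays = [values[groups == g] for g in uniq]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least two samples")
    return arrays


def anova_oneway(values, groups) -> tuple[float, float]:
    """One-way ANOVA F statistic and p-value across group labels."""
    arrays = _group_arrays(values, groups)
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def rank_features(df: pd.DataFrame) -> pd.DataFrame:
    """Per-feature F, p, rank (1 = largest F) and per-stage mean +/- std.

    ``df`` is a feature matrix with a ``label`` column.  Standard
    deviations are sample (ddof=1) std.
    """
    feat_cols = [c for c in df.columns if c not in META_COLUMNS]
    labels = df["label"].to_numpy()
    rows = {}
    for col in feat_cols:
        f, p = anova_oneway(df[col].to_numpy(), labels)
        row = {"F": f, "p": p}
        for s in STAGES:
            vals = df.loc[df["label"] == s, col]
            row[f"{s}_mean"] = float(vals.mean())
            row[f"{s}_std"] = float(vals.std(ddof=1))
        rows[col] = row
    out = pd.DataFrame(rows).T
    out["rank"] = out["F"].rank(ascending=False, method="first").astype(int)
    front = ["rank", "F", "p"]
    return out[front + [c for c in out.columns if c not in front]]


@dataclass
class LSDResult:
    pairs: pd.DataFrame
    omnibus_f: float
    omnibus_p: float
    protected: bool  # False when the omnibus ANOVA did not reject


def fisher_lsd(values, groups, alpha: float = 0.05) -> LSDResult:
    """Pairwise Fisher LSD comparisons of group means.

    For groups i, j the difference is significant when
    |mean_i - mean_j| > t_{1-alpha/2, N-g} * sqrt(MSE (1/n_i + 1/n_j))
    with MSE the pooled within-group mean square.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = [g for g in STAGES if g in groups] or list(pd.unique(groups))
    arrays = {g: values[groups == g] for g in uniq}
    ns = {g: len(a) for g, a in arrays.items()}
    N, g = len(values), len(uniq)
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / (N - g)
    tcrit = stats.t.ppf(1 - alpha / 2, N - g)
    f, p = anova_oneway(values, groups)

    recs = []
    for i in range(g):
        for j in range(i + 1, g):
            gi, gj = uniq[i], uniq[j]
            diff = float(arrays[gi].mean() - arrays[gj].mean())
            lsd = float(tcrit * np.sqrt(mse * (1 / ns[gi] + 1 / ns[gj])))
            recs.append(
                {"group_i": gi, "group_j": gj, "mean_diff": diff,
                 "lsd": lsd, "significant": abs(diff) > lsd}
            )
    return LSDResult(pairs=pd.DataFrame(recs), omnibus_f=f, omnibus_p=p,
                     protected=p < alpha)
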