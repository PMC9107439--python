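"""Group-difference testing on the network feature table.

Per metric, a one-way MANOVA with diagnosis as the factor and the K
network means as the multivariate response (Wilks' lambda, Rao's F
approximation), followed by per-network one-way ANOVAs as post-hoc
tests.  By default each diagnostic group is compared pairwise against
the reference (neurotypical) group and post-hoc p-values are left
uncorrected; an omnibus mode over all groups and Benjamini–Hochberg
correction are available.

MANOVA p-values are invariant to common affine rescaling of the
responses, so running the tests on raw or globally min-max scaled
network means gives identical results; raw values are used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .encoding import FeatureTable

__all__ = ["StatsResult", "wilks_manova", "manova_per_metric", "stats_table"]


@dataclass
class StatsResult:
    metric: str
    comparison: Tuple[str, ...]
    manova_stat: float  # Wilks' lambda
    manova_F: float
    manova_df: Tuple[float, float]
    manova_p: float
    posthoc: pd.DataFrame  # network, F, p (and p_adj if corrected)


def wilks_manova(groups: Sequence[np.ndarray]) -> Tuple[float, float, Tuple[float, float], float]:
    """One-way MANOVA: Wilks' lambda and Rao's F approximation.

    ``groups`` is a sequence of (n_i, p) response matrices.  Lambda is
    det(W) / det(W + B) with W and B the within- and between-group
    scatter matrices; Rao's transformation maps it to an approximate
    (exact for two groups) F statistic.
    """
    g = len(groups)
    if g < 2:
        raise ValueError("need at least 2 groups")
    p = groups[0].shape[1]
    ns = [x.shape[0] for x in groups]
    N = sum(ns)
    if N <= p + g:
        raise ValueError(
            f"too few subjects (N={N}) for a {p}-dimensional response with {g} groups; "
            "reduce dimensionality or add subjects"
        )
    grand = np.vstack(groups).mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for x in groups:
        mu = x.mean(axis=0)
        xc = x - mu
        W += xc.T @ xc
        d = (mu - grand)[:, None]
        B += x.shape[0] * (d @ d.T)
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(W + B)
    if sign_w <= 0 or sign_t <= 0:
        raise ValueError(
            "singular within-group scatter matrix; reduce response dimension or add subjects"
        )
    lam = float(np.exp(logdet_w - logdet_t))

    # Rao's F approximation
    q = g - 1
    m = N - 1 - (p + g) / 2.0
    denom = p * p + q * q - 5
    s = np.sqrt((p * p * q * q - 4) / denom) if denom > 0 else 1.0
    df1 = p * q
    df2 = m * s - (p * q) / 2.0 + 1
    lam_s = lam ** (1.0 / s)
    F = (1 - lam_s) / lam_s * (df2 / df1)
    pval = float(sps.f.sf(F, df1, df2))
    return lam, float(F), (float(df1), float(df2)), pval


def manova_per_metric(
    table: FeatureTable,
    metric: str,
    group: Optional[str] = None,
    reference: str = "TYP",
    bh_correct: bool = False,
) -> StatsResult:
    """MANOVA across the K networks of one metric, plus post-hoc ANOVAs.

    With ``group`` given, compares that group pairwise against the
    reference; with ``group=None``, an omnibus test over all groups.
    Raw (unscaled) network means are used.
    """
    df = table.data
    if group is not None:
        levels = [group, reference]
    else:
        levels = list(pd.unique(df["group"]))
    cols = table.metric_columns(metric)
    blocks = []
    for lv in levels:
        x = df.loc[df["group"] == lv, cols].to_numpy(dtype=float)
        if x.shape[0] == 0:
            raise ValueError(f"group {lv} has no subjects")
        blocks.append(x)
    lam, F, dfs, pval = wilks_manova(blocks)

    rows = []
    for j, net in enumerate(table.network_names):
        fa, pa = sps.f_oneway(*[b[:, j] for b in blocks])
        rows.append({"network": net, "F": float(fa), "p": float(pa)})
    posthoc = pd.DataFrame(rows)
    if bh_correct:
        posthoc["p_adj"] = _benjamini_hochberg(posthoc["p"].to_numpy())
    return StatsResult(
        metric=metric,
        comparison=tuple(levels),
        manova_stat=lam,
        manova_F=F,
        manova_df=dfs,
        manova_p=pval,
        posthoc=posthoc,
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = n - rank_from_top
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj


def stats_table(
    table: FeatureTable,
    reference: str = "TYP",
    bh_correct: bool = False,
) -> pd.DataFrame:
    """All pairwise (diagnosis vs reference) tests for all three metrics,
    as one long table mirroring a supplementary-results layout: one
    MANOVA header row per (metric, comparison) followed by the
    per-network post-hoc rows."""
    from .encoding import METRICS

    groups = [g for g in pd.unique(table.data["group"]) if g != reference]
    rows = []
    for metric in METRICS:
        for g in groups:
            res = manova_per_metric(table, metric, group=g, reference=reference,
                                    bh_correct=bh_correct)
            rows.append(
                {
                    "metric": metric,
                    "comparison": f"{g} vs {reference}",
                    "network": "(MANOVA)",
                    "stat_name": "Wilks lambda",
                    "stat": res.manova_stat,
                    "F": res.manova_F,
                    "p": res.manova_p,
                }
            )
            for _, r in res.posthoc.iterrows():
                rows.append(
                    {
                        "metric": metric,
                        "comparison": f"{g} vs {reference}",
                        "network": r["network"],
                        "stat_name": "ANOVA F",
                        "stat": np.nan,
                        "F": r["F"],
                        "p": r["p"],
                    }
                )
    return pd.DataFrame(rows)
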