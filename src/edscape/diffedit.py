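"""Differential editing across stages and trajectory clustering.

The editing matrix is sites x samples with NA below the coverage
minimum.  Per-site one-way ANOVA across stage groups is followed by
Benjamini-Hochberg adjustment; differential sites are clustered on
z-scored stage-mean vectors with agglomerative hierarchical clustering
driven by the Lance-Williams recurrence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster
from statsmodels.stats.multitest import multipletests

from .synthio import STAGES

__all__ = [
    "build_matrix",
    "anova_stages",
    "lance_williams_linkage",
    "cluster_trajectories",
    "stage_means",
]


def build_matrix(sites: pd.DataFrame, design: pd.DataFrame, min_cov: int = 5):
    """Build the sites x samples editing-ratio matrix.

    Cell values come from ``ratio_<sample>`` columns and are masked to
    NA where the HQ coverage ``cov_<sample>`` falls below ``min_cov``.
    Raises ``KeyError`` when a design sample has no columns in the sites
    table.
    """
    samples = design["sample_id"].tolist()
    index = sites["chrom"].astype(str) + ":" + sites["pos"].astype(str)
    data = {}
    for s in samples:
        rcol, ccol = f"ratio_{s}", f"cov_{s}"
        if rcol not in sites.columns:
            raise KeyError(f"sample {s!r} missing from sites table")
        vals = sites[rcol].values.astype(float)
        if ccol in sites.columns:
            vals = np.where(sites[ccol].values >= min_cov, vals, np.nan)
        data[s] = vals
    return pd.DataFrame(data, index=index)


def _anova_oneway(groups):
    """One-way fixed-effects ANOVA by direct sum-of-squares decomposition.

    Returns ``(F, p)``; degenerate inputs give NaN, a zero between-group
    sum of squares gives ``F=0, p=1`` and a zero within-group sum of
    squares with signal gives ``F=inf, p=0``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    k = len(groups)
    n = sum(len(g) for g in groups)
    if k < 2 or n <= k:
        return float("nan"), float("nan")
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb, dfw = k - 1, n - k
    if ssb <= 0:
        return 0.0, 1.0
    if ssw <= 0:
        return float("inf"), 0.0
    F = (ssb / dfb) / (ssw / dfw)
    return float(F), float(stats.f.sf(F, dfb, dfw))


def anova_stages(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    fdr: float = 0.05,
    min_per_stage: int = 2,
    min_stages: int = 2,
) -> pd.DataFrame:
    """Per-site ANOVA across stage groups with BH correction.

    A site is tested when at least ``min_stages`` stages have
    ``min_per_stage`` non-NA values; untested sites carry NaN
    statistics.  ``is_differential`` means q < ``fdr``.
    """
    stage_of = dict(zip(design["sample_id"], design["stage"]))
    stages_present = [s for s in STAGES if s in set(design["stage"])]
    cols_by_stage = {
        st: [c for c in matrix.columns if stage_of.get(c) == st]
        for st in stages_present
    }

    rows = []
    for site, row in matrix.iterrows():
        groups = []
        means = {}
        for st in stages_present:
            vals = row[cols_by_stage[st]].dropna().values
            means[f"mean_{st}"] = float(vals.mean()) if len(vals) else np.nan
            if len(vals) >= min_per_stage:
                groups.append(vals)
        if len(groups) >= min_stages:
            F, p = _anova_oneway(groups)
        else:
            F, p = np.nan, np.nan
        rows.append({"site": site, "F": F, "p": p, **means})
    res = pd.DataFrame(rows)

    res["q"] = np.nan
    tested = res["p"].notna()
    if tested.any():
        res.loc[tested, "q"] = multipletests(
            res.loc[tested, "p"].values, method="fdr_bh"
        )[1]
    res["is_differential"] = res["q"] < fdr
    return res


# Lance-Williams coefficients: d(k, i+j) = a_i d_ki + a_j d_kj + b d_ij
#                                          + g |d_ki - d_kj|
def _lw_coefficients(method, ni, nj, nk):
    if method == "single":
        return 0.5, 0.5, 0.0, -0.5
    if method == "complete":
        return 0.5, 0.5, 0.0, 0.5
    if method == "average":
        t = ni + nj
        return ni / t, nj / t, 0.0, 0.0
    if method == "ward":
        t = ni + nj + nk
        return (ni + nk) / t, (nj + nk) / t, -nk / t, 0.0
    raise ValueError(f"unknown linkage method: {method}")


def lance_williams_linkage(X: np.ndarray, method: str = "average") -> np.ndarray:
    """Agglomerative clustering via the Lance-Williams update formula.

    ``X`` is an (n, p) observation matrix; distances are Euclidean
    (Ward operates on squared distances internally, heights are reported
    on the distance scale).  Returns a linkage matrix in the standard
    ``(n-1, 4)`` layout: merged cluster ids, merge height, new size.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two observations")
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diff ** 2).sum(axis=2))
    squared = method == "ward"
    if squared:
        D = D ** 2
    np.fill_diagonal(D, np.inf)
    D[np.tril_indices(n)] = np.where(
        np.isinf(D[np.tril_indices(n)]), np.inf, D[np.tril_indices(n)]
    )

    active = np.ones(n, dtype=bool)
    sizes = np.ones(n, dtype=float)
    ids = np.arange(n)
    Z = np.zeros((n - 1, 4))
    work = D.copy()

    for step in range(n - 1):
        masked = np.where(
            active[:, None] & active[None, :], work, np.inf
        )
        np.fill_diagonal(masked, np.inf)
        i, j = np.unravel_index(np.argmin(masked), masked.shape)
        if i > j:
            i, j = j, i
        h = masked[i, j]
        Z[step] = [
            min(ids[i], ids[j]),
            max(ids[i], ids[j]),
            np.sqrt(h) if squared else h,
            sizes[i] + sizes[j],
        ]
        # Lance-Williams update of distances from every other cluster k
        # to the merged cluster (stored in slot i)
        ks = np.nonzero(active)[0]
        ks = ks[(ks != i) & (ks != j)]
        if ks.size:
            ai, aj, b, g = None, None, None, None
            dki = work[ks, i]
            dkj = work[ks, j]
            dij = work[i, j]
            new = np.empty(ks.size)
            for t, k in enumerate(ks):
                ai, aj, b, g = _lw_coefficients(method, sizes[i], sizes[j], sizes[k])
                new[t] = ai * dki[t] + aj * dkj[t] + b * dij + g * abs(dki[t] - dkj[t])
            work[ks, i] = new
            work[i, ks] = new
        active[j] = False
        sizes[i] = sizes[i] + sizes[j]
        ids[i] = n + step
    return Z


def stage_means(matrix: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-site stage-mean table (NaN where a stage has no values)."""
    stage_of = dict(zip(design["sample_id"], design["stage"]))
    stages_present = [s for s in STAGES if s in set(design["stage"])]
    out = {}
    for st in stages_present:
        cols = [c for c in matrix.columns if stage_of.get(c) == st]
        out[st] = matrix[cols].mean(axis=1)
    return pd.DataFrame(out)


def cluster_trajectories(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    site_ids=None,
    k: int = 3,
    linkage: str = "average",
):
    """Cluster differential-site trajectories on z-scored stage means.

    Sites lacking a value in any stage are excluded (reported in the
    returned frame with cluster 0).  Cluster labels are renumbered in
    decreasing size order (1 = largest).  Returns
    ``(labels_frame, curves_frame)`` where curves carry per-cluster
    per-stage mean and standard deviation of the stage-mean vectors.
    """
    sm = stage_means(matrix, design)
    if site_ids is not None:
        sm = sm.loc[[s for s in site_ids if s in sm.index]]
    complete = sm.dropna()
    if len(complete) < k:
        raise ValueError(
            f"fewer clusterable sites ({len(complete)}) than requested clusters ({k})"
        )

    vals = complete.values
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (vals - mu) / np.where(sd == 0, 1, sd), 0.0)

    if k == 1:
        raw = np.ones(len(complete), dtype=int)
    else:
        Z = lance_williams_linkage(z, method=linkage)
        raw = fcluster(Z, t=k, criterion="maxclust")

    # renumber by decreasing cluster size, ties by first appearance
    sizes = pd.Series(raw).value_counts()
    order = sizes.sort_values(ascending=False).index.tolist()
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([remap[r] for r in raw])

    labels_frame = pd.DataFrame({"site": complete.index, "cluster": labels})
    excluded = sm.index.difference(complete.index)
    if len(excluded):
        labels_frame = pd.concat(
            [
                labels_frame,
                pd.DataFrame({"site": excluded, "cluster": 0}),
            ],
            ignore_index=True,
        )

    curve_rows = []
    for cl in sorted(set(labels)):
        sub = complete.values[labels == cl]
        for si, st in enumerate(complete.columns):
            curve_rows.append(
                {
                    "cluster": cl,
                    "stage": st,
                    "mean": float(sub[:, si].mean()),
                    "sd": float(sub[:, si].std(ddof=0)),
                    "n_sites": int(sub.shape[0]),
                }
            )
    return labels_frame, pd.DataFrame(curve_rows)
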