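"""Independent oracles and small builders shared by the test modules.

Every oracle here is deliberately implemented by a different route than
the library code it checks (exact integer enumeration, direct
sum-of-squares, naive cluster-distance recomputation).
"""

from math import comb

import numpy as np
import pandas as pd


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration.

    Point weights are exact integers; the two-sided p sums every table
    (with the same margins) whose point probability does not exceed the
    observed one, using the standard 1+1e-7 relative tie tolerance.
    """
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(c1, r1)
    ws = [comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)]
    wobs = ws[a - lo]
    cutoff = wobs * (1 + 1e-7)
    num = sum(w for w in ws if w <= cutoff)
    return num / sum(ws)


def anova_oracle(groups):
    """One-way ANOVA F via scipy's independent implementation."""
    from scipy.stats import f_oneway

    res = f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def anova_ss_oracle(groups):
    """F statistic straight from the sum-of-squares decomposition."""
    groups = [np.asarray(g, float) for g in groups]
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = len(all_vals) - len(groups)
    return (ssb / dfb) / (ssw / dfw)


def bh_oracle(pvals):
    """Benjamini-Hochberg step-up computed directly from the definition."""
    p = np.asarray(pvals, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / (np.arange(n) + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(adj, 1.0)
    return q


def naive_average_linkage_heights(X):
    """Average-linkage merge heights by literal recomputation.

    At every step the distance between two clusters is recomputed as the
    plain mean of all pairwise point distances, with no recurrence.
    """
    X = np.asarray(X, float)
    n = len(X)
    pair = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([pair[a, b] for a in clusters[i] for b in clusters[j]])
                if d < best[0]:
                    best = (d, (i, j))
        d, (i, j) = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return np.array(heights)


def make_evidence(specs, read_len=100):
    """Build a read-evidence frame from compact per-group specs.

    Each spec is a dict with at least ``chrom, pos, sample, allele, n``;
    optional keys override base_qual, map_qual, pos_in_read, strand,
    best, second, overlaps (scalars or length-n sequences).
    """
    rows = []
    counter = 0
    for s in specs:
        n = s["n"]

        def get(key, default):
            v = s.get(key, default)
            return list(v) if hasattr(v, "__len__") and not isinstance(v, str) else [v] * n

        bq = get("base_qual", 35)
        mq = get("map_qual", 60)
        pir = get("pos_in_read", 50)
        strand = get("strand", "+")
        best = get("best", 100.0)
        second = get("second", 50.0)
        overlaps = get("overlaps", 1)
        for k in range(n):
            rows.append(
                {
                    "chrom": s["chrom"],
                    "pos": s["pos"],
                    "sample_id": s["sample"],
                    "stage": s.get("stage", "oocyte"),
                    "read_id": f"r{counter}",
                    "allele": s["allele"],
                    "base_qual": bq[k],
                    "map_qual": mq[k],
                    "read_len": read_len,
                    "pos_in_read": pir[k],
                    "strand": strand[k],
                    "best_hit_score": best[k],
                    "second_hit_score": second[k],
                    "best_hit_overlaps_site": overlaps[k],
                }
            )
            counter += 1
    return pd.DataFrame(rows)
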