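"""Exon editing rates, PSI, their correlation, and enrichment tests.

Exon editing rate pools edited (G) and unedited (A) high-quality reads
over the A-to-I-class sites inside an exon:
``rate = sum(G) / (sum(G) + sum(A))``.  PSI is the length-normalized
inclusion fraction
``(IR/len_inc) / (IR/len_inc + ER/len_exc)``, NA below a minimum read
count.  Group-level comparisons of per-exon Pearson correlations use a
10,000-pair random baseline with a fixed seed; contingency enrichments
report odds ratios with Haldane-Anscombe correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthio import STAGES

__all__ = [
    "compute_psi",
    "exon_editing_rates",
    "correlate",
    "per_exon_correlation",
    "correlation_distributions",
    "odds_ratio",
    "enrichment_tests",
    "simple_exon_de",
    "exon_expression",
]


def compute_psi(counts: pd.DataFrame, min_reads: int = 10) -> pd.DataFrame:
    """Add a ``psi`` column to an exon-counts frame.

    PSI = (IR/len_inc) / (IR/len_inc + ER/len_exc); NA when IR + ER <
    ``min_reads``.  Nonpositive lengths raise ``ValueError``.
    """
    if (counts["inclusion_len"] <= 0).any() or (counts["exclusion_len"] <= 0).any():
        raise ValueError("inclusion/exclusion lengths must be positive")
    ir = counts["inclusion_reads"].values.astype(float)
    er = counts["exclusion_reads"].values.astype(float)
    inc = ir / counts["inclusion_len"].values
    exc = er / counts["exclusion_len"].values
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = inc / (inc + exc)
    psi = np.where(ir + er < min_reads, np.nan, psi)
    out = counts.copy()
    out["psi"] = psi
    return out


def exon_expression(counts: pd.DataFrame) -> pd.Series:
    """Length-normalized, log1p-transformed inclusion counts."""
    return np.log1p(
        1e3 * counts["inclusion_reads"].values / counts["inclusion_len"].values
    )


def exon_editing_rates(
    sites: pd.DataFrame, samples, canonical: str = "A-to-I"
) -> pd.DataFrame:
    """Per-exon, per-sample editing rate pooled over the exon's sites.

    Uses ``hqvar_<s>`` (edited reads) and ``cov_<s>`` (edited+unedited
    HQ reads) columns of the sites table, restricted to sites whose
    ``canonical_type`` equals ``canonical``.  Sites list their host
    exons in ``exon_ids`` (semicolon-joined).  NA on zero denominator.
    """
    sub = sites[sites["canonical_type"] == canonical].copy()
    sub = sub[sub["exon_ids"].astype(str).str.len() > 0]
    if sub.empty:
        return pd.DataFrame(columns=list(samples))
    sub = sub.assign(exon_id=sub["exon_ids"].astype(str).str.split(";")).explode(
        "exon_id"
    )
    agg = {}
    for s in samples:
        agg[f"hqvar_{s}"] = "sum"
        agg[f"cov_{s}"] = "sum"
    pooled = sub.groupby("exon_id").agg(agg)
    rates = {}
    for s in samples:
        var = pooled[f"hqvar_{s}"].values.astype(float)
        cov = pooled[f"cov_{s}"].values.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rates[s] = np.where(cov > 0, var / cov, np.nan)
    return pd.DataFrame(rates, index=pooled.index)


def correlate(x, y, min_pairs: int = 3) -> float:
    """Pearson correlation over paired non-NA values.

    Returns NaN with fewer than ``min_pairs`` complete pairs or when
    either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < min_pairs:
        return float("nan")
    xv, yv = x[ok], y[ok]
    if xv.std() == 0 or yv.std() == 0:
        return float("nan")
    return float(np.corrcoef(xv, yv)[0, 1])


def per_exon_correlation(
    rates: pd.DataFrame, other: pd.DataFrame, min_pairs: int = 3
) -> pd.Series:
    """Per-exon Pearson R between editing rate and another per-sample value.

    ``other`` is an exon x sample frame (PSI or expression) aligned by
    exon id; samples are aligned by column name.
    """
    common = rates.index.intersection(other.index)
    cols = [c for c in rates.columns if c in other.columns]
    vals = {
        exon: correlate(rates.loc[exon, cols], other.loc[exon, cols], min_pairs)
        for exon in common
    }
    return pd.Series(vals, name="R").sort_index()


def correlation_distributions(
    rates: pd.DataFrame,
    other: pd.DataFrame,
    exon_groups: pd.Series,
    n_pairs: int = 10000,
    seed: int = 42,
    test: str = "mannwhitney",
    min_pairs: int = 3,
):
    """Compare per-exon correlation distributions between groups and baseline.

    ``exon_groups`` maps exon id -> group label (e.g. "lncRNA_splicing").
    The baseline distribution is built from ``n_pairs`` random pairings
    of one exon's editing-rate vector with a *different* exon's
    PSI/expression vector, drawn with a fixed seed.

    Returns ``(results_frame, group_R, baseline_R)``.
    """
    common = rates.index.intersection(other.index)
    cols = [c for c in rates.columns if c in other.columns]
    R = per_exon_correlation(rates, other, min_pairs)

    rng = np.random.default_rng(seed)
    n = len(common)
    if n < 2:
        raise ValueError("need at least two exons for the random baseline")
    idx_i = rng.integers(0, n, size=n_pairs)
    shift = rng.integers(1, n, size=n_pairs)
    idx_j = (idx_i + shift) % n
    rate_vals = rates.loc[common, cols].values
    other_vals = other.loc[common, cols].values
    baseline = np.array(
        [
            correlate(rate_vals[i], other_vals[j], min_pairs)
            for i, j in zip(idx_i, idx_j)
        ]
    )
    baseline = baseline[~np.isnan(baseline)]

    def compare(a, b):
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        if len(a) == 0 or len(b) == 0:
            return float("nan")
        if test == "mannwhitney":
            return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)

    groups = {}
    for g in sorted(exon_groups.dropna().unique()):
        members = exon_groups[exon_groups == g].index
        groups[g] = R.reindex(members).dropna().values

    rows = []
    for g, vals in groups.items():
        rows.append(
            {
                "comparison": f"{g}_vs_random",
                "group": g,
                "mean_R": float(np.mean(vals)) if len(vals) else np.nan,
                "n": len(vals),
                "baseline_mean_R": float(np.mean(baseline)),
                "p": compare(vals, baseline),
                "test": test,
            }
        )
    names = sorted(groups)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            rows.append(
                {
                    "comparison": f"{names[a]}_vs_{names[b]}",
                    "group": names[a],
                    "mean_R": float(np.mean(groups[names[a]]))
                    if len(groups[names[a]])
                    else np.nan,
                    "n": len(groups[names[a]]),
                    "baseline_mean_R": float(np.mean(groups[names[b]]))
                    if len(groups[names[b]])
                    else np.nan,
                    "p": compare(groups[names[a]], groups[names[b]]),
                    "test": test,
                }
            )
    return pd.DataFrame(rows), groups, baseline


def odds_ratio(a: float, b: float, c: float, d: float) -> float:
    """(a*d)/(b*c) with Haldane-Anscombe 0.5 correction on zero cells."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def _table_test(a, b, c, d, kind):
    """Chi-square (no continuity correction) or Fisher p for a 2x2 table."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return float("nan"), float("nan")
    if kind == "fisher":
        res = stats.fisher_exact(table.astype(int), alternative="two-sided")
        return float("nan"), float(res[1])
    if a + b + c + d == 0:
        return float("nan"), float("nan")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def enrichment_tests(
    sites: pd.DataFrame,
    differential: pd.Series = None,
    exon_de: pd.Series = None,
) -> pd.DataFrame:
    """Run the three contingency-test families on annotated sites.

    (i) differential vs non-differential x splice vs non-splice
    (chi-square); (ii) lncRNA vs non-lncRNA x splice, and the mRNA
    analogue (chi-square); (iii) splice vs non-splice x DE vs non-DE
    host exon (Fisher exact).  Every family is repeated on the non-Alu
    subset.  ``differential`` is indexed like ``sites``; ``exon_de``
    maps exon id -> bool.
    """
    rows = []

    def add(name, subset_name, mask_a, mask_b, frame, kind):
        a = int((mask_a & mask_b).sum())
        b = int((mask_a & ~mask_b).sum())
        c = int((~mask_a & mask_b).sum())
        d = int((~mask_a & ~mask_b).sum())
        stat, p = _table_test(a, b, c, d, kind)
        rows.append(
            {
                "comparison": name,
                "subset": subset_name,
                "a": a, "b": b, "c": c, "d": d,
                "odds_ratio": odds_ratio(a, b, c, d) if a + b + c + d else np.nan,
                "statistic": stat,
                "p": p,
                "test": kind,
                "note": "" if not np.isnan(p) else "degenerate table",
            }
        )

    subsets = {"all": pd.Series(True, index=sites.index)}
    if "repeat_class" in sites.columns:
        subsets["nonAlu"] = sites["repeat_class"] != "Alu"

    splice = sites["is_splice_site"].astype(bool)
    for subset_name, smask in subsets.items():
        sub = sites[smask]
        sp = splice[smask]
        if differential is not None:
            diff = differential.reindex(sub.index).fillna(False).astype(bool)
            add("differential_x_splice", subset_name, diff, sp, sub, "chi2")
        lnc = sub["transcript_class"].isin(["lncRNA_only", "overlap"])
        mrna = sub["transcript_class"].isin(["mRNA_only", "overlap"])
        add("lncRNA_x_splice", subset_name, lnc, sp, sub, "chi2")
        add("mRNA_x_splice", subset_name, mrna, sp, sub, "chi2")
        if exon_de is not None:
            def host_de(exon_ids):
                if not isinstance(exon_ids, str) or not exon_ids:
                    return np.nan
                flags = [exon_de.get(e) for e in exon_ids.split(";")]
                flags = [f for f in flags if f is not None and not pd.isna(f)]
                if not flags:
                    return np.nan
                return bool(any(flags))

            de_status = sub["exon_ids"].map(host_de)
            known = de_status.notna()
            add(
                "splice_x_de_exon",
                subset_name,
                sp[known],
                de_status[known].astype(bool),
                sub[known],
                "fisher",
            )
    return pd.DataFrame(rows)


def simple_exon_de(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    alpha: float = 0.05,
    de_flags: pd.Series = None,
) -> pd.Series:
    """Per-exon stage DE flags (plumbing stand-in, not a DESeq2 clone).

    One-way ANOVA on log1p length-normalized inclusion counts across
    stages, BH-adjusted at ``alpha``.  When ``de_flags`` is supplied it
    is passed through untouched.
    """
    if de_flags is not None:
        return de_flags.astype(bool)
    stage_of = dict(zip(design["sample_id"], design["stage"]))
    df = counts.copy()
    df["expr"] = exon_expression(df)
    df["stage"] = df["sample_id"].map(stage_of)

    pvals = {}
    for exon, sub in df.groupby("exon_id"):
        groups = [
            g["expr"].values for _, g in sub.groupby("stage") if len(g) >= 2
        ]
        if len(groups) < 2:
            pvals[exon] = np.nan
            continue
        grand = np.concatenate(groups)
        if np.allclose(grand, grand[0]):
            pvals[exon] = 1.0
            continue
        try:
            pvals[exon] = float(stats.f_oneway(*groups).pvalue)
        except Exception:
            pvals[exon] = np.nan
    p = pd.Series(pvals)
    q = pd.Series(np.nan, index=p.index)
    tested = p.notna()
    if tested.any():
        q[tested] = multipletests(p[tested].values, method="fdr_bh")[1]
    return (q < alpha).fillna(False)
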