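"""Candidate-to-reliable RNA-editing-site filter cascade.

The cascade operates on pileup-level read evidence (one row per read per
candidate position per sample) and applies, in order:

1. candidate calling — a position is a candidate when >=2 reads carry the
   same non-reference allele with base quality >=25 and mapping quality
   >=20;
2. known-SNP removal — catalog positions are dropped unless the catalog
   record is flagged as cDNA molecular type;
3. recurrence — variants must be seen in >=2 distinct samples (disabled
   in single-sample mode);
4. strand/position bias — reads spanning the site are split into
   reference-supporting and variant-supporting groups and compared by
   two-sided Fisher's exact tests on sequencing strand and on
   terminal-vs-interior read position; Bonferroni-corrected significance
   at alpha=0.01 marks the site a false positive;
5. paralog screening — a variant-supporting read passes when its best
   alignment hit overlaps the site and the second-best hit scores <95%
   of the best; the site is kept only when passing reads outnumber
   failing ones;
6. finalization — pooled mismatch frequency >=0.1, >=2 samples with >=5
   high-quality (PHRED>=20) reads and >=2 high-quality variant reads,
   and exclusion of multi-allelic sites.

Each stage only removes sites (monotone shrinkage) and each records a
pass/fail/NA flag so that disabled or unreached stages stay inspectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FilterParams",
    "CascadeResult",
    "call_candidates",
    "remove_known_snps",
    "require_recurrence",
    "bias_tests",
    "apply_bias_filter",
    "paralog_filter",
    "finalize_sites",
    "run_cascade",
    "canonical_variant_type",
    "load_reference",
]

#: Antisense collapse of raw variant types onto canonical editing classes.
_CANONICAL = {
    "A-to-G": "A-to-I",
    "T-to-C": "A-to-I",
    "C-to-T": "C-to-U",
    "G-to-A": "C-to-U",
}

STAGE_NAMES = ("snp", "recurrence", "strand", "position", "paralog", "final")


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the cascade; defaults follow the published pipeline."""

    min_base_qual: int = 25
    min_map_qual: int = 20
    hq_base_qual: int = 20
    min_var_reads: int = 2
    min_recurrence: int = 2
    alpha: float = 0.01
    terminal_fraction: float = 0.1
    paralog_score_ratio: float = 0.95
    min_freq: float = 0.1
    min_hq_reads: int = 5
    min_hq_var_reads: int = 2
    min_ratio_coverage: int = 5
    single_sample: bool = False


@dataclass
class CascadeResult:
    """All candidates with per-stage flags plus the surviving sites."""

    table: pd.DataFrame  # one row per candidate, flags pass_<stage>
    sites: pd.DataFrame  # finalized EditingSite rows
    samples: list


def load_reference(path) -> dict:
    """Load a FASTA into ``{chrom: sequence-string}``."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _ref_series(evidence: pd.DataFrame, reference) -> pd.Series:
    """Reference allele per evidence row, from FASTA dict or 'ref' column."""
    if reference is not None:
        if isinstance(reference, (str, bytes)) or hasattr(reference, "__fspath__"):
            reference = load_reference(reference)

        def lookup(row):
            try:
                return reference[row.chrom][row.pos - 1]
            except (KeyError, IndexError):
                raise KeyError(
                    f"position {row.chrom}:{row.pos} has no reference base"
                ) from None

        uniq = evidence[["chrom", "pos"]].drop_duplicates()
        uniq = uniq.assign(ref=[lookup(r) for r in uniq.itertuples()])
        return evidence.merge(uniq, on=["chrom", "pos"], how="left")["ref"].values
    if "ref" in evidence.columns:
        return evidence["ref"].values
    raise ValueError("no reference FASTA given and evidence lacks a 'ref' column")


def _check_alleles(evidence: pd.DataFrame) -> None:
    bad = set(evidence["allele"].unique()) - set("ACGT")
    if bad:
        raise ValueError(f"unknown allele symbol(s): {sorted(bad)}")


def call_candidates(
    evidence: pd.DataFrame,
    reference=None,
    params: FilterParams = FilterParams(),
) -> pd.DataFrame:
    """Call candidate sites from read evidence.

    Returns one row per candidate with ``chrom, pos, ref, alt`` and the
    count of qualifying mismatched reads.  A position qualifies when at
    least ``min_var_reads`` reads carry the same non-reference allele at
    base quality >= ``min_base_qual`` and mapping quality >=
    ``min_map_qual``.  The most-supported alternate allele becomes the
    primary ``alt`` (ties broken alphabetically).
    """
    _check_alleles(evidence)
    ev = evidence.copy()
    ev["ref"] = _ref_series(evidence, reference)
    qual = (ev["base_qual"] >= params.min_base_qual) & (
        ev["map_qual"] >= params.min_map_qual
    )
    mm = ev[qual & (ev["allele"] != ev["ref"])]
    if mm.empty:
        return pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "n_qual_var"])
    counts = (
        mm.groupby(["chrom", "pos", "ref", "allele"], sort=True)
        .size()
        .rename("n_qual_var")
        .reset_index()
    )
    counts = counts.sort_values(
        ["chrom", "pos", "n_qual_var", "allele"],
        ascending=[True, True, False, True],
    )
    top = counts.drop_duplicates(["chrom", "pos"], keep="first")
    top = top[top["n_qual_var"] >= params.min_var_reads]
    return (
        top.rename(columns={"allele": "alt"})
        .reset_index(drop=True)[["chrom", "pos", "ref", "alt", "n_qual_var"]]
    )


def remove_known_snps(sites: pd.DataFrame, snp_catalog: Optional[pd.DataFrame]) -> pd.Series:
    """Keep-mask: False for sites present in the catalog without a cDNA flag."""
    if snp_catalog is None or snp_catalog.empty:
        return pd.Series(True, index=sites.index)
    drop = snp_catalog.loc[~snp_catalog["is_cdna"].astype(bool), ["chrom", "pos"]]
    dropped = set(map(tuple, drop.itertuples(index=False)))
    keys = list(zip(sites["chrom"], sites["pos"]))
    return pd.Series([k not in dropped for k in keys], index=sites.index)


def require_recurrence(
    n_samples_with_variant: pd.Series, params: FilterParams = FilterParams()
) -> pd.Series:
    """Keep-mask: variant seen in >=``min_recurrence`` distinct samples.

    In single-sample mode the requirement collapses to >=1.
    """
    needed = 1 if params.single_sample else params.min_recurrence
    return n_samples_with_variant >= needed


def _fisher_or_na(table: np.ndarray) -> float:
    """Two-sided Fisher exact p, or NaN when a margin is zero."""
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return float("nan")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def bias_tests(
    site_reads: pd.DataFrame,
    alt: str,
    ref: str,
    terminal_fraction: float = 0.1,
):
    """Strand and read-position bias p-values for one site.

    ``site_reads`` holds the high-quality reads spanning the site; reads
    are split into reference-supporting and variant-supporting groups.
    The strand test is a two-sided Fisher exact test on
    {ref,var} x {+,-}; the position test on {ref,var} x
    {terminal,interior} where terminal means the read position falls in
    the outer ``terminal_fraction`` of the read length at either end.
    Returns ``(p_strand, p_position)`` with NaN for degenerate tables.
    """
    grp = site_reads[site_reads["allele"].isin((ref, alt))]
    is_var = (grp["allele"] == alt).values
    if not is_var.any() or is_var.all():
        return float("nan"), float("nan")

    plus = (grp["strand"] == "+").values
    strand_tab = np.array(
        [
            [int((~is_var & plus).sum()), int((~is_var & ~plus).sum())],
            [int((is_var & plus).sum()), int((is_var & ~plus).sum())],
        ]
    )
    p_strand = _fisher_or_na(strand_tab)

    lens = grp["read_len"].values
    tails = np.ceil(terminal_fraction * lens)
    pir = grp["pos_in_read"].values
    terminal = (pir <= tails) | (pir > lens - tails)
    pos_tab = np.array(
        [
            [int((~is_var & terminal).sum()), int((~is_var & ~terminal).sum())],
            [int((is_var & terminal).sum()), int((is_var & ~terminal).sum())],
        ]
    )
    p_position = _fisher_or_na(pos_tab)
    return p_strand, p_position


def apply_bias_filter(pvalues: pd.Series, alpha: float = 0.01) -> pd.Series:
    """Keep-mask after Bonferroni correction within one test family.

    The family size is the number of sites with a computable (non-NaN)
    p-value; NaN p-values (degenerate tables) are retained.
    """
    tested = pvalues.notna()
    n = int(tested.sum())
    if n == 0:
        return pd.Series(True, index=pvalues.index)
    threshold = alpha / n
    keep = pvalues.isna() | (pvalues >= threshold)
    return keep


def paralog_filter(
    var_reads: pd.DataFrame, score_ratio: float = 0.95
):
    """Keep/drop decision for one site from its variant-supporting reads.

    A read passes when its best hit overlaps the site and the
    second-best hit scores strictly below ``score_ratio`` of the best.
    Reads with missing scores count as failures.  The site is kept only
    when passing reads strictly outnumber failing reads.

    Returns ``(keep, n_pass, n_fail)``.
    """
    best = var_reads["best_hit_score"].values.astype(float)
    second = var_reads["second_hit_score"].values.astype(float)
    overlaps = var_reads["best_hit_overlaps_site"].values.astype(float)
    ok = (
        ~np.isnan(best)
        & ~np.isnan(second)
        & (overlaps == 1)
        & (second < score_ratio * best)
    )
    n_pass = int(ok.sum())
    n_fail = int(len(ok) - n_pass)
    return n_pass > n_fail, n_pass, n_fail


def canonical_variant_type(ref: str, alt: str) -> str:
    """Collapse a ref->alt change onto A-to-I / C-to-U / other.

    T-to-C and G-to-A are interpreted as antisense A-to-I and C-to-U
    respectively (incomplete strand annotation / antisense
    transcription).
    """
    return _CANONICAL.get(f"{ref}-to-{alt}", "other")


def finalize_sites(
    table: pd.DataFrame, params: FilterParams = FilterParams()
) -> pd.DataFrame:
    """Apply the finalization thresholds; expects per-sample stats attached.

    ``table`` must carry ``pooled_hq_var``, ``pooled_hq``,
    ``n_good_samples`` (samples with >=min_hq_reads HQ reads and
    >=min_hq_var_reads HQ variant reads) and ``n_second_alt_hq`` (HQ
    read count of the best secondary alternate allele).
    """
    needed = 1 if params.single_sample else 2
    freq_ok = (table["pooled_hq_var"] / table["pooled_hq"].clip(lower=1)) >= params.min_freq
    indiv_ok = table["n_good_samples"] >= needed
    biallelic_ok = table["n_second_alt_hq"] < params.min_hq_var_reads
    out = table.copy()
    out["pass_frequency"] = freq_ok
    out["pass_individual"] = indiv_ok
    out["pass_biallelic"] = biallelic_ok
    out["pass_final"] = freq_ok & indiv_ok & biallelic_ok
    return out


# ---------------------------------------------------------------------------
# cascade driver


def _per_sample_stats(ev: pd.DataFrame, sites: pd.DataFrame, params: FilterParams):
    """Attach pooled and per-sample HQ statistics to the candidate table.

    HQ means base quality >= ``hq_base_qual`` and mapping quality >=
    ``min_map_qual``.  Per-sample columns ``cov_<s>`` (HQ ref+var reads),
    ``hqvar_<s>`` and ``ratio_<s>`` are added; the ratio is NA below
    ``min_ratio_coverage``.
    """
    samples = sorted(ev["sample_id"].unique())
    key = ["chrom", "pos"]
    site_keys = sites.set_index(key)

    hq = ev[(ev["base_qual"] >= params.hq_base_qual) & (ev["map_qual"] >= params.min_map_qual)]
    hq = hq.merge(sites[key + ["ref", "alt"]], on=key, how="inner")

    hq_all = hq.groupby(key).size().rename("pooled_hq")
    is_var = hq["allele"] == hq["alt"]
    is_ref = hq["allele"] == hq["ref"]
    hq_var = hq[is_var].groupby(key).size().rename("pooled_hq_var")

    per = (
        hq.assign(v=is_var.astype(int), rv=(is_var | is_ref).astype(int))
        .groupby(key + ["sample_id"])
        .agg(hq_n=("allele", "size"), hq_var=("v", "sum"), hq_refvar=("rv", "sum"))
        .reset_index()
    )
    good = (
        per[(per["hq_n"] >= params.min_hq_reads) & (per["hq_var"] >= params.min_hq_var_reads)]
        .groupby(key)
        .size()
        .rename("n_good_samples")
    )
    # recurrence: distinct samples with >=1 variant read passing the
    # candidate-level quality gates
    qual = ev[(ev["base_qual"] >= params.min_base_qual) & (ev["map_qual"] >= params.min_map_qual)]
    qual = qual.merge(sites[key + ["alt"]], on=key, how="inner")
    recur = (
        qual[qual["allele"] == qual["alt"]]
        .groupby(key)["sample_id"]
        .nunique()
        .rename("n_samples_with_variant")
    )
    # secondary alternate alleles among HQ reads
    other = hq[(hq["allele"] != hq["ref"]) & (hq["allele"] != hq["alt"])]
    second_alt = (
        other.groupby(key + ["allele"]).size().groupby(key).max().rename("n_second_alt_hq")
    )

    out = sites.set_index(key)
    for series in (hq_all, hq_var, good, recur, second_alt):
        out = out.join(series, how="left")
    out = out.fillna(
        {
            "pooled_hq": 0,
            "pooled_hq_var": 0,
            "n_good_samples": 0,
            "n_samples_with_variant": 0,
            "n_second_alt_hq": 0,
        }
    )
    for c in (
        "pooled_hq", "pooled_hq_var", "n_good_samples",
        "n_samples_with_variant", "n_second_alt_hq",
    ):
        out[c] = out[c].astype(int)

    per_idx = per.set_index(key + ["sample_id"])
    for s in samples:
        cov = np.zeros(len(out), dtype=int)
        var = np.zeros(len(out), dtype=int)
        try:
            sub = per_idx.xs(s, level="sample_id")
            cov_s = sub["hq_refvar"].reindex(out.index).fillna(0).astype(int)
            var_s = sub["hq_var"].reindex(out.index).fillna(0).astype(int)
            cov, var = cov_s.values, var_s.values
        except KeyError:
            pass
        out[f"cov_{s}"] = cov
        out[f"hqvar_{s}"] = var
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(
                cov >= params.min_ratio_coverage, var / np.maximum(cov, 1), np.nan
            )
        out[f"ratio_{s}"] = ratio
    return out.reset_index(), samples


def run_cascade(
    evidence: pd.DataFrame,
    snp_catalog: Optional[pd.DataFrame] = None,
    reference=None,
    params: FilterParams = FilterParams(),
    disable: Iterable[str] = (),
) -> CascadeResult:
    """Run the full, order-faithful filter cascade.

    ``disable`` names stages to skip (subset of
    ``{"snp", "recurrence", "strand", "position", "paralog", "final"}``);
    a disabled stage records NA flags and removes nothing, so disabling
    any stage can only grow the surviving set.
    """
    disable = set(disable)
    unknown = disable - set(STAGE_NAMES)
    if unknown:
        raise ValueError(f"unknown stage name(s) to disable: {sorted(unknown)}")

    ev = evidence.copy()
    sites = call_candidates(ev, reference=reference, params=params)
    if sites.empty:
        empty = pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "variant_type", "canonical_type"]
        )
        return CascadeResult(table=sites, sites=empty, samples=[])

    table, samples = _per_sample_stats(ev, sites, params)
    alive = pd.Series(True, index=table.index)

    def flag(keep):
        # pass/fail for sites reaching the stage, NA for already-removed ones
        out = pd.Series(keep & alive, dtype="boolean")
        out[~alive] = pd.NA
        return out

    # stage: known SNPs
    if "snp" in disable:
        table["pass_snp"] = pd.Series(pd.NA, index=table.index, dtype="boolean")
    else:
        keep = remove_known_snps(table, snp_catalog)
        table["pass_snp"] = flag(keep)
        alive &= keep

    # stage: recurrence
    if "recurrence" in disable:
        table["pass_recurrence"] = pd.Series(pd.NA, index=table.index, dtype="boolean")
    else:
        keep = require_recurrence(table["n_samples_with_variant"], params)
        table["pass_recurrence"] = flag(keep)
        alive &= keep

    # stage: strand/position bias (tested only on surviving sites)
    hq = ev[
        (ev["base_qual"] >= params.hq_base_qual)
        & (ev["map_qual"] >= params.min_map_qual)
    ]
    grouped = dict(tuple(hq.groupby(["chrom", "pos"], sort=False)))
    p_strand = np.full(len(table), np.nan)
    p_position = np.full(len(table), np.nan)
    need_bias = [s for s in ("strand", "position") if s not in disable]
    if need_bias:
        for i, row in enumerate(table.itertuples()):
            if not alive.iloc[i]:
                continue
            reads = grouped.get((row.chrom, row.pos))
            if reads is None:
                continue
            ps, pp = bias_tests(reads, row.alt, row.ref, params.terminal_fraction)
            p_strand[i], p_position[i] = ps, pp
    table["p_strand"] = p_strand
    table["p_position"] = p_position

    for stage, col in (("strand", "p_strand"), ("position", "p_position")):
        if stage in disable:
            table[f"pass_{stage}"] = pd.Series(pd.NA, index=table.index, dtype="boolean")
            continue
        pvals = table[col].where(alive, np.nan)
        keep = apply_bias_filter(pvals, params.alpha)
        table[f"pass_{stage}"] = flag(keep)
        alive &= keep

    # stage: paralog screening
    if "paralog" in disable:
        table["pass_paralog"] = pd.Series(pd.NA, index=table.index, dtype="boolean")
        table["paralog_pass_reads"] = pd.NA
        table["paralog_fail_reads"] = pd.NA
    else:
        keep_vals = np.ones(len(table), dtype=bool)
        n_pass = np.zeros(len(table), dtype=int)
        n_fail = np.zeros(len(table), dtype=int)
        ev_grouped = dict(tuple(ev.groupby(["chrom", "pos"], sort=False)))
        for i, row in enumerate(table.itertuples()):
            if not alive.iloc[i]:
                continue
            reads = ev_grouped.get((row.chrom, row.pos))
            var_reads = reads[reads["allele"] == row.alt]
            keep_vals[i], n_pass[i], n_fail[i] = paralog_filter(
                var_reads, params.paralog_score_ratio
            )
        table["paralog_pass_reads"] = n_pass
        table["paralog_fail_reads"] = n_fail
        keep = pd.Series(keep_vals, index=table.index)
        table["pass_paralog"] = flag(keep)
        alive &= keep

    # stage: finalization
    table["variant_type"] = table["ref"] + "-to-" + table["alt"]
    table["canonical_type"] = [
        canonical_variant_type(r, a) for r, a in zip(table["ref"], table["alt"])
    ]
    if "final" in disable:
        for c in ("pass_frequency", "pass_individual", "pass_biallelic", "pass_final"):
            table[c] = pd.Series(pd.NA, index=table.index, dtype="boolean")
    else:
        fin = finalize_sites(table, params)
        for c in ("pass_frequency", "pass_individual", "pass_biallelic", "pass_final"):
            table[c] = flag(fin[c])
        alive &= fin["pass_final"]

    table["surviving"] = alive
    sites_out = table[alive].reset_index(drop=True)
    return CascadeResult(table=table, sites=sites_out, samples=samples)


def sites_to_vcf(sites: pd.DataFrame, path) -> None:
    """Minimal VCF export of finalized sites."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=VT,Number=1,Type=String,Description="Variant type">\n'
        )
        fh.write(
            '##INFO=<ID=CT,Number=1,Type=String,Description="Canonical editing type">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in sites.itertuples():
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                f"VT={row.variant_type};CT={row.canonical_type}\n"
            )
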