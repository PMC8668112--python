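import collections

import numpy as np
import pandas as pd
import pytest
from helpers import fisher_oracle, make_evidence

from edscape import siteflt
from edscape.siteflt import FilterParams, run_cascade

REF = {"chr1": "A" * 500}


def _cascade_counts(sim, disable=(), params=FilterParams(), catalog=None):
    res = run_cascade(sim["evidence"], snp_catalog=catalog,
                      reference=sim["reference"], params=params, disable=disable)
    labels = {(t.chrom, t.pos): t.label for t in sim["truth"]}
    surv = collections.Counter(
        labels.get((r.chrom, r.pos), "unknown") for r in res.sites.itertuples()
    )
    return res, surv


class TestCallCandidates:
    def test_single_mismatched_read_is_not_a_candidate(self):
        ev = make_evidence([
            dict(chrom="chr1", pos=10, sample="s1", allele="G", n=1),
            dict(chrom="chr1", pos=10, sample="s1", allele="A", n=20),
        ])
        out = siteflt.call_candidates(ev, reference=REF)
        assert out.empty

    def test_low_base_quality_read_does_not_count(self):
        ev = make_evidence([
            dict(chrom="chr1", pos=10, sample="s1", allele="G", n=2,
                 base_qual=[30, 24]),
            dict(chrom="chr1", pos=10, sample="s1", allele="A", n=20),
        ])
        out = siteflt.call_candidates(ev, reference=REF)
        assert out.empty

    def test_three_good_reads_make_a_candidate(self):
        ev = make_evidence([
            dict(chrom="chr1", pos=10, sample="s1", allele="G", n=3,
                 base_qual=30, map_qual=60),
            dict(chrom="chr1", pos=10, sample="s1", allele="A", n=20),
        ])
        out = siteflt.call_candidates(ev, reference=REF)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["ref"], row["alt"], row["n_qual_var"]) == ("A", "G", 3)

    def test_unknown_allele_raises(self):
        ev = make_evidence([dict(chrom="chr1", pos=10, sample="s1", allele="N", n=3)])
        with pytest.raises(ValueError, match="allele"):
            siteflt.call_candidates(ev, reference=REF)

    def test_position_without_reference_base_raises(self):
        ev = make_evidence([dict(chrom="chr1", pos=10**6, sample="s1", allele="G", n=3)])
        with pytest.raises(KeyError, match="reference"):
            siteflt.call_candidates(ev, reference=REF)


class TestSnpRemoval:
    def _sites(self):
        return pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [10, 20, 30]})

    def test_catalog_site_removed(self):
        catalog = pd.DataFrame({"chrom": ["chr1"], "pos": [10], "is_cdna": [False]})
        keep = siteflt.remove_known_snps(self._sites(), catalog)
        assert keep.tolist() == [False, True, True]

    def test_cdna_flagged_site_retained(self):
        catalog = pd.DataFrame({"chrom": ["chr1"], "pos": [10], "is_cdna": [True]})
        keep = siteflt.remove_known_snps(self._sites(), catalog)
        assert keep.tolist() == [True, True, True]

    def test_uncatalogued_site_retained(self):
        catalog = pd.DataFrame({"chrom": ["chr2"], "pos": [10], "is_cdna": [False]})
        keep = siteflt.remove_known_snps(self._sites(), catalog)
        assert keep.all()


class TestRecurrence:
    def test_one_sample_removed_two_kept(self):
        counts = pd.Series([1, 2, 5])
        assert siteflt.require_recurrence(counts).tolist() == [False, True, True]

    def test_single_sample_mode_keeps_singletons(self):
        counts = pd.Series([1, 0])
        keep = siteflt.require_recurrence(
            counts, FilterParams(single_sample=True)
        )
        assert keep.tolist() == [True, False]


class TestBiasTests:
    @staticmethod
    def _reads(ref_plus, ref_minus, var_plus, var_minus):
        return make_evidence([
            dict(chrom="chr1", pos=5, sample="s", allele="A", n=ref_plus, strand="+"),
            dict(chrom="chr1", pos=5, sample="s", allele="A", n=ref_minus, strand="-"),
            dict(chrom="chr1", pos=5, sample="s", allele="G", n=var_plus, strand="+"),
            dict(chrom="chr1", pos=5, sample="s", allele="G", n=var_minus, strand="-"),
        ])

    def test_symmetric_table_gives_p_one(self):
        reads = self._reads(10, 10, 5, 5)
        p_strand, _ = siteflt.bias_tests(reads, alt="G", ref="A")
        assert p_strand == pytest.approx(1.0)

    def test_extreme_table_matches_enumeration_oracle(self):
        reads = self._reads(20, 0, 0, 20)
        p_strand, _ = siteflt.bias_tests(reads, alt="G", ref="A")
        assert p_strand == pytest.approx(fisher_oracle(20, 0, 0, 20), abs=1e-9)

    def test_position_bias_matches_oracle(self):
        # all variant reads terminal, all reference reads interior, 10 vs 10
        reads = make_evidence([
            dict(chrom="chr1", pos=5, sample="s", allele="A", n=10, pos_in_read=50),
            dict(chrom="chr1", pos=5, sample="s", allele="G", n=10, pos_in_read=3),
        ])
        _, p_pos = siteflt.bias_tests(reads, alt="G", ref="A")
        assert p_pos == pytest.approx(fisher_oracle(0, 10, 10, 0), abs=1e-9)
        assert p_pos < 0.01

    def test_zero_margin_gives_nan(self):
        reads = self._reads(10, 10, 5, 0)
        # var group entirely on +: column margins fine; make a zero margin
        reads = reads[reads["strand"] == "+"]
        p_strand, _ = siteflt.bias_tests(reads, alt="G", ref="A")
        assert np.isnan(p_strand)

    def test_no_variant_reads_gives_nan(self):
        reads = self._reads(10, 10, 0, 0)
        p_strand, p_pos = siteflt.bias_tests(reads, alt="G", ref="A")
        assert np.isnan(p_strand) and np.isnan(p_pos)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_tables_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(1, 15, size=4)
        reads = self._reads(a, b, c, d)
        p_strand, _ = siteflt.bias_tests(reads, alt="G", ref="A")
        assert p_strand == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-9)


class TestBiasFilter:
    def test_threshold_arithmetic(self):
        p = pd.Series([5e-5] + [0.5] * 99)
        keep = siteflt.apply_bias_filter(p, alpha=0.01)  # threshold 1e-4
        assert not keep.iloc[0]
        assert keep.iloc[1:].all()

    def test_borderline_p_retained(self):
        p = pd.Series([2e-4] + [0.5] * 99)
        keep = siteflt.apply_bias_filter(p, alpha=0.01)
        assert keep.all()

    def test_nan_p_retained(self):
        p = pd.Series([np.nan, 1e-9])
        keep = siteflt.apply_bias_filter(p, alpha=0.01)
        assert keep.iloc[0]
        assert not keep.iloc[1]


class TestParalogFilter:
    def _reads(self, seconds, overlaps=None):
        n = len(seconds)
        return make_evidence([
            dict(chrom="chr1", pos=5, sample="s", allele="G", n=n,
                 second=seconds, overlaps=overlaps or [1] * n)
        ])

    def test_second_hit_below_95_passes(self):
        keep, n_pass, n_fail = siteflt.paralog_filter(self._reads([94.0]))
        assert (keep, n_pass, n_fail) == (True, 1, 0)

    def test_second_hit_at_95_fails(self):
        keep, n_pass, n_fail = siteflt.paralog_filter(self._reads([95.0]))
        assert (keep, n_pass, n_fail) == (False, 0, 1)

    def test_strict_majority_required(self):
        keep6, _, _ = siteflt.paralog_filter(self._reads([50.0] * 6 + [99.0] * 5))
        keep5, _, _ = siteflt.paralog_filter(self._reads([50.0] * 5 + [99.0] * 5))
        assert keep6 and not keep5

    def test_missing_scores_count_as_fail(self):
        reads = self._reads([np.nan, 50.0, 50.0])
        keep, n_pass, n_fail = siteflt.paralog_filter(reads)
        assert (n_pass, n_fail) == (2, 1)

    def test_nonoverlapping_best_hit_fails(self):
        keep, n_pass, n_fail = siteflt.paralog_filter(
            self._reads([50.0], overlaps=[0])
        )
        assert (keep, n_pass, n_fail) == (False, 0, 1)


class TestFinalize:
    def _table(self, **kw):
        base = dict(pooled_hq_var=25, pooled_hq=50, n_good_samples=3,
                    n_second_alt_hq=0)
        base.update(kw)
        return pd.DataFrame([base])

    def test_low_pooled_frequency_dropped(self):
        out = siteflt.finalize_sites(self._table(pooled_hq_var=4, pooled_hq=50))
        assert not out["pass_final"].iloc[0]
        assert not out["pass_frequency"].iloc[0]

    def test_two_good_samples_kept(self):
        out = siteflt.finalize_sites(
            self._table(pooled_hq_var=6, pooled_hq=12, n_good_samples=2)
        )
        assert out["pass_final"].iloc[0]

    def test_multiallelic_dropped(self):
        out = siteflt.finalize_sites(self._table(n_second_alt_hq=2))
        assert not out["pass_biallelic"].iloc[0]
        assert not out["pass_final"].iloc[0]

    def test_canonical_type_antisense_collapse(self):
        assert siteflt.canonical_variant_type("A", "G") == "A-to-I"
        assert siteflt.canonical_variant_type("T", "C") == "A-to-I"
        assert siteflt.canonical_variant_type("G", "A") == "C-to-U"
        assert siteflt.canonical_variant_type("C", "T") == "C-to-U"
        assert siteflt.canonical_variant_type("A", "C") == "other"


class TestCascade:
    def test_recall_and_fdr_on_planted_truth(self, small_sim, small_sim_dir):
        from edscape._io import read_snp_catalog

        catalog = read_snp_catalog(small_sim_dir["snps"])
        res, surv = _cascade_counts(small_sim, catalog=catalog)
        n_true = sum(1 for t in small_sim["truth"] if t.label == "true_edit")
        recall = surv["true_edit"] / n_true
        false_calls = sum(v for k, v in surv.items() if k != "true_edit")
        assert recall >= 0.90
        assert false_calls / max(len(res.sites), 1) <= 0.05

    def test_monotone_shrinkage_flags(self, small_sim):
        res, _ = _cascade_counts(small_sim)
        table = res.table
        # every stage flag is pass/fail for reached sites and NA afterwards;
        # surviving set equals the all-pass rows
        flags = ["pass_snp", "pass_recurrence", "pass_strand", "pass_position",
                 "pass_paralog", "pass_final"]
        all_pass = pd.Series(True, index=table.index)
        for f in flags:
            all_pass &= table[f].fillna(False).astype(bool)
        assert set(zip(res.sites["chrom"], res.sites["pos"])) == set(
            zip(table.loc[all_pass, "chrom"], table.loc[all_pass, "pos"])
        )

    @pytest.mark.parametrize(
        "stage,leaked_label",
        [
            ("strand", "strand_artifact"),
            ("position", "position_artifact"),
            ("paralog", "paralog"),
        ],
    )
    def test_disabling_stage_leaks_its_confounder(self, small_sim, small_sim_dir,
                                                  stage, leaked_label):
        from edscape._io import read_snp_catalog

        catalog = read_snp_catalog(small_sim_dir["snps"])
        _, surv_full = _cascade_counts(small_sim, catalog=catalog)
        _, surv_off = _cascade_counts(small_sim, catalog=catalog, disable={stage})
        assert surv_off[leaked_label] > surv_full.get(leaked_label, 0)

    def test_disabling_snp_stage_leaks_snvs(self, small_sim, small_sim_dir):
        from edscape._io import read_snp_catalog

        catalog = read_snp_catalog(small_sim_dir["snps"])
        _, surv_full = _cascade_counts(small_sim, catalog=catalog)
        _, surv_off = _cascade_counts(small_sim, catalog=None)
        assert surv_off["snv"] > surv_full.get("snv", 0)

    def test_disabling_any_stage_never_shrinks_survivors(self, small_sim,
                                                         small_sim_dir):
        from edscape._io import read_snp_catalog

        catalog = read_snp_catalog(small_sim_dir["snps"])
        res_full, _ = _cascade_counts(small_sim, catalog=catalog)
        for stage in ("snp", "recurrence", "strand", "position", "paralog", "final"):
            res_off, _ = _cascade_counts(small_sim, catalog=catalog,
                                         disable={stage})
            assert len(res_off.sites) >= len(res_full.sites)

    def test_single_sample_mode_keeps_single_sample_variants(self):
        specs = [
            dict(chrom="chr1", pos=10, sample="s1", allele="G", n=6),
            dict(chrom="chr1", pos=10, sample="s1", allele="A", n=6),
        ]
        ev = make_evidence(specs)
        res = run_cascade(ev, reference=REF)
        assert len(res.sites) == 0  # fails recurrence with one sample
        res_ss = run_cascade(ev, reference=REF,
                             params=FilterParams(single_sample=True))
        assert len(res_ss.sites) == 1

    def test_per_sample_ratio_definition(self):
        # 6 HQ var + 6 HQ ref reads in two samples -> ratio 0.5 each
        specs = []
        for s in ("s1", "s2"):
            specs.append(dict(chrom="chr1", pos=10, sample=s, allele="G", n=6))
            specs.append(dict(chrom="chr1", pos=10, sample=s, allele="A", n=6))
        res = run_cascade(make_evidence(specs), reference=REF)
        assert len(res.sites) == 1
        row = res.sites.iloc[0]
        assert row["ratio_s1"] == pytest.approx(0.5)
        assert row["ratio_s2"] == pytest.approx(0.5)
        assert row["variant_type"] == "A-to-G"
        assert row["canonical_type"] == "A-to-I"

    def test_low_coverage_sample_ratio_is_nan(self):
        specs = [
            dict(chrom="chr1", pos=10, sample="s1", allele="G", n=6),
            dict(chrom="chr1", pos=10, sample="s1", allele="A", n=6),
            dict(chrom="chr1", pos=10, sample="s3", allele="G", n=6),
            dict(chrom="chr1", pos=10, sample="s3", allele="A", n=6),
            dict(chrom="chr1", pos=10, sample="s2", allele="G", n=2),
            dict(chrom="chr1", pos=10, sample="s2", allele="A", n=1),
        ]
        res = run_cascade(make_evidence(specs), reference=REF)
        assert len(res.sites) == 1
        assert np.isnan(res.sites.iloc[0]["ratio_s2"])

    def test_multiallelic_site_dropped_end_to_end(self):
        specs = [
            dict(chrom="chr1", pos=10, sample="s1", allele="G", n=10),
            dict(chrom="chr1", pos=10, sample="s2", allele="G", n=10),
            dict(chrom="chr1", pos=10, sample="s1", allele="C", n=2),
            dict(chrom="chr1", pos=10, sample="s1", allele="A", n=10),
            dict(chrom="chr1", pos=10, sample="s2", allele="A", n=10),
        ]
        res = run_cascade(make_evidence(specs), reference=REF)
        assert len(res.sites) == 0
        assert not res.table["pass_biallelic"].iloc[0]
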