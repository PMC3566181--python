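"""Venn partitioning, miss-cause classification, false-positive estimation,
slop-tolerant indel matching."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from concordkit.concordance import (
    MissCategory,
    aggregate_cell_counts,
    aggregate_platform_totals,
    classify_missed_site,
    estimate_false_positives,
    indel_overlap,
    summarize_categories,
    venn_partition,
)
from concordkit.core import (
    PLATFORM_DEFAULTS,
    Callset,
    ChromClass,
    EvidenceRecord,
    GenomicSite,
    Interval,
    VariantCall,
    VariantKind,
    Zygosity,
    default_config,
)

ILM = PLATFORM_DEFAULTS["illumina"]
R454 = PLATFORM_DEFAULTS["roche454"]


def _cs(pid, positions):
    return Callset(pid, [
        VariantCall(GenomicSite("c", p), "A", "G", VariantKind.SUBSTITUTION,
                    Zygosity.HET, 40.0) for p in sorted(positions)])


def _ev(pos=0, depth=30, alt=6, **kv):
    defaults = dict(rms_mapq=50.0, snp_qual=60.0, nearby_snp_count=0,
                    nearest_indel_distance=None, in_unique_region=True)
    defaults.update(kv)
    return EvidenceRecord(site=GenomicSite("c", pos), depth=depth,
                          alt_count=alt, **defaults)


class TestVennPartition:
    def test_three_identical_single_site_callsets(self):
        p = venn_partition([_cs(x, [7]) for x in "ABC"])
        assert p.cell_sizes() == {frozenset("ABC"): 1}

    def test_direct_set_algebra_example(self):
        p = venn_partition([_cs("A", [1, 2]), _cs("B", [2, 3]), _cs("C", [2])])
        assert p.cell("A") == {GenomicSite("c", 1)}
        assert p.cell("B") == {GenomicSite("c", 3)}
        assert p.cell("A", "B", "C") == {GenomicSite("c", 2)}
        assert p.cell("A", "B") == set()

    def test_duplicate_platform_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            venn_partition([_cs("A", [1]), _cs("A", [2])])

    def test_random_callsets_match_brute_force_enumeration(self, rng):
        sets = {pid: set(rng.choice(3_000, size=1_000, replace=False).tolist())
                for pid in "ABC"}
        p = venn_partition([_cs(pid, s) for pid, s in sets.items()])
        union = set.union(*sets.values())
        for combo_size in (1, 2, 3):
            for combo in itertools.combinations("ABC", combo_size):
                expected = {pos for pos in union
                            if {pid for pid in "ABC" if pos in sets[pid]}
                            == set(combo)}
                assert {s.pos for s in p.cell(*combo)} == expected
        # disjoint and exhaustive
        total = sum(len(v) for v in p.cells.values())
        assert total == len(union) == len(p.union_sites())

    def test_totals_reproduce_callset_sizes(self, rng):
        sets = {pid: set(rng.choice(2_000, size=700, replace=False).tolist())
                for pid in "AB"}
        p = venn_partition([_cs(pid, s) for pid, s in sets.items()])
        totals = aggregate_platform_totals(p)
        assert totals["per_platform"] == {pid: len(s) for pid, s in sets.items()}


class TestAggregation:
    def test_three_platform_published_cell_counts(self):
        cells = {
            frozenset("ABC"): 3_401_954,
            frozenset("AB"): 439_122,
            frozenset("AC"): 47_381,
            frozenset("BC"): 624_306,
            frozenset("A"): 442_674,
            frozenset("B"): 225_981,
            frozenset("C"): 71_567,
        }
        out = aggregate_cell_counts(cells, ["A", "B", "C"])
        assert out["per_platform"] == {
            "A": 4_331_131, "B": 4_691_363, "C": 4_145_208}
        assert out["union"] == 5_252_985
        assert out["shared_by_all"] == 3_401_954
        assert out["discordant"] == 1_851_031

    def test_empty_and_single_cell(self):
        assert aggregate_cell_counts({}, ["A", "B"]) == {
            "per_platform": {"A": 0, "B": 0}, "union": 0,
            "shared_by_all": 0, "discordant": 0}
        out = aggregate_cell_counts({frozenset("A"): 5}, ["A", "B"])
        assert out["per_platform"]["A"] == 5 and out["union"] == 5


class TestClassifier:
    @pytest.mark.parametrize("ev, expected", [
        (_ev(depth=0, alt=0, rms_mapq=None, snp_qual=None),
         MissCategory.NO_COVERAGE),
        (_ev(depth=2, alt=1), MissCategory.LOW_COVERAGE),
        (_ev(depth=90, alt=40), MissCategory.EXCESS_COVERAGE),
        (_ev(depth=10, alt=0), MissCategory.ALT_NOT_SEEN),
        (_ev(depth=10, alt=1), MissCategory.ALT_SEEN_ONCE),
        (_ev(nearby_snp_count=5), MissCategory.SNP_CLUSTER),
        (_ev(nearest_indel_distance=1), MissCategory.NEAR_INDEL),
        (_ev(rms_mapq=10.0, snp_qual=50.0), MissCategory.LOW_RMS_MAPQ),
        (_ev(snp_qual=10.0), MissCategory.LOW_SNP_QUAL),
        (_ev(), MissCategory.UNEXPLAINED),
    ])
    def test_precedence_rules(self, ev, expected):
        assert classify_missed_site(ev, ILM) is expected

    def test_rms_mapq_beats_snp_quality(self):
        ev = _ev(depth=30, alt=6, rms_mapq=10.0, snp_qual=50.0)
        assert classify_missed_site(ev, ILM) is MissCategory.LOW_RMS_MAPQ
        ev2 = _ev(depth=30, alt=6, rms_mapq=10.0, snp_qual=5.0)
        assert classify_missed_site(ev2, ILM) is MissCategory.LOW_RMS_MAPQ

    def test_mapq_free_platform_uses_uniqueness_slot(self):
        ev = _ev(rms_mapq=None, in_unique_region=False)
        assert classify_missed_site(ev, R454) is MissCategory.NON_UNIQUE
        assert MissCategory.NON_UNIQUE.slot == MissCategory.LOW_RMS_MAPQ.slot == 8
        # with mapping qualities available, uniqueness is not consulted
        assert classify_missed_site(_ev(in_unique_region=False), ILM) \
            is MissCategory.UNEXPLAINED

    def test_excess_coverage_respects_chromosome_class(self):
        ev = _ev(depth=50, alt=20)
        assert classify_missed_site(ev, ILM, ChromClass.AUTOSOME) \
            is MissCategory.UNEXPLAINED
        assert classify_missed_site(ev, ILM, ChromClass.SEX) \
            is MissCategory.EXCESS_COVERAGE

    @given(st.integers(0, 120), st.integers(0, 10), st.integers(0, 8),
           st.one_of(st.none(), st.integers(0, 20)),
           st.one_of(st.none(), st.floats(0, 60)),
           st.one_of(st.none(), st.floats(0, 60)), st.booleans())
    def test_classifier_is_total_and_deterministic(
            self, depth, alt, nearby, indel_dist, mapq, qual, unique):
        ev = EvidenceRecord(site=GenomicSite("c", 0), depth=depth,
                            alt_count=min(alt, depth), rms_mapq=mapq,
                            snp_qual=qual, nearby_snp_count=nearby,
                            nearest_indel_distance=indel_dist,
                            in_unique_region=unique)
        first = classify_missed_site(ev, ILM)
        assert isinstance(first, MissCategory)
        assert classify_missed_site(ev, ILM) is first


class TestSummaries:
    def test_single_site_has_fraction_one(self):
        df = summarize_categories(
            {(GenomicSite("c", 1), "P"): MissCategory.ALT_NOT_SEEN})
        assert len(df) == 1
        assert df.iloc[0]["fraction"] == 1.0

    def test_empty_input_gives_empty_table(self):
        assert summarize_categories({}).empty

    def test_counts_and_fractions_per_platform(self):
        classified = {
            (GenomicSite("c", 1), "P"): MissCategory.NO_COVERAGE,
            (GenomicSite("c", 2), "P"): MissCategory.NO_COVERAGE,
            (GenomicSite("c", 3), "P"): MissCategory.LOW_SNP_QUAL,
            (GenomicSite("c", 1), "Q"): MissCategory.ALT_SEEN_ONCE,
        }
        df = summarize_categories(classified)
        p = df[df.platform == "P"].set_index("category")
        assert p.loc["NO_COVERAGE", "count"] == 2
        assert p.loc["NO_COVERAGE", "fraction"] == pytest.approx(2 / 3)
        for _, group in df.groupby("platform"):
            assert group.fraction.sum() == pytest.approx(1.0)


class TestFalsePositives:
    def _config(self):
        return default_config()

    def test_coverage_compromised_everywhere_is_plausible_true(self):
        site = GenomicSite("c", 5)
        others = {
            "illumina": {site: _ev(5, depth=0, alt=0, rms_mapq=None,
                                   snp_qual=None)},
            "solid": {site: _ev(5, depth=0, alt=0, rms_mapq=None,
                                snp_qual=None)},
        }
        est = estimate_false_positives([site], others, self._config())
        assert (est.plausible_true, est.putative_fp) == (1, 0)

    def test_clean_absence_everywhere_is_putative_fp(self):
        site = GenomicSite("c", 5)
        others = {
            "illumina": {site: _ev(5, depth=30, alt=0)},
            "solid": {site: _ev(5, depth=30, alt=0)},
        }
        est = estimate_false_positives([site], others, self._config())
        assert (est.plausible_true, est.putative_fp) == (0, 1)

    def test_every_other_platform_must_excuse(self):
        site = GenomicSite("c", 5)
        others = {
            "illumina": {site: _ev(5, depth=30, alt=2)},   # alt seen: excused
            "solid": {site: _ev(5, depth=30, alt=0)},      # clean: not excused
        }
        est = estimate_false_positives([site], others, self._config())
        assert est.putative_fp == 1

    def test_missing_evidence_is_an_error(self):
        with pytest.raises(KeyError):
            estimate_false_positives([GenomicSite("c", 5)],
                                     {"illumina": {}}, self._config())

    def test_bounds_on_random_input(self, rng):
        cfg = self._config()
        sites = [GenomicSite("c", int(p))
                 for p in rng.choice(10_000, 200, replace=False)]
        def rand_ev(s):
            depth = int(rng.integers(0, 90))
            return EvidenceRecord(site=s, depth=depth,
                                  alt_count=min(int(rng.integers(0, 3)), depth))

        others = {pid: {s: rand_ev(s) for s in sites}
                  for pid in ("illumina", "solid")}
        est = estimate_false_positives(sites, others, cfg)
        assert est.plausible_true + est.putative_fp == len(sites)
        assert 0 <= est.putative_fp <= len(sites)


class TestIndelOverlap:
    def test_identical_interval_is_exact_match(self):
        iv = Interval("c", 100, 105)
        res = indel_overlap([iv], [iv], 10)
        assert res.n_exact == 1 and res.n_slop_only == 0 and res.n_unmatched == 0

    def test_gap_within_slop_is_slop_only(self):
        res = indel_overlap([Interval("c", 100, 105)],
                            [Interval("c", 112, 113)], 10)
        assert res.n_slop_only == 1  # gap of 7 <= 10

    def test_gap_beyond_slop_is_unmatched(self):
        res = indel_overlap([Interval("c", 100, 105)],
                            [Interval("c", 155, 160)], 10)
        assert res.n_unmatched == 1

    def test_zero_slop_eliminates_slop_matches(self, rng):
        a = [Interval("c", int(s), int(s) + 3)
             for s in rng.integers(0, 5_000, 100)]
        b = [Interval("c", int(s), int(s) + 3)
             for s in rng.integers(0, 5_000, 100)]
        res = indel_overlap(a, b, 0)
        assert res.n_slop_only == 0
        assert res.n_exact + res.n_unmatched == len(a)

    def test_identical_sets_are_symmetric_in_counts(self, rng):
        ivs = [Interval("c", int(s), int(s + l))
               for s, l in zip(rng.integers(0, 9_000, 200),
                               rng.integers(1, 10, 200))]
        ab = indel_overlap(ivs, ivs, 10)
        assert ab.n_exact == len(ivs) and ab.n_unmatched == 0

    def test_thousand_intervals_match_brute_force_oracle(self, rng):
        def mk(n, chroms=("c1", "c2")):
            return [Interval(str(rng.choice(chroms)), int(s), int(s + l))
                    for s, l in zip(rng.integers(0, 50_000, n),
                                    rng.integers(1, 12, n))]
        a, b = mk(1_000), mk(1_000)
        res = indel_overlap(a, b, 10)
        exact = slop = unmatched = 0
        for iv in a:  # pure-python nearest-by-gap scan
            best = None
            for other in sorted(b):
                if other.chrom != iv.chrom:
                    continue
                g = iv.gap_to(other)
                if best is None or g < best:
                    best = g
            if best is None or best > 10:
                unmatched += 1
            elif best == 0:
                exact += 1
            else:
                slop += 1
        assert (res.n_exact, res.n_slop_only, res.n_unmatched) == \
            (exact, slop, unmatched)
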