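import numpy as np
import pytest

from promoterbench.dataset_builder import (
    BenchmarkConfig,
    LabeledWindow,
    LeakageError,
    PromoterDataset,
    RegionSpec,
    SplitRequest,
    build_benchmark,
    dataset_stats,
    deduplicate,
    disjoint_split,
    label_window,
    map_promoters_by_exact_match,
    promoter_region_from_tss,
    read_dataset,
    tss_relative_index,
    window_count,
    write_dataset,
)
from promoterbench.seqio import GenomeSequence, Interval, TssAnnotation, reverse_complement


def brute_force_tag(win_start, win_end, promoters, min_overlap):
    """Independent oracle: per-base scan for the longest contiguous run of
    window bases inside any single promoter interval."""
    for p in promoters:
        run = best = 0
        for pos in range(win_start, win_end):
            if p.start <= pos < p.end:
                run += 1
                best = max(best, run)
            else:
                run = 0
        if best >= min_overlap:
            return "I"
    return "O"


class TestRegionFromTss:
    def test_default_region_plus(self):
        iv = promoter_region_from_tss(TssAnnotation("c", 1000, "+"))
        assert (iv.start, iv.end) == (751, 1051) and iv.length == 300

    def test_default_region_minus_mirrors(self):
        iv = promoter_region_from_tss(TssAnnotation("c", 1000, "-"))
        assert (iv.start, iv.end) == (950, 1250) and iv.strand == "-"

    def test_short_region_length_251(self):
        iv = promoter_region_from_tss(TssAnnotation("c", 1000, "+"), RegionSpec(200, 50))
        assert iv.length == 251

    def test_boundary_error(self):
        with pytest.raises(ValueError):
            promoter_region_from_tss(TssAnnotation("c", 100, "+"))
        with pytest.raises(ValueError):
            promoter_region_from_tss(
                TssAnnotation("c", 1000, "+"), chrom_length=1050
            )


class TestTssRelativeIndex:
    def test_tss_plus_one_is_249(self):
        assert tss_relative_index(1) == 249

    def test_minus_one_is_248(self):
        assert tss_relative_index(-1) == 248

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            tss_relative_index(0)


class TestLabelWindow:
    win = Interval("c", 0, 300)

    def test_full_overlap(self):
        assert label_window(self.win, [Interval("c", 0, 300)], 250) == "I"

    def test_boundary_exactly_250_inclusive(self):
        # promoter [50, 350): intersection with [0, 300) is exactly 250
        assert label_window(self.win, [Interval("c", 50, 350)], 250) == "I"

    def test_overlap_249_is_O(self):
        p = Interval("c", 51, 351)
        assert self.win.overlap(p) == 249
        assert label_window(self.win, [p], 250) == "O"

    def test_two_disjoint_promoters_do_not_sum(self):
        ps = [Interval("c", 0, 150), Interval("c", 150, 300)]
        assert label_window(self.win, ps, 250) == "O"

    def test_empty_promoter_set(self):
        assert label_window(self.win, [], 250) == "O"

    def test_monotone_in_min_overlap(self):
        p = [Interval("c", 40, 340)]
        tags = [label_window(self.win, p, m) for m in (100, 200, 260, 261, 300)]
        # once O, always O as min_overlap grows
        assert "".join(tags) == "".join(sorted(tags, key=lambda t: t == "O"))


class TestBuildBenchmark:
    def test_single_window(self, rng):
        g = GenomeSequence("g", "".join(rng.choice(list("ACGT"), 300)))
        assert len(build_benchmark(g, [])) == 1

    @pytest.mark.parametrize("L,expected", [(300, 1), (1000, 15), (10_007, 195)])
    def test_window_count_closed_form(self, rng, L, expected):
        g = GenomeSequence("g", "".join(rng.choice(list("ACGT"), L)))
        ds = build_benchmark(g, [])
        assert len(ds) == expected == window_count(L, 300, 50)

    def test_planted_promoter_i_windows(self, rng):
        # promoter [600, 900): windows with >= 250-base intersection start
        # at 550 (overlap 250), 600 (300), 650 (250); flanks give 249 or less
        g = GenomeSequence("g", "".join(rng.choice(list("ACGT"), 2000)))
        prom = [Interval("g", 600, 900)]
        ds = build_benchmark(g, prom)
        i_starts = sorted(w.provenance.start for w in ds if w.tag == "I")
        assert i_starts == [550, 600, 650]
        for w in ds:
            assert w.tag == brute_force_tag(
                w.provenance.start, w.provenance.end, prom, 250
            )

    def test_n_windows_removed(self, rng):
        bases = list("".join(rng.choice(list("ACGT"), 1000)))
        bases[400] = "N"
        g = GenomeSequence("g", "".join(bases))
        ds = build_benchmark(g, [])
        # windows covering position 400 start at 150..400
        assert all(not (w.provenance.start <= 400 < w.provenance.end) for w in ds)
        kept = build_benchmark(g, [], BenchmarkConfig(drop_n=False))
        assert len(kept) == 15

    def test_deterministic(self, synthetic_bundle):
        g, _, truth = synthetic_bundle
        a = build_benchmark(g, list(truth))
        b = build_benchmark(g, list(truth))
        assert a.sequences == b.sequences and a.tags == b.tags

    def test_shorter_than_window_empty(self):
        g = GenomeSequence("g", "ACGT")
        assert len(build_benchmark(g, [])) == 0

    def test_every_i_window_verified_by_overlap(self, synthetic_bundle):
        g, _, truth = synthetic_bundle
        ds = build_benchmark(g, list(truth))
        for w in ds:
            if w.tag == "I":
                assert max(w.provenance.overlap(p) for p in truth) >= 250


def _mkds(pairs):
    return PromoterDataset(
        [
            LabeledWindow(s, t, Interval("c", 300 * i, 300 * (i + 1)))
            for i, (s, t) in enumerate(pairs)
        ]
    )


class TestDeduplicate:
    def test_removes_later_occurrences(self):
        ds = _mkds([("AAA", "I"), ("AAA", "I"), ("CCC", "O")])
        out, removed = deduplicate(ds)
        assert removed == 1 and out.sequences == ["AAA", "CCC"]

    def test_identity_on_distinct(self):
        ds = _mkds([("AAA", "I"), ("CCC", "O")])
        out, removed = deduplicate(ds)
        assert removed == 0 and out.sequences == ds.sequences

    def test_conflicting_tags_keep_first_and_log(self, caplog):
        import logging

        ds = _mkds([("AAA", "I"), ("AAA", "O")])
        with caplog.at_level(logging.WARNING):
            out, removed = deduplicate(ds)
        assert removed == 1 and out.windows[0].tag == "I"
        assert any("conflicting" in r.message for r in caplog.records)


class TestStats:
    def test_fraction(self):
        ds = _mkds([("A" * 3, "I")] * 2 + [(f"C{i}C", "O") for i in range(8)])
        st = dataset_stats(ds)
        assert st.total == 10 and st.n_promoter == 2 and st.promoter_fraction == 0.2

    def test_empty_flagged(self):
        st = dataset_stats(PromoterDataset([]))
        assert st.empty and st.total == 0 and st.promoter_fraction == 0.0

    def test_matches_brute_force_recount(self, synthetic_bundle):
        g, _, truth = synthetic_bundle
        ds = build_benchmark(g, list(truth))
        st = dataset_stats(ds)
        assert st.n_promoter == sum(1 for w in ds if w.tag == "I")
        assert st.n_promoter + st.n_nonpromoter == st.total == len(ds)


class TestDisjointSplit:
    @pytest.fixture()
    def pool(self, rng):
        pairs = [("".join(rng.choice(list("ACGT"), 30)), "I") for _ in range(100)]
        pairs += [("".join(rng.choice(list("ACGT"), 30)), "O") for _ in range(200)]
        return _mkds(pairs)

    def test_subsets_nest_in_master_sides(self, pool):
        reqs = {
            "big": SplitRequest(80, 20, 50, 20),
            "small": SplitRequest(50, 10, 30, 10),
        }
        out = disjoint_split(pool, reqs, rng_seed=5)
        big_tr_i = {w.sequence for w in out["big"][0] if w.tag == "I"}
        big_te_i = {w.sequence for w in out["big"][1] if w.tag == "I"}
        small_tr_i = {w.sequence for w in out["small"][0] if w.tag == "I"}
        small_te_i = {w.sequence for w in out["small"][1] if w.tag == "I"}
        assert small_tr_i <= big_tr_i and small_te_i <= big_te_i
        assert len(small_tr_i) == 50 and len(small_te_i) == 10

    def test_no_sequence_crosses_split(self, pool):
        out = disjoint_split(pool, {"m": SplitRequest(60, 20, 100, 50)}, rng_seed=1)
        train, test = out["m"]
        assert not set(train.sequences) & set(test.sequences)

    def test_infeasible_counts_error(self, pool):
        with pytest.raises(ValueError, match="infeasible"):
            disjoint_split(pool, {"m": SplitRequest(90, 20, 10, 10)}, rng_seed=1)

    def test_planted_leak_detected(self, pool):
        # duplicating a promoter sequence cannot leak: dedup collapses it.
        # But a deliberately shared sequence between classes is caught by
        # the verification if the split machinery were bypassed.
        from promoterbench.dataset_builder import _verify_disjoint

        ds = _mkds([("AAA", "I")])
        with pytest.raises(LeakageError):
            _verify_disjoint(ds, ds)


class TestExactMatchMapper:
    def test_forward_hit(self, rng):
        bases = "".join(rng.choice(list("ACGT"), 1000))
        g = GenomeSequence("g", bases)
        hits = map_promoters_by_exact_match(g, [bases[100:400]])
        assert Interval("g", 100, 400, "+") in hits

    def test_reverse_hit_reported_minus(self, rng):
        bases = "".join(rng.choice(list("ACGT"), 1000))
        g = GenomeSequence("g", bases)
        hits = map_promoters_by_exact_match(g, [reverse_complement(bases[100:400])])
        assert Interval("g", 100, 400, "-") in hits

    def test_absent_promoter_empty(self):
        g = GenomeSequence("g", "AAAA" * 100)
        assert map_promoters_by_exact_match(g, ["CCCCC"]) == set()


class TestDatasetFile:
    def test_roundtrip(self, tmp_path, synthetic_bundle):
        g, _, truth = synthetic_bundle
        ds = build_benchmark(g, list(truth))
        p = tmp_path / "ds.tsv"
        write_dataset(p, ds)
        back = read_dataset(p)
        assert back.sequences == ds.sequences and back.tags == ds.tags
        assert back.config == ds.config
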