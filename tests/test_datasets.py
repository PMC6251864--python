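"""Dataset-construction protocol: splitting, ratio-controlled negative
sampling, cross-tissue exclusion, comprehensive pooling."""

import numpy as np
import pytest

from m5cpred.datasets import (
    LabelledDataset,
    SplitSpec,
    build_comprehensive_dataset,
    build_dataset,
    build_tissue_datasets,
    draw_negative_windows,
    enumerate_negative_candidates,
    load_dataset,
    sample_negatives,
    split_sites,
    write_dataset,
)
from m5cpred.errors import EmptyNegativesError, M5cError
from m5cpred.seqio import SiteRecord, Transcript


def make_sites(n, tissue="x", prefix="t"):
    return [SiteRecord(f"{prefix}{i}", 7, "positive", tissue)
            for i in range(n)]


class TestNegativeCandidates:
    def test_all_c_minus_positives(self):
        t = Transcript(id="t", sequence="CCC")
        assert enumerate_negative_candidates(t, {2}) == {1, 3}

    def test_no_c_gives_empty(self):
        t = Transcript(id="t", sequence="AGT")
        assert enumerate_negative_candidates(t, set()) == set()

    def test_partition_of_c_positions(self, small_sim_maps):
        """Candidates plus on-C positives exactly tile the C positions."""
        _, transcripts, tables = small_sim_maps
        tissue = sorted(tables)[0]
        by_tid = {}
        for rec in tables[tissue]:
            if rec.label == "positive":
                by_tid.setdefault(rec.transcript_id, set()).add(rec.position)
        for tid, positives in by_tid.items():
            t = transcripts[tid]
            total_c = sum(1 for b in t.sequence if b == "C")
            candidates = enumerate_negative_candidates(t, positives)
            on_c = {p for p in positives if t.sequence[p - 1] == "C"}
            assert len(candidates) + len(on_c) == total_c
            assert not candidates & on_c


class TestSplit:
    def test_quarter_of_1000_is_exactly_250(self):
        train, test = split_sites(make_sites(1000), SplitSpec(seed=0))
        assert len(test) == 250
        assert len(train) == 750

    def test_same_seed_identical_partition(self):
        sites = make_sites(97)
        first = split_sites(sites, SplitSpec(seed=5))
        second = split_sites(sites, SplitSpec(seed=5))
        assert first == second

    def test_partition_is_disjoint_and_exhaustive(self):
        sites = make_sites(101)
        train, test = split_sites(sites, SplitSpec(seed=3))
        assert sorted(train + test, key=lambda s: s.key) == sorted(
            sites, key=lambda s: s.key)
        assert not {s.key for s in train} & {s.key for s in test}

    def test_input_order_does_not_matter(self):
        sites = make_sites(40)
        a = split_sites(sites, SplitSpec(seed=9))
        b = split_sites(sites[::-1], SplitSpec(seed=9))
        assert a == b

    def test_tiny_collection_still_yields_a_test_site(self):
        with pytest.warns(UserWarning, match="at least one"):
            train, test = split_sites(make_sites(2), SplitSpec(seed=0))
        assert len(test) == 1 and len(train) == 1


class TestSampleNegatives:
    def test_exact_ratio_arithmetic(self):
        chosen = sample_negatives(range(500), n_pos=10, ratio=30, seed=0)
        assert len(chosen) == 300
        assert len(set(chosen)) == 300

    def test_capped_at_pool_size_with_warning(self):
        with pytest.warns(UserWarning, match="120"):
            chosen = sample_negatives(range(120), n_pos=10, ratio=30, seed=0)
        assert sorted(chosen) == list(range(120))

    def test_empty_pool_is_an_error(self):
        with pytest.raises(EmptyNegativesError):
            sample_negatives([], n_pos=5, ratio=30, seed=0)

    def test_seeded_reproducibility_and_seed_sensitivity(self):
        a = sample_negatives(range(10_000), 10, 30, seed=1)
        b = sample_negatives(range(10_000), 10, 30, seed=1)
        c = sample_negatives(range(10_000), 10, 30, seed=2)
        assert a == b
        assert a != c


class TestBuildDataset:
    @pytest.fixture()
    def built(self, small_sim_maps):
        _, transcripts, tables = small_sim_maps
        return build_comprehensive_dataset(
            tables, transcripts, SplitSpec(seed=7), ratio=10, w=5)

    def test_train_ratio_exact(self, built, small_sim_maps):
        train, _ = built
        assert train.n_negative == min(
            10 * train.n_positive,
            train.n_negative,  # pool can only cap, never exceed
        )
        assert train.n_negative <= 10 * train.n_positive

    def test_train_test_site_disjointness(self, built):
        train, test = built
        assert not set(train.sites) & set(test.sites)

    def test_test_set_uses_all_remaining_candidates(self, built,
                                                    small_sim_maps):
        _, transcripts, tables = small_sim_maps
        train, test = built
        assert test.ratio == "all"
        pos_keys = {r.key for recs in tables.values() for r in recs
                    if r.label == "positive"}
        test_tids = {tid for tid, _ in test.sites if True}
        # every candidate C on test-side transcripts is present unless it
        # was spent on training
        train_keys = set(train.sites)
        test_keys = set(test.sites)
        for tid in {k for k, _ in test.sites}:
            seq = transcripts[tid].sequence
            for i, base in enumerate(seq):
                key = (tid, i + 1)
                if base != "C" or key in pos_keys:
                    continue
                assert (key in test_keys) == (key not in train_keys)

    def test_every_window_centred_on_c(self, built):
        for ds in built:
            assert all(w.bases[w.w] == "C" for w in ds.windows)

    def test_construction_is_pure_function_of_seed(self, small_sim_maps):
        _, transcripts, tables = small_sim_maps
        a = build_comprehensive_dataset(tables, transcripts,
                                        SplitSpec(seed=7), ratio=10, w=5)
        b = build_comprehensive_dataset(tables, transcripts,
                                        SplitSpec(seed=7), ratio=10, w=5)
        assert a[0].sites == b[0].sites and a[1].sites == b[1].sites
        c = build_comprehensive_dataset(tables, transcripts,
                                        SplitSpec(seed=8), ratio=10, w=5)
        assert a[0].sites != c[0].sites


class TestComprehensivePooling:
    def test_shared_site_counted_once(self):
        t = Transcript(id="t1", sequence="ACGTC" * 20)
        tables = {
            "a": [SiteRecord("t1", 5, "positive", "a"),
                  SiteRecord("t1", 10, "positive", "a")],
            "b": [SiteRecord("t1", 5, "positive", "b"),
                  SiteRecord("t1", 20, "positive", "b")],
        }
        train, test = build_comprehensive_dataset(
            tables, {"t1": t}, SplitSpec(test_fraction=0.25, seed=0),
            ratio=2, w=2)
        assert train.n_positive + test.n_positive == 3  # union, deduplicated

    def test_single_tissue_equals_plain_build(self, small_sim_maps):
        _, transcripts, tables = small_sim_maps
        tissue = sorted(tables)[0]
        solo = {tissue: tables[tissue]}
        comp = build_comprehensive_dataset(solo, transcripts,
                                           SplitSpec(seed=4), ratio=5, w=5)
        plain = build_dataset(tables[tissue], transcripts, SplitSpec(seed=4),
                              ratio=5, w=5, tissue="comprehensive")
        assert comp[0].sites == plain[0].sites
        assert comp[1].sites == plain[1].sites


class TestTissueDatasets:
    @pytest.fixture()
    def per_tissue(self, small_sim_maps):
        _, transcripts, tables = small_sim_maps
        return build_tissue_datasets(tables, transcripts, SplitSpec(seed=7),
                                     ratio=10, w=5)

    def test_cross_tissue_exclusion_set_algebra(self, per_tissue):
        """No tissue's test set retains a sample used to train another
        tissue's predictor (recomputed independently by set algebra)."""
        for tissue, (_, test) in per_tissue.items():
            foreign = set()
            for other, (other_train, _) in per_tissue.items():
                if other != tissue:
                    foreign |= set(other_train.sites)
            assert not set(test.sites) & foreign

    def test_exclusion_never_touches_own_training(self, per_tissue,
                                                  small_sim_maps):
        _, transcripts, tables = small_sim_maps
        rebuilt = build_tissue_datasets(tables, transcripts, SplitSpec(seed=7),
                                        ratio=10, w=5)
        for tissue in per_tissue:
            assert per_tissue[tissue][0].sites == rebuilt[tissue][0].sites

    def test_single_tissue_exclusion_is_noop(self, small_sim_maps):
        _, transcripts, tables = small_sim_maps
        tissue = sorted(tables)[0]
        solo = build_tissue_datasets({tissue: tables[tissue]}, transcripts,
                                     SplitSpec(seed=7), ratio=10, w=5)
        both = build_tissue_datasets(tables, transcripts, SplitSpec(seed=7),
                                     ratio=10, w=5)
        assert len(solo[tissue][1].sites) >= len(both[tissue][1].sites)

    def test_tissue_without_positives_skipped_with_warning(self,
                                                           small_sim_maps):
        _, transcripts, tables = small_sim_maps
        tables = dict(tables)
        tables["empty_tissue"] = [
            SiteRecord("t", 1, "negative", "empty_tissue")]
        with pytest.warns(UserWarning, match="empty_tissue"):
            built = build_tissue_datasets(tables, transcripts,
                                          SplitSpec(seed=7), ratio=10, w=5)
        assert "empty_tissue" not in built


class TestDrawNegativeWindows:
    def test_avoids_positives_and_exclusions(self, small_sim_maps):
        _, transcripts, tables = small_sim_maps
        pos_keys = {r.key for recs in tables.values() for r in recs
                    if r.label == "positive"}
        exclude = set(list(pos_keys)[:5])
        wins = draw_negative_windows(transcripts, sorted(transcripts),
                                     pos_keys, exclude, 50, seed=3, w=5)
        keys = {(w.transcript_id, w.center_index) for w in wins}
        assert len(wins) == 50
        assert not keys & pos_keys and not keys & exclude

    def test_insufficient_pool_is_an_error(self, toy_transcripts):
        with pytest.raises(EmptyNegativesError):
            draw_negative_windows(toy_transcripts, ["t1"], set(), set(),
                                  10_000, seed=0, w=2)


def test_dataset_round_trip_serialization(tmp_path, small_sim_maps):
    _, transcripts, tables = small_sim_maps
    train, _ = build_comprehensive_dataset(tables, transcripts,
                                           SplitSpec(seed=2), ratio=5, w=5)
    write_dataset(train, transcripts, tmp_path / "ds", {"seed": 2})
    loaded, _ = load_dataset(tmp_path / "ds")
    assert loaded.sites == train.sites
    assert np.array_equal(loaded.labels, train.labels)
    assert [w.bases for w in loaded.windows] == [w.bases for w in train.windows]
    assert (loaded.tissue, loaded.role, loaded.ratio) == (
        train.tissue, train.role, train.ratio)
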