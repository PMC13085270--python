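import numpy as np
import pytest
from helpers import chain, multi, random_layout
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import dcj_distance_bfs, dcj_distance_bfs_uni

from scafeval.errors import MetricError
from scafeval.metrics import (
    baseline_report,
    dcj_distance,
    grouping_accuracy,
    n50,
    ordering_accuracy,
    orientation_accuracy,
    overall_accuracy,
    score,
)


class TestDcjDistance:
    def test_identical(self):
        a = chain("c1+", "c2+", "c3+")
        assert dcj_distance(a, a) == 0

    def test_single_inversion(self):
        assert dcj_distance(chain("c1+", "c2-", "c3+"),
                            chain("c1+", "c2+", "c3+")) == 1

    def test_single_fusion(self):
        split = multi({"a": ["c1+", "c2+"], "b": ["c3+"]})
        joined = chain("c1+", "c2+", "c3+")
        assert dcj_distance(split, joined) == 1

    def test_different_contig_sets_rejected(self):
        with pytest.raises(MetricError, match="restrict_layout"):
            dcj_distance(chain("c1+"), chain("c2+"))

    def test_empty_rejected(self):
        from scafeval.layout import GenomeLayout

        with pytest.raises(MetricError):
            dcj_distance(GenomeLayout({}), GenomeLayout({}))

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_bfs_oracle_small(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 5))
        ids = [f"c{i}" for i in range(n)]
        a = random_layout(rng, ids)
        b = random_layout(rng, ids)
        assert dcj_distance(a, b) == dcj_distance_bfs(a, b)

    @pytest.mark.parametrize("seed", range(10))
    def test_bidirectional_oracle_agrees_with_plain_bfs(self, seed):
        rng = np.random.default_rng(1000 + seed)
        ids = ["c0", "c1", "c2"]
        a = random_layout(rng, ids)
        b = random_layout(rng, ids)
        assert dcj_distance_bfs(a, b) == dcj_distance_bfs_uni(a, b)

    @pytest.mark.parametrize("seed", range(15))
    def test_metric_axioms(self, seed):
        rng = np.random.default_rng(2000 + seed)
        ids = [f"c{i}" for i in range(6)]
        a, b, c = (random_layout(rng, ids) for _ in range(3))
        assert dcj_distance(a, b) == dcj_distance(b, a)
        assert dcj_distance(a, a) == 0
        assert dcj_distance(a, c) <= dcj_distance(a, b) + dcj_distance(b, c)

    @pytest.mark.parametrize("seed", range(10))
    def test_zero_iff_identical_adjacencies(self, seed):
        from scafeval.layout import layout_to_adjacencies

        rng = np.random.default_rng(3000 + seed)
        ids = [f"c{i}" for i in range(5)]
        a = random_layout(rng, ids)
        b = random_layout(rng, ids)
        same = layout_to_adjacencies(a) == layout_to_adjacencies(b)
        assert (dcj_distance(a, b) == 0) == same


class TestOverallAccuracy:
    def test_identical(self):
        a = multi({"x": ["c1+", "c2-"], "y": ["c3+"]})
        assert overall_accuracy(a, a) == 1.0

    def test_middle_swap_is_zero(self):
        # every contig has at least one wrong extremity pairing
        ref = chain("c1+", "c2+", "c3+", "c4+")
        asm = chain("c1+", "c3+", "c2+", "c4+")
        assert overall_accuracy(asm, ref) == 0.0

    def test_detached_tail_contig(self):
        ids = [f"c{i}" for i in range(1, 11)]
        ref = chain(*(f"{c}+" for c in ids))
        asm = multi({"main": [f"{c}+" for c in ids[:9]], "solo": ["c10+"]})
        assert overall_accuracy(asm, ref) == pytest.approx(0.8)


class TestGroupingAccuracy:
    def test_perfect_grouping_any_order(self):
        ref = multi({"chr1": ["c1+", "c2+", "c3+"], "chr2": ["c4+", "c5+"]})
        asm = multi({"s1": ["c2-", "c1+", "c3+"], "s2": ["c5+", "c4-"]})
        assert grouping_accuracy(asm, ref) == 1.0

    def test_megascaffold(self):
        ref = multi({"chr1": ["c1+", "c2+", "c3+"],
                     "chr2": ["c4+", "c5+", "c6+"]})
        asm = chain("c1+", "c2+", "c3+", "c4+", "c5+", "c6+", group="mega")
        assert grouping_accuracy(asm, ref) == pytest.approx(0.25)

    def test_chromosome_split_in_two(self):
        ref = chain("c1+", "c2+", "c3+", "c4+", group="chr1")
        asm = multi({"s1": ["c1+", "c2+"], "s2": ["c3+", "c4+"]})
        assert grouping_accuracy(asm, ref) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_invariant_to_renaming_and_reversal(self, seed):
        from scafeval.layout import GenomeLayout, reverse_group

        rng = np.random.default_rng(4000 + seed)
        ids = [f"c{i}" for i in range(8)]
        lengths = {c: int(rng.integers(50, 500)) for c in ids}
        ref = random_layout(rng, ids, lengths=lengths)
        asm = random_layout(rng, ids, lengths=lengths)
        base = grouping_accuracy(asm, ref)
        renamed = GenomeLayout(
            {f"zz{i}": list(g) for i, g in enumerate(asm.groups.values())}
        )
        assert grouping_accuracy(renamed, ref) == pytest.approx(base)
        flipped = reverse_group(asm, list(asm.groups)[0])
        assert grouping_accuracy(flipped, ref) == pytest.approx(base)


class TestOrderingAccuracy:
    def test_identical(self):
        a = chain("c1+", "c2+", "c3+")
        assert ordering_accuracy(a, a) == 1.0

    def test_full_reversal(self):
        ref = chain("c1+", "c2+", "c3+", "c4+")
        asm = chain("c4-", "c3-", "c2-", "c1-")
        assert ordering_accuracy(asm, ref) == 1.0

    def test_middle_swap_one_third(self):
        ref = chain("c1+", "c2+", "c3+", "c4+")
        asm = chain("c1+", "c3+", "c2+", "c4+")
        assert ordering_accuracy(asm, ref) == pytest.approx(1 / 3)

    def test_no_pairs_warns_and_returns_zero(self):
        ref = chain("c1+", "c2+")
        asm = multi({"a": ["c1+"], "b": ["c2+"]})
        with pytest.warns(UserWarning, match="no adjacent"):
            assert ordering_accuracy(asm, ref) == 0.0


class TestOrientationAccuracy:
    def test_identical(self):
        a = chain("c1+", "c2-", "c3+")
        assert orientation_accuracy(a, a) == 1.0

    def test_full_reversal(self):
        ref = chain("c1+", "c2-", "c3+")
        asm = chain("c3-", "c2+", "c1-")
        assert orientation_accuracy(asm, ref) == 1.0

    def test_single_flip(self):
        ref = chain("c1+", "c2+", "c3+")
        asm = chain("c1+", "c2-", "c3+")
        assert ordering_accuracy(asm, ref) == 1.0
        assert orientation_accuracy(asm, ref) == 0.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_never_exceeds_ordering(self, seed):
        rng = np.random.default_rng(seed)
        ids = [f"c{i}" for i in range(6)]
        lengths = {c: int(rng.integers(50, 500)) for c in ids}
        ref = random_layout(rng, ids, lengths=lengths)
        asm = random_layout(rng, ids, lengths=lengths)
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                assert orientation_accuracy(asm, ref) <= ordering_accuracy(
                    asm, ref
                ) + 1e-12


class TestN50:
    def test_worked_example(self):
        assert n50([100, 200, 300, 400]) == 300

    def test_all_equal(self):
        assert n50([70] * 9) == 70

    def test_single(self):
        assert n50([1234]) == 1234

    def test_empty_rejected(self):
        with pytest.raises(MetricError):
            n50([])


class TestScore:
    def test_perfect(self):
        ref = multi({"chr1": ["c1+", "c2-"], "chr2": ["c3+"]})
        report = score(ref, ref)
        assert report.edit_distance == 0
        assert report.overall_accuracy == 1.0
        assert report.grouping_accuracy == 1.0
        assert report.ordering_accuracy == 1.0
        assert report.orientation_accuracy == 1.0
        assert report.n_contigs_excluded == 0

    def test_exclusion_bookkeeping(self):
        ids = [f"c{i}" for i in range(10)]
        ref = chain(*(f"{c}+" for c in ids))
        asm = chain(*(f"{c}+" for c in ids[:8]))
        report = score(asm, ref, exclude_unscaffolded=True)
        assert report.n_contigs_excluded == 2
        assert report.n_contigs_evaluated == 8
        assert set(report.excluded_ids) == {"c8", "c9"}

    def test_unscaffolded_penalized_when_not_excluded(self):
        ids = [f"c{i}" for i in range(10)]
        ref = chain(*(f"{c}+" for c in ids))
        asm = chain(*(f"{c}+" for c in ids[:8]))
        inc = score(asm, ref, exclude_unscaffolded=False)
        exc = score(asm, ref, exclude_unscaffolded=True)
        assert inc.overall_accuracy <= exc.overall_accuracy
        assert inc.n_contigs_evaluated == 10

    def test_n50_reported(self):
        ref = chain("c1+", "c2+", lengths={"c1": 100, "c2": 300})
        assert score(ref, ref).n50 == 300


class TestBaseline:
    def test_chain_baseline(self):
        ref = chain("c1+", "c2+", "c3+", "c4+")
        contigs = [(f"c{i}", 100) for i in range(1, 5)]
        report = baseline_report(contigs, ref)
        assert report.edit_distance == 3  # k - 1 fusions
        assert report.overall_accuracy == 0.0
        assert report.ordering_accuracy == 0.0

    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    def test_chain_edit_distance_matches_oracle(self, k):
        from scafeval.layout import GenomeLayout, OrientedContig

        ids = [f"c{i}" for i in range(k)]
        ref = chain(*(f"{c}+" for c in ids))
        singles = GenomeLayout(
            {c: [OrientedContig(c, "+", 100)] for c in ids}
        )
        assert dcj_distance(singles, ref) == k - 1
        assert dcj_distance_bfs(singles, ref) == k - 1

    def test_single_contig_chromosomes_perfect(self):
        ref = multi({f"chr{i}": [f"c{i}+"] for i in range(5)})
        contigs = [(f"c{i}", 100) for i in range(5)]
        report = baseline_report(contigs, ref)
        assert report.edit_distance == 0
        assert report.overall_accuracy == 1.0
        assert report.grouping_accuracy == 1.0

    def test_unknown_contig_rejected(self):
        with pytest.raises(MetricError, match="cX"):
            baseline_report([("cX", 10)], chain("c1+"))
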