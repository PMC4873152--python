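"""Interval algebra: base-pair-exact set operations and the region logic."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aneuscreen.intervals import (
    AneuploidyModel,
    GeneRecord,
    GenomicInterval,
    IntervalError,
    SyntenyMap,
    candidate_gene_set,
    genes_in_segments,
    normalize_segments,
    project_orthologs,
    segment_set_op,
)
from aneuscreen.phenotype import PhenotypeCall

IV = GenomicInterval


def covered_positions(intervals):
    """Brute-force per-base-pair oracle: the set of covered (chrom, pos)."""
    return {
        (iv.chrom, pos) for iv in intervals for pos in range(iv.start, iv.end)
    }


@st.composite
def small_interval_lists(draw):
    n = draw(st.integers(0, 20))
    return [
        IV(
            draw(st.sampled_from(["chrA", "chrB"])),
            (start := draw(st.integers(0, 990))),
            draw(st.integers(start + 1, 1000)),
        )
        for _ in range(n)
    ]


class TestGenomicInterval:
    @pytest.mark.parametrize(
        "start,end", [(20, 10), (10, 10), (-5, 10)], ids=["inverted", "empty", "negative"]
    )
    def test_invalid_coordinates_rejected(self, start, end):
        with pytest.raises(IntervalError):
            IV("chr16", start, end)

    def test_length_and_containment(self):
        outer, inner = IV("chr16", 0, 100), IV("chr16", 40, 60)
        assert len(outer) == 100
        assert outer.contains(inner) and not inner.contains(outer)
        assert outer.overlaps(inner)
        assert not outer.overlaps(IV("chr17", 40, 60))


class TestNormalize:
    @pytest.mark.parametrize(
        "segments,expected",
        [
            ([IV("chr16", 10, 20), IV("chr16", 15, 30)], [IV("chr16", 10, 30)]),
            ([IV("chr16", 10, 20)], [IV("chr16", 10, 20)]),
            (
                [IV("chr16", 0, 5), IV("chr16", 5, 9), IV("chr17", 2, 4)],
                [IV("chr16", 0, 9), IV("chr17", 2, 4)],
            ),
        ],
        ids=["merge-overlap", "identity", "merge-bookended"],
    )
    def test_examples(self, segments, expected):
        assert normalize_segments(segments) == expected

    @given(small_interval_lists())
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_preserves_coverage_and_is_idempotent(self, segments):
        once = normalize_segments(segments)
        assert covered_positions(once) == covered_positions(segments)
        assert normalize_segments(once) == once
        # pairwise disjoint and non-adjacent per chromosome
        for a, b in zip(once, once[1:]):
            assert a.chrom != b.chrom or a.end < b.start


class TestSetOps:
    @pytest.mark.parametrize(
        "a,b,mode,expected",
        [
            ([IV("chr16", 0, 100)], [IV("chr16", 40, 60)], "intersect", [IV("chr16", 40, 60)]),
            (
                [IV("chr16", 0, 100)],
                [IV("chr16", 40, 60)],
                "subtract",
                [IV("chr16", 0, 40), IV("chr16", 60, 100)],
            ),
            (
                [IV("chr16", 0, 10)],
                [IV("chr17", 0, 10)],
                "union",
                [IV("chr16", 0, 10), IV("chr17", 0, 10)],
            ),
        ],
    )
    def test_examples(self, a, b, mode, expected):
        assert segment_set_op(a, b, mode) == expected

    def test_unknown_mode_rejected(self):
        with pytest.raises(IntervalError):
            segment_set_op([], [], "xor")

    @given(small_interval_lists(), small_interval_lists(), st.sampled_from(["union", "intersect", "subtract"]))
    @settings(deadline=None, max_examples=150, derandomize=True)
    def test_agrees_with_per_bp_oracle(self, a, b, mode):
        result = covered_positions(segment_set_op(a, b, mode))
        pa, pb = covered_positions(a), covered_positions(b)
        oracle = {"union": pa | pb, "intersect": pa & pb, "subtract": pa - pb}[mode]
        assert result == oracle


def _gene(gid, chrom, start, end, species="mouse"):
    return GeneRecord(gid, gid.upper(), species, IV(chrom, start, end))


class TestGenesInSegments:
    def test_full_containment(self):
        genes = [_gene("g1", "chr16", 50, 60)]
        assert genes_in_segments(genes, [IV("chr16", 0, 100)], "full") == {"g1"}

    def test_straddling_gene_excluded_under_full_included_under_overlap(self):
        genes = [_gene("g1", "chr16", 90, 110)]
        segments = [IV("chr16", 0, 100)]
        assert genes_in_segments(genes, segments, "full") == frozenset()
        assert genes_in_segments(genes, segments, "any_overlap") == {"g1"}

    def test_chromosome_mismatch_excluded(self):
        genes = [_gene("g1", "chr17", 50, 60)]
        for mode in ("full", "any_overlap"):
            assert genes_in_segments(genes, [IV("chr16", 0, 100)], mode) == frozenset()

    def test_empty_inputs(self):
        assert genes_in_segments([], [IV("chr16", 0, 10)]) == frozenset()
        assert genes_in_segments([_gene("g1", "chr16", 1, 2)], []) == frozenset()


class TestOrthologProjection:
    def test_single_link(self):
        smap = SyntenyMap((("Rcan1_m", "RCAN1_h"),))
        assert project_orthologs({"Rcan1_m"}, smap).mapped == {"RCAN1_h"}

    def test_empty_set(self):
        smap = SyntenyMap((("a", "A"),))
        assert project_orthologs(set(), smap) == (frozenset(), frozenset())

    def test_unlinked_genes_reported_not_lost(self):
        smap = SyntenyMap((("g1_m", "G1_h"),))
        result = project_orthologs({"g1_m", "g2_m"}, smap)
        assert result.mapped == {"G1_h"}
        assert result.dropped == {"g2_m"}

    def test_one_to_one_policy_drops_ambiguous_pairs(self):
        smap = SyntenyMap((("m1", "h1"), ("m1", "h2"), ("m2", "h3")))
        assert smap.pairs == (("m2", "h3"),)
        assert set(smap.dropped_ambiguous) == {("m1", "h1"), ("m1", "h2")}

    def test_keep_all_retains_ambiguity(self):
        smap = SyntenyMap((("m1", "h1"), ("m1", "h2")), policy="keep_all")
        assert len(smap.pairs) == 2

    @given(st.sets(st.integers(0, 30)))
    @settings(deadline=None, derandomize=True)
    def test_round_trip_projection_is_subset(self, indices):
        pairs = tuple((f"m{i}", f"h{i}") for i in range(0, 30, 2))
        smap = SyntenyMap(pairs)
        genes = {f"m{i}" for i in indices}
        fwd = project_orthologs(genes, smap, "mouse_to_human").mapped
        back = project_orthologs(fwd, smap, "human_to_mouse").mapped
        assert back <= genes

    def test_invalid_direction_rejected(self):
        with pytest.raises(IntervalError):
            project_orthologs(set(), SyntenyMap(()), "sideways")


def _call(label):
    return PhenotypeCall(label=label, p_value=0.001 if label != "normoglycaemic" else 0.5,
                         direction={"hyperglycaemic": 1, "hypoglycaemic": -1}.get(label, 0))


def _panel(spans_by_model, n_genes=20):
    """Tiny mouse panel: gene i occupies [i*10, i*10+5) on chrM."""
    genes = [
        _gene(f"m{i}", "chrM", i * 10, i * 10 + 5) for i in range(1, n_genes + 1)
    ] + [
        _gene(f"h{i}", "chrH", i * 10, i * 10 + 5, species="human")
        for i in range(1, n_genes + 1)
    ]
    smap = SyntenyMap(tuple((f"m{i}", f"h{i}") for i in range(1, n_genes + 1)))
    models = [
        AneuploidyModel(
            name=name,
            species="mouse",
            dosage_segments=(IV("chrM", a * 10, b * 10 + 5),),
            phenotype=_call(label),
        )
        for name, (a, b, label) in spans_by_model.items()
    ]
    return models, genes, smap


class TestCandidateGeneSet:
    def test_affected_intersection_minus_unaffected_union(self):
        models, genes, smap = _panel(
            {
                "A": (1, 10, "hyperglycaemic"),
                "B": (5, 15, "hyperglycaemic"),
                "C": (7, 8, "normoglycaemic"),
            }
        )
        result = candidate_gene_set(models, genes, smap)
        assert result.genes == {f"h{i}" for i in (5, 6, 9, 10)}

    def test_single_affected_model_returns_its_projected_set(self):
        models, genes, smap = _panel({"A": (3, 6, "hyperglycaemic")})
        result = candidate_gene_set(models, genes, smap)
        assert result.genes == {f"h{i}" for i in (3, 4, 5, 6)}

    def test_disjoint_affected_models_give_empty_set(self):
        models, genes, smap = _panel(
            {"A": (1, 5, "hyperglycaemic"), "B": (10, 15, "hyperglycaemic")}
        )
        assert candidate_gene_set(models, genes, smap).genes == frozenset()

    def test_hypoglycaemic_model_also_subtracts(self):
        models, genes, smap = _panel(
            {"A": (1, 10, "hyperglycaemic"), "B": (9, 10, "hypoglycaemic")}
        )
        assert candidate_gene_set(models, genes, smap).genes == {
            f"h{i}" for i in range(1, 9)
        }

    def test_human_model_contributes_directly_without_projection(self):
        models, genes, smap = _panel({"A": (1, 10, "hyperglycaemic")})
        tc1_like = AneuploidyModel(
            name="HsModel",
            species="human",
            dosage_segments=(IV("chrH", 90, 105),),  # human genes 9, 10
            phenotype=_call("hypoglycaemic"),
        )
        result = candidate_gene_set(models + [tc1_like], genes, smap)
        assert result.genes == {f"h{i}" for i in range(1, 9)}

    def test_no_affected_model_rejected(self):
        models, genes, smap = _panel({"A": (1, 5, "normoglycaemic")})
        with pytest.raises(ValueError, match="no model carries"):
            candidate_gene_set(models, genes, smap)

    def test_model_without_phenotype_rejected(self):
        models, genes, smap = _panel({"A": (1, 5, "hyperglycaemic")})
        models.append(
            AneuploidyModel("NoCall", "mouse", (IV("chrM", 0, 5),))
        )
        with pytest.raises(ValueError, match="without a phenotype"):
            candidate_gene_set(models, genes, smap)

    @given(
        st.integers(1, 15),
        st.integers(1, 15),
        st.sampled_from(["hyperglycaemic", "normoglycaemic", "hypoglycaemic"]),
    )
    @settings(deadline=None, derandomize=True)
    def test_adding_any_model_never_enlarges_candidates(self, a, b, label):
        models, genes, smap = _panel(
            {"A": (1, 12, "hyperglycaemic"), "B": (4, 15, "hyperglycaemic")}
        )
        base = candidate_gene_set(models, genes, smap).genes
        lo, hi = min(a, b), max(a, b)
        extra = AneuploidyModel(
            "X", "mouse", (IV("chrM", lo * 10, hi * 10 + 5),), _call(label)
        )
        extended = candidate_gene_set(models + [extra], genes, smap).genes
        assert extended <= base
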