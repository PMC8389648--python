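"""Template construction and GSR index, checked against brute-force oracles."""


import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gsreg.gsr import (
    PairOrderTemplate,
    build_template,
    build_templates,
    functionome,
    gsr_index,
    restrict_sets,
)
from gsreg.io import ExpressionMatrix, GeneSet, GeneSetCollection


def oracle_gsr(sample_values: dict, template: PairOrderTemplate) -> float:
    """Brute force: enumerate every unordered pair and count matches."""
    matches = 0
    n_pairs = 0
    for (i, j), direction in zip(template.pairs, template.directions):
        gi, gj = template.genes[i], template.genes[j]
        vi, vj = sample_values[gi], sample_values[gj]
        observed = (vi < vj) if vi != vj else (gi < gj)
        matches += observed == direction
        n_pairs += 1
    return matches / n_pairs


def single_control_template(genes, values):
    frame = pd.DataFrame({"ctrl": list(values)}, index=list(genes))
    return build_template(frame, tuple(genes), set_id="T")


class TestRestrictSets:
    def test_members_intersected_preserving_order(self):
        coll = GeneSetCollection([GeneSet("S", "d", ("C", "A", "B"))])
        matrix = ExpressionMatrix(
            pd.DataFrame({"s": [1.0, 2.0]}, index=["A", "C"]),
            pd.Series({"s": "control"}),
        )
        out = restrict_sets(coll, matrix, min_set_size=2)
        assert out["S"].members == ("C", "A")

    def test_undersized_set_dropped_and_empty_result_is_error(self):
        coll = GeneSetCollection(
            [GeneSet("S", "d", ("A", "Z")), GeneSet("T", "d", ("A", "B"))]
        )
        matrix = ExpressionMatrix(
            pd.DataFrame({"s": [1.0, 2.0]}, index=["A", "B"]),
            pd.Series({"s": "control"}),
        )
        out = restrict_sets(coll, matrix, min_set_size=2)
        assert list(out) == ["T"]
        only_z = GeneSetCollection([GeneSet("S", "d", ("Z", "Y"))])
        with pytest.raises(ValueError, match="no gene sets remain"):
            restrict_sets(only_z, matrix, min_set_size=2)

    def test_min_set_size_below_two_rejected(self, tiny_collection, tiny_matrix):
        with pytest.raises(ValueError, match="min_set_size"):
            restrict_sets(tiny_collection, tiny_matrix, min_set_size=1)


class TestBuildTemplate:
    def test_single_control_yields_full_support(self):
        tpl = single_control_template("ABC", [1.0, 2.0, 3.0])
        assert np.all(tpl.support == 1.0)
        # A<B, A<C, B<C
        assert np.all(tpl.directions)

    def test_majority_vote_and_support(self):
        frame = pd.DataFrame(
            {"c1": [1.0, 2.0], "c2": [1.0, 2.0], "c3": [2.0, 1.0]}, index=["A", "B"]
        )
        tpl = build_template(frame, ("A", "B"))
        assert tpl.directions[0]  # A < B wins 2/3
        assert tpl.support[0] == pytest.approx(2 / 3)

    def test_even_split_stored_as_lexicographic_with_half_support(self):
        frame = pd.DataFrame(
            {"c1": [1.0, 2.0], "c2": [1.0, 2.0], "c3": [2.0, 1.0], "c4": [2.0, 1.0]},
            index=["B", "A"],
        )
        tpl = build_template(frame, ("B", "A"))
        # pair stored as (B, A) in member order; lexicographically A is lower,
        # so the stored "B below A" direction is False with support 0.5
        assert tpl.support[0] == 0.5
        assert not tpl.directions[0]

    def test_within_sample_ties_fall_to_lexicographic_rule(self):
        frame = pd.DataFrame({"c1": [5.0, 5.0]}, index=["B", "A"])
        tpl = build_template(frame, ("B", "A"))
        assert not tpl.directions[0]  # A deemed lower than B

    def test_no_controls_or_missing_gene_is_error(self):
        with pytest.raises(ValueError, match="at least one control"):
            build_template(pd.DataFrame(index=["A", "B"]), ("A", "B"))
        frame = pd.DataFrame({"c": [1.0]}, index=["A"])
        with pytest.raises(ValueError, match="unmeasured"):
            build_template(frame, ("A", "B"))


class TestGsrIndex:
    def test_identical_ordering_scores_one(self):
        tpl = single_control_template("ABCDE", [1, 2, 3, 4, 5])
        assert gsr_index({"A": 10, "B": 20, "C": 30, "D": 40, "E": 50}, tpl) == 1.0

    def test_reversed_ordering_scores_zero(self):
        tpl = single_control_template("ABCDE", [1, 2, 3, 4, 5])
        assert gsr_index({"A": 50, "B": 40, "C": 30, "D": 20, "E": 10}, tpl) == 0.0

    def test_partial_agreement_counts_pairs(self):
        # template A<B<C; sample B<A<C: pair (A,B) discordant, others concordant
        tpl = single_control_template("ABC", [1, 2, 3])
        assert gsr_index({"A": 2, "B": 1, "C": 3}, tpl) == pytest.approx(2 / 3)

    def test_missing_gene_is_error(self):
        tpl = single_control_template("AB", [1, 2])
        with pytest.raises(ValueError, match="missing"):
            gsr_index({"A": 1.0}, tpl)

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            m = rng.integers(2, 7)
            genes = tuple(f"g{i}" for i in range(m))
            n_controls = int(rng.integers(1, 6))
            frame = pd.DataFrame(
                rng.integers(0, 5, size=(m, n_controls)).astype(float),
                index=genes,
                columns=[f"c{i}" for i in range(n_controls)],
            )
            tpl = build_template(frame, genes)
            sample = {g: float(v) for g, v in zip(genes, rng.integers(0, 5, size=m))}
            assert gsr_index(sample, tpl) == oracle_gsr(sample, tpl)

    @settings(deadline=None, derandomize=True)
    @given(
        values=st.lists(
            st.integers(min_value=-50, max_value=50), min_size=3, max_size=6, unique=True
        ),
        scale=st.floats(min_value=0.1, max_value=10),
        shift=st.floats(min_value=-100, max_value=100),
    )
    def test_invariant_under_strictly_increasing_transforms(self, values, scale, shift):
        genes = tuple(f"g{i}" for i in range(len(values)))
        tpl = single_control_template(genes, sorted(float(v) for v in values))
        sample = {g: float(v) for g, v in zip(genes, values)}
        transformed = {g: scale * v + shift for g, v in sample.items()}
        assert gsr_index(sample, tpl) == gsr_index(transformed, tpl)

    def test_consistent_gene_relabelling_leaves_index_unchanged(self):
        rng = np.random.default_rng(5)
        genes = ("a", "b", "c", "d")
        ctrl = rng.normal(size=(4, 3))
        sample = dict(zip(genes, rng.normal(size=4)))
        tpl = build_template(
            pd.DataFrame(ctrl, index=genes, columns=["c1", "c2", "c3"]), genes
        )
        base = gsr_index(sample, tpl)
        # relabel with an order-preserving map so the lexicographic tie rule
        # (the only label-dependent part) is untouched
        mapping = {"a": "w", "b": "x", "c": "y", "d": "z"}
        new_genes = tuple(mapping[g] for g in genes)
        tpl2 = build_template(
            pd.DataFrame(ctrl, index=new_genes, columns=["c1", "c2", "c3"]), new_genes
        )
        assert gsr_index({mapping[g]: v for g, v in sample.items()}, tpl2) == base

    def test_uniform_random_orderings_average_one_half(self):
        genes = tuple(f"g{i}" for i in range(8))
        tpl = single_control_template(genes, range(8))
        rng = np.random.default_rng(0)
        vals = np.array(
            [gsr_index(dict(zip(genes, rng.permutation(np.arange(8.0)))), tpl) for _ in range(10_000)]
        )
        assert abs(vals.mean() - 0.5) < 0.01


class TestFunctionome:
    def test_profile_shape_and_bounds(self, small_cohort):
        matrix, collection, _ = small_cohort
        templates = build_templates(matrix, collection, "control")
        profiles = functionome(matrix, collection, templates)
        assert profiles.shape == (len(matrix.samples), len(collection))
        assert ((profiles >= 0) & (profiles <= 1)).all().all()

    def test_single_control_scores_itself_one_everywhere(self, tiny_matrix, tiny_collection):
        single = tiny_matrix.subset_samples(["c1"])
        templates = build_templates(single, tiny_collection, "control")
        profiles = functionome(single, tiny_collection, templates)
        assert (profiles.loc["c1"] == 1.0).all()

    def test_fully_reversed_sample_scores_zero_everywhere(self, tiny_matrix, tiny_collection):
        sub = tiny_matrix.subset_samples(["c1", "k1"])  # k1 reverses c1 on S1
        templates = build_templates(
            tiny_matrix.subset_samples(["c1"]), tiny_collection, "control"
        )
        profiles = functionome(sub, tiny_collection, templates)
        assert (profiles.loc["k1"] == 0.0).all()

    def test_missing_template_is_error(self, tiny_matrix, tiny_collection):
        with pytest.raises(ValueError, match="no template"):
            functionome(tiny_matrix, tiny_collection, {})
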