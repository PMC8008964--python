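"""Numeric core: normalization, fractions, intensities, radii."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pieglyph import (
    CompositionConfig,
    Embedding,
    ExpressionMatrix,
    GeneGroup,
    GeneListSpec,
    GeneNotFoundError,
    ValidationError,
    build_cell_compositions,
    compute_fractions,
    compute_intensities,
    compute_radius,
    normalize_expression,
    resolve_genes,
)


def make_spec(*sizes, prefix="L"):
    groups = tuple(
        GeneGroup(
            name=f"{prefix}{k}",
            genes=tuple(f"{prefix}{k}_{j}" for j in range(n)),
            color_rule="#0000ff",
        )
        for k, n in enumerate(sizes)
    )
    return GeneListSpec(groups=groups)


class TestNormalizeExpression:
    @pytest.mark.parametrize(
        "x,n_total,n_list,expected",
        [
            (5.0, 7, 7, 5.0),  # single list: factor 1
            (2.0, 12, 4, 6.0),  # 2 * 12 / 4
            (0.0, 12, 8, 0.0),
            (1.5, 3, 1, 4.5),
        ],
    )
    def test_formula(self, x, n_total, n_list, expected):
        assert normalize_expression(x, n_total, n_list) == expected

    def test_linear_in_x(self):
        assert normalize_expression(10.0, 12, 4) == 5 * normalize_expression(2.0, 12, 4)

    @pytest.mark.parametrize("bad", [0, -1])
    def test_zero_list_size_rejected(self, bad):
        with pytest.raises(ValidationError):
            normalize_expression(1.0, 12, bad)

    def test_n_total_smaller_than_list_rejected(self):
        with pytest.raises(ValidationError):
            normalize_expression(1.0, 3, 4)


class TestComputeFractions:
    def test_two_genes_one_list(self):
        spec = make_spec(2)
        fractions, empty = compute_fractions(np.array([1.0, 3.0]), spec)
        assert not empty
        assert fractions == pytest.approx([0.25, 0.75], abs=0)

    def test_unequal_lists_weighted_equally(self):
        # groups of 8 and 4 genes, every gene at the same value: the
        # normalization gives each group exactly half the pie
        spec = make_spec(8, 4)
        fractions, empty = compute_fractions(np.full(12, 3.0), spec)
        assert not empty
        assert fractions[:8].sum() == pytest.approx(0.5, abs=1e-12)
        assert fractions[8:].sum() == pytest.approx(0.5, abs=1e-12)

    def test_all_zero_cell_is_empty(self):
        spec = make_spec(3)
        fractions, empty = compute_fractions(np.zeros(3), spec)
        assert empty
        assert np.all(fractions == 0.0)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            compute_fractions(np.array([1.0, -1.0]), make_spec(2))

    def test_wrong_length_rejected(self):
        with pytest.raises(ValidationError):
            compute_fractions(np.array([1.0]), make_spec(2))

    @given(
        sizes=st.lists(st.integers(1, 6), min_size=2, max_size=4),
        value=st.integers(1, 1000),
    )
    @settings(max_examples=200, derandomize=True)
    def test_property_list_size_neutrality(self, sizes, value):
        """g groups, every gene at a common value -> each group sums to 1/g."""
        spec = make_spec(*sizes)
        fractions, _ = compute_fractions(np.full(sum(sizes), float(value)), spec)
        start = 0
        for n in sizes:
            assert fractions[start : start + n].sum() == pytest.approx(
                1.0 / len(sizes), abs=1e-12
            )
            start += n

    @given(
        values=st.lists(st.integers(0, 10_000), min_size=2, max_size=5),
        scale=st.floats(1e-3, 1e3, allow_nan=False, allow_infinity=False),
    )
    @settings(max_examples=200, derandomize=True)
    def test_property_scale_invariance(self, values, scale):
        spec = make_spec(len(values))
        vals = np.array(values, dtype=float)
        if vals.sum() == 0:
            return
        f1, _ = compute_fractions(vals, spec)
        f2, _ = compute_fractions(vals * scale, spec)
        assert f1 == pytest.approx(f2.tolist(), rel=1e-12)

    @given(
        data=st.data(),
        sizes=st.lists(st.integers(1, 3), min_size=1, max_size=3).filter(
            lambda s: sum(s) <= 5
        ),
    )
    @settings(max_examples=300, derandomize=True)
    def test_property_exact_rational_oracle(self, data, sizes):
        """For <= 5 integer-count genes, float fractions equal the exact
        rational Xnorm_i / sum_j Xnorm_j bit-for-bit after conversion."""
        n = sum(sizes)
        values = data.draw(
            st.lists(st.integers(0, 100_000), min_size=n, max_size=n)
        )
        if sum(values) == 0:
            return
        spec = make_spec(*sizes)
        n_total = n
        list_sizes = [sz for sz in sizes for _ in range(sz)]
        xnorm = [
            Fraction(v) * n_total / n_list for v, n_list in zip(values, list_sizes)
        ]
        total = sum(xnorm)
        expected = [float(x / total) for x in xnorm]
        got, empty = compute_fractions(np.array(values, dtype=float), spec)
        assert not empty
        assert got.tolist() == expected  # bitwise


class TestComputeIntensities:
    def make_matrix(self, column):
        return ExpressionMatrix(
            cell_ids=tuple(f"c{i}" for i in range(len(column))),
            gene_ids=("G",),
            values=np.array(column, dtype=float).reshape(-1, 1),
        )

    def test_scaled_by_max_at_quantile_one(self):
        matrix = self.make_matrix([1.0, 2.0, 4.0])
        spec = GeneListSpec(groups=(GeneGroup("g", ("G",), "#ff0000"),))
        out = compute_intensities(matrix, spec, clip_quantile=1.0)
        assert out[:, 0] == pytest.approx([0.25, 0.5, 1.0])

    def test_constant_gene_all_ones_and_zero_stays_zero(self):
        matrix = self.make_matrix([3.0, 3.0, 0.0])
        spec = GeneListSpec(groups=(GeneGroup("g", ("G",), "#ff0000"),))
        out = compute_intensities(matrix, spec, clip_quantile=1.0)
        assert out[:, 0] == pytest.approx([1.0, 1.0, 0.0])

    def test_never_expressed_gene_is_zero_everywhere(self):
        matrix = self.make_matrix([0.0, 0.0])
        spec = GeneListSpec(groups=(GeneGroup("g", ("G",), "#ff0000"),))
        out = compute_intensities(matrix, spec, clip_quantile=0.99)
        assert np.all(out == 0.0)

    def test_clipping_caps_outliers(self):
        matrix = self.make_matrix(list(range(1, 101)))
        spec = GeneListSpec(groups=(GeneGroup("g", ("G",), "#ff0000"),))
        out = compute_intensities(matrix, spec, clip_quantile=0.5)
        assert out[-1, 0] == 1.0  # clipped
        assert np.all(np.diff(out[:, 0]) >= 0)  # monotone in expression


class TestComputeRadius:
    def test_endpoints_and_midpoint(self):
        assert compute_radius(0.0, 10.0, 1.0, 3.0) == 1.0
        assert compute_radius(10.0, 10.0, 1.0, 3.0) == 3.0
        assert compute_radius(2.5, 10.0, 1.0, 3.0) == pytest.approx(2.0)

    def test_clips_above_cap(self):
        assert compute_radius(50.0, 10.0, 1.0, 3.0) == 3.0

    def test_monotone(self):
        radii = [compute_radius(t, 10.0, 0.5, 2.0) for t in np.linspace(0, 12, 25)]
        assert all(b >= a for a, b in zip(radii, radii[1:]))

    def test_bad_cap_rejected(self):
        with pytest.raises(ValidationError):
            compute_radius(1.0, 0.0, 1.0, 2.0)


class TestResolveGenes:
    def test_all_present_unchanged(self, toy_matrix, toy_spec):
        assert resolve_genes(toy_matrix, toy_spec) == toy_spec

    def test_missing_gene_dropped_with_warning(self, toy_matrix, caplog):
        spec = GeneListSpec(
            groups=(GeneGroup("g", ("GA", "GB", "GHOST"), "#112233"),)
        )
        with caplog.at_level("WARNING"):
            resolved = resolve_genes(toy_matrix, spec, policy="drop_warn")
        assert resolved.groups[0].genes == ("GA", "GB")
        assert "GHOST" in caplog.text

    def test_missing_gene_error_policy(self, toy_matrix):
        spec = GeneListSpec(groups=(GeneGroup("g", ("GA", "GHOST"), "#112233"),))
        with pytest.raises(GeneNotFoundError):
            resolve_genes(toy_matrix, spec, policy="error")

    def test_group_emptied_is_error(self, toy_matrix):
        spec = GeneListSpec(groups=(GeneGroup("g", ("GHOST",), "#112233"),))
        with pytest.raises(ValidationError):
            resolve_genes(toy_matrix, spec, policy="drop_warn")

    def test_case_insensitive_keeps_matrix_spelling(self, toy_matrix):
        spec = GeneListSpec(groups=(GeneGroup("g", ("ga", "gb"), "#112233"),))
        resolved = resolve_genes(toy_matrix, spec, case_insensitive=True)
        assert resolved.groups[0].genes == ("GA", "GB")

    def test_case_sensitive_by_default(self, toy_matrix):
        spec = GeneListSpec(groups=(GeneGroup("g", ("ga", "GB"), "#112233"),))
        resolved = resolve_genes(toy_matrix, spec, policy="drop_warn")
        assert resolved.groups[0].genes == ("GB",)


class TestBuildCellCompositions:
    def test_toy_matches_componentwise(self, toy_matrix, toy_embedding, toy_spec):
        comps = build_cell_compositions(
            toy_matrix, toy_embedding, toy_spec,
            CompositionConfig(clip_quantile=1.0, r_min=0.1, r_max=0.4),
        )
        assert [c.cell_id for c in comps] == ["c1", "c2", "c3"]
        # c1: (1, 0) -> (1.0, 0.0); c2: (2, 2) -> (0.5, 0.5); c3: (0, 5) -> (0, 1)
        assert [e.fraction for e in comps[0].entries] == [1.0, 0.0]
        assert [e.fraction for e in comps[1].entries] == [0.5, 0.5]
        assert [e.fraction for e in comps[2].entries] == [0.0, 1.0]
        assert not any(c.is_empty for c in comps)

    def test_entry_order_is_gene_list_order(self, toy_matrix, toy_embedding):
        spec = GeneListSpec(groups=(GeneGroup("g", ("GB", "GA"), "#112233"),))
        comps = build_cell_compositions(toy_matrix, toy_embedding, spec)
        assert [e.gene for e in comps[0].entries] == ["GB", "GA"]

    def test_empty_cell_gets_small_dot_radius(self, toy_embedding):
        matrix = ExpressionMatrix(
            cell_ids=("c1", "c2", "c3"),
            gene_ids=("GA", "GB"),
            values=np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0]]),
        )
        spec = make_spec(2)
        spec = GeneListSpec(
            groups=(GeneGroup("g", ("GA", "GB"), "#112233"),)
        )
        comps = build_cell_compositions(
            matrix, toy_embedding, spec, CompositionConfig(r_min=0.2, r_max=0.8)
        )
        assert comps[0].is_empty
        assert comps[0].radius == pytest.approx(0.1)

    def test_misaligned_inputs_rejected(self, toy_matrix, toy_spec):
        emb = Embedding(cell_ids=("c3", "c1", "c2"), coords=np.zeros((3, 2)))
        with pytest.raises(ValidationError):
            build_cell_compositions(toy_matrix, emb, toy_spec)

    def test_deterministic(self, fixture_dataset):
        matrix, embedding, _, spec = fixture_dataset
        a = build_cell_compositions(matrix, embedding, spec)
        b = build_cell_compositions(matrix, embedding, spec)
        assert a == b

    def test_fraction_conservation_on_fixture(self, fixture_dataset):
        matrix, embedding, _, spec = fixture_dataset
        comps = build_cell_compositions(matrix, embedding, spec)
        for comp in comps:
            total = sum(e.fraction for e in comp.entries)
            if comp.is_empty:
                assert total == 0.0
            else:
                assert abs(total - 1.0) <= 1e-9
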