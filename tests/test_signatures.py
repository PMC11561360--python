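"""Signature construction: DEG filtering, set algebra, refinement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oligoscreen.signatures import (
    DEGTable,
    FormatError,
    RefineConfig,
    SignedGeneSet,
    apply_expression_floor,
    build_lineage_bundle,
    exclude_signatures,
    filter_degs,
    intersect_signatures,
    refine_combined,
)

from conftest import make_set


def deg_table(rows, fc_col="fc", **extra):
    frame = pd.DataFrame(rows, columns=["gene", fc_col, "pvalue"])
    for k, v in extra.items():
        frame[k] = v
    return DEGTable(frame)


signed_entries = st.dictionaries(
    st.sampled_from([f"g{i}" for i in range(12)]),
    st.sampled_from([1, -1]),
    max_size=12,
)


class TestFilterDegs:
    def test_threshold_examples(self):
        table = deg_table(
            [("G1", 1.5, 0.01), ("G2", 1.1, 0.01), ("G3", 1.5, 0.2), ("G4", 0.5, 0.01)]
        )
        out = filter_degs(table, fc_min=1.2, p_max=0.05, direction="both")
        assert out.entries == {"G1": 1, "G4": -1}

    def test_direction_restriction(self):
        table = deg_table([("G1", 1.5, 0.01), ("G4", 0.5, 0.01)])
        assert filter_degs(table, direction="up").entries == {"G1": 1}
        assert filter_degs(table, direction="down").entries == {"G4": -1}

    def test_empty_table(self):
        assert len(filter_degs(deg_table([]))) == 0

    def test_boundaries_are_strict(self):
        # fc == fc_min and p == p_max are both excluded
        table = deg_table([("G5", 1.2, 0.01), ("G6", 1.5, 0.05)])
        assert len(filter_degs(table, fc_min=1.2, p_max=0.05)) == 0

    def test_down_cutoff_is_reciprocal(self):
        table = deg_table([("A", 1 / 1.2, 0.01), ("B", 0.8, 0.01)])
        out = filter_degs(table, fc_min=1.2)
        assert out.entries == {"B": -1}  # 1/1.2 sits exactly on the boundary

    def test_missing_fc_column_is_format_error(self):
        with pytest.raises(FormatError, match="fold-change"):
            DEGTable(pd.DataFrame({"gene": ["A"], "pvalue": [0.1]}))

    def test_nonpositive_fc_names_row(self):
        with pytest.raises(ValueError, match="row 1"):
            deg_table([("A", 1.5, 0.01), ("B", -2.0, 0.01)])

    def test_invalid_thresholds_rejected(self):
        table = deg_table([("A", 1.5, 0.01)])
        with pytest.raises(ValueError):
            filter_degs(table, fc_min=1.0)
        with pytest.raises(ValueError):
            filter_degs(table, p_max=0.0)

    def test_monotone_in_thresholds(self, rng):
        genes = [f"g{i}" for i in range(200)]
        frame = pd.DataFrame(
            {
                "gene": genes,
                "fc": np.exp(rng.normal(0, 0.7, 200)),
                "pvalue": rng.uniform(0, 1, 200),
            }
        )
        table = DEGTable(frame)
        base = filter_degs(table, fc_min=1.2, p_max=0.1).genes()
        assert filter_degs(table, fc_min=1.5, p_max=0.1).genes() <= base
        assert filter_degs(table, fc_min=1.2, p_max=0.01).genes() <= base

    def test_log2_table_equals_linear_table(self, rng):
        fc = np.exp(rng.normal(0, 0.7, 100))
        pv = rng.uniform(0, 1, 100)
        genes = [f"g{i}" for i in range(100)]
        linear = DEGTable(pd.DataFrame({"gene": genes, "fc": fc, "pvalue": pv}))
        logt = DEGTable(
            pd.DataFrame({"gene": genes, "log2fc": np.log2(fc), "pvalue": pv})
        )
        assert filter_degs(linear).entries == filter_degs(logt).entries


class TestExpressionFloor:
    def test_strict_boundary(self):
        table = deg_table(
            [("A", 2, 0.01), ("B", 2, 0.01), ("C", 2, 0.01)],
            expression=[0.4, 0.5, 0.6],
        )
        out = apply_expression_floor(table, 0.5)
        assert list(out.frame["gene"]) == ["C"]

    def test_zero_floor_identity(self):
        table = deg_table([("A", 2, 0.01)], expression=[1.0])
        assert apply_expression_floor(table, 0.0) == table

    def test_all_below_floor_warns(self, caplog):
        table = deg_table([("A", 2, 0.01)], expression=[0.1])
        with caplog.at_level("WARNING"):
            out = apply_expression_floor(table, 0.5)
        assert len(out) == 0
        assert any("floor" in r.message for r in caplog.records)

    def test_missing_column_is_error_not_noop(self):
        table = deg_table([("A", 2, 0.01)])
        with pytest.raises(FormatError, match="expression"):
            apply_expression_floor(table, 0.5)


class TestSetAlgebra:
    def test_intersect_concordant(self):
        a, b = make_set({"A": 1, "B": 1}), make_set({"B": 1, "C": 1})
        assert intersect_signatures(a, b).entries == {"B": 1}

    def test_intersect_discordant_reported(self, caplog):
        with caplog.at_level("WARNING"):
            out = intersect_signatures(make_set({"A": 1}), make_set({"A": -1}))
        assert len(out) == 0
        assert out.provenance[-1]["discordant"] == ["A"]

    def test_intersect_idempotent(self):
        x = make_set({"A": 1, "B": -1})
        assert intersect_signatures(x, x) == x

    def test_exclude(self):
        out = exclude_signatures(make_set({"A": 1, "B": 1}), make_set({"B": 1}))
        assert out.entries == {"A": 1}

    def test_exclude_empty_identity(self):
        x = make_set({"A": 1, "B": -1})
        assert exclude_signatures(x, make_set({})) == x

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a=signed_entries, b=signed_entries)
    def test_partition_identity(self, a, b):
        """intersect ⊎ exclude ⊎ discordant reconstructs the base exactly."""
        sa, sb = make_set(dict(a)), make_set(dict(b))
        inter = intersect_signatures(sb, sa)
        excl = exclude_signatures(sb, sa)
        discordant = {
            g for g in sa.genes() & sb.genes() if sa.entries[g] != sb.entries[g]
        }
        assert inter.genes() & excl.genes() == set()
        assert inter.genes() | excl.genes() | discordant == sb.genes()
        if not discordant:  # the clean two-part identity
            merged = {**inter.entries, **excl.entries}
            assert merged == sb.entries


class TestRefineCombined:
    def test_disjoint_union_default(self):
        out = refine_combined([make_set({"A": 1}), make_set({"B": 1})])
        assert out.entries == {"A": 1, "B": 1}

    def test_conflict_drop(self):
        out = refine_combined([make_set({"A": 1}), make_set({"A": -1})])
        assert len(out) == 0
        assert out.provenance[-1]["dropped_conflict"] == ["A"]

    def test_conflict_majority(self):
        sources = [make_set({"A": 1}), make_set({"A": 1}), make_set({"A": -1})]
        out = refine_combined(sources, RefineConfig(conflict="majority"))
        assert out.entries == {"A": 1}

    def test_min_support(self):
        sources = [make_set({"A": 1, "B": 1}), make_set({"A": 1})]
        out = refine_combined(sources, {"min_support": 2})
        assert out.entries == {"A": 1}

    def test_unknown_criterion_key_rejected(self):
        with pytest.raises(ValueError, match="unknown refine criteria"):
            refine_combined([make_set({"A": 1})], {"min_suport": 2})


class TestLineageBundle:
    def test_partition_and_union(self):
        progenitor = make_set({"A": 1, "B": -1, "C": 1})
        mature = make_set({"B": -1, "C": -1, "D": 1})
        bundle = build_lineage_bundle(progenitor, mature)
        assert bundle.specification.entries == {"B": -1}
        # C is discordant between stages: it stays on the differentiation side
        assert bundle.differentiation.genes() == {"C", "D"}
        assert bundle.specification.genes() | bundle.differentiation.genes() == mature.genes()
        # combined drops the cross-stage direction conflict (C) by default
        assert bundle.combined.genes() == {"A", "B", "D"}


class TestSignedGeneSet:
    def test_symbol_normalization(self):
        s = SignedGeneSet(entries={" olig2 ": 1})
        assert s.entries == {"OLIG2": 1}

    def test_conflicting_signs_rejected(self):
        with pytest.raises(ValueError, match="both"):
            SignedGeneSet(entries={"a": 1, "A": -1})

    def test_flip_is_involution(self):
        s = make_set({"A": 1, "B": -1})
        assert s.flipped().flipped() == s
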