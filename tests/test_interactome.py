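import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_records
from tissueppi.interactome import (
    FilterConfig,
    build_ego_network,
    filter_confidence,
    filter_interaction_type,
    tissue_subnetwork,
)
from tissueppi.io_formats import InteractionRecord, parse_expression


def rec(a, b, conf, types=("MI:0407",)):
    return InteractionRecord(id_a=a, id_b=b, confidence=conf,
                             interaction_types=set(types))


class TestFilterConfig:
    def test_defaults_match_study_settings(self):
        cfg = FilterConfig()
        assert cfg.min_confidence == 0.72 and cfg.strict_greater
        assert cfg.allowed_interaction_types == {"MI:0407"}
        assert cfg.nx_min == 1.0

    def test_allowed_must_be_subset_of_broad(self):
        with pytest.raises(ValueError, match="subset"):
            FilterConfig(allowed_interaction_types=frozenset({"MI:9999"}))

    @pytest.mark.parametrize("kwargs", [
        {"min_confidence": 1.5}, {"min_confidence": -0.1}, {"nx_min": -1.0},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FilterConfig(**kwargs)


class TestFilterConfidence:
    def test_strict_boundary(self):
        records = [rec("S", "A", 0.73), rec("S", "B", 0.72),
                   rec("S", "C", 0.71)]
        kept = filter_confidence(records, FilterConfig())
        assert [r.confidence for r in kept] == [0.73]

    def test_inclusive_boundary(self):
        records = [rec("S", "A", 0.73), rec("S", "B", 0.72),
                   rec("S", "C", 0.71)]
        kept = filter_confidence(records, FilterConfig(strict_greater=False))
        assert sorted(r.confidence for r in kept) == [0.72, 0.73]

    def test_threshold_one_keeps_nothing(self):
        records = [rec("S", "A", 1.0), rec("S", "B", 0.99)]
        assert filter_confidence(records, FilterConfig(min_confidence=1.0)) == []

    def test_count_matches_linear_scan(self):
        rng = np.random.default_rng(5)
        records = random_records(rng, n=200)
        kept = filter_confidence(records, FilterConfig())
        assert len(kept) == sum(1 for r in records if r.confidence > 0.72)

    def test_order_preserving_and_input_unmodified(self):
        records = [rec("S", "A", 0.9), rec("S", "B", 0.1), rec("S", "C", 0.8)]
        before = list(records)
        kept = filter_confidence(records, FilterConfig())
        assert [r.partner_of("S") for r in kept] == ["A", "C"]
        assert records == before


class TestFilterInteractionType:
    def test_intersection_semantics(self):
        excluded = rec("S", "A", 0.9, types=("MI:0915",))
        kept = rec("S", "B", 0.9, types=("MI:0407", "MI:0915"))
        out = filter_interaction_type([excluded, kept], {"MI:0407"})
        assert out == [kept]

    def test_untyped_record_excluded(self):
        out = filter_interaction_type([rec("S", "A", 0.9, types=())],
                                      {"MI:0407"})
        assert out == []

    def test_planted_direct_subset_recovered(self):
        """A planted 42-of-118 direct subset survives the type filter."""
        rng = np.random.default_rng(11)
        direct = [rec("S", f"D{i}", 0.9, types=("MI:0407",))
                  for i in range(42)]
        other_types = ["MI:0915", "MI:0914", "MI:0403"]
        others = [rec("S", f"O{i}", 0.9, types=(str(rng.choice(other_types)),))
                  for i in range(76)]
        records = direct + others
        out = filter_interaction_type(records, {"MI:0407"})
        assert {r.partner_of("S") for r in out} == {f"D{i}" for i in range(42)}


class TestBuildEgoNetwork:
    def test_partner_partner_edges_excluded(self):
        records = [rec("S", "A", 0.9), rec("S", "B", 0.8), rec("A", "B", 0.7)]
        net = build_ego_network(records, "S")
        assert net.nodes == {"S", "A", "B"}
        assert net.edges() == {("A", "S"), ("B", "S")}

    def test_empty_records_single_node(self):
        net = build_ego_network([], "S")
        assert net.nodes == {"S"} and net.edges() == set()

    def test_seed_absent_from_records(self):
        net = build_ego_network([rec("A", "B", 0.9)], "S")
        assert net.nodes == {"S"} and net.edges() == set()

    @pytest.mark.parametrize("k", [1, 5, 20])
    def test_star_graph_has_k_interactors(self, k):
        records = [rec("S", f"L{i}", 0.9) for i in range(k)]
        net = build_ego_network(records, "S")
        assert net.n_interactors == k


EXPR = ("gene\tkidney\tlung\n"
        "AAA\t0.0\t5.0\n"
        "BBB\t2.0\t3.0\n"
        "CCC\t1.0\t0.5\n")


class TestTissueSubnetwork:
    @pytest.fixture()
    def ego(self):
        return build_ego_network(
            [rec("S", "AAA", 0.9), rec("S", "BBB", 0.9), rec("S", "CCC", 0.9)],
            "S")

    @pytest.fixture()
    def expression(self):
        return parse_expression(io.StringIO(EXPR))

    def test_non_expressed_node_removed(self, ego, expression):
        net = tissue_subnetwork(ego, expression, "kidney", FilterConfig())
        assert "AAA" not in net.nodes  # NX 0.0 < 1.0
        assert net.interactors == {"BBB", "CCC"}  # NX 1.0 counts as expressed
        assert net.tissue == "kidney"

    def test_all_expressed_is_identity(self, ego, expression):
        net = tissue_subnetwork(ego, expression, "lung",
                                FilterConfig(nx_min=0.0))
        assert net == ego

    def test_missing_gene_treated_as_not_expressed(self, expression):
        ego = build_ego_network([rec("S", "ZZZ", 0.9), rec("S", "BBB", 0.9)],
                                "S")
        net = tissue_subnetwork(ego, expression, "kidney", FilterConfig())
        assert net.interactors == {"BBB"}

    def test_seed_always_retained(self, expression):
        ego = build_ego_network([rec("S", "AAA", 0.9)], "S")
        net = tissue_subnetwork(ego, expression, "kidney", FilterConfig())
        assert net.nodes == {"S"}

    def test_unknown_tissue_error_lists_available(self, ego, expression):
        with pytest.raises(KeyError, match="kidney"):
            tissue_subnetwork(ego, expression, "spleen", FilterConfig())

    def test_survivors_match_generator_truth(self, synthetic_dataset):
        from tissueppi.io_formats import parse_mitab
        from tissueppi.interactome import build_tissue_interactomes
        ds = synthetic_dataset
        records = parse_mitab(ds.mitab)
        expression = parse_expression(ds.expression)
        tissues = list(ds.truth.interactors_by_tissue)
        nets = build_tissue_interactomes(records, ds.truth.seed_gene,
                                         expression, tissues)
        for t in tissues:
            assert nets[t].interactors == ds.truth.interactors_by_tissue[t]


@st.composite
def record_sets(draw):
    n = draw(st.integers(min_value=0, max_value=30))
    type_pool = ["MI:0407", "MI:0915", "MI:0914", "MI:0403"]
    records = []
    for i in range(n):
        types = draw(st.sets(st.sampled_from(type_pool), max_size=3))
        conf = draw(st.floats(min_value=0.0, max_value=1.0,
                              allow_nan=False, width=32))
        records.append(InteractionRecord(id_a="S", id_b=f"P{i:03d}",
                                         confidence=conf,
                                         interaction_types=types))
    return records


class TestFilterAlgebra:
    """Idempotence, commutativity and monotonicity of the cascade."""

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(records=record_sets())
    def test_confidence_filter_idempotent_and_monotone(self, records):
        cfg = FilterConfig()
        once = filter_confidence(records, cfg)
        assert filter_confidence(once, cfg) == once
        assert set(r.pair for r in once) <= set(r.pair for r in records)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(records=record_sets())
    def test_type_filter_idempotent_and_monotone(self, records):
        allowed = {"MI:0407"}
        once = filter_interaction_type(records, allowed)
        assert filter_interaction_type(once, allowed) == once
        assert set(r.pair for r in once) <= set(r.pair for r in records)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(records=record_sets())
    def test_confidence_and_type_filters_commute(self, records):
        cfg = FilterConfig()
        allowed = {"MI:0407"}
        ct = filter_interaction_type(filter_confidence(records, cfg), allowed)
        tc = filter_confidence(filter_interaction_type(records, allowed), cfg)
        assert ct == tc


def test_cascade_shape_is_monotone(synthetic_dataset):
    """Broad network >= tissue-filtered broad >= direct tissue network."""
    from tissueppi.io_formats import parse_mitab
    ds = synthetic_dataset
    records = parse_mitab(ds.mitab)
    expression = parse_expression(ds.expression)
    cfg = FilterConfig()
    confident = filter_confidence(records, cfg)
    broad = filter_interaction_type(confident, cfg.broad_interaction_types)
    broad_net = build_ego_network(broad, ds.truth.seed_gene)
    tissue = list(ds.truth.interactors_by_tissue)[0]
    broad_tissue = tissue_subnetwork(broad_net, expression, tissue, cfg)
    direct = filter_interaction_type(confident, cfg.allowed_interaction_types)
    direct_net = tissue_subnetwork(build_ego_network(direct, ds.truth.seed_gene),
                                   expression, tissue, cfg)
    assert (broad_net.n_interactors >= broad_tissue.n_interactors
            >= direct_net.n_interactors)
    assert direct_net.interactors <= broad_tissue.interactors
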