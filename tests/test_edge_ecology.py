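import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coocnet.edge_ecology import (
    EDGE_CLASSES,
    GENERALIST,
    SPECIALIST_GENERALIST_PAIR,
    SPECIALIST_SPECIALIST_PAIR,
    classify_edges,
    edge_type_correlations,
    edge_type_taxa_profile,
    environment_similarity,
    hub_presence_clustering,
    identify_hubs,
    jaccard_distance,
    negative_edge_profile,
    omission_analysis,
    omission_score,
)
from coocnet.io_model import AbundanceTable
from coocnet.synthetic import PlantedDesign, PlantedEdge, generate_dataset

from conftest import make_network


@pytest.fixture
def subnet_trio():
    soil = make_network("soil", [("a", "b"), ("b", "c"), ("c", "d")])
    water = make_network("saline water", [("a", "b"), ("a", "c")])
    gut = make_network("animal distal gut", [("x", "y")])
    return {"soil": soil, "saline water": water, "animal distal gut": gut}


class TestClassifyEdges:
    def test_three_classes(self, subnet_trio):
        cls = classify_edges(subnet_trio)
        # (a,b) present in soil + water -> generalist
        assert cls.class_of[("a", "b")] == GENERALIST
        # (b,c) only in soil, both endpoints in >= 2 subnetworks
        assert cls.class_of[("b", "c")] == SPECIALIST_GENERALIST_PAIR
        # (x,y) only in gut; endpoints unique to it
        assert cls.class_of[("x", "y")] == SPECIALIST_SPECIALIST_PAIR

    def test_environment_sets(self, subnet_trio):
        cls = classify_edges(subnet_trio)
        assert cls.environments_of[("a", "b")] == ("saline water", "soil")
        assert cls.environments_of[("x", "y")] == ("animal distal gut",)

    def test_proportions_sum_to_one(self, subnet_trio):
        cls = classify_edges(subnet_trio)
        for env, props in cls.proportions.items():
            assert sum(props.values()) == pytest.approx(1.0)
            assert set(props) == set(EDGE_CLASSES)

    def test_requires_two_subnetworks(self):
        with pytest.raises(ValueError):
            classify_edges({"soil": make_network("soil", [("a", "b")])})


@pytest.fixture(scope="module")
def exchangeable_table():
    envs = frozenset(["soil", "rhizosphere"])
    design = PlantedDesign(
        n_environments=2, samples_per_environment=60, n_esvs=10,
        planted_edges=[PlantedEdge("ESV1", "ESV2", 0.9, envs)], seed=33,
    )
    table, _ = generate_dataset(design)
    return table


class TestOmissionScore:

    def test_exchangeable_environment_not_local(self, exchangeable_table):
        """When the edge holds everywhere, removing one environment barely moves rho."""
        r = omission_score(exchangeable_table, ("ESV1", "ESV2"), "soil",
                           n_random=200, seed=0)
        assert r.ratio == pytest.approx(1.0, abs=0.15)

    def test_edge_driven_by_environment(self):
        """Correlation existing only in one environment collapses when it is omitted."""
        design = PlantedDesign(
            n_environments=2, samples_per_environment=100, n_esvs=10,
            planted_edges=[PlantedEdge("ESV1", "ESV2", 0.95, frozenset(["soil"]))],
            seed=7,
        )
        table, _ = generate_dataset(design)
        r = omission_score(table, ("ESV1", "ESV2"), "soil", n_random=300, seed=1)
        assert r.ratio < 0.5
        assert r.p < 0.05

    def test_p_counting_rule_strict(self, exchangeable_table):
        r = omission_score(exchangeable_table, ("ESV1", "ESV2"), "soil",
                           n_random=100, seed=3)
        assert 0.0 <= r.p <= 1.0

    def test_batch_analysis_sets_local_flag(self):
        design = PlantedDesign(
            n_environments=2, samples_per_environment=100, n_esvs=10,
            planted_edges=[PlantedEdge("ESV1", "ESV2", 0.95, frozenset(["soil"]))],
            seed=7,
        )
        table, _ = generate_dataset(design)
        results = omission_analysis(table, [(("ESV1", "ESV2"), "soil")],
                                    n_random=300, seed=0)
        assert results[0].local is (results[0].ratio < 1
                                    and results[0].p_adjusted < 0.05)

    def test_unknown_environment_raises(self, exchangeable_table):
        with pytest.raises(ValueError):
            omission_score(exchangeable_table, ("ESV1", "ESV2"), "mars")


class TestEnvironmentSimilarity:
    def test_identical_edge_sets_distance_zero(self):
        n1 = make_network("soil", [("a", "b"), ("b", "c")])
        n2 = make_network("saline water", [("a", "b"), ("b", "c")])
        envs, dist, _ = environment_similarity({"soil": n1, "saline water": n2})
        assert dist[0, 1] == 0.0

    def test_disjoint_edge_sets_distance_one(self):
        n1 = make_network("soil", [("a", "b")])
        n2 = make_network("saline water", [("x", "y")])
        _, dist, _ = environment_similarity({"soil": n1, "saline water": n2})
        assert dist[0, 1] == 1.0

    def test_hand_computed_jaccard(self):
        assert jaccard_distance({"a", "b", "c"}, {"b", "c", "d"}) == pytest.approx(0.5)

    @given(st.lists(st.sets(st.integers(0, 15)), min_size=3, max_size=3))
    @settings(deadline=None, max_examples=100)
    def test_jaccard_is_a_metric(self, sets):
        a, b, c = sets
        assert jaccard_distance(a, a) == 0.0
        assert jaccard_distance(a, b) == jaccard_distance(b, a)
        assert (jaccard_distance(a, c)
                <= jaccard_distance(a, b) + jaccard_distance(b, c) + 1e-12)

    def test_two_group_cut(self, subnet_trio):
        envs, _, groups = environment_similarity(subnet_trio)
        assert set(groups.values()) == {1, 2}


class TestEdgeTypeProfiles:
    def test_single_edge_class_includes_both_esvs(self, subnet_trio):
        cls = classify_edges(subnet_trio)
        rng = np.random.default_rng(0)
        esvs = sorted({v for k in cls.class_of for v in k})
        table = AbundanceTable(esvs, [f"S{j}" for j in range(5)],
                               rng.integers(1, 100, size=(len(esvs), 5)))
        profiles = edge_type_taxa_profile(cls, table, top_n=50)
        # (c,d) and (x,y) are the specialist-pair edges; all four endpoints
        assert set(profiles[SPECIALIST_SPECIALIST_PAIR]["top_esvs"]) == {"c", "d", "x", "y"}

    def test_top_n_ranking_oracle(self, subnet_trio):
        cls = classify_edges(subnet_trio)
        esvs = sorted({v for k in cls.class_of for v in k})
        counts = np.diag(np.arange(1, len(esvs) + 1))  # strictly increasing abundance
        table = AbundanceTable(esvs, [f"S{j}" for j in range(len(esvs))], counts)
        mean_abund = table.mean_relative_abundance()
        profiles = edge_type_taxa_profile(cls, table, top_n=2)
        for cls_name, prof in profiles.items():
            members = sorted({v for k, c in cls.class_of.items()
                              if c == cls_name for v in k})
            expected = sorted(members, key=lambda v: (-mean_abund[v], v))[:2]
            assert prof["top_esvs"] == expected


class TestEdgeTypeCorrelations:
    def test_complementary_proportions_anticorrelate(self):
        props = {}
        for i, env in enumerate(["e1", "e2", "e3", "e4", "e5"]):
            g = 0.1 * (i + 1)
            props[env] = {GENERALIST: g,
                          SPECIALIST_GENERALIST_PAIR: 0.2,
                          SPECIALIST_SPECIALIST_PAIR: 0.8 - g}
        out = edge_type_correlations(props)
        rho, _ = out[(GENERALIST, SPECIALIST_SPECIALIST_PAIR)]
        assert rho == pytest.approx(-1.0)
        rho_const, _ = out[(GENERALIST, SPECIALIST_GENERALIST_PAIR)]
        assert np.isnan(rho_const)

    def test_requires_four_subnetworks(self):
        props = {e: dict.fromkeys(EDGE_CLASSES, 1 / 3) for e in ["a", "b", "c"]}
        with pytest.raises(ValueError):
            edge_type_correlations(props)


class TestHubs:
    def test_star_center(self):
        net = make_network("soil", [("hub", leaf) for leaf in "abcde"])
        assert identify_hubs(net, 1) == ["hub"]

    def test_distinct_degrees_sort_oracle(self):
        net = make_network("soil", [("a", "b"), ("a", "c"), ("a", "d"),
                                    ("b", "c"), ("b", "d"), ("c", "d"),
                                    ("a", "e")])
        degrees = dict(net.graph.degree)
        expected = sorted(degrees, key=lambda v: (-degrees[v], v))[:3]
        assert identify_hubs(net, 3) == expected

    def test_fewer_vertices_than_k(self):
        net = make_network("soil", [("a", "b"), ("b", "c")])
        assert identify_hubs(net, 10) == ["b", "a", "c"]

    def test_input_order_invariance(self):
        edges = [("a", "b"), ("a", "c"), ("b", "c"), ("a", "d")]
        n1 = make_network("soil", edges)
        n2 = make_network("soil", list(reversed(edges)))
        assert identify_hubs(n1, 2) == identify_hubs(n2, 2)


class TestHubPresenceClustering:
    def test_identical_hub_sets(self):
        out = hub_presence_clustering({"soil": ["a", "b"], "water": ["a", "b"]})
        assert out["distance"][0, 1] == 0.0
        assert out["specialist_hubs"] == []

    def test_disjoint_hub_sets_all_specialist(self):
        out = hub_presence_clustering({"soil": ["a"], "water": ["b"]})
        assert out["specialist_hubs"] == ["a", "b"]

    def test_specialist_count_enumeration(self):
        hubs = {"e1": ["a", "b", "c"], "e2": ["b", "c", "d"], "e3": ["c", "e"]}
        out = hub_presence_clustering(hubs)
        # a: only e1; d: only e2; e: only e3 -> 3 specialists
        assert out["specialist_hubs"] == ["a", "d", "e"]
        assert out["presence"].shape == (5, 3)


class TestNegativeEdges:
    def test_percentage(self):
        edges = [(f"v{i}", f"v{i+1}") for i in range(10)]
        net = make_network("soil", edges, signs={("v0", "v1"): -1})
        out = negative_edge_profile({"soil": net})["soil"]
        assert out["percentage"] == pytest.approx(10.0)

    def test_no_negative_edges(self):
        net = make_network("soil", [("a", "b")])
        assert negative_edge_profile({"soil": net})["soil"]["percentage"] == 0.0

    def test_endpoint_class_composition_counts_both_vertices(self):
        net = make_network("soil", [("u", "v"), ("u", "w")],
                           signs={("u", "v"): -1, ("u", "w"): -1})
        taxonomy = {"u": ("B", "P", "A", "o", "f", "g"),
                    "v": ("B", "P", "B", "o", "f", "g"),
                    "w": ("B", "P", "C", "o", "f", "g")}
        out = negative_edge_profile({"soil": net}, taxonomy=taxonomy)["soil"]
        assert out["composition"] == {"A": 2, "B": 1, "C": 1}

    def test_zero_edge_subnetwork_undefined(self):
        net = make_network("soil", [])
        assert np.isnan(negative_edge_profile({"soil": net})["soil"]["percentage"])
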