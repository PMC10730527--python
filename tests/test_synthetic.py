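"""Synthetic-world generator: determinism, planted structure, file output."""

import filecmp

import networkx as nx
import numpy as np
import pytest

from anatomod.network import read_string_links
from anatomod.ontology import (
    AnnotationTable,
    collect_original_annotations,
    parse_obo,
)
from anatomod.synthetic import (
    SyntheticConfig,
    generate_ontology,
    generate_species_network,
    generate_world,
    write_world,
)


class TestConfig:
    def test_probability_domain(self):
        with pytest.raises(ValueError):
            SyntheticConfig(p_in=1.5)
        with pytest.raises(ValueError):
            SyntheticConfig(annotated_fraction=-0.1)

    def test_module_must_fit(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_proteins=10, module_size=20)

    def test_tree_size_formula(self):
        assert SyntheticConfig(depth=3, branching=2).n_tree_terms == 15


class TestGenerateOntology:
    def test_size_and_typed_extras(self):
        cfg = SyntheticConfig(depth=3, branching=2)
        g, ea, eb = generate_ontology(cfg)
        # 15-term is_a tree + embryonic term + 2 parts + 2 precursors
        assert len(g.terms) == 20
        assert ("is_a" not in
                [r for *_, r in g.graph.out_edges(ea.part, keys=True)])
        assert (ea.part, ea.target, "part_of") in g.graph.edges(keys=True)
        assert (ea.precursor, ea.target, "develops_from") in \
            g.graph.edges(keys=True)

    def test_seed_determinism(self):
        cfg = SyntheticConfig(seed=3)
        g1, *_ = generate_ontology(cfg)
        g2, *_ = generate_ontology(cfg)
        assert sorted(g1.graph.edges(keys=True)) == \
            sorted(g2.graph.edges(keys=True))

    def test_acyclic_over_random_configs(self):
        rng = np.random.default_rng(44)
        for _ in range(100):
            cfg = SyntheticConfig(
                seed=int(rng.integers(0, 10_000)),
                depth=int(rng.integers(2, 5)),
                branching=int(rng.integers(2, 4)),
            )
            g, *_ = generate_ontology(cfg)
            assert nx.is_directed_acyclic_graph(nx.DiGraph(g.graph))


class TestGenerateAnnotations:
    def test_original_hidden_split(self):
        cfg = SyntheticConfig(seed=5, module_size=40, annotated_fraction=0.75)
        world = generate_world(cfg)
        assert len(world.original_a) == 30
        assert len(world.hidden_a) == 10
        assert world.original_a | world.hidden_a == world.module_a

    def test_closure_recovers_exactly_the_originals(self):
        world = generate_world(SyntheticConfig(seed=6))
        got = collect_original_annotations(
            world.ontology, world.ann_a, world.entity_a.target
        )
        assert got == world.original_a

    def test_hidden_members_carry_no_target_annotation(self):
        world = generate_world(SyntheticConfig(seed=7))
        entity_terms = {world.entity_a.target, world.entity_a.part,
                        world.entity_a.precursor}
        p2t = world.ann_a.protein_to_terms()
        for p in world.hidden_a:
            assert not (p2t.get(p, set()) & entity_terms)


class TestGenerateSpeciesNetwork:
    def test_within_module_density(self):
        cfg = SyntheticConfig(seed=9, n_proteins=500, module_size=60,
                              hub_bias=0.0, noise_edges=0.0)
        rng = np.random.default_rng(9)
        proteins = [f"P{i}" for i in range(cfg.n_proteins)]
        members = proteins[:60]
        net = generate_species_network(cfg, members, set(), proteins, rng)
        mset = set(members)
        internal = sum(
            1 for u, v, _ in net.edges() if u in mset and v in mset
        )
        n_pairs = 60 * 59 / 2
        sigma = np.sqrt(n_pairs * cfg.p_in * (1 - cfg.p_in))
        assert abs(internal - n_pairs * cfg.p_in) < 3 * sigma

    def test_no_hub_bias_means_equal_expected_degree(self):
        cfg = SyntheticConfig(seed=10, hub_bias=0.0, noise_edges=0.0)
        rng = np.random.default_rng(10)
        proteins = [f"P{i}" for i in range(cfg.n_proteins)]
        members = proteins[: cfg.module_size]
        conserved = set(members[:18])
        net = generate_species_network(cfg, members, conserved, proteins, rng)
        from anatomod.network import weighted_degree

        deg_c = np.mean([weighted_degree(net, p) for p in conserved])
        deg_s = np.mean([weighted_degree(net, p)
                         for p in members if p not in conserved])
        # same distribution: means differ only by sampling noise
        assert abs(deg_c - deg_s) < 2.0

    def test_weight_ranges_respected(self):
        cfg = SyntheticConfig(seed=11, noise_edges=0.0)
        world = generate_world(cfg)
        mset = world.module_a
        for u, v, w in world.net_a.edges():
            if u in mset and v in mset:
                assert cfg.w_in[0] <= w <= cfg.w_in[1]
            else:
                assert cfg.w_out[0] <= w <= cfg.w_out[1]

    def test_undetectable_configuration_warns(self, caplog):
        import logging

        cfg = SyntheticConfig(seed=1, n_proteins=30, module_size=5,
                              p_in=0.01, p_out=0.05)
        proteins = [f"P{i}" for i in range(30)]
        with caplog.at_level(logging.WARNING):
            generate_species_network(cfg, proteins[:5], set(), proteins,
                                     np.random.default_rng(0))
        assert any("undetectable" in r.message for r in caplog.records)


class TestGenerateWorld:
    def test_conserved_pair_arithmetic(self):
        cfg = SyntheticConfig(seed=12, module_size=40, conserved_fraction=0.3)
        world = generate_world(cfg)
        assert len(world.conserved_a) == 12
        assert len(world.conserved_b) == 12
        fwd = world.orthologs.a_to_b()
        for a in world.conserved_a:
            assert fwd[a] & world.module_b

    def test_specific_members_never_map_into_other_module(self):
        world = generate_world(SyntheticConfig(seed=13))
        fwd = world.orthologs.a_to_b()
        for a in world.module_a - world.conserved_a:
            assert not (fwd.get(a, set()) & world.module_b)

    def test_duplication_rate(self):
        cfg = SyntheticConfig(seed=14, n_proteins=500,
                              duplication_rate=0.25)
        world = generate_world(cfg)
        back = world.orthologs.b_to_a()
        n_dup = sum(1 for copies in back.values() if len(copies) >= 2)
        n_genes = len(back)
        rate = n_dup / n_genes
        sigma = np.sqrt(0.25 * 0.75 / n_genes)
        assert abs(rate - 0.25) < 4 * sigma

    def test_seed_determinism_byte_identical_files(self, tmp_path):
        for d in ("w1", "w2"):
            write_world(generate_world(SyntheticConfig(seed=15)), tmp_path / d)
        mismatch = []
        for f in sorted((tmp_path / "w1").iterdir()):
            if not filecmp.cmp(f, tmp_path / "w2" / f.name, shallow=False):
                mismatch.append(f.name)
        assert mismatch == []

    def test_ground_truth_round_trips_through_files(self, tmp_path):
        world = generate_world(SyntheticConfig(seed=16))
        paths = write_world(world, tmp_path)
        g = parse_obo(paths["ontology"].read_text())
        assert g.terms == world.ontology.terms
        ann = AnnotationTable.read_tsv(paths["annotations_a"])
        assert ann.proteins == world.ann_a.proteins
        net = read_string_links(paths["links_a"])
        assert net.n_edges() == world.net_a.n_edges()
        # score quantization to 1/1000 on write
        for u, v, w in world.net_a.sorted_edges():
            assert net.weight(u, v) == pytest.approx(w, abs=5e-4)

    def test_pipeline_recovers_planted_conserved_labels(self):
        from anatomod.comparison import classify_conserved
        from anatomod.modules import assemble_module
        from anatomod.prediction import (
            loo_cross_validate,
            predict_candidates,
            select_score_cutoff,
        )

        world = generate_world(SyntheticConfig(seed=17))
        modules = {}
        for label, net, ann, entity in (
            ("a", world.net_a, world.ann_a, world.entity_a),
            ("b", world.net_b, world.ann_b, world.entity_b),
        ):
            originals = collect_original_annotations(
                world.ontology, ann, entity.target
            )
            cv = loo_cross_validate(net, originals)
            cutoff = select_score_cutoff(cv, 0.7)
            predicted = predict_candidates(net, originals, cutoff)
            modules[label] = assemble_module(
                net, entity.target, originals, predicted
            )
        ca, _, cb, _, _ = classify_conserved(
            modules["a"], modules["b"], world.orthologs
        )
        recovered = len(ca & world.conserved_a) / len(world.conserved_a)
        assert recovered >= 0.8
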