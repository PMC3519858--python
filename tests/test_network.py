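"""Interaction loading, perturbed-network reconstruction, module
assignment and the module-level overlay scores."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ranetkit.enrichment import GeneSetAnnotation
from ranetkit.errors import EmptySelectionError, FormatError
from ranetkit.network import (
    NetworkModule,
    build_network,
    load_interactions,
    module_enrichment_score,
    overlay_signature,
    reconstruct_perturbed_network,
    assign_network_modules,
    target_enrichment_score,
    write_graphml,
    write_sif,
)


def ann(term, genes):
    return GeneSetAnnotation(term, f"process:{term}", "process", frozenset(genes))


class TestLoadInteractions:
    def test_dedup_and_self_loop_drop(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tB\nB\tA\nA\tA\n")
        net = load_interactions(p)
        assert net.n_edges == 1
        assert net.load_report["n_self_loops_dropped"] == 1
        assert net.load_report["n_duplicates_dropped"] == 1

    def test_sif_line_with_relation_tag(self, tmp_path):
        p = tmp_path / "edges.sif"
        p.write_text("A pp B C\n")
        net = load_interactions(p)
        assert net.neighbors("A") == {"B", "C"}
        assert net.graph.edges["A", "B"]["source"] == "pp"

    def test_empty_file_gives_empty_network(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("")
        assert load_interactions(p).nodes == set()

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tB\nBROKEN\n")
        with pytest.raises(FormatError, match=":2"):
            load_interactions(p)


class TestReconstruction:
    def ppi(self):
        return build_network(
            [("A", "C", "pp"), ("B", "E", "pp"), ("C", "D", "pp"), ("A", "B", "pp")]
        )

    def test_seeds_and_interactors_by_rule(self):
        # A,B annotated; C core and adjacent to seed A; E not core
        net = reconstruct_perturbed_network(
            ["A", "B", "C", "D2"], [ann("M", ["A", "B"])], self.ppi()
        )
        assert net.nodes == {"A", "B", "C"}
        assert net.graph.nodes["C"]["role"] == "interactor"
        assert net.graph.nodes["A"]["role"] == "seed"

    def test_annotated_core_gene_is_always_seed(self):
        net = reconstruct_perturbed_network(
            ["A", "C"], [ann("M", ["A", "C"])], self.ppi()
        )
        assert net.graph.nodes["C"]["role"] == "seed"

    def test_no_seeds_raises(self):
        with pytest.raises(EmptySelectionError):
            reconstruct_perturbed_network(["Z"], [ann("M", ["A"])], self.ppi())

    def test_every_interactor_touches_a_seed(self):
        rng = np.random.default_rng(0)
        genes = [f"n{i}" for i in range(60)]
        edges = [
            (genes[int(rng.integers(60))], genes[int(rng.integers(60))], "pp") for _ in range(150)
        ]
        ppi = build_network([e for e in edges if e[0] != e[1]])
        core = [g for g in genes[:30] if g in ppi.nodes]
        terms = [ann("M", core[:8])]
        net = reconstruct_perturbed_network(core, terms, ppi)
        seeds = {n for n in net.nodes if net.graph.nodes[n]["role"] == "seed"}
        for n in net.nodes - seeds:
            assert ppi.neighbors(n) & seeds

    def test_edge_order_invariance(self):
        edges = [("A", "C", "pp"), ("B", "E", "pp"), ("C", "D", "pp"), ("A", "B", "pp")]
        n1 = reconstruct_perturbed_network(["A", "B", "C"], [ann("M", ["A", "B"])], build_network(edges))
        n2 = reconstruct_perturbed_network(
            ["A", "B", "C"], [ann("M", ["A", "B"])], build_network(edges[::-1])
        )
        assert n1.nodes == n2.nodes
        assert set(n1.graph.edges) == set(n2.graph.edges)


class TestModuleAssignment:
    def test_annotated_node_joins_its_terms(self):
        ppi = build_network([("A", "B", "pp")])
        net = reconstruct_perturbed_network(["A", "B"], [ann("M1", ["A", "B"])], ppi)
        modules = assign_network_modules(net, [ann("M1", ["A", "B"])])
        assert modules[0].genes == {"A", "B"}

    def test_interactor_majority_and_tie_rules(self):
        edges = [("I", "m1", "pp"), ("I", "m2", "pp"), ("I", "c1", "pp"),
                 ("J", "m1", "pp"), ("J", "c1", "pp")]
        ppi = build_network(edges)
        terms = [ann("MR", ["m1", "m2"]), ann("CC", ["c1"])]
        core = ["m1", "m2", "c1", "I", "J"]
        net = reconstruct_perturbed_network(core, terms, ppi)
        modules = {m.module_id: m.genes for m in assign_network_modules(net, terms)}
        assert "I" in modules["MR"] and "I" not in modules["CC"]  # 2 MR vs 1 CC
        assert "J" in modules["MR"] and "J" in modules["CC"]  # 1-1 tie joins both


class TestModuleScores:
    def module(self, n=10, prefix="m"):
        return NetworkModule("M", {f"{prefix}{i}" for i in range(n)})

    def test_disjoint_overlay_scores_zero(self):
        s = module_enrichment_score(self.module(), ["x1"], 242, 983)
        assert s.score == 0.0

    def test_printed_formula_toy_case(self):
        mod = self.module(10)
        overlay = list(mod.genes)[:5]
        s = module_enrichment_score(mod, overlay, network_size=242, core_set_size=983)
        assert s.score == pytest.approx((5 / 10) / (242 / 983), abs=1e-6)
        assert s.score == pytest.approx(2.0310, abs=1e-4)

    def test_ratios_cancel_when_overlay_is_module(self):
        mod = self.module(7)
        s = module_enrichment_score(mod, mod.genes, network_size=100, core_set_size=100)
        assert s.score == pytest.approx(1.0)

    def test_conventional_variant_inverts_background(self):
        mod = self.module(10)
        overlay = list(mod.genes)[:5]
        s = module_enrichment_score(mod, overlay, 242, 983, conventional=True)
        assert s.score == pytest.approx((5 / 10) / (983 / 242), abs=1e-6)

    @given(st.integers(1, 6), st.integers(1, 4))
    @settings(max_examples=20, deadline=None)
    def test_scale_consistency(self, overlap, mult):
        base = {f"g{i}" for i in range(10)}
        overlay = {f"g{i}" for i in range(overlap)}
        small = module_enrichment_score(NetworkModule("M", base), overlay, 242, 983)
        big_genes = base | {f"h{i}" for i in range((mult - 1) * 10)}
        big_overlay = overlay | {f"h{i}" for i in range((mult - 1) * overlap)}
        # grow module and overlap by the same factor: score unchanged
        grown = {f"g{i}" for i in range(10 * mult)}
        grown_overlay = {f"g{i}" for i in range(overlap * mult)}
        big = module_enrichment_score(NetworkModule("M", grown), grown_overlay, 242, 983)
        assert big.score == pytest.approx(small.score)

    def test_zero_module_size_raises(self):
        with pytest.raises(ValueError):
            module_enrichment_score(NetworkModule("M", set()), ["x"], 10, 10)

    @pytest.mark.parametrize(
        "targets,expected",
        [([], 0.0), (["m0", "m1"], 0.25), ([f"m{i}" for i in range(8)], 1.0)],
    )
    def test_target_enrichment_fraction(self, targets, expected):
        mod = NetworkModule("M", {f"m{i}" for i in range(8)})
        assert target_enrichment_score(mod, targets).score == pytest.approx(expected)


class TestOverlay:
    def net4(self):
        return reconstruct_perturbed_network(
            ["A", "B", "C", "D"],
            [ann("M", ["A", "B", "C", "D"])],
            build_network([("A", "B", "pp"), ("C", "D", "pp")]),
        )

    def test_empty_overlay_all_false(self):
        summary = overlay_signature(self.net4(), [], "sig")
        assert summary["fraction"] == 0.0

    def test_full_overlay_fraction_one(self):
        summary = overlay_signature(self.net4(), ["A", "B", "C", "D"], "sig")
        assert summary["fraction"] == 1.0

    def test_partial_overlay_fraction(self):
        net = self.net4()
        summary = overlay_signature(net, ["A", "C"], "sig")
        assert summary["fraction"] == 0.5
        assert net.graph.nodes["A"]["overlay_sig"] is True
        assert net.graph.nodes["B"]["overlay_sig"] is False


class TestExports:
    def test_sif_and_graphml_written(self, tmp_path):
        ppi = build_network([("A", "B", "pp"), ("B", "C", "pp")])
        net = reconstruct_perturbed_network(["A", "B", "C"], [ann("M", ["A", "B", "C"])], ppi)
        assign_network_modules(net, [ann("M", ["A", "B", "C"])])
        sif = tmp_path / "net.sif"
        gml = tmp_path / "net.graphml"
        write_sif(net, sif)
        write_graphml(net, gml)
        assert "A\tpp\tB" in sif.read_text()
        reload = load_interactions(sif)
        assert reload.nodes == net.nodes
        assert gml.stat().st_size > 0
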