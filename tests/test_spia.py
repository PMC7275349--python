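"""Perturbation propagation, its bootstrap null, and enrichment records."""

import math
from fractions import Fraction

import numpy as np
import pytest

from pathdr.model import (
    ContractError,
    Edge,
    GeneSignature,
    PathwayGraph,
    RunConfig,
    SingularPathwayError,
)
from pathdr.spia import (
    combine_p,
    p_nde,
    p_pert,
    run_enrichment,
    run_ora,
    simulate_null_pathways,
    solve_perturbation,
)


def _graph(members, edges, pid="P1"):
    return PathwayGraph(
        database="db",
        pathway_id=pid,
        members=frozenset(members),
        edges=tuple(
            Edge(s, t, b, "activation" if b > 0 else "inhibition")
            for s, t, b in edges
        ),
    )


def random_graph(rng, n_max=8):
    """A random signed graph for oracle comparisons (may be singular)."""
    n = int(rng.integers(2, n_max + 1))
    members = [f"g{i}" for i in range(n)]
    edges = []
    seen = set()
    for _ in range(int(rng.integers(1, 2 * n))):
        u, v = rng.choice(n, size=2)  # self-loops allowed
        if (u, v) in seen:
            continue
        seen.add((u, v))
        beta = float(rng.choice([-1.0, 1.0]))
        edges.append((members[u], members[v], beta))
    return _graph(members, edges), members


def oracle_pf(graph, delta_e):
    """Independent dense solve: assemble (I - B) by looping over edges."""
    members = sorted(graph.members)
    idx = {g: i for i, g in enumerate(members)}
    outdeg = {}
    for e in graph.edges:
        outdeg[e.source] = outdeg.get(e.source, 0) + 1
    A = np.eye(len(members))
    for e in graph.edges:
        A[idx[e.target], idx[e.source]] -= e.beta / outdeg[e.source]
    de = np.array([delta_e.get(g, 0.0) for g in members])
    if np.linalg.svd(A, compute_uv=False)[-1] < 1e-10:
        return None, None
    pf = np.linalg.solve(A, de)
    return members, pf


class TestSolvePerturbation:
    def test_edgeless_pathway_passes_effects_through(self):
        g = _graph(["a", "b"], [])
        sol = solve_perturbation(g, {"a": 1.0, "b": -2.0})
        assert sol.pf == {"a": 1.0, "b": -2.0}
        assert sol.acc == {"a": 0.0, "b": 0.0}
        assert sol.t_a == 0.0

    def test_activating_chain_accumulates_downstream(self):
        g = _graph(["A", "B"], [("A", "B", 1.0)])
        sol = solve_perturbation(g, {"A": 1.0, "B": 0.0})
        assert sol.pf == pytest.approx({"A": 1.0, "B": 1.0})
        assert sol.acc == pytest.approx({"A": 0.0, "B": 1.0})
        assert sol.t_a == pytest.approx(1.0)

    def test_inhibiting_chain_flips_the_sign(self):
        g = _graph(["A", "B"], [("A", "B", -1.0)])
        sol = solve_perturbation(g, {"A": 1.0, "B": 0.0})
        assert sol.pf == pytest.approx({"A": 1.0, "B": -1.0})
        assert sol.t_a == pytest.approx(-1.0)

    def test_genes_without_upstream_edges_have_zero_accumulation(self, rng):
        for _ in range(50):
            g, members = random_graph(rng)
            oracle_members, pf = oracle_pf(g, {})
            de = {m: float(rng.normal()) for m in members}
            try:
                sol = solve_perturbation(g, de)
            except SingularPathwayError:
                continue
            with_upstream = {e.target for e in g.edges}
            for m in members:
                if m not in with_upstream:
                    assert sol.acc[m] == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_dense_oracle(self, rng):
        checked = 0
        for _ in range(200):
            g, members = random_graph(rng)
            de = {m: float(rng.normal()) for m in members}
            oracle_members, pf_expected = oracle_pf(g, de)
            if pf_expected is None:
                with pytest.raises(SingularPathwayError):
                    solve_perturbation(g, de)
                continue
            sol = solve_perturbation(g, de)
            got = np.array([sol.pf[m] for m in oracle_members])
            assert np.max(np.abs(got - pf_expected)) < 1e-9
            checked += 1
        assert checked > 100

    def test_linearity_in_delta_e(self, rng):
        g, members = random_graph(rng)
        de = {m: float(rng.normal()) for m in members}
        try:
            base = solve_perturbation(g, de)
        except SingularPathwayError:
            pytest.skip("drew a singular graph")
        for c in (2.0, -3.5, 0.25):
            scaled = solve_perturbation(g, {m: c * v for m, v in de.items()})
            assert scaled.t_a == pytest.approx(c * base.t_a, rel=1e-12, abs=1e-12)

    def test_two_cycle_of_activations_is_singular(self):
        g = _graph(["A", "B"], [("A", "B", 1.0), ("B", "A", 1.0)])
        with pytest.raises(SingularPathwayError):
            solve_perturbation(g, {"A": 1.0, "B": 0.0})


class TestPNde:
    def test_matches_exact_fraction_sum(self):
        # P(X >= 3) for universe 20, pathway 5, 4 DE genes
        total = math.comb(20, 4)
        expected = sum(
            Fraction(math.comb(5, k) * math.comb(15, 4 - k), total) for k in (3, 4)
        )
        assert p_nde(20, 5, 4, 3) == pytest.approx(float(expected), rel=1e-12)

    def test_zero_overlap_is_certain(self):
        assert p_nde(100, 10, 5, 0) == 1.0

    def test_pathway_equal_to_universe_forces_overlap(self):
        assert p_nde(10, 10, 4, 4) == pytest.approx(1.0)

    def test_margin_violation_rejected(self):
        with pytest.raises(ContractError):
            p_nde(20, 5, 4, 5)


class TestPPert:
    def test_edgeless_pathway_gives_p_one(self, rng):
        g = _graph(["a", "b", "c"], [])
        p, med = p_pert(g, {"a": 2.0}, n_boot=99, rng=rng)
        assert p == 1.0 and med == 0.0

    def test_all_zero_effects_give_p_one(self, rng):
        g = _graph(["a", "b"], [("a", "b", 1.0)])
        assert p_pert(g, {"a": 0.0, "b": 0.0}, n_boot=50, rng=rng) == (1.0, 0.0)

    def test_same_seed_reproduces_p(self):
        g = _graph(
            ["a", "b", "c", "d"],
            [("a", "b", 1.0), ("b", "c", -1.0), ("a", "d", 1.0)],
        )
        de = {"a": 1.5, "c": -0.5}
        p1, m1 = p_pert(g, de, 200, np.random.default_rng(42))
        p2, m2 = p_pert(g, de, 200, np.random.default_rng(42))
        assert (p1, m1) == (p2, m2)

    def test_p_is_never_zero_and_at_most_one(self, rng):
        g = _graph(["a", "b", "c"], [("a", "b", 1.0), ("b", "c", 1.0)])
        p, _ = p_pert(g, {"a": 100.0}, n_boot=50, rng=rng)
        assert 1 / 51 <= p <= 1.0


class TestCombineP:
    def test_identity_at_one(self):
        assert combine_p(1.0, 1.0) == 1.0

    def test_closed_form_value(self):
        c = 0.05 * 0.05
        assert combine_p(0.05, 0.05) == pytest.approx(c - c * math.log(c), rel=1e-12)

    def test_bounded_between_product_and_one(self, rng):
        for _ in range(100):
            a, b = rng.uniform(1e-9, 1.0, size=2)
            pg = combine_p(float(a), float(b))
            assert a * b <= pg <= 1.0

    def test_rejects_out_of_range(self):
        with pytest.raises(ContractError):
            combine_p(0.0, 0.5)


class TestRunEnrichment:
    def _two_pathway_setup(self):
        p1 = _graph(["a", "b", "c"], [("a", "b", 1.0), ("b", "c", 1.0)], pid="P1")
        p2 = _graph(["x", "y", "z"], [("x", "y", 1.0)], pid="P2")
        universe = frozenset("abcxyz") | frozenset(f"u{i}" for i in range(30))
        return [p1, p2], universe

    def test_strongly_hit_pathway_scores_lower(self):
        pathways, universe = self._two_pathway_setup()
        sig = GeneSignature(
            "e", frozenset("abcx"), {"a": 2.0, "b": 1.5, "c": 1.0, "x": 0.5}
        )
        records = run_enrichment(sig, universe, pathways, RunConfig(n_boot=200))
        by_id = {r.pathway_id: r for r in records}
        assert by_id["P1"].p_g < by_id["P2"].p_g
        assert by_id["P1"].status == "activated"

    def test_negating_effects_flips_t_a_and_status(self):
        pathways, universe = self._two_pathway_setup()
        sig = GeneSignature("e", frozenset("abc"), {"a": 2.0, "b": -1.5})
        neg = GeneSignature("e", frozenset("abc"), {"a": -2.0, "b": 1.5})
        rec = run_enrichment(sig, universe, pathways, RunConfig(n_boot=100))
        rec_neg = run_enrichment(neg, universe, pathways, RunConfig(n_boot=100))
        for r, rn in zip(rec, rec_neg):
            assert rn.t_a == pytest.approx(-r.t_a, rel=1e-12)
            if r.status != "none":
                assert {r.status, rn.status} == {"activated", "inhibited"}

    def test_empty_signature_yields_no_records(self):
        pathways, universe = self._two_pathway_setup()
        sig = GeneSignature("e", frozenset(), {})
        assert run_enrichment(sig, universe, pathways, RunConfig()) == []

    def test_pathway_without_de_members_is_omitted(self):
        pathways, universe = self._two_pathway_setup()
        sig = GeneSignature("e", frozenset("abc"), {"a": 1.0})
        records = run_enrichment(sig, universe, pathways, RunConfig(n_boot=50))
        assert {r.pathway_id for r in records} == {"P1"}

    def test_fdr_is_bh_over_run_p_g(self):
        pathways, universe = self._two_pathway_setup()
        sig = GeneSignature(
            "e", frozenset("abcxy"), {"a": 2.0, "b": 1.0, "x": -1.0, "y": 0.5}
        )
        records = run_enrichment(sig, universe, pathways, RunConfig(n_boot=100))
        from pathdr.overlap import bh_adjust

        np.testing.assert_allclose(
            [r.p_g_fdr for r in records], bh_adjust([r.p_g for r in records])
        )


class TestRunOra:
    def test_direction_is_dominant_effect_sign_and_p_is_overrepresentation(self):
        p1 = _graph(["a", "b", "c"], [], pid="P1")
        universe = frozenset("abc") | frozenset(f"u{i}" for i in range(20))
        sig = GeneSignature("e", frozenset("ab"), {"a": -2.0, "b": 0.5})
        (rec,) = run_ora(sig, universe, [p1])
        assert rec.status == "inhibited"
        assert rec.p_pert == 1.0
        assert rec.p_nde == pytest.approx(p_nde(23, 3, 2, 2))
        assert rec.p_g == pytest.approx(combine_p(rec.p_nde, 1.0))


class TestSimulateNullPathways:
    def test_preserves_size_and_edge_count(self, small_world, rng):
        sim = simulate_null_pathways(small_world.pathways, small_world.universe, rng)
        for true, fake in zip(small_world.pathways, sim):
            assert len(fake.members) == len(true.members)
            assert len(fake.edges) == len(true.edges)
            assert fake.pathway_id.endswith(":sim")

    def test_fixed_seed_reproduces_draw(self, small_world):
        a = simulate_null_pathways(
            small_world.pathways, small_world.universe, np.random.default_rng(3)
        )
        b = simulate_null_pathways(
            small_world.pathways, small_world.universe, np.random.default_rng(3)
        )
        assert [g.members for g in a] == [g.members for g in b]

    def test_expected_de_overlap_matches_uniform_sampling(self, rng):
        universe = frozenset(f"g{i}" for i in range(200))
        de = frozenset(f"g{i}" for i in range(40))  # 20% of the universe
        template = _graph([f"g{i}" for i in range(10)], [], pid="T")
        n_draws = 600
        overlaps = [
            len(simulate_null_pathways([template], universe, rng)[0].members & de)
            for _ in range(n_draws)
        ]
        expected = 10 * 40 / 200
        se = np.std(overlaps, ddof=1) / np.sqrt(n_draws)
        assert abs(np.mean(overlaps) - expected) < 3 * se + 1e-9
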