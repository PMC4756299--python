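"""Network diagnostics against independent oracles."""

import math

import numpy as np
import pytest

import planknet as pk
from planknet.balancer import balance_from_rates
from planknet.indicators import (
    ascendency,
    keystoneness,
    mantel_correlation,
    mixed_trophic_impact,
    predatory_cycles,
    shannon_diversity,
    trophic_levels,
    weighted_degree,
)
from planknet.model_core import FlowMatrix


# ---------------------------------------------------------------------------
# trophic levels
# ---------------------------------------------------------------------------


def test_chain_trophic_levels(balanced_chain3):
    tl = trophic_levels(balanced_chain3)
    assert tl == pytest.approx({1: 1.0, 2: 2.0, 3: 3.0})


def test_omnivore_trophic_level():
    nodes = [
        pk.FunctionalNode(1, "P", pk.TrophicStatus.AUTOTROPH, pk.Layer.SURFACE,
                          100.0, production_rate_range=(1.0, 1.0)),
        pk.FunctionalNode(2, "Z", pk.TrophicStatus.HETEROTROPH, pk.Layer.SURFACE,
                          10.0, production_rate_range=(0.2, 0.2),
                          consumption_rate_range=(1.0, 1.0)),
        pk.FunctionalNode(3, "O", pk.TrophicStatus.HETEROTROPH, pk.Layer.SURFACE,
                          2.0, production_rate_range=(0.1, 0.1),
                          consumption_rate_range=(0.5, 0.5)),
    ]
    diet = pk.DietMatrix([1, 2, 3], {(1, 2): 1.0, (1, 3): 0.5, (2, 3): 0.5})
    model = pk.build_model(nodes, diet)
    rates = model.midpoint_rates()
    bal = balance_from_rates(model, rates)
    tl = trophic_levels(bal)
    assert tl[3] == pytest.approx(2.5)


def _power_iteration_tl(bal, tol=1e-12):
    """Independent fixed-point oracle: TL = 1 + D^T TL with mixotroph damping."""
    model = bal.model
    n = model.n
    F = bal.flows.flows
    living = model.living_mask
    intake = F[:, :].sum(axis=0)
    D = np.zeros((n, n))
    for j in range(n):
        if model.nodes[j].is_consumer and intake[j] > 0:
            D[:, j] = F[:, j] / intake[j]
    p_phi = model.p_phi
    tl = np.ones(n)
    for _ in range(10_000):
        new = np.ones(n)
        for j in range(n):
            if model.nodes[j].is_consumer:
                new[j] = 1.0 + (1.0 - p_phi[j]) * float(D[:, j] @ tl)
        if np.max(np.abs(new - tl)) < tol:
            return new
        tl = new
    return tl


def test_trophic_levels_match_power_iteration(balanced_random_web):
    tl = trophic_levels(balanced_random_web)
    oracle = _power_iteration_tl(balanced_random_web)
    model = balanced_random_web.model
    for nid, v in tl.items():
        assert v == pytest.approx(oracle[model.index(nid)], abs=1e-8)


def test_producers_and_detritus_at_tl1(balanced_random_web):
    tl = trophic_levels(balanced_random_web)
    for nd in balanced_random_web.model.nodes:
        if nd.trophic_status in (pk.TrophicStatus.AUTOTROPH, pk.TrophicStatus.DETRITUS):
            assert tl[nd.node_id] == pytest.approx(1.0)
        else:
            assert tl[nd.node_id] >= 1.0


# ---------------------------------------------------------------------------
# weighted degree / hubs
# ---------------------------------------------------------------------------


def test_single_link_degree(balanced_chain3):
    deg, hubs = weighted_degree(balanced_chain3)
    F = balanced_chain3.flows.flows
    assert deg[1] == pytest.approx(F[0, 1])
    assert deg[2] == pytest.approx(F[0, 1] + F[1, 2])


def test_star_hub():
    n = 6
    nodes = [
        pk.FunctionalNode(i, f"L{i}", pk.TrophicStatus.AUTOTROPH, pk.Layer.SURFACE,
                          10.0, production_rate_range=(1.0, 1.0))
        for i in range(1, n)
    ]
    nodes.append(
        pk.FunctionalNode(n, "center", pk.TrophicStatus.HETEROTROPH, pk.Layer.SURFACE,
                          5.0, production_rate_range=(0.1, 0.1),
                          consumption_rate_range=(1.0, 1.0))
    )
    diet = pk.DietMatrix(list(range(1, n + 1)), {(i, n): 0.2 for i in range(1, n)})
    model = pk.build_model(nodes, diet)
    bal = balance_from_rates(model, model.midpoint_rates())
    deg, hubs = weighted_degree(bal, n_hubs=1)
    assert hubs == [n]
    assert deg[n] == pytest.approx(5.0)
    assert deg[1] == pytest.approx(1.0)


def test_degree_matches_brute_force(balanced_random_web):
    deg, _ = weighted_degree(balanced_random_web)
    model = balanced_random_web.model
    F = balanced_random_web.flows.flows
    for nid in model.node_ids:
        k = model.index(nid)
        expected = 0.0
        for j, nd in enumerate(model.nodes):
            if model.nodes[k].is_living and nd.is_living:
                expected += F[k, j] + F[j, k]
        assert deg[nid] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# mixed trophic impact & keystoneness
# ---------------------------------------------------------------------------


def _two_node_mti_model():
    """P eaten by Z taking half of the predation on P (other half to Z2)."""
    nodes = [
        pk.FunctionalNode(1, "P", pk.TrophicStatus.AUTOTROPH, pk.Layer.SURFACE,
                          100.0, production_rate_range=(1.0, 1.0)),
        pk.FunctionalNode(2, "Z", pk.TrophicStatus.HETEROTROPH, pk.Layer.SURFACE,
                          10.0, production_rate_range=(0.1, 0.1),
                          consumption_rate_range=(1.0, 1.0)),
        pk.FunctionalNode(3, "Z2", pk.TrophicStatus.HETEROTROPH, pk.Layer.SURFACE,
                          10.0, production_rate_range=(0.1, 0.1),
                          consumption_rate_range=(1.0, 1.0)),
    ]
    diet = pk.DietMatrix([1, 2, 3], {(1, 2): 1.0, (1, 3): 1.0})
    model = pk.build_model(nodes, diet)
    return balance_from_rates(model, model.midpoint_rates())


def test_mti_closed_form_symmetric_predators():
    """P feeds two predators equally (g = 1 each, host share 0.5 each).

    Hand inversion of I - Q with Q = [[0,1,1],[-1/2,0,0],[-1/2,0,0]] gives
    det = 2, m_PZ = 1/2 and m_ZP = -1/4.
    """
    bal = _two_node_mti_model()
    M = mixed_trophic_impact(bal)
    i, j, k = bal.model.index(1), bal.model.index(2), bal.model.index(3)
    assert M[i, j] == pytest.approx(0.5)
    assert M[i, k] == pytest.approx(0.5)
    assert M[j, i] == pytest.approx(-0.25)
    assert M[k, i] == pytest.approx(-0.25)


def test_mti_zero_for_empty_flows():
    nodes = [
        pk.FunctionalNode(1, "P", pk.TrophicStatus.AUTOTROPH, pk.Layer.SURFACE,
                          10.0, production_rate_range=(0.0, 0.0)),
        pk.FunctionalNode(2, "P2", pk.TrophicStatus.AUTOTROPH, pk.Layer.SURFACE,
                          10.0, production_rate_range=(0.0, 0.0)),
    ]
    model = pk.build_model(nodes, pk.DietMatrix([1, 2]))
    bal = balance_from_rates(model, model.midpoint_rates())
    assert np.allclose(mixed_trophic_impact(bal), 0.0)


def _flow_stub(F):
    """All-living web with the given flow matrix (bypasses rate accounting)."""
    from planknet.balancer import BalancedModel
    from planknet.model_core import DietMatrix, FlowMatrix as FM, FoodWebModel

    n = F.shape[0]
    ids = list(range(1, n + 1))
    nodes = [
        pk.FunctionalNode(i, f"N{i}", pk.TrophicStatus.MIXOTROPH,
                          pk.Layer.WHOLE_COLUMN, 10.0,
                          production_rate_range=(0.1, 0.1),
                          consumption_rate_range=(0.5, 0.5),
                          unassimilated_fraction=0.2, ph_het=1.0)
        for i in ids
    ]
    model = FoodWebModel(nodes=nodes, diet=DietMatrix(ids))
    return BalancedModel(model=model, rates=None, diet=model.diet,
                         flows=FM(flows=F, node_ids=ids), budgets=[])


def _impact_q(bal):
    """Direct-impact matrix rebuilt from flows (oracle-side definition)."""
    model, F = bal.model, bal.flows.flows
    n = model.n
    living = model.living_mask
    intake = F.sum(axis=0)
    D = np.zeros((n, n))
    for j in range(n):
        if living[j] and intake[j] > 0:
            D[:, j] = F[:, j] / intake[j]
    predation = F[:, living].sum(axis=1)
    H = np.zeros((n, n))
    for j in range(n):
        if predation[j] > 0:
            H[:, j] = F[j, :] / predation[j]
    return D - H


def test_mti_agrees_with_neumann_series():
    """M = sum_{k>=1} Q^k on dense random webs with spectral radius < 1."""
    rng = np.random.default_rng(0)
    for _ in range(5):
        n = 10
        F = rng.uniform(0, 1, (n, n)) * (rng.uniform(size=(n, n)) < 0.9)
        np.fill_diagonal(F, 0.0)
        bal = _flow_stub(F)
        Q = _impact_q(bal)
        assert max(abs(np.linalg.eigvals(Q))) < 1
        M = mixed_trophic_impact(bal)
        S, P = np.zeros_like(Q), np.eye(n)
        for _ in range(200):
            P = P @ Q
            S += P
        assert np.allclose(M, S, atol=1e-6)


def test_mti_satisfies_defining_identity(balanced_random_web):
    """M = Q (I + M): direct impacts plus impacts routed through one more
    node; holds even when the Neumann series diverges."""
    bal = balanced_random_web
    M = mixed_trophic_impact(bal)
    Q = _impact_q(bal)
    assert np.allclose(M, Q @ (np.eye(bal.model.n) + M), atol=1e-9)


def test_keystoneness_favors_low_biomass(balanced_random_web):
    """Equal impact with lower biomass must give higher keystoneness."""
    model = balanced_random_web.model
    n = model.n
    mti = np.zeros((n, n))
    mti[model.index(1), :] = 0.1
    mti[model.index(2), :] = 0.1
    overall, ks = keystoneness(mti, model)
    b1, b2 = model.node(1).biomass, model.node(2).biomass
    lo, hi = (1, 2) if b1 > b2 else (2, 1)
    assert ks[hi] > ks[lo]


def test_zero_impact_gets_minus_inf_not_exception(balanced_random_web):
    model = balanced_random_web.model
    mti = np.zeros((model.n, model.n))
    mti[model.index(1), :] = 0.5
    overall, ks = keystoneness(mti, model)
    assert ks[2] == float("-inf")
    assert overall[1] == pytest.approx(1.0)


def test_overall_effect_matches_loop_sum(balanced_random_web):
    bal = balanced_random_web
    M = mixed_trophic_impact(bal)
    overall, _ = keystoneness(M, bal.model)
    model = bal.model
    raw = {}
    for nid in model.node_ids:
        if not model.node(nid).is_living:
            continue
        k = model.index(nid)
        s = 0.0
        for j in range(model.n):
            if j != k:
                s += M[k, j] ** 2
        raw[nid] = math.sqrt(s)
    mx = max(raw.values())
    for nid, v in raw.items():
        assert overall[nid] == pytest.approx(v / mx)


# ---------------------------------------------------------------------------
# ascendency
# ---------------------------------------------------------------------------


def test_disjoint_deterministic_flows_fully_organized():
    """Two parallel deterministic transfers: A/C = 1 (A = C = 2t log2(2))."""
    F = np.zeros((4, 4))
    F[0, 2] = 3.0
    F[1, 3] = 3.0
    A, C, rel, contrib = ascendency(FlowMatrix(flows=F, node_ids=[1, 2, 3, 4]))
    assert A == pytest.approx(2 * 3.0 * 1.0)
    assert rel == pytest.approx(1.0)
    assert sum(contrib.values()) == pytest.approx(rel)


def test_uniform_bipartite_has_zero_ascendency():
    F = np.zeros((4, 4))
    F[0, 2] = F[0, 3] = F[1, 2] = F[1, 3] = 2.0
    A, C, rel, _ = ascendency(FlowMatrix(flows=F, node_ids=[1, 2, 3, 4]))
    assert A == pytest.approx(0.0, abs=1e-12)
    assert C > 0


def test_ascendency_bounds_and_invariances(balanced_random_web):
    bal = balanced_random_web
    resp = np.array([b.respiration for b in bal.budgets])
    expo = np.array([b.export for b in bal.budgets])
    A, C, rel, contrib = ascendency(bal.flows, exports=expo, respiration=resp)
    assert 0 <= A <= C
    assert sum(contrib.values()) == pytest.approx(rel)
    # node reordering leaves A and C unchanged
    n = bal.model.n
    perm = np.random.default_rng(1).permutation(n)
    F2 = bal.flows.flows[np.ix_(perm, perm)]
    A2, C2, rel2, _ = ascendency(
        FlowMatrix(flows=F2, node_ids=list(np.array(bal.flows.node_ids)[perm])),
        exports=expo[perm], respiration=resp[perm],
    )
    assert A2 == pytest.approx(A)
    assert C2 == pytest.approx(C)
    # flow rescaling leaves A/C unchanged
    lam = 3.7
    A3, C3, rel3, _ = ascendency(
        FlowMatrix(flows=lam * bal.flows.flows, node_ids=bal.flows.node_ids),
        exports=lam * expo, respiration=lam * resp,
    )
    assert rel3 == pytest.approx(rel)


def test_all_zero_flows_rejected():
    with pytest.raises(ValueError):
        ascendency(FlowMatrix(flows=np.zeros((3, 3)), node_ids=[1, 2, 3]))


# ---------------------------------------------------------------------------
# Shannon diversity
# ---------------------------------------------------------------------------


def test_equal_biomasses_give_ln_n():
    assert shannon_diversity(np.array([5.0, 5.0])) == pytest.approx(math.log(2))
    for n in (3, 7, 20):
        assert shannon_diversity(np.full(n, 2.5)) == pytest.approx(math.log(n))


def test_negative_biomass_rejected():
    with pytest.raises(ValueError):
        shannon_diversity(np.array([1.0, -0.5]))


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------


def test_identical_matrices_r_one(balanced_random_web):
    f = balanced_random_web.flows
    r, p = mantel_correlation(f, f, n_permutations=99, seed=0)
    assert r == pytest.approx(1.0)
    assert p <= 0.05


def test_mantel_matches_direct_pearson():
    rng = np.random.default_rng(3)
    A = rng.uniform(0, 1, (4, 4))
    B = rng.uniform(0, 1, (4, 4))
    fa = FlowMatrix(flows=A, node_ids=[1, 2, 3, 4])
    fb = FlowMatrix(flows=B, node_ids=[1, 2, 3, 4])
    r, _ = mantel_correlation(fa, fb, n_permutations=99, seed=0)
    off = ~np.eye(4, dtype=bool)
    x, y = A[off], B[off]
    expected = float(
        ((x - x.mean()) * (y - y.mean())).sum()
        / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
    )
    assert r == pytest.approx(expected)


def test_mantel_invariant_under_joint_relabeling():
    rng = np.random.default_rng(4)
    A = rng.uniform(0, 1, (6, 6))
    B = rng.uniform(0, 1, (6, 6))
    ids = list(range(1, 7))
    r1, _ = mantel_correlation(FlowMatrix(A, ids), FlowMatrix(B, ids), 9, seed=0)
    perm = rng.permutation(6)
    r2, _ = mantel_correlation(
        FlowMatrix(A[np.ix_(perm, perm)], ids), FlowMatrix(B[np.ix_(perm, perm)], ids), 9, seed=0
    )
    assert r2 == pytest.approx(r1)


def test_dimension_mismatch_rejected():
    with pytest.raises(ValueError, match="mismatch"):
        mantel_correlation(
            FlowMatrix(np.zeros((3, 3)), [1, 2, 3]),
            FlowMatrix(np.zeros((4, 4)), [1, 2, 3, 4]),
        )


# ---------------------------------------------------------------------------
# predatory cycles
# ---------------------------------------------------------------------------


def _cycle_model(edges, detritus=()):
    ids = sorted({i for e in edges for i in e} | set(detritus))
    nodes = []
    for i in ids:
        if i in detritus:
            nodes.append(pk.FunctionalNode(i, f"D{i}", pk.TrophicStatus.DETRITUS,
                                           pk.Layer.WHOLE_COLUMN, 10.0))
        else:
            nodes.append(pk.FunctionalNode(i, f"N{i}", pk.TrophicStatus.MIXOTROPH,
                                           pk.Layer.WHOLE_COLUMN, 10.0,
                                           production_rate_range=(0.1, 0.1),
                                           consumption_rate_range=(0.5, 0.5),
                                           unassimilated_fraction=0.2, ph_het=1.0))
    # build flows directly; diet validation is not the point here
    n = len(ids)
    F = np.zeros((n, n))
    index = {i: k for k, i in enumerate(ids)}
    for a, b in edges:
        F[index[a], index[b]] = 1.0
    from planknet.balancer import BalancedModel
    from planknet.model_core import FlowMatrix as FM, FoodWebModel, DietMatrix
    model = FoodWebModel(nodes=nodes, diet=DietMatrix(ids))
    return BalancedModel(model=model, rates=None, diet=model.diet,
                         flows=FM(flows=F, node_ids=ids), budgets=[])


def test_three_node_living_cycle():
    bal = _cycle_model([(1, 2), (2, 3), (3, 1)])
    cs = predatory_cycles(bal)
    assert cs.cycle_count == 1
    assert cs.length_histogram == {3: 1}


def test_detritus_loop_excluded():
    # Z -> D -> bacteria -> Z with D non-living: no predatory cycle
    bal = _cycle_model([(1, 2), (2, 3), (3, 1)], detritus=(2,))
    cs = predatory_cycles(bal)
    assert cs.cycle_count == 0


def test_cycles_match_brute_force_enumeration():
    """Counts equal exhaustive simple-cycle enumeration on random digraphs."""
    rng = np.random.default_rng(7)
    for trial in range(10):
        n = 8
        edges = [
            (i, j)
            for i in range(1, n + 1)
            for j in range(1, n + 1)
            if i != j and rng.uniform() < 0.25
        ]
        if not edges:
            continue
        bal = _cycle_model(edges)
        cs = predatory_cycles(bal)
        expected = {}
        count = 0
        for cyc in _brute_force_cycles(edges):
            count += 1
            expected[len(cyc)] = expected.get(len(cyc), 0) + 1
        assert cs.cycle_count == count
        assert cs.length_histogram == expected


def _brute_force_cycles(edges):
    """Exhaustive DFS enumeration of simple directed cycles."""
    adj = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
    nodes = sorted({i for e in edges for i in e})
    cycles = []

    def dfs(start, current, path, visited):
        for nxt in adj.get(current, []):
            if nxt == start and len(path) >= 1:
                cycles.append(list(path))
            elif nxt > start and nxt not in visited:
                visited.add(nxt)
                path.append(nxt)
                dfs(start, nxt, path, visited)
                path.pop()
                visited.remove(nxt)

    for s in nodes:
        dfs(s, s, [s], {s})
    return cycles


def test_truncation_flagged():
    # complete digraph on 6 nodes has many cycles; cap at 5
    edges = [(i, j) for i in range(1, 7) for j in range(1, 7) if i != j]
    bal = _cycle_model(edges)
    cs = predatory_cycles(bal, max_cycles=5)
    assert cs.truncated
    assert cs.cycle_count == 5
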