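"""Network diagnostics for a balanced food web.

Implements the standard ecological-network-analysis suite: fractional
trophic levels, weighted degree and hub ranking, the mixed-trophic-impact
(MTI) matrix with the derived overall effect and keystoneness indices,
ascendency / development capacity, Shannon diversity of biomasses, a Mantel
permutation test for comparing flux matrices, and enumeration of predatory
cycles (directed cycles through living nodes only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .balancer import BalancedModel
from .model_core import FlowMatrix, FoodWebModel

__all__ = [
    "IndicatorReport",
    "CycleSummary",
    "trophic_levels",
    "weighted_degree",
    "mixed_trophic_impact",
    "keystoneness",
    "ascendency",
    "shannon_diversity",
    "mantel_correlation",
    "predatory_cycles",
    "compute_indicators",
]


@dataclass
class CycleSummary:
    cycle_count: int
    length_histogram: dict[int, int]
    max_length: int
    truncated: bool = False


@dataclass
class IndicatorReport:
    node_ids: list[int]
    trophic_level: dict[int, float]
    weighted_degree: dict[int, float]
    hubs: list[int]
    mti: np.ndarray
    overall_effect: dict[int, float]
    keystoneness: dict[int, float]
    ascendency: float
    capacity: float
    relative_ascendency: float
    node_ascendency_contribution: dict[int, float]
    shannon_h: float
    cycles: CycleSummary | None = None
    extras: dict = field(default_factory=dict)


def _realized_diet(balanced: BalancedModel) -> np.ndarray:
    """d[i, j] = realized fraction of consumer j's ingestion taken from node i."""
    F = balanced.flows.flows
    model = balanced.model
    living = model.living_mask
    D = np.zeros_like(F)
    # only flows into living consumers are ingestion; closure flows into
    # non-living pools are not diet
    intake = F[:, living].sum(axis=0)
    cols = np.where(living)[0]
    for c, k in enumerate(cols):
        if intake[c] > 0:
            D[:, k] = F[:, k] / intake[c]
    return D


def trophic_levels(balanced: BalancedModel) -> dict[int, float]:
    """Fractional trophic level of every node.

    Producers and non-living pools sit at TL 1; each consumer sits one step
    above the flow-weighted mean TL of its food.  A mixotroph's phototrophic
    production share counts as a TL-1 diet component, so a node that is
    mostly phototrophic sits close to TL 1 regardless of what it eats.
    Solved as a linear system over the realized diet fractions.
    """
    model = balanced.model
    n = model.n
    D = _realized_diet(balanced)
    p_phi = model.p_phi
    consumer = model.consumer_mask
    A = np.eye(n)
    b = np.ones(n)
    for k in range(n):
        if consumer[k]:
            A[k, :] -= (1.0 - p_phi[k]) * D[:, k]
    try:
        tl = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "trophic-level system is singular (diet cycle with no TL-1 anchor)"
        ) from exc
    return {nid: float(tl[model.index(nid)]) for nid in model.node_ids}


def weighted_degree(balanced: BalancedModel, n_hubs: int = 5) -> tuple[dict[int, float], list[int]]:
    """Total carbon exchanged with other living nodes, plus the top-``n_hubs``.

    The weighted degree of a node is the sum of flows it takes from and
    delivers to other living nodes; hubs are the highest-ranked nodes, ties
    broken by lower node id.
    """
    model = balanced.model
    F = balanced.flows.flows
    living = model.living_mask
    FL = F * np.outer(living, living)
    deg = FL.sum(axis=1) + FL.sum(axis=0)
    degrees = {nid: float(deg[model.index(nid)]) for nid in model.node_ids}
    living_ids = [nid for nid in model.node_ids if model.node(nid).is_living]
    hubs = sorted(living_ids, key=lambda nid: (-degrees[nid], nid))[:n_hubs]
    return degrees, hubs


def mixed_trophic_impact(balanced: BalancedModel) -> np.ndarray:
    """Mixed trophic impact matrix M = (I - Q)^-1 - I.

    ``q_ij``, the direct impact of node i on node j, is the fraction of j's
    ingestion supplied by i (positive, bottom-up) minus the share of the
    total predation on j that is exerted by i (negative, top-down).  M sums
    direct and all indirect pathways of influence.
    """
    model = balanced.model
    F = balanced.flows.flows
    n = model.n
    living = model.living_mask
    D = _realized_diet(balanced)  # g[i, j]
    # host shares: h[i, j] = F[j, i] / total predation on j (flows j -> living)
    predation = F[:, living].sum(axis=1)
    H = np.zeros((n, n))
    for j in range(n):
        if predation[j] > 0:
            H[:, j] = F[j, :] / predation[j]
    Qm = D - H
    I = np.eye(n)
    try:
        M = np.linalg.inv(I - Qm) - I
    except np.linalg.LinAlgError as exc:
        rho = float(np.max(np.abs(np.linalg.eigvals(Qm))))
        raise ValueError(
            f"(I - Q) is singular (spectral radius {rho:.3f}); consider damping the "
            "impact matrix"
        ) from exc
    return M


def keystoneness(
    mti: np.ndarray,
    model: FoodWebModel,
) -> tuple[dict[int, float], dict[int, float]]:
    """Overall relative effect and keystoneness from the MTI matrix.

    ``o_i = sqrt(sum_{j != i} m_ij^2)`` scaled to the maximum across nodes;
    ``KS_i = log10(o_i (1 - p_i))`` with ``p_i`` the node's share of total
    living biomass, so high-impact low-biomass nodes rank highest.  Nodes
    with zero impact get ``-inf`` (lowest rank), not an exception.
    """
    living_ids = [nid for nid in model.node_ids if model.node(nid).is_living]
    B = np.array([model.node(nid).biomass for nid in living_ids])
    btot = B.sum()
    eff = {}
    for nid in living_ids:
        k = model.index(nid)
        row = mti[k, :].copy()
        row[k] = 0.0
        eff[nid] = float(np.sqrt((row**2).sum()))
    emax = max(eff.values()) if eff else 0.0
    overall = {nid: (v / emax if emax > 0 else 0.0) for nid, v in eff.items()}
    ks = {}
    for nid, bi in zip(living_ids, B):
        p = bi / btot
        val = overall[nid] * (1.0 - p)
        ks[nid] = float(np.log10(val)) if val > 0 else float("-inf")
    return overall, ks


def ascendency(
    flows: FlowMatrix,
    imports: np.ndarray | None = None,
    exports: np.ndarray | None = None,
    respiration: np.ndarray | None = None,
) -> tuple[float, float, float, dict[int, float]]:
    """Ascendency A, development capacity C, A/C and per-node contributions.

    A is the throughput-scaled mutual information of the flow network,
    ``A = sum_ij T_ij log2(T_ij T.. / (T_i. T._j))``; C is the scaled flow
    entropy ``-sum_ij T_ij log2(T_ij / T..)``; 0 <= A <= C, and A/C is
    invariant to the log base and to uniform rescaling of the flows.
    Imports enter through a virtual source row, exports and respiration
    through virtual sink columns.  Each real node's contribution is the A
    share of the flows leaving it, divided by C; when there are no imports
    the contributions sum exactly to A/C.
    """
    n = len(flows.node_ids)
    T = np.zeros((n + 1, n + 3))
    T[:n, :n] = flows.flows
    if imports is not None:
        T[n, :n] = imports
    if exports is not None:
        T[:n, n + 1] = exports
    if respiration is not None:
        T[:n, n + 2] = respiration
    tot = T.sum()
    if tot <= 0:
        raise ValueError("ascendency undefined for an all-zero flow network")
    rowsum = T.sum(axis=1)
    colsum = T.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = T * tot / np.outer(rowsum, colsum)
        a_terms = np.where(T > 0, T * np.log2(np.where(T > 0, ratio, 1.0)), 0.0)
        c_terms = np.where(T > 0, -T * np.log2(np.where(T > 0, T / tot, 1.0)), 0.0)
    A = float(a_terms.sum())
    C = float(c_terms.sum())
    contrib = {
        nid: float(a_terms[k, :].sum() / C) for k, nid in enumerate(flows.node_ids)
    }
    return A, C, (A / C if C > 0 else 0.0), contrib


def shannon_diversity(biomasses: np.ndarray) -> float:
    """Shannon H = -sum p_i ln(p_i) over the given (living-node) biomasses."""
    b = np.asarray(biomasses, dtype=float)
    if np.any(b < 0):
        raise ValueError("biomasses must be non-negative")
    b = b[b > 0]
    if b.size == 0:
        raise ValueError("at least one positive biomass required")
    p = b / b.sum()
    return float(-(p * np.log(p)).sum())


def mantel_correlation(
    flows_a: FlowMatrix,
    flows_b: FlowMatrix,
    n_permutations: int = 9999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel test between two flux matrices over the same node ordering.

    R is the Pearson correlation of the off-diagonal entries; the p-value
    permutes node labels of the second matrix (simultaneous row/column
    relabeling) and uses the (count + 1)/(n + 1) convention.  Entry pairs
    where both fluxes are structurally zero are retained.
    """
    A, B = flows_a.flows, flows_b.flows
    if A.shape != B.shape:
        raise ValueError(f"dimension mismatch: {A.shape} vs {B.shape}")
    n = A.shape[0]
    off = ~np.eye(n, dtype=bool)

    def corr(X, Y):
        x, y = X[off], Y[off]
        if x.std() == 0 or y.std() == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(A, B)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if corr(A, B[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return r_obs, p


def predatory_cycles(
    balanced: BalancedModel,
    max_cycles: int = 100_000,
    max_length: int | None = None,
) -> CycleSummary:
    """Enumerate simple directed cycles through living nodes only.

    Pathways through any non-living pool (detritus, DOC) are excluded, so a
    grazer -> detritus -> bacteria -> grazer loop is not a predatory cycle.
    Enumeration stops (flagged, never silent) after ``max_cycles``.
    """
    model = balanced.model
    F = balanced.flows.flows
    G = nx.DiGraph()
    living_ids = [nid for nid in model.node_ids if model.node(nid).is_living]
    G.add_nodes_from(living_ids)
    for i in living_ids:
        for j in living_ids:
            if F[model.index(i), model.index(j)] > 0:
                G.add_edge(i, j)
    hist: dict[int, int] = {}
    count = 0
    truncated = False
    for cycle in nx.simple_cycles(G, length_bound=max_length):
        count += 1
        hist[len(cycle)] = hist.get(len(cycle), 0) + 1
        if count >= max_cycles:
            truncated = True
            break
    return CycleSummary(
        cycle_count=count,
        length_histogram=dict(sorted(hist.items())),
        max_length=max(hist) if hist else 0,
        truncated=truncated,
    )


def compute_indicators(
    balanced: BalancedModel,
    n_hubs: int = 5,
    with_cycles: bool = True,
    max_cycles: int = 100_000,
) -> IndicatorReport:
    """Run the full diagnostic suite on one balanced model."""
    model = balanced.model
    tl = trophic_levels(balanced)
    deg, hubs = weighted_degree(balanced, n_hubs=n_hubs)
    mti = mixed_trophic_impact(balanced)
    overall, ks = keystoneness(mti, model)
    resp = np.array([b.respiration for b in balanced.budgets])
    expo = np.array([b.export for b in balanced.budgets])
    A, C, rel, contrib = ascendency(balanced.flows, exports=expo, respiration=resp)
    living_b = np.array(
        [nd.biomass for nd in model.nodes if nd.is_living]
    )
    h = shannon_diversity(living_b)
    cycles = predatory_cycles(balanced, max_cycles=max_cycles) if with_cycles else None
    return IndicatorReport(
        node_ids=model.node_ids,
        trophic_level=tl,
        weighted_degree=deg,
        hubs=hubs,
        mti=mti,
        overall_effect=overall,
        keystoneness=ks,
        ascendency=A,
        capacity=C,
        relative_ascendency=rel,
        node_ascendency_contribution=contrib,
        shannon_h=h,
        cycles=cycles,
    )
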