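"""Lindeman spines: canonical trophic aggregation and transfer efficiencies.

A balanced web is collapsed onto a chain of integer trophic levels by
apportioning every node's biomass and flows over discrete levels according
to its diet-path decomposition: a producer is entirely at level 1, and the
fraction of a consumer's ingestion arriving at level k+1 equals the
flow-weighted share of its food that sits at level k.  Paths are kept
separate by their root - primary production (the grazing chain) or the
non-living pools (the detritus chain, whose pooled detritus box sits at
level 1) - yielding the classical two-chain spine.  The aggregation is
homologous to the source network: total spine throughput equals total
network throughput.

Transfer efficiency (TE) at step k+1 is the fraction of the input to level k
that is passed on to level k+1; the overall TE is a flow-weighted geometric
mean over the first steps (up to TL 4 by convention).

The unused production of consumers (their EE shortfall that is neither eaten
in the web nor routed to detritus) feeds a static projection of the
planktivorous fish biomass it could sustain, assuming a fixed TE for the
higher trophic levels and a carbon to dry-weight ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .balancer import BalancedModel

__all__ = [
    "LindemanSpine",
    "ChainLevel",
    "TransferEfficiencyProfile",
    "canonical_trophic_aggregation",
    "transfer_efficiencies",
    "unused_production",
    "potential_fish_biomass",
]

MAX_LEVELS = 8  # integer-TL compartments; deeper paths fold into the last


@dataclass
class ChainLevel:
    """Ledger of one integer-trophic-level compartment of one chain."""

    level: int
    biomass: float = 0.0
    input: float = 0.0
    respiration: float = 0.0
    flow_to_detritus: float = 0.0
    export: float = 0.0
    transfer_to_next: float = 0.0

    @property
    def outflow(self) -> float:
        return self.respiration + self.flow_to_detritus + self.export + self.transfer_to_next


@dataclass
class LindemanSpine:
    grazing: list[ChainLevel]
    detritus: list[ChainLevel]
    detritus_box_input: float = 0.0
    detritus_box_surplus: float = 0.0
    detritus_box_import: float = 0.0  # implied import when the pool runs a deficit
    meta: dict = field(default_factory=dict)

    def total_throughput(self) -> float:
        """Sum of all compartment inputs; homologous to the source network's
        total throughput (all internal flows plus gross primary production)."""
        return sum(lv.input for chain in (self.grazing, self.detritus) for lv in chain)


@dataclass
class TransferEfficiencyProfile:
    """Per-step and overall transfer efficiencies (fractions).

    ``grazing_te[k]``/``detritus_te[k]`` map step index (2 = TL1 -> TL2 ...)
    to the TE of that step; steps with zero input are missing, not zero.
    """

    grazing_te: dict[int, float]
    detritus_te: dict[int, float]
    overall_te_grazing: float | None
    overall_te_detritus: float | None
    overall_te: float | None


def _level_weights(balanced: BalancedModel) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-node level distributions split by path root.

    Returns ``(Wg, Wd, Cg, Cd)`` where ``Wg[i, k]`` is the fraction of living
    node i's activity at integer level k+1 reached through producer-rooted
    paths (``Wd`` detritus-rooted), and ``Cg``/``Cd`` are the corresponding
    fractions of its *ingestion* arriving at each level.  The weights are
    flow-consistent: a mixotroph's phototrophic inflow anchors part of its
    activity at level 1 in proportion to that inflow.
    """
    model = balanced.model
    n = model.n
    K = MAX_LEVELS
    F = balanced.flows.flows
    living = model.living_mask
    p_phi = model.p_phi
    P = np.array([b.production for b in balanced.budgets])
    Q = np.array([b.consumption for b in balanced.budgets])
    phi = p_phi * P  # phototrophic production inflow
    inflow = Q + phi

    # realized ingestion fractions d[i, j] = F_ij / ingestion of j
    D = np.zeros((n, n))
    intake = F.sum(axis=0)
    for j in range(n):
        if living[j] and intake[j] > 0:
            D[:, j] = F[:, j] / intake[j]

    det_share = D[~living, :].sum(axis=0)  # share of ingestion taken from non-living pools

    Wg = np.zeros((n, K))
    Wd = np.zeros((n, K))
    Cg = np.zeros((n, K))
    Cd = np.zeros((n, K))
    with np.errstate(invalid="ignore", divide="ignore"):
        Wg[:, 0] = np.where(inflow > 0, phi / np.where(inflow > 0, inflow, 1.0), 0.0)
    Wg[:, 0] = np.where(living, Wg[:, 0], 0.0)

    DL = D * living[:, np.newaxis]  # living-prey part of the diet
    for k in range(1, K):
        cg = DL.T @ Wg[:, k - 1]
        cd = DL.T @ Wd[:, k - 1]
        if k == 1:
            cd = cd + det_share  # the detritus box sits at level 1
        Cg[:, k] = np.where(living, cg, 0.0)
        Cd[:, k] = np.where(living, cd, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            Wg[:, k] = np.where(inflow > 0, Q * Cg[:, k] / np.where(inflow > 0, inflow, 1.0), 0.0)
            Wd[:, k] = np.where(inflow > 0, Q * Cd[:, k] / np.where(inflow > 0, inflow, 1.0), 0.0)

    # fold the unresolved tail (paths longer than K, incl. cycles) into level K
    tg, td = _asymptotic_root_shares(model, DL, det_share, Q, phi, inflow)
    resid_g = tg - Wg.sum(axis=1)
    resid_d = td - Wd.sum(axis=1)
    Wg[:, K - 1] += np.maximum(resid_g, 0.0)
    Wd[:, K - 1] += np.maximum(resid_d, 0.0)
    # the matching ingestion shares fold into level K as well
    with np.errstate(invalid="ignore", divide="ignore"):
        Cg[:, K - 1] += np.where(Q > 0, np.maximum(resid_g, 0.0) * inflow / np.where(Q > 0, Q, 1.0), 0.0)
        Cd[:, K - 1] += np.where(Q > 0, np.maximum(resid_d, 0.0) * inflow / np.where(Q > 0, Q, 1.0), 0.0)
    return Wg, Wd, Cg, Cd


def _asymptotic_root_shares(model, DL, det_share, Q, phi, inflow):
    """Solve for each living node's total grazing- vs detritus-rooted share."""
    n = model.n
    living = model.living_mask
    # t_i = (Q_i * sum_j d_ji t_j + phi_i) / inflow_i  for grazing;
    # detritus totals are the complement of grazing among nodes with inflow.
    A = np.eye(n)
    b = np.zeros(n)
    for i in range(n):
        if not living[i] or inflow[i] <= 0:
            continue
        A[i, :] -= (Q[i] / inflow[i]) * DL[:, i]
        b[i] = phi[i] / inflow[i]
    tg = np.linalg.solve(A, b)
    td = np.where(living & (inflow > 0), 1.0 - tg, 0.0)
    tg = np.where(living & (inflow > 0), tg, 0.0)
    return tg, td


def canonical_trophic_aggregation(
    balanced: BalancedModel,
    conservation_tolerance: float = 1e-6,
) -> LindemanSpine:
    """Aggregate a balanced web into grazing and detritus Lindeman chains.

    Every node's biomass, ingestion, respiration, detrital losses, exports
    and predation outflow are apportioned over integer trophic levels by its
    diet-path decomposition; compartments are capped at ``MAX_LEVELS`` with
    longer paths folded into the last.  Raises if the per-level ledgers fail
    to conserve carbon within ``conservation_tolerance`` (relative).
    """
    model = balanced.model
    n = model.n
    K = MAX_LEVELS
    F = balanced.flows.flows
    living = model.living_mask
    B = model.biomass
    Wg, Wd, Cg, Cd = _level_weights(balanced)
    Q = np.array([b.consumption for b in balanced.budgets])
    phi = model.p_phi * np.array([b.production for b in balanced.budgets])
    rho = np.array([b.respiration for b in balanced.budgets])
    to_det = np.array([b.flow_to_detritus for b in balanced.budgets])
    export = np.array([b.export for b in balanced.budgets])
    predation = F[:, living].sum(axis=1)

    grazing = [ChainLevel(level=k + 1) for k in range(K)]
    detritus = [ChainLevel(level=k + 1) for k in range(K)]
    # the pooled detritus box is the level-1 compartment of the detritus chain
    det_in = float(F[:, ~living].sum())
    det_out = float(F[~living, :].sum())
    surplus = det_in - det_out
    detritus[0].biomass = float(B[~living].sum())
    detritus[0].input = det_in
    detritus[0].transfer_to_next = det_out
    detritus[0].export = max(surplus, 0.0)

    for k in range(K):
        grazing[k].biomass += float((B * Wg[:, k]).sum())
        grazing[k].input += float((Q * Cg[:, k]).sum()) + (float(phi.sum()) if k == 0 else 0.0)
        grazing[k].respiration += float((rho * Wg[:, k]).sum())
        grazing[k].flow_to_detritus += float((to_det * Wg[:, k]).sum())
        grazing[k].export += float((export * Wg[:, k]).sum())
        grazing[k].transfer_to_next += float((predation * Wg[:, k]).sum())
        if k >= 1:
            detritus[k].biomass += float((B * Wd[:, k]).sum())
            detritus[k].input += float((Q * Cd[:, k]).sum())
            detritus[k].respiration += float((rho * Wd[:, k]).sum())
            detritus[k].flow_to_detritus += float((to_det * Wd[:, k]).sum())
            detritus[k].export += float((export * Wd[:, k]).sum())
            detritus[k].transfer_to_next += float((predation * Wd[:, k]).sum())
    # the last compartment has no next level: its onward transfer is export
    for chain in (grazing, detritus):
        lv = chain[K - 1]
        lv.export += lv.transfer_to_next
        lv.transfer_to_next = 0.0

    # conservation check: per-level inflow = outflow (living compartments)
    for chain, name in ((grazing, "grazing"), (detritus, "detritus")):
        for lv in chain:
            if name == "detritus" and lv.level == 1:
                continue
            scale = max(lv.input, 1e-9)
            if abs(lv.input - lv.outflow) > conservation_tolerance * scale:
                raise ValueError(
                    f"unaggregated flow remainder at {name} level {lv.level}: "
                    f"in {lv.input:.6g} vs out {lv.outflow:.6g}"
                )
    spine = LindemanSpine(
        grazing=grazing,
        detritus=detritus,
        detritus_box_input=det_in,
        detritus_box_surplus=surplus,
        detritus_box_import=max(-surplus, 0.0),
        meta={"max_levels": K, "state": model.state_label},
    )
    return spine


def transfer_efficiencies(
    spine: LindemanSpine,
    max_step_for_overall: int = 4,
    geometric: bool = True,
) -> TransferEfficiencyProfile:
    """Per-step and overall TEs of a spine.

    Step k+1 (reported with the conventional Roman index, II = TL1 -> TL2)
    is ``transfer_to_next at level k / input at level k``.  Overall TEs are
    flow-weighted (by level input) geometric means over the steps up to
    ``max_step_for_overall``; an arithmetic mean is available as a fallback
    convention.  Steps with zero input are reported as missing.
    """
    def chain_tes(chain: list[ChainLevel], box_import: float = 0.0) -> dict[int, float]:
        out = {}
        for lv in chain[:-1]:
            # a detritus pool running on implied imports still transfers a
            # fraction <= 1 of everything entering it
            inp = lv.input + (box_import if lv.level == 1 else 0.0)
            if inp > 0 and lv.transfer_to_next > 0:
                out[lv.level + 1] = lv.transfer_to_next / inp
        return out

    g_te = chain_tes(spine.grazing)
    d_te = chain_tes(spine.detritus, box_import=spine.detritus_box_import)

    def steps_of(chain: list[ChainLevel], tes: dict[int, float], box_import: float = 0.0):
        out = []
        for lv in chain[:-1]:
            s = lv.level + 1
            if s <= max_step_for_overall and s in tes and tes[s] > 0:
                w = lv.input + (box_import if lv.level == 1 else 0.0)
                out.append((w, tes[s]))
        return out

    def weighted_mean(steps) -> float | None:
        if not steps:
            return None
        w = np.array([s[0] for s in steps])
        te = np.array([s[1] for s in steps])
        if geometric:
            return float(np.exp((w * np.log(te)).sum() / w.sum()))
        return float((w * te).sum() / w.sum())

    g_steps = steps_of(spine.grazing, g_te)
    d_steps = steps_of(spine.detritus, d_te, box_import=spine.detritus_box_import)
    og = weighted_mean(g_steps)
    od = weighted_mean(d_steps)
    oc = weighted_mean(g_steps + d_steps)
    return TransferEfficiencyProfile(
        grazing_te=g_te,
        detritus_te=d_te,
        overall_te_grazing=og,
        overall_te_detritus=od,
        overall_te=oc,
    )


def unused_production(balanced: BalancedModel) -> float:
    """Consumer production neither eaten in the web nor routed to detritus.

    This EE shortfall (mgC m^-2 d^-1) is what the modelled plankton web
    leaves on the table for predators outside it (e.g. planktivorous fish).
    """
    total = 0.0
    for b, nd in zip(balanced.budgets, balanced.model.nodes):
        if b.is_consumer:
            gamma_sum = sum(nd.detritus_allocation.values())
            total += (1.0 - gamma_sum) * b.natural_mortality
    return total


def potential_fish_biomass(
    unused: float,
    te_higher: float = 0.1,
    c_to_dw: float = 9.0,
) -> float:
    """Planktivorous fish biomass (t km^-2) sustainable by unused production.

    ``fish = unused * te_higher * c_to_dw / 1000``: the unused consumer
    production (mgC m^-2 d^-1) is discounted by an average transfer
    efficiency for the higher trophic levels (10% by default), converted
    from carbon to dry weight (1 gC = 9 g DW) and from mg m^-2 to t km^-2.
    Displayed values are conventionally given to two decimals.
    """
    if unused < 0:
        raise ValueError("unused production must be >= 0")
    if not 0 < te_higher <= 1:
        raise ValueError("te_higher must be in (0, 1]")
    return unused * te_higher * c_to_dw * 1e-3
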