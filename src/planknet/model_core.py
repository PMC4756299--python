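"""Domain types and mass-balance accounting for plankton carbon-flux food webs.

The model follows the Ecopath steady-state convention: every functional node
(FN) is a carbon pool of biomass ``B_i`` (mgC m^-2) linked to the others by
diet preferences, and for every consumer the carbon it ingests is fully
accounted for as

    consumption = production + respiration + unassimilated food,

i.e. ``alpha_i B_i = mu_i B_i + rho_i + eps_i alpha_i B_i`` with all flows in
mgC m^-2 d^-1.  Production that is not eaten within the web is the node's
"other mortality" ``mu0_i = (1 - EE_i) mu_i B_i`` (EE = ecotrophic
efficiency); together with feces it is routed to the non-living pools
(detritus, DOC) by the node's ``gamma`` allocations, any unrouted remainder
being counted as export from the modelled web.

Mixotrophs are both producers and consumers.  Their production is split by
the phototrophy:heterotrophy metabolic ratio ``Ph/Het``: a phototrophic
share ``p_phi = (Ph/Het) / (1 + Ph/Het)`` is treated as primary production,
while the remaining heterotrophic share must be covered by their
consumption budget (and only that share enters the consumer balance above).

Water-column structure: unicellular nodes live either in the surface or the
deep layer; vertically migrating nodes span the whole column.  A consumer
may only eat prey it can reach: surface eats surface, deep eats deep, and
whole-column nodes bridge both layers (in either role).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "TrophicStatus",
    "Layer",
    "FunctionalNode",
    "DietMatrix",
    "FoodWebModel",
    "RealizedRates",
    "FlowMatrix",
    "NodeBudget",
    "ModelStructureError",
    "DietNormalizationError",
    "LayerCompatibilityError",
    "build_model",
    "compute_flows",
    "balance_accounting",
    "phototrophic_share",
]


class TrophicStatus(enum.Enum):
    AUTOTROPH = "autotroph"
    HETEROTROPH = "heterotroph"
    MIXOTROPH = "mixotroph"
    DETRITUS = "detritus"


class Layer(enum.Enum):
    SURFACE = "surface"
    DEEP = "deep"
    WHOLE_COLUMN = "whole_column"


# short codes used in the node tables (Table-1 style annotation)
STATUS_CODES = {
    "A": TrophicStatus.AUTOTROPH,
    "H": TrophicStatus.HETEROTROPH,
    "M": TrophicStatus.MIXOTROPH,
    "D": TrophicStatus.DETRITUS,
}
LAYER_CODES = {"s": Layer.SURFACE, "d": Layer.DEEP, "a": Layer.WHOLE_COLUMN}


class ModelStructureError(ValueError):
    """Structural problem in the node table (ids, statuses, ranges)."""


class DietNormalizationError(ValueError):
    """A consumer's diet fractions do not sum to one."""


class LayerCompatibilityError(ValueError):
    """A trophic link crosses the pycnocline illegally."""


def phototrophic_share(ph_het: float) -> float:
    """Phototrophic fraction of a mixotroph's production, (Ph/Het)/(1+Ph/Het)."""
    if ph_het < 0:
        raise ValueError(f"Ph/Het must be >= 0, got {ph_het}")
    return ph_het / (1.0 + ph_het)


@dataclass
class FunctionalNode:
    """One functional node of the web with its biological properties.

    Rates are per-biomass (d^-1) ranges within which the balancing search may
    place the realized value; ``epsilon`` is the not-assimilated fraction of
    ingested carbon; ``detritus_allocation`` maps non-living node ids to the
    fraction of this node's feces + other mortality routed there.
    """

    node_id: int
    name: str
    trophic_status: TrophicStatus
    layer: Layer
    biomass: float
    production_rate_range: tuple[float, float] = (0.0, 0.0)
    consumption_rate_range: tuple[float, float] = (0.0, 0.0)
    unassimilated_fraction: float = 0.0
    ph_het: float = 0.0
    detritus_allocation: dict[int, float] = field(default_factory=dict)

    @property
    def is_living(self) -> bool:
        return self.trophic_status is not TrophicStatus.DETRITUS

    @property
    def is_consumer(self) -> bool:
        return self.trophic_status in (TrophicStatus.HETEROTROPH, TrophicStatus.MIXOTROPH)

    @property
    def is_producer(self) -> bool:
        return self.trophic_status in (TrophicStatus.AUTOTROPH, TrophicStatus.MIXOTROPH)

    def validate(self) -> None:
        nid = self.node_id
        if self.biomass < 0:
            raise ModelStructureError(f"node {nid}: biomass must be >= 0")
        if self.is_living and self.biomass == 0:
            raise ModelStructureError(f"node {nid}: living node needs biomass > 0")
        for label, (lo, hi) in (
            ("production", self.production_rate_range),
            ("consumption", self.consumption_rate_range),
        ):
            if lo < 0 or hi < lo:
                raise ModelStructureError(
                    f"node {nid}: invalid {label} rate range ({lo}, {hi})"
                )
        if not 0.0 <= self.unassimilated_fraction < 1.0:
            raise ModelStructureError(f"node {nid}: epsilon must be in [0, 1)")
        if self.ph_het < 0:
            raise ModelStructureError(f"node {nid}: Ph/Het must be >= 0")
        if self.trophic_status is TrophicStatus.DETRITUS:
            if self.production_rate_range != (0.0, 0.0) or self.consumption_rate_range != (0.0, 0.0):
                raise ModelStructureError(f"node {nid}: detritus nodes carry no rates")
        if self.trophic_status is TrophicStatus.AUTOTROPH and self.consumption_rate_range != (0.0, 0.0):
            raise ModelStructureError(f"node {nid}: autotrophs have zero consumption range")
        if self.trophic_status is TrophicStatus.MIXOTROPH:
            if self.production_rate_range[1] <= 0 or self.consumption_rate_range[1] <= 0:
                raise ModelStructureError(
                    f"node {nid}: mixotrophs need both production and consumption ranges"
                )
        gsum = sum(self.detritus_allocation.values())
        if any(g < 0 for g in self.detritus_allocation.values()) or gsum > 1.0 + 1e-12:
            raise ModelStructureError(
                f"node {nid}: detritus allocations must be >= 0 and sum to <= 1 (got {gsum})"
            )


class DietMatrix:
    """Diet preferences delta_ij: fraction of predator j's ration taken from prey i.

    Stored densely over a fixed 1-based node ordering; columns are predators
    and each consumer's column sums to one over its prey (both layers it can
    access, non-living pools included).
    """

    def __init__(self, node_ids: Sequence[int], entries: Mapping[tuple[int, int], float] | None = None):
        self.node_ids = list(node_ids)
        self._index = {nid: k for k, nid in enumerate(self.node_ids)}
        n = len(self.node_ids)
        self.values = np.zeros((n, n))
        if entries:
            for (prey, pred), frac in entries.items():
                self[prey, pred] = frac

    def __getitem__(self, key: tuple[int, int]) -> float:
        prey, pred = key
        return float(self.values[self._index[prey], self._index[pred]])

    def __setitem__(self, key: tuple[int, int], frac: float) -> None:
        prey, pred = key
        if frac < 0:
            raise ValueError(f"diet fraction for ({prey}->{pred}) must be >= 0")
        self.values[self._index[prey], self._index[pred]] = frac

    def column_sum(self, pred: int) -> float:
        return float(self.values[:, self._index[pred]].sum())

    def predators(self) -> list[int]:
        return [nid for nid in self.node_ids if self.column_sum(nid) > 0]

    def items(self) -> Iterable[tuple[tuple[int, int], float]]:
        rows, cols = np.nonzero(self.values)
        for r, c in zip(rows, cols):
            yield (self.node_ids[r], self.node_ids[c]), float(self.values[r, c])

    def copy(self) -> "DietMatrix":
        out = DietMatrix(self.node_ids)
        out.values = self.values.copy()
        return out


@dataclass
class FoodWebModel:
    """A validated node set plus diet matrix for one system state."""

    nodes: list[FunctionalNode]
    diet: DietMatrix
    state_label: str = ""

    def __post_init__(self) -> None:
        self._index = {n.node_id: k for k, n in enumerate(self.nodes)}

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def node_ids(self) -> list[int]:
        return [n.node_id for n in self.nodes]

    def index(self, node_id: int) -> int:
        return self._index[node_id]

    def node(self, node_id: int) -> FunctionalNode:
        return self.nodes[self._index[node_id]]

    @property
    def biomass(self) -> np.ndarray:
        return np.array([n.biomass for n in self.nodes])

    @property
    def living_mask(self) -> np.ndarray:
        return np.array([n.is_living for n in self.nodes])

    @property
    def consumer_mask(self) -> np.ndarray:
        return np.array([n.is_consumer for n in self.nodes])

    @property
    def autotroph_mask(self) -> np.ndarray:
        return np.array([n.trophic_status is TrophicStatus.AUTOTROPH for n in self.nodes])

    @property
    def p_phi(self) -> np.ndarray:
        """Per-node phototrophic production share (1 for autotrophs, 0 for heterotrophs)."""
        out = np.zeros(self.n)
        for k, nd in enumerate(self.nodes):
            if nd.trophic_status is TrophicStatus.AUTOTROPH:
                out[k] = 1.0
            elif nd.trophic_status is TrophicStatus.MIXOTROPH:
                out[k] = phototrophic_share(nd.ph_het)
        return out

    @property
    def epsilon(self) -> np.ndarray:
        return np.array([n.unassimilated_fraction for n in self.nodes])

    def gamma_matrix(self) -> np.ndarray:
        """n x n matrix: gamma[i, d] = fraction of node i's feces+mortality sent to non-living node d."""
        G = np.zeros((self.n, self.n))
        for k, nd in enumerate(self.nodes):
            for did, frac in nd.detritus_allocation.items():
                G[k, self._index[did]] = frac
        return G

    def midpoint_rates(self) -> "RealizedRates":
        mu = np.array([0.5 * (n.production_rate_range[0] + n.production_rate_range[1]) for n in self.nodes])
        alpha = np.array([0.5 * (n.consumption_rate_range[0] + n.consumption_rate_range[1]) for n in self.nodes])
        return RealizedRates(mu=mu, alpha=alpha)


@dataclass
class RealizedRates:
    """Realized per-biomass rates (d^-1), aligned with the model's node order."""

    mu: np.ndarray
    alpha: np.ndarray

    def copy(self) -> "RealizedRates":
        return RealizedRates(mu=self.mu.copy(), alpha=self.alpha.copy())


@dataclass
class FlowMatrix:
    """Carbon flux matrix F[i, j] = flow from node i to node j (mgC m^-2 d^-1)."""

    flows: np.ndarray
    node_ids: list[int]

    def total(self) -> float:
        return float(self.flows.sum())


@dataclass
class NodeBudget:
    """Per-node carbon ledger of a candidate (not necessarily feasible) model."""

    node_id: int
    production: float  # mu* B (total; for mixotrophs includes phototrophic share)
    production_heterotrophic: float  # share that must be covered by consumption
    consumption: float  # alpha* B
    respiration: float  # rho = (1-eps) Q - het production
    natural_mortality: float  # mu0 = (1-EE) P
    unassimilated_flow: float  # eps Q
    ecotrophic_efficiency: float  # predation / production (living nodes)
    flow_to_detritus: float  # gamma-routed share of feces + mortality
    export: float  # unrouted remainder of feces + mortality
    residual: float  # mass-balance gap: max(0, predation - P) or detritus deficit
    is_consumer: bool = False
    is_living: bool = True
    detritus_input: float = 0.0  # non-living nodes only
    detritus_output: float = 0.0
    detritus_surplus: float = 0.0  # accumulation/export of the pool (deficit < 0)


def _check_layer(pred: FunctionalNode, prey: FunctionalNode) -> bool:
    if pred.layer is Layer.WHOLE_COLUMN or prey.layer is Layer.WHOLE_COLUMN:
        return True
    return pred.layer is prey.layer


def build_model(
    nodes: Iterable[FunctionalNode],
    diet: DietMatrix,
    state_label: str = "",
    diet_tolerance: float = 1e-9,
) -> FoodWebModel:
    """Validate a node table + diet matrix into a :class:`FoodWebModel`.

    Checks id uniqueness/contiguity, per-node invariants, diet normalization
    (each consumer's column sums to 1), that detritus nodes and autotrophs do
    not feed, and prey-predator layer compatibility.
    """
    node_list = list(nodes)
    if not node_list:
        raise ModelStructureError("empty node table")
    ids = [n.node_id for n in node_list]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ModelStructureError(f"duplicate node ids: {dup}")
    if sorted(ids) != list(range(1, len(ids) + 1)):
        raise ModelStructureError(f"node ids must be contiguous from 1, got {sorted(ids)}")
    for nd in node_list:
        nd.validate()
    by_id = {n.node_id: n for n in node_list}
    for nid in diet.node_ids:
        if nid not in by_id:
            raise ModelStructureError(f"diet refers to missing node id {nid}")
    if set(diet.node_ids) != set(ids):
        missing = sorted(set(ids) - set(diet.node_ids))
        raise ModelStructureError(f"diet matrix missing node ids {missing}")
    for nd in node_list:
        for did in nd.detritus_allocation:
            if did not in by_id:
                raise ModelStructureError(f"node {nd.node_id}: gamma targets missing node {did}")
            if by_id[did].is_living:
                raise ModelStructureError(
                    f"node {nd.node_id}: gamma target {did} is a living node"
                )

    for (prey_id, pred_id), frac in diet.items():
        pred, prey = by_id[pred_id], by_id[prey_id]
        if pred.trophic_status is TrophicStatus.DETRITUS:
            raise ModelStructureError(f"detritus node {pred_id} cannot have a diet")
        if pred.trophic_status is TrophicStatus.AUTOTROPH:
            raise ModelStructureError(f"autotroph node {pred_id} cannot have a diet")
        if not _check_layer(pred, prey):
            raise LayerCompatibilityError(
                f"{pred.name or pred_id} ({pred.layer.value}) cannot reach prey "
                f"{prey.name or prey_id} ({prey.layer.value})"
            )
    for nd in node_list:
        s = diet.column_sum(nd.node_id)
        if nd.is_consumer:
            if abs(s - 1.0) > diet_tolerance:
                raise DietNormalizationError(f"diet of {nd.name or nd.node_id} sums to {s:g}")
        elif s > diet_tolerance:
            raise ModelStructureError(
                f"non-consumer node {nd.node_id} has diet entries"
            )
    return FoodWebModel(nodes=node_list, diet=diet, state_label=state_label)


def compute_flows(
    model: FoodWebModel,
    rates: RealizedRates,
    diet: DietMatrix | None = None,
) -> FlowMatrix:
    """Realize the carbon flux matrix from biomasses, rates and diet fractions.

    Trophic links: ``F_ij = alpha*_j B_j delta_ij``.  Flows into non-living
    pools are each node's unassimilated ingestion ``eps_j alpha*_j B_j`` plus
    its other-mortality flow ``(1 - EE_j) mu*_j B_j``, partitioned by its
    gamma allocations.  ``diet`` overrides the model's diet (used by the
    balancer when link weights are perturbed).
    """
    if np.any(rates.mu < 0) or np.any(rates.alpha < 0):
        raise ValueError("rates must be non-negative")
    d = diet if diet is not None else model.diet
    B = model.biomass
    Q = rates.alpha * B
    for k, nd in enumerate(model.nodes):
        if not nd.is_consumer and d.column_sum(nd.node_id) > 0:
            raise ValueError(f"diet entry for non-consumer node {nd.node_id}")
        if nd.is_consumer and Q[k] == 0 and d.column_sum(nd.node_id) > 0:
            raise ValueError(
                f"node {nd.node_id} has diet entries but zero consumption rate"
            )
    F = d.values * Q[np.newaxis, :]

    # close the living nodes: feces + other mortality routed to non-living pools
    P = rates.mu * B
    living = model.living_mask
    predation = F[:, :].sum(axis=1)  # everything leaving i through trophic links
    mu0 = np.where(living, np.maximum(P - predation, 0.0), 0.0)
    feces = model.epsilon * Q
    G = model.gamma_matrix()
    F = F + G * (feces + mu0)[:, np.newaxis]
    return FlowMatrix(flows=F, node_ids=model.node_ids)


def balance_accounting(
    model: FoodWebModel,
    flows: FlowMatrix,
    rates: RealizedRates,
) -> list[NodeBudget]:
    """Derive per-node carbon budgets (respiration, mortality, EE, residuals).

    Infeasibility (negative respiration, EE > 1, detritus deficit) is reported
    in the budgets rather than raised, so the balancer can score candidates.
    """
    B = model.biomass
    p_phi = model.p_phi
    eps = model.epsilon
    G = model.gamma_matrix()
    F = flows.flows
    n = model.n

    P = rates.mu * B
    Q = rates.alpha * B
    living = model.living_mask
    feces = eps * Q
    gamma_sum = G.sum(axis=1)
    # diet links end in living consumers, gamma closure links in non-living
    # pools, so the two column sets are disjoint: predation on i is exactly
    # the part of i's outflow that enters living nodes.
    predation = F[:, living].sum(axis=1)
    mu0 = np.where(living, np.maximum(P - predation, 0.0), 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        ee = np.where(P > 0, predation / np.where(P > 0, P, 1.0), 0.0)

    budgets: list[NodeBudget] = []
    col_in = F.sum(axis=0)
    row_out = F.sum(axis=1)
    for k, nd in enumerate(model.nodes):
        if nd.is_living:
            p_het = (1.0 - p_phi[k]) * P[k]
            rho = (1.0 - eps[k]) * Q[k] - p_het if nd.is_consumer else 0.0
            routed = gamma_sum[k] * (feces[k] + mu0[k])
            export = (1.0 - gamma_sum[k]) * (feces[k] + mu0[k])
            residual = max(0.0, predation[k] - P[k])
            budgets.append(
                NodeBudget(
                    node_id=nd.node_id,
                    production=P[k],
                    production_heterotrophic=p_het,
                    consumption=Q[k],
                    respiration=rho,
                    natural_mortality=mu0[k],
                    unassimilated_flow=feces[k],
                    ecotrophic_efficiency=float(ee[k]),
                    flow_to_detritus=routed,
                    export=export,
                    residual=residual,
                    is_consumer=nd.is_consumer,
                    is_living=True,
                )
            )
        else:
            inp = col_in[k]
            out = row_out[k]
            surplus = inp - out
            budgets.append(
                NodeBudget(
                    node_id=nd.node_id,
                    production=0.0,
                    production_heterotrophic=0.0,
                    consumption=0.0,
                    respiration=0.0,
                    natural_mortality=0.0,
                    unassimilated_flow=0.0,
                    ecotrophic_efficiency=0.0,
                    flow_to_detritus=0.0,
                    export=max(surplus, 0.0),
                    residual=max(0.0, -surplus),
                    is_consumer=False,
                    is_living=False,
                    detritus_input=inp,
                    detritus_output=out,
                    detritus_surplus=surplus,
                )
            )
    return budgets
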