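"""Fixtures and generators for plankton food-web models.

Three kinds of inputs are produced here:

* the Gulf-of-Naples (GoN) summer plankton node table - 63 functional nodes
  with published carbon biomasses for the bloom ("green") and non-bloom
  ("blue") states - together with a guild-structured template diet matrix
  and guild-default physiological rate ranges.  Biomasses are the published
  values; the rate ranges and diet weights are synthetic reconstructions
  from the nodes' described trophic roles (the originals are not public),
  and are marked as such in the model metadata;
* tiny toy webs (linear chains) with closed-form trophic levels and
  transfer efficiencies, used as ground truth for the diagnostics;
* random guild-structured webs built flows-first, so that every generated
  web carries a known, exactly balanced parameterization that balancing
  searches can be scored against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model_core import (
    DietMatrix,
    FlowMatrix,
    FoodWebModel,
    FunctionalNode,
    Layer,
    LAYER_CODES,
    RealizedRates,
    STATUS_CODES,
    TrophicStatus,
    build_model,
    compute_flows,
)

__all__ = [
    "GON_TABLE",
    "WebGeneratorConfig",
    "GeneratedWeb",
    "gon_fixture",
    "gon_diet_template",
    "gon_model",
    "make_toy_chain",
    "generate_random_web",
    "generate_state_pair",
]

# ---------------------------------------------------------------------------
# GoN node table: (id, name, status, layer, biomass_blue, biomass_green),
# biomasses in mgC m^-2.  Status A/H/M/D, layer s/d/a (surface / deep /
# whole column).
# ---------------------------------------------------------------------------

GON_TABLE: list[tuple[int, str, str, str, float, float]] = [
    (1, "Cyanobacteria (s)", "A", "s", 3.2, 4.0),
    (2, "Prochlorophytes (s)", "A", "s", 0.3, 0.4),
    (3, "Phyto-nanoflagellates (s)", "A", "s", 22.0, 80.5),
    (4, "Chaetoceros spp. (s)", "A", "s", 4.2, 83.3),
    (5, "Leptocylindrus spp. (s)", "A", "s", 31.3, 317.0),
    (6, "Skeletonema spp. (s)", "A", "s", 5.7, 47.0),
    (7, "Small diatoms (s)", "A", "s", 4.3, 34.1),
    (8, "Pennate diatoms (s)", "A", "s", 1.2, 11.6),
    (9, "Pseudo-nitzschia spp. (s)", "A", "s", 2.3, 19.9),
    (10, "Centric diatoms (s)", "A", "s", 19.7, 83.9),
    (11, "Coccolithophores (s)", "A", "s", 3.9, 12.3),
    (12, "Phyto-microflagellates (s)", "A", "s", 3.9, 12.9),
    (13, "Mixotrophic nanoflagellates (s)", "M", "s", 0.1, 0.2),
    (14, "Small dinoflagellates (s)", "M", "s", 6.6, 23.5),
    (15, "Medium dinoflagellates (s)", "M", "s", 4.1, 13.5),
    (16, "Myrionecta rubra (a)", "M", "a", 0.6, 2.0),
    (17, "Tontonia spp. (s)", "M", "s", 9.5, 35.0),
    (18, "Laboea spp. (s)", "M", "s", 1.8, 6.5),
    (19, "Strombidium spp. (s)", "M", "s", 11.6, 34.6),
    (20, "HNF (s)", "H", "s", 0.4, 1.3),
    (21, "Hetero-dinoflagellates (s)", "H", "s", 7.7, 48.0),
    (22, "Prostomatids (s)", "H", "s", 1.7, 17.5),
    (23, "Strobilidium spp. (s)", "H", "s", 4.3, 12.9),
    (24, "Tintinnids (s)", "H", "s", 0.2, 1.7),
    (25, "Nanociliates (s)", "H", "s", 0.7, 2.3),
    (26, "Cyanobacteria (d)", "A", "d", 108.4, 155.9),
    (27, "Prochlorophytes (d)", "A", "d", 10.8, 15.6),
    (28, "Phyto-nanoflagellates (d)", "A", "d", 33.6, 48.3),
    (29, "Coccolithophorids (d)", "A", "d", 166.2, 239.0),
    (30, "Diatoms (d)", "A", "d", 10.3, 14.7),
    (31, "Mixotrophic nanoflagellates (d)", "M", "d", 0.1, 0.1),
    (32, "Small dinoflagellates (d)", "M", "d", 85.5, 108.2),
    (33, "Medium dinoflagellates (d)", "M", "d", 52.9, 62.3),
    (34, "HNF (d)", "H", "d", 0.1, 0.1),
    (35, "Hetero-dinoflagellates (d)", "H", "d", 34.2, 44.6),
    (36, "Prostomatids (d)", "H", "d", 7.3, 16.2),
    (37, "Strobilidium spp. (d)", "H", "d", 19.1, 12.0),
    (38, "Tintinnids (d)", "H", "d", 1.0, 1.6),
    (39, "Nanociliates (d)", "H", "d", 3.0, 2.1),
    (40, "Heterotrophic bacteria (s)", "H", "s", 32.7, 108.5),
    (41, "Heterotrophic bacteria (d)", "H", "d", 373.5, 397.3),
    (42, "Penilia avirostris (a)", "H", "a", 96.1, 100.8),
    (43, "Cladocerans (a)", "H", "a", 33.8, 65.7),
    (44, "Paracalanus parvus (a)", "H", "a", 25.5, 26.8),
    (45, "Acartia clausii (a)", "H", "a", 7.5, 22.0),
    (46, "Temora stylifera (a)", "H", "a", 39.1, 37.0),
    (47, "Centropages typicus (a)", "H", "a", 12.2, 24.6),
    (48, "Other calanoids (a)", "H", "a", 8.7, 7.7),
    (49, "Juvenile calanoids (a)", "H", "a", 14.6, 21.2),
    (50, "Appendicularia (a)", "H", "a", 36.1, 39.8),
    (51, "Doliolids (a)", "H", "a", 2.0, 3.7),
    (52, "Salps (a)", "H", "a", 16.2, 30.8),
    (53, "Meroplankton (a)", "H", "a", 3.5, 4.7),
    (54, "Oithona spp. (a)", "H", "a", 1.4, 1.3),
    (55, "Detritivora (a)", "H", "a", 7.4, 5.2),
    (56, "Carnivora (a)", "H", "a", 276.3, 295.5),
    (57, "Appendicularia houses (a)", "D", "a", 113.8, 489.9),
    (58, "Small F.P. (a)", "D", "a", 81.5, 396.5),
    (59, "Salp F.P. (a)", "D", "a", 3.8, 7.3),
    (60, "Carnivores F.P. (a)", "D", "a", 0.6, 1.2),
    (61, "DOC (s)", "D", "s", 16.6, 102.9),
    (62, "DOC (d)", "D", "d", 58.3, 81.9),
    (63, "Generic particulate detritus (a)", "D", "a", 4486.8, 2629.7),
]

SURFACE_PHYTO_IDS = list(range(1, 13))

# guild membership (by node id) used for rate defaults and the diet template
_GUILD_OF: dict[int, str] = {}
for _id in range(1, 13):
    _GUILD_OF[_id] = "phyto_s"
for _id in range(26, 31):
    _GUILD_OF[_id] = "phyto_d"
for _id in (14, 15, 16, 17, 18, 19, 32, 33):
    _GUILD_OF[_id] = "mixo"
for _id in (13, 31):
    _GUILD_OF[_id] = "mixo_nano"  # fast-growing nanoflagellate mixotrophs
for _id in (21, 22, 23, 24, 35, 36, 37, 38):
    _GUILD_OF[_id] = "hprot"
for _id in (20, 25, 34, 39):
    _GUILD_OF[_id] = "hprot_small"  # HNF and nanociliates: high turnover
for _id in (40, 41):
    _GUILD_OF[_id] = "bact"
for _id in (42, 43, 50, 51, 52):
    _GUILD_OF[_id] = "meso_filter"
for _id in (44, 45, 46, 47, 48, 49):
    _GUILD_OF[_id] = "meso_cal"
for _id in (53, 54, 55):
    _GUILD_OF[_id] = "meso_other"
_GUILD_OF[56] = "carn"
for _id in (57, 58, 59, 60, 61, 62, 63):
    _GUILD_OF[_id] = "det"

# guild-default rate ranges (d^-1) and unassimilated fractions.  These are
# synthetic literature-style defaults, NOT the original study's values.
_GUILD_RANGES: dict[str, dict] = {
    "phyto_s": {"mu": (0.5, 2.0), "alpha": (0.0, 0.0), "eps": 0.0},
    "phyto_d": {"mu": (0.15, 0.7), "alpha": (0.0, 0.0), "eps": 0.0},
    "mixo": {"mu": (0.15, 0.8), "alpha": (0.2, 1.2), "eps": 0.3},
    "mixo_nano": {"mu": (0.3, 2.0), "alpha": (0.5, 3.0), "eps": 0.3},
    "hprot": {"mu": (0.2, 1.0), "alpha": (0.5, 2.5), "eps": 0.3},
    "hprot_small": {"mu": (0.5, 2.5), "alpha": (1.0, 5.0), "eps": 0.3},
    "bact": {"mu": (0.15, 0.8), "alpha": (0.3, 2.0), "eps": 0.1},
    "meso_filter": {"mu": (0.08, 0.35), "alpha": (0.25, 1.0), "eps": 0.3},
    "meso_cal": {"mu": (0.06, 0.3), "alpha": (0.2, 0.8), "eps": 0.3},
    "meso_other": {"mu": (0.06, 0.3), "alpha": (0.2, 0.8), "eps": 0.3},
    "carn": {"mu": (0.02, 0.12), "alpha": (0.08, 0.35), "eps": 0.25},
    "det": {"mu": (0.0, 0.0), "alpha": (0.0, 0.0), "eps": 0.0},
}

# phototrophy:heterotrophy metabolic ratio for the mixotrophic nodes
_PH_HET: dict[int, float] = {13: 2.0, 14: 1.0, 15: 1.0, 16: 2.0, 17: 1.0,
                             18: 1.0, 19: 1.0, 31: 2.0, 32: 1.0, 33: 1.0}

# gamma: where each living node's feces + other mortality go
# (fractions over non-living node ids; the remainder leaves the web)
def _gamma_for(node_id: int, layer_code: str) -> dict[int, float]:
    if _GUILD_OF[node_id] == "det":
        return {}
    if node_id in (40,):
        return {61: 0.1, 63: 0.8}
    if node_id in (41,):
        return {62: 0.1, 63: 0.8}
    if node_id == 50:
        return {57: 0.5, 58: 0.2, 63: 0.2}
    if node_id == 52:
        return {59: 0.6, 63: 0.3}
    if node_id == 56:
        return {60: 0.5, 63: 0.4}
    if _GUILD_OF[node_id] in ("meso_filter", "meso_cal", "meso_other"):
        return {58: 0.5, 63: 0.4}
    # unicellular plankton: DOC of their layer plus the generic detritus pool
    if layer_code == "s":
        return {61: 0.15, 63: 0.75}
    if layer_code == "d":
        return {62: 0.15, 63: 0.75}
    return {61: 0.07, 62: 0.07, 63: 0.76}  # whole-column unicellulars


# diet template: predator id -> list of (prey id tuple, pool weight).
# Pool weights are split within the pool proportionally to prey biomass
# (geometric mean of the two states), which keeps grazing pressure per unit
# prey biomass roughly even inside a pool.
_DIET_POOLS: dict[int, list[tuple[tuple[int, ...], float]]] = {
    13: [((40,), 0.5), ((1, 2), 0.5)],
    31: [((41,), 0.5), ((26, 27), 0.5)],
    14: [((3, 4, 6, 7, 8, 9, 11, 12), 0.9), ((40,), 0.1)],
    15: [((3, 4, 6, 7, 8, 9, 10, 11, 12), 0.9), ((40,), 0.1)],
    16: [((3, 28), 1.0)],
    17: [((1, 2, 3, 11, 12), 0.82), ((40,), 0.15), ((20, 25), 0.03)],
    18: [((1, 2, 3, 11, 12), 0.84), ((40,), 0.15), ((20, 25), 0.01)],
    19: [((1, 2, 3, 11, 12), 0.82), ((40,), 0.15), ((20, 25), 0.03)],
    32: [((26, 27, 28, 29, 30), 0.9), ((41,), 0.1)],
    33: [((26, 27, 28, 29, 30), 0.9), ((41,), 0.1)],
    20: [((40,), 0.7), ((1, 2), 0.3)],
    34: [((41,), 0.7), ((26, 27), 0.3)],
    21: [((3, 4, 5, 6, 7, 8, 9, 10, 11, 12), 0.955), ((13, 20, 25), 0.015), ((22,), 0.03)],
    22: [((3, 4, 5, 6, 7, 10), 0.93), ((20, 25), 0.02), ((21,), 0.05)],
    23: [((1, 2, 3, 11, 12), 0.76), ((40,), 0.22), ((20, 25), 0.02)],
    24: [((3, 11, 12), 0.88), ((40,), 0.1), ((20, 25), 0.02)],
    25: [((40,), 0.5), ((1, 2), 0.3), ((3,), 0.2)],
    35: [((26, 27, 28, 29, 30), 0.96), ((31, 34, 39), 0.01), ((36,), 0.03)],
    36: [((28, 29, 30), 0.93), ((34, 39), 0.01), ((35,), 0.06)],
    37: [((26, 27, 28), 0.77), ((41,), 0.22), ((34, 39), 0.01)],
    38: [((28, 29), 0.88), ((41,), 0.11), ((34, 39), 0.01)],
    39: [((41,), 0.5), ((26, 27), 0.3), ((28,), 0.2)],
    40: [((61,), 0.5), ((63,), 0.5)],
    41: [((62,), 0.5), ((63,), 0.5)],
    42: [((1, 2, 3, 11, 12, 26, 27, 28, 29), 0.74), ((40, 41), 0.15),
         ((13, 20, 31, 34), 0.01), ((63,), 0.1)],
    43: [((3, 4, 6, 7, 11, 12, 28, 29, 30), 0.84), ((13, 20), 0.01), ((63,), 0.15)],
    44: [((4, 5, 6, 7, 8, 9, 10, 28, 29, 30), 0.55),
         ((14, 15, 17, 18, 19, 21, 22, 23, 24, 32, 33, 35, 36, 37, 38), 0.35),
         ((63,), 0.1)],
    45: [((4, 5, 6, 7, 8, 9, 10, 28, 29, 30), 0.55),
         ((14, 15, 17, 18, 19, 21, 22, 23, 24, 32, 33, 35, 36, 37, 38), 0.35),
         ((63,), 0.1)],
    46: [((4, 5, 6, 7, 8, 9, 10, 28, 29, 30), 0.55),
         ((14, 15, 17, 18, 19, 21, 22, 23, 24, 32, 33, 35, 36, 37, 38), 0.35),
         ((63,), 0.1)],
    47: [((4, 5, 6, 7, 8, 9, 10, 28, 29, 30), 0.5),
         ((14, 15, 17, 18, 19, 21, 22, 23, 24, 32, 33, 35, 36, 37, 38), 0.4),
         ((63,), 0.1)],
    48: [((4, 5, 6, 7, 8, 9, 10, 28, 29, 30), 0.55),
         ((14, 15, 17, 18, 19, 21, 22, 23, 24, 32, 33, 35, 36, 37, 38), 0.35),
         ((63,), 0.1)],
    49: [((3, 11, 12, 28, 29), 0.75), ((14, 15, 25, 32, 33, 39), 0.1), ((63,), 0.15)],
    50: [((1, 2, 26, 27), 0.38), ((3, 28), 0.25), ((40, 41), 0.3),
         ((13, 20, 31, 34), 0.02), ((63,), 0.05)],
    51: [((3, 4, 7, 11, 12, 26, 27, 28, 29, 30), 0.8), ((40, 41), 0.1), ((63,), 0.1)],
    52: [((1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 26, 27, 28, 29, 30), 0.9), ((63,), 0.1)],
    53: [((3, 4, 7, 10, 11, 12, 28, 29, 30), 0.7), ((63,), 0.3)],
    54: [((14, 15, 17, 19, 21, 23, 32, 33, 35, 37), 0.7), ((10,), 0.1), ((63,), 0.2)],
    55: [((57, 58, 59, 63), 0.8), ((10, 29, 30), 0.2)],
    56: [((42, 43, 44, 45, 46, 47, 48, 49, 50, 51, 52, 53, 54, 55), 1.0)],
}


def _geomean_biomass() -> dict[int, float]:
    return {row[0]: math.sqrt(row[4] * row[5]) for row in GON_TABLE}


def gon_diet_template() -> DietMatrix:
    """Guild-structured template diet matrix for the GoN node set.

    Shared by the green and blue states (the community is the same in both);
    pool weights follow each node's described trophic role, split within a
    pool by prey biomass.  This is a synthetic reconstruction, not the
    original study's diet matrix.
    """
    gb = _geomean_biomass()
    node_ids = [row[0] for row in GON_TABLE]
    diet = DietMatrix(node_ids)
    for pred, pools in _DIET_POOLS.items():
        total_w = sum(w for _, w in pools)
        for members, w in pools:
            weights = np.array([gb[m] for m in members])
            weights = weights / weights.sum()
            for m, frac in zip(members, weights):
                diet[m, pred] = diet[m, pred] + (w / total_w) * float(frac)
    return diet


def _calibrate_rate_scales(
    nodes: list[FunctionalNode],
    diet: DietMatrix,
    corner_ee: float = 0.85,
    n_rounds: int = 300,
) -> dict[int, float]:
    """Per-consumer activity scales making the favorable corner feasible.

    The favorable corner is production rates at range maxima and consumption
    rates at range minima - the configuration a mass-balance search is
    pushed towards when grazing pressure is high.  Each consumer gets a
    scale factor applied to *both* its rate ranges (preserving its gross
    growth efficiency envelope) such that, at the corner, no prey is grazed
    above ``corner_ee`` of the production it can achieve there.  Shrinking
    only the predators of overgrazed prey equalizes grazing pressure, so
    most consumers end up close to their feasibility boundary - the regime
    in which balanced solutions sit near the rate-range corners.  Producer
    and bacterial caps anchor the fixpoint (producers are never scaled;
    bacteria feed on non-living pools, which carry no production cap).
    """
    by_id = {n.node_id: n for n in nodes}
    scales = {n.node_id: 1.0 for n in nodes if n.is_consumer}

    def corner_cap(n: FunctionalNode) -> float:
        mu_hi = n.production_rate_range[1]
        if not n.is_consumer:
            return mu_hi * n.biomass
        s = scales[n.node_id]
        a_lo = n.consumption_rate_range[0] * s
        het_cap = 0.85 * (1.0 - n.unassimilated_fraction) * a_lo
        if n.trophic_status is TrophicStatus.MIXOTROPH:
            pphi = _PH_HET[n.node_id] / (1.0 + _PH_HET[n.node_id])
            mu_cap = het_cap / (1.0 - pphi)
        else:
            mu_cap = het_cap
        return min(mu_hi * s, mu_cap) * n.biomass

    predators_of: dict[int, list[tuple[int, float]]] = {}
    for (prey, pred), frac in diet.items():
        if by_id[prey].is_living and frac > 0:
            predators_of.setdefault(prey, []).append((pred, frac))

    for _ in range(n_rounds):
        # headroom ratio of each consumer's most binding prey
        factor = {j: float("inf") for j in scales}
        for prey, preds in predators_of.items():
            demand = sum(
                frac * by_id[j].consumption_rate_range[0] * scales[j] * by_id[j].biomass
                for j, frac in preds
            )
            if demand <= 0:
                continue
            r = corner_ee * corner_cap(by_id[prey]) / demand
            for j, _ in preds:
                factor[j] = min(factor[j], r)
        converged = True
        for j, r in factor.items():
            if r == float("inf"):  # no living prey (e.g. bacteria)
                continue
            if not 0.999 < r < 1.001:
                converged = False
            # damped move toward the binding point, both up and down
            scales[j] *= float(np.clip(r, 0.6, 1.5) ** 0.7)
        if converged:
            break
    else:
        raise ValueError(
            "rate calibration did not converge: the diet template contains a "
            "mutually-binding predation loop"
        )
    return scales


def gon_fixture(state: str) -> list[FunctionalNode]:
    """The 63-node GoN node table for one system state ("green" or "blue").

    Names, trophic statuses, layers and biomasses are the published values;
    rate ranges, unassimilated fractions, Ph/Het ratios and detrital-fate
    allocations are documented guild defaults (synthetic reconstructions),
    with consumption ranges calibrated per state so that a mass-balanced
    parameterization exists inside the declared ranges.
    """
    col = {"green": 5, "blue": 4}.get(state)
    if col is None:
        raise ValueError(f"unknown state {state!r}: expected 'green' or 'blue'")
    nodes: list[FunctionalNode] = []
    for row in GON_TABLE:
        nid, name, status, layer, *_ = row
        guild = _GUILD_OF[nid]
        rng = _GUILD_RANGES[guild]
        nodes.append(
            FunctionalNode(
                node_id=nid,
                name=name,
                trophic_status=STATUS_CODES[status],
                layer=LAYER_CODES[layer],
                biomass=row[col],
                production_rate_range=rng["mu"],
                consumption_rate_range=rng["alpha"],
                unassimilated_fraction=rng["eps"],
                ph_het=_PH_HET.get(nid, 0.0),
                detritus_allocation=_gamma_for(nid, layer),
            )
        )
    # state-specific calibration of consumer rate ranges (see docstring)
    diet = gon_diet_template()
    scales = _calibrate_rate_scales(nodes, diet)
    for n in nodes:
        if n.is_consumer:
            s = scales[n.node_id]
            lo, hi = n.consumption_rate_range
            n.consumption_rate_range = (lo * s, hi * s)
            lo, hi = n.production_rate_range
            n.production_rate_range = (lo * s, hi * s)
    return nodes


def gon_model(state: str) -> FoodWebModel:
    """Validated GoN food-web model (fixture nodes + template diet)."""
    return build_model(gon_fixture(state), gon_diet_template(), state_label=state)


# ---------------------------------------------------------------------------
# toy chains with closed-form answers
# ---------------------------------------------------------------------------


def make_toy_chain(
    n_levels: int,
    te_per_step: float,
    basal_production: float = 100.0,
) -> "GeneratedWeb":
    """A linear chain whose flows realize exactly the requested per-step TE.

    Node 1 is a producer with production ``basal_production``; consumer at
    level k ingests ``te_per_step`` of the input to level k-1 and produces
    ``te_per_step`` of its own ingestion, so every spine step has transfer
    efficiency ``te_per_step`` and trophic levels are the integers 1..n.
    Interior nodes have EE = 1 (fully grazed); the top consumer's production
    leaves the web unused.
    """
    if n_levels < 2:
        raise ValueError("need at least 2 levels")
    if not 0 < te_per_step < 1:
        raise ValueError("per-step TE must be in (0, 1)")
    t = te_per_step
    node_ids = list(range(1, n_levels + 1))
    nodes = [
        FunctionalNode(
            node_id=1,
            name="producer",
            trophic_status=TrophicStatus.AUTOTROPH,
            layer=Layer.SURFACE,
            biomass=basal_production,
            production_rate_range=(1.0, 1.0),
        )
    ]
    mu = np.zeros(n_levels)
    alpha = np.zeros(n_levels)
    mu[0] = 1.0
    q = t * basal_production  # ingestion of the level-2 consumer
    for k in range(2, n_levels + 1):
        nodes.append(
            FunctionalNode(
                node_id=k,
                name=f"consumer L{k}",
                trophic_status=TrophicStatus.HETEROTROPH,
                layer=Layer.SURFACE,
                biomass=q,
                production_rate_range=(t, t),
                consumption_rate_range=(1.0, 1.0),
                unassimilated_fraction=0.0,
            )
        )
        mu[k - 1] = t
        alpha[k - 1] = 1.0
        q *= t
    diet = DietMatrix(node_ids)
    for k in range(2, n_levels + 1):
        diet[k - 1, k] = 1.0
    model = build_model(nodes, diet, state_label=f"toy-chain-te{t:g}")
    rates = RealizedRates(mu=mu, alpha=alpha)
    flows = compute_flows(model, rates)
    return GeneratedWeb(model=model, rates=rates, flows=flows)


# ---------------------------------------------------------------------------
# random guild-structured webs with known balanced ground truth
# ---------------------------------------------------------------------------


@dataclass
class WebGeneratorConfig:
    """Study conditions for the random web generator.

    ``guild_mix`` gives node counts per guild; the default is a scaled-down
    version of the GoN community structure.  ``state_factor`` is the
    surface-phytoplankton biomass ratio between the paired bloom and
    non-bloom states (seven-fold by default, as observed).  Declared rate
    ranges are centred on the planted rates with half-width
    ``rate_range_halfwidth`` (fractional).
    """

    n_nodes: int = 25
    guild_mix: dict[str, int] = field(default_factory=lambda: {
        "phyto": 7, "mixo": 3, "hprot": 4, "bact": 2, "meso": 5, "carn": 1,
        "detritus": 2, "doc": 1,
    })
    layer_split: float = 0.5  # fraction of unicellular nodes in the surface layer
    state_factor: float = 7.0
    connectance: float = 0.6  # fraction of allowed prey actually linked
    rate_range_halfwidth: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if sum(self.guild_mix.values()) != self.n_nodes:
            raise ValueError(
                f"guild counts sum to {sum(self.guild_mix.values())}, expected {self.n_nodes}"
            )
        if self.state_factor <= 0:
            raise ValueError("state_factor must be > 0")
        if not 0 < self.connectance <= 1:
            raise ValueError("connectance must be in (0, 1]")


@dataclass
class GeneratedWeb:
    """A model together with its planted, exactly balanced parameterization."""

    model: FoodWebModel
    rates: RealizedRates
    flows: FlowMatrix


_GEN_BIOMASS_SCALE = {
    "phyto": 60.0, "mixo": 20.0, "hprot": 15.0, "bact": 80.0,
    "meso": 30.0, "carn": 100.0, "detritus": 400.0, "doc": 50.0,
}
_GEN_EPS = {"mixo": 0.3, "hprot": 0.3, "bact": 0.1, "meso": 0.3, "carn": 0.25}


def generate_random_web(
    config: WebGeneratorConfig | None = None,
    state: str = "green",
) -> GeneratedWeb:
    """Build a random guild-structured web with known balanced flows.

    Flows are constructed first - consumption is assigned top-down through
    the guild hierarchy (carnivore -> mesozooplankton -> protists ->
    producers/bacteria) and every prey's production is then set to cover the
    demand on it at a high ecotrophic efficiency - so the planted rates are
    feasible by construction.  Rates, diet fractions and declared ranges are
    derived from the flows.  Deterministic in ``config.seed``.
    """
    config = config or WebGeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed + (0 if state == "green" else 1_000_003))

    # --- nodes ------------------------------------------------------------
    nodes: list[FunctionalNode] = []
    guild_ids: dict[str, list[int]] = {g: [] for g in config.guild_mix}
    nid = 0
    struct_rng = np.random.default_rng(config.seed)  # shared across states
    layer_choices: dict[int, Layer] = {}
    biomass_draws: dict[int, float] = {}
    for guild, count in config.guild_mix.items():
        for k in range(count):
            nid += 1
            guild_ids[guild].append(nid)
            if guild in ("meso", "carn", "detritus"):
                layer = Layer.WHOLE_COLUMN
            elif guild == "doc":
                layer = Layer.SURFACE if k % 2 == 0 else Layer.DEEP
            else:
                layer = (
                    Layer.SURFACE
                    if struct_rng.uniform() < config.layer_split
                    else Layer.DEEP
                )
            layer_choices[nid] = layer
            b = _GEN_BIOMASS_SCALE[guild] * struct_rng.lognormal(0.0, 0.6)
            biomass_draws[nid] = b
    base_biomass = dict(biomass_draws)  # pre-state biomasses, shared by the pair
    if state == "blue":
        for i in guild_ids["phyto"]:
            if layer_choices[i] is Layer.SURFACE:
                biomass_draws[i] /= config.state_factor

    status_of = {
        "phyto": TrophicStatus.AUTOTROPH, "mixo": TrophicStatus.MIXOTROPH,
        "hprot": TrophicStatus.HETEROTROPH, "bact": TrophicStatus.HETEROTROPH,
        "meso": TrophicStatus.HETEROTROPH, "carn": TrophicStatus.HETEROTROPH,
        "detritus": TrophicStatus.DETRITUS, "doc": TrophicStatus.DETRITUS,
    }
    nonliving_ids = guild_ids["detritus"] + guild_ids["doc"]
    for guild, ids in guild_ids.items():
        for i in ids:
            ph_het = float(struct_rng.uniform(0.5, 2.0)) if guild == "mixo" else 0.0
            gamma: dict[int, float] = {}
            if status_of[guild] is not TrophicStatus.DETRITUS:
                targets = [
                    d for d in nonliving_ids
                    if layer_choices[d] is Layer.WHOLE_COLUMN
                    or layer_choices[d] is layer_choices[i]
                    or layer_choices[i] is Layer.WHOLE_COLUMN
                ]
                total = float(struct_rng.uniform(0.6, 0.9))
                w = struct_rng.dirichlet(np.ones(len(targets)))
                gamma = {d: total * float(x) for d, x in zip(targets, w)}
            nodes.append(
                FunctionalNode(
                    node_id=i,
                    name=f"{guild}-{i}",
                    trophic_status=status_of[guild],
                    layer=layer_choices[i],
                    biomass=biomass_draws[i],
                    ph_het=ph_het,
                    unassimilated_fraction=_GEN_EPS.get(guild, 0.0),
                    detritus_allocation=gamma,
                )
            )
    nodes.sort(key=lambda n: n.node_id)
    by_id = {n.node_id: n for n in nodes}

    # --- link structure (guild feeding rules + layer compatibility) -------
    def reachable(pred: int, prey: int) -> bool:
        lp, lq = layer_choices[pred], layer_choices[prey]
        return Layer.WHOLE_COLUMN in (lp, lq) or lp is lq

    allowed: dict[int, list[int]] = {}
    menu = {
        "mixo": ["phyto", "bact"],
        "hprot": ["phyto", "bact", "mixo"],
        "bact": ["detritus", "doc"],
        "meso": ["phyto", "mixo", "hprot", "detritus"],
        "carn": ["meso"],
    }
    for guild, prey_guilds in menu.items():
        for pred in guild_ids[guild]:
            pool = [
                q for pg in prey_guilds for q in guild_ids[pg] if reachable(pred, q)
            ]
            if not pool:
                raise ValueError(
                    f"generation error: consumer {pred} ({guild}) has no reachable prey"
                )
            k = max(2 if len(pool) >= 2 else 1, int(round(config.connectance * len(pool))))
            chosen = list(struct_rng.choice(pool, size=min(k, len(pool)), replace=False))
            allowed[pred] = [int(c) for c in chosen]

    # --- flows-first parameterization -------------------------------------
    node_ids = [n.node_id for n in nodes]
    diet = DietMatrix(node_ids)
    for pred, prey_list in allowed.items():
        # struct_rng + pre-state biomasses so the paired states share one diet;
        # non-living pools are down-weighted (consumers prefer living prey)
        w = np.array([
            base_biomass[q] * (0.25 if q in nonliving_ids else 1.0)
            for q in prey_list
        ])
        w = w * struct_rng.lognormal(0.0, 0.3, size=len(prey_list))
        w = w / w.sum()
        for q, frac in zip(prey_list, w):
            diet[q, pred] = float(frac)

    mu = np.zeros(len(nodes))
    alpha = np.zeros(len(nodes))
    demand: dict[int, float] = {i: 0.0 for i in node_ids}
    idx = {i: k for k, i in enumerate(node_ids)}

    def add_demand(pred: int, Q: float) -> None:
        for q in allowed[pred]:
            demand[q] += diet[q, pred] * Q

    # carnivores: consumption capped so mesozoo prey can cover the demand
    for pred in guild_ids["carn"]:
        prey_cap = sum(
            0.25 * (1.0 - _GEN_EPS["meso"]) * _alpha_default(by_id[q], rng) * biomass_draws[q]
            for q in allowed[pred]
        )
        Q = min(float(rng.uniform(0.08, 0.2)) * biomass_draws[pred], prey_cap)
        alpha[idx[pred]] = Q / biomass_draws[pred]
        add_demand(pred, Q)

    # mesozoo: draw consumption, set production to cover carnivore demand
    for pred in guild_ids["meso"]:
        Q = _alpha_default(by_id[pred], rng) * biomass_draws[pred]
        alpha[idx[pred]] = Q / biomass_draws[pred]
        add_demand(pred, Q)
    for pred in guild_ids["meso"]:
        eps = _GEN_EPS["meso"]
        Q = alpha[idx[pred]] * biomass_draws[pred]
        gge = float(rng.uniform(0.25, 0.4))
        P = max(demand[pred] / float(rng.uniform(0.9, 0.98)), 0.5 * gge * (1.0 - eps) * Q)
        if P > 0.9 * (1.0 - eps) * Q:
            raise ValueError(
                f"generation error: demand on mesozoo node {pred} exceeds its production cap"
            )
        mu[idx[pred]] = P / biomass_draws[pred]

    # protists: production covers mesozoo demand, consumption derived
    for tier in ("hprot", "mixo"):
        for pred in guild_ids[tier]:
            eps = _GEN_EPS[tier]
            u = float(rng.uniform(0.9, 0.98))
            P = demand[pred] / u if demand[pred] > 0 else (
                0.3 * biomass_draws[pred] * float(rng.uniform(0.5, 1.5))
            )
            gge = float(rng.uniform(0.25, 0.4))
            if tier == "mixo":
                pphi = by_id[pred].ph_het / (1.0 + by_id[pred].ph_het)
                Q = (1.0 - pphi) * P / ((1.0 - eps) * gge)
            else:
                Q = P / ((1.0 - eps) * gge)
            mu[idx[pred]] = P / biomass_draws[pred]
            alpha[idx[pred]] = Q / biomass_draws[pred]
            add_demand(pred, Q)

    # bacteria: production covers protist demand; they feed on the pools
    for pred in guild_ids["bact"]:
        eps = _GEN_EPS["bact"]
        u = float(rng.uniform(0.9, 0.98))
        P = demand[pred] / u if demand[pred] > 0 else 0.3 * biomass_draws[pred]
        gge = float(rng.uniform(0.3, 0.5))
        Q = P / ((1.0 - eps) * gge)
        mu[idx[pred]] = P / biomass_draws[pred]
        alpha[idx[pred]] = Q / biomass_draws[pred]
        add_demand(pred, Q)

    # producers: production covers all grazing at high ecotrophic efficiency
    for prod in guild_ids["phyto"]:
        u = float(rng.uniform(0.9, 0.98))
        P = demand[prod] / u if demand[prod] > 0 else 0.5 * biomass_draws[prod]
        mu[idx[prod]] = P / biomass_draws[prod]

    # system-level consistency: total primary production must exceed total
    # consumer production even when detritus-fed bacteria are very active;
    # give producers headroom by lowering their ecotrophic efficiency
    pphi = {i: by_id[i].ph_het / (1.0 + by_id[i].ph_het) for i in guild_ids["mixo"]}
    pp_total = sum(mu[idx[i]] * biomass_draws[i] for i in guild_ids["phyto"])
    pp_total += sum(pphi[i] * mu[idx[i]] * biomass_draws[i] for i in guild_ids["mixo"])
    cons_total = sum(
        (1.0 - pphi.get(i, 0.0)) * mu[idx[i]] * biomass_draws[i]
        for g in ("mixo", "hprot", "bact", "meso", "carn")
        for i in guild_ids[g]
    )
    phyto_pp = sum(mu[idx[i]] * biomass_draws[i] for i in guild_ids["phyto"])
    mixo_pp = pp_total - phyto_pp
    if pp_total < 1.15 * cons_total and phyto_pp > 0:
        boost = (1.15 * cons_total - mixo_pp) / phyto_pp
        for i in guild_ids["phyto"]:
            mu[idx[i]] *= boost

    w = 1.0 + config.rate_range_halfwidth
    for n in nodes:
        k = idx[n.node_id]
        if mu[k] > 0:
            n.production_rate_range = (mu[k] / w, mu[k] * w)
        if alpha[k] > 0:
            n.consumption_rate_range = (alpha[k] / w, alpha[k] * w)

    model = build_model(nodes, diet, state_label=state)
    rates = RealizedRates(mu=mu, alpha=alpha)
    flows = compute_flows(model, rates)
    return GeneratedWeb(model=model, rates=rates, flows=flows)


def _alpha_default(node: FunctionalNode, rng: np.random.Generator) -> float:
    return float(rng.uniform(0.3, 0.6))


def generate_state_pair(
    config: WebGeneratorConfig | None = None,
) -> tuple[GeneratedWeb, GeneratedWeb]:
    """Paired bloom/non-bloom webs sharing structure and diet template.

    The two states share node identities, link structure and diet fractions;
    surface-phytoplankton biomass differs by ``config.state_factor``.
    """
    config = config or WebGeneratorConfig()
    return generate_random_web(config, state="green"), generate_random_web(config, state="blue")
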