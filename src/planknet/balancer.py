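"""Monte-Carlo search for mass-balanced parameterizations of a food web.

Biomasses are observations; per-biomass rates and link weights are only known
within ranges.  The balancer explores those ranges with a seeded, fixed-
temperature Metropolis walk on a constraint-violation score and keeps
candidates that satisfy, for every node, the balance conditions:

  i)   carbon conserved at each node (residuals within tolerance),
  ii)  system-level consistency between total primary production and total
       consumer production (direction configurable, see ``BalanceConfig``),
  iii) ecotrophic efficiency EE <= 1 (no prey eaten faster than it is produced),
  iv)  prey-to-predator transfer efficiency < 1,
  v)   respiration > 0 for every consumer.

The walk has two phases: a coarse phase that redraws rates uniformly within
their declared ranges and link weights within +/- ``link_variability`` of
their initial values, and a fine phase that multiplies every parameter by
Uniform(1 - f, 1 + f) with f = ``fine_perturbation`` (5% by default), always
clipping rates to their ranges and renormalizing diets.  Links contributing
less than ``prune_threshold`` of a predator's diet are removed at every step.
Among all feasible candidates encountered, the one with the smallest residual
norm (node imbalances plus non-living pool deficits) is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .model_core import (
    DietMatrix,
    FlowMatrix,
    FoodWebModel,
    NodeBudget,
    RealizedRates,
    balance_accounting,
    compute_flows,
)

__all__ = [
    "BalanceConfig",
    "FeasibilityReport",
    "BalancedModel",
    "BalanceError",
    "prune_weak_links",
    "propose_candidate",
    "check_feasibility",
    "mcmc_balance",
    "balance_from_rates",
]


class BalanceError(RuntimeError):
    """No feasible mass-balanced solution was found."""

    def __init__(self, message: str, best_score: float = float("inf"), violations: list[str] | None = None):
        super().__init__(message)
        self.best_score = best_score
        self.violations = violations or []


@dataclass
class BalanceConfig:
    max_iterations: int = 5000
    n_feasible_target: int = 25
    link_variability: float = 1.0  # coarse phase: +/-100% of initial link weight
    fine_perturbation: float = 0.05  # fine phase: +/-5% multiplicative
    prune_threshold: float = 1e-4  # links < 0.01% of predator diet are dropped
    tolerance: float = 1e-6
    seed: int = 0
    pp_constraint_direction: Literal["pp_greater", "pp_less"] = "pp_greater"
    coarse_iterations: int = 0  # 0 => fine search only, from the initial values
    temperature: float = 0.02

    def validate(self) -> None:
        if not 0 < self.link_variability <= 1.0:
            raise ValueError("link_variability must be in (0, 1]")
        for name in ("fine_perturbation", "prune_threshold", "tolerance"):
            v = getattr(self, name)
            if not 0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.max_iterations <= 0 or self.n_feasible_target <= 0:
            raise ValueError("iteration counts must be positive")


@dataclass
class FeasibilityReport:
    """Outcome of the constraint checks for one candidate parameterization."""

    respiration_positive: dict[int, bool]
    ee_in_unit_interval: dict[int, bool]
    balanced: dict[int, bool]
    pp_vs_consumer_production: bool
    all_te_below_one: bool
    violation_score: float

    @property
    def feasible(self) -> bool:
        return self.violation_score == 0.0

    def violated(self) -> list[str]:
        out = []
        if not all(self.respiration_positive.values()):
            bad = [i for i, ok in self.respiration_positive.items() if not ok]
            out.append(f"respiration <= 0 for nodes {bad}")
        if not all(self.ee_in_unit_interval.values()):
            bad = [i for i, ok in self.ee_in_unit_interval.items() if not ok]
            out.append(f"EE > 1 for nodes {bad}")
        if not all(self.balanced.values()):
            bad = [i for i, ok in self.balanced.items() if not ok]
            out.append(f"residual above tolerance for nodes {bad}")
        if not self.pp_vs_consumer_production:
            out.append("system primary/consumer production constraint violated")
        if not self.all_te_below_one:
            out.append("prey-to-predator transfer efficiency >= 1")
        return out


@dataclass
class BalancedModel:
    """A feasible parameterization: rates, realized diet, flows and budgets."""

    model: FoodWebModel
    rates: RealizedRates
    diet: DietMatrix
    flows: FlowMatrix
    budgets: list[NodeBudget]
    provenance: dict = field(default_factory=dict)

    def budget(self, node_id: int) -> NodeBudget:
        return self.budgets[self.model.index(node_id)]


def prune_weak_links(diet: DietMatrix, threshold: float = 1e-4) -> DietMatrix:
    """Drop links below ``threshold`` of each predator's diet sum; renormalize.

    Mirrors the balancing rule that a prey contributing less than 0.01% of a
    predator's ration is removed from its diet.
    """
    out = diet.copy()
    V = out.values
    for c, pred in enumerate(out.node_ids):
        col = V[:, c]
        s = col.sum()
        if s <= 0:
            continue
        weak = (col > 0) & (col < threshold * s)
        if weak.any():
            if (col > 0).sum() == weak.sum():
                raise ValueError(
                    f"pruning would empty the diet of consumer {pred}"
                )
            col[weak] = 0.0
        V[:, c] = col / col.sum()
    return out


@dataclass
class _Candidate:
    rates: RealizedRates
    diet: DietMatrix


def _rate_bounds(model: FoodWebModel) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    mu_lo = np.array([n.production_rate_range[0] for n in model.nodes])
    mu_hi = np.array([n.production_rate_range[1] for n in model.nodes])
    al_lo = np.array([n.consumption_rate_range[0] for n in model.nodes])
    al_hi = np.array([n.consumption_rate_range[1] for n in model.nodes])
    return mu_lo, mu_hi, al_lo, al_hi


def propose_candidate(
    model: FoodWebModel,
    current: _Candidate,
    initial_diet: DietMatrix,
    config: BalanceConfig,
    rng: np.random.Generator,
    phase: Literal["coarse", "fine"] = "fine",
) -> _Candidate:
    """Perturb rates and link weights into a new candidate.

    Coarse phase: rates drawn uniformly within their declared ranges, link
    weights uniformly within +/- ``link_variability`` of their *initial*
    values.  Fine phase: every parameter multiplied by Uniform(1-f, 1+f),
    rates clipped to their ranges, link weights clipped to the coarse-phase
    envelope around the initial values.  Diet columns are renormalized.
    """
    mu_lo, mu_hi, al_lo, al_hi = _rate_bounds(model)
    diet = current.diet.copy()
    V = diet.values
    V0 = initial_diet.values
    active = V > 0
    if phase == "coarse":
        mu = rng.uniform(mu_lo, mu_hi)
        alpha = rng.uniform(al_lo, al_hi)
        lo = V0 * (1.0 - config.link_variability)
        hi = V0 * (1.0 + config.link_variability)
        V[active] = rng.uniform(lo[active], hi[active])
    else:
        f = config.fine_perturbation
        mu = current.rates.mu * rng.uniform(1.0 - f, 1.0 + f, size=model.n)
        alpha = current.rates.alpha * rng.uniform(1.0 - f, 1.0 + f, size=model.n)
        mu = np.clip(mu, mu_lo, mu_hi)
        alpha = np.clip(alpha, al_lo, al_hi)
        if f > 0:
            V[active] = V[active] * rng.uniform(1.0 - f, 1.0 + f, size=int(active.sum()))
            lo = V0 * (1.0 - config.link_variability)
            hi = V0 * (1.0 + config.link_variability)
            V[active] = np.clip(V[active], lo[active], hi[active])
    colsum = V.sum(axis=0)
    nz = colsum > 0
    V[:, nz] = V[:, nz] / colsum[nz]
    return _Candidate(rates=RealizedRates(mu=mu, alpha=alpha), diet=diet)


def check_feasibility(
    model: FoodWebModel,
    flows: FlowMatrix,
    budgets: list[NodeBudget],
    config: BalanceConfig,
) -> FeasibilityReport:
    """Score a candidate against balance constraints i-v.

    The violation score sums normalized constraint excesses (EE above one,
    negative respiration, residuals above tolerance, the system production
    check) and is zero exactly when every flag passes.
    """
    resp_ok: dict[int, bool] = {}
    ee_ok: dict[int, bool] = {}
    bal_ok: dict[int, bool] = {}
    score = 0.0
    tol = config.tolerance
    te_ok = True
    pp_total = 0.0
    cons_prod_total = 0.0
    for b, nd in zip(budgets, model.nodes):
        throughput = max(b.consumption, b.production, b.detritus_input, 1e-12)
        if b.is_consumer:
            ok = b.respiration > 0
            resp_ok[b.node_id] = ok
            if not ok:
                score += (-b.respiration) / throughput + tol
            if b.consumption > 0 and b.production_heterotrophic / b.consumption >= 1.0:
                te_ok = False
                score += b.production_heterotrophic / b.consumption - 1.0 + tol
        if b.is_living:
            ok = b.ecotrophic_efficiency <= 1.0 + tol
            ee_ok[b.node_id] = ok
            if not ok:
                score += b.ecotrophic_efficiency - 1.0
            pphi = model.p_phi[model.index(b.node_id)]
            pp_total += pphi * b.production
            cons_prod_total += b.production_heterotrophic
        if b.is_living:
            ok = b.residual <= tol * max(throughput, 1.0)
            bal_ok[b.node_id] = ok
            if not ok:
                score += b.residual / throughput
        else:
            # a non-living pool's deficit is an import warning (reported in
            # its budget and in the residual norm), not an infeasibility:
            # detritus closes the model
            bal_ok[b.node_id] = True
    if config.pp_constraint_direction == "pp_greater":
        pp_ok = pp_total > cons_prod_total
        excess = max(0.0, cons_prod_total - pp_total)
    else:
        pp_ok = pp_total < cons_prod_total
        excess = max(0.0, pp_total - cons_prod_total)
    if not pp_ok:
        score += excess / max(pp_total + cons_prod_total, 1e-12) + tol
    return FeasibilityReport(
        respiration_positive=resp_ok,
        ee_in_unit_interval=ee_ok,
        balanced=bal_ok,
        pp_vs_consumer_production=pp_ok,
        all_te_below_one=te_ok,
        violation_score=score,
    )


def _residual_norm(budgets: list[NodeBudget]) -> float:
    return float(
        np.sqrt(sum(b.residual**2 + min(0.0, b.detritus_surplus) ** 2 for b in budgets))
    )


def _evaluate(model: FoodWebModel, cand: _Candidate, config: BalanceConfig):
    flows = compute_flows(model, cand.rates, diet=cand.diet)
    budgets = balance_accounting(model, flows, cand.rates)
    report = check_feasibility(model, flows, budgets, config)
    return flows, budgets, report


def balance_from_rates(
    model: FoodWebModel,
    rates: RealizedRates,
    diet: DietMatrix | None = None,
) -> BalancedModel:
    """Realize a :class:`BalancedModel` directly from given rates (no search).

    Used when a consistent parameterization is already known - e.g. the
    planted ground truth of a generated web.  No feasibility is enforced;
    budgets report whatever the rates imply.
    """
    d = diet if diet is not None else model.diet
    flows = compute_flows(model, rates, diet=d)
    budgets = balance_accounting(model, flows, rates)
    return BalancedModel(
        model=model, rates=rates, diet=d, flows=flows, budgets=budgets,
        provenance={"method": "direct"},
    )


def mcmc_balance(
    model: FoodWebModel,
    config: BalanceConfig | None = None,
    initial_rates: RealizedRates | None = None,
) -> BalancedModel:
    """Search for a mass-balanced parameterization of ``model``.

    Runs the coarse phase (if configured) followed by the fine Metropolis
    walk; collects feasible candidates until ``n_feasible_target`` are found
    or ``max_iterations`` steps have been taken, and returns the feasible
    candidate with the smallest residual norm.  Fully reproducible from
    ``config.seed``.  Raises :class:`BalanceError` (carrying the best score
    and the violated constraints) if nothing feasible is found.
    """
    config = config or BalanceConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    mu_lo, mu_hi, al_lo, al_hi = _rate_bounds(model)
    rates0 = initial_rates.copy() if initial_rates is not None else model.midpoint_rates()
    rates0.mu = np.clip(rates0.mu, mu_lo, mu_hi)
    rates0.alpha = np.clip(rates0.alpha, al_lo, al_hi)
    initial_diet = prune_weak_links(model.diet, config.prune_threshold)
    current = _Candidate(rates=rates0, diet=initial_diet.copy())
    flows, budgets, report = _evaluate(model, current, config)
    best_infeasible = (report.violation_score, report)
    feasible: list[tuple[float, _Candidate]] = []
    if report.feasible:
        feasible.append((_residual_norm(budgets), current))

    n_iter = 0
    cur_score = report.violation_score
    T = config.temperature
    phases = [("coarse", config.coarse_iterations), ("fine", config.max_iterations)]
    for phase, n_phase in phases:
        for _ in range(n_phase):
            if len(feasible) >= config.n_feasible_target:
                break
            n_iter += 1
            cand = propose_candidate(model, current, initial_diet, config, rng, phase=phase)
            try:
                cand.diet = prune_weak_links(cand.diet, config.prune_threshold)
            except ValueError:
                continue  # proposal would empty a diet; reject
            _, cbudgets, creport = _evaluate(model, cand, config)
            delta = creport.violation_score - cur_score
            if delta <= 0 or rng.uniform() < np.exp(-delta / T):
                current = cand
                cur_score = creport.violation_score
                if creport.feasible:
                    feasible.append((_residual_norm(cbudgets), cand))
                elif creport.violation_score < best_infeasible[0]:
                    best_infeasible = (creport.violation_score, creport)

    if not feasible:
        score, rep = best_infeasible
        raise BalanceError(
            f"no feasible solution within {n_iter} iterations "
            f"(best violation score {score:.4g}): " + "; ".join(rep.violated()),
            best_score=score,
            violations=rep.violated(),
        )
    best_norm, best = min(feasible, key=lambda t: t[0])
    flows, budgets, report = _evaluate(model, best, config)
    return BalancedModel(
        model=model,
        rates=best.rates,
        diet=best.diet,
        flows=flows,
        budgets=budgets,
        provenance={
            "seed": config.seed,
            "iterations": n_iter,
            "n_feasible_found": len(feasible),
            "residual_norm": best_norm,
            "config": {
                "max_iterations": config.max_iterations,
                "n_feasible_target": config.n_feasible_target,
                "link_variability": config.link_variability,
                "fine_perturbation": config.fine_perturbation,
                "prune_threshold": config.prune_threshold,
                "tolerance": config.tolerance,
                "pp_constraint_direction": config.pp_constraint_direction,
                "coarse_iterations": config.coarse_iterations,
                "temperature": config.temperature,
            },
        },
    )
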