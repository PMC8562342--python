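"""Linear-programming core: FBA, FVA, knockouts, parsimonious FBA, and the
six-category reaction classification.

Parsimonious FBA is the bilevel program: maximize growth, then — with the
growth optimum fixed — minimize total flux through gene-associated
reactions.  The rationale is selection for minimal enzyme usage at maximal
growth yield.  Reactions are then classified by how they relate to that
parsimonious optimum:

=============  =========================================================
essential      knockout (lb = ub = 0) drops growth below ``eps_growth``
pfba_optima    carries flux in some minimal-total-flux growth optimum
ELE            can carry flux at optimal growth, but only by exceeding
               the minimal total gene-associated flux (extra enzymatic
               steps: "enzymatically less efficient")
MLE            carries flux only at sub-optimal growth ("metabolically
               less efficient": using it costs growth rate)
no_flux        cannot carry flux under the experimental bounds
blocked        cannot carry flux under *any* exchange condition
=============  =========================================================

The L1 objective is linearized by splitting each gene-associated flux into
a pair of non-negative auxiliary variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._lp import BIG_BOUND, solve_lp
from .constraint import MetabolicModel

__all__ = [
    "FluxSolution",
    "ReactionClassification",
    "CATEGORIES",
    "fba",
    "fva",
    "single_reaction_deletions",
    "pfba",
    "classify_reactions",
]

CATEGORIES = ("essential", "pfba_optima", "ELE", "MLE", "no_flux", "blocked")

#: Relative slack when fixing the growth optimum (strict equality is prone
#: to LP-degeneracy infeasibility).
OPT_SLACK = 1e-9
#: Absolute flux below which a reaction is considered to carry no flux.
FLUX_TOL = 1e-9


@dataclass
class FluxSolution:
    v: np.ndarray
    objective_value: float
    total_gene_flux: float
    status: str

    def flux(self, model: MetabolicModel, rxn: str) -> float:
        return float(self.v[model.rxn_index(rxn)])


@dataclass
class ReactionClassification:
    category: dict[str, str]
    wildtype_growth: float
    min_total_flux: float

    def reactions_in(self, cat: str) -> set[str]:
        return {r for r, c in self.category.items() if c == cat}


def _growth_vector(model: MetabolicModel, objective_rxn: str | None) -> np.ndarray:
    j = model.rxn_index(objective_rxn or model.biomass_rxn)
    c = np.zeros(len(model.reactions))
    c[j] = 1.0
    return c


def fba(model: MetabolicModel, objective_rxn: str | None = None) -> FluxSolution:
    """Maximize the objective flux subject to S v = 0 and bounds."""
    c = _growth_vector(model, objective_rxn)
    res = solve_lp(c, model.S, np.zeros(model.S.shape[0]), model.lb, model.ub)
    if not res.ok:
        return FluxSolution(
            v=np.full(len(model.reactions), np.nan),
            objective_value=np.nan,
            total_gene_flux=np.nan,
            status=res.status,
        )
    gene_flux = float(np.abs(res.x[model.gene_associated]).sum())
    return FluxSolution(res.x, float(res.objective), gene_flux, "optimal")


def fva(
    model: MetabolicModel,
    fraction_of_optimum: float = 1.0,
    reactions: list[str] | None = None,
    gene_flux_budget: float | None = None,
) -> dict[str, tuple[float, float]]:
    """Flux variability: per-reaction (min, max) at a fraction of the growth
    optimum; ``gene_flux_budget``, if given, additionally caps total
    gene-associated |flux| (used to probe the parsimonious optimal set).
    """
    if not 0 <= fraction_of_optimum <= 1:
        raise ValueError("fraction_of_optimum must be in [0, 1]")
    n = len(model.reactions)
    targets = reactions if reactions is not None else model.reactions
    jb = model.rxn_index(model.biomass_rxn)

    A_ub_rows: list[np.ndarray] = []
    b_ub_rows: list[float] = []
    n_split = 0
    gene_idx = np.flatnonzero(model.gene_associated)
    if fraction_of_optimum > 0:
        base = fba(model)
        if base.status != "optimal":
            raise RuntimeError(f"base FBA not optimal: {base.status}")
        row = np.zeros(n)
        row[jb] = -1.0
        A_ub_rows.append(row)
        b_ub_rows.append(-fraction_of_optimum * base.objective_value * (1 - OPT_SLACK))
    if gene_flux_budget is not None:
        # split variables s_i >= |v_i| for gene-associated reactions
        n_split = gene_idx.size
        padded = []
        for row, b in zip(A_ub_rows, b_ub_rows):
            padded.append((np.concatenate([row, np.zeros(n_split)]), b))
        A_ub_rows = [r for r, _ in padded]
        b_ub_rows = [b for _, b in padded]
        for k, j in enumerate(gene_idx):
            r1 = np.zeros(n + n_split)
            r1[j] = 1.0
            r1[n + k] = -1.0
            A_ub_rows.append(r1)
            b_ub_rows.append(0.0)
            r2 = np.zeros(n + n_split)
            r2[j] = -1.0
            r2[n + k] = -1.0
            A_ub_rows.append(r2)
            b_ub_rows.append(0.0)
        budget_row = np.concatenate([np.zeros(n), np.ones(n_split)])
        A_ub_rows.append(budget_row)
        b_ub_rows.append(gene_flux_budget)

    A_ub = np.vstack(A_ub_rows) if A_ub_rows else None
    b_ub = np.asarray(b_ub_rows) if b_ub_rows else None
    A_eq = model.S
    if n_split:
        A_eq = np.hstack([model.S, np.zeros((model.S.shape[0], n_split))])
    lb = np.concatenate([model.lb, np.zeros(n_split)])
    ub = np.concatenate([model.ub, np.full(n_split, BIG_BOUND)])

    out: dict[str, tuple[float, float]] = {}
    for r in targets:
        j = model.rxn_index(r)
        c = np.zeros(n + n_split)
        c[j] = 1.0
        lo = solve_lp(c, A_eq, np.zeros(A_eq.shape[0]), lb, ub, "min", A_ub, b_ub)
        hi = solve_lp(c, A_eq, np.zeros(A_eq.shape[0]), lb, ub, "max", A_ub, b_ub)
        if not (lo.ok and hi.ok):
            raise RuntimeError(f"FVA subproblem for {r!r} failed")
        out[r] = (float(lo.objective), float(hi.objective))
    return out


def single_reaction_deletions(
    model: MetabolicModel, eps_growth: float = 1e-6
) -> tuple[dict[str, float], set[str]]:
    """Knock out each reaction (lb = ub = 0) and record residual growth.

    Essential reactions are those whose knockout drops growth below
    ``eps_growth`` (infeasible knockouts count as zero growth).
    """
    wildtype = fba(model)
    if wildtype.status != "optimal" or wildtype.objective_value <= 0:
        raise RuntimeError("wildtype model must grow before deletions")
    growth: dict[str, float] = {}
    for j, r in enumerate(model.reactions):
        saved = model.lb[j], model.ub[j]
        model.lb[j] = model.ub[j] = 0.0
        sol = fba(model)
        growth[r] = float(sol.objective_value) if sol.status == "optimal" else 0.0
        model.lb[j], model.ub[j] = saved
    essential = {r for r, g in growth.items() if g < eps_growth}
    return growth, essential


def pfba(model: MetabolicModel) -> FluxSolution:
    """Parsimonious FBA: fix growth at its optimum (with relative slack),
    then minimize total flux through gene-associated reactions."""
    base = fba(model)
    if base.status != "optimal":
        raise RuntimeError(f"FBA stage failed: {base.status}")
    if base.objective_value <= 0:
        raise RuntimeError("pFBA requires positive growth")
    n = len(model.reactions)
    gene_idx = np.flatnonzero(model.gene_associated)
    k = gene_idx.size
    jb = model.rxn_index(model.biomass_rxn)

    A_eq = np.hstack([model.S, np.zeros((model.S.shape[0], k))])
    lb = np.concatenate([model.lb, np.zeros(k)])
    ub = np.concatenate([model.ub, np.full(k, BIG_BOUND)])
    rows = []
    rhs = []
    growth_row = np.zeros(n + k)
    growth_row[jb] = -1.0
    rows.append(growth_row)
    rhs.append(-base.objective_value * (1 - OPT_SLACK))
    for i, j in enumerate(gene_idx):
        r1 = np.zeros(n + k)
        r1[j], r1[n + i] = 1.0, -1.0
        r2 = np.zeros(n + k)
        r2[j], r2[n + i] = -1.0, -1.0
        rows.extend([r1, r2])
        rhs.extend([0.0, 0.0])
    cost = np.concatenate([np.zeros(n), np.ones(k)])
    res = solve_lp(
        cost, A_eq, np.zeros(A_eq.shape[0]), lb, ub, "min",
        np.vstack(rows), np.asarray(rhs),
    )
    if not res.ok:
        raise RuntimeError(
            f"pFBA stage-2 LP {res.status}; consider loosening the optimality "
            "slack"
        )
    v = res.x[:n]
    return FluxSolution(
        v=v,
        objective_value=float(v[jb]),
        total_gene_flux=float(res.objective),
        status="optimal",
    )


def _is_zero(rng: tuple[float, float], tol: float) -> bool:
    return abs(rng[0]) <= tol and abs(rng[1]) <= tol


def classify_reactions(
    model: MetabolicModel,
    eps_growth: float = 1e-6,
    flux_tol: float = FLUX_TOL,
) -> ReactionClassification:
    """Six-category classification of every reaction (decision cascade).

    Order: blocked (no flux even with every exchange fully opened) →
    essential (knockout kills growth) → no_flux (no flux under the
    experimental bounds) → MLE (flux only at sub-optimal growth) →
    pfba_optima (flux within the minimal-total-flux growth optimum) →
    ELE (flux at optimal growth only above the minimal total flux).
    """
    wildtype = fba(model)
    if wildtype.status != "optimal" or wildtype.objective_value <= 0:
        raise RuntimeError("model must be feasible with positive growth")
    parsimonious = pfba(model)
    # The optimality and flux-budget constraints carry a relative slack
    # (OPT_SLACK) to avoid degeneracy infeasibility; FVA maxima under those
    # constraints can reach the slack, so "carries flux" decisions there
    # must use a threshold dominating it.
    scale = max(abs(wildtype.objective_value), parsimonious.total_gene_flux, 1.0)
    slack_tol = flux_tol + 100.0 * OPT_SLACK * scale

    # blocked: open all exchanges, no growth requirement
    opened = model.copy()
    for r in opened.exchange_rxns:
        j = opened.rxn_index(r)
        opened.lb[j], opened.ub[j] = -BIG_BOUND, BIG_BOUND
    rng_open = fva(opened, fraction_of_optimum=0.0)
    rng_exp = fva(model, fraction_of_optimum=0.0)
    rng_opt = fva(model, fraction_of_optimum=1.0)
    rng_pfba = fva(
        model,
        fraction_of_optimum=1.0,
        gene_flux_budget=parsimonious.total_gene_flux * (1 + 1e-9) + flux_tol,
    )
    _, essential = single_reaction_deletions(model, eps_growth=eps_growth)

    category: dict[str, str] = {}
    for r in model.reactions:
        if _is_zero(rng_open[r], flux_tol):
            category[r] = "blocked"
        elif r in essential:
            category[r] = "essential"
        elif _is_zero(rng_exp[r], flux_tol):
            category[r] = "no_flux"
        elif _is_zero(rng_opt[r], slack_tol):
            category[r] = "MLE"
        elif not _is_zero(rng_pfba[r], slack_tol):
            category[r] = "pfba_optima"
        else:
            category[r] = "ELE"
    return ReactionClassification(
        category=category,
        wildtype_growth=float(wildtype.objective_value),
        min_total_flux=float(parsimonious.total_gene_flux),
    )
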