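"""Stoichiometric model container, TSV/SBML I/O, and model conditioning.

Conditioning mirrors how a yeast genome-scale model is prepared for an
anaerobic wine fermentation: the oxygen exchange is closed, sterol and
oleate analogue uptakes are opened (anaerobic growth factors that cannot be
synthesized without oxygen), redox-shuttle reactions are blocked, heme-like
components are dropped from the biomass equation, and measured exchange
rates are imposed as LB = UB (optionally with a relative tolerance band,
since exact equality constraints from noisy measurements are frequently
infeasible).

Sign convention throughout: exchange flux < 0 is uptake, > 0 is secretion.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._lp import BIG_BOUND, solve_lp
from .datamodel import FluxMeasurements

__all__ = [
    "MetabolicModel",
    "AnaerobicTemplate",
    "ModelParseError",
    "read_model_tsv",
    "write_model_tsv",
    "read_model_sbml",
    "load_template",
    "apply_anaerobic_template",
    "constrain_exchanges",
    "check_feasibility",
]


class ModelParseError(ValueError):
    pass


@dataclass
class MetabolicModel:
    """A stoichiometric model: S (metabolites x reactions), bounds, and
    per-reaction annotation (gene association flag, subsystem label)."""

    metabolites: list[str]
    reactions: list[str]
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    gene_associated: np.ndarray
    subsystem: list[str]
    biomass_rxn: str
    exchange_rxns: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self.gene_associated = np.asarray(self.gene_associated, dtype=bool)
        n_met, n_rxn = self.S.shape
        if n_met != len(self.metabolites) or n_rxn != len(self.reactions):
            raise ModelParseError("S shape does not match metabolite/reaction lists")
        if np.any(self.lb > self.ub):
            bad = [self.reactions[j] for j in np.flatnonzero(self.lb > self.ub)]
            raise ModelParseError(f"lb > ub for reaction(s): {bad}")
        if self.biomass_rxn not in self.reactions:
            raise ModelParseError(f"biomass reaction {self.biomass_rxn!r} not in model")
        for r in self.exchange_rxns:
            j = self.reactions.index(r)
            if np.count_nonzero(self.S[:, j]) != 1:
                raise ModelParseError(
                    f"exchange reaction {r!r} must touch exactly one metabolite"
                )

    # -- helpers ----------------------------------------------------------
    def rxn_index(self, rxn: str) -> int:
        try:
            return self.reactions.index(rxn)
        except ValueError:
            raise KeyError(f"reaction {rxn!r} not in model") from None

    def met_index(self, met: str) -> int:
        try:
            return self.metabolites.index(met)
        except ValueError:
            raise KeyError(f"metabolite {met!r} not in model") from None

    @property
    def biomass_components(self) -> dict[str, float]:
        """Metabolites consumed by the biomass reaction, with coefficients."""
        j = self.rxn_index(self.biomass_rxn)
        return {
            self.metabolites[i]: float(self.S[i, j])
            for i in np.flatnonzero(self.S[:, j])
        }

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    def infer_exchanges(self) -> set[str]:
        """Reactions touching a single metabolite (excluding biomass)."""
        cols = np.count_nonzero(self.S, axis=0)
        return {
            r
            for j, r in enumerate(self.reactions)
            if cols[j] == 1 and r != self.biomass_rxn
        }


# -- equation parsing ------------------------------------------------------

_TERM_RE = re.compile(r"^\s*(?:(\d+(?:\.\d+)?)\s+)?(\S+)\s*$")


def _parse_side(side: str, line_no: int) -> list[tuple[float, str]]:
    side = side.strip()
    if not side:
        return []
    out = []
    for term in side.split(" + "):
        m = _TERM_RE.match(term)
        if not m:
            raise ModelParseError(f"line {line_no}: cannot parse term {term!r}")
        coeff = float(m.group(1)) if m.group(1) else 1.0
        out.append((coeff, m.group(2)))
    return out


def _parse_equation(eq: str, line_no: int) -> tuple[list[tuple[float, str]], bool]:
    """Parse "a A + b B -> c C" / "<=>"; returns (signed terms, reversible)."""
    if "<=>" in eq:
        lhs, rhs = eq.split("<=>", 1)
        reversible = True
    elif "->" in eq:
        lhs, rhs = eq.split("->", 1)
        reversible = False
    else:
        raise ModelParseError(f"line {line_no}: equation {eq!r} lacks an arrow")
    left = _parse_side(lhs, line_no)
    right = _parse_side(rhs, line_no)
    if not left and not right:
        raise ModelParseError(f"line {line_no}: empty equation")
    terms = [(-c, m) for c, m in left] + [(c, m) for c, m in right]
    return terms, reversible


def _format_equation(model: MetabolicModel, j: int) -> str:
    lhs, rhs = [], []
    for i in np.flatnonzero(model.S[:, j]):
        c = model.S[i, j]
        name = model.metabolites[i]
        txt = name if abs(abs(c) - 1.0) < 1e-12 else f"{abs(c):g} {name}"
        (lhs if c < 0 else rhs).append(txt)
    arrow = "<=>" if model.lb[j] < 0 and model.ub[j] > 0 else "->"
    return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


# -- TSV dialect -----------------------------------------------------------

def read_model_tsv(path: str | Path) -> MetabolicModel:
    """Read the two-section TSV model dialect.

    Sections are introduced by ``# reactions`` (columns: id, equation, lb,
    ub, gene_associated, subsystem) and ``# metadata`` (key-value rows; the
    ``biomass`` key is mandatory).
    """
    path = Path(path)
    section = None
    header: list[str] | None = None
    rows: list[tuple[int, dict[str, str]]] = []
    meta: dict[str, str] = {}
    for line_no, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            section = line.lstrip("#").strip().lower()
            header = None
            continue
        if section == "reactions":
            parts = line.split("\t")
            if header is None:
                header = parts
                continue
            if len(parts) != len(header):
                raise ModelParseError(f"line {line_no}: expected {len(header)} fields")
            rows.append((line_no, dict(zip(header, parts))))
        elif section == "metadata":
            key, _, value = line.partition("\t")
            meta[key.strip()] = value.strip()
        else:
            raise ModelParseError(f"line {line_no}: content outside any section")

    if "biomass" not in meta:
        raise ModelParseError("metadata section lacks a 'biomass' entry")

    met_order: list[str] = []
    met_pos: dict[str, int] = {}
    parsed = []
    for line_no, row in rows:
        terms, reversible = _parse_equation(row["equation"], line_no)
        for _, m in terms:
            if m not in met_pos:
                met_pos[m] = len(met_order)
                met_order.append(m)
        parsed.append((line_no, row, terms, reversible))

    n_rxn = len(parsed)
    S = np.zeros((len(met_order), n_rxn))
    lb = np.zeros(n_rxn)
    ub = np.zeros(n_rxn)
    gene = np.zeros(n_rxn, dtype=bool)
    subsystem: list[str] = []
    rxns: list[str] = []
    for j, (line_no, row, terms, _) in enumerate(parsed):
        rxns.append(row["id"])
        for c, m in terms:
            S[met_pos[m], j] += c
        try:
            lb[j] = float(row["lb"])
            ub[j] = float(row["ub"])
        except ValueError as exc:
            raise ModelParseError(f"line {line_no}: bad bound: {exc}") from None
        gene[j] = row["gene_associated"].strip() in {"1", "true", "True", "yes"}
        subsystem.append(row.get("subsystem", ""))

    biomass = meta["biomass"]
    if biomass not in rxns:
        raise ModelParseError(f"biomass reaction {biomass!r} not among reactions")
    model = MetabolicModel(
        metabolites=met_order,
        reactions=rxns,
        S=S,
        lb=lb,
        ub=ub,
        gene_associated=gene,
        subsystem=subsystem,
        biomass_rxn=biomass,
        exchange_rxns=set(),
    )
    model.exchange_rxns = model.infer_exchanges()
    return model


def write_model_tsv(model: MetabolicModel, path: str | Path) -> None:
    lines = ["# reactions", "id\tequation\tlb\tub\tgene_associated\tsubsystem"]
    for j, r in enumerate(model.reactions):
        lines.append(
            "\t".join(
                [
                    r,
                    _format_equation(model, j),
                    f"{model.lb[j]:g}",
                    f"{model.ub[j]:g}",
                    "1" if model.gene_associated[j] else "0",
                    model.subsystem[j],
                ]
            )
        )
    lines += ["", "# metadata", f"biomass\t{model.biomass_rxn}"]
    Path(path).write_text("\n".join(lines) + "\n")


def read_model_sbml(path: str | Path) -> MetabolicModel:
    """Optional adapter: read an SBML Level 3 + FBC document via cobrapy.

    Requires the ``cobra`` package.  The objective reaction becomes the
    biomass reaction; an SBML file without an objective is rejected.
    """
    try:
        import cobra
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ImportError("the SBML adapter requires the 'cobra' package") from exc

    cm = cobra.io.read_sbml_model(str(path))
    obj = [r for r in cm.reactions if r.objective_coefficient != 0]
    if not obj:
        raise ModelParseError(f"{path}: SBML model declares no objective")
    mets = [m.id for m in cm.metabolites]
    rxns = [r.id for r in cm.reactions]
    S = np.zeros((len(mets), len(rxns)))
    midx = {m: i for i, m in enumerate(mets)}
    lb = np.zeros(len(rxns))
    ub = np.zeros(len(rxns))
    gene = np.zeros(len(rxns), dtype=bool)
    subsystem = []
    for j, r in enumerate(cm.reactions):
        for m, c in r.metabolites.items():
            S[midx[m.id], j] = c
        lb[j], ub[j] = r.lower_bound, r.upper_bound
        gene[j] = len(r.genes) > 0
        subsystem.append(r.subsystem or "")
    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        S=S,
        lb=lb,
        ub=ub,
        gene_associated=gene,
        subsystem=subsystem,
        biomass_rxn=obj[0].id,
    )
    model.exchange_rxns = model.infer_exchanges()
    return model


# -- conditioning ----------------------------------------------------------

@dataclass
class AnaerobicTemplate:
    """Identifier lists for anaerobic conditioning of a model.

    All identifiers must resolve in the target model; genome-scale-specific
    ids (e.g. the yeast sterol exchange reactions) live in shipped template
    files, not in code, so toy models use analogous templates.
    """

    block_exchanges: list[str] = field(default_factory=list)
    open_uptakes: list[str] = field(default_factory=list)
    block_reactions: list[str] = field(default_factory=list)
    remove_biomass_components: list[str] = field(default_factory=list)


def load_template(path: str | Path) -> AnaerobicTemplate:
    """Load an anaerobic template from a YAML key-value file."""
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    return AnaerobicTemplate(
        block_exchanges=list(data.get("block_exchanges", [])),
        open_uptakes=list(data.get("open_uptakes", [])),
        block_reactions=list(data.get("block_reactions", [])),
        remove_biomass_components=list(data.get("remove_biomass_components", [])),
    )


def apply_anaerobic_template(
    model: MetabolicModel, template: AnaerobicTemplate
) -> MetabolicModel:
    """Return a conditioned copy of the model (pure function).

    Blocked exchanges and reactions get lb = ub = 0; opened uptakes get
    lb = -1000 (unbounded-uptake sentinel); removed biomass components'
    coefficients are zeroed in the biomass column.
    """
    unknown = [
        r
        for r in template.block_exchanges
        + template.open_uptakes
        + template.block_reactions
        if r not in model.reactions
    ] + [m for m in template.remove_biomass_components if m not in model.metabolites]
    if unknown:
        raise KeyError(f"template identifiers not in model: {unknown}")

    out = model.copy()
    for r in template.block_exchanges + template.block_reactions:
        j = out.rxn_index(r)
        out.lb[j] = out.ub[j] = 0.0
    for r in template.open_uptakes:
        j = out.rxn_index(r)
        out.lb[j] = -BIG_BOUND
    jb = out.rxn_index(out.biomass_rxn)
    for m in template.remove_biomass_components:
        out.S[out.met_index(m), jb] = 0.0
    return out


def constrain_exchanges(
    model: MetabolicModel,
    fluxes: FluxMeasurements,
    rel_tolerance: float = 0.0,
    exchange_map: dict[str, str] | None = None,
) -> MetabolicModel:
    """Impose measured exchange rates as flux bounds (pure function).

    For measured rate q and relative tolerance d the bounds become
    [q - d|q|, q + d|q|]; d = 0 reproduces hard LB = UB constraining.
    ``exchange_map`` maps analyte names to exchange reaction ids and
    defaults to ``EX_<analyte>``.
    """
    out = model.copy()
    for analyte, q in fluxes.values.items():
        rxn = (exchange_map or {}).get(analyte, f"EX_{analyte}")
        if rxn not in out.reactions:
            raise KeyError(f"no exchange reaction for analyte {analyte!r} ({rxn!r})")
        j = out.rxn_index(rxn)
        delta = rel_tolerance * abs(q)
        out.lb[j] = q - delta
        out.ub[j] = q + delta
    return out


def check_feasibility(
    model: MetabolicModel,
) -> tuple[bool, float | None, dict[str, float]]:
    """Solve FBA; on infeasibility, diagnose which exchange bounds to relax.

    Returns (feasible, max_growth, diagnosis) where diagnosis maps exchange
    reaction ids to the minimal bound relaxation (elastic-variable LP:
    slacks on every exchange bound, minimizing total slack).
    """
    n = len(model.reactions)
    jb = model.rxn_index(model.biomass_rxn)
    c = np.zeros(n)
    c[jb] = 1.0
    res = solve_lp(c, model.S, np.zeros(model.S.shape[0]), model.lb, model.ub)
    if res.ok:
        return True, float(res.objective), {}
    if res.status != "infeasible":
        raise RuntimeError(f"LP solver failure: status {res.status}")

    ex_idx = [model.rxn_index(r) for r in sorted(model.exchange_rxns)]
    k = len(ex_idx)
    # variables: [v (n), s_plus (k), s_minus (k)]
    n_tot = n + 2 * k
    lb = np.concatenate([model.lb, np.zeros(2 * k)])
    ub = np.concatenate([model.ub, np.full(2 * k, np.inf)])
    # relax exchange bounds: lb_j - s_minus <= v_j <= ub_j + s_plus
    lb[ex_idx] = -np.inf
    ub[ex_idx] = np.inf
    A_ub = np.zeros((2 * k, n_tot))
    b_ub = np.zeros(2 * k)
    for row, j in enumerate(ex_idx):
        A_ub[row, j] = 1.0
        A_ub[row, n + row] = -1.0
        b_ub[row] = model.ub[j]
        A_ub[k + row, j] = -1.0
        A_ub[k + row, n + k + row] = -1.0
        b_ub[k + row] = -model.lb[j]
    A_eq = np.hstack([model.S, np.zeros((model.S.shape[0], 2 * k))])
    cost = np.concatenate([np.zeros(n), np.ones(2 * k)])
    elastic = solve_lp(
        cost, A_eq, np.zeros(model.S.shape[0]), lb, ub, sense="min",
        A_ub=A_ub, b_ub=b_ub,
    )
    diagnosis: dict[str, float] = {}
    if elastic.ok:
        s = elastic.x[n:]
        for row, j in enumerate(ex_idx):
            slack = s[row] + s[k + row]
            if slack > 1e-9:
                diagnosis[model.reactions[j]] = float(slack)
    return False, None, diagnosis
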