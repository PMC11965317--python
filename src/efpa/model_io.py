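"""Loading, validation and canonicalization of metabolic network models.

A model is held as a lightweight :class:`MetabolicNetwork` — stoichiometry,
flux bounds and gene-protein-reaction (GPR) rules per reaction — decoupled
from any particular file dialect.  SBML Level 3 / FBC files are read through
cobrapy; a plain JSON dialect (arrays of metabolites and reactions mirroring
the in-memory fields) is supported so that small models can be written and
versioned as text.

Reversible reactions are split into non-negative forward/reverse pairs
(:class:`DirectedNetwork`) because the expression-weighted flux-sum
constraint used downstream is linear only in non-negative fluxes.
"""

from __future__ import annotations

import ast
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "GprTree",
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "DirectedReaction",
    "DirectedNetwork",
    "parse_gpr",
    "load_model",
    "load_json_model",
    "load_sbml_model",
    "write_json_model",
    "write_summary_tsv",
    "split_reversible",
]


# ---------------------------------------------------------------------------
# GPR trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GprTree:
    """Boolean expression over gene ids.

    ``op`` is one of ``"gene"``, ``"and"``, ``"or"``.  Leaves carry the gene
    id in ``gene``; internal nodes carry two or more ``children``.
    """

    op: str
    gene: str | None = None
    children: tuple["GprTree", ...] = ()

    def genes(self) -> set[str]:
        if self.op == "gene":
            return {self.gene}
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def to_string(self) -> str:
        if self.op == "gene":
            return self.gene
        sep = f" {self.op} "
        parts = []
        for c in self.children:
            s = c.to_string()
            if c.op != "gene" and c.op != self.op:
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def _from_ast(node: ast.AST) -> GprTree:
    if isinstance(node, ast.Name):
        return GprTree("gene", gene=node.id)
    if isinstance(node, ast.BoolOp):
        op = "and" if isinstance(node.op, ast.And) else "or"
        return GprTree(op, children=tuple(_from_ast(v) for v in node.values))
    raise ValueError(f"unsupported GPR node: {ast.dump(node)}")


def parse_gpr(rule: str | None) -> GprTree | None:
    """Parse a GPR rule string into a :class:`GprTree`.

    Parentheses are honored; ``and`` binds tighter than ``or`` when absent,
    following common genome-scale-model conventions.  An empty string maps
    to ``None`` (no gene association).  An unparseable rule is logged and
    treated as absent rather than raised, so a single malformed rule cannot
    abort a model load.
    """
    if rule is None or not rule.strip():
        return None
    from cobra.core.gene import GPR  # mature and/or/parenthesis parser

    try:
        gpr = GPR.from_string(rule)
        if gpr.body is None:
            return None
        return _from_ast(gpr.body)
    except (SyntaxError, ValueError, TypeError) as exc:
        logger.warning("unparseable GPR %r ignored (%s)", rule, exc)
        return None


# ---------------------------------------------------------------------------
# Network containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str = "c"


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float
    upper_bound: float
    gpr: GprTree | None = None

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def is_boundary(self) -> bool:
        """Exchange/demand reactions, detected structurally."""
        return len(self.stoichiometry) == 1


@dataclass
class MetabolicNetwork:
    metabolites: list[Metabolite]
    reactions: list[Reaction]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ValueError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ValueError(f"duplicate reaction ids: {dup}")
        known = set(met_ids)
        for r in self.reactions:
            if not r.stoichiometry:
                raise ValueError(f"reaction {r.id}: empty stoichiometry")
            for m, coef in r.stoichiometry.items():
                if m not in known:
                    raise ValueError(
                        f"reaction {r.id}: unknown metabolite {m!r}"
                    )
                if not math.isfinite(coef):
                    raise ValueError(f"reaction {r.id}: bad coefficient for {m}")
            if r.lower_bound > r.upper_bound:
                raise ValueError(
                    f"reaction {r.id}: lower bound {r.lower_bound} exceeds "
                    f"upper bound {r.upper_bound}"
                )

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def gpr_strings(self) -> dict[str, str]:
        return {
            r.id: (r.gpr.to_string() if r.gpr is not None else "")
            for r in self.reactions
        }


# ---------------------------------------------------------------------------
# Directed (irreversible) form
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DirectedReaction:
    id: str
    base_id: str
    direction: str  # "fwd" | "rev"
    stoichiometry: Mapping[str, float]
    upper_bound: float


@dataclass
class DirectedNetwork:
    metabolites: list[Metabolite]
    reactions: list[DirectedReaction]
    base_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.base_ids:
            seen: list[str] = []
            for r in self.reactions:
                if r.base_id not in seen:
                    seen.append(r.base_id)
            self.base_ids = seen

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> DirectedReaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def producers(self, met: str) -> list[DirectedReaction]:
        return [r for r in self.reactions if r.stoichiometry.get(met, 0.0) > 0]

    def consumers(self, met: str) -> list[DirectedReaction]:
        return [r for r in self.reactions if r.stoichiometry.get(met, 0.0) < 0]


def directed_id(base_id: str, direction: str) -> str:
    return f"{base_id}[{'f' if direction == 'fwd' else 'r'}]"


def split_reversible(net: MetabolicNetwork) -> DirectedNetwork:
    """Split every reversible reaction into mirrored forward/reverse copies.

    After splitting all fluxes are non-negative: an irreversible reaction
    (lb >= 0) yields one forward copy; a reaction that can only run backward
    (ub <= 0) yields one reverse copy with negated stoichiometry; a genuinely
    reversible reaction yields both.
    """
    directed: list[DirectedReaction] = []
    for r in net.reactions:
        fwd_ub = max(r.upper_bound, 0.0)
        rev_ub = max(-r.lower_bound, 0.0)
        if fwd_ub > 0 or rev_ub == 0:
            directed.append(
                DirectedReaction(
                    id=directed_id(r.id, "fwd"),
                    base_id=r.id,
                    direction="fwd",
                    stoichiometry=dict(r.stoichiometry),
                    upper_bound=fwd_ub,
                )
            )
        if rev_ub > 0:
            directed.append(
                DirectedReaction(
                    id=directed_id(r.id, "rev"),
                    base_id=r.id,
                    direction="rev",
                    stoichiometry={m: -c for m, c in r.stoichiometry.items()},
                    upper_bound=rev_ub,
                )
            )
    return DirectedNetwork(
        metabolites=list(net.metabolites),
        reactions=directed,
        base_ids=[r.id for r in net.reactions],
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_sbml_model(path: str | Path) -> MetabolicNetwork:
    """Read an SBML L3/FBC model through cobrapy and canonicalize it."""
    from cobra.io import read_sbml_model

    model = read_sbml_model(str(path))
    mets = [Metabolite(m.id, m.compartment or "c") for m in model.metabolites]
    rxns = []
    for r in model.reactions:
        rxns.append(
            Reaction(
                id=r.id,
                stoichiometry={m.id: c for m, c in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                gpr=parse_gpr(r.gene_reaction_rule),
            )
        )
    return MetabolicNetwork(mets, rxns)


def load_json_model(path: str | Path) -> MetabolicNetwork:
    """Read the plain JSON dialect.

    Schema::

        {"metabolites": [{"id": ..., "compartment": ...}, ...],
         "reactions": [{"id": ..., "stoichiometry": {met: coef, ...},
                        "lower_bound": ..., "upper_bound": ..., "gpr": "..."},
                       ...]}
    """
    with open(path) as fh:
        doc = json.load(fh)
    mets = [
        Metabolite(m["id"], m.get("compartment", "c"))
        for m in doc["metabolites"]
    ]
    rxns = []
    for r in doc["reactions"]:
        stoich = r["stoichiometry"]
        if not isinstance(stoich, dict):
            raise ValueError(f"reaction {r.get('id')}: malformed stoichiometry")
        rxns.append(
            Reaction(
                id=r["id"],
                stoichiometry={str(k): float(v) for k, v in stoich.items()},
                lower_bound=float(r.get("lower_bound", 0.0)),
                upper_bound=float(r.get("upper_bound", 1000.0)),
                gpr=parse_gpr(r.get("gpr", "")),
            )
        )
    return MetabolicNetwork(mets, rxns)


def load_model(path: str | Path, format: str | None = None) -> MetabolicNetwork:
    """Load a model, inferring the dialect from the extension if not given."""
    path = Path(path)
    if format is None:
        format = "json_fallback" if path.suffix == ".json" else "sbml"
    if format == "sbml":
        return load_sbml_model(path)
    if format == "json_fallback":
        return load_json_model(path)
    raise ValueError(f"unknown model format {format!r}")


def write_sbml_model(net: MetabolicNetwork, path: str | Path) -> None:
    """Write the network as SBML L3/FBC through cobrapy."""
    import cobra
    from cobra.io import write_sbml_model as _write

    model = cobra.Model("model")
    comps = {m.compartment for m in net.metabolites}
    model.compartments = {c: c for c in comps}
    cobra_mets = {
        m.id: cobra.Metabolite(m.id, compartment=m.compartment)
        for m in net.metabolites
    }
    for r in net.reactions:
        cr = cobra.Reaction(r.id)
        model.add_reactions([cr])
        cr.add_metabolites(
            {cobra_mets[m]: c for m, c in r.stoichiometry.items()}
        )
        cr.lower_bound = r.lower_bound
        cr.upper_bound = r.upper_bound
        if r.gpr is not None:
            cr.gene_reaction_rule = r.gpr.to_string()
    _write(model, str(path))


def write_json_model(net: MetabolicNetwork, path: str | Path) -> None:
    doc = {
        "metabolites": [
            {"id": m.id, "compartment": m.compartment} for m in net.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr.to_string() if r.gpr is not None else "",
            }
            for r in net.reactions
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def _formula(r: Reaction) -> str:
    lhs = " + ".join(
        f"{-c:g} {m}" for m, c in sorted(r.stoichiometry.items()) if c < 0
    )
    rhs = " + ".join(
        f"{c:g} {m}" for m, c in sorted(r.stoichiometry.items()) if c > 0
    )
    arrow = "<=>" if r.reversible else "-->"
    return f"{lhs} {arrow} {rhs}".strip()


def write_summary_tsv(net: MetabolicNetwork, path: str | Path) -> None:
    """One row per reaction: id, formula, reversibility, GPR string."""
    import pandas as pd

    rows = [
        {
            "reaction_id": r.id,
            "formula": _formula(r),
            "reversible": r.reversible,
            "gpr": r.gpr.to_string() if r.gpr is not None else "",
        }
        for r in net.reactions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
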