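"""Synthetic networks and expression data for testing and simulation.

Everything here is generated programmatically and seeded, so any study-like
scenario — a coexpressed linear pathway feeding a data-less reaction, a hub
metabolite joining unrelated pathways, two branches sharing one GPR, or a
co-product drain that couples a reaction to a distant poorly expressed
route — can be rebuilt bit-identically from a :class:`SimSpec`.

The expression model is log-normal (multiplicative noise, matching the
log2-scale provenance of proteomics data): genes of a pathway share a
per-condition latent activity factor f ~ N(0, 1),

    log2 level = sqrt(rho) * f + sqrt(1 - rho) * noise_sd * eps,

which gives a pairwise coexpression of rho among members when noise_sd = 1.
The true pathway flux is beta * f plus independent noise, carried equally by
every reaction of the chain (stoichiometric coupling).  Single-cell dropout
is modeled as post-hoc Bernoulli zeroing: dropouts are zeros, not missing
values, and nothing is imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_io import MetabolicNetwork, Metabolite, Reaction, parse_gpr

__all__ = [
    "SimSpec",
    "Fixture",
    "make_toy_network",
    "simulate_expression",
    "apply_dropout",
]

UB = 1000.0


@dataclass
class SimSpec:
    """Generator parameters; seeded runs are bit-reproducible."""

    template: str = "branched"
    pathway_length: int = 4
    background_length: int = 6
    decoy_length: int = 4
    hub_degree: int = 8
    n_conditions: int = 25
    rho: float = 0.8
    beta: float = 1.0
    noise_sd: float = 1.0
    flux_noise_sd: float = 0.2
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not -1 <= self.rho <= 1:
            raise ValueError("rho must lie in [-1, 1]")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        if self.pathway_length < 1:
            raise ValueError("pathway length must be >= 1")


@dataclass
class Fixture:
    network: MetabolicNetwork
    roi: str
    pathway_reactions: list[str]
    pathway_genes: list[str]
    background_genes: list[str] = field(default_factory=list)
    decoy_genes: list[str] = field(default_factory=list)
    groups: dict = field(default_factory=dict)


def _rxn(rid, stoich, gpr="", lb=0.0, ub=UB):
    return Reaction(rid, stoich, lb, ub, parse_gpr(gpr))


def _linear(spec: SimSpec) -> Fixture:
    L = spec.pathway_length
    mets = [Metabolite(f"M{i}") for i in range(L + 1)]
    rxns = [_rxn("EX_in", {"M0": 1.0})]
    genes = []
    for i in range(1, L + 1):
        g = f"g{i}"
        genes.append(g)
        rxns.append(_rxn(f"R{i}", {f"M{i-1}": -1.0, f"M{i}": 1.0}, g))
    rxns.append(_rxn("EX_out", {f"M{L}": -1.0}))
    net = MetabolicNetwork(mets, rxns)
    return Fixture(net, roi=f"R{L}", pathway_reactions=[f"R{i}" for i in range(1, L + 1)],
                   pathway_genes=genes)


def _branched(spec: SimSpec) -> Fixture:
    """Background chain -> coexpressed pathway -> data-less ROI -> export,
    with an independent decoy branch splitting off upstream."""
    L, M, D = spec.pathway_length, spec.background_length, spec.decoy_length
    mets = [Metabolite("S")]
    rxns = [_rxn("EX_in", {"S": 1.0})]
    bg_genes, pw_genes, decoy_genes = [], [], []
    prev = "S"
    for i in range(1, M + 1):
        mets.append(Metabolite(f"U{i}"))
        g = f"bg{i}"
        bg_genes.append(g)
        rxns.append(_rxn(f"B{i}", {prev: -1.0, f"U{i}": 1.0}, g))
        prev = f"U{i}"
    for i in range(1, L + 1):
        mets.append(Metabolite(f"M{i}"))
        g = f"pw{i}"
        pw_genes.append(g)
        rxns.append(_rxn(f"P{i}", {prev: -1.0, f"M{i}": 1.0}, g))
        prev = f"M{i}"
    mets.append(Metabolite("PRODUCT"))
    rxns.append(_rxn("ROI", {prev: -1.0, "PRODUCT": 1.0}))  # no GPR
    rxns.append(_rxn("EX_out", {"PRODUCT": -1.0}))
    # decoy branch off the substrate
    prev = "S"
    for i in range(1, D + 1):
        mets.append(Metabolite(f"D{i}"))
        g = f"dec{i}"
        decoy_genes.append(g)
        rxns.append(_rxn(f"Q{i}", {prev: -1.0, f"D{i}": 1.0}, g))
        prev = f"D{i}"
    rxns.append(_rxn("EX_decoy", {prev: -1.0}))
    net = MetabolicNetwork(mets, rxns)
    return Fixture(
        net, roi="ROI",
        pathway_reactions=[f"P{i}" for i in range(1, L + 1)],
        pathway_genes=pw_genes,
        background_genes=bg_genes,
        decoy_genes=decoy_genes,
        groups={
            "background": [f"B{i}" for i in range(1, M + 1)],
            "decoy": [f"Q{i}" for i in range(1, D + 1)],
        },
    )


def _hub(spec: SimSpec) -> Fixture:
    """A hub metabolite with a configurable total degree (producers plus
    consumers), each leg supported by its own uptake or export."""
    k = spec.hub_degree
    if k < 2 or k % 2:
        raise ValueError("hub degree must be an even number >= 2")
    half = k // 2
    mets = [Metabolite("H")]
    rxns = []
    genes = []
    for i in range(1, half + 1):
        mets.append(Metabolite(f"X{i}"))
        rxns.append(_rxn(f"EX_x{i}", {f"X{i}": 1.0}))
        g = f"prod{i}"
        genes.append(g)
        rxns.append(_rxn(f"Pin{i}", {f"X{i}": -1.0, "H": 1.0}, g))
    for i in range(1, half + 1):
        mets.append(Metabolite(f"Y{i}"))
        g = f"cons{i}"
        genes.append(g)
        rxns.append(_rxn(f"Pout{i}", {"H": -1.0, f"Y{i}": 1.0}, g))
        rxns.append(_rxn(f"EX_y{i}", {f"Y{i}": -1.0}))
    net = MetabolicNetwork(mets, rxns)
    return Fixture(net, roi="Pout1",
                   pathway_reactions=["Pin1", "Pout1"], pathway_genes=genes,
                   groups={"hub_metabolite": ["H"]})


def _glycogen(spec: SimSpec) -> Fixture:
    """Two branches from one substrate; the second reaction of each branch
    carries the *same* gene, so reaction expression cannot tell the
    branches apart while their neighborhoods can."""
    mets = [Metabolite(m) for m in ("S", "A1", "A2", "B1", "B2")]
    rxns = [
        _rxn("EX_in", {"S": 1.0}),
        _rxn("Ra1", {"S": -1.0, "A1": 1.0}, "ga"),
        _rxn("RsharedA", {"A1": -1.0, "A2": 1.0}, "gshared"),
        _rxn("EX_a", {"A2": -1.0}),
        _rxn("Rb1", {"S": -1.0, "B1": 1.0}, "gb"),
        _rxn("RsharedB", {"B1": -1.0, "B2": 1.0}, "gshared"),
        _rxn("EX_b", {"B2": -1.0}),
    ]
    net = MetabolicNetwork(mets, rxns)
    return Fixture(net, roi="RsharedA",
                   pathway_reactions=["Ra1", "RsharedA"],
                   pathway_genes=["ga", "gshared"],
                   decoy_genes=["gb"],
                   groups={"branch_a": ["Ra1", "RsharedA"],
                           "branch_b": ["Rb1", "RsharedB"]})


def _coproduct(spec: SimSpec) -> Fixture:
    """A well-expressed ROI whose product can only drain through a lumping
    reaction that simultaneously requires a co-substrate made by a poorly
    expressed route.  The route feeds the drain, not the ROI, so it is at
    infinite directional distance for pathway integration, while a
    whole-network resistance score is forced to pay its penalties."""
    mets = [Metabolite(m) for m in ("S", "B", "X0", "X", "W")]
    rxns = [
        _rxn("EX_in", {"S": 1.0}),
        _rxn("ROI", {"S": -1.0, "B": 1.0}, "groi"),
        _rxn("EX_x0", {"X0": 1.0}),
        _rxn("Rx", {"X0": -1.0, "X": 1.0}, "gx"),
        _rxn("Lump", {"B": -1.0, "X": -1.0, "W": 2.0}),
        _rxn("EX_w", {"W": -1.0}),
    ]
    net = MetabolicNetwork(mets, rxns)
    return Fixture(net, roi="ROI",
                   pathway_reactions=["ROI"], pathway_genes=["groi"],
                   decoy_genes=["gx"],
                   groups={"drain_route": ["Rx", "Lump"]})


_TEMPLATES = {
    "linear": _linear,
    "branched": _branched,
    "hub": _hub,
    "glycogen": _glycogen,
    "coproduct": _coproduct,
}


def make_toy_network(spec: SimSpec) -> Fixture:
    """Build a mass-balanced toy network for the requested template.

    Every template ships uptakes and exports so all internal reactions can
    carry steady-state flux.
    """
    try:
        builder = _TEMPLATES[spec.template]
    except KeyError:
        raise ValueError(
            f"unknown template {spec.template!r}; "
            f"choose from {sorted(_TEMPLATES)}"
        ) from None
    return builder(spec)


def simulate_expression(
    fixture: Fixture, spec: SimSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate gene levels and ground-truth fluxes across conditions.

    Returns ``(gene_levels, flux_truth)``: genes x conditions unscaled
    levels (2 ** log2-model) and reactions x conditions true fluxes for the
    pathway chain (all members carry the shared pathway flux).
    """
    rng = np.random.default_rng(spec.seed)
    conds = [f"cond{j+1}" for j in range(spec.n_conditions)]
    factor = rng.standard_normal(spec.n_conditions)

    def member_logs(n_genes, f):
        eps = rng.standard_normal((n_genes, spec.n_conditions))
        a = np.sqrt(max(spec.rho, 0.0))
        b = np.sqrt(max(1.0 - spec.rho, 0.0)) * spec.noise_sd
        return a * f + b * eps

    rows, index = [], []
    if fixture.pathway_genes:
        rows.append(member_logs(len(fixture.pathway_genes), factor))
        index += fixture.pathway_genes
    other = fixture.background_genes + fixture.decoy_genes
    if other:
        rows.append(rng.standard_normal((len(other), spec.n_conditions)))
        index += other
    logs = np.vstack(rows) if rows else np.empty((0, spec.n_conditions))
    levels = pd.DataFrame(np.exp2(logs), index=index, columns=conds)

    flux = spec.beta * factor + spec.flux_noise_sd * rng.standard_normal(
        spec.n_conditions
    )
    flux_rows = {rid: flux for rid in fixture.pathway_reactions}
    flux_rows[fixture.roi] = flux
    flux_truth = pd.DataFrame(flux_rows, index=conds).T
    return levels, flux_truth


def apply_dropout(
    levels: pd.DataFrame, rate: float, seed: int = 0
) -> pd.DataFrame:
    """Set each entry independently to 0 with probability ``rate``.

    Measured status is untouched: a dropout is an (incorrect) zero
    observation, not a missing value.
    """
    if not 0 <= rate < 1:
        raise ValueError("dropout rate must lie in [0, 1)")
    if rate == 0:
        return levels.copy()
    rng = np.random.default_rng(seed)
    keep = rng.random(levels.shape) >= rate
    return levels.where(keep, 0.0)
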