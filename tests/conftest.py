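import numpy as np
import pandas as pd
import pytest

from efpa.expression import ReactionExpression, MISSING, COMPLETE
from efpa.model_io import MetabolicNetwork, Metabolite, Reaction, parse_gpr


def rxn(rid, stoich, gpr="", lb=0.0, ub=1000.0):
    return Reaction(rid, stoich, lb, ub, parse_gpr(gpr))


@pytest.fixture
def chain3():
    """uptake -> A, A -> B, B export: the canonical 3-reaction chain."""
    return MetabolicNetwork(
        metabolites=[Metabolite("A"), Metabolite("B")],
        reactions=[
            rxn("R1", {"A": 1.0}, "g1"),
            rxn("R2", {"A": -1.0, "B": 1.0}, "g2"),
            rxn("R3", {"B": -1.0}, "g3"),
        ],
    )


def uniform_rel(net, value=1.0, conditions=("c1",), missing=()):
    """ReactionExpression with one constant relative expression everywhere."""
    idx = net.reaction_ids
    values = pd.DataFrame(value, index=idx, columns=list(conditions))
    status = pd.Series(COMPLETE, index=idx, dtype=object)
    for rid in missing:
        status[rid] = MISSING
        values.loc[rid] = np.nan
    return ReactionExpression(values=values, status=status)


@pytest.fixture
def uniform_rel_factory():
    return uniform_rel


def random_network(rng, n_mets=6, n_rxns=20, p_rev=0.3):
    """Random mass-connected toy: every reaction touches 1-3 metabolites."""
    mets = [Metabolite(f"m{i}") for i in range(n_mets)]
    rxns = []
    for j in range(n_rxns):
        k = rng.integers(1, 4)
        chosen = rng.choice(n_mets, size=k, replace=False)
        stoich = {}
        for i, mi in enumerate(chosen):
            coef = float(rng.integers(1, 3)) * (1 if i % 2 else -1)
            stoich[f"m{mi}"] = coef
        lb = -1000.0 if rng.random() < p_rev else 0.0
        rxns.append(Reaction(f"r{j}", stoich, lb, 1000.0))
    return MetabolicNetwork(mets, rxns)
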