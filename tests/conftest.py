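import numpy as np
import pytest
from hypothesis import settings

from tetopsim.engine import CellCycleParams
from tetopsim.model import RateConstant, ReactionDef, ReactionNetwork, \
    SpeciesDef, build_tet_network

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


NO_DIVISION = CellCycleParams(enabled=False)


def make_network(species, reactions, constants, moieties=None):
    """Ad-hoc network for engine oracle tests.

    ``species``: (name, halved, initial) triples; ``reactions``: (id,
    reactants-dict, products-dict, rate-id[, shape-id]) tuples; ``constants``:
    {id: (value, unit_class)}.
    """
    sp = tuple(SpeciesDef(n, "small_molecule", h, i) for n, h, i in species)
    rxns = []
    for entry in reactions:
        rid, reac, prod, rate = entry[:4]
        shape = entry[4] if len(entry) > 4 else None
        rxns.append(ReactionDef(
            str(rid), 0, tuple(sorted(reac.items())),
            tuple(sorted(prod.items())), rate,
            "gamma_elongation" if shape else "mass_action", shape))
    consts = tuple(RateConstant(k, v, uc) for k, (v, uc) in constants.items())
    return ReactionNetwork(sp, tuple(rxns), consts, "test",
                           moieties or {}, {})


@pytest.fixture(scope="session")
def wt_network():
    return build_tet_network()


@pytest.fixture(scope="session")
def birth_death():
    # 0 -> A at 10/s, A -> 0 at 0.1/s; stationary law Poisson(100)
    return make_network(
        [("A", True, 0)],
        [("b", {}, {"A": 1}, "kb"), ("d", {"A": 1}, {}, "kd")],
        {"kb": (10.0, "per_second"), "kd": (0.1, "per_second")},
    )
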