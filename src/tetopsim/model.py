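"""Definition of the tetracycline-operon reaction network.

The tet operon confers tetracycline (Tc) resistance on *E. coli*: the TetR
repressor dimer (TetR2) sits on two operators (tetO1, tetO2) and silences both
its own gene (driven by promoters tetP_R1 and tetP_R2) and the efflux-pump gene
tetA (driven by tetP_A).  Intracellular Tc binds TetR2 at two independent
sites, releasing it from the operators and switching expression on; TetA then
pumps Tc back out of the cell.

The network encoded here has 40 species and 62 elementary irreversible
reactions (reversible steps are stored as forward/backward pairs), covering
repressor dimerization, operator and non-specific DNA binding, Tc influx and
Tc-repressor chemistry, transcription from the three promoters with explicit
closed- and open-complex intermediates, gamma-distributed transcript/peptide
elongation, translation, degradation, and TetA-mediated efflux.  A bookkeeping
species ``Complex`` stands for the operon locus when every promoter and
operator site is simultaneously free; its assembly/disassembly reactions have
no physical meaning and simply keep the mutually exclusive site occupancies
consistent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

__all__ = [
    "SpeciesDef",
    "RateConstant",
    "ReactionDef",
    "ReactionNetwork",
    "build_tet_network",
    "scale_affinity",
    "knockout_promoter_PR1",
    "validate_network",
    "AFFINITY_GROUPS",
    "AVOGADRO",
]

AVOGADRO = 6.02214076e23

# ---------------------------------------------------------------------------
# Rate constants (values as printed; units per the conventions documented in
# docs/methods.md).  unit_class:
#   per_second        - unimolecular / bookkeeping, s^-1
#   per_molar_second  - bimolecular association, M^-1 s^-1
#   per_step          - gamma elongation step rate, steps s^-1
#   step_count        - gamma shape parameter (number of nt or aa steps)
# ---------------------------------------------------------------------------

_RATE_VALUES = {
    "k1": 1e9, "k2": 10.0, "k3": 1e8, "k4": 1e-4, "k5": 5.00e8, "k6": 1e-4,
    "k7": 30.0, "k8": 0.10, "k9": 3.30e-4,
    "k10": 4.80e5, "k11": 1e-4, "k12": 2.40e5, "k13": 2.00e-4,
    "k14": 4.80e5, "k15": 1e-4, "k16": 2.40e5, "k17": 2.00e-4,
    "k18": 5.80e-3, "k19": 0.10,
    "k20": 4.80e5, "k21": 1e-4, "k22": 2.40e5, "k23": 2.00e-4,
    "k24": 5.80e-3, "k25": 0.10,
    "k26": 4.8e4, "k27": 0.10, "k28": 0.013, "k29": 30.0,
    "k30": 30.0, "k31": 621,
    "k32": 9.10e5, "k33": 0.10, "k34": 0.013, "k35": 30.0,
    "k36": 30.0, "k37": 621,
    "k38": 7.23e6, "k39": 0.10, "k40": 0.013, "k41": 30.0,
    "k42": 1e5, "k43": 100.0, "k44": 100.0, "k45": 207,
    "k46": 8.60e6, "k47": 0.10, "k48": 0.013, "k49": 30.0,
    "k50": 30.0, "k51": 1182,
    "k52": 1e5, "k53": 100.0, "k54": 100.0, "k55": 394,
    "k56": 3.85e-5, "k57": 3.85e-5, "k58": 0.002, "k59": 0.002,
    "k60": 2.67e-6, "k61": 1.0, "k62": 4.90e-5,
    "k63": 1e8, "k64": 1e8, "k65": 5.00e8, "k66": 0.10, "k67": 0.10,
}

_PER_MOLAR = {
    "k1", "k3", "k5", "k7", "k10", "k12", "k14", "k16", "k19", "k20", "k22",
    "k25", "k26", "k32", "k38", "k42", "k46", "k52", "k61",
    "k64", "k65", "k66", "k67",
}
_PER_STEP = {"k30", "k36", "k44", "k50", "k54"}
_STEP_COUNT = {"k31", "k37", "k45", "k51", "k55"}

_SOURCE_NOTES = {
    "k1": "TetR dimerization; equilibrium constant taken as 1e8 M^-1",
    "k9": "effective Tc membrane influx",
    "k56": "TetR2 degradation, 5 h half-life",
    "k58": "tetR mRNA decay, tuned for ~20 proteins per transcript",
    "k61": "TetA-mediated Tc efflux (unit interpretation uncertain; see docs)",
    "k63": "locus-assembly bookkeeping, made effectively instantaneous",
}


def _unit_class(kid: str) -> str:
    if kid in _PER_MOLAR:
        return "per_molar_second"
    if kid in _PER_STEP:
        return "per_step"
    if kid in _STEP_COUNT:
        return "step_count"
    return "per_second"


# Sensitivity-sweep groups: forward association constants scaled together.
AFFINITY_GROUPS = {
    "tc_tetr": ("k10", "k12", "k14", "k16", "k20", "k22"),
    "tetr_operator": ("k3", "k5", "k19", "k25", "k64", "k65", "k66", "k67"),
}


@dataclass(frozen=True)
class RateConstant:
    id: str
    value: float
    unit_class: str
    source_note: str = ""


@dataclass(frozen=True)
class SpeciesDef:
    name: str
    role: str  # dna_site | machinery | protein | protein_complex | mrna | small_molecule
    halved_on_division: bool
    initial_count: int = 0


@dataclass(frozen=True)
class ReactionDef:
    """One irreversible reaction.

    ``table_id`` is the Table-1 row number; ``id`` disambiguates the two
    directions of a reversible row ("2f"/"2b").  ``kinetics`` is
    ``mass_action`` or ``gamma_elongation``; for the latter, reactants are
    consumed when the reaction initiates and products appear after a
    Gamma(shape, rate)-distributed delay.
    """

    id: str
    table_id: int
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_ref: str
    kinetics: str = "mass_action"
    shape_ref: str | None = None


# ---------------------------------------------------------------------------
# Species table.  halved_on_division is true exactly for free proteins,
# protein complexes not containing DNA or machinery, free mRNA, and
# intracellular Tc; DNA sites, RNAp/Rib (and anything containing them),
# nsDNA and external Tc are not partitioned.
# ---------------------------------------------------------------------------

_SPECIES: tuple[SpeciesDef, ...] = (
    SpeciesDef("TcEx", "small_molecule", False),
    SpeciesDef("Tc", "small_molecule", True),
    SpeciesDef("TetR", "protein", True),
    SpeciesDef("TetR2", "protein_complex", True),
    SpeciesDef("TetA", "protein", True),
    SpeciesDef("tetO1", "dna_site", False, 1),
    SpeciesDef("tetO2", "dna_site", False, 1),
    SpeciesDef("nsDNA", "dna_site", False, 4_000_000),
    SpeciesDef("tetP_R1", "dna_site", False, 1),
    SpeciesDef("tetP_R2", "dna_site", False, 1),
    SpeciesDef("tetP_A", "dna_site", False, 1),
    SpeciesDef("RNAp", "machinery", False, 180),
    SpeciesDef("Rib", "machinery", False, 300),
    SpeciesDef("Complex", "dna_site", False),
    SpeciesDef("mRNA(tetR)", "mrna", True),
    SpeciesDef("mRNA(tetA)", "mrna", True),
    SpeciesDef("TetR2:tetO1", "dna_site", False),
    SpeciesDef("TetR2:tetO2", "dna_site", False),
    SpeciesDef("TetR2:nsDNA", "dna_site", False),
    SpeciesDef("TetR2:Tc", "protein_complex", True),
    SpeciesDef("TetR2:Tc2", "protein_complex", True),
    SpeciesDef("TetR2:tetO1:Tc", "dna_site", False),
    SpeciesDef("TetR2:tetO1:Tc2", "dna_site", False),
    SpeciesDef("TetR2:tetO2:Tc", "dna_site", False),
    SpeciesDef("TetR2:tetO2:Tc2", "dna_site", False),
    SpeciesDef("RNAp:PR1", "dna_site", False),       # closed complex at tetP_R1
    SpeciesDef("RNAp*:PR1", "dna_site", False),      # open complex at tetP_R1
    SpeciesDef("RNAp:PR2", "dna_site", False),
    SpeciesDef("RNAp*:PR2", "dna_site", False),
    SpeciesDef("RNAp:PR2:TetR2:tetO2", "dna_site", False),
    SpeciesDef("RNAp*:PR2:TetR2:tetO2", "dna_site", False),
    SpeciesDef("RNAp:PA", "dna_site", False),
    SpeciesDef("RNAp*:PA", "dna_site", False),
    SpeciesDef("Rib:mRNA(tetR)", "machinery", False),
    SpeciesDef("Rib:mRNA(tetA)", "machinery", False),
    SpeciesDef("Rib*:mRNA(tetR)", "machinery", False),
    SpeciesDef("Rib*:mRNA(tetA)", "machinery", False),
    SpeciesDef("RNAp*:DNA(PR1)", "machinery", False),
    SpeciesDef("RNAp*:DNA(PR2)", "machinery", False),
    SpeciesDef("RNAp*:DNA(PA)", "machinery", False),
)

# Conserved-moiety content of each species (species absent from a moiety's map
# carry zero).  The closed/open complexes reached through ``Complex`` contain
# the whole locus; the tetO2-repressed route (reactions 22-24) contains only
# tetP_R2, tetO1, tetO2 and a TetR2.  Elongating RNAp ("RNAp*:DNA(..)") has
# already released the locus.
_FULL_LOCUS = ("RNAp:PR1", "RNAp*:PR1", "RNAp:PR2", "RNAp*:PR2",
               "RNAp:PA", "RNAp*:PA")
_O2_ROUTE = ("RNAp:PR2:TetR2:tetO2", "RNAp*:PR2:TetR2:tetO2")

_MOIETIES: dict[str, dict[str, int]] = {
    "tetO1": {"tetO1": 1, "Complex": 1, "TetR2:tetO1": 1, "TetR2:tetO1:Tc": 1,
              "TetR2:tetO1:Tc2": 1,
              **{s: 1 for s in _FULL_LOCUS}, **{s: 1 for s in _O2_ROUTE}},
    "tetO2": {"tetO2": 1, "Complex": 1, "TetR2:tetO2": 1, "TetR2:tetO2:Tc": 1,
              "TetR2:tetO2:Tc2": 1,
              **{s: 1 for s in _FULL_LOCUS}, **{s: 1 for s in _O2_ROUTE}},
    "tetP_R1": {"tetP_R1": 1, "Complex": 1, **{s: 1 for s in _FULL_LOCUS}},
    "tetP_R2": {"tetP_R2": 1, "Complex": 1,
                **{s: 1 for s in _FULL_LOCUS}, **{s: 1 for s in _O2_ROUTE}},
    "tetP_A": {"tetP_A": 1, "Complex": 1, **{s: 1 for s in _FULL_LOCUS}},
    "nsDNA": {"nsDNA": 1, "TetR2:nsDNA": 1},
    "RNAp": {"RNAp": 1, **{s: 1 for s in _FULL_LOCUS}, **{s: 1 for s in _O2_ROUTE},
             "RNAp*:DNA(PR1)": 1, "RNAp*:DNA(PR2)": 1, "RNAp*:DNA(PA)": 1},
    "Rib": {"Rib": 1, "Rib:mRNA(tetR)": 1, "Rib:mRNA(tetA)": 1,
            "Rib*:mRNA(tetR)": 1, "Rib*:mRNA(tetA)": 1},
}


def _rows(include_pr1: bool) -> list[tuple]:
    """Table-1 rows as (num, reactants, products, fwd, rev, shape).

    Reactants/products are {species: stoichiometry} dicts; ``rev`` is None for
    irreversible rows; ``shape`` is the gamma shape constant id for
    elongation rows.
    """
    locus = ["tetP_R1", "tetP_R2", "tetP_A", "tetO1", "tetO2"]
    if not include_pr1:
        locus.remove("tetP_R1")
    sites = {s: 1 for s in locus}

    def minus(d, key):
        out = dict(d)
        del out[key]
        return out

    rows = [
        (1, {"TetR": 2}, {"TetR2": 1}, "k1", "k2", None),
        (2, {"TetR2": 1, "tetO1": 1}, {"TetR2:tetO1": 1}, "k3", "k4", None),
        (3, {"TetR2": 1, "tetO2": 1}, {"TetR2:tetO2": 1}, "k5", "k6", None),
        (4, {"TetR2": 1, "nsDNA": 1}, {"TetR2:nsDNA": 1}, "k7", "k8", None),
        (5, {"TcEx": 1}, {"Tc": 1}, "k9", None, None),
        (6, {"TetR2": 1, "Tc": 1}, {"TetR2:Tc": 1}, "k10", "k11", None),
        (7, {"TetR2:Tc": 1, "Tc": 1}, {"TetR2:Tc2": 1}, "k12", "k13", None),
        (8, {"TetR2:tetO1": 1, "Tc": 1}, {"TetR2:tetO1:Tc": 1}, "k14", "k15", None),
        (9, {"TetR2:tetO1:Tc": 1, "Tc": 1}, {"TetR2:tetO1:Tc2": 1}, "k16", "k17", None),
        (10, {"TetR2:tetO1:Tc2": 1}, {"TetR2:Tc2": 1, "tetO1": 1}, "k18", "k19", None),
        (11, {"TetR2:tetO2": 1, "Tc": 1}, {"TetR2:tetO2:Tc": 1}, "k20", "k21", None),
        (12, {"TetR2:tetO2:Tc": 1, "Tc": 1}, {"TetR2:tetO2:Tc2": 1}, "k22", "k23", None),
        (13, {"TetR2:tetO2:Tc2": 1}, {"TetR2:Tc2": 1, "tetO2": 1}, "k24", "k25", None),
    ]
    if include_pr1:
        rows += [
            (14, {"RNAp": 1, "Complex": 1}, {"RNAp:PR1": 1}, "k26", "k27", None),
            (15, {"RNAp:PR1": 1}, {"RNAp*:PR1": 1}, "k28", None, None),
            (16, {"RNAp*:PR1": 1}, {"RNAp*:DNA(PR1)": 1, "Complex": 1}, "k29", None, None),
            (17, {"RNAp*:DNA(PR1)": 1}, {"RNAp": 1, "mRNA(tetR)": 1}, "k30", None, "k31"),
        ]
    rows += [
        (18, {"RNAp": 1, "Complex": 1}, {"RNAp:PR2": 1}, "k32", "k33", None),
        (19, {"RNAp:PR2": 1}, {"RNAp*:PR2": 1}, "k34", None, None),
        (20, {"RNAp*:PR2": 1}, {"RNAp*:DNA(PR2)": 1, "Complex": 1}, "k35", None, None),
        (21, {"RNAp*:DNA(PR2)": 1}, {"RNAp": 1, "mRNA(tetR)": 1}, "k36", None, "k37"),
        (22, {"RNAp": 1, "tetP_R2": 1, "tetO1": 1, "TetR2:tetO2": 1},
             {"RNAp:PR2:TetR2:tetO2": 1}, "k38", "k39", None),
        (23, {"RNAp:PR2:TetR2:tetO2": 1}, {"RNAp*:PR2:TetR2:tetO2": 1}, "k40", None, None),
        (24, {"RNAp*:PR2:TetR2:tetO2": 1},
             {"RNAp*:DNA(PR2)": 1, "tetP_R2": 1, "tetO1": 1, "TetR2:tetO2": 1},
             "k41", None, None),
        (25, {"Rib": 1, "mRNA(tetR)": 1}, {"Rib:mRNA(tetR)": 1}, "k42", None, None),
        (26, {"Rib:mRNA(tetR)": 1}, {"Rib*:mRNA(tetR)": 1, "mRNA(tetR)": 1}, "k43", None, None),
        (27, {"Rib*:mRNA(tetR)": 1}, {"Rib": 1, "TetR": 1}, "k44", None, "k45"),
        (28, {"RNAp": 1, "Complex": 1}, {"RNAp:PA": 1}, "k46", "k47", None),
        (29, {"RNAp:PA": 1}, {"RNAp*:PA": 1}, "k48", None, None),
        (30, {"RNAp*:PA": 1}, {"RNAp*:DNA(PA)": 1, "Complex": 1}, "k49", None, None),
        (31, {"RNAp*:DNA(PA)": 1}, {"RNAp": 1, "mRNA(tetA)": 1}, "k50", None, "k51"),
        (32, {"Rib": 1, "mRNA(tetA)": 1}, {"Rib:mRNA(tetA)": 1}, "k52", None, None),
        (33, {"Rib:mRNA(tetA)": 1}, {"Rib*:mRNA(tetA)": 1, "mRNA(tetA)": 1}, "k53", None, None),
        (34, {"Rib*:mRNA(tetA)": 1}, {"Rib": 1, "TetA": 1}, "k54", None, "k55"),
        (35, {"TetR2": 1}, {}, "k56", None, None),
        (36, {"TetR2:Tc2": 1}, {"Tc": 2}, "k57", None, None),
        (37, {"mRNA(tetR)": 1}, {}, "k58", None, None),
        (38, {"mRNA(tetA)": 1}, {}, "k59", None, None),
        (39, {"Tc": 1}, {}, "k60", None, None),
        (40, {"Tc": 1, "TetA": 1}, {"TetA": 1}, "k61", "k62", None),
        (41, sites, {"Complex": 1}, "k63", None, None),
        (42, {"Complex": 1, "TetR2": 1},
             {"TetR2:tetO1": 1, **minus(sites, "tetO1")}, "k64", None, None),
        (43, {"Complex": 1, "TetR2": 1},
             {"TetR2:tetO2": 1, **minus(sites, "tetO2")}, "k65", None, None),
        (44, {"Complex": 1, "TetR2:Tc2": 1},
             {"TetR2:tetO1:Tc2": 1, **minus(sites, "tetO1")}, "k66", None, None),
        (45, {"Complex": 1, "TetR2:Tc2": 1},
             {"TetR2:tetO2:Tc2": 1, **minus(sites, "tetO2")}, "k67", None, None),
    ]
    return rows


@dataclass(frozen=True)
class ReactionNetwork:
    species: tuple[SpeciesDef, ...]
    reactions: tuple[ReactionDef, ...]
    constants: tuple[RateConstant, ...]
    variant_tag: str = "wild-type"
    moieties: dict = field(default_factory=dict, compare=False)
    overrides: dict = field(default_factory=dict, compare=False)

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self, name: str) -> int:
        return self.species_names.index(name)

    def constant(self, kid: str) -> RateConstant:
        for c in self.constants:
            if c.id == kid:
                return c
        raise KeyError(kid)

    def reaction(self, rid: str) -> ReactionDef:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def initial_counts(self) -> dict[str, int]:
        return {s.name: s.initial_count for s in self.species}

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "variant_tag": self.variant_tag,
            "species": [
                {"name": s.name, "role": s.role,
                 "halved_on_division": s.halved_on_division,
                 "initial_count": s.initial_count}
                for s in self.species
            ],
            "reactions": [
                {"id": r.id, "table_id": r.table_id,
                 "reactants": [list(p) for p in r.reactants],
                 "products": [list(p) for p in r.products],
                 "kinetics": r.kinetics, "rate_ref": r.rate_ref,
                 "shape_ref": r.shape_ref}
                for r in self.reactions
            ],
            "constants": [
                {"id": c.id, "value": c.value, "unit_class": c.unit_class,
                 "source_note": c.source_note}
                for c in self.constants
            ],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _build(overrides: dict[str, float], include_pr1: bool,
           variant_tag: str, unit_class_overrides: dict[str, str] | None = None,
           ) -> ReactionNetwork:
    values = dict(_RATE_VALUES)
    for kid, val in overrides.items():
        if kid not in values:
            raise KeyError(f"unknown rate-constant id in overrides: {kid!r}")
        if not (val >= 0):
            raise ValueError(f"override {kid}={val!r} must be non-negative")
        values[kid] = float(val)
    units = {kid: _unit_class(kid) for kid in values}
    if unit_class_overrides:
        for kid, uc in unit_class_overrides.items():
            if kid not in units:
                raise KeyError(f"unknown rate-constant id: {kid!r}")
            units[kid] = uc
    constants = tuple(
        RateConstant(kid, values[kid], units[kid], _SOURCE_NOTES.get(kid, ""))
        for kid in sorted(values, key=lambda k: int(k[1:]))
    )

    reactions: list[ReactionDef] = []
    for num, reac, prod, fwd, rev, shape in _rows(include_pr1):
        r_t = tuple(sorted(reac.items()))
        p_t = tuple(sorted(prod.items()))
        if shape is not None:
            reactions.append(ReactionDef(str(num), num, r_t, p_t, fwd,
                                         "gamma_elongation", shape))
        elif rev is None:
            reactions.append(ReactionDef(str(num), num, r_t, p_t, fwd))
        else:
            reactions.append(ReactionDef(f"{num}f", num, r_t, p_t, fwd))
            reactions.append(ReactionDef(f"{num}b", num, p_t, r_t, rev))

    species = _SPECIES
    moieties = {m: dict(content) for m, content in _MOIETIES.items()}
    if not include_pr1:
        species = tuple(
            replace(s, initial_count=0) if s.name == "tetP_R1" else s
            for s in species
        )
        # Complex and the closed/open complexes reached through it no longer
        # contain tetP_R1 in the knockout variant.
        for sp in ("Complex",) + _FULL_LOCUS:
            moieties["tetP_R1"].pop(sp, None)

    return ReactionNetwork(species, tuple(reactions), constants,
                           variant_tag, moieties, dict(overrides))


def build_tet_network(overrides: dict[str, float] | None = None,
                      unit_class_overrides: dict[str, str] | None = None,
                      ) -> ReactionNetwork:
    """Build the wild-type tet-operon network.

    Parameters
    ----------
    overrides
        Map of rate-constant id ("k1".."k67") to replacement value.
    unit_class_overrides
        Optional map of rate-constant id to unit_class, for exploring the
        unit-interpretation ambiguity of individual constants (e.g. ``k61``).
    """
    return _build(dict(overrides or {}), True, "wild-type", unit_class_overrides)


def scale_affinity(network: ReactionNetwork, group: str, factor: float
                   ) -> ReactionNetwork:
    """Scale a named group of forward association constants by ``factor``.

    ``group`` is ``"tc_tetr"`` (affinity of Tc for the repressor) or
    ``"tetr_operator"`` (affinity of TetR2, free or Tc-loaded, for the
    operators).  Returns a new network; the input is unchanged.
    """
    if group not in AFFINITY_GROUPS:
        raise KeyError(f"unknown affinity group: {group!r}")
    if not factor > 0:
        raise ValueError("factor must be positive")
    kids = AFFINITY_GROUPS[group]
    constants = tuple(
        replace(c, value=c.value * factor) if c.id in kids else c
        for c in network.constants
    )
    tag = network.variant_tag if factor == 1.0 else \
        f"affinity-scaled:{group}x{factor:g}"
    return replace(network, constants=constants, variant_tag=tag)


def knockout_promoter_PR1(network: ReactionNetwork) -> ReactionNetwork:
    """Variant lacking the tetP_R1 promoter.

    Reactions 14-17 are removed and the locus-assembly bookkeeping
    (reactions 41-45) is rewritten so ``Complex`` comprises only tetP_R2,
    tetP_A, tetO1 and tetO2.  Species indexing is unchanged; tetP_R1 and the
    intermediates reached through it simply never acquire molecules.
    """
    if network.variant_tag != "wild-type":
        raise ValueError("knockout applies to the wild-type network only")
    return _build(dict(network.overrides), False, "knockout")


def validate_network(network: ReactionNetwork) -> list[str]:
    """Consistency checks; returns a list of human-readable violations.

    Checks (a) that every reaction's net stoichiometry conserves each DNA
    moiety and the RNAp and Rib totals (gamma reactions are checked on their
    combined initiation+completion stoichiometry), (b) the documented
    parameter ratios, and (c) that every referenced constant exists.
    """
    violations: list[str] = []
    names = set(network.species_names)
    kids = {c.id for c in network.constants}

    for r in network.reactions:
        for sp, _ in r.reactants + r.products:
            if sp not in names:
                violations.append(f"reaction {r.id}: unknown species {sp!r}")
        for ref in (r.rate_ref, r.shape_ref):
            if ref is not None and ref not in kids:
                violations.append(f"reaction {r.id}: missing constant {ref!r}")
        for moiety, content in network.moieties.items():
            net = 0
            for sp, st in r.products:
                net += st * content.get(sp, 0)
            for sp, st in r.reactants:
                net -= st * content.get(sp, 0)
            if net != 0:
                violations.append(
                    f"reaction {r.id}: net {moiety} change {net:+d}")

    def val(kid):
        return network.constant(kid).value

    ratio_checks = [
        ("k5/k3", val("k5") / val("k3"), 5.0),
        ("k32/k26", val("k32") / val("k26"), 19.0),
        ("k46/(k26+k32)", val("k46") / (val("k26") + val("k32")), 9.0),
    ]
    for label, got, want in ratio_checks:
        if abs(got - want) > 0.05 * want:
            violations.append(f"ratio {label} = {got:.3f}, expected ~{want:g}")

    return violations
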