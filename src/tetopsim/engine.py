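"""Exact stochastic simulation of a single growing, dividing cell.

The simulator runs Gillespie's stochastic simulation algorithm (SSA) over the
mass-action reactions of a :class:`~tetopsim.model.ReactionNetwork`, with three
extensions needed by the tet-operon model:

* **Gamma-distributed elongation.**  Transcript and peptide elongation are
  modelled as single delayed events: as soon as an elongation-ready complex
  (e.g. ``RNAp*:DNA(PR2)``) is created, it is consumed and a completion is
  scheduled after a Gamma(shape, rate) delay — the sum of one exponential step
  per nucleotide or codon.  Products (polymerase/ribosome plus the finished
  mRNA or protein) appear at the completion time.
* **Cell growth and division.**  The volume grows exponentially from
  ``v0 = 1e-15 L``, doubling over the cell's own division interval, drawn from
  a truncated Normal(30 min, 4 min).  At division the freely diffusing species
  (proteins, protein:Tc complexes, mRNAs, intracellular Tc) are partitioned
  binomially with p = 1/2; DNA sites, polymerases and ribosomes stay with the
  tracked daughter and the volume resets to ``v0``.
* **Dosing.**  Scheduled events either add external tetracycline (``TcEx``)
  as a pulse or clamp it at a fixed level (continuous administration).

Bimolecular propensities use the cell volume: for a molar association
constant k the stochastic constant is ``k / (N_A V)`` (``2k / (N_A V)`` with
``n(n-1)/2`` combinations for the homodimerization 2 TetR -> TetR2), so the
simulation matches the deterministic mass-action limit.  By default the
growing volume is re-read at every event and propensities are treated as
constant between events; ``volume_coupling="fixed"`` instead evaluates all
propensities at ``v0`` (the convention implied by the
20-proteins-per-transcript calibration of the mRNA decay rate).

The hot loop is compiled with numba when available and falls back to plain
NumPy otherwise.  A fixed per-cell seed makes every trajectory reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import AVOGADRO, ReactionNetwork

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    def _jit(fn):
        return _njit(cache=True)(fn)
except Exception:  # pragma: no cover
    def _jit(fn):
        return fn

__all__ = [
    "CellCycleParams",
    "DoseSchedule",
    "CellState",
    "Trajectory",
    "stochastic_rate_constant",
    "propensity",
    "draw_elongation_delay",
    "divide",
    "simulate_cell",
    "simulate_ensemble",
]


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellCycleParams:
    """Cell-cycle model: division every Normal(30, 4) minutes, volume 1 fL."""

    mean_division: float = 1800.0  # s
    sd_division: float = 240.0     # s
    v0: float = 1e-15              # L
    halving: str = "binomial"      # "binomial" | "floor"
    enabled: bool = True
    # "exponential": bimolecular propensities track the exponentially growing
    # volume (V doubling over the cell's own division interval, reset at
    # division); "fixed": propensities always use v0, which is what the
    # 20-proteins-per-transcript calibration of the mRNA decay rate implies.
    # The two conventions cannot both hold; see docs/methods.md.
    volume_coupling: str = "exponential"

    def __post_init__(self):
        if self.mean_division <= 0 or self.sd_division < 0:
            raise ValueError("invalid division-time parameters")
        if self.halving not in ("binomial", "floor"):
            raise ValueError("halving must be 'binomial' or 'floor'")
        if self.volume_coupling not in ("fixed", "exponential"):
            raise ValueError("volume_coupling must be 'fixed' or 'exponential'")


@dataclass(frozen=True)
class DoseSchedule:
    """Timed manipulations of external tetracycline.

    ``events`` is a sequence of ``(time_s, mode, amount)`` with mode
    ``"pulse_add"`` (TcEx += amount) or ``"clamp"`` (TcEx held at ``amount``
    until overridden by a later event).
    """

    events: tuple[tuple[float, str, int], ...] = ()

    def __post_init__(self):
        times = [e[0] for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("dose times must be non-decreasing")
        for t, mode, amount in self.events:
            if mode not in ("pulse_add", "clamp"):
                raise ValueError(f"unknown dose mode {mode!r}")
            if amount < 0:
                raise ValueError("dose amounts must be non-negative")

    @classmethod
    def pulse(cls, time_s: float, amount: int) -> "DoseSchedule":
        return cls(((float(time_s), "pulse_add", int(amount)),))

    @classmethod
    def clamp(cls, time_s: float, level: int) -> "DoseSchedule":
        return cls(((float(time_s), "clamp", int(level)),))


@dataclass
class CellState:
    """Mutable single-cell state (API-level mirror of the kernel state)."""

    t: float
    volume: float
    counts: np.ndarray
    pending: list  # list of (completion_time, reaction_index)
    next_division: float
    t_birth: float = 0.0
    division_interval: float = 1800.0


@dataclass
class Trajectory:
    """Sampled counts of one cell plus per-reaction event counters.

    ``pending`` holds, per grid point and reaction, the number of scheduled
    but uncompleted gamma elongations (elongating polymerases/ribosomes) —
    needed to audit RNAp/Rib conservation mid-elongation.
    """

    grid: np.ndarray                # (G,) s
    counts: np.ndarray              # (G, S) molecules
    species: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    pending: np.ndarray             # (G, R)
    fire_counts: np.ndarray         # (R,) reaction firings (gamma: initiations)
    completion_counts: np.ndarray   # (R,) gamma completions
    seed: int = 0

    def series(self, species: str) -> np.ndarray:
        return self.counts[:, self.species.index(species)]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.counts, columns=list(self.species))
        df.insert(0, "time_s", self.grid)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def event_counter_summary(self) -> dict:
        return {
            "firings": {r: int(n) for r, n in
                        zip(self.reaction_ids, self.fire_counts)},
            "completions": {r: int(n) for r, n in
                            zip(self.reaction_ids, self.completion_counts)
                            if n > 0},
            "seed": int(self.seed),
        }


# ---------------------------------------------------------------------------
# Elementary conversions (also used standalone in tests)
# ---------------------------------------------------------------------------

def stochastic_rate_constant(k: float, unit_class: str, order: int,
                             volume: float, homodimer: bool = False) -> float:
    """Convert a printed rate constant into a stochastic constant (s^-1).

    ``per_second`` constants pass through; ``per_molar_second`` bimolecular
    constants are divided by ``N_A * volume`` (doubled for a homodimerization,
    whose combination count is n(n-1)/2).
    """
    if volume <= 0:
        raise ValueError("volume must be positive")
    if unit_class == "per_second":
        return k
    if unit_class == "per_molar_second":
        if order != 2:
            raise ValueError(
                f"per_molar_second constant with unsupported order {order}")
        c = k / (AVOGADRO * volume)
        return 2.0 * c if homodimer else c
    raise ValueError(f"unsupported unit_class {unit_class!r} for a propensity")


def propensity(network: ReactionNetwork, reaction, counts, volume: float) -> float:
    """Mass-action propensity of one reaction at the given counts and volume.

    ``counts`` may be a mapping from species name to count or an array in the
    network's species order.  Gamma-elongation reactions do not take part in
    the SSA race (they initiate on creation of their reactant) and return 0.
    """
    if isinstance(reaction, str):
        reaction = network.reaction(reaction)
    if reaction.kinetics == "gamma_elongation":
        return 0.0
    if isinstance(counts, dict):
        get = lambda sp: counts.get(sp, 0)  # noqa: E731
    else:
        get = lambda sp: counts[network.species_index(sp)]  # noqa: E731

    const = network.constant(reaction.rate_ref)
    homodimer = any(st == 2 for _, st in reaction.reactants)
    # The molar->stochastic conversion carries a single 1/(N_A V): the DNA-site
    # "indicator" reactants of the bookkeeping reactions are 0/1 counts.
    order = 2 if const.unit_class == "per_molar_second" else 1
    c = stochastic_rate_constant(const.value, const.unit_class, order,
                                 volume, homodimer)
    a = c
    for sp, st in reaction.reactants:
        n = get(sp)
        if n < st:
            return 0.0
        a *= n if st == 1 else n * (n - 1) / 2.0
    return a


def draw_elongation_delay(shape: int, step_rate: float, rng) -> float:
    """One gamma-distributed elongation time: sum of ``shape`` exponential
    single-step times with rate ``step_rate`` (mean = shape / step_rate)."""
    if shape < 1 or step_rate <= 0:
        raise ValueError("shape must be >= 1 and step_rate positive")
    return float(rng.gamma(shape, 1.0 / step_rate))


def divide(state: CellState, cycle: CellCycleParams, rng,
           halved_mask: np.ndarray) -> CellState:
    """Apply one division to ``state`` in place and return it.

    Species flagged in ``halved_mask`` are replaced by Binomial(n, 1/2)
    draws (or ``floor(n/2)`` in floor mode); everything else — DNA sites,
    polymerases, ribosomes, external Tc — is untouched.  Pending elongations
    stay with the tracked daughter.  The volume resets and the next division
    is scheduled a truncated Normal(mean, sd) interval away.
    """
    x = state.counts
    for i in np.nonzero(halved_mask)[0]:
        x[i] = rng.binomial(x[i], 0.5) if cycle.halving == "binomial" \
            else x[i] // 2
    state.volume = cycle.v0
    state.t_birth = state.t
    interval = _truncated_normal(cycle.mean_division, cycle.sd_division, rng)
    state.division_interval = interval
    state.next_division = state.t + interval
    return state


def _truncated_normal(mean, sd, rng, eps=1.0):
    d = rng.normal(mean, sd)
    while d <= eps:
        d = rng.normal(mean, sd)
    return d


# ---------------------------------------------------------------------------
# Network compilation: dataclasses -> flat arrays for the kernel
# ---------------------------------------------------------------------------

_MAX_REACTANTS = 5


@dataclass(frozen=True)
class _CompiledNetwork:
    species: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    react_sp: np.ndarray
    react_st: np.ndarray
    react_n: np.ndarray
    inst_update: np.ndarray
    compl_update: np.ndarray
    is_gamma: np.ndarray
    g_shape: np.ndarray
    g_rate: np.ndarray
    c0: np.ndarray
    vol_exp: np.ndarray
    halved: np.ndarray
    x0: np.ndarray


def compile_network(network: ReactionNetwork, v0: float) -> _CompiledNetwork:
    names = network.species_names
    idx = {n: i for i, n in enumerate(names)}
    S = len(names)
    R = network.n_reactions

    react_sp = np.zeros((R, _MAX_REACTANTS), dtype=np.int64)
    react_st = np.zeros((R, _MAX_REACTANTS), dtype=np.int64)
    react_n = np.zeros(R, dtype=np.int64)
    inst_update = np.zeros((R, S), dtype=np.int64)
    compl_update = np.zeros((R, S), dtype=np.int64)
    is_gamma = np.zeros(R, dtype=np.uint8)
    g_shape = np.zeros(R, dtype=np.float64)
    g_rate = np.zeros(R, dtype=np.float64)
    c0 = np.zeros(R, dtype=np.float64)
    vol_exp = np.zeros(R, dtype=np.int8)

    for r, rxn in enumerate(network.reactions):
        if len(rxn.reactants) > _MAX_REACTANTS:
            raise ValueError("too many distinct reactants")
        for j, (sp, st) in enumerate(rxn.reactants):
            if st > 2:
                raise ValueError("reactant stoichiometry > 2 not supported")
            react_sp[r, j] = idx[sp]
            react_st[r, j] = st
            inst_update[r, idx[sp]] -= st
        react_n[r] = len(rxn.reactants)
        const = network.constant(rxn.rate_ref)
        if rxn.kinetics == "gamma_elongation":
            is_gamma[r] = 1
            g_shape[r] = float(network.constant(rxn.shape_ref).value)
            g_rate[r] = const.value
            for sp, st in rxn.products:
                compl_update[r, idx[sp]] += st
        else:
            for sp, st in rxn.products:
                inst_update[r, idx[sp]] += st
            homodimer = any(st == 2 for _, st in rxn.reactants)
            order = 2 if const.unit_class == "per_molar_second" else 1
            c0[r] = stochastic_rate_constant(const.value, const.unit_class,
                                             order, v0, homodimer)
            vol_exp[r] = 1 if const.unit_class == "per_molar_second" else 0

    halved = np.array([s.halved_on_division for s in network.species],
                      dtype=np.uint8)
    x0 = np.array([s.initial_count for s in network.species], dtype=np.int64)
    return _CompiledNetwork(names, tuple(r.id for r in network.reactions),
                            react_sp, react_st, react_n, inst_update,
                            compl_update, is_gamma, g_shape, g_rate, c0,
                            vol_exp, halved, x0)


# ---------------------------------------------------------------------------
# The SSA kernel (numba-compiled)
# ---------------------------------------------------------------------------

_PEND_CAP = 2048
_INF = 1e300


def _ssa_kernel(react_sp, react_st, react_n, inst_update, compl_update,
                is_gamma, g_shape, g_rate, c0, vol_exp,
                x0, halved, grid, t_end,
                dose_t, dose_mode, dose_amt, tcex,
                division_on, growth_on, halving_floor,
                mean_div, sd_div, v0, seed):
    np.random.seed(seed)
    R = c0.shape[0]
    S = x0.shape[0]
    G = grid.shape[0]
    ND = dose_t.shape[0]

    x = x0.copy()
    counts_out = np.zeros((G, S), dtype=np.int64)
    pending_out = np.zeros((G, R), dtype=np.int64)
    fire = np.zeros(R, dtype=np.int64)
    compl = np.zeros(R, dtype=np.int64)

    pend_t = np.empty(_PEND_CAP, dtype=np.float64)
    pend_r = np.empty(_PEND_CAP, dtype=np.int64)
    pend_per_rxn = np.zeros(R, dtype=np.int64)
    pend_n = 0

    a = np.zeros(R, dtype=np.float64)

    t = 0.0
    tb = 0.0
    if division_on == 1:
        tdiv = np.random.normal(mean_div, sd_div)
        while tdiv <= 1.0:
            tdiv = np.random.normal(mean_div, sd_div)
    else:
        tdiv = mean_div
    next_div = tb + tdiv if division_on == 1 else _INF

    gi = 0
    di = 0
    clamp_on = 0
    clamp_val = 0
    status = 0

    # initial instant elongation triggers (none for default initial counts,
    # but user-supplied initial conditions may include elongation-ready forms)
    for r in range(R):
        if is_gamma[r] == 1:
            sp = react_sp[r, 0]
            while x[sp] > 0:
                x[sp] -= 1
                fire[r] += 1
                d = np.random.gamma(g_shape[r], 1.0 / g_rate[r])
                pend_t[pend_n] = t + d
                pend_r[pend_n] = r
                pend_n += 1
                pend_per_rxn[r] += 1

    while True:
        if growth_on == 1:
            V = v0 * 2.0 ** ((t - tb) / tdiv)
        else:
            V = v0
        vs = v0 / V

        a0 = 0.0
        for r in range(R):
            if is_gamma[r] == 1:
                a[r] = 0.0
                continue
            ar = c0[r]
            if vol_exp[r] == 1:
                ar *= vs
            for j in range(react_n[r]):
                n = x[react_sp[r, j]]
                st = react_st[r, j]
                if n < st:
                    ar = 0.0
                    break
                if st == 1:
                    ar *= n
                else:
                    ar *= n * (n - 1) / 2.0
            a[r] = ar
            a0 += ar

        if a0 > 0.0:
            t_ssa = t + np.random.exponential(1.0 / a0)
        else:
            t_ssa = _INF

        t_pend = _INF
        pi = -1
        for j in range(pend_n):
            if pend_t[j] < t_pend:
                t_pend = pend_t[j]
                pi = j

        t_dose = dose_t[di] if di < ND else _INF

        t_next = t_ssa
        if t_pend < t_next:
            t_next = t_pend
        if next_div < t_next:
            t_next = next_div
        if t_dose < t_next:
            t_next = t_dose

        if t_next >= t_end:
            while gi < G and grid[gi] <= t_end:
                for s in range(S):
                    counts_out[gi, s] = x[s]
                for r in range(R):
                    pending_out[gi, r] = pend_per_rxn[r]
                gi += 1
            break

        while gi < G and grid[gi] < t_next:
            for s in range(S):
                counts_out[gi, s] = x[s]
            for r in range(R):
                pending_out[gi, r] = pend_per_rxn[r]
            gi += 1

        t = t_next

        # tie-break priority: division > dose > completion > SSA reaction
        if next_div <= t:
            for s in range(S):
                if halved[s] == 1 and x[s] > 0:
                    if halving_floor == 1:
                        x[s] = x[s] // 2
                    else:
                        x[s] = np.random.binomial(x[s], 0.5)
            tb = t
            tdiv = np.random.normal(mean_div, sd_div)
            while tdiv <= 1.0:
                tdiv = np.random.normal(mean_div, sd_div)
            next_div = t + tdiv
        elif t_dose <= t:
            if dose_mode[di] == 0:
                x[tcex] += dose_amt[di]
            else:
                clamp_on = 1
                clamp_val = dose_amt[di]
            di += 1
        elif t_pend <= t:
            r = pend_r[pi]
            for s in range(S):
                x[s] += compl_update[r, s]
            compl[r] += 1
            pend_per_rxn[r] -= 1
            pend_n -= 1
            pend_t[pi] = pend_t[pend_n]
            pend_r[pi] = pend_r[pend_n]
        else:
            u = np.random.random() * a0
            acc = 0.0
            r = R - 1
            for rr in range(R):
                acc += a[rr]
                if u < acc:
                    r = rr
                    break
            for s in range(S):
                x[s] += inst_update[r, s]
            fire[r] += 1

        if clamp_on == 1:
            x[tcex] = clamp_val

        # instant initiation of any elongation-ready complexes
        for r in range(R):
            if is_gamma[r] == 1:
                sp = react_sp[r, 0]
                while x[sp] > 0:
                    if pend_n >= _PEND_CAP:
                        status = 3
                        break
                    x[sp] -= 1
                    fire[r] += 1
                    d = np.random.gamma(g_shape[r], 1.0 / g_rate[r])
                    pend_t[pend_n] = t + d
                    pend_r[pend_n] = r
                    pend_n += 1
                    pend_per_rxn[r] += 1
        if status != 0:
            break

        for s in range(S):
            if x[s] < 0:
                status = 2
                break
        if status != 0:
            break

    return counts_out, pending_out, fire, compl, status


_ssa_kernel_jit = _jit(_ssa_kernel)


# ---------------------------------------------------------------------------
# Public simulation drivers
# ---------------------------------------------------------------------------

def _dose_arrays(dose: DoseSchedule | None):
    if dose is None or not dose.events:
        return (np.zeros(0, dtype=np.float64), np.zeros(0, dtype=np.int64),
                np.zeros(0, dtype=np.int64))
    times = np.array([e[0] for e in dose.events], dtype=np.float64)
    modes = np.array([0 if e[1] == "pulse_add" else 1 for e in dose.events],
                     dtype=np.int64)
    amts = np.array([e[2] for e in dose.events], dtype=np.int64)
    return times, modes, amts


def default_grid(t_end: float, dt: float = 60.0) -> np.ndarray:
    return np.arange(0.0, t_end + dt * 0.5, dt)


def simulate_cell(network: ReactionNetwork | _CompiledNetwork,
                  t_end: float,
                  *,
                  grid: np.ndarray | None = None,
                  grid_dt: float = 60.0,
                  dose: DoseSchedule | None = None,
                  cycle: CellCycleParams | None = None,
                  init_counts: dict[str, int] | None = None,
                  seed: int = 0) -> Trajectory:
    """Simulate one cell and return its sampled :class:`Trajectory`.

    The trajectory is fully determined by ``(network, arguments, seed)``.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    cycle = cycle or CellCycleParams()
    compiled = network if isinstance(network, _CompiledNetwork) \
        else compile_network(network, cycle.v0)
    if grid is None:
        grid = default_grid(t_end, grid_dt)
    grid = np.asarray(grid, dtype=np.float64)
    if grid.size == 0 or grid[0] < 0 or grid[-1] > t_end:
        raise ValueError("grid must be non-empty and within [0, t_end]")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")

    x0 = compiled.x0.copy()
    if init_counts:
        for spn, n in init_counts.items():
            x0[compiled.species.index(spn)] = int(n)

    dose_t, dose_mode, dose_amt = _dose_arrays(dose)
    if "TcEx" in compiled.species:
        tcex = compiled.species.index("TcEx")
    elif dose_t.size:
        raise ValueError("dosing requires a TcEx species in the network")
    else:
        tcex = 0  # unused

    counts, pending, fire, compl, status = _ssa_kernel_jit(
        compiled.react_sp, compiled.react_st, compiled.react_n,
        compiled.inst_update, compiled.compl_update,
        compiled.is_gamma, compiled.g_shape, compiled.g_rate,
        compiled.c0, compiled.vol_exp,
        x0, compiled.halved, grid, float(t_end),
        dose_t, dose_mode, dose_amt, tcex,
        1 if cycle.enabled else 0,
        1 if cycle.volume_coupling == "exponential" else 0,
        1 if cycle.halving == "floor" else 0,
        cycle.mean_division, cycle.sd_division, cycle.v0, int(seed),
    )
    if status == 2:
        raise RuntimeError("internal error: negative count produced")
    if status == 3:
        raise RuntimeError("pending-elongation queue overflow")
    return Trajectory(grid, counts, compiled.species, compiled.reaction_ids,
                      pending, fire, compl, int(seed))


def cell_seed(master_seed: int, cell_index: int) -> int:
    """Per-cell kernel seed derived from (master seed, cell index)."""
    ss = np.random.SeedSequence((int(master_seed), int(cell_index)))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def simulate_ensemble(network: ReactionNetwork,
                      n_cells: int,
                      t_end: float,
                      *,
                      grid_dt: float = 60.0,
                      dose: DoseSchedule | None = None,
                      cycle: CellCycleParams | None = None,
                      init_counts: dict[str, int] | None = None,
                      master_seed: int = 0) -> list[Trajectory]:
    """Simulate ``n_cells`` independent cells on a shared grid.

    Each cell gets its own counter-derived seed, so the ensemble is
    reproducible and independent of execution order.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    cycle = cycle or CellCycleParams()
    compiled = compile_network(network, cycle.v0)
    grid = default_grid(t_end, grid_dt)
    return [
        simulate_cell(compiled, t_end, grid=grid, dose=dose, cycle=cycle,
                      init_counts=init_counts,
                      seed=cell_seed(master_seed, i))
        for i in range(n_cells)
    ]
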