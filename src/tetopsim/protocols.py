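"""Turnkey drivers for the five computational experiments on the tet operon.

Every protocol starts each cell from the unexpressed state (no TetR, TetR2 or
TetA; 300 ribosomes, 180 polymerases, the five DNA sites and 4e6 non-specific
sites) and, where tetracycline is involved, lets the population settle for
5 simulated hours before dosing:

* ``steady_state`` — no Tc, 10 h: the repressed baseline.
* ``tc_pulse`` — a single pulse of N external Tc molecules per cell at 5 h.
* ``tc_continuous`` — external Tc clamped at a level (default 500) from 5 h.
* ``knockout_PR1`` — wild type vs. the tetP_R1-less variant under a 400-Tc
  pulse, with a per-species discrepancy metric.
* ``sensitivity`` — dose-response grids over scaled Tc-repressor or
  repressor-operator affinities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import CellCycleParams, DoseSchedule, Trajectory, simulate_ensemble
from .model import ReactionNetwork, build_tet_network, knockout_promoter_PR1, \
    scale_affinity
from .stats import EnsembleSummary, max_of_mean, steady_window_mean, summarize

__all__ = [
    "ProtocolSpec",
    "ProtocolResult",
    "run_protocol",
    "run_steady_state",
    "run_tc_pulse",
    "run_tc_continuous",
    "run_knockout_comparison",
    "run_sensitivity",
    "PULSE_AMOUNTS",
    "SENSITIVITY_AMOUNTS",
    "SENSITIVITY_FACTORS",
]

HOUR = 3600.0
PULSE_AMOUNTS = (10, 20, 50, 100, 200, 400, 600, 800, 1000)
SENSITIVITY_AMOUNTS = (20, 50, 100, 200, 400, 600, 800, 1000)
SENSITIVITY_FACTORS = {
    "tc_tetr": (0.01, 0.1, 1.0, 10.0, 100.0),
    "tetr_operator": (0.01, 0.02, 0.1, 1.0),
}

PROTOCOL_NAMES = ("steady_state", "tc_pulse", "tc_continuous",
                  "knockout_PR1", "sensitivity")


@dataclass(frozen=True)
class ProtocolSpec:
    """A named in-silico experiment with its dosing and variant parameters."""

    name: str
    n_cells: int = 1000
    t_end: float = 10 * HOUR
    dose_amounts: tuple[int, ...] = ()
    dose_time: float = 5 * HOUR
    variant: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in PROTOCOL_NAMES:
            raise ValueError(f"unknown protocol {self.name!r}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.dose_amounts and self.dose_time >= self.t_end:
            raise ValueError("dose_time must precede t_end")


@dataclass
class ProtocolResult:
    summary: EnsembleSummary
    trajectories: list[Trajectory]
    scalars: dict


def run_protocol(network: ReactionNetwork, n_cells: int, t_end: float,
                 dose: DoseSchedule | None, seed: int,
                 *, grid_dt: float = 60.0,
                 cycle: CellCycleParams | None = None,
                 keep_trajectories: bool = True) -> ProtocolResult:
    trajs = simulate_ensemble(network, n_cells, t_end, grid_dt=grid_dt,
                              dose=dose, cycle=cycle, master_seed=seed)
    summary = summarize(trajs)
    return ProtocolResult(summary, trajs if keep_trajectories else [], {})


def _steady_scalars(result: ProtocolResult, window: tuple[float, float]):
    s = result.summary
    scalars = {}
    for sp in ("TetR", "TetR2", "TetA", "Tc"):
        t_pk, v_pk = max_of_mean(s, sp)
        scalars[f"max_of_mean:{sp}"] = v_pk
        scalars[f"argmax_of_mean:{sp}"] = t_pk
        scalars[f"steady_mean:{sp}"] = steady_window_mean(s, sp, window)
    return scalars


def run_steady_state(n_cells: int = 1000, t_end: float = 10 * HOUR,
                     seed: int = 0, *, network: ReactionNetwork | None = None,
                     grid_dt: float = 60.0,
                     cycle: CellCycleParams | None = None) -> ProtocolResult:
    """No-tetracycline baseline: a TetA burst while the cell is still
    repressor-free, then relaxation to tight repression."""
    network = network or build_tet_network()
    res = run_protocol(network, n_cells, t_end, None, seed,
                       grid_dt=grid_dt, cycle=cycle)
    res.scalars = _steady_scalars(res, (t_end / 2.0, t_end))
    return res


def run_tc_pulse(amounts=PULSE_AMOUNTS, pulse_time: float = 5 * HOUR,
                 n_cells: int = 1000, t_end: float = 15 * HOUR,
                 seed: int = 0, *, network: ReactionNetwork | None = None,
                 grid_dt: float = 60.0,
                 cycle: CellCycleParams | None = None
                 ) -> dict[int, ProtocolResult]:
    """One pulse of external Tc per cell after a 5 h unperturbed warm-up."""
    network = network or build_tet_network()
    out: dict[int, ProtocolResult] = {}
    for amount in amounts:
        dose = DoseSchedule.pulse(pulse_time, amount) if amount > 0 else None
        res = run_protocol(network, n_cells, t_end, dose, seed,
                           grid_dt=grid_dt, cycle=cycle)
        res.scalars = _steady_scalars(
            res, ((t_end + pulse_time) / 2.0, t_end))
        res.scalars["amount"] = amount
        out[amount] = res
    return out


def run_tc_continuous(level: int = 500, start: float = 5 * HOUR,
                      n_cells: int = 1000, t_end: float = 15 * HOUR,
                      seed: int = 0, *,
                      network: ReactionNetwork | None = None,
                      grid_dt: float = 60.0,
                      cycle: CellCycleParams | None = None) -> ProtocolResult:
    """External Tc clamped at ``level`` molecules per cell from ``start``."""
    if level < 0:
        raise ValueError("level must be >= 0")
    network = network or build_tet_network()
    dose = DoseSchedule.clamp(start, level) if level > 0 else None
    res = run_protocol(network, n_cells, t_end, dose, seed,
                       grid_dt=grid_dt, cycle=cycle)
    res.scalars = _steady_scalars(res, (t_end - 5 * HOUR, t_end))
    res.scalars["max_of_mean_first_hour:Tc"] = _window_peak(
        res.summary, "Tc", start, start + HOUR)
    return res


def _window_peak(summary: EnsembleSummary, species: str,
                 lo: float, hi: float) -> float:
    keep = (summary.grid >= lo) & (summary.grid <= hi)
    return float(summary.mean_series(species)[keep].max())


def run_knockout_comparison(pulse_amount: int = 400, n_cells: int = 1000,
                            seed: int = 0, *, t_end: float = 15 * HOUR,
                            pulse_time: float = 5 * HOUR,
                            grid_dt: float = 60.0,
                            cycle: CellCycleParams | None = None):
    """Wild type vs. the tetP_R1 knockout under the same 400-Tc pulse.

    Returns ``(wt_result, ko_result, discrepancy)`` where ``discrepancy``
    maps species to ``max_t |mean_wt - mean_ko| / peak`` with ``peak`` the
    larger of the two mean-curve maxima (species whose mean never exceeds
    one molecule are normalised by 1 to avoid inflating empty channels).
    """
    wt = build_tet_network()
    ko = knockout_promoter_PR1(wt)
    dose = DoseSchedule.pulse(pulse_time, pulse_amount) if pulse_amount else None
    res_wt = run_protocol(wt, n_cells, t_end, dose, seed,
                          grid_dt=grid_dt, cycle=cycle)
    res_ko = run_protocol(ko, n_cells, t_end, dose, seed,
                          grid_dt=grid_dt, cycle=cycle)
    discrepancy = {}
    for sp in ("Tc", "TetR", "TetR2", "TetA"):
        a = res_wt.summary.mean_series(sp)
        b = res_ko.summary.mean_series(sp)
        peak = max(a.max(), b.max(), 1.0)
        discrepancy[sp] = float(np.abs(a - b).max() / peak)
    res_wt.scalars = _steady_scalars(res_wt, ((t_end + pulse_time) / 2, t_end))
    res_ko.scalars = _steady_scalars(res_ko, ((t_end + pulse_time) / 2, t_end))
    return res_wt, res_ko, discrepancy


def run_sensitivity(group: str, factors=None, amounts=SENSITIVITY_AMOUNTS,
                    n_cells: int = 1000, seed: int = 0, *,
                    t_end: float = 15 * HOUR, pulse_time: float = 5 * HOUR,
                    basal_t_end: float = 10 * HOUR,
                    grid_dt: float = 60.0,
                    cycle: CellCycleParams | None = None,
                    include_basal: bool = True) -> pd.DataFrame:
    """Dose-response grid over affinity scale factors.

    For every (factor, administered amount) pair the maxima of the mean TetA
    and intracellular Tc curves are tabulated; with ``include_basal`` a no-Tc
    run per factor records the steady-state TetA/TetR/TetR2 means over the
    final half of ``basal_t_end``.  Returns a tidy DataFrame with columns
    (group, factor, amount, species, statistic, value); basal rows carry
    ``amount = -1``.
    """
    factors = tuple(factors) if factors is not None \
        else SENSITIVITY_FACTORS[group]
    wt = build_tet_network()
    rows = []
    for factor in factors:
        net = scale_affinity(wt, group, factor)
        if include_basal:
            basal = run_protocol(net, n_cells, basal_t_end, None, seed,
                                 grid_dt=grid_dt, cycle=cycle,
                                 keep_trajectories=False)
            for sp in ("TetA", "TetR", "TetR2"):
                rows.append((group, factor, -1, sp, "steady_mean",
                             steady_window_mean(basal.summary, sp,
                                                (basal_t_end / 2, basal_t_end))))
        for amount in amounts:
            dose = DoseSchedule.pulse(pulse_time, amount)
            res = run_protocol(net, n_cells, t_end, dose, seed,
                               grid_dt=grid_dt, cycle=cycle,
                               keep_trajectories=False)
            for sp in ("TetA", "Tc"):
                rows.append((group, factor, amount, sp, "max_of_mean",
                             max_of_mean(res.summary, sp)[1]))
    return pd.DataFrame(rows, columns=["group", "factor", "amount",
                                       "species", "statistic", "value"])
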