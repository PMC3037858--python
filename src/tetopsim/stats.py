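"""Ensemble aggregation and the scalar summaries reported for the tet operon.

Population behaviour is summarised by the pointwise mean/sd/min/max of the
per-cell trajectories, plus scalar reductions: the maximum of the
population-mean curve (``max_of_mean``), time-averages over a post-transient
window (``steady_window_mean``), the per-cell all-time extrema envelope, and
the translation yield (completed proteins per mRNA transcript).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import Trajectory

__all__ = [
    "EnsembleSummary",
    "summarize",
    "max_of_mean",
    "steady_window_mean",
    "per_cell_extrema",
    "proteins_per_transcript",
    "conservation_residuals",
]

# Table-1 numbering of the event counters entering the translation-yield
# ratio: elongation completions that produce an mRNA vs. a finished protein.
_GENE_COUNTERS = {
    "tetR": {"transcript": ("17", "21"), "protein": ("27",)},
    "tetA": {"transcript": ("31",), "protein": ("34",)},
}


@dataclass
class EnsembleSummary:
    grid: np.ndarray
    species: tuple[str, ...]
    mean: np.ndarray   # (G, S)
    sd: np.ndarray
    min: np.ndarray
    max: np.ndarray
    n_cells: int

    def _col(self, species: str) -> int:
        return self.species.index(species)

    def mean_series(self, species: str) -> np.ndarray:
        return self.mean[:, self._col(species)]

    def to_frame(self):
        import pandas as pd

        frames = []
        for stat, arr in (("mean", self.mean), ("sd", self.sd),
                          ("min", self.min), ("max", self.max)):
            df = pd.DataFrame(arr, columns=list(self.species))
            df.insert(0, "time_s", self.grid)
            df.insert(1, "statistic", stat)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def summarize(trajectories: list[Trajectory]) -> EnsembleSummary:
    """Pointwise mean/sd/min/max over cells (permutation invariant)."""
    if not trajectories:
        raise ValueError("no trajectories")
    grid = trajectories[0].grid
    for tr in trajectories[1:]:
        if tr.counts.shape != trajectories[0].counts.shape or \
                not np.array_equal(tr.grid, grid):
            raise ValueError("trajectories do not share a common grid")
    stack = np.stack([tr.counts for tr in trajectories])  # (N, G, S)
    return EnsembleSummary(
        grid=grid,
        species=trajectories[0].species,
        mean=stack.mean(axis=0),
        sd=stack.std(axis=0, ddof=0),
        min=stack.min(axis=0),
        max=stack.max(axis=0),
        n_cells=len(trajectories),
    )


def max_of_mean(summary: EnsembleSummary, species: str,
                t_max: float | None = None) -> tuple[float, float]:
    """(time, value) of the maximum of the population-mean curve.

    Ties resolve to the earliest grid time; ``t_max`` optionally restricts
    the search to ``grid <= t_max``.
    """
    curve = summary.mean_series(species)
    grid = summary.grid
    if t_max is not None:
        keep = grid <= t_max
        curve, grid = curve[keep], grid[keep]
    i = int(np.argmax(curve))  # argmax returns the first maximal index
    return float(grid[i]), float(curve[i])


def steady_window_mean(summary: EnsembleSummary, species: str,
                       window: tuple[float, float]) -> float:
    """Time-average of the population-mean curve over ``window`` (s)."""
    lo, hi = window
    keep = (summary.grid >= lo) & (summary.grid <= hi)
    if not np.any(keep):
        raise ValueError("window contains no grid points")
    return float(summary.mean_series(species)[keep].mean())


def per_cell_extrema(trajectories: list[Trajectory], species: str,
                     t_min: float = 0.0) -> tuple[float, float]:
    """Envelope of per-cell all-time maxima: (min, max) across the ensemble."""
    col = trajectories[0].species.index(species)
    maxima = [tr.counts[tr.grid >= t_min, col].max() for tr in trajectories]
    return float(np.min(maxima)), float(np.max(maxima))


def proteins_per_transcript(trajectories: list[Trajectory], gene: str) -> float:
    """Completed protein syntheses per mRNA produced, pooled over the ensemble.

    For *tetR* this is completions of the peptide-elongation reaction divided
    by completions of the two transcript-elongation reactions (both
    promoters); for *tetA*, the single-promoter analogues.
    """
    if gene not in _GENE_COUNTERS:
        raise KeyError(f"unknown gene {gene!r}")
    ids = trajectories[0].reaction_ids
    spec = _GENE_COUNTERS[gene]

    def total(rids):
        out = 0
        for rid in rids:
            if rid in ids:
                j = ids.index(rid)
                out += sum(int(tr.completion_counts[j]) for tr in trajectories)
        return out

    transcripts = total(spec["transcript"])
    proteins = total(spec["protein"])
    if transcripts == 0:
        raise ZeroDivisionError("no transcripts produced; ratio undefined")
    return proteins / transcripts


def conservation_residuals(trajectory: Trajectory, network) -> dict[str, int]:
    """Worst deviation of each conserved-moiety total along a trajectory.

    Totals count a moiety wherever it sits: free, inside a complex, or in
    flight inside a scheduled elongation (an elongating polymerase or
    ribosome is neither free nor in any species until its completion fires).
    Returns ``{moiety: max_t |total(t) - total(0)|}``; all zeros for a
    correct simulation.
    """
    names = trajectory.species
    rids = trajectory.reaction_ids
    out = {}
    for moiety, content in network.moieties.items():
        comp = np.array([content.get(n, 0) for n in names])
        totals = trajectory.counts @ comp
        for r in network.reactions:
            if r.kinetics != "gamma_elongation":
                continue
            inflight = sum(st * content.get(sp, 0) for sp, st in r.products)
            if inflight:
                totals = totals + inflight * \
                    trajectory.pending[:, rids.index(r.id)]
        out[moiety] = int(np.abs(totals - totals[0]).max())
    return out
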