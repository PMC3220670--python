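"""Measurements taken on the running simulation.

Every 900 steps during the recording window the observer takes a
snapshot: the wrap-corrected arithmetic group center, each agent's
distance to it, a circular centrality-peripherality index, the full
dyadic torus-distance matrix and its maximum (the group spread /
furthest-neighbor distance).  Directed encounters are counted on every
occurrence during the window, not only at snapshots.  Per-run results
are time-averaged over the scheduled snapshots into a RunSummary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .config import ModelConfig
from .geometry import torus_delta, torus_distance

__all__ = [
    "group_center",
    "distance_to_center",
    "centrality_index",
    "dyadic_matrix",
    "furthest_neighbor_distance",
    "record_encounter",
    "band_statistics",
    "RunSummary",
    "summarize_run",
]


@njit(cache=True)
def _axis_center(coords, L):
    """Wrap-corrected arithmetic mean of one coordinate axis.

    The coordinates are treated circularly: the largest empty gap in
    their sorted circular ordering is taken as the place where the
    group does *not* sit, coordinates below the gap are shifted up by
    L (the axis-wise border correction), and the plain mean of the
    shifted values is wrapped back.  For a group that does not straddle
    the border this is exactly the naive mean.
    """
    n = coords.shape[0]
    if n == 1:
        return coords[0] % L
    s = np.sort(coords)
    best_gap = s[0] + L - s[n - 1]  # wrap-around gap
    cut = -1.0                       # -1: no shift needed
    for k in range(n - 1):
        g = s[k + 1] - s[k]
        if g > best_gap:
            best_gap = g
            cut = s[k]
    total = 0.0
    for k in range(n):
        c = coords[k]
        if cut >= 0.0 and c <= cut:
            c += L
        total += c
    return (total / n) % L


@njit(cache=True)
def group_center(pos, L):
    """Wrap-corrected arithmetic center of all agents (x, y)."""
    return _axis_center(pos[:, 0], L), _axis_center(pos[:, 1], L)


@njit(cache=True)
def distance_to_center(x, y, cx, cy, L):
    """Torus distance from an agent to the group center (small = central)."""
    return torus_distance(x, y, cx, cy, L)


@njit(cache=True)
def centrality_index(pos, i, L):
    """Mean resultant length of the bearings from agent i to all others.

    0 means the others surround ego uniformly (a central position),
    1 means they all lie in one direction (a peripheral position).
    Coincident others contribute a null vector.
    """
    n = pos.shape[0]
    sx = 0.0
    sy = 0.0
    m = 0
    for j in range(n):
        if j == i:
            continue
        dx = torus_delta(pos[i, 0], pos[j, 0], L)
        dy = torus_delta(pos[i, 1], pos[j, 1], L)
        d = np.hypot(dx, dy)
        if d > 0.0:
            sx += dx / d
            sy += dy / d
        m += 1
    if m == 0:
        return 0.0
    return np.hypot(sx, sy) / m


@njit(cache=True)
def dyadic_matrix(pos, L):
    """Symmetric N x N matrix of pairwise torus distances."""
    n = pos.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = torus_distance(pos[i, 0], pos[i, 1], pos[j, 0], pos[j, 1], L)
            out[i, j] = d
            out[j, i] = d
    return out


@njit(cache=True)
def furthest_neighbor_distance(pos, L):
    """Group spread: the largest pairwise torus distance."""
    n = pos.shape[0]
    best = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d = torus_distance(pos[i, 0], pos[i, 1], pos[j, 0], pos[j, 1], L)
            if d > best:
                best = d
    return best


@njit(cache=True)
def record_snapshot(pos, L, idx, dist_center, centrality, spread,
                    dyadic_sum):
    """Fill row `idx` of the snapshot accumulators from current state."""
    n = pos.shape[0]
    cx, cy = group_center(pos, L)
    best = 0.0
    for i in range(n):
        dist_center[idx, i] = distance_to_center(pos[i, 0], pos[i, 1],
                                                 cx, cy, L)
        centrality[idx, i] = centrality_index(pos, i, L)
        for j in range(i + 1, n):
            d = torus_distance(pos[i, 0], pos[i, 1], pos[j, 0], pos[j, 1], L)
            dyadic_sum[i, j] += d
            dyadic_sum[j, i] += d
            if d > best:
                best = d
    spread[idx] = best


def record_encounter(matrix, initiator, target):
    """Score one directed encounter initiator -> target."""
    if initiator == target:
        raise ValueError("an agent cannot encounter itself")
    matrix[initiator, target] += 1
    return matrix


def band_statistics(encounter_matrix, dominance, band_width):
    """Fraction of encounters inside / outside a dominance-distance band.

    An encounter i -> j is "in band" when |D_i - D_j| <= band_width
    (within numerical tolerance).  Returns (in_fraction, out_fraction);
    both are NaN for an empty matrix.
    """
    enc = np.asarray(encounter_matrix, dtype=float)
    dom = np.asarray(dominance, dtype=float)
    total = enc.sum()
    if total == 0:
        return np.nan, np.nan
    gap = np.abs(dom[:, None] - dom[None, :])
    inside = enc[gap <= band_width + 1e-12].sum()
    return inside / total, 1.0 - inside / total


@dataclass(frozen=True)
class RunSummary:
    """Time-averaged observer output of one replicate."""

    config: ModelConfig
    dom: np.ndarray                 # (N,) dominance strengths, rank order
    snapshot_times: np.ndarray      # (S,) scheduled snapshot clocks
    dist_center: np.ndarray         # (S, N) distance to group center
    centrality: np.ndarray          # (S, N) circular centrality index
    spread: np.ndarray              # (S,) furthest-neighbor distance
    mean_dyadic: np.ndarray         # (N, N) time-averaged dyadic distances
    encounters: np.ndarray          # (N, N) directed encounter counts
    activations: np.ndarray         # (N,) activations over the whole run
    action_counts: np.ndarray       # (N, 5) per-agent counts by action kind
    fights: np.ndarray              # (N,) fights participated in
    fight_wins: np.ndarray          # (N,) fights won

    @property
    def seed(self) -> int:
        return self.config.seed

    @property
    def mean_spread(self) -> float:
        """Run-level group spread (time average over snapshots)."""
        return float(self.spread.mean())

    @property
    def mean_dist_center(self) -> np.ndarray:
        return self.dist_center.mean(axis=0)

    @property
    def mean_centrality(self) -> np.ndarray:
        return self.centrality.mean(axis=0)

    def agent_frame(self) -> pd.DataFrame:
        """One row per agent: rank, dominance, averaged observers."""
        n = self.dom.shape[0]
        return pd.DataFrame({
            "agent": np.arange(1, n + 1),
            "dom": self.dom,
            "mean_dist_center": self.mean_dist_center,
            "mean_centrality": self.mean_centrality,
            "encounters_initiated": self.encounters.sum(axis=1),
            "encounters_received": self.encounters.sum(axis=0),
            "activations": self.activations,
        })

    def scalars(self) -> dict:
        return {
            "seed": int(self.seed),
            "variant": self.config.variant,
            "mean_spread": self.mean_spread,
            "spread_sd_over_time": float(self.spread.std(ddof=1))
            if self.spread.size > 1 else 0.0,
            "total_encounters": int(self.encounters.sum()),
            "n_snapshots": int(self.spread.size),
        }

    def save(self, outdir, prefix="") -> None:
        """Write summary.csv / dyadic.csv / encounters.csv / scalars.json."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        ids = [str(i) for i in range(1, self.dom.shape[0] + 1)]
        self.agent_frame().to_csv(out / f"{prefix}summary.csv", index=False)
        pd.DataFrame(self.mean_dyadic, index=ids, columns=ids).to_csv(
            out / f"{prefix}dyadic.csv")
        pd.DataFrame(self.encounters, index=ids, columns=ids).to_csv(
            out / f"{prefix}encounters.csv")
        (out / f"{prefix}scalars.json").write_text(
            json.dumps(self.scalars(), indent=2))


def summarize_run(config, dom, snapshot_times, dist_center, centrality,
                  spread, dyadic_sum, encounters, activations,
                  action_counts, fights, fight_wins) -> RunSummary:
    """Assemble raw kernel output into a RunSummary (time averages)."""
    n_snap = spread.shape[0]
    expected = config.n_snapshots
    if n_snap != expected:
        raise ValueError(
            f"incomplete run: {n_snap} snapshots, expected {expected}")
    return RunSummary(
        config=config,
        dom=dom,
        snapshot_times=snapshot_times,
        dist_center=dist_center,
        centrality=centrality,
        spread=spread,
        mean_dyadic=dyadic_sum / n_snap,
        encounters=encounters,
        activations=activations,
        action_counts=action_counts,
        fights=fights,
        fight_wins=fight_wins,
    )
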