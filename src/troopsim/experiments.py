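"""Replicate orchestration, parameter sweeps and cross-run statistics.

A sweep runs a list of parameter settings, each with a fixed number of
independent replicates; replicate seeds are base_seed + replicate index
so any single run can be reproduced in isolation.  Cross-run analyses
cover the headline observers: group spread (mean and SD across
replicates), the dominance-centrality gradient, and the rank-band
structure of the directed encounter matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import ModelConfig
from .observers import RunSummary
from .world import run

__all__ = [
    "replicate_seeds",
    "run_replicates",
    "SweepSpec",
    "SweepResult",
    "run_sweep",
    "centrality_gradient",
    "subgroup_bands",
    "cross_band_fraction",
    "uniform_mixing_cross_fraction",
    "pooled_encounters",
]


def replicate_seeds(base_seed, n):
    """Deterministic replicate seeds: base, base+1, ..., base+n-1."""
    seeds = base_seed + np.arange(n)
    if seeds[-1] >= 2**31:
        raise ValueError("replicate seeds exceed 2**31")
    return seeds


def run_replicates(config: ModelConfig, replicates: int,
                   base_seed: int | None = None) -> list[RunSummary]:
    """Run independent replicates of one setting (seeds base+index)."""
    base = config.seed if base_seed is None else base_seed
    return [run(config.replace(seed=int(s)))
            for s in replicate_seeds(base, replicates)]


def _setting_label(setting: dict) -> str:
    return ",".join(f"{k}={setting[k]}" for k in sorted(setting)) or "default"


@dataclass(frozen=True)
class SweepSpec:
    """One sweep: a variant, parameter settings, replicate count, seed."""

    variant: str
    settings: tuple = (dict(),)     # iterable of override dicts
    replicates: int = 50
    base_seed: int = 0
    base_config: ModelConfig | None = None

    def configs(self):
        base = self.base_config or ModelConfig()
        base = base.replace(variant=self.variant, seed=self.base_seed)
        return [(dict(s), base.replace(**s)) for s in self.settings]


@dataclass
class SweepResult:
    """Per-setting replicate summaries plus tabulated statistics."""

    spec: SweepSpec
    runs: dict = field(default_factory=dict)  # label -> list[RunSummary]
    settings: dict = field(default_factory=dict)  # label -> override dict

    def table(self) -> pd.DataFrame:
        """One row per setting: spread mean/SD, centrality gradient."""
        rows = []
        for label, summaries in self.runs.items():
            spreads = np.array([s.mean_spread for s in summaries])
            slope, rho, pval = centrality_gradient(summaries)
            row = {"setting": label,
                   "replicates": len(summaries),
                   "spread_mean": spreads.mean(),
                   "spread_sd": spreads.std(ddof=1) if spreads.size > 1
                   else 0.0,
                   "centrality_slope": slope,
                   "centrality_spearman": rho,
                   "centrality_spearman_p": pval}
            row.update(self.settings[label])
            rows.append(row)
        return pd.DataFrame(rows)

    def agent_table(self) -> pd.DataFrame:
        """Per-setting, per-agent mean distance-to-center across reps."""
        rows = []
        for label, summaries in self.runs.items():
            dom = summaries[0].dom
            dc = np.mean([s.mean_dist_center for s in summaries], axis=0)
            for i in range(dom.shape[0]):
                rows.append({"setting": label, "agent": i + 1,
                             "dom": dom[i], "mean_dist_center": dc[i]})
        return pd.DataFrame(rows)

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.table().to_csv(out / "summary.csv", index=False)
        self.agent_table().to_csv(out / "agents.csv", index=False)
        manifest = {
            "variant": self.spec.variant,
            "replicates": self.spec.replicates,
            "base_seed": self.spec.base_seed,
            "settings": {label: s for label, s in self.settings.items()},
            "seeds": {label: [int(r.seed) for r in runs]
                      for label, runs in self.runs.items()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for label, summaries in self.runs.items():
            safe = label.replace("=", "-").replace(",", "_")
            for k, summary in enumerate(summaries):
                summary.save(out, prefix=f"{safe}_rep{k}_")


def run_sweep(spec: SweepSpec, progress: bool = False) -> SweepResult:
    """Execute every setting x replicate of a sweep."""
    result = SweepResult(spec=spec)
    for setting, config in spec.configs():
        label = _setting_label(setting)
        if progress:
            print(f"[troopsim] setting {label}: "
                  f"{spec.replicates} replicates")
        try:
            result.runs[label] = run_replicates(config, spec.replicates)
        except Exception as exc:  # surface which run failed
            raise RuntimeError(
                f"sweep failed at setting {label} "
                f"(base seed {config.seed}): {exc}") from exc
        result.settings[label] = setting
    return result


def centrality_gradient(summaries) -> tuple[float, float, float]:
    """Dominance-centrality relation pooled across replicates.

    Least-squares slope and Spearman correlation of per-agent
    run-averaged distance-to-center against dominance strength.  A
    negative slope/correlation means dominants sit nearer the group
    center.  Returns (slope, rho, p_value).
    """
    dom = np.concatenate([s.dom for s in summaries])
    dist = np.concatenate([s.mean_dist_center for s in summaries])
    slope = np.polyfit(dom, dist, 1)[0]
    rho, pval = stats.spearmanr(dom, dist)
    return float(slope), float(rho), float(pval)


def subgroup_bands(dominance, band_width, max_dom=1.0):
    """Rank bands of width band_width anchored at the top of the hierarchy.

    Band 0 is (max_dom - w, max_dom] (the alpha band), band 1 the next
    interval down, and so on.
    """
    dom = np.asarray(dominance, dtype=float)
    b = np.floor((max_dom - dom) / band_width + 1e-9).astype(int)
    return np.clip(b, 0, int(np.ceil(max_dom / band_width)) - 1)


def cross_band_fraction(encounter_matrix, dominance, band_width,
                        max_dom=1.0) -> float:
    """Fraction of encounters crossing rank-band boundaries."""
    enc = np.asarray(encounter_matrix, dtype=float)
    bands = subgroup_bands(dominance, band_width, max_dom)
    cross = bands[:, None] != bands[None, :]
    total = enc.sum()
    if total == 0:
        return np.nan
    return float(enc[cross].sum() / total)


def uniform_mixing_cross_fraction(dominance, band_width,
                                  max_dom=1.0) -> float:
    """Expected cross-band fraction if partners were chosen uniformly."""
    bands = subgroup_bands(dominance, band_width, max_dom)
    n = bands.shape[0]
    same = sum(int((bands == b).sum()) * (int((bands == b).sum()) - 1)
               for b in np.unique(bands))
    return 1.0 - same / (n * (n - 1))


def pooled_encounters(summaries) -> np.ndarray:
    """Sum the directed encounter matrices of several replicates."""
    return np.sum([s.encounters for s in summaries], axis=0)
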