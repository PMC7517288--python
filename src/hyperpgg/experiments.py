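"""Reproducible experiment driver: configs, sweep orchestration, summaries.

An :class:`ExperimentConfig` bundles everything one synergy-sweep campaign
needs (base-network model, promotion fractions, game parameters, grid,
replicate counts, master seed) and can be loaded from YAML/JSON. A ``scale``
factor in (0, 1] uniformly shrinks the replicate counts for desk-scale runs
without touching the grid, so reduced and full campaigns stay comparable.

Outputs are a tidy CSV (one row per (p, r) grid point) and a JSON provenance
record (config hash, per-hypergraph seeds, library versions), deterministic
for a fixed master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .dynamics import (
    SweepResult,
    SurvivalOnset,
    estimate_alpha_surv,
    mc_experiment,
)
from .generators import GeneratorConfig, PromotionConfig

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "summarize_r_endpoints",
]

logger = logging.getLogger("hyperpgg")


@dataclass(frozen=True)
class ExperimentConfig:
    """Full description of a sweep campaign (validated before any compute)."""

    model: str = "hk"
    n: int = 500
    m: int = 3
    pt: float = 1.0
    mean_degree: float = 6.0
    require_connected: bool = False
    p_list: Tuple[float, ...] = (0.0, 1.0)
    beta: float = 1.0
    b: float = 1.0
    c0: float = 0.5
    r_start: float = 0.5
    r_stop: float = 1.0
    r_step: float = 0.01
    runs_per_point: int = 100
    n_hypergraphs: int = 10
    tmax: int = 20_000
    seed: int = 0
    scale: float = 1.0
    stop_at_onset: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.scale <= 1.0):
            raise ValueError("scale must lie in (0, 1]")
        if self.r_step <= 0 or self.r_stop < self.r_start:
            raise ValueError("invalid r grid")
        if not all(0.0 <= p <= 1.0 for p in self.p_list):
            raise ValueError("p values must lie in [0, 1]")
        if not (0.0 <= self.c0 <= 1.0):
            raise ValueError("c0 must lie in [0, 1]")
        # early validation of the generator settings
        GeneratorConfig(
            model=self.model,
            n=self.n,
            m=self.m,
            pt=self.pt,
            mean_degree=self.mean_degree,
        )

    @property
    def r_grid(self) -> List[float]:
        n_pts = int(round((self.r_stop - self.r_start) / self.r_step)) + 1
        return [round(self.r_start + i * self.r_step, 10) for i in range(n_pts)]

    @property
    def scaled_runs(self) -> int:
        return max(1, round(self.scale * self.runs_per_point))

    @property
    def scaled_hypergraphs(self) -> int:
        return max(1, round(self.scale * self.n_hypergraphs))

    @staticmethod
    def from_file(path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["p_list"] = tuple(data.get("p_list", (0.0, 1.0)))
        return ExperimentConfig(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_experiment(
    cfg: ExperimentConfig,
    out_csv: Optional[Path] = None,
    out_provenance: Optional[Path] = None,
) -> Dict[float, SweepResult]:
    """Run one sweep per promotion fraction p; optionally write CSV + JSON.

    The per-run RNG streams depend only on (master seed, p index, replicate,
    grid index, run index), so results are independent of execution order.
    """
    results: Dict[float, SweepResult] = {}
    frames = []
    for p_idx, p in enumerate(cfg.p_list):
        logger.info(
            "sweep p=%.2f model=%s beta=%g (%d hypergraphs x %d runs)",
            p, cfg.model, cfg.beta, cfg.scaled_hypergraphs, cfg.scaled_runs,
        )
        sweep = mc_experiment(
            gen_cfg=GeneratorConfig(
                model=cfg.model,
                n=cfg.n,
                m=cfg.m,
                pt=cfg.pt,
                mean_degree=cfg.mean_degree,
                require_connected=cfg.require_connected,
            ),
            promo_cfg=PromotionConfig(p=p),
            b=cfg.b,
            beta=cfg.beta,
            r_grid=cfg.r_grid,
            runs_per_point=cfg.scaled_runs,
            n_hypergraphs=cfg.scaled_hypergraphs,
            c0=cfg.c0,
            tmax=cfg.tmax,
            seed=int(
                np.random.SeedSequence([cfg.seed, p_idx]).generate_state(1)[0]
                % (2**31)
            ),
            stop_when_cinf_above=(
                1.0 / (2 * cfg.n) if cfg.stop_at_onset else None
            ),
        )
        results[p] = sweep
        frame = sweep.table.copy()
        frame.insert(0, "p", p)
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    if out_csv is not None:
        Path(out_csv).parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_csv, index=False)
    if out_provenance is not None:
        prov = {
            "config": asdict(cfg),
            "config_hash": cfg.config_hash(),
            "hypergraph_seeds": {
                str(p): list(res.hypergraph_seeds) for p, res in results.items()
            },
            "versions": _library_versions(),
        }
        Path(out_provenance).parent.mkdir(parents=True, exist_ok=True)
        with open(out_provenance, "w") as fh:
            json.dump(prov, fh, indent=2, sort_keys=True)
    return results


def _library_versions() -> Dict[str, str]:
    import networkx
    import scipy

    import hyperpgg

    return {
        "hyperpgg": hyperpgg.__version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "networkx": networkx.__version__,
        "pandas": pd.__version__,
    }


def summarize_r_endpoints(
    results: Dict[float, SweepResult],
    n_vertices: int,
    epsilon: Optional[float] = None,
) -> pd.DataFrame:
    """Survival-onset r(p) for each promotion fraction in a campaign.

    Applies the onset estimator (smallest grid r with mean asymptotic
    density above epsilon, default half a player 1/(2N)) to every sweep;
    rows with no onset inside the grid are flagged ``found = False``.
    """
    rows = []
    for p in sorted(results):
        onset: SurvivalOnset = estimate_alpha_surv(
            results[p], epsilon=epsilon, n_vertices=n_vertices
        )
        rows.append(
            {
                "p": p,
                "found": onset.found,
                "r": onset.r,
                "alpha_surv": onset.alpha,
                "alpha_cr": results[p].alpha_cr,
            }
        )
    return pd.DataFrame(rows)
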