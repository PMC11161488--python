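"""Shared demo configuration for the numbered analysis scripts.

A three-tag cohort over the default 40x40-cell shelf domain for 120 days
from June, with one cooling-water plume source on the warm, shallow
south-eastern coast. Every script regenerates its inputs
deterministically from this config, so they can be run in any order.
"""

from __future__ import annotations

import sys
from datetime import date
from pathlib import Path

from basstrack.geolocate import HmmConfig
from basstrack.pipeline import PipelineConfig
from basstrack.synthetic import SimConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "demo"

SEED = 1

PLUME = (49.6, 4.4, 8.0, 10.0, date(2015, 7, 1), date(2015, 8, 15))


def demo_config(seed: int = SEED) -> PipelineConfig:
    sim = SimConfig(seed=seed, n_days=120, plume_sources=(PLUME,))
    hmm = HmmConfig(sigma_temp=0.2)
    return PipelineConfig(sim=sim, hmm=hmm, n_tags=3)


def acoustic_config(seed: int = SEED) -> PipelineConfig:
    """A coastal-resident acoustic cohort (low diffusion, released at
    receiver-guarded sites) for the residency and network analyses."""
    sim = SimConfig(seed=seed + 100, n_days=120, d_low=1.0, d_high=6.0)
    return PipelineConfig(
        sim=sim, n_tags=8, metrics={"group_by": "station"}
    )


def announce(title: str) -> None:
    print(f"== {title} ==", file=sys.stderr)
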