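"""Shared study configuration for the numbered analysis scripts.

The study dataset is synthetic and fully determined by a seed, so scripts
regenerate it on demand (about a second) instead of passing the ~100 MB raw
spectra table between steps.  Only result tables are written to results/.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from eggcolor import GeneratorConfig, generate_dataset

RESULTS = Path(__file__).resolve().parent.parent / "results"

#: Study conditions: 10 families x 5 species x 3 clutches x 3 eggs x 6
#: replicate spectra, lambda = 0.7, variance shares
#: (family, species, clutch, egg, replicate) = (25, 25, 12.5, 12.5, 25)%.
STUDY = GeneratorConfig()


def parse_seed(description: str) -> int:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=7)
    return ap.parse_args().seed


def study_dataset(seed: int):
    ds = generate_dataset(GeneratorConfig(**{**STUDY.__dict__, "seed": seed}))
    grid = ds.grid_spectra()
    meta = pd.DataFrame(
        {
            "family": [s.meta.family for s in grid],
            "species": [s.meta.species for s in grid],
            "clutch_id": [s.meta.clutch_id for s in grid],
            "egg_id": [s.meta.egg_id for s in grid],
            "replicate_idx": [s.meta.replicate_idx for s in grid],
        }
    )
    return ds, grid, meta


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
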