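#!/usr/bin/env python
"""Quantify pool-amplitude recovery of the fitting chain across noise levels.

For each noise SD, one 20x10 phantom (200 jittered voxels) is pushed
through the full chain (MLSVD denoising, B0 correction, sequential 4-step
fit) and, noise-free only, through the simultaneous five-pool fit. Per-pool
median relative errors go to results/recovery.csv.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from cestq.core import normalize_to_zspectrum
from cestq.lorentzian import POOL_NAMES, fit_voxelwise_pipeline
from cestq.phantom import PhantomConfig, generate_phantom
from cestq.pipeline import process_subject

OUT = Path(__file__).resolve().parent.parent / "results"
NOISE_LEVELS = (0.0, 0.005, 0.01, 0.02)


def median_rel_errors(maps: dict, truth: dict) -> dict:
    out = {}
    for pool in POOL_NAMES:
        rel = np.abs(maps[pool] - truth[pool]) / truth[pool]
        out[pool] = float(np.nanmedian(rel))
    return out


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sd in NOISE_LEVELS:
            ph = generate_phantom(PhantomConfig(grid_shape=(20, 10),
                                                noise_sd=sd, seed=101))
            _, maps = process_subject(ph, denoise=True)
            errs = median_rel_errors(maps, ph.truth["amplitude"])
            rows.append({"noise_sd": sd, "method": "sequential", **errs})
        ph0 = generate_phantom(PhantomConfig(grid_shape=(20, 10),
                                             noise_sd=0.0, seed=101))
        z = normalize_to_zspectrum(ph0.stack, None, ph0.schedule)
        res = fit_voxelwise_pipeline(z, method="five_pool")
        errs = median_rel_errors(res.maps, ph0.truth["amplitude"])
        rows.append({"noise_sd": 0.0, "method": "five_pool", **errs})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "recovery.csv", index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))


if __name__ == "__main__":
    main()
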