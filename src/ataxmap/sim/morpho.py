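"""Paranodal-length simulation.

Lengths are strictly positive and right-skewed, so each group is drawn
from a log-normal parameterized by moment matching to the target mean
and SD:

    sigma^2 = ln(1 + sd^2 / mean^2),  mu = ln(mean) - sigma^2 / 2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import GroupSpec


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given arithmetic mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


def simulate_paranodal_lengths(
    group_specs: list[GroupSpec], seed: int
) -> pd.DataFrame:
    """Draw per-section lengths (um) for each group; all lengths > 0."""
    rng = np.random.default_rng(seed)
    frames = []
    for spec in group_specs:
        mu, sigma = lognormal_params(spec.mean, spec.sd)
        lengths = rng.lognormal(mean=mu, sigma=sigma, size=spec.n)
        frames.append(
            pd.DataFrame(
                {
                    "length_um": lengths,
                    "group": spec.name,
                    "section": [f"{spec.name}_{i:04d}" for i in range(spec.n)],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
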