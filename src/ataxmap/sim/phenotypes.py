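"""Phenotype simulation under the single-locus animal model.

y = mu + effect(genotype) + u + e with u ~ N(0, A*sigma_a2) drawn
through a symmetric square root of A, and independent residuals. The
emitted phenotypes are pre-corrected (no herd/year/season structure); an
optional additive nuisance layer exists for stress testing and defaults
off.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..association import AEigen
from ..errors import DimensionError
from ..pedigree import Pedigree
from .config import SimConfig
from .genedrop import SimTruth


def simulate_phenotypes(
    pedigree: Pedigree,
    a: np.ndarray | None,
    truth: SimTruth,
    config: SimConfig,
    *,
    animal_order: list[str] | None = None,
    a_eig: AEigen | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one trait for every animal with a known genotype class.

    ``a`` (or a precomputed ``a_eig``) must be ordered like
    ``animal_order`` (default: pedigree topological order). Variance
    components derive from ``config.trait_sd`` and ``config.heritability``;
    genotype effects are ``config.effect_ag``/``config.effect_aa`` relative
    to GG. Deterministic given seed. The drawn components are recorded in
    ``truth``.
    """
    rng = rng or np.random.default_rng(config.seed)
    order = animal_order or pedigree.topological_order()
    n = len(order)
    if a_eig is None:
        if a is None:
            raise DimensionError("provide a relationship matrix or its eigendecomposition")
        a = np.asarray(a, dtype=float)
        if a.shape != (n, n):
            raise DimensionError(
                f"relationship matrix shape {a.shape} not conformable with "
                f"{n} pedigree animals"
            )
        a_eig = AEigen.from_matrix(a)
    if a_eig.n != n:
        raise DimensionError("eigendecomposition order does not match pedigree")

    var_p = config.trait_sd**2
    sigma_a2 = config.heritability * var_p
    sigma_e2 = (1.0 - config.heritability) * var_p

    effect = {"GG": 0.0, "AG": config.effect_ag, "AA": config.effect_aa}
    classes = [truth.carrier_status.get(animal, "GG") for animal in order]

    u = a_eig.sqrt_transform(rng.standard_normal(n)) * np.sqrt(sigma_a2)
    e = rng.standard_normal(n) * np.sqrt(sigma_e2)
    y = config.trait_mean + np.array([effect[c] for c in classes]) + u + e

    if config.nuisance_effects and config.nuisance_sd > 0:
        groups = rng.integers(config.n_nuisance_groups, size=n)
        group_effects = rng.standard_normal(config.n_nuisance_groups) * config.nuisance_sd
        y = y + group_effects[groups]

    truth.true_sigma_a2 = float(sigma_a2)
    truth.true_sigma_e2 = float(sigma_e2)
    truth.true_contrasts = {"AG-GG": config.effect_ag, "AA-GG": config.effect_aa}

    return pd.DataFrame(
        {
            "animal_id": order,
            "genotype": classes,
            "trait": "simulated_trait",
            "value": y,
        }
    )
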