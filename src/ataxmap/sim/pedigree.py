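"""Multi-generation linebred pedigree simulation.

One designated founder is given elevated mating weight, as is any later
animal in proportion to its expected genetic contribution from that
founder, producing the predominant-founder structure typical of a
linebred livestock population.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigurationError
from ..pedigree import Pedigree, PedigreeEntry
from .config import SimConfig


def founder_contribution(pedigree: Pedigree, founder_id: str) -> dict[str, float]:
    """Expected genetic contribution of one founder to every animal.

    c(founder) = 1; c(i) = (c(sire) + c(dam)) / 2 with unknown parents
    contributing 0.
    """
    contrib: dict[str, float] = {}
    for animal in pedigree.topological_order():
        if animal == founder_id:
            contrib[animal] = 1.0
            continue
        sire, dam = pedigree.parents(animal)
        c = 0.0
        if sire is not None:
            c += 0.5 * contrib[sire]
        if dam is not None:
            c += 0.5 * contrib[dam]
        contrib[animal] = c
    return contrib


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Generate an acyclic multi-generation pedigree; deterministic given seed."""
    if config.n_founders < 2:
        raise ConfigurationError("n_founders: must be >= 2")
    if config.n_generations < 1:
        raise ConfigurationError("n_generations: must be >= 1")
    rng = np.random.default_rng(config.seed)

    entries: list[PedigreeEntry] = []
    males: list[str] = []
    females: list[str] = []
    for i in range(config.n_founders):
        sex = "M" if i % 2 == 0 else "F"
        aid = f"G0_{i:04d}"
        entries.append(PedigreeEntry(aid, None, None, sex, 0))
        (males if sex == "M" else females).append(aid)
    if not males or not females:
        raise ConfigurationError("n_founders: need at least one founder of each sex")

    focus = config.linebreeding_founder or males[0]
    if focus not in {e.animal_id for e in entries}:
        raise ConfigurationError(f"linebreeding_founder: unknown id {focus!r}")

    contrib = {e.animal_id: (1.0 if e.animal_id == focus else 0.0) for e in entries}

    for g, size in enumerate(config.sizes(), start=1):
        sire_pool = list(males)
        dam_pool = list(females)
        sw = np.array([1.0 + config.linebreeding_weight * contrib[a] for a in sire_pool])
        dw = np.array([1.0 + config.linebreeding_weight * contrib[a] for a in dam_pool])
        sw /= sw.sum()
        dw /= dw.sum()
        new_males: list[str] = []
        new_females: list[str] = []
        for k in range(size):
            sire = sire_pool[int(rng.choice(len(sire_pool), p=sw))]
            dam = dam_pool[int(rng.choice(len(dam_pool), p=dw))]
            sex = "M" if rng.random() < 0.5 else "F"
            aid = f"G{g}_{k:04d}"
            entries.append(PedigreeEntry(aid, sire, dam, sex, g))
            contrib[aid] = 0.5 * contrib[sire] + 0.5 * contrib[dam]
            (new_males if sex == "M" else new_females).append(aid)
        # next generation mates among the current offspring when possible
        if new_males:
            males = new_males
        if new_females:
            females = new_females
    return Pedigree(entries)


def case_cohort_pedigree(config: SimConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Pedigree tailored to yield a large affected cohort by linebreeding.

    The focal founder sires every first-generation animal; the final
    generation comes from matings among his half-sib descendants, so
    each terminal offspring is homozygous-by-descent for any focal
    founder haplotype with probability 1/16.
    """
    rng = rng or np.random.default_rng(config.seed)
    entries: list[PedigreeEntry] = []
    focus = "G0_0000"
    entries.append(PedigreeEntry(focus, None, None, "M", 0))
    dams0 = [f"G0_D{i:03d}" for i in range(max(4, config.n_founders - 1))]
    for d in dams0:
        entries.append(PedigreeEntry(d, None, None, "F", 0))

    g1_m: list[str] = []
    g1_f: list[str] = []
    n_g1 = 40
    for k in range(n_g1):
        dam = dams0[int(rng.integers(len(dams0)))]
        sex = "M" if k % 2 == 0 else "F"
        aid = f"G1_{k:04d}"
        entries.append(PedigreeEntry(aid, focus, dam, sex, 1))
        (g1_m if sex == "M" else g1_f).append(aid)

    n_terminal = int(config.extras.get("n_terminal", 1000))
    for k in range(n_terminal):
        sire = g1_m[int(rng.integers(len(g1_m)))]
        dam = g1_f[int(rng.integers(len(g1_f)))]
        sex = "M" if rng.random() < 0.5 else "F"
        entries.append(PedigreeEntry(f"G2_{k:04d}", sire, dam, sex, 2))
    return Pedigree(entries)
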