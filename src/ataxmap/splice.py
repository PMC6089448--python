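"""Position-weight-matrix scoring of splice donor windows.

The donor window is 9 bases: the last 3 exonic bases (-3..-1) and the
first 6 intronic bases (+1..+6). Scores are log2 odds against a uniform
background. The packaged default matrix encodes the canonical mammalian
donor consensus (C A G | G T A A G T); it is a generic scorer, not a
re-implementation of any particular web server's matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ScoringError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
DONOR_WINDOW = 9
BACKGROUND = 0.25


@dataclass
class SplicePwm:
    """Probability matrix of shape (9, 4) over A, C, G, T; rows sum to 1."""

    probs: np.ndarray
    name: str = "donor"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (DONOR_WINDOW, len(BASES)):
            raise ScoringError(
                f"PWM must be {DONOR_WINDOW}x{len(BASES)}, got {self.probs.shape}"
            )
        if (self.probs <= 0).any():
            raise ScoringError("PWM probabilities must be strictly positive")
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ScoringError("each PWM position must sum to 1")

    @classmethod
    def uniform(cls) -> "SplicePwm":
        return cls(np.full((DONOR_WINDOW, len(BASES)), 0.25), name="uniform")

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))


# Base frequencies for donor positions -3..-1 | +1..+6, smoothed so no
# cell is zero. Consensus: CAG|GTAAGT.
_DEFAULT_FREQS = np.array(
    [
        #  A     C     G     T
        [0.33, 0.37, 0.18, 0.12],  # -3
        [0.60, 0.13, 0.12, 0.15],  # -2  (A consensus; C/A both common upstream variants)
        [0.10, 0.03, 0.80, 0.07],  # -1
        [0.01, 0.01, 0.97, 0.01],  # +1
        [0.01, 0.01, 0.01, 0.97],  # +2
        [0.60, 0.03, 0.30, 0.07],  # +3
        [0.70, 0.08, 0.11, 0.11],  # +4
        [0.07, 0.05, 0.82, 0.06],  # +5
        [0.16, 0.17, 0.20, 0.47],  # +6
    ]
)
# fix -3 consensus to C as in the canonical motif
_DEFAULT_FREQS[0] = [0.30, 0.40, 0.18, 0.12]


def default_donor_pwm() -> SplicePwm:
    probs = _DEFAULT_FREQS / _DEFAULT_FREQS.sum(axis=1, keepdims=True)
    return SplicePwm(probs, name="canonical-donor")


@dataclass(frozen=True)
class SpliceScore:
    score: float
    window: str
    pwm_name: str


def score_donor_site(window: str, pwm: SplicePwm | None = None) -> SpliceScore:
    """Log2-odds PWM score of a 9-base donor window against a uniform background."""
    pwm = pwm or default_donor_pwm()
    window = window.upper()
    if len(window) != DONOR_WINDOW:
        raise ScoringError(f"donor window must be {DONOR_WINDOW} bases, got {len(window)}")
    total = 0.0
    for i, b in enumerate(window):
        j = _BASE_INDEX.get(b)
        if j is None:
            raise ScoringError(f"ambiguous or invalid base {b!r} at window position {i + 1}")
        total += float(np.log2(pwm.probs[i, j] / BACKGROUND))
    return SpliceScore(score=total, window=window, pwm_name=pwm.name)


def donor_score_delta(
    ref_window: str, alt_window: str, pwm: SplicePwm | None = None
) -> float:
    """Score change alt - ref; negative values indicate donor weakening."""
    pwm = pwm or default_donor_pwm()
    return score_donor_site(alt_window, pwm).score - score_donor_site(ref_window, pwm).score
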