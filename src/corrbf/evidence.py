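"""Verbal evidence categories and posterior model probabilities.

Maps a Bayes factor BF10 onto Jeffreys's coarse category scheme
(anecdotal / substantial / strong / very strong / decisive, for H1 when
BF10 > 1 and mirrored for H0 when BF10 < 1), and converts Bayes factors to
posterior model probabilities given prior probabilities on the hypotheses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

__all__ = ["EvidenceLabel", "ModelProbabilities", "classify_bf", "posterior_from_bf"]

# magnitude thresholds, strongest first; exact boundary values are assigned
# to the stronger category (the scheme's published ranges are open-ended)
_THRESHOLDS = (
    (100.0, "Decisive"),
    (30.0, "Very Strong"),
    (10.0, "Strong"),
    (3.0, "Substantial"),
)


@dataclass(frozen=True)
class EvidenceLabel:
    """Verbal evidence category with the hypothesis it favors."""

    category: str
    direction: Literal["H1", "H0", "none"]

    def __str__(self) -> str:
        if self.direction == "none":
            return self.category
        return f"{self.category} evidence for {self.direction}"


@dataclass(frozen=True)
class ModelProbabilities:
    """Prior and posterior probabilities of H1 and H0."""

    prior_h1: float
    prior_h0: float
    posterior_h1: float
    posterior_h0: float

    def __post_init__(self) -> None:
        for name in ("prior_h1", "prior_h0", "posterior_h1", "posterior_h0"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.prior_h1 + self.prior_h0 - 1.0) > 1e-12:
            raise ValueError("prior probabilities must sum to 1")
        if abs(self.posterior_h1 + self.posterior_h0 - 1.0) > 1e-12:
            raise ValueError("posterior probabilities must sum to 1")


def classify_bf(bf10: float) -> EvidenceLabel:
    """Evidence category of a Bayes factor.

    BF10 = 1 is "No evidence"; +inf and 0 map to the decisive categories for
    H1 and H0 respectively. Boundary values (3, 10, 30, 100 and their
    reciprocals) belong to the stronger adjacent category.
    """
    if math.isnan(bf10) or bf10 < 0:
        raise ValueError(f"bf10 must be positive, got {bf10}")
    if bf10 == 1.0:
        return EvidenceLabel("No evidence", "none")
    if bf10 == 0.0:
        return EvidenceLabel("Decisive", "H0")
    direction: Literal["H1", "H0"] = "H1" if bf10 > 1.0 else "H0"
    magnitude = bf10 if bf10 > 1.0 else 1.0 / bf10
    for cutoff, name in _THRESHOLDS:
        if magnitude >= cutoff:
            return EvidenceLabel(name, direction)
    return EvidenceLabel("Anecdotal", direction)


def posterior_from_bf(bf10: float, prior_h1: float = 0.5) -> ModelProbabilities:
    """Posterior model probabilities implied by BF10 and a prior on H1.

    The Bayes factor is the change from prior odds to posterior odds:
    posterior odds = BF10 * prior_h1 / (1 - prior_h1).
    """
    if not bf10 >= 0:
        raise ValueError(f"bf10 must be non-negative, got {bf10}")
    if not 0.0 < prior_h1 < 1.0:
        raise ValueError(f"prior_h1 must lie strictly in (0, 1), got {prior_h1}")
    prior_h0 = 1.0 - prior_h1
    if math.isinf(bf10):
        post_h1 = 1.0
    else:
        odds = bf10 * prior_h1 / prior_h0
        post_h1 = odds / (1.0 + odds)
    return ModelProbabilities(
        prior_h1=prior_h1,
        prior_h0=prior_h0,
        posterior_h1=post_h1,
        posterior_h0=1.0 - post_h1,
    )
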