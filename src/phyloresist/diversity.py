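"""Taxonomic alpha-diversity indices.

Indices are computed from an abundance vector n_i (individuals or ramets per
species) with N = sum(n_i) and S species:

* Margalef richness   R = (S - 1) / ln N
* Shannon-Wiener      H' = -sum p_i ln p_i,   p_i = n_i / N   (natural log)
* Simpson             concentration D = sum n_i (n_i - 1) / (N (N - 1));
                      the reported diversity is the complement 1 - D
                      (Gini-Simpson), which is 0 for a monoculture
* Pielou evenness     E = H' / ln S

Conventions for degenerate communities: a monoculture (S = 1) has Pielou 0
(the 0/0 limit), and N = 1 gives Margalef 0 and Simpson complement 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ValidationError


@dataclass(frozen=True)
class DiversityProfile:
    """The five taxonomic alpha-diversity indices of one community."""

    richness: int
    margalef: float
    shannon: float
    simpson: float  #: complement form 1 - D (Gini-Simpson)
    simpson_concentration: float  #: raw D = sum n_i(n_i-1) / (N(N-1))
    pielou: float

    def as_dict(self) -> dict:
        return {
            "richness": self.richness,
            "margalef": self.margalef,
            "simpson": self.simpson,
            "shannon": self.shannon,
            "pielou": self.pielou,
        }


def _validate_counts(counts: Sequence[float]) -> np.ndarray:
    n = np.asarray(counts, dtype=float)
    if n.size == 0:
        raise ValidationError("empty abundance vector")
    if not np.all(np.isfinite(n)):
        raise ValidationError("non-finite abundance")
    if np.any(n < 1):
        raise ValidationError(
            "abundances must be >= 1; drop zero-abundance species upstream"
        )
    return n


def margalef(counts: Sequence[float]) -> float:
    """Margalef richness (S - 1)/ln N; 0 when N = 1 (0/0 convention)."""
    n = _validate_counts(counts)
    N = n.sum()
    if N <= 1:
        return 0.0
    return (n.size - 1) / math.log(N)


def shannon(counts: Sequence[float]) -> float:
    """Shannon-Wiener H' in nats."""
    n = _validate_counts(counts)
    p = n / n.sum()
    return float(-(p * np.log(p)).sum() + 0.0)  # + 0.0 normalizes -0.0


def simpson_concentration(counts: Sequence[float]) -> float:
    """Simpson concentration D = sum n_i(n_i-1)/(N(N-1)); 1 when N = 1."""
    n = _validate_counts(counts)
    N = n.sum()
    if N <= 1:
        return 1.0
    return float((n * (n - 1)).sum() / (N * (N - 1)))


def simpson(counts: Sequence[float]) -> float:
    """Gini-Simpson diversity 1 - D (0 for a monoculture)."""
    return 1.0 - simpson_concentration(counts)


def pielou(counts: Sequence[float]) -> float:
    """Pielou evenness H'/ln S; 0 for a monoculture (0/0 convention)."""
    n = _validate_counts(counts)
    if n.size == 1:
        return 0.0
    return shannon(counts) / math.log(n.size)


def diversity_profile(counts: Sequence[float]) -> DiversityProfile:
    """All five indices of one abundance vector in a single pass."""
    n = _validate_counts(counts)
    return DiversityProfile(
        richness=int(n.size),
        margalef=margalef(n),
        shannon=shannon(n),
        simpson=simpson(n),
        simpson_concentration=simpson_concentration(n),
        pielou=pielou(n),
    )
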