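"""Merger-rate kernels for Kingman and Lambda-coalescents, and event sampling.

A Lambda-coalescent allows a single merger of ``k`` out of ``b`` active
ancestral lineages per event (2 <= k <= b).  Two parametric families with a
clear biological interpretation are supported beyond the Kingman coalescent:

* the psi point-mass coalescent arising from sweepstakes reproduction, where
  a fraction ``psi`` of the population is replaced by the offspring of a
  single parent in one reproduction event::

      lambda_{b,k} = C(b,k) * psi**(k-2) * (1-psi)**(b-k),   psi in [0, 1]

* the Beta(2-alpha, alpha)-coalescent derived from heavy-tailed offspring
  distributions::

      lambda_{b,k} = C(b,k) * B(k-alpha, b-k+alpha) / B(2-alpha, alpha),
      alpha in (1, 2)

  where ``B`` is the beta function.  As ``alpha -> 2`` the Beta-coalescent
  converges to the Kingman coalescent; both families are normalised so that
  ``lambda_{2,2} = 1``, i.e. time is measured in units where a pair of
  lineages coalesces at rate 1.

Waiting times between events are exponential with rate ``sum_k lambda_{b,k}``
and the merger size ``k`` is drawn proportionally to ``lambda_{b,k}``; the
participating lineages are a uniformly random k-subset (exchangeability).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
from scipy.special import betaln, gammaln

__all__ = [
    "Family",
    "CoalescentParameter",
    "KINGMAN",
    "CoalescentState",
    "MergerEvent",
    "rate_kingman",
    "rate_psi",
    "rate_beta",
    "merger_rates",
    "total_rate",
    "sample_event",
]


class Family(str, Enum):
    """Coalescent family selector."""

    KINGMAN = "kingman"
    PSI = "psi"
    BETA = "beta"


@dataclass(frozen=True)
class CoalescentParameter:
    """A tagged coalescent-family selector.

    ``value`` is psi for the point-mass family (in [0, 1]) or alpha for the
    Beta family (in (1, 2)); it is ``None`` for the Kingman coalescent.
    """

    family: Family = Family.KINGMAN
    value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family == Family.PSI:
            if self.value is None or not 0.0 <= self.value <= 1.0:
                raise ValueError(f"psi must lie in [0, 1], got {self.value}")
        elif self.family == Family.BETA:
            if self.value is None or not 1.0 < self.value < 2.0:
                raise ValueError(f"alpha must lie in (1, 2), got {self.value}")
        elif self.value is not None:
            raise ValueError("Kingman coalescent takes no parameter value")

    @classmethod
    def from_value(cls, value: Optional[float]) -> "CoalescentParameter":
        """Dispatch a scalar to a family.

        ``None``, 0 and 2 select Kingman (psi = 0 collapses the point-mass
        rates to Kingman, and alpha -> 2 is the Kingman limit, so both
        endpoints are consistent); values in (0, 1] select psi; values in
        (1, 2) select alpha.  Anything outside [0, 2] is rejected.
        """
        if value is None:
            return cls(Family.KINGMAN)
        value = float(value)
        if value == 0.0 or value == 2.0:
            return cls(Family.KINGMAN)
        if 0.0 < value <= 1.0:
            return cls(Family.PSI, value)
        if 1.0 < value < 2.0:
            return cls(Family.BETA, value)
        raise ValueError(
            f"coalescent parameter must lie in [0, 2], got {value}"
        )

    def __str__(self) -> str:  # pragma: no cover - convenience only
        if self.family == Family.KINGMAN:
            return "kingman"
        sym = "psi" if self.family == Family.PSI else "alpha"
        return f"{sym}={self.value:g}"


KINGMAN = CoalescentParameter()


@dataclass
class CoalescentState:
    """The active ancestral lineages of a coalescent process."""

    lineages: list = field(default_factory=list)

    @property
    def b(self) -> int:
        return len(self.lineages)


@dataclass
class MergerEvent:
    """One coalescence event: a k-merger after an exponential waiting time."""

    k: int
    waiting_time: float
    participants: tuple


def _check_bk(b: int, k: int) -> None:
    if b < 2:
        raise ValueError(f"need at least 2 lineages, got b={b}")
    if not 2 <= k <= b:
        raise ValueError(f"merger size must satisfy 2 <= k <= b, got k={k}, b={b}")


def rate_kingman(b: int) -> float:
    """Pairwise coalescence rate C(b, 2); k > 2 mergers have rate 0."""
    if b < 2:
        raise ValueError(f"need at least 2 lineages, got b={b}")
    return b * (b - 1) / 2.0


def rate_psi(b: int, k: int, psi: float) -> float:
    """Point-mass coalescent k-merger rate C(b,k) psi^(k-2) (1-psi)^(b-k)."""
    _check_bk(b, k)
    if not 0.0 <= psi <= 1.0:
        raise ValueError(f"psi must lie in [0, 1], got {psi}")
    # 0**0 == 1 handles the boundary cases psi = 0 (k = 2) and psi = 1 (k = b)
    return math.comb(b, k) * psi ** (k - 2) * (1.0 - psi) ** (b - k)


def rate_beta(b: int, k: int, alpha: float) -> float:
    """Beta-coalescent k-merger rate C(b,k) B(k-a, b-k+a) / B(2-a, a).

    Computed in log space (log-gamma) for numerical stability at large b.
    """
    _check_bk(b, k)
    if not 1.0 < alpha < 2.0:
        raise ValueError(f"alpha must lie in (1, 2), got {alpha}")
    logcomb = gammaln(b + 1) - gammaln(k + 1) - gammaln(b - k + 1)
    return float(
        np.exp(logcomb + betaln(k - alpha, b - k + alpha) - betaln(2 - alpha, alpha))
    )


def merger_rates(b: int, p: CoalescentParameter) -> np.ndarray:
    """Vector of rates lambda_{b,k} for k = 2, ..., b."""
    if b < 2:
        raise ValueError(f"need at least 2 lineages, got b={b}")
    ks = np.arange(2, b + 1)
    if p.family == Family.KINGMAN:
        rates = np.zeros(b - 1)
        rates[0] = rate_kingman(b)
        return rates
    if p.family == Family.PSI:
        psi = p.value
        logcomb = gammaln(b + 1) - gammaln(ks + 1) - gammaln(b - ks + 1)
        comb = np.exp(logcomb)
        return comb * psi ** (ks - 2) * (1.0 - psi) ** (b - ks)
    alpha = p.value
    logcomb = gammaln(b + 1) - gammaln(ks + 1) - gammaln(b - ks + 1)
    return np.exp(
        logcomb + betaln(ks - alpha, b - ks + alpha) - betaln(2 - alpha, alpha)
    )


def total_rate(b: int, p: CoalescentParameter) -> float:
    """Total event rate sum_{k=2}^{b} lambda_{b,k}."""
    return float(merger_rates(b, p).sum())


def sample_event(
    state: CoalescentState, p: CoalescentParameter, rng: np.random.Generator
) -> MergerEvent:
    """Draw the next coalescence event for the current lineage set.

    The waiting time is Exponential(total rate), the merger size k is drawn
    with probability lambda_{b,k} / total, and the participants are a
    uniformly random k-subset of the active lineages.  Exactly one merger
    occurs per event (Lambda-coalescents have no simultaneous mergers).
    """
    b = state.b
    if b < 2:
        raise ValueError(f"cannot coalesce fewer than 2 lineages (b={b})")
    rates = merger_rates(b, p)
    tot = float(rates.sum())
    waiting_time = rng.exponential(1.0 / tot)
    if b == 2:
        k = 2
    else:
        k = 2 + int(rng.choice(b - 1, p=rates / tot))
    idx = rng.choice(b, size=k, replace=False)
    participants = tuple(state.lineages[i] for i in sorted(idx))
    return MergerEvent(k=k, waiting_time=waiting_time, participants=participants)
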