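"""Model parameters and statistic-kind descriptors.

The birth-death model is parameterised by the birth rate ``lam`` (lambda), the
death rate ``mu``, the Bernoulli sampling fraction ``sigma`` applied to extant
leaves, and the tree height ``T``.  All times are dimensionless; unit
conversion is an I/O concern.
"""
from __future__ import annotations

from dataclasses import dataclass

from .errors import ContractError, ParameterError

#: relative scale below which |lam - mu| * T is treated as critically small and
#: all closed forms are evaluated through their series branches
EPS_CRITICAL = 1e-8


@dataclass(frozen=True)
class YuleParams:
    """Parameters of a Yule (constant-rate birth-death) tree of height ``T``.

    Invariants: ``lam >= 0``, ``mu >= 0``, ``0 <= sigma <= 1``, ``T >= 0``.
    Density evaluations additionally require ``lam > 0`` (a tree needs
    branching events to produce pairs).
    """

    lam: float
    mu: float = 0.0
    sigma: float = 1.0
    T: float = 1.0

    def __post_init__(self):
        if not (self.lam >= 0.0):
            raise ParameterError(f"birth rate must be >= 0, got {self.lam}")
        if not (self.mu >= 0.0):
            raise ParameterError(f"death rate must be >= 0, got {self.mu}")
        if not (0.0 <= self.sigma <= 1.0):
            raise ParameterError(f"sampling fraction must lie in [0, 1], got {self.sigma}")
        if not (self.T >= 0.0):
            raise ParameterError(f"tree height must be >= 0, got {self.T}")

    @property
    def r(self) -> float:
        """Net growth rate lambda - mu."""
        return self.lam - self.mu

    @property
    def near_critical(self) -> bool:
        """True iff |lam - mu| * T is negligibly small (critical case lam = mu).

        All closed forms route through series branches automatically when the
        relevant exponents are small, so this flag is informational.
        """
        return abs(self.r) * self.T < EPS_CRITICAL * max(1.0, self.lam * self.T)

    def require_branching(self) -> None:
        if self.lam <= 0.0:
            raise ParameterError("density evaluation requires a positive birth rate")


@dataclass(frozen=True)
class PairStatisticKind:
    """One of the four pair-statistic families.

    ``pairwise``  -- all unordered leaf pairs (density N);
    ``nth_min``   -- per-leaf distance to its n-th nearest neighbour (N_n);
    ``cherry``    -- reciprocal-nearest pairs (N_Lambda);
    ``min2``      -- per-pair minimum of the two members' nearest distances (N_min2).
    """

    name: str
    n: int = 1

    _VALID = ("pairwise", "nth_min", "cherry", "min2")

    def __post_init__(self):
        if self.name not in self._VALID:
            raise ContractError(f"unknown statistic kind {self.name!r}")
        if self.name == "nth_min" and self.n < 1:
            raise ParameterError(f"nth_min requires n >= 1, got {self.n}")

    def __str__(self) -> str:
        return f"nmin{self.n}" if self.name == "nth_min" else self.name

    @classmethod
    def nth_min(cls, n: int) -> "PairStatisticKind":
        return cls("nth_min", n)

    @classmethod
    def parse(cls, text: str) -> "PairStatisticKind":
        """Parse CLI-style names: pairwise, nmin, nmin3, cherry, min2."""
        text = text.strip().lower()
        if text in ("pairwise", "cherry", "min2"):
            return cls(text)
        if text.startswith("nmin"):
            tail = text[4:]
            return cls.nth_min(int(tail) if tail else 1)
        if text == "nth_min":
            return cls.nth_min(1)
        raise ContractError(f"unknown statistic kind {text!r}")


PAIRWISE = PairStatisticKind("pairwise")
CHERRY = PairStatisticKind("cherry")
MIN2 = PairStatisticKind("min2")
NMIN1 = PairStatisticKind.nth_min(1)
NMIN2 = PairStatisticKind.nth_min(2)
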