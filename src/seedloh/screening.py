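"""Exact binomial statistics for the two-locus LOH screen.

Anthocyanin-less plants from the double-heterozygous screen fall into two
classes (tt4-type or tt8-type).  The question is whether the observed split
is compatible with a null probability for a tt4-type hit — either equal
odds (0.5) or odds proportional to gene length (TT4 is 1789 bp against
TT8's 4643 bp, i.e. p0 = 1789/6432 ≈ 0.28).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import binomtest

__all__ = [
    "ScreeningCounts",
    "BinomResult",
    "binom_test_exact",
    "length_weighted_null",
    "mutation_frequency",
    "class_ratio",
]

_SIDED = {
    "one-less": "less",
    "one-greater": "greater",
    "two": "two-sided",
}


@dataclass(frozen=True)
class ScreeningCounts:
    """Mutant-class counts from one screening group."""

    n_observed: int
    n_mutant: int
    n_tt4: int
    n_tt8: int
    group: str = ""

    def __post_init__(self) -> None:
        if min(self.n_observed, self.n_mutant, self.n_tt4, self.n_tt8) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_tt4 + self.n_tt8 != self.n_mutant:
            raise ValueError("n_tt4 + n_tt8 must equal n_mutant")
        if self.n_mutant > self.n_observed:
            raise ValueError("n_mutant cannot exceed n_observed")


@dataclass(frozen=True)
class BinomResult:
    """Exact binomial test outcome."""

    k: int
    n: int
    p0: float
    sided: str
    p_value: float


def binom_test_exact(k: int, n: int, p0: float, sided: str = "two") -> BinomResult:
    """Exact binomial tail test with no normal approximation.

    ``sided`` is ``"one-less"`` (P(X <= k)), ``"one-greater"`` (P(X >= k))
    or ``"two"`` — the minlike convention: the sum of P(X = j) over all j
    whose point mass does not exceed P(X = k).
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"null probability must be in (0, 1), got {p0}")
    if sided not in _SIDED:
        raise ValueError(f"sided must be one of {sorted(_SIDED)}, got {sided!r}")
    p = binomtest(k, n, p0, alternative=_SIDED[sided]).pvalue
    return BinomResult(k=k, n=n, p0=p0, sided=sided, p_value=float(p))


def length_weighted_null(l_target: int, l_other: int) -> float:
    """Null probability of a hit in the target gene when the per-bp hit
    rate is uniform: l_target / (l_target + l_other)."""
    if l_target < 0 or l_other < 0:
        raise ValueError("gene lengths must be non-negative")
    if l_target + l_other == 0:
        raise ValueError("at least one gene length must be positive")
    return l_target / (l_target + l_other)


def mutation_frequency(counts: ScreeningCounts) -> float:
    """Percentage of observed plants carrying a detected mutation,
    to one decimal place."""
    if counts.n_observed == 0:
        raise ValueError("no plants observed")
    return round(100.0 * counts.n_mutant / counts.n_observed, 1)


def class_ratio(counts: ScreeningCounts) -> float:
    """How many tt8-type mutants per tt4-type mutant."""
    if counts.n_tt4 == 0:
        raise ValueError("class ratio undefined with zero tt4-type mutants")
    return counts.n_tt8 / counts.n_tt4
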