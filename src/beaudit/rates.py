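"""Per-generation mutation-rate estimation.

The point estimate treats each observed de novo mutation as one event
over a diploid callable genome in a single generation:

    rate = n_dnm / (2 * callable_bp)

with an exact (chi-square based) Poisson 95% interval on the count
propagated to the rate.  The diploid factor of 2 matters when
comparing against published cohort rates; users supplying external
rates must use the same convention.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class MutationRateEstimate:
    n_dnm: int
    callable_bp: int
    rate: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.rate <= self.ci_high):
            raise ValueError("confidence bounds must bracket the rate")


def poisson_ci(n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact two-sided Poisson interval for an observed count *n*."""
    if n < 0:
        raise ValueError("count must be >= 0")
    lo = stats.chi2.ppf(alpha / 2, 2 * n) / 2 if n > 0 else 0.0
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * n + 2) / 2
    return (float(lo), float(hi))


def estimate_mutation_rate(n_dnm: int, callable_bp: int) -> MutationRateEstimate:
    """Per-bp, per-generation mutation rate from a de novo count.

    *callable_bp* is the haploid callable genome length; the
    denominator is 2 x callable_bp (diploid transmission).
    """
    if callable_bp <= 0:
        raise ValueError("callable_bp must be > 0")
    if n_dnm < 0:
        raise ValueError("n_dnm must be >= 0")
    denom = 2 * callable_bp
    lo, hi = poisson_ci(n_dnm)
    return MutationRateEstimate(
        n_dnm=n_dnm,
        callable_bp=callable_bp,
        rate=n_dnm / denom,
        ci_low=lo / denom,
        ci_high=hi / denom,
    )
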