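"""Shared test fixtures and independent oracles."""

from __future__ import annotations

from fractions import Fraction
from math import factorial

import pytest

from plasmatriage.synthetic import CohortSpec


def fisher_oracle_probs(r1: int, r2: int, c1: int) -> dict[int, Fraction]:
    """Brute force: exact probability of every 2x2 table with the given margins.

    Enumerates all admissible tables directly from factorials in rational
    arithmetic — an independent route from the package's comb-weight core.
    """
    n = r1 + r2
    denom = factorial(n) // (factorial(c1) * factorial(n - c1))
    probs = {}
    for a in range(max(0, c1 - r2), min(r1, c1) + 1):
        b, c = r1 - a, c1 - a
        d = r2 - c
        num = ((factorial(r1) // (factorial(a) * factorial(b)))
               * (factorial(r2) // (factorial(c) * factorial(d))))
        probs[a] = Fraction(num, denom)
    return probs


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration (exact rationals)."""
    r1, r2, c1 = a + b, c + d, a + c
    if r1 + r2 == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == r1 + r2:
        return 1.0
    probs = fisher_oracle_probs(r1, r2, c1)
    p_obs = probs[a]
    return float(min(sum(p for p in probs.values() if p <= p_obs), Fraction(1)))


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """A compact cohort with guaranteed plasma signal, for end-to-end tests."""
    return CohortSpec(n_patients=4, seed=11, germline_het_sites_per_patient=10,
                      somatic_sites_per_patient=5, plasma_only_sites_per_patient=2,
                      ctdna_fraction_range=(0.05, 0.2))
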