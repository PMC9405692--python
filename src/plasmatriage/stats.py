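"""Exact statistical core: two-sided Fisher's exact test on 2x2 tables.

The somatic/germline classification and the strand-bias filter both reduce
to the same question — are the allele proportions in two groups of reads
compatible with one underlying rate? — answered by the two-sided Fisher
exact test on the table::

        alt   ref
    A    a     b
    B    c     d

The two-sided p-value follows the standard convention: the sum of the
probabilities of all tables with the observed margins whose probability does
not exceed that of the observed table.

For small tables (total N <= EXACT_N_MAX) the computation is carried out in
exact integer arithmetic: the conditional probability of a table with
``k`` alt reads in group A is proportional to the integer weight
C(r1, k) * C(r2, c1 - k), so table probabilities can be compared and summed
without floating-point error. Larger tables use the hypergeometric
distribution in floating point with the conventional relative tie tolerance.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

from scipy.stats import hypergeom

EXACT_N_MAX = 512
# relative tolerance when comparing floating-point table probabilities
_FLOAT_TIE_GAMMA = 1e-7


def fisher_exact_counts(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the 2x2 table [[a, b], [c, d]].

    All-zero tables (no reads at all) return p = 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        # a degenerate margin admits a single table: p = 1
        return 1.0
    if n <= EXACT_N_MAX:
        return _fisher_exact_int(a, r1, r2, c1)
    return _fisher_float(a, r1, r2, c1)


def _support(r1: int, r2: int, c1: int):
    return range(max(0, c1 - r2), min(r1, c1) + 1)


def _fisher_exact_int(a: int, r1: int, r2: int, c1: int) -> float:
    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in _support(r1, r2, c1)}
    w_obs = weights[a]
    num = sum(w for w in weights.values() if w <= w_obs)
    den = sum(weights.values())
    return float(min(Fraction(num, den), 1))


def _fisher_float(a: int, r1: int, r2: int, c1: int) -> float:
    n = r1 + r2
    rv = hypergeom(n, r1, c1)
    ks = list(_support(r1, r2, c1))
    pmf = rv.pmf(ks)
    p_obs = rv.pmf(a)
    p = float(pmf[pmf <= p_obs * (1.0 + _FLOAT_TIE_GAMMA)].sum())
    return min(p, 1.0)
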