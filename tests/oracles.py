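"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library code paths they verify: exact Fraction
arithmetic over binomial coefficients for the Fisher and hypergeometric
tests, and a rule-by-rule literal transcription of the filtering procedure.
"""

from fractions import Fraction
from math import comb


def hypergeom_upper_tail(k: int, M: int, n: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(M population, n successes, N draws)."""
    total = comb(M, N)
    acc = Fraction(0)
    for x in range(max(k, 0, n + N - M), min(n, N) + 1):
        acc += Fraction(comb(n, x) * comb(M - n, N - x), total)
    return acc


def fisher_two_sided(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher exact p by summing all tables with the observed
    margins whose probability does not exceed the observed table's."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    total = comb(n, c1)

    def prob(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), total)

    p_obs = prob(a)
    acc = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if prob(x) <= p_obs:
            acc += prob(x)
    return acc


def reference_filter_status(
    panel_flag: bool,
    any_db_flag: bool,
    n_carriers: int,
    n_samples: int,
    somatic_fraction: float = 0.5,
    germline_fraction: float = 0.05,
) -> str:
    """Literal transcription of the filtering rules, applied one by one."""
    import math

    var_class = "germline" if any_db_flag else "somatic"
    frac = germline_fraction if var_class == "germline" else somatic_fraction
    threshold = math.ceil(frac * n_samples)
    if panel_flag:
        return "eliminated_panel"
    if n_carriers > threshold:
        return "eliminated_polymorphic"
    if n_carriers == 1:
        return "eliminated_private"
    return "retained"
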