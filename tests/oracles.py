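"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: naive Python loops,
full enumerations and textbook formulas only.
"""

from __future__ import annotations

from math import comb

from Bio.Seq import Seq


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration of tables with fixed margins,
    summing every table whose hypergeometric probability does not exceed
    the observed table's (minimum-likelihood rule)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    def prob(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def expected_counts_enum(cds: str, rate_fn) -> dict[str, float]:
    """Per-effect-class substitution probability of a CDS by exhaustive
    enumeration of all 9L/3 codon x position x alt substitutions.

    ``rate_fn(trimer, alt)`` supplies the per-substitution rate; trimers at
    the sequence edge use 'N' for the missing flank. Effect classes follow
    translation of the mutated codon: same amino acid = synonymous, new
    stop = LoF, anything else (including stop-loss) = missense.
    """
    totals = {"synonymous": 0.0, "missense": 0.0, "LoF": 0.0}
    for i in range(len(cds)):
        codon_start = (i // 3) * 3
        codon = cds[codon_start : codon_start + 3]
        within = i - codon_start
        aa_ref = str(Seq(codon).translate())
        left = cds[i - 1] if i > 0 else "N"
        right = cds[i + 1] if i < len(cds) - 1 else "N"
        for alt in "ACGT":
            if alt == cds[i]:
                continue
            mutated = codon[:within] + alt + codon[within + 1 :]
            aa_alt = str(Seq(mutated).translate())
            if aa_alt == aa_ref:
                klass = "synonymous"
            elif aa_alt == "*" and aa_ref != "*":
                klass = "LoF"
            else:
                klass = "missense"
            totals[klass] += rate_fn(left + cds[i] + right, alt)
    return totals


def poisson_lower_limit_by_inversion(observed: int, alpha: float = 0.025) -> float:
    """Exact Poisson lower confidence limit by grid inversion: the smallest
    mean mu for which P(X >= observed | mu) exceeds alpha."""
    from scipy.stats import poisson

    if observed == 0:
        return 0.0
    lo, hi = 0.0, observed * 3.0 + 10.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if poisson.sf(observed - 1, mid) > alpha:
            hi = mid
        else:
            lo = mid
    return (lo + hi) / 2
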