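"""Independent brute-force oracles used to check the package's arithmetic.

Everything here is deliberately naive — full enumeration, rational
arithmetic, plain loops — and shares no code path with the implementation.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

BASES = "ACGT"


# ---------------------------------------------------------------------------
# PWM percent score by enumeration


def logodds_bruteforce(seq: str, probs, background) -> float:
    score = 0.0
    for j, base in enumerate(seq):
        if base == "N":
            continue
        i = BASES.index(base)
        score += math.log2(probs[j][i] / background[i])
    return score


def percent_bruteforce(seq: str, anchor: int, probs, background,
                       window: tuple[int, int]) -> tuple[float, int]:
    """Percent-of-optimum by enumerating every offset and every possible
    L-mer for the score extrema."""
    L = len(probs)
    smax = -math.inf
    smin = math.inf
    for mer in itertools.product(BASES, repeat=L):
        s = logodds_bruteforce("".join(mer), probs, background)
        smax = max(smax, s)
        smin = min(smin, s)
    best, best_off = -math.inf, None
    for off in range(window[0], window[1] + 1):
        start = anchor + off
        s = logodds_bruteforce(seq[start:start + L], probs, background)
        if s > best:
            best, best_off = s, off
    return 100.0 * (best - smin) / (smax - smin), best_off


# ---------------------------------------------------------------------------
# initiation shape metrics on a plain list of counts


def dominant_offset_oracle(counts, offsets):
    best = max(counts)
    for off, c in zip(offsets, counts):
        if c == best:
            return off


def dominant_fraction_oracle(counts):
    return max(counts) / sum(counts)


def activated_oracle(counts, rel, inclusive):
    dom = max(counts)
    n = 0
    for c in counts:
        if c == 0:
            continue
        ratio = c / dom
        if (ratio >= rel if inclusive else ratio > rel):
            n += 1
    return max(n, 1) if not inclusive else n


def width_oracle(counts, floor=1):
    idx = [i for i, c in enumerate(counts) if c >= floor]
    return idx[-1] - idx[0] + 1


# ---------------------------------------------------------------------------
# exact conditional and Fisher tests by rational enumeration


def binom_two_sided_oracle(c: int, t: int, pi0: float) -> float:
    """Two-sided conditional binomial p with exact rational pmf."""
    n = c + t
    p = Fraction(pi0)
    pmf = [Fraction(math.comb(n, k)) * p ** k * (1 - p) ** (n - k)
           for k in range(n + 1)]
    obs = pmf[t]
    total = sum(v for v in pmf if v <= obs)
    return float(min(Fraction(1), total))


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by enumerating all tables with the observed margins
    in exact rational arithmetic."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def pmf(k: int) -> Fraction:
        return (Fraction(math.comb(col1, k) * math.comb(n - col1, row1 - k),
                         math.comb(n, row1)))

    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    obs = pmf(a)
    total = sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= obs)
    return float(min(Fraction(1), total))
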