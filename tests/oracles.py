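"""Independent oracles used only by the test suite.

These deliberately do not share code with the package: the Smith-Waterman
oracle is Biopython's PairwiseAligner, the Pearson oracle is the raw-sums
textbook formula with the p-value from scipy's t distribution, and the
lambda oracle is a plain bisection.
"""

from __future__ import annotations

import math

import numpy as np
from Bio import Align
from scipy import stats


def sw_aligner(match=2, mismatch=-3, gap_open=5, gap_extend=2) -> Align.PairwiseAligner:
    """Local affine-gap aligner with gap cost gap_open + gap_extend*L
    (Biopython scores the first gap base as open_gap_score)."""
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = -(gap_open + gap_extend)
    a.extend_gap_score = -gap_extend
    return a


def sw_score(a: str, b: str, **kw) -> int:
    return int(sw_aligner(**kw).score(a, b))


def optimal_alignment_has_exact_run(a: str, b: str, k: int, **kw) -> bool:
    """Whether a returned optimal local alignment contains >= k consecutive
    aligned identical bases."""
    aln = sw_aligner(**kw).align(a, b)[0]
    for (qa, qb), (sa, _sb) in zip(aln.aligned[0], aln.aligned[1]):
        run = 0
        for i in range(qb - qa):
            if a[qa + i] == b[sa + i]:
                run += 1
                if run >= k:
                    return True
            else:
                run = 0
    return False


def pearson_oracle(x, y):
    """Textbook raw-sums Pearson r, t statistic and two-sided p."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    r = num / den
    df = n - 2
    if abs(r) >= 1.0:
        return r, math.inf, 0.0
    t = r * math.sqrt(df / (1 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, t, p


def bisection_lambda(match: int, mismatch: int, p_match: float, tol: float = 1e-12):
    """Positive root of p*e^(lam*match) + (1-p)*e^(lam*mismatch) = 1."""

    def f(lam):
        return p_match * math.exp(lam * match) + (1 - p_match) * math.exp(lam * mismatch) - 1.0

    lo, hi = 1e-9, 1.0
    while f(hi) <= 0:
        hi *= 2
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)
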