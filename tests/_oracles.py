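"""Independent oracles: exhaustive enumeration, closed forms, brute force.

Everything here is deliberately implemented without scipy distributions,
lifelines, or the package's own interval machinery, so it can serve as a
second route against the implementation.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


# ---------------------------------------------------------------------------
# hypergeometric by exhaustive subset enumeration
# ---------------------------------------------------------------------------

def enum_hit_distribution(G: int, N: int, M: int) -> dict[int, Fraction]:
    """Exact P(k hits) by enumerating all C(G, M) altered-gene subsets.

    The pathway is the first N of G genes; every M-subset is equally
    likely under the uniform null.
    """
    counts: dict[int, int] = {}
    total = 0
    for subset in itertools.combinations(range(G), M):
        k = sum(1 for x in subset if x < N)
        counts[k] = counts.get(k, 0) + 1
        total += 1
    return {k: Fraction(c, total) for k, c in counts.items()}


def enum_upper_tail(G: int, N: int, M: int, k: int) -> Fraction:
    """Exact P(X >= k) from the enumeration above."""
    dist = enum_hit_distribution(G, N, M)
    return sum((p for kk, p in dist.items() if kk >= k), Fraction(0))


def comb_upper_tail(G: int, N: int, M: int, k: int) -> Fraction:
    """Exact P(X >= k) via binomial coefficients (for larger G)."""
    denom = math.comb(G, M)
    num = sum(
        math.comb(N, i) * math.comb(G - N, M - i)
        for i in range(max(k, max(0, M - (G - N))), min(N, M) + 1)
    )
    return Fraction(num, denom)


# ---------------------------------------------------------------------------
# Fisher's method closed form for even df
# ---------------------------------------------------------------------------

def fisher_even_df_closed_form(X: float, df: int) -> float:
    """Chi-square upper tail at X for even df: e^{-X/2} sum (X/2)^i / i!."""
    assert df % 2 == 0
    h = X / 2.0
    return math.exp(-h) * sum(h**i / math.factorial(i) for i in range(df // 2))


# ---------------------------------------------------------------------------
# log-rank statistic by hand + exhaustive permutation p-value
# ---------------------------------------------------------------------------

def logrank_stat_by_hand(times, events, groups) -> float:
    """Two-group log-rank chi-square statistic from first principles."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    g = np.asarray(groups, int)
    obs_minus_exp = 0.0
    var = 0.0
    for tj in np.unique(t[e == 1]):
        at_risk = t >= tj
        n = at_risk.sum()
        n1 = (at_risk & (g == 1)).sum()
        d = ((t == tj) & (e == 1)).sum()
        d1 = ((t == tj) & (e == 1) & (g == 1)).sum()
        obs_minus_exp += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return obs_minus_exp**2 / var


def logrank_permutation_pvalue(times, events, groups) -> float:
    """Exact permutation p over all relabelings with the same group sizes."""
    g = np.asarray(groups, int)
    n = g.size
    n1 = int(g.sum())
    s_obs = logrank_stat_by_hand(times, events, g)
    hits = total = 0
    for comb in itertools.combinations(range(n), n1):
        gg = np.zeros(n, int)
        gg[list(comb)] = 1
        if logrank_stat_by_hand(times, events, gg) >= s_obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def km_by_hand(times, events) -> list[tuple[float, float]]:
    """Product-limit estimate computed directly from the definition."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    s = 1.0
    out = [(0.0, 1.0)]
    for tj in np.unique(t[e == 1]):
        n = (t >= tj).sum()
        d = ((t == tj) & (e == 1)).sum()
        s *= 1 - d / n
        out.append((float(tj), s))
    return out


# ---------------------------------------------------------------------------
# per-base brute-force segment overlay
# ---------------------------------------------------------------------------

def brute_force_overlay(segments, genes, gene_intervals=None) -> dict[tuple[str, str], int]:
    """Per-base overlay of altered segments onto gene intervals.

    ``segments`` are (sample_id, chrom, start, end, state) tuples; genes
    are (gene_id, chrom, start, end). ``gene_intervals`` optionally
    overrides each gene's span (e.g. with its BAC's extended interval).
    Returns {(gene_id, sample_id): state} with the larger-overlap state,
    ties -> 0.
    """
    out: dict[tuple[str, str], int] = {}
    samples = sorted({s[0] for s in segments})
    for gene_id, chrom, gs, ge in genes:
        if gene_intervals is not None:
            chrom, gs, ge = gene_intervals[gene_id]
        for sample in samples:
            amp = dele = 0
            for base in range(gs, ge):
                for sid, sc, ss, se, state in segments:
                    if sid == sample and sc == chrom and ss <= base < se:
                        if state > 0:
                            amp += 1
                        else:
                            dele += 1
            out[(gene_id, sample)] = 1 if amp > dele else (-1 if dele > amp else 0)
    return out
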