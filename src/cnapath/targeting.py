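"""Population-level statistics for pathway targeting by copy-number alteration.

The model: in sample *j*, ``M_j`` of the ``G`` genes quantified on the
platform are altered. Under the null that alterations fall uniformly at
random over the universe, the number ``k_ij`` of altered genes landing in
a pathway of ``N_i`` genes is hypergeometric,

    P(X = k) = C(N_i, k) C(G - N_i, M_j - k) / C(G, M_j),

and the per-sample evidence that pathway *i* is targeted is the upper
tail p_ij = P(X >= k_ij). Because M_j and k_ij are counted per sample
while N_i is fixed per pathway, the statistic compensates for pathway
size: a larger pathway needs more hits for the same p. Per-sample
p-values are combined across the cohort with Fisher's Omnibus,

    X_i = -2 sum_j ln p_ij  ~  chi-square,

and the family of pathway-level p-values is controlled with Bonferroni.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import ValidationError

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # underflow clamp before taking logs in the omnibus


@dataclass(frozen=True)
class Pathway:
    """A curated gene set; gene content may overlap between pathways."""

    pathway_id: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) < 1:
            raise ValidationError(f"pathway {self.pathway_id} has no genes")

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneUniverse:
    """The sampling frame of the hypergeometric null: all platform genes."""

    genes: frozenset[str]

    @property
    def G(self) -> int:
        return len(self.genes)


class SampleHitSummary(NamedTuple):
    sample_id: str
    M: int
    k: int
    p: float


@dataclass
class PathwayTargetingResult:
    pathway_id: str
    N: int
    omnibus_stat: float
    df: int
    p_population: float
    per_sample: list[SampleHitSummary] = field(default_factory=list)
    p_adjusted: float | None = None
    significant: bool | None = None


def _check_counts(G: int, N: int, M: int, k: int) -> None:
    for name, v in (("G", G), ("N", N), ("M", M), ("k", k)):
        if not isinstance(v, (int, np.integer)):
            raise ValidationError(f"{name} must be an integer, got {v!r}")
        if v < 0:
            raise ValidationError(f"{name} must be non-negative, got {v}")
    if N > G:
        raise ValidationError(f"pathway size N={N} exceeds universe G={G}")
    if M > G:
        raise ValidationError(f"altered count M={M} exceeds universe G={G}")


def hypergeom_hit_pmf(G: int, N: int, M: int, k: int) -> float:
    """P(exactly ``k`` of the ``M`` altered genes fall in an ``N``-gene pathway).

    Computed in log space via the hypergeometric pmf; returns 0 outside
    the support ``[max(0, M-(G-N)), min(N, M)]``.
    """
    _check_counts(G, N, M, k)
    if k > min(N, M) or k < max(0, M - (G - N)):
        return 0.0
    return float(min(1.0, np.exp(stats.hypergeom.logpmf(k, G, N, M))))


def pathway_sample_pvalue(
    G: int, N: int, M: int, k: int, tail: str = "inclusive"
) -> float:
    """Upper-tail p-value for observing ``k`` pathway hits in one sample.

    ``tail="inclusive"`` (default) returns P(X >= k), so the observed
    count itself is evidence; ``tail="exclusive"`` returns P(X > k).
    Always in (0, 1]; k = 0 gives exactly 1 under the inclusive tail.
    """
    _check_counts(G, N, M, k)
    if tail not in ("inclusive", "exclusive"):
        raise ValidationError(f"unknown tail {tail!r}")
    kk = k - 1 if tail == "inclusive" else k
    p = float(stats.hypergeom.sf(kk, G, N, M))
    return min(1.0, max(p, 0.0))


def fisher_omnibus(
    pvals: Sequence[float], df_mode: str = "two_per_sample"
) -> tuple[float, float, int]:
    """Combine per-sample p-values with Fisher's Omnibus.

    Returns ``(statistic, combined_p, df)`` where the statistic is
    ``-2 sum ln p`` and the combined p is its chi-square upper tail.
    ``df_mode="two_per_sample"`` (standard Fisher's method) uses 2n
    degrees of freedom; ``"one_per_sample"`` uses n.
    """
    if df_mode not in ("two_per_sample", "one_per_sample"):
        raise ValidationError(f"unknown df_mode {df_mode!r}")
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValidationError("fisher_omnibus needs at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    if np.any(p < P_FLOOR):
        logger.warning(
            "%d p-value(s) below %.0e clamped before log", int((p < P_FLOOR).sum()), P_FLOOR
        )
        p = np.maximum(p, P_FLOOR)
    X = float(-2.0 * np.log(p).sum())
    df = 2 * p.size if df_mode == "two_per_sample" else p.size
    return X, float(stats.chi2.sf(X, df)), df


def bonferroni_adjust(
    results: Sequence[PathwayTargetingResult], alpha: float = 0.05
) -> float:
    """Apply Bonferroni control across pathways, in place.

    Sets ``p_adjusted = min(1, m * p)`` and flags significance at the
    family-wise threshold ``alpha / m``; returns that threshold.
    """
    m = len(results)
    if m < 1:
        raise ValidationError("no pathway results to adjust")
    threshold = alpha / m
    for r in results:
        r.p_adjusted = min(1.0, m * r.p_population)
        r.significant = r.p_population < threshold
    return threshold


_HIT_CODES = {"any_alteration": (1, -1), "amplification_only": (1,), "deletion_only": (-1,)}


def score_all_pathways(
    matrix: pd.DataFrame,
    pathways: Iterable[Pathway],
    universe: GeneUniverse | None = None,
    hit_definition: str = "any_alteration",
    tail: str = "inclusive",
    df_mode: str = "two_per_sample",
    alpha: float = 0.05,
    detailed: bool = True,
) -> list[PathwayTargetingResult]:
    """Score every pathway for non-random targeting across the cohort.

    ``matrix`` is the gene x sample alteration matrix in {-1, 0, +1}. The
    universe defaults to the matrix's gene index; pathway genes outside
    the universe are dropped (logged). Results carry raw and
    Bonferroni-adjusted population p-values; ``detailed=False`` skips the
    per-sample summaries, which speeds up large simulation sweeps.
    """
    if hit_definition not in _HIT_CODES:
        raise ValidationError(f"unknown hit_definition {hit_definition!r}")
    if universe is None:
        universe = GeneUniverse(frozenset(matrix.index))
    extra = set(matrix.index) - set(universe.genes)
    if extra:
        raise ValidationError(
            f"{len(extra)} matrix genes are not in the universe (e.g. {sorted(extra)[:3]})"
        )
    G = universe.G
    codes = _HIT_CODES[hit_definition]
    hits = matrix.isin(codes).to_numpy()
    M = hits.sum(axis=0).astype(int)
    gene_row = {g: i for i, g in enumerate(matrix.index)}
    samples = list(matrix.columns)

    results: list[PathwayTargetingResult] = []
    kk_shift = 1 if tail == "inclusive" else 0
    if tail not in ("inclusive", "exclusive"):
        raise ValidationError(f"unknown tail {tail!r}")
    for pw in pathways:
        in_universe = pw.genes & universe.genes
        dropped = len(pw.genes) - len(in_universe)
        if dropped:
            logger.info(
                "pathway %s: %d gene(s) outside the universe dropped", pw.pathway_id, dropped
            )
        N = len(in_universe)
        if N == 0:
            logger.warning("pathway %s has no genes in the universe; skipped", pw.pathway_id)
            continue
        rows = [gene_row[g] for g in in_universe if g in gene_row]
        if rows:
            k = hits[rows].sum(axis=0).astype(int)
        else:
            k = np.zeros(len(samples), dtype=int)
        p = stats.hypergeom.sf(k - kk_shift, G, N, M)
        p = np.clip(p, P_FLOOR, 1.0)
        X = float(-2.0 * np.log(p).sum())
        df = 2 * len(samples) if df_mode == "two_per_sample" else len(samples)
        res = PathwayTargetingResult(
            pathway_id=pw.pathway_id,
            N=N,
            omnibus_stat=X,
            df=df,
            p_population=float(stats.chi2.sf(X, df)),
        )
        if detailed:
            res.per_sample = [
                SampleHitSummary(s, int(M[j]), int(k[j]), float(p[j]))
                for j, s in enumerate(samples)
            ]
        results.append(res)

    if results:
        bonferroni_adjust(results, alpha=alpha)
    return results


def results_to_frame(results: Sequence[PathwayTargetingResult]) -> pd.DataFrame:
    """Per-pathway report table, sorted by population p-value."""
    df = pd.DataFrame(
        {
            "pathway_id": [r.pathway_id for r in results],
            "N": [r.N for r in results],
            "omnibus_stat": [r.omnibus_stat for r in results],
            "df": [r.df for r in results],
            "p_population": [r.p_population for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "significant": [r.significant for r in results],
        }
    )
    return df.sort_values(["p_population", "pathway_id"], kind="mergesort").reset_index(
        drop=True
    )


def per_sample_frame(results: Sequence[PathwayTargetingResult]) -> pd.DataFrame:
    """Long-format per-sample detail: one row per (pathway, sample)."""
    rows = [
        (r.pathway_id, s.sample_id, s.M, s.k, s.p)
        for r in results
        for s in r.per_sample
    ]
    return pd.DataFrame(rows, columns=["pathway_id", "sample_id", "M", "k", "p"])
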