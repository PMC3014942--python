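"""Reconciliation of BAC and gene coordinates for array-CGH analysis.

BAC probes on older CGH arrays frequently carry incomplete end-sequence
mapping, so their raw genomic spans understate the region they report on.
Two derived coordinate sets compensate:

* *expanded* coordinates grow each under-mapped BAC to a minimum genomic
  span (default 165 kb, the median span of fully end-sequenced BACs),
  growing away from any anchored end and resolving collisions between
  neighbours by splitting the intervening space equally;
* *extended* coordinates further divide the unassigned regions between
  neighbouring BACs, producing a pseudo-tiling of the arrayed span so
  that every position belongs to exactly one BAC.

Genes are then associated with BACs by interval intersection, and
per-sample altered segments are overlaid to produce the gene x sample
alteration matrix (entries in {-1, 0, +1}).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .intervals import BacClone, Gene, GenomicInterval, SegmentCall, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_TARGET_SPAN = 165_000
DEFAULT_SKIP_SPAN = 100_000
DEFAULT_STEP = 1_000


# ---------------------------------------------------------------------------
# overlap resolution
# ---------------------------------------------------------------------------

def resolve_bac_overlaps(bacs: Sequence[BacClone]) -> list[BacClone]:
    """Mark contained BACs as duplicates and freeze partially-overlapping ends.

    A BAC lying entirely within a larger BAC is essentially a duplicate
    probe: it is flagged with ``duplicate_of`` and later adopts the
    container's final coordinates. When two BACs partially overlap, the
    coordinates in the overlap region are left unchanged and the
    overlapping ends take no part in expansion or extension.
    """
    by_chrom: dict[str, list[BacClone]] = defaultdict(list)
    for b in bacs:
        by_chrom[b.chrom].append(b)
    for group in by_chrom.values():
        group.sort(key=lambda b: (b.raw.start, -b.raw.length))
        for i, a in enumerate(group):
            for b in group[i + 1 :]:
                if b.raw.start >= a.raw.end:
                    break
                if a.duplicate_of is not None or b.duplicate_of is not None:
                    continue
                if a.raw.contains(b.raw):
                    b.duplicate_of = a.bac_id
                elif b.raw.contains(a.raw):
                    a.duplicate_of = b.bac_id
                else:
                    # partial overlap: a starts first, so a's right end and
                    # b's left end lie in the shared region
                    a.right_frozen = True
                    b.left_frozen = True
    return list(bacs)


# ---------------------------------------------------------------------------
# expansion
# ---------------------------------------------------------------------------

def expand_bacs(
    bacs: Sequence[BacClone],
    target_span: int = DEFAULT_TARGET_SPAN,
    skip_span: int = DEFAULT_SKIP_SPAN,
    step: int = DEFAULT_STEP,
) -> list[BacClone]:
    """Grow under-mapped BACs toward ``target_span`` without colliding.

    BACs with both ends anchored, or whose raw mapping already spans
    ``skip_span`` or more, are left unchanged. Single-anchored BACs grow
    only away from the anchor; unanchored BACs grow symmetrically.
    Growth proceeds in multi-pass rounds of at most ``step`` bases per
    BAC, so two neighbours expanding into the same gap split it equally;
    when one direction is blocked the shortfall is redistributed to the
    other end unless that end is fixed.

    Input BACs are grouped by chromosome internally; duplicates (fully
    contained BACs) are skipped and inherit coordinates later.
    """
    by_chrom: dict[str, list[BacClone]] = defaultdict(list)
    for b in bacs:
        by_chrom[b.chrom].append(b)

    for group in by_chrom.values():
        active = [b for b in group if b.duplicate_of is None]
        active.sort(key=lambda b: b.raw.start)
        cur = {b.bac_id: [b.raw.start, b.raw.end] for b in active}

        def expandable(b: BacClone) -> bool:
            if b.left_anchored and b.right_anchored:
                return False
            if b.raw.length >= skip_span:
                return False
            return not (b.left_fixed and b.right_fixed)

        def wants(b: BacClone) -> int:
            s, e = cur[b.bac_id]
            return max(0, target_span - (e - s))

        def gap_capacity(idx: int, side: str) -> int:
            """Room available to BAC ``idx`` on ``side`` this round."""
            b = active[idx]
            s, e = cur[b.bac_id]
            if side == "left":
                if idx == 0:
                    return s  # clamp at position 0
                nb = active[idx - 1]
                gap = s - cur[nb.bac_id][1]
                opposing = (
                    expandable(nb) and wants(nb) > 0 and not nb.right_fixed
                )
            else:
                if idx == len(active) - 1:
                    return target_span  # effectively unbounded
                nb = active[idx + 1]
                gap = cur[nb.bac_id][0] - e
                opposing = expandable(nb) and wants(nb) > 0 and not nb.left_fixed
            if gap <= 0:
                return 0
            if opposing:
                # leave the neighbour its equal share; odd base to the
                # left-hand BAC of the gap
                share = gap // 2
                if side == "right":
                    share += gap % 2
                return share if share > 0 else (1 if gap == 1 and side == "right" else 0)
            return gap

        progress = True
        while progress:
            progress = False
            for idx, b in enumerate(active):
                if not expandable(b):
                    continue
                want = min(step, wants(b))
                if want == 0:
                    continue
                free_left = not b.left_fixed
                free_right = not b.right_fixed
                if free_left and free_right:
                    desire = {"left": want // 2, "right": want - want // 2}
                elif free_left:
                    desire = {"left": want, "right": 0}
                else:
                    desire = {"left": 0, "right": want}
                got = 0
                for side in ("left", "right"):
                    take = min(desire[side], gap_capacity(idx, side))
                    if take > 0:
                        if side == "left":
                            cur[b.bac_id][0] -= take
                        else:
                            cur[b.bac_id][1] += take
                        got += take
                # compensatory expansion on the free end when blocked
                leftover = want - got
                if leftover > 0:
                    for side in ("right", "left"):
                        if leftover == 0:
                            break
                        if side == "left" and not free_left:
                            continue
                        if side == "right" and not free_right:
                            continue
                        take = min(leftover, max(0, gap_capacity(idx, side) - desire[side]))
                        if take > 0:
                            if side == "left":
                                cur[b.bac_id][0] -= take
                            else:
                                cur[b.bac_id][1] += take
                            got += take
                            leftover -= take
                if got > 0:
                    progress = True

        for b in active:
            s, e = cur[b.bac_id]
            if s < 0:  # pragma: no cover - clamped in gap_capacity already
                logger.warning("BAC %s expansion clamped at position 0", b.bac_id)
                s = 0
            b.expanded = GenomicInterval(b.chrom, s, e)

    return list(bacs)


# ---------------------------------------------------------------------------
# extension (pseudo-tiling)
# ---------------------------------------------------------------------------

def extend_bacs(
    bacs: Sequence[BacClone],
    chrom_length: int | None = None,
    full_chromosome: bool = False,
) -> list[BacClone]:
    """Divide unassigned regions between neighbouring BACs.

    Consecutive non-overlapping BACs split the gap between their expanded
    intervals equally (odd gaps give the extra base to the left BAC).
    The first and last BAC on a chromosome extend to the boundary of the
    arrayed span (minimum raw start / maximum raw end), or to the full
    chromosome ``[0, chrom_length)`` when ``full_chromosome`` is set.
    Overlap-frozen ends receive no extension. Duplicate BACs adopt their
    container's extended coordinates.
    """
    by_chrom: dict[str, list[BacClone]] = defaultdict(list)
    for b in bacs:
        by_chrom[b.chrom].append(b)

    for group in by_chrom.values():
        active = [b for b in group if b.duplicate_of is None]
        if not active:
            continue
        for b in active:
            if b.expanded is None:
                raise ValidationError(
                    f"BAC {b.bac_id} has no expanded coordinates; run expand_bacs first"
                )
        active.sort(key=lambda b: b.expanded.start)
        covered_min = min(b.raw.start for b in group)
        covered_max = max(b.raw.end for b in group)
        if full_chromosome:
            if chrom_length is None:
                raise ValidationError("full_chromosome extension needs chrom_length")
            covered_min, covered_max = 0, chrom_length

        bounds = {b.bac_id: [b.expanded.start, b.expanded.end] for b in active}
        first, last = active[0], active[-1]
        if not first.left_fixed:
            bounds[first.bac_id][0] = min(bounds[first.bac_id][0], covered_min)
        if not last.right_fixed:
            bounds[last.bac_id][1] = max(bounds[last.bac_id][1], covered_max)

        for a, b in zip(active, active[1:]):
            gap = b.expanded.start - a.expanded.end
            if gap <= 0:
                continue
            left_share = gap // 2 + gap % 2
            right_share = gap // 2
            if a.right_frozen and not b.left_frozen:
                left_share, right_share = 0, gap
            elif b.left_frozen and not a.right_frozen:
                left_share, right_share = gap, 0
            elif a.right_frozen and b.left_frozen:
                left_share = right_share = 0
            bounds[a.bac_id][1] += left_share
            bounds[b.bac_id][0] -= right_share

        for b in active:
            s, e = bounds[b.bac_id]
            b.extended = GenomicInterval(b.chrom, s, e)

        by_id = {b.bac_id: b for b in group}
        for b in group:
            if b.duplicate_of is not None:
                container = by_id.get(b.duplicate_of)
                while container is not None and container.duplicate_of is not None:
                    container = by_id.get(container.duplicate_of)
                if container is not None:
                    b.expanded = container.expanded
                    b.extended = container.extended

    return list(bacs)


# ---------------------------------------------------------------------------
# gene-BAC association
# ---------------------------------------------------------------------------

def associate_gene_bac(
    gene: Gene,
    bac_interval: GenomicInterval,
    mode: str = "extended",
) -> bool:
    """Decide whether a gene should be associated with a BAC interval.

    The association is accepted when the two intervals intersect, the BAC
    mapping is at least one third the length of the gene mapping (guards
    against insubstantial overlaps with broad, e.g. cytogenetically
    derived, gene mappings), and — in extended mode, where BACs tile the
    genome — at least 50% of the gene's span lies within the BAC, which
    makes border-region assignment exclusive.
    """
    if mode not in ("expanded", "extended"):
        raise ValidationError(f"unknown association mode {mode!r}")
    if gene.interval.chrom != bac_interval.chrom:
        return False
    if gene.interval.length == 0:
        logger.warning("gene %s has a zero-length mapping; rejected", gene.gene_id)
        return False
    ov = gene.interval.overlap_length(bac_interval)
    if ov == 0:
        return False
    if bac_interval.length * 3 < gene.interval.length:
        return False
    if mode == "extended" and 2 * ov < gene.interval.length:
        return False
    return True


def assign_genes_to_bacs(
    genes: Sequence[Gene],
    bacs: Sequence[BacClone],
    mode: str = "extended",
) -> dict[str, list[str]]:
    """Map each gene to the BAC(s) it associates with.

    In extended mode each gene maps to at most one BAC (the tiling plus
    the 50% rule guarantee exclusivity; residual ties on exactly half the
    gene are broken toward the lower-start BAC). In expanded mode a gene
    may associate with several overlapping BACs.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    coords: dict[str, GenomicInterval] = {}
    for b in bacs:
        if b.duplicate_of is not None:
            continue
        iv = b.extended if mode == "extended" else b.expanded
        if iv is None:
            raise ValidationError(f"BAC {b.bac_id} lacks {mode} coordinates")
        coords[b.bac_id] = iv
        trees[iv.chrom].addi(iv.start, iv.end, b.bac_id)

    out: dict[str, list[str]] = {}
    for g in genes:
        hits = []
        for node in trees[g.interval.chrom].overlap(g.interval.start, g.interval.end):
            iv = coords[node.data]
            if associate_gene_bac(g, iv, mode):
                hits.append((g.interval.overlap_length(iv), -iv.start, node.data))
        if not hits:
            continue
        if mode == "extended":
            hits.sort(reverse=True)
            out[g.gene_id] = [hits[0][2]]
        else:
            out[g.gene_id] = sorted(h[2] for h in hits)
    return out


# ---------------------------------------------------------------------------
# segment overlay -> alteration matrix
# ---------------------------------------------------------------------------

def genes_in_altered_segments(
    segments: Iterable[SegmentCall],
    genes: Sequence[Gene],
    gene_bac_map: Mapping[str, Sequence[str]] | None = None,
    bacs: Sequence[BacClone] | None = None,
    mode: str = "extended",
) -> pd.DataFrame:
    """Overlay per-sample altered segments onto genes.

    Returns the gene x sample alteration matrix with entries +1
    (amplified), -1 (deleted) and 0 (no change). When ``gene_bac_map`` is
    given, each gene is represented by its assigned BAC's interval
    (extended or expanded per ``mode``) rather than its own span —
    mirroring BAC-mediated CGH calls; otherwise genes are overlaid
    directly. A gene hit by both states in one sample takes the state
    with the larger total overlap; exact ties become 0 with a warning.
    """
    seg_list = list(segments)
    samples = sorted({s.sample_id for s in seg_list})
    trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    for s in seg_list:
        trees[(s.sample_id, s.interval.chrom)].addi(
            s.interval.start, s.interval.end, s.state
        )

    bac_coords: dict[str, GenomicInterval] = {}
    if gene_bac_map is not None:
        if bacs is None:
            raise ValidationError("gene_bac_map given but no BACs supplied")
        for b in bacs:
            iv = b.extended if mode == "extended" else b.expanded
            if iv is not None:
                bac_coords[b.bac_id] = iv

    def effective_intervals(g: Gene) -> list[GenomicInterval]:
        if gene_bac_map is None:
            return [g.interval]
        ids = gene_bac_map.get(g.gene_id, [])
        return [bac_coords[i] for i in ids if i in bac_coords]

    mat = np.zeros((len(genes), len(samples)), dtype=np.int8)
    sample_idx = {s: j for j, s in enumerate(samples)}
    for i, g in enumerate(genes):
        ivs = effective_intervals(g)
        for sample in samples:
            amp = dele = 0
            for iv in ivs:
                for node in trees[(sample, iv.chrom)].overlap(iv.start, iv.end):
                    ov = min(node.end, iv.end) - max(node.begin, iv.start)
                    if node.data > 0:
                        amp += ov
                    else:
                        dele += ov
            j = sample_idx[sample]
            if amp > dele:
                mat[i, j] = 1
            elif dele > amp:
                mat[i, j] = -1
            elif amp > 0:  # tie between states
                logger.warning(
                    "gene %s in sample %s hit equally by amplification and "
                    "deletion; recorded as 0",
                    g.gene_id,
                    sample,
                )
    return pd.DataFrame(mat, index=[g.gene_id for g in genes], columns=samples)
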