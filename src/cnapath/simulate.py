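"""Synthetic genomes, pathway collections, CNA cohorts and survival data.

Everything downstream — coordinate reconciliation, the targeting
statistic, the survival screen — is testable on cohorts generated here,
with no external downloads. The generator emulates the structure of a
breast-cancer CGH cohort: a gene universe of a few thousand genes,
pathways of 2-80 genes with overlapping membership, per-sample altered
gene counts that vary around a background rate, optional "driver"
pathways planted with excess alterations in a random subset of samples
(different subjects hitting the same pathway through different genes),
and exponential survival with a hazard ratio between pathway-state
groups. All outputs are deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import BacClone, Gene, GenomicInterval, ValidationError
from .targeting import Pathway

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the standard study size.

    ``planted_pathways`` maps pathway ids to the excess per-gene hit
    probability added (in affected samples) on top of the background.
    """

    seed: int
    G: int = 2000
    n_pathways: int = 100
    pathway_size_range: tuple[int, int] = (2, 80)
    n_samples: int = 100
    background_rate: float = 0.05
    planted_pathways: dict[str, float] = field(default_factory=dict)
    planted_sample_fraction: float = 0.6
    amp_del_ratio: float = 0.5
    hazard_ratio: float = 3.0
    baseline_hazard: float = 0.1
    censor_rate: float = 0.2
    segment_mode: bool = False
    mean_segment_genes: float = 5.0
    # genome/BAC layout
    n_bacs: int = 12
    n_contained_bacs: int = 1
    n_partial_overlap_pairs: int = 1
    genes_per_bac: int = 2
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is mandatory for reproducibility")
        for name in ("background_rate", "amp_del_ratio", "censor_rate",
                     "planted_sample_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.pathway_size_range
        if not 1 <= lo <= hi <= self.G:
            raise ValidationError(f"invalid pathway size range {self.pathway_size_range}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pathway_size_range"] = list(self.pathway_size_range)
        return d


def gene_ids(G: int) -> list[str]:
    width = len(str(G))
    return [f"G{i:0{width}d}" for i in range(1, G + 1)]


def make_pathways(config: SimulationConfig, rng: np.random.Generator | None = None
                  ) -> list[Pathway]:
    """Random pathway collection over the universe; sizes uniform in range.

    Membership is drawn independently per pathway, so gene content
    overlaps between pathways, as in curated collections.
    """
    rng = config.rng() if rng is None else rng
    ids = np.array(gene_ids(config.G))
    lo, hi = config.pathway_size_range
    out = []
    for i in range(config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(config.G, size=size, replace=False)
        out.append(Pathway(f"PW{i + 1:04d}", frozenset(ids[members])))
    for pid in config.planted_pathways:
        if pid not in {p.pathway_id for p in out}:
            raise ValidationError(f"planted pathway {pid} was not generated")
    return out


def make_genome_and_bacs(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[Gene], list[BacClone]]:
    """Toy single-chromosome genome exercising the BAC pathologies.

    Produces well-spaced BACs with mixed anchoring, plus (by default) one
    fully-contained BAC and one partially-overlapping pair, and places
    genes inside each BAC's raw span so extended-mode association covers
    every gene.
    """
    rng = config.rng() if rng is None else rng
    bacs: list[BacClone] = []
    pos = int(rng.integers(50_000, 100_000))
    for i in range(config.n_bacs):
        span = int(rng.integers(30_000, 140_000))
        left = bool(rng.integers(0, 2))
        right = bool(rng.integers(0, 2))
        bacs.append(
            BacClone(
                f"BAC{i + 1:03d}",
                GenomicInterval(config.chrom, pos, pos + span),
                left_anchored=left,
                right_anchored=right,
            )
        )
        pos += span + int(rng.integers(40_000, 220_000))
    # containment pathology: drop a small BAC inside an existing one
    for i in range(config.n_contained_bacs):
        host = bacs[int(rng.integers(0, config.n_bacs))]
        off = int(rng.integers(0, max(1, host.raw.length // 3)))
        span = max(1000, host.raw.length // 3)
        bacs.append(
            BacClone(
                f"BACC{i + 1:02d}",
                GenomicInterval(
                    config.chrom, host.raw.start + off,
                    min(host.raw.end, host.raw.start + off + span),
                ),
            )
        )
    # partial-overlap pathology: a BAC straddling an existing right edge
    for i in range(config.n_partial_overlap_pairs):
        host = bacs[int(rng.integers(0, config.n_bacs - 1))]
        start = host.raw.end - max(1000, host.raw.length // 4)
        bacs.append(
            BacClone(
                f"BACP{i + 1:02d}",
                GenomicInterval(config.chrom, start, start + 40_000),
            )
        )
    genes: list[Gene] = []
    gid = 1
    for b in sorted(bacs, key=lambda b: b.raw.start):
        for _ in range(config.genes_per_bac):
            span = int(rng.integers(2_000, max(3_000, b.raw.length // 2)))
            start = int(rng.integers(b.raw.start, max(b.raw.start + 1, b.raw.end - span)))
            genes.append(
                Gene(f"TG{gid:04d}", GenomicInterval(config.chrom, start, start + span))
            )
            gid += 1
    return genes, bacs


def make_cna_cohort(
    config: SimulationConfig,
    pathways: list[Pathway] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, list[Pathway]]:
    """Gene x sample alteration matrix with optional planted driver pathways.

    Background alterations are gene-wise independent Bernoulli draws at
    ``background_rate`` (or contiguous gene runs in ``segment_mode``,
    emulating CGH segment structure at the same expected rate). Each
    planted pathway receives, in a random ``planted_sample_fraction`` of
    samples, additional hits at its excess probability — so different
    samples target the pathway through different member genes. Signs
    (+1/-1) are assigned per altered gene with P(amp) = ``amp_del_ratio``.
    """
    rng = config.rng() if rng is None else rng
    if pathways is None:
        pathways = make_pathways(config, rng)
    ids = gene_ids(config.G)
    row = {g: i for i, g in enumerate(ids)}
    G, n = config.G, config.n_samples

    if config.segment_mode:
        altered = np.zeros((G, n), dtype=bool)
        mean_len = config.mean_segment_genes
        lam = config.background_rate * G / mean_len  # expected segments/sample
        for j in range(n):
            for _ in range(rng.poisson(lam)):
                length = 1 + rng.geometric(1.0 / mean_len)
                start = int(rng.integers(0, G))
                altered[start : start + length, j] = True
    else:
        altered = rng.random((G, n)) < config.background_rate

    for pid, excess in config.planted_pathways.items():
        if excess <= config.background_rate:
            logger.warning(
                "planted pathway %s excess %.3f <= background %.3f: "
                "planting may be undetectable",
                pid, excess, config.background_rate,
            )
        pw = next(p for p in pathways if p.pathway_id == pid)
        rows = np.array([row[g] for g in sorted(pw.genes)])
        affected = rng.random(n) < config.planted_sample_fraction
        extra = rng.random((rows.size, n)) < excess
        extra[:, ~affected] = False
        altered[rows[:, None], np.arange(n)[None, :]] |= extra

    signs = np.where(rng.random((G, n)) < config.amp_del_ratio, 1, -1).astype(np.int8)
    mat = np.where(altered, signs, 0).astype(np.int8)
    samples = [f"S{j + 1:03d}" for j in range(n)]
    return pd.DataFrame(mat, index=ids, columns=samples), pathways


def make_survival(
    labels,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Exponential survival with hazard ratio between binary groups.

    Event times are exponential with hazard ``baseline_hazard`` in group
    0 and ``baseline_hazard * hazard_ratio`` in group 1; censoring is an
    independent exponential calibrated so each subject is censored with
    probability ``censor_rate``. Returns columns sample_id, time, event,
    group.
    """
    rng = config.rng() if rng is None else rng
    lab = np.asarray(labels, dtype=int)
    if set(np.unique(lab)) - {0, 1}:
        raise ValidationError("labels must be binary 0/1")
    n = lab.size
    haz = config.baseline_hazard * np.where(lab == 1, config.hazard_ratio, 1.0)
    T = rng.exponential(1.0 / haz)
    c = config.censor_rate
    if c >= 1.0:
        time, event = T, np.zeros(n, dtype=int)
    elif c <= 0.0:
        time, event = T, np.ones(n, dtype=int)
    else:
        theta = haz * c / (1.0 - c)
        C = rng.exponential(1.0 / theta)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
    if sample_ids is None:
        sample_ids = [f"S{j + 1:03d}" for j in range(n)]
    return pd.DataFrame(
        {"sample_id": sample_ids, "time": time, "event": event, "group": lab}
    )


def planted_sample_labels(
    matrix: pd.DataFrame, pathway: Pathway, min_hits: int = 1
) -> np.ndarray:
    """Binary label per sample: 1 when the pathway has >= min_hits altered genes."""
    rows = [g for g in pathway.genes if g in matrix.index]
    k = (matrix.loc[rows] != 0).sum(axis=0).to_numpy()
    return (k >= min_hits).astype(int)


def make_score_matrix(
    pathways: list[Pathway],
    labels_by_pathway: dict[str, np.ndarray],
    n_samples: int,
    separation: float = 4.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Bimodal pathway-score matrix: group 1 samples score higher.

    Scores are unit-variance Gaussians whose means differ by
    ``separation`` standard deviations for pathways with labels; pathways
    without labels get pure noise. Used to emulate externally supplied
    activity/consistency metrics.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    samples = [f"S{j + 1:03d}" for j in range(n_samples)]
    rows = {}
    for pw in pathways:
        base = rng.normal(0.0, 1.0, n_samples)
        lab = labels_by_pathway.get(pw.pathway_id)
        if lab is not None:
            base = base + separation * np.asarray(lab, dtype=float)
        rows[pw.pathway_id] = base
    return pd.DataFrame.from_dict(rows, orient="index", columns=samples)
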