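"""Readers and writers for GMT, BED-like and TSV matrix formats.

All tables are UTF-8, tab-separated, Unix line endings; coordinates are
converted to 0-based half-open on ingest (inputs are assumed already in
that convention, the BED standard). p-values are printed in scientific
notation with 6 significant digits.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .intervals import BacClone, Gene, GenomicInterval, SegmentCall, ValidationError
from .targeting import (
    Pathway,
    PathwayTargetingResult,
    per_sample_frame,
    results_to_frame,
)

logger = logging.getLogger(__name__)

PVAL_FMT = "%.6e"


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[Pathway]:
    """Read a GMT file: one pathway per line (id, description, genes...).

    Duplicate genes within a line are de-duplicated with a warning;
    a line with fewer than 3 fields is a format error.
    """
    out: list[Pathway] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            pid, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            uniq = set(genes)
            if len(uniq) < len(genes):
                logger.warning(
                    "%s:%d: pathway %s has %d duplicate gene id(s); de-duplicated",
                    path, lineno, pid, len(genes) - len(uniq),
                )
            out.append(Pathway(pid, frozenset(uniq), description=desc))
    return out


def write_gmt(pathways: Sequence[Pathway], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for p in pathways:
            genes = "\t".join(sorted(p.genes))
            fh.write(f"{p.pathway_id}\t{p.description}\t{genes}\n")


# ---------------------------------------------------------------------------
# BED-like interval files
# ---------------------------------------------------------------------------

def read_genes_bed(path: str | Path) -> list[Gene]:
    """4-column BED-like file: chrom, start, end, gene_id."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValidationError(f"{path}: gene BED needs >= 4 columns")
    genes = [
        Gene(str(r[3]), GenomicInterval(str(r[0]), int(r[1]), int(r[2])))
        for r in df.itertuples(index=False)
    ]
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValidationError(f"{path}: duplicate gene id {g.gene_id}")
        seen.add(g.gene_id)
    return genes


def write_genes_bed(genes: Sequence[Gene], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in genes:
            iv = g.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\n")


def read_bacs_bed(path: str | Path) -> list[BacClone]:
    """BED-like BAC file: chrom, start, end, bac_id, left_anchored, right_anchored."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValidationError(f"{path}: BAC BED needs 6 columns")
    return [
        BacClone(
            str(r[3]),
            GenomicInterval(str(r[0]), int(r[1]), int(r[2])),
            left_anchored=bool(int(r[4])),
            right_anchored=bool(int(r[5])),
        )
        for r in df.itertuples(index=False)
    ]


def write_bacs_bed(bacs: Sequence[BacClone], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for b in bacs:
            iv = b.raw
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{b.bac_id}\t"
                f"{int(b.left_anchored)}\t{int(b.right_anchored)}\n"
            )


def read_segments(path: str | Path) -> list[SegmentCall]:
    """Altered-segment calls: chrom, start, end, state[, sample_id].

    Without a sample column, the file stem is used as the sample id
    (per-sample file layout).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValidationError(f"{path}: segment file needs >= 4 columns")
    default_sample = Path(path).stem
    out = []
    for r in df.itertuples(index=False):
        sample = str(r[4]) if len(r) > 4 else default_sample
        out.append(
            SegmentCall(sample, GenomicInterval(str(r[0]), int(r[1]), int(r[2])), int(r[3]))
        )
    return out


def write_segments(segments: Sequence[SegmentCall], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for s in segments:
            iv = s.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s.state}\t{s.sample_id}\n")


# ---------------------------------------------------------------------------
# alteration matrix
# ---------------------------------------------------------------------------

def read_alteration_matrix(path: str | Path) -> pd.DataFrame:
    """Gene x sample matrix with entries in {-1, 0, 1}.

    First column holds gene ids, header row holds sample ids. Any other
    entry value is rejected with the offending gene and sample named.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"{path}: alteration matrix is empty")
    bad = ~df.isin([-1, 0, 1])
    if bad.to_numpy().any():
        loc = bad.stack()
        gene, sample = loc[loc].index[0]
        raise ValidationError(
            f"{path}: invalid entry {df.loc[gene, sample]!r} at gene {gene}, sample {sample}"
        )
    return df.astype("int8")


def write_alteration_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id", lineterminator="\n")


# ---------------------------------------------------------------------------
# survival and score tables
# ---------------------------------------------------------------------------

def read_survival_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event"}
    if not required <= set(df.columns):
        raise ValidationError(f"{path}: survival table needs columns {sorted(required)}")
    if (df["time"] < 0).any():
        raise ValidationError(f"{path}: negative follow-up time")
    if not df["event"].isin([0, 1]).all():
        raise ValidationError(f"{path}: event indicator must be 0/1")
    return df


def read_score_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    n_missing = int(df.isna().to_numpy().sum())
    if n_missing:
        logger.warning("%s: %d missing score value(s)", path, n_missing)
    return df


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_targeting_report(
    results: Sequence[PathwayTargetingResult], path: str | Path
) -> None:
    df = results_to_frame(results)
    for col in ("omnibus_stat", "p_population", "p_adjusted"):
        df[col] = df[col].map(lambda v: PVAL_FMT % v)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_per_sample_report(
    results: Sequence[PathwayTargetingResult], path: str | Path
) -> None:
    df = per_sample_frame(results)
    df["p"] = df["p"].map(lambda v: PVAL_FMT % v)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_survival_report(report: pd.DataFrame, path: str | Path) -> None:
    df = report.copy()
    for col in ("logrank_stat", "p", "p_adjusted"):
        if col in df:
            df[col] = df[col].map(lambda v: PVAL_FMT % v)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable configuration for the end-to-end pipeline.

    Every analytic choice exposed by the modules appears here with its
    default; a YAML file may override any subset.
    """

    seed: int = 0
    outdir: str = "cnapath_out"
    # inputs (optional: when absent the synthetic generator provides them)
    bacs: str | None = None
    genes: str | None = None
    segments: str | None = None
    matrix: str | None = None
    gmt: str | None = None
    universe: str | None = None
    scores: str | None = None
    clinical: str | None = None
    # analytic choices
    alpha: float = 0.05
    df_mode: str = "two_per_sample"
    tail: str = "inclusive"
    hit_definition: str = "any_alteration"
    coord_mode: str = "extended"
    stratify_method: str = "two_means"
    run_survival: bool = True
    simulate: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
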