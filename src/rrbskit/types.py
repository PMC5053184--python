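"""Shared domain types for the RRBS toolkit.

Coordinates are 0-based half-open everywhere in memory; exported tables use
1-based positions (see :mod:`rrbskit.io`).  A cytosine's ``pos`` is the
position of the C on its own strand, expressed in forward-reference
coordinates (for a minus-strand cytosine this is the position of the G on the
forward strand).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")
REPEAT_CLASSES = ("SINE", "LINE", "LTR", "satellite")

#: column order of the per-cytosine report DataFrame
REPORT_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "context",
    "count_meth",
    "count_unmeth",
    "level",
]


@dataclass(frozen=True)
class Region:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class RepeatRegion:
    region: Region
    family: str  # SINE | LINE | LTR | satellite


@dataclass(frozen=True)
class GeneModel:
    """A collapsed single-transcript gene model.

    ``start``/``end`` delimit the gene body (TSS through last-exon end,
    introns included); exons are disjoint, ordered, half-open sub-intervals.
    """

    name: str
    chrom: str
    strand: str  # '+' or '-'
    start: int
    end: int
    exons: tuple = ()

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for gene {self.name}")
        prev = self.start
        for s, e in self.exons:
            if s < prev or e <= s or e > self.end:
                raise ValueError(f"exons of {self.name} not disjoint/ordered")
            prev = e

    @property
    def tss(self) -> int:
        """Transcription start site (position of the first transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1

    def promoter(self, promoter_bp: int = 1500) -> Region:
        """The ``promoter_bp`` window immediately upstream of the TSS."""
        if self.strand == "+":
            return Region(self.chrom, max(0, self.start - promoter_bp), self.start)
        return Region(self.chrom, self.end, self.end + promoter_bp)


@dataclass
class GenomeAnnotation:
    """Genome sequence plus gene/CGI/repeat annotation and a spike-in contig.

    The spike-in contig is a fully unmethylated conversion control; it carries
    no genes, islands or repeats.
    """

    chromosomes: dict  # name -> uppercase sequence string
    genes: list = field(default_factory=list)  # list[GeneModel]
    cg_islands: list = field(default_factory=list)  # list[Region]
    repeats: list = field(default_factory=list)  # list[RepeatRegion]
    spike_in: Optional[str] = None

    def validate(self) -> None:
        for g in self.genes:
            self._check(Region(g.chrom, g.start, g.end))
        for r in self.cg_islands:
            self._check(r)
        for r in self.repeats:
            self._check(r.region)
        if self.spike_in is not None:
            if self.spike_in not in self.chromosomes:
                raise ValueError(f"spike-in contig {self.spike_in!r} missing")
            for feats, what in (
                (self.genes, "gene"),
                (self.cg_islands, "island"),
            ):
                for f in feats:
                    chrom = f.chrom
                    if chrom == self.spike_in:
                        raise ValueError(f"spike-in contig carries a {what}")
            if any(r.region.chrom == self.spike_in for r in self.repeats):
                raise ValueError("spike-in contig carries a repeat")

    def _check(self, r: Region) -> None:
        if r.chrom not in self.chromosomes:
            raise ValueError(f"unknown chromosome {r.chrom!r}")
        if r.end > len(self.chromosomes[r.chrom]):
            raise ValueError(f"interval {r} beyond chromosome end")

    @property
    def analysis_chroms(self) -> list:
        """Chromosome names excluding the spike-in control."""
        return [c for c in self.chromosomes if c != self.spike_in]


@dataclass(frozen=True)
class Fragment:
    """An MspI restriction fragment on the forward strand."""

    chrom: str
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignmentRecord:
    """A unique three-letter alignment of one read.

    ``strand_class`` is OT (read derives from the bisulfite-converted top
    strand) or OB (bottom strand); ``start`` is the leftmost forward-reference
    coordinate of the aligned window.
    """

    read_id: str
    chrom: str
    start: int
    length: int
    strand_class: str  # 'OT' | 'OB'
    unique: bool = True


@dataclass
class MethylationLandscape:
    """Ground-truth per-cytosine methylation probabilities.

    ``sites`` holds one row per reference cytosine on either strand
    (chrom, pos, strand, context), sorted by (chrom, pos, strand);
    ``base_prob`` the shared truth; ``sample_shifts`` maps a sample id to
    ``(site_indices, probabilities)`` overriding the base truth at
    tissue-effect sites.
    """

    sites: pd.DataFrame
    base_prob: np.ndarray
    sample_shifts: dict = field(default_factory=dict)

    def prob_for(self, sample_id: Optional[str] = None) -> np.ndarray:
        p = self.base_prob.copy()
        if sample_id is not None and sample_id in self.sample_shifts:
            idx, vals = self.sample_shifts[sample_id]
            p[idx] = vals
        return p

    def frame_for(self, sample_id: Optional[str] = None) -> pd.DataFrame:
        df = self.sites.copy()
        df["true_prob"] = self.prob_for(sample_id)
        return df


def empty_report() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "context": pd.Series(dtype=str),
            "count_meth": pd.Series(dtype=np.int64),
            "count_unmeth": pd.Series(dtype=np.int64),
            "level": pd.Series(dtype=float),
        }
    )


def make_report(df: pd.DataFrame) -> pd.DataFrame:
    """Normalise a per-cytosine report: column order, dtypes, sorting, level."""
    df = df.copy()
    total = df["count_meth"] + df["count_unmeth"]
    with np.errstate(invalid="ignore"):
        df["level"] = np.where(total > 0, df["count_meth"] / total, np.nan)
    df = df[REPORT_COLUMNS]
    df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort")
    return df.reset_index(drop=True)


def validate_report(df: pd.DataFrame) -> None:
    if list(df.columns) != REPORT_COLUMNS:
        raise ValueError("report columns malformed")
    if (df["count_meth"] < 0).any() or (df["count_unmeth"] < 0).any():
        raise ValueError("negative counts")
    if not df["context"].isin(CONTEXTS).all():
        raise ValueError("bad context label")
    total = df["count_meth"] + df["count_unmeth"]
    ok = np.isclose(df["level"], df["count_meth"] / total.where(total > 0))
    if not (ok | total.eq(0)).all():
        raise ValueError("level does not equal count ratio")
    if df.duplicated(["chrom", "pos", "strand"]).any():
        raise ValueError("duplicate (chrom, pos, strand) rows")


@dataclass
class MultiSampleMatrix:
    """Site-by-sample methylation levels and coverages (NaN = missing)."""

    sites: pd.DataFrame  # chrom, pos, strand, context
    samples: list
    levels: np.ndarray  # n_sites x n_samples, float, NaN missing
    coverages: np.ndarray  # n_sites x n_samples, float, NaN missing

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def shared_mask(self) -> np.ndarray:
        """Sites observed in every sample ('common shared' sites)."""
        return ~np.isnan(self.levels).any(axis=1)

    def subset(self, mask: np.ndarray) -> "MultiSampleMatrix":
        return MultiSampleMatrix(
            sites=self.sites.loc[mask].reset_index(drop=True),
            samples=list(self.samples),
            levels=self.levels[mask],
            coverages=self.coverages[mask],
        )


@dataclass(frozen=True)
class DMRecord:
    """A differential methylation call between two samples."""

    kind: str  # 'cytosine' | 'island'
    chrom: str
    start: int  # cytosine: pos; island: interval start
    end: int  # cytosine: pos + 1
    strand: str  # '.' for islands
    context: str  # '.' for islands
    sample_a: str
    sample_b: str
    level_a: float
    level_b: float
    p_value: float
    q_value: float
    significant: bool

    @property
    def difference(self) -> float:
        return self.level_a - self.level_b


@dataclass(frozen=True)
class IslandMethylation:
    """Per-sample summary of one CG island."""

    region: Region
    sample: str
    n_detected_cg: int
    mean_level: float
    count_meth: int
    count_unmeth: int


@dataclass
class Profile:
    """A binned methylation profile over flanks and a scaled feature body."""

    bin_labels: list  # e.g. up_00 .. body_00 .. down_00
    mean_level: np.ndarray
    site_count: np.ndarray
    n_flank_bins: int = 0
    n_body_bins: int = 0


@dataclass
class AutocorrelationCurve:
    context_a: str
    context_b: str
    strand_mode: str  # 'same' | 'opposite'
    distances: np.ndarray
    r: np.ndarray
    n_pairs: np.ndarray


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation between one feature's methylation and one gene."""

    feature_id: str
    gene: str
    region_class: str  # 'promoter' | 'gene_body'
    n: int
    r: float
    p_value: float
    q_value: float
    significant: bool
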