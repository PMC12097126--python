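"""Core domain types shared across the pipeline.

Coordinate convention: 0-based, half-open ``[start, end)`` everywhere,
as in BED.  A polyadenylation site (pAS) is a point feature of length 1
whose single base is the cleavage site; the first transcribed base 3' of
it on the transcript strand is the "+1" position.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

# positional pAS classes, 5'->3' on the transcript strand
SPA = "SPA"
PROXIMAL = "APA-proximal"
MIDDLE = "APA-middle"
DISTAL = "APA-distal"
PAS_CLASSES = (SPA, PROXIMAL, MIDDLE, DISTAL)

# UTR segment classes
CUTR = "cUTR"
AUTR = "aUTR"
PROXIMAL_REGION = "proximal-region"
MIDDLE_REGION = "middle-region"
DISTAL_REGION = "distal-region"
SEGMENT_CLASSES = (CUTR, AUTR, PROXIMAL_REGION, MIDDLE_REGION, DISTAL_REGION)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    ``score`` is None when the source column was "."; ``family`` holds the
    optional 7th BED column used for transposable-element family labels.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""
    score: Optional[float] = None
    family: Optional[str] = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def midpoint(self) -> int:
        """Integer midpoint base (floor of the centre coordinate)."""
        return (self.start + self.end - 1) // 2


@dataclass
class PasRecord:
    """One polyadenylation site.

    ``rank_5to3`` is 1 for the most proximal pAS of the gene in transcript
    orientation; ``utr_length`` is the stop-codon-to-pAS distance in nt and
    is filled only when the stop codon is known.
    """

    gene_id: str
    pas_id: str
    interval: GenomicInterval
    rank_5to3: Optional[int] = None
    pas_class: Optional[str] = None
    utr_length: Optional[int] = None

    def __post_init__(self):
        if self.interval.length != 1:
            raise ValueError(
                f"pAS {self.pas_id} of {self.gene_id} is not a point feature "
                f"(length {self.interval.length})"
            )

    @property
    def position(self) -> int:
        """0-based coordinate of the cleavage base."""
        return self.interval.start

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def key(self) -> tuple:
        return (self.gene_id, self.pas_id)


@dataclass(frozen=True)
class SampleMeta:
    """Sample annotation: tissue, ordered developmental stage, replicate."""

    sample_id: str
    tissue: str
    stage: str
    stage_index: int
    replicate: int


@dataclass
class UtrSegment:
    """A cUTR/aUTR or positional 3'-UTR region of one gene."""

    gene_id: str
    segment_class: str
    interval: GenomicInterval

    def __post_init__(self):
        if self.segment_class not in SEGMENT_CLASSES:
            raise ValueError(f"unknown segment class {self.segment_class!r}")

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class PasWindow:
    """Sequence context of one pAS on the transcript strand.

    ``upstream_seq`` covers positions -50..-1, ``downstream_seq`` +1..+50,
    and ``site_base`` is the cleavage base itself (position 0), kept so the
    101-position composition profile has its centre.
    """

    pas_id: str
    gene_id: str
    pas_class: Optional[str]
    upstream_seq: str
    downstream_seq: str
    site_base: str

    @property
    def plus_one(self) -> str:
        return self.downstream_seq[0] if self.downstream_seq else "N"

    @property
    def full_seq(self) -> str:
        """-flank..+flank sequence including the cleavage base."""
        return self.upstream_seq + self.site_base + self.downstream_seq

    def n_fraction(self) -> float:
        s = self.full_seq
        return s.count("N") / len(s) if s else 1.0


@dataclass(eq=False)
class MotifPwm:
    """A position-probability matrix over A,C,G,T with a background model."""

    motif_id: str
    matrix: np.ndarray  # (width, 4), rows sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"PWM {self.motif_id}: matrix must be (width, 4)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.motif_id}: rows must sum to 1 +- 1e-6")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self, pseudocount: float = 1e-3) -> np.ndarray:
        """Log2-odds matrix with a pseudocount applied before the ratio."""
        p = self.matrix + pseudocount
        p = p / p.sum(axis=1, keepdims=True)
        bg = self.background + pseudocount
        bg = bg / bg.sum()
        return np.log2(p / bg)

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))


@dataclass(eq=False)
class Trajectory:
    """Per-gene PPAU time course in one tissue over ordered stages."""

    gene_id: str
    tissue: str
    stage_indices: np.ndarray
    ppau_values: np.ndarray
    z_values: Optional[np.ndarray] = None


@dataclass(eq=False)
class TrajectoryCluster:
    """One cluster of standardized PPAU trajectories."""

    cluster_id: int
    gene_ids: list
    centroid: np.ndarray
    stage_indices: np.ndarray
    centroid_trend: Optional[float] = None  # Spearman rho of centroid vs stage


@dataclass
class EnrichmentResult:
    """Motif enrichment contrast between aUTR and cUTR gene sets."""

    motif_id: str
    autr_hit: int
    autr_miss: int
    cutr_hit: int
    cutr_miss: int
    odds_ratio: float
    p_value: float
    p_bonferroni: float

    @property
    def significant(self) -> bool:
        return self.p_bonferroni <= 1e-3


def interval_sort_key(iv: GenomicInterval) -> tuple:
    return (iv.chrom, iv.start, iv.end)


def as_dataclass_dict(obj) -> dict:
    return dataclasses.asdict(obj)
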