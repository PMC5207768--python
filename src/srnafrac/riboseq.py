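"""Ribosome-footprint feature assignment and protected-boundary detection.

Footprints are assigned to genomic feature categories when at least 80% of
the read length overlaps the category's intervals. Because UTRs are a subset
of exonic space, UTR categories are tested first, then exon, then intron;
reads qualifying for none are intergenic.

On a transcript cleaved by a miRNA, ribosomes occupy only the portion
upstream of the cleavage site; ``protected_boundary`` operationalizes the
resulting coverage step by smoothing per-nucleotide coverage with a centered
moving average and reporting the largest transcript coordinate whose smoothed
coverage is at least a fraction of the smoothed maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .records import AlignmentRecord, AnnotationSet

FEATURE_LABELS = ("exon", "five_prime_UTR", "three_prime_UTR", "intron", "intergenic")

DEFAULT_FOOTPRINT_RANGE = (25, 35)  # nt, typical monosome gel cut


@dataclass
class GeneModel:
    """One transcript: ordered exons with optional CDS/UTR structure."""

    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        self.cds = sorted(self.cds)
        self.utr5 = sorted(self.utr5)
        self.utr3 = sorted(self.utr3)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1]

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def genomic_to_transcript(self, pos: int) -> Optional[int]:
        """Transcript coordinate (0 at the 5' end) of a genomic position, or None if intronic/outside."""
        offset = 0
        for s, e in self.exons:
            if s <= pos < e:
                tpos = offset + (pos - s)
                break
            offset += e - s
        else:
            return None
        return tpos if self.strand == "+" else self.transcript_length - 1 - tpos


def gene_models_from_annotations(annotations: AnnotationSet) -> list[GeneModel]:
    """Assemble GeneModels from gene features and their exon/CDS/UTR children."""
    models = []
    for g in annotations.by_type("gene"):
        kids = annotations.children_of(g.id)
        exons = [(f.start, f.end) for f in kids if f.type == "exon"]
        if not exons:
            exons = [(g.start, g.end)]
        models.append(
            GeneModel(
                transcript_id=g.id,
                chrom=g.chrom,
                strand=g.strand,
                exons=exons,
                cds=[(f.start, f.end) for f in kids if f.type == "CDS"],
                utr5=[(f.start, f.end) for f in kids if f.type == "five_prime_UTR"],
                utr3=[(f.start, f.end) for f in kids if f.type == "three_prime_UTR"],
            )
        )
    return models


def _overlap(read: AlignmentRecord, intervals: Sequence[tuple[int, int]]) -> int:
    return sum(max(0, min(read.end, e) - max(read.start, s)) for s, e in intervals)


def assign_feature(
    read: AlignmentRecord,
    gene_models: Sequence[GeneModel],
    min_overlap_frac: float = 0.8,
) -> str:
    """Feature label for one footprint under the >=80%-of-read-length rule.

    UTR labels win over generic exon only when the read clears the threshold
    within the UTR subinterval itself; the threshold comparison is >=, exact
    at the boundary (17/21 qualifies, 16/21 does not).
    """
    needed = min_overlap_frac * read.length
    best = {"five_prime_UTR": 0, "three_prime_UTR": 0, "exon": 0, "intron": 0}
    for m in gene_models:
        if m.chrom != read.chrom:
            continue
        s, e = m.span
        if read.end <= s or read.start >= e:
            continue
        best["five_prime_UTR"] = max(best["five_prime_UTR"], _overlap(read, m.utr5))
        best["three_prime_UTR"] = max(best["three_prime_UTR"], _overlap(read, m.utr3))
        best["exon"] = max(best["exon"], _overlap(read, m.exons))
        best["intron"] = max(best["intron"], _overlap(read, m.introns))
    for label in ("five_prime_UTR", "three_prime_UTR", "exon", "intron"):
        if best[label] >= needed:
            return label
    return "intergenic"


def feature_composition(
    reads: Iterable[AlignmentRecord],
    gene_models: Sequence[GeneModel],
    min_overlap_frac: float = 0.8,
) -> pd.Series:
    """Copies-weighted fractions of footprints per feature label (sums to 1)."""
    totals = {label: 0 for label in FEATURE_LABELS}
    grand = 0
    for r in reads:
        totals[assign_feature(r, gene_models, min_overlap_frac)] += r.copies
        grand += r.copies
    if grand == 0:
        raise ValueError("feature_composition requires at least one read")
    return pd.Series({k: v / grand for k, v in totals.items()}, name="fraction")


@dataclass(frozen=True)
class BoundaryResult:
    transcript_id: str
    protected_end: int  # transcript coordinate where smoothed coverage collapses
    cleavage_site: int  # transcript coordinate
    threshold_frac: float
    smooth_window: int

    @property
    def offset(self) -> int:
        return self.protected_end - self.cleavage_site


def transcript_coverage(reads: Iterable[AlignmentRecord], model: GeneModel) -> np.ndarray:
    """Per-nucleotide footprint coverage in transcript coordinates (copies-weighted)."""
    cov = np.zeros(model.transcript_length, dtype=float)
    for r in reads:
        if r.chrom != model.chrom:
            continue
        for pos in range(r.start, r.end):
            t = model.genomic_to_transcript(pos)
            if t is not None:
                cov[t] += r.copies
    return cov


def protected_boundary(
    coverage: np.ndarray,
    cleavage_site: int,
    transcript_id: str = "transcript",
    threshold_frac: float = 0.1,
    smooth_window: int = 15,
) -> BoundaryResult:
    """Locate the 3' edge of the ribosome-protected portion of a transcript.

    Coverage is smoothed with a centered moving average of ``smooth_window``
    nt; the protected end is the largest coordinate whose smoothed coverage is
    >= ``threshold_frac`` times the smoothed maximum. On an ideal coverage
    step the recovered end lies within half the smoothing window of the step.
    """
    coverage = np.asarray(coverage, dtype=float)
    if coverage.size == 0 or coverage.max() <= 0:
        raise ValueError("protected_boundary requires nonzero coverage")
    smoothed = uniform_filter1d(coverage, size=smooth_window, mode="nearest")
    cutoff = threshold_frac * smoothed.max()
    above = np.nonzero(smoothed >= cutoff)[0]
    return BoundaryResult(
        transcript_id=transcript_id,
        protected_end=int(above[-1]),
        cleavage_site=cleavage_site,
        threshold_frac=threshold_frac,
        smooth_window=smooth_window,
    )
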