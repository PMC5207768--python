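"""Core in-memory types shared across the pipeline.

All genomic intervals are 0-based, half-open. Conversion from 1-based closed
conventions (GFF3) happens only at I/O boundaries. The biological 5' end of a
minus-strand alignment is its rightmost aligned base.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from intervaltree import IntervalTree

#: feature types carried by AnnotationSet; anything else maps to "other"
FEATURE_TYPES = frozenset(
    {
        "miRNA_mature",
        "TAS",
        "rRNA45S",
        "tRNA",
        "snoRNA",
        "gene",
        "exon",
        "CDS",
        "five_prime_UTR",
        "three_prime_UTR",
        "TE",
        "other",
    }
)

STRUCTURAL_TYPES = frozenset({"rRNA45S", "tRNA", "snoRNA"})


@dataclass(frozen=True, slots=True)
class AlignmentRecord:
    """One collapsed, genome-aligned small-RNA read.

    ``copies`` is the multiplicity of the collapsed read; every counting
    operation in the pipeline sums copies, never records.
    """

    chrom: str
    start: int  # 0-based leftmost aligned position
    length: int  # aligned length in nt
    strand: str  # '+' or '-'
    sequence: Optional[str] = None
    copies: int = 1

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.length < 1:
            raise ValueError(f"length must be >= 1, got {self.length}")
        if self.copies < 1:
            raise ValueError(f"copies must be >= 1, got {self.copies}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError("sequence length does not match record length")

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def five_prime(self) -> int:
        """Genomic position of the biological 5' end."""
        return self.start if self.strand == "+" else self.start + self.length - 1

    @property
    def three_prime(self) -> int:
        """Genomic position of the biological 3' end."""
        return self.start + self.length - 1 if self.strand == "+" else self.start


@dataclass(frozen=True, slots=True)
class Feature:
    """One annotated genomic feature (0-based half-open)."""

    id: str
    type: str
    chrom: str
    start: int
    end: int
    strand: str
    parent: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"feature {self.id}: end ({self.end}) must be > start ({self.start})")
        if self.type not in FEATURE_TYPES:
            raise ValueError(f"feature {self.id}: unknown type {self.type!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class AnnotationSet:
    """Collection of features with per-chromosome interval indexes."""

    def __init__(self, features: Iterable[Feature] = ()):
        self.features: list[Feature] = []
        self._by_id: dict[str, Feature] = {}
        self._by_type: dict[str, list[Feature]] = defaultdict(list)
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for f in features:
            self.add(f)

    def add(self, feature: Feature) -> None:
        if feature.id in self._by_id:
            raise ValueError(f"duplicate feature ID {feature.id!r}")
        self.features.append(feature)
        self._by_id[feature.id] = feature
        self._by_type[feature.type].append(feature)
        self._trees[feature.chrom].addi(feature.start, feature.end, feature)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def get(self, feature_id: str) -> Feature:
        return self._by_id[feature_id]

    def by_type(self, *types: str) -> list[Feature]:
        out: list[Feature] = []
        for t in types:
            out.extend(self._by_type.get(t, []))
        return out

    def overlapping(self, chrom: str, start: int, end: int, types: Optional[Iterable[str]] = None) -> list[Feature]:
        """Features overlapping [start, end) by >= 1 nt, optionally filtered by type."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        if types is not None:
            wanted = set(types)
            hits = [f for f in hits if f.type in wanted]
        return sorted(hits, key=lambda f: (f.start, f.end, f.id))

    def children_of(self, parent_id: str) -> list[Feature]:
        return sorted(
            (f for f in self.features if f.parent == parent_id),
            key=lambda f: (f.start, f.end, f.id),
        )


@dataclass(frozen=True, slots=True)
class Sample:
    sample_id: str
    compartment: str  # T, M, TP, MBP, FP, ER_IP
    genotype: str
    replicate: int
    path: Optional[str] = None


COMPARTMENTS = ("T", "M", "TP", "MBP", "FP", "ER_IP")


@dataclass
class SampleSheet:
    samples: list[Sample] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for s in self.samples:
            if s.compartment not in COMPARTMENTS:
                raise ValueError(f"sample {s.sample_id}: unknown compartment {s.compartment!r}")
            key = (s.compartment, s.genotype, s.replicate)
            if key in seen:
                raise ValueError(f"duplicate (compartment, genotype, replicate): {key}")
            seen.add(key)

    def condition(self, compartment: str, genotype: Optional[str] = None) -> list[Sample]:
        return [
            s
            for s in self.samples
            if s.compartment == compartment and (genotype is None or s.genotype == genotype)
        ]

    def __iter__(self) -> Iterator[Sample]:
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)
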