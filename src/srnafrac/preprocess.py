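"""Adapter trimming, size selection, structural-RNA filtering, and
45S rRNA-fragment counting.

Small-RNA libraries carry 18-41-nt degradation fragments of the 45S rRNA
precursor (5.8S/18S/25S from 80S ribosomes). These are removed from the
analysis set together with tRNA/snoRNA-matching reads, but their summed copy
count is retained per library as the internal control for RPMR normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .records import AlignmentRecord, AnnotationSet, STRUCTURAL_TYPES

DEFAULT_ADAPTERS = ("TGGAATTCT", "AGATCGGAA")


@dataclass
class PreprocessConfig:
    adapters: tuple[str, ...] = DEFAULT_ADAPTERS
    min_len: int = 18
    max_len: int = 42
    rrna_frag_min: int = 18
    rrna_frag_max: int = 41

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if not (self.min_len <= self.rrna_frag_min <= self.rrna_frag_max <= self.max_len):
            raise ValueError("rRNA fragment length range must lie within the read size range")


def trim_adapter(
    sequence: str,
    adapters: Sequence[str] = DEFAULT_ADAPTERS,
    policy: str = "require_adapter",
) -> Optional[str]:
    """Truncate a read at the leftmost exact match of any 3' adapter prefix.

    The full adapter prefix (9-mer by default) must match exactly. Returns the
    insert sequence, or None when no adapter is found (policy
    ``require_adapter``) or the insert is empty. With ``policy='keep_untrimmed'``
    adapter-free reads pass through unchanged.
    """
    if not sequence:
        return None
    if policy not in ("require_adapter", "keep_untrimmed"):
        raise ValueError(f"unknown policy {policy!r}")
    cut = min((i for a in adapters if (i := sequence.find(a)) != -1), default=-1)
    if cut == -1:
        return sequence if policy == "keep_untrimmed" else None
    return sequence[:cut] if cut > 0 else None


def size_select(reads: Iterable, min_len: int = 18, max_len: int = 42) -> list:
    """Keep reads whose length is within [min_len, max_len], inclusive on both ends.

    Accepts either sequences (str) or AlignmentRecords.
    """
    out = []
    for r in reads:
        n = len(r) if isinstance(r, str) else r.length
        if min_len <= n <= max_len:
            out.append(r)
    return out


@dataclass
class StructuralPartition:
    """Reads split by overlap with structural-RNA loci.

    ``rrna45S_fragment_count`` sums the copies of removed reads that map
    within annotated 45S rRNA loci with fragment-sized lengths; it is the raw
    material of the RPMR normalization factor.
    """

    kept: list[AlignmentRecord] = field(default_factory=list)
    removed: list[AlignmentRecord] = field(default_factory=list)
    rrna45S_fragment_count: int = 0

    @property
    def kept_copies(self) -> int:
        return sum(r.copies for r in self.kept)

    @property
    def removed_copies(self) -> int:
        return sum(r.copies for r in self.removed)


def filter_structural(
    reads: Iterable[AlignmentRecord],
    annotations: AnnotationSet,
    config: Optional[PreprocessConfig] = None,
) -> StructuralPartition:
    """Remove reads overlapping rRNA/tRNA/snoRNA loci by >= 1 nt.

    Reads removed by a 45S rRNA locus whose length lies in the configured
    fragment range (default 18-41 nt) accumulate into
    ``rrna45S_fragment_count``. Both partitions are preserved for audit.
    """
    config = config or PreprocessConfig()
    structural = annotations.by_type(*STRUCTURAL_TYPES)
    if not structural:
        raise ValueError(
            "annotations contain no rRNA45S/tRNA/snoRNA features; "
            "structural filtering (and RPMR normalization) is impossible"
        )
    part = StructuralPartition()
    for r in reads:
        hits = annotations.overlapping(r.chrom, r.start, r.end, types=STRUCTURAL_TYPES)
        if hits:
            part.removed.append(r)
            if config.rrna_frag_min <= r.length <= config.rrna_frag_max and any(
                f.type == "rRNA45S" for f in hits
            ):
                part.rrna45S_fragment_count += r.copies
        else:
            part.kept.append(r)
    return part
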