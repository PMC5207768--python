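"""miRNA quantification with 1-nt end tolerance, isomiR origin
classification, and compartment-enrichment ratios.

A read counts toward an annotated mature miRNA when it lies on the same
chromosome and strand and both of its ends are within ``shift_tol`` (default
1 nt) of the annotated ends. End offsets are expressed in RNA orientation:

* ``d5``: read 5' end relative to the annotated 5' end; negative values are
  templated extensions upstream of the annotated end.
* ``d3``: read 3' end relative to the annotated 3' end; positive values are
  extensions downstream.

A read is labeled ``m_{d5}_{d3}``; ``m_0_0`` is the annotated form and
``m_0_1`` the 3'-extended isoform one nucleotide longer (the predominant
route to 22-nt isoforms of 21-nt miRNAs). For every counted read,
``read_length = annotated_length - d5 + d3``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .normalization import NormFactor, PSEUDOCOUNT
from .records import AlignmentRecord, AnnotationSet

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MirnaAnnotation:
    """An annotated mature miRNA locus (0-based half-open genomic interval)."""

    mirna_id: str
    chrom: str
    strand: str
    start: int
    end: int
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if not (19 <= self.end - self.start <= 24):
            raise ValueError(
                f"{self.mirna_id}: annotated length {self.end - self.start} outside 19-24 nt"
            )

    @property
    def annotated_length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


def mirnas_from_annotations(annotations: AnnotationSet, genome: Optional[Mapping[str, str]] = None) -> list[MirnaAnnotation]:
    out = []
    for f in annotations.by_type("miRNA_mature"):
        seq = None
        if genome is not None:
            raw = genome[f.chrom][f.start : f.end]
            seq = raw if f.strand == "+" else _revcomp(raw)
        out.append(
            MirnaAnnotation(
                mirna_id=f.id, chrom=f.chrom, strand=f.strand, start=f.start, end=f.end, sequence=seq
            )
        )
    return sorted(out, key=lambda m: m.mirna_id)


@dataclass(frozen=True)
class IsoformLabel:
    d5: int
    d3: int

    @property
    def label(self) -> str:
        return f"m_{self.d5}_{self.d3}"

    @property
    def category(self) -> str:
        if self.d5 == 0 and self.d3 == 0:
            return "annotated"
        if self.d5 != 0 and self.d3 != 0:
            return "shifted"
        if self.d5 < 0:
            return "5p_extension"
        if self.d5 > 0:
            return "5p_trim"
        return "3p_extension" if self.d3 > 0 else "3p_trim"


def end_offsets(read: AlignmentRecord, mirna: MirnaAnnotation) -> tuple[int, int]:
    """(d5, d3) of a read relative to a mature annotation, in RNA orientation."""
    if mirna.strand == "+":
        d5 = read.five_prime - mirna.five_prime
        d3 = read.three_prime - mirna.three_prime
    else:
        d5 = mirna.five_prime - read.five_prime
        d3 = mirna.three_prime - read.three_prime
    return d5, d3


def classify_isoform(read: AlignmentRecord, mirna: MirnaAnnotation, shift_tol: int = 1) -> IsoformLabel:
    """IsoformLabel for a read already matched to a miRNA by quantify_mirna."""
    d5, d3 = end_offsets(read, mirna)
    if abs(d5) > shift_tol or abs(d3) > shift_tol:
        raise ValueError(
            f"read offsets (d5={d5}, d3={d3}) exceed shift tolerance {shift_tol}; "
            "classify_isoform requires a read counted by quantify_mirna"
        )
    return IsoformLabel(d5, d3)


def quantify_mirna(
    reads: Iterable[AlignmentRecord],
    mirnas: Sequence[MirnaAnnotation],
    shift_tol: int = 1,
    genome: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Count reads against annotated mature miRNAs with end tolerance.

    Returns one row per (mirna_id, d5, d3) with the isoform label, category,
    observed read length, and summed copies. When the read carries a sequence
    and a genome is given, the sequence must match the genome at the aligned
    interval (strand-aware) for the read to count.

    A read within tolerance of several (overlapping) annotations is assigned
    to the one with the smallest |d5| + |d3|; exact ties go to the
    lexicographically first mirna_id and are logged.
    """
    by_loc: dict[tuple[str, str], list[MirnaAnnotation]] = {}
    for m in mirnas:
        by_loc.setdefault((m.chrom, m.strand), []).append(m)
    for v in by_loc.values():
        v.sort(key=lambda m: m.start)
    starts = {k: np.array([m.start for m in v]) for k, v in by_loc.items()}

    acc: dict[tuple[str, int, int, int], int] = {}
    for r in reads:
        cand = by_loc.get((r.chrom, r.strand))
        if not cand:
            continue
        # candidate annotations must start within shift_tol of the read start
        arr = starts[(r.chrom, r.strand)]
        lo = int(np.searchsorted(arr, r.start - shift_tol, side="left"))
        hi = int(np.searchsorted(arr, r.start + shift_tol, side="right"))
        matches: list[tuple[int, str, int, int]] = []
        for m in cand[lo:hi]:
            d5, d3 = end_offsets(r, m)
            if abs(d5) > shift_tol or abs(d3) > shift_tol:
                continue
            if r.sequence is not None and genome is not None:
                ref = genome[r.chrom][r.start : r.end]
                expected = ref if r.strand == "+" else _revcomp(ref)
                if r.sequence != expected:
                    continue
            matches.append((abs(d5) + abs(d3), m.mirna_id, d5, d3))
        if not matches:
            continue
        matches.sort()
        offset, mid, d5, d3 = matches[0]
        ambiguous = [m[1] for m in matches if m[0] == offset]
        if len(ambiguous) > 1:
            logger.warning(
                "read %s:%d len %d matches multiple miRNAs (%s) at equal offset; "
                "counted toward %s",
                r.chrom, r.start, r.length, ",".join(ambiguous), mid,
            )
        k = (mid, d5, d3, r.length)
        acc[k] = acc.get(k, 0) + r.copies

    rows = []
    for (mid, d5, d3, length), copies in sorted(acc.items()):
        lab = IsoformLabel(d5, d3)
        rows.append(
            {
                "mirna_id": mid,
                "d5": d5,
                "d3": d3,
                "label": lab.label,
                "category": lab.category,
                "length": length,
                "raw": copies,
            }
        )
    return pd.DataFrame(
        rows, columns=["mirna_id", "d5", "d3", "label", "category", "length", "raw"]
    )


def mirna_length_table(quant: pd.DataFrame, factor: Optional[NormFactor] = None) -> pd.DataFrame:
    """Per-miRNA, per-observed-length totals (raw and, when a factor is given, RPMR)."""
    if quant.empty:
        return pd.DataFrame(columns=["mirna_id", "length", "raw", "rpmr"])
    g = quant.groupby(["mirna_id", "length"], as_index=False)["raw"].sum()
    if factor is not None:
        g["rpmr"] = g["raw"] / factor.rpmr_divisor
    return g


def isoform_fraction_table(quant: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fractions of observed lengths per miRNA and of isoform categories overall.

    miRNAs with zero counts are omitted. Per-miRNA length fractions sum to 1
    over observed lengths; category fractions sum to 1 over counted reads.
    """
    if quant.empty:
        return (
            pd.DataFrame(columns=["mirna_id", "length", "raw", "fraction"]),
            pd.DataFrame(columns=["category", "raw", "fraction"]),
        )
    lengths = quant.groupby(["mirna_id", "length"], as_index=False)["raw"].sum()
    totals = lengths.groupby("mirna_id")["raw"].transform("sum")
    lengths["fraction"] = lengths["raw"] / totals
    cats = quant.groupby("category", as_index=False)["raw"].sum()
    cats["fraction"] = cats["raw"] / cats["raw"].sum()
    return lengths, cats


def enrichment_ratio(
    counts_num: Mapping[str, float],
    counts_den: Mapping[str, float],
    factor_num: NormFactor,
    factor_den: NormFactor,
    comparison: str = "M/T",
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-feature RPMR enrichment ratios (numerator / denominator library).

    Raw counts are pseudocounted (raw scale) before dividing by each
    library's own RPMR divisor. Features absent from both libraries are
    omitted.
    """
    features = sorted(
        f for f in set(counts_num) | set(counts_den) if counts_num.get(f, 0) or counts_den.get(f, 0)
    )
    rows = []
    for feat in features:
        num = (counts_num.get(feat, 0.0) + pseudocount) / factor_num.rpmr_divisor
        den = (counts_den.get(feat, 0.0) + pseudocount) / factor_den.rpmr_divisor
        rows.append(
            {
                "feature_id": feat,
                "rpmr_numerator": num,
                "rpmr_denominator": den,
                "ratio": num / den,
                "comparison": comparison,
            }
        )
    return pd.DataFrame(rows)
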