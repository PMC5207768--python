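"""Readers and writers for external formats.

Alignments travel either as SAM/BAM (via pysam) or as a 6-column tabular
dialect with columns, in this exact order::

    chrom  start  end  strand  sequence  copies

where start/end are 0-based half-open, strand is '+' or '-', sequence is the
read sequence or '.' when absent, and copies is the collapsed multiplicity.

GFF3 is read with gffutils; its 1-based closed intervals are converted to the
internal 0-based half-open convention on the way in.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd

from .records import AlignmentRecord, AnnotationSet, Feature, Sample, SampleSheet

logger = logging.getLogger(__name__)

TABULAR_COLUMNS = ("chrom", "start", "end", "strand", "sequence", "copies")

#: GFF3 feature-type column -> internal type
GFF_TYPE_MAP = {
    "miRNA": "miRNA_mature",
    "miRNA_mature": "miRNA_mature",
    "TAS": "TAS",
    "TAS_locus": "TAS",
    "rRNA_45S": "rRNA45S",
    "rRNA45S": "rRNA45S",
    "tRNA": "tRNA",
    "snoRNA": "snoRNA",
    "gene": "gene",
    "exon": "exon",
    "CDS": "CDS",
    "five_prime_UTR": "five_prime_UTR",
    "three_prime_UTR": "three_prime_UTR",
    "transposable_element": "TE",
    "TE": "TE",
}


def _in_region(rec: AlignmentRecord, region: tuple[str, int, int]) -> bool:
    chrom, start, end = region
    return rec.chrom == chrom and rec.start < end and rec.end > start


def read_alignments(
    path: str | Path,
    region_filter: Optional[tuple[str, int, int]] = None,
) -> Iterator[AlignmentRecord]:
    """Stream alignment records from a tabular or SAM/BAM file.

    ``region_filter`` is an optional (chrom, start, end) interval (0-based
    half-open); only records overlapping it are yielded. Unmapped and
    secondary/supplementary SAM records are excluded.
    """
    path = Path(path)
    if path.suffix.lower() in (".sam", ".bam", ".cram"):
        yield from _read_sam(path, region_filter)
    else:
        yield from _read_tabular(path, region_filter)


def _read_tabular(path: Path, region_filter) -> Iterator[AlignmentRecord]:
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 tab-separated columns, got {len(parts)}")
            chrom, start_s, end_s, strand, seq, copies_s = parts
            try:
                start, end, copies = int(start_s), int(end_s), int(copies_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate or copies field") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end ({end}) must be > start ({start})")
            rec = AlignmentRecord(
                chrom=chrom,
                start=start,
                length=end - start,
                strand=strand,
                sequence=None if seq in (".", "") else seq,
                copies=copies,
            )
            if region_filter is None or _in_region(rec, region_filter):
                n += 1
                yield rec
    if n == 0:
        warnings.warn(f"no alignment records read from {path}", stacklevel=2)


def _read_sam(path: Path, region_filter) -> Iterator[AlignmentRecord]:
    import pysam

    mode = "rb" if path.suffix.lower() in (".bam", ".cram") else "r"
    with pysam.AlignmentFile(str(path), mode) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            copies = 1
            if aln.has_tag("XC"):
                copies = int(aln.get_tag("XC"))
            elif aln.query_name and "_x" in aln.query_name:
                # collapsed-read convention: ">id_xCOPIES"
                tail = aln.query_name.rsplit("_x", 1)[1]
                if tail.isdigit():
                    copies = int(tail)
            rec = AlignmentRecord(
                chrom=aln.reference_name,
                start=aln.reference_start,
                length=aln.reference_end - aln.reference_start,
                strand="-" if aln.is_reverse else "+",
                sequence=aln.query_sequence,
                copies=copies,
            )
            if region_filter is None or _in_region(rec, region_filter):
                yield rec


def write_alignments(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    """Write records in the 6-column tabular dialect."""
    with open(path, "w") as fh:
        for r in records:
            seq = r.sequence if r.sequence is not None else "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.strand}\t{seq}\t{r.copies}\n")


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read a GFF3 file into an AnnotationSet.

    1-based closed GFF intervals become 0-based half-open; feature types not
    in the internal vocabulary map to "other". Features must carry an ID
    attribute; duplicate IDs are an error.
    """
    import gffutils
    from gffutils.exceptions import EmptyInputError

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="error",
            keep_order=True,
            id_spec="ID",
        )
    except EmptyInputError:
        warnings.warn(f"no features in {path}; returning an empty annotation set", stacklevel=2)
        return AnnotationSet()
    annots = AnnotationSet()
    for f in db.all_features():
        if "ID" not in f.attributes:
            raise ValueError(f"GFF3 feature at {f.seqid}:{f.start}-{f.end} lacks an ID attribute")
        ftype = GFF_TYPE_MAP.get(f.featuretype, "other")
        parent = f.attributes.get("Parent", [None])[0]
        annots.add(
            Feature(
                id=f.attributes["ID"][0],
                type=ftype,
                chrom=f.seqid,
                start=f.start - 1,  # GFF3 1-based closed -> 0-based half-open
                end=f.end,
                strand=f.strand if f.strand in ("+", "-") else "+",
                parent=parent,
            )
        )
    return annots


def write_annotations(annots: AnnotationSet, path: str | Path, source: str = "srnafrac") -> None:
    """Write an AnnotationSet as GFF3 (internal 0-based half-open -> 1-based closed)."""
    inverse = {}
    for gff_type, internal in GFF_TYPE_MAP.items():
        inverse.setdefault(internal, gff_type)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in sorted(annots, key=lambda x: (x.chrom, x.start, x.end, x.id)):
            gff_type = inverse.get(f.type, f.type)
            attrs = f"ID={f.id}"
            if f.parent:
                attrs += f";Parent={f.parent}"
            fh.write(
                f"{f.chrom}\t{source}\t{gff_type}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


def read_genome(path: str | Path) -> dict[str, str]:
    """Load a FASTA genome into a dict of chrom -> uppercase sequence."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_genome(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a sample sheet TSV: sample_id, compartment, genotype, replicate, path."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "compartment", "genotype", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    samples = [
        Sample(
            sample_id=row.sample_id,
            compartment=row.compartment,
            genotype=row.genotype,
            replicate=int(row.replicate),
            path=getattr(row, "path", None),
        )
        for row in df.itertuples()
    ]
    return SampleSheet(samples)


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    params: Optional[Mapping[str, object]] = None,
    index: bool = False,
) -> None:
    """Write a TSV with a '#'-prefixed header block recording parameters and version."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# srnafrac {__version__}\n")
        for key, val in (params or {}).items():
            fh.write(f"# {key} = {val}\n")
        df.to_csv(fh, sep="\t", index=index)


def write_bedgraph(
    path: str | Path,
    chrom: str,
    positions: Sequence[int],
    scores: Sequence[float],
    track_name: str = "phasing_score",
) -> None:
    """Write single-nucleotide scores as bedGraph (absent scores are skipped)."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track_name}"\n')
        for pos, score in zip(positions, scores):
            if score is None or score != score:  # skip NaN / undefined
                continue
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{score:.6g}\n")
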