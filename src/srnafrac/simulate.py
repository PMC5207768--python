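"""Synthetic reference, ground truth, and library simulation.

Generates a toy two-chromosome genome with the locus classes the analysis
assumes — mature miRNA sites (with 21/22-nt isoform mixtures), TAS-like loci
producing phased 21-nt duplexes downstream of a cleavage site, dispersed
24-nt P4siRNA windows, a 45S rRNA locus shedding 18-41-nt fragments, tRNA and
snoRNA loci, and protein-coding gene models — plus compartment-specific
small-RNA and ribosome-footprint libraries with known ground truth.

Library composition follows absolute per-class weights scaled by a
per-compartment enrichment map; sequencing then samples a fixed read depth
multinomially, which is what makes total-read normalization misleading and
the rRNA-fragment internal control informative. P4siRNA window counts are
negative-binomially overdispersed (gamma-Poisson) around their expectations;
miRNA/TAS locus counts and the rRNA-fragment count are multinomial shares,
reflecting the premise that ribosome (rRNA fragment) content is stable across
fractions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

from .mirna import MirnaAnnotation
from .phasing import TasLocus
from .records import AlignmentRecord, AnnotationSet, Feature
from .riboseq import GeneModel

BASES = np.array(list("ACGT"))

DEFAULT_ISOFORM_PROBS = {
    "annotated": 0.86,
    "3p_extension": 0.10,
    "5p_extension": 0.01,
    "5p_trim": 0.01,
    "3p_trim": 0.01,
    "shifted": 0.01,
}

#: representative end offsets per isoform category
CATEGORY_OFFSETS = {
    "annotated": (0, 0),
    "3p_extension": (0, 1),
    "5p_extension": (-1, 0),
    "5p_trim": (1, 0),
    "3p_trim": (0, -1),
    "shifted": (-1, 1),
}

DEFAULT_CLASS_WEIGHTS = {
    "mirna": 0.25,
    "tasirna": 0.05,
    "p4sirna": 0.45,
    "rrna": 0.20,
    "background": 0.05,
}

#: multiplicative per-class abundance factors by compartment (relative to T)
DEFAULT_ENRICHMENT = {
    "mirna": {"T": 1.0, "M": 3.0, "TP": 1.0, "MBP": 3.0, "FP": 0.5, "ER_IP": 3.0},
    "tasirna": {"T": 1.0, "M": 3.0, "TP": 1.0, "MBP": 3.0, "FP": 0.5, "ER_IP": 3.0},
    "p4sirna": {"T": 1.0, "M": 0.1, "TP": 1.0, "MBP": 0.1, "FP": 1.0, "ER_IP": 0.1},
    "rrna": {},
    "background": {},
}


@dataclass
class SyntheticConfig:
    n_chroms: int = 2
    chrom_length: int = 200_000
    n_mir: int = 30
    mir_length: int = 21
    isoform_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ISOFORM_PROBS))
    n_tas: int = 6
    tas_locus_length: int = 600
    tas_cleavage_offset: int = 150
    tas_phased_fraction: float = 0.8
    tas_phase_cycles: int = 10
    n_p4_windows: int = 200
    p4_window_width: int = 100
    p4_read_length: int = 24
    n_genes: int = 20
    rrna_length: int = 8000
    n_trna: int = 5
    n_snorna: int = 5
    class_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS))
    enrichment: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ENRICHMENT.items()}
    )
    dispersion: float = 0.1  # NB overdispersion of per-window counts
    rrna_frag_range: tuple[int, int] = (18, 41)
    background_length_range: tuple[int, int] = (20, 26)
    riboseq_leakage: float = 0.02
    footprint_range: tuple[int, int] = (25, 35)

    def __post_init__(self) -> None:
        for p in self.isoform_probs.values():
            if not 0 <= p <= 1:
                raise ValueError("isoform probabilities must be in [0, 1]")
        if not 0 <= self.tas_phased_fraction <= 1:
            raise ValueError("phased fraction must be in [0, 1]")
        if any(w < 0 for w in self.class_weights.values()):
            raise ValueError("class weights must be >= 0")


@dataclass
class MirTruth:
    mirna_id: str
    chrom: str
    strand: str
    start: int
    end: int
    weight: float
    isoform_probs: dict[str, float]


@dataclass
class TasTruth:
    locus_id: str
    chrom: str
    strand: str
    start: int
    end: int
    cleavage_site: int
    phased_fraction: float
    cycles: int
    weight: float


@dataclass
class P4Truth:
    window_id: str
    chrom: str
    start: int
    end: int
    weight: float


@dataclass
class GeneTruth:
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    utr5: list[tuple[int, int]]
    utr3: list[tuple[int, int]]


@dataclass
class TruthManifest:
    """Everything needed to compute expected pipeline outputs in closed form."""

    seed: int
    chrom_sizes: dict[str, int]
    rrna_locus: tuple[str, int, int]
    trna_loci: list[tuple[str, int, int]]
    snorna_loci: list[tuple[str, int, int]]
    mir: list[MirTruth]
    tas: list[TasTruth]
    p4: list[P4Truth]
    genes: list[GeneTruth]
    class_weights: dict[str, float]
    enrichment: dict[str, dict[str, float]]
    dispersion: float
    rrna_frag_range: tuple[int, int]
    background_length_range: tuple[int, int]
    riboseq_leakage: float
    footprint_range: tuple[int, int]

    def annotations(self) -> AnnotationSet:
        annots = AnnotationSet()
        chrom, s, e = self.rrna_locus
        annots.add(Feature(id="rRNA45S_1", type="rRNA45S", chrom=chrom, start=s, end=e, strand="+"))
        for i, (c, s, e) in enumerate(self.trna_loci, 1):
            annots.add(Feature(id=f"tRNA_{i}", type="tRNA", chrom=c, start=s, end=e, strand="+"))
        for i, (c, s, e) in enumerate(self.snorna_loci, 1):
            annots.add(Feature(id=f"snoRNA_{i}", type="snoRNA", chrom=c, start=s, end=e, strand="+"))
        for m in self.mir:
            annots.add(
                Feature(id=m.mirna_id, type="miRNA_mature", chrom=m.chrom, start=m.start, end=m.end, strand=m.strand)
            )
        for t in self.tas:
            annots.add(
                Feature(id=t.locus_id, type="TAS", chrom=t.chrom, start=t.start, end=t.end, strand=t.strand)
            )
        for g in self.genes:
            span = (min(s for s, _ in g.exons), max(e for _, e in g.exons))
            annots.add(Feature(id=g.gene_id, type="gene", chrom=g.chrom, start=span[0], end=span[1], strand=g.strand))
            for j, (s, e) in enumerate(g.exons, 1):
                annots.add(Feature(id=f"{g.gene_id}.exon{j}", type="exon", chrom=g.chrom, start=s, end=e, strand=g.strand, parent=g.gene_id))
            for j, (s, e) in enumerate(g.cds, 1):
                annots.add(Feature(id=f"{g.gene_id}.cds{j}", type="CDS", chrom=g.chrom, start=s, end=e, strand=g.strand, parent=g.gene_id))
            for j, (s, e) in enumerate(g.utr5, 1):
                annots.add(Feature(id=f"{g.gene_id}.utr5_{j}", type="five_prime_UTR", chrom=g.chrom, start=s, end=e, strand=g.strand, parent=g.gene_id))
            for j, (s, e) in enumerate(g.utr3, 1):
                annots.add(Feature(id=f"{g.gene_id}.utr3_{j}", type="three_prime_UTR", chrom=g.chrom, start=s, end=e, strand=g.strand, parent=g.gene_id))
        return annots

    def tas_loci(self) -> list[TasLocus]:
        return [
            TasLocus(
                locus_id=t.locus_id, chrom=t.chrom, start=t.start, end=t.end,
                strand=t.strand, cleavage_site=t.cleavage_site,
            )
            for t in self.tas
        ]

    def gene_models(self) -> list[GeneModel]:
        return [
            GeneModel(
                transcript_id=g.gene_id, chrom=g.chrom, strand=g.strand,
                exons=[tuple(x) for x in g.exons], cds=[tuple(x) for x in g.cds],
                utr5=[tuple(x) for x in g.utr5], utr3=[tuple(x) for x in g.utr3],
            )
            for g in self.genes
        ]

    def mirna_annotations(self, genome: Optional[Mapping[str, str]] = None) -> list[MirnaAnnotation]:
        from .mirna import mirnas_from_annotations

        out = []
        for m in self.mir:
            seq = None
            if genome is not None:
                raw = genome[m.chrom][m.start : m.end]
                seq = raw if m.strand == "+" else raw[::-1].translate(str.maketrans("ACGT", "TGCA"))
            out.append(
                MirnaAnnotation(mirna_id=m.mirna_id, chrom=m.chrom, strand=m.strand, start=m.start, end=m.end, sequence=seq)
            )
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        d["mir"] = [MirTruth(**m) for m in d["mir"]]
        d["tas"] = [TasTruth(**t) for t in d["tas"]]
        d["p4"] = [P4Truth(**p) for p in d["p4"]]
        d["genes"] = [
            GeneTruth(
                gene_id=g["gene_id"], chrom=g["chrom"], strand=g["strand"],
                exons=[tuple(x) for x in g["exons"]], cds=[tuple(x) for x in g["cds"]],
                utr5=[tuple(x) for x in g["utr5"]], utr3=[tuple(x) for x in g["utr3"]],
            )
            for g in d["genes"]
        ]
        d["rrna_locus"] = tuple(d["rrna_locus"])
        d["trna_loci"] = [tuple(x) for x in d["trna_loci"]]
        d["snorna_loci"] = [tuple(x) for x in d["snorna_loci"]]
        d["rrna_frag_range"] = tuple(d["rrna_frag_range"])
        d["background_length_range"] = tuple(d["background_length_range"])
        d["footprint_range"] = tuple(d["footprint_range"])
        return cls(**d)


def _random_genome(rng: np.random.Generator, chrom_sizes: Mapping[str, int]) -> dict[str, str]:
    return {c: "".join(BASES[rng.integers(0, 4, size=n)]) for c, n in chrom_sizes.items()}


def generate_reference(
    config: Optional[SyntheticConfig] = None, seed: int = 0
) -> tuple[dict[str, str], AnnotationSet, TruthManifest]:
    """Deterministic toy genome, annotations, and ground truth for one seed."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    chrom_sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    chroms = list(chrom_sizes)
    genome = _random_genome(rng, chrom_sizes)

    cursors = {c: 1000 for c in chroms}

    def place(chrom: str, length: int, grid: Optional[int] = None) -> int:
        gap = int(rng.integers(150, 400))
        start = cursors[chrom] + gap
        if grid:
            start = ((start + grid - 1) // grid) * grid
        if start + length > chrom_sizes[chrom] - 500:
            raise ValueError(f"synthetic loci do not fit on {chrom} (need {start + length})")
        cursors[chrom] = start + length
        return start

    # 45S rRNA precursor plus a few tRNA/snoRNA loci, all on chr1
    rrna_start = place(chroms[0], config.rrna_length)
    rrna_locus = (chroms[0], rrna_start, rrna_start + config.rrna_length)
    trna_loci = [(chroms[0], s, s + 80) for s in (place(chroms[0], 80) for _ in range(config.n_trna))]
    snorna_loci = [(chroms[0], s, s + 150) for s in (place(chroms[0], 150) for _ in range(config.n_snorna))]

    mir_w = rng.lognormal(0.0, 0.5, config.n_mir)
    mir_w /= mir_w.sum()
    mir = []
    for i in range(config.n_mir):
        chrom = chroms[i % len(chroms)]
        start = place(chrom, config.mir_length)
        mir.append(
            MirTruth(
                mirna_id=f"miR{i + 1:03d}", chrom=chrom, strand="+" if i % 2 == 0 else "-",
                start=start, end=start + config.mir_length, weight=float(mir_w[i]),
                isoform_probs=dict(config.isoform_probs),
            )
        )

    tas_w = rng.lognormal(0.0, 0.5, config.n_tas)
    tas_w /= tas_w.sum()
    tas = []
    for i in range(config.n_tas):
        chrom = chroms[i % len(chroms)]
        start = place(chrom, config.tas_locus_length)
        tas.append(
            TasTruth(
                locus_id=f"TAS{i + 1}", chrom=chrom, strand="+",
                start=start, end=start + config.tas_locus_length,
                cleavage_site=start + config.tas_cleavage_offset,
                phased_fraction=config.tas_phased_fraction,
                cycles=config.tas_phase_cycles, weight=float(tas_w[i]),
            )
        )

    p4_w = rng.lognormal(0.0, 0.5, config.n_p4_windows)
    p4_w /= p4_w.sum()
    p4 = []
    for i in range(config.n_p4_windows):
        chrom = chroms[i % len(chroms)]
        start = place(chrom, config.p4_window_width, grid=config.p4_window_width)
        p4.append(
            P4Truth(
                window_id=f"P4W{i + 1:03d}", chrom=chrom, start=start,
                end=start + config.p4_window_width, weight=float(p4_w[i]),
            )
        )

    genes = []
    for i in range(config.n_genes):
        chrom = chroms[i % len(chroms)]
        strand = "+" if i % 2 == 0 else "-"
        # 3 exons; UTRs at the transcript ends, CDS in between
        e1 = place(chrom, 1140)
        exons = [(e1, e1 + 300), (e1 + 420, e1 + 720), (e1 + 840, e1 + 1140)]
        if strand == "+":
            utr5 = [(e1, e1 + 100)]
            cds = [(e1 + 100, e1 + 300), (e1 + 420, e1 + 720), (e1 + 840, e1 + 990)]
            utr3 = [(e1 + 990, e1 + 1140)]
        else:
            utr3 = [(e1, e1 + 150)]
            cds = [(e1 + 150, e1 + 300), (e1 + 420, e1 + 720), (e1 + 840, e1 + 1040)]
            utr5 = [(e1 + 1040, e1 + 1140)]
        genes.append(GeneTruth(gene_id=f"gene{i + 1:02d}", chrom=chrom, strand=strand, exons=exons, cds=cds, utr5=utr5, utr3=utr3))

    truth = TruthManifest(
        seed=seed, chrom_sizes=chrom_sizes, rrna_locus=rrna_locus,
        trna_loci=trna_loci, snorna_loci=snorna_loci,
        mir=mir, tas=tas, p4=p4, genes=genes,
        class_weights=dict(config.class_weights),
        enrichment={k: dict(v) for k, v in config.enrichment.items()},
        dispersion=config.dispersion,
        rrna_frag_range=tuple(config.rrna_frag_range),
        background_length_range=tuple(config.background_length_range),
        riboseq_leakage=config.riboseq_leakage,
        footprint_range=tuple(config.footprint_range),
    )
    return genome, truth.annotations(), truth


def _collapse(raw: Iterable[tuple[str, int, int, str]]) -> list[AlignmentRecord]:
    acc: dict[tuple[str, int, int, str], int] = {}
    for key in raw:
        acc[key] = acc.get(key, 0) + 1
    return [
        AlignmentRecord(chrom=c, start=s, length=n, strand=st, copies=copies)
        for (c, s, n, st), copies in sorted(acc.items())
    ]


def simulate_mirna_reads(mir: list[MirTruth], n: int, rng: np.random.Generator) -> list[tuple[str, int, int, str]]:
    """Raw (chrom, start, length, strand) tuples for n miRNA-class reads."""
    if not mir or n == 0:
        return []
    out = []
    weights = np.array([m.weight for m in mir])
    per_locus = rng.multinomial(n, weights / weights.sum())
    for m, c in zip(mir, per_locus):
        if c == 0:
            continue
        cats = list(m.isoform_probs)
        probs = np.array([m.isoform_probs[k] for k in cats], dtype=float)
        counts = rng.multinomial(c, probs / probs.sum())
        for cat, k in zip(cats, counts):
            if k == 0:
                continue
            d5, d3 = CATEGORY_OFFSETS[cat]
            if m.strand == "+":
                start, end = m.start + d5, m.end + d3
            else:
                start, end = m.start - d3, m.end - d5
            out.extend([(m.chrom, start, end - start, m.strand)] * int(k))
    return out


def simulate_tas_reads(
    t: TasTruth,
    n: int,
    rng: np.random.Generator,
    phased_fraction: Optional[float] = None,
    cycle: int = 21,
    overhang: int = 2,
) -> list[tuple[str, int, int, str]]:
    """Raw read tuples for one TAS locus: phased duplex reads plus uniform noise.

    Phased reads sit on the 21-nt register downstream of the cleavage site;
    minus-strand reads are emitted as the 2-nt-3'-overhang duplex partners of
    plus-strand positions. The remaining (1 - phased_fraction) reads start
    uniformly within the locus on either strand.
    """
    phi = t.phased_fraction if phased_fraction is None else phased_fraction
    out = []
    n_phased = int(rng.binomial(n, phi))
    ks = rng.integers(0, t.cycles, n_phased)
    minus = rng.random(n_phased) < 0.5
    for k, mn in zip(ks, minus):
        p = t.cleavage_site + cycle * int(k)
        if mn:
            out.append((t.chrom, p - overhang, cycle, "-"))
        else:
            out.append((t.chrom, p, cycle, "+"))
    n_noise = n - n_phased
    starts = rng.integers(t.start, t.end - cycle, n_noise)
    minus = rng.random(n_noise) < 0.5
    for s, mn in zip(starts, minus):
        out.append((t.chrom, int(s), cycle, "-" if mn else "+"))
    return out


def simulate_window_counts(
    means: np.ndarray,
    dispersion: float,
    n_reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(windows x reps) NB counts with the configured gamma-Poisson law."""
    means = np.asarray(means, dtype=float)
    if dispersion <= 0:
        return rng.poisson(means[:, None], size=(len(means), n_reps))
    r = 1.0 / dispersion
    p = r / (r + means)
    return rng.negative_binomial(r, p[:, None], size=(len(means), n_reps))


def simulate_srna_library(
    truth: TruthManifest,
    compartment: str,
    depth: int,
    seed: int,
    class_factors: Optional[Mapping[str, float]] = None,
    genome: Optional[Mapping[str, str]] = None,
) -> list[AlignmentRecord]:
    """One collapsed small-RNA library for a compartment at nominal depth.

    ``class_factors`` multiplies the per-class abundance on top of the
    compartment enrichment map (e.g. ``{"p4sirna": 0.05}`` emulates a Pol IV
    mutant). When ``genome`` is given, records carry genome-matching
    sequences.
    """
    rng = np.random.default_rng(seed)
    classes = list(truth.class_weights)
    w = np.array(
        [
            truth.class_weights[c]
            * truth.enrichment.get(c, {}).get(compartment, 1.0)
            * (class_factors or {}).get(c, 1.0)
            for c in classes
        ]
    )
    if depth == 0:
        return []
    n_class = dict(zip(classes, rng.multinomial(depth, w / w.sum())))

    raw: list[tuple[str, int, int, str]] = []
    raw.extend(simulate_mirna_reads(truth.mir, n_class.get("mirna", 0), rng))

    n_tas_total = n_class.get("tasirna", 0)
    tas_w = np.array([t.weight for t in truth.tas])
    if n_tas_total and len(truth.tas):
        for t, c in zip(truth.tas, rng.multinomial(n_tas_total, tas_w / tas_w.sum())):
            raw.extend(simulate_tas_reads(t, int(c), rng))

    n_p4_total = n_class.get("p4sirna", 0)
    if n_p4_total and len(truth.p4):
        p4_w = np.array([p.weight for p in truth.p4])
        expected = n_p4_total * p4_w / p4_w.sum()
        counts = simulate_window_counts(expected, truth.dispersion, 1, rng)[:, 0]
        L = 24
        for p, c in zip(truth.p4, counts):
            if c == 0:
                continue
            fives = rng.integers(p.start, p.end, int(c))
            minus = rng.random(int(c)) < 0.5
            for f, mn in zip(fives, minus):
                start = int(f) - (L - 1) if mn else int(f)
                raw.append((p.chrom, start, L, "-" if mn else "+"))

    n_rrna = n_class.get("rrna", 0)
    if n_rrna:
        chrom, rs, re_ = truth.rrna_locus
        lo, hi = truth.rrna_frag_range
        lens = rng.integers(lo, hi + 1, n_rrna)
        for ln in lens:
            start = int(rng.integers(rs, re_ - int(ln)))
            raw.append((chrom, start, int(ln), "+"))

    n_bg = n_class.get("background", 0)
    if n_bg:
        chroms = list(truth.chrom_sizes)
        lo, hi = truth.background_length_range
        for _ in range(n_bg):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            ln = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, truth.chrom_sizes[chrom] - ln))
            raw.append((chrom, start, ln, "-" if rng.random() < 0.5 else "+"))

    records = _collapse(raw)
    if genome is not None:
        comp = str.maketrans("ACGTN", "TGCAN")
        records = [
            dataclasses.replace(
                r,
                sequence=(
                    genome[r.chrom][r.start : r.end]
                    if r.strand == "+"
                    else genome[r.chrom][r.start : r.end].translate(comp)[::-1]
                ),
            )
            for r in records
        ]
    return records


def simulate_riboseq(
    truth: TruthManifest,
    depth: int,
    seed: int,
    leakage: Optional[float] = None,
) -> list[AlignmentRecord]:
    """Ribosome footprints over gene CDS and TAS upstream ORFs.

    Footprints (25-35 nt) fall uniformly within CDS intervals of genes and
    within the short ORF ending at the cleavage site of TAS-like transcripts;
    with probability ``leakage`` a footprint instead falls uniformly anywhere
    in the transcript span.
    """
    rng = np.random.default_rng(seed)
    leak = truth.riboseq_leakage if leakage is None else leakage
    lo, hi = truth.footprint_range
    targets = [("gene", g) for g in truth.genes] + [("tas", t) for t in truth.tas]
    if not targets or depth == 0:
        return []
    per_target = rng.multinomial(depth, np.full(len(targets), 1.0 / len(targets)))
    raw: list[tuple[str, int, int, str]] = []
    for (kind, obj), c in zip(targets, per_target):
        for _ in range(int(c)):
            ln = int(rng.integers(lo, hi + 1))
            if kind == "gene":
                strand = obj.strand
                chrom = obj.chrom
                span = (min(s for s, _ in obj.exons), max(e for _, e in obj.exons))
                if rng.random() < leak:
                    start = int(rng.integers(span[0], span[1] - ln))
                else:
                    widths = np.array([max(e - s - ln, 1) for s, e in obj.cds], dtype=float)
                    i = int(rng.choice(len(obj.cds), p=widths / widths.sum()))
                    s, e = obj.cds[i]
                    start = int(rng.integers(s, max(e - ln, s + 1)))
            else:
                strand = obj.strand
                chrom = obj.chrom
                if rng.random() < leak:
                    start = int(rng.integers(obj.start, obj.end - ln))
                else:
                    orf_start = obj.start + 30
                    start = int(rng.integers(orf_start, obj.cleavage_site - ln))
            raw.append((chrom, start, ln, strand))
    return _collapse(raw)
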