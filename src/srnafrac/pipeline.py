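"""End-to-end pipeline driver on synthetic or user-supplied inputs.

``run_pipeline`` wires the stages together: reference/library simulation (or
loading), structural filtering and RPMR factors, window counting and DSR
calling, miRNA quantification and isoform classification, phasing analysis of
TAS loci, and ribo-seq feature composition plus protected-boundary detection.
All outputs are TSVs with a '#'-prefixed parameter header (plus one bedGraph
score track); reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .mirna import enrichment_ratio, mirna_length_table, quantify_mirna
from .normalization import compute_norm_factors, factors_table
from .phasing import PhasingParams, quantify_tas, register_distribution, scan_phasing
from .preprocess import PreprocessConfig, filter_structural
from .riboseq import feature_composition, protected_boundary, transcript_coverage, GeneModel
from .simulate import SyntheticConfig, generate_reference, simulate_riboseq, simulate_srna_library
from .windows import annotate_dsr, call_dsr, count_windows

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    depth: int = 100_000
    n_replicates: int = 3
    compartments: tuple[str, ...] = ("MBP", "TP")
    comparison: tuple[str, str] = ("TP", "MBP")  # (A, B); hyper means B > A
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    phasing: PhasingParams = field(default_factory=PhasingParams)
    window_width: int = 100
    fc_min: float = 2.0
    fdr_max: float = 0.05
    riboseq_depth: int = 50_000

    def params_header(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("synthetic")
        return d


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Run every stage on synthetic data; return a manifest of output paths.

    Any stage failure removes partial outputs and re-raises with the stage
    name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"

    def emit(name: str, df: pd.DataFrame, extra_params: dict | None = None) -> Path:
        path = outdir / name
        params = {**config.params_header(), **(extra_params or {})}
        io.write_table(df, path, params=params)
        written.append(path)
        return path

    for comp in config.comparison:
        if comp not in config.compartments:
            raise ValueError(
                f"comparison condition {comp!r} has no samples (compartments: {config.compartments})"
            )

    try:
        stage = "reference"
        genome, annots, truth = generate_reference(config.synthetic, seed=config.seed)
        io.write_genome(genome, outdir / "genome.fa")
        io.write_annotations(annots, outdir / "annotations.gff3")
        truth.to_json(outdir / "truth.json")
        written += [outdir / "genome.fa", outdir / "annotations.gff3", outdir / "truth.json"]

        stage = "simulate"
        rng = np.random.default_rng(config.seed)
        libraries: dict[str, list] = {}
        for comp in config.compartments:
            for rep in range(1, config.n_replicates + 1):
                lib_seed = int(rng.integers(0, 2**31 - 1))
                lib_id = f"{comp}_{rep}"
                libraries[lib_id] = simulate_srna_library(truth, comp, config.depth, lib_seed)
                io.write_alignments(libraries[lib_id], outdir / f"{lib_id}.alignments.tsv")
                written.append(outdir / f"{lib_id}.alignments.tsv")

        stage = "preprocess/normalize"
        partitions = {
            lib_id: filter_structural(recs, annots, config.preprocess)
            for lib_id, recs in libraries.items()
        }
        factors = {
            lib_id: compute_norm_factors(part, library_id=lib_id)
            for lib_id, part in partitions.items()
        }
        emit("factors.tsv", factors_table(list(factors.values())))

        stage = "windows/dsr"
        cond_a, cond_b = config.comparison
        mats = {
            lib_id: count_windows(part.kept, truth.chrom_sizes, width=config.window_width)
            for lib_id, part in partitions.items()
        }
        ids_a = [f"{cond_a}_{r}" for r in range(1, config.n_replicates + 1)]
        ids_b = [f"{cond_b}_{r}" for r in range(1, config.n_replicates + 1)]
        dsr = call_dsr(
            [mats[i] for i in ids_a], [mats[i] for i in ids_b],
            [factors[i] for i in ids_a], [factors[i] for i in ids_b],
            fc_min=config.fc_min, fdr_max=config.fdr_max,
        )
        emit("dsr.tsv", dsr, {"comparison": f"{cond_b} vs {cond_a} (hyper = {cond_b} > {cond_a})"})
        called, comp_table = annotate_dsr(dsr, annots)
        emit("dsr_called.tsv", called, {"note": "a DSR overlapping multiple categories counts once per category"})
        emit("dsr_composition.tsv", comp_table, {"note": "a DSR overlapping multiple categories counts once per category"})

        stage = "mirna"
        mirnas = truth.mirna_annotations(genome)
        quants = {lib_id: quantify_mirna(part.kept, mirnas, genome=genome) for lib_id, part in partitions.items()}
        quant_rows = []
        iso_rows = []
        for lib_id, q in quants.items():
            lt = mirna_length_table(q, factors[lib_id])
            lt.insert(0, "library", lib_id)
            quant_rows.append(lt)
            qq = q.copy()
            qq.insert(0, "library", lib_id)
            qq["rpmr"] = qq["raw"] / factors[lib_id].rpmr_divisor
            iso_rows.append(qq)
        emit("mirna_quant.tsv", pd.concat(quant_rows, ignore_index=True))
        emit("isoforms.tsv", pd.concat(iso_rows, ignore_index=True))

        # pooled-replicate enrichment between the compared conditions
        def pooled(ids):
            counts: dict[str, float] = {}
            for i in ids:
                for row in quants[i].itertuples():
                    counts[row.mirna_id] = counts.get(row.mirna_id, 0) + row.raw
            frag = sum(factors[i].rrna45S_fragment_count for i in ids)
            total = sum(factors[i].total_mapped_count for i in ids)
            from .normalization import NormFactor

            return counts, NormFactor("+".join(ids), frag, total)
        counts_b, factor_b = pooled(ids_b)
        counts_a, factor_a = pooled(ids_a)
        enr = enrichment_ratio(counts_b, counts_a, factor_b, factor_a, comparison=f"{cond_b}/{cond_a}")
        emit("enrichment.tsv", enr)

        stage = "phasing"
        tas_loci = truth.tas_loci()
        all_kept_b = [r for i in ids_b for r in partitions[i].kept]
        track_frames = []
        reg_rows = []
        for locus in tas_loci:
            scan = scan_phasing(all_kept_b, (locus.chrom, locus.start, locus.end), config.phasing)
            scan.insert(0, "chrom", locus.chrom)
            scan.insert(0, "locus_id", locus.locus_id)
            track_frames.append(scan)
            reg = register_distribution(all_kept_b, locus, config.phasing)
            reg_rows.append(
                {
                    "locus_id": locus.locus_id,
                    **{f"reg{k}": f for k, f in enumerate(reg.fractions)},
                    "prominent_register": reg.prominent_register,
                    "in_register": reg.in_register,
                    "low_confidence": reg.low_confidence,
                }
            )
        track = pd.concat(track_frames, ignore_index=True)
        bg_path = outdir / "phasing_track.bedgraph"
        with open(bg_path, "w") as fh:
            fh.write('track type=bedGraph name="phasing_score"\n')
            for row in track.itertuples():
                if row.score == row.score:
                    fh.write(f"{row.chrom}\t{row.anchor}\t{row.anchor + 1}\t{row.score:.6g}\n")
        written.append(bg_path)
        emit("registers.tsv", pd.DataFrame(reg_rows), {"score_threshold": config.phasing.score_threshold})
        pooled_factor_b = factor_b
        emit("tas_quant.tsv", quantify_tas(all_kept_b, tas_loci, factor=pooled_factor_b))

        stage = "riboseq"
        ribo_seed = int(rng.integers(0, 2**31 - 1))
        ribo = simulate_riboseq(truth, config.riboseq_depth, ribo_seed)
        models = truth.gene_models() + [
            GeneModel(transcript_id=t.locus_id, chrom=t.chrom, strand=t.strand, exons=[(t.start, t.end)])
            for t in truth.tas
        ]
        comp_series = feature_composition(ribo, models)
        emit("ribo_composition.tsv", comp_series.rename_axis("feature").reset_index())
        boundary_rows = []
        for t in truth.tas:
            model = GeneModel(transcript_id=t.locus_id, chrom=t.chrom, strand=t.strand, exons=[(t.start, t.end)])
            cov = transcript_coverage(ribo, model)
            if cov.max() <= 0:
                continue
            cleave_t = model.genomic_to_transcript(t.cleavage_site)
            res = protected_boundary(cov, cleave_t, transcript_id=t.locus_id)
            boundary_rows.append(
                {
                    "transcript_id": res.transcript_id,
                    "protected_end": res.protected_end,
                    "cleavage_site": res.cleavage_site,
                    "offset": res.offset,
                    "threshold_frac": res.threshold_frac,
                    "smooth_window": res.smooth_window,
                }
            )
        emit("boundaries.tsv", pd.DataFrame(boundary_rows))
    except Exception as exc:
        for path in written:
            if path.exists():
                path.unlink()
        for aux in ("genome.fa.fai",):
            p = outdir / aux
            if p.exists():
                p.unlink()
        logger.error("pipeline failed during stage %r; partial outputs removed", stage)
        raise RuntimeError(f"pipeline failed during stage {stage!r}: {exc}") from exc

    return {p.name: p for p in written}
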