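"""Run every stage end to end and list the output tables.

Uses the pipeline driver on synthetic MBP/TP libraries; outputs land in
./pipeline_demo (TSVs with a '#' parameter header, plus a bedGraph score
track). Rerunning with the same seed reproduces every file byte for byte.
"""

import srnafrac as sf

manifest = sf.run_pipeline(sf.PipelineConfig(seed=7, depth=60_000, riboseq_depth=30_000),
                           "pipeline_demo")
for name in sorted(manifest):
    print(name)
print("\nSee dsr.tsv for window calls, enrichment.tsv for MBP/TP ratios,")
print("phasing_track.bedgraph for the score track, boundaries.tsv for ribo-seq.")
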