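"""100-bp-window counting and differential small-RNA region (DSR) calling.

The genome is tiled into consecutive, non-overlapping fixed-width windows
(default 100 bp). A read is assigned to the single window containing its
strand-aware 5' end, stratified by read length (size classes 21/22/23/24 nt).
Two conditions are compared per window and size class with a moderated
two-sample t-test on log2 of pseudocounted RPMR (0.5 added to raw counts
before dividing): per-window pooled variances are shrunk
toward the across-window mean variance with a prior weight of 4
pseudo-observations, and Benjamini-Hochberg FDR is applied within each size
class. Windows are called hyper (B > A) or hypo (B < A) when FDR and
fold-change thresholds are both met.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .normalization import NormFactor, PSEUDOCOUNT
from .records import AlignmentRecord, AnnotationSet

SIZE_CLASSES = (21, 22, 23, 24)

#: DSR feature-composition categories, by annotation type
DSR_CATEGORIES = {
    "MIR": ("miRNA_mature",),
    "TAS": ("TAS",),
    "gene": ("gene",),
    "TE": ("TE",),
}


def tile_genome(chrom_sizes: Mapping[str, int], width: int = 100) -> pd.DataFrame:
    """Tile each chromosome into ceil(L/width) consecutive disjoint windows.

    The last window of a chromosome may be short. Returns a frame with
    columns chrom, start, end.
    """
    if width <= 0:
        raise ValueError(f"window width must be > 0, got {width}")
    rows = []
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive size {size}")
        starts = np.arange(0, size, width)
        for s in starts:
            rows.append((chrom, int(s), int(min(s + width, size))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@dataclass
class WindowCountMatrix:
    """Per-window, per-size-class raw counts for one library.

    ``counts`` is indexed by (chrom, start) over the full tiling and has one
    integer column per size class plus ``other`` for kept reads outside the
    size classes (excluded from DSR testing).
    """

    counts: pd.DataFrame
    width: int
    chrom_sizes: dict[str, int]
    size_classes: tuple[int, ...] = SIZE_CLASSES

    def rpmr(self, factor: NormFactor) -> pd.DataFrame:
        return self.counts[list(map(str, self.size_classes))] / factor.rpmr_divisor


def count_windows(
    reads: Iterable[AlignmentRecord],
    chrom_sizes: Mapping[str, int],
    width: int = 100,
    size_classes: Sequence[int] = SIZE_CLASSES,
) -> WindowCountMatrix:
    """Assign each read to the window containing its 5' end; sum copies.

    Reads whose length is outside ``size_classes`` are tallied in an
    ``other`` column. A 5' end at or beyond the chromosome end is an error.
    """
    windows = tile_genome(chrom_sizes, width)
    idx = pd.MultiIndex.from_frame(windows[["chrom", "start"]])
    cols = [str(s) for s in size_classes] + ["other"]
    mat = pd.DataFrame(0, index=idx, columns=cols, dtype=np.int64)
    size_set = set(size_classes)
    acc: dict[tuple[str, int, str], int] = {}
    for r in reads:
        fp = r.five_prime
        size = chrom_sizes.get(r.chrom)
        if size is None:
            raise ValueError(f"read on unknown chromosome {r.chrom!r}")
        if fp >= size:
            raise ValueError(f"read 5' end {fp} beyond end of chromosome {r.chrom} ({size})")
        wstart = (fp // width) * width
        col = str(r.length) if r.length in size_set else "other"
        key = (r.chrom, int(wstart), col)
        acc[key] = acc.get(key, 0) + r.copies
    for (chrom, wstart, col), c in acc.items():
        mat.loc[(chrom, wstart), col] += c
    return WindowCountMatrix(counts=mat, width=width, chrom_sizes=dict(chrom_sizes), size_classes=tuple(size_classes))


def moderated_log_ratio_test(
    raw_a: np.ndarray,
    raw_b: np.ndarray,
    divisors_a: Sequence[float],
    divisors_b: Sequence[float],
    prior_weight: float = 4.0,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Moderated two-sample t-test on log2 pseudocounted RPMR, one row per window.

    ``raw_a``/``raw_b`` are (windows x replicates) raw count arrays;
    ``divisors_a``/``divisors_b`` the per-replicate RPMR divisors. Pooled
    per-window variances are shrunk toward their across-window mean with
    ``prior_weight`` pseudo-observations and the t statistic gains the same
    prior degrees of freedom. Returns mean RPMR per condition (pseudocounted),
    log2 fold change, t, p.
    """
    raw_a = np.asarray(raw_a, dtype=float)
    raw_b = np.asarray(raw_b, dtype=float)
    n_a, n_b = raw_a.shape[1], raw_b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("at least 2 replicates per condition are required")
    # pseudocount on the raw scale, before dividing: one spurious read in a
    # low-count window then moves y by ~log2(3), not by the full RPMR unit
    y_a = np.log2((raw_a + pseudocount) / np.asarray(divisors_a, dtype=float))
    y_b = np.log2((raw_b + pseudocount) / np.asarray(divisors_b, dtype=float))
    m_a, m_b = y_a.mean(axis=1), y_b.mean(axis=1)
    v_a = y_a.var(axis=1, ddof=1)
    v_b = y_b.var(axis=1, ddof=1)
    df = n_a + n_b - 2
    pooled = ((n_a - 1) * v_a + (n_b - 1) * v_b) / df
    prior_var = pooled.mean() if len(pooled) else 0.0
    shrunk = (df * pooled + prior_weight * prior_var) / (df + prior_weight)
    se = np.sqrt(shrunk * (1.0 / n_a + 1.0 / n_b))
    diff = m_b - m_a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    p = 2.0 * stats.t.sf(np.abs(t), df + prior_weight)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where((se == 0) & (diff == 0), 1.0, p)
    # pseudocounted RPMR means drive the fold-change threshold
    mean_a = ((raw_a + pseudocount) / np.asarray(divisors_a, dtype=float)).mean(axis=1)
    mean_b = ((raw_b + pseudocount) / np.asarray(divisors_b, dtype=float)).mean(axis=1)
    return pd.DataFrame(
        {
            "meanA_rpmr": mean_a,
            "meanB_rpmr": mean_b,
            "log2fc": np.log2(mean_b / mean_a),
            "t": t,
            "pvalue": p,
        }
    )


def call_dsr(
    matrices_a: Sequence[WindowCountMatrix],
    matrices_b: Sequence[WindowCountMatrix],
    factors_a: Sequence[NormFactor],
    factors_b: Sequence[NormFactor],
    fc_min: float = 2.0,
    fdr_max: float = 0.05,
    min_total: int = 5,
    prior_weight: float = 4.0,
) -> pd.DataFrame:
    """Call hyper/hypo DSRs between conditions A and B per window x size class.

    Windows with summed raw counts < ``min_total`` across all samples of a
    size class are excluded from testing (independent filtering). FDR is
    Benjamini-Hochberg within each size class. hyper means B > A.
    """
    if len(matrices_a) < 2 or len(matrices_b) < 2:
        raise ValueError("at least 2 replicates per condition are required")
    base = matrices_a[0]
    for m in list(matrices_a) + list(matrices_b):
        if not m.counts.index.equals(base.counts.index):
            raise ValueError("all matrices must share the same window set")
    out_frames = []
    windows = base.counts.index.to_frame(index=False)
    windows.columns = ["chrom", "start"]
    for size in base.size_classes:
        col = str(size)
        raw_a = np.column_stack([m.counts[col].to_numpy() for m in matrices_a])
        raw_b = np.column_stack([m.counts[col].to_numpy() for m in matrices_b])
        total = raw_a.sum(axis=1) + raw_b.sum(axis=1)
        tested = total >= min_total
        res = moderated_log_ratio_test(
            raw_a[tested],
            raw_b[tested],
            [f.rpmr_divisor for f in factors_a],
            [f.rpmr_divisor for f in factors_b],
            prior_weight=prior_weight,
        )
        res.insert(0, "chrom", windows.loc[tested, "chrom"].to_numpy())
        res.insert(1, "start", windows.loc[tested, "start"].to_numpy())
        res.insert(2, "end", res["start"] + base.width)
        res.insert(3, "size_class", size)
        if len(res):
            res["fdr"] = multipletests(res["pvalue"].to_numpy(), method="fdr_bh")[1]
        else:
            res["fdr"] = pd.Series(dtype=float)
        fc = res["meanB_rpmr"] / res["meanA_rpmr"]
        sig = res["fdr"] < fdr_max
        res["call"] = "ns"
        res.loc[sig & (fc > fc_min), "call"] = "hyper"
        res.loc[sig & (fc < 1.0 / fc_min), "call"] = "hypo"
        out_frames.append(res)
    return pd.concat(out_frames, ignore_index=True)


def annotate_dsr(dsr: pd.DataFrame, annotations: AnnotationSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label called DSRs with overlapping feature categories (>= 1-nt overlap).

    A DSR overlapping several categories counts once per category; DSRs
    overlapping none are intergenic. Returns (labeled DSR frame, composition
    frame of percentages per call class).
    """
    called = dsr[dsr["call"] != "ns"].copy()
    cats_per_row: list[list[str]] = []
    for row in called.itertuples():
        cats = [
            name
            for name, types in DSR_CATEGORIES.items()
            if annotations.overlapping(row.chrom, row.start, row.end, types=types)
        ]
        cats_per_row.append(cats or ["intergenic"])
    called["categories"] = [",".join(c) for c in cats_per_row]
    comp_rows = []
    for call in ("hyper", "hypo"):
        mask = (called["call"] == call).to_numpy()
        n = int(mask.sum())
        flat = [c for cats, m in zip(cats_per_row, mask) if m for c in cats]
        for cat in list(DSR_CATEGORIES) + ["intergenic"]:
            count = flat.count(cat)
            comp_rows.append(
                {
                    "call": call,
                    "category": cat,
                    "n_dsr": count,
                    "percent": 100.0 * count / n if n else 0.0,
                }
            )
    return called, pd.DataFrame(comp_rows)
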