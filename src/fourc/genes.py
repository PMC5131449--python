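"""Candidate-gene filtering: chromatin interaction x enhancer activity x
expression.

A gene becomes a candidate for a GWAS locus, in a given cell type, when
all three criteria hold:

1. its TSS co-localises with a significant interaction segment (within
   5 kbp, inclusive) of the locus viewpoint in that cell type;
2. the locus is active in that cell type -- the tag SNP or a variant in LD
   with it overlaps an H3K27ac peak;
3. the gene is expressed in that cell type, log2(RPKM) strictly > -0.5.

The module also produces the summary outputs built on the candidate table:
novelty flags against a supplied list of previously reported genes,
cell-type Venn counts and viewpoint-to-TSS distance statistics.
"""
from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .calling import InteractionSegment
from .fragends import ViewpointSpec

__all__ = [
    "genes_near_segments",
    "assess_locus_activity",
    "expression_filter",
    "rpkm",
    "assemble_candidates",
    "celltype_overlap",
    "distance_stats",
]


def _point_interval_distance(pos: int, start: int, end: int) -> int:
    """Distance from a point to a 0-based half-open interval (0 inside)."""
    if pos < start:
        return start - pos
    if pos >= end:
        return pos - (end - 1)
    return 0


def genes_near_segments(
    genes: pd.DataFrame,
    segments: list[InteractionSegment],
    max_dist: int = 5000,
) -> pd.DataFrame:
    """Criterion 1: genes whose TSS lies within ``max_dist`` bp (inclusive)
    of a significant segment.

    ``genes`` has columns gene_id, chrom, tss (a gene may have several TSS
    records; any qualifying TSS qualifies the gene). Returns one row per
    qualifying gene with the minimum p among qualifying segments and the
    minimum TSS-to-segment distance (0 when the TSS is inside a segment).
    """
    by_chrom: dict[str, list[InteractionSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    rows = []
    for rec in genes.itertuples(index=False):
        best_p, best_d, best_tss = None, None, None
        for seg in by_chrom.get(rec.chrom, []):
            d = _point_interval_distance(int(rec.tss), seg.start, seg.end)
            if d <= max_dist and (best_p is None or seg.min_p < best_p):
                best_p = seg.min_p
            if d <= max_dist and (best_d is None or d < best_d):
                best_d, best_tss = d, int(rec.tss)
        if best_p is not None:
            rows.append((rec.gene_id, best_p, best_d, best_tss))
    if not rows:
        return pd.DataFrame(columns=["gene_id", "min_p", "distance", "tss"])
    df = pd.DataFrame(rows, columns=["gene_id", "min_p", "distance", "tss"])
    return (
        df.groupby("gene_id", as_index=False)
        .agg(min_p=("min_p", "min"), distance=("distance", "min"), tss=("tss", "first"))
    )


def assess_locus_activity(
    viewpoints: list[ViewpointSpec],
    ld: pd.DataFrame,
    peaks: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Criterion 2: per SNP and cell type, is the locus an active enhancer?

    A locus is active when the tag SNP or any LD partner overlaps any
    H3K27ac peak of that cell type (point-in-interval). ``ld`` has columns
    tag_snp, variant_chrom, variant_pos; a SNP absent from it is assessed
    on the tag SNP alone (with a warning). ``peaks`` maps cell type to a
    BED-like table (chrom, start, end).
    """
    missing = [
        vp.snp_id for vp in viewpoints if vp.snp_id not in set(ld["tag_snp"])
    ]
    if missing:
        warnings.warn(
            f"{len(missing)} SNP(s) absent from the LD table, assessed on the "
            f"tag SNP alone: {', '.join(missing[:5])}"
        )
    rows = []
    for vp in viewpoints:
        variants = [(vp.chrom, vp.position, vp.snp_id)]
        for rec in ld[ld["tag_snp"] == vp.snp_id].itertuples(index=False):
            variants.append((rec.variant_chrom, int(rec.variant_pos), "LD"))
        for ct, peak_df in peaks.items():
            active, support = False, ""
            for chrom, pos, label in variants:
                hit = peak_df[
                    (peak_df["chrom"] == chrom)
                    & (peak_df["start"] <= pos)
                    & (pos < peak_df["end"])
                ]
                if len(hit):
                    active, support = True, f"{label}@{chrom}:{pos}"
                    break
            rows.append((vp.snp_id, ct, active, support))
    return pd.DataFrame(rows, columns=["snp_id", "cell_type", "active", "support"])


def expression_filter(
    expression: pd.DataFrame, cutoff: float = -0.5, value_col: str = "log2_rpkm"
) -> set[str]:
    """Criterion 3: genes with log2(RPKM) strictly greater than ``cutoff``."""
    expressed = expression.loc[expression[value_col] > cutoff, "gene_id"]
    return set(expressed)


def rpkm(count: float, gene_length: int, library_size: int) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if gene_length <= 0 or library_size <= 0:
        raise ValueError("gene_length and library_size must be positive")
    return count / (gene_length / 1000.0) / (library_size / 1e6)


def assemble_candidates(
    genes: pd.DataFrame,
    segments: dict[tuple[str, str], list[InteractionSegment]],
    activity: pd.DataFrame,
    expression: dict[str, pd.DataFrame],
    viewpoints: list[ViewpointSpec],
    known_genes: set[str] | None = None,
    max_dist: int = 5000,
    expr_cutoff: float = -0.5,
) -> pd.DataFrame:
    """Intersect the three criteria per cell type into the candidate table.

    ``segments`` maps (snp_id, cell_type) to the called segments of that
    viewpoint/cell-type dataset. Output columns: gene_id, cell_type,
    snp_id, p, distance_bp (viewpoint position to TSS), log2_rpkm, novel;
    rows sorted by (snp_id, gene_id, cell_type). Genes absent from the
    expression table are treated as not expressed and counted in a
    warning.
    """
    known_genes = known_genes or set()
    vp_by_id = {vp.snp_id: vp for vp in viewpoints}
    active_pairs = {
        (r.snp_id, r.cell_type)
        for r in activity.itertuples(index=False)
        if r.active
    }
    expr_values: dict[str, dict[str, float]] = {
        ct: dict(zip(df["gene_id"], df["log2_rpkm"])) for ct, df in expression.items()
    }
    n_missing_expr = 0
    rows = []
    for (snp_id, ct), segs in segments.items():
        if (snp_id, ct) not in active_pairs or not segs:
            continue
        vp = vp_by_id[snp_id]
        near = genes_near_segments(genes, segs, max_dist=max_dist)
        values = expr_values.get(ct, {})
        for rec in near.itertuples(index=False):
            value = values.get(rec.gene_id)
            if value is None:
                n_missing_expr += 1
                continue
            if not (value > expr_cutoff):
                continue
            rows.append(
                (
                    rec.gene_id,
                    ct,
                    snp_id,
                    rec.min_p,
                    abs(int(rec.tss) - vp.position),
                    value,
                    rec.gene_id not in known_genes,
                )
            )
    if n_missing_expr:
        warnings.warn(
            f"{n_missing_expr} interacting gene record(s) had no expression "
            "value and were treated as not expressed"
        )
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "cell_type", "snp_id", "p", "distance_bp", "log2_rpkm", "novel"],
    )
    return df.sort_values(["snp_id", "gene_id", "cell_type"], kind="stable").reset_index(
        drop=True
    )


def celltype_overlap(candidates: pd.DataFrame) -> dict[frozenset, int]:
    """Venn counts over cell types: distinct genes by exact membership.

    Returns a mapping from the frozenset of cell types in which a gene is
    a candidate to the number of such genes; the counts partition the
    distinct-gene total.
    """
    membership: dict[str, set[str]] = {}
    for rec in candidates.itertuples(index=False):
        membership.setdefault(rec.gene_id, set()).add(rec.cell_type)
    counts: dict[frozenset, int] = {}
    for cts in membership.values():
        key = frozenset(cts)
        counts[key] = counts.get(key, 0) + 1
    return counts


def venn_table(candidates: pd.DataFrame) -> pd.DataFrame:
    """``celltype_overlap`` as a TSV-friendly table (region, n_genes)."""
    counts = celltype_overlap(candidates)
    rows = [
        ("&".join(sorted(key)), n)
        for key, n in sorted(counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
    ]
    return pd.DataFrame(rows, columns=["region", "n_genes"])


def distance_stats(candidates: pd.DataFrame) -> pd.DataFrame:
    """Per-cell-type viewpoint-to-TSS distance summary (median, quartiles)."""
    if len(candidates) == 0:
        return pd.DataFrame(columns=["cell_type", "n", "median_bp", "q1_bp", "q3_bp"])
    rows = []
    for ct, grp in candidates.groupby("cell_type"):
        d = grp["distance_bp"].to_numpy(dtype=float)
        rows.append(
            (ct, len(d), float(np.median(d)), float(np.quantile(d, 0.25)),
             float(np.quantile(d, 0.75)))
        )
    return pd.DataFrame(rows, columns=["cell_type", "n", "median_bp", "q1_bp", "q3_bp"])


def distance_histogram(
    candidates: pd.DataFrame, binsize: int = 100_000
) -> pd.DataFrame:
    """Distance distribution as counts in fixed-width bins, per cell type."""
    rows = []
    for ct, grp in candidates.groupby("cell_type"):
        d = grp["distance_bp"].to_numpy()
        if len(d) == 0:
            continue
        n_bins = int(math.floor(d.max() / binsize)) + 1
        hist, edges = np.histogram(d, bins=n_bins, range=(0, n_bins * binsize))
        for lo, n in zip(edges[:-1], hist):
            rows.append((ct, int(lo), int(lo) + binsize, int(n)))
    return pd.DataFrame(rows, columns=["cell_type", "bin_start", "bin_end", "count"])
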