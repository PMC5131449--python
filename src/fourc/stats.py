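"""Downstream validation statistics for the candidate-gene set.

Covers the analyses used to corroborate 4C-derived candidates: chromatin
occupancy around TSS (detected vs undetected genes), counts of CTCF-bound
insulator sites bypassed by each interaction, eQTL concordance against the
candidate set, gene-set concordance between replicate datasets, and a
permutation-based gene set enrichment analysis (GSEA) of the candidates
against a ranked differential-expression list.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .fragends import ViewpointSpec

__all__ = [
    "tss_occupancy",
    "occupancy_contrast",
    "ctcf_between",
    "eqtl_concordance",
    "geneset_concordance",
    "gsea_es",
    "gsea_significance",
    "GseaResult",
]


def tss_occupancy(
    track: pd.DataFrame,
    genes: pd.DataFrame,
    halfwidth: int = 2000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.Series:
    """Mean track signal over [TSS - halfwidth, TSS + halfwidth) per gene.

    ``track`` is a bedGraph-like table (chrom, start, end, value); bases
    not covered by any interval contribute zero signal. Windows truncated
    at a chromosome edge are normalised by the in-bounds width. Genes with
    several TSS records are averaged over records.
    """
    by_chrom = {
        chrom: grp.sort_values("start")[["start", "end", "value"]].to_numpy(dtype=float)
        for chrom, grp in track.groupby("chrom")
    }
    rows = []
    for rec in genes.itertuples(index=False):
        lo = int(rec.tss) - halfwidth
        hi = int(rec.tss) + halfwidth
        lo_c = max(lo, 0)
        hi_c = hi
        if chrom_lengths is not None and rec.chrom in chrom_lengths:
            hi_c = min(hi, chrom_lengths[rec.chrom])
        width = hi_c - lo_c
        if width <= 0:
            rows.append((rec.gene_id, 0.0))
            continue
        total = 0.0
        for start, end, value in by_chrom.get(rec.chrom, np.empty((0, 3))):
            ov = min(end, hi_c) - max(start, lo_c)
            if ov > 0:
                total += value * ov
        rows.append((rec.gene_id, total / width))
    occ = pd.DataFrame(rows, columns=["gene_id", "occupancy"])
    return occ.groupby("gene_id")["occupancy"].mean()


def occupancy_contrast(
    occupancy: pd.Series, detected: set[str]
) -> dict[str, float]:
    """Contrast occupancy of 4C-detected genes against the remaining genes:
    group medians plus a two-sided Wilcoxon rank-sum test."""
    is_det = occupancy.index.isin(detected)
    a = occupancy[is_det].to_numpy(dtype=float)
    b = occupancy[~is_det].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty for the contrast")
    stat, p = mannwhitneyu(a, b, alternative="two-sided")
    return {
        "median_detected": float(np.median(a)),
        "median_other": float(np.median(b)),
        "n_detected": int(len(a)),
        "n_other": int(len(b)),
        "u_statistic": float(stat),
        "p_value": float(p),
    }


def ctcf_between(
    viewpoint: ViewpointSpec, gene_chrom: str, gene_tss: int, ctcf: pd.DataFrame
) -> int:
    """Number of CTCF peaks whose midpoint lies strictly between the
    viewpoint position and the gene TSS (symmetric in the endpoints)."""
    if gene_chrom != viewpoint.chrom:
        raise ValueError(
            f"viewpoint on {viewpoint.chrom} and TSS on {gene_chrom}: the "
            "intervening-site count is only defined in cis"
        )
    lo, hi = sorted((viewpoint.position, int(gene_tss)))
    peaks = ctcf[ctcf["chrom"] == gene_chrom]
    mid = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    return int(((mid > lo) & (mid < hi)).sum())


def eqtl_concordance(
    eqtl: pd.DataFrame,
    candidates: pd.DataFrame,
    genes: pd.DataFrame,
    viewpoints: list[ViewpointSpec],
    window: int = 2_000_000,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Concordance between eQTL target genes and the 4C candidate set.

    For each SNP, the fraction of its eQTL genes (restricted to the gene
    annotation universe) that are 4C candidates for that SNP, and as a
    control the fraction found among the non-interacting genes within
    +/- ``window`` bp of the viewpoint. Returns the per-SNP table and
    pooled totals across SNPs.
    """
    universe = set(genes["gene_id"])
    eq = eqtl[eqtl["gene_id"].isin(universe)]
    vp_by_id = {vp.snp_id: vp for vp in viewpoints}
    rows = []
    tot_e = tot_ec = tot_en = 0
    for snp, grp in eq.groupby("snp"):
        if snp not in vp_by_id:
            continue
        vp = vp_by_id[snp]
        e = set(grp["gene_id"])
        cand = set(candidates.loc[candidates["snp_id"] == snp, "gene_id"])
        near = genes[
            (genes["chrom"] == vp.chrom)
            & ((genes["tss"] - vp.position).abs() <= window)
        ]
        noninteracting = set(near["gene_id"]) - cand
        n_ec = len(e & cand)
        n_en = len(e & noninteracting)
        rows.append((snp, len(e), n_ec / len(e), n_en / len(e)))
        tot_e += len(e)
        tot_ec += n_ec
        tot_en += n_en
    per_snp = pd.DataFrame(
        rows, columns=["snp", "n_eqtl_genes", "interacting_fraction", "noninteracting_fraction"]
    )
    totals = {
        "n_eqtl_genes": tot_e,
        "interacting_fraction": tot_ec / tot_e if tot_e else float("nan"),
        "noninteracting_fraction": tot_en / tot_e if tot_e else float("nan"),
    }
    return per_snp, totals


def geneset_concordance(set_a, set_b) -> float:
    """Fraction of genes in A that are also in B: |A n B| / |A|."""
    a, b = set(set_a), set(set_b)
    if not a:
        raise ValueError("concordance is undefined for an empty reference set")
    return len(a & b) / len(a)


@dataclass(frozen=True)
class GseaResult:
    """Enrichment score, normalised score and permutation p for one set."""

    es: float
    nes: float
    pvalue: float
    n_perm: int

    @property
    def p_floor(self) -> float:
        return 1.0 / (self.n_perm + 1)


def _prepare_ranked(ranked: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    if ranked["gene_id"].duplicated().any():
        raise ValueError("ranked list contains duplicate gene ids")
    metric = ranked["metric"].to_numpy(dtype=float)
    if not np.isfinite(metric).all():
        raise ValueError("ranking metric must be finite")
    order = np.argsort(-metric, kind="stable")
    return list(ranked["gene_id"].to_numpy()[order]), metric[order]


def gsea_es(
    ranked: pd.DataFrame, gene_set, weight_exponent: float = 1.0
) -> tuple[float, np.ndarray]:
    """Classic weighted Kolmogorov-Smirnov enrichment score.

    Walking down the ranked list (descending metric), a gene in the set
    increments the running sum by |metric|^weight_exponent normalised over
    the set members; any other gene decrements it by 1/(N - N_set). The ES
    is the running sum's signed maximum deviation from zero. Returns
    (ES, running-sum profile).
    """
    ids, metric = _prepare_ranked(ranked)
    gene_set = set(gene_set)
    hits = np.fromiter((g in gene_set for g in ids), dtype=bool, count=len(ids))
    n_hit = int(hits.sum())
    if n_hit == 0:
        raise ValueError("gene set is disjoint from the ranked list")
    n = len(ids)
    w = np.abs(metric) ** weight_exponent
    sw = w[hits].sum()
    hit_inc = w / sw if sw > 0 else np.full(n, 1.0 / n_hit)
    miss_dec = 1.0 / (n - n_hit) if n > n_hit else 0.0
    running = np.cumsum(np.where(hits, hit_inc, -miss_dec))
    es = float(running[int(np.argmax(np.abs(running)))])
    return es, running


def _null_es(
    metric: np.ndarray, n_hit: int, n_perm: int, rng: np.random.Generator,
    weight_exponent: float,
) -> np.ndarray:
    """ES of ``n_perm`` random gene sets of size ``n_hit``, vectorised."""
    n = len(metric)
    w_all = np.abs(metric) ** weight_exponent
    pick = np.argpartition(rng.random((n_perm, n)), n_hit - 1, axis=1)[:, :n_hit]
    inc = np.full((n_perm, n), -1.0 / (n - n_hit))
    rows = np.repeat(np.arange(n_perm), n_hit)
    wpos = w_all[pick]
    sw = wpos.sum(axis=1)
    sw[sw == 0] = 1.0
    inc[rows, pick.ravel()] = (wpos / sw[:, None]).ravel()
    running = np.cumsum(inc, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), idx]


def gsea_significance(
    ranked: pd.DataFrame,
    gene_set,
    n_perm: int = 1000,
    seed: int | None = None,
    weight_exponent: float = 1.0,
    rng: np.random.Generator | None = None,
) -> GseaResult:
    """Permutation significance of the enrichment score.

    The null distribution is the ES of random gene sets of equal size
    drawn without replacement from the ranked genes. The reported p-value
    is two-sided on the ES magnitude with the add-one correction,
    p = (1 + #{|null ES| >= |ES|}) / (n_perm + 1), so it is exactly
    uniform for a random set and bounded below by 1/(n_perm + 1). The NES
    normalises the ES by the mean |null ES| of matching sign.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    ids, metric = _prepare_ranked(ranked)
    gene_set = set(gene_set) & set(ids)
    if not gene_set:
        raise ValueError("gene set is disjoint from the ranked list")
    if len(gene_set) >= len(ids):
        raise ValueError("gene set must be smaller than the ranked list")
    es, _ = gsea_es(ranked, gene_set, weight_exponent)
    rng = rng if rng is not None else np.random.default_rng(seed)
    null = _null_es(metric, len(gene_set), n_perm, rng, weight_exponent)
    p = (1 + int((np.abs(null) >= abs(es)).sum())) / (n_perm + 1)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    denom = np.abs(same_sign).mean() if len(same_sign) else np.abs(null).mean()
    nes = es / denom if denom > 0 else 0.0
    return GseaResult(es=es, nes=float(nes), pvalue=float(p), n_perm=n_perm)
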