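"""Downstream validation: eQTL concordance, intervening CTCF sites and
TSS occupancy contrast.

The synthetic eQTL table lists, for each tag SNP, genes whose expression
depends on the SNP genotype; all of them are planted targets, so every
eQTL gene should reappear among the 4C candidates while the surrounding
non-interacting genes contribute none.
"""
import pandas as pd

import fourc as fc

config = fc.SimConfig(
    seed=31, n_chromosomes=3, chromosome_length=1_200_000,
    background_coverage=0.02, n_viewpoints=3, n_cell_types=1,
)
study = fc.simulate_study(config, contact_coverage=0.95, decoys_per_viewpoint=6)
result = fc.run_candidate_pipeline(study)

per_snp, totals = fc.eqtl_concordance(
    study.eqtl, result.candidates, study.genes, study.viewpoints
)
print("eQTL concordance per SNP:")
print(per_snp.to_string(index=False))
print(f"pooled: {totals['interacting_fraction']:.0%} of eQTL genes are 4C "
      f"candidates; {totals['noninteracting_fraction']:.0%} fall among "
      "non-interacting genes within 2 Mb")

print("\nCTCF sites bypassed by each interaction:")
for rec in result.candidates.itertuples(index=False):
    vp = next(v for v in study.viewpoints if v.snp_id == rec.snp_id)
    tss = int(study.genes.loc[study.genes["gene_id"] == rec.gene_id, "tss"].iloc[0])
    n = fc.ctcf_between(vp, vp.chrom, tss, study.ctcf)
    print(f"  {rec.snp_id} -> {rec.gene_id}: {n} CTCF site(s) in between")

# occupancy contrast on a toy track where detected genes carry 2x signal
detected = set(result.candidates["gene_id"])
rows = [
    (g.chrom, max(0, g.tss - 2000), g.tss + 2000,
     2.0 if g.gene_id in detected else 1.0)
    for g in study.genes.itertuples(index=False)
]
track = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
occ = fc.tss_occupancy(track, study.genes)
contrast = fc.occupancy_contrast(occ, detected)
print(f"\nTSS occupancy: detected median = {contrast['median_detected']:.2f}, "
      f"other median = {contrast['median_other']:.2f}, "
      f"rank-sum p = {contrast['p_value']:.3g}")
print("Interactions freely bypass CTCF sites; candidate genes carry higher "
      "promoter signal than their undetected neighbours.")
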