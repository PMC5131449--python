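# Methods

## Fragend mapping model

The unit of 4C signal is the *fragend*: the sequence immediately flanking a
DpnII recognition site (GATC), to which the first bases of a
primer-stripped read are matched. The library is built by locating every
GATC occurrence on the forward strand (GATC is palindromic, so a
reverse-strand search is redundant) and recording, per site, the 16 bases
ending immediately before the site and the 16 bases starting immediately
after it. The 16-mers therefore *exclude* the GATC itself; the alternative
convention (including the site in the downstream 16-mer) would make every
downstream fragend share a 4-base prefix and is not used. 16-mers are
stored in forward-genomic orientation, and the simulator emits reads in the
same orientation, so mapping is a single exact dictionary lookup. A fragend
is non-mappable when its flank is truncated below 16 bases by the
chromosome end or an adjacent site, or contains an ambiguous base;
non-unique 16-mers (occurring at more than one fragend genome-wide) are
excluded at the library level, which under exact matching is equivalent to
per-read multi-hit rejection but cheaper and directly testable. Coverage
profiles are defined over the fragends that are both mappable and unique;
this is what makes the read-level round trip (emit → demultiplex → map)
exact. Reads may be any length ≥ primer + 16; only the first 16 payload
bases are used. The restriction site is configurable, though nothing else
in the pipeline depends on it.

## Interaction calling

Coverage is reduced to binary covered/uncovered per fragend, which
sacrifices dynamic range to remove PCR-efficiency bias between fragends. A
window of k consecutive usable fragends slides along the whole viewpoint
chromosome in steps of one fragend; calling is cis-only.

**Window size.** k is calibrated per viewpoint as k = round(target / r),
rounding half away from zero and floored at the target (default 20), where
r is the covered fraction of fragends within ± 100 kbp of the viewpoint.
The rounding convention is immaterial at the documented operating points
but is fixed and tested.

**Background.** p₀ is the covered fraction of all usable fragends on the
viewpoint chromosome *excluding* the ± 100 kbp viewpoint zone, whose
decay-dominated coverage would inflate the estimate. p₀ is clamped to
[1/(n+2), (n+1)/(n+2)] (n = eligible fragends) so the binomial tail is
always defined; fewer than 1000 eligible fragends triggers a warning, zero
is an error. Note the planted/real distal contacts do contribute to p₀ —
the background is deliberately estimated without masking unknown signal,
which makes the test conservative.

**Statistic and segments.** Each window's p-value is the binomial upper
tail P(X ≥ x) with X ~ Binomial(k, p₀), computed via the survival function
(verified against exhaustive summation to relative error < 10⁻¹⁰ for all
k ≤ 25). Windows with p < 10⁻⁸ are significant; the stringent fixed cutoff
replaces an explicit multiple-testing correction (a chromosome of 10⁴
windows has expected false calls ≈ 10⁻⁴ per dataset). Significant windows
whose start indices differ by at most k (overlapping or touching) merge
into a segment spanning from the first window's first fragend to the last
window's last fragend, carrying the minimum member p-value. Windows lying
wholly inside the viewpoint self-circle zone (viewpoint fragend ± 2
fragends) are excluded; with calibrated k (≥ 20) no window fits inside the
default zone, so the guard only bites when a caller passes a small k
explicitly — it exists to keep self-ligation signal out of deliberately
fine-grained scans and can be disabled.

## Candidate-gene filter

Criterion 1 uses merged segment boundaries: a gene qualifies when any of
its TSS records is within 5 kbp (inclusive — the 5,000 bp boundary is in,
5,001 bp is out) of a segment, at distance 0 when inside; the gene carries
the minimum p among qualifying segments. Criterion 2 is a point-in-interval
overlap of the tag SNP or any precomputed LD partner with any H3K27ac peak
of the cell type (LD computation from genotype panels is out of scope; a
SNP missing from the LD table is assessed on the tag SNP alone, with a
warning). Criterion 3 is strict: log₂ RPKM > −0.5, so a gene at exactly
−0.5 fails; genes absent from the expression table count as not expressed.
Candidate records are gene × cell type × locus; novelty is membership
against a user-supplied known-gene list, reported distance is |tag SNP
position − TSS|, and Venn regions partition distinct genes by exact
cell-type membership.

## Downstream statistics

*TSS occupancy* is the mean track signal over TSS ± 2 kbp, normalised by
the in-bounds window width at chromosome edges; the detected-vs-other
contrast reports group medians and a two-sided Wilcoxon rank-sum test (the
contrast needs a test; rank-sum is the natural nonparametric choice for
skewed occupancy values). *CTCF counts* use peak midpoints with strict
betweenness, symmetric in the endpoints and defined only in cis. *eQTL
concordance* first restricts eQTL genes to the annotation universe, then
reports per SNP the fraction of its eQTL genes found among that SNP's
candidates, and as a control the fraction falling among non-interacting
genes within ± 2 Mb of the viewpoint. *Gene-set concordance* is |A∩B|/|A|,
undefined (error) for empty A.

**GSEA.** The enrichment score is the classic weighted Kolmogorov–Smirnov
running sum: walking the list in descending metric order, set members add
|metric|^w normalised over set members (w = 1 by default), others subtract
1/(N − N_set); ES is the signed maximum deviation. Significance uses
gene-set permutation — random sets of equal size drawn without replacement
from the ranked genes — because the ranking metric arrives pre-computed
(no per-sample phenotypes are available at this stage), a documented
divergence from phenotype permutation. NES divides ES by the mean |null ES|
of matching sign. The reported p-value is two-sided on the ES magnitude
with the add-one correction, p = (1 + #{|ES_null| ≥ |ES|}) / (n_perm + 1).
A one-sided count conditioned on the observed sign would be miscalibrated:
since the sign itself is data-chosen, its null p-value is uniform on
(0, ~0.5) and rejects at twice the nominal rate, while the magnitude
statistic is exchangeable with its null draws and hence exactly uniform —
verified by the calibration test — and attains the floor 1/(n_perm + 1)
for a genuinely enriched set.

## Synthetic-data generator

The generator defines the study conditions; its outputs are first-class,
tested code. Per fragend, coverage is one Bernoulli draw with probability
max(background, 2^(−d/halflife), planted), i.e. the max — not the sum — of
the three mechanisms, keeping strata interpretable and each fragend a
single draw. Design choices and defaults:

- **GATC placement is explicit**: a Poisson(L · density/1000) number of
  sites at uniform positions (≥ 4 bp apart) is written into background
  sequence that is scrubbed GATC-free beforehand (every chance occurrence
  is overwritten with AAAA; occurrences cannot overlap and the replacement
  cannot create new ones, so the residual rate at density 0 is exactly
  zero). Site count is thus controllable, at the cost of slightly
  non-uniform background composition at scrub positions. Default density
  4/kbp matches both random-sequence expectation (4⁻⁴ per bp) and the
  genome-wide DpnII site spacing of a few hundred bp.
- **Decay halflife** default 20 kbp: cross-linking contact frequency falls
  to background within ~100 kbp of the viewpoint. No empirical decay curve
  is fitted; the halflife is a modelling choice, not a measured value, and
  tests that need a decay-free null set it to a few hundred bp.
- **Background coverage** default 0.05; planted contacts must exceed it
  (validated) so strata are identifiable.
- **Seeding**: one global seed fans out into named substreams
  (genome × chromosome, coverage × viewpoint × cell type, annotations), so
  outputs are byte-reproducible and adding a viewpoint leaves the others'
  draws untouched.
- **Annotations**: target genes get a TSS at the centre of each planted
  contact; decoy genes are placed ≥ 150 kbp from any viewpoint and
  ≥ 20 kbp from any contact, because the viewpoint decay zone genuinely
  produces significant proximal segments and a decoy inside it would be a
  *correct* call, not a false positive. Expression values straddle the
  log₂ RPKM = −0.5 boundary by construction (expressed ≈ +2 or +1,
  silent ≈ −2); eQTL genes are drawn from the true targets; the ranked DE
  table gives targets N(2.5, 0.5) fold changes against N(0, 1) decoys.

What the generator does *not* emulate — PCR duplication, ligation bias,
trans-chromosomal contacts, read-quality errors, realistic gene density or
LD structure — bounds what passing tests show: they certify the inference
machinery (calibration, error control, recovery, round-trip exactness)
under the stated coverage model, not performance on real sequencing
artefacts.

## Problem sizes in the test suite

The suites run on toy genomes (0.1–1.8 Mbp chromosomes at 4 GATC sites per
kbp, i.e. ~10³–10⁴ usable fragends per chromosome): planted-contact
recovery over 20 coverage seeds on a 1 Mbp chromosome; false-call control
over 100 null profiles of 10⁴ fragends; a 92-viewpoint × 3-cell-type study
on four 600 kbp chromosomes; GSEA calibration over 500 replicates at 199
permutations plus planted-power checks at 1000. These sizes give the
binomial and permutation checks their nominal resolution (e.g. 3·SE bands,
p-floors) while keeping the whole suite in the seconds-to-minutes range.

## Known limitations

Exact 16-mer matching has no mismatch tolerance, so sequencing errors in
real data would lower coverage uniformly (the binary statistic is
insensitive to uniform loss, but calibration of k absorbs it). The
background model is a single chromosome-wide rate; real profiles show
domain-scale heterogeneity that a monotone or domainogram background would
capture better. Trans interactions are counted during mapping but never
called. The eQTL and GSEA stages consume pre-computed tables; no
genotype-level discovery or per-sample differential expression is
performed.
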