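"""Downstream validation statistics: occupancy, CTCF counts, eQTL
concordance and permutation GSEA."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fourc as fc


def track(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def gene_table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss"])


class TestTssOccupancy:
    def test_constant_track_gives_one(self):
        t = track([("chr1", 0, 1_000_000, 1.0)])
        g = gene_table([("g1", "chr1", 50_000), ("g2", "chr1", 200_000)])
        occ = fc.tss_occupancy(t, g)
        assert occ["g1"] == pytest.approx(1.0)
        assert occ["g2"] == pytest.approx(1.0)

    def test_zero_track_gives_zero(self):
        t = track([("chr1", 0, 10, 0.0)])
        g = gene_table([("g1", "chr1", 50_000)])
        assert fc.tss_occupancy(t, g)["g1"] == 0.0

    def test_edge_window_normalised_by_covered_width(self):
        # TSS at 500: window [-1500, 2500) truncated to [0, 2500)
        t = track([("chr1", 0, 10_000, 1.0)])
        g = gene_table([("g1", "chr1", 500)])
        assert fc.tss_occupancy(t, g)["g1"] == pytest.approx(1.0)

    def test_contrast_recovers_planted_ratio(self):
        rows, detected = [], set()
        genes = []
        for i in range(30):
            pos = 10_000 + i * 10_000
            value = 2.0 if i % 2 == 0 else 1.0
            if i % 2 == 0:
                detected.add(f"g{i}")
            rows.append(("chr1", pos - 2000, pos + 2000, value))
            genes.append((f"g{i}", "chr1", pos))
        occ = fc.tss_occupancy(track(rows), gene_table(genes))
        res = fc.occupancy_contrast(occ, detected)
        assert res["median_detected"] / res["median_other"] == pytest.approx(2.0)
        assert res["p_value"] < 0.01


class TestCtcfBetween:
    @pytest.fixture()
    def peaks(self):
        return pd.DataFrame({"chrom": ["chr1"] * 3,
                             "start": [190, 290, 590], "end": [210, 310, 610]})

    def test_counts_strictly_between(self, peaks):
        vp = fc.ViewpointSpec("rs1", "chr1", 100, "AAAA")
        assert fc.ctcf_between(vp, "chr1", 500, peaks) == 2

    def test_no_peaks_between(self, peaks):
        vp = fc.ViewpointSpec("rs1", "chr1", 100, "AAAA")
        assert fc.ctcf_between(vp, "chr1", 150, peaks) == 0

    def test_symmetry(self, peaks):
        a = fc.ViewpointSpec("rs1", "chr1", 100, "AAAA")
        b = fc.ViewpointSpec("rs1", "chr1", 500, "AAAA")
        assert fc.ctcf_between(a, "chr1", 500, peaks) == fc.ctcf_between(b, "chr1", 100, peaks)

    def test_additivity_when_split(self, peaks):
        vp_lo = fc.ViewpointSpec("rs1", "chr1", 100, "AAAA")
        vp_mid = fc.ViewpointSpec("rs1", "chr1", 400, "AAAA")
        whole = fc.ctcf_between(vp_lo, "chr1", 700, peaks)
        parts = (fc.ctcf_between(vp_lo, "chr1", 400, peaks)
                 + fc.ctcf_between(vp_mid, "chr1", 700, peaks))
        assert whole == parts  # no midpoint at the split point 400

    def test_trans_pair_rejected(self, peaks):
        vp = fc.ViewpointSpec("rs1", "chr1", 100, "AAAA")
        with pytest.raises(ValueError, match="cis"):
            fc.ctcf_between(vp, "chr2", 500, peaks)


class TestEqtlConcordance:
    def _setup(self, eqtl_rows):
        vp = fc.ViewpointSpec("rs1", "chr1", 1_000_000, "AAAA")
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(20)],
            "chrom": ["chr1"] * 20,
            "tss": [900_000 + 10_000 * i for i in range(20)],
        })
        candidates = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(7)],
            "cell_type": ["ct1"] * 7,
            "snp_id": ["rs1"] * 7,
            "p": [1e-9] * 7, "distance_bp": [0] * 7,
            "log2_rpkm": [1.0] * 7, "novel": [True] * 7,
        })
        eqtl = pd.DataFrame(eqtl_rows, columns=["snp", "gene_id"])
        return eqtl, candidates, genes, [vp]

    def test_subset_of_candidates_gives_full_concordance(self):
        eqtl, cand, genes, vps = self._setup([("rs1", f"g{i}") for i in range(5)])
        per_snp, totals = fc.eqtl_concordance(eqtl, cand, genes, vps)
        assert totals["interacting_fraction"] == 1.0
        assert totals["noninteracting_fraction"] == 0.0

    def test_genes_outside_annotation_dropped(self):
        eqtl, cand, genes, vps = self._setup(
            [("rs1", "g0"), ("rs1", "not_in_annotation")]
        )
        per_snp, totals = fc.eqtl_concordance(eqtl, cand, genes, vps)
        assert per_snp.iloc[0]["n_eqtl_genes"] == 1
        assert totals["interacting_fraction"] == 1.0

    def test_seven_of_ten_eqtl_genes_planted(self):
        eqtl, cand, genes, vps = self._setup([("rs1", f"g{i}") for i in range(10)])
        per_snp, totals = fc.eqtl_concordance(eqtl, cand, genes, vps)
        assert totals["interacting_fraction"] == pytest.approx(0.7)
        assert totals["noninteracting_fraction"] == pytest.approx(0.3)


class TestGenesetConcordance:
    def test_subset_gives_one(self):
        assert fc.geneset_concordance({"a", "b"}, {"a", "b", "c"}) == 1.0

    def test_disjoint_gives_zero(self):
        assert fc.geneset_concordance({"a"}, {"b"}) == 0.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fc.geneset_concordance(set(), {"a"})

    def test_synthetic_replicates_are_concordant(self, strong_study):
        """Two coverage replicates of the same planted truth recover
        highly overlapping candidate gene sets."""
        import dataclasses

        res_a = fc.run_candidate_pipeline(strong_study)
        cfg_b = dataclasses.replace(strong_study.config, seed=12)
        study_b = dataclasses.replace(strong_study, config=cfg_b)
        study_b.profiles = {
            key: fc.simulate_coverage(
                strong_study.library, profile.viewpoint, cfg_b,
                cell_type=profile.cell_type,
                planted=strong_study.truth.planted[profile.viewpoint.snp_id],
            )[0]
            for key, profile in strong_study.profiles.items()
        }
        res_b = fc.run_candidate_pipeline(study_b)
        conc = fc.geneset_concordance(set(res_b.candidates["gene_id"]),
                                      set(res_a.candidates["gene_id"]))
        assert conc >= 0.9


class TestGseaEs:
    def test_top_single_hit_reaches_one(self):
        ranked = pd.DataFrame({"gene_id": [f"g{i}" for i in range(10)],
                               "metric": np.linspace(5, 0.5, 10)})
        es, running = fc.gsea_es(ranked, {"g0"})
        assert es == pytest.approx(1.0)
        assert running[0] == pytest.approx(1.0)

    def test_whole_list_as_set_gives_one(self):
        ranked = pd.DataFrame({"gene_id": ["a", "b", "c"], "metric": [3.0, 2.0, 1.0]})
        es, _ = fc.gsea_es(ranked, {"a", "b", "c"})
        assert es == pytest.approx(1.0)

    def test_matches_brute_force_running_sum(self):
        """Hand computation on a 6-gene list with signed metrics."""
        metrics = [3.0, 2.0, 1.0, -1.0, -2.0, -3.0]
        ranked = pd.DataFrame({"gene_id": [f"g{i}" for i in range(6)],
                               "metric": metrics})
        gene_set = {"g0", "g1"}
        # independent step-by-step walk
        sw = abs(metrics[0]) + abs(metrics[1])
        walk, run = [], 0.0
        for i, m in enumerate(metrics):
            run += abs(m) / sw if f"g{i}" in gene_set else -1.0 / 4
            walk.append(run)
        expected = walk[int(np.argmax(np.abs(walk)))]
        es, running = fc.gsea_es(ranked, gene_set)
        assert np.allclose(running, walk)
        assert es == pytest.approx(expected)

    def test_disjoint_set_rejected(self):
        ranked = pd.DataFrame({"gene_id": ["a"], "metric": [1.0]})
        with pytest.raises(ValueError, match="disjoint"):
            fc.gsea_es(ranked, {"zzz"})

    @given(scale=st.floats(0.1, 100.0), seed=st.integers(0, 100))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_bounds_and_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        ranked = pd.DataFrame({"gene_id": [f"g{i}" for i in range(30)],
                               "metric": rng.normal(size=30)})
        gene_set = {f"g{i}" for i in rng.choice(30, size=5, replace=False)}
        es, _ = fc.gsea_es(ranked, gene_set)
        assert abs(es) <= 1.0 + 1e-12
        scaled = ranked.assign(metric=ranked["metric"] * scale)
        es2, _ = fc.gsea_es(scaled, gene_set)
        assert es2 == pytest.approx(es, rel=1e-9)


@pytest.fixture(scope="module")
def ranked():
    rng = np.random.default_rng(0)
    return pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(200)],
        "metric": np.sort(rng.normal(size=200))[::-1],
    })


class TestGseaSignificance:

    def test_deterministic_given_seed(self, ranked):
        a = fc.gsea_significance(ranked, {f"g{i}" for i in range(15)}, seed=3)
        b = fc.gsea_significance(ranked, {f"g{i}" for i in range(15)}, seed=3)
        assert a == b

    def test_pvalue_respects_permutation_floor(self, ranked):
        res = fc.gsea_significance(ranked, {f"g{i}" for i in range(20)},
                                   n_perm=1000, seed=1)
        assert res.pvalue >= res.p_floor
        assert res.pvalue == pytest.approx(res.p_floor)  # planted top decile
        assert res.nes > 0

    def test_too_few_permutations_rejected(self, ranked):
        with pytest.raises(ValueError, match="100"):
            fc.gsea_significance(ranked, {"g0"}, n_perm=50)

    def test_set_as_large_as_list_rejected(self, ranked):
        with pytest.raises(ValueError, match="smaller"):
            fc.gsea_significance(ranked, set(ranked["gene_id"]), n_perm=100)
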