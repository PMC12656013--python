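"""Simulator contracts: panel construction, funnel genetics, phenotypes."""

import copy

import numpy as np
import pytest
from scipy import stats

import magic_ratoon as mr
import magic_ratoon.simulate as sim


class TestFounderPanel:
    def test_minimal_panel_is_polymorphic_biallelic(self):
        panel = mr.build_founder_panel(n_chr=1, sites_per_chr=1, indel_fraction=0, seed=3)
        fa = panel.founder_alleles["chr01"]
        assert fa.shape == (8, 1)
        assert 1 <= fa.sum() <= 4  # minor allele carried by 1..4 founders
        assert len(panel.ref["chr01"][0]) == len(panel.alt["chr01"][0]) == 1

    def test_site_count_and_ordering(self):
        panel = mr.build_founder_panel(n_chr=12, sites_per_chr=2000, seed=5)
        assert panel.n_sites == 24_000
        for c in panel.chrom_names:
            assert np.all(np.diff(panel.positions[c]) > 0)

    def test_determinism(self):
        a = mr.build_founder_panel(n_chr=2, sites_per_chr=50, seed=9)
        b = mr.build_founder_panel(n_chr=2, sites_per_chr=50, seed=9)
        for c in a.chrom_names:
            assert np.array_equal(a.positions[c], b.positions[c])
            assert np.array_equal(a.founder_alleles[c], b.founder_alleles[c])
            assert a.ref[c] == b.ref[c] and a.alt[c] == b.alt[c]

    @pytest.mark.parametrize("kwargs", [
        {"n_chr": 0}, {"sites_per_chr": 0}, {"indel_fraction": 1.5},
    ])
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            mr.build_founder_panel(**{"n_chr": 1, "sites_per_chr": 5, **kwargs})

    def test_minor_founder_counts_span_one_to_four(self):
        panel = mr.build_founder_panel(n_chr=1, sites_per_chr=400, seed=7)
        counts = panel.founder_alleles["chr01"].sum(axis=0)
        assert set(np.unique(counts)) == {1, 2, 3, 4}


class TestFunnel:
    def test_pedigree_invariants(self):
        with pytest.raises(ValueError):
            mr.FunnelPedigree(two_way_crosses=[("DA5", "DA5"), ("ZS97", "MH63"),
                                               ("YJSM", "IR34"), ("GC2", "Cypress")])
        with pytest.raises(ValueError):
            mr.FunnelPedigree(ssd_generations=0)

    def test_no_recombination_gives_single_founder_chromosomes(self, panel_small):
        panel = copy.deepcopy(panel_small)
        for c in panel.chromosomes:
            c.length_cm = 0.0
        ped = mr.FunnelPedigree(n_eight_way_families=10, f2_plants_per_family=2,
                                ssd_generations=3, n_selected_lines=15)
        lines = mr.simulate_funnel(panel, ped, seed=1)
        for ln in lines:
            for c in panel.chrom_names:
                founders = {f for hom in ln.mosaic[c] for _, _, f in hom}
                assert len(founders) <= 2  # one per homolog, no crossovers
                for hom in ln.mosaic[c]:
                    assert len({f for _, _, f in hom}) == 1

    def test_selection_larger_than_candidates_errors(self, panel_small):
        ped = mr.FunnelPedigree(n_eight_way_families=2, f2_plants_per_family=2,
                                ssd_generations=1, n_selected_lines=100)
        with pytest.raises(ValueError):
            mr.simulate_funnel(panel_small, ped, seed=0)

    def test_mosaic_tiles_chromosome(self, panel_small, lines_small):
        lengths = {c.name: c.length_bp for c in panel_small.chromosomes}
        for ln in lines_small[:10]:
            for c, (h1, h2) in ln.mosaic.items():
                for hom in (h1, h2):
                    assert hom[0][0] == 1.0
                    assert hom[-1][1] == lengths[c] + 1.0
                    for (s1, e1, _), (s2, e2, _) in zip(hom, hom[1:]):
                        assert e1 == s2  # no gaps, no overlaps

    def test_founder_origin_balance(self, panel_small):
        """Each founder contributes ~1/8 of the genome; chi-square goodness
        of fit on single-locus origin counts aggregated over seeds."""
        ped = mr.FunnelPedigree(n_eight_way_families=30, f2_plants_per_family=2,
                                ssd_generations=2, n_selected_lines=60)
        counts = np.zeros(8)
        mads = []
        for seed in range(6):
            lines = mr.simulate_funnel(panel_small, ped, seed=100 + seed)
            for c in panel_small.chrom_names:
                mid = int(panel_small.positions[c][len(panel_small.positions[c]) // 2])
                for ln in lines:
                    f1, f2 = ln.founder_at(c, mid)
                    counts[f1] += 1
                    counts[f2] += 1
            shares = sim.founder_shares(panel_small, lines)
            mads.append(np.abs(shares - 1 / 8).mean())
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert stats.chi2.sf(chi2, df=7) > 0.01
        # law of large numbers: genome-wide share deviation shrinks with n
        big = mr.simulate_funnel(
            panel_small,
            mr.FunnelPedigree(n_eight_way_families=100, f2_plants_per_family=3,
                              ssd_generations=2, n_selected_lines=300),
            seed=200,
        )
        mad_big = np.abs(sim.founder_shares(panel_small, big) - 1 / 8).mean()
        assert mad_big < np.mean(mads)

    def test_ssd_heterozygosity_decay(self, panel_small):
        """Residual heterozygosity halves per SSD generation from the F2
        baseline; lines are the independent replicates for the tolerance."""
        expected_f2 = sim.expected_f2_het(panel_small, mr.FunnelPedigree())
        obs = {}
        for g in (2, 5):
            per_line = []
            for seed in range(4):
                ped = mr.FunnelPedigree(n_eight_way_families=40, f2_plants_per_family=2,
                                        ssd_generations=g, n_selected_lines=80)
                lines = mr.simulate_funnel(panel_small, ped, seed=300 + seed)
                per_line.extend(ln.het_fraction(panel_small.chrom_names) for ln in lines)
            per_line = np.asarray(per_line)
            obs[g] = (per_line.mean(), per_line.std() / np.sqrt(len(per_line)))
        for g in (2, 5):
            mean, se = obs[g]
            assert abs(mean - expected_f2 * 0.5 ** g) < 4 * se + 5e-4
        assert obs[2][0] > obs[5][0]
        ratio = obs[2][0] / obs[5][0]
        assert 4 < ratio < 16  # ~2^3 with sampling slack


class TestPhenotypes:
    def test_noise_free_single_qtl_is_step_function(self, panel_small, lines_small):
        c = panel_small.chrom_names[0]
        pos = int(panel_small.positions[c][10])
        spec = sim.TraitSpec(
            mean={"MC": 10.0, "RC": 10.0}, sd={"MC": 2.0, "RC": 2.0},
            qtls={"MC": [sim.PlantedQTL.from_site(panel_small, c, pos, 0.5)], "RC": []},
            shared_var=0.0, batch_var=0.0, residual_var=0.0, specific=0.0,
        )
        arch = mr.TraitArchitecture.default(panel_small)
        arch.traits["PL"] = spec
        book = mr.simulate_phenotypes(panel_small, lines_small, arch, seed=5)
        means = book.line_means("MC")["PL"]
        classes = {}
        for ln in lines_small:
            classes.setdefault(ln.founder_at(c, pos), []).append(means[ln.line_id])
        for vals in classes.values():
            assert np.ptp(vals) < 1e-9  # same founder class -> same phenotype

    def test_qtl_position_must_exist(self, panel_small, lines_small):
        arch = mr.TraitArchitecture.default(panel_small)
        arch.traits["PL"].qtls["MC"] = [
            sim.PlantedQTL("chr01", 999_999_999, (0,) * 7 + (1,), 0.2)
        ]
        with pytest.raises(ValueError, match="no panel site"):
            mr.simulate_phenotypes(panel_small, lines_small, arch, seed=1)

    def test_planted_pve_contract(self, panel_302, lines_302):
        """A 0.20-PVE QTL yields squared class-phenotype correlation of
        about 0.20 across generator seeds."""
        from conftest import qtl_architecture

        arch, (c, pos) = qtl_architecture(panel_302, pve=0.20)
        r2s = []
        for seed in range(20):
            book = mr.simulate_phenotypes(panel_302, lines_302, arch, seed=400 + seed)
            means = book.line_means("MC")["PL"]
            cls = np.array([
                0.5 * sum(panel_302.founder_alleles[c][f, panel_302.site_index(c, pos)]
                          for f in ln.founder_at(c, pos))
                for ln in lines_302
            ])
            y = means.reindex([ln.line_id for ln in lines_302]).to_numpy()
            r2s.append(np.corrcoef(cls, y)[0, 1] ** 2)
        assert abs(np.mean(r2s) - 0.20) < 0.06

    def test_opposing_seasonal_effects_flip_sign(self, panel_302, lines_302):
        """The default architecture plants a TN locus with opposite effects
        in main and ratoon crops; class-mean differences change sign."""
        arch = mr.TraitArchitecture.default(panel_302)
        q = arch.traits["TN"].qtls["MC"][0]
        book = mr.simulate_phenotypes(panel_302, lines_302, arch, seed=77)
        idx = panel_302.site_index(q.chrom, q.pos)
        carrier = np.array([
            sum(panel_302.founder_alleles[q.chrom][f, idx] for f in ln.founder_at(q.chrom, q.pos)) > 0
            for ln in lines_302
        ])
        ids = [ln.line_id for ln in lines_302]
        diffs = {}
        for season in ("MC", "RC"):
            tn = book.line_means(season)["TN"].reindex(ids).to_numpy()
            diffs[season] = tn[carrier].mean() - tn[~carrier].mean()
        assert diffs["MC"] * diffs["RC"] < 0

    def test_cross_season_correlation_target(self, panel_302, lines_302):
        """Planted PL cross-season correlation ~0.67 is recovered."""
        arch = mr.TraitArchitecture.default(panel_302)
        target = arch.traits["PL"].expected_cross_season_r()
        assert abs(target - 0.67) < 0.03  # default architecture plants ~0.67
        rs = []
        for seed in range(6):
            book = mr.simulate_phenotypes(panel_302, lines_302, arch, seed=500 + seed)
            mc = book.line_means("MC")["PL"]
            rc = book.line_means("RC")["PL"]
            rs.append(np.corrcoef(mc, rc.reindex(mc.index))[0, 1])
        assert abs(np.mean(rs) - 0.67) < 0.08

    def test_phenotype_book_invariants(self, book_small):
        df = book_small.frame
        assert (df[["TN", "PL", "SPP"]] > 0).all().all()
        assert (df["GY"] >= 0).all()
        assert set(df["season"]) == {"MC", "RC"}
        assert set(df["batch"]) == {1, 2, 3}
        ra = book_small.ratooning_ability()
        assert ra.notna().all()


class TestBundle:
    def test_empty_line_list_valid_vcf(self, panel_small, genes_small, tmp_path):
        import pandas as pd

        from magic_ratoon.io import read_vcf

        book = sim.PhenotypeBook(frame=pd.DataFrame(
            columns=["line_id", "season", "replicate", "batch", "TN", "PL", "SPP", "GY"]
        ))
        paths = mr.write_synthetic_bundle(panel_small, [], genes_small, book, tmp_path, seed=1)
        vt = read_vcf(paths["vcf"])
        assert vt.n_samples == 0
        assert vt.n_sites == panel_small.n_sites

    def test_fail_fraction_contract(self, bundle_small, variants_small, panel_small):
        """fail_fraction=0.3 leaves ~70% of sites passing QC, within
        binomial tolerance."""
        import magic_ratoon.qc as qc

        stats_df = qc.compute_site_stats(variants_small)
        kept, _ = qc.filter_sites(stats_df)
        m = panel_small.n_sites
        expect = 0.7 * m
        assert abs(len(kept) - expect) < 3.5 * np.sqrt(m * 0.3 * 0.7) + 3

    def test_roundtrip_lossless(self, bundle_small, variants_small, panel_small, lines_small):
        dos = variants_small.dosage()
        truth = np.vstack([ln.dosage(panel_small.chrom_names) for ln in lines_small]).T
        assert np.array_equal(dos, truth)
        assert variants_small.samples == [ln.line_id for ln in lines_small]
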