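"""Synthetic panel, phenotype model, and full-dataset generation."""

import numpy as np
import pandas as pd
import pytest

from tamemap import (
    GroupSpec,
    MapSpec,
    PhenotypeModel,
    WHSDesign,
    classify_snp_sharing,
    generate_founder_panel,
    generate_whs_dataset,
    phenotype_trait,
    private_allele_frequencies,
    simulate_polygenic_breeding,
)
from tamemap.founders import PRIVATE_SNP_COUNTS, SHARING_CATEGORY_COUNTS
from tamemap.synthetic_data import DEFAULT_CATEGORY_COUNTS


class TestFounderPanelGeneration:
    def test_zero_counts_give_empty_panel(self):
        panel, gmap = generate_founder_panel(
            category_counts={1: 0, 2: 0, 3: 0, 4: 0}, seed=0
        )
        assert panel.n_snps == 0

    def test_requested_snps_beyond_grid_rejected(self):
        spec = MapSpec(n_chroms=1, length_cm=1.0, spacing_cm=0.5)
        with pytest.raises(ValueError, match="grid positions"):
            generate_founder_panel(category_counts={1: 10}, map_spec=spec, seed=0)

    def test_default_category_proportions_track_published_table(self):
        """Category share of the default panel matches the published 39.4%
        (category 1) and 37.8% (category 2) within rounding."""
        panel, _ = generate_founder_panel(seed=1)
        counts = classify_snp_sharing(panel).category_counts()
        total = sum(counts.values())
        for cat in (1, 2, 3, 4):
            published = SHARING_CATEGORY_COUNTS[cat] / sum(SHARING_CATEGORY_COUNTS.values())
            assert counts[cat] / total == pytest.approx(published, abs=0.005)

    def test_private_snp_counts_skewed_like_published_strains(self):
        panel, _ = generate_founder_panel(seed=2)
        priv = classify_snp_sharing(panel).private_counts_by_strain()
        # the two domesticus strains dominate, MSM/CHD/KJR are scarce
        assert priv["PGN2"] > priv["HMI"] > priv["MSM"] > 0
        w = np.array([PRIVATE_SNP_COUNTS[s] for s in priv])
        got = np.array(list(priv.values()))
        corr = np.corrcoef(w, got)[0, 1]
        assert corr > 0.98

    def test_uniform_weights_flatten_the_skew(self):
        panel, _ = generate_founder_panel(
            category_counts={1: 800}, strain_weights="uniform", seed=3
        )
        priv = classify_snp_sharing(panel).private_counts_by_strain()
        assert max(priv.values()) < 3 * min(priv.values())

    def test_extra_private_snp_pinned_at_position(self):
        panel, _ = generate_founder_panel(
            category_counts={1: 50}, extra_private=[("11", 35.0, "MSM")], seed=4
        )
        sub = panel.snps[(panel.snps["chrom"] == "11") & (panel.snps["cM"] == 35.0)]
        assert len(sub) == 1
        sharing = classify_snp_sharing(panel)
        row = sharing.table[sharing.table["snp_id"] == sub["snp_id"].iloc[0]].iloc[0]
        assert row["minor_strains"] == frozenset({"MSM"})

    def test_panel_and_map_invariants_hold(self, panel_and_map):
        panel, gmap = panel_and_map
        assert panel.validate() == []
        assert gmap.validate() == []


class TestPhenotypeModel:
    def test_deterministic_closed_forms(self):
        silent = PhenotypeModel(mu=1.0, qtl_effect=1.5, sigma_family=0.0, sigma_e=0.0)
        got = [phenotype_trait(d, silent, 0.0, rng=0)[0] for d in (0, 1, 2)]
        assert got == [1.0, 2.5, 4.0]

    def test_flooring_produces_zero_scores(self):
        m = PhenotypeModel(mu=-1.0, qtl_effect=0.0, sigma_family=0.0, sigma_e=0.0)
        c, h = phenotype_trait(0, m, 0.0, rng=0)
        assert c == 0.0 and h == 0.0

    def test_zero_noise_model_returns_mu_for_any_dosage(self):
        m = PhenotypeModel(mu=2.0, qtl_effect=0.0, sigma_family=0.0, sigma_e=0.0)
        assert {phenotype_trait(d, m, 0.0, rng=1)[0] for d in (0, 1, 2)} == {2.0}

    def test_heading_correlates_with_contacting_at_rho(self):
        m = PhenotypeModel(
            mu=0.0, qtl_effect=0.0, sigma_family=0.0, sigma_e=1.0, rho=0.6,
            floor_at_zero=False,
        )
        rng = np.random.default_rng(2)
        draws = np.array([phenotype_trait(0, m, 0.0, rng) for _ in range(20_000)])
        corr = np.corrcoef(draws[:, 0], draws[:, 1])[0, 1]
        assert corr == pytest.approx(0.6, abs=0.02)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PhenotypeModel(sigma_e=-1.0)
        with pytest.raises(ValueError):
            PhenotypeModel(rho=1.5)


class TestWHSDataset:
    def test_truth_dosage_matches_projected_genotypes(self, selected_dataset):
        """Genotype at the pinned QTL SNP equals the recorded truth dosage
        for every final-generation breeder."""
        ds = selected_dataset
        meta = ds.panel.snps
        qtl = ds.truth["qtl"]
        snp = meta[(meta["chrom"] == qtl["chrom"]) & (meta["cM"] == qtl["cM"])]
        snp_id = snp["snp_id"].iloc[0]
        for iid in ds.truth["final_breeders"]:
            expect = ds.genomes[iid].dosage_of(qtl["carrier_strain"], qtl["chrom"], qtl["cM"])
            assert ds.genotypes.values.at[iid, snp_id] == expect
            if iid in ds.truth["dosages"]:
                assert ds.truth["dosages"][iid] == expect

    def test_selection_raises_qtl_frequency_above_control(self, selected_dataset):
        ds = selected_dataset
        sharing = classify_snp_sharing(ds.panel)
        qtl = ds.truth["qtl"]
        freqs = {}
        for grp in ("S", "C"):
            ids = list(ds.pedigree.final_breeders(group=grp)["id"])
            res = private_allele_frequencies(ds.genotypes, sharing, qtl["carrier_strain"], ids)
            snp = ds.panel.snps[
                (ds.panel.snps["chrom"] == qtl["chrom"]) & (ds.panel.snps["cM"] == qtl["cM"])
            ]["snp_id"].iloc[0]
            freqs[grp] = float(res.frequencies.set_index("snp_id").at[snp, "frequency"])
        assert freqs["S"] > freqs["C"]

    def test_selected_line_contacting_exceeds_control(self, selected_dataset):
        ph = selected_dataset.phenotypes
        last = ph[ph["generation"] == ph["generation"].max()]
        means = last.groupby("group")["contacting"].mean()
        assert means["S"] > means["C"]

    def test_paired_seeds_qtl_enrichment_direction(self):
        """Across independent seeds, the carrier-haplotype frequency at the
        QTL among final breeders is higher with selection on than off."""
        design = WHSDesign(last_generation=8, groups=(GroupSpec("S", 3, None, True),))
        diffs = []
        for seed in (101, 102, 103):
            on = generate_whs_dataset(design=design, seed=seed)
            off = generate_whs_dataset(
                design=design, selection={"S": False}, seed=seed
            )
            def qtl_freq(ds):
                q = ds.truth["qtl"]
                ids = ds.truth["final_breeders"]
                return np.mean(
                    [ds.genomes[i].dosage_of(q["carrier_strain"], q["chrom"], q["cM"]) for i in ids]
                ) / 2.0
            diffs.append(qtl_freq(on) - qtl_freq(off))
        assert np.mean(diffs) > 0

    def test_seed_determinism(self):
        design = WHSDesign(last_generation=5)
        a = generate_whs_dataset(design=design, seed=77)
        b = generate_whs_dataset(design=design, seed=77)
        pd.testing.assert_frame_equal(a.pedigree.table, b.pedigree.table)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        pd.testing.assert_frame_equal(a.genotypes.values, b.genotypes.values)

    def test_null_model_groups_differ_only_by_noise(self):
        model = PhenotypeModel(qtl_effect=0.0)
        design = WHSDesign(last_generation=6)
        gaps = []
        for seed in (7, 8):
            ds = generate_whs_dataset(
                design=design, model=model, selection={"S": False}, seed=seed
            )
            m = ds.phenotypes.groupby("group")["contacting"].mean()
            gaps.append(abs(m["S"] - m["C"]))
        assert np.mean(gaps) < 0.8


class TestPolygenicBreeding:
    def test_layout_and_flags(self):
        ph = simulate_polygenic_breeding(0.2, last_generation=5, seed=0)
        assert set(ph["group"]) == {"S", "C"}
        cell = ph.groupby(["group", "generation", "family", "sex"]).size()
        assert (cell == 5).all()
        sel = ph[ph["selected"]]
        assert set(sel["group"]) == {"S"}
        # selected animal is the top scorer of its cell
        top = ph.groupby(["group", "generation", "family", "sex"])["contacting"].transform("max")
        assert np.allclose(sel["contacting"], top[sel.index])

    def test_invalid_h2_rejected(self):
        with pytest.raises(ValueError):
            simulate_polygenic_breeding(1.0)
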