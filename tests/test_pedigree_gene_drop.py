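"""WHS mating design, meiosis model, and the two gene-drop engines."""

import numpy as np
import pandas as pd
import pytest

from tamemap import (
    DEFAULT_STRAINS,
    DiploidGenome,
    GeneticMap,
    HaplotypeMosaic,
    Pedigree,
    build_whs_pedigree,
    gene_drop,
    genotypes_from_mosaics,
    simulate_meiosis,
    validate_pedigree,
)
from tamemap.pedigree_gene_drop import (
    PED_COLUMNS,
    ancestry_gene_drop,
    founder_strains,
    uniform_map,
)

from conftest import make_panel


def empty_map(chrom_lengths):
    return GeneticMap(
        chrom_lengths, pd.DataFrame({"chrom": [], "snp_id": [], "bp": [], "cM": []})
    )


def tiny_pedigree(rows):
    """Pedigree from (id, sire, dam, sex, gen, strain) tuples."""
    table = pd.DataFrame(
        [
            dict(
                id=i, sire=s, dam=d, sex=x, generation=g, group="T", family="01",
                selected=False, breeder=(g == max(r[4] for r in rows)),
                founder_strain=st,
            )
            for i, s, d, x, g, st in rows
        ],
        columns=PED_COLUMNS,
    )
    return Pedigree(table)


@pytest.fixture()
def ab_cross():
    """A x B founders -> one F1 pair -> two G2 offspring."""
    return tiny_pedigree(
        [
            ("fA", "", "", "F", 0, "A"),
            ("mB", "", "", "M", 0, "B"),
            ("f1F", "mB", "fA", "F", 1, ""),
            ("f1M", "mB", "fA", "M", 1, ""),
            ("c1", "f1M", "f1F", "F", 2, ""),
            ("c2", "f1M", "f1F", "M", 2, ""),
        ]
    )


class TestWHSDesign:
    def test_rotation_generation_one_structure(self):
        ped = build_whs_pedigree(last_generation=1, seed=0)
        g1 = ped.table[ped.table["generation"] == 1]
        assert g1["family"].nunique() == 8
        strain_of = dict(zip(ped.table["id"], ped.table["founder_strain"]))
        dam_strains, sire_strains = [], []
        for _, fam in g1.groupby("family"):
            parents = {(r["dam"], r["sire"]) for _, r in fam.iterrows()}
            assert len(parents) == 1  # one pair per family
            (dam, sire), = parents
            ds, ss = strain_of[dam], strain_of[sire]
            assert ds != ss
            dam_strains.append(ds)
            sire_strains.append(ss)
        # every strain is used exactly twice: once as a dam line, once as a sire line
        for strain in DEFAULT_STRAINS:
            assert dam_strains.count(strain) == 1
            assert sire_strains.count(strain) == 1

    def test_generation_zero_is_founders_only(self):
        ped = build_whs_pedigree(last_generation=0)
        assert len(ped) == 16
        assert validate_pedigree(ped) == []

    def test_full_design_is_structurally_valid(self, whs_pedigree):
        assert validate_pedigree(whs_pedigree) == []
        assert len(whs_pedigree.final_breeders()) == 32

    def test_random_mating_never_pairs_full_sibs(self):
        """Exhaustive scan of all matings over many seeded builds."""
        for seed in range(150):
            ped = build_whs_pedigree(last_generation=5, seed=seed)
            parents_of = {
                r["id"]: (r["sire"], r["dam"])
                for _, r in ped.table.iterrows()
                if r["generation"] > 0
            }
            matings = {
                (r["sire"], r["dam"])
                for _, r in ped.table.iterrows()
                if r["generation"] >= 4  # produced by G3+ random pairing
            }
            for sire, dam in matings:
                assert parents_of[sire] != parents_of[dam], (seed, sire, dam)

    def test_candidate_litters_and_hook_choice(self):
        picked = []

        def hook(group, gen, fam, sex, cands):
            picked.append((gen, fam, sex))
            return cands[-1]

        ped = build_whs_pedigree(last_generation=4, seed=3, selection_hook=hook)
        g4 = ped.table[ped.table["generation"] == 4]
        assert len(g4) == 16 * 10  # 5 candidates per sex per family
        assert g4["breeder"].sum() == 32
        assert all(i.endswith("5") for i in g4[g4["breeder"]]["id"])
        assert len(picked) == 2 * 16 * 2  # gens 3-4, 16 families, 2 sexes


class TestValidatePedigree:
    def test_cycle_detected(self):
        ped = tiny_pedigree(
            [
                ("fA", "", "", "F", 0, "A"),
                ("x", "y", "fA", "M", 1, ""),
                ("y", "x", "fA", "M", 2, ""),
            ]
        )
        assert any("cycle" in v for v in validate_pedigree(ped))

    def test_sex_inconsistent_dam_detected(self):
        ped = tiny_pedigree(
            [
                ("fA", "", "", "M", 0, "A"),  # dam recorded as male
                ("mB", "", "", "M", 0, "B"),
                ("kid", "mB", "fA", "F", 1, ""),
            ]
        )
        assert any("recorded as M" in v for v in validate_pedigree(ped))

    def test_single_recorded_parent_detected(self):
        ped = tiny_pedigree(
            [("fA", "", "", "F", 0, "A"), ("kid", "", "fA", "F", 1, "")]
        )
        assert any("one recorded parent" in v for v in validate_pedigree(ped))


class TestMeiosis:
    def _parent(self, lengths):
        return DiploidGenome(
            HaplotypeMosaic.founder("A", lengths), HaplotypeMosaic.founder("B", lengths)
        )

    def test_zero_length_chromosome_single_segment(self):
        lengths = {"1": 0.0}
        rng = np.random.default_rng(0)
        labels = {
            simulate_meiosis(self._parent(lengths), empty_map(lengths), rng).segments["1"][0][2]
            for _ in range(40)
        }
        assert labels == {"A", "B"}

    def test_crossover_count_is_poisson_with_map_length_mean(self):
        """Mean crossovers on a 100 cM chromosome is L/100 = 1."""
        lengths = {"1": 100.0}
        gmap = empty_map(lengths)
        parent = self._parent(lengths)
        rng = np.random.default_rng(1)
        n = 20_000
        # A/B labels differ at every breakpoint, so crossovers = segments - 1
        counts = np.array(
            [len(simulate_meiosis(parent, gmap, rng).segments["1"]) - 1 for _ in range(n)]
        )
        se = counts.std(ddof=1) / np.sqrt(n)
        assert counts.mean() == pytest.approx(1.0, abs=4 * se)

    def test_recombination_fraction_matches_haldane(self):
        """Loci 20 cM apart recombine with frequency (1 - e^-0.4)/2."""
        lengths = {"1": 40.0}
        gmap = empty_map(lengths)
        parent = self._parent(lengths)
        rng = np.random.default_rng(2)
        pos = np.array([10.0, 30.0])
        n = 20_000
        rec = 0
        for _ in range(n):
            lab = simulate_meiosis(parent, gmap, rng).ancestry_at("1", pos)
            rec += lab[0] != lab[1]
        expect = (1 - np.exp(-0.4)) / 2
        se = np.sqrt(expect * (1 - expect) / n)
        assert rec / n == pytest.approx(expect, abs=4 * se)

    def test_mosaic_tiling_invariant_after_chained_meioses(self):
        lengths = uniform_map(4, 80.0)
        gmap = empty_map(lengths)
        rng = np.random.default_rng(3)
        ped = build_whs_pedigree(last_generation=4, seed=5)
        genomes = gene_drop(ped, gmap, rng)
        for g in genomes.values():
            for hap in (g.maternal, g.paternal):
                assert hap.validate(lengths) == []


class TestGeneDrop:
    def test_founder_and_f1_ancestry(self, ab_cross):
        lengths = {"1": 50.0, "2": 60.0}
        genomes = gene_drop(ab_cross, empty_map(lengths), np.random.default_rng(0))
        for chrom, L in lengths.items():
            assert genomes["fA"].maternal.segments[chrom] == [(0.0, L, "A")]
            assert genomes["fA"].paternal.segments[chrom] == [(0.0, L, "A")]
            # F1: one complete A mosaic and one complete B mosaic
            assert genomes["f1F"].maternal.segments[chrom] == [(0.0, L, "A")]
            assert genomes["f1F"].paternal.segments[chrom] == [(0.0, L, "B")]
        assert genomes["f1F"].dosage_of("A", "1", 25.0) == 1

    def test_single_parent_rejected(self):
        ped = tiny_pedigree(
            [("fA", "", "", "F", 0, "A"), ("kid", "", "fA", "F", 1, "")]
        )
        with pytest.raises(ValueError, match="both parents"):
            gene_drop(ped, empty_map({"1": 10.0}), np.random.default_rng(0))

    def test_allele_loss_probability_matches_enumeration(self, ab_cross):
        """One A x B pair, two offspring kept: exhaustive enumeration of the
        2^4 equally likely transmissions gives P(A absent) = (1/2)^4 and
        P(either allele lost) = 2 x (1/2)^4."""
        from tamemap.design_sim import single_locus_drop

        n = 100_000
        A = single_locus_drop(ab_cross, n, rng=np.random.default_rng(9))
        final = A[:, 4:6, :].reshape(n, 4)  # the two G2 offspring
        lost_a = (final != 0).all(axis=1)
        lost_any = lost_a | (final != 1).all(axis=1)
        se = np.sqrt(0.0625 * (1 - 0.0625) / n)
        assert lost_a.mean() == pytest.approx(0.0625, abs=3 * se)
        se2 = np.sqrt(0.125 * (1 - 0.125) / n)
        assert lost_any.mean() == pytest.approx(0.125, abs=3 * se2)


class TestGenotypesFromMosaics:
    def test_founder_homozygous_and_f1_single_copy(self, ab_cross):
        panel = make_panel(
            {
                "a_priv": ["T"] + ["C"] * 7,   # private to strain A = PGN2 slot
                "shared": ["G"] * 4 + ["A"] * 4,
            },
            strains=["A", "B", "S3", "S4", "S5", "S6", "S7", "S8"],
        )
        lengths = {"1": 10.0}
        gmap = GeneticMap(lengths, panel.snps[["chrom", "snp_id", "bp", "cM"]])
        genomes = gene_drop(ab_cross, gmap, np.random.default_rng(0))
        gm = genotypes_from_mosaics(
            {i: genomes[i] for i in ("fA", "mB", "f1F")}, panel, gmap
        )
        assert gm.values.at["fA", "a_priv"] == 2.0
        assert gm.values.at["mB", "a_priv"] == 0.0
        assert gm.values.at["f1F", "a_priv"] == 1.0

    def test_agrees_with_naive_segment_scan(self, panel_and_map):
        """Vectorized projection equals a linear scan over mosaic segments."""
        panel, gmap = panel_and_map
        ped = build_whs_pedigree(last_generation=3, seed=8)
        genomes = gene_drop(ped, gmap, np.random.default_rng(8))
        ids = list(ped.final_breeders()["id"])[:4]
        gm = genotypes_from_mosaics({i: genomes[i] for i in ids}, panel, gmap)

        alleles = panel.allele_matrix()
        strain_idx = {s: k for k, s in enumerate(panel.strains)}
        sub = panel.snps.sample(n=60, random_state=0)
        for iid in ids:
            g = genomes[iid]
            for _, snp in sub.iterrows():
                minor = gm.counted_allele[snp["snp_id"]]
                dose = 0
                for hap in (g.maternal, g.paternal):
                    lab = None
                    for s0, s1, strain in hap.segments[str(snp["chrom"])]:
                        if s0 <= snp["cM"] < s1 or (snp["cM"] == s1 == hap.segments[str(snp["chrom"])][-1][1]):
                            lab = strain
                            break
                    dose += alleles[strain_idx[lab], panel.snps.index[panel.snps["snp_id"] == snp["snp_id"]][0]] == minor
                assert gm.values.at[iid, snp["snp_id"]] == dose

    def test_snp_outside_map_span_raises(self):
        panel = make_panel({"far": ["A"] * 4 + ["C"] * 4})
        gmap = GeneticMap({"1": 0.05}, panel.snps[["chrom", "snp_id", "bp", "cM"]])
        ped = tiny_pedigree([("fA", "", "", "F", 0, "A")])
        genomes = gene_drop(ped, gmap, np.random.default_rng(0))
        with pytest.raises(ValueError, match="far"):
            genotypes_from_mosaics(genomes, panel, gmap)


class TestAncestryEngine:
    def test_matches_mosaic_engine_distribution(self):
        """Dual route: marker-resolution Markov engine vs segment mosaics.

        Compare per-strain ancestry frequencies among G3 breeders and the
        between-replicate spread at matched positions.
        """
        ped = build_whs_pedigree(last_generation=3, seed=21)
        lengths = uniform_map(3, 60.0)
        gmap = empty_map(lengths)
        positions = {c: np.array([5.0, 30.0, 55.0]) for c in lengths}
        strains = founder_strains(ped)
        rows = ped.table.index[
            (ped.table["generation"] == 3) & ped.table["breeder"]
        ].to_numpy()
        ids = ped.table.loc[rows, "id"]

        n = 250
        rng = np.random.default_rng(0)
        fast = np.zeros((n, len(strains)))
        for i in range(n):
            anc = ancestry_gene_drop(ped, positions, strains, rng)
            allc = np.concatenate([anc[c][rows].reshape(-1, 3) for c in anc], axis=1)
            fast[i] = [(allc == k).mean() for k in range(len(strains))]

        slow = np.zeros((n, len(strains)))
        rng2 = np.random.default_rng(1)
        for i in range(n):
            genomes = gene_drop(ped, gmap, rng2)
            labs = []
            for c in lengths:
                for iid in ids:
                    g = genomes[iid]
                    labs.extend(g.maternal.ancestry_at(c, positions[c]))
                    labs.extend(g.paternal.ancestry_at(c, positions[c]))
            labs = np.array(labs, dtype=object)
            slow[i] = [(labs == s).mean() for s in strains]

        se = np.sqrt(fast.var(axis=0) / n + slow.var(axis=0) / n)
        assert np.all(np.abs(fast.mean(0) - slow.mean(0)) < 4 * se + 1e-12)
        # spread of the drift process agrees between engines
        assert np.allclose(fast.std(0).mean(), slow.std(0).mean(), rtol=0.2)

    def test_equal_founder_contribution_expectation(self, whs_pedigree):
        """Expected ancestry of each founder among G12 breeders is 1/8."""
        strains = founder_strains(whs_pedigree)
        rows = whs_pedigree.table.index[
            (whs_pedigree.table["generation"] == 12) & whs_pedigree.table["breeder"]
        ].to_numpy()
        positions = {"7": np.array([10.0, 35.0, 60.0])}
        rng = np.random.default_rng(5)
        n = 400
        freqs = np.zeros((n, 8))
        for i in range(n):
            anc = ancestry_gene_drop(whs_pedigree, positions, strains, rng)["7"]
            sub = anc[rows].reshape(-1, 3)
            freqs[i] = [(sub == k).mean() for k in range(8)]
        se = freqs.std(axis=0, ddof=1) / np.sqrt(n)
        assert np.all(np.abs(freqs.mean(0) - 0.125) < 4 * se)

    def test_chromosome_exchangeability(self, whs_pedigree):
        """Statistics are invariant under chromosome relabeling: the same
        seeded engine run yields identical arrays regardless of labels."""
        strains = founder_strains(whs_pedigree)
        pos = np.array([5.0, 25.0])
        a = ancestry_gene_drop(
            whs_pedigree, {"3": pos, "9": pos}, strains, np.random.default_rng(11)
        )
        b = ancestry_gene_drop(
            whs_pedigree, {"9": pos, "3": pos}, strains, np.random.default_rng(11)
        )
        assert np.array_equal(a["3"], b["9"]) and np.array_equal(a["9"], b["3"])
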