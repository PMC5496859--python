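"""Synthetic founder panels, breeding datasets, and phenotypes.

No genotype, pedigree, or behaviour data were deposited for the WHS study,
so this module generates datasets with the statistical structure the
analysis assumes: a founder panel whose allele-sharing categories mirror
the published GigaMUGA tallies (scaled down), the WHS mating design with
within-family truncation selection on "contacting" (ties broken by
"heading"), and a planted additive QTL carried on one founder's haplotype.
Every pipeline stage can therefore run end to end with full ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .founders import DEFAULT_STRAINS, N_AUTOSOMES, PRIVATE_SNP_COUNTS
from .genotype_panel import FounderPanel, GenotypeMatrix
from .pedigree_gene_drop import (
    DiploidGenome,
    GeneticMap,
    GroupSpec,
    HaplotypeMosaic,
    Pedigree,
    build_whs_pedigree,
    genotypes_from_mosaics,
    simulate_meiosis,
    uniform_map,
)
from .utils import as_rng

#: published sharing-category counts scaled down tenfold: the default
#: desk-scale panel (5,214 SNPs over ~1,330 cM)
DEFAULT_CATEGORY_COUNTS: dict[int, int] = {1: 2053, 2: 1972, 3: 917, 4: 272}

_NUCS = np.array(list("ACGT"))


@dataclass
class MapSpec:
    """Synthetic genome layout: 19 autosomes on a discrete cM grid."""

    n_chroms: int = N_AUTOSOMES
    length_cm: float = 70.0
    spacing_cm: float = 0.01     # SNP position grid
    bp_per_cm: int = 2_000_000

    def chrom_lengths(self) -> dict[str, float]:
        return uniform_map(self.n_chroms, self.length_cm)


@dataclass
class PhenotypeModel:
    """Generative model for the behaviour scores (seconds).

    contacting_raw = mu + a * dosage + family_effect + e,  e ~ N(0, sigma_e)
    heading is correlated with contacting at ``rho`` given dosage and
    family; both are floored at zero when ``floor_at_zero`` (the source of
    the zero-inflation seen in unselected lines).  A second linked QTL on
    the same founder haplotype can be enabled with ``qtl2_effect > 0``.
    All defaults are desk-scale choices, not estimates from any real stock.
    """

    mu: float = 1.0
    qtl_effect: float = 1.5
    qtl_chrom: str = "11"
    qtl_cm: float = 35.0
    carrier_strain: str = "MSM"
    sigma_family: float = 0.5
    sigma_e: float = 2.0
    rho: float = 0.6
    floor_at_zero: bool = True
    qtl2_effect: float = 0.0
    qtl2_cm_offset: float = 20.0

    def __post_init__(self) -> None:
        if self.sigma_family < 0 or self.sigma_e < 0:
            raise ValueError("standard deviations must be non-negative")
        if abs(self.rho) > 1:
            raise ValueError("|rho| must be <= 1")

    @property
    def qtl2_cm(self) -> float:
        return self.qtl_cm + self.qtl2_cm_offset


@dataclass
class WHSDesign:
    """Breeding-design configuration for dataset generation."""

    n_strains: int = 8
    pairs_after_expansion: int = 16
    last_generation: int = 12
    candidates_per_sex: int = 5
    groups: tuple[GroupSpec, ...] = (
        GroupSpec("S", 3, None, True),
        GroupSpec("C", 3, None, False),
    )


@dataclass
class SyntheticDataset:
    """A complete synthetic study with full ground truth."""

    panel: FounderPanel
    gmap: GeneticMap
    pedigree: Pedigree
    genomes: dict[str, DiploidGenome]
    genotypes: GenotypeMatrix          # final-generation breeders, all groups
    phenotypes: pd.DataFrame
    truth: dict

    def to_dir(self, outdir) -> None:
        from . import io as tio
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        tio.write_panel_tsv(self.panel, out / "panel.tsv")
        tio.write_map_tsv(self.gmap, out / "map.tsv")
        tio.write_pedigree_tsv(self.pedigree, out / "ped.tsv")
        tio.write_genotypes_tsv(self.genotypes, out / "geno.tsv")
        self.phenotypes.to_csv(out / "pheno.tsv", sep="\t", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1)


def generate_founder_panel(
    category_counts: dict[int, int] | None = None,
    n_strains: int = 8,
    map_spec: MapSpec | None = None,
    seed: int | np.random.Generator | None = None,
    strains: tuple[str, ...] | None = None,
    strain_weights: str = "published",
    extra_private: list[tuple[str, float, str]] | None = None,
) -> tuple[FounderPanel, GeneticMap]:
    """Synthetic founder panel emulating the published sharing structure.

    SNPs are placed uniformly on a discrete cM grid across the autosomes.
    A category-c SNP assigns its minority allele to a random c-subset of
    strains; with ``strain_weights="published"`` the carrier of a
    category-1 (private) SNP is drawn proportional to the published
    per-strain private-SNP counts, which is what makes per-strain private
    marker densities (and hence threshold spreads) realistic.
    ``extra_private`` pins additional private SNPs at exact (chrom, cM,
    carrier) locations, e.g. at a planted QTL.
    """
    rng = as_rng(seed)
    if category_counts is None:
        category_counts = dict(DEFAULT_CATEGORY_COUNTS)
    if map_spec is None:
        map_spec = MapSpec()
    if strains is None:
        strains = DEFAULT_STRAINS[:n_strains]
    if len(strains) != n_strains:
        raise ValueError("strains length must match n_strains")
    if any(v < 0 for v in category_counts.values()):
        raise ValueError("category counts must be non-negative")

    n_total = int(sum(category_counts.values()))
    extra_private = extra_private or []
    grid_per_chrom = int(np.floor(map_spec.length_cm / map_spec.spacing_cm)) + 1
    if n_total > grid_per_chrom * map_spec.n_chroms:
        raise ValueError(
            f"{n_total} SNPs requested but only {grid_per_chrom * map_spec.n_chroms} "
            f"grid positions exist at spacing {map_spec.spacing_cm} cM"
        )

    chrom_labels = [str(i) for i in range(1, map_spec.n_chroms + 1)]
    # sample distinct grid positions uniformly over the pooled genome
    flat = rng.choice(grid_per_chrom * map_spec.n_chroms, size=n_total, replace=False)
    chrom_idx = flat // grid_per_chrom
    cm = (flat % grid_per_chrom) * map_spec.spacing_cm

    categories = np.repeat(
        list(category_counts), [category_counts[c] for c in category_counts]
    )
    rng.shuffle(categories)

    if strain_weights == "published":
        w = np.array([PRIVATE_SNP_COUNTS.get(s, 1) for s in strains], dtype=float)
        w /= w.sum()
    elif strain_weights == "uniform":
        w = np.full(n_strains, 1.0 / n_strains)
    else:
        raise ValueError(f"unknown strain_weights {strain_weights!r}")

    rows = []
    for k in range(n_total):
        cat = int(categories[k])
        if cat == 1:
            carriers = [int(rng.choice(n_strains, p=w))]
        else:
            carriers = list(rng.choice(n_strains, size=cat, replace=False))
        rows.append((chrom_labels[chrom_idx[k]], float(cm[k]), carriers))
    for chrom, pos, carrier in extra_private:
        rows.append((str(chrom), float(pos), [list(strains).index(carrier)]))

    rows.sort(key=lambda r: (int(r[0]), r[1]))
    records = []
    for k, (chrom, pos, carriers) in enumerate(rows):
        ref, alt = rng.choice(4, size=2, replace=False)
        calls = [_NUCS[ref]] * n_strains
        for c in carriers:
            calls[c] = _NUCS[alt]
        records.append(
            {
                "chrom": chrom,
                "snp_id": f"snp{k:05d}",
                "bp": int(round(pos * map_spec.bp_per_cm)) + 1,
                "cM": pos,
                **{s: calls[i] for i, s in enumerate(strains)},
            }
        )
    snps = pd.DataFrame(
        records, columns=["chrom", "snp_id", "bp", "cM", *strains]
    )
    # de-duplicate any grid collision with a pinned extra SNP
    snps = snps.drop_duplicates(subset=["chrom", "bp"], keep="last").reset_index(drop=True)
    panel = FounderPanel(list(strains), snps)
    gmap = GeneticMap(map_spec.chrom_lengths(), snps[["chrom", "snp_id", "bp", "cM"]])
    return panel, gmap


def phenotype_trait(
    qtl_dosage: int,
    model: PhenotypeModel,
    family_effect: float,
    rng: np.random.Generator | int | None = None,
    extra_genetic: float = 0.0,
) -> tuple[float, float]:
    """One mouse's (contacting, heading) given its QTL dosage."""
    rng = as_rng(rng)
    e1 = rng.normal(0.0, model.sigma_e) if model.sigma_e > 0 else 0.0
    e2 = rng.normal(0.0, model.sigma_e) if model.sigma_e > 0 else 0.0
    base = model.mu + model.qtl_effect * qtl_dosage + extra_genetic + family_effect
    contacting = base + e1
    heading = base + model.rho * e1 + np.sqrt(1.0 - model.rho**2) * e2
    if model.floor_at_zero:
        contacting = max(0.0, contacting)
        heading = max(0.0, heading)
    return float(contacting), float(heading)


def generate_whs_dataset(
    design: WHSDesign | None = None,
    model: PhenotypeModel | None = None,
    selection: dict[str, bool] | None = None,
    seed: int = 0,
    category_counts: dict[int, int] | None = None,
    map_spec: MapSpec | None = None,
) -> SyntheticDataset:
    """Forward-simulate a full WHS study with a planted QTL.

    Breeding follows the WHS design; in selected groups the breeder of each
    family and sex is the candidate with the highest contacting score (ties
    broken by heading, then at random), in control groups a uniformly
    random candidate.  ``selection`` can override per-group selection
    (defaults to each group's ``selected`` flag).  Returns the panel, map,
    pedigree, all genomes, final-breeder genotypes, the phenotype table for
    all tested candidates, and a truth record with per-individual QTL
    dosages.
    """
    design = design or WHSDesign()
    model = model or PhenotypeModel()
    root = np.random.SeedSequence(seed)
    panel_seed, ped_seed, bio_seed = root.spawn(3)
    bio_rng = np.random.default_rng(bio_seed)

    extra = [(model.qtl_chrom, model.qtl_cm, model.carrier_strain)]
    if model.qtl2_effect > 0:
        extra.append((model.qtl_chrom, model.qtl2_cm, model.carrier_strain))
    panel, gmap = generate_founder_panel(
        category_counts=category_counts,
        n_strains=design.n_strains,
        map_spec=map_spec,
        seed=np.random.default_rng(panel_seed),
        extra_private=extra,
    )

    sel_enabled = {g.name: g.selected for g in design.groups}
    if selection:
        sel_enabled.update(selection)

    genomes: dict[str, DiploidGenome] = {}
    pheno_rows: list[dict] = []
    scores: dict[str, tuple[float, float]] = {}
    dosages: dict[str, int] = {}
    family_effects: dict[tuple, float] = {}

    def qtl_dosage(g: DiploidGenome) -> int:
        return g.dosage_of(model.carrier_strain, model.qtl_chrom, model.qtl_cm)

    def on_offspring(iid, dam, sire, gen, group, fam, sex):
        if dam is None:  # founder; family slot holds the strain label
            hap = HaplotypeMosaic.founder(fam, gmap.chrom_lengths)
            genomes[iid] = DiploidGenome(hap, HaplotypeMosaic(dict(hap.segments)))
            return
        genomes[iid] = DiploidGenome(
            maternal=simulate_meiosis(genomes[dam], gmap, bio_rng),
            paternal=simulate_meiosis(genomes[sire], gmap, bio_rng),
        )
        if gen < 3:
            return
        d = qtl_dosage(genomes[iid])
        extra_gen = 0.0
        if model.qtl2_effect > 0:
            extra_gen = model.qtl2_effect * genomes[iid].dosage_of(
                model.carrier_strain, model.qtl_chrom, model.qtl2_cm
            )
        key = (group, gen, fam)
        if key not in family_effects:
            family_effects[key] = (
                bio_rng.normal(0.0, model.sigma_family) if model.sigma_family > 0 else 0.0
            )
        contacting, heading = phenotype_trait(
            d, model, family_effects[key], bio_rng, extra_genetic=extra_gen
        )
        scores[iid] = (contacting, heading)
        dosages[iid] = d
        pheno_rows.append(
            dict(individual=iid, contacting=contacting, heading=heading, sex=sex,
                 generation=gen, family=fam, group=group)
        )

    def choose(group, gen, fam, sex, candidates):
        if sel_enabled.get(group, False):
            # highest contacting; ties -> higher heading, then random
            jitter = bio_rng.random(len(candidates))
            ranked = sorted(
                range(len(candidates)),
                key=lambda i: (scores[candidates[i]][0], scores[candidates[i]][1], jitter[i]),
                reverse=True,
            )
            return candidates[ranked[0]]
        return candidates[int(bio_rng.integers(len(candidates)))]

    ped = build_whs_pedigree(
        n_strains=design.n_strains,
        pairs_after_expansion=design.pairs_after_expansion,
        last_generation=design.last_generation,
        seed=np.random.default_rng(ped_seed),
        selection_hook=choose,
        candidates_per_sex=design.candidates_per_sex,
        groups=design.groups,
        offspring_callback=on_offspring,
    )

    phenotypes = pd.DataFrame(
        pheno_rows,
        columns=["individual", "contacting", "heading", "sex", "generation", "family", "group"],
    )
    flags = ped.table.set_index("id")[["selected", "breeder"]]
    phenotypes["selected"] = flags.loc[phenotypes["individual"], "selected"].to_numpy()
    phenotypes["breeder"] = flags.loc[phenotypes["individual"], "breeder"].to_numpy()

    final_ids = list(ped.final_breeders()["id"])
    genotypes = genotypes_from_mosaics(
        {i: genomes[i] for i in final_ids}, panel, gmap
    )
    truth = {
        "seed": seed,
        "qtl": {
            "chrom": model.qtl_chrom,
            "cM": model.qtl_cm,
            "bp": int(round(model.qtl_cm * (map_spec or MapSpec()).bp_per_cm)) + 1,
            "carrier_strain": model.carrier_strain,
            "effect": model.qtl_effect,
        },
        "model": asdict(model),
        "selection": sel_enabled,
        "dosages": {i: int(d) for i, d in dosages.items()},
        "final_breeders": final_ids,
    }
    if model.qtl2_effect > 0:
        truth["qtl2"] = {
            "chrom": model.qtl_chrom, "cM": model.qtl2_cm,
            "carrier_strain": model.carrier_strain, "effect": model.qtl2_effect,
        }
    return SyntheticDataset(
        panel=panel, gmap=gmap, pedigree=ped, genomes=genomes,
        genotypes=genotypes, phenotypes=phenotypes, truth=truth,
    )


def realized_within_family_h2(va: float, ve: float) -> float:
    """Heritability realized by within-family selection: (Va/2)/(Va/2 + Ve).

    Selecting on within-family phenotypic deviations, the regression of a
    candidate's breeding-value deviation on its phenotypic deviation
    involves only the segregation variance Va/2 and the residual Ve; this
    is the slope the cumulative response/differential regression recovers.
    """
    denom = va / 2.0 + ve
    return (va / 2.0) / denom if denom > 0 else 0.0


def simulate_polygenic_breeding(
    realized_h2: float,
    n_families: int = 16,
    candidates_per_sex: int = 5,
    first_generation: int = 3,
    last_generation: int = 12,
    mu: float = 1.0,
    phen_var: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Infinitesimal-model truncation breeding for heritability calibration.

    Generates a selected line "S" (top contacting per family and sex) and a
    control line "C" (random choice) with ``candidates_per_sex`` candidates
    per family.  Breeding values follow the infinitesimal model (child =
    mid-parent + N(0, Va/2)); the additive variance is chosen so that
    within-family selection realizes ``realized_h2`` (see
    :func:`realized_within_family_h2`).  Phenotypes are not floored so the
    planted slope stays linear.  Returns a phenotype table in the quantgen
    layout.
    """
    if not 0.0 <= realized_h2 < 1.0:
        raise ValueError("realized_h2 must be in [0, 1)")
    rng = as_rng(seed)
    # solve (Va/2) / (Va/2 + Ve) = realized_h2 with Va + Ve = phen_var
    va = 2.0 * realized_h2 * phen_var / (1.0 + realized_h2)
    ve = phen_var - va

    from .pedigree_gene_drop import random_nonsib_permutation

    rows = []
    lines = {}
    for line, do_select in (("S", True), ("C", False)):
        # founding breeders: unrelated, BV ~ N(0, Va)
        f_bv = rng.normal(0.0, np.sqrt(va), size=n_families) if va > 0 else np.zeros(n_families)
        m_bv = rng.normal(0.0, np.sqrt(va), size=n_families) if va > 0 else np.zeros(n_families)
        lines[line] = (f_bv, m_bv, do_select)

    for line, (f_bv, m_bv, do_select) in lines.items():
        for gen in range(first_generation, last_generation + 1):
            sigma = random_nonsib_permutation(n_families, rng)
            mid = (f_bv + m_bv[sigma]) / 2.0
            new_f = np.empty(n_families)
            new_m = np.empty(n_families)
            for fam in range(n_families):
                for sex, store in (("F", new_f), ("M", new_m)):
                    bv = mid[fam] + (
                        rng.normal(0.0, np.sqrt(va / 2.0), size=candidates_per_sex)
                        if va > 0 else np.zeros(candidates_per_sex)
                    )
                    phen = mu + bv + rng.normal(0.0, np.sqrt(ve), size=candidates_per_sex)
                    heading = phen + rng.normal(0.0, np.sqrt(ve), size=candidates_per_sex)
                    pick = int(np.argmax(phen)) if do_select else int(rng.integers(candidates_per_sex))
                    for k in range(candidates_per_sex):
                        rows.append(
                            dict(
                                individual=f"{line}_G{gen}_{fam:02d}_{sex}{k}",
                                contacting=float(phen[k]),
                                heading=float(heading[k]),
                                sex=sex,
                                generation=gen,
                                family=f"{fam:02d}",
                                group=line,
                                selected=bool(do_select and k == pick),
                                breeder=bool(k == pick),
                            )
                        )
                    store[fam] = bv[pick]
            f_bv, m_bv = new_f, new_m
    return pd.DataFrame(rows)
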