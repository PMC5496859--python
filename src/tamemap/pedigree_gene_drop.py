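"""Pedigrees, the WHS mating design, and gene dropping with recombination.

The wild-derived heterogeneous stock (WHS) design: eight inbred founder
strains are crossed by circular rotation (G0 pairs), their G1 offspring are
again paired by rotation, the number of breeding pairs is expanded from 8 to
16 at G2, and from G3 onward pairs are formed by random mating that avoids
full-sib crosses.  One female and one male offspring per pair are carried
forward as breeders each generation (five candidates per sex per family when
phenotypic selection is simulated).

Gene dropping simulates Mendelian transmission of founder haplotypes down a
fixed pedigree.  Crossovers follow a Poisson process along the genetic map
(Haldane model: no interference, no obligate chiasma), and the 19 autosomes
are inherited independently.  Two engines are provided: a segment-mosaic
engine (``simulate_meiosis`` / ``gene_drop``) that tracks full haplotype
mosaics, and a marker-resolution engine (``ancestry_gene_drop``) that
simulates founder ancestry only at marker positions via the two-state Markov
property of the Poisson crossover process — exact at the markers and much
faster for null-distribution work.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .founders import DEFAULT_STRAINS, N_AUTOSOMES
from .utils import as_rng

Segment = tuple[float, float, str]

#: rotation offset used when pairing G1 (and G2) animals: the female of
#: family i is mated with the male of family i-2 (mod n), mirroring the
#: realized scheme (female of cage 1 x male of cage 7, etc.)
ROTATION_OFFSET = 2

MAX_PAIRING_TRIES = 1000


class PedigreeBuildError(RuntimeError):
    """Raised when a mating constraint cannot be satisfied."""


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------


@dataclass
class GeneticMap:
    """Per-chromosome map lengths (cM) and per-SNP genetic positions."""

    chrom_lengths: dict[str, float]
    snps: pd.DataFrame  # chrom, snp_id, bp, cM

    def __post_init__(self) -> None:
        self.snps = self.snps.reset_index(drop=True)

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    def positions(self, chrom: str) -> np.ndarray:
        """Sorted cM positions of the SNPs on ``chrom``."""
        sub = self.snps[self.snps["chrom"].astype(str) == str(chrom)]
        return np.sort(sub["cM"].to_numpy(dtype=float))

    def snp_positions(self, chrom: str) -> pd.DataFrame:
        sub = self.snps[self.snps["chrom"].astype(str) == str(chrom)]
        return sub.sort_values("cM").reset_index(drop=True)

    def validate(self) -> list[str]:
        problems = []
        for chrom, sub in self.snps.groupby("chrom", sort=False):
            chrom = str(chrom)
            if chrom not in self.chrom_lengths:
                problems.append(f"SNPs on unknown chromosome {chrom}")
                continue
            L = self.chrom_lengths[chrom]
            cm = sub["cM"].to_numpy(dtype=float)
            if np.any((cm < 0) | (cm > L)):
                problems.append(f"chrom {chrom}: cM outside [0, {L}]")
        return problems

    def total_length(self) -> float:
        return float(sum(self.chrom_lengths.values()))


def uniform_map(n_chroms: int = N_AUTOSOMES, length_cm: float = 70.0) -> dict[str, float]:
    """Equal-length autosome map, the default synthetic genome (~1,330 cM)."""
    return {str(i): float(length_cm) for i in range(1, n_chroms + 1)}


# ---------------------------------------------------------------------------
# haplotype mosaics
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeMosaic:
    """One gamete/haplotype as founder-labelled segments per chromosome.

    Segments are half-open ``[start, end)`` in cM and tile ``[0, L)``
    exactly; adjacent segments carry distinct founder labels after
    :meth:`normalize`.
    """

    segments: dict[str, list[Segment]]

    @classmethod
    def founder(cls, strain: str, chrom_lengths: dict[str, float]) -> "HaplotypeMosaic":
        return cls({c: [(0.0, L, strain)] for c, L in chrom_lengths.items()})

    def normalize(self) -> "HaplotypeMosaic":
        """Merge adjacent segments with identical founder labels."""
        out: dict[str, list[Segment]] = {}
        for chrom, segs in self.segments.items():
            merged: list[Segment] = []
            for s in segs:
                if s[0] >= s[1] and not (s[0] == s[1] == 0.0 and not merged and len(segs) == 1):
                    continue  # drop zero-length pieces (keep a 0-length chromosome)
                if merged and merged[-1][2] == s[2]:
                    merged[-1] = (merged[-1][0], s[1], s[2])
                else:
                    merged.append(s)
            out[chrom] = merged
        return HaplotypeMosaic(out)

    def ancestry_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Founder label covering each cM position (object array)."""
        segs = self.segments[chrom]
        ends = np.array([e for _, e, _ in segs], dtype=float)
        labels = np.array([lab for _, _, lab in segs], dtype=object)
        idx = np.searchsorted(ends, np.asarray(positions, dtype=float), side="right")
        idx = np.clip(idx, 0, len(segs) - 1)
        return labels[idx]

    def validate(self, chrom_lengths: dict[str, float]) -> list[str]:
        problems = []
        for chrom, L in chrom_lengths.items():
            segs = self.segments.get(chrom)
            if not segs:
                problems.append(f"chrom {chrom}: no segments")
                continue
            if segs[0][0] != 0.0:
                problems.append(f"chrom {chrom}: first segment starts at {segs[0][0]}")
            if abs(segs[-1][1] - L) > 1e-9:
                problems.append(f"chrom {chrom}: last segment ends at {segs[-1][1]} != {L}")
            for a, b in zip(segs, segs[1:]):
                if abs(a[1] - b[0]) > 1e-9:
                    problems.append(f"chrom {chrom}: gap/overlap at {a[1]}")
                if a[2] == b[2]:
                    problems.append(f"chrom {chrom}: un-merged adjacent labels")
            if L > 0:
                for s in segs:
                    if s[1] <= s[0]:
                        problems.append(f"chrom {chrom}: empty segment {s}")
        return problems


@dataclass
class DiploidGenome:
    """Maternal and paternal haplotype mosaics over the same map."""

    maternal: HaplotypeMosaic
    paternal: HaplotypeMosaic

    def dosage_of(self, strain: str, chrom: str, cm: float) -> int:
        pos = np.array([cm])
        return int(self.maternal.ancestry_at(chrom, pos)[0] == strain) + int(
            self.paternal.ancestry_at(chrom, pos)[0] == strain
        )


# ---------------------------------------------------------------------------
# pedigree container
# ---------------------------------------------------------------------------

PED_COLUMNS = [
    "id", "sire", "dam", "sex", "generation", "group",
    "family", "selected", "breeder", "founder_strain",
]


@dataclass
class Pedigree:
    """Generation-ordered pedigree table with founder-to-strain mapping.

    Columns: ``id, sire, dam, sex, generation, group, family, selected,
    breeder, founder_strain``; empty string marks "no parent" (founders
    only) and "no strain" (non-founders).
    """

    table: pd.DataFrame
    _pos: dict[str, int] = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        missing = [c for c in PED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"pedigree table lacks columns {missing}")
        self.table = self.table.reset_index(drop=True)
        self._pos = {i: k for k, i in enumerate(self.table["id"])}

    def __len__(self) -> int:
        return len(self.table)

    @property
    def founders(self) -> pd.DataFrame:
        return self.table[self.table["generation"] == 0]

    @property
    def last_generation(self) -> int:
        return int(self.table["generation"].max())

    def breeders(self, generation: int | None = None, group: str | None = None) -> pd.DataFrame:
        sub = self.table[self.table["breeder"]]
        if generation is not None:
            sub = sub[sub["generation"] == generation]
        if group is not None:
            sub = sub[sub["group"] == group]
        return sub

    def final_breeders(self, group: str | None = None) -> pd.DataFrame:
        return self.breeders(generation=self.last_generation, group=group)

    def groups(self) -> list[str]:
        return sorted(self.table["group"].unique())

    def drop_arrays(self, strains: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[np.ndarray]]:
        """Integer arrays for the fast engines.

        Returns ``(dam_pos, sire_pos, founder_strain_idx, generation_slices)``
        where positions are row indices (-1 for founders) and
        ``generation_slices`` lists the row indices of each non-founder
        generation in order.
        """
        t = self.table
        strain_idx = {s: i for i, s in enumerate(strains)}
        dam_pos = np.array([self._pos.get(d, -1) for d in t["dam"]], dtype=np.int64)
        sire_pos = np.array([self._pos.get(s, -1) for s in t["sire"]], dtype=np.int64)
        fs = np.array(
            [strain_idx.get(s, -1) for s in t["founder_strain"]], dtype=np.int64
        )
        gens = []
        for g in range(1, self.last_generation + 1):
            gens.append(np.flatnonzero((t["generation"] == g).to_numpy()))
        return dam_pos, sire_pos, fs, gens


def founder_strains(ped: Pedigree) -> list[str]:
    """Founder strain labels in order of first appearance."""
    seen: list[str] = []
    for s in ped.founders["founder_strain"]:
        if s not in seen:
            seen.append(s)
    return seen


def validate_pedigree(ped: Pedigree) -> list[str]:
    """Structural checks; returns a list of violations (empty when valid)."""
    t = ped.table
    problems: list[str] = []
    pos = {i: k for k, i in enumerate(t["id"])}
    if len(pos) != len(t):
        problems.append("duplicate individual ids")
    sex = dict(zip(t["id"], t["sex"]))
    gen = dict(zip(t["id"], t["generation"]))
    for _, row in t.iterrows():
        iid, sire, dam = row["id"], row["sire"], row["dam"]
        if row["generation"] == 0:
            if sire or dam:
                problems.append(f"founder {iid} has recorded parents")
            if not row["founder_strain"]:
                problems.append(f"founder {iid} lacks a strain label")
            continue
        if bool(sire) != bool(dam):
            problems.append(f"{iid}: exactly one recorded parent")
        for parent, want_sex, role in ((sire, "M", "sire"), (dam, "F", "dam")):
            if not parent:
                problems.append(f"{iid}: missing {role}")
                continue
            if parent not in pos:
                problems.append(f"{iid}: unknown {role} {parent}")
                continue
            if sex.get(parent) != want_sex:
                problems.append(f"{iid}: {role} {parent} recorded as {sex.get(parent)}")
            if gen[parent] >= row["generation"]:
                problems.append(
                    f"{iid}: {role} {parent} not from an earlier generation"
                )
    # cycle check via parent links (generation ordering already covers the
    # consistent case; walk anyway so corrupted generation fields are caught)
    parents = {r["id"]: [p for p in (r["sire"], r["dam"]) if p] for _, r in t.iterrows()}
    state: dict[str, int] = {}

    def visit(node: str, stack: set[str]) -> bool:
        if node in stack:
            return True
        if state.get(node) == 2:
            return False
        stack.add(node)
        for p in parents.get(node, []):
            if visit(p, stack):
                return True
        stack.discard(node)
        state[node] = 2
        return False

    for iid in t["id"]:
        if visit(iid, set()):
            problems.append(f"cycle involving {iid}")
            break
    return problems


# ---------------------------------------------------------------------------
# WHS mating design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """One breeding line: when it starts, whom it splits from, selected or not."""

    name: str
    start_generation: int = 3
    parent: str | None = None
    selected: bool = False


#: the realized four-line design: selection line S1 and control C1 from G3;
#: S2 split from C1 and C2 split from S1 at G5.
FOUR_GROUP_PLAN: tuple[GroupSpec, ...] = (
    GroupSpec("S1", 3, None, True),
    GroupSpec("C1", 3, None, False),
    GroupSpec("S2", 5, "C1", True),
    GroupSpec("C2", 5, "S1", False),
)


def random_nonsib_permutation(families: int, rng: np.random.Generator,
                              max_tries: int = MAX_PAIRING_TRIES) -> np.ndarray:
    """Permutation sigma with sigma(j) != j: random pairing avoiding full sibs."""
    for _ in range(max_tries):
        sigma = rng.permutation(families)
        if not np.any(sigma == np.arange(families)):
            return sigma
    raise PedigreeBuildError(
        f"could not find a full-sib-avoiding pairing in {max_tries} tries"
    )


def build_whs_pedigree(
    n_strains: int = 8,
    pairs_after_expansion: int = 16,
    last_generation: int = 12,
    seed: int | np.random.Generator | None = None,
    selection_hook=None,
    candidates_per_sex: int | None = None,
    groups: tuple[GroupSpec, ...] | None = None,
    strains: tuple[str, ...] | None = None,
    offspring_callback=None,
) -> Pedigree:
    """Generate a design-faithful WHS pedigree.

    ``selection_hook(group, generation, family, sex, candidate_ids) -> id``
    chooses the breeder among each family's candidates; when given,
    ``candidates_per_sex`` defaults to 5 (the realized selection pool),
    otherwise to 1.  ``groups=None`` builds a single line "W"; pass
    :data:`FOUR_GROUP_PLAN` for the realized four-line design.

    ``offspring_callback(child_id, dam_id, sire_id, generation, group,
    family, sex)`` is invoked for every individual as it is created
    (``dam_id``/``sire_id`` are ``None`` for founders, whose family slot
    carries the strain label); the synthetic-data generator uses it to grow
    genomes and phenotypes in step with the breeding so that selection can
    act on them.

    The returned pedigree is ordered by generation; breeder flags mark the
    animals used (or that would be used) to produce the next generation,
    including in the final generation.
    """
    if n_strains % 2:
        raise ValueError("n_strains must be even")
    if pairs_after_expansion < n_strains or pairs_after_expansion % n_strains:
        raise ValueError("pairs_after_expansion must be a multiple of n_strains")
    rng = as_rng(seed)
    if strains is None:
        strains = DEFAULT_STRAINS[:n_strains]
    if len(strains) != n_strains:
        raise ValueError("strains length must equal n_strains")
    if groups is None:
        groups = (GroupSpec("W", 3, None, selection_hook is not None),)
    if candidates_per_sex is None:
        candidates_per_sex = 5 if selection_hook is not None else 1
    first_split = min(g.start_generation for g in groups)
    if first_split < 3:
        raise ValueError("groups cannot start before generation 3")

    rows: list[dict] = []
    row_by_id: dict[str, dict] = {}

    def add(iid, sire, dam, sex, gen, group, fam, selected=False, breeder=False, strain=""):
        row = dict(id=iid, sire=sire, dam=dam, sex=sex, generation=gen, group=group,
                   family=fam, selected=selected, breeder=breeder, founder_strain=strain)
        rows.append(row)
        row_by_id[iid] = row
        if offspring_callback is not None:
            offspring_callback(iid, dam or None, sire or None, gen, group, fam, sex)
        return iid

    # --- founders -----------------------------------------------------------
    g0_f, g0_m = {}, {}
    for i, s in enumerate(strains):
        g0_f[i] = add(f"G0_{s}_F", "", "", "F", 0, "pre-split", s, breeder=True, strain=s)
        g0_m[i] = add(f"G0_{s}_M", "", "", "M", 0, "pre-split", s, breeder=True, strain=s)
    if last_generation == 0:
        return Pedigree(pd.DataFrame(rows, columns=PED_COLUMNS))

    # --- G1: circular rotation, 8 pairs (female of strain i x male of i-1) --
    pairs = [(g0_f[i], g0_m[(i - 1) % n_strains], f"{i + 1:02d}") for i in range(n_strains)]
    g1: list[tuple[str, str]] = []  # per family (female, male)
    for dam, sire, fam in pairs:
        f = add(f"G1_{fam}_F", sire, dam, "F", 1, "pre-split", fam, breeder=True)
        m = add(f"G1_{fam}_M", sire, dam, "M", 1, "pre-split", fam, breeder=True)
        g1.append((f, m))
    if last_generation == 1:
        return Pedigree(pd.DataFrame(rows, columns=PED_COLUMNS))

    # --- G2: rotation among G1 families; litters of 2F+2M feed the expansion
    copies = pairs_after_expansion // n_strains
    g2: dict[int, dict[str, list[str]]] = {}
    for i in range(n_strains):
        dam = g1[i][0]
        sire = g1[(i - ROTATION_OFFSET) % n_strains][1]
        fam = f"{i + 1:02d}"
        g2[i] = {"F": [], "M": []}
        for c in range(copies):
            g2[i]["F"].append(
                add(f"G2_{fam}_F{c + 1}", sire, dam, "F", 2, "pre-split", fam, breeder=True)
            )
            g2[i]["M"].append(
                add(f"G2_{fam}_M{c + 1}", sire, dam, "M", 2, "pre-split", fam, breeder=True)
            )
    if last_generation == 2:
        return Pedigree(pd.DataFrame(rows, columns=PED_COLUMNS))

    # --- expansion pairs: 16 pairs of G2 animals by rotation ---------------
    expansion_pairs = []
    for j in range(pairs_after_expansion):
        dam = g2[j % n_strains]["F"][j // n_strains]
        sire = g2[(j - ROTATION_OFFSET) % n_strains]["M"][j // n_strains]
        expansion_pairs.append((dam, sire))

    def breed_generation(gen, group_name, parent_pairs, select_this_gen):
        """Produce one generation for one line and pick its breeders."""
        n_cand = candidates_per_sex if gen >= 3 else 1
        new_pairs_breeders = []
        for j, (dam, sire) in enumerate(parent_pairs):
            fam = f"{j + 1:02d}"
            chosen = {}
            for sex in ("F", "M"):
                cands = [
                    add(f"G{gen}_{group_name}_{fam}_{sex}{k + 1}", sire, dam, sex,
                        gen, group_name, fam)
                    for k in range(n_cand)
                ]
                if selection_hook is not None and n_cand > 1:
                    pick = selection_hook(group_name, gen, fam, sex, list(cands))
                    if pick not in cands:
                        raise PedigreeBuildError(
                            f"selection hook returned non-candidate {pick!r}"
                        )
                elif n_cand > 1:
                    pick = cands[int(rng.integers(n_cand))]
                else:
                    pick = cands[0]
                row_by_id[pick]["breeder"] = True
                row_by_id[pick]["selected"] = bool(select_this_gen)
                chosen[sex] = pick
            new_pairs_breeders.append((chosen["F"], chosen["M"]))
        return new_pairs_breeders

    # --- G3 .. last: per-line breeding --------------------------------------
    # state per line: list of (female, male) breeders of the current generation
    line_breeders: dict[str, list[tuple[str, str]]] = {}
    line_pairs: dict[str, list[tuple[str, str]]] = {}

    for gen in range(3, last_generation + 1):
        for spec in groups:
            if gen < spec.start_generation:
                continue
            if gen == spec.start_generation:
                if spec.parent is None:
                    parent_pairs = expansion_pairs
                else:
                    parent_pairs = line_pairs[spec.parent]
            else:
                parent_pairs = line_pairs[spec.name]
            select = spec.selected and selection_hook is not None
            line_breeders[spec.name] = breed_generation(gen, spec.name, parent_pairs, select)
        # form next pairs by random non-sib mating within each active line
        for spec in groups:
            if gen < spec.start_generation:
                continue
            br = line_breeders[spec.name]
            sigma = random_nonsib_permutation(len(br), rng)
            line_pairs[spec.name] = [(br[j][0], br[int(sigma[j])][1]) for j in range(len(br))]

    return Pedigree(pd.DataFrame(rows, columns=PED_COLUMNS))


# ---------------------------------------------------------------------------
# meiosis and gene dropping (segment-mosaic engine)
# ---------------------------------------------------------------------------


def _copy_interval(segs: list[Segment], a: float, b: float) -> list[Segment]:
    """Clip a haplotype's segments to [a, b)."""
    out = []
    ends = [e for _, e, _ in segs]
    i = bisect_right(ends, a)
    i = min(i, len(segs) - 1)
    while i < len(segs) and segs[i][0] < b:
        s, e, lab = segs[i]
        lo, hi = max(s, a), min(e, b)
        if hi > lo:
            out.append((lo, hi, lab))
        i += 1
    return out


def simulate_meiosis(
    parent: DiploidGenome,
    gmap: GeneticMap,
    rng: np.random.Generator | int | None = None,
) -> HaplotypeMosaic:
    """One gamete from a diploid parent under the Haldane crossover model.

    Per chromosome of map length L cM: the crossover count is
    Poisson(L/100), breakpoints are uniform on (0, L), the starting
    haplotype is a fair coin, and the copied haplotype alternates at each
    breakpoint (no interference, no obligate chiasma).
    """
    rng = as_rng(rng)
    chrom_lengths = gmap.chrom_lengths
    gamete: dict[str, list[Segment]] = {}
    for chrom, L in chrom_lengths.items():
        mat = parent.maternal.segments[chrom]
        pat = parent.paternal.segments[chrom]
        if L <= 0:
            pick = mat if rng.integers(2) == 0 else pat
            gamete[chrom] = [(0.0, 0.0, pick[0][2])]
            continue
        k = int(rng.poisson(L / 100.0))
        breaks = np.sort(rng.uniform(0.0, L, size=k)) if k else np.empty(0)
        bounds = np.concatenate(([0.0], breaks, [L]))
        hap = int(rng.integers(2))
        segs: list[Segment] = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            src = mat if hap == 0 else pat
            segs.extend(_copy_interval(src, float(a), float(b)))
            hap ^= 1
        gamete[chrom] = segs
    return HaplotypeMosaic(gamete).normalize()


def gene_drop(
    ped: Pedigree,
    gmap: GeneticMap,
    rng: np.random.Generator | int | None = None,
) -> dict[str, DiploidGenome]:
    """Drop founder haplotypes through the whole pedigree.

    Founders receive homozygous single-strain mosaics; every non-founder
    receives one :func:`simulate_meiosis` gamete from each parent, in
    generation order.
    """
    rng = as_rng(rng)
    genomes: dict[str, DiploidGenome] = {}
    for _, row in ped.table.iterrows():
        iid = row["id"]
        if row["generation"] == 0:
            hap = HaplotypeMosaic.founder(row["founder_strain"], gmap.chrom_lengths)
            genomes[iid] = DiploidGenome(hap, HaplotypeMosaic(dict(hap.segments)))
            continue
        if not row["dam"] or not row["sire"]:
            raise ValueError(f"{iid}: gene drop requires both parents")
        genomes[iid] = DiploidGenome(
            maternal=simulate_meiosis(genomes[row["dam"]], gmap, rng),
            paternal=simulate_meiosis(genomes[row["sire"]], gmap, rng),
        )
    return genomes


def genotypes_from_mosaics(genomes, panel, gmap):
    """Project ancestry mosaics onto SNP alleles (valid: founders are inbred).

    Returns a :class:`~tamemap.genotype_panel.GenotypeMatrix` whose entries
    count copies of each SNP's founder-minority allele.  A SNP whose covering
    founder call is missing yields a missing genotype for that individual.
    """
    from .genotype_panel import MISSING_ALLELE, GenotypeMatrix

    strains = list(panel.strains)
    strain_idx = {s: i for i, s in enumerate(strains)}
    alleles = panel.allele_matrix()  # (S, m) over panel order

    # minority allele per SNP among non-missing founder calls
    counts = np.zeros((4, panel.n_snps), dtype=int)
    nucs = np.array(list("ACGT"))
    for i, nuc in enumerate("ACGT"):
        counts[i] = (alleles == nuc).sum(axis=0)
    masked = np.where(counts == 0, np.iinfo(int).max, counts)
    minor = nucs[np.argmin(masked, axis=0)]
    has_minor = alleles == minor[None, :]
    call_missing = alleles == MISSING_ALLELE

    snp_ids = panel.snps["snp_id"].to_numpy()
    ids = list(genomes)
    out = np.full((len(ids), panel.n_snps), np.nan)

    for chrom, sub in panel.snps.groupby("chrom", sort=False):
        chrom = str(chrom)
        cols = sub.index.to_numpy()
        pos = sub["cM"].to_numpy(dtype=float)
        L = gmap.chrom_lengths.get(chrom)
        if L is None:
            raise ValueError(f"chromosome {chrom} absent from the genetic map")
        bad = (pos < 0) | (pos > L)
        if bad.any():
            raise ValueError(
                f"SNP {sub['snp_id'].iloc[int(np.argmax(bad))]} lies outside "
                f"chromosome {chrom} span [0, {L}] cM"
            )
        for r, iid in enumerate(ids):
            g = genomes[iid]
            dose = np.zeros(len(cols))
            miss = np.zeros(len(cols), dtype=bool)
            for hap in (g.maternal, g.paternal):
                lab = hap.ancestry_at(chrom, pos)
                sidx = np.array([strain_idx[x] for x in lab])
                dose += has_minor[sidx, cols]
                miss |= call_missing[sidx, cols]
            row = dose.astype(float)
            row[miss] = np.nan
            out[r, cols] = row

    values = pd.DataFrame(out, index=ids, columns=snp_ids)
    return GenotypeMatrix(values=values, counted_allele=pd.Series(minor, index=snp_ids))


# ---------------------------------------------------------------------------
# marker-resolution ancestry engine
# ---------------------------------------------------------------------------


def ancestry_gene_drop(
    ped: Pedigree,
    positions_by_chrom: dict[str, np.ndarray],
    strains: list[str],
    rng: np.random.Generator | int | None = None,
    drop_arrays=None,
) -> dict[str, np.ndarray]:
    """Founder ancestry of every haplotype at marker positions only.

    Exploits the Markov property of the Poisson crossover process: along a
    chromosome, the copied-haplotype indicator switches between consecutive
    markers d cM apart with the Haldane probability (1 - exp(-2d/100))/2,
    independently across intervals.  This reproduces the marker-locus
    distribution of the segment-mosaic engine exactly.

    Returns ``{chrom: int8 array (n_individuals, 2, n_markers)}`` of founder
    strain indices, rows in pedigree order (axis 1: maternal, paternal).
    """
    rng = as_rng(rng)
    if drop_arrays is None:
        drop_arrays = ped.drop_arrays(strains)
    dam_pos, sire_pos, founder_idx, gens = drop_arrays
    n = len(dam_pos)

    # Concatenate chromosomes into one marker axis: across a chromosome
    # boundary the copied-haplotype indicator switches with probability 1/2,
    # which is exactly an independently re-tossed starting haplotype.
    chroms = [c for c, p in positions_by_chrom.items() if len(p) > 0]
    if not chroms:
        return {}
    pos_list = [np.asarray(positions_by_chrom[c], dtype=float) for c in chroms]
    sizes = [len(p) for p in pos_list]
    r_parts: list[np.ndarray] = []
    for i, p in enumerate(pos_list):
        if i > 0:
            r_parts.append(np.array([0.5]))
        if len(p) > 1:
            r_parts.append(0.5 * (1.0 - np.exp(-2.0 * np.diff(p) / 100.0)))
    r = np.concatenate(r_parts) if r_parts else np.empty(0)
    m = int(sum(sizes))

    anc = np.empty((n, 2, m), dtype=np.int8)
    founders = founder_idx >= 0
    anc[founders] = founder_idx[founders, None, None].astype(np.int8)
    cols = np.arange(m)
    for rows_g in gens:
        k = len(rows_g)
        if k == 0:
            continue
        for axis, par in ((0, dam_pos[rows_g]), (1, sire_pos[rows_g])):
            start = rng.integers(0, 2, size=(k, 1), dtype=np.int64)
            if m > 1:
                sw = rng.random((k, m - 1)) < r
                hap = np.empty((k, m), dtype=np.int64)
                hap[:, 0] = start[:, 0]
                np.cumsum(sw, axis=1, out=hap[:, 1:])
                hap[:, 1:] += start
                hap &= 1
            else:
                hap = start & 1
            anc[rows_g, axis, :] = anc[par[:, None], hap, cols[None, :]]

    out: dict[str, np.ndarray] = {}
    off = 0
    for c, s in zip(chroms, sizes):
        out[c] = anc[:, :, off:off + s]
        off += s
    return out
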