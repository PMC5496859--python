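"""Founder SNP panel handling: QC filters, allele-sharing classes, frequencies.

The founder panel holds one allele call per inbred founder strain per SNP.
Because the founders are fully inbred, a single call per strain suffices and
every SNP partitions the founders into two allele-carrier sets.  SNPs whose
minority allele is carried by exactly one strain ("private" SNPs) act as
perfect ancestry markers for that strain and drive the selection-mapping
test downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .founders import AUTOSOME_LABELS

logger = logging.getLogger(__name__)

MISSING_ALLELE = "N"

META_COLUMNS = ("chrom", "snp_id", "bp", "cM")


class NoSNPsRetainedError(ValueError):
    """Raised when a filter removes every SNP from the panel."""


@dataclass
class FounderPanel:
    """SNP metadata plus one allele call per founder strain per SNP.

    Parameters
    ----------
    strains
        Ordered founder strain labels (columns of ``snps`` after the
        metadata columns).
    snps
        Table with columns ``chrom, snp_id, bp, cM`` followed by one allele
        column per strain; alleles are single characters in ``{A,C,G,T}``
        with ``"N"`` for missing.
    """

    strains: list[str]
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.snps.columns]
        if missing:
            raise ValueError(f"panel table lacks columns {missing}")
        absent = [s for s in self.strains if s not in self.snps.columns]
        if absent:
            raise ValueError(f"panel table lacks strain columns {absent}")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def allele_matrix(self) -> np.ndarray:
        """Founder calls as an (n_strains, n_snps) array of single chars."""
        return self.snps[list(self.strains)].to_numpy(dtype="U1").T

    def sort(self) -> "FounderPanel":
        """Sort SNPs by (chromosome, bp); chromosome order is numeric."""
        key = self.snps["chrom"].astype(str).map(_chrom_sort_key)
        order = np.lexsort((self.snps["bp"].to_numpy(), key.to_numpy()))
        return FounderPanel(list(self.strains), self.snps.iloc[order])

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when clean)."""
        problems: list[str] = []
        for chrom, sub in self.snps.groupby("chrom", sort=False):
            bp = sub["bp"].to_numpy()
            cm = sub["cM"].to_numpy(dtype=float)
            if not np.all(np.diff(bp) > 0):
                problems.append(f"chrom {chrom}: bp not strictly increasing")
            if not np.all(np.diff(cm) >= 0):
                problems.append(f"chrom {chrom}: cM not non-decreasing")
            if np.any(cm < 0):
                problems.append(f"chrom {chrom}: negative cM positions")
        alleles = self.allele_matrix()
        n_distinct = _distinct_allele_counts(alleles)
        if np.any(n_distinct < 2):
            problems.append("monomorphic SNPs present")
        if np.any(n_distinct > 2):
            problems.append("SNPs with more than two alleles present")
        return problems


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix.

    Entries count copies of each SNP's designated (minority among founders)
    allele: 0, 1 or 2, with NaN for missing.  ``counted_allele`` records
    which nucleotide is being counted at each SNP.
    """

    values: pd.DataFrame
    counted_allele: pd.Series | None = None

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        ok = np.isnan(arr) | np.isin(arr, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype entries must be 0/1/2 or missing")
        if self.counted_allele is not None:
            self.counted_allele = self.counted_allele.reindex(self.values.columns)

    @property
    def individuals(self) -> list[str]:
        return list(self.values.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SharingTable:
    """Per-SNP allele-sharing classification plus summary counts.

    ``table`` has one row per classified SNP: ``snp_id``, ``category``
    (size of the smaller allele-carrier partition), ``minor_allele``,
    ``minor_strains`` (frozenset of carrier strains) and ``n_carriers``
    (raw carrier count of the minor allele).
    """

    table: pd.DataFrame
    n_strains: int
    n_excluded_missing: int = 0

    def category_counts(self) -> dict[int, int]:
        counts = self.table["category"].value_counts().to_dict()
        return {int(k): int(v) for k, v in sorted(counts.items())}

    def private_counts_by_strain(self) -> dict[str, int]:
        """Category-1 SNP counts per carrier strain."""
        sub = self.table[self.table["category"] == 1]
        out: dict[str, int] = {}
        for carriers in sub["minor_strains"]:
            (s,) = tuple(carriers)
            out[s] = out.get(s, 0) + 1
        return out

    def private_snps(self, strain: str) -> pd.DataFrame:
        """Rows for SNPs private to ``strain``."""
        sub = self.table[self.table["category"] == 1]
        mask = sub["minor_strains"].map(lambda c: strain in c)
        return sub[mask]


@dataclass
class PrivateFrequencyResult:
    """Per-SNP private-allele frequencies in a sample, with summaries."""

    frequencies: pd.DataFrame  # snp_id, frequency, n_called
    mean: float
    sd: float
    strain: str = ""


def _chrom_sort_key(label: str) -> int:
    try:
        return int(label)
    except ValueError:
        return 10_000 + hash(label) % 1000


def _distinct_allele_counts(alleles: np.ndarray) -> np.ndarray:
    """Number of distinct non-missing calls per SNP column."""
    n_snps = alleles.shape[1]
    counts = np.zeros(n_snps, dtype=int)
    for nuc in "ACGT":
        counts += (alleles == nuc).any(axis=0)
    return counts


def filter_snps(
    panel: FounderPanel,
    max_missing: float = 0.01,
    autosomes_only: bool = True,
    sample_genotypes: GenotypeMatrix | None = None,
) -> FounderPanel:
    """Apply the panel QC rules and return the retained SNPs, order preserved.

    Removes SNPs that are (i) monomorphic across the founders, (ii) carry
    more than two distinct alleles (logged, not an error), (iii) lie off the
    autosomes when ``autosomes_only``, or (iv) have a missing-call fraction
    of ``max_missing`` or more.  Missingness is computed over the founder
    calls plus any attached sample genotypes; pass ``sample_genotypes=None``
    to restrict the rule to founders only.
    """
    alleles = panel.allele_matrix()
    n_strains = len(panel.strains)
    n_distinct = _distinct_allele_counts(alleles)

    keep = np.ones(panel.n_snps, dtype=bool)

    if autosomes_only:
        autosomal = panel.snps["chrom"].astype(str).isin(AUTOSOME_LABELS).to_numpy()
        keep &= autosomal

    keep &= n_distinct >= 2
    multi = n_distinct > 2
    if multi.any():
        logger.info("dropping %d SNPs with >2 observed alleles", int(multi.sum()))
    keep &= ~multi

    founder_missing = (alleles == MISSING_ALLELE).sum(axis=0).astype(float)
    denom = float(n_strains)
    if sample_genotypes is not None:
        geno = sample_genotypes.values.reindex(
            columns=panel.snps["snp_id"], fill_value=np.nan
        ).to_numpy(dtype=float)
        founder_missing += np.isnan(geno).sum(axis=0)
        denom += geno.shape[0]
    miss_frac = founder_missing / denom
    keep &= miss_frac < max_missing

    out = panel.snps.loc[keep]
    if out.empty:
        raise NoSNPsRetainedError("no SNPs retained after filtering")
    return FounderPanel(list(panel.strains), out)


def classify_snp_sharing(panel: FounderPanel) -> SharingTable:
    """Assign each biallelic SNP its allele-sharing category.

    The category of a SNP is ``min(k, S - k)`` where ``k`` is the number of
    founder strains carrying one of the two alleles: a SNP where one strain
    differs from the other seven is category 1 ("private"), and so on up to
    ``S // 2``.  SNPs with any missing founder call are excluded (count kept
    on the result).
    """
    alleles = panel.allele_matrix()
    strains = np.asarray(panel.strains)
    n_strains = len(strains)

    rows = []
    n_excluded = 0
    snp_ids = panel.snps["snp_id"].to_numpy()
    for j in range(panel.n_snps):
        col = alleles[:, j]
        if (col == MISSING_ALLELE).any():
            n_excluded += 1
            continue
        uniq, counts = np.unique(col, return_counts=True)
        if len(uniq) != 2:
            raise ValueError(
                f"SNP {snp_ids[j]} is not biallelic-polymorphic; filter first"
            )
        minor_idx = int(np.argmin(counts))
        if counts[0] == counts[1]:
            # perfect 50/50 split: call the lexicographically smaller allele
            # "minor" so the classification is deterministic
            minor_idx = 0
        carriers = frozenset(strains[col == uniq[minor_idx]])
        k = len(carriers)
        rows.append(
            {
                "snp_id": snp_ids[j],
                "category": min(k, n_strains - k),
                "minor_allele": str(uniq[minor_idx]),
                "minor_strains": carriers,
                "n_carriers": k,
            }
        )
    if n_excluded:
        logger.info("excluded %d SNPs with missing founder calls", n_excluded)
    table = pd.DataFrame(
        rows, columns=["snp_id", "category", "minor_allele", "minor_strains", "n_carriers"]
    )
    return SharingTable(table=table, n_strains=n_strains, n_excluded_missing=n_excluded)


def private_allele_frequencies(
    genotypes: GenotypeMatrix,
    sharing: SharingTable,
    strain: str,
    sample_ids: list[str] | None = None,
) -> PrivateFrequencyResult:
    """Frequencies of one founder strain's private alleles in a sample.

    For each SNP private to ``strain`` the frequency is the number of copies
    of the private allele divided by twice the number of non-missing
    individuals.  Genotype dosages count the founder-minority allele, which
    for a category-1 SNP is exactly the private allele, so the frequency is
    ``mean(dosage) / 2`` over called individuals.
    """
    priv = sharing.private_snps(strain)
    if priv.empty:
        raise ValueError(f"no private SNPs for strain {strain!r}")
    if sample_ids is None:
        sample_ids = genotypes.individuals
    if len(sample_ids) == 0:
        raise ValueError("sample_ids must be non-empty")

    snp_ids = [s for s in priv["snp_id"] if s in genotypes.values.columns]
    if not snp_ids:
        raise ValueError(f"genotypes contain none of the private SNPs of {strain!r}")
    sub = genotypes.values.loc[sample_ids, snp_ids].to_numpy(dtype=float)

    n_called = (~np.isnan(sub)).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(sub, axis=0) / (2.0 * n_called)
    freq[n_called == 0] = np.nan

    table = pd.DataFrame(
        {"snp_id": snp_ids, "frequency": freq, "n_called": n_called.astype(int)}
    )
    called = freq[~np.isnan(freq)]
    return PrivateFrequencyResult(
        frequencies=table,
        mean=float(np.mean(called)) if called.size else float("nan"),
        sd=float(np.std(called, ddof=1)) if called.size > 1 else float("nan"),
        strain=strain,
    )
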