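"""Selection mapping against a gene-drop drift null.

The test asks whether any founder-private allele rose in frequency beyond
what genetic drift through the realized pedigree can explain.  For each
founder strain, the null distribution of the *genome-wide maximum* of that
strain's private-allele frequencies among the final-generation breeders is
built by repeated no-selection gene drops; observed frequencies are then
compared against upper-tail thresholds of those maxima (genome-wide
significance with Bonferroni correction across strains and selected
groups), and empirical p-values are plug-in tail fractions.

Because the founders are inbred, the private-allele frequency at a SNP
equals the founder-ancestry frequency at its position, so the simulation
runs on ancestry tracks at the private-SNP positions.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_panel import (
    FounderPanel,
    GenotypeMatrix,
    SharingTable,
    private_allele_frequencies,
)
from .pedigree_gene_drop import GeneticMap, Pedigree, ancestry_gene_drop, founder_strains
from .utils import as_rng


@dataclass
class NullMaxDistribution:
    """Per-strain simulated genome-wide maxima of private-allele frequency."""

    maxima: dict[str, np.ndarray]  # sorted ascending, values in [0, 1]
    n_sims: int
    sample_ids: list[str]
    seed: int | None = None

    def __post_init__(self) -> None:
        clean = {}
        for s, v in self.maxima.items():
            arr = np.sort(np.asarray(v, dtype=float))
            if len(arr) != self.n_sims:
                raise ValueError(f"strain {s}: {len(arr)} maxima != n_sims {self.n_sims}")
            if arr.size and (arr[0] < 0 or arr[-1] > 1):
                raise ValueError(f"strain {s}: maxima outside [0, 1]")
            clean[s] = arr
        self.maxima = clean

    @property
    def strains(self) -> list[str]:
        return list(self.maxima)

    def to_json(self, path) -> None:
        payload = {
            "n_sims": self.n_sims,
            "sample_ids": self.sample_ids,
            "seed": self.seed,
            "maxima": {s: list(map(float, v)) for s, v in self.maxima.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "NullMaxDistribution":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            maxima={s: np.asarray(v) for s, v in payload["maxima"].items()},
            n_sims=int(payload["n_sims"]),
            sample_ids=list(payload["sample_ids"]),
            seed=payload.get("seed"),
        )


@dataclass
class ScanResult:
    """Observed private-SNP frequencies against the drift null."""

    table: pd.DataFrame  # snp_id, chrom, bp, strain, frequency, threshold, exceeds, p
    regions: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["exceeds"]]


def private_snp_positions(
    panel: FounderPanel, sharing: SharingTable
) -> dict[str, pd.DataFrame]:
    """Per-strain tables (chrom, snp_id, bp, cM) of category-1 SNPs."""
    meta = panel.snps.set_index("snp_id")
    out: dict[str, pd.DataFrame] = {}
    for strain in panel.strains:
        priv = sharing.private_snps(strain)
        if priv.empty:
            continue
        sub = meta.loc[priv["snp_id"], ["chrom", "bp", "cM"]].reset_index()
        out[strain] = sub
    return out


def simulate_null_max(
    ped: Pedigree,
    gmap: GeneticMap,
    private_snps_by_strain: dict[str, pd.DataFrame],
    n_sims: int = 10_000,
    sample: list[str] | None = None,
    group: str | None = None,
    rng: np.random.Generator | int | None = None,
) -> NullMaxDistribution:
    """Null distribution of per-strain maximum private-allele frequency.

    Each simulation performs one no-selection gene drop through ``ped`` and
    records, for every strain, the maximum over its private SNPs of the
    strain-ancestry frequency in the sample (default: the final-generation
    breeders, optionally of one group).  Strains with zero private SNPs are
    omitted with a warning.
    """
    seed = rng if isinstance(rng, int) else None
    rng = as_rng(rng)
    strains = [s for s in private_snps_by_strain]
    empty = [s for s, df in private_snps_by_strain.items() if df.empty]
    for s in empty:
        warnings.warn(f"strain {s} has no private SNPs; omitted from the null")
    strains = [s for s in strains if s not in empty]
    if not strains:
        raise ValueError("no strain has private SNPs")

    if sample is None:
        sample = list(ped.final_breeders(group=group)["id"])
    if not sample:
        raise ValueError("empty sample")
    rows = np.array([ped._pos[i] for i in sample])

    # assemble marker positions per chromosome and per-strain column masks
    pos_by_chrom: dict[str, list[float]] = {}
    strain_cols: dict[str, list[tuple[str, int]]] = {s: [] for s in strains}
    for s in strains:
        df = private_snps_by_strain[s]
        for chrom, cm in zip(df["chrom"].astype(str), df["cM"].astype(float)):
            pos_by_chrom.setdefault(chrom, []).append(cm)
            strain_cols[s].append((chrom, len(pos_by_chrom[chrom]) - 1))
    positions = {}
    order = {}
    for chrom, p in pos_by_chrom.items():
        p = np.asarray(p)
        srt = np.argsort(p, kind="stable")
        positions[chrom] = p[srt]
        inv = np.empty(len(p), dtype=int)
        inv[srt] = np.arange(len(p))
        order[chrom] = inv
    masks = {
        s: {
            chrom: np.array(
                [order[chrom][j] for c2, j in cols if c2 == chrom], dtype=int
            )
            for chrom in positions
        }
        for s, cols in strain_cols.items()
    }

    all_strains = founder_strains(ped)
    sidx = {s: i for i, s in enumerate(all_strains)}
    da = ped.drop_arrays(all_strains)
    maxima = {s: np.empty(n_sims) for s in strains}
    n_hap = 2 * len(rows)
    for it in range(n_sims):
        anc = ancestry_gene_drop(ped, positions, all_strains, rng, drop_arrays=da)
        flat = {c: a[rows].reshape(n_hap, -1) for c, a in anc.items()}
        for s in strains:
            best = 0.0
            code = sidx[s]
            for chrom, cols in masks[s].items():
                if len(cols) == 0:
                    continue
                freq = (flat[chrom][:, cols] == code).mean(axis=0)
                m = float(freq.max())
                if m > best:
                    best = m
            maxima[s][it] = best
    return NullMaxDistribution(
        maxima=maxima, n_sims=n_sims, sample_ids=list(sample), seed=seed
    )


def compute_thresholds(
    null: NullMaxDistribution, alpha: float = 0.05, n_tests: int = 16
) -> dict[str, float]:
    """Genome-wide per-strain significance thresholds.

    The threshold is the smallest simulated value t with
    #{maxima >= t} / N <= alpha / n_tests, i.e. the attained rejection
    level never exceeds the nominal one even when the maxima are heavily
    tied (they live on a grid of multiples of 1 / (2 x sample size), so
    ties are the rule, not the exception).  A degenerate null in which no
    simulated value reaches the target tail — e.g. every maximum identical
    — falls back to the largest simulated value, with a warning.
    Bonferroni divides alpha by n_tests (the realized analysis used
    8 strains x 2 selected groups = 16 tests).
    """
    target = alpha / n_tests
    n_min = math.ceil(n_tests / alpha)
    if null.n_sims < n_min:
        raise ValueError(
            f"n_sims={null.n_sims} too small for tail {target}; need >= {n_min}"
        )
    out: dict[str, float] = {}
    for s, arr in null.maxima.items():
        n = len(arr)
        uniq = np.unique(arr)
        idx = np.searchsorted(arr, uniq, side="left")
        tails = (n - idx) / n
        ok = np.flatnonzero(tails <= target + 1e-12)
        if len(ok) == 0:
            warnings.warn(
                f"strain {s}: no simulated value reaches tail {target} "
                "(degenerate null); using the largest simulated maximum"
            )
            out[s] = float(uniq[-1])
        else:
            out[s] = float(uniq[ok[0]])
    return out


def attained_level(null: NullMaxDistribution, thresholds: dict[str, float]) -> dict[str, float]:
    """Per-strain tail fraction of the null at each threshold.

    Because the maxima are discrete, the attained rejection level
    #{maxima >= t} / N is typically below the nominal alpha / n_tests;
    calibration checks should compare fresh replicates against this value.
    """
    return {
        s: float((null.maxima[s] >= t).mean()) for s, t in thresholds.items()
    }


def empirical_p(null: NullMaxDistribution, strain: str, observed: float) -> float:
    """Plug-in empirical p-value: fraction of null maxima >= observed."""
    if strain not in null.maxima:
        raise KeyError(f"unknown strain {strain!r}")
    if not 0.0 <= observed <= 1.0:
        raise ValueError("observed frequency must lie in [0, 1]")
    arr = null.maxima[strain]
    return float((arr >= observed).sum() / len(arr))


def format_p(p: float, n_sims: int) -> str:
    """Zero p-values are reported as a bound, not as exactly zero."""
    return f"< {1.0 / n_sims:g}" if p == 0.0 else f"{p:g}"


def scan_observed(
    genotypes: GenotypeMatrix,
    sharing: SharingTable,
    thresholds: dict[str, float],
    null: NullMaxDistribution,
    panel: FounderPanel,
    sample_ids: list[str] | None = None,
) -> ScanResult:
    """Compare observed private-SNP frequencies with the drift null.

    Frequencies are computed with :func:`private_allele_frequencies` on the
    same sample the null was simulated for; a SNP is significant when its
    frequency meets or exceeds its strain's threshold.  Significant SNPs on
    the same chromosome for the same strain are merged into contiguous
    candidate regions (bp of first to bp of last significant SNP).
    """
    if sample_ids is None:
        sample_ids = [i for i in null.sample_ids if i in genotypes.values.index]
        if set(sample_ids) != set(null.sample_ids):
            raise ValueError(
                "genotypes do not cover the sample the null was simulated for"
            )
    meta = panel.snps.set_index("snp_id")
    rows = []
    for strain, thr in thresholds.items():
        if strain not in null.maxima:
            continue
        priv = sharing.private_snps(strain)
        if priv.empty:
            continue
        res = private_allele_frequencies(genotypes, sharing, strain, sample_ids)
        for snp_id, freq in zip(res.frequencies["snp_id"], res.frequencies["frequency"]):
            if np.isnan(freq):
                continue
            rows.append(
                {
                    "snp_id": snp_id,
                    "chrom": str(meta.at[snp_id, "chrom"]),
                    "bp": int(meta.at[snp_id, "bp"]),
                    "strain": strain,
                    "frequency": float(freq),
                    "threshold": float(thr),
                    "exceeds": bool(freq >= thr),
                    "p": empirical_p(null, strain, float(freq)),
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["snp_id", "chrom", "bp", "strain", "frequency", "threshold", "exceeds", "p"],
    )
    regions = _merge_significant(table)
    return ScanResult(table=table, regions=regions)


def _merge_significant(table: pd.DataFrame) -> pd.DataFrame:
    """Runs of consecutive significant private SNPs become candidate regions.

    A run breaks where a non-significant private SNP of the same strain
    intervenes on the chromosome.
    """
    out = []
    for (strain, chrom), sub in table.groupby(["strain", "chrom"], sort=False):
        sub = sub.sort_values("bp")
        start = None
        prev = None
        n = 0
        for bp, sig in zip(sub["bp"], sub["exceeds"]):
            if sig:
                if start is None:
                    start = bp
                    n = 0
                prev = bp
                n += 1
            elif start is not None:
                out.append({"strain": strain, "chrom": chrom, "start_bp": int(start),
                            "end_bp": int(prev), "n_snps": int(n)})
                start = None
        if start is not None:
            out.append({"strain": strain, "chrom": chrom, "start_bp": int(start),
                        "end_bp": int(prev), "n_snps": int(n)})
    return pd.DataFrame(out, columns=["strain", "chrom", "start_bp", "end_bp", "n_snps"])
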