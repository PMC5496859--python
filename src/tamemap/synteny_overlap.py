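"""Permutation test for overlap between a projected region and annotations.

Given a query region in genome A (here: a selected region in mouse), the
genes it contains are projected through one-to-one orthologues into genome B
(dog), and the number of annotation segments (published selective-sweep
regions) overlapping those projected positions is counted.  The null
distribution places regions of the same length uniformly over genome A and
recounts; the empirical P is the fraction of placements reaching at least
the observed count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .utils import as_rng


@dataclass
class IntervalSet:
    """Named-genome intervals, 0-based half-open."""

    genome: str
    intervals: pd.DataFrame  # chrom, start, end, label

    def __post_init__(self) -> None:
        df = self.intervals.reset_index(drop=True).copy()
        if "label" not in df.columns:
            df["label"] = [f"iv{i}" for i in range(len(df))]
        if (df["start"] >= df["end"]).any():
            raise ValueError("intervals must satisfy start < end")
        df["chrom"] = df["chrom"].astype(str)
        self.intervals = df


@dataclass
class OrthologueMap:
    """One-to-one gene orthologue positions in two genomes."""

    records: pd.DataFrame  # gene, chrom_a, start_a, end_a, chrom_b, start_b, end_b

    def __post_init__(self) -> None:
        df = self.records.reset_index(drop=True).copy()
        dup = df["gene"].duplicated()
        if dup.any():
            # keep the one-to-one subset: first mapping per gene
            df = df[~dup].reset_index(drop=True)
        for c in ("chrom_a", "chrom_b"):
            df[c] = df[c].astype(str)
        self.records = df


def _overlaps(starts, ends, lo, hi):
    """Boolean mask of half-open intervals overlapping [lo, hi)."""
    return (starts < hi) & (ends > lo)


class _OverlapCounter:
    """Precomputed gene -> sweep-segment incidence for fast recounting."""

    def __init__(self, genes: IntervalSet, orth: OrthologueMap, sweeps: IntervalSet):
        gdf = genes.intervals.merge(
            orth.records, left_on="label", right_on="gene", how="inner"
        )
        sw = sweeps.intervals
        gene_sweeps = []
        for _, row in gdf.iterrows():
            on_chrom = sw[sw["chrom"] == row["chrom_b"]]
            hit = on_chrom[
                _overlaps(on_chrom["start"], on_chrom["end"], row["start_b"], row["end_b"])
            ]
            gene_sweeps.append(hit.index.to_numpy())
        self.table = gdf
        self.gene_sweeps = gene_sweeps

    def count(self, chrom: str, lo: int, hi: int) -> int:
        df = self.table
        mask = (df["chrom"].to_numpy() == str(chrom)) & _overlaps(
            df["start"].to_numpy(), df["end"].to_numpy(), lo, hi
        )
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            return 0
        hits = [self.gene_sweeps[i] for i in idx if len(self.gene_sweeps[i])]
        if not hits:
            return 0
        return int(len(np.unique(np.concatenate(hits))))


def count_sweep_overlaps(
    region: tuple[str, int, int],
    genes: IntervalSet,
    orth: OrthologueMap,
    sweeps: IntervalSet,
) -> int:
    """Distinct sweep segments hit by orthologues of genes in ``region``.

    ``region`` is (chrom, start, end), 0-based half-open, in the gene set's
    genome.  Genes overlapping the region are projected through the
    orthologue map; the count is the number of distinct sweep segments
    overlapping any projected gene interval.
    """
    chrom, lo, hi = str(region[0]), int(region[1]), int(region[2])
    if lo < 0 or hi <= lo:
        raise ValueError(f"malformed region {region}")
    return _OverlapCounter(genes, orth, sweeps).count(chrom, lo, hi)


@dataclass
class OverlapTestResult:
    p: float
    k_obs: int
    n_samples: int
    k_samples: np.ndarray
    placements: pd.DataFrame | None = None  # chrom, start per sample


def overlap_permutation_test(
    region_length: int,
    chrom_sizes: dict[str, int],
    genes: IntervalSet,
    orth: OrthologueMap,
    sweeps: IntervalSet,
    k_obs: int,
    n_samples: int = 10_000,
    rng: np.random.Generator | int | None = None,
    keep_placements: bool = False,
) -> OverlapTestResult:
    """Empirical P of observing >= ``k_obs`` sweep overlaps by chance.

    Each sample places one region of ``region_length`` uniformly over all
    genome-A positions admitting a full-length placement (start positions
    pooled across chromosomes, so a chromosome's probability is
    proportional to its admissible length); P = #{samples with
    k >= k_obs} / n_samples.
    """
    rng = as_rng(rng)
    chroms = []
    n_starts = []
    for chrom, size in chrom_sizes.items():
        ns = int(size) - int(region_length) + 1
        if ns > 0:
            chroms.append(str(chrom))
            n_starts.append(ns)
    if not chroms:
        raise ValueError("region_length exceeds every chromosome; no valid placement")
    n_starts = np.asarray(n_starts, dtype=np.int64)
    counter = _OverlapCounter(genes, orth, sweeps)

    cum = np.cumsum(n_starts)
    draws = rng.integers(0, cum[-1], size=n_samples)
    which = np.searchsorted(cum, draws, side="right")
    start = draws - np.concatenate(([0], cum[:-1]))[which]

    ks = np.empty(n_samples, dtype=np.int64)
    for i in range(n_samples):
        c = chroms[which[i]]
        lo = int(start[i])
        ks[i] = counter.count(c, lo, lo + int(region_length))
    p = float((ks >= int(k_obs)).mean())
    placements = None
    if keep_placements:
        placements = pd.DataFrame(
            {"chrom": [chroms[w] for w in which], "start": start.astype(int)}
        )
    return OverlapTestResult(
        p=p, k_obs=int(k_obs), n_samples=n_samples, k_samples=ks,
        placements=placements,
    )
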