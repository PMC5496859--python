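"""Observed heterozygosity tracks and sliding-window sweep candidates.

A region driven toward fixation by selection loses heterozygosity relative
to the rest of the genome.  The scan computes per-SNP observed
heterozygosity Ho (fraction of heterozygous calls among genotyped
individuals), averages it in sliding windows of 100 SNPs advanced by 10
SNPs within each chromosome, and flags the lowest decile of window means
genome-wide as candidate selected regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_panel import FounderPanel, GenotypeMatrix


@dataclass
class WindowResult:
    """Sliding-window means plus merged low-diversity candidate intervals."""

    windows: pd.DataFrame   # chrom, start_bp, end_bp, start_idx, end_idx, mean_ho, flagged
    intervals: pd.DataFrame  # chrom, start_bp, end_bp (merged flagged windows)
    cutoff: float


def heterozygosity_track(genotypes: GenotypeMatrix, panel: FounderPanel) -> pd.DataFrame:
    """Per-SNP observed heterozygosity, ordered by (chrom, bp).

    Ho = #(genotype == 1) / #non-missing; a SNP with no called individuals
    gets Ho = NaN.
    """
    meta = panel.snps[["chrom", "snp_id", "bp"]].copy()
    snp_ids = [s for s in meta["snp_id"] if s in genotypes.values.columns]
    meta = meta[meta["snp_id"].isin(snp_ids)]
    arr = genotypes.values[meta["snp_id"]].to_numpy(dtype=float)
    n_called = (~np.isnan(arr)).sum(axis=0).astype(float)
    n_het = (arr == 1.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n_called > 0, n_het / n_called, np.nan)
    out = meta.reset_index(drop=True)
    out["Ho"] = ho
    out["chrom"] = out["chrom"].astype(str)
    order = np.lexsort((out["bp"].to_numpy(), out["chrom"].map(_chrom_key).to_numpy()))
    return out.iloc[order].reset_index(drop=True)


def _chrom_key(c: str) -> int:
    try:
        return int(c)
    except ValueError:
        return 10_000


def low_diversity_regions(
    track: pd.DataFrame,
    window: int = 100,
    step: int = 10,
    quantile: float = 0.10,
) -> WindowResult:
    """Flag the lowest-decile heterozygosity windows genome-wide.

    Windows of ``window`` consecutive SNPs advanced by ``step`` SNPs are
    computed within chromosomes only; trailing SNPs not covered by a full
    window are ignored.  A window is flagged when its mean Ho is <= the
    empirical ``quantile`` of all window means (ties included), and
    overlapping or abutting flagged windows are merged into candidate
    intervals reported in bp.
    """
    rows = []
    any_window = False
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.sort_values("bp").reset_index(drop=True)
        n = len(sub)
        if n < window:
            warnings.warn(f"chromosome {chrom}: fewer than {window} SNPs; skipped")
            continue
        any_window = True
        ho = sub["Ho"].to_numpy(dtype=float)
        bp = sub["bp"].to_numpy()
        n_windows = (n - window) // step + 1
        for w in range(n_windows):
            i0 = w * step
            i1 = i0 + window  # exclusive
            rows.append(
                {
                    "chrom": str(chrom),
                    "start_bp": int(bp[i0]),
                    "end_bp": int(bp[i1 - 1]),
                    "start_idx": i0,
                    "end_idx": i1 - 1,
                    "mean_ho": float(np.nanmean(ho[i0:i1])),
                }
            )
    if not any_window:
        raise ValueError(f"no chromosome holds a full window of {window} SNPs")
    windows = pd.DataFrame(rows)
    cutoff = float(np.quantile(windows["mean_ho"].to_numpy(), quantile))
    windows["flagged"] = windows["mean_ho"] <= cutoff

    intervals = []
    for chrom, sub in windows[windows["flagged"]].groupby("chrom", sort=False):
        sub = sub.sort_values("start_idx")
        cur_start, cur_end, cur_end_idx = None, None, None
        for _, row in sub.iterrows():
            if cur_start is None:
                cur_start, cur_end, cur_end_idx = row["start_bp"], row["end_bp"], row["end_idx"]
            elif row["start_idx"] <= cur_end_idx + 1:
                cur_end = max(cur_end, row["end_bp"])
                cur_end_idx = max(cur_end_idx, row["end_idx"])
            else:
                intervals.append({"chrom": chrom, "start_bp": int(cur_start), "end_bp": int(cur_end)})
                cur_start, cur_end, cur_end_idx = row["start_bp"], row["end_bp"], row["end_idx"]
        if cur_start is not None:
            intervals.append({"chrom": chrom, "start_bp": int(cur_start), "end_bp": int(cur_end)})
    return WindowResult(
        windows=windows,
        intervals=pd.DataFrame(intervals, columns=["chrom", "start_bp", "end_bp"]),
        cutoff=cutoff,
    )


def intervals_to_bed(intervals: pd.DataFrame) -> pd.DataFrame:
    """Candidate intervals as 0-based half-open BED records."""
    bed = intervals.copy()
    bed["start"] = bed["start_bp"] - 1
    bed["end"] = bed["end_bp"]
    return bed[["chrom", "start", "end"]]
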