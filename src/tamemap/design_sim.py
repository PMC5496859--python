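"""Breeding-design evaluation: founder-allele retention under drift.

Before committing to a breeding design, one asks how much founder diversity
a stock of a given size retains under no selection.  Each replicate drops a
single unlinked locus carrying 8 distinct founder alleles through an
independent realization of the mating design and asks which alleles survive
among the final-generation breeders (the animals that would found the next
generation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .pedigree_gene_drop import (
    ROTATION_OFFSET,
    Pedigree,
    founder_strains,
    random_nonsib_permutation,
)
from .utils import as_rng


@dataclass
class RetentionResult:
    """Founder-allele survival across replicate drops of one unlinked locus."""

    n_reps: int
    n_alleles: int
    lost_counts: np.ndarray      # per replicate: founder alleles absent at the end
    allele_freqs: np.ndarray     # (n_reps, n_alleles) final frequencies

    @property
    def fraction_lost(self) -> float:
        """Fraction of replicates losing at least one founder allele."""
        return float((self.lost_counts >= 1).mean())

    @property
    def fraction_fixed(self) -> float:
        """Fraction of replicates where a single allele reached fixation."""
        return float((self.lost_counts == self.n_alleles - 1).mean())

    def summary(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "fraction_lost": self.fraction_lost,
            "fraction_fixed": self.fraction_fixed,
            "mean_lost": float(self.lost_counts.mean()),
            "mean_allele_freq": [float(x) for x in self.allele_freqs.mean(axis=0)],
        }


def _offspring(dam, sire, k, rng):
    """k offspring allele-pairs per family from (f, 2) parent allele arrays."""
    f = len(dam)
    rows = np.arange(f)[:, None]
    di = rng.integers(0, 2, size=(f, k))
    si = rng.integers(0, 2, size=(f, k))
    return np.stack([dam[rows, di], sire[rows, si]], axis=2)  # (f, k, 2)


def _whs_replicate(rng, n_strains, n_pairs, last_generation):
    """Final-generation breeder alleles for one WHS-design realization."""
    fam = np.arange(n_strains)
    # G1: rotation pairs of inbred founders -> every child of family i is
    # deterministically {strain i, strain i-1}
    g1 = np.stack([fam, (fam - 1) % n_strains], axis=1).astype(np.int8)
    if last_generation == 1:
        return np.concatenate([g1, g1], axis=0)  # 1F + 1M per family
    # G2: rotation among G1 families, litters of (n_pairs // n_strains) per sex
    copies = n_pairs // n_strains
    dam = g1
    sire = g1[(fam - ROTATION_OFFSET) % n_strains]
    g2f = _offspring(dam, sire, copies, rng)  # (n_strains, copies, 2)
    g2m = _offspring(dam, sire, copies, rng)
    if last_generation == 2:
        return np.concatenate([g2f.reshape(-1, 2), g2m.reshape(-1, 2)], axis=0)
    # expansion pairs: pair j takes the j//n-th daughter of family j % n and
    # the j//n-th son of family (j - offset) % n
    j = np.arange(n_pairs)
    F = g2f[j % n_strains, j // n_strains]          # (n_pairs, 2)
    M = g2m[(j - ROTATION_OFFSET) % n_strains, j // n_strains]
    for gen in range(3, last_generation + 1):
        sigma = random_nonsib_permutation(n_pairs, rng)
        dam, sire = F, M[sigma]
        F = _offspring(dam, sire, 1, rng)[:, 0, :]
        M = _offspring(dam, sire, 1, rng)[:, 0, :]
    return np.concatenate([F, M], axis=0)


def _constant_pairs_replicate(rng, n_strains, n_pairs, last_generation):
    """Random-union scheme with a constant pair count from G1 on."""
    j = np.arange(n_pairs)
    g1 = np.stack([j % n_strains, (j - 1) % n_strains], axis=1).astype(np.int8)
    F, M = g1, g1.copy()
    for gen in range(2, last_generation + 1):
        sigma = random_nonsib_permutation(n_pairs, rng)
        dam, sire = F, M[sigma]
        F = _offspring(dam, sire, 1, rng)[:, 0, :]
        M = _offspring(dam, sire, 1, rng)[:, 0, :]
    return np.concatenate([F, M], axis=0)


def simulate_allele_retention(
    n_pairs: int = 16,
    last_generation: int = 12,
    scheme: str = "whs-design",
    n_reps: int = 100_000,
    n_strains: int = 8,
    rng: np.random.Generator | int | None = None,
) -> RetentionResult:
    """Distribution of founder-allele loss under the no-selection design.

    Each replicate is an independent pedigree realization with a single
    unlinked locus carrying ``n_strains`` distinct founder alleles;
    ``scheme="whs-design"`` uses the rotation -> expansion -> random
    non-sib design, ``"constant-pairs"`` keeps ``n_pairs`` random-union
    pairs every generation.
    """
    if n_reps < 100:
        warnings.warn("fewer than 100 replicates gives unstable estimates")
    if scheme not in ("whs-design", "constant-pairs"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "whs-design" and n_pairs % n_strains:
        raise ValueError("whs-design requires n_pairs to be a multiple of n_strains")
    rng = as_rng(rng)

    lost = np.empty(n_reps, dtype=np.int16)
    freqs = np.empty((n_reps, n_strains), dtype=np.float32)
    rep_fn = _whs_replicate if scheme == "whs-design" else _constant_pairs_replicate
    for i in range(n_reps):
        final = rep_fn(rng, n_strains, n_pairs, last_generation)
        counts = np.bincount(final.ravel(), minlength=n_strains)
        lost[i] = int((counts == 0).sum())
        freqs[i] = counts / counts.sum()
    return RetentionResult(
        n_reps=n_reps, n_alleles=n_strains, lost_counts=lost, allele_freqs=freqs
    )


def single_locus_drop(
    ped: Pedigree,
    n_reps: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Drop one unlinked locus through a fixed pedigree, many times at once.

    Founder alleles are the founder-strain indices (in order of first
    appearance).  Returns an ``(n_reps, n_individuals, 2)`` int8 array of
    allele indices, rows in pedigree order.  This is the cross-check path
    for the design-specific replicate engines and the enumeration oracles.
    """
    rng = as_rng(rng)
    strains = founder_strains(ped)
    dam_pos, sire_pos, founder_idx, gens = ped.drop_arrays(strains)
    n = len(dam_pos)
    A = np.empty((n_reps, n, 2), dtype=np.int8)
    founders = founder_idx >= 0
    A[:, founders, :] = founder_idx[founders, None].astype(np.int8)
    reps = np.arange(n_reps)[:, None]
    for rows_g in gens:
        if len(rows_g) == 0:
            continue
        for axis, par in ((0, dam_pos[rows_g]), (1, sire_pos[rows_g])):
            pick = rng.integers(0, 2, size=(n_reps, len(rows_g)))
            A[:, rows_g, axis] = A[reps, par[None, :], pick]
    return A
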