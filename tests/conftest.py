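"""Shared fixtures: one synthetic panel, pedigree, and drift null per session."""

import numpy as np
import pandas as pd
import pytest

from tamemap import (
    build_whs_pedigree,
    classify_snp_sharing,
    filter_snps,
    generate_founder_panel,
    generate_whs_dataset,
    simulate_null_max,
)
from tamemap.genotype_panel import FounderPanel
from tamemap.selection_mapping import private_snp_positions

SESSION_SEED = 20170704


@pytest.fixture(scope="session")
def panel_and_map():
    """Default desk-scale founder panel (~5,214 SNPs over 19 x 70 cM)."""
    return generate_founder_panel(seed=SESSION_SEED)


@pytest.fixture(scope="session")
def sharing(panel_and_map):
    panel, _ = panel_and_map
    return classify_snp_sharing(filter_snps(panel))


@pytest.fixture(scope="session")
def whs_pedigree():
    """One 16-pair, 12-generation WHS-design pedigree (single line)."""
    return build_whs_pedigree(seed=SESSION_SEED)


@pytest.fixture(scope="session")
def drift_null(whs_pedigree, panel_and_map, sharing):
    """No-selection null of per-strain maximum private-allele frequency.

    2,000 gene drops of the session pedigree at the session panel's
    private-SNP positions; shared by the threshold, calibration and power
    checks.
    """
    panel, gmap = panel_and_map
    priv = private_snp_positions(filter_snps(panel), sharing)
    return simulate_null_max(
        whs_pedigree, gmap, priv, n_sims=2000, rng=SESSION_SEED
    )


@pytest.fixture(scope="session")
def selected_dataset():
    """Full two-line synthetic study (selection on in S, off in C)."""
    return generate_whs_dataset(seed=SESSION_SEED)


def make_panel(calls: dict[str, list[str]], chroms=None, strains=None) -> FounderPanel:
    """Small hand-written panel; ``calls`` maps snp_id -> 8 founder calls."""
    from tamemap import DEFAULT_STRAINS

    strains = list(strains or DEFAULT_STRAINS)
    n = len(calls)
    chroms = chroms or ["1"] * n
    rows = []
    for k, (snp_id, alleles) in enumerate(calls.items()):
        rows.append(
            {
                "chrom": chroms[k],
                "snp_id": snp_id,
                "bp": 1000 * (k + 1),
                "cM": 0.1 * (k + 1),
                **dict(zip(strains, alleles)),
            }
        )
    return FounderPanel(strains, pd.DataFrame(rows))
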