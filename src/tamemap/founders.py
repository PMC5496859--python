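"""Reference data for the wild-derived heterogeneous stock (WHS) founders.

The WHS was founded from eight wild-derived inbred mouse strains spanning
three *Mus musculus* subspecies.  The per-strain private-SNP counts and the
allele-sharing category counts below are the published GigaMUGA founder-panel
tallies for this stock; they parameterize the synthetic panel generator and
serve as a documented point of comparison for classification output.
"""

from __future__ import annotations

#: Founder strains in the published tabulation order ("/" dropped from BFM/2
#: for file-format friendliness).
DEFAULT_STRAINS: tuple[str, ...] = (
    "PGN2", "BFM2", "HMI", "NJL", "BLG2", "MSM", "CHD", "KJR",
)

#: Subspecies of origin for each founder strain.
STRAIN_SUBSPECIES: dict[str, str] = {
    "PGN2": "domesticus",
    "BFM2": "domesticus",
    "HMI": "castaneus",
    "NJL": "musculus",
    "BLG2": "musculus",
    "MSM": "musculus",
    "CHD": "musculus",
    "KJR": "musculus",
}

#: Published GigaMUGA counts of SNPs private to a single founder strain.
PRIVATE_SNP_COUNTS: dict[str, int] = {
    "PGN2": 8109,
    "BFM2": 6038,
    "HMI": 4533,
    "NJL": 724,
    "BLG2": 585,
    "MSM": 275,
    "CHD": 158,
    "KJR": 108,
}

#: Published counts of SNPs by allele-sharing category: a category-c SNP has
#: its minority allele carried by exactly c of the 8 founders (c = 1..4).
SHARING_CATEGORY_COUNTS: dict[int, int] = {
    1: 20_530,
    2: 19_719,
    3: 9_167,
    4: 2_719,
}

#: Total SNPs retained after QC in the published founder panel.
SHARING_TOTAL: int = 52_135

#: Number of mouse autosomes; the X and Y are excluded throughout.
N_AUTOSOMES: int = 19

AUTOSOME_LABELS: tuple[str, ...] = tuple(str(i) for i in range(1, N_AUTOSOMES + 1))
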