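"""Bundled reference data.

Murine TRB gene-segment labels used by the repertoire simulator, and the
published worked-example summary of the eight murine splenic Teff aliquots
(nominal cell numbers per aliquot and the Shannon-index effective clonotype
numbers measured on their sequenced repertoires) that serves as a fixed
input for similarity/correlation worked examples.

The simulator's calibration anchors are also stored here: for each evenness
parameter ``A`` of the simulated Zipf repertoires, the published
post-rarefaction clonotype richness ``N_A`` of the 6*10^5-sequence dataset
and the total token count ``M_A`` of the pre-rarefaction abundance list.
"""

from __future__ import annotations

# Murine TRBV / TRBJ functional gene segments (IMGT nomenclature).
TRBV_GENES: tuple[str, ...] = (
    "TRBV1", "TRBV2", "TRBV3", "TRBV4", "TRBV5", "TRBV12-1", "TRBV12-2",
    "TRBV13-1", "TRBV13-2", "TRBV13-3", "TRBV14", "TRBV15", "TRBV16",
    "TRBV17", "TRBV19", "TRBV20", "TRBV23", "TRBV26", "TRBV29", "TRBV30",
    "TRBV31",
)

TRBJ_GENES: tuple[str, ...] = (
    "TRBJ1-1", "TRBJ1-2", "TRBJ1-3", "TRBJ1-4", "TRBJ1-5", "TRBJ1-6",
    "TRBJ1-7", "TRBJ2-1", "TRBJ2-2", "TRBJ2-3", "TRBJ2-4", "TRBJ2-5",
    "TRBJ2-6", "TRBJ2-7",
)

#: Nominal cell-equivalents of the eight Teff RNA aliquots (two replicates
#: per dilution), in cells.
ALIQUOT_CELL_NUMBERS: tuple[int, ...] = (
    500, 500, 1_000, 1_000, 5_000, 5_000, 50_000, 50_000,
)

#: Shannon-index effective clonotype numbers measured on the corresponding
#: sequenced repertoires (round(exp(H)), clonotypes), same aliquot order.
ALIQUOT_SHANNON_EFFECTIVE: tuple[int, ...] = (
    171, 238, 1_034, 735, 3_124, 5_337, 30_432, 35_027,
)

#: Evenness parameters A = 1/alpha of the seven simulated Zipf repertoires.
ZIPF_A_VALUES: tuple[int, ...] = (2, 3, 4, 5, 10, 20, 100)

#: Published clonotype richness N_A of each simulated dataset after
#: rarefaction to 6*10^5 sequences (clonotypes) -- the calibration anchors.
RICHNESS_ANCHORS: dict[int, int] = {
    2: 155_495,
    3: 394_784,
    4: 435_528,
    5: 450_625,
    10: 469_974,
    20: 476_829,
    100: 480_919,
}

#: Total token count M_A of the pre-rarefaction abundance list Z_A for each
#: A (sequences) -- inputs to the multinomial sampling step.
TOKEN_TOTALS: dict[int, int] = {
    2: 131_000_000,
    3: 21_000_000,
    4: 16_000_000,
    5: 14_400_000,
    10: 12_300_000,
    20: 11_600_000,
    100: 11_100_000,
}

#: Number of distinct clonotype labels in the simulated library.
LIBRARY_SIZE: int = 2_000_000

#: Size, in sequences, of each simulated dataset after rarefaction.
DATASET_SIZE: int = 600_000

#: Subsampling depths, in sequences, of the rarefaction experiment grid.
EXPERIMENT_DEPTHS: tuple[int, ...] = (500, 1_000, 5_000, 50_000, 500_000, 1_000_000)
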