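"""Small worked-example tables bundled for tests and documentation.

Both tables come from a silica-exposure study of mouse macrophage and
liver expression arrays re-analysed with this pipeline:

* the twelve lncRNA probe sets found differentially expressed in both
  tissues, with their per-tissue regulation direction; and
* the genomic coordinates (mm, 1-based inclusive) of the five shared
  lncRNA loci and the four coding genes proposed as their cis targets
  within 10 kb.

They are tiny, so they live as in-source constants rather than data files.
"""

from __future__ import annotations

import pandas as pd

from lncarray.cis import GenomicInterval

# probe_set_id, gene_symbol, direction in macrophage, direction in liver
_SHARED_PROBE_ROWS = [
    ("1427580_a_at", "Rian", "up", "up"),
    ("1428055_at", "Rian", "up", "up"),
    ("1427140_at", "Pvt1", "down", "down"),
    ("1452324_at", "Pvt1", "down", "down"),
    ("1426758_s_at", "Meg3", "up", "down"),
    ("1436057_at", "Meg3", "up", "down"),
    ("1436713_s_at", "Meg3", "up", "down"),
    ("1439380_x_at", "Meg3", "up", "down"),
    ("1452183_a_at", "Meg3", "up", "down"),
    ("1428286_at", "2900097C17Rik", "down", "up"),
    ("1432646_a_at", "2900097C17Rik", "down", "up"),
    ("1430989_a_at", "1700020I14Rik", "down", "down"),
]


def shared_lncrna_probes() -> pd.DataFrame:
    """Probe-level regulation of the lncRNAs dysregulated in both tissues."""
    return pd.DataFrame(
        _SHARED_PROBE_ROWS,
        columns=["probe_set_id", "gene_symbol",
                 "direction_macrophage", "direction_liver"],
    )


# lncRNA loci of the five shared genes (name, chrom, start, end)
_LNC_INTERVALS = [
    ("Rian", "chr12", 109_603_945, 109_661_711),
    ("Pvt1", "chr15", 62_037_986, 62_250_976),
    ("Meg3", "chr12", 109_545_398, 109_568_650),
    ("2900097C17Rik", "chr2", 156_388_063, 156_392_979),
    ("1700020I14Rik", "chr2", 119_594_296, 119_600_744),
]

# coding genes reported as cis targets of those loci
_GENE_INTERVALS = [
    ("Rtl1", "chr12", 109_589_192, 109_600_330),
    ("Z11981", "chr15", 62_176_887, 62_180_977),
    ("Chp1", "chr2", 119_547_706, 119_587_022),
    ("Oip5", "chr2", 119_609_531, 119_618_505),
]

# published relation of each target gene to its lncRNA
CIS_EXPECTED_RELATIONS = {
    ("Rian", "Rtl1"): "upstream",
    ("Pvt1", "Z11981"): "overlap",
    ("1700020I14Rik", "Chp1"): "upstream",
    ("1700020I14Rik", "Oip5"): "downstream",
}


def cis_lncrna_intervals() -> list[GenomicInterval]:
    """The six lncRNA interval rows of the cis worked example (the
    1700020I14Rik locus appears once; it carries two targets)."""
    return [GenomicInterval(chrom=c, start=s, end=e, name=n)
            for n, c, s, e in _LNC_INTERVALS]


def cis_gene_intervals() -> list[GenomicInterval]:
    return [GenomicInterval(chrom=c, start=s, end=e, name=n)
            for n, c, s, e in _GENE_INTERVALS]
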