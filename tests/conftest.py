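"""Shared fixtures: the published Cxqdsx splice-junction contexts and
deterministic hypothesis settings."""

from collections import namedtuple

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

Junction = namedtuple("Junction", "intron_id exon_end6 donor16 acceptor16 next_exon10 Y")

# The eight published Cxqdsx splice junctions: last 6 exon nt, first 16 intron
# nt (donor), last 16 intron nt (12-nt tract + 4-nt acceptor), first 10 nt of
# the next exon, and the tract pyrimidine count.
CXQDSX_JUNCTIONS = [
    Junction("intron1", "AAAAAG", "gtgggcttctttatct", "ctttttcccgtttcag", "ATCCTTGCTT", 11),
    Junction("intron2", "AAGGAG", "gtaagttcgcaacctc", "cctcctctctttgcag", "CCAATCATGC", 12),
    Junction("intron3a", "TACCAG", "gtacgtgtcttccgct", "cattatatcatttcag", "TCCCTCCAAA", 8),
    Junction("intron3b", "GATCAG", "gtgagtgctagaagtc", "tattatcccctttcag", "ACGATGAACT", 10),
    Junction("intron4", "ACGAAG", "gtatggccgagtgttc", "ttccgttcctacgcag", "GTCAAGCCGT", 10),
    Junction("intron4ex", "TAAAAT", "gtacgcaagagattcg", "ttccgttcctacgcag", "GTCAAGCCGT", 10),
    Junction("intron5", "TGACAG", "gtacttgaactaatta", "ccaaccaacaaaacag", "CTCAGGCTGT", 5),
    Junction("intron6", "GCGAAG", "gtgagttgagcattgt", "cttatcatcattacag", "ATGCCGCTAG", 9),
]

# Genome-wide acceptor-tract statistics over 52,278 internal exons, as
# published for the Culex assembly; used as given constants.
GENOME_WIDE_MEAN_Y = 8.58
GENOME_WIDE_SD_Y = 1.39

DSXRE = "NMDNCRWNCWAYM"
NV_TRA = "NGAAGAWN"
RBP1A = "DCADCTTTA"
RBP1B = "ATCYNNA"
TRA2_ISS = "CAAGR"


@pytest.fixture
def cxqdsx_junctions():
    return CXQDSX_JUNCTIONS
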