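"""Splice-site context extraction and polypyrimidine-tract acceptor strength.

The strength statistic is the pyrimidine (C/T) count of the 12 nt immediately
upstream of the 4-nt splice-acceptor end of an intron: a pyrimidine-poor tract
(purine interruptions) makes a 3' acceptor "weak"/suboptimal and dependent on
splicing enhancers.  Acceptors are scored against a population mean/SD and
flagged weak when their z-score falls at or below a one-sided low threshold
(default z <= -2).  Canonical junctions are GT..AG.

Gene models are exon interval lists; minus-strand genes are processed on the
reverse complement so that contexts always read in the transcript sense.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._seq import normalize, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "DonorContext",
    "AcceptorContext",
    "AcceptorStats",
    "SpliceSiteCall",
    "load_gene_models",
    "extract_splice_contexts",
    "pyrimidine_count",
    "acceptor_stats",
    "flag_weak_acceptor",
    "validate_canonical",
]

MIN_INTRON = 30  # contexts need 16 nt at each intron end

TRACT_LEN = 12
ACCEPTOR_LEN = 4
DONOR_LEN = 16
EXON_END_LEN = 6


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of one transcript on one contig.

    Exons are 0-based half-open, sorted, non-overlapping, in genomic order
    regardless of strand.
    """

    seq_id: str
    gene_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.exons) < 1:
            raise ValueError(f"gene {self.gene_id}: needs at least one exon")
        for (s, e) in self.exons:
            if not 0 <= s < e:
                raise ValueError(f"gene {self.gene_id}: bad exon interval ({s}, {e})")
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError(f"gene {self.gene_id}: exons overlap or are unsorted")


@dataclass(frozen=True)
class DonorContext:
    intron_id: str
    exon_end6: str  # last 6 exon nt (uppercase)
    donor16: str  # first 16 intron nt (lowercase)


@dataclass(frozen=True)
class AcceptorContext:
    intron_id: str
    tract12: str  # 12 nt immediately 5' of the acceptor 4-mer (lowercase)
    acceptor4: str  # terminal 4 intron nt (lowercase)

    @property
    def Y(self) -> int:
        return pyrimidine_count(self.tract12)


@dataclass(frozen=True)
class AcceptorStats:
    n: int
    mean: float
    sd: float
    se: float


@dataclass(frozen=True)
class SpliceSiteCall:
    intron_id: str
    canonical: bool | None = None
    weak: bool | None = None
    z: float | None = None


def pyrimidine_count(tract12: str) -> int:
    """Number of C/T in a 12-nt polypyrimidine tract (N counts as neither)."""
    t = normalize(tract12)
    if len(t) != TRACT_LEN:
        raise ValueError(f"tract must be {TRACT_LEN} nt, got {len(t)}")
    return sum(1 for b in t if b in "CT")


def acceptor_stats(counts: Sequence[int]) -> AcceptorStats:
    """Mean, sample SD and SE of a population of tract pyrimidine counts."""
    n = len(counts)
    if n < 2:
        raise ValueError("need at least two acceptors for mean/SD")
    mean = sum(counts) / n
    var = sum((c - mean) ** 2 for c in counts) / (n - 1)
    sd = math.sqrt(var)
    return AcceptorStats(n=n, mean=mean, sd=sd, se=sd / math.sqrt(n))


def flag_weak_acceptor(
    Y: int,
    stats: AcceptorStats,
    z_threshold: float = 2.0,
    intron_id: str = "",
    canonical: bool | None = None,
) -> SpliceSiteCall:
    """Call an acceptor weak when its tract is significantly pyrimidine-poor.

    One-sided: weak iff z = (Y - mean)/sd <= -z_threshold.  A pyrimidine-rich
    outlier (large positive z) is a strong acceptor, not a weak one.
    """
    if stats.sd <= 0:
        raise ValueError("population SD must be positive to compute z-scores")
    z = (Y - stats.mean) / stats.sd
    return SpliceSiteCall(intron_id=intron_id, canonical=canonical, weak=z <= -z_threshold, z=z)


def _oriented(genome: Mapping[str, str], model: GeneModel) -> tuple[str, list[tuple[int, int]]]:
    """Contig sequence and exon intervals in transcript orientation."""
    try:
        contig = normalize(str(genome[model.seq_id]))
    except KeyError:
        raise KeyError(f"gene {model.gene_id}: contig {model.seq_id!r} not in genome") from None
    L = len(contig)
    for i, (s, e) in enumerate(model.exons, 1):
        if e > L:
            raise ValueError(
                f"gene {model.gene_id} exon {i} ({s}, {e}) out of bounds for "
                f"contig {model.seq_id} of length {L}"
            )
    if model.strand == "+":
        return contig, list(model.exons)
    rc = reverse_complement(contig)
    exons = sorted((L - e, L - s) for s, e in model.exons)
    return rc, exons


def extract_splice_contexts(
    genome: Mapping[str, str],
    gene_models: Iterable[GeneModel],
) -> list[tuple[DonorContext, AcceptorContext]]:
    """One (donor, acceptor) context pair per intron, in transcript order.

    Single-exon genes yield nothing; introns shorter than 30 nt are skipped
    with a warning (their two contexts would overlap).
    """
    out: list[tuple[DonorContext, AcceptorContext]] = []
    for model in gene_models:
        seq, exons = _oriented(genome, model)
        for i, ((_, e0), (s1, _)) in enumerate(zip(exons, exons[1:]), 1):
            intron_id = f"{model.gene_id}.intron{i}"
            intron = seq[e0:s1]
            if len(intron) < MIN_INTRON:
                logger.warning("skipping %s: intron of %d nt < %d", intron_id, len(intron), MIN_INTRON)
                continue
            donor = DonorContext(
                intron_id=intron_id,
                exon_end6=seq[max(0, e0 - EXON_END_LEN) : e0],
                donor16=intron[:DONOR_LEN].lower(),
            )
            acceptor = AcceptorContext(
                intron_id=intron_id,
                tract12=intron[-(TRACT_LEN + ACCEPTOR_LEN) : -ACCEPTOR_LEN].lower(),
                acceptor4=intron[-ACCEPTOR_LEN:].lower(),
            )
            out.append((donor, acceptor))
    return out


def validate_canonical(
    genome: Mapping[str, str],
    gene_models: Iterable[GeneModel],
) -> list[SpliceSiteCall]:
    """GT..AG check for every intron (case-insensitive)."""
    calls: list[SpliceSiteCall] = []
    for model in gene_models:
        seq, exons = _oriented(genome, model)
        for i, ((_, e0), (s1, _)) in enumerate(zip(exons, exons[1:]), 1):
            intron = seq[e0:s1]
            if len(intron) < MIN_INTRON:
                continue
            calls.append(
                SpliceSiteCall(
                    intron_id=f"{model.gene_id}.intron{i}",
                    canonical=intron[:2] == "GT" and intron[-2:] == "AG",
                )
            )
    return calls


def load_gene_models(gff3_path: str | Path) -> list[GeneModel]:
    """Read exon features from GFF3 (1-based closed), grouped by transcript.

    Exons are grouped by their Parent attribute (falling back to ID, then
    transcript_id) and converted to 0-based half-open coordinates.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    groups: dict[str, dict] = {}
    for exon in db.features_of_type("exon", order_by=("seqid", "start")):
        parents = exon.attributes.get("Parent") or exon.attributes.get("transcript_id")
        if not parents:
            parents = [exon.id]
        for parent in parents:
            g = groups.setdefault(parent, {"seq_id": exon.seqid, "strand": exon.strand, "exons": []})
            g["exons"].append((exon.start - 1, exon.end))
    models = []
    for gene_id, g in groups.items():
        models.append(
            GeneModel(
                seq_id=g["seq_id"],
                gene_id=gene_id,
                strand=g["strand"] if g["strand"] in "+-" else "+",
                exons=tuple(sorted(g["exons"])),
            )
        )
    return models
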