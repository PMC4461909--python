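"""Seeded generators for every input the pipeline consumes, with ground truth.

Each generator emulates one class of study input: i.i.d. background
transcripts; transcripts with a planted k-in-w degenerate-motif cluster;
multi-exon gene loci with canonical GT..AG introns whose acceptor tracts
realise prescribed pyrimidine counts; promoter regions with Inr and DPE
planted at a fixed spacing; and codon-sequence pairs diverged at a chosen
dN/dS (omega).  Everything is reproducible from a seed, and every generator
returns a truth record sufficient to score the matching pipeline stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ._seq import BASES, normalize, reverse_complement
from .cluster_null import UNIFORM, BackgroundModel
from .codon_rates import STOPS, _pair_differences, _translate
from .motif_engine import DegeneratePattern
from .promoter_scan import INR_TSS_OFFSET
from .splice_sites import GeneModel

__all__ = [
    "TruthRecord",
    "LocusSpec",
    "gen_background",
    "gen_transcriptome",
    "plant_cluster",
    "gen_gene_locus",
    "gen_promoter_region",
    "evolve_codon_pair",
]


@dataclass
class TruthRecord:
    """Ground truth emitted alongside a synthetic dataset."""

    kind: str
    seed: int | None
    params: dict[str, Any] = field(default_factory=dict)
    features: list[dict[str, Any]] = field(default_factory=list)


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_background(
    L: int,
    background: BackgroundModel = UNIFORM,
    seed: int | np.random.Generator | None = None,
) -> str:
    """i.i.d. nucleotide sequence of length L under a 0-order background."""
    if L < 0:
        raise ValueError("L must be non-negative")
    if L == 0:
        return ""
    rng = _rng(seed)
    codes = rng.choice(4, size=L, p=background.freqs)
    return "".join(BASES[c] for c in codes)


def gen_transcriptome(
    n: int,
    length: int,
    background: BackgroundModel = UNIFORM,
    seed: int | None = None,
    prefix: str = "tx",
) -> dict[str, str]:
    """n background transcripts of a fixed length, ids ``tx0001``..."""
    rng = _rng(seed)
    width = max(4, len(str(n)))
    return {
        f"{prefix}{i + 1:0{width}d}": gen_background(length, background, rng)
        for i in range(n)
    }


def _sample_word(pattern: DegeneratePattern, rng: np.random.Generator) -> str:
    """One concrete expansion, uniform over the expansion set."""
    from ._seq import IUPAC_CLASSES

    return "".join(s if len(IUPAC_CLASSES[s]) == 1 else IUPAC_CLASSES[s][rng.integers(len(IUPAC_CLASSES[s]))] for s in pattern.symbols)


def plant_cluster(
    sequence: str,
    pattern: DegeneratePattern | str,
    k: int,
    w: int,
    seed: int | np.random.Generator | None = None,
) -> tuple[str, TruthRecord]:
    """Write k concrete motif expansions into one random w-nt window.

    Placements are non-overlapping (so every planted copy is guaranteed to
    match on rescan) and the sequence outside the window is unchanged.
    """
    if isinstance(pattern, str):
        pattern = DegeneratePattern.from_iupac(pattern)
    seq = normalize(sequence)
    if len(seq) < w:
        raise ValueError(f"sequence of {len(seq)} nt shorter than window {w}")
    truth = TruthRecord(
        kind="planted_cluster",
        seed=seed if isinstance(seed, int) else None,
        params={"pattern": str(pattern), "k": k, "w": w},
    )
    if k == 0:
        return seq, truth
    m = pattern.length
    if k * m > w:
        raise ValueError(f"{k} non-overlapping copies of a {m}-mer do not fit in {w} nt")
    rng = _rng(seed)
    window_start = int(rng.integers(0, len(seq) - w + 1))
    # k sorted slack offsets in [0, w - k*m]; copy i starts at slack_i + i*m
    slack = np.sort(rng.integers(0, w - k * m + 1, size=k))
    chars = list(seq)
    for i in range(k):
        start = window_start + int(slack[i]) + i * m
        word = _sample_word(pattern, rng)
        chars[start : start + m] = word
        truth.features.append({"start": start, "end": start + m, "word": word})
    truth.params["window_start"] = window_start
    return "".join(chars), truth


@dataclass(frozen=True)
class LocusSpec:
    """Multi-exon locus blueprint: one intron per requested tract Y value."""

    y_targets: tuple[int, ...]
    exon_len: tuple[int, int] = (60, 120)
    intron_len: tuple[int, int] = (40, 90)
    flank: int = 50
    strand: str = "+"
    seq_id: str = "contig1"
    gene_id: str = "gene1"

    def __post_init__(self) -> None:
        for y in self.y_targets:
            if not 0 <= y <= 12:
                raise ValueError(f"tract pyrimidine target {y} outside [0, 12]")
        if self.intron_len[0] < 36:
            raise ValueError("introns need >= 36 nt (gt + donor/acceptor contexts)")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


def _make_tract(y: int, rng: np.random.Generator) -> str:
    """12-nt tract with exactly y pyrimidines."""
    pos = rng.permutation(12)[:y]
    return "".join(
        ("CT"[rng.integers(2)]) if i in pos else ("AG"[rng.integers(2)]) for i in range(12)
    )


def gen_gene_locus(
    spec: LocusSpec,
    seed: int | None = None,
    background: BackgroundModel = UNIFORM,
) -> tuple[dict[str, str], list[GeneModel], TruthRecord]:
    """A contig with one multi-exon gene whose introns are GT..AG and whose
    acceptor tracts realise exactly the requested pyrimidine counts."""
    rng = _rng(seed)
    n_introns = len(spec.y_targets)
    n_exons = n_introns + 1
    parts: list[str] = [gen_background(spec.flank, background, rng)]
    exons: list[tuple[int, int]] = []
    truth = TruthRecord(kind="gene_locus", seed=seed, params={"spec": spec.__dict__.copy()})
    pos = spec.flank
    for i in range(n_exons):
        elen = int(rng.integers(spec.exon_len[0], spec.exon_len[1] + 1))
        parts.append(gen_background(elen, background, rng))
        exons.append((pos, pos + elen))
        pos += elen
        if i < n_introns:
            ilen = int(rng.integers(spec.intron_len[0], spec.intron_len[1] + 1))
            tract = _make_tract(int(spec.y_targets[i]), rng)
            acceptor4 = BASES[rng.integers(4)] + "CAG"
            middle = gen_background(ilen - 2 - 14 - 16, background, rng)
            intron = "GT" + gen_background(14, background, rng) + middle + tract + acceptor4
            assert len(intron) == ilen
            parts.append(intron)
            truth.features.append(
                {"intron_index": i + 1, "Y": int(spec.y_targets[i]), "tract12": tract.lower()}
            )
            pos += ilen
    parts.append(gen_background(spec.flank, background, rng))
    contig = "".join(parts)
    if spec.strand == "-":
        L = len(contig)
        contig = reverse_complement(contig)
        exons = sorted((L - e, L - s) for s, e in exons)
    model = GeneModel(
        seq_id=spec.seq_id, gene_id=spec.gene_id, strand=spec.strand, exons=tuple(exons)
    )
    return {spec.seq_id: contig}, [model], truth


def gen_promoter_region(
    length: int = 300,
    inr_variant: str = "YYANWY",
    dpe_variant: str = "RGWYV",
    dpe_position: int = 28,
    tss_at: int | None = None,
    background: BackgroundModel = UNIFORM,
    seed: int | None = None,
    seq_id: str = "promoter1",
) -> tuple[str, TruthRecord]:
    """Background sequence with an Inr and a DPE planted at the canonical
    spacing (DPE first base at +``dpe_position`` from the Inr adenine)."""
    rng = _rng(seed)
    inr = DegeneratePattern.from_iupac(inr_variant, "Inr")
    dpe = DegeneratePattern.from_iupac(dpe_variant, "DPE")
    min_tss = INR_TSS_OFFSET
    max_tss = length - (dpe_position - 1) - dpe.length
    if max_tss < min_tss:
        raise ValueError("region too short for the requested Inr/DPE spacing")
    tss = int(rng.integers(min_tss, max_tss + 1)) if tss_at is None else tss_at
    if not min_tss <= tss <= max_tss:
        raise ValueError(f"tss_at={tss_at} does not fit the region")
    chars = list(gen_background(length, background, rng))
    inr_word = list(_sample_word(inr, rng))
    inr_word[INR_TSS_OFFSET] = "A"
    inr_start = tss - INR_TSS_OFFSET
    chars[inr_start : inr_start + inr.length] = inr_word
    dpe_start = tss + dpe_position - 1
    chars[dpe_start : dpe_start + dpe.length] = _sample_word(dpe, rng)
    truth = TruthRecord(
        kind="promoter_region",
        seed=seed,
        params={
            "inr_variant": str(inr),
            "dpe_variant": str(dpe),
            "dpe_position": dpe_position,
            "seq_id": seq_id,
        },
        features=[{"inr_start": inr_start, "tss": tss, "dpe_start": dpe_start}],
    )
    return "".join(chars), truth


def _random_cds(n_codons: int, rng: np.random.Generator, background: BackgroundModel) -> list[str]:
    codons: list[str] = []
    while len(codons) < n_codons:
        codon = gen_background(3, background, rng)
        if codon not in STOPS:
            codons.append(codon)
    return codons


def evolve_codon_pair(
    cds_length_codons: int,
    omega: float,
    subs_per_codon: float,
    seed: int | None = None,
    background: BackgroundModel = UNIFORM,
) -> tuple[str, str, TruthRecord]:
    """Ancestor/descendant CDS pair diverged at a target dN/dS.

    Single-nucleotide changes are proposed at uniform random positions;
    proposals creating stop codons are rejected.  For omega <= 1 synonymous
    proposals are accepted with probability 1 and nonsynonymous with
    probability omega; for omega > 1 the asymmetry is inverted (synonymous
    acceptance 1/omega).  Substitution continues until
    round(subs_per_codon * length) changes have been accepted.

    At omega = 0 the divergence must be *purely* synonymous: a synonymous
    step is additionally rejected if the resulting codon, compared with the
    ancestral codon, would admit a minimal substitution pathway containing a
    nonsynonymous step (e.g. CTT -> CTA -> TTA, all leucine, leaves the
    path-ambiguous pair CTT/TTA).
    """
    if omega < 0:
        raise ValueError("omega must be non-negative")
    if cds_length_codons < 1:
        raise ValueError("need at least one codon")
    rng = _rng(seed)
    ancestor = _random_cds(cds_length_codons, rng, background)
    descendant = list(ancestor)
    target = int(round(subs_per_codon * cds_length_codons))
    accept_syn = 1.0 if omega <= 1.0 else 1.0 / omega
    accept_non = min(omega, 1.0)
    realized_syn = realized_non = 0
    accepted = 0
    max_proposals = 1000 * (target + 10)
    proposals = 0
    while accepted < target:
        proposals += 1
        if proposals > max_proposals:
            raise RuntimeError("substitution target unreachable (acceptance too low)")
        ci = int(rng.integers(cds_length_codons))
        pos = int(rng.integers(3))
        codon = descendant[ci]
        base = BASES[rng.integers(4)]
        if base == codon[pos]:
            continue
        candidate = codon[:pos] + base + codon[pos + 1 :]
        if candidate in STOPS:
            continue
        synonymous = _translate(candidate) == _translate(codon)
        p_accept = accept_syn if synonymous else accept_non
        if p_accept < 1.0 and rng.random() >= p_accept:
            continue
        if synonymous and omega == 0.0:
            _, nd = _pair_differences(ancestor[ci], candidate)
            if nd > 0:
                continue
        descendant[ci] = candidate
        accepted += 1
        if synonymous:
            realized_syn += 1
        else:
            realized_non += 1
    truth = TruthRecord(
        kind="codon_pair",
        seed=seed,
        params={
            "omega": omega,
            "subs_per_codon": subs_per_codon,
            "cds_length_codons": cds_length_codons,
        },
        features=[{"accepted_synonymous": realized_syn, "accepted_nonsynonymous": realized_non}],
    )
    return "".join(ancestor), "".join(descendant), truth
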