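"""Pairwise Ka/Ks by Nei–Gojobori (1986) counting with a sliding-window profile.

The NG86 estimator counts, per codon, fractional synonymous (S) and
nonsynonymous (N) *sites* — at each codon position the fraction of single-
nucleotide changes that preserve the encoded amino acid — and, per aligned
codon pair, fractional synonymous/nonsynonymous *differences* averaged over
all minimum-length substitution pathways.  Mutations or pathway steps through
stop codons are excluded, with renormalisation, so every codon still
contributes exactly three sites.  Proportions p = differences/sites receive
the Jukes–Cantor multiple-hit correction d = -3/4 ln(1 - 4p/3); omega = Ka/Ks.

The windowed profile recomputes Ka/Ks in 30-nt (10-codon) windows sliding
3 nt (one codon) at a time along the codon alignment, keyed by the 1-based
coordinate of each window's central nucleotide, with the display ratio
truncated at 6 (raw values are retained).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from math import log
from typing import Sequence

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from ._seq import normalize

__all__ = [
    "CodonAlignment",
    "PairwiseRates",
    "RateWindow",
    "codon_align",
    "ng86_sites",
    "ng86_pair",
    "sliding_kaks",
]

GAP_CODON = "---"
STOPS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA
_BASES = "ACGT"

MIN_COMPARABLE_CODONS = 5  # windows with fewer comparable codons are undefined


def _translate(codon: str) -> str:
    return standard_dna_table.forward_table.get(codon, "*")


@dataclass(frozen=True)
class CodonAlignment:
    """Aligned codon columns of two coding sequences; gaps are whole codons."""

    id_a: str
    id_b: str
    columns: tuple[tuple[str, str], ...]

    @property
    def aligned_nt(self) -> int:
        return 3 * len(self.columns)

    def comparable_columns(self) -> list[tuple[str, str]]:
        """Gap-free columns of unambiguous non-stop codons."""
        out = []
        for a, b in self.columns:
            if GAP_CODON in (a, b):
                continue
            if any(c not in _BASES for c in a + b):
                continue
            if a in STOPS or b in STOPS:
                continue
            out.append((a, b))
        return out


@dataclass(frozen=True)
class PairwiseRates:
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ka: float | None
    Ks: float | None
    ratio: float | None


@dataclass(frozen=True)
class RateWindow:
    center_nt: int  # 1-based coordinate of the window's central nucleotide
    Ka: float | None
    Ks: float | None
    ratio: float | None
    display_ratio: float | None
    comparable_codons: int


def _prepare_cds(seq: str, name: str) -> str:
    seq = normalize(seq)
    if len(seq) % 3 != 0:
        raise ValueError(f"{name}: CDS length {len(seq)} is not a multiple of 3")
    if len(seq) >= 3 and seq[-3:] in STOPS:
        seq = seq[:-3]
    if not seq:
        raise ValueError(f"{name}: empty CDS after trimming the terminal stop")
    for i in range(0, len(seq), 3):
        if seq[i : i + 3] in STOPS:
            raise ValueError(f"{name}: internal stop codon at codon index {i // 3}")
    return seq


def codon_align(
    cds_a: str,
    cds_b: str,
    id_a: str = "a",
    id_b: str = "b",
    open_gap: float = -10.0,
    extend_gap: float = -0.5,
) -> CodonAlignment:
    """Global protein-level alignment (BLOSUM62, affine gaps) back-threaded to
    codons; gaps only in whole-codon units.  Terminal stops are trimmed."""
    a = _prepare_cds(cds_a, id_a)
    b = _prepare_cds(cds_b, id_b)
    codons_a = [a[i : i + 3] for i in range(0, len(a), 3)]
    codons_b = [b[i : i + 3] for i in range(0, len(b), 3)]
    prot_a = str(Seq(a).translate())
    prot_b = str(Seq(b).translate())

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    aln = aligner.align(prot_a.replace("X", "A"), prot_b.replace("X", "A"))[0]
    sa, sb = aln[0], aln[1]

    columns: list[tuple[str, str]] = []
    ia = ib = 0
    for ca, cb in zip(sa, sb):
        col_a = GAP_CODON if ca == "-" else codons_a[ia]
        col_b = GAP_CODON if cb == "-" else codons_b[ib]
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
        columns.append((col_a, col_b))
    return CodonAlignment(id_a=id_a, id_b=id_b, columns=tuple(columns))


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) sites of one codon.

    Per position, the synonymous fraction is taken over the non-stop single-
    nucleotide neighbours (stop mutations excluded with renormalisation), so
    s + n = 3 exactly.
    """
    codon = normalize(codon)
    if len(codon) != 3 or any(c not in _BASES for c in codon):
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    if codon in STOPS:
        raise ValueError(f"stop codon has no sites: {codon}")
    aa = _translate(codon)
    s = 0.0
    for pos in range(3):
        syn = nonstop = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            neighbor = codon[:pos] + b + codon[pos + 1 :]
            if neighbor in STOPS:
                continue
            nonstop += 1
            if _translate(neighbor) == aa:
                syn += 1
        if nonstop:
            s += syn / nonstop
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _pair_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) differences between two codons,
    averaged over all minimum-length substitution pathways.

    Pathways passing through a stop codon are excluded; if every pathway is
    blocked (possible only for 2-3 differences between rare codon pairs), all
    pathways are used unfiltered.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        current = codon_a
        steps = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOPS:
                blocked = True
            steps.append((current, nxt))
            current = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked]
    if not usable:
        usable = [steps for _, steps in paths]
    sd = nd = 0.0
    for steps in usable:
        for before, after in steps:
            if _translate(before) == _translate(after):
                sd += 1.0
            else:
                nd += 1.0
    k = len(usable)
    return sd / k, nd / k


def _jc_correct(p: float) -> float | None:
    """Jukes–Cantor distance d = -3/4 ln(1 - 4p/3); None when saturated."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    x = 1.0 - 4.0 * p / 3.0
    if x <= 0.0:
        return None
    return -0.75 * log(x) + 0.0  # + 0.0 normalises -0.0 at p = 0


def ng86_pair(alignment: CodonAlignment | Sequence[tuple[str, str]]) -> PairwiseRates:
    """NG86 Ka, Ks and their ratio for a pairwise codon alignment.

    Sites are averaged over the two sequences; the estimate is symmetric under
    swapping them.  ``ratio`` is None when Ks = 0 or the correction saturates.
    """
    columns = (
        alignment.comparable_columns()
        if isinstance(alignment, CodonAlignment)
        else list(alignment)
    )
    if not columns:
        raise ValueError("no comparable codon columns")
    S = N = Sd = Nd = 0.0
    for a, b in columns:
        sa, na = ng86_sites(a)
        sb, nb = ng86_sites(b)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _pair_differences(a, b)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    Ks = _jc_correct(ps)
    Ka = _jc_correct(pn)
    ratio = Ka / Ks if (Ka is not None and Ks is not None and Ks > 0) else None
    return PairwiseRates(S_sites=S, N_sites=N, Sd=Sd, Nd=Nd, ps=ps, pn=pn, Ka=Ka, Ks=Ks, ratio=ratio)


def _display_ratio(ka: float | None, ks: float | None, ratio: float | None, cap: float) -> float | None:
    if ratio is not None:
        return min(ratio, cap)
    if ka is None or ks is None:
        return None
    if ks == 0.0 and ka > 0.0:
        return cap
    if ka == 0.0 and ks == 0.0:
        return 0.0
    return None


def sliding_kaks(
    alignment: CodonAlignment,
    window_nt: int = 30,
    step_nt: int = 3,
    display_cap: float = 6.0,
) -> list[RateWindow]:
    """Ka/Ks recomputed in sliding windows along the codon alignment.

    Windows are ``window_nt`` aligned nucleotides wide and advance ``step_nt``
    at a time; each is keyed by its central nucleotide (1-based; position
    window_start + 15 for the default 30-nt window).  Gap columns and
    ambiguous codons are skipped inside each window; windows with fewer than
    5 comparable codons are reported undefined.
    """
    if window_nt % 3 or step_nt % 3:
        raise ValueError("window and step must be multiples of 3")
    total = alignment.aligned_nt
    if window_nt > total:
        raise ValueError(f"window of {window_nt} nt exceeds alignment of {total} nt")
    win_codons = window_nt // 3
    step_codons = step_nt // 3
    half = window_nt // 2
    out: list[RateWindow] = []
    n_windows = (total - window_nt) // step_nt + 1
    for i in range(n_windows):
        cols = alignment.columns[i * step_codons : i * step_codons + win_codons]
        comparable = [
            (a, b)
            for a, b in cols
            if GAP_CODON not in (a, b)
            and all(c in _BASES for c in a + b)
            and a not in STOPS
            and b not in STOPS
        ]
        center = i * step_nt + half + 1  # 1-based central nucleotide
        if len(comparable) < MIN_COMPARABLE_CODONS:
            out.append(RateWindow(center, None, None, None, None, len(comparable)))
            continue
        r = ng86_pair(comparable)
        out.append(
            RateWindow(
                center_nt=center,
                Ka=r.Ka,
                Ks=r.Ks,
                ratio=r.ratio,
                display_ratio=_display_ratio(r.Ka, r.Ks, r.ratio, display_cap),
                comparable_codons=len(comparable),
            )
        )
    return out
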