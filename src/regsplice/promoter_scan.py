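"""TATA-less Inr + DPE core-promoter detection.

Focal core promoters in culicine mosquitoes pair an initiator (Inr) element —
consensus YYANWY (or YYANWYY), whose adenine at motif position 3 marks the
transcription start site (+1) — with a downstream promoter element (DPE,
consensus RGWYV or its fifth-position-T specialisation RGWYT) whose first base
sits at canonical position +28 relative to the Inr adenine.  A TATA box
(TATAWAW by default) is searched upstream only to report its absence, the
hallmark of the Inr/DPE promoter class.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import normalize
from .motif_engine import DegeneratePattern, scan_sequence

__all__ = ["PromoterCall", "find_inr", "find_promoter", "INR_TSS_OFFSET"]

INR_TSS_OFFSET = 2  # the Inr adenine is motif position 3 (0-based offset 2)

DEFAULT_TATA = "TATAWAW"


@dataclass(frozen=True)
class PromoterCall:
    seq_id: str
    inr_start: int  # 0-based
    tss: int  # 0-based index of the Inr adenine (reported as +1)
    inr_variant: str
    dpe_start: int  # 0-based
    dpe_variant: str
    dpe_position: int  # 1-based position of dpe_start relative to tss = +1
    tata_found: bool


def find_inr(seq: str, variant: str = "YYANWY", seq_id: str = "seq") -> list[tuple[int, int]]:
    """All (inr_start, tss) candidate positions for an initiator variant."""
    variant = normalize(variant)
    if variant[INR_TSS_OFFSET] != "A":
        raise ValueError(f"Inr variant {variant!r} must have A at position 3")
    return [
        (h.start, h.start + INR_TSS_OFFSET)
        for h in scan_sequence(seq, DegeneratePattern.from_iupac(variant, "Inr"), seq_id=seq_id)
    ]


def find_promoter(
    seq: str,
    inr_variant: str = "YYANWY",
    dpe_variant: str = "RGWYV",
    dpe_position: int = 28,
    slack: int = 0,
    tata_window: tuple[int, int] = (-40, -15),
    tata_consensus: str = DEFAULT_TATA,
    seq_id: str = "seq",
) -> list[PromoterCall]:
    """Inr candidates retained only when the DPE starts at +``dpe_position``
    (± ``slack``) downstream of the Inr adenine (+1).

    ``tata_found`` reports whether the TATA consensus starts anywhere within
    ``tata_window`` (positions relative to the TSS at +1, e.g. (-40, -15)).
    """
    if tata_window[0] > tata_window[1]:
        raise ValueError(f"malformed TATA window {tata_window}")
    if dpe_position < 2:
        raise ValueError("dpe_position must be downstream of the TSS")
    seq = normalize(seq)
    dpe_pat = DegeneratePattern.from_iupac(dpe_variant, "DPE")
    dpe_starts = {h.start for h in scan_sequence(seq, dpe_pat, seq_id=seq_id)}
    tata_starts = (
        {h.start for h in scan_sequence(seq, DegeneratePattern.from_iupac(tata_consensus, "TATA"), seq_id=seq_id)}
        if len(seq) >= len(tata_consensus)
        else set()
    )
    calls: list[PromoterCall] = []
    for inr_start, tss in find_inr(seq, inr_variant, seq_id=seq_id):
        for offset in range(-slack, slack + 1):
            dpe_start = tss + (dpe_position - 1) + offset
            if dpe_start in dpe_starts:
                # position p (1-based, TSS=+1) has 0-based index tss + p - 1
                lo = tss + tata_window[0] - 1
                hi = tss + tata_window[1] - 1
                tata_found = any(lo <= t <= hi for t in tata_starts)
                calls.append(
                    PromoterCall(
                        seq_id=seq_id,
                        inr_start=inr_start,
                        tss=tss,
                        inr_variant=normalize(inr_variant),
                        dpe_start=dpe_start,
                        dpe_variant=normalize(dpe_variant),
                        dpe_position=dpe_start - tss + 1,
                        tata_found=tata_found,
                    )
                )
                break
    return calls
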