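"""Shared readers/writers, coordinate conventions and small report helpers.

Internal coordinates are 0-based half-open everywhere; GFF3 (1-based closed)
and BED (0-based half-open) conventions are honoured at the boundaries and
human-readable reports are 1-based.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from ._seq import normalize
from .motif_engine import MotifHit, ScreenRow

logger = logging.getLogger(__name__)

__all__ = [
    "JunctionCount",
    "read_fasta",
    "write_fasta",
    "write_gff3",
    "splice_usage",
    "hits_to_bed",
    "screen_to_table",
    "round_half_up",
    "write_manifest",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-FASTA -> {id: uppercase sequence}.  CRLF-safe; empty file warns."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text_head = path.read_text(errors="replace").lstrip()
    if text_head and not text_head.startswith(">"):
        bad_line = next(
            i for i, line in enumerate(path.read_text(errors="replace").splitlines(), 1) if line.strip()
        )
        raise ValueError(f"{path}: malformed FASTA, no '>' header at line {bad_line}")
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        records[rec.id] = normalize(str(rec.seq))
    if not records:
        logger.warning("%s: no FASTA records found", path)
    return records


def write_fasta(records: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in records.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(models, path: str | Path, source: str = "regsplice") -> None:
    """Write gene models (0-based half-open internally) as GFF3 exon features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for model in models:
            g_start = min(s for s, _ in model.exons) + 1
            g_end = max(e for _, e in model.exons)
            fh.write(
                f"{model.seq_id}\t{source}\tmRNA\t{g_start}\t{g_end}\t.\t{model.strand}\t.\t"
                f"ID={model.gene_id}\n"
            )
            for i, (s, e) in enumerate(model.exons, 1):
                fh.write(
                    f"{model.seq_id}\t{source}\texon\t{s + 1}\t{e}\t.\t{model.strand}\t.\t"
                    f"ID={model.gene_id}.exon{i};Parent={model.gene_id}\n"
                )


@dataclass(frozen=True)
class JunctionCount:
    library_id: str
    junction: str
    donor_class: str  # e.g. "canonical" or "extension"
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("read counts must be non-negative")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (report convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def splice_usage(table: Iterable[JunctionCount]) -> pd.DataFrame:
    """Per-junction percentage of reads in each donor class, to 1 decimal.

    E.g. 47 extension + 119 canonical reads over one junction -> 28.3 / 71.7.
    """
    rows = list(table)
    if not rows:
        raise ValueError("empty junction-count table")
    df = pd.DataFrame([r.__dict__ for r in rows])
    totals = df.groupby(["library_id", "junction"])["count"].transform("sum")
    if (totals == 0).any():
        bad = df.loc[totals == 0, ["library_id", "junction"]].iloc[0]
        raise ValueError(f"zero total reads for junction {bad.junction!r} in {bad.library_id!r}")
    df["percent"] = [
        round_half_up(100.0 * c / t) for c, t in zip(df["count"], totals)
    ]
    return df


def hits_to_bed(hits: Sequence[MotifHit], path: str | Path, score: int = 0) -> None:
    """BED6 (0-based half-open) of motif hits."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.seq_id}\t{h.start}\t{h.end}\t{h.pattern_id}\t{score}\t{h.strand}\n")


def screen_to_table(rows: Sequence[ScreenRow]) -> pd.DataFrame:
    """Screen summary with 1-based window starts for human-readable output."""
    return pd.DataFrame(
        {
            "seq_id": [r.seq_id for r in rows],
            "total_hits": [r.total_hits for r in rows],
            "best_window_start": [r.best_window.window_start + 1 for r in rows],
            "best_window_count": [r.best_window.count for r in rows],
            "retained": [r.retained for r in rows],
        }
    )


def write_manifest(outdir: str | Path, params: dict) -> Path:
    """Machine-readable parameter manifest written alongside every output."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
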