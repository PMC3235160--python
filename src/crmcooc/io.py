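"""Readers and writers for the pipeline's on-disk formats.

FASTA and MAF go through Biopython; BED, bedGraph and fixed-step WIG are
simple line formats handled directly.  Coordinates are 0-based half-open
throughout, matching BED.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .conservation import ConservationTrack, PairwiseAlignment
from .cooccurrence import CandidateRegion
from .motif_scan import MotifHit

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_hits_bed",
    "read_hits_bed",
    "write_regions",
    "read_regions_bed",
    "read_track",
    "read_pairwise_maf",
]

logger = logging.getLogger(__name__)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA -> {id: uppercase sequence}."""
    from Bio import SeqIO

    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA record id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(records: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# BED


def write_hits_bed(hits: Iterable[MotifHit], path: str | Path) -> None:
    """Hits as BED6: name = motif, score = match score x100 rounded."""
    with open(path, "w") as fh:
        for h in sorted(hits, key=lambda h: (h.seq_id, h.start, h.end)):
            score = int(round(h.score * 100))
            fh.write(
                f"{h.seq_id}\t{h.start}\t{h.end}\t{h.motif_name}\t{score}\t{h.strand}\n"
            )


def read_hits_bed(path: str | Path, sequences: dict[str, str] | None = None) -> list[MotifHit]:
    """BED6 -> MotifHit list; site_seq filled from ``sequences`` if given."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected BED6")
            seq_id, start, end, name, score, strand = parts[:6]
            start, end = int(start), int(end)
            site = ""
            if sequences and seq_id in sequences:
                site = sequences[seq_id][start:end]
            hits.append(
                MotifHit(
                    seq_id=seq_id,
                    start=start,
                    end=end,
                    motif_name=name,
                    strand=strand,
                    score=float(score) / 100.0,
                    site_seq=site,
                )
            )
    return sorted(hits, key=lambda h: (h.seq_id, h.start, h.end))


def write_regions(
    regions: Sequence[CandidateRegion], bed_path: str | Path, tsv_path: str | Path | None = None
) -> None:
    """Regions as BED4 plus a TSV sidecar of per-motif counts and flags."""
    with open(bed_path, "w") as fh:
        for r in regions:
            fh.write(f"{r.seq_id}\t{r.start}\t{r.end}\t{r.name}\n")
    if tsv_path is not None:
        motif_names = sorted({m for r in regions for m in r.counts})
        rows = []
        for r in regions:
            row = {"region_id": r.name, "seq_id": r.seq_id, "start": r.start, "end": r.end}
            for m in motif_names:
                row[f"n_{m}"] = r.counts.get(m, 0)
            row["selected"] = int(r.selected)
            rows.append(row)
        pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def read_regions_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """BED -> list of (seq_id, start, end, name)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least BED3")
            name = parts[3] if len(parts) > 3 else f"{parts[0]}:{parts[1]}-{parts[2]}"
            out.append((parts[0], int(parts[1]), int(parts[2]), name))
    return out


# ---------------------------------------------------------------------------
# conservation tracks


def read_track(path: str | Path) -> dict[str, ConservationTrack]:
    """Read a bedGraph or fixed-step WIG file into per-sequence tracks.

    Uncovered positions inside a track's span are NaN (treated as not
    covered); out-of-range scores are clamped to [0, 1] with a warning.
    """
    path = Path(path)
    values: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        mode = "bedgraph"
        chrom = None
        pos = step = span = 1
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                mode = "fixedstep"
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                pos = int(fields["start"]) - 1  # WIG is 1-based
                step = int(fields.get("step", 1))
                span = int(fields.get("span", 1))
                continue
            if line.startswith("variableStep"):
                raise ValueError(f"{path}:{lineno}: variableStep WIG is not supported")
            if mode == "fixedstep":
                values.setdefault(chrom, []).append((pos, pos + span, float(line)))
                pos += step
            else:
                parts = line.split()
                if len(parts) != 4:
                    raise ValueError(f"{path}:{lineno}: expected 'chrom start end value'")
                values.setdefault(parts[0], []).append(
                    (int(parts[1]), int(parts[2]), float(parts[3]))
                )
    tracks = {}
    clamped = False
    for chrom, entries in values.items():
        entries.sort()
        lo = entries[0][0]
        hi = max(e[1] for e in entries)
        scores = np.full(hi - lo, np.nan)
        for s, e, v in entries:
            if v < 0 or v > 1:
                clamped = True
                v = min(max(v, 0.0), 1.0)
            scores[s - lo:e - lo] = v
        tracks[chrom] = ConservationTrack(seq_id=chrom, start=lo, scores=scores)
    if clamped:
        logger.warning("%s: scores outside [0, 1] were clamped", path)
    return tracks


# ---------------------------------------------------------------------------
# MAF


def read_pairwise_maf(path: str | Path) -> list[PairwiseAlignment]:
    """Read strictly pairwise MAF blocks; multi-species blocks are an error.

    The first row of each block is the reference.  Reference rows must be
    on the plus strand.
    """
    from Bio import AlignIO

    alignments = []
    for block in AlignIO.parse(str(path), "maf"):
        if len(block) != 2:
            raise ValueError(
                f"{path}: MAF block with {len(block)} rows; only pairwise "
                "(two-species) MAF is supported"
            )
        ref, alt = block[0], block[1]
        if ref.annotations.get("strand", 1) != 1:
            raise ValueError(f"{path}: reference MAF row must be on the + strand")
        alignments.append(
            PairwiseAlignment(
                ref_id=ref.id,
                alt_id=alt.id,
                ref_row=str(ref.seq).upper(),
                alt_row=str(alt.seq).upper(),
                ref_start=int(ref.annotations["start"]),
                alt_start=int(alt.annotations["start"]),
            )
        )
    return alignments
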