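"""Region- and site-level evolutionary conservation metrics.

For every candidate region the pipeline reports up to seven values, each a
fraction in [0, 1] or MISSING:

* ``avid_fraction`` — proportion of the region's reference bases whose
  alignment column is an identical match (gaps and substitutions both
  count as non-conserved; unaligned bases count in the denominator).
* ``block_score`` — the region is extended by a flank (default 700 bp),
  conserved ungapped blocks are extracted from the extended alignment,
  the evaluation span is trimmed to the first and last blocks that contain
  a binding site, and the proportion of aligned reference bases inside
  conserved blocks within that span is reported.
* ``track_mean`` — mean per-base conservation-track score over the region.
* ``peak_score[w]`` — maximum mean track score over every w-bp window
  fully inside the region (the first window starts at the region's first
  base and the last ends at its final base); MISSING when the region is
  shorter than w.
* ``tfbs_presence`` — fraction of factor classes retaining at least one
  conserved site (gap-free and still matching the motif in the ortholog).
* ``tfbs_mismatch`` — pooled per-base mismatch fraction over all site
  bases within the aligned span.

A "conserved ungapped block" is a maximal gap-free column run, trimmed to
identical-match boundaries, kept when it is at least ``block_min_len``
columns long with identity at least ``block_min_identity``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .missing import MISSING, is_missing
from .motif_scan import MotifHit, MotifModel, reverse_complement, score_site

__all__ = [
    "PairwiseAlignment",
    "ConservedBlock",
    "ConservationTrack",
    "ConservationConfig",
    "RegionConservationReport",
    "pairwise_align",
    "conserved_fraction",
    "extract_conserved_blocks",
    "block_conservation_score",
    "mean_track_score",
    "peak_window_score",
    "classify_by_peak",
    "site_conserved",
    "tfbs_presence",
    "tfbs_mismatch_rate",
    "build_report",
]

logger = logging.getLogger(__name__)

_GAP = "-"


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped two-row alignment anchored on ungapped coordinates."""

    ref_id: str
    alt_id: str
    ref_row: str
    alt_row: str
    ref_start: int = 0
    alt_start: int = 0

    def __post_init__(self):
        if len(self.ref_row) != len(self.alt_row):
            raise ValueError("alignment rows must have equal length")
        for r, a in zip(self.ref_row, self.alt_row):
            if r == _GAP and a == _GAP:
                raise ValueError("gap/gap column in alignment")

    @property
    def n_columns(self) -> int:
        return len(self.ref_row)

    @property
    def ref_end(self) -> int:
        """End (exclusive) of the aligned span on the ungapped reference."""
        return self.ref_start + sum(1 for c in self.ref_row if c != _GAP)

    def ref_positions(self) -> np.ndarray:
        """Per-column reference coordinate; gap columns get the coordinate
        of the next reference base (never matched by position lookups)."""
        is_base = np.frombuffer(self.ref_row.encode(), dtype=np.uint8) != ord(_GAP)
        return self.ref_start + np.cumsum(is_base) - is_base.astype(int)

    def column_of(self, ref_pos: int) -> int | None:
        """Alignment column holding reference base ``ref_pos``, or None."""
        if not (self.ref_start <= ref_pos < self.ref_end):
            return None
        pos = self.ref_positions()
        is_base = np.frombuffer(self.ref_row.encode(), dtype=np.uint8) != ord(_GAP)
        cols = np.nonzero(is_base & (pos == ref_pos))[0]
        return int(cols[0]) if len(cols) else None

    def identity_columns(self) -> np.ndarray:
        """Bool per column: identical A/C/G/T match (gaps, N never identical)."""
        r = np.frombuffer(self.ref_row.upper().encode(), dtype=np.uint8)
        a = np.frombuffer(self.alt_row.upper().encode(), dtype=np.uint8)
        good = np.isin(r, np.frombuffer(b"ACGT", dtype=np.uint8))
        return (r == a) & good


@dataclass(frozen=True)
class ConservedBlock:
    """A gap-free alignment-column run meeting length/identity thresholds."""

    col_start: int
    col_end: int
    identity: float

    @property
    def n_columns(self) -> int:
        return self.col_end - self.col_start


@dataclass(frozen=True)
class ConservationTrack:
    """Per-base conservation scores (e.g. phastCons) on one sequence."""

    seq_id: str
    start: int
    scores: np.ndarray

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 1 or len(scores) < 1:
            raise ValueError("track must hold at least one score")
        finite = scores[np.isfinite(scores)]
        if len(finite) and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("track scores must lie in [0, 1]")
        object.__setattr__(self, "scores", scores)

    @property
    def end(self) -> int:
        return self.start + len(self.scores)

    def covers(self, start: int, end: int) -> bool:
        if not (self.start <= start and end <= self.end):
            return False
        return bool(np.isfinite(self.scores[start - self.start:end - self.start]).all())

    def slice(self, start: int, end: int) -> np.ndarray:
        if not self.covers(start, end):
            raise ValueError(
                f"track on {self.seq_id} [{self.start},{self.end}) does not cover "
                f"[{start},{end})"
            )
        return self.scores[start - self.start:end - self.start]


@dataclass(frozen=True)
class ConservationConfig:
    """Knobs of the conservation layer (units: bp or fractions)."""

    extension_bp: int = 700
    peak_windows: tuple[int, ...] = (100, 200, 500)
    peak_cutoff: float = 0.13
    block_min_len: int = 6
    block_min_identity: float = 0.7

    def __post_init__(self):
        if self.extension_bp < 0:
            raise ValueError("extension_bp must be >= 0")
        if any(w < 1 for w in self.peak_windows):
            raise ValueError("peak windows must be >= 1")
        if not 0 <= self.peak_cutoff <= 1:
            raise ValueError("peak_cutoff must lie in [0, 1]")


@dataclass
class RegionConservationReport:
    """All conservation metrics for one region; MISSING where undefined."""

    region_id: str
    avid_fraction: object = MISSING
    block_score: object = MISSING
    track_mean: object = MISSING
    peak_score: dict[int, object] = field(default_factory=dict)
    tfbs_presence: object = MISSING
    tfbs_mismatch: object = MISSING


# ---------------------------------------------------------------------------
# alignment construction


def pairwise_align(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
    ref_id: str = "ref",
    alt_id: str = "alt",
) -> PairwiseAlignment:
    """Optimal global alignment with affine gap costs.

    A desk-scale aligner for simulated orthologs; genome-scale alignments
    (MAF) are consumed as input instead.  Ties between equally optimal
    paths are broken deterministically (first path reported by the
    underlying dynamic program).
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(a.upper(), b.upper())[0]
    return PairwiseAlignment(
        ref_id=ref_id, alt_id=alt_id, ref_row=str(aln[0]), alt_row=str(aln[1])
    )


# ---------------------------------------------------------------------------
# region-level metrics


def conserved_fraction(aln: PairwiseAlignment, region: tuple[int, int]) -> float:
    """Fraction of region reference bases in identical alignment columns.

    Bases outside the aligned span count as non-conserved; the denominator
    is always the full region length.
    """
    start, end = region
    if end <= start:
        raise ValueError("zero-length region")
    ident = aln.identity_columns()
    pos = aln.ref_positions()
    is_base = np.frombuffer(aln.ref_row.encode(), dtype=np.uint8) != ord(_GAP)
    in_region = is_base & (pos >= start) & (pos < end)
    return float((ident & in_region).sum()) / (end - start)


def extract_conserved_blocks(
    aln: PairwiseAlignment, cfg: ConservationConfig | None = None
) -> list[ConservedBlock]:
    """Maximal gap-free column runs, trimmed to identical-match boundaries
    and filtered by minimum length and identity."""
    cfg = cfg or ConservationConfig()
    r = np.frombuffer(aln.ref_row.encode(), dtype=np.uint8)
    a = np.frombuffer(aln.alt_row.encode(), dtype=np.uint8)
    gapfree = (r != ord(_GAP)) & (a != ord(_GAP))
    ident = aln.identity_columns()
    blocks: list[ConservedBlock] = []
    n = aln.n_columns
    i = 0
    while i < n:
        if not gapfree[i]:
            i += 1
            continue
        j = i
        while j < n and gapfree[j]:
            j += 1
        s, e = i, j
        while s < e and not ident[s]:
            s += 1
        while e > s and not ident[e - 1]:
            e -= 1
        if e - s >= cfg.block_min_len:
            identity = float(ident[s:e].mean())
            if identity >= cfg.block_min_identity:
                blocks.append(ConservedBlock(col_start=s, col_end=e, identity=identity))
        i = j
    return blocks


def block_conservation_score(
    crm: tuple[int, int],
    crm_hits: Iterable[MotifHit],
    aln_window: PairwiseAlignment,
    cfg: ConservationConfig | None = None,
):
    """Fraction of aligned reference bases inside conserved blocks, within
    the span delimited by the first and last site-containing blocks.

    ``aln_window`` covers the region extended by ``extension_bp`` on each
    side.  Returns MISSING when no conserved block overlaps any site.
    """
    cfg = cfg or ConservationConfig()
    crm_hits = list(crm_hits)
    if not crm_hits:
        raise ValueError("block_conservation_score requires at least one hit")
    blocks = extract_conserved_blocks(aln_window, cfg)
    if not blocks:
        return MISSING
    pos = aln_window.ref_positions()
    is_base = np.frombuffer(aln_window.ref_row.encode(), dtype=np.uint8) != ord(_GAP)

    def block_ref_interval(b: ConservedBlock) -> tuple[int, int]:
        cols = slice(b.col_start, b.col_end)
        return int(pos[cols].min()), int(pos[cols].max()) + 1

    anchored = []
    for b in blocks:
        bs, be = block_ref_interval(b)
        if any(h.start < be and bs < h.end for h in crm_hits):
            anchored.append(b)
    if not anchored:
        return MISSING
    span = slice(anchored[0].col_start, anchored[-1].col_end)
    in_block = np.zeros(aln_window.n_columns, dtype=bool)
    for b in blocks:
        in_block[b.col_start:b.col_end] = True
    aligned = is_base[span]
    denom = int(aligned.sum())
    if denom == 0:
        return MISSING
    num = int((aligned & in_block[span]).sum())
    return num / denom


def mean_track_score(track: ConservationTrack, region: tuple[int, int]) -> float:
    """Arithmetic mean of per-base track scores over the region."""
    start, end = region
    if end <= start:
        raise ValueError("zero-length region")
    return float(track.slice(start, end).mean())


def peak_window_score(track: ConservationTrack, region: tuple[int, int], w: int):
    """Maximum w-bp window mean within the region; the first window starts
    at the region's first base and the last ends at its final base.
    Returns MISSING when the region is shorter than w."""
    if w < 1:
        raise ValueError("window size must be >= 1")
    start, end = region
    scores = track.slice(start, end)
    if end - start < w:
        return MISSING
    csum = np.concatenate([[0.0], np.cumsum(scores)])
    means = (csum[w:] - csum[:-w]) / w
    return float(means.max())


def classify_by_peak(score, cutoff: float) -> bool:
    """True iff score >= cutoff; MISSING classifies negative with a warning."""
    if is_missing(score):
        logger.warning("classify_by_peak: MISSING score classified as below cutoff")
        return False
    return score >= cutoff


# ---------------------------------------------------------------------------
# site-level metrics


def _hit_columns(hit: MotifHit, aln: PairwiseAlignment) -> np.ndarray | None:
    """Alignment columns of the hit's reference bases, or None when the
    hit is not fully inside the aligned span."""
    if hit.start < aln.ref_start or hit.end > aln.ref_end:
        return None
    pos = aln.ref_positions()
    is_base = np.frombuffer(aln.ref_row.encode(), dtype=np.uint8) != ord(_GAP)
    cols = np.nonzero(is_base & (pos >= hit.start) & (pos < hit.end))[0]
    if len(cols) != hit.end - hit.start:
        return None
    return cols


def site_conserved(hit: MotifHit, aln: PairwiseAlignment, motif: MotifModel) -> bool:
    """A site counts as conserved when its columns are gap-free and the
    orthologous subsequence still meets the motif threshold (on either
    orientation).  Column identity is not required: substitutions that
    keep a degenerate position satisfied still count."""
    cols = _hit_columns(hit, aln)
    if cols is None:
        return False
    colspan = slice(int(cols[0]), int(cols[-1]) + 1)
    if len(cols) != cols[-1] - cols[0] + 1:
        return False  # ref gap inside the site footprint
    alt = aln.alt_row[colspan]
    if _GAP in alt or _GAP in aln.ref_row[colspan]:
        return False
    for kmer in (alt, reverse_complement(alt)):
        if score_site(motif, kmer) >= motif.threshold:
            return True
    return False


def tfbs_presence(
    region_hits: Mapping[str, Sequence[MotifHit]],
    aln: PairwiseAlignment,
    motifs: Mapping[str, MotifModel],
) -> float:
    """Fraction of the motif universe retaining >= 1 conserved site."""
    if not motifs:
        raise ValueError("empty motif universe")
    conserved = 0
    for name, motif in motifs.items():
        hits = region_hits.get(name, ())
        if any(site_conserved(h, aln, motif) for h in hits):
            conserved += 1
    return conserved / len(motifs)


def tfbs_mismatch_rate(
    region_hits: Mapping[str, Sequence[MotifHit]], aln: PairwiseAlignment
):
    """Pooled per-base mismatch fraction over all site bases within the
    aligned span (gap columns count as mismatches).  MISSING when no site
    overlaps the aligned span."""
    ident = aln.identity_columns()
    pos = aln.ref_positions()
    is_base = np.frombuffer(aln.ref_row.encode(), dtype=np.uint8) != ord(_GAP)
    total = 0
    mismatched = 0
    for hits in region_hits.values():
        for h in hits:
            sel = is_base & (pos >= h.start) & (pos < h.end)
            n = int(sel.sum())
            total += n
            mismatched += n - int((sel & ident).sum())
    if total == 0:
        return MISSING
    return mismatched / total


# ---------------------------------------------------------------------------
# report assembly


def build_report(
    region_id: str,
    region: tuple[int, int],
    region_hits: Mapping[str, Sequence[MotifHit]] | None,
    motifs: Mapping[str, MotifModel] | None,
    aln: PairwiseAlignment | None,
    aln_window: PairwiseAlignment | None,
    track: ConservationTrack | None,
    cfg: ConservationConfig | None = None,
) -> RegionConservationReport:
    """Populate every metric slot for one region, or MISSING with a logged
    cause: no alignment leaves the alignment metrics undefined ("nd"), no
    track leaves the track metrics undefined, a region shorter than a peak
    window leaves that window's cell undefined ("(<500 bp)" semantics)."""
    cfg = cfg or ConservationConfig()
    report = RegionConservationReport(region_id=region_id)

    def attempt(label, fn):
        try:
            return fn()
        except Exception as exc:  # component failure -> MISSING, not fatal
            logger.warning("%s: %s undefined (%s)", region_id, label, exc)
            return MISSING

    if aln is not None:
        report.avid_fraction = attempt(
            "avid_fraction", lambda: conserved_fraction(aln, region)
        )
    if aln is not None and region_hits is not None:
        all_hits = [h for hs in region_hits.values() for h in hs]
        window_aln = aln_window if aln_window is not None else aln
        if all_hits:
            report.block_score = attempt(
                "block_score",
                lambda: block_conservation_score(region, all_hits, window_aln, cfg),
            )
        report.tfbs_mismatch = attempt(
            "tfbs_mismatch", lambda: tfbs_mismatch_rate(region_hits, aln)
        )
        if motifs is not None:
            report.tfbs_presence = attempt(
                "tfbs_presence", lambda: tfbs_presence(region_hits, aln, motifs)
            )
    if track is not None:
        report.track_mean = attempt("track_mean", lambda: mean_track_score(track, region))
        for w in cfg.peak_windows:
            report.peak_score[w] = attempt(
                f"peak_score[{w}]", lambda w=w: peak_window_score(track, region, w)
            )
    else:
        for w in cfg.peak_windows:
            report.peak_score[w] = MISSING
    return report
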