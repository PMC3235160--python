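"""Candidate CRM discovery by binding-site co-occurrence.

A fixed-width window (default 500 bp) "qualifies" when it fully contains at
least one hit for every required factor.  Overlapping qualifying windows on
the same sequence are merged and the merged span trimmed to the footprint
of the contained hits, giving disjoint, deterministic candidate regions.
A second-stage filter ("selected subset") keeps regions with a minimum
instance count per factor — by default at least two sites per factor,
except one for dTcf.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .motif_scan import MotifHit

__all__ = ["DEFAULT_FACTORS", "SearchConfig", "CandidateRegion", "cluster_hits", "select_subset"]

DEFAULT_FACTORS = ("dTcf", "Mad", "Pnt", "Tin", "Twi")


def _default_min_instances() -> dict[str, int]:
    return {m: (1 if m == "dTcf" else 2) for m in DEFAULT_FACTORS}


@dataclass(frozen=True)
class SearchConfig:
    """Parameters of the co-occurrence search."""

    window_bp: int = 500
    required_motifs: tuple[str, ...] = DEFAULT_FACTORS
    min_instances: Mapping[str, int] = field(default_factory=_default_min_instances)

    def __post_init__(self):
        if self.window_bp < 1:
            raise ValueError("window_bp must be >= 1")
        object.__setattr__(self, "required_motifs", tuple(self.required_motifs))
        mi = dict(self.min_instances)
        for m in self.required_motifs:
            mi.setdefault(m, 1)
            if mi[m] < 1:
                raise ValueError(f"min_instances[{m!r}] must be >= 1")
        object.__setattr__(self, "min_instances", mi)


@dataclass
class CandidateRegion:
    """A maximal merged co-occurrence window with its contained hits."""

    seq_id: str
    start: int
    end: int
    hits: dict[str, list[MotifHit]]
    counts: dict[str, int]
    selected: bool = False

    @property
    def name(self) -> str:
        return f"{self.seq_id}:{self.start}-{self.end}"


def _union(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of closed integer intervals (window start positions)."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for a, b in intervals[1:]:
        if a <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [tuple(x) for x in out]


def _intersect(xs: list[tuple[int, int]], ys: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    while i < len(xs) and j < len(ys):
        a = max(xs[i][0], ys[j][0])
        b = min(xs[i][1], ys[j][1])
        if a <= b:
            out.append((a, b))
        if xs[i][1] < ys[j][1]:
            i += 1
        else:
            j += 1
    return out


def cluster_hits(hits: Iterable[MotifHit], config: SearchConfig) -> list[CandidateRegion]:
    """Merge qualifying co-occurrence windows into maximal candidate regions.

    A window [x, x+W) qualifies iff every required motif has at least one
    hit lying entirely inside it; a hit [s, e) is inside the window iff
    x <= s and e <= x+W, i.e. x in the closed interval [e-W, s].  The set
    of qualifying x is therefore the intersection, over motifs, of the
    union of those per-hit intervals.  Windows sharing at least one base
    merge; the merged span is trimmed to the first/last contained hit.
    """
    hits = sorted(hits)
    required = set(config.required_motifs)
    for h in hits:
        if h.motif_name not in required:
            raise ValueError(
                f"hit motif {h.motif_name!r} not in required_motifs {sorted(required)}"
            )
    regions: list[CandidateRegion] = []
    by_seq: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_seq.setdefault(h.seq_id, []).append(h)
    W = config.window_bp
    for seq_id in sorted(by_seq):
        seq_hits = by_seq[seq_id]
        per_motif: dict[str, list[tuple[int, int]]] = {m: [] for m in required}
        for h in seq_hits:
            if h.end - h.start > W:
                continue  # hit wider than the window can never be inside it
            per_motif[h.motif_name].append((max(0, h.end - W), h.start))
        qualifying: list[tuple[int, int]] | None = None
        for m in required:
            u = _union(per_motif[m])
            qualifying = u if qualifying is None else _intersect(qualifying, u)
            if not qualifying:
                break
        if not qualifying:
            continue
        # coverage of qualifying windows: x in [a, b] covers [a, b + W)
        coverage = _union([(a, b + W - 1) for a, b in qualifying])
        for a, b in coverage:
            span = (a, b + 1)  # half-open bp interval
            contained = [h for h in seq_hits if h.start >= span[0] and h.end <= span[1]]
            start = min(h.start for h in contained)
            end = max(h.end for h in contained)
            region_hits: dict[str, list[MotifHit]] = {m: [] for m in config.required_motifs}
            for h in contained:
                region_hits[h.motif_name].append(h)
            counts = {m: len(v) for m, v in region_hits.items()}
            regions.append(
                CandidateRegion(
                    seq_id=seq_id, start=start, end=end, hits=region_hits, counts=counts
                )
            )
    return regions


def select_subset(
    regions: Sequence[CandidateRegion], config: SearchConfig
) -> list[CandidateRegion]:
    """Apply the minimum-instance-count filter; returns selected regions.

    Marks ``region.selected`` on every input region and returns, in input
    order, only those meeting ``min_instances`` for every required motif.
    """
    out = []
    for r in regions:
        ok = all(
            r.counts.get(m, 0) >= config.min_instances[m] for m in config.required_motifs
        )
        r.selected = ok
        if ok:
            out.append(r)
    return out
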