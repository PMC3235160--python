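"""In-silico binding-site knockout design with collateral-damage reporting.

Site-directed mutagenesis of a predicted binding site is only informative
if (a) the substitutions really abolish every match of the targeted motif
over the site's footprint and (b) they do not silently create or destroy
sites for other factors with similar or overlapping sequence preferences.
``design_knockout`` guarantees (a) by exhaustive search over minimal
substitution sets with rescan verification; ``collision_report`` makes
(b) explicit by diffing hits of a whole motif library between the
original and mutated sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Iterable, Mapping, Sequence

from .motif_scan import MotifHit, MotifModel, scan, score_site

__all__ = ["Substitution", "CollateralRecord", "KnockoutPlan", "design_knockout", "collision_report"]

# per original base: replacement candidates, transversions first
_REPLACEMENTS = {
    "A": ("C", "T", "G"),
    "G": ("C", "T", "A"),
    "C": ("A", "G", "T"),
    "T": ("A", "G", "C"),
}


@dataclass(frozen=True)
class Substitution:
    position: int
    old: str
    new: str


@dataclass(frozen=True)
class CollateralRecord:
    motif_name: str
    effect: str  # "created" | "destroyed"
    start: int
    end: int
    strand: str


@dataclass
class KnockoutPlan:
    """A verified minimal-substitution knockout of one binding site."""

    target_hit: MotifHit
    substitutions: tuple[Substitution, ...]
    mutated_seq: str
    collateral: list[CollateralRecord] = field(default_factory=list)


def _residual_hits(seq: str, motif: MotifModel, footprint: tuple[int, int]) -> list[MotifHit]:
    """Target-motif hits on ``seq`` overlapping the footprint interval."""
    start, end = footprint
    L = motif.length
    lo = max(0, start - L + 1)
    hi = min(len(seq), end + L - 1)
    local = scan(seq[lo:hi], motif)
    return [h for h in local if lo + h.start < end and start < lo + h.end]


def design_knockout(
    seq: str,
    hit: MotifHit,
    motif: MotifModel,
    motif_library: Iterable[MotifModel] = (),
    cap: int = 3,
) -> KnockoutPlan:
    """Choose a minimal substitution set abolishing the targeted site.

    Substitutions are confined to the hit's footprint.  Candidate sets are
    enumerated exhaustively by size (1..cap), positions in lexicographic
    order, replacement bases preferring transversions; the first set after
    which no window overlapping the footprint meets the target motif's
    threshold on either strand is returned, so plans are deterministic.
    Collateral effects on ``motif_library`` are attached to the plan.
    """
    seq = seq.upper()
    footprint = (hit.start, hit.end)
    site = seq[hit.start:hit.end]
    if len(site) != motif.length:
        raise ValueError("hit footprint does not match the motif length")
    if not _residual_hits(seq, motif, footprint):
        raise ValueError("no target-motif match at the hit: nothing to knock out")
    positions = range(hit.start, hit.end)
    for size in range(1, cap + 1):
        for pos_set in combinations(positions, size):
            olds = [seq[p] for p in pos_set]
            if any(b not in _REPLACEMENTS for b in olds):
                continue  # ambiguous reference base: leave untouched
            for news in product(*(_REPLACEMENTS[b] for b in olds)):
                mutated = bytearray(seq.encode())
                for p, nb in zip(pos_set, news):
                    mutated[p] = ord(nb)
                mutated_seq = mutated.decode()
                if _residual_hits(mutated_seq, motif, footprint):
                    continue
                subs = tuple(
                    Substitution(position=p, old=o, new=n)
                    for p, o, n in zip(pos_set, olds, news)
                )
                plan = KnockoutPlan(
                    target_hit=hit, substitutions=subs, mutated_seq=mutated_seq
                )
                library = list(motif_library)
                if library:
                    plan.collateral = collision_report(seq, mutated_seq, library)
                return plan
    raise ValueError(
        f"no substitution set of size <= {cap} abolishes {motif.name!r} over "
        f"[{hit.start},{hit.end}); retry with a larger cap"
    )


def collision_report(
    original: str, mutated: str, motif_library: Iterable[MotifModel]
) -> list[CollateralRecord]:
    """Diff hits of every library motif between two equal-length sequences.

    Hits present only in the original are reported as "destroyed", hits
    present only in the mutated sequence as "created"; matching is by
    (start, end, strand) per motif.
    """
    if len(original) != len(mutated):
        raise ValueError("sequences must have equal length")
    records: list[CollateralRecord] = []
    for motif in motif_library:
        before = {(h.start, h.end, h.strand) for h in scan(original, motif)}
        after = {(h.start, h.end, h.strand) for h in scan(mutated, motif)}
        for s, e, strand in sorted(before - after):
            records.append(CollateralRecord(motif.name, "destroyed", s, e, strand))
        for s, e, strand in sorted(after - before):
            records.append(CollateralRecord(motif.name, "created", s, e, strand))
    return records
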