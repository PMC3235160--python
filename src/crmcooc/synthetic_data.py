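"""Synthetic genomes, orthologs and conservation tracks with known truth.

The real study scanned the fly genome and compared candidate regions with
a second species' genome; neither genome is bundled here.  Instead this
module generates inputs with the same statistical structure: i.i.d.
background DNA of chosen GC content, planted clusters of exact-consensus
binding sites satisfying the co-occurrence model (plus optional decoy
clusters missing one factor), an ortholog derived by per-base
substitutions and between-site indels with purifying-selection bias
inside planted sites, and conservation tracks with localized peaks.
Every generator is driven by an explicit integer seed.

The printed score matrix of the published evaluation (13 regions, eight
metrics) ships as an in-package TSV and is exposed via
``table2_fixture()`` for the statistics layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .conservation import ConservationTrack, PairwiseAlignment
from .motif_scan import IUPAC, MotifHit, MotifModel
from .set_statistics import MetricTable

__all__ = [
    "PlantedRegion",
    "SyntheticTruth",
    "placeholder_motifs",
    "simulate_background",
    "plant_clusters",
    "simulate_ortholog",
    "simulate_track",
    "table2_fixture",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


def placeholder_motifs() -> dict[str, MotifModel]:
    """Stand-in consensus models for the five factors.

    These are arbitrary fixed 10-mers for testing and simulation only —
    they are NOT the binding models of dTcf, Mad, Pnt, Tin or Twi, which
    must be supplied by the user for any real scan.  Fully specified
    10-mers keep the chance of background matches per 500 bp window
    around 1e-3, so planted-cluster recovery is essentially noiseless;
    the words are chosen so that no motif overlaps itself, another motif,
    or any reverse complement by more than 3 bp, avoiding shifted
    spurious matches around planted instances.
    """
    consensi = {
        "dTcf": "CTTTGATCGG",
        "Mad": "GCATTGCTGC",
        "Pnt": "ACGGAAGTCC",
        "Tin": "TCAAGTGGCA",
        "Twi": "CAAGTATTCG",
    }
    return {name: MotifModel(name=name, consensus=c) for name, c in consensi.items()}


@dataclass
class PlantedRegion:
    start: int
    end: int
    counts: dict[str, int]
    is_decoy: bool = False


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated genome."""

    seed: int
    planted_regions: list[PlantedRegion] = field(default_factory=list)
    planted_sites: list[MotifHit] = field(default_factory=list)
    true_alignment: PairwiseAlignment | None = None
    track_peaks: list[tuple[int, int, float]] = field(default_factory=list)


def simulate_background(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """i.i.d. background DNA with P(G) + P(C) = gc."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= gc <= 1:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=length, p=p))


def _realize_consensus(consensus: str, rng: np.random.Generator) -> str:
    """One concrete sequence matching a (possibly degenerate) consensus."""
    return "".join(
        c if len(IUPAC[c]) == 1 else rng.choice(list(IUPAC[c])) for c in consensus
    )


def plant_clusters(
    seq: str,
    motifs: Mapping[str, MotifModel],
    counts: Mapping[str, int],
    window_bp: int = 500,
    n_clusters: int = 1,
    decoys: int = 0,
    seed: int = 0,
    seq_id: str = "synth",
) -> tuple[str, SyntheticTruth]:
    """Plant co-occurrence clusters of exact consensus instances.

    Each of ``n_clusters`` windows receives exactly ``counts[m]``
    non-overlapping instances of every motif m, all within a span of
    ``window_bp``; ``decoys`` additional clusters omit one motif class
    each (rotating over the non-dTcf classes) as negative controls.
    Clusters are separated by more than ``window_bp`` of background so
    they can never merge.  Raises on infeasible packing.
    """
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed)
    n_total = n_clusters + decoys
    if n_total == 0:
        return seq, truth
    footprint = sum(motifs[m].length * c for m, c in counts.items())
    if footprint > window_bp:
        raise ValueError(
            f"total planted footprint {footprint} bp exceeds window {window_bp} bp"
        )
    gap = window_bp  # inter-cluster spacing; prevents window merging
    need = n_total * (window_bp + 2 * gap)
    if len(seq) < need:
        raise ValueError(
            f"sequence of {len(seq)} bp cannot hold {n_total} clusters "
            f"(needs >= {need} bp)"
        )
    slot = len(seq) // n_total
    starts = []
    for k in range(n_total):
        lo = k * slot + (gap if k == 0 else gap // 2)
        hi = (k + 1) * slot - window_bp - (gap if k == n_total - 1 else gap // 2)
        if hi < lo:
            raise ValueError("infeasible cluster packing")
        starts.append(int(rng.integers(lo, hi + 1)))
    # which motif class each decoy omits (never dTcf: its minimum is 1,
    # so a single chance hit could rescue the decoy)
    droppable = [m for m in counts if m != "dTcf"] or list(counts)
    out = bytearray(seq.upper().encode())
    for k, win_start in enumerate(starts):
        is_decoy = k >= n_clusters
        cluster_counts = dict(counts)
        if is_decoy:
            dropped = droppable[(k - n_clusters) % len(droppable)]
            cluster_counts[dropped] = 0
        items = [m for m, c in cluster_counts.items() for _ in range(c)]
        rng.shuffle(items)
        used = sum(motifs[m].length for m in items)
        free = window_bp - used
        gaps = rng.multinomial(free, [1.0 / (len(items) + 1)] * (len(items) + 1))
        pos = win_start
        region_counts = {m: 0 for m in counts}
        sites = []
        for item, g in zip(items, gaps[:-1]):
            pos += int(g)
            inst = _realize_consensus(motifs[item].consensus, rng)
            out[pos:pos + len(inst)] = inst.encode()
            sites.append(
                MotifHit(
                    seq_id=seq_id,
                    start=pos,
                    end=pos + len(inst),
                    motif_name=item,
                    strand="+",
                    score=float(len(inst)),
                    site_seq=inst,
                )
            )
            region_counts[item] += 1
            pos += len(inst)
        truth.planted_regions.append(
            PlantedRegion(
                start=win_start,
                end=win_start + window_bp,
                counts=region_counts,
                is_decoy=is_decoy,
            )
        )
        truth.planted_sites.extend(sorted(sites))
    return out.decode(), truth


def simulate_ortholog(
    seq: str,
    sub_rate: float = 0.1,
    indel_rate: float = 0.01,
    site_bias: float = 0.1,
    truth: SyntheticTruth | None = None,
    seed: int = 0,
) -> tuple[str, PairwiseAlignment]:
    """Derive a second-species sequence and its generative alignment.

    Each base substitutes with probability ``sub_rate`` (multiplied by
    ``site_bias`` < 1 inside planted sites, emulating purifying selection
    on functional sites).  Geometric-length insertions/deletions occur
    between sites at ``indel_rate`` per eligible base; indels never
    interrupt a planted site, so site conservation is controlled solely
    by ``site_bias``.  Returns the ortholog and the true alignment.
    """
    for name, r in (("sub_rate", sub_rate), ("indel_rate", indel_rate)):
        if not 0 <= r < 1:
            raise ValueError(f"{name} must lie in [0, 1)")
    if not 0 <= site_bias <= 1:
        raise ValueError("site_bias must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    seq = seq.upper()
    n = len(seq)
    in_site = np.zeros(n, dtype=bool)
    if truth is not None:
        for s in truth.planted_sites:
            in_site[s.start:s.end] = True
    ref_row: list[str] = []
    alt_row: list[str] = []
    i = 0
    while i < n:
        if not in_site[i] and indel_rate > 0 and rng.random() < indel_rate:
            k = int(rng.geometric(0.5))
            if rng.random() < 0.5:  # insertion in the ortholog
                for _ in range(k):
                    ref_row.append("-")
                    alt_row.append(rng.choice(_BASES))
            else:  # deletion: skip up to k non-site reference bases
                j = i
                while j < n and j - i < k and not in_site[j]:
                    ref_row.append(seq[j])
                    alt_row.append("-")
                    j += 1
                i = j
                continue
        base = seq[i]
        rate = sub_rate * site_bias if in_site[i] else sub_rate
        if base in "ACGT" and rng.random() < rate:
            alt = rng.choice([b for b in "ACGT" if b != base])
        else:
            alt = base
        ref_row.append(base)
        alt_row.append(alt)
        i += 1
    aln = PairwiseAlignment(
        ref_id="ref",
        alt_id="ortholog",
        ref_row="".join(ref_row),
        alt_row="".join(alt_row),
    )
    if truth is not None:
        truth.true_alignment = aln
    ortholog = aln.alt_row.replace("-", "")
    return ortholog, aln


def simulate_track(
    length: int,
    baseline: float = 0.1,
    peaks: Sequence[tuple[int, int, float]] = (),
    seed: int = 0,
    noise_sd: float = 0.0,
    seq_id: str = "synth",
) -> ConservationTrack:
    """Per-base conservation track: baseline plus elevated peak intervals,
    optionally with clamped Gaussian noise.  Overlapping peaks error."""
    if not 0 <= baseline <= 1:
        raise ValueError("baseline must lie in [0, 1]")
    peaks = sorted(peaks)
    for (s1, e1, lv1), (s2, e2, lv2) in zip(peaks, peaks[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping peak intervals [{s1},{e1}) and [{s2},{e2})")
    scores = np.full(length, float(baseline))
    for s, e, level in peaks:
        if not 0 <= level <= 1:
            raise ValueError("peak level must lie in [0, 1]")
        if not (0 <= s < e <= length):
            raise ValueError("peak interval outside the track")
        scores[s:e] = level
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        scores = scores + rng.normal(0.0, noise_sd, size=length)
    return ConservationTrack(seq_id=seq_id, start=0, scores=np.clip(scores, 0.0, 1.0))


def table2_fixture() -> MetricTable:
    """The published 13-region score matrix (6 '+' rows, 7 '-' rows).

    Cells that the original table leaves undefined are MISSING: the DME4
    row has no alignment-based values ("nd"), and DME3 is shorter than
    500 bp so its 500-bp peak window cell is undefined.
    """
    path = resources.files("crmcooc").joinpath("data/table2.tsv")
    with resources.as_file(path) as p:
        return MetricTable.from_tsv(p)
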