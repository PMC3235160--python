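"""Binding-site models and both-strand sequence scanning.

A motif is either a degenerate IUPAC consensus (scored as the number of
positions satisfying the code; a hit allows at most ``max_violations``
failures, default 0) or a position frequency matrix (scored as summed
log2 odds against a uniform background; a hit must reach ``threshold``).

Scanning conventions
--------------------
* Coordinates are 0-based, half-open, always on the plus strand.
* Ambiguity codes in the *model* match their IUPAC set; ambiguous bases in
  the *sequence* (N etc.) never match anything.
* A site matching on both strands at the same interval (palindrome) is
  reported once, with strand '+', so instance counts are per-interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "IUPAC",
    "MotifModel",
    "MotifHit",
    "load_motifs",
    "scan",
    "score_site",
    "reverse_complement",
]

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# base -> row index; anything else (N, ambiguity codes in data) -> 4
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_PSEUDOCOUNT = 0.5


def reverse_complement(seq: str) -> str:
    """Reverse complement; supports IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class MotifModel:
    """A named binding-site model: IUPAC consensus or count matrix.

    Exactly one of ``consensus`` / ``pfm`` is set.  ``pfm`` is a (4, L)
    array of non-negative counts (rows A, C, G, T); every column must have
    a positive total.  ``threshold`` is the minimum acceptable match score;
    for a consensus it is derived as ``length - max_violations``, for a
    matrix it defaults to 80% of the maximum attainable log-odds score.
    """

    name: str
    consensus: str | None = None
    pfm: np.ndarray | None = None
    threshold: float | None = None
    max_violations: int = 0

    def __post_init__(self):
        if (self.consensus is None) == (self.pfm is None):
            raise ValueError("exactly one of consensus or pfm must be given")
        if self.consensus is not None:
            cons = self.consensus.upper()
            for ch in cons:
                if ch not in IUPAC:
                    raise ValueError(
                        f"motif {self.name!r}: {ch!r} is not an IUPAC nucleotide code"
                    )
            if len(cons) < 1:
                raise ValueError(f"motif {self.name!r}: empty consensus")
            object.__setattr__(self, "consensus", cons)
            if self.max_violations < 0:
                raise ValueError("max_violations must be >= 0")
            object.__setattr__(
                self, "threshold", float(len(cons) - self.max_violations)
            )
        else:
            pfm = np.asarray(self.pfm, dtype=float)
            if pfm.ndim != 2 or pfm.shape[0] != 4 or pfm.shape[1] < 1:
                raise ValueError(f"motif {self.name!r}: pfm must be 4 x L")
            if np.any(pfm < 0) or np.any(pfm.sum(axis=0) <= 0):
                raise ValueError(
                    f"motif {self.name!r}: pfm columns must sum to a positive total"
                )
            object.__setattr__(self, "pfm", pfm)
            if self.threshold is None:
                object.__setattr__(
                    self, "threshold", 0.8 * float(self._log_odds()[:4].max(axis=0).sum())
                )

    @property
    def length(self) -> int:
        return len(self.consensus) if self.consensus is not None else self.pfm.shape[1]

    # -- internal scoring tables ------------------------------------------

    def _allowed(self) -> np.ndarray:
        """(5, L) bool: row b allowed at column j. Row 4 (ambiguous data) False."""
        tab = np.zeros((5, self.length), dtype=bool)
        for j, code in enumerate(self.consensus):
            for b in IUPAC[code]:
                tab["ACGT".index(b), j] = True
        return tab

    def _log_odds(self) -> np.ndarray:
        """(5, L) float: log2((c+p)/(total+4p) / 0.25); row 4 is -inf."""
        pfm = self.pfm + _PSEUDOCOUNT
        probs = pfm / pfm.sum(axis=0, keepdims=True)
        lo = np.vstack([np.log2(probs / 0.25), np.full(self.length, -np.inf)])
        return lo

    def reverse_complement(self) -> "MotifModel":
        if self.consensus is not None:
            return MotifModel(
                name=self.name,
                consensus=reverse_complement(self.consensus),
                max_violations=self.max_violations,
            )
        return MotifModel(
            name=self.name, pfm=self.pfm[::-1, ::-1].copy(), threshold=self.threshold
        )


@dataclass(frozen=True, order=True)
class MotifHit:
    """A scored binding-site match, in plus-strand coordinates."""

    seq_id: str = field(compare=False)
    start: int
    end: int
    motif_name: str = field(compare=False)
    strand: str = field(compare=False)
    score: float = field(compare=False)
    site_seq: str = field(compare=False)

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("hit interval must be non-empty")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


def score_site(motif: MotifModel, kmer: str) -> float:
    """Score a single k-mer against a motif (plus orientation).

    Consensus mode returns ``length - violations``; matrix mode the summed
    log2 odds versus a uniform background.  Ambiguous bases in ``kmer``
    never satisfy the model.
    """
    if len(kmer) != motif.length:
        raise ValueError(
            f"kmer length {len(kmer)} != motif {motif.name!r} length {motif.length}"
        )
    codes = _encode(kmer.upper())
    idx = np.arange(motif.length)
    if motif.consensus is not None:
        return float(motif._allowed()[codes, idx].sum())
    return float(motif._log_odds()[codes, idx].sum())


def _position_scores(codes: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Score every start position of a sequence against a (5, L) table."""
    L = table.shape[1]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0, dtype=float)
    acc = np.zeros(n, dtype=float)
    for j in range(L):
        acc += table[:, j][codes[j:j + n]]
    return acc


def scan(seq: str, motif: MotifModel, seq_id: str = "seq") -> list[MotifHit]:
    """Report every match of ``motif`` on both strands of ``seq``.

    Returns hits sorted by (start, end); palindromic double-matches are
    collapsed to a single '+' record.  A sequence shorter than the motif
    yields an empty list.
    """
    seq = seq.upper()
    L = motif.length
    if len(seq) < L:
        return []
    codes = _encode(seq)
    if motif.consensus is not None:
        fwd_tab = motif._allowed().astype(float)
        rev_tab = motif.reverse_complement()._allowed().astype(float)
    else:
        fwd_tab = motif._log_odds()
        rev_tab = motif.reverse_complement()._log_odds()
    fwd = _position_scores(codes, fwd_tab)
    rev = _position_scores(codes, rev_tab)
    hits: list[MotifHit] = []
    thr = motif.threshold
    fwd_ok = fwd >= thr
    rev_ok = rev >= thr
    for s in np.nonzero(fwd_ok | rev_ok)[0]:
        s = int(s)
        plus = bool(fwd_ok[s])
        strand = "+" if plus else "-"
        score = float(fwd[s]) if plus else float(rev[s])
        hits.append(
            MotifHit(
                seq_id=seq_id,
                start=s,
                end=s + L,
                motif_name=motif.name,
                strand=strand,
                score=score,
                site_seq=seq[s:s + L],
            )
        )
    return hits


# ---------------------------------------------------------------------------
# motif file parsing


def load_motifs(path: str | Path, format: str) -> list[MotifModel]:
    """Load motif models from a file.

    Supported dialects: ``iupac-table`` (two whitespace-separated columns:
    name, consensus; '#' comments), ``jaspar-pfm`` and ``meme-minimal``
    (parsed with Bio.motifs).  Duplicate names are an error.
    """
    path = Path(path)
    if format in ("iupac", "iupac-table"):
        models = _load_iupac_table(path)
    elif format in ("jaspar", "jaspar-pfm"):
        models = _load_bio_motifs(path, "jaspar")
    elif format in ("meme", "meme-minimal"):
        models = _load_bio_motifs(path, "minimal")
    else:
        raise ValueError(f"unknown motif format {format!r}")
    names = [m.name for m in models]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate motif names: {sorted(dupes)}")
    return models


def _load_iupac_table(path: Path) -> list[MotifModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'name consensus'")
            name, cons = parts[0], parts[1]
            models.append(MotifModel(name=name, consensus=cons))
    return models


def _load_bio_motifs(path: Path, dialect: str) -> list[MotifModel]:
    from Bio import motifs as bio_motifs

    models = []
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, dialect)
        for m in parsed:
            name = m.name or getattr(m, "matrix_id", None) or "motif"
            pfm = np.array([list(m.counts[b]) for b in "ACGT"], dtype=float)
            models.append(MotifModel(name=name, pfm=pfm))
    return models


def consensus_match_probability(motif: MotifModel, gc: float = 0.5) -> float:
    """Per-position probability that an i.i.d. base string matches the
    consensus on a *given* strand (used by analytic hit-rate checks)."""
    if motif.consensus is None:
        raise ValueError("analytic match probability is defined for consensus motifs")
    p = {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}
    prob = 1.0
    for code in motif.consensus:
        prob *= sum(p[b] for b in IUPAC[code])
    return prob
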