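"""GC-skew profiling, skew-shift localisation and terminus-motif search.

The origin candidate is taken at the global minimum of the cumulative
per-step (G-C) sum and the terminus candidate at its global maximum, the
standard cumulative-skew reading of a bidirectionally replicating circular
chromosome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .genome_model import AnnotatedGenome, CircularInterval, GenomeError, reverse_complement

__all__ = ["SkewProfile", "SkewShift", "MotifHit", "gc_skew_profile",
           "find_skew_shifts", "find_motif", "locate_origin_intergenic"]

_IUPAC_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15,
}


@dataclass
class SkewProfile:
    window: int
    step: int
    genome_length: int
    midpoints: np.ndarray          # 1-based window midpoints
    values: np.ndarray             # (G-C)/(G+C) per window, 0 where G+C == 0
    cumulative: np.ndarray         # running sum of per-step-chunk (G-C)
    chunk_starts: np.ndarray       # 1-based start of each step chunk

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SkewShift:
    position: int
    direction: str  # "origin" (min->max) or "terminus" (max->min)


@dataclass(frozen=True)
class MotifHit:
    interval: CircularInterval
    strand: str
    mismatches: int


def _base_counts(seq: str) -> tuple[np.ndarray, np.ndarray]:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return (arr == ord("G")).astype(np.int64), (arr == ord("C")).astype(np.int64)


def gc_skew_profile(genome: AnnotatedGenome, window: int = 10_000,
                    step: Optional[int] = None) -> SkewProfile:
    """Windowed (G-C)/(G+C) profile; windows wrap on circular genomes."""
    if step is None:
        step = max(1, window // 10)
    if not (window >= step >= 1):
        raise GenomeError(f"need window >= step >= 1, got window={window} step={step}")
    L = genome.length
    if window > L:
        raise GenomeError(f"window {window} exceeds genome length {L}")
    g, c = _base_counts(genome.sequence)
    if genome.topology == "circular":
        g2 = np.concatenate([g, g[:window]])
        c2 = np.concatenate([c, c[:window]])
    else:
        g2, c2 = g, c
    cg = np.concatenate([[0], np.cumsum(g2)])
    cc = np.concatenate([[0], np.cumsum(c2)])
    n_windows = math.ceil(L / step) if genome.topology == "circular" \
        else max(1, (L - window) // step + 1)
    starts = np.arange(n_windows) * step
    ends = np.minimum(starts + window, len(g2))
    wg = cg[ends] - cg[starts]
    wc = cc[ends] - cc[starts]
    tot = wg + wc
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(tot > 0, (wg - wc) / np.maximum(tot, 1), 0.0)
    mids = ((starts + window // 2) % L) + 1

    # cumulative over disjoint step-sized chunks, so the final value equals
    # the genome's total (G - C)
    cg0 = np.concatenate([[0], np.cumsum(g)])
    cc0 = np.concatenate([[0], np.cumsum(c)])
    chunk_starts = np.arange(0, L, step)
    chunk_ends = np.minimum(chunk_starts + step, L)
    chunk_gc = (cg0[chunk_ends] - cg0[chunk_starts]) - (cc0[chunk_ends] - cc0[chunk_starts])
    cumulative = np.cumsum(chunk_gc)
    return SkewProfile(window=window, step=step, genome_length=L,
                       midpoints=mids, values=vals, cumulative=cumulative,
                       chunk_starts=chunk_starts + 1)


def find_skew_shifts(profile: SkewProfile) -> tuple[Optional[SkewShift], Optional[SkewShift]]:
    """Locate (origin_candidate, terminus_candidate) from cumulative skew extrema.

    Returns ``(None, None)`` when the profile carries no skew structure.
    Ties resolve to the smallest coordinate.
    """
    cum = profile.cumulative
    if len(cum) == 0 or cum.max() == cum.min():
        return None, None
    i_min = int(np.argmin(cum))
    i_max = int(np.argmax(cum))
    # extremum at chunk i: boundary at the end of that chunk
    pos_min = int(profile.chunk_starts[i_min] - 1 + min(profile.step, profile.genome_length -
                                                        profile.chunk_starts[i_min] + 1))
    pos_max = int(profile.chunk_starts[i_max] - 1 + min(profile.step, profile.genome_length -
                                                        profile.chunk_starts[i_max] + 1))
    return (SkewShift(pos_min, "origin"), SkewShift(pos_max, "terminus"))


def _motif_bits(motif: str) -> np.ndarray:
    try:
        return np.array([_IUPAC_BITS[c] for c in motif.upper()], dtype=np.uint8)
    except KeyError as exc:
        raise GenomeError(f"non-IUPAC character in motif: {exc.args[0]!r}") from None


def _scan_strand(seq_bits: np.ndarray, motif: np.ndarray, max_mm: int, L: int) -> list[tuple[int, int]]:
    m = len(motif)
    n_pos = L
    mismatch = np.zeros(n_pos, dtype=np.int32)
    for j in range(m):
        mismatch += (seq_bits[j:j + n_pos] & motif[j]) == 0
    idx = np.nonzero(mismatch <= max_mm)[0]
    return [(int(i), int(mismatch[i])) for i in idx]


def find_motif(genome: AnnotatedGenome, motif: str, max_mismatches: int = 0) -> list[MotifHit]:
    """All positions on either strand within Hamming distance of the motif.

    Hits are ranked by (mismatches, position).  Wrapping occurrences are
    found on circular genomes.  Intervals are forward-strand 1-based.
    """
    if max_mismatches < 0:
        raise GenomeError("max_mismatches must be >= 0")
    m = len(motif)
    L = genome.length
    if m > L:
        raise GenomeError("motif longer than genome")
    bits = _motif_bits(motif)
    seq = genome.sequence
    if genome.topology == "circular":
        seq = seq + seq[:m - 1]
    seq_bits = np.array([_IUPAC_BITS.get(ch, 0) for ch in seq], dtype=np.uint8)
    n_pos = L if genome.topology == "circular" else L - m + 1
    hits = []
    fwd = _scan_strand(seq_bits[:n_pos + m - 1], bits, max_mismatches, n_pos)
    for p0, mm in fwd:
        end = ((p0 + m - 1) % L) + 1
        hits.append(MotifHit(CircularInterval(p0 + 1, end, wraps=end < p0 + 1), "+", mm))
    rc_bits = _motif_bits(reverse_complement(motif))
    if not np.array_equal(rc_bits, bits):
        rev = _scan_strand(seq_bits[:n_pos + m - 1], rc_bits, max_mismatches, n_pos)
        for p0, mm in rev:
            end = ((p0 + m - 1) % L) + 1
            hits.append(MotifHit(CircularInterval(p0 + 1, end, wraps=end < p0 + 1), "-", mm))
    hits.sort(key=lambda h: (h.mismatches, h.interval.start, h.strand))
    return hits


def locate_origin_intergenic(genome_a: AnnotatedGenome, genome_b: AnnotatedGenome,
                             anchor_gene_pairs: tuple[tuple[str, str], tuple[str, str]],
                             scheme=None) -> dict:
    """Align the intergenic region between an ortholog anchor pair in each genome.

    ``anchor_gene_pairs`` is ``((a_left, a_right), (b_left, b_right))`` of locus
    tags flanking the putative origin in each genome.  Returns identity
    percentage, aligned length and per-genome intergenic intervals.
    """
    from .align import ScoringScheme, align_local

    if scheme is None:
        scheme = ScoringScheme.nucleotide()

    def intergenic(genome: AnnotatedGenome, left_tag: str, right_tag: str) -> tuple[str, CircularInterval]:
        try:
            left = genome.get_feature(left_tag)
            right = genome.get_feature(right_tag)
        except KeyError as exc:
            raise GenomeError(f"anchor gene missing in {genome.id}: {exc.args[0]}") from None
        start = genome.wrap(left.interval.end + 1)
        end = genome.wrap(right.interval.start - 1)
        iv = CircularInterval(start, end, wraps=end < start)
        return genome.subsequence(iv), iv

    seq_a, iv_a = intergenic(genome_a, *anchor_gene_pairs[0])
    seq_b, iv_b = intergenic(genome_b, *anchor_gene_pairs[1])
    alns = align_local(seq_a, seq_b, scheme)
    if not alns:
        return {"identity_pct": None, "aligned_length": 0,
                "interval_a": iv_a, "interval_b": iv_b, "alignment": None}
    best = alns[0]
    return {"identity_pct": best.identity_pct, "aligned_length": best.aligned_length,
            "interval_a": iv_a, "interval_b": iv_b, "alignment": best}
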