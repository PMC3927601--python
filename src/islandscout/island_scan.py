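"""tRNA-anchored genomic-island detection and symbiosis-island assembly.

A typical island is delimited by an intact tRNA gene at one end and an
exact duplication of the tRNA's 3'-terminal portion at the other.  Stacked
(nested) islands at one anchor are each closed by their own duplication:
island ``i`` runs from the base after the previous boundary (the intact
tRNA 3' end for the first island) to the last base of its duplication.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .genome_model import (AnnotatedGenome, CircularInterval, Feature, GenomeError,
                           gc_fraction, reverse_complement)

__all__ = ["GenomicIsland", "CandidateIsland", "PartialTrnaHit",
           "SymbiosisFragment", "SymbiosisIslandSet",
           "find_trna_anchored_islands", "find_candidate_low_gc_islands",
           "find_partial_trna_copies", "assemble_symbiosis_islands"]

INTEGRASE_KEYWORDS = ("integrase", "recombinase", "phage integrase")


@dataclass
class GenomicIsland:
    name: str
    anchor_trna: Feature
    interval: CircularInterval
    length: int
    gc_pct: float
    duplication_length: int
    duplication_interval: CircularInterval
    nesting_index: int
    integrase_locus: Optional[str] = None

    @property
    def left_end(self) -> int:
        return self.interval.start

    @property
    def right_end(self) -> int:
        return self.interval.end


@dataclass
class CandidateIsland:
    flanking_trna: Feature
    interval: CircularInterval
    gc_pct: float
    evidence: str = "low_gc_only"


@dataclass(frozen=True)
class PartialTrnaHit:
    """3'-portion copy; minus-strand hits carry descending coordinates."""

    start: int
    end: int
    strand: str
    length: int

    @property
    def interval(self) -> CircularInterval:
        lo, hi = min(self.start, self.end), max(self.start, self.end)
        return CircularInterval(lo, hi)


@dataclass
class SymbiosisFragment:
    name: str
    interval: CircularInterval
    length: int
    gc_pct: float
    evidence: list[str]
    is_count: int = 0
    integrase_locus: Optional[str] = None

    @property
    def kb(self) -> float:
        return self.length / 1000.0


@dataclass
class SymbiosisIslandSet:
    anchor_trnv: str
    fragments: dict[str, SymbiosisFragment]
    partial_trnv_hits: list[PartialTrnaHit]
    total_kb: float
    complete: bool
    notes: list[str] = field(default_factory=list)


def _wrap(pos: int, L: int) -> int:
    return ((pos - 1) % L) + 1


def _interval_mod(start: int, end: int, L: int) -> CircularInterval:
    start, end = _wrap(start, L), _wrap(end, L)
    return CircularInterval(start, end, wraps=end < start)


def _to_rc_coords(iv: CircularInterval, L: int) -> CircularInterval:
    """Map a forward-coordinate interval into reverse-complement coordinates."""
    return _interval_mod(L - iv.end + 1, L - iv.start + 1, L)


def _find_integrase(genome: AnnotatedGenome, interval: CircularInterval,
                    keywords: Sequence[str] = INTEGRASE_KEYWORDS) -> Optional[str]:
    pat = re.compile("|".join(re.escape(k) for k in keywords), re.IGNORECASE)
    for f in genome.features_of_kind("CDS"):
        if interval.contains(f.interval.midpoint(genome.length), genome.length) \
                and pat.search(f.product or ""):
            return f.feature_id
    return None


def _scan_anchor_plus(seq: str, L: int, t_end: int, trna_seq: str, min_dup: int,
                      max_island: int, max_stack: int) -> list[tuple[int, int, int, int]]:
    """Islands downstream of a 3' end at 1-based ``t_end`` in ``seq`` orientation.

    Returns (island_start, island_end, dup_start, dup_len) in that
    orientation's coordinates; positions may exceed L (caller wraps).
    """
    doubled = seq + seq
    s_min = trna_seq[-min_dup:]
    islands = []
    boundary = t_end  # island starts at boundary+1
    scan_limit = t_end + min(max_stack * max_island, L - 1)
    for _ in range(max_stack):
        window_end = min(boundary + max_island, scan_limit)
        # find nearest occurrence of the minimal suffix fully inside the window
        p0 = doubled.find(s_min, boundary)  # 0-based start; boundary = 1-based prev end
        if p0 == -1 or p0 + min_dup > window_end:
            break
        # grow the duplication to the longest matching suffix ending here
        ext = 0
        while (min_dup + ext < len(trna_seq)
               and p0 - 1 - ext >= 0
               and doubled[p0 - 1 - ext] == trna_seq[-(min_dup + ext + 1)]):
            ext += 1
        dup_len = min_dup + ext
        dup_start = p0 - ext + 1          # 1-based
        island_end = p0 + min_dup         # 1-based last base of duplication
        islands.append((boundary + 1, island_end, dup_start, dup_len))
        boundary = island_end
    return islands


def find_trna_anchored_islands(genome: AnnotatedGenome, min_dup: int = 14,
                               max_island: int = 110_000, max_stack: int = 4,
                               gc_filter: bool = True,
                               name_prefix: str = "GI") -> list[GenomicIsland]:
    """Detect islands closed by exact 3'-suffix duplications of tRNA genes."""
    if not genome.sequence:
        raise GenomeError("genome carries no sequence; cannot scan for duplications")
    trnas = genome.features_of_kind("tRNA")
    if not trnas:
        raise GenomeError("genome has no tRNA features")
    L = genome.length
    mean_gc = gc_fraction(genome)
    found: list[GenomicIsland] = []
    for trna in trnas:
        trna_seq = genome.feature_sequence(trna)
        if len(trna_seq) < min_dup:
            continue
        if trna.strand == "+":
            t_end = trna.interval.end
            raw = _scan_anchor_plus(genome.sequence, L, t_end, trna_seq,
                                    min_dup, max_island, max_stack)
            mapper = lambda a, b: _interval_mod(a, b, L)
        else:
            rc_seq = reverse_complement(genome.sequence)
            rc_iv = _to_rc_coords(trna.interval, L)
            raw = _scan_anchor_plus(rc_seq, L, rc_iv.end, trna_seq,
                                    min_dup, max_island, max_stack)
            mapper = lambda a, b: _interval_mod(L - b + 1, L - a + 1, L)
        for nesting, (i_start, i_end, d_start, d_len) in enumerate(raw, 1):
            iv = mapper(i_start, i_end)
            dup_iv = mapper(d_start, d_start + d_len - 1)
            gc = gc_fraction(genome, iv)
            if gc_filter and gc >= mean_gc:
                continue
            found.append(GenomicIsland(
                name="", anchor_trna=trna, interval=iv,
                length=iv.length(L), gc_pct=gc,
                duplication_length=d_len, duplication_interval=dup_iv,
                nesting_index=nesting,
                integrase_locus=_find_integrase(genome, iv)))
    found.sort(key=lambda g: (g.interval.start, g.nesting_index))
    for i, isl in enumerate(found, 1):
        isl.name = f"{name_prefix}{i:02d}"
    return found


def _grow_low_gc(genome: AnnotatedGenome, origin: int, direction: int,
                 gc_limit: float, chunk: int) -> int:
    """Number of bases in the maximal low-GC run from ``origin`` (exclusive)."""
    L = genome.length
    grown = 0
    while grown + chunk <= L - chunk:
        if direction > 0:
            iv = _interval_mod(origin + grown + 1, origin + grown + chunk, L)
        else:
            iv = _interval_mod(origin - grown - chunk, origin - grown - 1, L)
        if gc_fraction(genome, iv) >= gc_limit:
            break
        grown += chunk
    return grown


def find_candidate_low_gc_islands(genome: AnnotatedGenome, gc_margin: float = 2.0,
                                  min_len: int = 10_000, chunk: int = 1_000,
                                  min_dup: int = 14) -> list[CandidateIsland]:
    """Duplication-free low-GC segments downstream of tRNA genes."""
    L = genome.length
    mean_gc = gc_fraction(genome)
    gc_limit = mean_gc - gc_margin
    # anchors already closed by a terminal duplication host typical islands,
    # not candidates (mutual exclusion)
    anchored = {g.anchor_trna.feature_id
                for g in find_trna_anchored_islands(genome, min_dup=min_dup,
                                                    gc_filter=False)}
    out = []
    for trna in genome.features_of_kind("tRNA"):
        if trna.feature_id in anchored:
            continue
        if trna.strand == "+":
            origin, direction = trna.interval.end, +1
        else:
            origin, direction = trna.interval.start, -1
        grown = _grow_low_gc(genome, origin, direction, gc_limit, chunk)
        if grown < min_len:
            continue
        if direction > 0:
            iv = _interval_mod(origin + 1, origin + grown, L)
        else:
            iv = _interval_mod(origin - grown, origin - 1, L)
        out.append(CandidateIsland(flanking_trna=trna, interval=iv,
                                   gc_pct=gc_fraction(genome, iv)))
    out.sort(key=lambda c: c.interval.start)
    return out


def find_partial_trna_copies(genome: AnnotatedGenome, trna_seq: str, min_len: int = 45,
                             exclude: Optional[CircularInterval] = None) -> list[PartialTrnaHit]:
    """Genome-wide copies (both strands) of the tRNA 3'-terminal portion.

    The intact gene itself is excluded via ``exclude``.  Minus-strand hits
    are reported with descending coordinates.
    """
    trna_seq = trna_seq.upper()
    if len(trna_seq) <= min_len:
        raise GenomeError("tRNA sequence must be longer than min_len")
    L = genome.length
    suffix = trna_seq[-min_len:]
    hits: list[PartialTrnaHit] = []

    def scan(seq: str, to_fwd) -> None:
        doubled = seq + seq[:len(suffix) - 1] if genome.topology == "circular" else seq
        p0 = doubled.find(suffix)
        while p0 != -1 and p0 < L:
            ext = 0
            while (min_len + ext < len(trna_seq) and p0 - 1 - ext >= 0
                   and doubled[p0 - 1 - ext] == trna_seq[-(min_len + ext + 1)]):
                ext += 1
            hits.append(to_fwd(p0 - ext + 1, p0 + min_len, min_len + ext))
            p0 = doubled.find(suffix, p0 + 1)

    scan(genome.sequence,
         lambda a, b, n: PartialTrnaHit(_wrap(a, L), _wrap(b, L), "+", n))
    scan(reverse_complement(genome.sequence),
         lambda a, b, n: PartialTrnaHit(_wrap(L - a + 1, L), _wrap(L - b + 1, L), "-", n))
    if exclude is not None:
        hits = [h for h in hits if not h.interval.overlaps(exclude, L)]
    hits.sort(key=lambda h: min(h.start, h.end))
    return hits


def _circular_distance(a: int, b: int, L: int) -> int:
    d = abs(a - b)
    return min(d, L - d)


def assemble_symbiosis_islands(genome: AnnotatedGenome,
                               candidates: Sequence[CandidateIsland],
                               is_copies: Sequence,
                               tier1_loci: Sequence[CircularInterval],
                               trnv_locus: str,
                               partial_min_len: int = 45,
                               is_density_threshold: float = 5.0,
                               gc_margin: float = 1.0,
                               chunk: int = 1_000) -> SymbiosisIslandSet:
    """Reconstruct a split symbiosis island from three lines of evidence.

    Fragment A is the low-GC candidate abutting the intact anchor tRNA;
    fragment B is the low-GC run adjacent to a distal partial copy of the
    anchor tRNA's 3' portion; fragment C is a remaining region flagged by
    both IS density (copies per 100 kb >= threshold) and overlap with a
    high-conservation locus.  Each reported fragment must satisfy at least
    two of {low GC, IS density, conserved-locus overlap}.
    """
    L = genome.length
    mean_gc = gc_fraction(genome)
    gc_limit = mean_gc - gc_margin
    try:
        trnv = genome.get_feature(trnv_locus)
    except KeyError:
        raise GenomeError(f"anchor tRNA {trnv_locus!r} not found in genome") from None
    notes: list[str] = []
    fragments: dict[str, SymbiosisFragment] = {}

    def is_count(iv: CircularInterval) -> int:
        return sum(1 for c in is_copies if iv.contains(c.interval.midpoint(L), L))

    def density(iv: CircularInterval) -> float:
        return is_count(iv) / iv.length(L) * 100_000.0

    def evidence(iv: CircularInterval) -> list[str]:
        ev = []
        if gc_fraction(genome, iv) < mean_gc:
            ev.append("low_gc")
        if density(iv) >= is_density_threshold:
            ev.append("is_density")
        if any(iv.overlaps(t, L) for t in tier1_loci):
            ev.append("tier1_overlap")
        return ev

    # fragment A: low-GC candidate anchored at the intact trnV
    cand_a = next((c for c in candidates
                   if c.flanking_trna.feature_id == trnv.feature_id), None)
    if cand_a is None:
        notes.append(f"no low-GC candidate abuts {trnv_locus}; fragment A missing")
    else:
        ev = evidence(cand_a.interval)
        if len(ev) >= 2:
            fragments["A"] = SymbiosisFragment(
                "A", cand_a.interval, cand_a.interval.length(L),
                cand_a.gc_pct, ev, is_count(cand_a.interval))
        else:
            notes.append(f"fragment A rejected: evidence {ev} (need >= 2)")

    # fragment B: low-GC run beside a distal partial trnV 3'-portion copy
    trnv_seq = genome.feature_sequence(trnv)
    partials = find_partial_trna_copies(genome, trnv_seq, partial_min_len,
                                        exclude=trnv.interval)
    if not partials:
        notes.append("no distal partial copy of the anchor tRNA 3' portion found")
    else:
        distal = max(partials,
                     key=lambda h: _circular_distance(h.interval.start,
                                                      trnv.interval.start, L))
        right = _grow_low_gc(genome, distal.interval.end, +1, gc_limit, chunk)
        left = _grow_low_gc(genome, distal.interval.start, -1, gc_limit, chunk)
        if max(right, left) == 0:
            notes.append("partial-copy flank is not GC-poor; fragment B missing")
        else:
            if right >= left:
                iv = _interval_mod(distal.interval.end + 1,
                                   distal.interval.end + right, L)
            else:
                iv = _interval_mod(distal.interval.start - left,
                                   distal.interval.start - 1, L)
            near = _interval_mod(distal.interval.start - 5_000,
                                 distal.interval.end + 5_000, L)
            ev = evidence(iv)
            if len(ev) >= 2:
                fragments["B"] = SymbiosisFragment(
                    "B", iv, iv.length(L), gc_fraction(genome, iv), ev,
                    is_count(iv), integrase_locus=_find_integrase(genome, near))
            else:
                notes.append(f"fragment B rejected: evidence {ev} (need >= 2)")

    # fragment C: remaining IS-dense, conserved region
    used = [f.interval for f in fragments.values()]
    best_c = None
    for t_iv in tier1_loci:
        if any(t_iv.overlaps(u, L) for u in used):
            continue
        if density(t_iv) >= is_density_threshold:
            if best_c is None or density(t_iv) > density(best_c):
                best_c = t_iv
    if best_c is None:
        notes.append("no IS-dense conserved locus left for fragment C")
    else:
        ev = evidence(best_c)
        if len(ev) >= 2:
            fragments["C"] = SymbiosisFragment(
                "C", best_c, best_c.length(L), gc_fraction(genome, best_c),
                ev, is_count(best_c))
        else:
            notes.append(f"fragment C rejected: evidence {ev} (need >= 2)")

    total_kb = round(sum(f.length for f in fragments.values()) / 1000.0, 1)
    return SymbiosisIslandSet(anchor_trnv=trnv.feature_id, fragments=fragments,
                              partial_trnv_hits=partials, total_kb=total_kb,
                              complete=len(fragments) == 3, notes=notes)
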