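"""Seeded local pairwise alignment with BLAST-like scoring and statistics.

The engine finds exact k-mer seed matches, groups them into diagonal
clusters, and runs an affine-gap Smith-Waterman extension (Biopython's C
``PairwiseAligner``) on the clustered subject window.  Scores are converted
to bit scores and E-values with Karlin-Altschul statistics:

    bit = (lambda * raw - ln K) / ln 2
    E   = m * n * 2**(-bit)

with ``m``, ``n`` the query and subject lengths (no edge correction).
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_model import CircularInterval, GenomeError, reverse_complement

__all__ = ["ScoringScheme", "Alignment", "KmerIndex", "align_local", "best_hit",
           "external_blast_adapter", "AlphabetError"]

_NT = set("ACGTN")
_AA = set("ACDEFGHIKLMNPQRSTVWYX*")


class AlphabetError(GenomeError):
    pass


@dataclass(frozen=True)
class ScoringScheme:
    """Scoring parameters plus Karlin-Altschul constants for one mode."""

    mode: str                       # "nucleotide" | "protein"
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5               # cost of a length-1 gap is open + extend
    gap_extend: int = 2
    matrix: Optional[str] = None    # substitution-matrix name for protein mode
    lambda_: float = 0.625
    K: float = 0.41
    seed_k: int = 11

    @classmethod
    def nucleotide(cls) -> "ScoringScheme":
        # BLASTN defaults: +2/-3, gap 5/2; gapped Karlin-Altschul constants
        return cls(mode="nucleotide")

    @classmethod
    def protein(cls) -> "ScoringScheme":
        # BLASTP defaults: BLOSUM62, gap 11/1
        return cls(mode="protein", matrix="BLOSUM62", gap_open=11, gap_extend=1,
                   lambda_=0.267, K=0.041, seed_k=3)

    def __post_init__(self):
        if self.lambda_ <= 0 or self.K <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")

    def bit_score(self, raw: float) -> float:
        return (self.lambda_ * raw - math.log(self.K)) / math.log(2)

    def evalue(self, raw: float, m: int, n: int) -> float:
        return m * n * 2.0 ** (-self.bit_score(raw))

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        if self.mode == "protein":
            aligner.substitution_matrix = substitution_matrices.load(self.matrix or "BLOSUM62")
        else:
            aligner.match_score = self.match
            aligner.mismatch_score = self.mismatch
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


@dataclass
class Alignment:
    query_id: str
    subject_id: str
    query_interval: CircularInterval
    subject_interval: CircularInterval
    strand: str
    aligned_length: int
    matches: int
    identity_pct: float
    raw_score: float
    bit_score: float
    evalue: float

    def to_row(self) -> tuple:
        return (self.query_id, self.subject_id, round(self.identity_pct, 2),
                self.aligned_length, round(self.bit_score, 1), f"{self.evalue:.2e}",
                self.query_interval.start, self.query_interval.end,
                self.subject_interval.start, self.subject_interval.end, self.strand)


def _validate(seq: str, scheme: ScoringScheme, label: str) -> str:
    seq = seq.upper()
    alphabet = _NT if scheme.mode == "nucleotide" else _AA
    bad = set(seq) - alphabet
    if bad:
        raise AlphabetError(f"{label} contains characters outside the {scheme.mode} "
                            f"alphabet: {sorted(bad)}")
    return seq


class KmerIndex:
    """Exact k-mer position index of a subject sequence."""

    def __init__(self, seq: str, k: int, max_positions: int = 200):
        self.seq = seq
        self.k = k
        self.max_positions = max_positions
        table: dict[str, list[int]] = {}
        for i in range(len(seq) - k + 1):
            table.setdefault(seq[i:i + k], []).append(i)
        self._table = table

    def lookup(self, kmer: str) -> list[int]:
        hits = self._table.get(kmer, ())
        if len(hits) > self.max_positions:
            return []
        return list(hits)


def _seed_clusters(query: str, index: KmerIndex, band: int = 24,
                   max_seed_gap: int = 250, max_clusters: int = 400):
    """Group seed matches into (q_lo, q_hi, s_lo, s_hi) diagonal clusters."""
    k = index.k
    seeds = []
    for q in range(len(query) - k + 1):
        for s in index.lookup(query[q:q + k]):
            seeds.append((s - q, s, q))
    if not seeds:
        return []
    seeds.sort()
    clusters = []
    cur = None
    for d, s, q in seeds:
        if cur is not None and d - cur[0] <= band and -band <= s - cur[4] <= max_seed_gap:
            cur[2] = min(cur[2], q)
            cur[3] = max(cur[3], q + k)
            cur[4] = max(cur[4], s + k)
            cur[5] = min(cur[5], s)
            cur[6] += 1
        else:
            if cur is not None:
                clusters.append(cur)
            cur = [d, d, q, q + k, s + k, s, 1, q, s]
        cur[1] = d
    clusters.append(cur)
    # two-hit trigger: once any cluster holds multiple seeds, lone background
    # seeds are not worth extending
    if max(c[6] for c in clusters) >= 2:
        clusters = [c for c in clusters if c[6] >= 2]
    clusters.sort(key=lambda c: -c[6])
    out = []
    for d0, d1, q_lo, q_hi, s_hi, s_lo, _count, q0, s0 in clusters[:max_clusters]:
        out.append((q_lo, q_hi, s_lo, s_hi, q0, s0))
    return out


def _ungapped_score(query: str, subject: str, q0: int, s0: int, k: int,
                    match: int, mismatch: int, xdrop: int = 20) -> int:
    """X-drop ungapped extension score around a seed at (q0, s0)."""
    score = k * match
    best = score
    q, s = q0 + k, s0 + k
    while q < len(query) and s < len(subject):
        score += match if query[q] == subject[s] else mismatch
        if score > best:
            best = score
        elif best - score > xdrop:
            break
        q += 1
        s += 1
    score = best
    q, s = q0 - 1, s0 - 1
    while q >= 0 and s >= 0:
        score += match if query[q] == subject[s] else mismatch
        if score > best:
            best = score
        elif best - score > xdrop:
            break
        q -= 1
        s -= 1
    return best


def _columns_and_matches(alignment) -> tuple[int, int]:
    t_blocks, q_blocks = alignment.aligned
    cols = 0
    matches = 0
    prev_t = prev_q = None
    target = alignment.target
    query = alignment.query
    for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks):
        if prev_t is not None:
            cols += (t0 - prev_t) + (q0 - prev_q)
        cols += t1 - t0
        sub_t = target[t0:t1]
        sub_q = query[q0:q1]
        matches += sum(a == b for a, b in zip(sub_t, sub_q))
        prev_t, prev_q = t1, q1
    return cols, matches


def _extend_window(query: str, subject: str, s_lo: int, s_hi: int,
                   q_lo: int, q_hi: int, aligner, slack: int = 60):
    """Run local DP of the full query against a padded subject window."""
    pad_left = q_lo + slack
    pad_right = (len(query) - q_hi) + slack
    w_lo = max(0, s_lo - pad_left)
    w_hi = min(len(subject), s_hi + pad_right)
    window = subject[w_lo:w_hi]
    alignments = aligner.align(window, query)
    # never call len() on the lazy result: counting co-optimal local paths
    # of unrelated sequences can overflow
    if alignments.score <= 0:
        return None
    aln = alignments[0]
    return aln, w_lo


def _build_alignment(aln, w_lo: int, strand: str, query_len: int,
                     query_id: str, subject_id: str, scheme: ScoringScheme,
                     m: int, n: int) -> Optional[Alignment]:
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return None
    cols, matches = _columns_and_matches(aln)
    if cols == 0:
        return None
    s0 = int(t_blocks[0][0]) + w_lo
    s1 = int(t_blocks[-1][1]) + w_lo
    q0 = int(q_blocks[0][0])
    q1 = int(q_blocks[-1][1])
    if strand == "-":
        q0, q1 = query_len - q1, query_len - q0
    raw = float(aln.score)
    return Alignment(
        query_id=query_id, subject_id=subject_id,
        query_interval=CircularInterval(q0 + 1, q1),
        subject_interval=CircularInterval(s0 + 1, s1),
        strand=strand, aligned_length=cols, matches=matches,
        identity_pct=100.0 * matches / cols, raw_score=raw,
        bit_score=scheme.bit_score(raw), evalue=scheme.evalue(raw, m, n))


_DIRECT_DP_LIMIT = 4_000_000  # max m*n for seedless full-matrix fallback
_UNGAPPED_TRIGGER = 40        # min gapless extension score to run the DP


def align_local(query_seq: str, subject_seq: str, scheme: Optional[ScoringScheme] = None,
                query_id: str = "query", subject_id: str = "subject",
                subject_index: Optional[KmerIndex] = None,
                min_raw_score: float = 1.0) -> list[Alignment]:
    """Local alignments of query against subject, best first.

    Nucleotide mode searches both strands.  Overlapping hits are collapsed
    to the best-scoring one.  Returns an empty list when nothing aligns.
    """
    if scheme is None:
        scheme = ScoringScheme.nucleotide()
    query_seq = _validate(query_seq, scheme, "query")
    subject_seq = _validate(subject_seq, scheme, "subject")
    if not query_seq or not subject_seq:
        raise GenomeError("sequences must be non-empty")
    m, n = len(query_seq), len(subject_seq)
    aligner = scheme.make_aligner()
    direct = m * n <= _DIRECT_DP_LIMIT
    if subject_index is None and not direct:
        subject_index = KmerIndex(subject_seq, scheme.seed_k)
    queries = [("+", query_seq)]
    if scheme.mode == "nucleotide":
        rc = reverse_complement(query_seq)
        if rc != query_seq:
            queries.append(("-", rc))
    candidates: list[Alignment] = []
    for strand, qseq in queries:
        if direct:  # small problems: one full-matrix local DP, no seeding
            clusters = [(0, len(qseq), 0, len(subject_seq), None, None)]
        else:
            clusters = _seed_clusters(qseq, subject_index)
        for q_lo, q_hi, s_lo, s_hi, q0, s0 in clusters:
            if q0 is not None:
                # gapless pre-screen: junk clusters never reach the DP
                ungapped = _ungapped_score(qseq, subject_seq, q0, s0,
                                           subject_index.k,
                                           scheme.match if scheme.mode == "nucleotide" else 2,
                                           scheme.mismatch if scheme.mode == "nucleotide" else -2)
                if ungapped < _UNGAPPED_TRIGGER:
                    continue
            res = _extend_window(qseq, subject_seq, s_lo, s_hi, q_lo, q_hi, aligner)
            if res is None:
                continue
            aln, w_lo = res
            built = _build_alignment(aln, w_lo, strand, m, query_id, subject_id, scheme, m, n)
            if built is not None and built.raw_score >= min_raw_score:
                candidates.append(built)
    candidates.sort(key=lambda a: (-a.raw_score, a.subject_interval.start, a.strand))
    kept: list[Alignment] = []
    for cand in candidates:
        redundant = False
        for acc in kept:
            if (cand.subject_interval.overlaps(acc.subject_interval, n)
                    and cand.query_interval.overlaps(acc.query_interval, m)
                    and cand.strand == acc.strand):
                redundant = True
                break
        if not redundant:
            kept.append(cand)
    return kept


def best_hit(query_seq: str, database: Sequence[tuple[str, str]],
             scheme: Optional[ScoringScheme] = None,
             evalue_cutoff: float = 10.0,
             query_id: str = "query",
             indices: Optional[dict[str, KmerIndex]] = None) -> Optional[Alignment]:
    """Best alignment of a query against a database of (id, sequence) records.

    Ordering: bit score desc, then E-value asc, then database order, then
    subject position.  Returns None when the best E-value exceeds the cutoff.
    """
    if scheme is None:
        scheme = ScoringScheme.nucleotide()
    if not database:
        raise GenomeError("database must be non-empty")
    best: Optional[tuple] = None
    for db_idx, (sid, sseq) in enumerate(database):
        idx = indices.get(sid) if indices else None
        for aln in align_local(query_seq, sseq, scheme, query_id=query_id,
                               subject_id=sid, subject_index=idx):
            key = (-aln.bit_score, aln.evalue, db_idx, aln.subject_interval.start)
            if best is None or key < best[0]:
                best = (key, aln)
            break  # align_local returns best-first; only the top hit matters
    if best is None or best[1].evalue > evalue_cutoff:
        return None
    return best[1]


def external_blast_adapter(query_fasta: str, subject_fasta: str,
                           mode: str = "nucleotide",
                           evalue_cutoff: float = 10.0) -> list[Alignment]:
    """Cross-validation path through an installed BLAST+ (optional dependency)."""
    prog = "blastn" if mode == "nucleotide" else "blastp"
    if shutil.which(prog) is None:
        raise GenomeError(f"optional dependency missing: {prog} (BLAST+) is not on PATH")
    scheme = ScoringScheme.nucleotide() if mode == "nucleotide" else ScoringScheme.protein()
    with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as out:
        out_path = out.name
    cmd = [prog, "-query", query_fasta, "-subject", subject_fasta,
           "-evalue", str(evalue_cutoff), "-out", out_path,
           "-outfmt", "6 qseqid sseqid pident length mismatch gapopen qstart qend "
                      "sstart send evalue bitscore score"]
    subprocess.run(cmd, check=True, capture_output=True)
    hits = []
    with open(out_path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 13:
                continue
            qs, qe, ss, se = int(f[6]), int(f[7]), int(f[8]), int(f[9])
            strand = "+"
            if ss > se:
                ss, se = se, ss
                strand = "-"
            length = int(f[3])
            pident = float(f[2])
            raw = float(f[12])
            hits.append(Alignment(
                query_id=f[0], subject_id=f[1],
                query_interval=CircularInterval(qs, qe),
                subject_interval=CircularInterval(ss, se),
                strand=strand, aligned_length=length,
                matches=round(pident * length / 100.0),
                identity_pct=pident, raw_score=raw,
                bit_score=float(f[11]), evalue=float(f[10])))
    return hits
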