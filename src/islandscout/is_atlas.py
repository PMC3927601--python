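"""Insertion-sequence copy mapping and per-region count tables."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .align import Alignment, KmerIndex, ScoringScheme, align_local
from .genome_model import AnnotatedGenome, CircularInterval, GenomeError

__all__ = ["ISFamily", "ISCopy", "map_is_copies", "count_by_region"]


@dataclass(frozen=True)
class ISFamily:
    name: str
    reference_seq: str
    source: str = ""

    def __post_init__(self):
        if len(self.reference_seq) < 100:
            raise ValueError(f"IS family {self.name}: reference shorter than 100 bp")


@dataclass
class ISCopy:
    family: str
    interval: CircularInterval
    strand: str
    identity_pct: float
    evalue: float
    aligned_length: int
    bit_score: float


def _overlap_len(a: CircularInterval, b: CircularInterval, L: int) -> int:
    def spans(iv):
        if iv.wraps:
            return [(iv.start, L), (1, iv.end)]
        return [(iv.start, iv.end)]

    total = 0
    for a0, a1 in spans(a):
        for b0, b1 in spans(b):
            total += max(0, min(a1, b1) - max(a0, b0) + 1)
    return total


def map_is_copies(genome: AnnotatedGenome, families: Sequence[ISFamily],
                  min_len: int = 100, evalue_max: float = 1e-60,
                  scheme: Optional[ScoringScheme] = None) -> list[ISCopy]:
    """Map IS family copies onto a genome.

    Qualifying alignments are >= ``min_len`` bp with E-value <= ``evalue_max``.
    Same-family hits overlapping by more than half of the shorter hit are
    merged (best bit score wins); regions claimed by several families go to
    the best-scoring family.
    """
    usable = []
    for fam in families:
        if len(fam.reference_seq) < min_len:
            warnings.warn(f"IS family {fam.name}: reference shorter than min_len "
                          f"({len(fam.reference_seq)} < {min_len}); skipped")
            continue
        usable.append(fam)
    if not usable:
        raise GenomeError("no usable IS family references")
    if scheme is None:
        scheme = ScoringScheme.nucleotide()
    L = genome.length
    index = KmerIndex(genome.sequence, scheme.seed_k)
    raw_hits: list[tuple[str, Alignment]] = []
    for fam in usable:
        for aln in align_local(fam.reference_seq, genome.sequence, scheme,
                               query_id=fam.name, subject_id=genome.id,
                               subject_index=index):
            if aln.aligned_length >= min_len and aln.evalue <= evalue_max:
                raw_hits.append((fam.name, aln))

    # merge same-family hits overlapping >50% of the shorter hit
    merged: list[tuple[str, Alignment]] = []
    for name, aln in sorted(raw_hits, key=lambda x: -x[1].bit_score):
        absorbed = False
        for m_name, kept in merged:
            if m_name != name:
                continue
            ov = _overlap_len(aln.subject_interval, kept.subject_interval, L)
            shorter = min(aln.subject_interval.length(L), kept.subject_interval.length(L))
            if shorter and ov / shorter > 0.5:
                absorbed = True
                break
        if not absorbed:
            merged.append((name, aln))

    # cross-family conflicts: best bit score claims the region
    final: list[tuple[str, Alignment]] = []
    for name, aln in sorted(merged, key=lambda x: -x[1].bit_score):
        conflict = False
        for f_name, kept in final:
            if f_name == name:
                continue
            ov = _overlap_len(aln.subject_interval, kept.subject_interval, L)
            shorter = min(aln.subject_interval.length(L), kept.subject_interval.length(L))
            if shorter and ov / shorter > 0.5:
                conflict = True
                break
        if not conflict:
            final.append((name, aln))

    copies = [ISCopy(family=name, interval=aln.subject_interval, strand=aln.strand,
                     identity_pct=aln.identity_pct, evalue=aln.evalue,
                     aligned_length=aln.aligned_length, bit_score=aln.bit_score)
              for name, aln in final]
    copies.sort(key=lambda c: c.interval.start)
    return copies


def count_by_region(copies: Sequence[ISCopy],
                    named_regions: Sequence[tuple[str, CircularInterval]],
                    genome_length: int) -> pd.DataFrame:
    """Per-family x per-region copy counts (midpoint rule), plus backbone and totals.

    A copy belongs to the first declared region containing its midpoint;
    copies outside every region count as ``backbone``.
    """
    for i, (name_a, iv_a) in enumerate(named_regions):
        for name_b, iv_b in named_regions[i + 1:]:
            if iv_a.overlaps(iv_b, genome_length):
                warnings.warn(f"regions {name_a} and {name_b} overlap; copies are "
                              "assigned to the first region in declared order")
    region_names = [name for name, _ in named_regions]
    families = sorted({c.family for c in copies})
    counts = {name: {fam: 0 for fam in families} for name in region_names + ["backbone"]}
    for copy in copies:
        mid = copy.interval.midpoint(genome_length)
        for name, iv in named_regions:
            if iv.contains(mid, genome_length):
                counts[name][copy.family] += 1
                break
        else:
            counts["backbone"][copy.family] += 1
    df = pd.DataFrame(counts, index=families)
    df["total"] = df.sum(axis=1)
    df.loc["total"] = df.sum(axis=0)
    return df
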