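"""Three-tier gene-conservation classification against a reference genome.

Tiers, from a gene's best nucleotide alignment to the reference:
  * distinct_identical    - bit score >= 100 and identity > 99%
  * significant_similarity - bit score >= 100 and identity <= 99%
  * no_similarity          - bit score < 100 (or no alignment at all)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .align import Alignment, KmerIndex, ScoringScheme, best_hit
from .genome_model import AnnotatedGenome, CircularInterval, Feature, GenomeError

__all__ = ["ConservationRecord", "IdentityHistogram", "Tier1Locus",
           "classify_genes", "identity_histogram", "cluster_tier1_loci",
           "TIER_DISTINCT", "TIER_SIMILAR", "TIER_NONE"]

TIER_DISTINCT = "distinct_identical"
TIER_SIMILAR = "significant_similarity"
TIER_NONE = "no_similarity"


@dataclass
class ConservationRecord:
    gene_id: str
    tier: str
    best: Optional[Alignment]


@dataclass
class IdentityHistogram:
    edges: np.ndarray
    counts: np.ndarray
    population: int


@dataclass
class Tier1Locus:
    name: str
    interval: CircularInterval
    gene_count: int
    members: list[str]


def _assign_tier(aln: Optional[Alignment], bit_cutoff: float,
                 identity_cutoff: float) -> str:
    if aln is None or aln.bit_score < bit_cutoff:
        return TIER_NONE
    return TIER_DISTINCT if aln.identity_pct > identity_cutoff else TIER_SIMILAR


def classify_genes(gene_features: Sequence[Feature], query_genome: AnnotatedGenome,
                   reference_genome: AnnotatedGenome,
                   scheme: Optional[ScoringScheme] = None,
                   bit_cutoff: float = 100.0,
                   identity_cutoff: float = 99.0) -> list[ConservationRecord]:
    """Best-hit each gene's nucleotide sequence against the full reference."""
    if scheme is None:
        scheme = ScoringScheme.nucleotide()
    index = KmerIndex(reference_genome.sequence, scheme.seed_k)
    database = [(reference_genome.id, reference_genome.sequence)]
    indices = {reference_genome.id: index}
    records = []
    for feat in gene_features:
        seq = query_genome.feature_sequence(feat)
        if not seq:
            raise GenomeError(f"gene {feat.feature_id} has zero length")
        aln = best_hit(seq, database, scheme, evalue_cutoff=float("inf"),
                       query_id=feat.feature_id, indices=indices)
        records.append(ConservationRecord(feat.feature_id,
                                          _assign_tier(aln, bit_cutoff, identity_cutoff),
                                          aln))
    return records


def identity_histogram(records: Sequence[ConservationRecord], n_bins: int = 23,
                       lo: float = 54.0, hi: float = 100.0,
                       bit_cutoff: float = 100.0,
                       population: str = "qualifying") -> IdentityHistogram:
    """Equal-width identity histogram of genes with qualifying alignments.

    ``population`` selects the binned genes: "qualifying" (bit score >= cutoff,
    tiers 1+2 together) or "similar" (tier 2 only).
    """
    if population == "qualifying":
        pool = [r for r in records if r.tier in (TIER_DISTINCT, TIER_SIMILAR)]
    elif population == "similar":
        pool = [r for r in records if r.tier == TIER_SIMILAR]
    else:
        raise ValueError(f"unknown population {population!r}")
    edges = np.linspace(lo, hi, n_bins + 1)
    idents = np.array([r.best.identity_pct for r in pool], dtype=float)
    n_out = int(((idents < lo) | (idents > hi)).sum())
    if n_out:
        warnings.warn(f"{n_out} identity value(s) outside [{lo}, {hi}] clamped to edge bins")
        idents = np.clip(idents, lo, hi)
    counts, _ = np.histogram(idents, bins=edges)
    return IdentityHistogram(edges=edges, counts=counts, population=len(pool))


def cluster_tier1_loci(records: Sequence[ConservationRecord],
                       gene_features: Sequence[Feature], genome_length: int,
                       max_gap: int = 25_000, min_genes: int = 3,
                       name_prefix: str = "Locus") -> list[Tier1Locus]:
    """Single-linkage positional clustering of tier-1 genes on the circle.

    Runs of tier-1 genes whose neighbouring gaps are <= ``max_gap`` merge into
    loci; loci smaller than ``min_genes`` are dropped.  A locus may wrap the
    origin.
    """
    by_id = {f.feature_id: f for f in gene_features}
    tier1 = [(by_id[r.gene_id], r) for r in records
             if r.tier == TIER_DISTINCT and r.gene_id in by_id]
    if not tier1:
        return []
    tier1.sort(key=lambda t: t[0].interval.midpoint(genome_length))
    n = len(tier1)
    if n == 1:
        groups = [[0]]
    else:
        # gap after gene i (to gene i+1, circularly)
        gaps = []
        for i in range(n):
            cur = tier1[i][0].interval
            nxt = tier1[(i + 1) % n][0].interval
            gap = (nxt.start - cur.end - 1) % genome_length
            gaps.append(gap)
        breaks = [i for i, g in enumerate(gaps) if g > max_gap]
        if not breaks:
            groups = [list(range(n))]
        else:
            groups = []
            for j, b in enumerate(breaks):
                start = (breaks[j - 1] + 1) % n
                members = []
                i = start
                while True:
                    members.append(i)
                    if i == b:
                        break
                    i = (i + 1) % n
                groups.append(members)
    loci = []
    for members in groups:
        if len(members) < min_genes:
            continue
        first = tier1[members[0]][0].interval
        last = tier1[members[-1]][0].interval
        start, end = first.start, last.end
        iv = CircularInterval(start, end, wraps=end < start)
        loci.append(Tier1Locus(name="", interval=iv, gene_count=len(members),
                               members=[tier1[i][1].gene_id for i in members]))
    loci.sort(key=lambda l: -l.gene_count)
    for i, locus in enumerate(loci):
        locus.name = f"{name_prefix} {chr(ord('A') + i)}" if i < 26 else f"{name_prefix} {i}"
    return loci
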