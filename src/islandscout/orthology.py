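"""Reciprocal-best-hit orthology, three-way Venn partitioning and
single-linkage protein clustering."""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

from .align import Alignment, KmerIndex, ScoringScheme, align_local, best_hit
from .genome_model import GenomeError

__all__ = ["ProteinSet", "VennPartition", "OrthoCluster",
           "reciprocal_best_hits", "venn_partition", "single_linkage_clusters",
           "read_protein_fasta"]

_REGIONS3 = ("A", "B", "C", "AB", "AC", "BC", "ABC")


@dataclass
class ProteinSet:
    genome_id: str
    proteins: list[tuple[str, str]]  # (locus tag, amino-acid sequence)

    def __post_init__(self):
        tags = [t for t, _ in self.proteins]
        if len(tags) != len(set(tags)):
            raise GenomeError(f"duplicate locus tags in protein set {self.genome_id}")

    def __len__(self) -> int:
        return len(self.proteins)

    def tags(self) -> list[str]:
        return [t for t, _ in self.proteins]


@dataclass
class VennPartition:
    set_ids: tuple[str, str, str]
    region_counts: dict[str, int]               # family-level (non-redundant) counts
    gene_region_counts: dict[str, dict[str, int]]  # per-genome gene accounting
    total_nonredundant: int


@dataclass
class OrthoCluster:
    cluster_id: int
    members: list[tuple[str, str]]  # (genome_id, locus tag)
    single_copy: bool = False


def read_protein_fasta(path: str, genome_id: Optional[str] = None) -> ProteinSet:
    from Bio import SeqIO
    proteins = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]
    return ProteinSet(genome_id or path, proteins)


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _best_hits_one_way(src: ProteinSet, dst: ProteinSet, scheme: ScoringScheme,
                       evalue_max: float,
                       dst_indices: dict[str, KmerIndex]) -> dict[str, str]:
    database = [(tag, seq) for tag, seq in dst.proteins]
    out = {}
    for tag, seq in src.proteins:
        aln = best_hit(seq, database, scheme, evalue_cutoff=evalue_max,
                       query_id=tag, indices=dst_indices)
        if aln is not None:
            out[tag] = aln.subject_id
    return out


def _indices(pset: ProteinSet, k: int) -> dict[str, KmerIndex]:
    return {tag: KmerIndex(seq, k) for tag, seq in pset.proteins}


def reciprocal_best_hits(set_a: ProteinSet, set_b: ProteinSet,
                         evalue_max: float = 1e-4,
                         scheme: Optional[ScoringScheme] = None) -> list[tuple[str, str]]:
    """Ortholog pairs (a, b): mutual best hits with E-value <= cutoff."""
    if not set_a.proteins or not set_b.proteins:
        raise GenomeError("protein sets must be non-empty")
    if scheme is None:
        scheme = ScoringScheme.protein()
    fwd = _best_hits_one_way(set_a, set_b, scheme, evalue_max, _indices(set_b, scheme.seed_k))
    rev = _best_hits_one_way(set_b, set_a, scheme, evalue_max, _indices(set_a, scheme.seed_k))
    pairs = [(a, b) for a, b in fwd.items() if rev.get(b) == a]
    pairs.sort()
    return pairs


def venn_partition(set_a: ProteinSet, set_b: ProteinSet, set_c: ProteinSet,
                   evalue_max: float = 1e-4,
                   scheme: Optional[ScoringScheme] = None) -> VennPartition:
    """Seven-region Venn partition of the non-redundant gene-family union.

    Pairwise RBH graphs are merged; each connected component (gene family)
    is counted once, in the region given by the set of genomes it spans.
    A per-genome gene accounting is reported alongside.
    """
    if scheme is None:
        scheme = ScoringScheme.protein()
    sets = {"A": set_a, "B": set_b, "C": set_c}
    uf = _UnionFind()
    for label, pset in sets.items():
        for tag, _ in pset.proteins:
            uf.find((label, tag))
    for la, lb in combinations("ABC", 2):
        for a, b in reciprocal_best_hits(sets[la], sets[lb], evalue_max, scheme):
            uf.union((la, a), (lb, b))
    components: dict = {}
    for label, pset in sets.items():
        for tag, _ in pset.proteins:
            components.setdefault(uf.find((label, tag)), []).append((label, tag))
    region_counts = {r: 0 for r in _REGIONS3}
    gene_counts = {r: {g: 0 for g in "ABC"} for r in _REGIONS3}
    for members in components.values():
        labels = sorted({m[0] for m in members})
        region = "".join(labels)
        region_counts[region] += 1
        for label, _tag in members:
            gene_counts[region][label] += 1
    return VennPartition(
        set_ids=(set_a.genome_id, set_b.genome_id, set_c.genome_id),
        region_counts=region_counts,
        gene_region_counts=gene_counts,
        total_nonredundant=len(components))


def _pair_qualifies(seq_q: str, seq_s: str, scheme: ScoringScheme,
                    min_identity: float, min_coverage: float,
                    index_s: Optional[KmerIndex]) -> bool:
    alns = align_local(seq_q, seq_s, scheme, subject_index=index_s)
    if not alns:
        return False
    best = alns[0]
    return (best.identity_pct >= min_identity
            and best.aligned_length >= min_coverage * len(seq_q))


def single_linkage_clusters(protein_sets: Sequence[ProteinSet],
                            min_identity: float = 60.0, min_coverage: float = 0.7,
                            scheme: Optional[ScoringScheme] = None) -> list[OrthoCluster]:
    """Transitive closure of qualifying all-vs-all protein links.

    A link requires identity >= ``min_identity`` and an alignment covering at
    least ``min_coverage`` of the query length; either query orientation
    passing suffices.  Clusters with exactly one member per genome are
    flagged ``single_copy``.
    """
    if len(protein_sets) < 2:
        raise GenomeError("need at least two protein sets")
    if scheme is None:
        scheme = ScoringScheme.protein()
    entries = [(ps.genome_id, tag, seq)
               for ps in protein_sets for tag, seq in ps.proteins]
    indices = {(gid, tag): KmerIndex(seq, scheme.seed_k) for gid, tag, seq in entries}
    uf = _UnionFind()
    for gid, tag, _ in entries:
        uf.find((gid, tag))
    for i, (gid_i, tag_i, seq_i) in enumerate(entries):
        for gid_j, tag_j, seq_j in entries[i + 1:]:
            if (_pair_qualifies(seq_i, seq_j, scheme, min_identity, min_coverage,
                                indices[(gid_j, tag_j)])
                    or _pair_qualifies(seq_j, seq_i, scheme, min_identity, min_coverage,
                                       indices[(gid_i, tag_i)])):
                uf.union((gid_i, tag_i), (gid_j, tag_j))
    components: dict = {}
    for gid, tag, _ in entries:
        components.setdefault(uf.find((gid, tag)), []).append((gid, tag))
    n_genomes = len(protein_sets)
    clusters = []
    for cid, members in enumerate(sorted(components.values(), key=lambda m: m[0])):
        genome_ids = [m[0] for m in members]
        single = (len(members) == n_genomes and len(set(genome_ids)) == n_genomes)
        clusters.append(OrthoCluster(cluster_id=cid, members=sorted(members),
                                     single_copy=single))
    return clusters
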