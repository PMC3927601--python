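"""Deterministic synthetic annotated-genome generator with truth ledgers.

Every feature class the pipeline detects can be planted: a bidirectional
GC-skew structure with a terminus motif, tRNA genes, tRNA-anchored islands
(with or without terminal duplications), IS-family copies, protein genes,
and a three-fragment split symbiosis island shared near-identically with a
diverged partner genome.  Output is byte-reproducible for a given spec and
seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genome_model import (AnnotatedGenome, CircularInterval, Feature, GenomeError,
                           reverse_complement)
from .orthology import ProteinSet

__all__ = ["TrnaPlan", "IslandPlan", "ISFamilyPlan", "GenePlan", "SymbiosisPlan",
           "SynthSpec", "SyntheticTruth", "TriplePlan", "generate_pair",
           "generate_triple"]

_BASES = np.array(list("ACGT"))
_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class TrnaPlan:
    name: str
    isotype: str = "Val"
    anticodon: str = "CAC"
    strand: str = "+"
    length: int = 76


@dataclass(frozen=True)
class IslandPlan:
    """One island at an anchor; ``dup_length`` 0 plants a duplication-free,
    low-GC candidate instead of a typical island."""

    anchor: str
    length: int
    dup_length: int
    gc_target: float = 0.52
    integrase: bool = False


@dataclass(frozen=True)
class ISFamilyPlan:
    name: str
    length: int = 800
    copies: int = 0                      # backbone copies
    identity: float = 1.0                # per-copy identity vs the reference


@dataclass(frozen=True)
class GenePlan:
    count: int = 0
    min_len: int = 300
    max_len: int = 3000
    protected_flank: int = 15            # bases at each end shielded from divergence


@dataclass(frozen=True)
class SymbiosisPlan:
    frag_a_len: int = 60_000             # low-GC candidate at the anchor tRNA
    frag_b_len: int = 4_000              # low-GC run beside the distal partial copy
    frag_c_len: int = 20_000             # IS-dense conserved region
    partial_len: int = 45
    partial_strand: str = "-"
    gc_target: float = 0.52
    partner_identity: float = 0.995
    is_in_a: int = 6
    is_in_c: int = 4


@dataclass(frozen=True)
class SynthSpec:
    seed: int = 0
    genome_length: int = 300_000
    background_gc: float = 0.62
    skew_boundaries: tuple[float, float] = (0.1, 0.6)   # fractions (origin, terminus)
    skew_bias: float = 0.05
    dif: bool = True
    trna_catalog: tuple[TrnaPlan, ...] = ()
    island_plans: tuple[IslandPlan, ...] = ()
    is_family_plans: tuple[ISFamilyPlan, ...] = ()
    gene_plan: GenePlan = GenePlan()
    divergence: float = 0.08
    symbiosis_plan: Optional[SymbiosisPlan] = None
    symbiosis_anchor: Optional[str] = None               # tRNA name hosting fragment A


@dataclass
class SyntheticTruth:
    genome_length: int = 0
    skew_origin: Optional[int] = None
    skew_terminus: Optional[int] = None
    dif_motif: Optional[str] = None
    dif_position: Optional[int] = None                   # 1-based start
    trnas: list[dict] = field(default_factory=list)
    islands: list[dict] = field(default_factory=list)
    candidates: list[dict] = field(default_factory=list)
    is_families: dict[str, str] = field(default_factory=dict)
    is_copies: list[dict] = field(default_factory=list)
    genes: list[dict] = field(default_factory=list)
    partial_trnv: Optional[dict] = None
    symbiosis: dict[str, dict] = field(default_factory=dict)
    ortho_families: list[dict] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _mutate(rng: np.random.Generator, seq: str, n_sub: int,
            protected: Sequence[int] = ()) -> tuple[str, int]:
    """Apply exactly n_sub substitutions at distinct unprotected positions."""
    allowed = np.setdiff1d(np.arange(len(seq)), np.asarray(protected, dtype=int))
    n_sub = min(n_sub, len(allowed))
    pos = rng.choice(allowed, size=n_sub, replace=False)
    arr = np.array(list(seq))
    for p in pos:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(3)]
    return "".join(arr), n_sub


def _guard_before(b: "_Builder", trna_seq: str, k: int) -> None:
    """Ensure the base preceding a planted 3'-suffix copy cannot extend the
    match, so detectors recover the planted duplication length exactly."""
    if k >= len(trna_seq) or not b.parts:
        return
    bad = trna_seq[-(k + 1)]
    last = b.parts[-1]
    if last and last[-1] == bad:
        repl = "ACGT"[("ACGT".index(bad) + 1) % 4]
        b.parts[-1] = last[:-1] + repl


class _Builder:
    """Assembles a genome left-to-right, recording coordinates as it goes."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.parts: list[str] = []
        self.cursor = 0  # 0-based length so far

    def append(self, seq: str) -> tuple[int, int]:
        """Append and return the 1-based (start, end) of the segment."""
        start = self.cursor + 1
        self.parts.append(seq)
        self.cursor += len(seq)
        return start, self.cursor

    def sequence(self) -> str:
        return "".join(self.parts)


def _spurious_cleanup(seq: list[str], motifs: Sequence[str],
                      reserved: Sequence[tuple[int, int]],
                      rng: np.random.Generator) -> None:
    """Destroy unplanned occurrences of the given motifs (both strands) by a
    single substitution, never touching reserved (1-based) intervals."""
    text = "".join(seq)
    res = sorted(reserved)

    def is_reserved(p0: int, length: int) -> bool:
        a, b = p0 + 1, p0 + length
        return any(not (b < s or a > e) for s, e in res)

    for motif in motifs:
        for m in {motif, reverse_complement(motif)}:
            start = 0
            while True:
                p = text.find(m, start)
                if p == -1:
                    break
                if not is_reserved(p, len(m)):
                    mid = p + len(m) // 2
                    old = text[mid]
                    new = {"A": "C", "C": "A", "G": "T", "T": "G"}[old]
                    text = text[:mid] + new + text[mid + 1:]
                start = p + 1
    seq[:] = [text]


def _default_catalog() -> tuple[TrnaPlan, ...]:
    return (TrnaPlan("trnV", "Val", "CAC"), TrnaPlan("trnK", "Lys", "CTT"),
            TrnaPlan("trnQ", "Gln", "TTG", strand="-"))


def generate_pair(spec: SynthSpec) -> tuple[AnnotatedGenome, AnnotatedGenome, SyntheticTruth]:
    """Generate (genome A, diverged genome B, truth ledger) for a spec."""
    rng = np.random.default_rng(spec.seed)
    truth = SyntheticTruth()
    catalog = spec.trna_catalog or _default_catalog()
    cat_by_name = {t.name: t for t in catalog}
    for plan in spec.island_plans:
        if plan.anchor not in cat_by_name:
            raise GenomeError(f"island plan anchors unknown tRNA {plan.anchor!r}")
        if plan.dup_length and not (1 <= plan.dup_length < cat_by_name[plan.anchor].length):
            raise GenomeError(f"dup_length {plan.dup_length} outside the tRNA")

    # -- pre-generate planted sequences -------------------------------------
    trna_seqs = {t.name: _random_dna(rng, t.length, 0.55) for t in catalog}
    # IS references are AT-rich, like the island DNA they ride in
    fam_refs = {f.name: _random_dna(rng, f.length, 0.52) for f in spec.is_family_plans}
    truth.is_families = dict(fam_refs)
    dif_motif = "".join(_BASES[rng.integers(4, size=28)]) if spec.dif else None

    # -- plan groups (ordered along the genome) -----------------------------
    # each group: (kind, payload); genes are interleaved between groups
    groups: list[tuple] = []
    plans_by_anchor: dict[str, list[IslandPlan]] = {}
    for plan in spec.island_plans:
        plans_by_anchor.setdefault(plan.anchor, []).append(plan)
    sym = spec.symbiosis_plan
    sym_anchor = spec.symbiosis_anchor or (catalog[0].name if sym else None)
    if sym and plans_by_anchor.get(sym_anchor):
        raise GenomeError("symbiosis anchor cannot also carry island plans")
    for t in catalog:
        groups.append(("trna_group", t))
    if dif_motif:
        groups.append(("dif", dif_motif))
    for f in spec.is_family_plans:
        for i in range(f.copies):
            groups.append(("is_copy", (f, i)))
    if sym:
        groups.append(("partial_group", sym))
        groups.append(("frag_c", sym))
    gene_queue = list(range(spec.gene_plan.count))

    # -- feasibility --------------------------------------------------------
    def group_len(g) -> int:
        kind, payload = g
        if kind == "trna_group":
            t = payload
            n = t.length + sum(p.length for p in plans_by_anchor.get(t.name, []))
            if sym and t.name == sym_anchor:
                n += sym.frag_a_len
            return n
        if kind == "dif":
            return 28
        if kind == "is_copy":
            return payload[0].length
        if kind == "partial_group":
            return payload.partial_len + payload.frag_b_len
        if kind == "frag_c":
            return payload.frag_c_len
        raise AssertionError(kind)

    gene_lens = [int(rng.integers(spec.gene_plan.min_len, spec.gene_plan.max_len + 1))
                 for _ in gene_queue]
    planted = sum(group_len(g) for g in groups) + sum(gene_lens)
    n_gaps = len(groups) + len(gene_lens) + 1
    if planted + n_gaps * 50 > spec.genome_length:
        raise GenomeError(f"infeasible packing: {planted} planted bp plus minimum "
                          f"spacing exceeds genome length {spec.genome_length}")
    backbone_total = spec.genome_length - planted
    gap = backbone_total // n_gaps
    extra = backbone_total - gap * n_gaps

    # -- skew arcs ----------------------------------------------------------
    b_origin = int(spec.skew_boundaries[0] * spec.genome_length)
    b_term = int(spec.skew_boundaries[1] * spec.genome_length)
    truth.skew_origin = b_origin
    truth.skew_terminus = b_term

    def backbone(n: int, start0: int) -> str:
        """Biased background: G-rich on the origin->terminus arc."""
        if n <= 0:
            return ""
        pos = (np.arange(start0, start0 + n)) % spec.genome_length
        in_lead = (pos >= b_origin) & (pos < b_term)
        gc = spec.background_gc
        out = np.empty(n, dtype="<U1")
        for lead, idx in ((True, np.nonzero(in_lead)[0]), (False, np.nonzero(~in_lead)[0])):
            if len(idx) == 0:
                continue
            g = gc / 2 + (spec.skew_bias if lead else -spec.skew_bias)
            c = gc - g
            p = np.array([(1 - gc) / 2, c, g, (1 - gc) / 2])
            out[idx] = _BASES[rng.choice(4, size=len(idx), p=p)]
        return "".join(out)

    # -- assemble -----------------------------------------------------------
    b = _Builder(rng)
    features: list[Feature] = []
    reserved: list[tuple[int, int]] = []  # 1-based intervals exempt from cleanup
    sym_fragments: dict[str, tuple[int, int]] = {}
    is_serial = [0]

    def emit_backbone(n: int) -> None:
        b.append(backbone(n, b.cursor))

    def emit_is_copy(fam: ISFamilyPlan, region: str) -> None:
        ref = fam_refs[fam.name]
        n_sub = round((1.0 - fam.identity) * len(ref))
        seq, realized = _mutate(rng, ref, n_sub)
        start, end = b.append(seq)
        reserved.append((start, end))
        is_serial[0] += 1
        truth.is_copies.append({
            "family": fam.name, "start": start, "end": end, "strand": "+",
            "identity": round(100.0 * (len(ref) - realized) / len(ref), 2),
            "region": region})

    gene_i = 0

    def emit_gene() -> None:
        nonlocal gene_i
        if gene_i >= len(gene_lens):
            return
        n = gene_lens[gene_i]
        seq = _random_dna(rng, n, spec.background_gc)
        start, end = b.append(seq)
        strand = "+" if rng.integers(2) == 0 else "-"
        gid = f"SYN{gene_i:05d}"
        features.append(Feature(gid, "CDS", CircularInterval(start, end), strand,
                                product="hypothetical protein"))
        truth.genes.append({"id": gid, "start": start, "end": end, "strand": strand})
        gene_i += 1

    def emit_island_body(length: int, gc: float, integrase: bool,
                         fams_inside: Sequence[ISFamilyPlan] = (),
                         region_label: str = "island") -> Optional[str]:
        """Low-GC body of given total length; optionally an integrase CDS and
        embedded IS copies (counted into the enclosing region label)."""
        locus = None
        remaining = length
        if integrase:
            int_len = min(900, max(300, length // 4))
            pre = max(0, (remaining - int_len) // 3)
            b.append(_random_dna(rng, pre, gc))
            s, e = b.append(_random_dna(rng, int_len, gc))
            locus = f"INT{len(features):04d}"
            features.append(Feature(locus, "CDS", CircularInterval(s, e), "+",
                                    product="phage integrase"))
            remaining -= pre + int_len
        slots = sum(f.length for f in fams_inside)
        lead = max(0, (remaining - slots) // (len(fams_inside) + 1)) if fams_inside else 0
        for fam in fams_inside:
            if remaining - fam.length < 0:
                break
            b.append(_random_dna(rng, min(lead, remaining - fam.length), gc))
            emit_is_copy(fam, region=region_label)
            remaining -= min(lead, remaining - fam.length) + fam.length
        b.append(_random_dna(rng, remaining, gc))
        return locus

    emit_backbone(gap + extra)
    genes_between = max(1, len(gene_lens) // max(1, len(groups)))
    for g in groups:
        kind, payload = g
        if kind == "trna_group":
            t: TrnaPlan = payload
            seq = trna_seqs[t.name]
            raw = seq if t.strand == "+" else reverse_complement(seq)
            ts, te = b.append(raw)
            reserved.append((ts, te))
            features.append(Feature(t.name, "tRNA", CircularInterval(ts, te), t.strand,
                                    product=f"tRNA-{t.isotype}", anticodon=t.anticodon))
            truth.trnas.append({"name": t.name, "start": ts, "end": te,
                                "strand": t.strand, "seq": seq})
            anchor_plans = plans_by_anchor.get(t.name, [])
            hosts_sym = sym is not None and t.name == sym_anchor
            if t.strand == "-" and (anchor_plans or hosts_sym):
                raise GenomeError("builder plants anchored structures on + tRNAs only; "
                                  "use + strand anchors in island plans")
            boundary = te
            for nesting, plan in enumerate(anchor_plans, 1):
                if plan.dup_length:
                    body_len = plan.length - plan.dup_length
                    integrase_locus = emit_island_body(body_len, plan.gc_target,
                                                       plan.integrase)
                    _guard_before(b, seq, plan.dup_length)
                    dup = seq[-plan.dup_length:]
                    ds, de = b.append(dup)
                    reserved.append((ds, de))
                    truth.islands.append({
                        "anchor": t.name, "start": boundary + 1, "end": de,
                        "dup_start": ds, "dup_end": de,
                        "dup_length": plan.dup_length, "nesting": nesting,
                        "gc_target": plan.gc_target,
                        "integrase_locus": integrase_locus})
                    boundary = de
                else:
                    s0 = b.cursor + 1
                    emit_island_body(plan.length, plan.gc_target, plan.integrase)
                    truth.candidates.append({"anchor": t.name, "start": s0,
                                             "end": b.cursor, "gc_target": plan.gc_target})
                    boundary = b.cursor
            if sym and t.name == sym_anchor:
                s0 = b.cursor + 1
                fams = [dataclasses.replace(f, copies=0)
                        for f in spec.is_family_plans][: 1] * sym.is_in_a
                emit_island_body(sym.frag_a_len, sym.gc_target, False,
                                 fams_inside=fams, region_label="symA")
                sym_fragments["A"] = (s0, b.cursor)
        elif kind == "dif":
            s, e = b.append(payload)
            reserved.append((s, e))
            truth.dif_motif = payload
            truth.dif_position = s
        elif kind == "is_copy":
            fam, _i = payload
            emit_is_copy(fam, region="backbone")
        elif kind == "partial_group":
            sp: SymbiosisPlan = payload
            anchor_seq = trna_seqs[sym_anchor]
            partial = anchor_seq[-sp.partial_len:]
            guard_len = 0
            if sp.partial_strand == "-":
                # descending-coordinate hit; reading-direction extension runs
                # into ascending coordinates, so the guard base follows the copy
                ps, pe = b.append(reverse_complement(partial))
                reserved.append((ps, pe))
                truth.partial_trnv = {"start": pe, "end": ps, "strand": "-",
                                      "length": sp.partial_len}
                if sp.partial_len < len(anchor_seq):
                    bad = reverse_complement(anchor_seq[-(sp.partial_len + 1)])
                    b.append("ACGT"[("ACGT".index(bad) + 1) % 4])
                    guard_len = 1
            else:
                _guard_before(b, anchor_seq, sp.partial_len)
                ps, pe = b.append(partial)
                reserved.append((ps, pe))
                truth.partial_trnv = {"start": ps, "end": pe, "strand": "+",
                                      "length": sp.partial_len}
            s0 = b.cursor + 1
            emit_island_body(sp.frag_b_len - guard_len, sp.gc_target, True)
            sym_fragments["B"] = (s0, b.cursor)
        elif kind == "frag_c":
            sp = payload
            s0 = b.cursor + 1
            fams = [dataclasses.replace(f, copies=0)
                    for f in spec.is_family_plans][: 1] * sp.is_in_c
            emit_island_body(sp.frag_c_len, sp.gc_target, False,
                             fams_inside=fams, region_label="symC")
            sym_fragments["C"] = (s0, b.cursor)
        for _ in range(genes_between):
            if gene_i < len(gene_lens):
                emit_backbone(gap)
                emit_gene()
        emit_backbone(gap)
    while gene_i < len(gene_lens):
        emit_gene()
        emit_backbone(gap)

    seq_parts = [b.sequence()]
    motifs = [trna_seqs[t.name][-14:] for t in catalog]
    if dif_motif:
        motifs.append(dif_motif)
    _spurious_cleanup(seq_parts, motifs, reserved, rng)
    seq_a = seq_parts[0]
    truth.genome_length = len(seq_a)
    for name, (s, e) in sym_fragments.items():
        truth.symbiosis[name] = {"start": s, "end": e}

    genome_a = AnnotatedGenome(id="SYNA", sequence=seq_a, topology="circular",
                               features=[dataclasses.replace(f) for f in features],
                               description="synthetic genome A")

    # -- partner genome: per-site divergence outside protected intervals ----
    protected = set()
    for s, e in reserved:
        protected.update(range(s - 1, e))
    for g in truth.genes:
        flank = spec.gene_plan.protected_flank
        protected.update(range(g["start"] - 1, g["start"] - 1 + flank))
        protected.update(range(g["end"] - flank, g["end"]))
    sym_sites = set()
    for s, e in sym_fragments.values():
        sym_sites.update(range(s - 1, e))
    arr = np.array(list(seq_a))
    u = rng.random(len(arr))
    rate = np.full(len(arr), spec.divergence)
    if sym:
        idx = np.fromiter(sym_sites, dtype=int)
        rate[idx] = 1.0 - sym.partner_identity
    if protected:
        rate[np.fromiter(protected, dtype=int)] = 0.0
    hit = np.nonzero(u < rate)[0]
    for p in hit:
        choices = [c for c in "ACGT" if c != arr[p]]
        arr[p] = choices[rng.integers(3)]
    seq_b = "".join(arr)
    for g in truth.genes:
        s, e = g["start"] - 1, g["end"]
        n = e - s
        same = sum(1 for i in range(s, e) if seq_a[i] == seq_b[i])
        g["identity_in_b"] = round(100.0 * same / n, 3)
    genome_b = AnnotatedGenome(id="SYNB", sequence=seq_b, topology="circular",
                               features=[dataclasses.replace(f) for f in features],
                               description="synthetic genome B")
    return genome_a, genome_b, truth


# ---------------------------------------------------------------------------
# triple generation for orthology tests

@dataclass(frozen=True)
class TriplePlan:
    seed: int = 0
    core: int = 20                      # families in all three sets
    pair_ab: int = 0
    pair_ac: int = 0
    pair_bc: int = 0
    unique: tuple[int, int, int] = (3, 3, 3)
    length_range: tuple[int, int] = (150, 400)
    family_identity: float = 0.7


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(_AA20[rng.integers(20, size=n)])


def _diverge_protein(rng: np.random.Generator, seq: str, identity: float) -> str:
    n_sub = round((1.0 - identity) * len(seq))
    pos = rng.choice(len(seq), size=n_sub, replace=False)
    arr = np.array(list(seq))
    for p in pos:
        choices = [a for a in _AA20 if a != arr[p]]
        arr[p] = choices[rng.integers(len(choices))]
    return "".join(arr)


def generate_triple(plan: TriplePlan) -> tuple[ProteinSet, ProteinSet, ProteinSet, SyntheticTruth]:
    """Three protein sets with planted ortholog families, plus truth."""
    sizes = {"A": plan.core + plan.pair_ab + plan.pair_ac + plan.unique[0],
             "B": plan.core + plan.pair_ab + plan.pair_bc + plan.unique[1],
             "C": plan.core + plan.pair_ac + plan.pair_bc + plan.unique[2]}
    for label, size in sizes.items():
        if size == 0:
            raise GenomeError(f"set {label} would be empty; inconsistent plan")
    rng = np.random.default_rng(plan.seed)
    truth = SyntheticTruth()
    sets: dict[str, list[tuple[str, str]]] = {"A": [], "B": [], "C": []}
    serial = 0

    def plant_family(labels: str) -> None:
        nonlocal serial
        n = int(rng.integers(plan.length_range[0], plan.length_range[1] + 1))
        ancestor = _random_protein(rng, n)
        members = []
        for i, label in enumerate(labels):
            tag = f"{label}_{serial:04d}"
            # first member carries the ancestral sequence so every sibling
            # stays linkable to it at the planted identity
            seq = ancestor if i == 0 else _diverge_protein(rng, ancestor,
                                                           plan.family_identity)
            sets[label].append((tag, seq))
            members.append([label, tag])
        truth.ortho_families.append({"region": labels, "members": members})
        serial += 1

    for _ in range(plan.core):
        plant_family("ABC")
    for _ in range(plan.pair_ab):
        plant_family("AB")
    for _ in range(plan.pair_ac):
        plant_family("AC")
    for _ in range(plan.pair_bc):
        plant_family("BC")
    for label, count in zip("ABC", plan.unique):
        for _ in range(count):
            plant_family(label)
    return (ProteinSet("A", sets["A"]), ProteinSet("B", sets["B"]),
            ProteinSet("C", sets["C"]), truth)
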