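"""Data model and I/O for circular annotated genomes.

Coordinates are 1-based inclusive everywhere in the public API.  Intervals on
a circular chromosome may wrap past the origin; a wrapped interval is
rendered as ``"start-0-end"``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CircularInterval",
    "Feature",
    "AnnotatedGenome",
    "GenomeError",
    "GenomeParseError",
    "GenomeValidationError",
    "read_genome",
    "write_genome",
    "write_fasta",
    "write_gff3",
    "gc_fraction",
    "set_origin_at_site",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


class GenomeError(Exception):
    """Base class for genome model errors."""


class GenomeParseError(GenomeError):
    pass


class GenomeValidationError(GenomeError):
    pass


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CircularInterval:
    """1-based inclusive interval, possibly wrapping the circular origin."""

    start: int
    end: int
    wraps: bool = False

    def __post_init__(self):
        if self.start < 1 or self.end < 1:
            raise GenomeValidationError(
                f"interval coordinates must be >= 1, got {self.start}-{self.end}")
        if not self.wraps and self.end < self.start:
            raise GenomeValidationError(
                f"non-wrapping interval must have end >= start ({self.start}-{self.end})")

    def length(self, genome_length: Optional[int] = None) -> int:
        if self.wraps:
            if genome_length is None:
                raise GenomeValidationError("wrapped interval length needs genome_length")
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1

    def contains(self, pos: int, genome_length: Optional[int] = None) -> bool:
        if self.wraps:
            if genome_length is None:
                raise GenomeValidationError("wrapped interval containment needs genome_length")
            return pos >= self.start or pos <= self.end
        return self.start <= pos <= self.end

    def midpoint(self, genome_length: Optional[int] = None) -> int:
        if self.wraps:
            if genome_length is None:
                raise GenomeValidationError("wrapped interval midpoint needs genome_length")
            m = self.start + self.length(genome_length) // 2
            return ((m - 1) % genome_length) + 1
        return (self.start + self.end) // 2

    def overlaps(self, other: "CircularInterval", genome_length: Optional[int] = None) -> bool:
        def spans(iv):
            if iv.wraps:
                return [(iv.start, genome_length), (1, iv.end)]
            return [(iv.start, iv.end)]

        for a0, a1 in spans(self):
            for b0, b1 in spans(other):
                if a0 <= b1 and b0 <= a1:
                    return True
        return False

    def __str__(self) -> str:
        if self.wraps:
            return f"{self.start}-0-{self.end}"
        return f"{self.start}-{self.end}"


@dataclass
class Feature:
    """A typed annotation on a genome (CDS, tRNA, rRNA or misc)."""

    feature_id: str
    kind: str
    interval: CircularInterval
    strand: str
    product: str = ""
    translation: Optional[str] = None
    anticodon: Optional[str] = None

    def __post_init__(self):
        if self.kind not in ("CDS", "tRNA", "rRNA", "misc"):
            self.kind = "misc"
        if self.strand not in ("+", "-"):
            raise GenomeValidationError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class AnnotatedGenome:
    id: str
    sequence: str
    topology: str = "circular"
    features: list[Feature] = field(default_factory=list)
    description: str = ""

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if self.topology not in ("circular", "linear"):
            raise GenomeValidationError(f"topology must be circular or linear: {self.topology}")
        seen = set()
        for f in self.features:
            if f.feature_id in seen:
                raise GenomeValidationError(f"duplicate locus tag {f.feature_id}")
            seen.add(f.feature_id)
            hi = max(f.interval.start, f.interval.end)
            if hi > len(self.sequence):
                raise GenomeValidationError(
                    f"feature {f.feature_id} interval {f.interval} outside sequence "
                    f"of length {len(self.sequence)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def wrap(self, pos: int) -> int:
        """Reduce a 1-based coordinate modulo the genome length."""
        return ((pos - 1) % self.length) + 1

    def subsequence(self, interval: CircularInterval) -> str:
        s = self.sequence
        if interval.wraps:
            if self.topology != "circular":
                raise GenomeValidationError("wrapped interval on a linear genome")
            return s[interval.start - 1:] + s[:interval.end]
        return s[interval.start - 1:interval.end]

    def feature_sequence(self, feat: Feature) -> str:
        raw = self.subsequence(feat.interval)
        return reverse_complement(raw) if feat.strand == "-" else raw

    def get_feature(self, feature_id: str) -> Feature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(f"no feature with locus tag {feature_id!r}")

    def features_of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]

    def features_in(self, interval: CircularInterval) -> list[Feature]:
        return [f for f in self.features
                if interval.contains(f.interval.midpoint(self.length), self.length)]


# ---------------------------------------------------------------------------
# I/O

_KIND_MAP = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


def _feature_from_seqfeature(sf: SeqFeature, idx: int, genome_length: int) -> Optional[Feature]:
    kind = _KIND_MAP.get(sf.type)
    if kind is None:
        if sf.type in ("gene", "source"):
            return None
        kind = "misc"
    q = sf.qualifiers
    fid = q.get("locus_tag", q.get("gene", [f"feat{idx:05d}"]))[0]
    product = q.get("product", [""])[0]
    translation = q.get("translation", [None])[0]
    anticodon = None
    if kind == "tRNA":
        note = q.get("note", [""])[0]
        anticodon = q.get("anticodon", [note or None])[0]
    loc = sf.location
    start = int(loc.start) + 1
    end = int(loc.end)
    wraps = False
    if len(loc.parts) > 1:
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        if int(parts[-1].end) == genome_length and int(parts[0].start) == 0:
            start = int(parts[-1].start) + 1
            end = int(parts[0].end)
            wraps = True
    if start > genome_length or end > genome_length:
        raise GenomeValidationError(
            f"feature {fid} coordinates {start}-{end} outside sequence length {genome_length}")
    strand = "-" if loc.strand == -1 else "+"
    return Feature(fid, kind, CircularInterval(start, end, wraps), strand,
                   product=product, translation=translation, anticodon=anticodon)


def _read_genbank(path: str) -> AnnotatedGenome:
    try:
        record = SeqIO.read(path, "genbank")
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise GenomeParseError(f"malformed GenBank record in {path}: {exc}") from exc
    topology = record.annotations.get("topology", "circular")
    if topology not in ("circular", "linear"):
        topology = "circular"
    feats = []
    for i, sf in enumerate(record.features):
        f = _feature_from_seqfeature(sf, i, len(record.seq))
        if f is not None:
            feats.append(f)
    return AnnotatedGenome(id=record.id, sequence=str(record.seq), topology=topology,
                           features=feats, description=record.description)


def _parse_gff3_line(line: str, lineno: int) -> Optional[Feature]:
    cols = line.rstrip("\n").split("\t")
    if len(cols) != 9:
        raise GenomeParseError(f"GFF3 line {lineno}: expected 9 columns, got {len(cols)}")
    _, _, ftype, start, end, _, strand, _, attrs = cols
    if ftype in ("region", "gene"):
        return None
    kind = _KIND_MAP.get(ftype, "misc")
    attrd = {}
    for item in attrs.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            attrd[k.strip()] = v.strip()
    fid = attrd.get("locus_tag") or attrd.get("ID") or f"feat{lineno:05d}"
    wraps = attrd.get("wraps", "false").lower() == "true"
    try:
        iv = CircularInterval(int(start), int(end), wraps)
    except ValueError as exc:
        raise GenomeParseError(f"GFF3 line {lineno}: bad coordinates") from exc
    return Feature(fid, kind, iv, strand if strand in "+-" else "+",
                   product=attrd.get("product", ""),
                   translation=attrd.get("translation"),
                   anticodon=attrd.get("anticodon"))


def _read_fasta_gff(fasta_path: str, gff_path: str) -> AnnotatedGenome:
    try:
        record = SeqIO.read(fasta_path, "fasta")
    except Exception as exc:  # noqa: BLE001
        raise GenomeParseError(f"malformed FASTA in {fasta_path}: {exc}") from exc
    topology = "circular"
    if "topology=linear" in record.description:
        topology = "linear"
    feats = []
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = _parse_gff3_line(line, lineno)
            if f is not None:
                feats.append(f)
    return AnnotatedGenome(id=record.id, sequence=str(record.seq), topology=topology,
                           features=feats, description=record.description)


def read_genome(path: str, format: Optional[str] = None,
                features: Optional[str] = None) -> AnnotatedGenome:
    """Read a genome from GenBank, or from FASTA plus a GFF3 feature table.

    ``format`` is inferred from the extension when omitted.  For FASTA input
    pass the GFF3 path via ``features`` (a bare FASTA yields a featureless
    genome).
    """
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = "genbank" if ext in (".gb", ".gbk", ".genbank", ".gbff") else "fasta"
    if format == "genbank":
        return _read_genbank(path)
    if format == "fasta":
        if features:
            return _read_fasta_gff(path, features)
        try:
            record = SeqIO.read(path, "fasta")
        except Exception as exc:  # noqa: BLE001
            raise GenomeParseError(f"malformed FASTA in {path}: {exc}") from exc
        return AnnotatedGenome(id=record.id, sequence=str(record.seq),
                               description=record.description)
    raise GenomeParseError(f"unsupported format {format!r}")


def _to_seqrecord(genome: AnnotatedGenome) -> SeqRecord:
    record = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id.split(".")[0],
                       description=genome.description)
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = genome.topology
    for f in genome.features:
        strand = -1 if f.strand == "-" else 1
        if f.interval.wraps:
            loc = SimpleLocation(f.interval.start - 1, genome.length, strand) + \
                SimpleLocation(0, f.interval.end, strand)
        else:
            loc = SimpleLocation(f.interval.start - 1, f.interval.end, strand)
        quals = {"locus_tag": [f.feature_id]}
        if f.product:
            quals["product"] = [f.product]
        if f.translation:
            quals["translation"] = [f.translation]
        if f.anticodon:
            quals["anticodon"] = [f.anticodon]
        record.features.append(SeqFeature(loc, type=f.kind, qualifiers=quals))
    return record


def write_genome(genome: AnnotatedGenome, path: str) -> None:
    """Write a GenBank flat file."""
    SeqIO.write([_to_seqrecord(genome)], path, "genbank")


def write_fasta(genome: AnnotatedGenome, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id} topology={genome.topology}\n")
        seq = genome.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")


def write_gff3(genome: AnnotatedGenome, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {genome.length}\n")
        for f in genome.features:
            attrs = [f"ID={f.feature_id}", f"locus_tag={f.feature_id}"]
            if f.product:
                attrs.append(f"product={f.product}")
            if f.anticodon:
                attrs.append(f"anticodon={f.anticodon}")
            if f.interval.wraps:
                attrs.append("wraps=true")
            fh.write("\t".join([genome.id, "islandscout", f.kind,
                                str(f.interval.start), str(f.interval.end), ".",
                                f.strand, ".", ";".join(attrs)]) + "\n")


# ---------------------------------------------------------------------------
# Sequence accounting

def gc_fraction(genome: AnnotatedGenome | str,
                interval: Optional[CircularInterval] = None) -> float:
    """GC percentage over a region, to two decimals.

    N (and other ambiguity codes) contribute to neither numerator nor
    denominator.
    """
    if isinstance(genome, AnnotatedGenome):
        seq = genome.subsequence(interval) if interval is not None else genome.sequence
    else:
        seq = genome.upper()
    if not seq:
        raise GenomeValidationError("empty interval for GC computation")
    gc = seq.count("G") + seq.count("C")
    atgc = gc + seq.count("A") + seq.count("T")
    if atgc == 0:
        raise GenomeValidationError("interval contains no unambiguous bases")
    return round(100.0 * gc / atgc, 2)


def _remap(pos: int, shift: int, length: int) -> int:
    return ((pos - 1 - shift) % length) + 1


def set_origin_at_site(genome: AnnotatedGenome, recognition_seq: str,
                       occurrence: int = 1) -> AnnotatedGenome:
    """Rotate a circular genome so numbering starts at a recognition site.

    ``occurrence`` selects which occurrence (1-based, in ascending coordinate
    order) becomes position 1.
    """
    if genome.topology != "circular":
        raise GenomeValidationError("origin can only be moved on a circular genome")
    motif = recognition_seq.upper()
    doubled = genome.sequence + genome.sequence[:len(motif) - 1]
    positions = []
    i = doubled.find(motif)
    while i != -1:
        positions.append(i)
        i = doubled.find(motif, i + 1)
    if not positions:
        raise GenomeValidationError(f"recognition sequence {motif!r} not found in genome")
    if not 1 <= occurrence <= len(positions):
        raise GenomeValidationError(
            f"occurrence {occurrence} out of range (motif occurs {len(positions)} times)")
    shift = positions[occurrence - 1]
    L = genome.length
    seq = genome.sequence[shift:] + genome.sequence[:shift]
    feats = []
    for f in genome.features:
        if f.interval.wraps:
            start0 = f.interval.start
            length = f.interval.length(L)
        else:
            start0 = f.interval.start
            length = f.interval.length()
        new_start = _remap(start0, shift, L)
        new_end = ((new_start - 1 + length - 1) % L) + 1
        wraps = new_end < new_start
        feats.append(replace(f, interval=CircularInterval(new_start, new_end, wraps)))
    return AnnotatedGenome(id=genome.id, sequence=seq, topology="circular",
                           features=feats, description=genome.description)
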