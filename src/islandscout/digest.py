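"""In-silico restriction digestion of circular and linear genomes."""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .genome_model import AnnotatedGenome, CircularInterval, GenomeError, reverse_complement

__all__ = ["Enzyme", "Fragment", "FragmentTable", "ENZYMES",
           "find_sites", "digest", "UnsupportedEnzymeError"]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class UnsupportedEnzymeError(GenomeError):
    pass


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: recognition motif (IUPAC) and top-strand cut offset."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self):
        if len(self.recognition) < 4:
            raise ValueError(f"{self.name}: recognition length must be >= 4")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(f"{self.name}: cut offset outside recognition motif")
        bad = set(self.recognition.upper()) - set(_IUPAC)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC characters {sorted(bad)}")

    @property
    def is_palindromic(self) -> bool:
        r = self.recognition.upper()
        return r.translate(_IUPAC_COMPLEMENT)[::-1] == r

    def regex(self) -> re.Pattern:
        pat = "".join(c if len(_IUPAC[c]) == 1 else f"[{_IUPAC[c]}]"
                      for c in self.recognition.upper())
        return re.compile(f"(?=({pat}))")


#: Enzymes used by the digestion workflows (standard REBASE definitions).
ENZYMES = {
    "PmeI": Enzyme("PmeI", "GTTTAAAC", 4),
    "SwaI": Enzyme("SwaI", "ATTTAAAT", 4),
    "PacI": Enzyme("PacI", "TTAATTAA", 5),
}


def get_enzyme(name: str) -> Enzyme:
    try:
        return ENZYMES[name]
    except KeyError:
        raise KeyError(f"unknown enzyme {name!r}; known: {sorted(ENZYMES)}") from None


@dataclass(frozen=True)
class Fragment:
    interval: CircularInterval
    length: int

    @property
    def length_kb(self) -> int:
        # round half away from zero, as fragment tables conventionally print
        return int(self.length / 1000.0 + 0.5)


@dataclass
class FragmentTable:
    genome_id: str
    enzymes: list[str]
    fragments: list[Fragment]
    total: int
    topology: str = "circular"

    def lengths(self) -> list[int]:
        return [f.length for f in self.fragments]

    def lengths_kb(self) -> list[int]:
        return [f.length_kb for f in self.fragments]

    def to_rows(self) -> list[tuple]:
        return [(rank, f.interval.start, f.interval.end, f.length, f.length_kb)
                for rank, f in enumerate(self.fragments, 1)]


def find_sites(genome: AnnotatedGenome, enzyme: Enzyme) -> list[int]:
    """Return sorted 0-based cut coordinates on the top strand.

    On circular genomes occurrences spanning the origin are found; a cut
    coordinate ``c`` means the phosphodiester bond between 1-based positions
    ``c`` and ``c+1`` is severed (a fragment starts at ``c+1``).
    """
    if genome.length == 0:
        raise GenomeError("cannot digest an empty genome")
    if not enzyme.is_palindromic:
        raise UnsupportedEnzymeError(
            f"{enzyme.name} recognition {enzyme.recognition} is not palindromic; "
            "bottom-strand scanning is not supported")
    seq = genome.sequence
    m = len(enzyme.recognition)
    if genome.topology == "circular":
        scan = seq + seq[:m - 1]
    else:
        scan = seq
    cuts = set()
    for match in enzyme.regex().finditer(scan):
        site_start = match.start()  # 0-based
        cut = site_start + enzyme.cut_offset
        if genome.topology == "circular":
            cut %= genome.length
        cuts.add(cut)
    return sorted(cuts)


def digest(genome: AnnotatedGenome, enzymes: Sequence[Enzyme]) -> FragmentTable:
    """Digest with one or more enzymes and tabulate fragments (sorted, descending)."""
    if not enzymes:
        raise GenomeError("at least one enzyme is required")
    L = genome.length
    cuts = sorted({c for e in enzymes for c in find_sites(genome, e)})
    frags: list[Fragment] = []
    if genome.topology == "circular":
        if not cuts:
            frags.append(Fragment(CircularInterval(1, L), L))
        else:
            for i, c in enumerate(cuts):
                nxt = cuts[(i + 1) % len(cuts)]
                start = c + 1  # 1-based first position of fragment
                if i + 1 < len(cuts):
                    frags.append(Fragment(CircularInterval(start, nxt), nxt - start + 1))
                else:  # final fragment runs through the origin back to the first cut
                    length = (nxt - c) % L or L  # single cut => full-length fragment
                    end = nxt if nxt > 0 else L
                    wraps = end < start
                    frags.append(Fragment(CircularInterval(start, end, wraps), length))
    else:
        bounds = [0] + cuts + [L]
        for a, b in zip(bounds, bounds[1:]):
            if b > a:
                frags.append(Fragment(CircularInterval(a + 1, b), b - a))
    frags.sort(key=lambda f: (-f.length, f.interval.start))
    return FragmentTable(genome_id=genome.id, enzymes=[e.name for e in enzymes],
                         fragments=frags, total=sum(f.length for f in frags),
                         topology=genome.topology)
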