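"""Independent brute-force oracles used to validate the package's fast paths.

These deliberately avoid the implementation's algorithms: digestion uses a
character-stepping scan of the doubled sequence, alignment is a full Gotoh
matrix in pure Python, and counting is done with plain loops.
"""

from __future__ import annotations


def naive_circular_cuts(sequence: str, recognition: str, cut_offset: int) -> list[int]:
    """All cut coordinates by stepping through the doubled sequence."""
    L = len(sequence)
    doubled = sequence + sequence
    cuts = set()
    for i in range(L):
        if doubled[i:i + len(recognition)] == recognition:
            cuts.add((i + cut_offset) % L)
    return sorted(cuts)


def naive_fragment_lengths(sequence: str, enzymes: list[tuple[str, int]]) -> list[int]:
    """Circular fragment length multiset from a naive doubled-sequence scan."""
    L = len(sequence)
    cuts = set()
    for recognition, offset in enzymes:
        cuts.update(naive_circular_cuts(sequence, recognition, offset))
    cuts = sorted(cuts)
    if not cuts:
        return [L]
    lengths = []
    for i in range(len(cuts)):
        nxt = cuts[(i + 1) % len(cuts)]
        lengths.append((nxt - cuts[i]) % L or L)
    return sorted(lengths)


def gc_count(seq: str) -> tuple[int, int]:
    """(gc, unambiguous) by per-base tallying."""
    gc = acgt = 0
    for ch in seq.upper():
        if ch in "GC":
            gc += 1
        if ch in "ACGT":
            acgt += 1
    return gc, acgt


def window_skew(seq: str) -> float:
    g = sum(1 for ch in seq if ch == "G")
    c = sum(1 for ch in seq if ch == "C")
    return 0.0 if g + c == 0 else (g - c) / (g + c)


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[ch] for ch in reversed(seq))


def hamming_hits(sequence: str, motif: str, max_mm: int, circular: bool = True):
    """(pos0, strand, mismatches) for every window within Hamming distance."""
    L = len(sequence)
    m = len(motif)
    doubled = sequence + sequence[:m - 1] if circular else sequence
    n_pos = L if circular else L - m + 1
    out = []
    for strand, probe in (("+", motif), ("-", revcomp(motif))):
        for i in range(n_pos):
            window = doubled[i:i + m]
            mm = sum(1 for a, b in zip(window, probe) if a != b)
            if mm <= max_mm:
                out.append((i, strand, mm))
    return out


def smith_waterman(a: str, b: str, match: int = 2, mismatch: int = -3,
                   gap_open: int = 5, gap_extend: int = 2) -> int:
    """Optimal local alignment score; a length-g gap costs open + g*extend."""
    n, m = len(a), len(b)
    NEG = -10 ** 9
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          F[i - 1][j] - gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def suffix_occurrences(sequence: str, suffix: str, circular: bool = True) -> list[int]:
    """0-based start positions of exact occurrences, wrapping allowed."""
    L = len(sequence)
    doubled = sequence + sequence[:len(suffix) - 1] if circular else sequence
    n_pos = L if circular else L - len(suffix) + 1
    return [i for i in range(n_pos) if doubled[i:i + len(suffix)] == suffix]


class UnionFindOracle:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def groups(self):
        out = {}
        for x in self.parent:
            out.setdefault(self.find(x), []).append(x)
        return sorted(sorted(g) for g in out.values())
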