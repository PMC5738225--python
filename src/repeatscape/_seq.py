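"""Internal sequence helpers: 2-bit-ish encoding, reverse complement, motifs."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_ENC = np.full(256, 4, dtype=np.uint8)  # everything unknown -> 4 (N)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMP = str.maketrans("ACGTN", "TGCAN")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else -> 4, as uint8."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return _DEC[arr].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def revcomp_encoded(arr: np.ndarray) -> np.ndarray:
    out = arr[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def random_sequence(length: int, rng: np.random.Generator, gc: float = 0.44) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return decode(rng.choice(4, size=length, p=p).astype(np.uint8))


# ---------------------------------------------------------------------------
# degenerate motifs
# ---------------------------------------------------------------------------

def parse_degenerate(pattern: str) -> list[frozenset[str]]:
    """Parse a degenerate string into per-position nucleotide sets.

    Accepts IUPAC letters ('WWNNT'), lowercase 'n', and bracket classes
    ('[T/A][T/A]nnT').
    """
    out: list[frozenset[str]] = []
    i = 0
    while i < len(pattern):
        c = pattern[i]
        if c == "[":
            j = pattern.index("]", i)
            letters = [x for x in pattern[i + 1:j] if x.isalpha()]
            out.append(frozenset(letters))
            i = j + 1
        else:
            cu = c.upper()
            if cu not in IUPAC:
                raise ValueError(f"bad motif character {c!r} in {pattern!r}")
            out.append(frozenset(IUPAC[cu]))
            i += 1
    return out


def render_position(allowed: frozenset[str]) -> str:
    """Canonical text for one motif position: letter, [X/Y] class, or 'n'."""
    if len(allowed) == 1:
        return next(iter(allowed))
    if len(allowed) == 4:
        return "n"
    # complementary-pair classes printed T-before-A / G-before-C, else sorted
    order = {"T": 0, "A": 1, "G": 2, "C": 3}
    letters = sorted(allowed, key=lambda x: order[x])
    return "[" + "/".join(letters) + "]"


def matches_at(seq: str, pos: int, motif: list[frozenset[str]]) -> bool:
    """True iff seq[pos:pos+len(motif)] satisfies the motif (in bounds)."""
    if pos < 0 or pos + len(motif) > len(seq):
        return False
    return all(seq[pos + k] in allowed for k, allowed in enumerate(motif))


def sample_instance(motif: list[frozenset[str]], rng: np.random.Generator) -> str:
    return "".join(sorted(allowed)[rng.integers(len(allowed))] for allowed in motif)


def revcomp_motif(motif: list[frozenset[str]]) -> list[frozenset[str]]:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return [frozenset(comp[x] for x in allowed) for allowed in motif[::-1]]


def motifs_equivalent(a: str, b: str) -> bool:
    """Positional-set equality of two degenerate strings ('-' must align)."""
    ta, tb = a.replace("-", "|"), b.replace("-", "|")
    if ta.count("|") != tb.count("|"):
        return False
    sa = [parse_degenerate(x) for x in ta.split("|")]
    sb = [parse_degenerate(x) for x in tb.split("|")]
    return sa == sb
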