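"""Segment-based homology annotation of TEs.

Chromosomes are tiled into short segments (default 180 bp) which are searched
against the reference library; per-segment hits are then merged with two
bridging rules: gaps shorter than ``bridge_gap`` between same-family,
same-strand hits are closed (unless a hit of another family lies in the gap),
and annotations within ``gap_extend`` bp of an assembly N-gap are extended to
the gap edge. Family membership follows the 80/80 rule: >80% identity over
>80% of the shorter sequence.
"""

from __future__ import annotations

import bisect
import logging
import re
import shutil
import subprocess
import tempfile
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from . import _aligner
from .io_formats import (SUPERFAMILY_CODES, FormatError, GenomeAssembly,
                         TEAnnotation, TELibraryEntry)

logger = logging.getLogger("repeatscape")

DEFAULT_SEGMENT_LENGTH = 180
DEFAULT_BRIDGE_GAP = 100
DEFAULT_GAP_EXTEND = 80
DEFAULT_MIN_IDENTITY = 80.0
DEFAULT_MIN_HIT_LENGTH = 50
DEFAULT_END_TOLERANCE = 20


@dataclass(frozen=True)
class SegmentHit:
    """One local alignment between a genome segment and a library consensus.

    ``lib_start``/``lib_end`` are forward-consensus coordinates regardless of
    strand.
    """

    chromosome: str
    segment_index: int
    start: int
    end: int
    family: str
    strand: str
    identity: float
    lib_start: int
    lib_end: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity {self.identity} outside [0,100]")


@dataclass
class MergedAnnotation(TEAnnotation):
    """A TE annotation that remembers the consensus span of its support."""

    lib_min: int = -1
    lib_max: int = -1


@dataclass
class ConsensusBuild:
    family: str
    n_copies: int
    n_columns: int
    consensus: str
    majority_fraction: np.ndarray


def _superfamily(family: str) -> str:
    return SUPERFAMILY_CODES.get(family[:3], "unknown")


# ---------------------------------------------------------------------------
# segmentation + search
# ---------------------------------------------------------------------------

def segment_genome(assembly: GenomeAssembly | Mapping[str, str],
                   segment_length: int = DEFAULT_SEGMENT_LENGTH
                   ) -> list[tuple[str, int, int]]:
    """Tile each chromosome into consecutive segments; the final partial
    segment is retained."""
    if segment_length < 20:
        raise ValueError("segment_length must be >= 20")
    sequences = assembly.sequences if isinstance(assembly, GenomeAssembly) else assembly
    segments = []
    for chrom in sequences:
        n = len(sequences[chrom])
        for s in range(0, n, segment_length):
            segments.append((chrom, s, min(s + segment_length, n)))
    return segments


def search_segments(assembly: GenomeAssembly | Mapping[str, str],
                    library: Sequence[TELibraryEntry],
                    min_identity: float = DEFAULT_MIN_IDENTITY,
                    min_hit_length: int = DEFAULT_MIN_HIT_LENGTH,
                    segment_length: int = DEFAULT_SEGMENT_LENGTH,
                    index: _aligner.LibraryIndex | None = None) -> list[SegmentHit]:
    """Best hit per library family/strand for every genome segment."""
    if not library:
        raise ValueError("library is empty")
    sequences = assembly.sequences if isinstance(assembly, GenomeAssembly) else assembly
    if index is None:
        index = _aligner.build_index(library)
    hits: list[SegmentHit] = []
    for chrom, seq in sequences.items():
        res = _aligner.scan_chromosome(seq, index, segment_length,
                                       min_identity, min_hit_length)
        for seg, fam, minus, gs, ge, ls, le, m, span in res.tolist():
            hits.append(SegmentHit(
                chrom, int(seg), int(gs), int(ge), index.names[fam],
                "-" if minus else "+", 100.0 * m / span, int(ls), int(le)))
    logger.info("search_segments: %d hits over %d chromosomes",
                len(hits), len(sequences))
    return hits


def read_external_hits(path: str | Path, segment_length: int = DEFAULT_SEGMENT_LENGTH
                       ) -> list[SegmentHit]:
    """Adapter for an external aligner's tabular output (BLAST ``-outfmt 6``:
    qseqid sseqid pident length mismatch gapopen qstart qend sstart send ...),
    with query ids of the form ``<chrom>:<segment_start>``."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 10:
                raise FormatError(f"{path}:{lineno}: expected >= 10 tabular fields")
            try:
                chrom, seg_start = f[0].rsplit(":", 1)
                qstart, qend = int(f[6]), int(f[7])
                sstart, send = int(f[8]), int(f[9])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            off = int(seg_start)
            strand = "+" if send >= sstart else "-"
            lo, hi = (sstart, send) if strand == "+" else (send, sstart)
            hits.append(SegmentHit(chrom, off // segment_length,
                                   off + qstart - 1, off + qend, f[1], strand,
                                   float(f[2]), lo - 1, hi))
    return hits


# ---------------------------------------------------------------------------
# merge + bridge
# ---------------------------------------------------------------------------

def merge_and_bridge(hits: Sequence[SegmentHit | TEAnnotation],
                     bridge_gap: int = DEFAULT_BRIDGE_GAP,
                     gap_extend: int = DEFAULT_GAP_EXTEND,
                     assembly_gaps: Mapping[str, Sequence[tuple[int, int]]] | None = None
                     ) -> list[MergedAnnotation]:
    """Combine per-segment hits into TE annotations.

    Same-family same-strand hits are unioned when overlapping/adjacent or when
    separated by a gap strictly shorter than ``bridge_gap`` (gap measured
    end-to-start in half-open coordinates) with no other family's hit inside
    the gap. Annotations within ``gap_extend`` bp of an assembly N-gap are
    extended to the gap edge. Each annotation records the best supporting
    identity.
    """
    by_chrom: dict[str, list] = defaultdict(list)
    for h in hits:
        by_chrom[h.chromosome].append(h)

    out: list[MergedAnnotation] = []
    for chrom in sorted(by_chrom):
        chrom_hits = sorted(by_chrom[chrom], key=lambda h: (h.start, h.end))
        starts = np.array([h.start for h in chrom_hits])
        ends = np.array([h.end for h in chrom_hits])
        fams = np.array([h.family for h in chrom_hits])

        def blocked(gap_start: int, gap_end: int, family: str) -> bool:
            # a different family's hit overlapping the open gap breaks bridging
            lo = np.searchsorted(starts, gap_end)
            cand = (ends[:lo] > gap_start) & (fams[:lo] != family)
            return bool(cand.any())

        groups: dict[tuple[str, str], list] = defaultdict(list)
        for h in chrom_hits:
            groups[(h.family, h.strand)].append(h)

        for (family, strand), ghits in sorted(groups.items()):
            cur_start, cur_end = ghits[0].start, ghits[0].end
            cur_ident = ghits[0].identity
            cur_lmin = getattr(ghits[0], "lib_start", getattr(ghits[0], "lib_min", -1))
            cur_lmax = getattr(ghits[0], "lib_end", getattr(ghits[0], "lib_max", -1))

            def emit():
                out.append(MergedAnnotation(
                    chrom, cur_start, cur_end, family, _superfamily(family),
                    strand, cur_ident, lib_min=cur_lmin, lib_max=cur_lmax))

            for h in ghits[1:]:
                gap = h.start - cur_end
                if gap < bridge_gap and (gap <= 0 or not blocked(cur_end, h.start, family)):
                    cur_end = max(cur_end, h.end)
                    cur_ident = max(cur_ident, h.identity)
                    lmin = getattr(h, "lib_start", getattr(h, "lib_min", -1))
                    lmax = getattr(h, "lib_end", getattr(h, "lib_max", -1))
                    if lmin >= 0:
                        cur_lmin = lmin if cur_lmin < 0 else min(cur_lmin, lmin)
                    if lmax >= 0:
                        cur_lmax = max(cur_lmax, lmax)
                else:
                    emit()
                    cur_start, cur_end, cur_ident = h.start, h.end, h.identity
                    cur_lmin = getattr(h, "lib_start", getattr(h, "lib_min", -1))
                    cur_lmax = getattr(h, "lib_end", getattr(h, "lib_max", -1))
            emit()

    if assembly_gaps:
        _extend_to_assembly_gaps(out, assembly_gaps, gap_extend)
    out.sort(key=lambda a: (a.chromosome, a.start, a.end, a.family))
    logger.info("merge_and_bridge: %d hits -> %d annotations", len(hits), len(out))
    return out


def _extend_to_assembly_gaps(annotations: list[MergedAnnotation],
                             assembly_gaps: Mapping[str, Sequence[tuple[int, int]]],
                             gap_extend: int) -> None:
    gap_starts = {c: [g[0] for g in gs] for c, gs in assembly_gaps.items()}
    gap_ends = {c: [g[1] for g in gs] for c, gs in assembly_gaps.items()}
    for ann in annotations:
        gs = gap_starts.get(ann.chromosome)
        if not gs:
            continue
        ge = gap_ends[ann.chromosome]
        # next N-gap at/after the annotation end
        i = bisect.bisect_left(gs, ann.end)
        if i < len(gs) and 0 <= gs[i] - ann.end <= gap_extend:
            ann.end = gs[i]
        # previous N-gap ending at/before the annotation start
        j = bisect.bisect_right(ge, ann.start) - 1
        if j >= 0 and 0 <= ann.start - ge[j] <= gap_extend:
            ann.start = ge[j]


# ---------------------------------------------------------------------------
# full-length detection
# ---------------------------------------------------------------------------

def detect_full_length(annotations: Sequence[MergedAnnotation],
                       library: Sequence[TELibraryEntry] | Mapping[str, int],
                       end_tolerance: int = DEFAULT_END_TOLERANCE,
                       hits: Sequence[SegmentHit] | None = None
                       ) -> list[MergedAnnotation]:
    """Set intactness flags from how far the supporting alignments reach on
    the consensus (within ``end_tolerance`` bp of either consensus end).

    Consensus spans are taken from the annotations' recorded support; ``hits``
    may be passed to (re)derive spans for annotations lacking them.
    Annotations without support are flagged unknown (None).
    """
    lengths = ({e.name: e.length for e in library}
               if not isinstance(library, Mapping) else dict(library))
    hit_lookup: dict[tuple[str, str, str], list[SegmentHit]] = defaultdict(list)
    if hits:
        for h in hits:
            hit_lookup[(h.chromosome, h.family, h.strand)].append(h)
    for ann in annotations:
        lmin, lmax = ann.lib_min, ann.lib_max
        if lmin < 0 and hits is not None:
            support = [h for h in hit_lookup.get((ann.chromosome, ann.family, ann.strand), [])
                       if h.start < ann.end and h.end > ann.start]
            if support:
                lmin = min(h.lib_start for h in support)
                lmax = max(h.lib_end for h in support)
        if lmin < 0 or ann.family not in lengths:
            ann.five_prime_intact = None
            ann.three_prime_intact = None
            continue
        L = lengths[ann.family]
        ann.five_prime_intact = lmin <= end_tolerance
        ann.three_prime_intact = lmax >= L - end_tolerance
        ann.lib_min, ann.lib_max = lmin, lmax
    return list(annotations)


# ---------------------------------------------------------------------------
# family assignment (80/80)
# ---------------------------------------------------------------------------

def assign_family_80_80(sequence: str,
                        library: Sequence[TELibraryEntry],
                        index: _aligner.LibraryIndex | None = None,
                        min_identity: float = 80.0,
                        min_coverage: float = 0.8) -> str:
    """Best family with >80% identity over >80% of the shorter of (sequence,
    consensus); ``"unassigned"`` when no family qualifies.

    Backed by the built-in aligner run on the whole sequence (one segment);
    coverage is the union of supporting alignment spans on the sequence.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if index is None:
        index = _aligner.build_index(library)
    lengths = {name: index.family_length(i)
               for i, name in enumerate(index.names)}
    hits = search_segments({"q": sequence}, library, min_identity=0.0,
                           min_hit_length=min(len(sequence), 30),
                           segment_length=max(len(sequence), 20), index=index)
    per_family: dict[str, list[SegmentHit]] = defaultdict(list)
    for h in hits:
        per_family[h.family].append(h)
    best: tuple[float, str] | None = None
    for family, fhits in per_family.items():
        ivals = sorted((h.start, h.end) for h in fhits)
        covered, hi = 0, -1
        matches = span = 0
        for s, e in ivals:
            covered += max(0, e - max(s, hi))
            hi = max(hi, e)
        for h in fhits:
            span += h.end - h.start
            matches += round(h.identity * (h.end - h.start) / 100.0)
        identity = 100.0 * matches / span if span else 0.0
        shorter = min(len(sequence), lengths[family])
        if identity > min_identity and covered > min_coverage * shorter:
            key = (identity, family)
            if best is None or identity > best[0] or \
                    (identity == best[0] and family < best[1]):
                best = key
    return best[1] if best else "unassigned"


# ---------------------------------------------------------------------------
# consensus construction
# ---------------------------------------------------------------------------

def _mafft_align(seqs: Sequence[str]) -> list[str]:
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft not found on PATH and copies are not "
                           "pre-aligned (unequal lengths)")
    with tempfile.TemporaryDirectory() as tmp:
        fa = Path(tmp) / "in.fa"
        with open(fa, "w") as fh:
            for i, s in enumerate(seqs):
                fh.write(f">s{i}\n{s}\n")
        res = subprocess.run(["mafft", "--quiet", "--retree", "2", str(fa)],
                             capture_output=True, text=True, check=True)
    aligned: dict[str, str] = {}
    name = None
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].strip()
            aligned[name] = ""
        elif name:
            aligned[name] += line.strip().upper()
    return [aligned[f"s{i}"] for i in range(len(seqs))]


def build_consensus(copies: Sequence[str], family: str = "consensus",
                    min_copies: int = 3, max_copies: int = 100) -> ConsensusBuild:
    """Majority-rule consensus of a multiple alignment of full-length copies.

    Copies of equal length are treated as pre-aligned columns; otherwise they
    are aligned with mafft. Gap-majority columns are dropped; nucleotide ties
    within a column are broken by overall frequency across the alignment,
    then alphabetically.
    """
    if len(copies) < min_copies:
        raise ValueError(f"need at least {min_copies} copies, got {len(copies)}")
    copies = list(copies)[:max_copies]
    if len({len(c) for c in copies}) > 1:
        rows = _mafft_align(copies)
    else:
        rows = [c.upper() for c in copies]
    mat = np.array([list(r) for r in rows])
    n, ncol = mat.shape
    alphabet = np.array(["A", "C", "G", "T", "N", "-"])
    counts = np.stack([(mat == a).sum(axis=0) for a in alphabet])  # 6 x ncol
    global_freq = counts[:4].sum(axis=1)

    cons_chars: list[str] = []
    majority: list[float] = []
    for j in range(ncol):
        col = counts[:, j]
        if col[5] > n - col[5]:
            continue  # gap-majority column dropped
        nuc = col[:4]
        top = nuc.max()
        if top == 0:
            cons_chars.append("N")
            majority.append(0.0)
            continue
        tied = np.flatnonzero(nuc == top)
        if len(tied) > 1:
            gsub = global_freq[tied]
            tied = tied[gsub == gsub.max()]
        pick = tied[0]  # alphabet is alphabetical already
        cons_chars.append(alphabet[pick])
        majority.append(top / n)
    return ConsensusBuild(family, len(copies), ncol, "".join(cons_chars),
                          np.array(majority))


# ---------------------------------------------------------------------------
# autonomy classification
# ---------------------------------------------------------------------------

def classify_autonomy(consensus: str, min_orf_codons: int = 300) -> str:
    """``"autonomous"`` iff any of the six reading frames contains an intact
    ORF (ATG .. stop) of at least ``min_orf_codons`` codons."""
    if not consensus:
        raise ValueError("empty consensus")
    seq = consensus.upper()
    pattern = re.compile(r"M[^*]{%d,}\*" % (min_orf_codons - 1))
    for strand_seq in (seq, str(Seq(seq).reverse_complement())):
        for frame in range(3):
            sub = strand_seq[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            protein = str(Seq(sub).translate())
            if pattern.search(protein):
                return "autonomous"
    return "non-autonomous"


# ---------------------------------------------------------------------------
# convenience pipeline
# ---------------------------------------------------------------------------

def annotate_genome(assembly: GenomeAssembly,
                    library: Sequence[TELibraryEntry],
                    segment_length: int = DEFAULT_SEGMENT_LENGTH,
                    min_identity: float = DEFAULT_MIN_IDENTITY,
                    min_hit_length: int = DEFAULT_MIN_HIT_LENGTH,
                    bridge_gap: int = DEFAULT_BRIDGE_GAP,
                    gap_extend: int = DEFAULT_GAP_EXTEND,
                    end_tolerance: int = DEFAULT_END_TOLERANCE
                    ) -> tuple[list[MergedAnnotation], list[SegmentHit]]:
    """segment -> search -> merge/bridge -> intactness, in one call."""
    hits = search_segments(assembly, library, min_identity, min_hit_length,
                           segment_length)
    annotations = merge_and_bridge(hits, bridge_gap, gap_extend, assembly.gaps)
    detect_full_length(annotations, library, end_tolerance)
    return annotations, hits
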