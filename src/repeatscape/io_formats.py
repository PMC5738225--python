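"""Domain types and readers/writers for the standard formats the pipeline touches.

Conventions
-----------
* In-memory coordinates are **0-based, half-open** everywhere.
* On disk, GFF3 is 1-based inclusive and the methylation table carries
  1-based positions; the converters here are mutually inverse.
* Genome sequences are canonicalized to uppercase A/C/G/T/N; other IUPAC
  ambiguity codes are mapped to N with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("repeatscape")

#: valid three-letter superfamily prefixes of library entry names
SUPERFAMILY_CODES: Mapping[str, str] = {
    "RLC": "Copia",
    "RLG": "Gypsy",
    "RLX": "LTR-unknown",
    "RIX": "LINE",
    "RSX": "SINE",
    "DTC": "CACTA",
    "DTT": "Mariner",
    "DTH": "Harbinger",
    "DHH": "Helitron",
    "XXX": "unknown",
}

#: TE class (1 = retrotransposon, 2 = DNA transposon) per superfamily code
CODE_TO_CLASS: Mapping[str, int] = {
    "RLC": 1, "RLG": 1, "RLX": 1, "RIX": 1, "RSX": 1,
    "DTC": 2, "DTT": 2, "DTH": 2, "DHH": 2, "XXX": 2,
}

VALID_CONTEXTS = ("CG", "CHG", "CHH")

_CANONICAL = set("ACGTN")


class FormatError(ValueError):
    """Raised on malformed input files; the message names the offending line."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeAssembly:
    """A set of chromosome sequences plus derived assembly-gap intervals.

    ``gaps`` maps chromosome name to a sorted list of half-open intervals
    covering the maximal runs of N.
    """

    sequences: dict[str, str]
    gaps: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gaps:
            self.gaps = {name: _n_runs(seq) for name, seq in self.sequences.items()}

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass(frozen=True)
class GeneModel:
    """A gene interval; TSS/TES fall out of the strand."""

    id: str
    chromosome: str
    start: int
    end: int
    strand: str
    confidence: str = "HC1"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gene interval [{self.start},{self.end}) for {self.id}")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.id}: strand must be + or -")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class TELibraryEntry:
    """A reference (consensus) TE sequence; the name's three-letter prefix
    encodes the superfamily (TREP-style nomenclature)."""

    name: str
    sequence: str
    autonomous: bool = False

    def __post_init__(self) -> None:
        code = self.name[:3]
        if code not in SUPERFAMILY_CODES or (len(self.name) > 3 and self.name[3] != "_"):
            raise ValueError(
                f"library entry {self.name!r}: name must start with a three-letter "
                f"superfamily code from {sorted(SUPERFAMILY_CODES)} followed by '_'"
            )

    @property
    def code(self) -> str:
        return self.name[:3]

    @property
    def superfamily(self) -> str:
        return SUPERFAMILY_CODES[self.code]

    @property
    def te_class(self) -> int:
        return CODE_TO_CLASS[self.code]

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class TEAnnotation:
    """A located TE copy on the genome."""

    chromosome: str
    start: int
    end: int
    family: str
    superfamily: str
    strand: str
    identity: float = 100.0
    five_prime_intact: bool | None = None
    three_prime_intact: bool | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"TE interval [{self.start},{self.end}) is empty")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity {self.identity} outside [0,100]")

    @property
    def complete(self) -> bool:
        return bool(self.five_prime_intact) and bool(self.three_prime_intact)

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MethylationCall:
    """One cytosine site: counts of methylated (#C) and unmethylated (#T) reads."""

    chromosome: str
    position: int
    strand: str
    context: str
    methylated: int
    total: int

    def __post_init__(self) -> None:
        if self.context not in VALID_CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.methylated < 0 or self.total < 0 or self.methylated > self.total:
            raise ValueError(
                f"bad counts at {self.chromosome}:{self.position}: "
                f"methylated={self.methylated} total={self.total}"
            )

    @property
    def unmethylated(self) -> int:
        return self.total - self.methylated


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _n_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal runs of N as sorted, disjoint half-open intervals."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_n = arr == ord("N")
    if not is_n.any():
        return []
    d = np.diff(is_n.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if is_n[0]:
        starts = np.insert(starts, 0, 0)
    if is_n[-1]:
        ends = np.append(ends, len(seq))
    return list(zip(starts.tolist(), ends.tolist()))


def _canonicalize(seq: str, name: str) -> str:
    seq = seq.upper()
    extra = set(seq) - _CANONICAL
    if extra:
        logger.warning("record %s: mapping ambiguity codes %s to N", name, sorted(extra))
        seq = seq.translate(str.maketrans({c: "N" for c in extra}))
    return seq


def read_fasta(path: str | Path) -> GenomeAssembly:
    """Read a FASTA file into a :class:`GenomeAssembly`."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = _canonicalize(str(rec.seq), rec.id)
    if not records:
        raise FormatError(f"{path}: no records")
    logger.info("read_fasta: %d records from %s", len(records), path)
    return GenomeAssembly(records)


def write_fasta(assembly: GenomeAssembly | Mapping[str, str], path: str | Path,
                width: int = 80) -> None:
    sequences = assembly.sequences if isinstance(assembly, GenomeAssembly) else assembly
    recs = (SeqRecord(Seq(s), id=n, description="") for n, s in sequences.items())
    SeqIO.write(recs, str(path), "fasta")


def read_te_library(path: str | Path, autonomy: Mapping[str, bool] | None = None
                    ) -> list[TELibraryEntry]:
    """Read a TE reference library FASTA; names must carry three-letter codes."""
    assembly = read_fasta(path)
    autonomy = autonomy or {}
    return [TELibraryEntry(n, s, autonomous=autonomy.get(n, False))
            for n, s in assembly.sequences.items()]


def write_te_library(library: Iterable[TELibraryEntry], path: str | Path) -> None:
    write_fasta({e.name: e.sequence for e in library}, path)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------
# Reading is hand-parsed (plain 9-column TSV) so that the row-level accept/
# reject policy below can be applied; gffutils' transactional DB build does
# not expose per-row recovery.

def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3_genes(path: str | Path, feature_types: tuple[str, ...] = ("gene",)
                    ) -> list[GeneModel]:
    """Read gene features from GFF3 into 0-based half-open :class:`GeneModel`.

    Records with missing strand ('.' or '?') are rejected with a warning;
    ``end < start`` is a parse error.
    """
    genes: list[GeneModel] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in feature_types:
                continue
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise FormatError(f"{path}:{lineno}: end < start")
            if strand not in "+-":
                logger.warning("%s:%d: gene without strand rejected", path, lineno)
                skipped += 1
                continue
            a = _parse_attributes(attrs)
            gid = a.get("ID", f"gene{lineno}")
            genes.append(GeneModel(gid, chrom, start_i - 1, end_i, strand,
                                   confidence=a.get("confidence", "HC1")))
    logger.info("read_gff3_genes: %d genes (%d rejected) from %s", len(genes), skipped, path)
    return genes


def write_gff3_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.id};confidence={g.confidence}"
            fh.write(f"{g.chromosome}\trepeatscape\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")


def read_gff3_te(path: str | Path) -> list[TEAnnotation]:
    """Read TE annotations written by :func:`write_gff3_te`."""
    out: list[TEAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _src, ftype, start, end, score, strand, _phase, attrs = fields
            if ftype != "transposable_element":
                continue
            a = _parse_attributes(attrs)
            flags = {"true": True, "false": False, "unknown": None}
            out.append(TEAnnotation(
                chrom, int(start) - 1, int(end),
                family=a["family"], superfamily=a.get("superfamily", "unknown"),
                strand=strand if strand in "+-" else "+",
                identity=float(score) if score != "." else 100.0,
                five_prime_intact=flags[a.get("five_prime_intact", "unknown")],
                three_prime_intact=flags[a.get("three_prime_intact", "unknown")],
            ))
    return out


def write_gff3_te(annotations: Iterable[TEAnnotation], path: str | Path) -> None:
    def flag(v: bool | None) -> str:
        return "unknown" if v is None else ("true" if v else "false")

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, t in enumerate(annotations):
            attrs = (f"ID=te{i};family={t.family};superfamily={t.superfamily};"
                     f"five_prime_intact={flag(t.five_prime_intact)};"
                     f"three_prime_intact={flag(t.three_prime_intact)}")
            fh.write(f"{t.chromosome}\trepeatscape\ttransposable_element\t"
                     f"{t.start + 1}\t{t.end}\t{t.identity:.1f}\t{t.strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# methylation table
# ---------------------------------------------------------------------------

METHYLATION_COLUMNS = ["chromosome", "position", "strand", "context",
                       "methylated", "total"]


def read_methylation_table(path: str | Path) -> pd.DataFrame:
    """Read a per-cytosine call table (tab-separated, header line required).

    Columns: chromosome, position (1-based on disk), strand, context,
    methylated, total. Positions are converted to 0-based. Rows with
    total == 0 are retained. Returns a DataFrame in call-table layout; use
    :func:`calls_from_frame` for dataclass records.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = [c for c in METHYLATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if len(df):
        bad = df[~df["context"].isin(VALID_CONTEXTS)]
        if len(bad):
            raise FormatError(f"{path}: unknown context {bad['context'].iloc[0]!r} "
                              f"at row {bad.index[0] + 2}")
        over = df[df["methylated"] > df["total"]]
        if len(over):
            raise FormatError(f"{path}: methylated > total at row {over.index[0] + 2}")
        if (df[["methylated", "total"]] < 0).any().any():
            raise FormatError(f"{path}: negative counts")
    df = df.copy()
    df["position"] = df["position"].astype(np.int64) - 1
    logger.info("read_methylation_table: %d calls from %s", len(df), path)
    return df


def write_methylation_table(calls: pd.DataFrame | Sequence[MethylationCall],
                            path: str | Path) -> None:
    df = frame_from_calls(calls) if not isinstance(calls, pd.DataFrame) else calls
    out = df.copy()
    out["position"] = out["position"] + 1
    out.to_csv(path, sep="\t", index=False, columns=METHYLATION_COLUMNS)


def calls_from_frame(df: pd.DataFrame) -> list[MethylationCall]:
    return [MethylationCall(r.chromosome, int(r.position), r.strand, r.context,
                            int(r.methylated), int(r.total))
            for r in df.itertuples(index=False)]


def frame_from_calls(calls: Sequence[MethylationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.chromosome, c.position, c.strand, c.context, c.methylated, c.total)
         for c in calls],
        columns=METHYLATION_COLUMNS,
    )


# ---------------------------------------------------------------------------
# BED + centromere sidecar + flat config
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[tuple[str, int, int, str]], path: str | Path) -> None:
    """Write (chrom, start, end, name) tuples as BED (0-based half-open on disk)."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED fields")
            out.append((f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else "."))
    return out


def write_centromeres(centromeres: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chromosome\tcentromere\n")
        for chrom, pos in centromeres.items():
            fh.write(f"{chrom}\t{pos}\n")


def read_centromeres(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return dict(zip(df["chromosome"], df["centromere"].astype(int)))


def read_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` text config; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected 'key = value'")
            k, v = line.split("=", 1)
            out[k.strip()] = v.strip()
    return out
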