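"""Genome-wide TE abundance statistics.

Copy numbers from occupied bp / consensus length, genome fractions,
chromosomal bin distributions (occupied kb per bin), terminal-arm enrichment,
and per-chromosome abundance contrasts. Count-based statistics use copy
midpoints; occupied-kb statistics use bp overlap.

A reference abundance table for the high-copy barley TE families (TREP
nomenclature) ships in ``data/barley_te_families.tsv`` with columns
family, superfamily, block, total_kb, consensus_bp, reported_copies.
"""

from __future__ import annotations

import math
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import TEAnnotation

DEFAULT_BIN_SIZE = 30_000_000


def load_barley_reference_table() -> pd.DataFrame:
    """The bundled barley high-copy family abundance table."""
    with resources.files("repeatscape.data").joinpath(
            "barley_te_families.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def estimate_copy_number(total_bp: float, consensus_length: int) -> int:
    """Total annotated bp divided by consensus length, rounded half away
    from zero."""
    if consensus_length <= 0:
        raise ValueError("consensus_length must be > 0")
    if total_bp < 0:
        raise ValueError("total_bp must be >= 0")
    return int(math.floor(total_bp / consensus_length + 0.5))


def _group_key(group_by: str):
    if group_by not in ("family", "superfamily", "class"):
        raise ValueError("group_by must be family, superfamily, or class")
    if group_by == "class":
        from .io_formats import CODE_TO_CLASS
        return lambda a: CODE_TO_CLASS.get(a.family[:3], 2)
    return lambda a: getattr(a, group_by)


def genome_fraction(annotations: Sequence[TEAnnotation], genome_length: int,
                    group_by: str = "family") -> pd.Series:
    """Percent of the genome occupied per group. Overlapping annotations of
    different families each count their own bp."""
    if genome_length <= 0:
        raise ValueError("genome_length must be > 0")
    key = _group_key(group_by)
    acc: dict = {}
    for a in annotations:
        acc[key(a)] = acc.get(key(a), 0) + a.span
    return pd.Series({g: 100.0 * bp / genome_length for g, bp in sorted(
        acc.items(), key=lambda kv: str(kv[0]))}, dtype=float, name="percent")


def bin_distribution(annotations: Sequence[TEAnnotation],
                     chromosome_lengths: Mapping[str, int],
                     bin_size: int = DEFAULT_BIN_SIZE) -> pd.DataFrame:
    """Occupied kb per (family, chromosome, bin); annotation bp apportioned
    to bins by overlap, so per-family kb is conserved."""
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    rows = []
    for a in annotations:
        b0 = a.start // bin_size
        b1 = (a.end - 1) // bin_size
        for b in range(b0, b1 + 1):
            lo = max(a.start, b * bin_size)
            hi = min(a.end, (b + 1) * bin_size)
            rows.append((a.family, a.chromosome, b, hi - lo))
    df = pd.DataFrame(rows, columns=["family", "chromosome", "bin", "bp"])
    if not len(df):
        return pd.DataFrame(columns=["family", "chromosome", "bin", "kb"])
    out = (df.groupby(["family", "chromosome", "bin"], as_index=False)["bp"]
             .sum())
    out["kb"] = out.pop("bp") / 1000.0
    # carry empty bins so bin matrices are rectangular per chromosome
    full = []
    for chrom, length in chromosome_lengths.items():
        nbins = (length + bin_size - 1) // bin_size
        for fam in out["family"].unique():
            base = pd.DataFrame({"family": fam, "chromosome": chrom,
                                 "bin": np.arange(nbins), "kb": 0.0})
            full.append(base)
    grid = pd.concat(full, ignore_index=True)
    merged = (grid.merge(out, on=["family", "chromosome", "bin"], how="left",
                         suffixes=("_zero", ""))
                  .assign(kb=lambda d: d["kb"].fillna(d["kb_zero"]))
                  .drop(columns="kb_zero"))
    return merged.sort_values(["family", "chromosome", "bin"]).reset_index(drop=True)


def terminal_arm_enrichment(annotations: Sequence[TEAnnotation],
                            centromeres: Mapping[str, int],
                            chromosome_lengths: Mapping[str, int],
                            terminal_fraction: float = 0.2) -> pd.Series:
    """Per family, the fraction of copies (by midpoint) lying in the distal
    ``terminal_fraction`` of either chromosome arm. Families with no copies
    are reported as NaN (missing)."""
    for chrom, c in centromeres.items():
        if chrom in chromosome_lengths and not 0 < c < chromosome_lengths[chrom]:
            raise ValueError(f"centromere of {chrom} outside the chromosome")
    counts: dict[str, int] = {}
    terminal: dict[str, int] = {}
    for a in annotations:
        c = centromeres[a.chromosome]
        length = chromosome_lengths[a.chromosome]
        mid = a.midpoint
        counts[a.family] = counts.get(a.family, 0) + 1
        if mid < c:  # short arm [0, c): telomere at 0
            is_term = mid < terminal_fraction * c
        else:        # long arm [c, length): telomere at length
            is_term = mid >= length - terminal_fraction * (length - c)
        terminal[a.family] = terminal.get(a.family, 0) + int(is_term)
    fams = sorted(counts)
    return pd.Series({f: terminal[f] / counts[f] if counts[f] else np.nan
                      for f in fams}, dtype=float, name="terminal_fraction")


def per_chromosome_abundance(annotations: Sequence[TEAnnotation]
                             ) -> tuple[pd.DataFrame, pd.Series]:
    """(family x chromosome occupied-kb matrix, per-family max/min chromosome
    ratio). The ratio is NaN when the family is absent from any chromosome."""
    rows = [(a.family, a.chromosome, a.span) for a in annotations]
    df = pd.DataFrame(rows, columns=["family", "chromosome", "bp"])
    if not len(df):
        return pd.DataFrame(), pd.Series(dtype=float)
    mat = (df.pivot_table(index="family", columns="chromosome", values="bp",
                          aggfunc="sum", fill_value=0.0) / 1000.0)
    ratio = pd.Series(
        {fam: (row.max() / row.min() if row.min() > 0 else np.nan)
         for fam, row in mat.iterrows()}, dtype=float, name="max_min_ratio")
    return mat, ratio


def copy_number_table(annotations: Sequence[TEAnnotation],
                      consensus_lengths: Mapping[str, int]) -> pd.DataFrame:
    """Per-family total occupied bp and copy-number estimate."""
    totals: dict[str, int] = {}
    supers: dict[str, str] = {}
    for a in annotations:
        totals[a.family] = totals.get(a.family, 0) + a.span
        supers[a.family] = a.superfamily
    rows = []
    for fam in sorted(totals):
        L = consensus_lengths.get(fam)
        rows.append({
            "family": fam, "superfamily": supers[fam],
            "total_kb": totals[fam] / 1000.0, "consensus_bp": L,
            "copy_number": estimate_copy_number(totals[fam], L) if L else None})
    return pd.DataFrame(rows)
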