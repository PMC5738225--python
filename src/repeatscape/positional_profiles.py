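"""TSS/TES-anchored TE frequency profiles, Gypsy:Copia ratio curves, and
target-site nucleotide composition.

Profiles sample every ``step``-th bp over a ``flank``-bp window on the
biological upstream/downstream side of each gene; at each sampled position
the covering alignment with the longest span wins (ties broken by higher
identity, then lexicographic name). Offset 0 (the anchor base itself) is
excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _seq
from .io_formats import GeneModel, GenomeAssembly, TEAnnotation

logger = logging.getLogger("repeatscape")

DEFAULT_FLANK = 10_000
DEFAULT_STEP = 20
DEFAULT_TSD_FLANK = 30


@dataclass
class AnchoredProfile:
    """Per-offset group frequencies around TSS or TES anchors.

    ``frequencies`` is indexed by offset (bp from the anchor base, always
    positive, growing away from the gene) with one column per group;
    ``valid`` counts the genes contributing at each offset.
    """

    anchor: str
    frequencies: pd.DataFrame
    valid: pd.Series

    @property
    def offsets(self) -> np.ndarray:
        return self.frequencies.index.to_numpy()


@dataclass
class TargetSiteMatrix:
    """Per-position A/C/G/T fractions in the 30 bp flanks of complete copies.

    Positions -flank..-1 are upstream of the element's 5' boundary and
    1..flank downstream of its 3' boundary, in element orientation.
    """

    fractions: pd.DataFrame  # index: position, columns A,C,G,T
    n_counts: pd.Series      # non-N observations per position
    n_skipped_n: pd.Series   # N observations per position
    n_copies: int


# ---------------------------------------------------------------------------
# anchored profiles
# ---------------------------------------------------------------------------

def _paint_winners(items: Sequence, chrom: str, length: int,
                   group_of: Callable[[str], str | None],
                   group_index: Mapping[str, int]) -> np.ndarray:
    """Per-position winning group over one chromosome; longest span wins,
    then identity, then lexicographically smaller family name."""
    winner = np.full(length, -1, dtype=np.int16)
    rows = [it for it in items if it.chromosome == chrom
            and group_of(it.family) is not None]
    # paint in ascending priority so the best item lands last: longest span,
    # then identity, then lexicographically smaller family name
    rows.sort(key=lambda it: it.family, reverse=True)
    rows.sort(key=lambda it: (it.end - it.start, it.identity))
    for it in rows:
        gi = group_index[group_of(it.family)]
        winner[max(0, it.start):min(length, it.end)] = gi
    return winner


def build_anchor_profile(genes: Sequence[GeneModel],
                         hits_or_annotations: Sequence,
                         chromosome_lengths: Mapping[str, int],
                         flank: int = DEFAULT_FLANK,
                         step: int = DEFAULT_STEP,
                         groups: Mapping[str, str] | None = None
                         ) -> tuple[AnchoredProfile, AnchoredProfile]:
    """(upstream-of-TSS, downstream-of-TES) frequency profiles.

    ``groups`` maps family name to a group label (e.g. superfamily); families
    missing from the mapping are ignored. Sampled positions beyond the
    chromosome end are excluded from that offset's denominator.
    """
    if flank % step != 0:
        raise ValueError("flank must be divisible by step")
    if groups is None:
        fams = sorted({it.family for it in hits_or_annotations})
        groups = {f: f for f in fams}
    group_names = sorted(set(groups.values()))
    gidx = {g: i for i, g in enumerate(group_names)}
    group_of = groups.get

    n_off = flank // step
    offsets = np.arange(1, n_off + 1) * step
    counts = {a: np.zeros((len(group_names), n_off), dtype=np.int64)
              for a in ("TSS", "TES")}
    valid = {a: np.zeros(n_off, dtype=np.int64) for a in ("TSS", "TES")}

    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chromosome, []).append(g)

    for chrom, chrom_genes in genes_by_chrom.items():
        length = chromosome_lengths[chrom]
        winner = _paint_winners(hits_or_annotations, chrom, length,
                                group_of, gidx)
        for g in chrom_genes:
            # anchor bases (0-based): TSS base and TES base of the transcript
            if g.strand == "+":
                anchors = {"TSS": (g.start, -1), "TES": (g.end - 1, +1)}
            else:
                anchors = {"TSS": (g.end - 1, +1), "TES": (g.start, -1)}
            for name, (base, direction) in anchors.items():
                pos = base + direction * offsets
                ok = (pos >= 0) & (pos < length)
                valid[name][ok] += 1
                w = winner[pos[ok]]
                covered = w >= 0
                np.add.at(counts[name], (w[covered],
                                         np.flatnonzero(ok)[covered]), 1)

    out = []
    for name in ("TSS", "TES"):
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = counts[name] / valid[name]
        df = pd.DataFrame(freq.T, index=pd.Index(offsets, name="offset"),
                          columns=group_names)
        out.append(AnchoredProfile(name, df,
                                   pd.Series(valid[name], index=df.index)))
    return out[0], out[1]


def gypsy_copia_ratio(profile: AnchoredProfile, gypsy: str = "Gypsy",
                      copia: str = "Copia",
                      smooth: int | None = None) -> pd.Series:
    """Per-offset Gypsy/Copia frequency ratio; offsets with zero Copia
    frequency are missing (NaN), never infinite."""
    for col in (gypsy, copia):
        if col not in profile.frequencies.columns:
            raise ValueError(f"profile lacks group {col!r}")
    g = profile.frequencies[gypsy]
    c = profile.frequencies[copia]
    if smooth:
        g = g.rolling(smooth, center=True, min_periods=1).mean()
        c = c.rolling(smooth, center=True, min_periods=1).mean()
    ratio = g / c.where(c > 0)
    return ratio.rename("gypsy_copia_ratio")


# ---------------------------------------------------------------------------
# target sites
# ---------------------------------------------------------------------------

def target_site_matrix(annotations: Sequence[TEAnnotation],
                       assembly: GenomeAssembly,
                       flank: int = DEFAULT_TSD_FLANK) -> TargetSiteMatrix:
    """Nucleotide composition of the flanks of complete (both-ends-intact)
    copies, element-oriented: minus-strand flanks are reverse-complemented.
    Copies closer than ``flank`` bp to a chromosome end are skipped."""
    usable = [a for a in annotations if a.complete]
    if not usable:
        raise ValueError("no usable copies (none flagged complete)")
    positions = np.concatenate([np.arange(-flank, 0), np.arange(1, flank + 1)])
    counts = np.zeros((2 * flank, 5), dtype=np.int64)  # A C G T N
    n_used = 0
    skipped = 0
    for a in usable:
        seq = assembly.sequences[a.chromosome]
        if a.start - flank < 0 or a.end + flank > len(seq):
            skipped += 1
            continue
        left = seq[a.start - flank:a.start]
        right = seq[a.end:a.end + flank]
        if a.strand == "-":
            left, right = _seq.revcomp(right), _seq.revcomp(left)
        enc = _seq.encode(left + right)
        counts[np.arange(2 * flank), enc] += 1
        n_used += 1
    if skipped:
        logger.info("target_site_matrix: skipped %d copies too close to a "
                    "chromosome end", skipped)
    if n_used == 0:
        raise ValueError("no usable copies (all too close to chromosome ends)")
    non_n = counts[:, :4].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = counts[:, :4] / non_n[:, None]
    idx = pd.Index(positions, name="position")
    return TargetSiteMatrix(
        pd.DataFrame(frac, index=idx, columns=list("ACGT")),
        pd.Series(non_n, index=idx), pd.Series(counts[:, 4], index=idx),
        n_used)


def consensus_motif(matrix: TargetSiteMatrix,
                    majority_threshold: float = 0.8,
                    window: tuple[int, int] | None = None) -> str:
    """Degenerate motif string from a target-site matrix.

    Per position: a single letter if its fraction reaches the threshold, a
    two-letter class ('[T/A]') if the best pair does, else 'n'; the insertion
    point is marked '-'. ``window=(left, right)`` restricts to the innermost
    positions on each side."""
    frac = matrix.fractions
    if window is not None:
        left, right = window
        keep = list(range(-left, 0)) + list(range(1, right + 1))
        frac = frac.loc[keep]
    parts: list[str] = []
    for pos, row in frac.iterrows():
        if pos > 0 and (not parts or "-" not in parts):
            parts.append("-")
        vals = row.sort_values(ascending=False)
        if vals.iloc[0] >= majority_threshold:
            parts.append(str(vals.index[0]))
        elif vals.iloc[0] + vals.iloc[1] >= majority_threshold:
            parts.append(_seq.render_position(
                frozenset({str(vals.index[0]), str(vals.index[1])})))
        else:
            parts.append("n")
    return "".join(parts)
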