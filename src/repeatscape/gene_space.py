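"""Gene clustering, its randomization null, TE-to-gene distances,
island/intergenic TE composition, and TE orientation bias near genes.

Clustering is single-linkage chaining with a strict edge-to-edge gap
threshold (< 20 kb by default). Midpoints are floor((start+end)/2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneModel, TEAnnotation

logger = logging.getLogger("repeatscape")

DEFAULT_MAX_GAP = 20_000
DEFAULT_MIN_INTERGENIC = 200_000
DEFAULT_ISLAND_FLANK = 5_000


@dataclass
class GeneClusterSet:
    clusters: list[list[GeneModel]]
    size_histogram: pd.Series
    clustered_fraction: float

    @property
    def n_genes(self) -> int:
        return sum(len(c) for c in self.clusters)


@dataclass
class OrientationCounts:
    region: str
    forward: int
    reverse: int
    chi2: float | None
    p_value: float | None

    @property
    def total(self) -> int:
        return self.forward + self.reverse


# ---------------------------------------------------------------------------
# clustering + null
# ---------------------------------------------------------------------------

def cluster_genes(genes: Sequence[GeneModel],
                  max_gap: int = DEFAULT_MAX_GAP,
                  midpoint_mode: bool = False) -> GeneClusterSet:
    """Partition genes into clusters by chaining gaps strictly below
    ``max_gap``. Gap = next.start - prev.end (edge-to-edge); with
    ``midpoint_mode`` the midpoint separation is used instead. Overlapping
    genes count as gap 0."""
    clusters: list[list[GeneModel]] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    overlaps = 0
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end))
        current = [ordered[0]]
        for prev, g in zip(ordered, ordered[1:]):
            if midpoint_mode:
                gap = g.midpoint - prev.midpoint
            else:
                gap = g.start - prev.end
            if gap < 0:
                overlaps += 1
                gap = 0
            if gap < max_gap:
                current.append(g)
            else:
                clusters.append(current)
                current = [g]
        clusters.append(current)
    if overlaps:
        logger.warning("cluster_genes: %d overlapping gene pairs treated as "
                       "gap 0", overlaps)
    sizes = pd.Series([len(c) for c in clusters])
    hist = sizes.value_counts().sort_index()
    n = int(sizes.sum())
    clustered = int(sizes[sizes >= 2].sum())
    return GeneClusterSet(clusters, hist, clustered / n if n else 0.0)


def _uniform_nonoverlapping_starts(lengths: np.ndarray, chrom_len: int,
                                   rng: np.random.Generator) -> np.ndarray:
    """Uniform placement of non-overlapping intervals via the spacing
    construction: ordered uniform draws in the slack, plus cumulative
    lengths."""
    slack = chrom_len - int(lengths.sum())
    if slack < 0:
        raise ValueError("genes cannot fit on the chromosome")
    u = np.sort(rng.uniform(0, slack, size=len(lengths)))
    return (u + np.concatenate([[0], np.cumsum(lengths[:-1])])).astype(np.int64)


def random_placement_null(n_genes: int,
                          gene_lengths: Sequence[int],
                          chromosome_lengths: Mapping[str, int],
                          max_gap: int = DEFAULT_MAX_GAP,
                          n_reps: int = 100,
                          seed: int = 0,
                          observed_fraction: float | None = None) -> dict:
    """Null distribution of the clustered-gene fraction under uniform random
    non-overlapping placement of the observed gene lengths."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    lengths = np.asarray(gene_lengths[:n_genes], dtype=np.int64)
    if len(lengths) != n_genes:
        raise ValueError("need one length per gene")
    chroms = list(chromosome_lengths)
    sizes = np.array([chromosome_lengths[c] for c in chroms], dtype=np.int64)
    if lengths.sum() > sizes.sum():
        raise ValueError("genes cannot fit in the genome")
    rng = np.random.default_rng(seed)
    fractions = np.empty(n_reps)
    for rep in range(n_reps):
        for _ in range(1000):
            assign = rng.choice(len(chroms), size=n_genes,
                                p=sizes / sizes.sum())
            ok = all(lengths[assign == i].sum() <= sizes[i]
                     for i in range(len(chroms)))
            if ok:
                break
        else:
            raise ValueError("genes cannot fit in the genome")
        placed = []
        for i, chrom in enumerate(chroms):
            sub = lengths[assign == i]
            if not len(sub):
                continue
            order = rng.permutation(len(sub))
            starts = _uniform_nonoverlapping_starts(sub[order], sizes[i], rng)
            for s, L in zip(starts, sub[order]):
                placed.append(GeneModel(f"r{len(placed)}", chrom, int(s),
                                        int(s + L), "+"))
        fractions[rep] = cluster_genes(placed, max_gap).clustered_fraction
    out = {"mean": float(fractions.mean()),
           "sd": float(fractions.std(ddof=1)) if n_reps > 1 else 0.0,
           "fractions": fractions}
    if observed_fraction is not None:
        out["p_value"] = float(
            (1 + (fractions >= observed_fraction).sum()) / (n_reps + 1))
    return out


# ---------------------------------------------------------------------------
# TE-to-gene distances
# ---------------------------------------------------------------------------

def te_gene_distance(te_annotations: Sequence[TEAnnotation],
                     genes: Sequence[GeneModel]
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Midpoint-to-midpoint distance from each TE to its nearest gene on the
    same chromosome (NaN where the chromosome carries no gene), plus
    per-superfamily fractions within 5 kb and 10 kb.

    The per-TE table also carries ``edge_distance`` (nearest edge-to-edge
    separation, 0 when overlapping) as the alternative mode.
    """
    gene_mids: dict[str, np.ndarray] = {}
    gene_ivals: dict[str, np.ndarray] = {}
    for g in genes:
        gene_mids.setdefault(g.chromosome, []).append(g.midpoint)
    gene_mids = {c: np.sort(np.array(v)) for c, v in gene_mids.items()}
    for g in genes:
        gene_ivals.setdefault(g.chromosome, []).append((g.start, g.end))
    gene_ivals = {c: np.array(sorted(v)) for c, v in gene_ivals.items()}

    rows = []
    for t in te_annotations:
        mids = gene_mids.get(t.chromosome)
        if mids is None or not len(mids):
            rows.append((t.family, t.superfamily, t.chromosome, np.nan, np.nan))
            continue
        m = t.midpoint
        i = np.searchsorted(mids, m)
        cand = [abs(m - mids[j]) for j in (i - 1, i) if 0 <= j < len(mids)]
        dist = float(min(cand))
        iv = gene_ivals[t.chromosome]
        gaps = np.maximum(iv[:, 0] - t.end, t.start - iv[:, 1])
        edge = float(max(0, gaps.min()))
        rows.append((t.family, t.superfamily, t.chromosome, dist, edge))
    table = pd.DataFrame(rows, columns=["family", "superfamily", "chromosome",
                                        "distance", "edge_distance"])
    valid = table.dropna(subset=["distance"])
    frac = valid.groupby("superfamily")["distance"].agg(
        within_5kb=lambda d: float((d <= 5000).mean()),
        within_10kb=lambda d: float((d <= 10000).mean()),
        n="size")
    return table, frac.reset_index()


def distance_histogram(table: pd.DataFrame, bin_size: int = 1000,
                       max_distance: int = 50_000) -> pd.DataFrame:
    """Counts of TE-gene midpoint distances per superfamily per bin."""
    d = table.dropna(subset=["distance"]).copy()
    d = d[d["distance"] <= max_distance]
    d["bin"] = (d["distance"] // bin_size).astype(int)
    return (d.groupby(["superfamily", "bin"]).size()
             .rename("count").reset_index())


# ---------------------------------------------------------------------------
# island vs intergenic composition
# ---------------------------------------------------------------------------

def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _overlap_bp(ivals: list[tuple[int, int]], start: int, end: int) -> int:
    return sum(max(0, min(e, end) - max(s, start)) for s, e in ivals)


def island_vs_intergenic_composition(
        te_annotations: Sequence[TEAnnotation],
        genes: Sequence[GeneModel],
        chromosome_lengths: Mapping[str, int],
        min_intergenic: int = DEFAULT_MIN_INTERGENIC,
        island_flank: int = DEFAULT_ISLAND_FLANK,
        max_gap: int = DEFAULT_MAX_GAP) -> pd.DataFrame:
    """Per-superfamily occupied-bp percentage inside gene islands (cluster
    spans +- ``island_flank``) versus gene-free stretches of at least
    ``min_intergenic`` bp. Regions qualifying as neither are excluded."""
    islands: dict[str, list[tuple[int, int]]] = {c: [] for c in chromosome_lengths}
    if genes:
        for cluster in cluster_genes(genes, max_gap).clusters:
            chrom = cluster[0].chromosome
            lo = max(0, min(g.start for g in cluster) - island_flank)
            hi = min(chromosome_lengths[chrom],
                     max(g.end for g in cluster) + island_flank)
            islands[chrom].append((lo, hi))
    islands = {c: _merge_intervals(v) for c, v in islands.items()}

    intergenic: dict[str, list[tuple[int, int]]] = {}
    for chrom, length in chromosome_lengths.items():
        gene_iv = _merge_intervals([(g.start, g.end) for g in genes
                                    if g.chromosome == chrom])
        free, prev = [], 0
        for s, e in gene_iv + [(length, length)]:
            if s - prev >= min_intergenic:
                free.append((prev, s))
            prev = max(prev, e)
        # island flanks belong to the island compartment
        clipped = []
        for s, e in free:
            cur = [(s, e)]
            for is_, ie in islands[chrom]:
                nxt = []
                for cs, ce in cur:
                    if ie <= cs or is_ >= ce:
                        nxt.append((cs, ce))
                    else:
                        if cs < is_:
                            nxt.append((cs, is_))
                        if ie < ce:
                            nxt.append((ie, ce))
                cur = nxt
            clipped.extend(cur)
        intergenic[chrom] = clipped

    rows = []
    for label, compartment in (("island", islands), ("intergenic", intergenic)):
        comp_bp = sum(e - s for iv in compartment.values() for s, e in iv)
        occupied: dict[str, int] = {}
        for t in te_annotations:
            bp = _overlap_bp(compartment.get(t.chromosome, []), t.start, t.end)
            if bp:
                occupied[t.superfamily] = occupied.get(t.superfamily, 0) + bp
        for sf in sorted(occupied):
            rows.append({"compartment": label, "superfamily": sf,
                         "occupied_bp": occupied[sf],
                         "compartment_bp": comp_bp,
                         "percent": 100.0 * occupied[sf] / comp_bp if comp_bp else 0.0})
        if not occupied:
            rows.append({"compartment": label, "superfamily": None,
                         "occupied_bp": 0, "compartment_bp": comp_bp,
                         "percent": 0.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orientation bias
# ---------------------------------------------------------------------------

def _chi_square_50_50(forward: int, reverse: int
                      ) -> tuple[float | None, float | None]:
    total = forward + reverse
    if total == 0:
        return None, None
    res = stats.chisquare([forward, reverse])
    return float(res.statistic), float(res.pvalue)


def orientation_bias(te_annotations: Sequence[TEAnnotation],
                     genes: Sequence[GeneModel],
                     region: str = "upstream",
                     window: int = 500,
                     sliding: int | None = None,
                     sliding_window: int = 100) -> OrientationCounts | pd.DataFrame:
    """TE orientation relative to nearby genes, chi-square against 50:50
    (df=1, no continuity correction). Forward = TE strand equals gene strand;
    TE membership is by midpoint inside the strand-aware window.

    With ``sliding`` set to a span in bp, returns a per-offset series of
    ``sliding_window``-bp windows moved in 1 bp steps.
    """
    if region not in ("upstream", "downstream"):
        raise ValueError("region must be 'upstream' or 'downstream'")
    te_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tmp: dict[str, list] = {}
    for t in te_annotations:
        tmp.setdefault(t.chromosome, []).append((t.midpoint, t.strand == "+"))
    for chrom, pairs in tmp.items():
        pairs.sort()
        te_by_chrom[chrom] = (np.array([p[0] for p in pairs]),
                              np.array([p[1] for p in pairs]))

    # per-offset counters indexed by offset-1 (offsets run 1..span)
    span = sliding if sliding is not None else window
    offsets_fwd = np.zeros(span, dtype=np.int64)
    offsets_rev = np.zeros(span, dtype=np.int64)
    for g in genes:
        if g.chromosome not in te_by_chrom:
            continue
        mids, plus = te_by_chrom[g.chromosome]
        anchor = g.tss if region == "upstream" else g.tes
        # offset grows away from the gene in the region's direction
        if (region == "upstream") == (g.strand == "+"):
            lo, hi = anchor - span, anchor
            sel = slice(np.searchsorted(mids, lo),
                        np.searchsorted(mids, hi))
            offs = anchor - mids[sel]
        else:
            lo, hi = anchor, anchor + span
            sel = slice(np.searchsorted(mids, lo),
                        np.searchsorted(mids, hi))
            offs = mids[sel] - anchor + 1
        fwd = plus[sel] == (g.strand == "+")
        np.add.at(offsets_fwd, offs[fwd] - 1, 1)
        np.add.at(offsets_rev, offs[~fwd] - 1, 1)

    if sliding is None:
        f, r = int(offsets_fwd.sum()), int(offsets_rev.sum())
        chi2, p = _chi_square_50_50(f, r)
        return OrientationCounts(region, f, r, chi2, p)

    kernel = np.ones(sliding_window, dtype=np.int64)
    fwd_s = np.convolve(offsets_fwd, kernel, mode="valid")
    rev_s = np.convolve(offsets_rev, kernel, mode="valid")
    rows = []
    for off in range(len(fwd_s)):
        chi2, p = _chi_square_50_50(int(fwd_s[off]), int(rev_s[off]))
        rows.append({"offset": off, "forward": int(fwd_s[off]),
                     "reverse": int(rev_s[off]), "chi2": chi2, "p_value": p})
    return pd.DataFrame(rows)
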