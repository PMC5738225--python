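"""Windowed bisulfite-methylation levels and promoter-TE group contrasts.

Levels are computed per context (CG/CHG/CHH) in 100 bp non-overlapping
windows with no coverage filter by default. The default estimator pools read
counts within the window (sum #C / sum (#C + #T)); a per-site binarized
estimator (site methylated iff #C/(#C+#T) > 0.5) is available by flag.

The "promoter" is the strand-aware window [TSS-1500, TSS+500); genes are
grouped by whether a TE of a given superfamily overlaps it, and TSS-anchored
1000 bp bin profiles compare group means (gene-level bin means averaged
across genes, each gene weighted equally).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, TEAnnotation

logger = logging.getLogger("repeatscape")

DEFAULT_WINDOW = 100
PROMOTER_UPSTREAM = 1500
PROMOTER_DOWNSTREAM = 500
DEFAULT_SPAN = (-10_000, 2_000)
DEFAULT_BIN = 1000
CONTEXTS = ("CG", "CHG", "CHH")
DEFAULT_SUPERFAMILIES = ("Mariner", "Harbinger", "Helitron")


@dataclass
class MethylationRatioProfile:
    """TSS-anchored binned group means and between-group ratios.

    ``means`` is indexed by bin start offset (bp relative to the TSS,
    strand-oriented) with one column per (context, group); the two ratio
    frames are without/with and with/without per context.
    """

    contrast: str
    means: pd.DataFrame
    ratio_without_over_with: pd.DataFrame
    ratio_with_over_without: pd.DataFrame
    n_genes: dict[str, int]


# ---------------------------------------------------------------------------
# windowed levels
# ---------------------------------------------------------------------------

def window_methylation(calls: pd.DataFrame, window: int = DEFAULT_WINDOW,
                       estimator: str = "pooled",
                       min_coverage: int = 1) -> pd.DataFrame:
    """Per-window, per-context methylation level.

    ``calls`` is a call-table frame (see ``io_formats.read_methylation_table``).
    Windows with no covered site for a context are simply absent (missing).
    Columns: chromosome, window_start, context, level, covered_sites.
    """
    if estimator not in ("pooled", "site"):
        raise ValueError("estimator must be 'pooled' or 'site'")
    covered = calls[calls["total"] >= max(1, min_coverage)].copy()
    if not len(covered):
        return pd.DataFrame(columns=["chromosome", "window_start", "context",
                                     "level", "covered_sites"])
    covered["window_start"] = (covered["position"] // window) * window
    grp = covered.groupby(["chromosome", "window_start", "context"],
                          observed=True)
    if estimator == "pooled":
        agg = grp.agg(meth=("methylated", "sum"), tot=("total", "sum"),
                      covered_sites=("total", "size")).reset_index()
        agg["level"] = agg["meth"] / agg["tot"]
    else:
        covered["is_meth"] = (covered["methylated"] / covered["total"]) > 0.5
        agg = grp.agg(level=("is_meth", "mean"),
                      covered_sites=("total", "size")).reset_index()
    out = agg[["chromosome", "window_start", "context", "level",
               "covered_sites"]].sort_values(
        ["chromosome", "window_start", "context"]).reset_index(drop=True)
    logger.info("window_methylation: %d windows (%s estimator)",
                len(out), estimator)
    return out


# ---------------------------------------------------------------------------
# promoter classification
# ---------------------------------------------------------------------------

def promoter_window(gene: GeneModel, upstream: int = PROMOTER_UPSTREAM,
                    downstream: int = PROMOTER_DOWNSTREAM) -> tuple[int, int]:
    if gene.strand == "+":
        return gene.tss - upstream, gene.tss + downstream
    return gene.tss - downstream, gene.tss + upstream


def classify_promoters(genes: Sequence[GeneModel],
                       te_annotations: Sequence[TEAnnotation],
                       upstream: int = PROMOTER_UPSTREAM,
                       downstream: int = PROMOTER_DOWNSTREAM,
                       superfamilies: Sequence[str] = DEFAULT_SUPERFAMILIES
                       ) -> pd.DataFrame:
    """Per-gene booleans for each superfamily (any bp overlap of such a TE
    with the promoter window) plus ``no_te``: none of the listed
    superfamilies present. Indexed by gene id."""
    per_chrom: dict[str, list[TEAnnotation]] = {}
    for t in te_annotations:
        if t.superfamily in superfamilies:
            per_chrom.setdefault(t.chromosome, []).append(t)
    arrays = {}
    for chrom, lst in per_chrom.items():
        lst.sort(key=lambda t: t.start)
        arrays[chrom] = (np.array([t.start for t in lst]),
                         np.array([t.end for t in lst]),
                         np.array([t.superfamily for t in lst]))
    rows = []
    for g in genes:
        w0, w1 = promoter_window(g, upstream, downstream)
        flags = dict.fromkeys(superfamilies, False)
        if g.chromosome in arrays:
            starts, ends, sfs = arrays[g.chromosome]
            hit = (starts < w1) & (ends > w0)
            for sf in np.unique(sfs[hit]):
                flags[sf] = True
        flags["no_te"] = not any(flags[sf] for sf in superfamilies)
        rows.append({"gene_id": g.id, **flags})
    df = pd.DataFrame(rows).set_index("gene_id")
    logger.info("classify_promoters: %s",
                {sf: int(df[sf].sum()) for sf in list(superfamilies) + ["no_te"]})
    return df


# ---------------------------------------------------------------------------
# TSS-anchored binned profile + ratios
# ---------------------------------------------------------------------------

def tss_anchored_methylation(genes: Sequence[GeneModel],
                             windows: pd.DataFrame,
                             status: pd.DataFrame,
                             contrast: str,
                             span: tuple[int, int] = DEFAULT_SPAN,
                             bin_size: int = DEFAULT_BIN,
                             window: int = DEFAULT_WINDOW
                             ) -> MethylationRatioProfile:
    """Compare binned methylation around the TSS between genes carrying a
    ``contrast``-superfamily TE in the promoter and genes with no such TE.

    100 bp windows are mapped into strand-oriented ``bin_size`` bins by their
    midpoints; bins average gene-level means across genes. Bins reaching past
    chromosome ends simply lack contributions.
    """
    if contrast not in status.columns:
        raise ValueError(f"status table lacks column {contrast!r}")
    n_bins = (span[1] - span[0]) // bin_size
    bin_starts = span[0] + bin_size * np.arange(n_bins)
    ctx_codes = {c: i for i, c in enumerate(CONTEXTS)}

    per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in windows.groupby("chromosome"):
        sub = sub.sort_values("window_start")
        per_chrom[chrom] = (sub["window_start"].to_numpy(),
                            sub["context"].map(ctx_codes).to_numpy(),
                            sub["level"].to_numpy())

    sums = {grp: np.zeros((len(CONTEXTS), n_bins)) for grp in ("with", "without")}
    cnts = {grp: np.zeros((len(CONTEXTS), n_bins)) for grp in ("with", "without")}
    n_genes = {"with": 0, "without": 0}
    flags = status[contrast].to_dict()
    no_te = status["no_te"].to_dict() if "no_te" in status.columns else {}

    for g in genes:
        if flags.get(g.id):
            grp = "with"
        elif no_te.get(g.id, False):
            grp = "without"
        else:
            continue
        n_genes[grp] += 1
        data = per_chrom.get(g.chromosome)
        if data is None:
            continue
        wstart, wctx, wlev = data
        reach = span[1] if g.strand == "+" else -span[0]
        back = span[0] if g.strand == "+" else -span[1]
        lo = np.searchsorted(wstart, g.tss + back - window)
        hi = np.searchsorted(wstart, g.tss + reach)
        if lo >= hi:
            continue
        mid = wstart[lo:hi] + window // 2
        d = mid - g.tss if g.strand == "+" else g.tss - mid
        bin_idx = (d - span[0]) // bin_size
        ok = (bin_idx >= 0) & (bin_idx < n_bins) & ~np.isnan(wlev[lo:hi])
        # gene-level means first, then the across-gene average
        gsum = np.zeros((len(CONTEXTS), n_bins))
        gcnt = np.zeros((len(CONTEXTS), n_bins))
        np.add.at(gsum, (wctx[lo:hi][ok], bin_idx[ok]), wlev[lo:hi][ok])
        np.add.at(gcnt, (wctx[lo:hi][ok], bin_idx[ok]), 1)
        has = gcnt > 0
        sums[grp][has] += gsum[has] / gcnt[has]
        cnts[grp][has] += 1

    cols = {}
    for grp in ("with", "without"):
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = sums[grp] / cnts[grp]
        for i, ctx in enumerate(CONTEXTS):
            cols[(ctx, grp)] = mean[i]
    means = pd.DataFrame(cols, index=pd.Index(bin_starts, name="bin_start"))
    means.columns = pd.MultiIndex.from_tuples(means.columns,
                                              names=["context", "group"])
    ratio_wo = pd.DataFrame(
        {ctx: means[(ctx, "without")] / means[(ctx, "with")] for ctx in CONTEXTS})
    ratio_w = pd.DataFrame(
        {ctx: means[(ctx, "with")] / means[(ctx, "without")] for ctx in CONTEXTS})
    return MethylationRatioProfile(contrast, means, ratio_wo, ratio_w, n_genes)
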