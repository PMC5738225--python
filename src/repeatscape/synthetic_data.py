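"""Synthetic genomes, TE libraries, gene models and methylomes with ground truth.

Every downstream stage of the pipeline is testable against the ``TruthSet``
this module records: exact planted TE boundaries and intactness, gene models,
per-gene promoter-TE status, and motif-fallback flags. All outputs are
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _seq
from .io_formats import (SUPERFAMILY_CODES, GeneModel,
                         GenomeAssembly, TEAnnotation, TELibraryEntry,
                         write_centromeres, write_fasta, write_gff3_genes,
                         write_gff3_te, write_methylation_table,
                         write_te_library)

logger = logging.getLogger("repeatscape")

NICHES = ("distal", "interstitial", "proximal", "uniform")

_NON_STOP_CODONS = [a + b + c
                    for a in "ACGT" for b in "ACGT" for c in "ACGT"
                    if a + b + c not in ("TAA", "TAG", "TGA")]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetSiteMotif:
    """Degenerate flanking pattern in element orientation.

    ``left`` must match immediately 5' of the element, ``right`` immediately
    3'. Accepts IUPAC strings ('WWNNT') or bracket classes ('[T/A][T/A]nnT').
    """

    left: str
    right: str

    def __post_init__(self) -> None:
        for side in (self.left, self.right):
            sets = _seq.parse_degenerate(side)
            if len(sets) > 30:
                raise ValueError("motif window exceeds 30 bp per side")

    @property
    def left_sets(self):
        return _seq.parse_degenerate(self.left)

    @property
    def right_sets(self):
        return _seq.parse_degenerate(self.right)


@dataclass(frozen=True)
class FamilySpec:
    """How to plant one TE family: abundance, niche, motif, truncation."""

    entry: TELibraryEntry
    copy_number: int
    niche: str = "uniform"
    concentration: float = 3.0
    motif: TargetSiteMotif | None = None
    motif_search_radius: int = 600
    truncation_prob: float = 0.0
    truncation_frac: tuple[float, float] = (0.1, 0.7)
    strand_bias: float = 0.5
    divergence: float = 0.0
    tss_distance: tuple[float, float] | None = None  # lognormal (mean, sigma) in bp

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ValueError("copy number must be >= 0")
        if self.niche not in NICHES:
            raise ValueError(f"niche must be one of {NICHES}")
        for p in (self.truncation_prob, self.strand_bias, self.divergence):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0,1]")


@dataclass(frozen=True)
class GeneSpec:
    """Gene complement: count, sizes, and cluster structure."""

    n_genes: int
    length_range: tuple[int, int] = (1500, 3000)
    cluster_size_probs: Sequence[float] = (0.42, 0.25, 0.14, 0.09, 0.05, 0.03, 0.02)
    intra_cluster_gap: tuple[int, int] = (500, 15000)
    cluster_margin: int = 25000
    gc: float = 0.58


@dataclass(frozen=True)
class MethylomeSpec:
    """Shape of the simulated methylome around genes."""

    baseline: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 0.85, "CHG": 0.70, "CHH": 0.10})
    tss_dip_depth: float = 0.9
    tss_dip_width: int = 2000
    genic_cg_recovery: float = 0.85
    chh_mound_height: float = 0.15
    chh_mound_width: int = 1500
    promoter_te_superfamily: str = "Mariner"
    promoter_te_cg_chg_factor: float = 1.0
    promoter_te_chh_factor: float = 1.0
    depth_mean: float = 20.0

    def __post_init__(self) -> None:
        for v in self.baseline.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("baseline levels must lie in [0,1]")
        if self.promoter_te_cg_chg_factor <= 0 or self.promoter_te_chh_factor <= 0:
            raise ValueError("promoter-TE factors must be > 0")


@dataclass
class TruthSet:
    """Ground truth of one simulated genome."""

    annotations: list[TEAnnotation]
    genes: list[GeneModel]
    centromeres: dict[str, int]
    fallback: list[bool] = field(default_factory=list)
    promoter_status: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# TE library generation
# ---------------------------------------------------------------------------

_DEFAULT_MIX = ("RLG", "RLC", "DTC", "DTT", "DTH", "DHH", "RIX", "RSX")


def _embed_orf(seq: str, rng: np.random.Generator, n_codons: int = 320) -> str:
    orf = "ATG" + "".join(_NON_STOP_CODONS[i] for i in
                          rng.integers(len(_NON_STOP_CODONS), size=n_codons)) + "TAA"
    if len(orf) + 2 > len(seq):
        raise ValueError(f"sequence of {len(seq)} bp too short for a "
                         f"{n_codons}-codon ORF")
    start = int(rng.integers(0, len(seq) - len(orf) + 1))
    return seq[:start] + orf + seq[start + len(orf):]


def generate_te_library(n_families: int,
                        length_range: tuple[int, int] = (500, 9000),
                        superfamily_mix: Mapping[str, int] | Sequence[str] | None = None,
                        seed: int = 0,
                        autonomous_fraction: float = 0.4,
                        gc: float = 0.44,
                        max_retries: int = 20) -> list[TELibraryEntry]:
    """Random consensus library whose families are mutually distinct under the
    80/80 rule (verified; offending families are resampled).

    ``superfamily_mix`` is either an explicit code->count mapping (counts must
    sum to ``n_families``) or a sequence of codes cycled over the families.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(superfamily_mix, Mapping):
        codes = [c for c, n in superfamily_mix.items() for _ in range(n)]
        if len(codes) != n_families:
            raise ValueError("superfamily_mix counts must sum to n_families")
    else:
        pool = list(superfamily_mix) if superfamily_mix else list(_DEFAULT_MIX)
        codes = [pool[i % len(pool)] for i in range(n_families)]
    bad = set(codes) - set(SUPERFAMILY_CODES)
    if bad:
        raise ValueError(f"unknown superfamily codes {sorted(bad)}")

    from .te_annotation import assign_family_80_80, classify_autonomy

    def make_entry(i: int) -> TELibraryEntry:
        code = codes[i]
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        autonomous = rng.random() < autonomous_fraction and length >= 1100
        for _ in range(max_retries):
            seq = _seq.random_sequence(length, rng, gc=gc)
            if autonomous:
                seq = _embed_orf(seq, rng)
            if (classify_autonomy(seq) == "autonomous") == autonomous:
                return TELibraryEntry(f"{code}_sim{i:02d}", seq, autonomous=autonomous)
        raise RuntimeError(f"could not generate a {'' if autonomous else 'non-'}"
                           f"autonomous {length} bp consensus after {max_retries} tries")

    library = [make_entry(i) for i in range(n_families)]
    for attempt in range(max_retries):
        clash = None
        for i, entry in enumerate(library):
            others = library[:i] + library[i + 1:]
            if others and assign_family_80_80(entry.sequence, others) != "unassigned":
                clash = i
                break
        if clash is None:
            return library
        logger.warning("library family %d violates the 80/80 distinctness "
                       "requirement; resampling", clash)
        library[clash] = make_entry(clash)
    raise RuntimeError(
        f"could not generate {n_families} mutually <80/80 families in "
        f"{length_range}; the length range / alphabet cannot host that many "
        f"distinct families")


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

class _Occupancy:
    """Sorted disjoint intervals with bisect-based free-interval queries."""

    def __init__(self, length: int):
        self.length = length
        self.starts: list[int] = []
        self.ends: list[int] = []

    def is_free(self, start: int, end: int, margin: int = 0) -> bool:
        if start < 0 or end > self.length or start >= end:
            return False
        lo, hi = start - margin, end + margin
        i = bisect.bisect_left(self.starts, hi)
        return not (i > 0 and self.ends[i - 1] > lo)

    def add(self, start: int, end: int) -> None:
        i = bisect.bisect_left(self.starts, start)
        self.starts.insert(i, start)
        self.ends.insert(i, end)


def _motif_mask(sets: list[frozenset[str]]) -> np.ndarray:
    """(len, 5) boolean lookup: mask[k, encoded_base] — N never matches."""
    m = np.zeros((len(sets), 5), dtype=bool)
    for k, allowed in enumerate(sets):
        for b in allowed:
            m[k, "ACGT".index(b)] = True
    return m


def _match_encoded(arr: np.ndarray, pos: int, mask: np.ndarray) -> bool:
    k = len(mask)
    if pos < 0 or pos + k > len(arr):
        return False
    return bool(mask[np.arange(k), arr[pos:pos + k]].all())


def _sample_niche_position(rng: np.random.Generator, niche: str, conc: float,
                           centromere: int, length: int) -> int:
    if niche == "uniform":
        return int(rng.integers(0, length))
    # pick an arm by length; t in [0,1] runs centromere -> telomere
    left = centromere
    right = length - centromere
    use_left = rng.random() < left / (left + right)
    if niche == "distal":
        t = rng.beta(conc, 1.0)
    elif niche == "proximal":
        t = rng.beta(1.0, conc)
    else:  # interstitial
        t = rng.beta(conc, conc)
    if use_left:
        return min(left - 1, int(round(centromere * (1.0 - t))))
    return min(length - 1, centromere + int(round(t * right)))


def _place_genes(rng: np.random.Generator, spec: GeneSpec,
                 chrom_names: list[str], lengths: Mapping[str, int],
                 occupancy: Mapping[str, _Occupancy]) -> list[GeneModel]:
    total_len = sum(lengths.values())
    probs = np.array([lengths[c] / total_len for c in chrom_names])
    sizes = np.arange(1, len(spec.cluster_size_probs) + 1)
    p = np.array(spec.cluster_size_probs, dtype=float)
    p = p / p.sum()
    genes: list[GeneModel] = []
    gid = 0
    tries = 0
    while len(genes) < spec.n_genes:
        tries += 1
        if tries > 200 * spec.n_genes:
            raise RuntimeError("could not place all genes; genome too crowded")
        k = int(rng.choice(sizes, p=p))
        k = min(k, spec.n_genes - len(genes))
        chrom = chrom_names[int(rng.choice(len(chrom_names), p=probs))]
        glens = rng.integers(spec.length_range[0], spec.length_range[1] + 1, size=k)
        gaps = rng.integers(spec.intra_cluster_gap[0], spec.intra_cluster_gap[1] + 1,
                            size=k)
        span = int(glens.sum() + gaps[:-1].sum()) if k else 0
        if span + 2 * spec.cluster_margin >= lengths[chrom]:
            continue
        anchor = int(rng.integers(spec.cluster_margin,
                                  lengths[chrom] - span - spec.cluster_margin))
        if not occupancy[chrom].is_free(anchor, anchor + span,
                                       margin=spec.cluster_margin):
            continue
        pos = anchor
        for j in range(k):
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"g{gid:05d}", chrom, pos, pos + int(glens[j]),
                                   strand))
            gid += 1
            pos += int(glens[j]) + int(gaps[j])
        occupancy[chrom].add(anchor, anchor + span)
    genes.sort(key=lambda g: (g.chromosome, g.start))
    return genes


def promoter_te_status(genes: Sequence[GeneModel],
                       annotations: Sequence[TEAnnotation],
                       upstream: int = 1500, downstream: int = 500
                       ) -> pd.DataFrame:
    """Per-gene booleans: does a TE of each superfamily overlap the
    strand-aware window [TSS-upstream, TSS+downstream)?"""
    supers = sorted({a.superfamily for a in annotations})
    by_chrom: dict[str, list[TEAnnotation]] = {}
    for a in annotations:
        by_chrom.setdefault(a.chromosome, []).append(a)
    for lst in by_chrom.values():
        lst.sort(key=lambda a: a.start)
    starts = {c: [a.start for a in lst] for c, lst in by_chrom.items()}
    rows = []
    for g in genes:
        if g.strand == "+":
            w0, w1 = g.tss - upstream, g.tss + downstream
        else:
            w0, w1 = g.tss - downstream, g.tss + upstream
        flags = dict.fromkeys(supers, False)
        lst = by_chrom.get(g.chromosome, [])
        if lst:
            i = bisect.bisect_left(starts[g.chromosome], w1)
            for a in lst[max(0, i - 200):i]:  # planted TEs are short-bounded
                if a.end > w0:
                    flags[a.superfamily] = True
        rows.append({"gene_id": g.id, **flags})
    return pd.DataFrame(rows).set_index("gene_id")


def simulate_genome(chromosome_lengths: Mapping[str, int],
                    gene_spec: GeneSpec,
                    family_specs: Sequence[FamilySpec],
                    seed: int = 0,
                    centromere_fraction: float = 0.45,
                    gc: float = 0.44,
                    max_place_tries: int = 200
                    ) -> tuple[GenomeAssembly, TruthSet]:
    """Plant clustered genes and niche/motif-guided TE copies on random
    background; returns the assembly plus full ground truth.

    TE positions are sampled from the family's niche density, then shifted to
    the nearest flanking-motif match within ``motif_search_radius``; copies
    with no match fall back to motif-free placement and are flagged in
    ``TruthSet.fallback``.
    """
    total_te = sum(s.copy_number * s.entry.length for s in family_specs)
    approx_gene = gene_spec.n_genes * sum(gene_spec.length_range) / 2
    if total_te + approx_gene > sum(chromosome_lengths.values()):
        raise ValueError("planted TE bp + gene bp exceed the genome size")

    rng = np.random.default_rng(seed)
    chrom_names = list(chromosome_lengths)
    lengths = dict(chromosome_lengths)
    centromeres = {c: int(n * centromere_fraction) for c, n in lengths.items()}
    background = {c: _seq.encode(_seq.random_sequence(n, rng, gc=gc))
                  for c, n in lengths.items()}
    occupancy = {c: _Occupancy(n) for c, n in lengths.items()}

    genes = _place_genes(rng, gene_spec, chrom_names, lengths, occupancy)
    for g in genes:
        body = _seq.encode(_seq.random_sequence(g.end - g.start, rng,
                                                gc=gene_spec.gc))
        background[g.chromosome][g.start:g.end] = body

    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chromosome, []).append(g)

    total_w = sum(lengths.values())
    chrom_probs = np.array([lengths[c] / total_w for c in chrom_names])
    annotations: list[TEAnnotation] = []
    fallback_flags: list[bool] = []
    n_fallback = 0

    for spec in family_specs:
        entry = spec.entry
        for _ in range(spec.copy_number):
            placed = False
            for _try in range(max_place_tries):
                strand = "+" if rng.random() < spec.strand_bias else "-"
                seq = entry.sequence
                t5 = t3 = 0
                if rng.random() < spec.truncation_prob:
                    frac = rng.uniform(*spec.truncation_frac)
                    cut = max(1, int(frac * entry.length))
                    side = rng.integers(3)  # 0: 5', 1: 3', 2: both
                    if side in (0, 2):
                        t5 = cut // (2 if side == 2 else 1)
                    if side in (1, 2):
                        t3 = cut // (2 if side == 2 else 1)
                    if t5 + t3 >= entry.length:
                        continue
                seq = seq[t5:entry.length - t3]
                if spec.divergence > 0:
                    enc = _seq.encode(seq)
                    nmut = rng.binomial(len(seq), spec.divergence)
                    if nmut:
                        at = rng.choice(len(seq), size=nmut, replace=False)
                        enc[at] = (enc[at] + rng.integers(1, 4, size=nmut)) % 4
                    seq = _seq.decode(enc)
                if strand == "-":
                    seq = _seq.revcomp(seq)
                Lc = len(seq)

                if spec.tss_distance is not None:
                    cands = genes
                    g = cands[int(rng.integers(len(cands)))]
                    d = int(rng.lognormal(np.log(spec.tss_distance[0]),
                                          spec.tss_distance[1]))
                    pos = g.tss - d - Lc if g.strand == "+" else g.tss + d
                    chrom = g.chromosome
                else:
                    chrom = chrom_names[int(rng.choice(len(chrom_names),
                                                       p=chrom_probs))]
                    pos = _sample_niche_position(rng, spec.niche,
                                                 spec.concentration,
                                                 centromeres[chrom],
                                                 lengths[chrom])

                B = background[chrom]
                occ = occupancy[chrom]
                is_fb = False
                q = -1
                if spec.motif is not None:
                    if strand == "+":
                        lsets = spec.motif.left_sets
                        rsets = spec.motif.right_sets
                    else:
                        lsets = _seq.revcomp_motif(spec.motif.right_sets)
                        rsets = _seq.revcomp_motif(spec.motif.left_sets)
                    lmask, rmask = _motif_mask(lsets), _motif_mask(rsets)
                    for off in range(spec.motif_search_radius + 1):
                        for cand in ((pos + off, pos - off) if off else (pos,)):
                            if not occ.is_free(cand - len(lsets),
                                               cand + Lc + len(rsets)):
                                continue
                            if _match_encoded(B, cand - len(lsets), lmask) and \
                                    _match_encoded(B, cand + Lc, rmask):
                                q = cand
                                break
                        if q >= 0:
                            break
                    if q < 0:
                        is_fb = True
                if q < 0:  # motif-free (or fallback) placement
                    if not occ.is_free(pos, pos + Lc):
                        continue
                    q = pos

                B[q:q + Lc] = _seq.encode(seq)
                occ.add(q, q + Lc)
                identity = round(100.0 * (1.0 - spec.divergence), 2)
                # cuts were applied before reverse-complementing, so the
                # intactness flags are element-oriented on either strand
                five_ok, three_ok = t5 == 0, t3 == 0
                annotations.append(TEAnnotation(
                    chrom, q, q + Lc, entry.name, entry.superfamily, strand,
                    identity, five_prime_intact=five_ok,
                    three_prime_intact=three_ok))
                fallback_flags.append(is_fb)
                n_fallback += int(is_fb)
                placed = True
                break
            if not placed:
                logger.warning("dropped a %s copy: no free placement found",
                               entry.name)
    if n_fallback:
        logger.info("simulate_genome: %d/%d copies placed without motif match "
                    "(fallback)", n_fallback, len(annotations))

    pairs = sorted(range(len(annotations)),
                   key=lambda i: (annotations[i].chromosome, annotations[i].start))
    annotations = [annotations[i] for i in pairs]
    fallback_flags = [fallback_flags[i] for i in pairs]

    assembly = GenomeAssembly({c: _seq.decode(background[c]) for c in chrom_names})
    truth = TruthSet(annotations, genes, centromeres, fallback_flags,
                     promoter_te_status(genes, annotations))
    return assembly, truth


# ---------------------------------------------------------------------------
# methylome simulation
# ---------------------------------------------------------------------------

def _context_plus(enc: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """0=CG, 1=CHG, 2=CHH, -1=undetermined, for C sites on the plus strand."""
    n = len(enc)
    ctx = np.full(len(pos), 2, dtype=np.int8)
    nxt = np.where(pos + 1 < n, enc[np.minimum(pos + 1, n - 1)], 4)
    nxt2 = np.where(pos + 2 < n, enc[np.minimum(pos + 2, n - 1)], 4)
    ctx[nxt == 2] = 0
    ctx[(nxt != 2) & (nxt2 == 2)] = 1
    ctx[(nxt == 4) | ((nxt != 2) & (nxt2 == 4))] = -1
    ctx[pos + 1 >= n] = -1
    ctx[(pos + 2 >= n) & (ctx != 0)] = -1
    return ctx


def simulate_methylome(assembly: GenomeAssembly,
                       genes: Sequence[GeneModel],
                       truth: TruthSet,
                       spec: MethylomeSpec,
                       seed: int = 0) -> pd.DataFrame:
    """Binomially sampled per-cytosine calls (call-table layout).

    Site probability = context baseline x TSS-shape x promoter-TE factor;
    the CHH promoter mound adds to the CHH baseline before the TE factor.
    """
    rng = np.random.default_rng(seed)
    status = truth.promoter_status if truth.promoter_status is not None else \
        promoter_te_status(genes, truth.annotations)
    target = spec.promoter_te_superfamily
    affected = set(status.index[status[target]]) if target in status.columns else set()

    frames = []
    for chrom, seqstr in assembly.sequences.items():
        enc = _seq.encode(seqstr)
        n = len(enc)
        dip = np.ones(n, dtype=np.float32)
        chh_mound = np.zeros(n, dtype=np.float32)
        te_cgchg = np.ones(n, dtype=np.float32)
        te_chh = np.ones(n, dtype=np.float32)
        for g in genes:
            if g.chromosome != chrom:
                continue
            w = spec.tss_dip_width
            lo, hi = max(0, g.tss - w), min(n, g.tss + w)
            d = np.abs(np.arange(lo, hi) - g.tss) / w
            np.minimum(dip[lo:hi],
                       1.0 - spec.tss_dip_depth * (1.0 - d), out=dip[lo:hi])
            if g.strand == "+":
                m0, m1 = max(0, g.tss - spec.chh_mound_width), g.tss
                b0, b1 = g.start, g.end
            else:
                m0, m1 = g.tss, min(n, g.tss + spec.chh_mound_width)
                b0, b1 = g.start, g.end
            np.maximum(chh_mound[m0:m1], spec.chh_mound_height,
                       out=chh_mound[m0:m1])
            np.maximum(dip[b0:b1], spec.genic_cg_recovery, out=dip[b0:b1])
            if g.id in affected:
                if g.strand == "+":
                    p0, p1 = max(0, g.tss - 1500), min(n, g.tss + 500)
                else:
                    p0, p1 = max(0, g.tss - 500), min(n, g.tss + 1500)
                te_cgchg[p0:p1] = spec.promoter_te_cg_chg_factor
                te_chh[p0:p1] = spec.promoter_te_chh_factor

        for strand in "+-":
            if strand == "+":
                pos = np.flatnonzero(enc == 1)
                ctx = _context_plus(enc, pos)
            else:
                pos = np.flatnonzero(enc == 2)
                ctx = _context_plus(_seq.revcomp_encoded(enc), n - 1 - pos)
            keep = ctx >= 0
            pos, ctx = pos[keep], ctx[keep]
            base = np.array([spec.baseline["CG"], spec.baseline["CHG"],
                             spec.baseline["CHH"]], dtype=np.float32)[ctx]
            p = np.where(ctx == 2,
                         (base + chh_mound[pos]) * te_chh[pos],
                         base * dip[pos] * te_cgchg[pos])
            p = np.clip(p, 0.0, 1.0)
            depth = rng.poisson(spec.depth_mean, size=len(pos))
            meth = rng.binomial(depth, p)
            frames.append(pd.DataFrame({
                "chromosome": chrom, "position": pos, "strand": strand,
                "context": np.array(["CG", "CHG", "CHH"])[ctx],
                "methylated": meth, "total": depth}))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chromosome", "position", "strand", "context", "methylated",
                 "total"])
    df = df.sort_values(["chromosome", "position", "strand"],
                        kind="stable").reset_index(drop=True)
    logger.info("simulate_methylome: %d cytosine calls", len(df))
    return df


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_simulation(outdir: str | Path, assembly: GenomeAssembly,
                     truth: TruthSet, library: Sequence[TELibraryEntry],
                     methylome: pd.DataFrame | None = None) -> None:
    """Write genome FASTA, truth TE/gene GFF3, library FASTA, centromere
    sidecar TSV, and (optionally) the methylation call table."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(assembly, out / "genome.fa")
    write_te_library(library, out / "library.fa")
    write_gff3_te(truth.annotations, out / "truth_te.gff3")
    write_gff3_genes(truth.genes, out / "genes.gff3")
    write_centromeres(truth.centromeres, out / "centromeres.tsv")
    if methylome is not None:
        write_methylation_table(methylome, out / "methylation.tsv")
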