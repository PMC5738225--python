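"""Seed-and-extend ungapped local search of genome segments against a TE library.

This is the built-in aligner behind ``te_annotation.search_segments``: an
exact k-mer seed stage followed by x-drop ungapped extension, confined to the
query segment. Kernels are numba-compiled; the Python wrapper owns the
library index and coordinate bookkeeping (minus-strand hits are reported in
forward-consensus coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from ._seq import encode, revcomp_encoded

MATCH = 1
MISMATCH = -2
XDROP = 20


@dataclass(frozen=True)
class LibraryIndex:
    """Concatenated, k-mer indexed library (forward + reverse complement)."""

    names: tuple[str, ...]          # per entry pair index -> family name
    k: int
    seq: np.ndarray                 # uint8 concat of all entry sequences
    entry_start: np.ndarray         # int64 per entry
    entry_end: np.ndarray
    entry_family: np.ndarray        # int32 index into names
    entry_minus: np.ndarray         # bool: entry holds the reverse complement
    kcodes: np.ndarray              # sorted int64 k-mer codes
    kpos: np.ndarray                # int64 absolute position in ``seq``
    kentry: np.ndarray              # int32 entry index

    def family_length(self, fam_idx: int) -> int:
        e = 2 * fam_idx
        return int(self.entry_end[e] - self.entry_start[e])


def _kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(codes, start positions) of all N-free k-mers of an encoded sequence."""
    if len(enc) < k:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    win = np.lib.stride_tricks.sliding_window_view(enc, k)
    ok = (win < 4).all(axis=1)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    codes = win.astype(np.int64) @ powers
    pos = np.flatnonzero(ok).astype(np.int64)
    return codes[ok], pos


def build_index(library, k: int = 12) -> LibraryIndex:
    """Index a list of ``TELibraryEntry`` (or (name, sequence) pairs)."""
    names, parts, fam, minus = [], [], [], []
    for i, entry in enumerate(library):
        name, seq = (entry.name, entry.sequence) if hasattr(entry, "name") else entry
        names.append(name)
        enc = encode(seq)
        parts.append(enc)
        fam.append(i)
        minus.append(False)
        parts.append(revcomp_encoded(enc))
        fam.append(i)
        minus.append(True)
    lengths = np.array([len(p) for p in parts], dtype=np.int64)
    entry_end = np.cumsum(lengths)
    entry_start = entry_end - lengths
    concat = np.concatenate(parts) if parts else np.empty(0, np.uint8)

    codes_all, pos_all, ent_all = [], [], []
    for e, part in enumerate(parts):
        codes, pos = _kmer_codes(part, k)
        codes_all.append(codes)
        pos_all.append(pos + entry_start[e])
        ent_all.append(np.full(len(codes), e, dtype=np.int32))
    kcodes = np.concatenate(codes_all) if codes_all else np.empty(0, np.int64)
    kpos = np.concatenate(pos_all) if pos_all else np.empty(0, np.int64)
    kentry = np.concatenate(ent_all) if ent_all else np.empty(0, np.int32)
    order = np.argsort(kcodes, kind="stable")
    return LibraryIndex(tuple(names), k, concat, entry_start, entry_end,
                        np.array(fam, np.int32), np.array(minus, bool),
                        kcodes[order], kpos[order], kentry[order])


@njit(cache=True)
def _extend(enc, lib, g0, l0, k, s0, s1, e0, e1):
    """X-drop ungapped extension around an exact k-mer seed.

    Returns (gstart, gend, lstart, lend, matches) of the max-scoring span.
    """
    # right of the seed
    score = k * MATCH
    best = score
    g_best = g0 + k
    l_best = l0 + k
    g, l = g0 + k, l0 + k
    while g < s1 and l < e1:
        if enc[g] < 4 and enc[g] == lib[l]:
            score += MATCH
        else:
            score += MISMATCH
        g += 1
        l += 1
        if score > best:
            best = score
            g_best = g
            l_best = l
        elif best - score > XDROP:
            break
    gend, lend = g_best, l_best
    # left of the seed
    score = best
    g_best, l_best = g0, l0
    g, l = g0 - 1, l0 - 1
    while g >= s0 and l >= e0:
        if enc[g] < 4 and enc[g] == lib[l]:
            score += MATCH
        else:
            score += MISMATCH
        if score > best:
            best = score
            g_best = g
            l_best = l
        elif best - score > XDROP:
            break
        g -= 1
        l -= 1
    gstart, lstart = g_best, l_best
    matches = 0
    for t in range(gend - gstart):
        if enc[gstart + t] < 4 and enc[gstart + t] == lib[lstart + t]:
            matches += 1
    return gstart, gend, lstart, lend, matches


@njit(cache=True)
def _scan(enc, seg_len, lib, kcodes, kpos, kentry, entry_start, entry_end, k, out):
    """Per segment, best hit per library entry. ``out`` is (cap, 8) int64.

    Row: seg_index, entry, gstart, gend, lstart, lend, matches, span.
    Returns number of rows written (-1 on overflow).
    """
    n = len(enc)
    n_entries = len(entry_start)
    nseg = (n + seg_len - 1) // seg_len
    mask = (np.int64(1) << np.int64(2 * k)) - 1
    stamp = np.full(n_entries, -1, np.int64)
    b_score = np.zeros(n_entries, np.int64)
    b_fields = np.zeros((n_entries, 5), np.int64)
    touched = np.zeros(n_entries, np.int32)
    nk = len(kcodes)
    out_n = 0
    for seg in range(nseg):
        s0 = seg * seg_len
        s1 = min(s0 + seg_len, n)
        ntouch = 0
        code = np.int64(0)
        valid = 0
        for i in range(s0, s1):
            b = enc[i]
            if b > 3:
                valid = 0
                continue
            code = ((code << 2) | np.int64(b)) & mask
            valid += 1
            if valid < k:
                continue
            g0 = i - k + 1
            # equal range of `code` in sorted kcodes
            lo, hi = 0, nk
            while lo < hi:
                mid = (lo + hi) >> 1
                if kcodes[mid] < code:
                    lo = mid + 1
                else:
                    hi = mid
            t = lo
            while t < nk and kcodes[t] == code:
                e = kentry[t]
                l0 = kpos[t]
                t += 1
                if (stamp[e] == seg and b_fields[e, 0] <= g0
                        and g0 + k <= b_fields[e, 1]):
                    continue  # seed inside the best hit already found
                gs, ge, ls, le, m = _extend(enc, lib, g0, l0, k, s0, s1,
                                            entry_start[e], entry_end[e])
                span = ge - gs
                score = m * MATCH + (span - m) * MISMATCH
                if stamp[e] != seg:
                    stamp[e] = seg
                    touched[ntouch] = e
                    ntouch += 1
                    b_score[e] = -(1 << 60)
                if score > b_score[e]:
                    b_score[e] = score
                    b_fields[e, 0] = gs
                    b_fields[e, 1] = ge
                    b_fields[e, 2] = ls
                    b_fields[e, 3] = le
                    b_fields[e, 4] = m
        for j in range(ntouch):
            e = touched[j]
            if out_n >= out.shape[0]:
                return -1
            out[out_n, 0] = seg
            out[out_n, 1] = e
            out[out_n, 2] = b_fields[e, 0]
            out[out_n, 3] = b_fields[e, 1]
            out[out_n, 4] = b_fields[e, 2]
            out[out_n, 5] = b_fields[e, 3]
            out[out_n, 6] = b_fields[e, 4]
            out[out_n, 7] = b_fields[e, 1] - b_fields[e, 0]
            out_n += 1
    return out_n


def scan_chromosome(sequence: str, index: LibraryIndex, segment_length: int,
                    min_identity: float, min_hit_length: int) -> np.ndarray:
    """Run the segment scan over one chromosome.

    Returns an int64 array with columns (segment, family, strand(0/1 for +/-),
    gstart, gend, lstart, lend, matches, span) where lstart/lend are
    forward-consensus coordinates and identity filtering is applied.
    """
    enc = encode(sequence)
    cap = max(1024, 8 * (len(enc) // segment_length + 1))
    while True:
        out = np.zeros((cap, 8), np.int64)
        n = _scan(enc, segment_length, index.seq, index.kcodes, index.kpos,
                  index.kentry, index.entry_start, index.entry_end, index.k, out)
        if n >= 0:
            out = out[:n]
            break
        cap *= 4
    if not len(out):
        return np.empty((0, 9), np.int64)
    ent = out[:, 1].astype(np.int64)
    fam = index.entry_family[ent].astype(np.int64)
    minus = index.entry_minus[ent]
    ls = out[:, 4] - index.entry_start[ent]
    le = out[:, 5] - index.entry_start[ent]
    elen = index.entry_end[ent] - index.entry_start[ent]
    # minus-strand entries hold the reverse complement: map back
    ls2 = np.where(minus, elen - le, ls)
    le2 = np.where(minus, elen - ls, le)
    res = np.column_stack([out[:, 0], fam, minus.astype(np.int64),
                           out[:, 2], out[:, 3], ls2, le2, out[:, 6], out[:, 7]])
    keep = (res[:, 8] >= min_hit_length) & \
           (res[:, 7] * 100.0 >= min_identity * res[:, 8])
    return res[keep]
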