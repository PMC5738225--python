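"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by naive enumeration / quadratic scans
so they stay independent of the implementation paths they check.
"""

from __future__ import annotations

import numpy as np


def best_ungapped_local(a: str, b: str, match: int = 1, mismatch: int = -2
                        ) -> tuple[int, int, float]:
    """Quadratic scan over all diagonals for the best ungapped local
    alignment of two sequences. Returns (score, length, identity_percent)."""
    ea = np.frombuffer(a.encode(), dtype=np.uint8)
    eb = np.frombuffer(b.encode(), dtype=np.uint8)
    best = (0, 0, 0.0)
    for d in range(-(len(b) - 1), len(a)):
        i0, j0 = max(0, d), max(0, -d)
        n = min(len(a) - i0, len(b) - j0)
        if n <= 0:
            continue
        eq = ea[i0:i0 + n] == eb[j0:j0 + n]
        scores = np.where(eq, match, mismatch)
        # Kadane with span tracking
        cur = 0
        cur_start = 0
        matches = 0
        for k in range(n):
            if cur <= 0:
                cur = 0
                cur_start = k
                matches = 0
            cur += scores[k]
            matches += int(eq[k])
            if cur > best[0]:
                length = k - cur_start + 1
                best = (cur, length, 100.0 * matches / length)
    return best


def merge_bridge_fixpoint(hits, bridge_gap: int = 100):
    """Repeatedly apply the two merge rules until nothing changes.

    ``hits``: sequence of objects with start/end/family/strand/identity.
    A gap between same-family same-strand intervals is bridged when strictly
    shorter than ``bridge_gap`` and no hit of a *different* family overlaps
    the open gap. Returns sorted (start, end, family, strand, identity).
    """
    blockers = [(h.start, h.end, h.family) for h in hits]
    items = [[h.start, h.end, h.family, h.strand, h.identity] for h in hits]

    def blocked(a: int, b: int, family: str) -> bool:
        return any(s < b and e > a and f != family for s, e, f in blockers)

    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                hi, hj = items[i], items[j]
                if hi[2] != hj[2] or hi[3] != hj[3]:
                    continue
                first, second = (hi, hj) if hi[0] <= hj[0] else (hj, hi)
                gap = second[0] - first[1]
                if gap <= 0 or (gap < bridge_gap and
                                not blocked(first[1], second[0], hi[2])):
                    hi[0] = min(hi[0], hj[0])
                    hi[1] = max(hi[1], hj[1])
                    hi[4] = max(hi[4], hj[4])
                    del items[j]
                    changed = True
                    break
            if changed:
                break
    return sorted((s, e, f, st, idn) for s, e, f, st, idn in items)


def clustered_fraction_expectation_n3(gene_length: int, chrom_length: int,
                                      max_gap: int) -> float:
    """Exact expected clustered-gene fraction for 3 equal-length genes placed
    uniformly (discretized, non-overlapping) on one chromosome.

    Enumerates inner-gap pairs (g1, g2); the number of placements with those
    inner gaps is the count of non-negative outer slack splits.
    """
    slack = chrom_length - 3 * gene_length
    g = np.arange(slack + 1)
    g1, g2 = np.meshgrid(g, g, indexing="ij")
    weight = (slack - g1 - g2 + 1).astype(float)
    weight[weight < 0] = 0.0
    near1 = g1 < max_gap
    near2 = g2 < max_gap
    frac = np.where(near1 & near2, 1.0,
                    np.where(near1 | near2, 2.0 / 3.0, 0.0))
    return float((weight * frac).sum() / weight.sum())


def pooled_window_level(calls, chrom: str, window_start: int, window: int,
                        context: str) -> float | None:
    """Direct-summation #C/(#C+#T) over one window, one context."""
    meth = tot = 0
    for c in calls:
        if (c.chromosome == chrom and c.context == context and c.total > 0
                and window_start <= c.position < window_start + window):
            meth += c.methylated
            tot += c.total
    return meth / tot if tot else None
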