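"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive expected values by a different route than the
package (exhaustive substring enumeration, pandas group-bys, python loops)
so that agreement is evidence of correctness, not shared code.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def exhaustive_maximal_segments(seq: str, reward: int = 17, penalty: int = 1):
    """All maximal-scoring segments by recursive exhaustive search.

    Tokenises the sequence (CG pairs reward, every other base penalised),
    then recursively extracts the best-scoring token substring — scanning
    every (i, j) — with ties resolved max score -> shortest -> leftmost,
    and recurses into the flanks.  Returns sorted (start, end, score) in
    base coordinates.
    """
    seq = seq.upper()
    tok = []
    i = 0
    while i < len(seq):
        if seq[i : i + 2] == "CG":
            tok.append((i, 2, reward))
            i += 2
        else:
            tok.append((i, 1, -penalty))
            i += 1
    prefix = [0]
    for _, _, s in tok:
        prefix.append(prefix[-1] + s)

    def best(lo, hi):
        bs, bl, bi, bj = 0, None, None, None
        for a in range(lo, hi):
            for b in range(a + 1, hi + 1):
                sc = prefix[b] - prefix[a]
                ln = b - a
                if sc > bs or (
                    sc == bs
                    and bi is not None
                    and (ln < bl or (ln == bl and a < bi))
                ):
                    bs, bl, bi, bj = sc, ln, a, b
        return bs, bi, bj

    out = []

    def rec(lo, hi):
        sc, a, b = best(lo, hi)
        if a is None:
            return
        rec(lo, a)
        out.append((tok[a][0], tok[b - 1][0] + tok[b - 1][1], sc))
        rec(b, hi)

    rec(0, len(tok))
    return sorted(out)


def gg_recount(seq: str):
    """Sliding per-position recount of GC fraction and O/E ratio."""
    seq = seq.upper()
    n_c = n_g = n_cg = 0
    for i, base in enumerate(seq):
        if base == "C":
            n_c += 1
        elif base == "G":
            n_g += 1
        if seq[i : i + 2] == "CG":
            n_cg += 1
    gc = (n_c + n_g) / len(seq)
    oe = n_cg * len(seq) / (n_c * n_g) if n_c * n_g else 0.0
    return gc, oe


def binned_means_groupby(meth_frame: pd.DataFrame, island, all_islands, flank, bin_width):
    """Per-bin shore means via an independent pandas group-by.

    ``island`` and ``all_islands`` carry .chrom/.start/.end.  Returns
    {(side, bin_index_0based): (mean_percent, n_cpgs)} for non-empty bins.
    """
    df = meth_frame[meth_frame["chrom"] == island.chrom].copy()
    df["percent"] = 100.0 * df["n_meth"] / (df["n_meth"] + df["n_unmeth"])
    inside_any = pd.Series(False, index=df.index)
    for other in all_islands:
        if other.chrom == island.chrom:
            inside_any |= (df["pos"] >= other.start) & (df["pos"] < other.end)
    df = df[~inside_any]
    out = {}
    for side in ("upstream", "downstream"):
        if side == "downstream":
            sel = df[(df["pos"] >= island.end) & (df["pos"] < island.end + flank)]
            offset = sel["pos"] - island.end + 1
        else:
            sel = df[(df["pos"] >= island.start - flank) & (df["pos"] < island.start)]
            offset = island.start - sel["pos"]
        bins = (offset - 1) // bin_width
        grouped = sel.groupby(bins)["percent"]
        for k, grp in grouped:
            out[(side, int(k))] = (float(grp.mean()), int(len(grp)))
    return out


def reverse_methylome_frame(frame: pd.DataFrame, chrom_length: int) -> pd.DataFrame:
    """Point-reflect sites: pos -> chrom_length - 1 - pos.

    Together with interval reflection this swaps upstream/downstream roles
    while preserving every site-to-boundary distance exactly, which is the
    transformation the mirror-symmetry invariants are stated over.
    """
    out = frame.copy()
    out["pos"] = chrom_length - 1 - out["pos"]
    return out.sort_values(["chrom", "pos"]).reset_index(drop=True)


def reverse_interval(start: int, end: int, chrom_length: int) -> tuple[int, int]:
    return chrom_length - end, chrom_length - start
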