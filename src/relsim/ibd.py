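"""Exact pairwise IBD segments from tracked founder ids, and IBD summaries.

At every genomic interval the four haplotypes of a pair are compared by
their founder-haplotype ids under a maximal bipartite matching: two matched
haplotype pairs with distinct partners give IBD2, one gives IBD1.  Segment
genetic coordinates are always reported on the sex-averaged axis, and the
sharing fractions k1/k2 are genetic-length fractions of the total
sex-averaged autosomal map.

Summaries follow the standard definitions: IBD proportion (diploid sharing
fraction) ``k2 + k1/2`` and kinship coefficient ``k2/2 + k1/4``.  Kinship is
mapped to a degree of relatedness with the powers-of-two ranges KING uses:
degree ``d`` for kinship in ``(2**-(d+1.5), 2**-(d+0.5)]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Individual
from .genetic_map import GeneticMap


@dataclass
class IBDSegment:
    pair: tuple[str, str]
    chrom: str
    phys_start: float
    phys_end: float
    type: str  # "IBD1" | "IBD2"
    gen_start: float  # sex-averaged cM
    gen_end: float

    @property
    def length_cM(self) -> float:
        return self.gen_end - self.gen_start


@dataclass
class IBDStats:
    k1: float
    k2: float
    n_segments: int
    total_cM: float

    @property
    def proportion(self) -> float:
        """Diploid genome sharing fraction, k2 + k1/2."""
        return self.k2 + 0.5 * self.k1

    @property
    def kinship(self) -> float:
        """k2/2 + k1/4 (half the IBD proportion)."""
        return 0.5 * self.k2 + 0.25 * self.k1


def _match_count(a1: int, a2: int, b1: int, b2: int) -> int:
    """Maximal matching between {a1, a2} and {b1, b2} by founder id."""
    direct = (a1 == b1) + (a2 == b2)
    crossed = (a1 == b2) + (a2 == b1)
    return max(direct, crossed)


def ibd_segments(a: Individual, b: Individual, gmap: GeneticMap) -> list[IBDSegment]:
    """Exact IBD segments between two individuals from one founder pool.

    Sweeps the merged run boundaries of the four haplotypes, classifies each
    interval as IBD2/IBD1/none by maximal id matching, and merges adjacent
    intervals of equal type.  Symmetric in its arguments.
    """
    if a.founder_pool != b.founder_pool:
        raise ValueError(
            f"individuals come from different founder pools: "
            f"{a.founder_pool} vs {b.founder_pool}"
        )
    segments: list[IBDSegment] = []
    pair = (a.id, b.id)
    for c in gmap:
        haps = [
            a.haplotypes[0][c.name],
            a.haplotypes[1][c.name],
            b.haplotypes[0][c.name],
            b.haplotypes[1][c.name],
        ]
        bounds = sorted({e for _, ends in haps for e in ends})
        ptr = [0, 0, 0, 0]
        start = c.span()[0]
        prev = start
        open_seg: list | None = None  # [type, phys_start]
        raw: list[tuple[str, float, float]] = []
        for edge in bounds:
            ids = [haps[k][0][ptr[k]] for k in range(4)]
            m = _match_count(*ids)
            typ = None if m == 0 else ("IBD1" if m == 1 else "IBD2")
            if open_seg is not None and open_seg[0] != typ:
                raw.append((open_seg[0], open_seg[1], prev))
                open_seg = None
            if typ is not None and open_seg is None:
                open_seg = [typ, prev]
            for k in range(4):
                if haps[k][1][ptr[k]] <= edge:
                    ptr[k] += 1
            prev = edge
        if open_seg is not None:
            raw.append((open_seg[0], open_seg[1], prev))
        if not raw:
            continue
        # genetic coordinates on the sex-averaged axis, one interp call
        pts = np.array([[s, e] for _, s, e in raw], dtype=float)
        # the implicit start of the first interval is the chromosome start
        gen = np.interp(pts, c.phys, c.gen_column("averaged"))
        for (typ, s, e), (gs, ge) in zip(raw, gen):
            segments.append(IBDSegment(pair, c.name, s, e, typ, float(gs), float(ge)))
    return segments


def ibd_stats(segments: list[IBDSegment], gmap: GeneticMap) -> IBDStats:
    """Genome-wide sharing fractions from a segment list (possibly empty)."""
    total = gmap.total_length_cM("averaged")
    len1 = sum(s.length_cM for s in segments if s.type == "IBD1")
    len2 = sum(s.length_cM for s in segments if s.type == "IBD2")
    return IBDStats(
        k1=len1 / total,
        k2=len2 / total,
        n_segments=len(segments),
        total_cM=len1 + len2,
    )


def pair_stats(a: Individual, b: Individual, gmap: GeneticMap) -> IBDStats:
    return ibd_stats(ibd_segments(a, b, gmap), gmap)


def degree_of_relatedness(kinship: float, max_degree: int = 9) -> int | None:
    """Degree of relatedness from a kinship coefficient.

    Returns 0 for duplicate/monozygotic pairs (kinship > 2**-1.5 ~ 0.354),
    an integer degree ``d`` when kinship lies in ``(2**-(d+1.5),
    2**-(d+0.5)]``, and ``None`` (unrelated) below the supported range.
    """
    if not 0.0 <= kinship <= 0.5:
        raise ValueError("kinship must be in [0, 0.5]")
    if kinship > 2.0**-1.5:
        return 0
    for d in range(1, max_degree + 1):
        if kinship > 2.0 ** -(d + 1.5):
            return d
    return None


# ---------------------------------------------------------------------------
# segment file I/O (PREFIX.seg)

_SEG_HEADER = "#id1\tid2\tchrom\tphys_start\tphys_end\ttype\tgen_start_cM\tgen_end_cM\tlength_cM"


def write_seg(segments: list[IBDSegment], path) -> None:
    """Write segments in the tab-separated .seg format.

    Physical coordinates are rounded to integer bp at output time (a
    crossover at real coordinate x closes the previous run at floor(x));
    genetic coordinates are sex-averaged cM.
    """
    with open(path, "w") as fh:
        fh.write(_SEG_HEADER + "\n")
        for s in segments:
            fh.write(
                f"{s.pair[0]}\t{s.pair[1]}\t{s.chrom}\t{int(np.floor(s.phys_start))}\t"
                f"{int(np.floor(s.phys_end))}\t{s.type}\t{s.gen_start:.6f}\t"
                f"{s.gen_end:.6f}\t{s.length_cM:.6f}\n"
            )


def read_seg(path) -> list[IBDSegment]:
    out: list[IBDSegment] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}: expected 9 tab-separated columns")
            out.append(
                IBDSegment(
                    pair=(f[0], f[1]),
                    chrom=f[2],
                    phys_start=float(f[3]),
                    phys_end=float(f[4]),
                    type=f[5],
                    gen_start=float(f[6]),
                    gen_end=float(f[7]),
                )
            )
    return out
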