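"""Genetic maps: containers, file I/O, interpolation, and synthetic fixtures.

A genetic map relates physical coordinates (base pairs) to genetic
coordinates (centiMorgans) through a table of knots per chromosome.  Two
dialects are supported:

* ``sex-specific``: each knot carries a male and a female cM position
  (columns ``chrom phys_bp male_cM female_cM``);
* ``sex-averaged``: each knot carries a single cM position
  (columns ``chrom phys_bp avg_cM``).

Files are whitespace-delimited plain text; lines starting with ``#`` are
comments.  The sex-averaged coordinate of a sex-specific map is defined as
the midpoint of the male and female coordinates at the same physical
position.  No extrapolation is performed beyond the mapped span: simulated
chromosomes begin at the first knot and end at the last, and the crossover
rate is treated as zero outside the mapped region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

SEX_SPECIFIC = "sex-specific"
SEX_AVERAGED = "sex-averaged"

_VALID_SEXES = ("male", "female", "averaged")


class MalformedMapError(ValueError):
    """A map file or knot table violates the map invariants."""


class MapRangeError(ValueError):
    """A queried coordinate lies outside the mapped span (no extrapolation)."""


@dataclass
class ChromosomeMap:
    """Knot table for one chromosome.

    Physical positions are 1-based integer bp and strictly increasing; each
    genetic column is non-decreasing.  Interpolated physical positions are
    real-valued internally and rounded to integer bp only at output time.
    """

    name: str
    phys: np.ndarray
    gen: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        self.phys = np.asarray(self.phys, dtype=float)
        if self.phys.size < 2:
            raise MalformedMapError(
                f"chromosome {self.name!r}: needs >=2 knots, got {self.phys.size}"
            )
        if np.any(np.diff(self.phys) <= 0):
            raise MalformedMapError(
                f"chromosome {self.name!r}: physical positions must strictly increase"
            )
        if self.phys[0] < 1:
            raise MalformedMapError(f"chromosome {self.name!r}: physical positions are 1-based bp")
        self.gen = {s: np.asarray(g, dtype=float) for s, g in self.gen.items()}
        for sex, g in self.gen.items():
            if g.shape != self.phys.shape:
                raise MalformedMapError(
                    f"chromosome {self.name!r}: genetic column {sex!r} length mismatch"
                )
            if np.any(np.diff(g) < 0):
                raise MalformedMapError(
                    f"chromosome {self.name!r}: genetic column {sex!r} must be non-decreasing"
                )

    # -- basic geometry ----------------------------------------------------
    @property
    def dialect(self) -> str:
        return SEX_AVERAGED if "averaged" in self.gen else SEX_SPECIFIC

    def span(self) -> tuple[float, float]:
        """(first, last) mapped physical position in bp."""
        return float(self.phys[0]), float(self.phys[-1])

    def gen_column(self, sex: str) -> np.ndarray:
        """Genetic positions (cM) at the knots for ``sex``.

        ``averaged`` on a sex-specific map returns the male/female midpoint.
        On a sex-averaged map every sex resolves to the single column.
        """
        if sex not in _VALID_SEXES:
            raise ValueError(f"unknown sex {sex!r}")
        if "averaged" in self.gen:
            return self.gen["averaged"]
        if sex == "averaged":
            return 0.5 * (self.gen["male"] + self.gen["female"])
        return self.gen[sex]

    def length_cM(self, sex: str = "averaged") -> float:
        g = self.gen_column(sex)
        return float(g[-1] - g[0])

    # -- interpolation -----------------------------------------------------
    def phys_to_gen(self, bp, sex: str = "averaged"):
        bp_arr = np.asarray(bp, dtype=float)
        lo, hi = self.span()
        if np.any(bp_arr < lo - 1e-9) or np.any(bp_arr > hi + 1e-9):
            raise MapRangeError(
                f"chromosome {self.name!r}: physical position outside mapped span [{lo}, {hi}]"
            )
        out = np.interp(bp_arr, self.phys, self.gen_column(sex))
        return float(out) if np.isscalar(bp) or bp_arr.ndim == 0 else out

    def gen_to_phys(self, cM, sex: str = "averaged"):
        g = self.gen_column(sex)
        cm_arr = np.asarray(cM, dtype=float)
        if np.any(cm_arr < g[0] - 1e-9) or np.any(cm_arr > g[-1] + 1e-9):
            raise MapRangeError(
                f"chromosome {self.name!r}: genetic position outside mapped span "
                f"[{g[0]}, {g[-1]}] cM"
            )
        out = np.interp(cm_arr, g, self.phys)
        return float(out) if np.isscalar(cM) or cm_arr.ndim == 0 else out


class GeneticMap:
    """Ordered collection of :class:`ChromosomeMap` with a common dialect."""

    def __init__(self, chromosomes: Sequence[ChromosomeMap]):
        if not chromosomes:
            raise MalformedMapError("a genetic map needs at least one chromosome")
        dialects = {c.dialect for c in chromosomes}
        if len(dialects) != 1:
            raise MalformedMapError("all chromosomes must share one dialect")
        self.chromosomes: list[ChromosomeMap] = list(chromosomes)
        self._by_name = {c.name: c for c in self.chromosomes}
        if len(self._by_name) != len(self.chromosomes):
            raise MalformedMapError("duplicate chromosome labels")

    @property
    def dialect(self) -> str:
        return self.chromosomes[0].dialect

    def __iter__(self) -> Iterator[ChromosomeMap]:
        return iter(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    def chrom(self, name: str) -> ChromosomeMap:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"chromosome {name!r} not in map") from None

    def total_length_cM(self, sex: str = "averaged") -> float:
        return sum(c.length_cM(sex) for c in self.chromosomes)


# ---------------------------------------------------------------------------
# file I/O


def read_genetic_map(path, dialect: str | None = None) -> GeneticMap:
    """Read a whitespace-delimited genetic map file.

    ``dialect`` may be ``"sex-specific"``, ``"sex-averaged"`` or ``None`` to
    infer it from the column count (4 vs 3).  Malformed files (non-monotone
    columns, <2 knots per chromosome, ragged rows) raise
    :class:`MalformedMapError` naming the offending line.
    """
    order: list[str] = []
    rows: dict[str, list[tuple[int, list[float]]]] = {}
    ncol_expected = {SEX_SPECIFIC: 4, SEX_AVERAGED: 3}.get(dialect)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if ncol_expected is None:
                if len(fields) not in (3, 4):
                    raise MalformedMapError(f"{path}:{lineno}: expected 3 or 4 columns")
                ncol_expected = len(fields)
                dialect = SEX_SPECIFIC if ncol_expected == 4 else SEX_AVERAGED
            if len(fields) != ncol_expected:
                raise MalformedMapError(
                    f"{path}:{lineno}: expected {ncol_expected} columns, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                vals = [float(v) for v in fields[1:]]
            except ValueError as exc:
                raise MalformedMapError(f"{path}:{lineno}: {exc}") from None
            if chrom not in rows:
                rows[chrom] = []
                order.append(chrom)
            prev = rows[chrom][-1][1] if rows[chrom] else None
            if prev is not None:
                if vals[0] <= prev[0]:
                    raise MalformedMapError(
                        f"{path}:{lineno}: physical position not increasing on chromosome {chrom}"
                    )
                for j in range(1, len(vals)):
                    if vals[j] < prev[j] - 1e-12:
                        raise MalformedMapError(
                            f"{path}:{lineno}: genetic position decreases on chromosome {chrom}"
                        )
            rows[chrom].append((lineno, vals))

    chroms = []
    for chrom in order:
        table = np.array([v for _, v in rows[chrom]], dtype=float)
        if table.shape[0] < 2:
            lineno = rows[chrom][0][0]
            raise MalformedMapError(f"{path}:{lineno}: chromosome {chrom} has <2 knots")
        if dialect == SEX_SPECIFIC:
            gen = {"male": table[:, 1], "female": table[:, 2]}
        else:
            gen = {"averaged": table[:, 1]}
        chroms.append(ChromosomeMap(chrom, table[:, 0], gen))
    return GeneticMap(chroms)


def write_genetic_map(gmap: GeneticMap, path) -> None:
    """Write ``gmap`` in the same plain-text format :func:`read_genetic_map` reads."""
    with open(path, "w") as fh:
        if gmap.dialect == SEX_SPECIFIC:
            fh.write("#chrom\tphys_bp\tmale_cM\tfemale_cM\n")
            for c in gmap:
                for bp, m, f in zip(c.phys, c.gen["male"], c.gen["female"]):
                    fh.write(f"{c.name}\t{int(round(bp))}\t{m:.10g}\t{f:.10g}\n")
        else:
            fh.write("#chrom\tphys_bp\tavg_cM\n")
            for c in gmap:
                for bp, a in zip(c.phys, c.gen["averaged"]):
                    fh.write(f"{c.name}\t{int(round(bp))}\t{a:.10g}\n")


def interpolate(gmap: GeneticMap, chrom: str, sex: str, value: float, direction: str) -> float:
    """Piecewise-linear interpolation on one chromosome.

    ``direction`` is ``"phys->gen"`` or ``"gen->phys"``.  Exact at knots; out
    of span raises :class:`MapRangeError`.
    """
    c = gmap.chrom(chrom)
    if direction == "phys->gen":
        return c.phys_to_gen(value, sex)
    if direction == "gen->phys":
        return c.gen_to_phys(value, sex)
    raise ValueError(f"unknown direction {direction!r}")


def sex_averaged_coordinate(gmap: GeneticMap, chrom: str, phys: float) -> float:
    """Sex-averaged cM at ``phys``: the male/female midpoint on a sex-specific
    map, or the single genetic coordinate on a sex-averaged map."""
    return gmap.chrom(chrom).phys_to_gen(phys, "averaged")


def to_sex_averaged(gmap: GeneticMap) -> GeneticMap:
    """Collapse a sex-specific map to its sex-averaged dialect."""
    if gmap.dialect == SEX_AVERAGED:
        return gmap
    chroms = [
        ChromosomeMap(c.name, c.phys.copy(), {"averaged": c.gen_column("averaged").copy()})
        for c in gmap
    ]
    return GeneticMap(chroms)


# ---------------------------------------------------------------------------
# synthetic fixture maps


def _per_chrom(value, n_chrom: int, name: str) -> list[float]:
    if np.isscalar(value):
        return [float(value)] * n_chrom
    vals = [float(v) for v in value]
    if len(vals) != n_chrom:
        raise ValueError(f"{name} must be scalar or length {n_chrom}")
    return vals


def make_synthetic_map(
    n_chrom: int = 1,
    phys_len: float | Sequence[float] = 100_000_000,
    male_len: float | Sequence[float] = 100.0,
    female_factor: float = 1.57,
    n_knots: int = 11,
    roughness: float = 0.0,
    seed: int = 0,
) -> GeneticMap:
    """Generate a deterministic synthetic sex-specific map.

    Per chromosome, the female genetic length is ``female_factor * male_len``
    (human females produce about 1.57 times more autosomal crossovers per
    meiosis than males, which motivates the default).  ``roughness`` controls
    local rate variation: 0 gives linear (uniform-rate) maps; larger values
    draw knot-interval weights from a gamma distribution with shape
    ``1/roughness**2``, independently for the male and female columns, so the
    local male:female rate ratio varies along the chromosome.

    ``phys_len`` and ``male_len`` may be scalars or per-chromosome sequences.
    Deterministic given ``seed``.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if n_knots < 2:
        raise ValueError("n_knots must be >= 2")
    if female_factor <= 0:
        raise ValueError("female_factor must be > 0")
    if roughness < 0:
        raise ValueError("roughness must be >= 0")
    phys_lens = _per_chrom(phys_len, n_chrom, "phys_len")
    male_lens = _per_chrom(male_len, n_chrom, "male_len")
    if any(v <= 0 for v in phys_lens):
        raise ValueError("phys_len must be positive")
    if any(v < 0 for v in male_lens):
        raise ValueError("male_len must be >= 0")

    rng = np.random.default_rng(seed)
    chroms = []
    for i in range(n_chrom):
        phys = np.round(np.linspace(1, phys_lens[i], n_knots)).astype(float)
        # guard against duplicate bp on very short chromosomes
        phys = np.unique(phys)
        k = phys.size
        gen = {}
        for sex, total in (("male", male_lens[i]), ("female", male_lens[i] * female_factor)):
            if roughness == 0:
                w = np.ones(k - 1)
            else:
                shape = 1.0 / roughness**2
                w = rng.gamma(shape, 1.0 / shape, size=k - 1)
                w = np.maximum(w, 1e-12)
            cum = np.concatenate([[0.0], np.cumsum(w)])
            gen[sex] = cum / cum[-1] * total
        chroms.append(ChromosomeMap(str(i + 1), phys, gen))
    return GeneticMap(chroms)
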