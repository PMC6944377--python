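"""Crossover position sampling along one meiosis.

Two inter-crossover models are provided, both producing positions in Morgans
along a chromosome of given genetic length:

* **Poisson**: inter-arrival distances are i.i.d. Exponential(1), i.e. one
  crossover per Morgan on average and no interference.
* **Housworth-Stahl two-pathway interference**: a fraction ``p`` of
  crossovers escape interference and form a Poisson process of rate ``p``
  per Morgan ("free"); the remaining crossovers arise from chiasmata placed
  as a stationary renewal process with gamma(shape ``nu``, rate
  ``2*nu*(1-p)``) inter-chiasma distances, each chiasma landing on the
  modeled gamete with independent probability 1/2 (thinning; no chromatid
  interference).  The thinned renewal has rate ``1-p`` crossovers per
  Morgan, so the superposed process keeps the Morgan calibration: mean
  inter-crossover distance of 1 Morgan.

Stationarity of the regulated process is achieved by starting the chiasma
renewal a burn-in distance ``B = max(10, 5/(2*nu*(1-p)))`` Morgans before
coordinate 0 and truncating to ``[0, length]``; renewal processes forget
their origin geometrically, which avoids numerical inversion of the
equilibrium first-interval density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class InterferenceParams:
    """Housworth-Stahl two-pathway parameters: gamma shape ``nu`` > 0 and
    escape fraction ``p`` in [0, 1]."""

    nu: float
    p: float

    def __post_init__(self) -> None:
        if not self.nu > 0:
            raise ValueError(f"nu must be > 0, got {self.nu}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {self.p}")


# Package defaults: representative of published human family-data fits of the
# two-pathway model (gamma shape ~4-8, escape fraction 2-10%, females with
# weaker interference and a larger escape fraction than males).
DEFAULT_FEMALE = InterferenceParams(nu=5.0, p=0.06)
DEFAULT_MALE = InterferenceParams(nu=7.0, p=0.04)


def sex_averaged_interference(
    female: InterferenceParams, male: InterferenceParams
) -> InterferenceParams:
    """Sex-averaged (nu, p) from the per-sex parameters.

    ``p_a`` is the arithmetic mean of the escape fractions.  ``nu_a`` is
    chosen so that the variance of the sex-averaged inter-chiasma
    distribution equals the mean of the male and female variances (the mean
    is 1/(2(1-p)) for every ``nu``), giving
    ``nu_a = (1/(2 nu_f) + 1/(2 nu_m))**-1``.
    """
    p_a = 0.5 * (female.p + male.p)
    nu_a = 1.0 / (0.5 / female.nu + 0.5 / male.nu)
    return InterferenceParams(nu=nu_a, p=p_a)


@dataclass
class SexedInterferenceParams:
    """Per-sex interference parameters, optionally per chromosome.

    ``female``/``male`` are genome-wide defaults; ``per_chrom`` maps a
    chromosome label to a (female, male) override pair.
    """

    female: InterferenceParams = DEFAULT_FEMALE
    male: InterferenceParams = DEFAULT_MALE
    per_chrom: dict[str, tuple[InterferenceParams, InterferenceParams]] = field(
        default_factory=dict
    )

    def resolve(self, sex: str, chrom: str | None = None) -> InterferenceParams:
        """The (nu, p) pair used for one meiosis of the given sex.

        ``sex`` is ``"male"``, ``"female"`` or ``"averaged"`` (the latter
        combines the two sexes via :func:`sex_averaged_interference`).
        """
        f, m = self.female, self.male
        if chrom is not None and chrom in self.per_chrom:
            f, m = self.per_chrom[chrom]
        if sex == "female":
            return f
        if sex == "male":
            return m
        if sex == "averaged":
            return sex_averaged_interference(f, m)
        raise ValueError(f"unknown sex {sex!r}")


def read_interference_params(path) -> SexedInterferenceParams:
    """Read an interference parameter file.

    Whitespace-delimited lines ``chrom nu_female p_female nu_male p_male``;
    a line with chromosome ``*`` supplies the genome-wide default.
    """
    female = male = None
    per_chrom: dict[str, tuple[InterferenceParams, InterferenceParams]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            chrom = fields[0]
            try:
                nu_f, p_f, nu_m, p_m = (float(v) for v in fields[1:])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            pair = (InterferenceParams(nu_f, p_f), InterferenceParams(nu_m, p_m))
            if chrom == "*":
                female, male = pair
            else:
                per_chrom[chrom] = pair
    if female is None:
        if not per_chrom:
            raise ValueError(f"{path}: no parameter lines found")
        # no genome-wide default: fall back to the first per-chromosome entry
        female, male = next(iter(per_chrom.values()))
    return SexedInterferenceParams(female=female, male=male, per_chrom=per_chrom)


def write_interference_params(params: SexedInterferenceParams, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tnu_female\tp_female\tnu_male\tp_male\n")
        fh.write(
            f"*\t{params.female.nu:.10g}\t{params.female.p:.10g}"
            f"\t{params.male.nu:.10g}\t{params.male.p:.10g}\n"
        )
        for chrom, (f, m) in params.per_chrom.items():
            fh.write(f"{chrom}\t{f.nu:.10g}\t{f.p:.10g}\t{m.nu:.10g}\t{m.p:.10g}\n")


# ---------------------------------------------------------------------------
# samplers


def sample_poisson_crossovers(length: float, rng: np.random.Generator) -> np.ndarray:
    """Crossover positions on ``(0, length)`` Morgans under the Poisson model.

    Sequentially accumulates Exponential(1) inter-arrival distances and
    terminates after sampling a crossover beyond the chromosome end.
    """
    if length < 0:
        raise ValueError("length must be >= 0")
    out = []
    pos = 0.0
    while True:
        pos += rng.exponential(1.0)
        if pos >= length:
            break
        out.append(pos)
    return np.asarray(out, dtype=float)


def _poisson_batch(length: float, n: int, rng: np.random.Generator) -> list[np.ndarray]:
    """n independent Poisson crossover draws (count + sorted-uniform construction)."""
    if length < 0:
        raise ValueError("length must be >= 0")
    if length == 0:
        return [np.empty(0)] * n
    counts = rng.poisson(length, size=n)
    total = int(counts.sum())
    pos = rng.random(total) * length
    out = []
    start = 0
    for c in counts:
        xs = np.sort(pos[start : start + c])
        out.append(xs)
        start += c
    return out


def _burn_in(params: InterferenceParams) -> float:
    return max(10.0, 5.0 / (2.0 * params.nu * (1.0 - params.p)))


def _stahl_batch(
    length: float, params: InterferenceParams, n: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """n independent Housworth-Stahl crossover draws on ``(0, length)``.

    Draw order (fixed for reproducibility): free Poisson events first, then
    the regulated chiasma renewal, then the thinning coins.
    """
    if length < 0:
        raise ValueError("length must be >= 0")
    p, nu = params.p, params.nu
    free = _poisson_batch(length * p, n, rng) if p > 0 else [np.empty(0)] * n
    # free positions were drawn on a scaled axis of length p*L; rescale
    if p > 0 and p != 1.0:
        free = [xs / p for xs in free]

    if p >= 1.0 or length == 0:
        return [np.sort(xs) for xs in free]

    beta = 2.0 * nu * (1.0 - p)  # gamma rate (per Morgan)
    B = _burn_in(params)
    span = B + length
    mean_count = 2.0 * (1.0 - p) * span  # chiasma rate is beta/nu = 2(1-p)
    m = int(mean_count + 6.0 * np.sqrt(mean_count / nu) + nu + 16)
    draws = rng.gamma(nu, 1.0 / beta, size=(n, m))
    pos = np.cumsum(draws, axis=1) - B
    # top up the rare rows whose chiasmata do not yet cover the chromosome
    short = np.where(pos[:, -1] < length)[0]
    extras: dict[int, np.ndarray] = {}
    for i in short:
        tail = [pos[i, -1]]
        while tail[-1] < length:
            tail.append(tail[-1] + rng.gamma(nu, 1.0 / beta))
        extras[i] = np.asarray(tail[1:])
    keep = rng.random((n, m)) < 0.5

    out = []
    for i in range(n):
        reg = pos[i][keep[i]]
        if i in extras:
            ex = extras[i]
            ex_keep = rng.random(ex.size) < 0.5
            reg = np.concatenate([reg, ex[ex_keep]])
        reg = reg[(reg > 0.0) & (reg < length)]
        merged = np.concatenate([free[i], reg])
        merged.sort()
        out.append(merged)
    return out


def sample_stahl_crossovers(
    length: float, params: InterferenceParams, rng: np.random.Generator
) -> np.ndarray:
    """Single Housworth-Stahl crossover draw; see :func:`_stahl_batch`."""
    return _stahl_batch(length, params, 1, rng)[0]


def sample_crossovers_batch(
    length: float,
    n: int,
    rng: np.random.Generator,
    params: InterferenceParams | None = None,
) -> list[np.ndarray]:
    """Batch sampler used by the simulation engine: interference model when
    ``params`` is given, Poisson otherwise."""
    if params is None:
        return _poisson_batch(length, n, rng)
    return _stahl_batch(length, params, n, rng)
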