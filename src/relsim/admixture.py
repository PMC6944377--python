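"""Recently admixed haplotypes and the censoring-aware admixture-time MLE.

The admixture pedigree: a two-way admixture event ``T`` generations ago in
which every ancestor couple of that generation pairs one member of
population A with one of population B.  The focal individual carries one
admixed haplotype per chromosome, descended through the admixed lineage;
ancestry switches along it occur at rate ``T/2`` per Morgan (crossovers
only switch ancestry when the transmitting parent is ancestry-heterozygous,
which holds on average for half of the ``T - 2`` recent meioses and always
for the second generation).

Because generation-1 ancestors are unadmixed, their chromosomes have
uniform ancestry and their meioses cannot move an ancestry breakpoint; the
simulation therefore starts from the generation-2 individuals, each
carrying one whole-genome population-A haplotype and one population-B
haplotype — exactly equivalent for local-ancestry output.

Segment lengths ``x_i`` (sex-averaged Morgans) are exponential with rate
``T/2`` except that segments abutting a chromosome end are censored (their
likelihood is the survival function).  Maximizing the censored exponential
likelihood gives the closed form ``T_hat = 2 (n - m) / sum_i x_i`` with
``n`` segments of which ``m`` are censored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .core import CrossoverModel, _recombine, _validate_model
from .crossover import SexedInterferenceParams, sample_crossovers_batch
from .genetic_map import GeneticMap


@dataclass
class AncestrySegment:
    chrom: str
    start: float  # sex-averaged Morgans from chromosome start
    end: float
    population: str  # "A" | "B"
    censored: bool  # abuts a chromosome end

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass
class AdmixtureEstimate:
    T_hat: float
    n: int
    m: int  # censored count
    total_len: float  # sum of segment lengths, Morgans
    degenerate: bool = False  # every segment censored; no interior switches


def estimate_T(segments: Iterable[AncestrySegment | float]) -> AdmixtureEstimate:
    """Censored-exponential MLE of the time since admixture.

    Accepts :class:`AncestrySegment` objects or plain ``(length, censored)``
    tuples.  Censored segments contribute their length to the denominator
    but not to the switch count ``n - m``.  If every segment is censored the
    estimate degenerates to ``T_hat = 0`` and the ``degenerate`` flag is
    set.
    """
    n = m = 0
    total = 0.0
    for seg in segments:
        if isinstance(seg, AncestrySegment):
            length, censored = seg.length, seg.censored
        else:
            length, censored = seg
        n += 1
        m += int(bool(censored))
        total += float(length)
    if n == 0:
        raise ValueError("need at least one segment")
    if n == m:
        return AdmixtureEstimate(T_hat=0.0, n=n, m=m, total_len=total, degenerate=True)
    return AdmixtureEstimate(T_hat=2.0 * (n - m) / total, n=n, m=m, total_len=total)


def simulate_admixed(
    T: int,
    gmap: GeneticMap,
    model,
    interference: SexedInterferenceParams | None = None,
    seed: int = 0,
    n_replicates: int = 1,
    chunk_size: int = 512,
) -> list[list[AncestrySegment]]:
    """Simulate admixed haplotypes; one segment list per replicate.

    Each replicate builds the full ancestor tree of the focal haplotype
    (2**(T-2) mixed couples at generation 2 of the reduced pedigree, see
    module docstring), runs the meioses down the tree under the requested
    crossover model, merges same-population neighbors, and flags the first
    and last segment of every chromosome as censored.
    """
    return list(
        simulate_admixed_stream(T, gmap, model, interference, seed, n_replicates, chunk_size)
    )


def simulate_admixed_stream(
    T: int,
    gmap: GeneticMap,
    model,
    interference: SexedInterferenceParams | None = None,
    seed: int = 0,
    n_replicates: int = 1,
    chunk_size: int = 512,
) -> Iterator[list[AncestrySegment]]:
    if T < 2:
        raise ValueError("T must be >= 2")
    model = CrossoverModel.parse(model)
    _validate_model(model, gmap, interference)
    rng = np.random.default_rng(seed)

    # reduced tree: level g (g = 2..T) holds 2**(T-g) ancestry-heterozygous
    # individuals; the single level-T individual is the focal parent, whose
    # final meiosis yields the focal haplotype.  Level-2 haplotype ids:
    # 0 = population A, 1 = population B.
    founder = {}
    for c in gmap:
        end = c.span()[1]
        founder[c.name] = (([0], [end]), ([1], [end]))

    done = 0
    while done < n_replicates:
        R = min(chunk_size, n_replicates - done)
        n2 = 2 ** (T - 2)
        # current[r][i] = {chrom: (hap0, hap1)}
        current = [[founder for _ in range(n2)] for _ in range(R)]
        for level in range(2, T):  # pair level-g individuals, produce level g+1
            n_par = 2 ** (T - level)
            coins = rng.random((R, n_par // 2)) < 0.5
            children = [[None] * (n_par // 2) for _ in range(R)]
            for ci in range(n_par // 2):
                child_haps = [[None, None] for _ in range(R)]
                for side in (0, 1):
                    pi = 2 * ci + side
                    flip = coins[:, ci] ^ (side == 1)
                    psex = np.where(flip, "female", "male")
                    gam = _meiosis_batch(gmap, model, interference, psex, current, pi, rng)
                    for r in range(R):
                        child_haps[r][side] = gam[r]
                for r in range(R):
                    children[r][ci] = {
                        cn: (child_haps[r][0][cn], child_haps[r][1][cn])
                        for cn in child_haps[r][0]
                    }
            current = children
        # final meiosis: the level-T individual's sex is a fair coin
        psex = np.where(rng.random(R) < 0.5, "female", "male")
        focal = _meiosis_batch(gmap, model, interference, psex, current, 0, rng)
        for r in range(R):
            segs: list[AncestrySegment] = []
            for c in gmap:
                segs.extend(_runs_to_segments(focal[r][c.name], c))
            yield segs
        done += R


def _meiosis_batch(gmap, model, interference, psex, current, pi, rng):
    """One meiosis slot (parent index ``pi``) across all replicates; returns
    per-replicate {chrom: runs} gametes."""
    R = psex.shape[0]
    out = [dict() for _ in range(R)]
    for c in gmap:
        xs_all = _batch_crossovers_by_sex(c, model, interference, psex, rng)
        starts = rng.random(R) < 0.5
        for r in range(R):
            h0, h1 = current[r][pi][c.name]
            out[r][c.name] = _recombine(h0, h1, xs_all[r], int(starts[r]))
    return out


def _batch_crossovers_by_sex(c, model, interference, psex, rng):
    from .core import _axis_sex, _resolve_intf

    R = psex.shape[0]
    xs_all: list[np.ndarray] = [None] * R  # type: ignore
    for sex in ("male", "female"):
        axis = _axis_sex(model, sex)
        gcol = c.gen_column(axis)
        g0 = float(gcol[0])
        length_m = float(gcol[-1] - gcol[0]) / 100.0
        idx = np.where(psex == sex)[0]
        if idx.size == 0:
            continue
        params = _resolve_intf(model, interference, sex, c.name)
        batch = sample_crossovers_batch(length_m, idx.size, rng, params)
        sizes = [b.size for b in batch]
        if sum(sizes):
            concat = np.concatenate(batch) * 100.0 + g0
            phys = np.interp(concat, gcol, c.phys)
            offs = np.cumsum([0] + sizes)
            for j, ri in enumerate(idx):
                xs_all[ri] = phys[offs[j] : offs[j + 1]]
        else:
            empty = np.empty(0)
            for ri in idx:
                xs_all[ri] = empty
    return xs_all


def _runs_to_segments(runs, c) -> list[AncestrySegment]:
    ids, ends = runs
    # merge adjacent same-population runs (ids are 0/1 already)
    pops = []
    bnds = []
    for fid, end in zip(ids, ends):
        if pops and pops[-1] == fid:
            bnds[-1] = end
        else:
            pops.append(fid)
            bnds.append(end)
    gcol = c.gen_column("averaged")
    g0 = float(gcol[0])
    gens = (np.interp(np.asarray(bnds, dtype=float), c.phys, gcol) - g0) / 100.0
    out = []
    start = 0.0
    n = len(pops)
    for i, (fid, ge) in enumerate(zip(pops, gens)):
        # Only the segment running into the chromosome end is censored: the
        # first segment's length is a complete draw of the switch process
        # (the per-chromosome likelihood is (T/2)^k exp(-TL/2), one censored
        # term per chromosome), which keeps the MLE unbiased.  A single
        # whole-chromosome segment is censored (counts once in m).
        out.append(
            AncestrySegment(
                chrom=c.name,
                start=start,
                end=float(ge),
                population="A" if fid == 0 else "B",
                censored=(i == n - 1),
            )
        )
        start = float(ge)
    return out
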