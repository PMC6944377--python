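"""Genotype synthesis for simulated pedigrees from phased input haplotypes.

Each founder of every replicate is assigned (injectively within the
replicate) one sample from a phased input VCF; descendant alleles are then
copied from the assigned founder haplotypes using the tracked segment ids
and end points.  A simple genotyping-error and missingness model can
perturb the output: per site and individual, independently,

* with probability ``err_rate`` an error occurs (biallelic sites only):
  a heterozygous genotype becomes either homozygous class with equal
  probability; a homozygous genotype becomes heterozygous, except that with
  probability ``err_hom_to_opposite`` it becomes the opposite homozygote;
* with probability ``miss_rate`` the genotype is set missing (applied after
  and overriding errors).

Input and output are VCF (phased GT with the ``|`` separator), read and
written with pysam; gzipped files work transparently.  Sites outside the
genetic map span are dropped (counted in the return value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam

from .core import SimulationResult


class UnphasedInputError(ValueError):
    """The input VCF contains unphased genotypes."""


class FounderCapacityError(ValueError):
    """Fewer input samples than founders in one replicate."""


@dataclass(frozen=True)
class ErrorModel:
    err_rate: float = 1e-3
    miss_rate: float = 1e-3
    err_hom_to_opposite: float = 0.0

    def __post_init__(self) -> None:
        for name in ("err_rate", "miss_rate", "err_hom_to_opposite"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def assign_founders(
    input_samples: list[str], founders: list, rng_or_seed
) -> dict:
    """Injective random assignment of input samples to founders.

    ``founders`` may be any hashable keys (one replicate's founders).
    Raises :class:`FounderCapacityError` when there are fewer input samples
    than founders.  Deterministic given the seed.
    """
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    if len(input_samples) < len(founders):
        raise FounderCapacityError(
            f"need >= {len(founders)} input samples, got {len(input_samples)}"
        )
    chosen = rng.permutation(len(input_samples))[: len(founders)]
    return {f: input_samples[i] for f, i in zip(founders, chosen)}


def synthesize(
    sim: SimulationResult,
    vcf_in,
    out_path,
    model: ErrorModel = ErrorModel(),
    seed: int = 0,
    keep_founders: bool = False,
) -> int:
    """Write a phased VCF for the simulated individuals; returns the number
    of input sites dropped for lying outside the mapped span."""
    rng = np.random.default_rng(seed)
    gmap = sim.gmap
    graph = sim.graph

    with pysam.VariantFile(str(vcf_in)) as vin:
        in_samples = list(vin.header.samples)
        founder_slots = graph.founder_hap_slots()
        founder_keys = [m.key for m in graph.founders]

        # per replicate: founder key -> input sample column
        col_of = {s: i for i, s in enumerate(in_samples)}
        assignments = []
        for rep_idx, individuals in enumerate(sim.replicates):
            amap = assign_founders(in_samples, founder_keys, rng)
            assignments.append({k: col_of[s] for k, s in amap.items()})

        # output columns: (replicate, member key); founders only on request
        out_cols: list[tuple[int, str]] = []
        for rep_idx, individuals in enumerate(sim.replicates):
            for key, ind in individuals.items():
                if ind.founder and not keep_founders:
                    continue
                out_cols.append((rep_idx, key))
        if not out_cols:
            raise ValueError("no simulated individuals to write (re-simulate with keep='all'?)")
        missing = [
            (r, k) for r, k in out_cols if k not in sim.replicates[r]
        ]
        if missing:
            raise ValueError(f"simulation result lacks members: {missing[:3]}")

        header = pysam.VariantHeader()
        header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        for contig in vin.header.contigs:
            header.contigs.add(contig, length=vin.header.contigs[contig].length)
        for r, k in out_cols:
            header.add_sample(sim.replicates[r][k].id)

        # fid -> (founder key, hap index); per replicate the same mapping
        slot_of_fid = {i: slot for i, slot in enumerate(founder_slots)}
        spans = {c.name: c.span() for c in gmap}
        # run pointers per output haplotype per chromosome, advanced as
        # positions increase (VCF records are coordinate-sorted per contig)
        pointers: dict[tuple[int, str, int], int] = {}
        cur_chrom = None
        n_dropped = 0

        with pysam.VariantFile(str(out_path), "w", header=header) as vout:
            for rec in vin:
                chrom = rec.chrom
                if chrom not in spans:
                    n_dropped += 1
                    continue
                lo, hi = spans[chrom]
                if rec.pos < lo or rec.pos > hi:
                    n_dropped += 1
                    continue
                if chrom != cur_chrom:
                    cur_chrom = chrom
                    pointers = {}
                in_gts = _phased_alleles(rec, in_samples)
                n_out = len(out_cols)
                gts = np.empty((n_out, 2), dtype=np.int16)
                for j, (r, k) in enumerate(out_cols):
                    ind = sim.replicates[r][k]
                    amap = assignments[r]
                    for hidx in (0, 1):
                        ids, ends = ind.haplotypes[hidx][chrom]
                        p = pointers.get((j, chrom, hidx), 0)
                        while ends[p] < rec.pos:
                            p += 1
                        pointers[(j, chrom, hidx)] = p
                        fkey, fhap = slot_of_fid[ids[p]]
                        gts[j, hidx] = in_gts[amap[fkey], fhap]
                gts = _perturb(gts, rec, model, rng)
                out = vout.new_record(
                    contig=chrom, start=rec.start, stop=rec.stop,
                    alleles=rec.alleles, id=rec.id,
                )
                for j in range(n_out):
                    a0, a1 = int(gts[j, 0]), int(gts[j, 1])
                    sample = out.samples[j]
                    sample["GT"] = (None, None) if a0 < 0 else (a0, a1)
                    sample.phased = True
                vout.write(out)
    return n_dropped


def _phased_alleles(rec, samples) -> np.ndarray:
    gts = np.empty((len(samples), 2), dtype=np.int16)
    for i, s in enumerate(samples):
        sv = rec.samples[i]
        alleles = sv["GT"]
        if len(alleles) != 2 or alleles[0] is None or alleles[1] is None:
            raise UnphasedInputError(f"missing input genotype at {rec.chrom}:{rec.pos}")
        if not sv.phased:
            raise UnphasedInputError(
                f"unphased input genotype for sample {s} at {rec.chrom}:{rec.pos}"
            )
        gts[i] = alleles
    return gts


def _perturb(gts: np.ndarray, rec, model: ErrorModel, rng: np.random.Generator) -> np.ndarray:
    n = gts.shape[0]
    biallelic = len(rec.alleles) == 2
    if model.err_rate > 0 and biallelic:
        err = rng.random(n) < model.err_rate
        if err.any():
            coin = rng.random(n)  # reused for the het->hom class / hom branch
            for j in np.where(err)[0]:
                a0, a1 = gts[j]
                if a0 != a1:  # heterozygous -> either homozygote, equal odds
                    allele = 1 if coin[j] < 0.5 else 0
                    gts[j] = (allele, allele)
                else:  # homozygous -> het, or opposite homozygote
                    if coin[j] < model.err_hom_to_opposite:
                        gts[j] = (1 - a0, 1 - a1)
                    else:
                        order = rng.random() < 0.5
                        gts[j] = (0, 1) if order else (1, 0)
    if model.miss_rate > 0:
        miss = rng.random(n) < model.miss_rate
        gts[miss] = (-1, -1)
    return gts
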