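# relsim

Simulation of close relatives with **sex-specific genetic maps** and
**crossover interference**, yielding exact identical-by-descent (IBD)
segments, plus the closed-form theory of IBD segment lengths and a
censoring-aware estimator of the time since admixture.

## The scientific problem

IBD segments — genomic regions two individuals co-inherited from a recent
common ancestor — underpin relationship inference, pedigree studies and
local-ancestry dating. Most simulators place crossovers as a Poisson
process on a sex-averaged map, ignoring two well-characterized features of
human meiosis:

* **sex differences**: females produce ~1.57× more autosomal crossovers
  per meiosis than males, and the male and female maps differ locally;
* **crossover interference**: nearby crossovers suppress each other,
  making inter-crossover spacing more regular than Poisson.

`relsim` simulates relatives under all four combinations of these factors
(`ss+intf`, `ss+poiss`, `sa+intf`, `sa+poiss`). Interference follows the
Housworth–Stahl two-pathway model: a fraction *p* of crossovers escape
regulation (Poisson with rate *p* per Morgan), the rest arise from
chiasmata placed as a stationary renewal process with gamma(ν, 2ν(1−p))
inter-chiasma distances (in Morgans), each chiasma landing on the modeled
gamete with probability 1/2 (thinning; no chromatid interference). The
superposition averages one crossover per Morgan.

The simulator tracks haplotypes as runs of (founder-haplotype id, segment
end), so pairwise IBD segments are exact — no inference step. It can also
synthesize phased genotypes for the simulated individuals from an input
panel, with a configurable genotyping-error and missingness model.

For relatives separated by 2*T* meioses under a sex-averaged map with
interference, the package evaluates the closed-form density φ(x) of IBD
segment lengths

φ(x) = e^(−2pTx) [G̃(x)]^(2T−1) [4pT g(x) + (2T−1) g²(x)/G̃(x) + (1−p) f(x) + 2p²T G̃(x)]

where f is the thinned inter-crossover density, g the stationary forward
distance to the next regulated crossover and G̃ its upper tail, together
with the finite-chromosome correction (a continuous part plus an atom at
the chromosome length). The sex-specific Poisson counterpart works on the
physical axis with the inhomogeneous-Poisson inter-event density, mixed
over the binomial number of female transmissions.

For recently admixed genomes (admixture *T* generations ago, every
founding couple mixing the two source populations), local-ancestry segment
lengths are exponential with rate *T*/2 per Morgan; the MLE with
right-censoring at chromosome ends is `T_hat = 2(n − m) / Σ x_i` for *n*
segments, *m* of them censored.

## Worked example

```python
import relsim as rs
from relsim import ibd

# a dimorphic synthetic genome: 8 chromosomes, 90 cM male / 141.3 cM female
gmap = rs.make_synthetic_map(n_chrom=8, phys_len=120_000_000, male_len=90.0,
                             female_factor=1.57, n_knots=31, roughness=0.4, seed=20)
intf = rs.SexedInterferenceParams()     # human-regime (nu, p) defaults

res = rs.simulate("full-sibs", gmap, "ss+intf", intf, seed=1, copies=200)
stats = [ibd.pair_stats(r["c1"], r["c2"], gmap) for r in res.replicates]
print(f"mean IBD proportion {sum(s.proportion for s in stats)/200:.3f}")
print(f"mean IBD2 fraction  {sum(s.k2 for s in stats)/200:.3f}")
segs = ibd.ibd_segments(res.replicates[0]["c1"], res.replicates[0]["c2"], gmap)
print(f"first pair: {len(segs)} segments, first = {segs[0].type} "
      f"{segs[0].length_cM:.1f} cM")
```

prints (seed 1):

```
mean IBD proportion 0.499
mean IBD2 fraction  0.248
first pair: 30 segments, first = IBD2 11.5 cM
```

Full siblings share half their genome on average (a quarter on both
haplotypes), regardless of the crossover model; the model choice shifts
the *spread* of sharing and the segment counts, which is what the
experiment drivers in `relsim.experiments` quantify.

### Command line

```bash
relsim simulate --def peds.def --map map.txt --intf intf.txt --seed 7 -o out
relsim theory --model intf --T 2 --nu 5 --p 0.06 --L 2.8
relsim admix --T 4 --reps 1000 --map map.txt --model sa+poiss --seed 3 -o admix.tsv
relsim experiment --config configs/ibd_variance.cfg --scale 0.1 --seed 5
```

`relsim simulate` writes `out.seg` (exact IBD segments: id1 id2 chrom
phys_start phys_end IBD1|IBD2 gen_start gen_end length, genetic
coordinates always sex-averaged cM), `out.fam` (6-column pedigree table)
and `out.log`; with `--vcf-in founders.vcf` it also writes phased
genotypes for the simulated individuals.

### File formats

* **Genetic map** (plain text, whitespace-delimited, `#` comments):
  sex-specific dialect `chrom phys_bp male_cM female_cM`; sex-averaged
  dialect `chrom phys_bp avg_cM`. Physical positions strictly increase,
  genetic columns are non-decreasing; no extrapolation beyond the mapped
  span.
* **Interference parameters**: lines `chrom nu_female p_female nu_male
  p_male`; chromosome `*` sets the genome-wide default.
* **def file**: `def NAME COPIES N_GENERATIONS [M|F]` followed by
  `GENERATION N_PRINT [N_BRANCHES]` lines. Generation 1 is one founder
  couple; generation 2 defaults to two branches; later generations default
  to one child per branch with a new founder spouse. `M`/`F` forces the
  sex of all reproducing non-founders.
* **Experiment configs** (`configs/*.cfg`): `key = value` lines, run with
  `relsim experiment` (the `--scale` flag shrinks sample sizes).

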