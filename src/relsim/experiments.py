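"""Simulation experiment drivers and summary statistics.

These functions orchestrate the package's simulation studies: IBD sharing
distributions for several relationship types under the four crossover
models, half-sibling segment-count dimorphism, distant-cousin sharing
rates, admixture-time estimation, and IBD segment-length histograms against
the closed-form densities.  Summary statistics come with bootstrap standard
errors, and the separation between two datasets is quantified as the number
of combined standard errors, D = |theta_model - theta_real| /
sqrt(se_model**2 + se_real**2).

Experiment configurations are small key-value text files (``key = value``
per line, ``#`` comments); every experiment runs at reduced size via the
``scale`` argument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import admixture as admix_mod
from . import core, ibd
from .crossover import SexedInterferenceParams
from .genetic_map import GeneticMap, make_synthetic_map


def summarize(values) -> dict:
    """Mean, sd (n-1 denominator), quartiles (linear interpolation between
    closest ranks), min and max of a sample."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    out = {
        "mean": float(np.mean(v)),
        "sd": float(np.std(v, ddof=1)) if v.size > 1 else float("nan"),
        "q25": float(np.percentile(v, 25)),
        "median": float(np.percentile(v, 50)),
        "q75": float(np.percentile(v, 75)),
        "min": float(np.min(v)),
        "max": float(np.max(v)),
    }
    return out


def bootstrap_se(values, stat=np.mean, B: int = 1000, seed: int = 0) -> float:
    """Bootstrap standard error of ``stat`` over ``B`` with-replacement
    resamples.  Deterministic given ``seed``."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need n >= 2")
    if B < 2:
        raise ValueError("need B >= 2")
    rng = np.random.default_rng(seed)
    reps = np.empty(B)
    chunk = max(1, int(5e6 // max(v.size, 1)))
    b = 0
    while b < B:
        nb = min(chunk, B - b)
        idx = rng.integers(0, v.size, size=(nb, v.size))
        sample = v[idx]
        reps[b : b + nb] = np.apply_along_axis(stat, 1, sample)
        b += nb
    return float(np.std(reps, ddof=1))


def d_statistic(theta_model: float, se_model: float, theta_real: float, se_real: float) -> float:
    """Separation between two point estimates in combined standard errors."""
    if se_model < 0 or se_real < 0:
        raise ValueError("standard errors must be >= 0")
    denom = math.hypot(se_model, se_real)
    if denom == 0:
        raise ValueError("both standard errors are zero; D is undefined")
    return abs(theta_model - theta_real) / denom


# ---------------------------------------------------------------------------
# per-pair statistic collection


@dataclass
class PairTable:
    """Tidy per-pair IBD statistics for one (relationship, model) cell."""

    relationship: str
    model: str
    table: pd.DataFrame  # proportion, k1, k2, kinship, n_segments, total_cM


def collect_pair_stats(
    relationship,
    gmap: GeneticMap,
    model,
    interference: SexedInterferenceParams | None = None,
    n_pairs: int = 1000,
    seed: int = 0,
    chunk_size: int = 2048,
) -> PairTable:
    """Simulate ``n_pairs`` replicates of a two-person relationship and
    tabulate exact pairwise IBD statistics."""
    graph = core._as_graph(relationship)
    printed = graph.printed
    if len(printed) != 2:
        raise ValueError(f"relationship {graph.name!r} prints {len(printed)} != 2 individuals")
    rows = np.empty((n_pairs, 6))
    for rep_idx, individuals in core.simulate_stream(
        graph, gmap, model, interference, seed=seed, copies=n_pairs, chunk_size=chunk_size
    ):
        a, b = individuals[printed[0]], individuals[printed[1]]
        stats = ibd.pair_stats(a, b, gmap)
        rows[rep_idx] = (
            stats.proportion,
            stats.k1,
            stats.k2,
            stats.kinship,
            stats.n_segments,
            stats.total_cM,
        )
    table = pd.DataFrame(
        rows, columns=["proportion", "k1", "k2", "kinship", "n_segments", "total_cM"]
    )
    return PairTable(relationship=graph.name, model=core.CrossoverModel.parse(model).name, table=table)


def segment_lengths(
    relationship,
    gmap: GeneticMap,
    model,
    interference: SexedInterferenceParams | None = None,
    n_pairs: int = 1000,
    seed: int = 0,
    chunk_size: int = 2048,
) -> np.ndarray:
    """Pooled IBD segment lengths (sex-averaged Morgans) across pairs."""
    graph = core._as_graph(relationship)
    printed = graph.printed
    out: list[float] = []
    for _, individuals in core.simulate_stream(
        graph, gmap, model, interference, seed=seed, copies=n_pairs, chunk_size=chunk_size
    ):
        segs = ibd.ibd_segments(individuals[printed[0]], individuals[printed[1]], gmap)
        out.extend(s.length_cM / 100.0 for s in segs)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# synthetic genomes used by the packaged experiments


def desk_genome(seed: int = 20) -> GeneticMap:
    """Small dimorphic genome for fast experiments: 8 chromosomes of 90 cM
    (male) / 141.3 cM (female) with rough local rates."""
    return make_synthetic_map(
        n_chrom=8,
        phys_len=120_000_000,
        male_len=90.0,
        female_factor=1.57,
        n_knots=31,
        roughness=0.4,
        seed=seed,
    )


def human_scale_genome(seed: int = 21) -> GeneticMap:
    """22 autosomes with human-like genetic and physical lengths.

    Male lengths decrease linearly from 190 to 55 cM (total ~2700 cM) and
    female lengths are 1.57x longer (total ~4230 cM), mirroring the
    male/female autosomal totals of published pedigree-based maps; physical
    lengths run 250 Mb down to 50 Mb."""
    male = np.linspace(190.0, 55.0, 22)
    phys = np.linspace(250e6, 50e6, 22)
    return make_synthetic_map(
        n_chrom=22,
        phys_len=phys,
        male_len=male,
        female_factor=1.57,
        n_knots=25,
        roughness=0.35,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# experiment drivers


MODELS = ("ss+intf", "ss+poiss", "sa+intf", "sa+poiss")


def run_relatives_experiment(
    relationships,
    gmap: GeneticMap,
    interference: SexedInterferenceParams,
    n_pairs: int,
    seed: int = 0,
    models=MODELS,
    bootstrap_B: int = 200,
) -> pd.DataFrame:
    """IBD-sharing summary statistics per (relationship, model).

    One row per cell with mean/sd/quartiles of the IBD proportion (plus the
    IBD2 fraction and segment counts) and bootstrap SEs of mean and sd.
    """
    rows = []
    for ri, rel in enumerate(relationships):
        for mi, model in enumerate(models):
            cell_seed = seed + 1000 * ri + 10 * mi
            pt = collect_pair_stats(
                rel, gmap, model, interference, n_pairs=n_pairs, seed=cell_seed
            )
            v = pt.table["proportion"].to_numpy()
            s = summarize(v)
            row = {
                "relationship": pt.relationship,
                "model": pt.model,
                "n_pairs": n_pairs,
                **{f"proportion_{k}": x for k, x in s.items()},
                "proportion_se_mean": bootstrap_se(v, np.mean, B=bootstrap_B, seed=cell_seed),
                "proportion_se_sd": bootstrap_se(
                    v, lambda x: np.std(x, ddof=1), B=bootstrap_B, seed=cell_seed + 1
                ),
                "k2_mean": float(pt.table["k2"].mean()),
                "k2_sd": float(pt.table["k2"].std(ddof=1)),
                "n_segments_mean": float(pt.table["n_segments"].mean()),
                "n_segments_sd": float(pt.table["n_segments"].std(ddof=1)),
                "frac_sharing": float((pt.table["n_segments"] > 0).mean()),
            }
            rows.append(row)
    return pd.DataFrame(rows)


def sd_effect_pct(table: pd.DataFrame, factor: str) -> float:
    """Average percent change in SD(IBD proportion) attributable to one
    modeling factor, over relationships and the levels of the other factor.

    ``factor="interference"``: percent *decrease* moving Poisson ->
    interference at matched map type.  ``factor="map"``: percent *increase*
    moving sex-averaged -> sex-specific at matched crossover process.
    """
    t = table.set_index(["relationship", "model"])["proportion_sd"]
    rels = table["relationship"].unique()
    deltas = []
    for rel in rels:
        if factor == "interference":
            for dialect in ("ss", "sa"):
                sd_p = t[(rel, f"{dialect}+poiss")]
                sd_i = t[(rel, f"{dialect}+intf")]
                deltas.append(100.0 * (1.0 - sd_i / sd_p))
        elif factor == "map":
            for proc in ("intf", "poiss"):
                sd_sa = t[(rel, f"sa+{proc}")]
                sd_ss = t[(rel, f"ss+{proc}")]
                deltas.append(100.0 * (sd_ss / sd_sa - 1.0))
        else:
            raise ValueError(f"unknown factor {factor!r}")
    return float(np.mean(deltas))


def run_halfsib_experiment(
    gmap: GeneticMap,
    interference: SexedInterferenceParams,
    n_pairs: int,
    seed: int = 0,
    model: str = "ss+intf",
) -> pd.DataFrame:
    """Segment counts for maternal vs paternal half-siblings (the
    sex-specific-map bimodality)."""
    rows = []
    for i, rel in enumerate(("maternal-half-sibs", "paternal-half-sibs")):
        pt = collect_pair_stats(rel, gmap, model, interference, n_pairs=n_pairs, seed=seed + i)
        counts = pt.table["n_segments"].to_numpy()
        rows.append(
            {
                "relationship": rel,
                "model": model,
                "n_pairs": n_pairs,
                "n_segments_mean": float(counts.mean()),
                "n_segments_sd": float(counts.std(ddof=1)),
                "n_segments_se_mean": float(counts.std(ddof=1) / np.sqrt(n_pairs)),
                "total_cM_mean": float(pt.table["total_cM"].mean()),
            }
        )
    return pd.DataFrame(rows)


def run_admixture_experiment(
    T_values,
    gmap: GeneticMap,
    interference: SexedInterferenceParams,
    n_replicates: int,
    seed: int = 0,
    models=MODELS,
) -> pd.DataFrame:
    """Distribution of the admixture-time estimate per (T, model)."""
    rows = []
    for ti, T in enumerate(T_values):
        for mi, model in enumerate(models):
            cell_seed = seed + 1000 * ti + 10 * mi
            intf = interference if core.CrossoverModel.parse(model).interference else None
            hats = np.empty(n_replicates)
            for r, segs in enumerate(
                admix_mod.simulate_admixed_stream(
                    T, gmap, model, intf, seed=cell_seed, n_replicates=n_replicates
                )
            ):
                hats[r] = admix_mod.estimate_T(segs).T_hat
            rows.append(
                {
                    "T": T,
                    "model": core.CrossoverModel.parse(model).name,
                    "n_replicates": n_replicates,
                    "T_hat_mean": float(hats.mean()),
                    "T_hat_sd": float(hats.std(ddof=1)),
                    "T_hat_se_mean": float(hats.std(ddof=1) / np.sqrt(n_replicates)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# config files


def load_config(path) -> dict:
    """Parse a ``key = value`` experiment config file."""
    cfg: dict = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            cfg[key] = val
    return cfg


def _parse_list(s: str) -> list[str]:
    return [t.strip() for t in s.split(",") if t.strip()]


def run_experiment(config, scale: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """Run a declarative experiment config (path or dict).

    Required keys: ``kind`` (relatives | halfsib-counts | admixture);
    ``n_pairs`` or ``n_replicates``; for relatives: ``relationships`` and
    optionally ``models``; for admixture: ``T_values``.  The genome is the
    packaged synthetic desk genome unless ``genome = human-scale`` or
    ``map_file = PATH`` is given.  ``scale`` multiplies the sample sizes.
    """
    cfg = dict(config) if isinstance(config, dict) else load_config(config)
    kind = cfg.get("kind")
    genome = cfg.get("genome", "desk")
    if "map_file" in cfg:
        from .genetic_map import read_genetic_map

        gmap = read_genetic_map(cfg["map_file"])
    elif genome == "human-scale":
        gmap = human_scale_genome()
    else:
        gmap = desk_genome()
    if "interference_file" in cfg:
        from .crossover import read_interference_params

        intf = read_interference_params(cfg["interference_file"])
    else:
        intf = SexedInterferenceParams()
    models = tuple(_parse_list(cfg["models"])) if "models" in cfg else MODELS

    if kind == "relatives":
        n = max(2, int(round(int(cfg["n_pairs"]) * scale)))
        rels = _parse_list(cfg["relationships"])
        return run_relatives_experiment(rels, gmap, intf, n_pairs=n, seed=seed, models=models)
    if kind == "halfsib-counts":
        n = max(2, int(round(int(cfg["n_pairs"]) * scale)))
        return run_halfsib_experiment(
            gmap, intf, n_pairs=n, seed=seed, model=cfg.get("model", "ss+intf")
        )
    if kind == "admixture":
        n = max(2, int(round(int(cfg["n_replicates"]) * scale)))
        T_values = [int(t) for t in _parse_list(cfg["T_values"])]
        return run_admixture_experiment(T_values, gmap, intf, n_replicates=n, seed=seed,
                                        models=models)
    raise ValueError(f"unknown experiment kind {kind!r}")
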