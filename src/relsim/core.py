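"""Pedigree definitions, the segment-tracking meiosis engine, and replicate
simulation under the four crossover models.

Haplotypes are tracked as runs of ``(founder_haplotype_id, end)`` covering a
chromosome, with physical end coordinates kept real-valued internally and
rounded to integer bp only when written to disk.  Founders carry two
chromosome-length runs with globally unique ids (per replicate); a
non-founder's haplotype is produced by a meiosis on one parent: a fair coin
picks the starting parental haplotype, crossover positions are sampled in
Morgans on the genetic axis of the parent's sex (or on the sex-averaged
axis), mapped to physical coordinates by linear interpolation, and the
copied-from haplotype alternates at every crossover.

The four models are named ``ss+intf``, ``ss+poiss``, ``sa+intf`` and
``sa+poiss`` (sex-specific / sex-averaged map, interference / Poisson
inter-crossover distances).

Pedigree structures come from ``def`` files (:func:`parse_def`) or from the
relationship presets (:func:`full_sib_pair`, :func:`cousin_pair`, ...).
Replicates are simulated in chunks with crossovers drawn in batches per
(meiosis slot, chromosome, parent sex) so large runs stay fast; the draw
order is fixed, making output deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .crossover import (
    InterferenceParams,
    SexedInterferenceParams,
    sample_crossovers_batch,
)
from .genetic_map import SEX_AVERAGED, SEX_SPECIFIC, ChromosomeMap, GeneticMap

MODEL_NAMES = ("ss+intf", "ss+poiss", "sa+intf", "sa+poiss")


class DefParseError(ValueError):
    """A pedigree definition file is malformed."""


class ConfigurationError(ValueError):
    """Incompatible model / map / parameter combination."""


@dataclass(frozen=True)
class CrossoverModel:
    """Map dialect (sex-specific vs sex-averaged axis) x crossover process."""

    sex_specific: bool
    interference: bool

    @classmethod
    def parse(cls, name) -> "CrossoverModel":
        if isinstance(name, CrossoverModel):
            return name
        key = str(name).strip().lower().replace("poisson", "poiss")
        try:
            ss, proc = key.split("+")
        except ValueError:
            raise ConfigurationError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")
        if ss not in ("ss", "sa") or proc not in ("intf", "poiss"):
            raise ConfigurationError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")
        return cls(sex_specific=(ss == "ss"), interference=(proc == "intf"))

    @property
    def name(self) -> str:
        return ("ss" if self.sex_specific else "sa") + "+" + (
            "intf" if self.interference else "poiss"
        )


# ---------------------------------------------------------------------------
# pedigree structure


@dataclass
class Member:
    """One pedigree slot (shared across replicates).

    ``sex_mode`` is ``"male"``/``"female"`` (fixed), ``"random"``
    (independent fair coin per replicate) or ``("couple", c, side)`` where a
    single coin per couple ``c`` per replicate sets side 0 and side 1 gets
    the complement.
    """

    key: str
    generation: int
    parents: tuple[str, str] | None = None  # couple members; order is structural
    sex_mode: object = "random"
    printed: bool = False

    @property
    def founder(self) -> bool:
        return self.parents is None


@dataclass
class PedigreeGraph:
    name: str
    members: list[Member]
    n_couples: int
    copies: int = 1

    def __post_init__(self) -> None:
        self._by_key = {m.key: m for m in self.members}
        if len(self._by_key) != len(self.members):
            raise ValueError("duplicate member keys")

    def member(self, key: str) -> Member:
        return self._by_key[key]

    @property
    def founders(self) -> list[Member]:
        return [m for m in self.members if m.founder]

    @property
    def printed(self) -> list[str]:
        return [m.key for m in self.members if m.printed]

    def founder_hap_slots(self) -> list[tuple[str, int]]:
        """(member key, hap index) in founder-id assignment order."""
        return [(m.key, i) for m in self.founders for i in (0, 1)]


@dataclass
class PedigreeSpec:
    """Parsed ``def`` block: name, replicate count, generations, optional
    forced sex of reproducing non-founders, and the per-generation print /
    branch plan."""

    name: str
    copies: int
    n_generations: int
    forced_sex: str = "none"  # none | male | female
    print_plan: dict[int, int] = field(default_factory=dict)  # gen -> n_print per branch
    branch_plan: dict[int, int] = field(default_factory=dict)  # gen -> n_branches


def parse_def(text: str) -> list[PedigreeSpec]:
    """Parse pedigree definition text.

    Blocks start with ``def NAME COPIES N_GENERATIONS [M|F]``; subsequent
    lines ``GENERATION N_PRINT [N_BRANCHES]`` set the printing and branching
    plan.  Unlisted generations print nothing and use the default branch
    counts (one founder couple at generation 1, two branches at generation
    2, one child per branch afterwards).
    """
    specs: list[PedigreeSpec] = []
    cur: PedigreeSpec | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if fields[0] == "def":
            if len(fields) not in (4, 5):
                raise DefParseError(f"line {lineno}: expected 'def name copies generations [M|F]'")
            name = fields[1]
            try:
                copies = int(fields[2])
                n_gen = int(fields[3])
            except ValueError:
                raise DefParseError(f"line {lineno}: copies and generations must be integers")
            if copies < 1:
                raise DefParseError(f"line {lineno}: copies must be >= 1")
            if n_gen < 2:
                raise DefParseError(f"line {lineno}: a pedigree needs >= 2 generations")
            forced = "none"
            if len(fields) == 5:
                token = fields[4].upper()
                if token not in ("M", "F"):
                    raise DefParseError(f"line {lineno}: forced sex must be 'M' or 'F'")
                forced = "male" if token == "M" else "female"
            cur = PedigreeSpec(name=name, copies=copies, n_generations=n_gen, forced_sex=forced)
            specs.append(cur)
        else:
            if cur is None:
                raise DefParseError(f"line {lineno}: print line before any 'def'")
            if len(fields) not in (2, 3):
                raise DefParseError(f"line {lineno}: expected 'generation n_print [n_branches]'")
            try:
                gen = int(fields[0])
                n_print = int(fields[1])
            except ValueError:
                raise DefParseError(f"line {lineno}: generation and n_print must be integers")
            if not 1 <= gen <= cur.n_generations:
                raise DefParseError(
                    f"line {lineno}: generation {gen} outside 1..{cur.n_generations}"
                )
            if n_print < 0:
                raise DefParseError(f"line {lineno}: n_print must be >= 0")
            if gen == 1 and n_print > 2:
                raise DefParseError(
                    f"line {lineno}: generation 1 is a single founder couple (n_print <= 2)"
                )
            cur.print_plan[gen] = n_print
            if len(fields) == 3:
                try:
                    nb = int(fields[2])
                except ValueError:
                    raise DefParseError(f"line {lineno}: n_branches must be an integer")
                if nb < 1:
                    raise DefParseError(f"line {lineno}: n_branches must be >= 1")
                if gen == 1:
                    raise DefParseError(f"line {lineno}: generation 1 has a single branch")
                cur.branch_plan[gen] = nb
    return specs


def build_pedigree(spec: PedigreeSpec) -> PedigreeGraph:
    """Expand a :class:`PedigreeSpec` into a concrete pedigree graph."""
    G = spec.n_generations
    branches = {1: 1}
    for g in range(2, G + 1):
        branches[g] = spec.branch_plan.get(g, 2 if g == 2 else branches[g - 1])
    for g in range(3, G + 1):
        if branches[g] < branches[g - 1]:
            raise DefParseError(
                f"pedigree {spec.name!r}: branch count may not shrink (generation {g})"
            )

    lineage_sex = {"none": None, "male": "male", "female": "female"}[spec.forced_sex]
    members: list[Member] = []
    couples: list[tuple[str, str]] = []  # (lineage-or-first, spouse)
    couple_of_branch: dict[tuple[int, int], int] = {}

    def add_couple(m1: str, m2: str) -> int:
        couples.append((m1, m2))
        return len(couples) - 1

    def sex_mode_for(cidx: int, side: int):
        if lineage_sex is None:
            return ("couple", cidx, side)
        if side == 0:
            return lineage_sex
        return "female" if lineage_sex == "male" else "male"

    # generation 1: one founder couple
    g1a, g1b = "g1-b1-i1", "g1-b1-s1"
    c0 = add_couple(g1a, g1b)
    members.append(Member(g1a, 1, None, sex_mode_for(c0, 0)))
    members.append(Member(g1b, 1, None, sex_mode_for(c0, 1)))
    couple_of_branch[(1, 1)] = c0
    n_print1 = spec.print_plan.get(1, 0)
    for i, key in enumerate((g1a, g1b)):
        if i < n_print1:
            members[i].printed = True

    for g in range(2, G + 1):
        nb, nb_par = branches[g], branches[g - 1]
        n_print = spec.print_plan.get(g, 0)
        reproduces = g < G
        for b in range(1, nb + 1):
            parent_branch = (b - 1) * nb_par // nb + 1
            pc = couple_of_branch[(g - 1, parent_branch)]
            parents = couples[pc]
            lineage_key = f"g{g}-b{b}-i1"
            if reproduces:
                spouse_key = f"g{g}-b{b}-s1"
                cidx = add_couple(lineage_key, spouse_key)
                members.append(Member(lineage_key, g, parents, sex_mode_for(cidx, 0)))
                members.append(Member(spouse_key, g, None, sex_mode_for(cidx, 1)))
                couple_of_branch[(g, b)] = cidx
            else:
                members.append(Member(lineage_key, g, parents, "random"))
            if n_print >= 1:
                # the branch's lineage member is printed first
                (members[-2] if reproduces else members[-1]).printed = True
            # extra printed siblings beyond the lineage member
            for j in range(2, n_print + 1):
                extra = Member(f"g{g}-b{b}-i{j}", g, parents, "random", printed=True)
                members.append(extra)
    return PedigreeGraph(spec.name, members, n_couples=len(couples), copies=spec.copies)


# ---------------------------------------------------------------------------
# relationship presets


def _graph(name: str, members: list[Member], couples: int, copies: int = 1) -> PedigreeGraph:
    return PedigreeGraph(name, members, n_couples=couples, copies=copies)


def parent_child_pair() -> PedigreeGraph:
    members = [
        Member("p", 1, None, ("couple", 0, 0), printed=True),
        Member("s", 1, None, ("couple", 0, 1)),
        Member("c", 2, ("p", "s"), "random", printed=True),
    ]
    return _graph("parent-child", members, couples=1)


def full_sib_pair() -> PedigreeGraph:
    members = [
        Member("p", 1, None, ("couple", 0, 0)),
        Member("s", 1, None, ("couple", 0, 1)),
        Member("c1", 2, ("p", "s"), "random", printed=True),
        Member("c2", 2, ("p", "s"), "random", printed=True),
    ]
    return _graph("full-sibs", members, couples=1)


def half_sib_pair(shared_parent_sex: str = "random") -> PedigreeGraph:
    """Two half-siblings through one shared parent and two founder spouses."""
    if shared_parent_sex == "random":
        mode_p: object = ("couple", 0, 0)
    elif shared_parent_sex in ("mother", "female"):
        mode_p = "female"
    elif shared_parent_sex in ("father", "male"):
        mode_p = "male"
    else:
        raise ValueError(f"bad shared_parent_sex {shared_parent_sex!r}")
    members = [
        Member("p", 1, None, mode_p),
        Member("s1", 1, None, ("couple", 0, 1)),
        Member("s2", 1, None, ("couple", 1, 1)),
        Member("c1", 2, ("p", "s1"), "random", printed=True),
        Member("c2", 2, ("p", "s2"), "random", printed=True),
    ]
    # coin columns: couple 0 = (p, s1), couple 1 = (p, s2); spouses resolve
    # to the complement of p's per-replicate sex.
    return _graph("half-sibs", members, couples=2)


def grandparent_pair() -> PedigreeGraph:
    members = [
        Member("gp", 1, None, ("couple", 0, 0), printed=True),
        Member("gs", 1, None, ("couple", 0, 1)),
        Member("p", 2, ("gp", "gs"), ("couple", 1, 0)),
        Member("ps", 2, None, ("couple", 1, 1)),
        Member("gc", 3, ("p", "ps"), "random", printed=True),
    ]
    return _graph("grandparent", members, couples=2)


def cousin_pair(
    degree: int = 1,
    removed: int = 0,
    half: bool = False,
    lineage_sex: str = "random",
) -> PedigreeGraph:
    """k-th cousins (optionally removed or half).

    Full cousins share a founder couple; half cousins share a single founder
    common ancestor with two founder spouses.  ``degree`` 0 with
    ``half=True`` gives half-siblings; ``degree`` k means the printed pair
    sit k+2 generations below the shared ancestor(s) (plus ``removed`` on
    one side).  ``lineage_sex`` of ``"random"``, ``"female"`` or ``"male"``
    controls the sex of the connecting non-founders (spouses take the
    complement), matching the all-female / all-male lineage analyses.
    """
    if degree < 0 or removed < 0:
        raise ValueError("degree and removed must be >= 0")
    if degree == 0 and not half:
        raise ValueError("degree 0 requires half=True (half-siblings); use full_sib_pair()")
    if lineage_sex not in ("random", "female", "male"):
        raise ValueError(f"bad lineage_sex {lineage_sex!r}")

    members: list[Member] = []
    couples: list[tuple[str, str]] = []

    def mode(cidx: int, side: int):
        if lineage_sex == "random":
            return ("couple", cidx, side)
        if side == 0:
            return lineage_sex
        return "male" if lineage_sex == "female" else "female"

    if half:
        couples.append(("a", "s1"))
        couples.append(("a", "s2"))
        members.append(Member("a", 1, None, mode(0, 0)))
        members.append(Member("s1", 1, None, mode(0, 1)))
        members.append(Member("s2", 1, None, mode(1, 1)))
        top = [("a", "s1"), ("a", "s2")]
    else:
        couples.append(("a", "s"))
        members.append(Member("a", 1, None, mode(0, 0)))
        members.append(Member("s", 1, None, mode(0, 1)))
        top = [("a", "s"), ("a", "s")]

    depths = (degree + 1, degree + 1 + removed)  # generations below the ancestors per side
    for side in (0, 1):
        parents = top[side]
        for d in range(1, depths[side] + 1):
            key = f"L{side}-{d}"
            last = d == depths[side]
            if last:
                members.append(Member(key, 1 + d, parents, "random", printed=True))
            else:
                spouse = f"L{side}-{d}s"
                cidx = len(couples)
                couples.append((key, spouse))
                members.append(Member(key, 1 + d, parents, mode(cidx, 0)))
                members.append(Member(spouse, 1 + d, None, mode(cidx, 1)))
                parents = (key, spouse)

    kind = "half-" if half else ""
    name = f"{kind}cousins-{degree}" + (f"-r{removed}" if removed else "")
    if half and degree == 0:
        name = "half-sibs"
    members.sort(key=lambda m: m.generation)
    return _graph(name, members, couples=len(couples))


_PRESET_BUILDERS = {
    "parent-child": parent_child_pair,
    "full-sibs": full_sib_pair,
    "half-sibs": half_sib_pair,
    "maternal-half-sibs": lambda: half_sib_pair("mother"),
    "paternal-half-sibs": lambda: half_sib_pair("father"),
    "grandparent": grandparent_pair,
}

_ORDINALS = {
    "first": 1, "second": 2, "third": 3, "fourth": 4,
    "fifth": 5, "sixth": 6, "seventh": 7, "eighth": 8,
}


def relationship_graph(name: str) -> PedigreeGraph:
    """Build a pedigree graph from a relationship name.

    Recognized: the presets above plus ``<ordinal>-cousins``,
    ``half-<ordinal>-cousins``, ``<ordinal>-cousins-once-removed``, and
    ``female-``/``male-`` prefixes forcing the lineage sex.
    """
    key = name.strip().lower()
    if key in _PRESET_BUILDERS:
        return _PRESET_BUILDERS[key]()
    lineage = "random"
    for prefix, sex in (("female-", "female"), ("male-", "male")):
        if key.startswith(prefix):
            lineage = sex
            key = key[len(prefix):]
    half = key.startswith("half-")
    if half:
        key = key[len("half-"):]
    removed = 0
    if key.endswith("-once-removed"):
        removed = 1
        key = key[: -len("-once-removed")]
    elif key.endswith("-twice-removed"):
        removed = 2
        key = key[: -len("-twice-removed")]
    if key.endswith("-cousins"):
        ordinal = key[: -len("-cousins")]
        if ordinal in _ORDINALS:
            g = cousin_pair(_ORDINALS[ordinal], removed=removed, half=half, lineage_sex=lineage)
            return g
    if key == "sibs" and half:
        return half_sib_pair()
    raise ValueError(f"unknown relationship {name!r}")


# ---------------------------------------------------------------------------
# individuals and the simulation engine

Runs = tuple[list[int], list[float]]  # (founder ids, physical end coordinates)


@dataclass
class Individual:
    """A simulated pedigree member: two haplotypes, each a per-chromosome
    list of founder-segment runs."""

    id: str
    sex: str
    generation: int
    founder: bool
    haplotypes: tuple[dict[str, Runs], dict[str, Runs]]
    founder_pool: tuple[str, int] = ("", 0)  # (pedigree name, replicate index)


@dataclass
class SimulationResult:
    graph: PedigreeGraph
    model: CrossoverModel
    gmap: GeneticMap
    seed: int
    replicates: list[dict[str, Individual]]

    def __len__(self) -> int:
        return len(self.replicates)


def _axis_sex(model: CrossoverModel, parent_sex: str) -> str:
    return parent_sex if model.sex_specific else "averaged"


def _resolve_sexes(
    graph: PedigreeGraph, R: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-replicate sexes for every member; arrays of 'male'/'female'.

    One coin per couple per replicate; side 1 takes the complement of side
    0.  Members sharing a slot across couples (half-sib shared parents) are
    resolved by their own mode; dependent spouses then complement.
    """
    coins = rng.random((R, graph.n_couples)) < 0.5
    sexes: dict[str, np.ndarray] = {}
    pending: list[Member] = []
    for m in graph.members:
        mode = m.sex_mode
        if mode == "male" or mode == "female":
            sexes[m.key] = np.full(R, mode, dtype=object)
        elif mode == "random":
            bits = rng.random(R) < 0.5
            sexes[m.key] = np.where(bits, "female", "male")
        else:
            _, cidx, side = mode
            base = coins[:, cidx] if side == 0 else ~coins[:, cidx]
            sexes[m.key] = np.where(base, "female", "male")
    # couples must be opposite-sexed: spouses with ('couple', c, 1) already
    # complement the coin; when side 0 has a fixed sex, override side 1
    for m in graph.members:
        mode = m.sex_mode
        if isinstance(mode, tuple):
            _, cidx, side = mode
            if side == 1:
                partner = _couple_partner(graph, m.key)
                if partner is not None:
                    psex = sexes[partner]
                    sexes[m.key] = np.where(psex == "male", "female", "male")
    return sexes


def _couple_partner(graph: PedigreeGraph, spouse_key: str) -> str | None:
    # find the member whose children list this spouse as a parent
    for m in graph.members:
        if m.parents and spouse_key in m.parents:
            other = m.parents[0] if m.parents[1] == spouse_key else m.parents[1]
            return other
    return None


def _recombine(h0: Runs, h1: Runs, xs: np.ndarray, start: int) -> Runs:
    """Form a gamete from two parental haplotypes and sorted crossover
    positions (physical).  Runs are treated as immutable and shared when no
    crossover occurs.  A crossover exactly on a run boundary keeps the left
    run's identity (ties go left)."""
    haps = (h0, h1)
    if xs.size == 0:
        return haps[start]
    out_ids: list[int] = []
    out_ends: list[float] = []
    ptr = [0, 0]
    cur = start
    for x in xs:
        ids, ends = haps[cur]
        i = ptr[cur]
        while ends[i] < x:
            out_ids.append(ids[i])
            out_ends.append(ends[i])
            i += 1
        ptr[cur] = i
        if not out_ends or out_ends[-1] < x:
            out_ids.append(ids[i])
            out_ends.append(x)
        cur ^= 1
        ids2, ends2 = haps[cur]
        j = ptr[cur]
        while ends2[j] <= x:
            j += 1
        ptr[cur] = j
    ids, ends = haps[cur]
    i = ptr[cur]
    out_ids.extend(ids[i:])
    out_ends.extend(ends[i:])
    # canonical merge of adjacent runs with equal founder id
    merged_ids = [out_ids[0]]
    merged_ends = [out_ends[0]]
    for fid, end in zip(out_ids[1:], out_ends[1:]):
        if fid == merged_ids[-1]:
            merged_ends[-1] = end
        else:
            merged_ids.append(fid)
            merged_ends.append(end)
    return merged_ids, merged_ends


def _resolve_intf(
    model: CrossoverModel,
    interference: SexedInterferenceParams | None,
    sex: str,
    chrom: str,
) -> InterferenceParams | None:
    if not model.interference:
        return None
    assert interference is not None
    return interference.resolve(_axis_sex(model, sex), chrom)


def meiosis(
    parent: Individual,
    chrom: str,
    gmap: GeneticMap,
    model,
    rng: np.random.Generator,
    interference: SexedInterferenceParams | None = None,
) -> Runs:
    """One meiosis of ``parent`` on one chromosome, returning the gamete's
    founder-segment runs."""
    model = CrossoverModel.parse(model)
    _validate_model(model, gmap, interference)
    try:
        c = gmap.chrom(chrom)
    except KeyError:
        raise ConfigurationError(f"chromosome {chrom!r} missing from map") from None
    axis = _axis_sex(model, parent.sex)
    length_m = c.length_cM(axis) / 100.0
    params = _resolve_intf(model, interference, parent.sex, chrom)
    xs_gen = sample_crossovers_batch(length_m, 1, rng, params)[0]
    g0 = c.gen_column(axis)[0]
    xs_phys = np.asarray(c.gen_to_phys(xs_gen * 100.0 + g0, axis), dtype=float).reshape(-1)
    start = int(rng.random() < 0.5)
    h0 = parent.haplotypes[0][chrom]
    h1 = parent.haplotypes[1][chrom]
    return _recombine(h0, h1, np.sort(xs_phys), start)


def _validate_model(
    model: CrossoverModel, gmap: GeneticMap, interference: SexedInterferenceParams | None
) -> None:
    if model.sex_specific and gmap.dialect == SEX_AVERAGED:
        raise ConfigurationError("sex-specific models need a sex-specific map")
    if model.interference and interference is None:
        raise ConfigurationError("interference models need interference parameters")


def _chunk_stream(
    graph: PedigreeGraph,
    gmap: GeneticMap,
    model: CrossoverModel,
    interference: SexedInterferenceParams | None,
    rng: np.random.Generator,
    copies: int,
    keep: Sequence[str],
    chunk_size: int,
) -> Iterator[tuple[int, dict[str, Individual]]]:
    founder_slots = graph.founder_hap_slots()
    fid_of_slot = {slot: i for i, slot in enumerate(founder_slots)}
    nonfounders = [m for m in graph.members if not m.founder]
    keep_set = set(keep)
    chrom_names = [c.name for c in gmap]

    done = 0
    while done < copies:
        R = min(chunk_size, copies - done)
        sexes = _resolve_sexes(graph, R, rng)
        # haps[(key, hap_idx)][chrom] = list over replicates of Runs
        haps: dict[tuple[str, int], dict[str, list[Runs]]] = {}
        for m in graph.founders:
            for hidx in (0, 1):
                fid = fid_of_slot[(m.key, hidx)]
                per_chrom = {}
                for c in gmap:
                    run: Runs = ([fid], [c.span()[1]])
                    per_chrom[c.name] = [run] * R
                haps[(m.key, hidx)] = per_chrom
        for m in nonfounders:
            haps[(m.key, 0)] = {cn: [None] * R for cn in chrom_names}  # type: ignore
            haps[(m.key, 1)] = {cn: [None] * R for cn in chrom_names}  # type: ignore

        for c in gmap:
            axes = {}
            for sex in ("male", "female", "averaged"):
                g = c.gen_column(sex)
                axes[sex] = (g, c.phys, float(g[0]), float(g[-1] - g[0]) / 100.0)
            for m in nonfounders:
                for hidx, parent_key in enumerate(m.parents):
                    parent_sex = sexes[parent_key]
                    starts = rng.random(R) < 0.5
                    xs_all: list[np.ndarray] = [None] * R  # type: ignore
                    for sex in ("male", "female"):
                        axis = _axis_sex(model, sex)
                        gcol, pcol, g0, length_m = axes[axis]
                        idx = np.where(parent_sex == sex)[0]
                        if idx.size == 0:
                            continue
                        params = _resolve_intf(model, interference, sex, c.name)
                        batch = sample_crossovers_batch(length_m, idx.size, rng, params)
                        if any(b.size for b in batch):
                            concat = np.concatenate(batch) * 100.0 + g0
                            phys = np.interp(concat, gcol, pcol)
                            offs = np.cumsum([0] + [b.size for b in batch])
                            for j, ri in enumerate(idx):
                                xs_all[ri] = phys[offs[j] : offs[j + 1]]
                        else:
                            for ri in idx:
                                xs_all[ri] = batch[0][:0]
                    p0 = haps[(parent_key, 0)][c.name]
                    p1 = haps[(parent_key, 1)][c.name]
                    out = haps[(m.key, hidx)][c.name]
                    for r in range(R):
                        out[r] = _recombine(p0[r], p1[r], xs_all[r], int(starts[r]))

        for r in range(R):
            rep_idx = done + r
            individuals: dict[str, Individual] = {}
            for m in graph.members:
                if m.key not in keep_set:
                    continue
                h0 = {cn: haps[(m.key, 0)][cn][r] for cn in chrom_names}
                h1 = {cn: haps[(m.key, 1)][cn][r] for cn in chrom_names}
                individuals[m.key] = Individual(
                    id=f"{graph.name}{rep_idx + 1}_{m.key}",
                    sex=str(sexes[m.key][r]),
                    generation=m.generation,
                    founder=m.founder,
                    haplotypes=(h0, h1),
                    founder_pool=(graph.name, rep_idx),
                )
            yield rep_idx, individuals
        done += R


def simulate_stream(
    spec,
    gmap: GeneticMap,
    model,
    interference: SexedInterferenceParams | None = None,
    seed: int = 0,
    copies: int | None = None,
    keep: str | Sequence[str] = "printed",
    chunk_size: int = 2048,
) -> Iterator[tuple[int, dict[str, Individual]]]:
    """Stream simulated replicates as ``(replicate_index, {key: Individual})``.

    ``spec`` is a :class:`PedigreeGraph`, :class:`PedigreeSpec`, or a
    relationship name string.  ``keep`` selects which members are
    materialized (``"printed"``, ``"all"``, or an explicit key list).
    Deterministic given ``seed``.
    """
    graph = _as_graph(spec)
    model = CrossoverModel.parse(model)
    _validate_model(model, gmap, interference)
    if copies is None:
        copies = graph.copies
    if keep == "printed":
        keep_keys: Sequence[str] = graph.printed
    elif keep == "all":
        keep_keys = [m.key for m in graph.members]
    else:
        keep_keys = list(keep)
    rng = np.random.default_rng(seed)
    yield from _chunk_stream(
        graph, gmap, model, interference, rng, copies, keep_keys, chunk_size
    )


def simulate(
    spec,
    gmap: GeneticMap,
    model,
    interference: SexedInterferenceParams | None = None,
    seed: int = 0,
    copies: int | None = None,
    keep: str | Sequence[str] = "printed",
    chunk_size: int = 2048,
) -> SimulationResult:
    """Simulate all replicates of a pedigree and return them in memory.

    See :func:`simulate_stream` for the streaming variant (preferred for
    very large replicate counts)."""
    graph = _as_graph(spec)
    reps = [
        individuals
        for _, individuals in simulate_stream(
            graph, gmap, model, interference, seed, copies, keep, chunk_size
        )
    ]
    return SimulationResult(
        graph=graph, model=CrossoverModel.parse(model), gmap=gmap, seed=seed, replicates=reps
    )


def _as_graph(spec) -> PedigreeGraph:
    if isinstance(spec, PedigreeGraph):
        return spec
    if isinstance(spec, PedigreeSpec):
        return build_pedigree(spec)
    if isinstance(spec, str):
        return relationship_graph(spec)
    raise TypeError(f"cannot interpret pedigree spec {spec!r}")


# ---------------------------------------------------------------------------
# output writers


def write_fam(result: SimulationResult, path) -> None:
    """6-column pedigree table: family, id, father, mother, sex (1=male,
    2=female), phenotype (-9).  Unprinted parents are written as 0.

    ``path`` may be a filesystem path or an open text handle."""
    own = not hasattr(path, "write")
    fh = open(path, "w") if own else path
    try:
        for rep_idx, individuals in enumerate(result.replicates):
            fam = f"{result.graph.name}{rep_idx + 1}"
            for key, ind in individuals.items():
                member = result.graph.member(key)
                father = mother = "0"
                if member.parents:
                    for pk in member.parents:
                        if pk in individuals:
                            if individuals[pk].sex == "male":
                                father = individuals[pk].id
                            else:
                                mother = individuals[pk].id
                sex_code = 1 if ind.sex == "male" else 2
                fh.write(f"{fam}\t{ind.id}\t{father}\t{mother}\t{sex_code}\t-9\n")
    finally:
        if own:
            fh.close()
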