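import numpy as np
import pytest
from scipy import stats as sps

import relsim as rs
from relsim.core import (
    CrossoverModel,
    DefParseError,
    ConfigurationError,
    _recombine,
    build_pedigree,
    parse_def,
)
from relsim.crossover import _poisson_batch
from relsim.genetic_map import to_sex_averaged
from relsim import ibd


class TestDefParsing:
    def test_full_sib_example(self):
        specs = parse_def("def full-sibs 10000 2\n2 1\n")
        assert len(specs) == 1
        spec = specs[0]
        assert spec.copies == 10_000 and spec.n_generations == 2
        graph = build_pedigree(spec)
        printed = [graph.member(k) for k in graph.printed]
        assert len(printed) == 2
        assert all(m.generation == 2 for m in printed)
        # both printed children descend from the single generation-1 couple
        assert printed[0].parents == printed[1].parents

    def test_second_cousin_male_example(self):
        spec = parse_def("def second-cous-male 5000 4 M\n4 1\n")[0]
        assert spec.forced_sex == "male" and spec.n_generations == 4
        graph = build_pedigree(spec)
        assert len(graph.printed) == 2
        # reproducing non-founders are all male, spouses female
        for m in graph.members:
            if not m.founder and m.generation < 4:
                assert m.sex_mode == "male"

    def test_one_generation_pedigree_rejected(self):
        with pytest.raises(DefParseError):
            parse_def("def x 10 1\n")

    def test_generation_out_of_range_rejected(self):
        with pytest.raises(DefParseError, match="line 2"):
            parse_def("def x 10 2\n3 1\n")

    def test_generation_one_capacity(self):
        with pytest.raises(DefParseError):
            parse_def("def x 10 3\n1 3\n")

    def test_unknown_tokens_rejected(self):
        with pytest.raises(DefParseError):
            parse_def("def x 10 2 Q\n")
        with pytest.raises(DefParseError):
            parse_def("def x ten 2\n")

    def test_extra_siblings_printed_per_branch(self):
        # n_print is per branch: generation 2 defaults to 2 branches, so
        # printing 3 per branch yields 6 full siblings
        graph = build_pedigree(parse_def("def sibs6 5 2\n2 3\n")[0])
        assert len(graph.printed) == 6
        parents = {graph.member(k).parents for k in graph.printed}
        assert len(parents) == 1


class TestModelParsing:
    @pytest.mark.parametrize("name,ss,intf", [
        ("ss+intf", True, True), ("SA+Poiss", False, False),
        ("sa+intf", False, True), ("ss+poisson", True, False),
    ])
    def test_names(self, name, ss, intf):
        m = CrossoverModel.parse(name)
        assert m.sex_specific is ss and m.interference is intf

    def test_bad_name(self):
        with pytest.raises(ConfigurationError):
            CrossoverModel.parse("chi2")

    def test_ss_model_needs_ss_map(self, rough_map, intf_params):
        sa = to_sex_averaged(rough_map)
        with pytest.raises(ConfigurationError):
            rs.simulate("full-sibs", sa, "ss+poiss", None, copies=1)

    def test_interference_needs_params(self, rough_map):
        with pytest.raises(ConfigurationError):
            rs.simulate("full-sibs", rough_map, "sa+intf", None, copies=1)


class TestRecombine:
    def test_no_crossover_copies_one_parental_haplotype(self):
        h0, h1 = ([1], [100.0]), ([2], [100.0])
        assert _recombine(h0, h1, np.array([]), 0) == h0
        assert _recombine(h0, h1, np.array([]), 1) == h1

    def test_single_crossover_switches_at_position(self):
        h0, h1 = ([1], [100.0]), ([2], [100.0])
        ids, ends = _recombine(h0, h1, np.array([40.0]), 0)
        assert ids == [1, 2] and ends == [40.0, 100.0]

    def test_double_crossover_returns_to_start_haplotype(self):
        h0, h1 = ([1], [100.0]), ([2], [100.0])
        ids, ends = _recombine(h0, h1, np.array([30.0, 60.0]), 0)
        assert ids == [1, 2, 1] and ends == [30.0, 60.0, 100.0]

    def test_crossover_on_existing_boundary_keeps_left_run(self):
        # parent haplotype already switches at 50; a crossover exactly there
        # must not create a zero-length run
        h0, h1 = ([1, 3], [50.0, 100.0]), ([2], [100.0])
        ids, ends = _recombine(h0, h1, np.array([50.0]), 0)
        assert ids == [1, 2] and ends == [50.0, 100.0]

    def test_adjacent_equal_ids_are_merged(self):
        h0, h1 = ([1], [100.0]), ([1, 2], [70.0, 100.0])
        ids, ends = _recombine(h0, h1, np.array([30.0]), 0)
        assert ids == [1, 2] and ends == [70.0, 100.0]


class TestMeiosis:
    def test_zero_crossover_gamete_is_fair_coin_over_parents(self):
        # a zero-genetic-length chromosome never recombines, so the gamete
        # equals either parental haplotype with probability 1/2
        gmap = rs.make_synthetic_map(n_chrom=1, male_len=0.0, female_factor=1.0, seed=8)
        res = rs.simulate("parent-child", gmap, "sa+poiss", None, seed=11, copies=4000,
                          keep="all")
        n0 = 0
        for reps in res.replicates:
            child_run = reps["c"].haplotypes[0]["1"]
            parent_run0 = reps["p"].haplotypes[0]["1"]
            n0 += child_run[0] == parent_run0[0]
        pval = sps.binomtest(n0, 4000, 0.5).pvalue
        assert pval > 1e-3

    def test_single_meiosis_api(self, toy_map, intf_params, rng):
        res = rs.simulate("full-sibs", toy_map, "ss+intf", intf_params, seed=1, copies=1,
                          keep="all")
        parent = res.replicates[0]["p"]
        runs = rs.meiosis(parent, "1", toy_map, "ss+intf", rng, intf_params)
        ids, ends = runs
        assert ends[-1] == toy_map.chrom("1").span()[1]
        assert all(e2 > e1 for e1, e2 in zip(ends, ends[1:]))
        parent_ids = set(parent.haplotypes[0]["1"][0]) | set(parent.haplotypes[1]["1"][0])
        assert set(ids) <= parent_ids

    def test_missing_chromosome_raises(self, toy_map, intf_params, rng):
        res = rs.simulate("full-sibs", toy_map, "ss+intf", intf_params, seed=1, copies=1,
                          keep="all")
        with pytest.raises(ConfigurationError):
            rs.meiosis(res.replicates[0]["p"], "99", toy_map, "ss+intf", rng, intf_params)


class TestSimulate:
    def test_haplotypes_tile_each_chromosome(self, rough_map, intf_params):
        res = rs.simulate("first-cousins", rough_map, "ss+intf", intf_params,
                          seed=5, copies=30, keep="all")
        for reps in res.replicates:
            for ind in reps.values():
                for c in rough_map:
                    for h in (0, 1):
                        ids, ends = ind.haplotypes[h][c.name]
                        assert ends[-1] == pytest.approx(c.span()[1])
                        assert all(b > a for a, b in zip(ends, ends[1:]))
                        # canonical merge: no adjacent equal ids
                        assert all(i != j for i, j in zip(ids, ids[1:]))

    def test_fullsib_mean_sharing_is_half(self, rough_map, intf_params):
        res = rs.simulate("full-sibs", rough_map, "ss+intf", intf_params, seed=6,
                          copies=1500)
        props, k2s = [], []
        for reps in res.replicates:
            s = ibd.pair_stats(reps["c1"], reps["c2"], rough_map)
            props.append(s.proportion)
            k2s.append(s.k2)
        se_p = np.std(props, ddof=1) / np.sqrt(len(props))
        se_k = np.std(k2s, ddof=1) / np.sqrt(len(k2s))
        assert np.mean(props) == pytest.approx(0.5, abs=3 * se_p)
        assert np.mean(k2s) == pytest.approx(0.25, abs=3 * se_k)

    def test_sa_poisson_crossover_counts(self, rng):
        """Under the sex-averaged Poisson model the per-meiosis crossover
        count is Poisson with mean equal to the chromosome length in
        Morgans."""
        counts = np.array([b.size for b in _poisson_batch(1.28, 100_000, rng)])
        kmax = int(sps.poisson.ppf(0.999, 1.28)) + 1
        obs = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1).astype(float)
        probs = sps.poisson.pmf(np.arange(kmax + 1), 1.28)
        probs[-1] = 1 - probs[:-1].sum()
        exp = probs * counts.size
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert sps.chi2.sf(chi2, kmax) > 0.01

    def test_maternal_halfsibs_share_more_segments(self, rough_map, intf_params):
        counts = {}
        for rel in ("maternal-half-sibs", "paternal-half-sibs"):
            res = rs.simulate(rel, rough_map, "ss+intf", intf_params, seed=9, copies=250)
            counts[rel] = [
                ibd.pair_stats(reps["c1"], reps["c2"], rough_map).n_segments
                for reps in res.replicates
            ]
        mat, pat = counts["maternal-half-sibs"], counts["paternal-half-sibs"]
        se = np.sqrt(np.var(mat, ddof=1) / len(mat) + np.var(pat, ddof=1) / len(pat))
        assert np.mean(mat) - np.mean(pat) > 5 * se

    def test_same_seed_identical_seg_output(self, tmp_path, rough_map, intf_params):
        paths = []
        for name in ("a", "b"):
            res = rs.simulate("full-sibs", rough_map, "ss+intf", intf_params, seed=33,
                              copies=20)
            segs = []
            for reps in res.replicates:
                segs.extend(ibd.ibd_segments(reps["c1"], reps["c2"], rough_map))
            p = tmp_path / f"{name}.seg"
            ibd.write_seg(segs, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_forced_sex_assignments(self, rough_map, intf_params):
        res = rs.simulate(
            rs.cousin_pair(degree=1, lineage_sex="female"),
            rough_map, "ss+intf", intf_params, seed=3, copies=10, keep="all",
        )
        for reps in res.replicates:
            for key, ind in reps.items():
                if key.endswith("s") and not key.startswith("L"):
                    continue
                if key in ("a",):
                    assert ind.sex == "female"
                if key.endswith("-1s"):
                    assert ind.sex == "male"

    def test_fam_output(self, tmp_path, rough_map, intf_params):
        res = rs.simulate("parent-child", rough_map, "ss+intf", intf_params, seed=2,
                          copies=3, keep="all")
        p = tmp_path / "out.fam"
        rs.write_fam(res, p)
        lines = p.read_text().strip().split("\n")
        assert len(lines) == 9  # 3 members x 3 replicates
        fields = lines[0].split("\t")
        assert len(fields) == 6 and fields[5] == "-9"
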