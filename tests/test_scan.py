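import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lethalscan import (
    MatingGroup,
    ScanConfig,
    carrier_concordance,
    deficit_test,
    enumerate_window_haplotypes,
    estimate_frequencies,
    expected_homozygotes,
    merge_windows,
    observed_homozygotes,
    scan_genome,
)
from lethalscan.io_qc import PhasedGenotypes
from lethalscan.simulate import _lethal_columns, lethal_haplotype_string

from .conftest import phased_from_strings, trivial_map


def pedigree_rows(rows):
    return pd.DataFrame(rows, columns=["animal_id", "sire_id", "mgs_id",
                                       "dam_id", "sex", "parity_class"])


@pytest.fixture(scope="module")
def power_population():
    """~3,200 progeny with a fully penetrant lethal at f = 0.15: strong signal."""
    from lethalscan import LethalSpec
    from lethalscan.simulate import simulate_marker_map, simulate_population
    from .conftest import small_config

    config = small_config(
        seed=31, n_sires=40, n_mgs=40, n_dams=800,
        lethal_specs=[LethalSpec(window_start_marker=20, target_frequency=0.15)],
    )
    mm = simulate_marker_map(config)
    ped, phased, truth = simulate_population(mm, config)
    return config, mm, ped, phased, truth


@pytest.fixture(scope="module")
def pooled_null_results():
    """>10^4 (window, haplotype) tests pooled over null simulations."""
    from lethalscan.simulate import simulate_marker_map, simulate_population
    from .conftest import small_config

    frames = []
    for seed in (101, 102, 103, 104):
        config = small_config(seed=seed, n_dams=1000, markers_per_chromosome=200,
                              chromosome_length_bp=12_000_000)
        mm = simulate_marker_map(config)
        ped, phased, _ = simulate_population(mm, config)
        frames.append(scan_genome(phased, ped, mm))
    return pd.concat(frames, ignore_index=True)


class TestWindowKeys:
    def test_key_is_the_allele_string(self):
        ph = phased_from_strings([("a", "121", "212")])
        keys = enumerate_window_haplotypes(ph, trivial_map(3), 1, 0, 3)
        assert keys[0, 0] == "121" and keys[0, 1] == "212"

    def test_identical_strings_share_a_key(self):
        ph = phased_from_strings([("a", "1122", "1122"), ("b", "1122", "2211")])
        keys = enumerate_window_haplotypes(ph, trivial_map(4), 1, 0, 4)
        assert keys[0, 0] == keys[0, 1] == keys[1, 0]
        assert keys[1, 1] != keys[1, 0]

    def test_distinct_key_count_bounded_by_chromosome_copies(self, null_population):
        _, marker_map, _, phased, _ = null_population
        keys = enumerate_window_haplotypes(phased, marker_map, 1, 0, 20)
        assert len(np.unique(keys)) <= min(2 * phased.n_animals, 2 ** 20)

    def test_window_must_fit_chromosome(self):
        ph = phased_from_strings([("a", "11", "11")])
        with pytest.raises(ValueError):
            enumerate_window_haplotypes(ph, trivial_map(2), 1, 1, 2)


class TestFrequencies:
    PED = pedigree_rows(
        [("k%d" % i, "s1" if i < 3 else "0", "0", "0", "F", "na") for i in range(3)]
        + [("s1", "0", "0", "0", "M", "na")]
        + [(f"p{i}", "0", "0", f"k{i}", "F", "na") for i in range(3)]
    )

    def test_counting_over_eligible_maternal_chromosomes(self):
        # 5 animals with progeny (k0..k2 as dams, s1 as sire, plus unused)
        ph = phased_from_strings(
            [("k0", "11", "12"), ("k1", "11", "12"), ("k2", "11", "11"),
             ("s1", "11", "22"), ("x", "22", "22")]  # x: no progeny, excluded
        )
        f = estimate_frequencies(
            enumerate_window_haplotypes(ph, trivial_map(2), 1, 0, 2),
            ph.animal_ids, self.PED,
        )
        # eligible maternal chromosomes: 12, 12, 11, 22 (x excluded)
        assert f["12"] == pytest.approx(0.5)
        assert f["11"] == pytest.approx(0.25)
        assert f["22"] == pytest.approx(0.25)
        assert f.sum() == pytest.approx(1.0)

    def test_single_haplotype_degenerate(self):
        ph = phased_from_strings([("k0", "11", "11"), ("p", "11", "11")])
        ped = pedigree_rows([("p", "0", "0", "k0", "F", "na")])
        f = estimate_frequencies(
            enumerate_window_haplotypes(ph, trivial_map(2), 1, 0, 2),
            ph.animal_ids, ped,
        )
        assert list(f.items()) == [("11", 1.0)]

    def test_no_parents_yields_empty_with_warning(self, caplog):
        ph = phased_from_strings([("a", "11", "11")])
        ped = pedigree_rows([("a", "0", "0", "0", "F", "na")])
        with caplog.at_level("WARNING"):
            f = estimate_frequencies(
                enumerate_window_haplotypes(ph, trivial_map(2), 1, 0, 2),
                ph.animal_ids, ped,
            )
        assert f.empty


class TestExpectedHomozygotes:
    def test_single_group_closed_form(self):
        groups = [MatingGroup("s", "g", n=100, p=0.5, q=0.5)]
        # E = 100 * 0.5 * (0.5 + 0.1)/2 = 15
        assert expected_homozygotes(groups, f_k=0.1) == pytest.approx(15.0)

    def test_dam_variant_with_certain_transmission(self):
        groups = [MatingGroup("s", "g", n=7, p=1.0, q=0.0, r=1.0)]
        assert expected_homozygotes(groups, f_k=0.3, use_dam=True) == pytest.approx(7.0)

    def test_zero_when_dam_cannot_carry(self):
        groups = [MatingGroup("s", "g", n=50, p=1.0, q=0.0)]
        assert expected_homozygotes(groups, f_k=0.0) == 0.0

    def test_noncarrier_sire_group_rejected(self):
        with pytest.raises(ValueError):
            expected_homozygotes([MatingGroup("s", "g", n=5, p=0.0, q=0.5)], f_k=0.1)

    @given(st.floats(0.0, 0.4), st.floats(0.0, 0.4))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_dam_formulation_invariant_to_frequency(self, f1, f2):
        groups = [MatingGroup("s", "g", n=40, p=0.5, q=0.5, r=0.5),
                  MatingGroup("s2", "g", n=10, p=1.0, q=0.0, r=0.0)]
        e1 = expected_homozygotes(groups, f_k=f1, use_dam=True)
        e2 = expected_homozygotes(groups, f_k=f2, use_dam=True)
        assert e1 == e2

    def test_formula_matches_transmission_sampling(self):
        rng = np.random.default_rng(42)
        groups = pd.DataFrame({"n": [60, 25], "p": [0.5, 1.0], "q": [0.5, 0.0]})
        f_k = 0.12
        e_formula = expected_homozygotes(groups, f_k)
        draws = 200_000
        total, var = 0.0, 0.0
        for n, p, q in groups.itertuples(index=False):
            sire_t = rng.random(draws) < p
            dam_pat = rng.random(draws) < q
            dam_mat = rng.random(draws) < f_k
            from_pat = rng.random(draws) < 0.5
            dam_t = np.where(from_pat, dam_pat, dam_mat)
            hom = sire_t & dam_t
            total += n * hom.mean()
            var += n**2 * hom.mean() * (1 - hom.mean()) / draws
        assert abs(e_formula - total) <= 3 * np.sqrt(var)


class TestDeficitTest:
    @pytest.mark.parametrize(
        "observed, expected, chi2_val, p_str",
        [
            (0, 49, 49.0, "2.6E-12"),
            (24, 68, None, "9.5E-08"),
        ],
    )
    def test_published_pairs(self, observed, expected, chi2_val, p_str):
        chi2, p = deficit_test(observed, expected)
        if chi2_val is not None:
            assert chi2 == pytest.approx(chi2_val)
        assert f"{p:.1E}" == p_str

    def test_null_identity(self):
        chi2, p = deficit_test(33, 33)
        assert chi2 == 0.0 and p == 1.0

    def test_undefined_for_zero_expectation(self):
        with pytest.raises(ValueError):
            deficit_test(0, 0)


class TestObservedHomozygotes:
    def test_counts_double_matches_only(self):
        keys = np.array([["11", "11"], ["11", "12"], ["11", "11"], ["22", "22"]])
        assert observed_homozygotes(keys, "11") == 2
        assert observed_homozygotes(keys, "12") == 0
        assert observed_homozygotes(keys, "11", mask=[True, True, False, True]) == 1


class TestCarrierConcordance:
    def test_published_overlap_percentage(self):
        a = {f"cvm{i}" for i in range(244)}
        b = {f"cvm{i}" for i in range(209)} | {f"extra{i}" for i in range(225)}
        out = carrier_concordance(a, b)
        assert out["percent"] == 86
        assert out["n_overlap"] == 209 and out["n_b_only"] == 225

    def test_subset_and_disjoint_extremes(self):
        assert carrier_concordance({"a", "b"}, {"a", "b", "c"})["percent"] == 100
        assert carrier_concordance({"a"}, {"b"})["percent"] == 0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            carrier_concordance(set(), {"a"})


class TestMergeWindows:
    @staticmethod
    def result_row(window, observed, p, chromosome=1, expected=30.0):
        start_bp = 1_000_000 + window * 60_000
        return dict(
            chromosome=chromosome, window=window, start_marker=window,
            end_marker=window + 19, start_bp=start_bp,
            end_bp=start_bp + 19 * 60_000, haplotype="1" * 20, freq=0.05,
            expected=expected, observed=observed,
            chi2=(observed - expected) ** 2 / expected,
            p=p, deficit=observed < expected,
        )

    def test_consecutive_minimum_windows_merge_to_one_region(self):
        rows = [self.result_row(w, 0, 1e-8) for w in range(10, 15)]
        res = pd.DataFrame(rows)
        regions = merge_windows(res, trivial_map(60))
        assert len(regions) == 1
        r = regions.iloc[0]
        assert r["start_bp"] == rows[0]["start_bp"]
        assert r["end_bp"] == rows[-1]["end_bp"]
        assert r["observed"] == 0

    def test_single_window_region(self):
        regions = merge_windows(pd.DataFrame([self.result_row(4, 1, 1e-6)]),
                                trivial_map(60))
        assert len(regions) == 1
        assert regions.iloc[0]["observed"] == 1

    def test_two_separated_runs_give_two_regions(self):
        rows = [self.result_row(w, 2, 2.5e-6) for w in (10, 11)]
        rows += [self.result_row(w, 5, 1.1e-6) for w in (30, 31, 32)]
        regions = merge_windows(pd.DataFrame(rows), trivial_map(80))
        assert len(regions) == 2
        assert list(regions["observed"]) == [2, 5]

    def test_nonsignificant_and_excess_windows_ignored(self):
        rows = [self.result_row(3, 0, 1e-3),              # not significant
                self.result_row(8, 60, 1e-9, expected=30.0)]  # excess, not deficit
        regions = merge_windows(pd.DataFrame(rows), trivial_map(60))
        assert regions.empty


class TestScanGenome:
    def test_empty_genotypes_give_empty_result(self):
        ph = PhasedGenotypes(np.array([], dtype=object),
                             np.empty((0, 2, 30), dtype=np.uint8))
        ped = pedigree_rows([])
        res = scan_genome(ph, ped, trivial_map(30))
        assert res.empty

    def test_embedded_lethal_is_top_ranked_deficit(self, power_population):
        config, mm, ped, phased, _ = power_population
        res = scan_genome(phased, ped, mm)
        spec = config.lethal_specs[0]
        deficits = res[res["deficit"]]
        best = deficits[deficits["p"] == deficits["p"].min()]
        # the window coinciding exactly with the embedded lethal is among the
        # most significant deficits, carries its allele string, and has O = 0
        exact = best[(best["window"] == spec.window_start_marker)
                     & (best["haplotype"] == lethal_haplotype_string(mm, config))]
        assert len(exact) == 1
        assert exact.iloc[0]["observed"] == 0
        assert exact.iloc[0]["p"] < 1e-4

    def test_frequencies_sum_to_one_before_filter(self, null_population):
        _, mm, ped, phased, _ = null_population
        keys = enumerate_window_haplotypes(phased, mm, 1, 0, 20)
        f = estimate_frequencies(keys, phased.animal_ids, ped)
        assert f.sum() == pytest.approx(1.0)

    def test_bounds_on_counts(self, null_population):
        _, mm, ped, phased, _ = null_population
        res = scan_genome(phased, ped, mm)
        genotyped = set(phased.animal_ids)
        n_prog = int((ped["sire_id"].isin(genotyped) & ped["mgs_id"].isin(genotyped)
                      & ped["animal_id"].isin(genotyped)).sum())
        assert (res["observed"] <= n_prog).all()
        assert (res["expected"] <= n_prog + 1e-9).all()

    def test_null_false_positive_rate_bounded(self, pooled_null_results):
        res = pooled_null_results
        assert len(res) > 10_000
        frac = ((res["p"] < 1e-4) & res["deficit"]).mean()
        assert frac <= 10 * 1e-4

    def test_use_dam_requires_dam_genotypes(self, lethal_population):
        config, mm, ped, phased, _ = lethal_population
        res = scan_genome(phased, ped, mm, use_dam=True)
        assert res.empty  # dams are withheld by default, nothing to scan

    def test_dam_genotype_variant_detects_lethal(self):
        from lethalscan import LethalSpec
        from lethalscan.simulate import simulate_marker_map, simulate_population
        from .conftest import small_config

        config = small_config(
            seed=31, n_sires=40, n_mgs=40, n_dams=800, emit_dam_genotypes=True,
            lethal_specs=[LethalSpec(window_start_marker=20, target_frequency=0.15)],
        )
        mm = simulate_marker_map(config)
        ped, phased, _ = simulate_population(mm, config)
        res = scan_genome(phased, ped, mm, use_dam=True)
        hap = lethal_haplotype_string(mm, config)
        hit = res[(res["haplotype"] == hap) & (res["window"] == 20)]
        assert len(hit) == 1
        assert hit.iloc[0]["observed"] == 0
        assert hit.iloc[0]["p"] < 1e-8
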