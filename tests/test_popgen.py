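"""Clonal discrimination and diversity statistics vs exact oracles."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driftline import (GenoSimSpec, GenotypeTable, allele_counts,
                       assign_clones, clonal_richness, diversity, find_mlgs,
                       genet_dataset, make_genotypes, pairwise_fst, pgen, psex,
                       rarefied_allelic_richness, rarefied_private_alleles,
                       read_genepop, wc_theta, write_genepop)


def table_from_lists(geno_by_pop, loci=None):
    """geno_by_pop: {pop: [[(a, b), ...] per individual]}."""
    alleles, pops, ids = [], [], []
    k = 0
    for pop, inds in geno_by_pop.items():
        for g in inds:
            alleles.append(g)
            pops.append(pop)
            ids.append(f"i{k}")
            k += 1
    L = len(alleles[0])
    return GenotypeTable(alleles=np.array(alleles, dtype=np.int16),
                         pops=np.array(pops), ids=ids,
                         loci=loci or [f"L{j}" for j in range(L)])


class TestFindMlgs:
    def test_identical_genotypes_grouped(self):
        g = [[(1, 2)] * 8, [(1, 2)] * 8]
        ca = find_mlgs(table_from_lists({"p": g}))
        assert len(np.unique(ca.genet_ids)) == 1
        assert ca.pop_table.iloc[0]["G"] == 1

    def test_single_allele_difference_separates(self):
        a = [(1, 2)] * 8
        b = [(1, 2)] * 7 + [(1, 3)]
        ca = find_mlgs(table_from_lists({"p": [a, b]}))
        assert len(np.unique(ca.genet_ids)) == 2

    def test_grouping_is_within_populations_only(self):
        g = [(1, 1), (2, 2)]
        ca = find_mlgs(table_from_lists({"p1": [g], "p2": [g]}))
        assert len(np.unique(ca.genet_ids)) == 2

    def test_missing_loci_match_as_wildcards(self):
        a = [(1, 2), (3, 3), (2, 4), (1, 1)]
        b = [(1, 2), (0, 0), (2, 4), (1, 1)]  # 25% missing, matches a
        ca = find_mlgs(table_from_lists({"p": [a, b]}))
        assert len(np.unique(ca.genet_ids)) == 1

    def test_mostly_missing_ramet_never_grouped(self):
        a = [(1, 2), (3, 3), (2, 4), (1, 1)]
        b = [(1, 2), (0, 0), (0, 0), (0, 0)]  # 75% missing
        ca = find_mlgs(table_from_lists({"p": [a, b]}))
        assert len(np.unique(ca.genet_ids)) == 2

    def test_all_missing_ramet_excluded_with_warning(self):
        a = [(1, 2), (3, 3)]
        b = [(0, 0), (0, 0)]
        with pytest.warns(UserWarning, match="excluded"):
            ca = find_mlgs(table_from_lists({"p": [a, b]}))
        assert ca.excluded == [1]
        assert ca.genet_ids[1] == -1

    def test_recovers_simulator_truth_without_missing_data(self):
        gt, truth = make_genotypes(GenoSimSpec(n_pops=5, genets_per_pop=6,
                                               ramets_per_pop=20, clonality=0.5,
                                               alleles_per_locus=8, seed=31))
        ca = find_mlgs(gt)
        # same partition: equal label co-membership
        a = truth.genet_ids
        b = ca.genet_ids
        for i in range(gt.n):
            for j in range(i + 1, gt.n):
                assert (a[i] == a[j]) == (b[i] == b[j])


class TestPgen:
    def test_fixed_homozygote_probability_one(self):
        freqs = np.array([[0.0, 1.0]])  # allele 1 fixed
        assert pgen(np.array([[1, 1]]), freqs) == 1.0

    def test_heterozygote_half_half(self):
        freqs = np.array([[0.0, 0.5, 0.5]])
        assert pgen(np.array([[1, 2]]), freqs) == pytest.approx(0.5)

    def test_product_over_loci(self):
        freqs = np.array([[0.0, 0.5, 0.5], [0.0, 0.5, 0.5]])
        assert pgen(np.array([[1, 2], [1, 2]]), freqs) == pytest.approx(0.25)

    def test_missing_locus_skipped(self):
        freqs = np.array([[0.0, 0.5, 0.5], [0.0, 0.5, 0.5]])
        assert pgen(np.array([[1, 2], [0, 0]]), freqs) == pytest.approx(0.5)

    def test_absent_allele_raises(self):
        freqs = np.array([[0.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="absent"):
            pgen(np.array([[1, 2]]), freqs)


class TestPsex:
    def test_impossible_genotype_always_clonal(self):
        assert psex(0.0, 2, 10) == 0.0

    def test_certain_genotype_never_clonal(self):
        assert psex(1.0, 2, 10) == 1.0
        assert psex(1.0, 10, 10) == 1.0

    def test_binomial_tail_example(self):
        # P(X >= 2), X ~ Bin(3, 0.1): 3*0.01*0.9 + 0.001
        assert psex(0.1, 2, 3) == pytest.approx(0.028, rel=1e-12)

    def test_exact_enumeration_small_samples(self):
        """Oracle: exact binomial tail with Fraction arithmetic."""
        for N in (2, 5, 12, 20):
            for n in (2, max(2, N // 2), N):
                for p in (Fraction(1, 10), Fraction(1, 3), Fraction(9, 10)):
                    exact = sum(Fraction(math.comb(N, i)) * p ** i * (1 - p) ** (N - i)
                                for i in range(n, N + 1))
                    assert psex(float(p), n, N) == pytest.approx(float(exact), rel=1e-9)

    def test_monotone_in_pgen_and_copies(self):
        ps = [psex(p, 3, 20) for p in (0.01, 0.05, 0.2, 0.8)]
        assert ps == sorted(ps)
        ns = [psex(0.2, n, 20) for n in (2, 3, 5, 10)]
        assert ns == sorted(ns, reverse=True)

    def test_conditional_variant(self):
        from scipy.stats import binom

        assert psex(0.2, 3, 10, conditional=True) == \
            pytest.approx(float(binom.sf(1, 9, 0.2)), rel=1e-12)

    def test_singleton_rejected(self):
        with pytest.raises(ValueError):
            psex(0.1, 1, 10)

    @settings(max_examples=60, deadline=None)
    @given(p=st.floats(0.0, 1.0), N=st.integers(2, 300), frac=st.floats(0.0, 1.0))
    def test_always_a_probability(self, p, N, frac):
        n = 2 + int(frac * (N - 2))
        assert 0.0 <= psex(p, n, N) <= 1.0


@settings(max_examples=60, deadline=None)
@given(N=st.integers(2, 500), frac=st.floats(0.0, 1.0))
def test_clonal_richness_always_in_unit_interval(N, frac):
    G = 1 + int(frac * (N - 1))
    r = clonal_richness(N, G)
    assert 0.0 <= r <= 1.0
    if G == 1:
        assert r == 0.0
    if G == N:
        assert r == 1.0


class TestAssignClones:
    def test_rare_repeated_mlg_merged(self):
        """Many distinct genotypes plus one repeated rare MLG: Psex is
        tiny, so the copies merge into one genet."""
        rng = np.random.default_rng(3)
        inds = [[(a, b) for a, b in zip(rng.integers(1, 9, 8), rng.integers(1, 9, 8))]
                for _ in range(20)]
        rare = [(1, 2)] * 8
        table = table_from_lists({"p": inds + [rare, rare, rare]})
        ca = assign_clones(table, threshold=0.01)
        row = ca.mlg_table[ca.mlg_table["n"] == 3].iloc[0]
        assert row["merged"] and row["psex"] < 0.01
        assert ca.pop_table.iloc[0]["G"] < ca.pop_table.iloc[0]["N"]

    def test_common_genotype_in_tiny_sample_not_merged(self):
        """One locus, both alleles at 0.5: a repeated heterozygote is
        entirely plausible from sex (pgen = 0.5), so Psex stays high."""
        table = table_from_lists({"p": [[(1, 2)], [(1, 2)], [(1, 1)], [(2, 2)]]})
        ca = assign_clones(table, threshold=0.01)
        row = ca.mlg_table[ca.mlg_table["n"] == 2].iloc[0]
        assert not row["merged"]
        assert ca.pop_table.iloc[0]["G"] == 4

    def test_pipeline_converges_on_genet_dataset(self):
        gt, _ = make_genotypes(GenoSimSpec(n_pops=4, genets_per_pop=8,
                                           ramets_per_pop=24, clonality=0.5,
                                           alleles_per_locus=8, seed=37))
        ca1 = assign_clones(gt)
        genets = genet_dataset(gt, ca1)
        ca2 = assign_clones(genets)
        # second pass finds nothing more to merge
        assert len(genets.ids) == int(ca2.pop_table["G"].sum())


class TestClonalRichness:
    def test_endpoints_and_midpoint(self):
        assert clonal_richness(10, 1) == 0.0
        assert clonal_richness(10, 10) == 1.0
        assert clonal_richness(25, 13) == pytest.approx(0.5)

    def test_single_ramet_undefined(self):
        assert math.isnan(clonal_richness(1, 1))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            clonal_richness(5, 6)


class TestRarefaction:
    def exhaustive(self, counts, g, private=None):
        """Average allele count over all C(N, g) subsamples, exact."""
        pool = [a for a, c in counts.items() for _ in range(c)]
        tot = Fraction(0)
        nsub = 0
        for sub in itertools.combinations(range(len(pool)), g):
            seen = {pool[i] for i in sub}
            if private is not None:
                seen &= private
            tot += len(seen)
            nsub += 1
        return tot / nsub

    def test_worked_example(self):
        # counts {A:3, B:1}, g=2 -> 1 + (1 - C(3,2)/C(4,2)) = 1.5
        t = table_from_lists({
            "p1": [[(1, 1)], [(1, 2)]],
            "p2": [[(1, 1)], [(1, 1)]],
        })
        out = rarefied_allelic_richness(t, g=2)
        assert out[out["pop"] == "p1"]["A_hat"].iloc[0] == pytest.approx(1.5)

    def test_full_sample_recovers_observed_count(self):
        t = table_from_lists({"p1": [[(1, 2)], [(2, 3)]],
                              "p2": [[(1, 1)], [(1, 2)]]})
        out = rarefied_allelic_richness(t, g=4)
        assert out[out["pop"] == "p1"]["A_hat"].iloc[0] == 3.0
        assert out[out["pop"] == "p2"]["A_hat"].iloc[0] == 2.0

    def test_single_copy_sees_one_allele(self):
        t = table_from_lists({"p1": [[(1, 2)], [(2, 3)]],
                              "p2": [[(1, 3)], [(1, 2)]]})
        out = rarefied_allelic_richness(t, g=1)
        assert np.allclose(out["A_hat"], 1.0)

    def test_exhaustive_enumeration_many_configs(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            n_alleles = int(rng.integers(1, 5))
            counts = {a + 1: int(rng.integers(1, 5)) for a in range(n_alleles)}
            N = sum(counts.values())
            if N > 12 or N < 2:
                continue
            g = int(rng.integers(1, N + 1))
            from driftline.popgen import _hurlbert_expected

            arr = np.zeros(max(counts) + 1, dtype=int)
            for a, c in counts.items():
                arr[a] = c
            assert _hurlbert_expected(arr, g) == pytest.approx(
                float(self.exhaustive(counts, g)), abs=1e-12)

    def test_monotone_in_g(self):
        from driftline.popgen import _hurlbert_expected

        arr = np.array([0, 5, 3, 2, 1, 1])
        vals = [_hurlbert_expected(arr, g) for g in range(1, 13)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_oversized_subsample_rejected(self):
        t = table_from_lists({"p1": [[(1, 2)]], "p2": [[(1, 1)]]})
        with pytest.raises(ValueError, match="exceeds"):
            rarefied_allelic_richness(t, g=6)


class TestPrivateAlleles:
    def test_shared_allele_contributes_zero(self):
        t = table_from_lists({"p1": [[(1, 1)], [(1, 1)]],
                              "p2": [[(1, 1)], [(1, 1)]]})
        out = rarefied_private_alleles(t, g=2)
        assert np.allclose(out["PA_hat"], 0.0)

    def test_focal_only_allele_closed_form(self):
        # p1 carries allele 2 privately with count 1 of N=4 copies
        t = table_from_lists({"p1": [[(1, 1)], [(1, 2)]],
                              "p2": [[(1, 1)], [(1, 1)]]})
        out = rarefied_private_alleles(t, g=2)
        expect = 1 - math.comb(3, 2) / math.comb(4, 2)
        assert out[out["pop"] == "p1"]["PA_hat"].iloc[0] == pytest.approx(expect)

    def test_exhaustive_enumeration(self):
        rng = np.random.default_rng(29)
        rar = TestRarefaction()
        for _ in range(10):
            c1 = {a + 1: int(rng.integers(0, 4)) for a in range(4)}
            c2 = {a + 1: int(rng.integers(0, 4)) for a in range(4)}
            c1 = {a: c for a, c in c1.items() if c}
            c2 = {a: c for a, c in c2.items() if c}
            if not (2 <= sum(c1.values()) <= 12 and sum(c2.values()) >= 1):
                continue
            private = set(c1) - set(c2)
            g = int(rng.integers(1, sum(c1.values()) + 1))
            from driftline.popgen import _hurlbert_expected

            arr = np.zeros(5, dtype=int)
            for a, c in c1.items():
                arr[a] = c
            mask = np.zeros(5, dtype=bool)
            for a in private:
                mask[a] = True
            assert _hurlbert_expected(arr, g, private_mask=mask) == pytest.approx(
                float(rar.exhaustive(c1, g, private=private)), abs=1e-12)


class TestDiversity:
    def test_all_heterozygotes_closed_form(self):
        # 10 individuals Aa: HO = 1, HE = (20/19) * 0.5, FIS ~ -0.9
        t = table_from_lists({"p": [[(1, 2)]] * 10, "q": [[(1, 1)]] * 3})
        d = diversity(t)
        row = d["per_pop"][d["per_pop"]["pop"] == "p"].iloc[0]
        assert row["HO"] == 1.0
        assert row["HE"] == pytest.approx(20 / 19 * 0.5)
        assert row["FIS"] == pytest.approx(1 - 1 / (20 / 19 * 0.5))
        assert row["FIS"] == pytest.approx(-0.9, abs=0.001)

    def test_all_homozygotes_fis_one(self):
        t = table_from_lists({"p": [[(1, 1)]] * 5 + [[(2, 2)]] * 5})
        row = diversity(t)["per_pop"].iloc[0]
        assert row["HO"] == 0.0 and row["FIS"] == 1.0

    def test_monomorphic_locus_flagged_undefined(self):
        t = table_from_lists({"p": [[(1, 1), (1, 2)], [(1, 1), (2, 2)]]})
        per_locus = diversity(t)["per_locus"]
        mono = per_locus[per_locus["locus"] == "L0"].iloc[0]
        assert mono["HE"] == 0.0 and math.isnan(mono["FIS"])

    def test_hardy_weinberg_population_fis_near_zero(self):
        """Mean multilocus FIS over replicate random-mating samples
        must sit within 3 SE of zero."""
        vals = []
        for rep in range(30):
            gt, _ = make_genotypes(GenoSimSpec(n_pops=1, genets_per_pop=50,
                                               ramets_per_pop=50, clonality=0.0,
                                               n_loci=6, seed=100 + rep))
            vals.append(diversity(gt)["per_pop"]["FIS"].iloc[0])
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se


class TestWcTheta:
    def test_fixed_alternative_alleles_theta_one(self):
        t = table_from_lists({"p1": [[(1, 1)]] * 8, "p2": [[(2, 2)]] * 8})
        assert wc_theta(t) == pytest.approx(1.0)

    def test_duplicated_population_theta_zero(self):
        """Hand-computed oracle on 4 genets: identical populations give
        a = 0 exactly (no among-population variance beyond sampling)."""
        inds = [[(1, 2)], [(1, 1)], [(2, 2)], [(1, 2)]]
        t = table_from_lists({"p1": inds, "p2": [list(g) for g in inds]})
        theta, comp = wc_theta(t, return_components=True)
        assert theta == pytest.approx(_hand_theta_two_pops(t), abs=1e-12)
        assert theta < 0.1  # identical samples: no real differentiation

    def test_hand_computed_variance_components(self):
        """Independent re-derivation of a, b, c for a small two-pop
        table, locus by locus."""
        t = table_from_lists({
            "p1": [[(1, 1)], [(1, 2)], [(2, 2)], [(1, 2)], [(1, 1)]],
            "p2": [[(2, 2)], [(2, 2)], [(1, 2)], [(2, 2)], [(2, 2)]],
        })
        assert wc_theta(t) == pytest.approx(_hand_theta_two_pops(t), abs=1e-12)

    def test_invariant_under_allele_relabeling_and_pop_order(self):
        gt, _ = make_genotypes(GenoSimSpec(n_pops=3, genets_per_pop=15,
                                           ramets_per_pop=15, clonality=0.0,
                                           differentiation=0.2, seed=41))
        base = wc_theta(gt)
        relabeled = GenotypeTable(
            alleles=np.where(gt.alleles > 0, 7 - gt.alleles, 0),
            pops=gt.pops, ids=gt.ids, loci=gt.loci)
        assert wc_theta(relabeled) == pytest.approx(base, abs=1e-12)
        names = gt.pop_names
        assert wc_theta(gt, pops=names[::-1]) == pytest.approx(base, abs=1e-12)

    def test_pairwise_matrix_symmetric_zero_diagonal(self):
        gt, _ = make_genotypes(GenoSimSpec(n_pops=4, genets_per_pop=20,
                                           ramets_per_pop=20, clonality=0.0,
                                           differentiation=0.2, seed=43))
        fst = pairwise_fst(gt)
        assert np.allclose(fst.theta, fst.theta.T)
        assert np.all(np.diag(fst.theta) == 0)

    def test_negative_estimates_not_truncated(self):
        found = False
        for seed in range(10):
            gt, _ = make_genotypes(GenoSimSpec(n_pops=2, genets_per_pop=8,
                                               ramets_per_pop=8, clonality=0.0,
                                               differentiation=0.0, seed=900 + seed))
            if wc_theta(gt) < 0:
                found = True
                break
        assert found  # undifferentiated pops often yield slightly negative theta


def _hand_theta_two_pops(t):
    """Direct variance-components computation (independent of
    driftline.popgen) for a two-population, possibly multi-locus table."""
    names = list(dict.fromkeys(t.pops))
    r = len(names)
    A = B = C = 0.0
    for l in range(t.n_loci):
        sub = {p: t.alleles[(t.pops == p) & (t.alleles[:, l, 0] > 0), l, :]
               for p in names}
        ni = np.array([len(sub[p]) for p in names], dtype=float)
        nbar = ni.mean()
        nc = (r * nbar - (ni ** 2).sum() / (r * nbar)) / (r - 1)
        alleles = np.unique(np.concatenate([sub[p].ravel() for p in names]))
        for a in alleles:
            p_i = np.array([(sub[p] == a).sum() / (2 * len(sub[p])) for p in names])
            h_i = np.array([np.mean((sub[p] == a).sum(axis=1) == 1) for p in names])
            pbar = (ni * p_i).sum() / (r * nbar)
            s2 = (ni * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (ni * h_i).sum() / (r * nbar)
            inner = pbar * (1 - pbar) - (r - 1) / r * s2
            A += (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
            B += (nbar / (nbar - 1)) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
            C += hbar / 2
    return A / (A + B + C)


class TestGenepopIO:
    def test_roundtrip_preserves_genotypes_and_pops(self, tmp_path):
        gt, _ = make_genotypes(GenoSimSpec(n_pops=3, genets_per_pop=5,
                                           ramets_per_pop=8, missing_rate=0.1,
                                           seed=47))
        path = tmp_path / "data.gen"
        write_genepop(gt, path)
        back = read_genepop(path)
        assert np.array_equal(back.alleles, gt.alleles)
        assert list(back.loci) == list(gt.loci)
        assert list(back.pops) == list(gt.pops)

    def test_two_digit_alleles_parsed(self, tmp_path):
        gt = table_from_lists({"p": [[(1, 2), (3, 0)], [(2, 2), (1, 3)]]})
        # genepop normalises (3, 0) to fully missing
        path = tmp_path / "two.gen"
        write_genepop(gt, path, digits=2)
        back = read_genepop(path)
        assert np.array_equal(back.alleles, gt.alleles)

    def test_malformed_file_rejected(self, tmp_path):
        p = tmp_path / "bad.gen"
        p.write_text("title\nloc1\nPop\nind1 , 001002 003003\n")
        with pytest.raises(ValueError, match="expected 1 loci"):
            read_genepop(p)
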