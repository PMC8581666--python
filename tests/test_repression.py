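"""Fold changes, KS repression test, down-regulation calls, Fisher test."""

import itertools
import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from scipy.stats import hypergeom

from mirclust.io import ExpressionTable, SequenceRecord
from mirclust.repression import (
    call_downregulated,
    compare_position9,
    fisher_exact,
    ks_two_sample,
    log2_fold_changes,
    position9_composition,
    shared_downregulated,
)
from mirclust.overlap import OrthologMap
from mirclust.targets import SeedSite


def table(values: dict, samples=("r1", "r2")):
    df = pd.DataFrame(
        {s: [v if np.isscalar(v) else v[i] for v in values.values()]
         for i, s in enumerate(samples)},
        index=list(values),
    )
    return ExpressionTable(df.astype(float), unit="FPKM")


class TestLog2FoldChanges:
    def test_halving_is_minus_one(self):
        dx = log2_fold_changes(table({"g": 4.0}), table({"g": 2.0}))
        assert dx.lfc["g"] == pytest.approx(-1.0)

    def test_no_change_is_zero(self):
        dx = log2_fold_changes(table({"g": 3.0}), table({"g": 3.0}))
        assert dx.lfc["g"] == 0.0

    def test_zero_expression_excluded(self):
        dx = log2_fold_changes(table({"g": 0.0, "h": 2.0}), table({"g": 1.0, "h": 1.0}))
        assert dx.excluded == ["g"]
        assert list(dx.lfc.index) == ["h"]

    def test_replicates_averaged_before_ratio(self):
        dx = log2_fold_changes(table({"g": (2.0, 6.0)}), table({"g": (1.0, 1.0)}))
        assert dx.lfc["g"] == pytest.approx(math.log2(1 / 4))

    def test_disjoint_gene_sets_rejected(self):
        with pytest.raises(ValueError, match="no genes"):
            log2_fold_changes(table({"g": 1.0}), table({"h": 1.0}))


def ks_statistic(x, y):
    xs = np.sort(np.asarray(x, float))
    ys = np.sort(np.asarray(y, float))
    grid = np.concatenate([xs, ys])
    fx = np.searchsorted(xs, grid, side="right") / len(xs)
    fy = np.searchsorted(ys, grid, side="right") / len(ys)
    return np.max(np.abs(fx - fy))


def permutation_ks_pvalue(x, y):
    """Exact permutation null of the two-sample KS statistic."""
    pooled = list(x) + list(y)
    n = len(x)
    d_obs = ks_statistic(x, y)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        mask = np.zeros(len(pooled), bool)
        mask[list(idx)] = True
        d = ks_statistic(np.array(pooled)[mask], np.array(pooled)[~mask])
        hits += d >= d_obs - 1e-12
        total += 1
    return hits / total


class TestKsTwoSample:
    def test_identical_samples(self):
        res = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_fully_separated_samples(self):
        res = ks_two_sample([1, 2], [10, 20])
        assert res.statistic == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ks_two_sample([], [1.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_small_sample_p_matches_permutation_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        x = rng.normal(size=n)
        y = rng.normal(loc=rng.uniform(0, 1.5), size=n)
        res = ks_two_sample(x, y)  # auto -> exact for small samples
        assert res.method == "exact"
        assert res.p_value == pytest.approx(permutation_ks_pvalue(x, y), abs=0.01)

    def test_large_samples_use_asymptotic(self):
        rng = np.random.default_rng(0)
        res = ks_two_sample(rng.normal(size=50), rng.normal(size=80))
        assert res.method == "asymp"


class TestCallDownregulated:
    def dx(self, ctrl, treat):
        return log2_fold_changes(table({"g": ctrl}), table({"g": treat}))

    def test_1_3_fold_called_at_1_2_cutoff(self):
        assert call_downregulated(self.dx(1.3, 1.0)) == {"g"}

    def test_1_1_fold_not_called(self):
        assert call_downregulated(self.dx(1.1, 1.0)) == set()

    def test_exact_cutoff_included(self):
        assert call_downregulated(self.dx(1.2, 1.0)) == {"g"}

    def test_cutoff_of_one_rejected(self):
        with pytest.raises(ValueError):
            call_downregulated(self.dx(2.0, 1.0), fold_cutoff=1.0)

    def test_upregulated_never_called(self):
        assert call_downregulated(self.dx(1.0, 5.0)) == set()


def enumerate_fisher_pvalue(t):
    """Two-sided Fisher p by hypergeometric enumeration over fixed margins."""
    (a, b), (c, d) = t
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    p_obs = hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for k in range(lo, hi + 1):
        p = hypergeom.pmf(k, n, col1, row1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


class TestFisherExact:
    def test_diagonal_2x2(self):
        res = fisher_exact([[2, 0], [0, 2]])
        assert res.p_two_sided == pytest.approx(1 / 3)

    def test_flat_table(self):
        res = fisher_exact([[1, 1], [1, 1]])
        assert res.odds_ratio == 1.0
        assert res.p_two_sided == 1.0

    def test_strong_diagonal(self):
        res = fisher_exact([[10, 0], [0, 10]])
        assert res.p_two_sided == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="zero margin"):
            fisher_exact([[0, 0], [1, 2]])

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_hypergeometric_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            t = rng.integers(0, 16, size=(2, 2))
            if (t.sum(axis=0) > 0).all() and (t.sum(axis=1) > 0).all():
                break
        res = fisher_exact(t)
        assert res.p_two_sided == pytest.approx(enumerate_fisher_pvalue(t), rel=1e-7)


class TestSharedDownregulated:
    def test_published_structure(self):
        omap = OrthologMap.identity([f"g{i}" for i in range(80)], ["mel", "sim"])
        shared = {f"g{i}" for i in range(6)}
        sets = {
            "mel": shared | {f"g{i}" for i in range(10, 40)},
            "sim": shared | {f"g{i}" for i in range(40, 69)},
        }
        (res,) = shared_downregulated(sets, omap)
        assert res.shared_count == 6
        assert round(res.pct_union, 1) == 9.2

    def test_disjoint_and_empty(self):
        omap = OrthologMap.identity(["g1", "g2"], ["a", "b"])
        (res,) = shared_downregulated({"a": {"g1"}, "b": {"g2"}}, omap)
        assert res.shared_count == 0
        (res,) = shared_downregulated({"a": set(), "b": {"g2"}}, omap)
        assert res.shared_count == 0


class TestPosition9:
    def test_forced_composition(self):
        # one UTR with an 8mer site at p=10; base at p-1 pairs mature nt 9
        utr = SequenceRecord("g", "AAAAAAAAA" + "C" + "GUGCAAUA" + "AAAA")
        sites = [SeedSite("g", 10, "8mer")]
        counts, excluded = position9_composition(sites, [utr])
        assert counts == Counter({"C": 1})
        assert excluded == 0

    def test_7mer_1a_context_is_two_back(self):
        utr = SequenceRecord("g", "AAAAAAAA" + "G" + "UGCAAUA")
        # match m6 = UGCAAU at p=9; mature nt 8 pairs p-1, nt 9 pairs p-2
        sites = [SeedSite("g", 9, "7mer-1A")]
        counts, _ = position9_composition(sites, [utr])
        assert counts == Counter({"A": 1})

    def test_boundary_site_excluded(self):
        utr = SequenceRecord("g", "GUGCAAUA" + "AAAA")
        counts, excluded = position9_composition([SeedSite("g", 0, "8mer")], [utr])
        assert excluded == 1
        assert counts == Counter()

    def test_species_comparison_fisher(self):
        a = Counter({"A": 8, "C": 2})
        b = Counter({"A": 2, "C": 8})
        res = compare_position9(a, b, "A")
        assert res.table == ((8, 2), (2, 8))
        assert res.p_two_sided < 0.05


class TestRepressionPower:
    """Statistical behaviour of the KS test on the generator's output."""

    N_TARGETS, N_NONTARGETS, N_REP = 100, 2000, 200

    def _rejection_rate(self, fold):
        from mirclust.simulate import RepressionParams, simulate_expression

        genes = [f"g{i}" for i in range(self.N_TARGETS + self.N_NONTARGETS)]
        targets = set(genes[: self.N_TARGETS])
        params = RepressionParams(fold=fold, noise_sd=0.25)
        rng = np.random.default_rng(12345)
        rejections = 0
        for _ in range(self.N_REP):
            ctrl, treat = simulate_expression(targets, genes, params, rng)
            dx = log2_fold_changes(ctrl, treat)
            t = [g for g in dx.lfc.index if g in targets]
            nt = [g for g in dx.lfc.index if g not in targets]
            res = ks_two_sample(dx.lfc[t], dx.lfc[nt])
            rejections += res.p_value < 0.05
        return rejections / self.N_REP

    def test_power_at_weak_repression(self):
        assert self._rejection_rate(1.3) >= 0.95

    def test_type_i_error_under_null(self):
        assert 0.02 <= self._rejection_rate(1.0) <= 0.08

    def test_mean_target_lfc_matches_generator_closed_form(self):
        from mirclust.simulate import RepressionParams, simulate_expression

        genes = [f"g{i}" for i in range(2000)]
        targets = set(genes[:200])
        rng = np.random.default_rng(5)
        ctrl, treat = simulate_expression(
            targets, genes, RepressionParams(fold=1.5, noise_sd=0.1), rng
        )
        dx = log2_fold_changes(ctrl, treat)
        mean_t = dx.lfc[sorted(targets)].mean()
        assert mean_t == pytest.approx(-math.log2(1.5), abs=0.05)

    def test_noiseless_strong_repression_all_called(self):
        from mirclust.simulate import RepressionParams, simulate_expression

        genes = [f"g{i}" for i in range(300)]
        targets = set(genes[:50])
        rng = np.random.default_rng(6)
        ctrl, treat = simulate_expression(
            targets, genes, RepressionParams(fold=2.0, noise_sd=1e-9), rng
        )
        dx = log2_fold_changes(ctrl, treat)
        assert call_downregulated(dx, 1.2) == targets
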