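"""Correlation statistics, merging, and the EM loop itself."""

import itertools
import math

import numpy as np
import pytest

from emdetwin.em_core import (Assignment, EMConfig, ModeCorrelations,
                              assign_modes, merge, pattern_model_correlation,
                              pattern_pair_correlation, pearson, random_model,
                              run_em, target_score)
from emdetwin.evaluate import label_and_score
from emdetwin.reflection_io import Dataset, MergedModel, Pattern
from emdetwin.simulate import SimulationConfig, simulate_dataset
from emdetwin.symmetry import (IDENTITY, P63_TWIN, AmbiguityGroup, PointGroup,
                               apply_operator, asu_map)


class TestPearson:
    def test_perfectly_linear(self):
        assert pearson([2, 4], [1, 3]) == pytest.approx(1.0)

    def test_anti_linear(self):
        assert pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_textbook_formula_oracle(self):
        """Agree with the covariance/sd definition to 1e-12."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.exponential(10.0, size=100)
            y = 0.3 * x + rng.normal(size=100)
            num = np.mean((x - x.mean()) * (y - y.mean()))
            expect = num / (x.std() * y.std())
            assert pearson(x, y) == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_undefined(self):
        assert math.isnan(pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))
        assert math.isnan(pearson([1.0, 2.0], [5.0, 5.0]))

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert pearson(3.0 * x + 7.0, y) == pytest.approx(pearson(x, y),
                                                          abs=1e-12)


class TestPairCorrelation:
    def test_self_correlation(self, pg1):
        rng = np.random.default_rng(2)
        p = Pattern("p", rng.integers(1, 9, size=(30, 3)),
                    rng.exponential(size=30))
        r, n = pattern_pair_correlation(p, p, IDENTITY, pg1)
        assert n == len(np.unique(p.hkl, axis=0))
        assert r == pytest.approx(1.0)

    def test_disjoint_sets_undefined(self, pg1):
        p = Pattern("p", [[1, 0, 0], [2, 0, 0], [3, 0, 0],
                          [4, 0, 0], [5, 0, 0], [6, 0, 0]], np.arange(6.0))
        q = Pattern("q", [[0, 1, 0], [0, 2, 0], [0, 3, 0],
                          [0, 4, 0], [0, 5, 0], [0, 6, 0]], np.arange(6.0))
        r, n = pattern_pair_correlation(p, q, IDENTITY, pg1)
        assert n == 0 and math.isnan(r)

    def test_twin_reindexed_self(self, pg6):
        """A pattern correlates perfectly with its twin-reindexed copy
        under the twin operator."""
        rng = np.random.default_rng(3)
        hkl = asu_map(rng.integers(1, 12, size=(40, 3)), pg6)
        hkl, idx = np.unique(hkl, axis=0, return_index=True)
        inten = rng.exponential(size=len(hkl))
        p = Pattern("p", hkl, inten)
        q_hkl = asu_map(apply_operator(P63_TWIN, hkl), pg6)
        q = Pattern("q", q_hkl, inten)
        r, n = pattern_pair_correlation(p, q, P63_TWIN, pg6)
        assert r == pytest.approx(1.0)
        assert n == len(hkl)


class TestModelCorrelation:
    def test_scaled_pattern_gives_unity(self, pg1):
        rng = np.random.default_rng(4)
        hkl = np.unique(rng.integers(1, 20, size=(80, 3)), axis=0)[:50]
        means = rng.exponential(100.0, size=len(hkl))
        model = MergedModel.from_means(hkl, means)
        p = Pattern("p", hkl, 0.5 * means)
        r, n = pattern_model_correlation(p, model, IDENTITY, pg1)
        assert n == len(hkl)
        assert r == pytest.approx(1.0)

    def test_uniform_partiality_closed_form(self, pg1):
        """corr(p*I, I) = (1/2)/sqrt(5/12) for p ~ U(0,1), I ~ Exp.

        Cov(pI, I) = E[p] Var(I); Var(pI) = E[p^2]E[I^2] - E[p]^2 E[I]^2
        = 5/12 for unit-mean I, giving r = 0.5 / sqrt(5/12) = 0.77460.
        """
        rng = np.random.default_rng(5)
        n = 120_000
        side = int(round(n ** (1 / 3))) + 2
        grid = np.array(list(itertools.product(range(1, side + 1),
                                               repeat=3)))[:n]
        means = rng.exponential(1.0, size=n)
        model = MergedModel.from_means(grid, means)
        part = rng.uniform(size=n)
        p = Pattern("p", grid, part * means)
        r, _ = pattern_model_correlation(p, model, IDENTITY, pg1)
        assert r == pytest.approx(0.5 / math.sqrt(5.0 / 12.0), abs=0.01)

    def test_unobserved_entries_invisible(self, pg1):
        hkl = np.array([[i, 0, 0] for i in range(1, 11)])
        means = np.arange(1.0, 11.0)
        model_a = MergedModel.from_means(hkl, means)
        extra = np.vstack([hkl, [[0, 5, 5], [0, 6, 6]]])
        model_b = MergedModel.from_means(
            extra, np.concatenate([means, [1e6, 1e7]]),
            n_obs=np.concatenate([np.ones(10, dtype=int), [0, 0]]))
        p = Pattern("p", hkl, means ** 2)
        ra, _ = pattern_model_correlation(p, model_a, IDENTITY, pg1)
        rb, _ = pattern_model_correlation(p, model_b, IDENTITY, pg1)
        assert ra == pytest.approx(rb, abs=1e-12)

    def test_low_resolution_exclusion(self, pg1, small_cell):
        """Reflections beyond the low-resolution cutoff drop out."""
        hkl = np.array([[0, 0, 1]] + [[i, 0, 0] for i in range(3, 13)])
        means = np.exp(np.arange(len(hkl), dtype=float))
        model = MergedModel.from_means(hkl, means)
        p = Pattern("p", hkl, means * 0.5)
        # d of (0,0,1) is 40 A > 20 A cutoff; the rest are below
        _, n_with = pattern_model_correlation(p, model, IDENTITY, pg1,
                                              cell=small_cell)
        _, n_without = pattern_model_correlation(p, model, IDENTITY, pg1)
        assert n_without - n_with == 1


class TestAssignModes:
    def test_single_mode_all_zero(self, group1, pg1):
        rng = np.random.default_rng(6)
        hkl = np.unique(rng.integers(1, 10, size=(40, 3)), axis=0)
        ds = Dataset([Pattern(f"p{i}", hkl, rng.exponential(size=len(hkl)))
                      for i in range(4)])
        model = MergedModel.from_means(hkl, rng.exponential(size=len(hkl)))
        _, assigns = assign_modes(ds, model, group1, pg1)
        assert all(a.mode == 0 for a in assigns)

    def test_exact_match_under_twin(self, group2, pg6):
        rng = np.random.default_rng(7)
        hkl = np.unique(asu_map(rng.integers(1, 15, size=(60, 3)), pg6),
                        axis=0)
        means = rng.exponential(size=len(hkl))
        model = MergedModel.from_means(hkl, means)
        # pattern recorded in the twin setting of the model
        twin_hkl = asu_map(apply_operator(P63_TWIN, hkl), pg6)
        ds = Dataset([Pattern("p", twin_hkl, means)])
        corrs, assigns = assign_modes(ds, model, group2, pg6)
        assert assigns[0].mode == 1
        assert assigns[0].best_r == pytest.approx(1.0)


class TestMerge:
    def test_two_observations_average(self, group1, pg1):
        mk = lambda pid, inten: Pattern(
            pid, [[1, 0, 0], [2, 0, 0], [3, 0, 0], [4, 0, 0], [5, 0, 0]],
            [inten, 1, 1, 1, 1])
        ds = Dataset([mk("a", 2.0), mk("b", 4.0)])
        assigns = [Assignment("a", 0, 1.0), Assignment("b", 0, 1.0)]
        model = merge(ds, assigns, group1, pg1)
        entry = model.entries()[(1, 0, 0)]
        assert entry == (6.0, 2, 3.0)

    def test_intensity_conservation(self, group2, pg6, sim_uniform):
        _, ds, truth = sim_uniform
        sub = ds.subset(range(50))
        assigns = [Assignment(p.id, i % 2, 0.0)
                   for i, p in enumerate(sub)]
        model = merge(sub, assigns, group2, pg6)
        total_in = sum(p.intensity.sum() for p in sub)
        assert model.sum_intensity.sum() == pytest.approx(total_in,
                                                          rel=1e-12)

    def test_gauge_invariance(self, group2, pg6, sim_uniform):
        """Twin-reindexing the dataset and flipping assignments leaves
        the merged model untouched."""
        _, ds, _ = sim_uniform
        sub = ds.subset(range(40))
        assigns = [Assignment(p.id, i % 2, 0.0)
                   for i, p in enumerate(sub)]
        model = merge(sub, assigns, group2, pg6)

        flipped_ds = Dataset([
            Pattern(p.id, asu_map(apply_operator(P63_TWIN, p.hkl), pg6),
                    p.intensity) for p in sub])
        flipped_assigns = [Assignment(a.pattern_id, 1 - a.mode, a.best_r)
                           for a in assigns]
        model2 = merge(flipped_ds, flipped_assigns, group2, pg6)
        a = model.entries()
        b = model2.entries()
        assert set(a) == set(b)
        for key in a:
            assert a[key][1] == b[key][1]  # n_obs
            if a[key][1] > 0:
                assert a[key][2] == pytest.approx(b[key][2], rel=1e-12)


class TestRandomModel:
    def test_deterministic(self):
        hkl = np.array([[i, j, 1] for i in range(1, 11)
                        for j in range(1, 11)])
        a = random_model(hkl, seed=9)
        b = random_model(hkl, seed=9)
        np.testing.assert_array_equal(a.mean_intensity, b.mean_intensity)

    def test_independent_across_seeds(self):
        side = 22
        hkl = np.array([[i, j, k] for i in range(1, side)
                        for j in range(1, side) for k in range(1, side)])
        a = random_model(hkl, seed=1)
        b = random_model(hkl, seed=2)
        r = pearson(a.mean_intensity, b.mean_intensity)
        assert abs(r) < 0.05

    def test_values_positive_and_visible(self):
        m = random_model([[1, 0, 0], [0, 1, 0]], seed=0)
        assert np.all(m.mean_intensity > 0)
        assert np.all(m.mean_intensity < 1)
        assert np.all(m.n_obs == 1)


class TestTargetScore:
    def test_direct_formula(self):
        cs = [ModeCorrelations("a", np.array([0.9, 0.3]), np.array([9, 9])),
              ModeCorrelations("b", np.array([0.2, 0.8]), np.array([9, 9]))]
        assert target_score(cs) == pytest.approx(0.85)

    def test_undefined_patterns_excluded(self):
        nan = float("nan")
        cs = [ModeCorrelations("a", np.array([0.6, nan]), np.array([9, 0])),
              ModeCorrelations("b", np.array([nan, nan]), np.array([0, 0]))]
        assert target_score(cs) == pytest.approx(0.6)

    def test_all_undefined_errors(self):
        nan = float("nan")
        cs = [ModeCorrelations("a", np.array([nan, nan]), np.array([0, 0]))]
        with pytest.raises(ValueError):
            target_score(cs)

    def test_reimplementation_oracle(self, sim_uniform, group2, pg6):
        cfg, ds, _ = sim_uniform
        sub = ds.subset(range(60))
        model = random_model(
            np.unique(np.concatenate([p.hkl for p in sub]), axis=0), seed=3)
        corrs, _ = assign_modes(sub, model, group2, pg6, cell=cfg.cell)
        best = [np.nanmax(c.r_per_mode) for c in corrs
                if np.isfinite(c.r_per_mode).any()]
        assert target_score(corrs) == pytest.approx(np.mean(best), abs=1e-12)


class TestRunEM:
    def test_noiseless_copies_converge_fast(self, group2, pg6):
        """Copies of one reference under random modes: perfect internal
        consistency within three iterations."""
        rng = np.random.default_rng(10)
        hkl = np.unique(asu_map(rng.integers(1, 15, size=(200, 3)), pg6),
                        axis=0)
        means = rng.exponential(size=len(hkl))
        twin_hkl = asu_map(apply_operator(P63_TWIN, hkl), pg6)
        pats = []
        true_modes = rng.integers(0, 2, size=30)
        for i, m in enumerate(true_modes):
            pats.append(Pattern(f"p{i}", hkl if m == 0 else twin_hkl, means))
        state = run_em(Dataset(pats), group2, pg6, EMConfig(seed=4))
        assert state.converged and state.iteration <= 3
        a = state.assignment_vector
        consist = max((a == true_modes).mean(), (a != true_modes).mean())
        assert consist == 1.0

    def test_single_mode_converges_immediately(self, group1, pg1):
        rng = np.random.default_rng(11)
        hkl = np.unique(rng.integers(1, 10, size=(60, 3)), axis=0)
        ds = Dataset([Pattern(f"p{i}", hkl, rng.exponential(size=len(hkl)))
                      for i in range(5)])
        state = run_em(ds, group1, pg1, EMConfig(seed=0))
        assert state.converged
        assert state.iteration == 1
        assert state.n_changed == 0

    def test_first_iteration_split_roughly_even(self, sim_uniform, group2,
                                                pg6):
        cfg, ds, _ = sim_uniform
        state = run_em(ds, group2, pg6, EMConfig(seed=21, max_iterations=1,
                                                 convergence_fraction=0.0),
                       cell=cfg.cell)
        pops = state.history[0].mode_populations
        assert abs(pops[0] - pops[1]) < 0.25 * ds.n_patterns

    def test_uniform_simulation_recovers_truth(self, sim_uniform, group2,
                                               pg6):
        cfg, ds, truth = sim_uniform
        state = run_em(ds, group2, pg6, EMConfig(seed=2), cell=cfg.cell)
        assert state.converged
        rep = label_and_score(state, truth.true_model, group2, pg6, ds,
                              truth=truth, cell=cfg.cell)
        assert rep.fraction_truth > 0.99

    def test_score_history_recorded(self, sim_uniform, group2, pg6):
        cfg, ds, _ = sim_uniform
        state = run_em(ds, group2, pg6, EMConfig(seed=2), cell=cfg.cell)
        assert len(state.score_history) == state.iteration
        assert state.history[-1].n_changed <= 0.001 * ds.n_patterns


class TestBruteForceObjective:
    def test_em_matches_exhaustive_maximization(self, group2, pg6):
        """On a 5-pattern toy set, the EM fixed point attains the global
        maximum of the summed best-correlation objective over all 2^5
        mode vectors (up to a global gauge flip)."""
        from emdetwin.symmetry import twin_invariant_mask
        rng = np.random.default_rng(12)
        hkl = np.unique(asu_map(rng.integers(1, 7, size=(80, 3)), pg6),
                        axis=0)
        hkl = hkl[~twin_invariant_mask(hkl, P63_TWIN, pg6)][:10]
        means = rng.exponential(size=len(hkl))
        twin_hkl = asu_map(apply_operator(P63_TWIN, hkl), pg6)
        true_modes = np.array([0, 1, 0, 1, 1])
        pats = []
        for i, m in enumerate(true_modes):
            part = rng.uniform(0.8, 1.0, size=len(hkl))
            pats.append(Pattern(f"p{i}", hkl if m == 0 else twin_hkl,
                                part * means))
        ds = Dataset(pats)

        def objective(modes):
            assigns = [Assignment(p.id, int(m), 0.0)
                       for p, m in zip(ds, modes)]
            model = merge(ds, assigns, group2, pg6)
            total = 0.0
            for p, m in zip(ds, modes):
                r, _ = pattern_model_correlation(
                    p, model, group2.operators[int(m)], pg6, min_common=3)
                total += r
            return total

        best_modes, best_val = None, -np.inf
        for modes in itertools.product((0, 1), repeat=5):
            val = objective(np.array(modes))
            if val > best_val:
                best_modes, best_val = np.array(modes), val

        # EM ascends the objective from a random start; take the best of
        # a few starts (multi-start), as one would on real data
        states = [run_em(ds, group2, pg6, EMConfig(seed=s, min_common=3))
                  for s in range(5)]
        state = max(states, key=lambda s: s.score_history[-1])
        em_modes = state.assignment_vector
        same = (em_modes == best_modes).all()
        flipped = (em_modes == 1 - best_modes).all()
        assert same or flipped


class TestMonteCarloErrorDecay:
    def test_inverse_sqrt_n(self, group2, pg6):
        """RMS relative error of merged means vs 0.5 x truth shrinks as
        N^(-1/2) when merging with the true modes (no shot noise)."""
        errors = {}
        for n in (250, 1000, 4000):
            cfg = SimulationConfig(n_patterns=n, seed=77, noise="none",
                                   reflections_per_pattern=60)
            ds, truth = simulate_dataset(cfg)
            assigns = [Assignment(p.id, truth.true_modes[p.id], 0.0)
                       for p in ds]
            model = merge(ds, assigns, group2, pg6)
            # align rows of model and truth
            t = truth.true_model.entries()
            rel = []
            means = model.mean_intensity
            for i, key in enumerate(map(tuple, model.hkl)):
                if model.n_obs[i] >= 5:
                    rel.append(means[i] / (0.5 * t[key][2]) - 1.0)
            errors[n] = float(np.sqrt(np.mean(np.square(rel))))
        # each 4x increase in N should halve the error (allow 35% slack)
        for a, b in ((250, 1000), (1000, 4000)):
            ratio = errors[a] / errors[b]
            assert 1.3 < ratio < 3.1, errors
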