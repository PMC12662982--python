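"""Shift-based population fitting and Akaike ensemble selection."""

import itertools
import math

import numpy as np
import pytest
from scipy.optimize import minimize

import anisofit as af
from anisofit.case3d import (
    aic_score,
    case3d_select,
    enumerate_models,
    fit_populations,
    scale_computed_shifts,
    simplex_lstsq,
)
from anisofit.errors import ProtocolError, ValidationError


def _shift_set(rng, n_c=8, n_h=12, conformers=("c1", "c2", "c3")):
    """Random per-conformer computed shifts with exp = plain c1 values."""
    shifts = []
    for i in range(n_c):
        computed = {c: rng.uniform(10, 180) for c in conformers}
        shifts.append(af.ShiftDatum(f"C{i + 1}", "C13", computed[conformers[0]],
                                    computed))
    for i in range(n_h):
        computed = {c: rng.uniform(0.5, 8.0) for c in conformers}
        shifts.append(af.ShiftDatum(f"H{i + 1}", "H1", computed[conformers[0]],
                                    computed))
    return shifts


def _mixture_shifts(rng, weights, conformers, n_c=8, n_h=12,
                    sigma_c=0.0, sigma_h=0.0):
    """Shifts whose experimental values are an exact (or noisy) mixture."""
    shifts = []
    for i in range(n_c + n_h):
        is_c = i < n_c
        computed = {
            c: rng.uniform(10, 180) if is_c else rng.uniform(0.5, 8.0)
            for c in conformers
        }
        exp = sum(w * computed[c] for c, w in weights.items())
        exp += rng.normal(0, sigma_c if is_c else sigma_h) if (sigma_c or sigma_h) else 0.0
        label = f"C{i + 1}" if is_c else f"H{i + 1}"
        shifts.append(af.ShiftDatum(label, "C13" if is_c else "H1", exp, computed))
    return shifts


class TestSimplexLstsq:
    def test_matches_slsqp_oracle(self, rng):
        for _ in range(20):
            n, k = 15, 4
            a = rng.normal(size=(n, k))
            y = rng.normal(size=n)
            p, obj = simplex_lstsq(a, y)
            assert p.min() >= 0 and p.sum() == pytest.approx(1.0, abs=1e-12)

            def f(q):
                r = a @ q - y
                return r @ r
            res = minimize(
                f, np.full(k, 1 / k), method="SLSQP",
                bounds=[(0, None)] * k,
                constraints={"type": "eq", "fun": lambda q: q.sum() - 1},
                options={"ftol": 1e-14, "maxiter": 500},
            )
            assert obj <= res.fun + 1e-8

    def test_exact_vertex_solution(self, rng):
        a = rng.normal(size=(10, 3))
        y = a[:, 1].copy()  # exactly reproducible by p = e_2
        p, obj = simplex_lstsq(a, y)
        assert p[1] == pytest.approx(1.0, abs=1e-9)
        assert obj < 1e-18

    def test_guard_on_width(self, rng):
        with pytest.raises(ValidationError):
            simplex_lstsq(rng.normal(size=(5, 17)), rng.normal(size=5))


class TestScaleComputedShifts:
    def test_identity_when_exact(self, rng):
        shifts = _shift_set(rng)
        avg = [s.computed["c1"] for s in shifts]
        scaled, params = scale_computed_shifts(shifts, avg)
        for cls in ("C13", "H1"):
            assert params[cls][0] == pytest.approx(1.0, abs=1e-12)
            assert params[cls][1] == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(scaled, avg)

    def test_exact_affine_inverted(self, rng):
        shifts = _shift_set(rng)
        # computed = 2*experimental + 5  ->  recovered slope 0.5
        avg = [2.0 * s.value_exp + 5.0 for s in shifts]
        scaled, params = scale_computed_shifts(shifts, avg)
        for cls in ("C13", "H1"):
            assert params[cls][0] == pytest.approx(0.5, abs=1e-10)
        exp = np.array([s.value_exp for s in shifts])
        assert np.allclose(scaled, exp, atol=1e-10)

    def test_noisy_affine_recovery_within_3_sigma(self, rng):
        slope_true, icept_true = 1.04, -2.1
        shifts = []
        calc = rng.uniform(10, 180, size=30)
        exp = slope_true * calc + icept_true + rng.normal(0, 0.1, size=30)
        for i, (c, e) in enumerate(zip(calc, exp)):
            shifts.append(af.ShiftDatum(f"C{i + 1}", "C13", float(e), {"c1": float(c)}))
        _, params = scale_computed_shifts(shifts, calc)
        slope, icept = params["C13"]
        # rough standard error of the slope at n=30, sigma=0.1, spread~50 ppm
        assert slope == pytest.approx(slope_true, abs=3 * 0.1 / (50 * math.sqrt(30)) * 30)
        assert icept == pytest.approx(icept_true, abs=1.0)

    def test_small_class_disabled_with_warning(self, rng):
        shifts = _shift_set(rng, n_c=8, n_h=2)
        avg = [s.computed["c1"] for s in shifts]
        with pytest.warns(UserWarning, match="fewer than 3"):
            _, params = scale_computed_shifts(shifts, avg)
        assert params["H1"] == (1.0, 0.0)


class TestFitPopulations:
    def test_singleton_subset(self, rng):
        shifts = _shift_set(rng)
        pops, rss, _ = fit_populations(["c2"], shifts)
        assert pops == {"c2": 1.0}
        assert rss >= 0

    def test_exact_mixture_recovered(self, rng):
        shifts = _mixture_shifts(rng, {"c1": 0.5, "c2": 0.5}, ("c1", "c2"))
        pops, rss, _ = fit_populations(["c1", "c2"], shifts)
        assert pops["c1"] == pytest.approx(0.5, abs=1e-9)
        assert pops["c2"] == pytest.approx(0.5, abs=1e-9)
        assert rss < 1e-12

    def test_noisy_mixture_recovery_rate(self):
        """0.7/0.3 truth recovered within ±0.1 in >=90% of seeded trials."""
        hits = 0
        trials = 100
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            shifts = _mixture_shifts(
                rng, {"c1": 0.7, "c2": 0.3}, ("c1", "c2"),
                sigma_c=0.2, sigma_h=0.02)
            pops, _, _ = fit_populations(["c1", "c2"], shifts)
            if abs(pops["c1"] - 0.7) <= 0.1 and abs(pops["c2"] - 0.3) <= 0.1:
                hits += 1
        assert hits >= 90

    def test_nucleus_filtering(self, rng):
        shifts = _shift_set(rng)
        pops_c, _, params_c = fit_populations(["c1", "c2"], shifts, nucleus="c13")
        assert set(params_c) == {"C13"}
        assert sum(pops_c.values()) == pytest.approx(1.0)


class TestAicScore:
    def test_halving_rss_lowers_by_n_ln2(self):
        n, k = 30, 4
        delta = aic_score(10.0, n, k, corrected=False) \
            - aic_score(5.0, n, k, corrected=False)
        assert delta == pytest.approx(n * math.log(2.0), rel=1e-12)

    def test_extra_parameter_threshold(self):
        # one more parameter wins only if n ln(rss ratio) beats the penalty
        n = 30
        a1 = aic_score(10.0, n, 4)
        penalty = (2 + 2 * 5 * 6 / (n - 5 - 1) - 2 * 4 * 5 / (n - 4 - 1))
        rss_break = 10.0 * math.exp(-penalty / n)
        a2 = aic_score(rss_break, n, 5)
        assert a2 == pytest.approx(a1, abs=1e-9)
        assert aic_score(rss_break * 0.99, n, 5) < a1
        assert aic_score(rss_break * 1.01, n, 5) > a1

    def test_perfect_fit_sentinel(self):
        with pytest.warns(UserWarning, match="perfect fit"):
            assert aic_score(0.0, 30, 4) == -math.inf

    def test_insufficient_n_raises(self):
        with pytest.raises(ValidationError):
            aic_score(1.0, 5, 4)


class TestEnumerateModels:
    def test_counts_all_subsets(self, rng):
        shifts = _shift_set(rng)
        models = enumerate_models(["c1", "c2", "c3"], shifts, 3)
        assert len(models) == 7  # 2^3 - 1
        assert [m.rank for m in models] == list(range(1, 8))
        aics = [m.aic for m in models]
        assert aics == sorted(aics)

    def test_nesting_best_rss_nonincreasing(self, rng):
        shifts = _shift_set(rng)
        models = enumerate_models(["c1", "c2", "c3"], shifts, 3)
        best_by_size = {}
        for m in models:
            s = len(m.subset)
            best_by_size[s] = min(best_by_size.get(s, math.inf), m.rss)
        # slack: the joint scale+population coordinate descent converges
        # tightly but not to machine precision near simplex vertices
        assert best_by_size[1] >= best_by_size[2] - 1e-8
        assert best_by_size[2] >= best_by_size[3] - 1e-8

    def test_guard_on_combinatorics(self, rng):
        ids = [f"c{i}" for i in range(40)]
        shifts = _shift_set(rng, conformers=tuple(ids))
        with pytest.raises(ValidationError, match="guard"):
            enumerate_models(ids, shifts, 10)

    def test_exhaustive_brute_force_oracle(self):
        """Ranked list equals an independent brute-force re-implementation.

        The oracle enumerates active sets and solves each sum-to-one
        equality-constrained least squares by variable substitution
        (eliminating one population), a different algebraic route than the
        package's KKT solver.
        """
        rng = np.random.default_rng(42)
        conformers = ("c1", "c2", "c3", "c4", "c5")
        shifts = _mixture_shifts(
            rng, {"c2": 0.6, "c4": 0.4}, conformers, sigma_c=0.3, sigma_h=0.03)
        models = enumerate_models(conformers, shifts, 3, scale=False)

        y = np.array([s.value_exp for s in shifts])
        w = np.array([5.0 if s.nucleus == "H1" else 1.0 for s in shifts])

        def brute(subset):
            a = np.array([[s.computed[c] for c in subset] for s in shifts])
            kk = len(subset)
            best = math.inf
            for support in itertools.chain.from_iterable(
                    itertools.combinations(range(kk), s) for s in range(1, kk + 1)):
                asub = a[:, list(support)] * w[:, None]
                yw = y * w
                # substitute q_last = 1 - sum(others): unconstrained lstsq
                if len(support) == 1:
                    q = np.array([1.0])
                else:
                    a_red = asub[:, :-1] - asub[:, -1:]
                    rhs = yw - asub[:, -1]
                    q_red, *_ = np.linalg.lstsq(a_red, rhs, rcond=None)
                    q = np.append(q_red, 1.0 - q_red.sum())
                if np.any(q < -1e-10):
                    continue
                r = asub @ q - yw
                best = min(best, float(r @ r))
            n, k = len(shifts), len(subset) - 1
            return n * math.log(best / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)

        oracle = {}
        for size in (1, 2, 3):
            for subset in itertools.combinations(conformers, size):
                oracle[subset] = brute(subset)
        for m in models:
            assert m.aic == pytest.approx(oracle[m.subset], abs=1e-8)
        oracle_order = sorted(oracle, key=lambda s: (oracle[s], len(s), s))
        assert [m.subset for m in models] == oracle_order

    def test_matches_slsqp_end_to_end(self):
        """Sanity: a general-purpose NLP solver agrees to its tolerance."""
        rng = np.random.default_rng(7)
        conformers = ("c1", "c2", "c3", "c4")
        shifts = _mixture_shifts(
            rng, {"c1": 0.5, "c3": 0.5}, conformers, sigma_c=0.3, sigma_h=0.03)
        models = enumerate_models(conformers, shifts, 2, scale=False)
        y = np.array([s.value_exp for s in shifts])
        w = np.array([5.0 if s.nucleus == "H1" else 1.0 for s in shifts])
        for m in models:
            a = np.array([[s.computed[c] for c in m.subset] for s in shifts])

            def f(q):
                r = (a @ q - y) * w
                return r @ r
            res = minimize(
                f, np.full(len(m.subset), 1 / len(m.subset)), method="SLSQP",
                bounds=[(0, None)] * len(m.subset),
                constraints={"type": "eq", "fun": lambda q: q.sum() - 1},
                options={"ftol": 1e-14, "maxiter": 500})
            assert m.rss == pytest.approx(res.fun, rel=1e-4, abs=1e-6) \
                or m.rss < res.fun

    def test_selection_consistency_noise_free(self, rng):
        """Noise-free mixtures: the AIC-best subset is the generating one."""
        conformers = tuple(f"c{i}" for i in range(1, 6))
        shifts = _mixture_shifts(rng, {"c2": 0.65, "c5": 0.35}, conformers)
        models = enumerate_models(conformers, shifts, 3)
        assert set(models[0].subset) == {"c2", "c5"}
        assert models[0].populations["c2"] == pytest.approx(0.65, abs=1e-6)


class TestCase3DSelect:
    def _configs(self, rng, perturb_seed=None):
        ens = af.make_toy_ensemble(3, seed=2)
        conformers = ens.conformer_ids
        shifts = _mixture_shifts(
            rng, {"c1": 0.7, "c3": 0.3}, conformers,
            sigma_c=0.2, sigma_h=0.02)
        decoy_shifts = (af.synthetic.perturb_computed_shifts(shifts, perturb_seed)
                        if perturb_seed is not None else shifts)
        return ens, shifts, decoy_shifts

    def test_identical_configurations_tie(self, rng):
        ens, shifts, _ = self._configs(rng)
        rep = case3d_select({"a": (ens, shifts), "b": (ens, shifts)})
        assert rep.s1["a"].aic == pytest.approx(rep.s1["b"].aic, abs=1e-12)

    def test_truth_beats_perturbed_decoy(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            ens, shifts, decoy_shifts = self._configs(rng, perturb_seed=seed)
            rep = case3d_select({"truth": (ens, shifts),
                                 "decoy": (ens, decoy_shifts)})
            wins += rep.best == "truth"
        assert wins >= 19

    def test_exported_populations_consistent(self, rng):
        ens, shifts, _ = self._configs(rng)
        rep = case3d_select({"a": (ens, shifts), "b": (ens, shifts)})
        for label, (sub, pops) in rep.selected.items():
            assert sum(pops.weights.values()) == pytest.approx(1.0, abs=1e-12)
            assert pops.source == "FITTED"
            assert set(sub.conformer_ids) == set(rep.s1[label].subset)
            refit, _, _ = fit_populations(rep.s1[label].subset, shifts)
            for cid, w in refit.items():
                assert pops[cid] == pytest.approx(w, abs=1e-12)

    def test_differing_experimental_shifts_rejected(self, rng):
        ens, shifts, _ = self._configs(rng)
        other = [af.ShiftDatum(s.atom_label, s.nucleus, s.value_exp + 0.1,
                               s.computed) for s in shifts]
        with pytest.raises(ProtocolError):
            case3d_select({"a": (ens, shifts), "b": (ens, other)})
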