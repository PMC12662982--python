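"""Single-tensor ensemble fitting, Q factors and configuration ranking."""

import warnings

import numpy as np
import pytest

import anisofit as af
from anisofit.errors import UnderDeterminedError, ValidationError
from anisofit.fit import (
    build_design_matrix,
    discriminate,
    fit_alignment_tensor,
    fit_data,
    q_factor,
    reference_rcsas,
)
from anisofit.records import EXTERNAL
from anisofit.tensor import AlignmentTensor, DipolarPair, back_calc_rdc


class TestQFactor:
    def test_perfect_agreement(self):
        assert q_factor([1.0, -2.0, 3.0], [1.0, -2.0, 3.0]) == 0.0

    def test_zero_calc_gives_one(self):
        assert q_factor([1.0, -2.0, 3.0], [0.0, 0.0, 0.0]) == pytest.approx(1.0)

    def test_analytic_example(self):
        assert q_factor([1.0, 1.0], [1.0, 0.0]) == pytest.approx(0.70711, abs=1e-5)

    def test_all_zero_exp_undefined(self):
        with pytest.raises(ValidationError):
            q_factor([0.0, 0.0], [1.0, 2.0])


class TestDesignMatrix:
    def test_single_conformer_equals_rigid(self, toy_ensemble, clean_data):
        single = toy_ensemble.subset(["c1"])
        pops = af.PopulationSet.uniform(["c1"])
        design = build_design_matrix(single, pops, clean_data.rdcs[:6])
        for i, datum in enumerate(clean_data.rdcs[:6]):
            pair = DipolarPair.from_conformer(
                single.conformers[0], datum.label_a, datum.label_b)
            for k in range(5):
                e = np.zeros(5)
                e[k] = 1.0
                coeff = back_calc_rdc(
                    single.conformers[0], pair, AlignmentTensor.from_vector(e))
                assert design.raw_matrix[i, k] == pytest.approx(coeff, rel=1e-12)

    def test_duplicate_conformers_idempotent(self, toy_ensemble, clean_data):
        single = toy_ensemble.subset(["c1"])
        doubled = af.ConformationalEnsemble(
            "dup",
            (
                single.conformers[0],
                af.Conformer("c1b", single.atom_labels,
                             single.conformers[0].elements,
                             single.conformers[0].coords),
            ),
        )
        d1 = build_design_matrix(
            single, af.PopulationSet.uniform(["c1"]), clean_data.rdcs)
        d2 = build_design_matrix(
            doubled, af.PopulationSet.uniform(["c1", "c1b"]), clean_data.rdcs)
        assert np.allclose(d1.matrix, d2.matrix, atol=1e-14)

    def test_finite_difference_oracle(self, toy_ensemble, uniform_pops, clean_data):
        """Rows equal central differences of the ensemble-averaged RDC."""
        data = clean_data.rdcs[:8]
        design = build_design_matrix(toy_ensemble, uniform_pops, data)
        eps = 1e-6

        def averaged_rdc(datum, svec):
            t = AlignmentTensor.from_vector(svec)
            total = 0.0
            for conf in toy_ensemble.conformers:
                pair = DipolarPair.from_conformer(conf, datum.label_a, datum.label_b)
                total += uniform_pops[conf.conformer_id] * back_calc_rdc(conf, pair, t)
            return total

        for i, datum in enumerate(data):
            for k in range(5):
                e = np.zeros(5)
                e[k] = eps
                fd = (averaged_rdc(datum, e) - averaged_rdc(datum, -e)) / (2 * eps)
                assert design.raw_matrix[i, k] == pytest.approx(fd, rel=1e-6, abs=1e-9)

    def test_rcsa_reference_row_subtraction(self, toy_ensemble, uniform_pops,
                                            clean_data):
        smap = af.shielding_map(clean_data.shieldings)
        base = clean_data.rcsas
        ref_label = base[0].atom_label
        referenced = reference_rcsas(base, ref_label)
        d_ext = build_design_matrix(toy_ensemble, uniform_pops, base, smap)
        d_ref = build_design_matrix(toy_ensemble, uniform_pops, referenced, smap)
        # referenced rows = own coefficients minus the reference atom's
        idx = {d.atom_label: i for i, d in enumerate(base)}
        for i, datum in enumerate(referenced):
            expected = (d_ext.raw_matrix[idx[datum.atom_label]]
                        - d_ext.raw_matrix[idx[ref_label]])
            assert np.allclose(d_ref.raw_matrix[i], expected, atol=1e-12)


class TestFitAlignmentTensor:
    def test_noise_free_identity(self, toy_ensemble, uniform_pops,
                                 clean_data, true_tensor):
        smap = af.shielding_map(clean_data.shieldings)
        res = fit_data(toy_ensemble, uniform_pops,
                       list(clean_data.rdcs) + list(clean_data.rcsas), smap)
        assert np.max(np.abs(res.tensor.saupe - true_tensor.saupe)) < 1e-8
        assert res.q_combined < 1e-6
        assert res.rank == 5 and not res.rank_deficient

    def test_exactly_determined_matches_dense_solve(self, rng):
        a = rng.normal(size=(5, 5))
        y = rng.normal(size=5)
        res = fit_alignment_tensor(a, y)
        direct = np.linalg.solve(a, y)  # dense solve oracle
        assert np.allclose(res.tensor.to_vector(), direct, atol=1e-9)

    def test_underdetermined_raises(self, rng):
        with pytest.raises(UnderDeterminedError):
            fit_alignment_tensor(rng.normal(size=(4, 5)), rng.normal(size=4))

    def test_collinear_bonds_rank_deficient(self):
        # all bond vectors parallel -> one independent row direction
        conf = af.Conformer(
            "c1",
            tuple(f"C{i}" for i in range(1, 7)) + tuple(f"H{i}" for i in range(1, 7)),
            ("C",) * 6 + ("H",) * 6,
            np.vstack([
                np.column_stack([np.arange(6) * 3.0, np.zeros(6), np.zeros(6)]),
                np.column_stack([np.arange(6) * 3.0, np.zeros(6), np.full(6, 1.09)]),
            ]),
        )
        ens = af.ConformationalEnsemble("degenerate", (conf,))
        pops = af.PopulationSet.uniform(["c1"])
        data = [af.RDCDatum(f"C{i}", f"H{i}", 10.0, 0.5) for i in range(1, 7)]
        with pytest.warns(UserWarning, match="rank-deficient"):
            res = fit_data(ens, pops, data)
        assert res.rank_deficient

    def test_svd_beats_random_search(self, toy_ensemble, uniform_pops, rng):
        """No 5-vector near the SVD solution achieves a lower RSS."""
        truth = af.SyntheticTruth(
            af.make_true_tensor(5e-4, 0.2, 3),
            uniform_pops, af.NoiseModel(sigma_rdc_hz=1.0), seed=5)
        data = af.simulate_dataset(toy_ensemble, truth)
        design = build_design_matrix(toy_ensemble, uniform_pops, data.rdcs)
        res = fit_alignment_tensor(design)
        x = res.tensor.to_vector()
        rss = float(np.sum((design.matrix @ x - design.observations) ** 2))
        draws = x[None, :] + rng.normal(scale=np.abs(x).max() * 0.3,
                                        size=(10_000, 5))
        rss_draws = np.sum(
            (draws @ design.matrix.T - design.observations) ** 2, axis=1)
        assert rss <= rss_draws.min() + 1e-12
        # and equals the normal-equations solution
        xn = np.linalg.solve(design.matrix.T @ design.matrix,
                             design.matrix.T @ design.observations)
        rss_n = float(np.sum((design.matrix @ xn - design.observations) ** 2))
        assert rss == pytest.approx(rss_n, abs=1e-9)

    def test_scale_equivariance(self, toy_ensemble, uniform_pops, clean_data):
        c = 3.7
        data = clean_data.rdcs
        scaled = [af.RDCDatum(d.label_a, d.label_b, c * d.value, c * d.sigma)
                  for d in data]
        r1 = fit_data(toy_ensemble, uniform_pops, data)
        r2 = fit_data(toy_ensemble, uniform_pops, scaled)
        assert np.allclose(r2.calc, c * r1.calc, rtol=1e-9)
        assert r2.q_combined == pytest.approx(r1.q_combined, abs=1e-12)

    def test_monte_carlo_spread_reported(self, toy_ensemble, uniform_pops,
                                         clean_data):
        res = fit_data(toy_ensemble, uniform_pops, clean_data.rdcs,
                       mc_draws=50, seed=1)
        assert res.q_combined_se is not None and res.q_combined_se >= 0
        assert res.tensor_se.shape == (5,)


class TestNoiseMonotonicity:
    def test_q_and_tensor_error_decrease_with_noise(self, toy_ensemble,
                                                    uniform_pops):
        true = af.make_true_tensor(5e-4, 0.3, 4)
        qs, errs = [], []
        for rel in (0.20, 0.05, 0.0):
            noise = (af.NoiseModel(relative=rel) if rel > 0
                     else af.NoiseModel.noiseless())
            truth = af.SyntheticTruth(true, uniform_pops, noise, seed=9)
            data = af.simulate_dataset(toy_ensemble, truth)
            res = fit_data(toy_ensemble, uniform_pops, data.rdcs)
            qs.append(res.q_combined)
            errs.append(np.max(np.abs(res.tensor.saupe - true.saupe)))
        assert qs[0] > qs[1] > qs[2]
        assert errs[0] > errs[1] > errs[2]


class TestReferenceInvariance:
    def test_fit_quality_insensitive_to_reference_choice(
            self, toy_ensemble, uniform_pops):
        """For offset-free synthetic data any reference atom fits equally."""
        truth = af.SyntheticTruth(
            af.make_true_tensor(5e-4, 0.3, 6), uniform_pops,
            af.NoiseModel(sigma_rcsa_ppb=1.0), seed=21)
        data = af.simulate_dataset(toy_ensemble, truth)
        smap = af.shielding_map(data.shieldings)
        qs = []
        for ref in [EXTERNAL] + [d.atom_label for d in data.rcsas[:4]]:
            refd = reference_rcsas(data.rcsas, ref)
            qs.append(fit_data(toy_ensemble, uniform_pops, refd, smap).q_combined)
        assert max(qs) - min(qs) < 0.25  # within the noise-induced spread


class TestDiscriminate:
    def test_identical_ensembles_tie(self, toy_ensemble, uniform_pops, clean_data):
        smap = af.shielding_map(clean_data.shieldings)
        configs = {
            "alpha": (toy_ensemble, uniform_pops, smap),
            "beta": (toy_ensemble, uniform_pops, smap),
        }
        rep = discriminate(configs, clean_data.rdcs, clean_data.rcsas)
        q_a = rep.fits["alpha"]["combined"].q_combined
        q_b = rep.fits["beta"]["combined"].q_combined
        assert q_a == pytest.approx(q_b, abs=1e-12)
        assert set(rep.indistinguishable) == {"alpha", "beta"}

    def test_truth_beats_decoy_at_5_percent_noise(self, toy_ensemble,
                                                  uniform_pops):
        decoy = af.make_decoy_configuration(toy_ensemble, "C1")
        truth = af.SyntheticTruth(
            af.make_true_tensor(5e-4, 0.3, 2), uniform_pops,
            af.NoiseModel(relative=0.05), seed=17)
        data = af.simulate_dataset(toy_ensemble, truth)
        decoy_sh = af.make_shieldings(decoy, seed=9001)
        rep = discriminate(
            {
                "truth": (toy_ensemble, uniform_pops,
                          af.shielding_map(data.shieldings)),
                "decoy": (decoy, uniform_pops, af.shielding_map(decoy_sh)),
            },
            data.rdcs, data.rcsas,
        )
        assert rep.best == "truth"
        assert (rep.fits["truth"]["combined"].q_combined
                < rep.fits["decoy"]["combined"].q_combined)

    def test_incomplete_configuration_flagged_not_fatal(
            self, toy_ensemble, uniform_pops, clean_data):
        smap = af.shielding_map(clean_data.shieldings)
        empty_smap = {}
        rep = discriminate(
            {
                "good": (toy_ensemble, uniform_pops, smap),
                "bad": (toy_ensemble, uniform_pops, empty_smap),
            },
            clean_data.rdcs, clean_data.rcsas,
        )
        assert "bad" in rep.failed
        assert rep.verdict == ["good"]

    def test_balanced_weighting_mode_runs(self, toy_ensemble, uniform_pops,
                                          clean_data):
        smap = af.shielding_map(clean_data.shieldings)
        res = fit_data(toy_ensemble, uniform_pops,
                       list(clean_data.rdcs) + list(clean_data.rcsas),
                       smap, weighting="balanced")
        assert res.q_combined < 1e-6  # noise-free: weighting scheme irrelevant
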