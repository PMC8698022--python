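"""MST and Bartle correlations, consistency check, estimation pipeline."""

import math

import numpy as np
import pytest

from scsol.constants import BAR, R
from scsol.datasets import SolubilityDataset
from scsol.empirical import (
    BARTLE_RHO_REF,
    aard,
    bartle_fit,
    consistency_check,
    estimate_new_psub,
    mst_fit,
)
from scsol.errors import InputError


class TestAard:
    def test_perfect_fit(self):
        assert aard([1e-5, 2e-5], [1e-5, 2e-5]) == 0.0

    def test_uniform_doubling(self):
        y = np.array([1e-6, 5e-6, 2e-5])
        assert aard(y, 2 * y) == pytest.approx(100.0)

    def test_hand_arithmetic(self):
        assert aard([1e-5, 2e-5], [1.1e-5, 1.8e-5]) == pytest.approx(10.0)

    def test_validation(self):
        with pytest.raises(InputError):
            aard([1.0], [1.0, 2.0])
        with pytest.raises(InputError):
            aard([0.0, 1.0], [1.0, 1.0])


def _mst_exact_dataset(A, B, C):
    T = np.repeat([313.15, 323.15, 333.15], 5)
    rho = np.tile([300.0, 450.0, 600.0, 750.0, 900.0], 3)
    P = np.full_like(T, 2e7)
    y2 = np.exp((A + B * rho + C * T) / T) / P
    return SolubilityDataset.from_arrays(T, P, y2, rho)


class TestMstFit:
    def test_exact_recovery(self, mst_consistent_dataset):
        ds, (A, B, C) = mst_consistent_dataset
        fit = mst_fit(ds)
        assert fit.A == pytest.approx(A, rel=1e-9)
        assert fit.B == pytest.approx(B, rel=1e-9)
        assert fit.C == pytest.approx(C, rel=1e-9)
        assert fit.aard < 1e-8

    def test_normal_equations_oracle(self, peng_noiseless):
        ds, _ = peng_noiseless
        fit = mst_fit(ds)
        T = ds.frame["temperature_K"].to_numpy()
        P = ds.frame["pressure_Pa"].to_numpy()
        y2 = ds.frame["y2"].to_numpy()
        rho = ds.frame["density_kg_m3"].to_numpy()
        X = np.column_stack([np.ones_like(T), rho, T])
        y = T * np.log(y2 * P)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.A == pytest.approx(beta[0], rel=1e-10)
        assert fit.B == pytest.approx(beta[1], rel=1e-10)
        assert fit.C == pytest.approx(beta[2], rel=1e-10)

    def test_row_order_invariance(self, peng_noiseless):
        ds, _ = peng_noiseless
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(ds))
        shuffled = SolubilityDataset(ds.frame.iloc[perm].copy())
        a, b = mst_fit(ds), mst_fit(shuffled)
        assert (a.A, a.B, a.C) == pytest.approx((b.A, b.B, b.C), rel=1e-12)

    def test_requires_density(self):
        ds = SolubilityDataset.from_arrays(
            np.array([313.15, 323.15, 333.15]), np.full(3, 2e7),
            np.array([1e-5, 2e-5, 3e-5]))
        with pytest.raises(InputError):
            mst_fit(ds)

    def test_density_unit_affects_only_B(self, peng_noiseless):
        ds, _ = peng_noiseless
        kg = mst_fit(ds, density_unit="kg_m3")
        mol = mst_fit(ds, density_unit="mol_cm3")
        assert kg.C == pytest.approx(mol.C, rel=1e-9)
        assert kg.A == pytest.approx(mol.A, rel=1e-9)
        assert kg.B != pytest.approx(mol.B, rel=1e-3)


class TestBartleFit:
    def test_enthalpy_identity_values(self):
        assert -(-10_260.3) * R / 1e3 == pytest.approx(85.3, abs=0.1)
        assert -(-5_049.7) * R / 1e3 == pytest.approx(41.9, abs=0.15)

    def test_exact_recovery(self):
        a, b, c = 25.1, -10_260.3, 1.2e-2
        T = np.repeat([313.15, 323.15, 333.15], 5)
        rho = np.tile([300.0, 450.0, 600.0, 750.0, 900.0], 3)
        P = np.full_like(T, 2e7)
        y2 = np.exp(a + b / T + c * (rho - BARTLE_RHO_REF)) * BAR / P
        ds = SolubilityDataset.from_arrays(T, P, y2, rho)
        fit = bartle_fit(ds)
        assert fit.a == pytest.approx(a, rel=1e-9)
        assert fit.b == pytest.approx(b, rel=1e-9)
        assert fit.c == pytest.approx(c, rel=1e-9)
        assert fit.dHs == -fit.b * R  # definitional, machine exact

    def test_row_order_invariance(self, peng_noiseless):
        ds, _ = peng_noiseless
        perm = np.random.default_rng(2).permutation(len(ds))
        shuffled = SolubilityDataset(ds.frame.iloc[perm].copy())
        a, b = bartle_fit(ds), bartle_fit(shuffled)
        assert (a.a, a.b, a.c) == pytest.approx((b.a, b.b, b.c), rel=1e-9)


class TestConsistencyCheck:
    def test_perfect_line_no_flags(self, mst_consistent_dataset):
        ds, _ = mst_consistent_dataset
        rep = consistency_check(ds)
        assert rep.n_flagged == 0
        assert rep.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_infinite_threshold_never_flags(self, peng_with_outliers):
        ds, _ = peng_with_outliers
        rep = consistency_check(ds, z_threshold=math.inf)
        assert rep.n_flagged == 0

    def test_constructed_outliers_recovered(self, peng_with_outliers):
        """Exactly the two perturbed low-pressure points are flagged."""
        ds, _ = peng_with_outliers
        rep = consistency_check(ds)
        flagged = ds.frame[rep.flags]
        assert len(flagged) == 2
        assert set(zip(flagged["temperature_K"], flagged["pressure_Pa"] / BAR)) == {
            (323.15, 100.0), (333.15, 100.0)}


class TestEstimatePipeline:
    def test_consistent_data_exact_roundtrip(self):
        """Data whose ln(y2 P) is exactly Clausius-Clapeyron (density playing
        no role) return the generating (AS, BS) to numerical precision."""
        AS, BS = 26.2, 85_300.0
        T = np.repeat([313.15, 323.15, 333.15], 5)
        P = np.tile([1e7, 1.5e7, 2e7, 2.5e7, 3e7], 3)
        rho = np.tile([300.0, 450.0, 600.0, 750.0, 900.0], 3)
        y2 = np.exp(AS - BS / (R * T)) / P
        ds = SolubilityDataset.from_arrays(T, P, y2, rho)
        out = estimate_new_psub(ds)
        assert out.n_dropped == 0
        assert out.model.AS == pytest.approx(AS, rel=1e-7)
        assert out.model.BS == pytest.approx(BS, rel=1e-7)
        for t in (313.15, 333.15):
            assert out.model.pressure(t) == pytest.approx(
                math.exp(AS - BS / (R * t)), rel=1e-6)

    def test_idempotent_on_consistent_data_with_outliers(self):
        """Planted outliers are dropped once; a second pass on the cleaned
        subset reproduces the same model with nothing further flagged."""
        AS, BS = 26.2, 85_300.0
        T = np.repeat([313.15, 323.15, 333.15], 6)
        P = np.tile([1e7, 1.5e7, 2e7, 2.5e7, 3e7, 3.5e7], 3)
        rho = np.tile([300.0, 420.0, 540.0, 660.0, 780.0, 900.0], 3)
        y2 = np.exp(AS - BS / (R * T)) / P
        y2[6] *= 5.0
        y2[12] /= 5.0
        ds = SolubilityDataset.from_arrays(T, P, y2, rho)
        first = estimate_new_psub(ds)
        assert first.n_dropped == 2
        clean = SolubilityDataset(ds.frame[~first.consistency.flags].copy())
        second = estimate_new_psub(clean)
        assert second.n_dropped == 0
        assert second.model.AS == pytest.approx(first.model.AS, rel=1e-9)
        assert second.model.BS == pytest.approx(first.model.BS, rel=1e-9)

    def test_fixture_pipeline_runs_and_reports(self, peng_with_outliers):
        ds, _ = peng_with_outliers
        out = estimate_new_psub(ds)
        assert out.n_dropped == 2
        assert out.model.BS > 0
        assert out.mst.aard >= 0 and out.bartle.aard >= 0
        # estimated model is a valid increasing sublimation curve
        t = np.linspace(313.0, 334.0, 10)
        p = [out.model.pressure(ti) for ti in t]
        assert np.all(np.diff(p) > 0)

    def test_density_autofill_contract(self, peng_noiseless):
        """Dropping the density column and refilling from the EoS reproduces
        the stored densities and hence the same pipeline output."""
        ds, _ = peng_noiseless
        bare = SolubilityDataset(ds.frame.drop(columns=["density_kg_m3"]).copy())
        refilled = bare.with_densities()
        np.testing.assert_allclose(refilled.frame["density_kg_m3"],
                                   ds.frame["density_kg_m3"], rtol=1e-12)
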