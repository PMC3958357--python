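"""Tests of uSEM maximum-likelihood estimation and score-test machinery."""

import numpy as np
import pytest
from scipy import stats

from gimmesub.simulate import SimulationDesign, generate_individual, simulate_series
from gimmesub.usem import (USEMSpec, embed_lag, fit_indices, fit_usem,
                           modification_indices)


def chain_system(p=5, extra=None):
    A = np.zeros((p, p))
    for i in range(p - 1):
        A[i + 1, i] = 0.5
    if extra:
        for (i, j), w in extra.items():
            A[i, j] = w
    Phi = 0.6 * np.eye(p)
    return A, Phi


class TestEmbedLag:
    def test_complete_series_yields_t_minus_1_pairs(self):
        pairs, n = embed_lag(np.random.default_rng(0).normal(size=(200, 3)))
        assert n == 199 and pairs.shape == (199, 6)

    def test_missing_frame_drops_adjacent_pairs(self):
        ts = np.random.default_rng(0).normal(size=(200, 3))
        ts[5] = np.nan
        pairs, n = embed_lag(ts)
        assert n == 197  # pairs (4,5) and (5,6) gone

    def test_alternating_missing_frames_rejected(self):
        ts = np.random.default_rng(0).normal(size=(200, 3))
        ts[::2] = np.nan
        with pytest.raises(ValueError, match="usable lag-embedded pairs"):
            embed_lag(ts)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            embed_lag(np.zeros((1, 3)))


class TestFitUSEM:
    def test_parameter_recovery_at_t2000(self, rng):
        """Estimates from a correctly specified model are within 0.05 of truth."""
        d = SimulationDesign(n_timepoints=2000)
        ts, A, Phi, _ = generate_individual(d, 0, rng, include_unique=True)
        spec = USEMSpec(p=10, free_A=A != 0, free_Phi=Phi != 0)
        fit = fit_usem(ts, spec)
        assert np.abs(fit.A_hat - A).max() < 0.05
        assert np.abs(fit.Phi_hat - Phi).max() < 0.05

    def test_null_model_on_white_noise(self, rng):
        p = 5
        ts = rng.normal(size=(2000, p))
        fit = fit_usem(ts, USEMSpec.ar_only(p), compute_se=False)
        assert np.abs(np.diag(fit.Phi_hat)).max() < 0.06
        assert 0.6 < fit.chi2 / fit.df < 1.5

    def test_saturated_model_has_zero_discrepancy(self, rng):
        ts = rng.normal(size=(300, 4))
        fit = fit_usem(ts, USEMSpec.saturated(4), compute_se=False)
        assert fit.F == pytest.approx(0.0, abs=1e-6)
        assert fit.df == 0

    def test_ols_equivalence_on_recursive_spec(self, rng):
        """For lower-triangular A, per-equation least squares reproduces
        the ML estimates (recursive-system identity) within 1e-4."""
        A, Phi = chain_system()
        ts = simulate_series(A, Phi, 500, rng)
        spec = USEMSpec(p=5, free_A=A != 0, free_Phi=np.eye(5, dtype=bool))
        fit = fit_usem(ts, spec, compute_se=False)
        pairs, _ = embed_lag(ts)
        X, Y = pairs[:, :5], pairs[:, 5:]
        for i in range(5):
            cols = ([("A", j) for j in np.where(spec.free_A[i])[0]]
                    + [("Phi", j) for j in np.where(spec.free_Phi[i])[0]])
            D = np.column_stack([Y[:, j] if k == "A" else X[:, j]
                                 for k, j in cols])
            D = D - D.mean(0)
            b = np.linalg.lstsq(D, Y[:, i] - Y[:, i].mean(), rcond=None)[0]
            for (k, j), bv in zip(cols, b):
                est = fit.A_hat[i, j] if k == "A" else fit.Phi_hat[i, j]
                assert est == pytest.approx(bv, abs=1e-4)

    def test_chi2_monotone_in_nesting(self, rng):
        A, Phi = chain_system()
        ts = simulate_series(A, Phi, 400, rng)
        mask = A != 0
        chi2s = []
        spec_mask = np.zeros_like(mask)
        order = list(zip(*np.where(mask)))
        fit = fit_usem(ts, USEMSpec(5, spec_mask.copy(), np.eye(5, dtype=bool)),
                       compute_se=False)
        chi2s.append(fit.chi2)
        for i, j in order:
            spec_mask[i, j] = True
            fit = fit_usem(ts, USEMSpec(5, spec_mask.copy(), np.eye(5, dtype=bool)),
                           compute_se=False)
            chi2s.append(fit.chi2)
        assert all(b <= a + 1e-6 for a, b in zip(chi2s, chi2s[1:]))

    def test_df_formula(self):
        p = 4
        spec = USEMSpec.ar_only(p)
        ts = np.random.default_rng(1).normal(size=(200, p))
        fit = fit_usem(ts, spec, compute_se=False)
        assert fit.df == p * p + p * (p + 1) // 2 - (p + p)


class TestModificationIndices:
    def test_null_elements_rarely_exceed_critical(self):
        """MI of truly-zero elements stays below the chi2(1) 5% critical
        value in at least 90% of replicates."""
        A, Phi = chain_system(p=4)
        crit = stats.chi2.isf(0.05, 1)
        below = total = 0
        for seed in range(12):
            ts = simulate_series(A, Phi, 300, np.random.default_rng(seed))
            fit = fit_usem(ts, USEMSpec(4, A != 0, np.eye(4, dtype=bool)),
                           compute_se=False)
            for (kind, i, j), (mi, _) in modification_indices(fit).items():
                total += 1
                below += mi < crit
        assert below / total >= 0.90

    def test_omitted_path_detected(self, rng):
        """A true 0.5 path left out of the spec produces an MI above the
        Bonferroni-corrected critical value at T=200."""
        d = SimulationDesign()
        ts, A, Phi, _ = generate_individual(d, 0, rng, include_unique=True)
        mask = A != 0
        i0, j0 = d.unique_paths[0]
        mask[i0, j0] = False
        fit = fit_usem(ts, USEMSpec(10, mask, Phi != 0), compute_se=False)
        mis = modification_indices(fit)
        crit = stats.chi2.isf(0.05 / len(mis), 1)
        assert mis[("A", i0, j0)][0] > crit

    def test_mi_approximates_refit_chi2_drop(self, rng):
        """Score-test MI tracks the actual chi-square drop from refitting
        with the element freed (within 20% for a moderate effect)."""
        A, Phi = chain_system(p=5, extra={(3, 2): 0.15})
        ts = simulate_series(A, Phi, 400, rng)
        mask = A != 0
        mask[3, 2] = False
        spec = USEMSpec(5, mask, np.eye(5, dtype=bool))
        fit = fit_usem(ts, spec)
        mi = modification_indices(fit)[("A", 3, 2)][0]
        freed = mask.copy()
        freed[3, 2] = True
        drop = fit.chi2 - fit_usem(ts, USEMSpec(5, freed, np.eye(5, dtype=bool)),
                                   compute_se=False).chi2
        assert mi == pytest.approx(drop, rel=0.20)


class TestFitIndices:
    def test_saturated_model_flagged_undefined(self, rng):
        ts = rng.normal(size=(300, 4))
        fit = fit_usem(ts, USEMSpec.saturated(4), compute_se=False)
        null = fit_usem(ts, USEMSpec.ar_only(4), compute_se=False)
        with pytest.warns(UserWarning, match="df = 0"):
            idx = fit_indices(fit, null)
        assert not idx.defined
        assert idx.srmr == pytest.approx(0.0, abs=1e-3)

    def test_cfi_zero_when_fit_equals_null(self, rng):
        # data with real contemporaneous structure, so the AR-only null misfits
        A, Phi = chain_system(p=4)
        ts = simulate_series(A, Phi, 400, rng)
        null = fit_usem(ts, USEMSpec.ar_only(4), compute_se=False)
        idx = fit_indices(null, null)
        assert idx.cfi == pytest.approx(0.0, abs=1e-12)

    def test_well_specified_model_fits_excellently(self, rng):
        d = SimulationDesign(n_timepoints=2000)
        ts, A, Phi, _ = generate_individual(d, 0, rng, include_unique=False)
        fit = fit_usem(ts, USEMSpec(10, A != 0, Phi != 0), compute_se=False)
        null = fit_usem(ts, USEMSpec.ar_only(10), compute_se=False)
        idx = fit_indices(fit, null)
        assert idx.rmsea <= 0.05
        assert idx.cfi >= 0.95
        assert idx.excellent()
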