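"""Transition probabilities, the amplification curve, and block assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coculture.core_model import (
    OTHER,
    PREFERRED,
    LanguageModelParams,
    ParameterError,
    amplification_pi,
    biological_transition_probs,
    block_arrays,
    build_blocks,
    build_custom_model,
    build_language_model,
    cultural_transition_matrix,
    moran_transition_probs,
)


class TestAmplificationPi:
    @pytest.mark.parametrize(
        "x, alpha, beta, expected",
        [
            (0.0, 2.0, 0.7, 0.5),     # no specialists: states equivalent
            (0.0, 0.3, 0.0, 0.5),
            (1.0, 2.0, 1.0, 1.0),     # ceiling beta=1: always preferred
            (0.5, 1.0, 1.0, 0.75),    # alpha=beta=1 is the line (1+x)/2
            (1.0, 3.0, 0.0, 0.5),     # beta=0: composition never matters
        ],
    )
    def test_known_values(self, x, alpha, beta, expected):
        assert amplification_pi(x, alpha, beta) == pytest.approx(expected, abs=1e-15)

    @given(
        alpha=st.floats(0.01, 20.0),
        beta=st.floats(0.0, 1.0),
        xs=st.lists(st.floats(0.0, 1.0), min_size=2, max_size=10),
    )
    @settings(deadline=None, max_examples=200)
    def test_monotone_and_bounded(self, alpha, beta, xs):
        xs = np.sort(np.asarray(xs))
        pi = amplification_pi(xs, alpha, beta)
        assert np.all(pi >= 0.5 - 1e-12) and np.all(pi <= 1.0 + 1e-12)
        assert np.all(np.diff(pi) >= -1e-12)

    def test_endpoints_parametric(self):
        for alpha in (0.25, 1.0, 4.0):
            for beta in (0.0, 0.5, 1.0):
                assert amplification_pi(0.0, alpha, beta) == pytest.approx(0.5, abs=1e-15)
                assert amplification_pi(1.0, alpha, beta) == pytest.approx(
                    (1 + beta) / 2, abs=1e-15
                )

    def test_rejects_bad_domain(self):
        with pytest.raises(ParameterError):
            amplification_pi(0.5, -1.0, 0.5)
        with pytest.raises(ParameterError):
            amplification_pi(0.5, 1.0, 1.5)
        with pytest.raises(ParameterError):
            amplification_pi(1.5, 1.0, 0.5)


class TestBiologicalTransitions:
    def test_absorbing_boundaries(self):
        for i, N in [(0, 10), (10, 10)]:
            p_down, p_stay, p_up = biological_transition_probs(i, N, 0.2, PREFERRED)
            assert p_down == 0 and p_up == 0 and p_stay == 1

    def test_small_population_substitution(self):
        # N=2, i=1, phi=0.1, preferred: p_up = (1/2)(1.1/2.1), p_down = (1/2)(1/2.1)
        p_down, p_stay, p_up = biological_transition_probs(1, 2, 0.1, PREFERRED)
        assert p_up == pytest.approx(0.5 * 1.1 / 2.1, abs=1e-15)
        assert p_down == pytest.approx(0.5 * 1.0 / 2.1, abs=1e-15)
        assert p_down + p_stay + p_up == pytest.approx(1.0, abs=1e-15)

    def test_neutral_symmetry(self):
        p_down, _, p_up = biological_transition_probs(3, 10, 0.0, PREFERRED)
        assert p_up == pytest.approx(21 / 100, abs=1e-15)
        assert p_down == pytest.approx(21 / 100, abs=1e-15)

    def test_neutral_is_culture_independent(self):
        for i in range(11):
            assert biological_transition_probs(i, 10, 0.0, PREFERRED) == pytest.approx(
                biological_transition_probs(i, 10, 0.0, OTHER)
            )

    def test_other_state_mirrors_preferred(self):
        # advantage in + equals disadvantage in -: same probs as moran with -phi
        assert biological_transition_probs(4, 9, 0.2, OTHER) == pytest.approx(
            moran_transition_probs(4, 9, -0.2)
        )


class TestCulturalTransitions:
    def test_no_specialists_symmetric_switching(self):
        params = LanguageModelParams(N=100, phi=0.1, eta=0.1)
        mat = cultural_transition_matrix(0, params)
        assert mat[1, 0] == pytest.approx(5e-4, abs=1e-18)  # P(+|-)
        assert mat[0, 1] == pytest.approx(5e-4, abs=1e-18)  # P(-|+)

    def test_all_specialists_beta_one_locks_culture(self):
        params = LanguageModelParams(N=50, phi=0.1, eta=2.0, alpha=3.0, beta=1.0)
        mat = cultural_transition_matrix(50, params)
        assert mat[0, 1] == 0.0  # never leaves the preferred state

    def test_half_specialists_values(self):
        params = LanguageModelParams(N=100, phi=0.1, eta=0.1)
        mat = cultural_transition_matrix(50, params)
        assert mat[1, 0] == pytest.approx(7.5e-4, abs=1e-18)
        assert mat[0, 1] == pytest.approx(2.5e-4, abs=1e-18)

    def test_rows_sum_to_one(self):
        params = LanguageModelParams(N=30, phi=0.2, eta=5.0, alpha=2.0, beta=0.8)
        for i in (0, 7, 30):
            assert cultural_transition_matrix(i, params).sum(axis=1) == pytest.approx(
                [1.0, 1.0], abs=1e-15
            )

    def test_eta_above_N_rejected(self):
        with pytest.raises(ParameterError):
            LanguageModelParams(N=10, phi=0.1, eta=11.0)


class TestModelAssembly:
    @given(
        N=st.integers(2, 12),
        phi=st.floats(-0.5, 0.5),
        eta=st.floats(0.0, 2.0),
        alpha=st.floats(0.1, 5.0),
        beta=st.floats(0.0, 1.0),
    )
    @settings(deadline=None, max_examples=100)
    def test_interior_rows_are_stochastic(self, N, phi, eta, alpha, beta):
        model = build_language_model(
            LanguageModelParams(N=N, phi=phi, eta=eta, alpha=alpha, beta=beta)
        )
        M, K, L = block_arrays(model)
        total = (M + K + L).sum(axis=2)  # outgoing mass per (i, source c)
        assert np.allclose(total[1:-1], 1.0, atol=1e-12, rtol=0)

    def test_boundary_blocks_have_no_drift(self):
        model = build_language_model(LanguageModelParams(N=5, phi=0.3, eta=1.0))
        blocks = build_blocks(model)
        assert np.all(blocks[0].M == 0) and np.all(blocks[0].L == 0)
        assert np.all(blocks[5].M == 0) and np.all(blocks[5].L == 0)

    def test_blocks_factorise_bio_times_culture(self):
        params = LanguageModelParams(N=3, phi=0.1, eta=0.3)
        model = build_language_model(params)
        blocks = build_blocks(model)
        for c, label in enumerate(model.state_labels):
            p_down, p_stay, p_up = biological_transition_probs(1, 3, 0.1, label)
            kernel_row = cultural_transition_matrix(1, params)[c]
            assert blocks[1].M[c] == pytest.approx(p_down * kernel_row, abs=1e-15)
            assert blocks[1].K[c] == pytest.approx(p_stay * kernel_row, abs=1e-15)
            assert blocks[1].L[c] == pytest.approx(p_up * kernel_row, abs=1e-15)

    def test_single_state_reduces_to_classic_scalars(self):
        N, f = 6, 0.2
        model = build_custom_model(
            N, ["only"], np.full((N + 1, 1), f), np.ones((N + 1, 1, 1))
        )
        M, K, L = block_arrays(model)
        for i in range(1, N):
            mu, kappa, lam = moran_transition_probs(i, N, f)
            assert M[i][0, 0] == pytest.approx(mu, abs=1e-15)
            assert K[i][0, 0] == pytest.approx(kappa, abs=1e-15)
            assert L[i][0, 0] == pytest.approx(lam, abs=1e-15)

    def test_beta_zero_kernel_composition_independent(self):
        model = build_language_model(
            LanguageModelParams(N=20, phi=0.1, eta=0.5, alpha=3.0, beta=0.0)
        )
        kernels = model.cultural_kernel
        assert np.allclose(kernels, kernels[0], atol=1e-15)

    def test_phi_zero_types_indistinguishable(self):
        model = build_language_model(LanguageModelParams(N=10, phi=0.0, eta=0.1))
        assert np.all(model.advantage == 0.0)

    def test_kernel_row_sum_validation(self):
        bad = np.ones((4, 1, 1)) * 0.9
        with pytest.raises(ParameterError):
            build_custom_model(3, ["a"], np.zeros((4, 1)), bad)

    def test_label_permutation_symmetry(self):
        """Relabelling cultural states permutes the model without changing it."""
        params = LanguageModelParams(N=8, phi=0.2, eta=0.7, alpha=2.0, beta=0.6)
        model = build_language_model(params)
        perm = [1, 0]
        mirrored = build_custom_model(
            model.N,
            [model.state_labels[p] for p in perm],
            model.advantage[:, perm],
            model.cultural_kernel[:, perm][:, :, perm],
        )
        M1, K1, L1 = block_arrays(model)
        M2, K2, L2 = block_arrays(mirrored)
        assert np.allclose(M2, M1[:, perm][:, :, perm], atol=1e-15)
        assert np.allclose(K2, K1[:, perm][:, :, perm], atol=1e-15)
        assert np.allclose(L2, L1[:, perm][:, :, perm], atol=1e-15)


class TestParameterValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(N=1, phi=0.1, eta=0.1),
            dict(N=10, phi=1.0, eta=0.1),
            dict(N=10, phi=0.1, eta=-0.1),
            dict(N=10, phi=0.1, eta=0.1, alpha=0.0),
            dict(N=10, phi=0.1, eta=0.1, beta=1.2),
            dict(N=10, phi=0.1, eta=0.1, start_state="x"),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            LanguageModelParams(**kwargs)
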