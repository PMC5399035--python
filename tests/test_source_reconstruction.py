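"""Atlas labelling, covariance, LCMV beamforming and leakage diagnostics."""

import numpy as np
import pytest

from alphasync.connectivity import hilbert_phase, plv_area
from alphasync.forward import leadfield_matrix
from alphasync.preprocessing import SensorEpochs
from alphasync.source_reconstruction import (BeamformerFilter, Leadfield,
                                             SingularCovarianceError,
                                             apply_weights, epoch_covariance,
                                             label_sources, lcmv_weights,
                                             weight_correlation_matrix)


def _epochs(data, rate=250.0):
    n_ch = data.shape[1]
    return SensorEpochs(data, rate, np.zeros((n_ch, 3)),
                        np.tile([0, 0, 1.0], (n_ch, 1)))


class TestLabelSources:
    def test_all_inside_one_area(self, geometry):
        *_, atlas = geometry
        center = atlas.centers[0]
        pts = center + np.random.default_rng(0).normal(
            scale=atlas.radius / 4, size=(5, 3))
        ss = label_sources(pts, atlas)
        assert ss.n_retained == 5
        assert set(ss.retained_labels) == {atlas.names[0]}

    def test_outside_point_masked(self, geometry):
        *_, atlas = geometry
        pts = np.vstack([atlas.centers[0], [0.0, 0.0, 0.0]])
        ss = label_sources(pts, atlas)
        assert ss.n_retained == 1
        assert not ss.retained_mask[1]

    def test_fixture_counts_per_area(self, geometry):
        _, _, src_p, _, labels, atlas = geometry
        ss = label_sources(src_p, atlas)
        assert ss.n_retained == len(src_p)
        table = ss.area_table()
        assert table["n_sources"].sum() == len(src_p)
        # generator places 2 sources per area in this fixture
        assert (table["n_sources"] == 2).all()

    def test_empty_atlas_rejected(self):
        from alphasync.synthetic import SphereAtlas
        empty = SphereAtlas((), np.zeros((0, 3)), 0.01)
        with pytest.raises(ValueError):
            label_sources(np.zeros((2, 3)), empty)


class TestEpochCovariance:
    def test_identical_epochs_equal_single_epoch(self, rng):
        x = rng.normal(size=(1, 4, 300))
        rep = np.repeat(x, 5, axis=0)
        np.testing.assert_allclose(epoch_covariance(_epochs(rep)),
                                   epoch_covariance(_epochs(x)), rtol=1e-12)

    def test_uncorrelated_unit_variance_near_identity(self, rng):
        n = 30_000
        x = rng.normal(size=(1, 2, n))
        cov = epoch_covariance(_epochs(x))
        # 3σ sampling band: var entries have sd √2/√n, covariance 1/√n
        np.testing.assert_allclose(cov, np.eye(2),
                                   atol=3.0 * np.sqrt(2.0 / n))

    def test_zero_data_zero_matrix(self):
        cov = epoch_covariance(_epochs(np.zeros((3, 2, 100))))
        assert np.all(cov == 0.0)

    def test_psd_and_symmetric(self, rng):
        cov = epoch_covariance(_epochs(rng.normal(size=(4, 6, 200))))
        np.testing.assert_allclose(cov, cov.T)
        assert np.linalg.eigvalsh(cov).min() >= -1e-12


class TestLCMV:
    def test_identity_covariance_gives_pseudoinverse_rows(self, rng):
        lf = rng.normal(size=(8, 3))
        filt = lcmv_weights(Leadfield(lf), np.eye(8),
                            regularization_fraction=0.0)
        for s in range(3):
            l = lf[:, s]
            expected = l / (l @ l)
            np.testing.assert_allclose(filt.weights[s], expected, rtol=1e-10)

    def test_unit_gain_every_source(self, geometry, rng):
        sens_p, sens_o, src_p, src_o, _, _ = geometry
        lf = leadfield_matrix(src_p, sens_p, sens_o, source_orientations=src_o)
        cov = np.cov(rng.normal(size=(len(sens_p), 4000)))
        filt = lcmv_weights(Leadfield(lf), cov)
        gains = np.einsum("sc,cs->s", filt.weights, lf)
        np.testing.assert_allclose(gains, 1.0, atol=1e-6)

    def test_single_source_recovery(self, geometry):
        """Noiseless single active source: reconstruction correlates ≥ 0.99
        with the true series."""
        sens_p, sens_o, src_p, src_o, _, _ = geometry
        lf = leadfield_matrix(src_p, sens_p, sens_o, source_orientations=src_o)
        rng = np.random.default_rng(1)
        truth = rng.normal(size=2000)
        sensor = np.outer(lf[:, 4], truth)
        epochs = SensorEpochs(sensor[np.newaxis], 250.0, sens_p, sens_o)
        cov = epoch_covariance(epochs)
        filt = lcmv_weights(Leadfield(lf), cov, regularization_fraction=0.01)
        rec = apply_weights(filt, epochs)[0, 4]
        assert np.corrcoef(rec, truth)[0, 1] > 0.99

    def test_free_orientation_matches_true_tangential(self, geometry):
        sens_p, sens_o, src_p, src_o, _, _ = geometry
        lf_free = leadfield_matrix(src_p, sens_p, sens_o)
        rng = np.random.default_rng(2)
        sig = rng.normal(size=(len(src_p), 3000))
        lf_fixed = leadfield_matrix(src_p, sens_p, sens_o,
                                    source_orientations=src_o)
        sensor = lf_fixed @ sig
        epochs = SensorEpochs(sensor[np.newaxis], 250.0, sens_p, sens_o)
        cov = epoch_covariance(epochs)
        filt = lcmv_weights(Leadfield(lf_free), cov)
        gains = np.abs(np.einsum("sc,cs->s", filt.weights, lf_fixed))
        # scalar orientation must capture most of each true source's gain
        assert np.median(gains) > 0.7

    def test_variance_never_below_unregularized_optimum(self, geometry, rng):
        sens_p, sens_o, src_p, src_o, _, _ = geometry
        lf = leadfield_matrix(src_p, sens_p, sens_o, source_orientations=src_o)
        x = rng.normal(size=(len(sens_p), 5000))
        cov = np.cov(x) + 0.1 * np.eye(len(sens_p))
        base = lcmv_weights(Leadfield(lf), cov, regularization_fraction=0.0)
        var0 = np.einsum("sc,cd,sd->s", base.weights, cov, base.weights)
        prev = var0
        for lam in (0.01, 0.05, 0.2, 1.0):
            filt = lcmv_weights(Leadfield(lf), cov, regularization_fraction=lam)
            var = np.einsum("sc,cd,sd->s", filt.weights, cov, filt.weights)
            assert np.all(var >= var0 - 1e-12)
            assert np.all(var >= prev - 1e-9)  # monotone inflation
            prev = var

    def test_singular_covariance_raises_helpful_error(self):
        lf = np.ones((3, 1))
        with pytest.raises(SingularCovarianceError, match="regularization"):
            lcmv_weights(Leadfield(lf), np.zeros((3, 3)),
                         regularization_fraction=0.0)

    def test_negative_regularization_rejected(self):
        with pytest.raises(ValueError):
            lcmv_weights(Leadfield(np.ones((3, 1))), np.eye(3),
                         regularization_fraction=-0.1)


class TestApplyWeights:
    def test_zero_weights_zero_sources(self, rng):
        filt = BeamformerFilter(np.zeros((2, 4)), np.eye(4), 0.0)
        out = apply_weights(filt, _epochs(rng.normal(size=(3, 4, 50))))
        assert out.shape == (3, 2, 50) and np.all(out == 0.0)

    def test_identity_passthrough(self, rng):
        data = rng.normal(size=(2, 1, 30))
        filt = BeamformerFilter(np.ones((1, 1)), np.eye(1), 0.0)
        np.testing.assert_array_equal(apply_weights(filt, _epochs(data)), data)

    def test_dimension_mismatch_rejected(self, rng):
        filt = BeamformerFilter(np.zeros((2, 5)), np.eye(5), 0.0)
        with pytest.raises(ValueError):
            apply_weights(filt, _epochs(rng.normal(size=(1, 4, 50))))

    def test_crosstalk_below_leakage_bound(self, geometry):
        """Point-spread between two well-separated sources stays below the
        unit self-gain by a clear margin."""
        sens_p, sens_o, src_p, src_o, _, _ = geometry
        pair = [0, 11]  # one anterior, one posterior source
        lf = leadfield_matrix(src_p[pair], sens_p, sens_o,
                              source_orientations=src_o[pair])
        rng = np.random.default_rng(3)
        sig = rng.normal(size=(2, 4000))
        sensor = lf @ sig
        cov = np.cov(sensor) + 1e-4 * np.trace(np.cov(sensor)) / len(sens_p) \
            * np.eye(len(sens_p))
        filt = lcmv_weights(Leadfield(lf), cov, regularization_fraction=0.01)
        psf = filt.weights @ lf  # rows: reconstructed; cols: true
        off = np.abs(psf[~np.eye(2, dtype=bool)])
        assert np.all(off < 0.3)


class TestWeightCorrelation:
    def test_identical_weight_vectors_r_one(self):
        w = np.tile(np.arange(5.0), (2, 1))
        filt = BeamformerFilter(w, np.eye(5), 0.0)
        m = weight_correlation_matrix(filt, ["A", "B"])
        assert m.loc["A", "B"] == pytest.approx(1.0)

    def test_orthogonal_vectors_r_zero(self):
        w = np.array([[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, 1.0, 1.0]])
        # second row has zero variance: use a sign-balanced orthogonal pair
        w = np.array([[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]])
        filt = BeamformerFilter(w, np.eye(4), 0.0)
        m = weight_correlation_matrix(filt, ["A", "B"])
        assert m.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_norm_vector_rejected(self):
        w = np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 3.0]])
        filt = BeamformerFilter(w, np.eye(3), 0.0)
        with pytest.raises(ValueError, match="undefined"):
            weight_correlation_matrix(filt, ["A", "B"])


def test_coupled_pair_is_strongest_link_in_small_toy(geometry):
    """Beamformer + PLV end to end on a toy with known mixing: three active,
    well-separated sources, two of them phase-coupled; the coupled pair must
    come out as the strongest reconstructed link."""
    from alphasync.synthetic import simulate_coupled_phases, \
        phases_to_source_signals
    sens_p, sens_o, src_p, src_o, labels, _ = geometry
    active = [0, 10, 17]  # FP-L, SP-R, PC areas
    target = np.eye(3)
    target[0, 1] = target[1, 0] = 0.9  # FP-L — SP-R coupled; PC independent
    ph = simulate_coupled_phases(3, target, 20_000, center_freq=9.4,
                                 rate=250.0, seed=5)
    sig = phases_to_source_signals(ph, amplitude=1.0, amplitude_sd=0.2,
                                   noise_sd=0.1, seed=6, rate=250.0)
    lf = leadfield_matrix(src_p[active], sens_p, sens_o,
                          source_orientations=src_o[active])
    sensor = lf @ sig
    rng = np.random.default_rng(7)
    sensor += rng.normal(0, 0.02 * sensor.std(), size=sensor.shape)
    epochs = SensorEpochs(sensor.reshape(len(sens_p), 20, 1000)
                          .transpose(1, 0, 2), 250.0, sens_p, sens_o)
    cov = epoch_covariance(epochs)
    filt = lcmv_weights(Leadfield(lf), cov)
    src = apply_weights(filt, epochs)
    phases = hilbert_phase(src, pad_samples=500)
    conn = plv_area(phases, labels[active])
    off = conn.plv.copy()
    np.fill_diagonal(off, 0.0)
    best = np.unravel_index(np.argmax(off), off.shape)
    truth = {conn.area_names.index(labels[active[0]]),
             conn.area_names.index(labels[active[1]])}
    assert set(int(b) for b in best) == truth
    # and the recovered coupling is strong in absolute terms
    assert off[best] > 0.6
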