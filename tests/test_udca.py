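"""Diffusion-component pipeline: segmentation, metric, kernel spectra,
Nystrom extension, embedding selection, outlier rules, end-to-end behavior."""

import math

import numpy as np
import pytest

from ptebio import (ArgumentError, EEGRecording, UDCAConfig, affinity_kernel,
                    diffusion_decomposition, mahalanobis_metric,
                    nystrom_extension, outlier_scores, pairwise_mahalanobis,
                    qc_cross_correlation, run_udca, segment, select_embedding)
from ptebio.udca import SegmentSet


# ---------------------------------------------------------------------------
# independent brute-force oracle (pure-python normalization, dense eig)
# ---------------------------------------------------------------------------

def brute_force_point_clouds(a, n_eig):
    """Reference two-stage normalization + dense eigensolve, written with
    explicit loops, independent of the library implementation."""
    n = len(a)
    j1 = [sum(a[i][j] for j in range(n)) for i in range(n)]
    a1 = [[a[i][j] / math.sqrt(j1[i] * j1[j]) for j in range(n)]
          for i in range(n)]
    w1 = [[sum(a1[i][k] * a1[k][j] for k in range(n)) for j in range(n)]
          for i in range(n)]
    j2 = [sum(w1[i][j] for j in range(n)) for i in range(n)]
    a2 = [[w1[i][j] / math.sqrt(j2[i] * j2[j]) for j in range(n)]
          for i in range(n)]
    w2 = [[sum(a2[i][k] * a2[k][j] for k in range(n)) for j in range(n)]
          for i in range(n)]
    evals, evecs = np.linalg.eig(np.array(w2))
    order = np.argsort(evals.real)[::-1]
    evals = evals.real[order][:n_eig]
    evecs = evecs.real[:, order][:, :n_eig]
    clds = evecs / np.sqrt(np.array(j2))[:, None]
    return evals, clds


def random_kernel(rng, n):
    d = np.abs(rng.normal(0.0, 2.0, size=(n, n)))
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return affinity_kernel(d, k_e=0.5)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

class TestSegment:
    def test_segment_count_formula(self, rng):
        rec = EEGRecording(rng.normal(size=(3, 1000)), 200.0,
                           ["a", "b", "c"])
        seg = segment(rec, 200)
        assert seg.n_segments == 9  # (1000 - 200) / 100 + 1
        assert seg.features.shape == (9, 3 * 200)
        # consecutive segments share exactly half a window
        np.testing.assert_array_equal(seg.segments[0][:, 100:],
                                      seg.segments[1][:, :100])

    def test_single_segment_when_window_equals_length(self, rng):
        rec = EEGRecording(rng.normal(size=(2, 400)), 200.0, ["a", "b"])
        assert segment(rec, 400).n_segments == 1

    def test_window_longer_than_recording_rejected(self, rng):
        rec = EEGRecording(rng.normal(size=(2, 150)), 200.0, ["a", "b"])
        with pytest.raises(ArgumentError):
            segment(rec, 200)

    def test_odd_window_rejected(self, rng):
        rec = EEGRecording(rng.normal(size=(2, 500)), 200.0, ["a", "b"])
        with pytest.raises(ArgumentError):
            segment(rec, 201)

    def test_covariances_are_symmetric_psd(self, white_recording):
        seg = segment(white_recording, 400)
        for c in seg.covariances:
            np.testing.assert_allclose(c, c.T, atol=1e-12)
            assert np.linalg.eigvalsh(c).min() >= -1e-10


class TestQCCrossCorrelation:
    def test_identical_channels_summary_is_one(self, rng):
        x = rng.normal(size=4096)
        rec = EEGRecording(np.vstack([x, x]), 200.0, ["a", "b"])
        qc = qc_cross_correlation(segment(rec, 512), max_lag=32)
        assert qc[("a", "b")] == pytest.approx(1.0, abs=1e-9)

    def test_independent_white_noise_summary_is_small(self, rng):
        rec = EEGRecording(rng.normal(size=(2, 8192)), 200.0, ["a", "b"])
        qc = qc_cross_correlation(segment(rec, 512), max_lag=32)
        assert qc[("a", "b")] < 0.3

    def test_max_lag_at_least_window_rejected(self, white_recording):
        seg = segment(white_recording, 400)
        with pytest.raises(ArgumentError):
            qc_cross_correlation(seg, max_lag=400)


# ---------------------------------------------------------------------------
# metric and kernel
# ---------------------------------------------------------------------------

def synthetic_segment_set(means, inv_covs):
    """Minimal SegmentSet with prescribed summary statistics."""
    means = np.asarray(means, dtype=float)
    n, c = means.shape
    return SegmentSet(segments=np.zeros((n, c, 4)),
                      features=np.zeros((n, 4 * c)),
                      covariances=np.stack([np.eye(c)] * n),
                      inv_covariances=np.asarray(inv_covs, dtype=float),
                      channel_means=means,
                      start_samples=np.arange(n) * 2, fs=200.0, t0=0.0,
                      channel_labels=[f"c{i}" for i in range(c)])


class TestMahalanobisMetric:
    def test_identical_consecutive_segments_have_zero_distance(self, rng):
        x = rng.normal(size=(2, 200))
        rec = EEGRecording(np.tile(x, (1, 3)), 200.0, ["a", "b"])
        seg = segment(rec, 400)
        d = mahalanobis_metric(seg)
        # consecutive segments are identical copies -> exactly zero distance
        assert d[0] == pytest.approx(0.0, abs=1e-12)
        assert d.min() >= 0.0

    def test_identity_metric_hand_value(self):
        seg = synthetic_segment_set([[0.0, 0.0], [3.0, 4.0]],
                                    [np.eye(2), np.eye(2)])
        d = mahalanobis_metric(seg)
        assert d[0] == pytest.approx(25.0)  # (3,4) . I . (3,4)

    def test_quadratic_homogeneity_under_identity_covariance(self):
        base = synthetic_segment_set([[0.0, 0.0], [1.0, 2.0]],
                                     [np.eye(2), np.eye(2)])
        scaled = synthetic_segment_set([[0.0, 0.0], [3.0, 6.0]],
                                       [np.eye(2), np.eye(2)])
        assert mahalanobis_metric(scaled)[0] == pytest.approx(
            9.0 * mahalanobis_metric(base)[0])

    def test_pairwise_matrix_is_symmetric_zero_diagonal(self, white_recording):
        seg = segment(white_recording, 400)
        d = pairwise_mahalanobis(seg)
        np.testing.assert_allclose(d, d.T, atol=1e-12)
        assert np.all(np.diag(d) == 0.0)
        assert d.min() >= 0.0
        # consecutive entries agree with the dedicated consecutive form
        np.testing.assert_allclose(np.diag(d, k=1), mahalanobis_metric(seg),
                                   atol=1e-10)


class TestAffinityKernel:
    def test_zero_distance_gives_affinity_one(self):
        assert affinity_kernel(np.array(0.0), 10.0) == 1.0

    def test_printed_form_d40_ke10(self):
        assert affinity_kernel(np.array(40.0), 10.0) == pytest.approx(
            math.exp(-1.0))

    def test_strictly_decreasing_in_distance(self):
        d = np.linspace(0, 100, 50)
        a = affinity_kernel(d, 10.0)
        assert (np.diff(a) < 0).all()

    def test_negative_distance_rejected(self):
        with pytest.raises(ArgumentError):
            affinity_kernel(np.array([-1.0]), 10.0)


# ---------------------------------------------------------------------------
# spectral decomposition
# ---------------------------------------------------------------------------

class TestDiffusionDecomposition:
    def test_equidistant_points_have_degenerate_tail(self):
        # kernel a*I + b*(J - I): eigenvalues of the normalized chain are
        # 1 and a repeated pair
        a = np.full((3, 3), 0.4)
        np.fill_diagonal(a, 1.0)
        dec = diffusion_decomposition(a, 3)
        assert dec.eigenvalues[0] == pytest.approx(1.0, abs=1e-12)
        assert dec.eigenvalues[1] == pytest.approx(dec.eigenvalues[2],
                                                   abs=1e-12)

    def test_two_point_kernel_matches_hand_derivation(self):
        # symmetric 2x2 kernel [[1, a], [a, 1]]: the normalized chain has
        # eigenvalues 1 and ((1-a)/(1+a))^4 after two normalize-and-square
        # stages (row sums stay uniform, so each stage squares the gap)
        a = 0.3
        dec = diffusion_decomposition(np.array([[1.0, a], [a, 1.0]]), 2)
        expected = ((1 - a) / (1 + a)) ** 4
        assert dec.eigenvalues[1] == pytest.approx(expected, abs=1e-12)

    def test_leading_eigenpair_is_stochastic_fixed_point(self, rng):
        dec = diffusion_decomposition(random_kernel(rng, 20), 8)
        assert dec.eigenvalues[0] == pytest.approx(1.0, abs=1e-8)
        lead = dec.point_clouds[:, 0]
        assert np.ptp(lead) / np.abs(lead).mean() < 1e-6

    def test_matches_brute_force_oracle_up_to_sign(self, rng):
        for n in (6, 9, 12):
            a = random_kernel(rng, n)
            dec = diffusion_decomposition(a, n_eigenvectors=5)
            ev_ref, clds_ref = brute_force_point_clouds(a.tolist(), 5)
            np.testing.assert_allclose(dec.eigenvalues, ev_ref, atol=1e-8)
            for k in range(5):
                got, ref = dec.point_clouds[:, k], clds_ref[:, k]
                assert (np.abs(got - ref).max() < 1e-8
                        or np.abs(got + ref).max() < 1e-8)

    def test_spectrum_bounds_and_psd(self, rng):
        for _ in range(10):
            dec = diffusion_decomposition(random_kernel(rng, 15), 15)
            assert dec.eigenvalues.min() >= -1e-10
            assert dec.eigenvalues.max() <= 1 + 1e-8

    def test_asymmetric_kernel_rejected(self):
        a = np.array([[1.0, 0.5], [0.1, 1.0]])
        with pytest.raises(ArgumentError):
            diffusion_decomposition(a, 2)


class TestNystromExtension:
    def test_training_rows_reproduce_their_coordinates(self, rng):
        a = random_kernel(rng, 25)
        dec = diffusion_decomposition(a, 8)
        psi = nystrom_extension(a, dec)
        denom = np.abs(dec.point_clouds[:, :8]).max(axis=0)
        rel = np.abs(psi - dec.point_clouds[:, :8]) / denom
        assert rel.max() < 1e-6

    def test_duplicate_of_training_point_matches_it(self, rng):
        a = random_kernel(rng, 15)
        dec = diffusion_decomposition(a, 6)
        psi = nystrom_extension(a[4], dec)
        np.testing.assert_allclose(psi[0], dec.point_clouds[4, :6],
                                   atol=1e-8)

    def test_midpoint_between_clusters_stays_in_hull(self, rng):
        from scipy.spatial.distance import cdist
        pts = np.vstack([rng.normal(0, 0.1, (10, 3)),
                         rng.normal(5, 0.1, (10, 3))])
        d = cdist(pts, pts) ** 2
        k_e = np.median(d[d > 0]) / 4
        dec = diffusion_decomposition(affinity_kernel(d, k_e), 6)
        mid = 0.5 * (pts[0] + pts[10])
        row = np.exp(-((pts - mid) ** 2).sum(axis=1) / (4 * k_e))
        psi = nystrom_extension(row, dec, n_coords=2)
        lo = dec.point_clouds[:, :2].min(axis=0)
        hi = dec.point_clouds[:, :2].max(axis=0)
        assert np.all(psi >= lo - 1e-9) and np.all(psi <= hi + 1e-9)

    def test_too_many_coordinates_rejected(self, rng):
        a = random_kernel(rng, 10)
        dec = diffusion_decomposition(a, 4)
        with pytest.raises(ArgumentError):
            nystrom_extension(a[0], dec, n_coords=9)

    def test_zero_affinity_row_names_the_segment(self, rng):
        a = random_kernel(rng, 10)
        dec = diffusion_decomposition(a, 4)
        rows = np.vstack([a[0], np.zeros(10)])
        with pytest.raises(ArgumentError, match="1"):
            nystrom_extension(rows, dec)


# ---------------------------------------------------------------------------
# embedding selection and outliers
# ---------------------------------------------------------------------------

class TestSelectEmbedding:
    def test_four_eigenvectors_give_single_triple(self, rng):
        clds = rng.normal(size=(30, 4))
        triple, _, _, spreads = select_embedding(clds)
        assert triple == (1, 2, 3)
        assert len(spreads) == 1

    def test_seven_eigenvectors_give_twenty_triples(self, rng):
        _, _, _, spreads = select_embedding(rng.normal(size=(30, 7)))
        assert len(spreads) == 20  # C(6, 3)

    def test_degenerate_triple_never_beats_spread(self, rng):
        clds = rng.normal(size=(30, 5))
        clds[:, 3] = clds[:, 4] = clds[:, 1] = 0.0  # triple (1,3,4) collapses
        triple, _, spread, spreads = select_embedding(clds)
        assert spreads[(1, 3, 4)] == 0.0
        assert triple != (1, 3, 4) and spread > 0

    def test_fewer_than_four_rejected(self, rng):
        with pytest.raises(ArgumentError):
            select_embedding(rng.normal(size=(30, 3)))


class TestOutlierScores:
    def test_identical_points_give_no_mad_flags(self):
        coords = np.ones((20, 3))
        _, flags = outlier_scores(coords, "mad", 3.0)
        assert not flags.any()

    def test_single_distant_point_flagged_by_mad(self, rng):
        coords = np.vstack([rng.normal(0, 1e-3, size=(99, 3)),
                            [[10.0, 0.0, 0.0]]])
        _, flags = outlier_scores(coords, "mad", 3.0)
        assert flags[99] and flags.sum() == 1

    def test_quantile_rule_flags_exact_count(self, rng):
        _, flags = outlier_scores(rng.normal(size=(100, 3)),
                                  "quantile", 0.05)
        assert flags.sum() == 5

    def test_nonpositive_param_rejected(self, rng):
        with pytest.raises(ArgumentError):
            outlier_scores(rng.normal(size=(10, 3)), "mad", 0.0)


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------

class TestRunUDCA:
    def test_deterministic_rerun_is_bitwise_identical(self, rng):
        rec = EEGRecording(rng.normal(0, 15, size=(4, 6000)), 200.0,
                           ["a", "b", "c", "d"])
        r1 = run_udca(rec, UDCAConfig(window_size=400, k_e="median"))
        r2 = run_udca(rec, UDCAConfig(window_size=400, k_e="median"))
        np.testing.assert_array_equal(r1.eigenvalues, r2.eigenvalues)
        np.testing.assert_array_equal(r1.outlier_flags, r2.outlier_flags)
        assert r1.selected_embedding == r2.selected_embedding

    def test_channel_permutation_changes_nothing(self, rng):
        data = rng.normal(0, 15, size=(4, 6000))
        rec = EEGRecording(data, 200.0, ["a", "b", "c", "d"])
        perm = [2, 0, 3, 1]
        rec_p = EEGRecording(data[perm], 200.0,
                             [rec.channel_labels[i] for i in perm])
        r1, r2 = run_udca(rec), run_udca(rec_p)
        np.testing.assert_allclose(r1.pairwise_distances,
                                   r2.pairwise_distances, atol=1e-9)
        np.testing.assert_allclose(r1.distances, r2.distances, atol=1e-9)
        np.testing.assert_array_equal(r1.outlier_flags, r2.outlier_flags)

    def test_time_reversal_reverses_flags(self, rng):
        # 6000 = 400 + 28*200 exactly: segmentation covers the record
        data = rng.normal(0, 15, size=(3, 6000))
        data[:, 2000:2100] += 80.0  # one anomalous burst
        rec = EEGRecording(data, 200.0, ["a", "b", "c"])
        rec_rev = EEGRecording(data[:, ::-1].copy(), 200.0, ["a", "b", "c"])
        cfg = UDCAConfig(window_size=400, k_e="median", outlier_rule="mad",
                         outlier_param=3.0)
        r_fwd, r_rev = run_udca(rec, cfg), run_udca(rec_rev, cfg)
        np.testing.assert_array_equal(r_fwd.outlier_flags,
                                      r_rev.outlier_flags[::-1])

    def test_white_noise_has_no_dominant_embedding(self, rng):
        rec = EEGRecording(rng.normal(0, 15, size=(5, 20000)), 200.0,
                           [f"C{i}" for i in range(5)])
        res = run_udca(rec, UDCAConfig(k_e="median"))
        spreads = np.array(list(res.embeddings.values()))
        assert res.selected_spread <= 2.0 * np.median(spreads)

    def test_too_short_recording_rejected(self, rng):
        rec = EEGRecording(rng.normal(size=(2, 500)), 200.0, ["a", "b"])
        with pytest.raises(ArgumentError):
            run_udca(rec, UDCAConfig(window_size=400))
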