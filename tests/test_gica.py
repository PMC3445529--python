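"""Group ICA: PCA reductions, infomax, ICASSO stability, back-reconstruction."""

import numpy as np
import pytest

import fncpipe as f
from fncpipe import gica
from fncpipe.gica import (
    NotWhitenedError,
    RunData,
    cluster_estimates,
    infomax_ica,
    icasso,
    normalize_signs,
    reduce_group,
    reduce_run,
)


def _laplace_blob_sources(rng, n_sources=3, n_vox=600):
    """Disjoint super-Gaussian spatial sources (Laplace-amplitude blobs)."""
    S = np.zeros((n_sources, n_vox))
    width = n_vox // n_sources
    for k in range(n_sources):
        block = slice(k * width, k * width + width // 3)
        S[k, block] = rng.laplace(size=width // 3) * 3.0
    S += 0.05 * rng.standard_normal(S.shape)
    return S / S.std(axis=1, keepdims=True)


def _amari_distance(P):
    """Amari separation index of a mixing-unmixing product (0 = perfect)."""
    P = np.abs(P)
    m = P.shape[0]
    rows = (P.sum(axis=1) / P.max(axis=1) - 1).sum()
    cols = (P.sum(axis=0) / P.max(axis=0) - 1).sum()
    return (rows + cols) / (2 * m * (m - 1))


class TestReduceRun:
    def test_exact_rank_two_roundtrip(self, rng):
        t = np.linspace(0, 8 * np.pi, 60)
        tcs = np.column_stack([np.sin(t), np.cos(2 * t)])
        load = rng.standard_normal((2, 500))
        X = tcs @ load
        X -= X.mean(axis=0, keepdims=True)
        run = RunData(X, "s", 0)
        red, reduced = reduce_run(run, 2)
        assert np.allclose(red.debasis @ reduced, X, atol=1e-8)

    def test_eigenvalues_match_svd_oracle(self, rng):
        X = rng.standard_normal((40, 800))
        X -= X.mean(axis=0, keepdims=True)
        red, _ = reduce_run(RunData(X, "s", 0), 10)
        sv = np.linalg.svd(X, compute_uv=False)
        assert np.allclose(red.eigenvalues, (sv[:10] ** 2) / 800, atol=1e-8)

    def test_full_rank_retention_is_lossless(self, rng):
        # voxel demeaning leaves rank scans-1; retaining that is lossless
        X = rng.standard_normal((20, 300))
        X -= X.mean(axis=0, keepdims=True)
        red, reduced = reduce_run(RunData(X, "s", 0), 19)
        assert np.allclose(red.debasis @ reduced, X, atol=1e-8)

    def test_output_is_whitened(self, rng):
        X = rng.standard_normal((40, 1000))
        X -= X.mean(axis=0, keepdims=True)
        _, reduced = reduce_run(RunData(X, "s", 0), 8)
        cov = reduced @ reduced.T / 1000
        assert np.allclose(cov, np.eye(8), atol=1e-6)

    def test_basis_debasis_identity(self, rng):
        X = rng.standard_normal((30, 400))
        red, _ = reduce_run(RunData(X, "s", 0), 12)
        assert np.allclose(red.basis @ red.debasis, np.eye(12), atol=1e-8)
        assert np.all(np.diff(red.eigenvalues) <= 1e-12)

    def test_retained_exceeding_scans_rejected(self, rng):
        X = rng.standard_normal((10, 50))
        with pytest.raises(ValueError, match="exceeds"):
            reduce_run(RunData(X, "s", 0), 11)

    def test_rank_deficient_input_rejected(self, rng):
        tcs = rng.standard_normal((30, 2))
        X = tcs @ rng.standard_normal((2, 200))
        with pytest.raises(ValueError, match="rank"):
            reduce_run(RunData(X, "s", 0), 5)

    def test_variance_conservation(self, rng):
        # unwhitened projection scores carry exactly the eigenvalues
        X = rng.standard_normal((30, 500))
        X -= X.mean(axis=0, keepdims=True)
        red, reduced = reduce_run(RunData(X, "s", 0), 29)
        scores = np.sqrt(red.eigenvalues)[:, None] * reduced
        total = (scores**2).sum() / 500
        assert total == pytest.approx(red.eigenvalues.sum(), rel=1e-6)


class TestReduceGroup:
    def test_small_stack_lossless(self, rng):
        blocks = [rng.standard_normal((3, 200)) for _ in range(2)]
        stacked = np.vstack(blocks)
        red, reduced = reduce_group(stacked, 6)
        assert np.allclose(red.debasis @ reduced, stacked, atol=1e-8)

    def test_planted_orthogonal_subspace_recovered(self, rng):
        from scipy.linalg import subspace_angles

        patterns = np.linalg.qr(rng.standard_normal((300, 4)))[0].T  # 4 x 300
        loadings = rng.standard_normal((24, 4))
        stacked = loadings @ patterns
        red, reduced = reduce_group(stacked, 4)
        angles = subspace_angles(reduced.T, patterns.T)
        assert angles.max() < 1e-6

    def test_subject_permutation_preserves_span(self, rng):
        blocks = [rng.standard_normal((3, 150)) for _ in range(4)]
        red1, r1 = reduce_group(np.vstack(blocks), 5)
        red2, r2 = reduce_group(np.vstack(blocks[::-1]), 5)
        p1 = r1.T @ np.linalg.pinv(r1.T)
        p2 = r2.T @ np.linalg.pinv(r2.T)
        assert np.allclose(p1, p2, atol=1e-8)


class TestInfomax:
    def test_planted_super_gaussian_sources_recovered(self, rng):
        S = _laplace_blob_sources(rng)
        A = rng.standard_normal((3, 3))
        X = A @ S
        red, white = gica._temporal_pca(X - X.mean(1, keepdims=True), 3)
        _, est, conv = infomax_ica(white, seed=11)
        corr = np.abs(np.corrcoef(np.vstack([est, S]))[:3, 3:])
        assert conv
        assert (corr.max(axis=1) > 0.99).all()

    def test_seeded_determinism(self, rng):
        S = _laplace_blob_sources(rng)
        X = rng.standard_normal((3, 3)) @ S
        _, white = gica._temporal_pca(X, 3)
        W1, s1, _ = infomax_ica(white, seed=5)
        W2, s2, _ = infomax_ica(white, seed=5)
        assert np.array_equal(W1, W2)
        assert np.array_equal(s1, s2)

    def test_non_whitened_input_rejected(self, rng):
        X = 3.0 * rng.standard_normal((3, 500))
        with pytest.raises(NotWhitenedError):
            infomax_ica(X, seed=0)

    def test_gaussian_sources_have_no_stable_rotation(self, rng):
        X = rng.standard_normal((3, 4000))
        _, white = gica._temporal_pca(X, 3)
        W1, _, _ = infomax_ica(white, seed=1)
        W2, _, _ = infomax_ica(white, seed=2)
        assert _amari_distance(W1 @ np.linalg.pinv(W2)) > 0.05


class TestIcasso:
    def test_planted_sources_all_stable(self, rng):
        S = _laplace_blob_sources(rng)
        X = rng.standard_normal((3, 3)) @ S
        _, white = gica._temporal_pca(X, 3)
        sources, mixing, iq, conv = icasso(white, n_reps=5, seed=0)
        assert (iq > 0.9).all()
        corr = np.abs(np.corrcoef(np.vstack([sources, S]))[:3, 3:])
        assert (corr.max(axis=1) > 0.99).all()

    def test_duplicate_seeds_give_unit_stability(self, rng):
        S = _laplace_blob_sources(rng)
        X = rng.standard_normal((3, 3)) @ S
        _, white = gica._temporal_pca(X, 3)
        _, _, iq, _ = icasso(white, seeds=[7, 7])
        # intra-cluster similarity is exactly 1 for duplicated estimates;
        # Iq subtracts the (small, nonzero) extra-cluster similarity
        assert np.all(iq > 0.99)

    def test_cluster_labels_partition_estimates(self, rng):
        pooled = rng.standard_normal((12, 100))
        labels, _ = cluster_estimates(pooled, 4)
        assert labels.shape == (12,)
        assert set(labels) == {1, 2, 3, 4}

    def test_too_few_repetitions_rejected(self, rng):
        _, white = gica._temporal_pca(rng.standard_normal((3, 500)), 3)
        with pytest.raises(ValueError):
            icasso(white, n_reps=1)


class TestSignConvention:
    def test_normalize_signs_idempotent(self, rng):
        S = rng.standard_normal((5, 200))
        once = normalize_signs(S)
        assert np.array_equal(normalize_signs(once), once)

    def test_peak_weight_positive(self, rng):
        S = normalize_signs(rng.standard_normal((5, 200)))
        for row in S:
            assert row[np.argmax(np.abs(row))] > 0


class TestBackReconstruction:
    def _tiny_study(self, rng, scale_first_subject=1.0):
        S = _laplace_blob_sources(rng, n_sources=3, n_vox=500)
        runs = []
        true_tcs = {}
        for s in range(4):
            tc = rng.standard_normal((50, 3))
            X = tc @ S
            if s == 0:
                X = X * scale_first_subject
            runs.append(RunData.from_raw(X, f"sub{s}", 0))
            true_tcs[f"sub{s}"] = tc
        return S, runs, true_tcs

    def test_noiseless_timecourse_recovery(self, rng):
        S, runs, true_tcs = self._tiny_study(rng)
        model = gica.fit_group_ica(runs, n_ic=3, run_pcs=3, n_reps=3, seed=2)
        sc = gica.back_reconstruct(model, [runs[0]])
        tc = true_tcs["sub0"]
        corr = np.abs(np.corrcoef(np.hstack([sc.timecourses, tc]).T)[:3, 3:])
        assert (corr.max(axis=1) > 0.999).all()

    def test_gica_and_dual_regression_agree_on_phantom(self, rng):
        S, runs, _ = self._tiny_study(rng)
        model = gica.fit_group_ica(runs, n_ic=3, run_pcs=3, n_reps=3, seed=2)
        a = gica.back_reconstruct(model, [runs[1]], method="gica")
        b = gica.back_reconstruct(model, [runs[1]], method="dual_regression")
        for k in range(3):
            r = np.corrcoef(a.timecourses[:, k], b.timecourses[:, k])[0, 1]
            assert abs(r) > 0.95

    def test_scaling_subject_data_scales_its_timecourses(self, rng):
        state = rng.bit_generator.state
        S, runs, _ = self._tiny_study(rng)
        rng.bit_generator.state = state
        _, runs2x, _ = self._tiny_study(rng, scale_first_subject=2.0)
        m1 = gica.fit_group_ica(runs, n_ic=3, run_pcs=3, n_reps=3, seed=2)
        m2 = gica.fit_group_ica(runs2x, n_ic=3, run_pcs=3, n_reps=3, seed=2)
        tc1 = gica.back_reconstruct(m1, [runs[0]]).timecourses
        tc2 = gica.back_reconstruct(m2, [runs2x[0]]).timecourses
        other1 = gica.back_reconstruct(m1, [runs[1]]).timecourses
        other2 = gica.back_reconstruct(m2, [runs2x[1]]).timecourses
        assert np.allclose(tc2, 2.0 * tc1, atol=1e-8)
        assert np.allclose(other1, other2, atol=1e-8)

    def test_unknown_run_rejected(self, rng):
        S, runs, _ = self._tiny_study(rng)
        model = gica.fit_group_ica(runs[:3], n_ic=3, run_pcs=3, n_reps=3, seed=2)
        with pytest.raises(gica.MissingReductionError):
            gica.back_reconstruct(model, [runs[3]])


class TestModelSerialization:
    def test_save_load_roundtrip(self, rng, tmp_path):
        S = _laplace_blob_sources(rng)
        runs = [RunData.from_raw(rng.standard_normal((40, 3)) @ S
                                 + 0.1 * rng.standard_normal((40, 600)),
                                 f"s{i}", 0) for i in range(3)]
        model = gica.fit_group_ica(runs, n_ic=3, run_pcs=5, n_reps=3, seed=0)
        path = tmp_path / "model.npz"
        gica.save_model(model, path)
        loaded = gica.load_model(path)
        assert np.array_equal(loaded.sources, model.sources)
        assert loaded.stack_order == model.stack_order
        tc1 = gica.back_reconstruct(model, [runs[0]]).timecourses
        tc2 = gica.back_reconstruct(loaded, [runs[0]]).timecourses
        assert np.allclose(tc1, tc2, atol=1e-12)


class TestEndToEndRecovery:
    def test_planted_sources_and_fnc_recovered(self, reduced_study, fitted_model):
        """Full pipeline on the reduced study: spatial maps match planted
        sources and recovered FNC tracks the generated time courses."""
        data, model, comps = fitted_model
        assign, rs = f.match_sources(model.sources, reduced_study.truth.source_maps)
        assert (rs > 0.9).all()

        cfg = reduced_study.config
        errs = []
        for s in reduced_study.subjects:
            sc = comps[s.subject_id]
            z_est = f.compute_fnc(sc.timecourses, sc.run_lengths).z
            scans = cfg.scans_per_run
            parts = []
            for r in range(cfg.runs):
                blk = s.true_timecourses[r * scans : (r + 1) * scans]
                parts.append(blk - blk.mean(axis=0))
            z_true = np.arctanh(
                np.clip(np.corrcoef(np.vstack(parts), rowvar=False),
                        -1 + 1e-9, 1 - 1e-9)
            )
            iu = np.triu_indices(cfg.n_sources, 1)
            errs.extend(
                (z_est[np.ix_(assign, assign)][iu] - z_true[iu]).tolist()
            )
        assert np.quantile(np.abs(errs), 0.95) < 0.1


class TestArtifactRule:
    def test_edge_peaked_component_flagged(self, reduced_study, fitted_model):
        data, model, comps = fitted_model
        mask = reduced_study.truth.mask
        mask_index = np.flatnonzero(mask.ravel())
        # move one component's peak to the mask rim
        doctored = model.sources.copy()
        from scipy.ndimage import binary_erosion

        interior = binary_erosion(mask, iterations=1)
        rim_lin = np.flatnonzero(mask.ravel() & ~interior.ravel())
        rim_pos = np.flatnonzero(np.isin(mask_index, rim_lin))[0]
        doctored[0, rim_pos] = 2 * np.abs(doctored[0]).max()
        m = gica.GroupICAModel(
            sources=doctored, group_mixing=model.group_mixing,
            run_reductions=model.run_reductions,
            group_reduction=model.group_reduction,
            stack_order=model.stack_order,
        )
        flagged = gica.flag_artifact_components(m, mask, mask_index)
        assert 0 in flagged

    def test_high_frequency_timecourse_flagged(self, reduced_study, fitted_model):
        data, model, comps = fitted_model
        mask = reduced_study.truth.mask
        mask_index = np.flatnonzero(mask.ravel())
        n_scans = 69
        tcs = np.zeros((n_scans, model.n_ic))
        t = np.arange(n_scans)
        tcs[:, 0] = np.sin(2 * np.pi * 0.02 * t * 3.0)  # slow: kept
        tcs[:, 1] = np.sin(2 * np.pi * 0.15 * t * 3.0)  # fast: flagged
        flagged = gica.flag_artifact_components(
            model, mask, mask_index, timecourses=tcs, TR_s=3.0
        )
        assert 1 in flagged and 0 not in flagged
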