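"""Base assembly, component matching, group-level dynamics, evaluation."""
import numpy as np
import pandas as pd
import pytest

from swdl.framework import (EvalReport, aggregate_reports, assemble_bases,
                            evaluate_recovery, group_rest_average,
                            group_task_svd, make_mhr, match_components)
from swdl.hrf import CANONICAL_HRF, hrf_kernel
from swdl.synthgen import GroundTruth


class _Fake:
    """Minimal component carrier (D: N x K, X: K x V)."""

    def __init__(self, D, X):
        self.D, self.X = D, X


class TestAssembleBases:
    def test_block_shapes_and_order(self, default_bases):
        results, bases = default_bases
        assert bases.D_q.shape == (300, 36)
        assert bases.X_q.shape == (36, 2500)
        # column 10 of D_q (index 9) is column 1 (index 0) of subject 2
        np.testing.assert_array_equal(bases.D_q[:, 9], results[1].T[:, 0])
        np.testing.assert_array_equal(bases.X_q[9], results[1].S[0])

    def test_single_subject_passthrough(self, default_bases):
        results, _ = default_bases
        b1 = assemble_bases(results[:1])
        np.testing.assert_array_equal(b1.D_q, results[0].T)
        np.testing.assert_array_equal(b1.X_q, results[0].S)

    def test_block_index_bijection(self, default_bases):
        results, bases = default_bases
        P = 9
        for m in range(4):
            blk = bases.block(m, P)
            np.testing.assert_array_equal(bases.D_q[:, blk], results[m].T)
            assert bases.provenance[blk] == [m] * P


class TestMakeMhr:
    def test_single_block_matches_direct_convolution(self):
        ev = pd.DataFrame(
            {"onset": [0.0], "duration": [12.0], "condition": ["task"]}
        )
        col = make_mhr(ev, 60, 1.0)[:, 0]
        box = np.zeros(60)
        box[:12] = 1.0
        kern = hrf_kernel(CANONICAL_HRF, 1.0)
        oracle = np.array(
            [sum(box[t - i] * kern[i] for i in range(min(t + 1, kern.size)))
             for t in range(60)]
        )
        np.testing.assert_allclose(col, oracle, atol=1e-10)

    def test_condition_without_events_gives_zero_column(self):
        ev = pd.DataFrame({"onset": [5.0], "duration": [3.0],
                           "condition": ["a"]})
        M = make_mhr(ev, 40, 1.0, conditions=["a", "b"])
        assert M.shape == (40, 2)
        assert np.allclose(M[:, 1], 0.0)

    def test_one_column_per_condition(self):
        ev = pd.DataFrame(
            {
                "onset": [0.0, 30.0, 60.0, 90.0, 120.0, 150.0],
                "duration": [12.0] * 6,
                "condition": list("abcdef"),
            }
        )
        assert make_mhr(ev, 200, 1.0).shape == (200, 6)

    def test_unknown_condition_rejected(self):
        ev = pd.DataFrame({"onset": [0.0], "duration": [1.0],
                           "condition": ["x"]})
        with pytest.raises(ValueError, match="unknown"):
            make_mhr(ev, 20, 1.0, conditions=["a"])


class TestMatchComponents:
    def test_exact_match(self):
        rng = np.random.default_rng(0)
        cands = rng.standard_normal((5, 100))
        idx, vals = match_components(cands, cands[[3]])
        assert idx[0] == 3
        assert vals[0] == pytest.approx(1.0, abs=1e-12)

    def test_sign_invariance(self):
        rng = np.random.default_rng(1)
        cands = rng.standard_normal((4, 80))
        idx, vals = match_components(cands, -cands[[2]])
        assert idx[0] == 2
        assert vals[0] == pytest.approx(1.0, abs=1e-12)

    def test_null_correlation_is_small(self):
        rng = np.random.default_rng(2)
        cands, _ = np.linalg.qr(rng.standard_normal((300, 10)))
        ref = rng.standard_normal((1, 300))
        _, vals = match_components(cands.T, ref)
        assert vals[0] < 0.5

    def test_zero_variance_candidate_scores_zero(self):
        cands = np.vstack([np.ones(50), np.arange(50.0)])
        _, vals = match_components(cands[:1], np.arange(50.0)[None])
        assert vals[0] == 0.0


class TestGroupTaskSvd:
    def test_single_subject_rank_one(self):
        rng = np.random.default_rng(3)
        d = rng.standard_normal((30, 1))
        d /= np.linalg.norm(d)
        x = rng.standard_normal((1, 70))
        gr = group_task_svd([_Fake(d, x)], mhr=d.copy())
        np.testing.assert_allclose(np.linalg.norm(gr.D_g[:, 0]), 1.0,
                                   atol=1e-12)
        np.testing.assert_allclose(np.outer(gr.D_g[:, 0], gr.X_g[0]),
                                   d @ x, atol=1e-10)

    def test_leading_triplet_matches_dense_svd(self):
        rng = np.random.default_rng(4)
        M = 4
        Ds = [rng.standard_normal((20, 3)) for _ in range(M)]
        Xs = [rng.standard_normal((3, 50)) for _ in range(M)]
        mhr = rng.standard_normal((20, 1))
        models = [_Fake(D / np.linalg.norm(D, axis=0), X)
                  for D, X in zip(Ds, Xs)]
        gr = group_task_svd(models, mhr)
        # oracle: dense SVD of the averaged matched outer products
        G = np.mean(
            [np.outer(m.D[:, gr.matches[i, 0]], m.X[gr.matches[i, 0]])
             for i, m in enumerate(models)],
            axis=0,
        )
        U, s, Vt = np.linalg.svd(G)
        approx = np.outer(gr.D_g[:, 0], gr.X_g[0])
        oracle = s[0] * np.outer(U[:, 0], Vt[0])
        assert abs(np.linalg.norm(G - approx) - np.linalg.norm(G - oracle)) \
            <= 1e-10

    def test_identical_subjects_return_shared_pair(self):
        rng = np.random.default_rng(5)
        d = rng.standard_normal((25, 1))
        d /= np.linalg.norm(d)
        x = rng.standard_normal((1, 40))
        models = [_Fake(d.copy(), x.copy()) for _ in range(3)]
        gr = group_task_svd(models, mhr=d.copy())
        np.testing.assert_allclose(np.abs(gr.D_g[:, 0]), np.abs(d[:, 0]),
                                   atol=1e-10)
        np.testing.assert_allclose(np.outer(gr.D_g[:, 0], gr.X_g[0]), d @ x,
                                   atol=1e-10)

    def test_sign_aligned_to_reference(self, default_fits, default_dataset):
        gr = group_task_svd(default_fits["swsdl"],
                            default_dataset.group_truth.tcs)
        refs = default_dataset.group_truth.tcs
        for r in range(refs.shape[1]):
            a = gr.D_g[:, r] - gr.D_g[:, r].mean()
            b = refs[:, r] - refs[:, r].mean()
            assert a @ b >= 0


class TestGroupRestAverage:
    def test_identical_rows(self):
        x = np.random.default_rng(6).standard_normal((1, 30))
        models = [_Fake(np.ones((10, 1)), x.copy()) for _ in range(4)]
        gr = group_rest_average(models, templates=np.abs(x))
        np.testing.assert_allclose(gr.X_g[0], np.abs(x[0]), atol=1e-12)

    def test_two_subject_hand_example(self):
        m1 = _Fake(np.ones((5, 1)), np.array([[1.0, -1.0]]))
        m2 = _Fake(np.ones((5, 1)), np.array([[3.0, 1.0]]))
        gr = group_rest_average([m1, m2], templates=np.array([[1.0, 0.5]]))
        np.testing.assert_allclose(gr.X_g[0], [2.0, 1.0], atol=1e-12)

    def test_nonnegative_output(self, default_fits, default_dataset):
        gr = group_rest_average(default_fits["swsdl"],
                                default_dataset.group_truth.sms)
        assert np.all(gr.X_g >= 0)
        assert gr.D_g is None


class TestEvaluateRecovery:
    def test_perfect_candidates(self):
        rng = np.random.default_rng(7)
        T = rng.standard_normal((50, 4))
        S = rng.standard_normal((4, 60))
        truth = GroundTruth(tcs=T, sms=S, sharing_labels=["x"] * 4)
        rep = evaluate_recovery(_Fake(T, S), truth)
        assert rep.mmctc == pytest.approx(1.0, abs=1e-12)
        assert rep.mmcsm == pytest.approx(1.0, abs=1e-12)

    def test_mean_of_two_sources(self):
        rep = EvalReport(
            ctc=np.array([[0.8, 0.6]]), csm=np.array([[0.8, 0.6]]),
            tc_indices=np.zeros((1, 2), int), sm_indices=np.zeros((1, 2), int),
        )
        assert rep.mctc[0] == pytest.approx(0.7)
        assert rep.mmctc == pytest.approx(0.7)

    def test_internal_mean_consistency(self, default_fits, default_dataset):
        rep = evaluate_recovery(default_fits["acsd"], default_dataset.truths)
        assert abs(rep.mmctc - rep.ctc.mean(axis=1).mean()) <= 1e-12
        assert abs(rep.mmcsm - rep.csm.mean(axis=1).mean()) <= 1e-12
        assert np.all((rep.ctc >= 0) & (rep.ctc <= 1))
        assert np.all((rep.csm >= 0) & (rep.csm <= 1))

    def test_dimension_mismatch_rejected(self):
        truth = GroundTruth(tcs=np.zeros((10, 2)), sms=np.zeros((2, 5)),
                            sharing_labels=["a", "b"])
        with pytest.raises(ValueError):
            evaluate_recovery(_Fake(np.zeros((8, 2)), np.zeros((2, 5))), truth)

    def test_aggregate_reports(self):
        reps = [
            EvalReport(ctc=np.array([[v]]), csm=np.array([[v]]),
                       tc_indices=np.zeros((1, 1), int),
                       sm_indices=np.zeros((1, 1), int))
            for v in (0.5, 0.7)
        ]
        agg = aggregate_reports(reps)
        assert agg["mmcTC"] == pytest.approx(0.6)
        assert agg["n_trials"] == 2
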