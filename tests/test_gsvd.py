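"""Standardization, concatenation, decomposition and component selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegnets.core import EEGRecording, make_montage
from eegnets.gsvd import (
    GroupMatrix,
    component_timecourses,
    concatenate_group,
    group_svd,
    match_topographies,
    pairwise_pcc,
    reproducibility_check,
    select_components,
    weight_fraction,
    zstandardize,
)


def _rec(data, subject="S1", condition="active", rate=256):
    return EEGRecording(data=data, rate=rate, montage=make_montage(),
                        subject_id=subject, condition=condition)


class TestZStandardize:
    def test_mean_zero_sd_one(self, rng):
        out = zstandardize(_rec(rng.standard_normal((64, 500)) * 3 + 2))
        assert np.abs(out.data.mean(axis=1)).max() < 1e-12
        assert np.abs(out.data.std(axis=1) - 1).max() < 1e-12

    @settings(max_examples=25, deadline=None)
    @given(a=st.floats(0.1, 100), b=st.floats(-50, 50))
    def test_affine_invariance(self, a, b):
        x = np.random.default_rng(7).standard_normal((64, 200))
        z1 = zstandardize(_rec(x)).data
        z2 = zstandardize(_rec(a * x + b)).data
        assert np.allclose(z1, z2, atol=1e-9)

    def test_flat_channel_rejected(self, rng):
        x = rng.standard_normal((64, 100))
        x[5] = 4.2
        with pytest.raises(ValueError, match="flat"):
            zstandardize(_rec(x))


class TestConcatenateGroup:
    def test_shape_and_blocks(self, rng):
        recs = [
            zstandardize(_rec(rng.standard_normal((64, 1000)), s, c))
            for s in ("S1", "S2") for c in ("active", "sham")
        ]
        G = concatenate_group(recs)
        assert G.B.shape == (4000, 64)
        spans = sorted(G.index_map.values())
        assert spans[0][0] == 0 and spans[-1][1] == 4000
        assert all(a[1] == b[0] for a, b in zip(spans, spans[1:]))

    def test_round_trip_blocks_bitwise(self, rng):
        recs = [
            zstandardize(_rec(rng.standard_normal((64, 300)), s, c))
            for s in ("S1", "S2") for c in ("active", "sham")
        ]
        G = concatenate_group(recs)
        for r in recs:
            assert np.array_equal(G.block(r.key), r.data.T)

    def test_active_sorts_before_sham(self, rng):
        recs = [
            zstandardize(_rec(rng.standard_normal((64, 100)), "S1", c))
            for c in ("sham", "active")
        ] + [zstandardize(_rec(rng.standard_normal((64, 100)), "S2", "active"))]
        G = concatenate_group(recs + [])
        keys = sorted(G.index_map, key=lambda k: G.index_map[k][0])
        assert keys == [("S1", "active"), ("S1", "sham"), ("S2", "active")]

    def test_mixed_rates_and_duplicates_rejected(self, rng):
        r1 = _rec(rng.standard_normal((64, 100)), "S1", "active", rate=256)
        r2 = _rec(rng.standard_normal((64, 100)), "S2", "active", rate=512)
        with pytest.raises(ValueError, match="rate"):
            concatenate_group([r1, r2])
        with pytest.raises(ValueError, match="duplicate"):
            concatenate_group([r1, r1])


class TestGroupSVD:
    def test_diagonal_case(self):
        B = np.zeros((100, 64))
        B[0, 0], B[1, 1], B[2, 2] = 3.0, 2.0, 1.0
        R = group_svd(GroupMatrix(B=B, index_map={("S1", "active"): (0, 100)}))
        assert np.allclose(R.S[:3], [3, 2, 1])
        assert np.allclose(R.S[3:], 0)

    def test_reconstruction_and_orthonormality(self, small_decomposition):
        G, R = small_decomposition
        assert np.abs(R.U.T @ R.U - np.eye(64)).max() < 1e-8
        assert np.abs(R.V.T @ R.V - np.eye(64)).max() < 1e-8
        recon = (R.U * R.S) @ R.V.T
        assert np.linalg.norm(recon - G.B) / np.linalg.norm(G.B) < 1e-8

    def test_parseval(self, small_decomposition):
        G, R = small_decomposition
        assert np.sum(R.S**2) == pytest.approx(np.linalg.norm(G.B) ** 2, rel=1e-10)

    def test_gram_route_matches_exact(self, rng):
        B = rng.standard_normal((5000, 64))
        G = GroupMatrix(B=B, index_map={("S1", "active"): (0, 5000)})
        Re = group_svd(G, method="exact")
        Rg = group_svd(G, method="gram")
        assert np.allclose(Re.S, Rg.S, rtol=1e-9)
        assert np.abs(np.abs(Re.V) - np.abs(Rg.V)).max() < 1e-7
        # sign convention makes the columns identical, not just up to sign
        assert np.abs(Re.V - Rg.V).max() < 1e-7

    def test_sign_convention(self, small_decomposition):
        _, R = small_decomposition
        idx = np.abs(R.V).argmax(axis=0)
        assert np.all(R.V[idx, np.arange(64)] > 0)

    def test_nonfinite_rejected(self):
        B = np.zeros((100, 64))
        B[1, 1] = np.inf
        with pytest.raises(ValueError):
            group_svd(GroupMatrix(B=B, index_map={("S1", "active"): (0, 100)}))


class TestSelection:
    def test_strict_cutoff(self):
        # with a 90% decay rule, weights at or below 10% of the top are dropped
        assert select_components(np.array([21500.0, 5000.0, 2150.0, 100.0])) == [0, 1]

    def test_equal_weights_all_retained(self):
        assert select_components(np.full(10, 3.0)) == list(range(10))

    def test_first_three_kept(self):
        assert select_components(np.array([100.0, 50.0, 10.01, 10.0, 1.0])) == [0, 1, 2]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_components(np.array([]))

    @settings(max_examples=30, deadline=None)
    @given(
        s=st.lists(st.floats(0.01, 1000), min_size=2, max_size=20),
        t1=st.floats(0.05, 0.95),
        t2=st.floats(0.05, 0.95),
    )
    def test_selection_monotone_in_threshold(self, s, t1, t2):
        S = np.sort(np.array(s))[::-1]
        lo, hi = sorted([t1, t2])
        assert set(select_components(S, lo)) <= set(select_components(S, hi))

    def test_weight_fraction(self):
        S = np.array([8.0, 2.0])
        assert weight_fraction(S, [0]) == pytest.approx(0.8)
        assert weight_fraction(S, [0, 1]) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            weight_fraction(S, [])


class TestTimecourses:
    def test_blocks_partition_u_columns(self, small_decomposition):
        G, R = small_decomposition
        sel = [0, 1, 2]
        tcs = component_timecourses(R, G, sel)
        keys = sorted(G.index_map, key=lambda k: G.index_map[k][0])
        stacked = np.vstack([tcs[k] for k in keys])
        assert np.array_equal(stacked, R.U[:, sel])

    def test_projection_identity(self, small_decomposition):
        """U column j equals B v_j / S_j."""
        G, R = small_decomposition
        j = 2
        u = (G.B @ R.V[:, j]) / R.S[j]
        assert np.allclose(u, R.U[:, j], atol=1e-8)

    def test_gram_route_timecourses_match(self, small_decomposition):
        G, R = small_decomposition
        Rg = group_svd(G, method="gram")
        t_exact = component_timecourses(R, G, [0, 1])
        t_gram = component_timecourses(Rg, G, [0, 1])
        for k in t_exact:
            assert np.allclose(t_exact[k], t_gram[k], atol=1e-6)

    def test_unknown_key_rejected(self, small_decomposition):
        G, R = small_decomposition
        tcs = component_timecourses(R, G, [0])
        assert ("nope", "active") not in tcs


class TestPairwisePCC:
    def test_orthogonal_vectors_uncorrelated(self):
        t = np.linspace(0, 1, 1000, endpoint=False)
        tc = np.column_stack([np.sin(2 * np.pi * 5 * t), np.cos(2 * np.pi * 5 * t)])
        pcc = pairwise_pcc({("S1", "active"): tc})
        assert abs(pcc.values[0, 1]) < 1e-10

    def test_diagonal_not_applicable(self, rng):
        pcc = pairwise_pcc({("S1", "active"): rng.standard_normal((100, 3))})
        assert np.all(np.isnan(np.diag(pcc.values)))
        off = pcc.values[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) <= 1)
        assert np.allclose(pcc.values, pcc.values.T, equal_nan=True)

    def test_zero_variance_rejected(self):
        tc = np.zeros((100, 2))
        with pytest.raises(ValueError):
            pairwise_pcc({("S1", "active"): tc})

    def test_selected_components_minimally_correlated(self, small_decomposition):
        G, R = small_decomposition
        tcs = component_timecourses(R, G, list(range(5)))
        assert pairwise_pcc(tcs).max_abs_offdiag < 0.07


class TestSignInvariance:
    def test_flip_leaves_reconstruction_and_pcc_unchanged(self, small_decomposition):
        G, R = small_decomposition
        V2, U2 = R.V.copy(), R.U.copy()
        V2[:, 3] *= -1
        U2[:, 3] *= -1
        recon = (U2 * R.S) @ V2.T
        assert np.linalg.norm(recon - G.B) / np.linalg.norm(G.B) < 1e-8
        tcs = component_timecourses(R, G, [2, 3])
        flipped = {k: v * np.array([1, -1]) for k, v in tcs.items()}
        a = np.abs(pairwise_pcc(tcs).values)
        b = np.abs(pairwise_pcc(flipped).values)
        assert np.allclose(a, b, equal_nan=True)


class TestReproducibility:
    def test_full_subset_gives_unity(self, small_group):
        sims = reproducibility_check(small_group, strategy="full", n_components=5)
        assert np.allclose(sims, 1.0, atol=1e-9)

    def test_random_half_recovers_topographies(self, small_group, small_networks):
        sims = reproducibility_check(small_group, strategy="random-half", seed=3,
                                     n_components=5)
        assert np.all(sims > 0.9)

    def test_sham_only_recovers_topographies(self, small_group):
        sims = reproducibility_check(small_group, strategy="sham-only", n_components=5)
        assert np.all(sims > 0.9)

    def test_baseline_only_runs(self, small_group):
        sims = reproducibility_check(small_group, strategy="baseline-only",
                                     n_components=5)
        assert np.all(sims > 0.8)

    def test_too_few_subjects_rejected(self, small_group):
        two = [r for r in small_group if r.subject_id in ("S1", "S2")]
        with pytest.raises(ValueError):
            reproducibility_check(two, strategy="random-half")


class TestMatchTopographies:
    def test_sign_and_permutation_invariant(self, rng):
        W = np.linalg.qr(rng.standard_normal((64, 4)))[0]
        shuffled = W[:, [2, 0, 3, 1]] * np.array([1, -1, 1, -1])
        assert np.allclose(match_topographies(W, shuffled), 1.0, atol=1e-12)
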