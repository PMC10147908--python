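"""Two-step clustering: distance algebra, pre-clustering, auto-k, silhouette."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from melanotype.twostep import (
    ClusterFeatureSpace,
    ClusterSummary,
    build_feature_space,
    fit_twostep,
    loglik_distance,
    precluster,
    search_feature_subset,
    silhouette_cohesion_separation,
)


def space_1d(var=1.0):
    return ClusterFeatureSpace(("x",), np.zeros(1), np.ones(1), np.array([var]))


def blobs(centers, n_per, sd=0.05, seed=0):
    rng = np.random.default_rng(seed)
    xs, labels = [], []
    for i, c in enumerate(centers):
        xs.append(rng.normal(loc=c, scale=sd, size=(n_per, len(c))))
        labels.append(np.full(n_per, i))
    return np.vstack(xs), np.concatenate(labels)


class TestLoglikDistance:
    def test_coincident_singletons_zero(self):
        space = space_1d()
        a = ClusterSummary.from_points([[0.3]])
        b = ClusterSummary.from_points([[0.3]])
        assert loglik_distance(a, b, space) == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_1d(self):
        """Singletons at 0 and 1 with global variance 1: merged ML variance
        is 0.25, so d = ln(1.25)."""
        space = space_1d(var=1.0)
        a = ClusterSummary.from_points([[0.0]])
        b = ClusterSummary.from_points([[1.0]])
        assert loglik_distance(a, b, space) == pytest.approx(np.log(1.25), abs=1e-12)

    def test_monotone_in_separation(self):
        space = space_1d()
        prev = -1.0
        for gap in np.linspace(0.1, 5, 25):
            d = loglik_distance(
                ClusterSummary.from_points([[0.0]]),
                ClusterSummary.from_points([[gap]]),
                space,
            )
            assert d > prev
            prev = d

    def test_symmetric_nonnegative(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(30, 3))
        space = build_feature_space(x, ("a", "b", "c"))
        z = space.transform(x)
        for _ in range(20):
            i, j = rng.integers(0, 10, 2)
            a = ClusterSummary.from_points(z[i * 3 : i * 3 + 3])
            b = ClusterSummary.from_points(z[j * 3 : j * 3 + 3])
            dij = loglik_distance(a, b, space)
            dji = loglik_distance(b, a, space)
            assert dij == pytest.approx(dji, abs=1e-12)
            assert dij >= -1e-12

    @settings(derandomize=True, max_examples=60)
    @given(
        a=st.floats(-50, 50),
        b=st.floats(-50, 50),
        var=st.floats(0.1, 10),
    )
    def test_singleton_distance_properties(self, a, b, var):
        """d is symmetric, non-negative, and zero only for coincident points."""
        space = space_1d(var=var)
        pa = ClusterSummary.from_points([[a]])
        pb = ClusterSummary.from_points([[b]])
        d = loglik_distance(pa, pb, space)
        assert d == pytest.approx(loglik_distance(pb, pa, space), abs=1e-12)
        assert d >= 0
        if a == b:
            assert d == pytest.approx(0.0, abs=1e-12)
        # closed form for two singletons: merged ML variance is (a-b)²/4
        expected = np.log(var + (a - b) ** 2 / 4) - np.log(var)
        assert d == pytest.approx(expected, abs=1e-9)

    def test_empty_cluster_rejected(self):
        space = space_1d()
        empty = ClusterSummary(0.0, np.zeros(1), np.zeros(1))
        with pytest.raises(ValueError):
            loglik_distance(empty, ClusterSummary.from_points([[0.0]]), space)

    def test_merge_invariance(self):
        """Distance from merged sufficient statistics equals distance from
        the concatenated raw members (1e-9)."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=(40, 2))
        space = build_feature_space(x, ("a", "b"))
        z = space.transform(x)
        a = ClusterSummary.from_points(z[:10])
        b = ClusterSummary.from_points(z[10:25])
        merged = a.merge(b)
        direct = ClusterSummary.from_points(z[:25])
        c = ClusterSummary.from_points(z[25:])
        assert loglik_distance(merged, c, space) == pytest.approx(
            loglik_distance(direct, c, space), abs=1e-9
        )


class TestPrecluster:
    def test_bypass_gives_singletons(self):
        x = np.random.default_rng(0).normal(size=(10, 2))
        space = build_feature_space(x, ("a", "b"))
        n, s, q, member = precluster(space.transform(x), space, bypass_n=5000)
        assert len(n) == 10 and (n == 1).all()
        assert np.array_equal(member, np.arange(10))

    def test_blob_purity(self):
        """Forced pre-clustering on three tight separated blobs yields
        subclusters pure with respect to their blob."""
        x, truth = blobs([(0, 0), (10, 0), (0, 10)], 2000, sd=0.1, seed=4)
        space = build_feature_space(x, ("a", "b"))
        n, s, q, member = precluster(
            space.transform(x), space, max_leaf_entries=128, bypass_n=0
        )
        assert n.sum() == len(x)
        for sub in range(len(n)):
            owners = np.unique(truth[member == sub])
            assert len(owners) == 1

    def test_deterministic(self):
        x = np.random.default_rng(3).normal(size=(8000, 2))
        space = build_feature_space(x, ("a", "b"))
        z = space.transform(x)
        r1 = precluster(z, space, bypass_n=0, max_leaf_entries=64)
        r2 = precluster(z, space, bypass_n=0, max_leaf_entries=64)
        for a, b in zip(r1, r2):
            assert np.array_equal(a, b)

    def test_membership_stats_consistent(self):
        x = np.random.default_rng(7).normal(size=(3000, 2))
        space = build_feature_space(x, ("a", "b"))
        z = space.transform(x)
        n, s, q, member = precluster(z, space, bypass_n=0, max_leaf_entries=64)
        counts = np.bincount(member, minlength=len(n))
        assert np.array_equal(counts, n.astype(int))
        for sub in (0, len(n) // 2):
            assert np.allclose(z[member == sub].sum(axis=0), s[sub], atol=1e-8)


class TestModelSelection:
    @pytest.mark.parametrize("k_true", [2, 3, 4])
    def test_recovers_separated_blobs(self, k_true):
        centers = [(i * 8.0, (i % 2) * 8.0) for i in range(k_true)]
        x, truth = blobs(centers, 800, sd=0.5, seed=k_true)
        df = pd.DataFrame(x, columns=["a", "b"])
        model = fit_twostep(df, ("a", "b"), seed=1)
        assert model.k == k_true
        # assignments are a relabeling of the truth
        for lab in range(k_true):
            assert len(np.unique(model.assignments[truth == lab])) == 1

    def test_bic_trace_shape(self):
        x, _ = blobs([(0, 0), (6, 0)], 500, sd=0.4, seed=1)
        model = fit_twostep(pd.DataFrame(x, columns=["a", "b"]), ("a", "b"), seed=0)
        assert len(model.bic) == 6
        assert np.isfinite(model.bic).all()
        assert (model.sizes.sum()) == len(x)

    def test_single_record_k1(self):
        df = pd.DataFrame({"a": [1.0, 1.1, 0.9]})
        model = fit_twostep(df, ("a",), seed=0)
        assert model.k >= 1

    def test_seeded_determinism(self):
        x, _ = blobs([(0, 0), (5, 5)], 3000, sd=1.0, seed=9)
        df = pd.DataFrame(x, columns=["a", "b"])
        m1 = fit_twostep(df, ("a", "b"), seed=123, bypass_n=1000)
        m2 = fit_twostep(df, ("a", "b"), seed=123, bypass_n=1000)
        assert m1.k == m2.k
        assert np.array_equal(m1.assignments, m2.assignments)

    def test_zero_variance_feature_rejected(self):
        df = pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)})
        with pytest.raises(ValueError, match="zero variance"):
            fit_twostep(df, ("a", "b"), seed=0)


def brute_force_reference(x, features, jmax=6, seed=0):
    """Independent re-implementation: greedy agglomeration over raw records
    with full distance rescans (no pre-clustering, no neighbour caching)."""
    from melanotype.twostep import _assign_records, _choose_k, _xi

    space = build_feature_space(x, features)
    z = space.transform(x)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(z))
    zs = z[order]
    n = np.ones(len(zs))
    s = zs.copy()
    q = zs**2
    g = space.g
    active = list(range(len(zs)))
    xi = _xi(n, s, q, g)
    merge_dists, snaps = {}, {}
    while len(active) > 1:
        # full rescan of every pair at every step (no caching)
        idx = np.array(active)
        best = None
        for pos, i in enumerate(active[:-1]):
            others = idx[pos + 1 :]
            nm = n[i] + n[others]
            sm = s[i] + s[others]
            qm = q[i] + q[others]
            var = np.clip(qm / nm[:, None] - (sm / nm[:, None]) ** 2, 0, None)
            xim = -nm * 0.5 * np.log(g + var).sum(axis=1)
            d = xi[i] + xi[others] - xim
            jj = int(np.argmin(d))
            if best is None or d[jj] < best[0]:
                best = (float(d[jj]), i, int(others[jj]))
        d, i, j = best
        n[i] += n[j]
        s[i] += s[j]
        q[i] += q[j]
        xi[i] = _xi(n[i : i + 1], s[i : i + 1], q[i : i + 1], g)[0]
        active.remove(j)
        merge_dists[len(active) + 1] = d
        if len(active) <= jmax:
            snaps[len(active)] = {
                "n": n[active].copy(),
                "s": s[active].copy(),
                "q": q[active].copy(),
                "sum_xi": float(xi[active].sum()),
            }
    bic = np.full(jmax, np.nan)
    for jc, snap in snaps.items():
        bic[jc - 1] = -2 * snap["sum_xi"] + 2 * z.shape[1] * jc * np.log(len(z))
    k = _choose_k(bic, merge_dists, jmax, available=max(snaps))
    assign = _assign_records(zs, snaps[k], space)
    out = np.empty(len(z), dtype=int)
    out[order] = assign
    return k, out, bic


class TestOracleEquivalence:
    def test_pipeline_matches_brute_force(self):
        """Full pipeline output (k and assignments) equals an independent
        brute-force agglomeration on a small mixture."""
        x, _ = blobs([(0, 0), (4, 1), (1, 5)], 120, sd=0.6, seed=6)
        df = pd.DataFrame(x, columns=["a", "b"])
        model = fit_twostep(df, ("a", "b"), seed=11)
        k_ref, assign_ref, bic_ref = brute_force_reference(x, ("a", "b"), seed=11)
        assert model.k == k_ref
        assert np.array_equal(model.assignments, assign_ref)
        assert np.allclose(model.bic, bic_ref, atol=1e-6)

    def test_silhouette_matches_direct_recomputation(self):
        """Centroid silhouette equals a per-object double-loop recomputation
        of the same formula to 1e-12."""
        x, truth = blobs([(0, 0), (3, 0)], 5000, sd=1.0, seed=8)
        space = build_feature_space(x, ("a", "b"))
        z = space.transform(x)
        val = silhouette_cohesion_separation(z, truth)
        cents = [z[truth == c].mean(axis=0) for c in (0, 1)]
        s_vals = []
        for i in range(len(z)):
            dists = [np.sqrt(((z[i] - c) ** 2).sum()) for c in cents]
            a = dists[truth[i]]
            b = min(d for j, d in enumerate(dists) if j != truth[i])
            s_vals.append((b - a) / max(a, b))
        assert val == pytest.approx(np.mean(s_vals), abs=1e-12)


class TestSilhouette:
    def test_point_masses_one(self):
        z = np.array([[0.0, 0.0]] * 5 + [[3.0, 3.0]] * 5)
        labels = np.array([0] * 5 + [1] * 5)
        assert silhouette_cohesion_separation(z, labels) == pytest.approx(1.0)

    def test_equidistant_zero(self):
        z = np.array([[0.0], [1.0], [0.0], [1.0]])
        labels = np.array([0, 0, 1, 1])  # both centroids at 0.5
        assert silhouette_cohesion_separation(z, labels) == pytest.approx(0.0)

    def test_single_cluster_nan_with_warning(self):
        z = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.warns(UserWarning, match="silhouette"):
            out = silhouette_cohesion_separation(z, np.zeros(10, dtype=int))
        assert np.isnan(out)


class TestSubsetSearch:
    def test_informative_feature_beats_structureless_noise(self):
        """With one bimodal feature and structureless Gaussian noise
        features, the search selects the informative feature."""
        rng = np.random.default_rng(21)
        n = 1200
        informative = np.concatenate(
            [rng.normal(-3, 0.4, n // 2), rng.normal(3, 0.4, n // 2)]
        )
        df = pd.DataFrame(
            {
                "signal": rng.permutation(informative),
                "noise1": rng.normal(size=n),
                "noise2": rng.normal(size=n),
            }
        )
        best, models, sils = search_feature_subset(
            df, ("signal", "noise1", "noise2"), seed=2
        )
        assert best == ("signal",)
        assert len(models) == 7
        assert sils[("signal",)] > 0.8

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            search_feature_subset(pd.DataFrame({"a": [1.0, 2.0]}), (), seed=0)

    def test_report_covers_all_subsets(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(300, 2)), columns=["a", "b"])
        df["a"] = np.concatenate([rng.normal(-4, 0.3, 150), rng.normal(4, 0.3, 150)])
        best, models, sils = search_feature_subset(df, ("a", "b"), seed=0)
        assert set(models) == {("a",), ("b",), ("a", "b")}
        assert best == ("a",)
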