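import numpy as np
import pytest
from scipy.spatial.distance import chebyshev

from sglife.clustering import (
    TIMECOURSE_LABELS,
    TIMECOURSE_MINUTES,
    TemporalProfile,
    assign_early_late,
    fit_sigmoid,
    hierarchical_cluster,
    logistic4,
    pca_loadings,
    zscore_profiles,
)

from conftest import make_matrix


def _profiles_from(zmat, prefix="P"):
    return [
        TemporalProfile(f"{prefix}{i:03d}", TIMECOURSE_LABELS, np.asarray(row, float))
        for i, row in enumerate(zmat)
    ]


def _two_template_profiles(n_per=30, noise_sd=0.2, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(9, dtype=float)
    dec = (t.max() - t) / t.std() - ((t.max() - t) / t.std()).mean()
    inc = -dec
    rows, truth = [], []
    for i in range(2 * n_per):
        template = dec if i < n_per else inc
        rows.append(template + rng.normal(0, noise_sd, 9))
        truth.append("dec" if i < n_per else "inc")
    return _profiles_from(rows), truth


class TestZScore:
    def test_three_point_row_uses_sample_sd(self):
        # log2 means (1,2,3): sample sd (ddof=1) is exactly 1 -> z = (-1, 0, 1)
        prof = np.tile([1.0, 2.0, 3.0], (1, 1))
        m = make_matrix(prof, labels=["HS0", "HS10", "HS20"], replicates=2)
        out = zscore_profiles(m, labels=("HS0", "HS10", "HS20"))
        assert np.allclose(out[0].z, [-1.0, 0.0, 1.0], atol=1e-9)

    def test_constant_row_flagged_zero(self):
        prof = np.tile([[5.0] * 9], (1, 1))
        m = make_matrix(prof)
        out = zscore_profiles(m)
        assert out[0].degenerate and np.allclose(out[0].z, 0.0)

    def test_rows_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.normal(20, 1, size=(20, 9)), seed=4)
        for p in zscore_profiles(m):
            assert abs(p.z.mean()) < 1e-9
            assert abs(p.z.std(ddof=1) - 1) < 1e-9


class TestHierarchicalCluster:
    def test_chebyshev_metric_definition(self):
        assert chebyshev([0, 0], [3, 4]) == 4.0

    def test_planted_two_templates_recovered_exactly(self):
        profiles, truth = _two_template_profiles()
        _, labels = hierarchical_cluster(profiles, k=2)
        split = {}
        for p, t in zip(profiles, truth):
            split.setdefault(t, set()).add(labels[p.protein])
        # each template maps to exactly one cluster, and they differ
        assert all(len(v) == 1 for v in split.values())
        assert split["dec"] != split["inc"]

    def test_invariant_to_input_order(self):
        profiles, _ = _two_template_profiles(seed=1)
        _, labels_a = hierarchical_cluster(profiles, k=2)
        rng = np.random.default_rng(2)
        shuffled = list(profiles)
        rng.shuffle(shuffled)
        _, labels_b = hierarchical_cluster(shuffled, k=2)
        # cluster ids may swap; membership partition must be identical
        part_a = {}
        part_b = {}
        for acc in labels_a:
            part_a.setdefault(labels_a[acc], set()).add(acc)
            part_b.setdefault(labels_b[acc], set()).add(acc)
        assert {frozenset(s) for s in part_a.values()} == {frozenset(s) for s in part_b.values()}

    def test_k_exceeding_n_errors(self):
        profiles, _ = _two_template_profiles(n_per=2)
        with pytest.raises(ValueError):
            hierarchical_cluster(profiles, k=10)


class TestPCALoadings:
    def test_antiphase_templates_split_by_sign(self):
        profiles, truth = _two_template_profiles(noise_sd=0.15, seed=3)
        df, evr = pca_loadings(profiles)
        dec_load = [df.loc[p.protein, "PC1"] for p, t in zip(profiles, truth) if t == "dec"]
        inc_load = [df.loc[p.protein, "PC1"] for p, t in zip(profiles, truth) if t == "inc"]
        assert (np.sign(np.mean(dec_load)) != np.sign(np.mean(inc_load)))
        assert min(np.abs(np.mean(dec_load)), np.abs(np.mean(inc_load))) > 0.5
        assert evr[0] > 0.5
        # decreasing-in-time templates take the positive sign by convention
        assert np.mean(dec_load) > 0

    def test_duplicated_profile_has_no_variance(self):
        row = np.linspace(-1, 1, 9)
        profiles = _profiles_from(np.tile(row, (5, 1)))
        df, evr = pca_loadings(profiles)
        assert np.allclose(evr, 0.0, atol=1e-12)

    def test_order_invariance_up_to_global_sign(self):
        profiles, _ = _two_template_profiles(seed=5)
        df_a, _ = pca_loadings(profiles)
        perm = list(reversed(profiles))
        df_b, _ = pca_loadings(perm)
        a = df_a.sort_index()["PC1"].to_numpy()
        b = df_b.sort_index()["PC1"].to_numpy()
        assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)


class TestAssignEarlyLate:
    def test_rule_on_constructed_clusters(self):
        profiles, truth = _two_template_profiles(seed=6)
        labels = {p.protein: (1 if t == "dec" else 2) for p, t in zip(profiles, truth)}
        assignments, warnings = assign_early_late(labels, profiles)
        assert not warnings
        for a, (p, t) in zip(sorted(assignments, key=lambda x: x.protein),
                             sorted(zip(profiles, truth), key=lambda x: x[0].protein)):
            assert a.cluster == ("early" if t == "dec" else "late")

    def test_both_decreasing_warns_and_picks_steeper(self):
        t = np.arange(9, dtype=float)
        steep = -2.0 * (t - t.mean()) / t.std()
        shallow = -0.5 * (t - t.mean()) / t.std()
        profiles = _profiles_from([steep] * 3 + [shallow] * 3)
        labels = {p.protein: (1 if i < 3 else 2) for i, p in enumerate(profiles)}
        assignments, warnings = assign_early_late(labels, profiles)
        assert warnings
        steep_cluster = {a.cluster for a in assignments if a.protein in
                         {p.protein for p in profiles[:3]}}
        assert steep_cluster == {"early"}

    def test_relabeling_clusters_keeps_assignment(self):
        profiles, truth = _two_template_profiles(seed=7)
        labels1 = {p.protein: (1 if t == "dec" else 2) for p, t in zip(profiles, truth)}
        labels2 = {p.protein: (9 if t == "dec" else 4) for p, t in zip(profiles, truth)}
        a1, _ = assign_early_late(labels1, profiles)
        a2, _ = assign_early_late(labels2, profiles)
        assert [(a.protein, a.cluster) for a in a1] == [(a.protein, a.cluster) for a in a2]

    def test_exact_tie_errors(self):
        row_up = np.array([0, 1, 0, 0, 0, 0, 0, 0, 0], dtype=float)
        profiles = _profiles_from([row_up, row_up.copy()])
        labels = {profiles[0].protein: 1, profiles[1].protein: 2}
        with pytest.raises(ValueError, match="tie|identical"):
            assign_early_late(labels, profiles)


class TestFitSigmoid:
    def test_noiseless_generative_identity(self):
        t = np.array([0.0, 10, 20, 30, 60, 120, 180])
        v = logistic4(t, lower=-1.0, upper=1.0, t0=25.0, slope=-0.2)
        fit = fit_sigmoid(t, v)
        assert fit.converged
        assert fit.t0 == pytest.approx(25.0, abs=1e-3)
        assert fit.direction == "decreasing"

    def test_flat_input_degenerate(self):
        t = np.array([0.0, 10, 20, 30])
        fit = fit_sigmoid(t, np.full(4, 2.0))
        assert not fit.converged or abs(fit.upper - fit.lower) < 1e-6

    def test_noisy_group_average_recovers_inflection(self):
        rng = np.random.default_rng(11)
        t = np.asarray(TIMECOURSE_MINUTES)
        template = logistic4(t, 1.0, -1.0, 21.0, 0.15)
        profiles = template[None, :] + rng.normal(0, 0.2, size=(200, t.size))
        fit = fit_sigmoid(t, profiles.mean(axis=0))
        assert abs(fit.t0 - 21.0) <= 3.0

    def test_strictly_increasing_times_required(self):
        with pytest.raises(ValueError):
            fit_sigmoid([0, 10, 10, 30], [1, 2, 3, 4])
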