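"""Discovery subset, PAM, prediction strength, genotyping and profiling."""

import numpy as np
import pandas as pd
import pytest

from subspec.dissimilarity import DistMatrix, pairwise_dissimilarity
from subspec.snv_core import to_freq_matrix, FilterParams
from subspec.subpop import (
    ClusterResult,
    DiscoveryParams,
    GenotypeParams,
    InsufficientDiscoverySamplesError,
    _ps_from_labels,
    choose_k,
    genotype_alleles,
    pam_cluster,
    prediction_strength,
    profile_subspecies,
    select_discovery_subset,
)
from subspec.synth import SimConfig, simulate_dataset

from conftest import random_freq_matrix


def two_tight_groups(n_per=10, within=0.01, between=0.9):
    n = 2 * n_per
    d = np.full((n, n), between)
    d[:n_per, :n_per] = within
    d[n_per:, n_per:] = within
    np.fill_diagonal(d, 0.0)
    return d


def as_dist(d, ids=None):
    n = d.shape[0]
    ids = ids or [f"s{i}" for i in range(n)]
    ns = np.full((n, n), 10_000)
    return DistMatrix(ids, d, ns, min_shared=1)


# ---------------------------------------------------------------------------
# discovery subset
# ---------------------------------------------------------------------------

def test_discovery_includes_mostly_fixed_sample():
    # 85% of observed SNVs near-fixed -> included
    f = np.full(100, 0.5)
    f[:85] = 0.97
    fm = pd.DataFrame({"a": f, "b": np.full(100, 0.5)})
    res = select_discovery_subset(fm, DiscoveryParams())
    assert res.scores.loc["a", "phaseability"] == pytest.approx(0.85)
    assert res.subset == ["a"]
    # maximally mixed population: phaseability 0, excluded
    assert res.scores.loc["b", "phaseability"] == 0.0


def test_discovery_boundary_is_inclusive_on_fraction():
    # exactly 80% of SNVs phaseable -> included (>= comparison)
    f = np.concatenate([np.full(80, 0.95), np.full(20, 0.5)])
    fm = pd.DataFrame({"a": f})
    res = select_discovery_subset(fm, DiscoveryParams())
    assert res.scores.loc["a", "phaseability"] == pytest.approx(0.8)
    assert res.subset == ["a"]


def test_discovery_major_allele_rule_is_strict():
    # major allele fraction exactly 0.9 does NOT satisfy "over 90%"
    fm = pd.DataFrame({"a": np.full(50, 0.9)})
    res = select_discovery_subset(fm, DiscoveryParams())
    assert res.scores.loc["a", "phaseability"] == 0.0
    assert res.empty


def test_discovery_requires_snv_coverage():
    f = np.full(100, 0.98)
    f[30:] = np.nan  # only 30% of dataset-wide SNVs observed
    fm = pd.DataFrame({"a": f})
    res = select_discovery_subset(fm, DiscoveryParams())
    assert res.scores.loc["a", "snv_coverage_fraction"] == pytest.approx(0.3)
    assert not res.scores.loc["a", "included"]


def test_discovery_matches_brute_force(rng):
    dp = DiscoveryParams()
    for _ in range(10):
        fm = random_freq_matrix(rng, n_snvs=40, n_samples=6, missing_rate=0.3)
        res = select_discovery_subset(fm, dp)
        for s in fm.columns:
            obs = [v for v in fm[s] if not np.isnan(v)]
            phase = (
                sum(1 for v in obs if max(v, 1 - v) > dp.major_freq_threshold)
                / len(obs) if obs else 0.0
            )
            included = (
                phase >= dp.phaseable_snv_fraction
                and len(obs) / fm.shape[0] >= dp.min_snv_coverage_fraction
            )
            assert res.scores.loc[s, "phaseability"] == pytest.approx(phase)
            assert bool(res.scores.loc[s, "included"]) == included


# ---------------------------------------------------------------------------
# PAM
# ---------------------------------------------------------------------------

def test_pam_recovers_tight_groups():
    d = two_tight_groups()
    medoids, labels = pam_cluster(d, 2)
    assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
    assert labels[0] != labels[10]


def test_pam_is_deterministic_and_equivariant(rng):
    d = rng.random((12, 12))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    m1, l1 = pam_cluster(d, 3)
    m2, l2 = pam_cluster(d, 3)
    np.testing.assert_array_equal(m1, m2)
    np.testing.assert_array_equal(l1, l2)
    # permuting samples permutes the partition identically
    perm = rng.permutation(12)
    _, lp = pam_cluster(d[np.ix_(perm, perm)], 3)
    for i in range(12):
        for j in range(12):
            assert (lp[i] == lp[j]) == (l1[perm[i]] == l1[perm[j]])


def test_pam_k_equals_n_and_k_one():
    d = two_tight_groups(3)
    _, labels1 = pam_cluster(d, 1)
    assert set(labels1) == {0}
    medoids, labels = pam_cluster(d, 6)
    assert sorted(medoids) == list(range(6))


# ---------------------------------------------------------------------------
# prediction strength
# ---------------------------------------------------------------------------

def test_ps_k1_is_one_by_definition():
    est = prediction_strength(as_dist(two_tight_groups()), 1, seed=0)
    assert est.mean == 1.0 and est.sd == 0.0


def test_ps_two_tight_groups_is_perfect():
    est = prediction_strength(as_dist(two_tight_groups()), 2,
                              n_iterations=50, seed=3)
    assert (est.values == 1.0).all()


def test_ps_oversplitting_tight_groups_scores_low():
    # jitter within-group distances so oversplitting yields real (non-
    # singleton) subgroups whose co-membership is not reproducible
    rng = np.random.default_rng(5)
    d = two_tight_groups(n_per=12)
    noise = rng.uniform(0, 0.005, d.shape)
    d = d + (noise + noise.T)
    np.fill_diagonal(d, 0.0)
    est = prediction_strength(as_dist(d), 4, n_iterations=50, seed=3)
    assert est.mean_informative < 0.8


def test_ps_uniform_groups_oversplit_is_all_degenerate():
    # with exactly uniform within-group distances the extra clusters are
    # singletons: every iteration is flagged, conventional score 1
    est = prediction_strength(as_dist(two_tight_groups()), 4,
                              n_iterations=20, seed=3)
    assert est.n_degenerate == 20
    assert np.isnan(est.mean_informative)


def test_ps_k_bound_error():
    with pytest.raises(ValueError, match="floor"):
        prediction_strength(as_dist(two_tight_groups(3)), 4, seed=0)


def test_ps_invariant_to_cluster_relabeling(rng):
    test_labels = rng.integers(0, 3, size=12)
    assigned = rng.integers(0, 3, size=12)
    ps, _ = _ps_from_labels(test_labels, assigned, 3)
    relabel = np.array([2, 0, 1])
    ps2, _ = _ps_from_labels(relabel[test_labels], assigned, 3)
    ps3, _ = _ps_from_labels(test_labels, relabel[assigned], 3)
    assert ps == ps2 == ps3


def test_ps_degenerate_singleton_flagged():
    # 2 clusters where one test cluster will often be tiny
    labels = np.array([0, 0, 0, 1])
    assigned = np.array([0, 0, 1, 1])
    ps, degenerate = _ps_from_labels(labels, assigned, 2)
    assert degenerate  # cluster 1 is a singleton
    assert ps == pytest.approx(1 / 3)  # cluster 0: 1 of 3 pairs co-assigned


# ---------------------------------------------------------------------------
# choose_k
# ---------------------------------------------------------------------------

def test_choose_k_guards_small_subsets():
    d = two_tight_groups(9)  # 18 samples < 20
    with pytest.raises(InsufficientDiscoverySamplesError):
        choose_k(as_dist(d), min_discovery_size=20)


def test_choose_k_no_structure_returns_one():
    n = 24
    d = np.full((n, n), 0.5)
    np.fill_diagonal(d, 0.0)
    cr = choose_k(as_dist(d), k_max=5, n_iterations=30, seed=0)
    assert cr.k_selected == 1
    assert (cr.sample_stability == 1.0).all()


def test_choose_k_recovers_three_groups_with_stability():
    n_per = 8
    rng = np.random.default_rng(0)
    n = 3 * n_per
    d = np.full((n, n), 0.8) + rng.normal(0, 0.01, (n, n))
    for g in range(3):
        sl = slice(g * n_per, (g + 1) * n_per)
        d[sl, sl] = 0.02
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    cr = choose_k(as_dist(np.clip(d, 0, 1)), k_max=6, n_iterations=50, seed=1)
    assert cr.k_selected == 3
    sizes = cr.assignments.value_counts()
    assert sorted(sizes) == [8, 8, 8]
    assert (cr.sample_stability > 0.9).all()
    assert set(cr.ps_per_k.columns) >= {"k", "mean_ps", "sd_ps", "n_degenerate"}


def test_choose_k_reproducible_given_seed():
    d = two_tight_groups(12)
    cr1 = choose_k(as_dist(d), n_iterations=20, seed=7)
    cr2 = choose_k(as_dist(d), n_iterations=20, seed=7)
    assert cr1.k_selected == cr2.k_selected
    pd.testing.assert_frame_equal(cr1.ps_per_k, cr2.ps_per_k)
    pd.testing.assert_series_equal(cr1.sample_stability, cr2.sample_stability)


# ---------------------------------------------------------------------------
# genotyping alleles
# ---------------------------------------------------------------------------

def _cluster_result(assignments: dict) -> ClusterResult:
    s = pd.Series(assignments, name="cluster")
    return ClusterResult(
        k_selected=len(set(assignments.values())),
        assignments=s,
        ps_per_k=pd.DataFrame(),
        sample_stability=pd.Series(1.0, index=s.index),
        ps_threshold=0.8, n_iterations=0, seed=0, medoids=[],
    )


def make_fm(rows, samples):
    return pd.DataFrame(
        rows, index=[f"c1:{i + 1}:A>T" for i in range(len(rows))], columns=samples
    )


def test_genotype_marker_rules():
    samples = ["a1", "a2", "a3", "b1", "b2", "b3"]
    cr = _cluster_result({s: 1 if s.startswith("a") else 2 for s in samples})
    fm = make_fm(
        [
            [0.95, 0.96, 0.94, 0.02, 0.01, 0.03],  # alt_high for cluster 1
            [0.5, 0.5, 0.5, 0.5, 0.5, 0.5],        # no marker
            [0.85, 0.86, 0.84, 0.25, 0.26, 0.24],  # outside median 0.25 > 0.2
            [0.03, 0.02, 0.01, 0.97, 0.98, 0.99],  # alt_low for 1 / alt_high for 2
        ],
        samples,
    )
    gs = genotype_alleles(fm, cr, GenotypeParams())
    m1 = gs.markers_for(1)
    assert ("c1:1:A>T", "alt_high") in list(zip(m1["snv_id"], m1["state"]))
    assert ("c1:4:A>T", "alt_low") in list(zip(m1["snv_id"], m1["state"]))
    assert "c1:2:A>T" not in set(gs.markers["snv_id"])
    assert "c1:3:A>T" not in set(gs.markers["snv_id"])
    # oriented frequencies satisfy the documented thresholds
    assert (gs.markers["within_freq"] >= 0.8).all()
    assert (gs.markers["outside_freq"] <= 0.2).all()


def test_genotype_max_markers_and_tie_break():
    samples = ["a1", "a2", "b1", "b2"]
    cr = _cluster_result({"a1": 1, "a2": 1, "b1": 2, "b2": 2})
    rows = [[1.0, 1.0, 0.0, 0.0]] * 6
    fm = make_fm(rows, samples)
    gs = genotype_alleles(fm, cr, GenotypeParams(max_markers=4))
    m1 = gs.markers_for(1)
    assert len(m1) == 4
    # identical margins -> lexicographic snv id order retained
    assert list(m1["snv_id"]) == sorted(m1["snv_id"])


def test_genotype_unprofilable_cluster_flagged():
    samples = ["a1", "a2", "b1", "b2", "c1", "c2"]
    cr = _cluster_result(
        {"a1": 1, "a2": 1, "b1": 2, "b2": 2, "c1": 3, "c2": 3}
    )
    # cluster 3 is intermediate everywhere -> no markers for it
    fm = make_fm([[1.0, 1.0, 0.0, 0.0, 0.5, 0.5]] * 3, samples)
    gs = genotype_alleles(fm, cr, GenotypeParams())
    assert 3 in gs.unprofilable_clusters


def test_genotype_requires_k_at_least_two():
    cr = _cluster_result({"a": 1, "b": 1})
    with pytest.raises(ValueError):
        genotype_alleles(make_fm([[0.5, 0.5]], ["a", "b"]), cr)


# ---------------------------------------------------------------------------
# profiling
# ---------------------------------------------------------------------------

def _marker_set():
    samples = ["a1", "a2", "b1", "b2"]
    cr = _cluster_result({"a1": 1, "a2": 1, "b1": 2, "b2": 2})
    rows = [[1.0, 1.0, 0.0, 0.0]] * 10
    fm = make_fm(rows, samples)
    return fm, genotype_alleles(fm, cr, GenotypeParams())


def test_profile_pure_sample_is_one_zero():
    fm, gs = _marker_set()
    prof = profile_subspecies(fm, gs, min_markers_observed=5)
    assert prof.raw.loc["a1", 1] == 1.0 and prof.raw.loc["a1", 2] == 0.0
    assert prof.normalized.loc["a1", 1] == 1.0


def test_profile_missing_below_min_markers():
    fm, gs = _marker_set()
    new = fm.copy()
    new.iloc[3:, :] = np.nan  # only 3 markers observed
    prof = profile_subspecies(new, gs, min_markers_observed=5)
    assert prof.raw.isna().all().all()


def test_profile_no_markers_present_is_unprofilable():
    fm, gs = _marker_set()
    alien = pd.DataFrame({"x": [0.5, 0.5]}, index=["cZ:1:A>T", "cZ:2:A>T"])
    prof = profile_subspecies(alien, gs)
    assert prof.unprofilable_samples == ["x"]
    assert prof.raw.isna().all().all()


def test_profile_mean_option_and_half_mixture():
    fm, gs = _marker_set()
    mix = pd.DataFrame({"m": np.full(10, 0.5)}, index=fm.index)
    for agg in ("median", "mean"):
        prof = profile_subspecies(mix, gs, agg=agg)
        assert prof.raw.loc["m", 1] == pytest.approx(0.5)
        assert prof.raw.loc["m", 2] == pytest.approx(0.5)
        assert prof.normalized.loc["m", 1] == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# end to end on simulated data
# ---------------------------------------------------------------------------

def test_simulated_three_subspecies_recovered_end_to_end():
    table, _, truth = simulate_dataset(SimConfig(k_true=3, seed=11))
    fm = to_freq_matrix(table, FilterParams())
    dm = pairwise_dissimilarity(fm, min_shared=50)
    disc = select_discovery_subset(fm)
    sub, _ = dm.restrict(disc.subset).drop_isolated()
    cr = choose_k(sub, seed=11)
    assert cr.k_selected == 3
    # assignments agree with truth up to label permutation
    ct = pd.crosstab(truth.cluster[cr.assignments.index], cr.assignments)
    assert (ct.gt(0).sum(axis=1) == 1).all()
    gs = genotype_alleles(fm, cr)
    assert not gs.unprofilable_clusters
    prof = profile_subspecies(fm, gs)
    # pure samples profile near 1 for their own cluster
    own = prof.raw.to_numpy().max(axis=1)
    assert np.nanmedian(own) > 0.9
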