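"""Subspecies detection and profiling from SNV profiles.

The method, in order:

1. **Discovery subset selection.**  For each species, keep the metagenomes
   whose within-sample population is quasi-phaseable: most dataset-wide SNVs
   have a clearly dominant allele in the sample, so the sample likely
   carries a single subspecies and its dominant alleles can be read off
   directly.
2. **Cluster-number selection.**  The discovery samples are clustered on
   their SNV-profile dissimilarities with medoid (PAM) clustering, and the
   number of clusters is chosen with the prediction-strength statistic of
   Tibshirani & Walther, estimated by repeated subsampling.  Confidence is
   reported both for the number of clusters (prediction strength per k) and
   for each sample's assignment (co-clustering stability across
   subsampling iterations).
3. **Genotyping alleles.**  SNV alleles near-fixed within one cluster and
   rare in all others are extracted as subspecies markers.
4. **Profiling.**  The marker alleles estimate each subspecies' relative
   abundance in any metagenome, including samples outside the discovery
   subset or from later studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dissimilarity import DistMatrix


class InsufficientDiscoverySamplesError(RuntimeError):
    """Discovery subset too small for confident clustering."""


# ---------------------------------------------------------------------------
# Discovery subset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscoveryParams:
    """Quasi-phaseability criterion parameters.

    A sample enters the discovery subset iff at least
    ``phaseable_snv_fraction`` of the dataset-wide SNVs it covers have a
    major allele above ``major_freq_threshold`` (strict: "in over 90% of
    reads"), and it covers at least ``min_snv_coverage_fraction`` of the
    dataset-wide SNVs at all.
    """

    major_freq_threshold: float = 0.9
    phaseable_snv_fraction: float = 0.8
    min_snv_coverage_fraction: float = 0.8

    def __post_init__(self) -> None:
        for v in (self.major_freq_threshold, self.phaseable_snv_fraction,
                  self.min_snv_coverage_fraction):
            if not 0.0 <= v <= 1.0:
                raise ValueError("DiscoveryParams fields must be in [0, 1]")


@dataclass
class DiscoveryResult:
    """Per-sample phaseability scores and inclusion decisions."""

    scores: pd.DataFrame  # columns: phaseability, snv_coverage_fraction, included

    @property
    def subset(self) -> list[str]:
        return list(self.scores.index[self.scores["included"]])

    @property
    def empty(self) -> bool:
        return not bool(self.scores["included"].any())


def select_discovery_subset(
    fm: pd.DataFrame, dp: DiscoveryParams | None = None
) -> DiscoveryResult:
    """Select quasi-phaseable metagenomes from a FreqMatrix.

    Phaseability of a sample = fraction of its observed (non-missing)
    dataset-wide SNVs whose major allele fraction max(f, 1-f) exceeds
    ``major_freq_threshold``.  A sample with no observed SNVs scores 0.
    """
    dp = dp or DiscoveryParams()
    if fm.shape[0] == 0:
        raise ValueError("empty frequency matrix")
    vals = fm.to_numpy(dtype=float)
    obs = ~np.isnan(vals)
    n_obs = obs.sum(axis=0)
    major = np.where(obs, np.maximum(vals, 1.0 - vals), 0.0) > dp.major_freq_threshold
    with np.errstate(invalid="ignore"):
        phase = np.where(n_obs > 0, (major & obs).sum(axis=0) / np.maximum(n_obs, 1), 0.0)
    cov_frac = n_obs / fm.shape[0]
    included = (phase >= dp.phaseable_snv_fraction) & (
        cov_frac >= dp.min_snv_coverage_fraction
    )
    scores = pd.DataFrame(
        {
            "phaseability": phase,
            "snv_coverage_fraction": cov_frac,
            "included": included,
        },
        index=fm.columns,
    )
    return DiscoveryResult(scores)


# ---------------------------------------------------------------------------
# Medoid (PAM) clustering
# ---------------------------------------------------------------------------

def pam_cluster(d: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic k-medoid clustering of a dissimilarity matrix.

    Initialization picks the most central point, then greedily the point
    farthest from the chosen medoids (maximally distant seeds); the swap
    phase then exchanges (medoid, non-medoid) pairs while total
    within-cluster dissimilarity strictly decreases.  All ties break to the
    lowest index, so the result is a pure function of ``d`` and ``k``.

    Returns (medoid indices sorted ascending, labels in 0..k-1 where label
    j means "nearest to the j-th sorted medoid").
    """
    n = d.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for n={n}")
    medoids = [int(np.argmin(d.sum(axis=0)))]
    while len(medoids) < k:
        near = d[:, medoids].min(axis=1)
        near[medoids] = -np.inf
        medoids.append(int(np.argmax(near)))
    medoids = sorted(medoids)

    eps = 1e-12
    while True:
        dm = d[:, medoids]  # (n, k)
        order = np.argsort(dm, axis=1, kind="stable")
        near_idx = order[:, 0]
        near = dm[np.arange(n), near_idx]
        second = dm[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        # delta_other[p, h]: cost change at p if h added and p's medoid kept
        delta_other = np.minimum(d - near[:, None], 0.0)
        # delta_own[p, h]: cost change at p if p's own medoid removed, h added
        delta_own = np.minimum(d, second[:, None]) - near[:, None]
        total_other = delta_other.sum(axis=0)
        best_delta, best_swap = -eps, None
        for mi in range(k):
            mask = near_idx == mi
            delta = total_other - delta_other[mask].sum(axis=0) + delta_own[mask].sum(axis=0)
            delta[medoids] = np.inf
            h = int(np.argmin(delta))
            if delta[h] < best_delta:
                best_delta, best_swap = float(delta[h]), (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        medoids[mi] = h
        medoids = sorted(medoids)

    labels = np.argmin(d[:, medoids], axis=1)
    return np.asarray(medoids), labels


# ---------------------------------------------------------------------------
# Prediction strength
# ---------------------------------------------------------------------------

def _ps_from_labels(
    test_labels: np.ndarray, train_assigned: np.ndarray, k: int
) -> tuple[float, bool]:
    """Prediction strength of one train/test split from the two labelings.

    For each test cluster with >= 2 members, the fraction of its member
    pairs that the train-derived classifier also co-assigns; the iteration
    score is the minimum over test clusters.  Test clusters with < 2
    members contribute 1 (degenerate; flagged via the returned bool).
    """
    worst, degenerate = 1.0, False
    for j in range(k):
        members = np.nonzero(test_labels == j)[0]
        nj = len(members)
        if nj < 2:
            degenerate = True
            continue
        counts = np.bincount(train_assigned[members])
        co_pairs = int((counts * (counts - 1) // 2).sum())
        frac = co_pairs / (nj * (nj - 1) // 2)
        worst = min(worst, frac)
    return worst, degenerate


@dataclass
class PSIteration:
    train_idx: np.ndarray
    test_idx: np.ndarray
    train_medoids: np.ndarray  # global sample indices
    test_labels: np.ndarray    # labels of test samples (test-side clustering)
    train_assigned: np.ndarray  # train-classifier labels of test samples
    ps: float
    degenerate: bool


@dataclass
class PSEstimate:
    k: int
    mean: float
    sd: float
    values: np.ndarray
    n_degenerate: int
    iterations: list[PSIteration] = field(default_factory=list, repr=False)
    degenerate_mask: np.ndarray = field(default=None, repr=False)

    @property
    def mean_informative(self) -> float:
        """Mean ps over non-degenerate iterations (NaN if all degenerate).

        Iterations where some test cluster has < 2 members carry no
        evidence about cluster-number validity (the singleton's
        conventional score of 1 inflates the min), so model selection
        should rely on this estimate rather than ``mean``.
        """
        if self.degenerate_mask is None:
            return self.mean
        ok = ~self.degenerate_mask
        return float(self.values[ok].mean()) if ok.any() else float("nan")

    @property
    def se_informative(self) -> float:
        """Standard error of the informative-iteration mean."""
        ok = (~self.degenerate_mask if self.degenerate_mask is not None
              else np.ones(len(self.values), bool))
        n = int(ok.sum())
        if n < 2:
            return float("nan")
        return float(self.values[ok].std(ddof=1) / np.sqrt(n))


def _make_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def prediction_strength(
    dm: DistMatrix | np.ndarray,
    k: int,
    n_iterations: int = 100,
    train_fraction: float = 0.5,
    seed=0,
    keep_iterations: bool = False,
) -> PSEstimate:
    """Estimate prediction strength for k clusters by repeated subsampling.

    Each iteration splits the samples into train/test halves, clusters both
    on their distance submatrices, classifies test samples to their nearest
    train medoid, and scores co-membership agreement; ps(k=1) is 1 by
    definition.  Deterministic given ``seed``.
    """
    d = dm.d if isinstance(dm, DistMatrix) else np.asarray(dm, dtype=float)
    n = d.shape[0]
    if np.isnan(d).any():
        raise ValueError("distance matrix contains invalid (NaN) pairs")
    if k > n // 2:
        raise ValueError(f"k={k} exceeds floor(n/2)={n // 2}")
    if k == 1:
        vals = np.ones(n_iterations)
        return PSEstimate(1, 1.0, 0.0, vals, 0,
                          degenerate_mask=np.zeros(n_iterations, bool))

    rng = _make_rng(seed)
    n_train = int(round(n * train_fraction))
    n_train = min(max(n_train, k), n - k)  # both halves must admit k clusters
    vals = np.empty(n_iterations)
    degenerate_mask = np.zeros(n_iterations, bool)
    iters: list[PSIteration] = []
    for t in range(n_iterations):
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:n_train])
        test_idx = np.sort(perm[n_train:])
        tr_med_local, _ = pam_cluster(d[np.ix_(train_idx, train_idx)], k)
        train_medoids = train_idx[tr_med_local]
        _, test_labels = pam_cluster(d[np.ix_(test_idx, test_idx)], k)
        train_assigned = np.argmin(d[np.ix_(test_idx, train_medoids)], axis=1)
        ps, degenerate = _ps_from_labels(test_labels, train_assigned, k)
        vals[t] = ps
        degenerate_mask[t] = degenerate
        if keep_iterations:
            iters.append(
                PSIteration(train_idx, test_idx, train_medoids,
                            test_labels, train_assigned, ps, degenerate)
            )
    return PSEstimate(k, float(vals.mean()), float(vals.std(ddof=0)), vals,
                      int(degenerate_mask.sum()), iters, degenerate_mask)


# ---------------------------------------------------------------------------
# Cluster-number selection
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Outcome of subspecies clustering on the discovery subset.

    k_selected = 1 means no subspecies detected.  ``sample_stability`` is
    the fraction of subsampling iterations in which a sample co-clusters
    with the majority of its final cluster.
    """

    k_selected: int
    assignments: pd.Series  # sample id -> cluster id (1-based)
    ps_per_k: pd.DataFrame  # columns: k, mean_ps, sd_ps, n_degenerate
    sample_stability: pd.Series
    ps_threshold: float
    n_iterations: int
    seed: int
    medoids: list[str]


def choose_k(
    dm: DistMatrix,
    k_max: int = 10,
    ps_threshold: float = 0.8,
    n_iterations: int = 100,
    train_fraction: float = 0.5,
    seed: int = 0,
    min_discovery_size: int = 20,
) -> ClusterResult:
    """Select the number of subspecies as the largest k whose mean
    prediction strength reaches ``ps_threshold``; cluster the full
    discovery subset at that k and score per-sample stability.
    """
    n = len(dm.sample_ids)
    if n < min_discovery_size:
        raise InsufficientDiscoverySamplesError(
            f"discovery subset has {n} samples; need >= {min_discovery_size}"
        )
    d = dm.d
    if np.isnan(d).any():
        raise ValueError(
            "distance matrix has invalid pairs; drop isolated samples first"
        )
    k_upper = min(k_max, n // 2)
    # independent, reproducible subsampling stream per k
    children = np.random.SeedSequence(seed).spawn(k_upper + 1)
    estimates: dict[int, PSEstimate] = {}
    for k in range(1, k_upper + 1):
        estimates[k] = prediction_strength(
            dm, k, n_iterations, train_fraction,
            seed=np.random.default_rng(children[k]), keep_iterations=True,
        )
    ps_per_k = pd.DataFrame(
        {
            "k": list(estimates),
            "mean_ps": [e.mean for e in estimates.values()],
            "mean_ps_informative": [e.mean_informative for e in estimates.values()],
            "sd_ps": [e.sd for e in estimates.values()],
            "n_degenerate": [e.n_degenerate for e in estimates.values()],
        }
    )
    # selection trusts only informative (non-degenerate) iterations — a
    # singleton test cluster scores 1 by convention, which inflates the
    # mean precisely at k above the true cluster number — and demands the
    # threshold is cleared by one standard error, so borderline spurious
    # splits do not slip through
    def accepts(e: PSEstimate) -> bool:
        if e.k == 1:
            return True
        if e.n_degenerate > n_iterations // 2:
            return False
        m, se = e.mean_informative, e.se_informative
        margin = se if np.isfinite(se) else 0.0
        return np.isfinite(m) and m - margin >= ps_threshold

    passing = [k for k, e in estimates.items() if accepts(e)]
    k_selected = max(passing) if passing else 1

    medoid_idx, labels = pam_cluster(d, k_selected)
    assignments = pd.Series(labels + 1, index=dm.sample_ids, name="cluster")

    if k_selected == 1:
        stability = pd.Series(1.0, index=dm.sample_ids, name="stability")
    else:
        stability = _sample_stability(d, labels, estimates[k_selected])
        stability = pd.Series(stability, index=dm.sample_ids, name="stability")

    return ClusterResult(
        k_selected=k_selected,
        assignments=assignments,
        ps_per_k=ps_per_k,
        sample_stability=stability,
        ps_threshold=ps_threshold,
        n_iterations=n_iterations,
        seed=seed,
        medoids=[dm.sample_ids[i] for i in medoid_idx],
    )


def _sample_stability(
    d: np.ndarray, final_labels: np.ndarray, est: PSEstimate
) -> np.ndarray:
    """Fraction of iterations where each sample follows its final cluster's
    majority under the iteration's train-medoid classifier."""
    n = d.shape[0]
    hits = np.zeros(n)
    n_iters = len(est.iterations)
    for it in est.iterations:
        assigned = np.argmin(d[:, it.train_medoids], axis=1)
        for c in np.unique(final_labels):
            members = final_labels == c
            counts = np.bincount(assigned[members])
            majority = int(np.argmax(counts))
            hits[members] += assigned[members] == majority
    return hits / max(n_iters, 1)


# ---------------------------------------------------------------------------
# Genotyping alleles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeParams:
    """Marker extraction thresholds, applied to marker-oriented
    frequencies (f for alt_high markers, 1-f for alt_low)."""

    within_threshold: float = 0.8
    outside_threshold: float = 0.2
    max_markers: int = 100


@dataclass
class GenotypeAlleleSet:
    """Distinctive marker alleles per cluster.

    ``markers`` columns: cluster, snv_id, state (alt_high/alt_low),
    within_freq, outside_freq — both frequencies marker-oriented, so every
    row satisfies within_freq >= within_threshold and outside_freq <=
    outside_threshold on the discovery subset.
    """

    markers: pd.DataFrame
    params: GenotypeParams
    unprofilable_clusters: list[int]

    def markers_for(self, cluster: int) -> pd.DataFrame:
        return self.markers[self.markers["cluster"] == cluster]


def genotype_alleles(
    fm: pd.DataFrame, cr: ClusterResult, params: GenotypeParams | None = None
) -> GenotypeAlleleSet:
    """Extract per-cluster distinctive SNV alleles from the discovery subset.

    An SNV is an alt_high marker for cluster c when its median frequency
    within c reaches ``within_threshold`` while the maximum of the other
    clusters' medians stays at or below ``outside_threshold``; alt_low is
    the symmetric rule on 1-f.  Per cluster the top ``max_markers`` by
    (within - outside) margin are kept, ties broken by SNV id.
    """
    params = params or GenotypeParams()
    if cr.k_selected < 2:
        raise ValueError("genotyping requires k_selected >= 2")
    clusters = sorted(cr.assignments.unique())
    sub = fm[cr.assignments.index]
    med = pd.DataFrame(
        {
            c: np.nanmedian(
                sub.loc[:, cr.assignments.index[cr.assignments == c]].to_numpy(),
                axis=1,
            )
            for c in clusters
        },
        index=fm.index,
    )

    rows = []
    for c in clusters:
        others = [o for o in clusters if o != c]
        inner = med[c]
        outer_max = med[others].max(axis=1)  # NaN-propagating via min_count? max skips NaN
        outer_has_nan = med[others].isna().any(axis=1)
        outer_min = med[others].min(axis=1)
        for state in ("alt_high", "alt_low"):
            if state == "alt_high":
                w = inner
                o = outer_max
            else:
                w = 1.0 - inner
                o = 1.0 - outer_min
            ok = (
                (w >= params.within_threshold)
                & (o <= params.outside_threshold)
                & ~inner.isna()
                & ~outer_has_nan
            )
            for snv_id in fm.index[ok]:
                rows.append(
                    (c, snv_id, state, float(w.loc[snv_id]), float(o.loc[snv_id]))
                )

    df = pd.DataFrame(
        rows, columns=["cluster", "snv_id", "state", "within_freq", "outside_freq"]
    )
    if len(df):
        df["margin"] = df["within_freq"] - df["outside_freq"]
        df = (
            df.sort_values(
                ["cluster", "margin", "snv_id"],
                ascending=[True, False, True],
                kind="stable",
            )
            .groupby("cluster", sort=True)
            .head(params.max_markers)
            .drop(columns="margin")
            .reset_index(drop=True)
        )
    found = set(df["cluster"]) if len(df) else set()
    unprofilable = [c for c in clusters if c not in found]
    return GenotypeAlleleSet(df, params, unprofilable)


# ---------------------------------------------------------------------------
# Subspecies abundance profiling
# ---------------------------------------------------------------------------

@dataclass
class SubspeciesProfile:
    """Per-sample subspecies abundance estimates from marker alleles.

    ``raw`` holds the median (or mean) marker-oriented frequency per
    sample x cluster, NaN where fewer than ``min_markers_observed`` markers
    were observed.  ``normalized`` rescales rows to sum to 1 where every
    cluster has an estimate.
    """

    raw: pd.DataFrame
    n_markers: pd.DataFrame
    normalized: pd.DataFrame
    unprofilable_samples: list[str]


def profile_subspecies(
    fm_any: pd.DataFrame,
    gs: GenotypeAlleleSet,
    min_markers_observed: int = 5,
    agg: str = "median",
) -> SubspeciesProfile:
    """Estimate subspecies abundances in arbitrary metagenomes.

    For each sample and cluster, the abundance estimate is the median
    (default; mean optional) over the cluster's observed markers of the
    marker-oriented frequency: f for alt_high markers, 1-f for alt_low.
    """
    if agg not in ("median", "mean"):
        raise ValueError("agg must be 'median' or 'mean'")
    clusters = sorted(gs.markers["cluster"].unique()) if len(gs.markers) else []
    samples = list(fm_any.columns)
    raw = pd.DataFrame(np.nan, index=samples, columns=clusters, dtype=float)
    n_obs = pd.DataFrame(0, index=samples, columns=clusters, dtype=int)

    for c in clusters:
        mk = gs.markers_for(c)
        present = mk[mk["snv_id"].isin(fm_any.index)]
        if not len(present):
            continue
        f = fm_any.loc[present["snv_id"]].to_numpy(dtype=float)
        orient = (present["state"] == "alt_low").to_numpy()
        f[orient] = 1.0 - f[orient]
        obs = ~np.isnan(f)
        n_obs[c] = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            est = np.nanmedian(f, axis=0) if agg == "median" else np.nanmean(f, axis=0)
        est = np.where(n_obs[c].to_numpy() >= min_markers_observed, est, np.nan)
        raw[c] = est

    complete = raw.notna().all(axis=1) if clusters else pd.Series(False, index=samples)
    sums = raw.sum(axis=1)
    normalized = raw.div(sums, axis=0)
    normalized[~(complete & (sums > 0))] = np.nan
    unprofilable = list(raw.index[(n_obs.sum(axis=1) == 0)]) if clusters else samples
    return SubspeciesProfile(raw, n_obs, normalized, unprofilable)


# ---------------------------------------------------------------------------
# TSV outputs
# ---------------------------------------------------------------------------

def write_cluster_result(cr: ClusterResult, clusters_path, ps_path) -> None:
    pd.DataFrame(
        {
            "sample": cr.assignments.index,
            "cluster": cr.assignments.to_numpy(),
            "stability": cr.sample_stability.reindex(cr.assignments.index).to_numpy(),
        }
    ).to_csv(clusters_path, sep="\t", index=False)
    cr.ps_per_k.to_csv(ps_path, sep="\t", index=False)


def write_genotype_alleles(gs: GenotypeAlleleSet, path) -> None:
    gs.markers.to_csv(path, sep="\t", index=False)


def read_genotype_alleles(path, params: GenotypeParams | None = None) -> GenotypeAlleleSet:
    df = pd.read_csv(path, sep="\t")
    clusters = sorted(df["cluster"].unique()) if len(df) else []
    return GenotypeAlleleSet(df, params or GenotypeParams(), [])


def write_subspecies_profile(sp: SubspeciesProfile, path) -> None:
    raw = sp.raw.add_prefix("raw_cluster_")
    norm = sp.normalized.add_prefix("norm_cluster_")
    nm = sp.n_markers.add_prefix("n_markers_cluster_")
    pd.concat([raw, norm, nm], axis=1).to_csv(
        path, sep="\t", index_label="sample", na_rep="NA"
    )
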