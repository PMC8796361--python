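"""Pairwise SNV-profile dissimilarities between metagenomes.

Each sample's SNV profile is its vector of alt-allele frequencies; the
dissimilarity between two samples is an average per-SNV frequency
difference over the SNVs observed in both (missing values are pairwise
deleted, never imputed).  Pairs sharing fewer than ``min_shared`` SNVs are
flagged invalid rather than reported as noisy distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

METRICS = ("mean_abs", "euclidean_mean")


@dataclass
class DistMatrix:
    """Symmetric dissimilarity matrix with shared-SNV support counts.

    d[i, j] is NaN where n_shared[i, j] < min_shared (invalid pair).
    """

    sample_ids: list[str]
    d: np.ndarray
    n_shared: np.ndarray
    min_shared: int
    metric: str = "mean_abs"

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.d.shape != (n, n) or self.n_shared.shape != (n, n):
            raise ValueError("matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("dissimilarity matrix not symmetric")

    @property
    def valid_pair(self) -> np.ndarray:
        return self.n_shared >= self.min_shared

    def isolated_samples(self) -> list[str]:
        """Samples sharing < min_shared SNVs with every other sample."""
        off = self.valid_pair & ~np.eye(len(self.sample_ids), dtype=bool)
        return [s for s, ok in zip(self.sample_ids, off.any(axis=1)) if not ok]

    def drop_isolated(self) -> tuple["DistMatrix", list[str]]:
        """Remove samples invalid against all others (reported separately)."""
        iso = set(self.isolated_samples())
        keep = np.array([s not in iso for s in self.sample_ids], dtype=bool)
        sub = DistMatrix(
            [s for s in self.sample_ids if s not in iso],
            self.d[np.ix_(keep, keep)],
            self.n_shared[np.ix_(keep, keep)],
            self.min_shared,
            self.metric,
        )
        return sub, sorted(iso)

    def restrict(self, sample_ids: list[str]) -> "DistMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistMatrix(
            list(sample_ids),
            self.d[np.ix_(idx, idx)],
            self.n_shared[np.ix_(idx, idx)],
            self.min_shared,
            self.metric,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids)


def pairwise_dissimilarity(
    fm: pd.DataFrame, metric: str = "mean_abs", min_shared: int = 100
) -> DistMatrix:
    """Compute the sample x sample dissimilarity matrix from a FreqMatrix.

    mean_abs:       d(a,b) = mean over jointly observed SNVs of |f_a - f_b|
    euclidean_mean: d(a,b) = sqrt(mean of squared differences)

    Both lie in [0, 1] since frequencies do.  Pairs with fewer than
    ``min_shared`` jointly observed SNVs get d = NaN and are flagged invalid.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if fm.shape[1] < 2:
        raise ValueError("need at least 2 samples")

    vals = fm.to_numpy(dtype=float)
    mask = ~np.isnan(vals)
    n = vals.shape[1]
    n_shared = (mask.astype(np.int64).T @ mask.astype(np.int64))
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = mask[:, i] & mask[:, j]
            ns = int(both.sum())
            if ns < min_shared or ns == 0:
                d[i, j] = d[j, i] = np.nan
                continue
            diff = vals[both, i] - vals[both, j]
            if metric == "mean_abs":
                val = float(np.abs(diff).mean())
            else:
                val = float(np.sqrt((diff ** 2).mean()))
            d[i, j] = d[j, i] = val
    np.fill_diagonal(d, 0.0)
    return DistMatrix(list(fm.columns), d, n_shared, min_shared, metric)


def write_dist_matrix(dm: DistMatrix, d_path, n_shared_path=None) -> None:
    dm.to_frame().to_csv(d_path, sep="\t", index_label="sample", na_rep="NA")
    if n_shared_path is not None:
        pd.DataFrame(
            dm.n_shared, index=dm.sample_ids, columns=dm.sample_ids
        ).to_csv(n_shared_path, sep="\t", index_label="sample")


def read_dist_matrix(d_path, n_shared_path=None, min_shared: int = 100) -> DistMatrix:
    df = pd.read_csv(d_path, sep="\t", index_col="sample", na_values=["NA"])
    samples = list(df.columns)
    if n_shared_path is not None:
        ns = pd.read_csv(n_shared_path, sep="\t", index_col="sample").to_numpy()
    else:
        # without support counts, trust the NaN pattern in d
        ns = np.where(np.isnan(df.to_numpy()), 0, min_shared)
    return DistMatrix(samples, df.to_numpy(dtype=float), ns.astype(np.int64), min_shared)
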