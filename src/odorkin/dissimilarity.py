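"""Bray-Curtis dissimilarity matrices over samples or individual means.

Bray-Curtis, D(x, y) = sum_k |x_k - y_k| / sum_k (x_k + y_k), is the
profile-dissimilarity measure throughout: it uses both presence/absence
and abundance and makes no distributional assumptions. Sample-level
matrices are computed on standardized, log(x+1)-transformed relative
abundances; individual-level matrices average each individual's
standardized profiles first and transform the means, mirroring the
sample-level chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .preprocess import PreprocessError, transform_similarity
from .profile_io import IndividualMetadata, PeakTable

__all__ = [
    "DissimilarityMatrix",
    "bray_curtis",
    "individual_mean_profiles",
    "attribute_distance",
]


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise distances with id labels."""

    ids: list[str]
    values: np.ndarray  # square symmetric, zero diagonal
    level: str = "sample"  # or "individual"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("distance matrix diagonal not zero")

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def subset(self, keep: list[str]) -> "DissimilarityMatrix":
        idx = [self.ids.index(i) for i in keep]
        return DissimilarityMatrix(list(keep), self.values[np.ix_(idx, idx)], self.level)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", float_format="%.12g", index_label="id"
        )


def bray_curtis(X: np.ndarray | PeakTable, ids: list[str] | None = None,
                level: str = "sample") -> DissimilarityMatrix:
    """Pairwise Bray-Curtis dissimilarities between rows of X."""
    if isinstance(X, PeakTable):
        ids = list(X.sample_ids) if ids is None else ids
        X = X.areas
    X = np.asarray(X, dtype=float)
    if ids is None:
        ids = [str(i) for i in range(X.shape[0])]
    if np.any(X < 0):
        raise ValueError("Bray-Curtis input must be non-negative")
    zero_rows = np.flatnonzero(X.sum(axis=1) == 0)
    if zero_rows.size:
        raise ValueError(f"all-zero rows make Bray-Curtis undefined: {[ids[i] for i in zero_rows]}")
    D = squareform(pdist(X, metric="braycurtis"))
    return DissimilarityMatrix(ids, D, level)


def individual_mean_profiles(rel: PeakTable, meta: IndividualMetadata) -> PeakTable:
    """Average each individual's standardized sample profiles.

    Means are taken on the percent scale (before the log transform), so
    output rows remain row-stochastic (sum to 100). The caller applies
    `transform_similarity` before computing distances.
    """
    inds = meta.individuals_of(rel.sample_ids)
    frame = rel.to_frame()
    frame.index = pd.Index(inds, name="individual_id")
    means = frame.groupby(level=0, sort=True).mean()
    missing = sorted(set(meta.individuals.index) - set(means.index))
    if missing:
        raise PreprocessError(f"individuals without any sample: {missing}")
    return PeakTable.from_frame(means)


def attribute_distance(meta: IndividualMetadata, attribute: str,
                       individual_ids: list[str] | None = None) -> DissimilarityMatrix:
    """Pairwise absolute differences of a numeric attribute (age or rank)."""
    if attribute not in ("age", "rank"):
        raise ValueError("attribute must be 'age' or 'rank'")
    ids = list(individual_ids) if individual_ids is not None else list(meta.individuals.index)
    vals = meta.individuals.loc[ids, attribute].astype(float)
    missing = vals.index[vals.isna()].tolist()
    if missing:
        raise ValueError(f"attribute {attribute!r} missing for individuals: {missing}")
    a = vals.to_numpy()
    D = np.abs(a[:, None] - a[None, :])
    return DissimilarityMatrix(ids, D, level="individual")
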