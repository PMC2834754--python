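"""Statistics over descriptor panels: group t-values, PCA, k-means and
the class I/II rule.

The group comparison statistic is the unequal-variance two-sample t

    t = (M1 - M2) / sqrt(Var1/n1 + Var2/n2)

with the working significance threshold |t| > 1.34 (about 90% confidence
for the group sizes involved).  Multivariate structure of the six key
descriptors is explored with a PCA on the correlation matrix (descriptors
span incompatible units, so each column is standardized) followed by
k-means with k = 3, which is exposed as a statsmodels-style model: build
:class:`InterfaceClassification` from a panel DataFrame and call
``fit()``; the results object carries scores, loadings, explained
variance, cluster labels and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from ppiface.reference_data import GroupStats, KEY_DESCRIPTORS

T_SIGNIFICANCE = 1.34


def t_value(g1: GroupStats, g2: GroupStats) -> float:
    """Unequal-variance two-sample t statistic between two groups."""
    pooled = g1.variance / g1.n + g2.variance / g2.n
    if pooled <= 0:
        raise ValueError("zero pooled variance: t-value undefined")
    return (g1.mean - g2.mean) / float(np.sqrt(pooled))


def t_significant(t: float, threshold: float = T_SIGNIFICANCE) -> bool:
    return abs(t) > threshold


def assign_class(n_segments: int) -> str:
    """Peptide-like class I iff the interface has fewer than six segments."""
    if n_segments < 0:
        raise ValueError("segment count must be non-negative")
    return "I" if n_segments < 6 else "II"


@dataclass
class PCAResult:
    scores: np.ndarray               # (n, p) projections of standardized data
    loadings: np.ndarray             # (p, p) columns = components
    explained_variance: np.ndarray   # (p,) fractions summing to 1
    means: np.ndarray
    sds: np.ndarray
    columns: list[str]


def pca(panel: pd.DataFrame | np.ndarray, standardize: bool = True) -> PCAResult:
    """Principal components of a descriptor panel.

    Columns are centered and (by default) scaled to unit variance, so the
    decomposition is of the correlation matrix.  Component signs are fixed
    by making the largest-magnitude loading positive.  Constant columns
    are rejected by name.
    """
    if isinstance(panel, pd.DataFrame):
        columns = list(panel.columns)
        x = panel.to_numpy(dtype=float)
    else:
        x = np.asarray(panel, dtype=float)
        columns = [f"x{i}" for i in range(x.shape[1])]
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("panel must be 2-D with at least 3 rows")
    if np.any(~np.isfinite(x)):
        raise ValueError("panel contains missing values")
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    for j, s in enumerate(sds):
        if s <= 0:
            raise ValueError(f"constant column {columns[j]!r} cannot be standardized")
    z = (x - means) / (sds if standardize else 1.0)
    if not standardize:
        z = x - means
    cov = z.T @ z / (len(z) - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    loadings = evecs[:, order]
    for j in range(loadings.shape[1]):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = z @ loadings
    total = evals.sum()
    frac = evals / total if total > 0 else evals
    return PCAResult(
        scores=scores, loadings=loadings, explained_variance=frac,
        means=means, sds=sds, columns=columns,
    )


def kmeans(
    scores: np.ndarray,
    k: int = 3,
    restarts: int = 50,
    seed: int | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Best-of-restarts k-means on PCA scores.

    Labels are canonicalized by ordering cluster centroids along the first
    score axis, so the same seed always yields identical labels (and
    well-separated data yields seed-independent ones).  Labels are 1-based.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if k > len(x):
        raise ValueError(f"k={k} exceeds the number of rows ({len(x)})")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    raw = km.fit_predict(x)
    centroids = km.cluster_centers_
    order = np.argsort(centroids[:, 0])
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    return relabel[raw], centroids[order]


class InterfaceClassification:
    """PCA + k-means classification model over a descriptor panel.

    Parameters
    ----------
    panel : DataFrame
        One row per complex; must contain the six key descriptors
        (interface area, segment count, gap volume, pocket volume,
        hydrogen-bond density, charged-residue percentage).  Extra columns
        are ignored.  Row index identifies the complexes.
    k : int
        Number of clusters (3 by default).
    """

    def __init__(
        self,
        panel: pd.DataFrame,
        k: int = 3,
        descriptors: list[str] | None = None,
        standardize: bool = True,
        n_components: int = 2,
    ):
        self.descriptors = descriptors or KEY_DESCRIPTORS
        missing = [d for d in self.descriptors if d not in panel.columns]
        if missing:
            raise ValueError(f"panel lacks descriptors {missing}")
        self.panel = panel
        self.k = k
        self.standardize = standardize
        # clusters live in the plane of the leading components (the biplot
        # plane); full-dimensional k-means is available with n_components=None
        self.n_components = n_components

    @classmethod
    def from_dataframe(cls, panel: pd.DataFrame, **kwargs) -> "InterfaceClassification":
        return cls(panel, **kwargs)

    def fit(self, restarts: int = 50, seed: int = 0) -> "InterfaceClassificationResults":
        sub = self.panel[self.descriptors]
        p = pca(sub, standardize=self.standardize)
        ncomp = self.n_components or p.scores.shape[1]
        labels, centroids = kmeans(p.scores[:, :ncomp], k=self.k,
                                   restarts=restarts, seed=seed)
        return InterfaceClassificationResults(
            model=self, pca_=p, labels=labels, centroids=centroids,
            seed=seed, restarts=restarts,
        )


@dataclass
class InterfaceClassificationResults:
    model: InterfaceClassification
    pca_: PCAResult
    labels: np.ndarray
    centroids: np.ndarray
    seed: int
    restarts: int

    @property
    def scores(self) -> np.ndarray:
        return self.pca_.scores

    @property
    def loadings(self) -> pd.DataFrame:
        p = self.pca_
        return pd.DataFrame(
            p.loadings, index=p.columns,
            columns=[f"PC{i+1}" for i in range(p.loadings.shape[1])],
        )

    @property
    def explained_variance(self) -> np.ndarray:
        return self.pca_.explained_variance

    def cluster_members(self) -> dict[int, list]:
        out: dict[int, list] = {}
        idx = list(self.model.panel.index)
        for name, lab in zip(idx, self.labels):
            out.setdefault(int(lab), []).append(name)
        return out

    def to_dict(self) -> dict:
        return {
            "explained_variance": self.explained_variance.tolist(),
            "loadings": self.loadings.to_dict(),
            "labels": {str(k): int(v) for k, v in
                       zip(self.model.panel.index, self.labels)},
            "seed": self.seed,
            "restarts": self.restarts,
        }

    def summary(self) -> str:
        lines = ["Interface descriptor classification (PCA + k-means)",
                 "=" * 52]
        ev = self.explained_variance
        lines.append(f"complexes: {len(self.labels)}   descriptors: "
                     f"{len(self.model.descriptors)}   k: {self.model.k}")
        lines.append("explained variance: " +
                     "  ".join(f"PC{i+1} {v:5.1%}" for i, v in enumerate(ev[:4])))
        lines.append("")
        lines.append("loadings (PC1, PC2):")
        for name, row in self.loadings.iloc[:, :2].iterrows():
            lines.append(f"  {name:<22s} {row.iloc[0]:+6.3f}  {row.iloc[1]:+6.3f}")
        lines.append("")
        for lab, members in sorted(self.cluster_members().items()):
            lines.append(f"cluster {lab}: " + ", ".join(str(m) for m in members))
        return "\n".join(lines)
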