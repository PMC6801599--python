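"""Phenotype descriptive statistics, correlations, PCA and clustering.

Traits have heterogeneous units (mm vs g) and very different variances, so
both the PCA and the Euclidean clustering operate on z-standardized traits;
per-cluster means are reported on the raw scale.  Skewness and kurtosis use
the bias-adjusted G1/G2 estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .markers import PhenotypeTable

__all__ = [
    "TraitSummary",
    "describe_traits",
    "correlations",
    "phenotype_pca",
    "phenotype_clusters",
    "standardized_trait_matrix",
]


@dataclass(frozen=True)
class TraitSummary:
    trait: str
    n: int
    min: float
    max: float
    range: float
    mean: float
    se_mean: float
    sd: float
    variance: float
    cv: float
    skewness_g1: float  # NaN when undefined (constant trait)
    kurtosis_g2: float

    def to_dict(self) -> dict:
        return asdict(self)


def describe_traits(ph: PhenotypeTable) -> list[TraitSummary]:
    out = []
    for trait in ph.trait_names:
        x = ph.values(trait)
        x = x[~np.isnan(x)]
        if x.size == 0:
            raise ValueError(f"trait {trait} has no non-missing values")
        if x.size < 3:
            raise ValueError(f"trait {trait} needs >= 3 non-missing values")
        sd = float(np.std(x, ddof=1))
        mean = float(np.mean(x))
        if sd > 0:
            g1 = float(stats.skew(x, bias=False))
            g2 = float(stats.kurtosis(x, fisher=True, bias=False))
        else:
            g1 = g2 = float("nan")
        out.append(
            TraitSummary(
                trait=trait,
                n=int(x.size),
                min=float(np.min(x)),
                max=float(np.max(x)),
                range=float(np.max(x) - np.min(x)),
                mean=mean,
                se_mean=sd / float(np.sqrt(x.size)),
                sd=sd,
                variance=sd**2,
                cv=sd / mean if mean else float("nan"),
                skewness_g1=g1,
                kurtosis_g2=g2,
            )
        )
    return out


@dataclass
class CorrelationMatrix:
    traits: list[str]
    r: pd.DataFrame
    p: pd.DataFrame

    def star(self, t1: str, t2: str) -> str:
        p = self.p.loc[t1, t2]
        if p <= 0.01:
            return "**"
        if p <= 0.05:
            return "*"
        return ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, t1 in enumerate(self.traits):
            for t2 in self.traits[i + 1:]:
                rows.append(
                    {
                        "trait_1": t1,
                        "trait_2": t2,
                        "r": self.r.loc[t1, t2],
                        "p_value": self.p.loc[t1, t2],
                        "stars": self.star(t1, t2),
                    }
                )
        return pd.DataFrame(rows)


def correlations(ph: PhenotypeTable) -> CorrelationMatrix:
    """Pairwise Pearson correlations with two-sided t-test p-values.

    Missing values are excluded pairwise; stars mark p <= 0.05 (*) and
    p <= 0.01 (**).
    """
    traits = ph.trait_names
    k = len(traits)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            x, y = ph.values(traits[i]), ph.values(traits[j])
            ok = ~np.isnan(x) & ~np.isnan(y)
            if ok.sum() < 3:
                raise ValueError(
                    f"traits {traits[i]}/{traits[j]}: need >= 3 paired values"
                )
            if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                raise ValueError("zero-variance trait in correlation")
            res = stats.pearsonr(x[ok], y[ok])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    rdf = pd.DataFrame(r, index=traits, columns=traits)
    pdf = pd.DataFrame(p, index=traits, columns=traits)
    return CorrelationMatrix(list(traits), rdf, pdf)


def standardized_trait_matrix(ph: PhenotypeTable) -> tuple[np.ndarray, list[str]]:
    """Complete-case z-scored trait matrix and the accession ids retained."""
    vals = ph.traits.to_numpy(dtype=float)
    ok = ~np.isnan(vals).any(axis=1)
    x = vals[ok]
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [t for t, s in zip(ph.trait_names, sd) if s == 0]
        raise ValueError(f"constant trait(s): {bad}")
    z = (x - x.mean(axis=0)) / sd
    ids = [a for a, keep in zip(ph.accession_ids, ok) if keep]
    return z, ids


@dataclass
class PhenotypePca:
    accession_ids: list[str]
    scores: np.ndarray          # n x k component scores
    loadings: np.ndarray        # traits x k, orthonormal columns
    variance_fraction: np.ndarray
    traits: list[str]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"PC{i+1}": self.scores[:, i] for i in range(self.scores.shape[1])}
        return pd.DataFrame(cols, index=pd.Index(self.accession_ids, name="accession"))


def phenotype_pca(ph: PhenotypeTable) -> PhenotypePca:
    """PCA of z-standardized traits; variance fractions sum to 1."""
    z, ids = standardized_trait_matrix(ph)
    if z.shape[0] < 3 or z.shape[1] < 2:
        raise ValueError("PCA needs >= 3 accessions and >= 2 traits")
    pca = PCA(n_components=min(z.shape))
    scores = pca.fit_transform(z)
    return PhenotypePca(
        accession_ids=ids,
        scores=scores,
        loadings=pca.components_.T,
        variance_fraction=pca.explained_variance_ratio_,
        traits=ph.trait_names,
    )


@dataclass
class ClusterReport:
    accession_ids: list[str]
    linkage: np.ndarray
    assignments: dict[str, int]
    cluster_means: pd.DataFrame  # cluster x trait, raw scale

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "accession": self.accession_ids,
                "cluster": [self.assignments[a] for a in self.accession_ids],
            }
        )


def phenotype_clusters(ph: PhenotypeTable, k: int) -> ClusterReport:
    """UPGMA (average linkage) clustering of accessions on standardized
    Euclidean trait distances, cut to k clusters; cluster means reported on
    the raw trait scale."""
    if k < 1:
        raise ValueError("k must be >= 1")
    z, ids = standardized_trait_matrix(ph)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds {len(ids)} complete-case accessions")
    lk = average(pdist(z))
    labels = fcluster(lk, t=k, criterion="maxclust")
    assignments = dict(zip(ids, (int(c) for c in labels)))
    raw = ph.traits.loc[ids]
    means = raw.groupby(labels).mean()
    means.index.name = "cluster"
    return ClusterReport(ids, lk, assignments, means)


def cophenetic_is_ultrametric(linkage_matrix: np.ndarray, tol: float = 1e-8) -> bool:
    """Check the three-point ultrametric condition on cophenetic distances."""
    from scipy.spatial.distance import squareform

    c = squareform(cophenet(linkage_matrix))
    n = c.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            # c_ij <= max(c_ik, c_jk) for every third leaf k
            third = np.maximum(c[i], c[j])
            third[i] = third[j] = np.inf
            if np.any(c[i, j] > third + tol):
                return False
    return True
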