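"""Principal Coordinate Analysis (metric MDS) of a distance matrix.

Classical Gower procedure: double-center -1/2 d^2, eigendecompose, scale the
eigenvectors by sqrt(eigenvalue).  Non-Euclidean distances (the Ochiai
dissimilarity is one) can yield negative eigenvalues; these axes carry no
real coordinates, so they are excluded from the percent-explained
denominator and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from skbio import DistanceMatrix

__all__ = ["PcoaResult", "pcoa"]


@dataclass
class PcoaResult:
    accession_ids: list[str]
    coordinates: np.ndarray       # n x axes
    eigenvalues: np.ndarray       # all eigenvalues, descending
    percent_explained: np.ndarray  # per returned axis, of the positive total
    negative_eigenvalue_fraction: float

    def to_frame(self) -> pd.DataFrame:
        cols = {
            f"PCo{i+1}": self.coordinates[:, i]
            for i in range(self.coordinates.shape[1])
        }
        return pd.DataFrame(cols, index=pd.Index(self.accession_ids, name="accession"))


def pcoa(dm: DistanceMatrix, axes: int = 2) -> PcoaResult:
    n = dm.shape[0]
    if axes > n - 1:
        raise ValueError(f"axes={axes} exceeds n-1={n - 1}")
    d2 = dm.data**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    g = (g + g.T) / 2.0
    vals, vecs = eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10
    pos_total = vals[pos].sum()
    neg_frac = float(np.abs(vals[vals < 0]).sum() / pos_total) if pos_total else 0.0
    coords = np.zeros((n, axes))
    k = min(axes, int(pos.sum()))
    coords[:, :k] = vecs[:, :k] * np.sqrt(vals[:k])
    pct = np.zeros(axes)
    pct[:k] = 100.0 * vals[:k] / pos_total
    return PcoaResult(
        accession_ids=list(dm.ids),
        coordinates=coords,
        eigenvalues=vals,
        percent_explained=pct,
        negative_eigenvalue_fraction=neg_frac,
    )
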