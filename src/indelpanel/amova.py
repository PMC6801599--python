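"""Single-level AMOVA with the PhiPT differentiation statistic.

The analysis partitions squared-Euclidean distance among binary
allele-presence profiles into among- and within-population components, the
convention used for dominant/binary marker data (GenAlEx-style):

    SS_total  = sum_{i<j} d2_ij / N
    SS_within = sum_g sum_{i<j in g} d2_ij / n_g
    SS_among  = SS_total - SS_within

    V_within = SS_within / (N - k)
    V_among  = (SS_among / (k - 1) - V_within) / n0,
               n0 = (N - sum_g n_g^2 / N) / (k - 1)

    PhiPT = V_among / (V_among + V_within)   (V_among clamped at 0)

Significance is a label-permutation test with the add-one correction:
p = (#{permuted PhiPT >= observed} + 1) / (n_perm + 1).

Missing binary cells are mean-imputed per column within each group before
distances are computed (AMOVA needs complete pairwise distances); the
imputation is optional but on by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .markers import BinaryAlleleMatrix, PhenotypeTable

__all__ = [
    "AmovaResult",
    "amova",
    "pairwise_phi",
    "grain_type_grouping",
    "drop_singleton_groups",
]


def drop_singleton_groups(groups: dict[str, str]) -> dict[str, str]:
    """Remove accessions whose group has fewer than 2 members (a variance
    partition needs within-group pairs); warns when anything is dropped."""
    from collections import Counter

    sizes = Counter(groups.values())
    small = {g for g, c in sizes.items() if c < 2}
    if small:
        warnings.warn(f"singleton group(s) excluded: {sorted(small)}", stacklevel=2)
        return {a: g for a, g in groups.items() if g not in small}
    return dict(groups)


@dataclass(frozen=True)
class AmovaResult:
    grouping: str
    n_groups: int
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    v_among: float
    v_within: float
    percent_among: float
    percent_within: float
    phi_pt: float
    p_value: float
    n_permutations: int

    def to_dict(self) -> dict:
        return asdict(self)


def _impute_within_group(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Fill missing cells with the within-group column mean (falling back to
    the global column mean when a group is entirely missing in a column)."""
    out = x.copy()
    global_mean = np.nanmean(x, axis=0)
    for g in np.unique(labels):
        rows = labels == g
        block = out[rows]
        col_mean = np.nanmean(np.where(np.isnan(block), np.nan, block), axis=0)
        col_mean = np.where(np.isnan(col_mean), global_mean, col_mean)
        nan_r, nan_c = np.where(np.isnan(block))
        block[nan_r, nan_c] = col_mean[nan_c]
        out[rows] = block
    return out


def _squared_euclidean(x: np.ndarray) -> np.ndarray:
    sq = np.sum(x**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * x @ x.T
    np.fill_diagonal(d2, 0.0)
    return np.clip(d2, 0.0, None)


def _phi_components(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    n = d2.shape[0]
    groups, counts = np.unique(labels, return_counts=True)
    k = len(groups)
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g, ng in zip(groups, counts):
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(ng, k=1)].sum() / ng
    ss_among = ss_total - ss_within
    df_among, df_within = k - 1, n - k
    v_within = ss_within / df_within
    n0 = (n - np.sum(counts**2) / n) / df_among
    v_among = (ss_among / df_among - v_within) / n0
    total = v_among + v_within
    # unclamped statistic: the permutation test needs the raw value, else
    # null p-values pile up at 1 whenever V_among is clamped to 0
    phi = v_among / total if total > 0 else 0.0
    return phi, ss_among, ss_within


def amova(
    bm: BinaryAlleleMatrix,
    groups: dict[str, str],
    n_permutations: int = 999,
    seed: int = 0,
    grouping_name: str = "groups",
    impute_missing: bool = True,
) -> AmovaResult:
    """AMOVA / PhiPT for the accessions present in ``groups``."""
    members = [a for a in bm.accession_ids if a in groups]
    labels = np.array([groups[a] for a in members])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    if np.any(counts < 2):
        bad = [g for g, c in zip(uniq, counts) if c < 2]
        raise ValueError(f"singleton group(s): {bad}")
    rows = [bm.accession_ids.index(a) for a in members]
    x = bm.cells[rows]
    if np.isnan(x).any():
        if not impute_missing:
            raise ValueError("missing cells present and impute_missing=False")
        x = _impute_within_group(x, labels)
    d2 = _squared_euclidean(x)
    phi_raw, ss_among, ss_within = _phi_components(d2, labels)
    phi = max(0.0, phi_raw)  # reported value; raw value drives the test
    n = len(members)
    k = len(uniq)
    df_among, df_within = k - 1, n - k
    v_within = ss_within / df_within
    n0 = (n - np.sum(counts**2) / n) / df_among
    v_among = max(0.0, (ss_among / df_among - v_within) / n0)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        phi_p, _, _ = _phi_components(d2, perm)
        if phi_p >= phi_raw - 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    total_v = v_among + v_within
    return AmovaResult(
        grouping=grouping_name,
        n_groups=k,
        df_among=df_among,
        df_within=df_within,
        ss_among=ss_among,
        ss_within=ss_within,
        v_among=v_among,
        v_within=v_within,
        percent_among=100.0 * v_among / total_v if total_v else 0.0,
        percent_within=100.0 * v_within / total_v if total_v else 100.0,
        phi_pt=phi,
        p_value=p,
        n_permutations=n_permutations,
    )


def pairwise_phi(
    bm: BinaryAlleleMatrix,
    groups: dict[str, str],
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """PhiPT for every group pair; columns phi_pt and p_value per pair."""
    names = sorted(set(groups.values()))
    rows = []
    for i, g1 in enumerate(names):
        for g2 in names[i + 1:]:
            sub = {a: g for a, g in groups.items() if g in (g1, g2)}
            res = amova(
                bm, sub, n_permutations=n_permutations,
                seed=seed, grouping_name=f"{g1}|{g2}",
            )
            rows.append({"group_1": g1, "group_2": g2,
                         "phi_pt": res.phi_pt, "p_value": res.p_value})
    return pd.DataFrame(rows)


#: grain-type bin edges on grain length (mm); short < 7.5 <= medium < 8.5
#: <= long <= 9.5 < extra-long
GRAIN_TYPE_BINS = (7.5, 8.5, 9.5)


def grain_type_grouping(ph: PhenotypeTable) -> dict[str, str]:
    """Assign each accession a grain-type subpopulation from its GL."""
    gl = ph.values("GL")
    out: dict[str, str] = {}
    skipped = []
    lo, mid, hi = GRAIN_TYPE_BINS
    for acc, v in zip(ph.accession_ids, gl):
        if np.isnan(v):
            skipped.append(acc)
            continue
        if v < lo:
            out[acc] = "short"
        elif v < mid:
            out[acc] = "medium"
        elif v <= hi:
            out[acc] = "long"
        else:
            out[acc] = "extra-long"
    if skipped:
        warnings.warn(f"accessions without GL left unassigned: {skipped}",
                      stacklevel=2)
    return out
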