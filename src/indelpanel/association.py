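"""Marker-trait association, Duncan's multiple range test, favorable-allele
classification and pyramiding summaries.

Accessions are grouped by the allele class they carry at a locus (A- and
B-homozygotes; heterozygotes form a third group only when sufficiently
numerous, otherwise they are excluded rather than merged).  A one-way
fixed-effects ANOVA tests the group trait means; Duncan's multiple range test
assigns letter ranks (groups sharing a letter are not separable at the chosen
alpha).

A *major* allele class is one carried by at least ``min_group_n`` accessions
(default 20).  A major class at a marker significantly associated with a
trait is *favorable* when its group mean exceeds the breeding threshold
(grain length > 8 mm by default) and it holds the top Duncan letter;
remaining major classes at significant markers are the non-favorable
comparison set.  Pyramiding summaries report the unweighted mean +/- SD of
the favorable and non-favorable group means.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np
from scipy import stats

from .markers import HET_AB, HOM_A, HOM_B, MarkerGenotypeTable, PhenotypeTable

__all__ = [
    "GroupStats",
    "AssociationResult",
    "AlleleClassification",
    "FavorableRule",
    "PyramidReport",
    "allele_group_anova",
    "duncan_mrt",
    "classify_alleles",
    "pyramid_summary",
    "significance_label",
]

SIGNIFICANCE_TIERS = ((0.01, "**"), (0.05, "*"), (0.1, "+"))


from functools import lru_cache


@lru_cache(maxsize=4096)
def _duncan_q(alpha: float, p: int, df: int) -> float:
    """Studentized-range quantile at Duncan's protection level
    alpha_p = 1-(1-alpha)^(p-1); cached (the scipy ppf is expensive)."""
    alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
    return float(stats.studentized_range.ppf(1.0 - alpha_p, p, df))


def significance_label(p: float) -> str:
    for thresh, label in SIGNIFICANCE_TIERS:
        if p <= thresh:
            return label
    return ""


@dataclass(frozen=True)
class GroupStats:
    allele: str  # "A", "B" or "AB"
    n: int
    mean: float
    sd: float
    letter: str

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class AssociationResult:
    marker_id: str
    trait: str
    groups: tuple[GroupStats, ...]
    f_statistic: float
    p_value: float

    @property
    def significance(self) -> str:
        return significance_label(self.p_value)

    def group(self, allele: str) -> GroupStats:
        for g in self.groups:
            if g.allele == allele:
                return g
        raise KeyError(f"no group {allele!r} at {self.marker_id}")

    def to_dict(self) -> dict:
        d = {"marker_id": self.marker_id, "trait": self.trait,
             "f_statistic": self.f_statistic, "p_value": self.p_value,
             "significance": self.significance}
        for g in self.groups:
            d[f"mean_{g.allele}"] = g.mean
            d[f"sd_{g.allele}"] = g.sd
            d[f"n_{g.allele}"] = g.n
            d[f"letter_{g.allele}"] = g.letter
        return d


def duncan_mrt(
    group_means: np.ndarray,
    group_ns: np.ndarray,
    mse: float,
    df_error: int,
    alpha: float = 0.05,
) -> list[str]:
    """Duncan's multiple range test letters, in the input group order.

    Critical range for a stretch of p ordered means uses the studentized
    range quantile at Duncan's protection level alpha_p = 1 - (1-alpha)^(p-1)
    and the harmonic mean of the group sizes (Kramer's adjustment for unequal
    n).  Letters come from the standard stepwise procedure: spans whose
    extremes differ by less than the critical range are declared homogeneous,
    sub-spans of homogeneous spans are never tested.
    """
    if mse <= 0:
        raise ValueError("mse must be > 0")
    if df_error < 1:
        raise ValueError("df_error must be >= 1")
    means = np.asarray(group_means, dtype=float)
    ns = np.asarray(group_ns, dtype=float)
    k = len(means)
    if k == 1:
        return ["a"]
    order = np.argsort(-means)  # descending
    sorted_means = means[order]
    n_h = k / np.sum(1.0 / ns)
    se = np.sqrt(mse / n_h)
    # critical range for a span of p means
    crit = {p: _duncan_q(alpha, p, df_error) * se for p in range(2, k + 1)}
    homogeneous: set[tuple[int, int]] = set()

    def covered(i: int, j: int) -> bool:
        return any(a <= i and j <= b for a, b in homogeneous)

    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if covered(i, j):
                continue
            if sorted_means[i] - sorted_means[j] <= crit[span]:
                homogeneous.add((i, j))
    # maximal homogeneous intervals (plus singletons not inside any interval)
    intervals = [iv for iv in homogeneous
                 if not any(iv != other and other[0] <= iv[0] and iv[1] <= other[1]
                            for other in homogeneous)]
    for i in range(k):
        if not any(a <= i <= b for a, b in intervals):
            intervals.append((i, i))
    intervals.sort()
    letters_sorted = [""] * k
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for idx, (a, b) in enumerate(intervals):
        for i in range(a, b + 1):
            letters_sorted[i] += alphabet[idx % len(alphabet)]
    out = [""] * k
    for pos, orig in enumerate(order):
        out[orig] = letters_sorted[pos]
    return out


def allele_group_anova(
    tab: MarkerGenotypeTable,
    ph: PhenotypeTable,
    marker_id: str,
    trait: str,
    alpha: float = 0.05,
    min_group_n: int = 20,
) -> AssociationResult:
    """One-way ANOVA of a trait across allele-class groups at one locus."""
    j = tab.marker_index(marker_id)
    col = tab.calls[:, j]
    y = ph.traits.loc[tab.accession_ids, trait].to_numpy(dtype=float)
    groups: list[tuple[str, np.ndarray]] = []
    for allele, code in (("A", HOM_A), ("B", HOM_B)):
        vals = y[(col == code) & ~np.isnan(y)]
        if vals.size >= 2:
            groups.append((allele, vals))
    het_vals = y[(col == HET_AB) & ~np.isnan(y)]
    if het_vals.size >= min_group_n:
        groups.append(("AB", het_vals))
    if len(groups) < 2:
        raise ValueError(f"{marker_id}/{trait}: fewer than 2 eligible groups")
    samples = [v for _, v in groups]
    if all(np.var(v) == 0 for v in samples):
        raise ValueError(f"{marker_id}/{trait}: zero within-group variance")
    f, p = stats.f_oneway(*samples)
    n_total = sum(v.size for v in samples)
    df_error = n_total - len(samples)
    mse = sum(np.sum((v - v.mean()) ** 2) for v in samples) / df_error
    means = np.array([v.mean() for v in samples])
    ns = np.array([v.size for v in samples])
    letters = duncan_mrt(means, ns, mse, df_error, alpha=alpha)
    stats_out = tuple(
        GroupStats(
            allele=name,
            n=int(v.size),
            mean=float(v.mean()),
            sd=float(np.std(v, ddof=1)),
            letter=letters[idx],
        )
        for idx, (name, v) in enumerate(groups)
    )
    return AssociationResult(marker_id, trait, stats_out, float(f), float(p))


@dataclass(frozen=True)
class FavorableRule:
    """When is a major allele class favorable for a trait?"""

    trait: str = "GL"
    mean_threshold: float = 8.0  # breeding threshold (mm for GL)
    alpha: float = 0.05          # marker must be trait-associated at this level
    min_group_n: int = 20        # major-allele carrier-count threshold
    higher_is_better: bool = True


@dataclass(frozen=True)
class AlleleClassification:
    marker_id: str
    allele: str
    n: int
    mean: float
    sd: float
    letter: str
    status: str  # "major" or "minor"
    favorable: bool

    def to_dict(self) -> dict:
        return asdict(self)


def classify_alleles(
    assoc: list[AssociationResult],
    rule: FavorableRule = FavorableRule(),
) -> list[AlleleClassification]:
    """Major/minor and favorable classification of every allele group.

    Only groups at markers whose ANOVA p <= alpha can be favorable; within
    such a marker a major group is favorable when its mean beats the
    threshold and it carries the top Duncan letter ("a").
    """
    out = []
    for res in assoc:
        if res.trait != rule.trait:
            raise ValueError(f"association for {res.trait}, rule for {rule.trait}")
        significant = res.p_value <= rule.alpha
        for g in res.groups:
            major = g.n >= rule.min_group_n
            beats = (g.mean > rule.mean_threshold if rule.higher_is_better
                     else g.mean < rule.mean_threshold)
            fav = bool(major and significant and beats and "a" in g.letter)
            out.append(
                AlleleClassification(
                    marker_id=res.marker_id, allele=g.allele, n=g.n,
                    mean=g.mean, sd=g.sd, letter=g.letter,
                    status="major" if major else "minor", favorable=fav,
                )
            )
    return out


@dataclass
class PyramidReport:
    trait: str
    favorable: list[AlleleClassification]
    non_favorable: list[AlleleClassification]
    fa_mean: float
    fa_sd: float
    nfa_mean: float
    nfa_sd: float
    t_statistic: float = float("nan")
    p_value: float = float("nan")

    def to_frame(self):
        import pandas as pd

        rows = [
            {"set": "FA", "marker_id": c.marker_id, "allele": c.allele,
             "group_mean": c.mean, "group_sd": c.sd}
            for c in self.favorable
        ] + [
            {"set": "N-FA", "marker_id": c.marker_id, "allele": c.allele,
             "group_mean": c.mean, "group_sd": c.sd}
            for c in self.non_favorable
        ]
        return pd.DataFrame(rows)


def pyramid_summary(
    classified: list[AlleleClassification],
    assoc: list[AssociationResult],
    trait: str,
    alpha: float = 0.05,
) -> PyramidReport:
    """Cumulative favorable vs non-favorable comparison for one trait.

    The non-favorable set contains the major, non-favorable allele groups of
    the markers that contributed at least one favorable allele (the
    pyramiding counterparts).  Cumulative statistics are the unweighted mean
    and SD of the member group means; the two sets of group means are
    compared with a two-sample Welch t-test.
    """
    import warnings

    fa = [c for c in classified if c.favorable]
    fa_markers = {c.marker_id for c in fa}
    sig = {r.marker_id for r in assoc if r.p_value <= alpha and r.trait == trait}
    nfa = [
        c for c in classified
        if not c.favorable and c.status == "major"
        and c.marker_id in fa_markers and c.marker_id in sig
    ]
    if not fa or not nfa:
        warnings.warn(f"{trait}: empty favorable or non-favorable set", stacklevel=2)
    fa_means = np.array([c.mean for c in fa])
    nfa_means = np.array([c.mean for c in nfa])

    def _ms(x: np.ndarray) -> tuple[float, float]:
        if x.size == 0:
            return float("nan"), float("nan")
        return float(x.mean()), float(np.std(x, ddof=1)) if x.size > 1 else 0.0

    fa_mean, fa_sd = _ms(fa_means)
    nfa_mean, nfa_sd = _ms(nfa_means)
    t = p = float("nan")
    if fa_means.size >= 2 and nfa_means.size >= 2:
        t, p = stats.ttest_ind(fa_means, nfa_means, equal_var=False)
    return PyramidReport(
        trait=trait, favorable=fa, non_favorable=nfa,
        fa_mean=fa_mean, fa_sd=fa_sd, nfa_mean=nfa_mean, nfa_sd=nfa_sd,
        t_statistic=float(t), p_value=float(p),
    )
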