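"""Synthetic genotype + phenotype panels with the statistical structure of a
mostly-inbred crop diversity panel.

The generator draws genotype *classes* directly (hom-A, hom-B, het, missing)
rather than pairing gametes under Hardy-Weinberg: rice accessions in a
diversity panel are largely inbred uniform lines, so heterozygosity is a
per-locus property of the panel, not a function of allele frequency.  Default
class probabilities per locus are the published class counts of the
204-accession reference panel (near-zero heterozygosity except the GS7
locus at ~0.245, small per-locus missingness).

Population structure: accessions belong to one of four grain-type
subpopulations (short / medium / long / extra-long, sizes 55/78/48/23).
Within subpopulation g the B-allele class probability at each locus is
shifted by delta * ladder_g * sign(locus GL effect), an ordered frequency
ladder that makes the short vs extra-long pair the most diverged (and, via
the allele effects, sorts grain length along it).

Traits: additive allele effects (B homozygote = full contrast taken from the
published group comparisons, heterozygote = midpoint, missing = expected
value) plus correlated Gaussian residuals.  Residual variance per trait is
the published marginal variance minus the analytic genetic variance
(floored at 20% of the marginal), so simulated marginal moments match the
reference panel; the residual correlation matrix carries the published trait
correlation signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import refpanel
from .markers import (
    HET_AB,
    HOM_A,
    HOM_B,
    MISSING,
    MarkerDef,
    MarkerGenotypeTable,
    PhenotypeTable,
)

__all__ = ["LocusSpec", "PanelSpec", "generate_panel", "generate_null_panel"]

SUBPOP_LADDER = {"short": -1.5, "medium": -0.5, "long": 0.5, "extra-long": 1.5}

#: causal marker per gene for genes tagged by several markers -- the markers
#: of one gene assay the same functional variant, so planting the published
#: contrast at each of them would double-count the genetic variance
CAUSAL_MARKERS = {"GW8": "GW8-InDel", "GS5": "GS5-InDel1A", "GS2": "GS2-InDel1A"}


def centered_ladder(subpop_sizes: dict[str, int]) -> dict[str, float]:
    """Subpopulation divergence ladder with size-weighted mean zero, so the
    panel-wide expected allele frequency stays at the base frequency."""
    n = sum(subpop_sizes.values())
    mean = sum(SUBPOP_LADDER[g] * s for g, s in subpop_sizes.items()) / n
    return {g: SUBPOP_LADDER[g] - mean for g in subpop_sizes}


@dataclass(frozen=True)
class LocusSpec:
    marker_id: str
    gene: str
    band_bp: dict[str, int]
    p_hom_a: float
    p_hom_b: float
    p_het: float
    p_missing: float
    #: additive effect of the B allele (homozygote contrast) per trait
    effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        probs = (self.p_hom_a, self.p_hom_b, self.p_het, self.p_missing)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError(f"{self.marker_id}: class probabilities outside [0,1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"{self.marker_id}: class probabilities must sum to 1")

    @property
    def p_allele_a(self) -> float:
        """A-allele chromosome frequency over all accessions."""
        return self.p_hom_a + self.p_het / 2.0

    @property
    def p_allele_b(self) -> float:
        return self.p_hom_b + self.p_het / 2.0


def _default_loci() -> list[LocusSpec]:
    loci = []
    n = refpanel.N_ACCESSIONS
    for mid, (gene, band_a, band_b, *_rest) in refpanel.REFERENCE_LOCI.items():
        c = refpanel.class_counts(mid)
        entry = refpanel.REFERENCE_ASSOCIATIONS[mid]
        effects = {}
        if CAUSAL_MARKERS.get(gene, mid) == mid:
            for trait, p in entry["p"].items():
                if p <= 0.05:
                    by_allele = {a: tr[trait][0] for a, _n, tr in entry["groups"]}
                    contrast = by_allele["B"] - by_allele["A"]
                    if contrast != 0.0:
                        effects[trait] = contrast
        loci.append(
            LocusSpec(
                marker_id=mid,
                gene=gene,
                band_bp={"A": band_a, "B": band_b},
                p_hom_a=c["hom_a"] / n,
                p_hom_b=c["hom_b"] / n,
                p_het=c["het"] / n,
                p_missing=c["missing"] / n,
                effects=effects,
            )
        )
    return loci


@dataclass(frozen=True)
class PanelSpec:
    n_accessions: int = refpanel.N_ACCESSIONS
    loci: tuple[LocusSpec, ...] = field(default_factory=lambda: tuple(_default_loci()))
    subpop_sizes: dict[str, int] = field(
        default_factory=lambda: dict(refpanel.SUBPOP_SIZES)
    )
    divergence: float = 0.16  # frequency-offset unit of the subpop ladder
    trait_means: dict[str, float] = field(
        default_factory=lambda: {t: m[2] for t, m in refpanel.TRAIT_MOMENTS.items()}
    )
    trait_sds: dict[str, float] = field(
        default_factory=lambda: {t: m[3] for t, m in refpanel.TRAIT_MOMENTS.items()}
    )
    trait_correlations: np.ndarray = field(
        default_factory=lambda: refpanel.TRAIT_CORRELATIONS.copy()
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.subpop_sizes.values()) != self.n_accessions:
            raise ValueError("subpopulation sizes must sum to n_accessions")

    @property
    def trait_names(self) -> tuple[str, ...]:
        return tuple(self.trait_means)


def _nearest_positive_definite_cov(c: np.ndarray, rel_eps: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues so the residual covariance is positive definite (the
    target covariance minus the genetic covariance need not be)."""
    sym = (c + c.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    floor = rel_eps * float(np.max(np.abs(vals)))
    vals = np.clip(vals, floor, None)
    return vecs @ np.diag(vals) @ vecs.T


def _subpop_class_probs(locus: LocusSpec, shift: float) -> np.ndarray:
    """Shift mass between the two homozygote classes, clipped to feasibility."""
    pa, pb = locus.p_hom_a, locus.p_hom_b
    total = pa + pb
    pb_new = float(np.clip(pb + shift, 0.0, total))
    pa_new = total - pb_new
    return np.array([pa_new, pb_new, locus.p_het, locus.p_missing])


def _genetic_contribution(code: int, effect: float, mean_contrib: float) -> float:
    if code == HOM_A:
        return 0.0
    if code == HOM_B:
        return effect
    if code == HET_AB:
        return effect / 2.0
    return mean_contrib  # missing genotype: expected value, keeps trait unbiased


def generate_panel(
    spec: PanelSpec | None = None, seed: int | None = None
) -> tuple[MarkerGenotypeTable, PhenotypeTable, dict]:
    """Draw a synthetic panel; returns (genotypes, phenotypes, truth record).

    The truth record stores every latent parameter needed to recompute the
    planted quantities: subpopulation labels, per-subpopulation class
    probabilities, allele frequencies, effects, intercepts and the residual
    covariance.
    """
    spec = spec or PanelSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_accessions
    codes = np.array([HOM_A, HOM_B, HET_AB, MISSING], dtype=np.int8)

    labels: list[str] = []
    for name, size in spec.subpop_sizes.items():
        labels.extend([name] * size)
    labels_arr = np.array(labels)
    weights = {g: s / n for g, s in spec.subpop_sizes.items()}
    ladder = centered_ladder(spec.subpop_sizes)

    # per-locus, per-subpop genotype class probabilities; the ladder shifts
    # mass toward the allele that lengthens grains in the longer-grain
    # subpopulations (direction +1, i.e. toward B, when a locus has no GL
    # effect), so structure and phenotype sort together
    class_probs: dict[str, dict[str, np.ndarray]] = {}
    for locus in spec.loci:
        sign = float(np.sign(locus.effects.get("GL", 0.0))) or 1.0
        class_probs[locus.marker_id] = {
            g: _subpop_class_probs(locus, spec.divergence * ladder[g] * sign)
            for g in spec.subpop_sizes
        }

    calls = np.empty((n, len(spec.loci)), dtype=np.int8)
    for j, locus in enumerate(spec.loci):
        for g in spec.subpop_sizes:
            rows = np.flatnonzero(labels_arr == g)
            probs = class_probs[locus.marker_id][g]
            calls[rows, j] = rng.choice(codes, size=rows.size, p=probs)

    traits = spec.trait_names
    k = len(traits)
    # exact first two moments of the genetic contribution under the
    # subpopulation mixture: per locus the dose g is 0 / 1 / 0.5 / E[g]
    # (hom-A / hom-B / het / missing) and the contribution to trait t is
    # g * effect_t, so Cov_genetic = sum_l Var(g_l) e_l e_l^T
    genetic = np.zeros((n, k))
    exp_contrib = np.zeros(k)
    gen_cov = np.zeros((k, k))
    panel_freq_a: dict[str, float] = {}
    for j, locus in enumerate(spec.loci):
        e = np.array([locus.effects.get(t, 0.0) for t in traits])
        probs_g = class_probs[locus.marker_id]
        # mixture class probabilities over the whole panel
        mix = sum(weights[g] * probs_g[g] for g in spec.subpop_sizes)
        pa, pb, ph_, pm = mix
        panel_freq_a[locus.marker_id] = pa + ph_ / 2.0
        scored = max(pa + pb + ph_, 1e-12)
        mean_g = (pb + ph_ / 2.0) / scored  # dose imputed for missing calls
        eg = pb + ph_ / 2.0 + pm * mean_g
        eg2 = pb + ph_ / 4.0 + pm * mean_g**2
        var_g = eg2 - eg**2
        if np.any(e != 0.0):
            exp_contrib += eg * e
            gen_cov += var_g * np.outer(e, e)
            dose = np.array(
                [_genetic_contribution(c, 1.0, mean_g) for c in calls[:, j]]
            )
            genetic += np.outer(dose, e)

    target_sd = np.array([spec.trait_sds[t] for t in traits])
    target_cov = np.asarray(spec.trait_correlations) * np.outer(target_sd, target_sd)
    resid_cov = _nearest_positive_definite_cov(target_cov - gen_cov)
    chol = np.linalg.cholesky(resid_cov)
    resid = rng.standard_normal((n, k)) @ chol.T
    intercepts = np.array([spec.trait_means[t] for t in traits]) - exp_contrib
    values = intercepts + genetic + resid
    values = np.maximum(values, 1e-3)  # traits are physical, strictly positive

    ids = [f"SIM{i + 1:03d}" for i in range(n)]
    defs = [
        MarkerDef(l.marker_id, l.gene, ("A", "B"), dict(l.band_bp))
        for l in spec.loci
    ]
    tab = MarkerGenotypeTable(ids, defs, calls)
    ph = PhenotypeTable(ids, pd.DataFrame(values, index=ids, columns=list(traits)))
    truth = {
        "seed": spec.seed,
        "divergence": spec.divergence,
        "subpop_labels": dict(zip(ids, labels)),
        "subpop_sizes": dict(spec.subpop_sizes),
        "allele_freq_a": {l.marker_id: l.p_allele_a for l in spec.loci},
        "panel_allele_freq_a": panel_freq_a,
        "ladder": ladder,
        "class_probs": {
            m: {g: probs.tolist() for g, probs in by_g.items()}
            for m, by_g in class_probs.items()
        },
        "effects": {l.marker_id: dict(l.effects) for l in spec.loci},
        "intercepts": dict(zip(traits, intercepts.tolist())),
        "residual_covariance": resid_cov.tolist(),
        "trait_order": list(traits),
    }
    return tab, ph, truth


def generate_null_panel(
    spec: PanelSpec | None = None, seed: int | None = None
) -> tuple[MarkerGenotypeTable, PhenotypeTable, dict]:
    """Panel with no allele effects and no subpopulation divergence; used for
    type-I error and differentiation-test calibration."""
    spec = spec or PanelSpec()
    null_loci = tuple(replace(l, effects={}) for l in spec.loci)
    null_spec = replace(spec, loci=null_loci, divergence=0.0)
    return generate_panel(null_spec, seed=seed)
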