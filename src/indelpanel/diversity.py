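"""Per-locus diversity statistics: gene diversity, PIC, heterozygosity.

Gene diversity D = 1 - sum(p_i^2) and the polymorphism information content
PIC = D - sum_{i<j} 2 p_i^2 p_j^2 (Botstein's form) are computed over *allele
classes*.  At a locus where the two declared allele frequencies sum to less
than one (some chromosomes unscored), the deficit forms a third residual
class that enters D and PIC and raises the allele-class count A to 3.  This
residual-class convention is what co-dominant marker software applies to
binary-scored data, and it is the unique convention under which the
reference panel's published D/PIC values are reproducible from its published
frequencies.

The heterozygosity column is *observed* heterozygosity, the proportion of
accessions called heterozygous (het_count / N).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .allele_stats import AlleleFrequencyRecord, residual_frequency

__all__ = [
    "LocusDiversity",
    "locus_diversity",
    "panel_diversity_summary",
    "informativeness_class",
]

RESIDUAL_TOL = 1e-6  # below this, a frequency deficit is float noise, not a class


@dataclass(frozen=True)
class LocusDiversity:
    marker_id: str
    n_allele_classes: int
    major_allele_freq: float
    gene_diversity: float
    observed_heterozygosity: float
    pic: float

    def to_dict(self) -> dict:
        return asdict(self)


def _pic(class_freqs: np.ndarray) -> float:
    d = 1.0 - float(np.sum(class_freqs**2))
    sq = class_freqs**2
    cross = float(np.sum(np.outer(sq, sq))) - float(np.sum(sq**2))
    return d - cross  # cross already counts each (i,j) pair twice


def locus_diversity(
    freqs: list[AlleleFrequencyRecord], het_count: int, n: int
) -> LocusDiversity:
    """Diversity statistics at one locus from its allele frequency records."""
    if not freqs:
        raise ValueError("no frequency records")
    marker_id = freqs[0].marker_id
    p = np.array([r.frequency for r in freqs], dtype=float)
    r = residual_frequency(freqs)  # validates single locus and sum <= 1
    classes = np.append(p, r) if r > RESIDUAL_TOL else p
    d = 1.0 - float(np.sum(classes**2))
    return LocusDiversity(
        marker_id=marker_id,
        n_allele_classes=len(classes),
        major_allele_freq=float(np.max(p)),
        gene_diversity=d,
        observed_heterozygosity=het_count / n,
        pic=_pic(classes),
    )


def panel_diversity_summary(rows: list[LocusDiversity]) -> dict:
    """Unweighted across-locus means of the diversity statistics."""
    if not rows:
        raise ValueError("no loci")
    return {
        "n_loci": len(rows),
        "mean_allele_classes": float(np.mean([r.n_allele_classes for r in rows])),
        "mean_major_allele_freq": float(np.mean([r.major_allele_freq for r in rows])),
        "mean_gene_diversity": float(np.mean([r.gene_diversity for r in rows])),
        "mean_observed_heterozygosity": float(
            np.mean([r.observed_heterozygosity for r in rows])
        ),
        "mean_pic": float(np.mean([r.pic for r in rows])),
    }


def informativeness_class(d: LocusDiversity) -> str:
    """Marker informativeness label: high (D >= 0.5 and PIC >= 0.4),
    low (D <= 0.3 and PIC <= 0.2), else moderate."""
    if d.gene_diversity >= 0.5 and d.pic >= 0.4:
        return "high"
    if d.gene_diversity <= 0.3 and d.pic <= 0.2:
        return "low"
    return "moderate"
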