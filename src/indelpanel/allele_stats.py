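"""Per-locus allele frequency estimation with sampling variance.

Frequencies are chromosome proportions: each accession contributes two
chromosomes, a homozygote contributes 2 copies of its allele, a heterozygote
one of each.  The denominator is fixed at 2 * N_total (all accessions,
including those missing at the locus), so frequencies at a locus with missing
calls sum to less than one; the deficit is the residual (unscored) class used
downstream by the diversity statistics.  The sampling variance convention is
p(1-p)/N_total.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .markers import HET_AB, HOM_A, HOM_B, MarkerGenotypeTable

__all__ = ["AlleleFrequencyRecord", "allele_frequencies", "residual_frequency"]


@dataclass(frozen=True)
class AlleleFrequencyRecord:
    marker_id: str
    allele_id: str
    band_bp: int | None
    hom_count: int          # accessions homozygous for the allele
    het_count: int          # heterozygous accessions carrying it
    allele_count: int       # chromosomes: 2*hom + het
    frequency: float
    sampling_variance: float
    sd: float

    def to_dict(self) -> dict:
        return asdict(self)


def allele_frequencies(
    tab: MarkerGenotypeTable,
    marker_id: str,
    *,
    scored_only: bool = False,
) -> list[AlleleFrequencyRecord]:
    """Allele frequencies at one locus.

    With ``scored_only=True`` the denominator is the number of scored
    chromosomes at the locus instead of 2*N_total (non-default; the fixed
    denominator is the convention the reference panel statistics use).
    """
    j = tab.marker_index(marker_id)
    m = tab.markers[j]
    col = tab.calls[:, j]
    n_total = tab.n_accessions
    hom_a = int(np.sum(col == HOM_A))
    hom_b = int(np.sum(col == HOM_B))
    het = int(np.sum(col == HET_AB))
    denom = 2 * (hom_a + hom_b + het) if scored_only else 2 * n_total
    var_n = (hom_a + hom_b + het) if scored_only else n_total
    records = []
    for allele, hom in (("A", hom_a), ("B", hom_b)):
        count = 2 * hom + het
        p = count / denom if denom else 0.0
        var = p * (1.0 - p) / var_n if var_n else 0.0
        records.append(
            AlleleFrequencyRecord(
                marker_id=marker_id,
                allele_id=allele,
                band_bp=m.band_bp.get(allele),
                hom_count=hom,
                het_count=het,
                allele_count=count,
                frequency=p,
                sampling_variance=var,
                sd=float(np.sqrt(var)),
            )
        )
    return records


def residual_frequency(records: list[AlleleFrequencyRecord]) -> float:
    """Unscored-chromosome proportion at a locus: max(0, 1 - sum of p)."""
    if not records:
        raise ValueError("no records")
    loci = {r.marker_id for r in records}
    if len(loci) > 1:
        raise ValueError(f"records span multiple loci: {sorted(loci)}")
    total = sum(r.frequency for r in records)
    if total > 1.0 + 1e-9:
        raise ValueError(f"frequencies sum to {total} > 1")
    return max(0.0, 1.0 - total)
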