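"""Published summary statistics of the motivating 204-accession rice panel.

The pipeline was designed around a diversity panel of 204 rice accessions
genotyped at 14 InDel loci in nine grain size/weight genes (qPE9~1, GW2,
SLG7, GW5, GS3, GS7, GW8, GS5, GS2) and phenotyped for grain length (GL),
grain width (GW), grain thickness (GT) and thousand grain weight (TGW).
The per-accession raw matrix is not public; what is public are per-locus
genotype-class counts, per-trait moments, trait correlations and per-allele
trait group statistics.  Those published summaries are collected here and
serve two purposes:

* defaults for :mod:`indelpanel.simulate`, so synthetic panels reproduce the
  panel's statistical structure;
* exactly reproducible inputs for the per-locus statistics (allele
  frequencies, diversity, pyramiding summaries) that depend only on counts
  and group means, not on the raw matrix.

Allele counts are chromosome counts out of 2N = 408 (two per accession);
``het`` is the number of heterozygous accessions at the locus.  Homozygote
accession counts follow as (allele_count - het) / 2.
"""

from __future__ import annotations

import numpy as np

from .markers import HET_AB, HOM_A, HOM_B, MISSING, MarkerDef, MarkerGenotypeTable

N_ACCESSIONS = 204

#: marker -> (gene, band_A bp, band_B bp, A-allele count, B-allele count, het accessions)
REFERENCE_LOCI: dict[str, tuple[str, int, int, int, int, int]] = {
    "qPE9~1-InDel": ("qPE9~1", 270, 350, 364, 44, 0),
    "GW2-InDel": ("GW2", 500, 520, 290, 116, 0),
    "SLG7-InDel": ("SLG7", 450, 500, 308, 100, 0),
    "GW5-InDel": ("GW5", 450, 500, 294, 114, 0),
    "GS3-InDel": ("GS3", 650, 750, 284, 124, 0),
    "GS7-InDel": ("GS7", 200, 250, 230, 176, 50),
    "GW8-InDel": ("GW8", 350, 450, 122, 256, 0),
    "GW8-InDel1A": ("GW8", 350, 450, 127, 271, 1),
    "GW8-InDel2B": ("GW8", 270, 300, 188, 212, 0),
    "GS5-InDel1A": ("GS5", 500, 530, 181, 215, 1),
    "GS5-InDel2B": ("GS5", 500, 550, 14, 370, 0),
    "GS2-InDel": ("GS2", 400, 500, 65, 339, 1),
    "GS2-InDel1A": ("GS2", 400, 450, 215, 185, 1),
    "GS2-InDel2B": ("GS2", 250, 300, 101, 295, 1),
}

MARKER_IDS = list(REFERENCE_LOCI)

#: per-trait (min, max, mean, sd) in the panel; GL/GW/GT mm, TGW g
TRAIT_MOMENTS: dict[str, tuple[float, float, float, float]] = {
    "GL": (6.010, 10.650, 8.162, 0.929),
    "GW": (2.050, 3.850, 2.932, 0.270),
    "GT": (1.860, 2.860, 2.156, 0.165),
    "TGW": (17.0, 37.0, 25.858, 2.841),
}

TRAIT_ORDER = ("GL", "GW", "GT", "TGW")

#: Pearson correlations among traits (lower triangle as reported)
TRAIT_CORRELATIONS = np.array(
    [
        [1.000, -0.604, -0.398, 0.249],
        [-0.604, 1.000, 0.686, 0.374],
        [-0.398, 0.686, 1.000, 0.491],
        [0.249, 0.374, 0.491, 1.000],
    ]
)

#: Per-marker allele-group trait statistics: marker -> list of
#: (allele, n, {trait: (mean, sd, duncan_letter)}), plus per-trait ANOVA p.
#: These are the published one-way comparisons of accessions grouped by the
#: allele they carry (heterozygotes a separate group only at GS7, where the
#: het class is large).
REFERENCE_ASSOCIATIONS: dict[str, dict] = {
    "qPE9~1-InDel": {
        "p": {"GL": 0.32, "GW": 0.49, "GT": 0.86, "TGW": 0.32},
        "groups": [
            ("A", 182, {"GL": (7.94, 0.920, "b"), "GW": (2.95, 0.275, "b"),
                        "GT": (2.13, 0.167, "a"), "TGW": (26.0, 2.837, "a")}),
            ("B", 22, {"GL": (8.24, 0.961, "a"), "GW": (3.06, 0.209, "a"),
                       "GT": (2.12, 0.149, "a"), "TGW": (26.5, 2.672, "a")}),
        ],
    },
    "GW2-InDel": {
        "p": {"GL": 0.56, "GW": 0.17, "GT": 0.47, "TGW": 0.52},
        "groups": [
            ("A", 145, {"GL": (7.98, 0.934, "a"), "GW": (2.95, 0.273, "b"),
                        "GT": (2.13, 0.167, "a"), "TGW": (26.0, 2.984, "a")}),
            ("B", 58, {"GL": (8.03, 0.907, "a"), "GW": (3.02, 0.253, "a"),
                       "GT": (2.12, 0.160, "a"), "TGW": (26.0, 2.441, "a")}),
        ],
    },
    "SLG7-InDel": {
        "p": {"GL": 0.89, "GW": 0.98, "GT": 0.23, "TGW": 0.027},
        "groups": [
            ("A", 154, {"GL": (7.97, 0.933, "a"), "GW": (2.95, 0.268, "a"),
                        "GT": (2.12, 0.160, "a"), "TGW": (26.0, 2.857, "a")}),
            ("B", 50, {"GL": (8.03, 0.907, "a"), "GW": (2.99, 0.273, "a"),
                       "GT": (2.16, 0.178, "a"), "TGW": (26.0, 2.695, "a")}),
        ],
    },
    "GW5-InDel": {
        "p": {"GL": 0.93, "GW": 0.047, "GT": 0.29, "TGW": 0.031},
        "groups": [
            ("A", 147, {"GL": (7.98, 0.894, "a"), "GW": (2.95, 0.261, "a"),
                        "GT": (2.13, 0.163, "a"), "TGW": (25.0, 2.847, "b")}),
            ("B", 57, {"GL": (7.93, 1.008, "a"), "GW": (3.00, 0.285, "a"),
                       "GT": (2.13, 0.170, "a"), "TGW": (26.0, 2.708, "a")}),
        ],
    },
    "GS3-InDel": {
        "p": {"GL": 0.019, "GW": 0.44, "GT": 0.012, "TGW": 0.61},
        "groups": [
            ("A", 142, {"GL": (7.90, 0.926, "a"), "GW": (2.97, 0.279, "a"),
                        "GT": (2.14, 0.166, "a"), "TGW": (26.0, 2.729, "a")}),
            ("B", 62, {"GL": (8.16, 0.917, "a"), "GW": (2.95, 0.244, "a"),
                       "GT": (2.11, 0.159, "a"), "TGW": (25.5, 3.054, "a")}),
        ],
    },
    "GS7-InDel": {
        "p": {"GL": 0.022, "GW": 0.56, "GT": 0.0194, "TGW": 0.96},
        "groups": [
            ("A", 90, {"GL": (8.19, 0.921, "a"), "GW": (2.95, 0.299, "a"),
                       "GT": (2.10, 0.162, "b"), "TGW": (26.0, 2.889, "a")}),
            ("B", 63, {"GL": (8.08, 0.828, "a"), "GW": (2.97, 0.190, "a"),
                       "GT": (2.12, 0.162, "b"), "TGW": (26.0, 2.504, "a")}),
            ("AB", 50, {"GL": (7.57, 0.974, "b"), "GW": (2.95, 0.293, "a"),
                        "GT": (2.20, 0.159, "a"), "TGW": (25.0, 3.116, "b")}),
        ],
    },
    "GW8-InDel": {
        "p": {"GL": 0.0001, "GW": 0.0001, "GT": 0.0001, "TGW": 0.06},
        "groups": [
            ("A", 60, {"GL": (7.34, 0.578, "b"), "GW": (3.05, 0.203, "b"),
                       "GT": (2.27, 0.133, "a"), "TGW": (25.0, 2.694, "b")}),
            ("B", 128, {"GL": (8.41, 0.890, "a"), "GW": (2.92, 0.259, "a"),
                        "GT": (2.08, 0.118, "b"), "TGW": (26.0, 2.583, "a")}),
        ],
    },
    "GW8-InDel1A": {
        "p": {"GL": 0.0001, "GW": 0.0001, "GT": 0.0001, "TGW": 0.062},
        "groups": [
            ("A", 63, {"GL": (7.42, 0.667, "b"), "GW": (3.06, 0.231, "b"),
                       "GT": (2.27, 0.169, "a"), "TGW": (26.0, 3.309, "a")}),
            ("B", 135, {"GL": (8.40, 0.901, "a"), "GW": (2.91, 0.260, "a"),
                        "GT": (2.09, 0.118, "b"), "TGW": (26.0, 2.615, "a")}),
        ],
    },
    "GW8-InDel2B": {
        "p": {"GL": 0.0045, "GW": 0.003, "GT": 0.0001, "TGW": 0.0001},
        "groups": [
            ("A", 94, {"GL": (7.64, 0.965, "b"), "GW": (3.00, 0.238, "a"),
                       "GT": (2.19, 0.158, "a"), "TGW": (26.0, 2.824, "a")}),
            ("B", 106, {"GL": (8.35, 0.852, "a"), "GW": (2.92, 0.274, "b"),
                        "GT": (2.10, 0.129, "b"), "TGW": (25.0, 2.611, "b")}),
        ],
    },
    "GS5-InDel1A": {
        "p": {"GL": 0.12, "GW": 0.75, "GT": 0.22, "TGW": 0.016},
        "groups": [
            ("A", 90, {"GL": (7.79, 0.921, "b"), "GW": (2.97, 0.259, "a"),
                       "GT": (2.13, 0.165, "a"), "TGW": (24.0, 3.180, "b")}),
            ("B", 107, {"GL": (8.16, 0.925, "a"), "GW": (2.94, 0.272, "a"),
                        "GT": (2.12, 0.150, "a"), "TGW": (27.0, 2.535, "a")}),
        ],
    },
    "GS5-InDel2B": {
        "p": {"GL": 0.87, "GW": 0.33, "GT": 0.44, "TGW": 0.038},
        "groups": [
            ("A", 7, {"GL": (7.40, 0.900, "b"), "GW": (2.78, 0.261, "b"),
                      "GT": (2.14, 0.161, "a"), "TGW": (23.0, 2.729, "b")}),
            ("B", 185, {"GL": (8.24, 0.934, "a"), "GW": (2.99, 0.265, "a"),
                        "GT": (2.21, 0.161, "b"), "TGW": (26.2, 2.899, "a")}),
        ],
    },
    "GS2-InDel": {
        "p": {"GL": 0.96, "GW": 0.99, "GT": 0.18, "TGW": 0.58},
        "groups": [
            ("A", 32, {"GL": (7.57, 1.035, "a"), "GW": (3.03, 0.314, "a"),
                       "GT": (2.22, 0.180, "a"), "TGW": (27.0, 3.258, "a")}),
            ("B", 169, {"GL": (7.98, 0.900, "a"), "GW": (2.94, 0.261, "b"),
                        "GT": (2.12, 0.161, "b"), "TGW": (25.0, 2.729, "b")}),
        ],
    },
    "GS2-InDel1A": {
        "p": {"GL": 0.0001, "GW": 0.0005, "GT": 0.0001, "TGW": 0.89},
        "groups": [
            ("A", 107, {"GL": (7.66, 0.820, "b"), "GW": (3.01, 0.246, "a"),
                        "GT": (2.19, 0.180, "a"), "TGW": (26.0, 2.943, "a")}),
            ("B", 92, {"GL": (8.44, 0.908, "a"), "GW": (2.84, 0.275, "b"),
                       "GT": (2.09, 0.126, "b"), "TGW": (26.0, 2.754, "a")}),
        ],
    },
    "GS2-InDel2B": {
        "p": {"GL": 0.0001, "GW": 0.0001, "GT": 0.0074, "TGW": 0.12},
        "groups": [
            ("A", 50, {"GL": (9.32, 0.951, "a"), "GW": (2.65, 0.303, "b"),
                       "GT": (2.08, 0.153, "b"), "TGW": (26.0, 3.136, "a")}),
            ("B", 147, {"GL": (7.81, 0.742, "b"), "GW": (3.01, 0.201, "a"),
                        "GT": (2.16, 0.155, "a"), "TGW": (25.0, 2.761, "b")}),
        ],
    },
}

#: grain-type subpopulation sizes (short, medium, long, extra-long)
SUBPOP_SIZES = {"short": 55, "medium": 78, "long": 48, "extra-long": 23}


def reference_association_results(trait: str) -> list:
    """Published allele-group comparisons as AssociationResult records.

    F statistics were not published; they are set to NaN.  Used to drive the
    favorable-allele / pyramiding stages from the published group statistics
    alone (the raw per-accession matrix not being public).
    """
    from .association import AssociationResult, GroupStats

    out = []
    for marker_id, entry in REFERENCE_ASSOCIATIONS.items():
        groups = tuple(
            GroupStats(allele=a, n=n, mean=tr[trait][0], sd=tr[trait][1],
                       letter=tr[trait][2])
            for a, n, tr in entry["groups"]
        )
        out.append(
            AssociationResult(
                marker_id=marker_id, trait=trait, groups=groups,
                f_statistic=float("nan"), p_value=entry["p"][trait],
            )
        )
    return out


def reference_marker_defs() -> list[MarkerDef]:
    return [
        MarkerDef(mid, gene, ("A", "B"), {"A": ba, "B": bb})
        for mid, (gene, ba, bb, *_rest) in REFERENCE_LOCI.items()
    ]


def class_counts(marker_id: str) -> dict[str, int]:
    """Genotype-class accession counts at one locus (hom_A/hom_B/het/missing)."""
    _, _, _, a_count, b_count, het = REFERENCE_LOCI[marker_id]
    hom_a = (a_count - het) // 2
    hom_b = (b_count - het) // 2
    missing = N_ACCESSIONS - hom_a - hom_b - het
    if (a_count - het) % 2 or (b_count - het) % 2 or missing < 0:
        raise ValueError(f"inconsistent reference counts at {marker_id}")
    return {"hom_a": hom_a, "hom_b": hom_b, "het": het, "missing": missing}


def build_reference_genotype_table() -> MarkerGenotypeTable:
    """A deterministic 204-accession table reproducing the published per-locus
    genotype-class counts.

    Calls are assigned per locus independently (first the A-homozygotes, then
    B-homozygotes, heterozygotes, missing), so every per-locus statistic
    (allele frequency, variance, diversity, PIC, heterozygosity) equals the
    published panel's exactly.  Across-locus structure (distances, trees,
    ordination) is NOT meaningful for this table; use the synthetic generator
    for those stages.
    """
    defs = reference_marker_defs()
    calls = np.empty((N_ACCESSIONS, len(defs)), dtype=np.int8)
    for j, m in enumerate(defs):
        c = class_counts(m.marker_id)
        col = (
            [HOM_A] * c["hom_a"] + [HOM_B] * c["hom_b"]
            + [HET_AB] * c["het"] + [MISSING] * c["missing"]
        )
        calls[:, j] = col
    ids = [f"ACC{i + 1:03d}" for i in range(N_ACCESSIONS)]
    return MarkerGenotypeTable(ids, defs, calls)
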