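"""Data model and CSV I/O for co-dominant InDel marker panels.

An InDel marker scores an insertion/deletion polymorphism as the presence or
absence of band-length variants on a gel.  Each locus declares two alleles
(A and B); an accession is scored as homozygous A, homozygous B, heterozygous
(both bands) or missing.  All distance-based stages of the pipeline operate on
the derived *binary allele-presence matrix*: one column per (marker, allele),
1 where the accession carries the allele, 0 where it does not, and missing
propagated as missing (never as 0 -- absence of a band is data, absence of a
call is not).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HOM_A",
    "HOM_B",
    "HET_AB",
    "MISSING",
    "CALL_LABELS",
    "MarkerDef",
    "MarkerGenotypeTable",
    "PhenotypeTable",
    "BinaryAlleleMatrix",
    "CallVocabulary",
    "read_genotype_table",
    "write_genotype_table",
    "read_marker_defs",
    "write_marker_defs",
    "read_phenotype_table",
    "write_phenotype_table",
    "to_binary_matrix",
    "write_tables",
]

# Genotype call codes (int8 storage).
HOM_A: int = 0
HOM_B: int = 1
HET_AB: int = 2
MISSING: int = -1

CALL_LABELS: dict[int, str] = {HOM_A: "A", HOM_B: "B", HET_AB: "AB", MISSING: "NA"}

TRAIT_NAMES = ("GL", "GW", "GT", "TGW")


@dataclass(frozen=True)
class MarkerDef:
    """One InDel locus: its gene, allele labels and band sizes (bp)."""

    marker_id: str
    gene: str
    allele_ids: tuple[str, ...] = ("A", "B")
    band_bp: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.allele_ids:
            raise ValueError(f"{self.marker_id}: allele_ids must be non-empty")
        if len(set(self.allele_ids)) != len(self.allele_ids):
            raise ValueError(f"{self.marker_id}: duplicate allele ids")
        if self.band_bp:
            if set(self.band_bp) != set(self.allele_ids):
                raise ValueError(
                    f"{self.marker_id}: band_bp keys must equal allele_ids"
                )
            for a, bp in self.band_bp.items():
                if int(bp) <= 0:
                    raise ValueError(f"{self.marker_id}/{a}: band length must be > 0")


@dataclass(frozen=True)
class CallVocabulary:
    """Mapping from file tokens to genotype-call states.

    The input format is not standardized across genotyping labs, so the token
    set is configurable; defaults accept "A", "B", "AB" and "NA"/"" for
    missing, with "H" as a synonym for the heterozygote.
    """

    hom_a: tuple[str, ...] = ("A",)
    hom_b: tuple[str, ...] = ("B",)
    het: tuple[str, ...] = ("AB", "H")
    missing: tuple[str, ...] = ("NA", "-", "")

    def decode(self, token: str) -> int:
        t = token.strip()
        if t in self.hom_a:
            return HOM_A
        if t in self.hom_b:
            return HOM_B
        if t in self.het:
            return HET_AB
        if t in self.missing:
            return MISSING
        raise ValueError(f"unknown call token {token!r}")


@dataclass
class MarkerGenotypeTable:
    """N accessions x L markers grid of genotype calls."""

    accession_ids: list[str]
    markers: list[MarkerDef]
    calls: np.ndarray  # int8, shape (N, L), values in {HOM_A, HOM_B, HET_AB, MISSING}

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, l = self.calls.shape
        if len(self.accession_ids) != n or len(self.markers) != l:
            raise ValueError("calls shape does not match accession/marker lists")
        if len(set(self.accession_ids)) != n:
            dupes = {a for a in self.accession_ids if self.accession_ids.count(a) > 1}
            raise ValueError(f"duplicate accession ids: {sorted(dupes)}")
        if n < 2 or l < 1:
            raise ValueError("need at least 2 accessions and 1 marker")
        valid = np.isin(self.calls, (HOM_A, HOM_B, HET_AB, MISSING))
        if not valid.all():
            raise ValueError("invalid genotype call code in table")

    @property
    def n_accessions(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"unknown marker {marker_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        data = np.vectorize(CALL_LABELS.get)(self.calls)
        return pd.DataFrame(data, index=self.accession_ids, columns=self.marker_ids)


@dataclass
class PhenotypeTable:
    """Per-accession grain traits: GL/GW/GT in mm, TGW in g; NaN = missing."""

    accession_ids: list[str]
    traits: pd.DataFrame  # index = accession_ids, columns = trait names

    def __post_init__(self) -> None:
        if list(self.traits.index) != list(self.accession_ids):
            self.traits = self.traits.loc[self.accession_ids]
        vals = self.traits.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise ValueError("non-missing trait values must be positive")

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits.columns)

    def values(self, trait: str) -> np.ndarray:
        if trait not in self.traits.columns:
            raise KeyError(f"unknown trait {trait!r}")
        return self.traits[trait].to_numpy(dtype=float)


@dataclass
class BinaryAlleleMatrix:
    """Allele-presence scores: 1 present, 0 absent, NaN missing."""

    accession_ids: list[str]
    column_ids: list[tuple[str, str]]  # (marker_id, allele_id)
    cells: np.ndarray  # float, shape (N, sum of allele counts)
    marker_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float)
        if self.cells.shape != (len(self.accession_ids), len(self.column_ids)):
            raise ValueError("cells shape does not match ids")
        if not self.marker_ids:
            seen: list[str] = []
            for m, _ in self.column_ids:
                if m not in seen:
                    seen.append(m)
            self.marker_ids = seen

    def marker_columns(self, marker_id: str) -> list[int]:
        return [i for i, (m, _) in enumerate(self.column_ids) if m == marker_id]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{m}:{a}" for m, a in self.column_ids]
        return pd.DataFrame(self.cells, index=self.accession_ids, columns=cols)


def to_binary_matrix(tab: MarkerGenotypeTable) -> BinaryAlleleMatrix:
    """Expand genotype calls into the 0/1 allele-presence matrix.

    Per marker the two allele columns encode HOM_A -> (1,0), HOM_B -> (0,1),
    HET_AB -> (1,1) and MISSING -> (NaN,NaN).  Column order follows marker
    order then allele order, so the four call states map to four distinct
    column pairs (the encoding is injective per marker).
    """
    n = tab.n_accessions
    columns: list[tuple[str, str]] = []
    blocks: list[np.ndarray] = []
    for j, m in enumerate(tab.markers):
        if len(m.allele_ids) != 2:
            raise ValueError(f"{m.marker_id}: binary encoding requires 2 alleles")
        col = tab.calls[:, j]
        block = np.full((n, 2), np.nan)
        block[col == HOM_A] = (1.0, 0.0)
        block[col == HOM_B] = (0.0, 1.0)
        block[col == HET_AB] = (1.0, 1.0)
        blocks.append(block)
        columns.extend((m.marker_id, a) for a in m.allele_ids)
    cells = np.hstack(blocks)
    return BinaryAlleleMatrix(list(tab.accession_ids), columns, cells)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_marker_defs(path) -> list[MarkerDef]:
    """Read marker metadata: marker, gene, band_A, band_B columns."""
    df = pd.read_csv(path, dtype=str)
    required = {"marker", "gene", "band_A", "band_B"}
    if not required.issubset(df.columns):
        raise ValueError(f"marker definition file must have columns {sorted(required)}")
    return [
        MarkerDef(
            marker_id=row["marker"],
            gene=row["gene"],
            allele_ids=("A", "B"),
            band_bp={"A": int(row["band_A"]), "B": int(row["band_B"])},
        )
        for _, row in df.iterrows()
    ]


def write_marker_defs(defs: Sequence[MarkerDef], path) -> None:
    pd.DataFrame(
        {
            "marker": [m.marker_id for m in defs],
            "gene": [m.gene for m in defs],
            "band_A": [m.band_bp.get("A", "") for m in defs],
            "band_B": [m.band_bp.get("B", "") for m in defs],
        }
    ).to_csv(path, index=False)


def read_genotype_table(
    path,
    marker_defs: Sequence[MarkerDef],
    vocab: CallVocabulary | None = None,
) -> MarkerGenotypeTable:
    """Read an accession x marker call CSV (first column = accession id)."""
    vocab = vocab or CallVocabulary()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    acc_col = df.columns[0]
    accession_ids = df[acc_col].tolist()
    by_id = {m.marker_id: m for m in marker_defs}
    markers: list[MarkerDef] = []
    for col in df.columns[1:]:
        if col not in by_id:
            raise ValueError(f"header marker {col!r} not in marker definitions")
        markers.append(by_id[col])
    calls = np.empty((len(accession_ids), len(markers)), dtype=np.int8)
    for j, m in enumerate(markers):
        for i, token in enumerate(df[m.marker_id]):
            calls[i, j] = vocab.decode(token)
    return MarkerGenotypeTable(accession_ids, markers, calls)


def write_genotype_table(tab: MarkerGenotypeTable, path) -> None:
    frame = tab.to_frame()
    frame.index.name = "accession"
    frame.to_csv(path)


def read_phenotype_table(path, traits: Iterable[str] = TRAIT_NAMES) -> PhenotypeTable:
    df = pd.read_csv(path)
    acc_col = df.columns[0]
    df = df.set_index(acc_col)
    present = [t for t in traits if t in df.columns]
    if not present:
        raise ValueError(f"phenotype file has none of the trait columns {list(traits)}")
    return PhenotypeTable(list(df.index.astype(str)), df[present].astype(float))


def write_phenotype_table(ph: PhenotypeTable, path) -> None:
    out = ph.traits.copy()
    out.index.name = "accession"
    out.to_csv(path)


def write_tables(obj, path, columns: Sequence[str] | None = None) -> None:
    """Write any pipeline result that exposes ``to_frame()`` (or is a
    DataFrame / list of records) as CSV.  ``columns`` supplies the header for
    an empty record list."""
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False)
        return
    if hasattr(obj, "to_frame"):
        frame = obj.to_frame()
        frame.to_csv(path, index=frame.index.name is not None or not isinstance(
            frame.index, pd.RangeIndex))
        return
    if isinstance(obj, (list, tuple)):
        rows = [r.to_dict() if hasattr(r, "to_dict") else dict(r) for r in obj]
        cols = list(rows[0]) if rows else list(columns or [])
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
        return
    raise TypeError(f"cannot serialize object of type {type(obj).__name__}")
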