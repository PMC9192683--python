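"""Domain types and I/O for phenotype-by-sample community data.

The survey design this package serves compares sessile-invertebrate
communities across benthic (sub-)habitats: fleshy red-algae (*Phyllophora
crispa*) mats, seagrass (*Posidonia oceanica*) leaves and rhizomes, and the
combined seagrass "holobiont" (leaves + subsurface structures).  Specimens
that cannot be identified to species level are distinguished as visual
*phenotypes*; colonies of colonial taxa count as individuals.

Two in-memory containers carry the data through the workflow:

``CountTable``
    integer phenotype x sample counts plus the surface-area metadata needed
    to normalise abundances to habitat-m2 and seafloor-m2.
``IncidenceMatrix``
    the binary presence table derived from counts; all Hill-number
    estimation downstream is incidence-based (sampling units, not
    individuals, are the unit of replication).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("habdiv")

#: Closed vocabulary of higher taxa recorded by the survey protocol.
TAXA = frozenset(
    {
        "Ascidiacea",
        "Bryozoa",
        "Cnidaria",
        "Entoprocta",
        "Foraminifera",
        "Mollusca (Bivalvia)",
        "Polychaeta (Sedentaria)",
        "Rotifera",
        "Porifera",
    }
)


class Habitat(str, Enum):
    """Surveyed (sub-)habitats.  ``PO_holobiont`` is derived, never stored."""

    PC_MAT = "PC_mat"
    PO_LEAVES = "PO_leaves"
    PO_RHIZOMES = "PO_rhizomes"
    PO_HOLOBIONT = "PO_holobiont"


#: Planar sampling-frame areas in m2, by substrate type.
FRAME_AREAS = {
    "PC_mat": 0.09,          # 30 x 30 cm algal-mat frame
    "PO_rhizomes": 0.16,     # 40 x 40 cm rhizome-density frame
    "hard_bottom": 0.04,     # 20 x 20 cm chain frame on bare rock
}

_LONG_COLUMNS = ["phenotype_id", "taxon", "sample_id", "habitat", "count"]


@dataclass
class PhenotypeOccurrence:
    """One phenotype record in one sampling unit."""

    phenotype_id: str
    taxon: str
    sample_id: str
    habitat: Habitat
    count: int

    def __post_init__(self) -> None:
        if self.taxon not in TAXA:
            raise ValueError(f"unknown taxon {self.taxon!r}; expected one of {sorted(TAXA)}")
        if self.count < 0:
            raise ValueError(f"negative count {self.count} for {self.phenotype_id!r}")
        self.habitat = Habitat(self.habitat)
        if self.habitat is Habitat.PO_HOLOBIONT:
            raise ValueError("PO_holobiont is a derived habitat and is never stored")


@dataclass
class CountTable:
    """Phenotype x sample counts with surface-area metadata.

    Parameters
    ----------
    counts
        Integer DataFrame, phenotypes as rows, sampling units as columns.
    habitat
        Habitat the samples came from, if homogeneous.
    taxa
        Optional Series mapping phenotype_id -> higher taxon.
    sample_area_3d
        Optional Series of per-sample 3-D substrate surface area (m2).
    enlargement_factor
        Dimensionless EF (>= 1) converting habitat-m2 to seafloor-m2.
    frame_area
        Planar frame area in m2 (0.09 mats / 0.16 rhizome frames / 0.04 rock).
    """

    counts: pd.DataFrame
    habitat: Optional[Habitat] = None
    taxa: Optional[pd.Series] = None
    sample_area_3d: Optional[pd.Series] = None
    enlargement_factor: Optional[float] = None
    frame_area: Optional[float] = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.shape[0] == 0 or c.shape[1] == 0:
            raise ValueError("count table must have at least one phenotype and one sample")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if (arr < 0).any():
            raise ValueError("negative counts are not allowed")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        self.counts = c.astype(np.int64)
        if c.index.duplicated().any():
            raise ValueError("duplicate phenotype rows")
        if self.habitat is not None:
            self.habitat = Habitat(self.habitat)
        if self.taxa is not None:
            bad = set(self.taxa.dropna()) - TAXA
            if bad:
                raise ValueError(f"unknown taxon codes {sorted(bad)}")
        if self.sample_area_3d is not None:
            self.sample_area_3d = self.sample_area_3d.reindex(c.columns)
            if (self.sample_area_3d <= 0).any() or self.sample_area_3d.isna().any():
                raise ValueError("sample_area_3d must be positive for every sample")
        if self.enlargement_factor is not None and self.enlargement_factor < 1:
            raise ValueError("enlargement_factor must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass
class IncidenceMatrix:
    """Binary phenotype x sampling-unit presence table for one habitat."""

    presence: pd.DataFrame
    habitat: Optional[Habitat] = None

    def __post_init__(self) -> None:
        arr = self.presence.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("presence entries must be 0/1")
        if self.presence.index.duplicated().any():
            raise ValueError("duplicate phenotype rows")
        self.presence = self.presence.astype(np.int8)
        if self.habitat is not None:
            self.habitat = Habitat(self.habitat)

    @property
    def T(self) -> int:
        """Number of sampling units."""
        return self.presence.shape[1]

    @property
    def phenotypes(self) -> list:
        return list(self.presence.index)

    def detected_set(self) -> set:
        """Phenotypes with at least one occurrence."""
        pres = self.presence.sum(axis=1) > 0
        return set(self.presence.index[pres])


@dataclass
class HabitatAbundance:
    """Mean +/- SE abundance per habitat-m2 and per seafloor-m2."""

    ind_per_habitat_m2: float
    se_habitat: float
    ind_per_seafloor_m2: float
    se_seafloor: float
    n_samples: int


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path, dialect: str = "long") -> CountTable:
    """Read a CSV count table in ``long`` or ``wide`` dialect.

    The long dialect has columns (phenotype_id, taxon, sample_id, habitat,
    count); the wide dialect has phenotypes as rows and samples as columns.
    """
    path = Path(path)
    try:
        if dialect == "long":
            df = pd.read_csv(path)
        elif dialect == "wide":
            df = pd.read_csv(path, index_col=0)
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise ValueError(f"malformed CSV {path}: {exc}") from exc

    if dialect == "wide":
        return CountTable(counts=df)

    missing = [c for c in _LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: long dialect missing columns {missing}")
    bad_taxa = set(df["taxon"].dropna()) - TAXA
    if bad_taxa:
        raise ValueError(f"{path}: unknown taxon codes {sorted(bad_taxa)}")
    if (df["count"] < 0).any():
        line = int(df.index[df["count"] < 0][0]) + 2  # header + 1-based
        raise ValueError(f"{path}: negative count at line {line}")
    habitats = set(df["habitat"].unique())
    habitat = Habitat(habitats.pop()) if len(habitats) == 1 else None
    wide = df.pivot_table(
        index="phenotype_id", columns="sample_id", values="count",
        aggfunc="sum", fill_value=0,
    )
    taxa = df.drop_duplicates("phenotype_id").set_index("phenotype_id")["taxon"]
    return CountTable(counts=wide, habitat=habitat, taxa=taxa.reindex(wide.index))


def write_count_table(table: CountTable, path: str | Path, dialect: str = "wide") -> None:
    """Write a count table back to CSV (inverse of :func:`read_count_table`)."""
    path = Path(path)
    if dialect == "wide":
        table.counts.to_csv(path)
        return
    if dialect == "long":
        long = table.counts.stack().rename("count").reset_index()
        long.columns = ["phenotype_id", "sample_id", "count"]
        long["taxon"] = (
            table.taxa.reindex(long["phenotype_id"]).to_numpy()
            if table.taxa is not None else "Bryozoa"
        )
        long["habitat"] = (table.habitat or Habitat.PC_MAT).value
        long[_LONG_COLUMNS].to_csv(path, index=False)
        return
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def to_incidence(counts: CountTable) -> IncidenceMatrix:
    """Collapse counts to presence/absence (1 iff count > 0).

    All-zero phenotype rows are retained (they carry no incidence mass and
    cannot affect any estimator) but are logged for the analyst.
    """
    presence = (counts.counts > 0).astype(np.int8)
    zero = presence.sum(axis=1) == 0
    if zero.any():
        logger.warning(
            "to_incidence: %d all-zero phenotype row(s) retained: %s",
            int(zero.sum()), list(presence.index[zero]),
        )
    return IncidenceMatrix(presence=presence, habitat=counts.habitat)


def derive_holobiont(leaves: IncidenceMatrix, rhizomes: IncidenceMatrix) -> IncidenceMatrix:
    """Combine leaf and rhizome sampling units into the seagrass holobiont.

    Units are concatenated as independent sampling units (T = T_leaves +
    T_rhizomes); the phenotype set is the union of the two inputs.
    """
    if leaves.habitat not in (None, Habitat.PO_LEAVES):
        raise ValueError(f"leaves input has habitat {leaves.habitat}")
    if rhizomes.habitat not in (None, Habitat.PO_RHIZOMES):
        raise ValueError(f"rhizomes input has habitat {rhizomes.habitat}")
    overlap = set(leaves.presence.columns) & set(rhizomes.presence.columns)
    if overlap:
        raise ValueError(f"overlapping sample_ids between leaves and rhizomes: {sorted(overlap)}")
    combined = (
        pd.concat([leaves.presence, rhizomes.presence], axis=1)
        .fillna(0)
        .astype(np.int8)
    )
    return IncidenceMatrix(presence=combined, habitat=Habitat.PO_HOLOBIONT)


def normalize_abundance(counts: CountTable) -> HabitatAbundance:
    """Normalise raw counts to individuals per habitat-m2 and seafloor-m2.

    Each sample's total count is divided by that sample's 3-D substrate
    surface area, then multiplied by the habitat enlargement factor for the
    seafloor projection; means and standard errors are taken over samples
    (per-sample computation, then averaging).
    """
    if counts.sample_area_3d is None:
        raise ValueError("sample_area_3d metadata required for normalisation")
    if counts.enlargement_factor is None:
        raise ValueError("enlargement_factor metadata required for normalisation")
    totals = counts.counts.sum(axis=0).astype(float)
    area = counts.sample_area_3d
    if (area <= 0).any():
        raise ValueError("zero or negative sample area")
    habitat_density = totals / area
    seafloor_density = habitat_density * counts.enlargement_factor
    n = len(totals)

    def _se(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    return HabitatAbundance(
        ind_per_habitat_m2=float(habitat_density.mean()),
        se_habitat=_se(habitat_density),
        ind_per_seafloor_m2=float(seafloor_density.mean()),
        se_seafloor=_se(seafloor_density),
        n_samples=n,
    )
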