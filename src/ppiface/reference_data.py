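"""The bundled reference dataset of druggable protein-protein interfaces.

Seventeen protein/protein complexes from fourteen protein families, each
with at least one non-covalent small-molecule inhibitor bound at the
interface, together with their published interface descriptor panel
(planarity, eccentricity, secondary-structure pair, gap volume and index,
hydrogen-bond density, salt bridges, buried surface area, inhibitor
coverage, unbound-form RMSD, interface pocket volume, segment count).
Complexes split into class I (peptide-like partner, fewer than six
interface segments; micromolar affinities) and class II (globular
partner, more segments; nano- to sub-nanomolar affinities).

The transcription is a reviewed CSV asset with dot-decimal numbers;
missing affinities are stored as missing, never zero, and inhibition
constants (Ki) are flagged as such.  The per-complex percentage of
charged interface residues is not part of the published panel (only its
group statistics are) and is carried as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

#: descriptor columns of the reference panel, in canonical order
DESCRIPTOR_COLUMNS = [
    "planarity", "eccentricity", "gap_volume", "gap_index", "hb_per_100A2",
    "salt_bridges", "asa_mean_side", "h_asa_percent", "rmsd_unbound",
    "pocket_volume", "n_segments", "pct_charged_residues",
]

#: the six descriptors used for multivariate clustering and comparison
KEY_DESCRIPTORS = [
    "asa_mean_side", "n_segments", "gap_volume", "pocket_volume",
    "hb_per_100A2", "pct_charged_residues",
]

#: published group statistics for the charged-residue percentage (the
#: per-complex values are not part of the printed panel)
PCT_CHARGED_OVERALL = (18.9, 13.8)   # mean, sd for the reference interfaces
PCT_CHARGED_TRANSIENT = (27.0, 12.5)  # mean, sd for transient heterodimers


class ReferenceDataError(RuntimeError):
    """Bundled reference file missing or failing its integrity checks."""


@dataclass
class GroupStats:
    """(mean, variance, n) of one descriptor in one group of complexes.

    The variance uses the n-1 denominator, matching the published
    group standard deviations.
    """

    mean: float
    variance: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("insufficient group size: variance needs n >= 2")
        if self.variance < 0:
            raise ValueError("variance must be non-negative")

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))


@dataclass
class ReferenceComplex:
    family_name: str
    ppi_class: str                 # "I" or "II"
    pdb_pp_complex: str
    n_inhibitors: int
    affinity_nM: float | None
    affinity_kind: str             # "KD", "Ki" or "missing"
    descriptors: dict[str, float]
    pdb_unbound: list[str] = field(default_factory=list)
    pdb_ligand_complexes: list[str] = field(default_factory=list)


@dataclass
class ReferenceDataset:
    complexes: list[ReferenceComplex]
    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.complexes)

    @property
    def families(self) -> list[str]:
        seen = []
        for c in self.complexes:
            if c.family_name not in seen:
                seen.append(c.family_name)
        return seen

    @property
    def total_inhibitors(self) -> int:
        """Inhibitor count summed over families (per-family counts are
        repeated on every structure of a family)."""
        per_family: dict[str, int] = {}
        for c in self.complexes:
            per_family.setdefault(c.family_name, c.n_inhibitors)
        return sum(per_family.values())

    def record(self, key: str) -> ReferenceComplex:
        """Look up a complex by PDB code or family name."""
        for c in self.complexes:
            if c.pdb_pp_complex == key.lower() or c.family_name == key:
                return c
        raise KeyError(f"no reference complex {key!r}")

    def subset(self, which: str = "all") -> pd.DataFrame:
        if which == "all":
            return self.table
        if which in ("classI", "I"):
            return self.table[self.table["ppi_class"] == "I"]
        if which in ("classII", "II"):
            return self.table[self.table["ppi_class"] == "II"]
        raise ValueError(f"unknown subset {which!r}")


def _validate(ds: ReferenceDataset) -> None:
    if len(ds) != 17:
        raise ReferenceDataError(f"expected 17 reference complexes, got {len(ds)}")
    if len(ds.families) != 14:
        raise ReferenceDataError(f"expected 14 families, got {len(ds.families)}")
    n_class1 = sum(c.ppi_class == "I" for c in ds.complexes)
    if n_class1 != 6 or len(ds) - n_class1 != 11:
        raise ReferenceDataError("class split must be 6 class I / 11 class II")
    if ds.total_inhibitors != 56:
        raise ReferenceDataError(
            f"inhibitor count over families is {ds.total_inhibitors}, expected 56"
        )
    for c in ds.complexes:
        seg = c.descriptors["n_segments"]
        expected = "I" if seg < 6 else "II"
        if c.ppi_class != expected:
            raise ReferenceDataError(
                f"{c.pdb_pp_complex}: class {c.ppi_class} inconsistent with "
                f"{seg} interface segments"
            )


def load_reference() -> ReferenceDataset:
    """Load the bundled reference panel and verify its integrity."""
    try:
        src = resources.files("ppiface").joinpath("data/reference_panel.csv")
        with resources.as_file(src) as path:
            table = pd.read_csv(path)
    except (FileNotFoundError, OSError) as exc:
        raise ReferenceDataError(f"bundled reference file unreadable: {exc}") from exc

    required = {"family_name", "ppi_class", "pdb_pp_complex", "n_inhibitors",
                "affinity_nM", "affinity_kind"} | set(DESCRIPTOR_COLUMNS)
    missing = required - set(table.columns)
    if missing:
        raise ReferenceDataError(f"reference file lacks columns {sorted(missing)}")

    complexes = []
    for _, row in table.iterrows():
        desc = {k: (float(row[k]) if pd.notna(row[k]) else float("nan"))
                for k in DESCRIPTOR_COLUMNS}
        aff = float(row["affinity_nM"]) if pd.notna(row["affinity_nM"]) else None

        def _codes(cell):
            return [] if pd.isna(cell) else str(cell).split(";")

        complexes.append(ReferenceComplex(
            family_name=row["family_name"],
            ppi_class=row["ppi_class"],
            pdb_pp_complex=str(row["pdb_pp_complex"]).lower(),
            n_inhibitors=int(row["n_inhibitors"]),
            affinity_nM=aff,
            affinity_kind=row["affinity_kind"],
            descriptors=desc,
            pdb_unbound=_codes(row.get("pdb_unbound")),
            pdb_ligand_complexes=_codes(row.get("pdb_ligand_complexes")),
        ))
    ds = ReferenceDataset(complexes=complexes, table=table)
    _validate(ds)
    return ds


def aggregate(
    dataset: ReferenceDataset,
    descriptor: str,
    subset: str = "all",
) -> GroupStats:
    """Unweighted mean and n-1 variance of one descriptor over a subset.

    *subset* is ``"all"``, ``"classI"`` or ``"classII"``.  Raises when the
    descriptor is missing for any record in the subset or when the subset
    has fewer than two members.
    """
    table = dataset.subset(subset)
    if descriptor not in table.columns:
        raise KeyError(f"unknown descriptor {descriptor!r}")
    values = table[descriptor].to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        raise ValueError(f"descriptor {descriptor!r} is missing for some records")
    if len(values) < 2:
        raise ValueError("insufficient group size: variance needs n >= 2")
    return GroupStats(
        mean=float(values.mean()),
        variance=float(values.var(ddof=1)),
        n=len(values),
    )
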