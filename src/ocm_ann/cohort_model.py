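"""Domain types for case-control cohorts and their numeric design matrices.

A cohort is a list of :class:`SubjectRecord` — one subject's class label
(``AD`` or ``control``), nine three-level polymorphism genotypes, and three
serum biomarkers.  Two coding schemes turn a cohort into a ``[0, 1]`` design
matrix:

* the *classification* matrix: 27 one-hot genotype indicators plus the three
  min-max-scaled biomarkers (30 columns, class labels carried separately);
* the *association* matrix: the same 30 columns plus a ``_LOW`` complement
  (``1 - x``) for each scaled biomarker and two one-hot class-indicator
  columns (35 columns), used by the auto-contractive map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GROUP_AD",
    "GROUP_CONTROL",
    "GROUPS",
    "BIOMARKER_COLUMNS",
    "GENOTYPE_SUFFIXES",
    "CodingError",
    "ScalingError",
    "PolymorphismDef",
    "SubjectRecord",
    "DesignMatrix",
    "load_default_panel",
    "load_panel_json",
    "encode_genotypes",
    "decode_genotypes",
    "scale_biomarkers",
    "add_complements",
    "assemble_classification_matrix",
    "assemble_autocm_matrix",
    "load_cohort_csv",
    "write_cohort_csv",
]

GROUP_AD = "AD"
GROUP_CONTROL = "control"
#: Class label order; ties in classifier votes resolve to the earlier label.
GROUPS = (GROUP_CONTROL, GROUP_AD)

GENOTYPE_SUFFIXES = ("wild_type", "heterozygous", "mutant")

#: design-matrix column name -> SubjectRecord attribute
BIOMARKER_COLUMNS = {
    "Folates": "folate",
    "Homocysteine": "homocysteine",
    "Vitamin_B12": "vitamin_b12",
}

CLASS_COLUMNS = ("Alzheimer", "Control")

PROV_GENOTYPE = "genotype-indicator"
PROV_SCALED = "scaled-biomarker"
PROV_COMPLEMENT = "complement-biomarker"
PROV_CLASS = "class-indicator"


class CodingError(ValueError):
    """A genotype string cannot be coded against the panel."""


class ScalingError(ValueError):
    """A biomarker column cannot be min-max scaled."""


@dataclass(frozen=True)
class PolymorphismDef:
    """One biallelic polymorphism: three genotype labels and an rsID."""

    name: str
    rsid: str
    wild_label: str
    het_label: str
    mut_label: str

    def __post_init__(self) -> None:
        labels = (self.wild_label, self.het_label, self.mut_label)
        if len(set(labels)) != 3:
            raise ValueError(
                f"{self.name}: genotype labels must be pairwise distinct, got {labels}"
            )

    @property
    def labels(self) -> tuple[str, str, str]:
        return (self.wild_label, self.het_label, self.mut_label)

    def column_names(self) -> list[str]:
        return [f"{self.name}_{suffix}" for suffix in GENOTYPE_SUFFIXES]


def load_panel_json(path_or_text: str | Path) -> list[PolymorphismDef]:
    """Load a panel from a JSON list of {name, rsid, wild, het, mut}."""
    text = str(path_or_text)
    if not text.lstrip().startswith("["):
        text = Path(text).read_text()
    entries = json.loads(text)
    panel = [
        PolymorphismDef(
            name=e["name"], rsid=e["rsid"],
            wild_label=e["wild"], het_label=e["het"], mut_label=e["mut"],
        )
        for e in entries
    ]
    names = [p.name for p in panel]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate polymorphism names in panel: {names}")
    return panel


def load_default_panel() -> list[PolymorphismDef]:
    """The packaged nine-polymorphism folate-pathway panel."""
    text = resources.files("ocm_ann.data").joinpath("panel_folate9.json").read_text()
    return load_panel_json(text)


@dataclass
class SubjectRecord:
    """One subject: class label, genotype map, three biomarkers."""

    subject_id: str
    group: str
    genotypes: dict[str, str]
    folate: float
    homocysteine: float
    vitamin_b12: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(
                f"subject {self.subject_id!r}: group must be one of {GROUPS}, got {self.group!r}"
            )
        for col, attr in BIOMARKER_COLUMNS.items():
            value = float(getattr(self, attr))
            if not np.isfinite(value) or value < 0:
                raise ValueError(
                    f"subject {self.subject_id!r}: {attr} must be finite and >= 0, got {value}"
                )

    def validate_against_panel(self, panel: Sequence[PolymorphismDef]) -> None:
        for poly in panel:
            if poly.name not in self.genotypes:
                raise CodingError(
                    f"subject {self.subject_id!r}: missing genotype for {poly.name}"
                )
            genotype = self.genotypes[poly.name]
            if genotype not in poly.labels:
                raise CodingError(
                    f"subject {self.subject_id!r}: genotype {genotype!r} for {poly.name} "
                    f"is not one of {poly.labels}"
                )


@dataclass
class DesignMatrix:
    """Named ``[0, 1]`` matrix with per-column provenance tags.

    ``scaling_bounds`` stores the (min, max) used by min-max scaling so the
    affine map can be inverted and applied to held-out cohorts.
    """

    column_names: list[str]
    values: np.ndarray
    class_labels: np.ndarray | None = None
    column_provenance: list[str] = field(default_factory=list)
    scaling_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.column_names):
            raise ValueError("values shape does not match column_names")
        if self.column_provenance and len(self.column_provenance) != len(self.column_names):
            raise ValueError("column_provenance length mismatch")
        if self.class_labels is not None:
            self.class_labels = np.asarray(self.class_labels, dtype=object)
            if len(self.class_labels) != self.values.shape[0]:
                raise ValueError("class_labels length mismatch")

    @property
    def n_records(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_names)

    def hstack(self, other: "DesignMatrix") -> "DesignMatrix":
        """Concatenate columns; class labels must agree when both present."""
        if other.n_records != self.n_records:
            raise ValueError("record count mismatch")
        labels = self.class_labels if self.class_labels is not None else other.class_labels
        if (
            self.class_labels is not None
            and other.class_labels is not None
            and not np.array_equal(self.class_labels, other.class_labels)
        ):
            raise ValueError("class label mismatch between blocks")
        bounds = dict(self.scaling_bounds)
        bounds.update(other.scaling_bounds)
        return DesignMatrix(
            column_names=self.column_names + other.column_names,
            values=np.hstack([self.values, other.values]),
            class_labels=labels,
            column_provenance=list(self.column_provenance) + list(other.column_provenance),
            scaling_bounds=bounds,
        )

    def select_columns(self, mask: np.ndarray) -> "DesignMatrix":
        mask = np.asarray(mask, dtype=bool)
        names = [n for n, m in zip(self.column_names, mask) if m]
        prov = [p for p, m in zip(self.column_provenance, mask) if m]
        return DesignMatrix(
            column_names=names,
            values=self.values[:, mask],
            class_labels=self.class_labels,
            column_provenance=prov,
            scaling_bounds={k: v for k, v in self.scaling_bounds.items() if k in names},
        )

    def write_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Write values as CSV; provenance/bounds/labels to a JSON sidecar."""
        path = Path(path)
        df = self.to_dataframe()
        df.to_csv(path, index=False, float_format="%.12g")
        if sidecar is None:
            sidecar = path.with_suffix(".meta.json")
        meta = {
            "column_provenance": list(self.column_provenance),
            "scaling_bounds": {k: list(v) for k, v in self.scaling_bounds.items()},
            "class_labels": None if self.class_labels is None else list(self.class_labels),
        }
        Path(sidecar).write_text(json.dumps(meta, indent=1))

    @classmethod
    def read_csv(cls, path: str | Path, sidecar: str | Path | None = None) -> "DesignMatrix":
        path = Path(path)
        df = pd.read_csv(path)
        if sidecar is None:
            sidecar = path.with_suffix(".meta.json")
        provenance: list[str] = []
        bounds: dict[str, tuple[float, float]] = {}
        labels = None
        sidecar = Path(sidecar)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            provenance = meta.get("column_provenance", [])
            bounds = {k: tuple(v) for k, v in meta.get("scaling_bounds", {}).items()}
            if meta.get("class_labels") is not None:
                labels = np.asarray(meta["class_labels"], dtype=object)
        return cls(
            column_names=list(df.columns),
            values=df.to_numpy(dtype=float),
            class_labels=labels,
            column_provenance=provenance,
            scaling_bounds=bounds,
        )


def _check_unit_interval(values: np.ndarray, context: str) -> None:
    if values.size and (np.min(values) < 0.0 or np.max(values) > 1.0):
        raise ValueError(f"{context}: entries must lie in [0, 1]")


def encode_genotypes(
    cohort: Sequence[SubjectRecord], panel: Sequence[PolymorphismDef]
) -> DesignMatrix:
    """One-hot code every genotype: 0 if variable absent, 1 if present.

    Produces three indicator columns per polymorphism (wild type /
    heterozygous / mutant, in panel order); exactly one of the three is 1
    per record.
    """
    if not cohort:
        raise CodingError("empty cohort")
    for record in cohort:
        record.validate_against_panel(panel)
    n = len(cohort)
    columns: list[str] = []
    blocks: list[np.ndarray] = []
    for poly in panel:
        block = np.zeros((n, 3))
        label_to_idx = {label: i for i, label in enumerate(poly.labels)}
        for row, record in enumerate(cohort):
            block[row, label_to_idx[record.genotypes[poly.name]]] = 1.0
        columns.extend(poly.column_names())
        blocks.append(block)
    labels = np.asarray([r.group for r in cohort], dtype=object)
    return DesignMatrix(
        column_names=columns,
        values=np.hstack(blocks),
        class_labels=labels,
        column_provenance=[PROV_GENOTYPE] * len(columns),
    )


def decode_genotypes(
    matrix: DesignMatrix, panel: Sequence[PolymorphismDef]
) -> list[dict[str, str]]:
    """Invert :func:`encode_genotypes` — recover genotype strings per record."""
    out: list[dict[str, str]] = [dict() for _ in range(matrix.n_records)]
    name_to_col = {name: i for i, name in enumerate(matrix.column_names)}
    for poly in panel:
        cols = [name_to_col[c] for c in poly.column_names()]
        block = matrix.values[:, cols]
        if not np.array_equal(block.sum(axis=1), np.ones(matrix.n_records)):
            raise CodingError(f"{poly.name}: indicator triple does not sum to 1")
        hits = np.argmax(block, axis=1)
        for row, hit in enumerate(hits):
            out[row][poly.name] = poly.labels[hit]
    return out


def scale_biomarkers(
    cohort: Sequence[SubjectRecord],
    which: Iterable[str] = ("Folates", "Homocysteine", "Vitamin_B12"),
) -> DesignMatrix:
    """Min-max scale each biomarker over the pooled cohort to [0, 1]."""
    if not cohort:
        raise ScalingError("empty cohort")
    which = list(which)
    n = len(cohort)
    values = np.zeros((n, len(which)))
    bounds: dict[str, tuple[float, float]] = {}
    for j, col in enumerate(which):
        attr = BIOMARKER_COLUMNS[col]
        raw = np.asarray([float(getattr(r, attr)) for r in cohort])
        lo, hi = float(raw.min()), float(raw.max())
        if hi == lo:
            raise ScalingError(f"{col}: constant column (zero range), cannot scale")
        values[:, j] = (raw - lo) / (hi - lo)
        bounds[col] = (lo, hi)
    return DesignMatrix(
        column_names=which,
        values=values,
        class_labels=np.asarray([r.group for r in cohort], dtype=object),
        column_provenance=[PROV_SCALED] * len(which),
        scaling_bounds=bounds,
    )


def unscale(matrix: DesignMatrix, column: str) -> np.ndarray:
    """Invert min-max scaling for one column using the stored bounds."""
    lo, hi = matrix.scaling_bounds[column]
    j = matrix.column_names.index(column)
    return matrix.values[:, j] * (hi - lo) + lo


def add_complements(scaled: DesignMatrix) -> DesignMatrix:
    """Append, for each column x, a column ``<x>_LOW`` with value 1 - x."""
    _check_unit_interval(scaled.values, "add_complements")
    comp = DesignMatrix(
        column_names=[f"{c}_LOW" for c in scaled.column_names],
        values=1.0 - scaled.values,
        class_labels=scaled.class_labels,
        column_provenance=[PROV_COMPLEMENT] * scaled.n_columns,
    )
    return scaled.hstack(comp)


def _class_indicators(cohort: Sequence[SubjectRecord]) -> DesignMatrix:
    labels = np.asarray([r.group for r in cohort], dtype=object)
    values = np.zeros((len(cohort), 2))
    values[:, 0] = labels == GROUP_AD
    values[:, 1] = labels == GROUP_CONTROL
    return DesignMatrix(
        column_names=list(CLASS_COLUMNS),
        values=values,
        class_labels=labels,
        column_provenance=[PROV_CLASS, PROV_CLASS],
    )


def assemble_classification_matrix(
    cohort: Sequence[SubjectRecord], panel: Sequence[PolymorphismDef]
) -> DesignMatrix:
    """27 genotype indicators + 3 scaled biomarkers = 30 input columns."""
    return encode_genotypes(cohort, panel).hstack(scale_biomarkers(cohort))


def assemble_autocm_matrix(
    cohort: Sequence[SubjectRecord], panel: Sequence[PolymorphismDef]
) -> DesignMatrix:
    """27 indicators + 3 scaled + 3 complements + 2 class columns = 35."""
    genotypes = encode_genotypes(cohort, panel)
    biomarkers = add_complements(scale_biomarkers(cohort))
    return genotypes.hstack(biomarkers).hstack(_class_indicators(cohort))


def write_cohort_csv(cohort: Sequence[SubjectRecord], path: str | Path,
                     panel: Sequence[PolymorphismDef] | None = None) -> None:
    if panel is None:
        panel = load_default_panel()
    rows = []
    for r in cohort:
        row = {"subject_id": r.subject_id, "group": r.group}
        for poly in panel:
            row[poly.name] = r.genotypes[poly.name]
        row.update(folate=r.folate, homocysteine=r.homocysteine, vitamin_b12=r.vitamin_b12)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def load_cohort_csv(path: str | Path,
                    panel: Sequence[PolymorphismDef] | None = None) -> list[SubjectRecord]:
    if panel is None:
        panel = load_default_panel()
    df = pd.read_csv(path, dtype=str)
    required = {"subject_id", "group", "folate", "homocysteine", "vitamin_b12"}
    missing = required.union(p.name for p in panel) - set(df.columns)
    if missing:
        raise CodingError(f"cohort CSV missing columns: {sorted(missing)}")
    cohort = []
    for _, row in df.iterrows():
        record = SubjectRecord(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            genotypes={p.name: str(row[p.name]) for p in panel},
            folate=float(row["folate"]),
            homocysteine=float(row["homocysteine"]),
            vitamin_b12=float(row["vitamin_b12"]),
        )
        record.validate_against_panel(panel)
        cohort.append(record)
    return cohort
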