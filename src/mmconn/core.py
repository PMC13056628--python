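"""Shared data model for the multimodal connectome pipeline.

Everything downstream operates on three objects: a :class:`NodeScheme`
(the unified 104-node parcellation: 68 Desikan-Killiany cortical regions
plus 36 subcortical/cerebellar regions, each tagged with a hemisphere and
a network affiliation), a :class:`ConnectivityMatrix` (a symmetric,
zero-diagonal 104x104 weighted matrix tagged with its modality), and a
:class:`CohortTable` (per-subject demographics and clinical scores).

All file exchange is plain TSV so that every intermediate artifact is
human-inspectable; matrices are stored dense with a node-name header.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "DimensionError",
    "UnknownNodeError",
    "AsymmetryError",
    "NonFiniteError",
    "RangeError",
    "MissingColumnError",
    "NodeScheme",
    "ConnectivityMatrix",
    "CohortTable",
    "default_node_scheme",
    "read_matrix",
    "write_matrix",
    "read_cohort",
    "write_cohort",
]

SYMMETRY_TOL = 1e-9

Modality = Literal["SCN", "DTI", "FC_rest", "FC_task"]
AFFILIATIONS = ("Motor", "Sensory", "Premotor", "Frontotemporal", "Subcortical/Cerebellar")

#: connectogram edge-colour palette, one colour per network affiliation
AFFILIATION_COLORS = {
    "Motor": "red",
    "Sensory": "blue",
    "Premotor": "orange",
    "Frontotemporal": "purple",
    "Subcortical/Cerebellar": "green",
}


class ValidationError(ValueError):
    """Base class for data-model validation failures."""


class DimensionError(ValidationError):
    """Matrix or table has the wrong shape for its scheme."""


class UnknownNodeError(ValidationError):
    """A node name does not occur in the scheme."""


class AsymmetryError(ValidationError):
    """Matrix asymmetry exceeds tolerance."""


class NonFiniteError(ValidationError):
    """NaN or infinity in numeric data."""


class RangeError(ValidationError):
    """A value violates its documented physiological/score range."""


class MissingColumnError(ValidationError):
    """A required TSV column is absent."""


@dataclass(frozen=True)
class NodeScheme:
    """Ordered node table of the parcellation.

    ``nodes`` has columns index, name, hemisphere, affiliation, kind and is
    ordered left cortical, right cortical, subcortical, cerebellar; every
    matrix in the pipeline is aligned to this order on read so cross-modal
    edge vectors match element-wise.
    """

    nodes: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"index", "name", "hemisphere", "affiliation", "kind"}
        missing = required - set(self.nodes.columns)
        if missing:
            raise MissingColumnError(f"node table lacks columns {sorted(missing)}")
        idx = self.nodes["index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(self.nodes))):
            raise ValidationError("node indices must be contiguous 0..N-1 in order")
        if self.nodes["name"].duplicated().any():
            dup = self.nodes["name"][self.nodes["name"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate node name {dup!r}")
        bad = set(self.nodes["affiliation"]) - set(AFFILIATIONS)
        if bad:
            raise ValidationError(f"unknown affiliation classes {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def names(self) -> list[str]:
        return self.nodes["name"].tolist()

    @property
    def hemisphere(self) -> np.ndarray:
        return self.nodes["hemisphere"].to_numpy()

    @property
    def affiliation(self) -> np.ndarray:
        return self.nodes["affiliation"].to_numpy()

    @property
    def kind(self) -> np.ndarray:
        return self.nodes["kind"].to_numpy()

    def indices_of(self, names: list[str]) -> np.ndarray:
        lookup = {n: i for i, n in enumerate(self.names)}
        unknown = [n for n in names if n not in lookup]
        if unknown:
            raise UnknownNodeError(f"unknown node name(s): {unknown[:5]}")
        return np.array([lookup[n] for n in names])

    def homotopic_pairs(self) -> list[tuple[int, int]]:
        """(left, right) index pairs of mirror-named regions (L_x / R_x)."""
        lookup = {n: i for i, n in enumerate(self.names)}
        pairs = []
        for name, i in lookup.items():
            if name.startswith("L_"):
                j = lookup.get("R_" + name[2:])
                if j is not None:
                    pairs.append((i, j))
        return pairs

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NodeScheme":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(df.reset_index(drop=True))


def default_node_scheme() -> NodeScheme:
    """The packaged unified 104-node scheme.

    68 cortical nodes (34 Desikan-Killiany regions per hemisphere) and 36
    subcortical/cerebellar nodes (7 deep-grey pairs + ventral diencephalon
    + 10 cerebellar lobule pairs). Affiliation classes follow the five-colour
    network palette (Motor, Sensory, Premotor, Frontotemporal,
    Subcortical/Cerebellar); the region-to-class map is a packaged, editable
    TSV because only the palette, not the enumeration, is standardised.
    """
    with resources.files("mmconn.data").joinpath("nodes_104.tsv").open() as f:
        return NodeScheme.from_tsv(f)


@dataclass
class ConnectivityMatrix:
    """Symmetric weighted connectivity matrix tied to a node scheme.

    Invariants (enforced by :meth:`validate`): values are N x N with N equal
    to the scheme size, symmetric within 1e-9, finite, zero diagonal.
    """

    values: np.ndarray
    scheme: NodeScheme
    modality: str = "DTI"
    level: Literal["subject", "group"] = "subject"
    subject_id: str | None = None
    weight_kind: Literal["fisher_z", "normalized_count", "raw"] = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.scheme)
        if self.values.shape != (n, n):
            raise DimensionError(
                f"matrix shape {self.values.shape} does not match scheme size {n}"
            )
        if not np.isfinite(self.values).all():
            raise NonFiniteError("matrix contains non-finite entries")
        asym = np.abs(self.values - self.values.T).max()
        if asym > SYMMETRY_TOL:
            raise AsymmetryError(f"matrix asymmetry {asym:.3g} exceeds {SYMMETRY_TOL}")
        if np.any(np.diag(self.values) != 0.0):
            raise ValidationError("matrix diagonal must be exactly zero")

    @classmethod
    def create(cls, values, scheme, **kw) -> "ConnectivityMatrix":
        """Build from raw values: symmetrize tiny asymmetry, zero the diagonal."""
        v = np.asarray(values, dtype=float)
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        return cls(v, scheme, **kw)

    def copy_with(self, **kw) -> "ConnectivityMatrix":
        return replace(self, values=self.values.copy(), **kw)


def write_matrix(matrix: ConnectivityMatrix, path: str | Path) -> Path:
    """Write a matrix as dense TSV: node-name header row, N data rows, 13
    significant digits (round-trips within 1e-12 relative error)."""
    path = Path(path)
    names = matrix.scheme.names
    with open(path, "w") as f:
        f.write("\t".join(names) + "\n")
        for row in matrix.values:
            f.write("\t".join(format(v, ".13g") for v in row) + "\n")
    return path


def read_matrix(
    path: str | Path,
    scheme: NodeScheme,
    *,
    modality: str = "DTI",
    level: str = "subject",
    subject_id: str | None = None,
    weight_kind: str = "raw",
) -> ConnectivityMatrix:
    """Read a dense TSV matrix and align its rows/columns to ``scheme`` by name.

    The file must carry a header row of node names and N data rows in the
    same order as the header. Raises :class:`DimensionError`,
    :class:`UnknownNodeError`, :class:`NonFiniteError` or
    :class:`AsymmetryError` for the corresponding malformation.
    """
    path = Path(path)
    with open(path) as f:
        header = f.readline().rstrip("\n").split("\t")
        rows = [line.rstrip("\n").split("\t") for line in f if line.strip()]
    n = len(scheme)
    if len(header) != n or len(rows) != n:
        raise DimensionError(
            f"{path.name}: expected {n} columns x {n} rows, got {len(header)} x {len(rows)}"
        )
    order = scheme.indices_of(header)  # raises UnknownNodeError
    try:
        values = np.array(rows, dtype=float)
    except ValueError as e:
        raise NonFiniteError(f"{path.name}: non-numeric entry ({e})") from None
    if not np.isfinite(values).all():
        raise NonFiniteError(f"{path.name}: non-finite entry")
    if values.shape != (n, n):
        raise DimensionError(f"{path.name}: ragged rows")
    # reorder file order -> scheme order
    inv = np.empty(n, dtype=int)
    inv[order] = np.arange(n)
    values = values[np.ix_(inv, inv)]
    asym = np.abs(values - values.T).max()
    if asym > SYMMETRY_TOL:
        raise AsymmetryError(f"{path.name}: asymmetry {asym:.3g} exceeds {SYMMETRY_TOL}")
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return ConnectivityMatrix(
        values, scheme, modality=modality, level=level,
        subject_id=subject_id, weight_kind=weight_kind,
    )


COHORT_COLUMNS = [
    "subject_id", "group", "age", "sex", "handedness",
    "grip_right", "grip_left", "alsfrs_r",
]

_GROUP_ALIASES = {"als": "patient", "patient": "patient", "control": "control",
                  "ctrl": "control", "hc": "control"}


@dataclass
class CohortTable:
    """Per-subject demographics and clinical scores.

    Columns: subject_id, group (patient|control), age (years), sex (M|F),
    handedness (R|L), grip_right/grip_left (kg), alsfrs_r (0-48; 48 =
    clinically unimpaired).
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.rows
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise MissingColumnError(f"cohort table lacks columns {missing}")
        if df["subject_id"].duplicated().any():
            dups = sorted(df.loc[df["subject_id"].duplicated(), "subject_id"].unique())
            warnings.warn(f"duplicate subject rows dropped (kept first): {dups}")
            df = df.drop_duplicates(subset="subject_id", keep="first")
        df = df.reset_index(drop=True).copy()
        df["group"] = [
            _GROUP_ALIASES.get(str(g).strip().lower(), str(g).strip().lower())
            for g in df["group"]
        ]
        bad_group = set(df["group"]) - {"patient", "control"}
        if bad_group:
            raise RangeError(f"unknown group label(s) {sorted(bad_group)}")
        a = df["alsfrs_r"].to_numpy(dtype=float)
        if np.any((a < 0) | (a > 48)):
            raise RangeError("ALSFRS-R outside [0, 48]")
        g = df[["grip_right", "grip_left"]].to_numpy(dtype=float)
        if np.any(g < 0):
            raise RangeError("negative grip strength")
        if np.any((df["age"].to_numpy(dtype=float) <= 0)):
            raise RangeError("non-positive age")
        self.rows = df

    def __len__(self) -> int:
        return len(self.rows)

    def group(self, name: str) -> pd.DataFrame:
        return self.rows[self.rows["group"] == name]

    @property
    def patients(self) -> pd.DataFrame:
        return self.group("patient")

    @property
    def controls(self) -> pd.DataFrame:
        return self.group("control")


def read_cohort(path: str | Path) -> CohortTable:
    """Read a cohort TSV; duplicated subject_ids keep the first occurrence."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return CohortTable(df)


def write_cohort(cohort: CohortTable, path: str | Path) -> Path:
    path = Path(path)
    cohort.rows.to_csv(path, sep="\t", index=False)
    return path


def packaged_cohort() -> CohortTable:
    """The packaged per-subject clinical fixture (15 patients / 14 controls
    after deduplication)."""
    with resources.files("mmconn.data").joinpath("table1_cohort.tsv").open() as f:
        return read_cohort(f)
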