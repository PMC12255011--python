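"""Data model and on-disk formats for interaction tables and feature matrices.

An *interaction table* holds one row per (ligand, receptor) measurement with a
functional-class annotation (0 = antagonist, 1 = agonist, 2 = modulator) and an
optional Ki value in nM. Duplicate (ligand, receptor) rows are legal on ingest;
the curation module resolves them.

A *feature matrix* is a dense numeric matrix whose columns carry a provenance
role (descriptor | embedding | ki | meta_probability) and a frozen order,
persisted as a TSV plus a sidecar JSON manifest so that save/load round-trips
are exact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_CLASSES = (0, 1, 2)
CLASS_NAMES = {0: "antagonist", 1: "agonist", 2: "modulator"}
COLUMN_ROLES = ("descriptor", "embedding", "ki", "meta_probability")

REQUIRED_COLUMNS = ("ligand_id", "smiles", "receptor_id")


class SchemaError(ValueError):
    """A required column is missing or a cell fails validation."""


@dataclass
class InteractionRecord:
    """One ligand-receptor pair with its functional-class annotation."""

    ligand_id: str
    smiles: str
    receptor_id: str
    action_class: int
    action_raw: str = ""
    ki_values_nM: list[float] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        if not self.ligand_id or not self.receptor_id:
            raise SchemaError("ligand_id and receptor_id must be non-empty")
        if self.action_class not in VALID_CLASSES:
            raise SchemaError(
                f"action_class must be one of {VALID_CLASSES}, got {self.action_class!r}"
            )
        for v in self.ki_values_nM:
            if not (v > 0):
                raise SchemaError(f"Ki values must be positive, got {v!r}")


@dataclass
class InteractionTable:
    """Ordered collection of interaction records keyed by (ligand_id, receptor_id)."""

    records: list[InteractionRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def keys(self) -> list[tuple[str, str]]:
        return [(r.ligand_id, r.receptor_id) for r in self.records]

    def class_counts(self) -> dict[int, int]:
        counts = {c: 0 for c in VALID_CLASSES}
        for r in self.records:
            counts[r.action_class] += 1
        return counts

    def ligand_ids(self) -> list[str]:
        return [r.ligand_id for r in self.records]

    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    def labels(self) -> np.ndarray:
        return np.array([r.action_class for r in self.records], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            ki = ";".join(repr(v) for v in r.ki_values_nM) if r.ki_values_nM else ""
            rows.append(
                {
                    "ligand_id": r.ligand_id,
                    "smiles": r.smiles,
                    "receptor_id": r.receptor_id,
                    "action_raw": r.action_raw,
                    "action_class": r.action_class,
                    "ki_nM": ki,
                    "source": r.source,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["ligand_id", "smiles", "receptor_id", "action_raw",
                     "action_class", "ki_nM", "source"],
        )


def _detect_sep(path: Path, dialect: str | None) -> str:
    if dialect in (",", "\t"):
        return dialect
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    if dialect is not None:
        raise ValueError(f"unknown dialect {dialect!r}; use 'csv', 'tsv', ',' or '\\t'")
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def _parse_ki_cell(cell, row_number: int) -> list[float]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return []
    text = str(cell).strip()
    if not text:
        return []
    values = []
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            values.append(float(token))
        except ValueError as exc:
            raise SchemaError(
                f"row {row_number}: non-numeric Ki value {token!r}"
            ) from exc
    return values


def read_interaction_table(path: str | Path, dialect: str | None = None) -> InteractionTable:
    """Read a CSV/TSV interaction table.

    The header must contain ligand_id, smiles, receptor_id and either
    action_class (integer 0/1/2) or action_raw; optional columns are ki_nM
    (one value per row, or ';'-separated) and source. The delimiter is
    auto-detected from the extension and can be forced with *dialect*
    ('csv' | 'tsv' | ',' | '\\t'). Duplicate (ligand, receptor) rows are kept
    as separate records; curation resolves them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _detect_sep(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")

    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    if "action_class" not in df.columns and "action_raw" not in df.columns:
        raise SchemaError("missing required column 'action_class' (or 'action_raw')")

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        row = row._asdict()
        if "action_class" in row and str(row["action_class"]).strip() != "":
            try:
                action = int(str(row["action_class"]).strip())
            except ValueError as exc:
                raise SchemaError(
                    f"row {i}: non-integer action_class {row['action_class']!r}"
                ) from exc
        else:
            action = _action_from_raw(str(row.get("action_raw", "")), i)
        if action not in VALID_CLASSES:
            raise SchemaError(
                f"row {i}: action_class {action} outside {VALID_CLASSES}"
            )
        records.append(
            InteractionRecord(
                ligand_id=str(row["ligand_id"]).strip(),
                smiles=str(row["smiles"]).strip(),
                receptor_id=str(row["receptor_id"]).strip(),
                action_class=action,
                action_raw=str(row.get("action_raw", "")),
                ki_values_nM=_parse_ki_cell(row.get("ki_nM"), i),
                source=str(row.get("source", "")),
            )
        )
    return InteractionTable(records)


_RAW_ACTION_MAP = {"antagonist": 0, "agonist": 1, "modulator": 2}


def _action_from_raw(raw: str, row_number: int) -> int:
    key = raw.strip().lower()
    if key in _RAW_ACTION_MAP:
        return _RAW_ACTION_MAP[key]
    raise SchemaError(
        f"row {row_number}: cannot map action_raw {raw!r} to a class; "
        "expected antagonist/agonist/modulator or an explicit action_class"
    )


def write_interaction_table(table: InteractionTable, path: str | Path,
                            dialect: str | None = None) -> None:
    path = Path(path)
    sep = _detect_sep(path, dialect)
    table.to_frame().to_csv(path, sep=sep, index=False, encoding="utf-8")


@dataclass
class FeatureMatrix:
    """Row-aligned numeric matrix with per-column provenance and frozen order."""

    row_keys: list[tuple[str, str]]
    column_names: list[str]
    column_roles: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, k = self.values.shape
        if len(self.row_keys) != n:
            raise ValueError(f"{len(self.row_keys)} row keys for {n} rows")
        if len(self.column_names) != k or len(self.column_roles) != k:
            raise ValueError(
                f"column metadata length mismatch: {len(self.column_names)} names, "
                f"{len(self.column_roles)} roles, {k} columns"
            )
        bad = set(self.column_roles) - set(COLUMN_ROLES)
        if bad:
            raise SchemaError(f"unknown column roles {sorted(bad)}; allowed: {COLUMN_ROLES}")
        if len(set(self.column_names)) != k:
            raise ValueError("column names must be unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def columns_with_role(self, role: str) -> list[int]:
        return [i for i, r in enumerate(self.column_roles) if r == role]

    def select_rows(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            row_keys=[self.row_keys[i] for i in idx],
            column_names=list(self.column_names),
            column_roles=list(self.column_roles),
            values=self.values[idx],
        )

    def select_columns(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            row_keys=list(self.row_keys),
            column_names=[self.column_names[i] for i in idx],
            column_roles=[self.column_roles[i] for i in idx],
            values=self.values[:, idx],
        )


def write_feature_matrix(m: FeatureMatrix, path: str | Path) -> None:
    """Persist values as TSV and the column manifest as a sidecar JSON.

    The manifest freezes column names, roles and order; `read_feature_matrix`
    refuses a data file whose header disagrees with the manifest.
    """
    path = Path(path)
    df = pd.DataFrame(m.values, columns=m.column_names)
    df.insert(0, "ligand_id", [k[0] for k in m.row_keys])
    df.insert(1, "receptor_id", [k[1] for k in m.row_keys])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g", encoding="utf-8")
    manifest = {
        "column_names": m.column_names,
        "column_roles": m.column_roles,
    }
    path.with_suffix(path.suffix + ".manifest.json").write_text(
        json.dumps(manifest, indent=1), encoding="utf-8"
    )


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    manifest_path = path.with_suffix(path.suffix + ".manifest.json")
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing sidecar manifest {manifest_path}")
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    df = pd.read_csv(path, sep="\t", dtype={"ligand_id": str, "receptor_id": str},
                     encoding="utf-8", float_precision="round_trip")
    names = manifest["column_names"]
    header = [c for c in df.columns if c not in ("ligand_id", "receptor_id")]
    if header != names:
        raise SchemaError(
            "feature file column order disagrees with its manifest; refusing to load"
        )
    values = df[names].to_numpy(dtype=float) if names else np.empty((len(df), 0))
    return FeatureMatrix(
        row_keys=list(zip(df["ligand_id"].astype(str), df["receptor_id"].astype(str))),
        column_names=list(names),
        column_roles=list(manifest["column_roles"]),
        values=values,
    )


class SmilesError(ValueError):
    """A SMILES string could not be parsed."""


def canonicalize_smiles(smiles: str) -> str:
    """Return RDKit's canonical SMILES; idempotent; raises SmilesError on junk."""
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def canonicalize_table(table: InteractionTable) -> tuple[InteractionTable, list[str]]:
    """Canonicalize every record's SMILES; drop and report unparseable ones."""
    kept, dropped = [], []
    for r in table.records:
        try:
            smi = canonicalize_smiles(r.smiles)
        except SmilesError:
            dropped.append(r.smiles)
            logger.warning("dropping record (%s, %s): unparseable SMILES %r",
                           r.ligand_id, r.receptor_id, r.smiles)
            continue
        kept.append(
            InteractionRecord(r.ligand_id, smi, r.receptor_id, r.action_class,
                              r.action_raw, list(r.ki_values_nM), r.source)
        )
    return InteractionTable(kept), dropped
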