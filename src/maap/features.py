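"""Per-pair feature assembly and standardization.

Each (ligand, receptor) pair is represented by the concatenation of the
ligand's molecular descriptors, the receptor's sequence-embedding vector and,
optionally, the pair's single deduplicated Ki value:
``[descriptors | embeddings | ki?]``. Columns are standardized to zero mean
and unit variance with parameters fitted on the training rows only, so test
and independent rows never leak into the scaling.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from maap.io import FeatureMatrix, InteractionTable


def assemble_features(table: InteractionTable, descriptors: pd.DataFrame,
                      embeddings: pd.DataFrame, include_ki: bool = False,
                      log10_ki: bool = False) -> FeatureMatrix:
    """Build the per-pair feature matrix from per-ligand and per-receptor tables.

    *descriptors* is indexed (or indexable) by ligand_id; *embeddings* by
    receptor_id. Row i of the output corresponds to record i of *table*.
    With *include_ki*, every record must carry exactly one Ki value, appended
    as the final column (optionally log10-transformed).
    """
    desc = _indexed(descriptors, "ligand_id")
    embed = _indexed(embeddings, "receptor_id")

    missing_l = sorted({r.ligand_id for r in table} - set(desc.index))
    missing_r = sorted({r.receptor_id for r in table} - set(embed.index))
    if missing_l or missing_r:
        raise KeyError(
            f"missing descriptor rows for ligands {missing_l[:5]} "
            f"and embedding rows for receptors {missing_r[:5]}"
            + (" (truncated)" if len(missing_l) > 5 or len(missing_r) > 5 else "")
        )
    if include_ki:
        bad = [(r.ligand_id, r.receptor_id) for r in table if len(r.ki_values_nM) != 1]
        if bad:
            raise ValueError(
                f"include_ki requires exactly one Ki per record; offending keys: {bad[:5]}"
            )

    ligand_rows = desc.loc[[r.ligand_id for r in table]].to_numpy(dtype=float)
    receptor_rows = embed.loc[[r.receptor_id for r in table]].to_numpy(dtype=float)
    blocks = [ligand_rows, receptor_rows]
    names = list(desc.columns) + list(embed.columns)
    roles = ["descriptor"] * desc.shape[1] + ["embedding"] * embed.shape[1]
    if include_ki:
        ki = np.array([[r.ki_values_nM[0]] for r in table], dtype=float)
        if log10_ki:
            ki = np.log10(ki)
        blocks.append(ki)
        names.append("ki_nM" if not log10_ki else "log10_ki_nM")
        roles.append("ki")

    values = np.hstack(blocks) if len(table) else np.empty((0, len(names)))
    return FeatureMatrix(row_keys=table.keys(), column_names=names,
                         column_roles=roles, values=values)


def _indexed(df: pd.DataFrame, key: str) -> pd.DataFrame:
    if key in df.columns:
        df = df.set_index(key)
    if df.index.has_duplicates:
        raise ValueError(f"duplicate {key} rows in feature table")
    return df


@dataclass
class ScalerParams:
    """Per-column affine standardization parameters (mean, scale).

    Columns constant on the fitting rows get scale 1 and are listed in
    *constant_columns* so they map to exactly 0 after scaling.
    """

    mean: np.ndarray
    scale: np.ndarray
    fitted_on: str = "train"
    constant_columns: list[int] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "fitted_on": self.fitted_on,
            "constant_columns": list(self.constant_columns),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerParams":
        return cls(mean=np.asarray(d["mean"], dtype=float),
                   scale=np.asarray(d["scale"], dtype=float),
                   fitted_on=d.get("fitted_on", "train"),
                   constant_columns=list(d.get("constant_columns", [])))


def fit_scaler(m: FeatureMatrix, rows: Sequence[int] | None = None,
               fitted_on: str = "train") -> ScalerParams:
    """Fit zero-mean unit-variance parameters on the given rows (all if None)."""
    idx = list(range(m.shape[0])) if rows is None else list(rows)
    if not idx:
        raise ValueError("cannot fit a scaler on an empty row set")
    X = m.values[idx]
    mean = X.mean(axis=0)
    std = X.std(axis=0)  # population std, as StandardScaler uses
    constant = np.flatnonzero(std == 0.0).tolist()
    scale = np.where(std == 0.0, 1.0, std)
    return ScalerParams(mean=mean, scale=scale, fitted_on=fitted_on,
                        constant_columns=constant)


def apply_scaler(m: FeatureMatrix, p: ScalerParams) -> FeatureMatrix:
    """Apply stored affine parameters; never reads any statistics from *m*."""
    if m.shape[1] != p.mean.shape[0]:
        raise ValueError(
            f"scaler fitted on {p.mean.shape[0]} columns, matrix has {m.shape[1]}"
        )
    return FeatureMatrix(row_keys=list(m.row_keys), column_names=list(m.column_names),
                         column_roles=list(m.column_roles),
                         values=(m.values - p.mean) / p.scale)


def invert_scaler(m: FeatureMatrix, p: ScalerParams) -> FeatureMatrix:
    return FeatureMatrix(row_keys=list(m.row_keys), column_names=list(m.column_names),
                         column_roles=list(m.column_roles),
                         values=m.values * p.scale + p.mean)


# ---------------------------------------------------------------------------
# Toy fallback featurizer — NOT scientific. Real descriptors come from an
# external Mold2-style table and real embeddings from a protein language
# model; these stand-ins only exercise the plumbing in tests and demos.
# ---------------------------------------------------------------------------

def toy_ligand_descriptors(smiles_by_ligand: dict[str, str],
                           n_features: int = 32) -> pd.DataFrame:
    """Hashed SMILES k-mer counts. Deterministic, chemistry-free; tests only."""
    rows = {}
    for ligand_id, smi in smiles_by_ligand.items():
        vec = np.zeros(n_features)
        for k in (2, 3):
            for i in range(max(0, len(smi) - k + 1)):
                h = hashlib.blake2b(smi[i:i + k].encode(), digest_size=4).digest()
                vec[int.from_bytes(h, "little") % n_features] += 1.0
        rows[ligand_id] = vec
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[f"T{i:03d}" for i in range(n_features)])
    df.index.name = "ligand_id"
    return df


def toy_receptor_embeddings(receptor_ids: Sequence[str], n_dims: int = 16,
                            seed: int = 0) -> pd.DataFrame:
    """Receptor one-hot blocks plus seeded Gaussian noise; tests only."""
    ids = list(receptor_ids)
    rng = np.random.default_rng(seed)
    base = rng.normal(scale=0.05, size=(len(ids), n_dims))
    for i in range(len(ids)):
        base[i, i % n_dims] += 1.0
    df = pd.DataFrame(base, index=ids, columns=[f"E{i:04d}" for i in range(n_dims)])
    df.index.name = "receptor_id"
    return df
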