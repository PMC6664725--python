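"""Loading and cleansing of GDSC-style drug-screen tables.

Three CSV inputs are consumed: a drug list (with an offline drug_id ->
canonical SMILES mapping replacing any live database lookup), a binary
cell-line feature table (mutation states and copy-number alterations), and a
long-format log-IC50 table.  Cleansing mirrors the standard preprocessing of
such exports: duplicate drugs are dropped, drugs without a SMILES mapping
are dropped with a warning, and cell lines with fewer than the required
number of defined features are removed.

Log-IC50 values x (natural log of the molar IC50 y = e^x) are squashed into
(0, 1) with y -> 1 / (1 + y^(-0.1)), i.e. a logistic in 0.1 * x.  The
exponent -0.1 spreads the typically tiny y values (< 1e-3) more uniformly
over the unit interval; it is configurable via ``alpha``.

The assembled :class:`InteractionTable` is a dense drug x cell matrix of
normalized responses with a missingness mask and a per-entry flag marking
responses measured below the maximum screening concentration (values above
max_conc are extrapolated rather than experimentally verified).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "DataError",
    "DrugRecord",
    "CellLineRecord",
    "InteractionTable",
    "load_drug_list",
    "load_cell_lines",
    "normalize_ic50",
    "denormalize_ic50",
    "build_interaction_table",
    "max_conc_subset",
    "save_table",
    "load_table",
]

DEFAULT_ALPHA = -0.1


class SchemaError(ValueError):
    """A CSV does not match the documented column schema."""


class DataError(ValueError):
    """The data violate a content contract (duplicates, empty result, ...)."""


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    name: str
    canonical_smiles: str


@dataclass(frozen=True)
class CellLineRecord:
    cell_id: str
    tissue: str
    features: np.ndarray  # binary vector, mutation states then CNAs


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def load_drug_list(path: str | Path, smiles_map: str | Path) -> list[DrugRecord]:
    """Read the drug list, de-duplicate, and attach canonical SMILES.

    Duplicated drug_ids keep their first occurrence; drugs absent from the
    SMILES mapping are dropped with a logged warning.  Records are returned
    sorted by drug_id so the result is independent of input row order.
    """
    drugs = pd.read_csv(path, dtype=str)
    _require_columns(drugs, ["drug_id", "name"], str(path))
    mapping = pd.read_csv(smiles_map, dtype=str)
    _require_columns(mapping, ["drug_id", "canonical_smiles"], str(smiles_map))
    smiles = dict(zip(mapping["drug_id"], mapping["canonical_smiles"]))

    drugs = drugs.drop_duplicates(subset="drug_id", keep="first")
    records = []
    for row in drugs.itertuples(index=False):
        s = smiles.get(row.drug_id)
        if not s or not isinstance(s, str):
            logger.warning("drug %s has no SMILES mapping; dropped", row.drug_id)
            continue
        records.append(
            DrugRecord(drug_id=row.drug_id, name=row.name, canonical_smiles=s)
        )
    if not records:
        raise DataError(f"{path}: no drugs left after cleansing")
    return sorted(records, key=lambda r: r.drug_id)


def _cell_frame_to_wide(df: pd.DataFrame, path: str) -> pd.DataFrame:
    """Accept wide (cell_id,tissue,feat...) or long (cell_id,tissue,feature_name,value)."""
    if {"feature_name", "value"}.issubset(df.columns):
        wide = df.pivot_table(
            index=["cell_id", "tissue"],
            columns="feature_name",
            values="value",
            aggfunc="first",
        ).reset_index()
        wide.columns.name = None
        return wide
    _require_columns(df, ["cell_id", "tissue"], path)
    return df


def load_cell_lines(
    path: str | Path,
    required_features: int | None = None,
    feature_catalogue: Sequence[str] | None = None,
) -> list[CellLineRecord]:
    """Read the cell-line feature table and drop incomplete cell lines.

    A cell line is kept iff it has at least ``required_features`` defined
    (non-missing) feature values; the strict "fewer than" drop rule keeps
    cells sitting exactly at the threshold.  ``required_features`` defaults
    to the size of the feature catalogue (all columns defined).  Features are
    ordered by ``feature_catalogue`` when given, else by column order.
    """
    df = pd.read_csv(path)
    df = _cell_frame_to_wide(df, str(path))
    feat_cols = [c for c in df.columns if c not in ("cell_id", "tissue")]
    if feature_catalogue is not None:
        unknown = [c for c in feat_cols if c not in set(feature_catalogue)]
        if unknown:
            raise SchemaError(f"{path}: unknown feature name(s) {unknown[:5]}")
        feat_cols = [c for c in feature_catalogue if c in df.columns]
    if not feat_cols:
        raise SchemaError(f"{path}: no feature columns found")
    if required_features is None:
        required_features = len(feat_cols)

    records = []
    values = df[feat_cols].to_numpy(dtype=float)
    defined = np.isfinite(values).sum(axis=1)
    for i, row in enumerate(df.itertuples(index=False)):
        if defined[i] < required_features:
            continue
        feats = values[i]
        if not np.isin(feats[np.isfinite(feats)], (0.0, 1.0)).all():
            raise DataError(f"{path}: non-binary feature value for {row.cell_id}")
        records.append(
            CellLineRecord(
                cell_id=str(row.cell_id),
                tissue=str(row.tissue),
                features=np.nan_to_num(feats).astype(np.uint8),
            )
        )
    if not records:
        raise DataError(f"{path}: no cell lines left after cleansing")
    return sorted(records, key=lambda r: r.cell_id)


def normalize_ic50(x_log, alpha: float = DEFAULT_ALPHA):
    """Map log-IC50 x to (0,1) via 1/(1 + y^alpha) with y = e^x.

    With the default alpha = -0.1 this is the logistic function of 0.1*x:
    strictly increasing, normalize_ic50(0) == 0.5.
    """
    x = np.asarray(x_log, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("log-IC50 values must be finite")
    out = 1.0 / (1.0 + np.exp(alpha * x))
    return out if out.ndim else float(out)


def denormalize_ic50(v, alpha: float = DEFAULT_ALPHA):
    """Inverse of :func:`normalize_ic50`; domain (0, 1)."""
    v_arr = np.asarray(v, dtype=float)
    if np.any(v_arr <= 0.0) or np.any(v_arr >= 1.0):
        raise ValueError("normalized IC50 must lie strictly in (0, 1)")
    out = np.log((1.0 - v_arr) / v_arr) / alpha
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class InteractionTable:
    """Dense drug x cell matrix of normalized IC50 with masks.

    ``values[i, j]`` is meaningful only where ``known_mask[i, j] == 1``;
    ``below_max_conc_mask`` is 1 only on known entries whose measurement fell
    below the maximum screening concentration.
    """

    drugs: tuple[DrugRecord, ...]
    cells: tuple[CellLineRecord, ...]
    values: np.ndarray
    known_mask: np.ndarray
    below_max_conc_mask: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.drugs), len(self.cells))
        for name in ("values", "known_mask", "below_max_conc_mask"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} has shape {getattr(self, name).shape}, "
                                 f"expected {shape}")
        if np.any(self.below_max_conc_mask > self.known_mask):
            raise DataError("below_max_conc_mask set on an unknown entry")
        known = self.known_mask.astype(bool)
        v = self.values[known]
        if v.size and (v.min() <= 0.0 or v.max() >= 1.0):
            raise DataError("normalized values must lie strictly in (0, 1)")

    @property
    def drug_ids(self) -> list[str]:
        return [d.drug_id for d in self.drugs]

    @property
    def cell_ids(self) -> list[str]:
        return [c.cell_id for c in self.cells]

    @property
    def tissues(self) -> list[str]:
        return sorted({c.tissue for c in self.cells})

    def drug_index(self, drug_id: str) -> int:
        try:
            return self.drug_ids.index(drug_id)
        except ValueError:
            raise KeyError(f"unknown drug {drug_id!r}") from None

    def cell_index(self, cell_id: str) -> int:
        try:
            return self.cell_ids.index(cell_id)
        except ValueError:
            raise KeyError(f"unknown cell line {cell_id!r}") from None

    def known_pairs(self) -> list[tuple[str, str]]:
        """All (drug_id, cell_id) pairs with a measured response, row-major."""
        di, ci = np.nonzero(self.known_mask)
        return [(self.drugs[i].drug_id, self.cells[j].cell_id)
                for i, j in zip(di, ci)]

    def missing_pairs(self) -> list[tuple[str, str]]:
        di, ci = np.nonzero(1 - self.known_mask)
        return [(self.drugs[i].drug_id, self.cells[j].cell_id)
                for i, j in zip(di, ci)]

    def pair_values(self, pairs: Sequence[tuple[str, str]]) -> np.ndarray:
        di = {d: i for i, d in enumerate(self.drug_ids)}
        ci = {c: j for j, c in enumerate(self.cell_ids)}
        out = np.empty(len(pairs))
        for k, (d, c) in enumerate(pairs):
            i, j = di[d], ci[c]
            if not self.known_mask[i, j]:
                raise KeyError(f"pair ({d}, {c}) has no measured value")
            out[k] = self.values[i, j]
        return out

    def known_fraction(self) -> float:
        return float(self.known_mask.sum()) / self.known_mask.size

    def below_max_conc_fraction(self) -> float:
        """Fraction of known responses measured below max_conc."""
        known = self.known_mask.sum()
        return float(self.below_max_conc_mask.sum()) / known if known else 0.0


def build_interaction_table(
    drugs: Sequence[DrugRecord],
    cells: Sequence[CellLineRecord],
    ic50_path: str | Path,
    alpha: float = DEFAULT_ALPHA,
) -> InteractionTable:
    """Assemble the interaction table from a long-format IC50 CSV.

    Rows referencing drugs or cells dropped by the cleansing steps are
    discarded; surviving log-IC50 values are normalized into (0, 1).  The
    optional ``below_max_conc`` column defaults to 1 when absent.
    """
    df = pd.read_csv(ic50_path, dtype={"drug_id": str, "cell_id": str})
    _require_columns(df, ["drug_id", "cell_id", "log_ic50"], str(ic50_path))
    if "below_max_conc" not in df.columns:
        df["below_max_conc"] = 1

    di = {d.drug_id: i for i, d in enumerate(drugs)}
    ci = {c.cell_id: j for j, c in enumerate(cells)}
    df = df[df["drug_id"].isin(di) & df["cell_id"].isin(ci)]
    dup = df.duplicated(subset=["drug_id", "cell_id"])
    if dup.any():
        first = df[dup].iloc[0]
        raise DataError(
            f"duplicate IC50 row for pair ({first['drug_id']}, {first['cell_id']})"
        )

    values = np.zeros((len(drugs), len(cells)))
    known = np.zeros_like(values, dtype=np.uint8)
    below = np.zeros_like(known)
    for row in df.itertuples(index=False):
        try:
            x = float(row.log_ic50)
        except (TypeError, ValueError):
            raise DataError(
                f"unparseable log_ic50 for pair ({row.drug_id}, {row.cell_id})"
            ) from None
        i, j = di[row.drug_id], ci[row.cell_id]
        values[i, j] = normalize_ic50(x, alpha=alpha)
        known[i, j] = 1
        below[i, j] = 1 if int(row.below_max_conc) else 0
    return InteractionTable(
        drugs=tuple(drugs), cells=tuple(cells),
        values=values, known_mask=known, below_max_conc_mask=below,
    )


def max_conc_subset(table: InteractionTable) -> InteractionTable:
    """Restrict the known set to responses measured below max_conc."""
    if table.below_max_conc_mask is None:
        raise ValueError("below_max_conc_mask is not populated")
    known = (table.known_mask & table.below_max_conc_mask).astype(np.uint8)
    return replace(table, known_mask=known, below_max_conc_mask=known.copy())


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def save_table(table: InteractionTable, out_dir: str | Path) -> Path:
    """Serialize as binary arrays plus a JSON manifest with checksums."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = {
        "values": table.values,
        "known_mask": table.known_mask,
        "below_max_conc_mask": table.below_max_conc_mask,
        "cell_features": np.stack([c.features for c in table.cells]),
    }
    for name, arr in arrays.items():
        np.save(out / f"{name}.npy", arr)
    manifest = {
        "drugs": [[d.drug_id, d.name, d.canonical_smiles] for d in table.drugs],
        "cells": [[c.cell_id, c.tissue] for c in table.cells],
        "shapes": {k: list(v.shape) for k, v in arrays.items()},
        "checksums": {k: _sha256(out / f"{k}.npy") for k in arrays},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def load_table(in_dir: str | Path) -> InteractionTable:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    arrays = {}
    for name, digest in manifest["checksums"].items():
        path = in_dir / f"{name}.npy"
        if _sha256(path) != digest:
            raise DataError(f"checksum mismatch for {path}")
        arrays[name] = np.load(path)
    feats = arrays["cell_features"]
    cells = tuple(
        CellLineRecord(cell_id=c, tissue=t, features=feats[j].astype(np.uint8))
        for j, (c, t) in enumerate(manifest["cells"])
    )
    drugs = tuple(DrugRecord(*row) for row in manifest["drugs"])
    return InteractionTable(
        drugs=drugs, cells=cells,
        values=arrays["values"],
        known_mask=arrays["known_mask"].astype(np.uint8),
        below_max_conc_mask=arrays["below_max_conc_mask"].astype(np.uint8),
    )
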