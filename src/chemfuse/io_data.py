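"""Reading and writing compound tables and pipeline outputs.

A *labeled dataset* is an ordered list of compounds, each carrying a
canonical SMILES, a binary hepatotoxicity (DILI) label, and optional in
vitro potency values for seven assay endpoints (two hepatic cell lines and
five cytochromes). Row order is significant: it defines the row order of
every feature matrix, embedding and distance summary downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .errors import AlignmentError, ConfigurationError, EmptyDatasetError

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: Assay endpoints of the in vitro profile, in canonical column order.
ASSAYS: tuple[str, ...] = (
    "HepG2",
    "Huh7",
    "CYP1A2",
    "CYP2A6",
    "CYP2C9",
    "CYP2D6",
    "CYP3A4",
)

#: Default guesses for the semantic roles of a compound table's columns.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "id": "compound_id",
    "smiles": "smiles",
    "dili": "dili",
    **{a: a for a in ASSAYS},
}


@dataclass
class CompoundRecord:
    """One molecule with its label and (possibly partial) assay profile.

    ``activities`` maps assay names to potency values on a pChEMBL-like
    scale; ``activity_missing`` marks, per assay, whether the value was
    absent in the source (imputation happens later, in the descriptor
    layer, not here).
    """

    compound_id: str
    smiles: str
    dili_positive: bool
    activities: dict[str, float] = field(default_factory=dict)
    activity_missing: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for assay in self.activities:
            self.activity_missing.setdefault(assay, False)


@dataclass
class LabeledDataset:
    """Ordered collection of :class:`CompoundRecord` with a name."""

    records: list[CompoundRecord]
    name: str = "dataset"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def compound_ids(self) -> list[str]:
        return [r.compound_id for r in self.records]

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        """Boolean vector, True = associated with DILI events."""
        return np.array([r.dili_positive for r in self.records], dtype=bool)

    def validate(self) -> None:
        ids = self.compound_ids
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate compound_id in dataset {self.name!r}")


def canonical_smiles(smiles: str) -> str | None:
    """RDKit-canonical form of *smiles*, or None if it does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def _coerce_bool(value) -> bool:
    if isinstance(value, str):
        v = value.strip().lower()
        if v in {"1", "true", "yes", "y", "positive", "pos"}:
            return True
        if v in {"0", "false", "no", "n", "negative", "neg"}:
            return False
        raise ValueError(f"cannot interpret DILI label {value!r}")
    return bool(value)


def _records_from_frame(
    frame: pd.DataFrame, column_map: Mapping[str, str], name: str
) -> LabeledDataset:
    for role in ("id", "smiles", "dili"):
        col = column_map.get(role)
        if col is None or col not in frame.columns:
            raise ConfigurationError(
                f"column map does not resolve mandatory role {role!r} "
                f"(got {col!r}; available columns: {list(frame.columns)})"
            )
    activity_cols = {
        a: column_map[a]
        for a in ASSAYS
        if a in column_map and column_map[a] in frame.columns
    }

    records: list[CompoundRecord] = []
    seen: dict[str, CompoundRecord] = {}
    n_bad, n_dup = 0, 0
    for _, row in frame.iterrows():
        can = canonical_smiles(str(row[column_map["smiles"]]))
        if can is None:
            n_bad += 1
            continue
        label = _coerce_bool(row[column_map["dili"]])
        if can in seen:
            n_dup += 1
            if seen[can].dili_positive != label:
                logger.warning(
                    "conflicting DILI labels for canonical SMILES %s; "
                    "keeping first occurrence (%s)",
                    can,
                    seen[can].dili_positive,
                )
            continue
        activities: dict[str, float] = {}
        missing: dict[str, bool] = {}
        for assay, col in activity_cols.items():
            raw = row[col]
            if pd.isna(raw):
                missing[assay] = True
            else:
                activities[assay] = float(raw)
                missing[assay] = False
        rec = CompoundRecord(
            compound_id=str(row[column_map["id"]]),
            smiles=can,
            dili_positive=label,
            activities=activities,
            activity_missing=missing,
        )
        seen[can] = rec
        records.append(rec)

    if n_bad:
        logger.info("dropped %d rows with unparseable SMILES", n_bad)
    if n_dup:
        logger.info("collapsed %d duplicate canonical SMILES rows", n_dup)
    if not records:
        raise EmptyDatasetError("no parseable compound rows in input")
    ds = LabeledDataset(records=records, name=name)
    ds.validate()
    return ds


def load_compound_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> LabeledDataset:
    """Load a compound table from CSV, SDF, or one-SMILES-per-line text.

    ``column_map`` maps semantic roles (``id``, ``smiles``, ``dili``, and
    optionally the assay names) to column names / SDF property tags. SMILES
    are canonicalized; rows that fail to parse are dropped and counted in
    the log; rows whose canonical SMILES duplicates an earlier row are
    collapsed to the first occurrence.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    suffix = path.suffix.lower()
    if suffix == ".sdf":
        frame = _frame_from_sdf(path, cmap)
    elif suffix in {".smi", ".smiles", ".txt"}:
        frame = _frame_from_smiles_list(path)
        cmap.update({"id": "compound_id", "smiles": "smiles", "dili": "dili"})
    else:
        frame = pd.read_csv(path, sep=delimiter)
    return _records_from_frame(frame, cmap, name=path.stem)


def _frame_from_sdf(path: Path, cmap: Mapping[str, str]) -> pd.DataFrame:
    rows = []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            rows.append({cmap["smiles"]: "*invalid*", cmap["id"]: f"sdf_{i}", cmap["dili"]: 0})
            continue
        props = mol.GetPropsAsDict()
        row = {cmap["smiles"]: Chem.MolToSmiles(mol)}
        row[cmap["id"]] = str(props.get(cmap["id"], f"sdf_{i}"))
        row[cmap["dili"]] = props.get(cmap["dili"], 0)
        for assay in ASSAYS:
            tag = cmap.get(assay, assay)
            if tag in props:
                row[tag] = props[tag]
        rows.append(row)
    return pd.DataFrame(rows)


def _frame_from_smiles_list(path: Path) -> pd.DataFrame:
    rows = []
    for i, line in enumerate(path.read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        rows.append(
            {
                "smiles": parts[0],
                "compound_id": parts[1] if len(parts) > 1 else f"smi_{i}",
                "dili": 0,
            }
        )
    return pd.DataFrame(rows)


def write_compound_table(dataset: LabeledDataset, path: str | Path) -> Path:
    """Write *dataset* in the CSV dialect :func:`load_compound_table` reads."""
    path = Path(path)
    rows = []
    for rec in dataset:
        row: dict = {
            "compound_id": rec.compound_id,
            "smiles": rec.smiles,
            "dili": int(rec.dili_positive),
        }
        for assay in ASSAYS:
            if rec.activity_missing.get(assay, True):
                row[assay] = ""
            else:
                row[assay] = repr(rec.activities[assay])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_embedding_table(
    embeddings: Sequence, path: str | Path, labels: Iterable[bool] | None = None
) -> Path:
    """Write one CSV with a coordinate-pair column block per space.

    All embeddings must share the same compound order. Floats are written
    with ``repr``-stable formatting and round-trip at 10 significant digits.
    Each embedding must expose ``compound_ids``, ``coords`` (n x 2),
    ``space_name`` and ``axis_names``; both per-representation and consensus
    embeddings qualify. ``labels`` adds a ``dili`` column.
    """
    embeddings = list(embeddings)
    if not embeddings:
        raise ValueError("no embeddings to write")
    ref_ids = list(embeddings[0].compound_ids)
    for emb in embeddings[1:]:
        if list(emb.compound_ids) != ref_ids:
            raise AlignmentError(
                f"compound order of space {emb.space_name!r} does not match "
                f"{embeddings[0].space_name!r}"
            )
    data: dict[str, list] = {"compound_id": ref_ids}
    if labels is not None:
        data["dili"] = [int(v) for v in labels]
    for emb in embeddings:
        ax = emb.axis_names
        data[f"{emb.space_name}:{ax[0]}"] = list(emb.coords[:, 0])
        data[f"{emb.space_name}:{ax[1]}"] = list(emb.coords[:, 1])
    path = Path(path)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")
    return path
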