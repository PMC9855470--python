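"""Per-representation feature matrices.

Five representations of a compound library are supported:

``maccs``
    166-bit MACCS structural keys.
``rdkit_fp``
    path-based RDKit topological fingerprint, 2048 bits.
``ecfp4``
    circular (Morgan) fingerprint of radius 2, hashed to 1024 bits.
``properties``
    six physicochemical descriptors: H-bond donors, H-bond acceptors,
    rotatable bonds, molecular weight, atom-contribution (Crippen) cLogP,
    and topological polar surface area (TPSA). The Crippen logP differs in
    absolute value from other estimators; here it is only one of six
    embedding features.
``invitro``
    the seven-assay bioactivity profile: per-assay z-scored potency with
    missing values imputed to 0 after z-scoring, plus a binary
    missing-value mask column per assay (14 columns total).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .errors import ConfigurationError, TooFewCompoundsError
from .io_data import ASSAYS, LabeledDataset

logger = logging.getLogger(__name__)

REPRESENTATIONS: tuple[str, ...] = ("maccs", "rdkit_fp", "ecfp4", "properties", "invitro")

_FP_WIDTHS = {"maccs": 166, "rdkit_fp": 2048, "ecfp4": 1024}

PROPERTY_NAMES: tuple[str, ...] = ("HBD", "HBA", "RotB", "MW", "cLogP", "TPSA")


@dataclass
class FeatureMatrix:
    """One representation of all compounds, rows in dataset order."""

    representation: str
    values: np.ndarray
    feature_names: list[str]
    compound_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length does not match matrix width")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.compound_ids, columns=self.feature_names)


def _mols(dataset: LabeledDataset) -> list[Chem.Mol]:
    mols = []
    for rec in dataset:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            raise ValueError(f"record {rec.compound_id!r} has invalid SMILES {rec.smiles!r}")
        mols.append(mol)
    return mols


def compute_fingerprints(dataset: LabeledDataset, kind: str) -> FeatureMatrix:
    """Binary fingerprint matrix for every compound.

    ``maccs`` exposes the 166 public keys (the generator's internal bit 0
    placeholder is dropped); ``rdkit_fp`` is the default path-based
    fingerprint folded to 2048 bits; ``ecfp4`` is Morgan radius 2 folded to
    1024 bits. Deterministic for a given SMILES.
    """
    if kind not in _FP_WIDTHS:
        raise ConfigurationError(
            f"unknown fingerprint kind {kind!r}; expected one of {sorted(_FP_WIDTHS)}"
        )
    width = _FP_WIDTHS[kind]
    mols = _mols(dataset)
    rows = np.zeros((len(mols), width), dtype=float)
    if kind == "maccs":
        for i, mol in enumerate(mols):
            bv = MACCSkeys.GenMACCSKeys(mol)  # 167 slots, slot 0 always unset
            arr = np.zeros((167,), dtype=np.uint8)
            for b in bv.GetOnBits():
                arr[b] = 1
            rows[i] = arr[1:]
    else:
        if kind == "rdkit_fp":
            gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=2048)
        else:
            gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)
        for i, mol in enumerate(mols):
            bv = gen.GetFingerprint(mol)
            for b in bv.GetOnBits():
                rows[i, b] = 1.0
    names = [f"{kind}_{j}" for j in range(width)]
    return FeatureMatrix(kind, rows, names, dataset.compound_ids)


def compute_properties(dataset: LabeledDataset) -> FeatureMatrix:
    """Six physicochemical descriptors per compound (unscaled).

    Column order: HBD, HBA, RotB, MW, cLogP, TPSA.
    """
    mols = _mols(dataset)
    rows = np.empty((len(mols), 6), dtype=float)
    for i, mol in enumerate(mols):
        rows[i] = (
            Lipinski.NumHDonors(mol),
            Lipinski.NumHAcceptors(mol),
            rdMolDescriptors.CalcNumRotatableBonds(mol),
            Descriptors.MolWt(mol),
            Crippen.MolLogP(mol),
            rdMolDescriptors.CalcTPSA(mol),
        )
    return FeatureMatrix("properties", rows, list(PROPERTY_NAMES), dataset.compound_ids)


def encode_invitro(dataset: LabeledDataset) -> FeatureMatrix:
    """Seven z-scored assay columns plus seven missing-mask columns.

    Each assay is z-scored over its *observed* values (population SD);
    missing entries are imputed to 0 after z-scoring, i.e. to the observed
    mean, and flagged with 1 in the corresponding mask column. An assay
    observed in no compound yields an all-zero value column (logged).
    """
    n = len(dataset)
    values = np.zeros((n, 7), dtype=float)
    masks = np.zeros((n, 7), dtype=float)
    for j, assay in enumerate(ASSAYS):
        raw = np.full(n, np.nan)
        for i, rec in enumerate(dataset):
            if not rec.activity_missing.get(assay, True):
                raw[i] = rec.activities[assay]
        observed = ~np.isnan(raw)
        masks[~observed, j] = 1.0
        if not observed.any():
            logger.info("assay %s observed in zero compounds; value column all-zeros", assay)
            continue
        obs = raw[observed]
        sd = obs.std()  # population SD
        centered = obs - obs.mean()
        values[observed, j] = centered / sd if sd > 0 else 0.0
    mat = np.hstack([values, masks])
    names = list(ASSAYS) + [f"{a}_missing" for a in ASSAYS]
    return FeatureMatrix("invitro", mat, names, dataset.compound_ids)


def scale_properties(matrix: FeatureMatrix) -> FeatureMatrix:
    """Z-score each property column (population SD); constant columns to 0.

    Mixed units (daltons vs counts) would otherwise dominate the distance
    geometry of the embedding.
    """
    if matrix.representation != "properties":
        raise ConfigurationError("scale_properties expects the properties matrix")
    if matrix.n_compounds < 2:
        raise TooFewCompoundsError("z-scoring requires at least 2 compounds")
    vals = matrix.values
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0)
    scaled = np.where(sd > 0, (vals - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return FeatureMatrix(
        "properties", scaled, list(matrix.feature_names), list(matrix.compound_ids)
    )


def featurize(dataset: LabeledDataset, representation: str) -> FeatureMatrix:
    """Dispatch to the right feature computation, scaling where needed."""
    if representation in _FP_WIDTHS:
        return compute_fingerprints(dataset, representation)
    if representation == "properties":
        return scale_properties(compute_properties(dataset))
    if representation == "invitro":
        return encode_invitro(dataset)
    raise ConfigurationError(
        f"unknown representation {representation!r}; expected one of {REPRESENTATIONS}"
    )
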