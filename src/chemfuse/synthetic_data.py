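"""Seeded synthetic compound libraries with DILI-like label structure.

The generator emulates a curated hepatotoxicity table: a few hundred
drug-like molecules, a binary DILI label, and a partially missing
seven-assay in vitro profile. Two label signals can be switched on
independently:

``structure``
    DILI-positive compounds are preferentially (probability 0.8) assembled
    from halogen-, sulfur- or phosphorus-bearing scaffolds, mirroring the
    over-representation of organohalogen/organosulfur/organophosphorus
    classes among hepatotoxic drugs.
``invitro``
    positives' assay potencies are drawn from Normal(base + effect, sd)
    versus Normal(base, sd) for negatives.

The generator provides statistical, not pharmacological, realism: labels
are linked to descriptor distributions, not to any toxicophore model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from .io_data import ASSAYS, CompoundRecord, LabeledDataset, write_compound_table

# Scaffold templates: one substitution point each. "hetero" scaffolds carry
# halogen, sulfur or phosphorus atoms; the rest are plain C/N/O frameworks.
# Digit 9 is reserved for ring closures inside substituents.
HETERO_SCAFFOLDS: tuple[str, ...] = (
    "Clc1ccc({})cc1",            # chlorobenzene
    "Fc1ccc({})cc1",             # fluorobenzene
    "Brc1ccc({})cc1",            # bromobenzene
    "FC(F)(F)c1ccc({})cc1",      # trifluoromethylbenzene
    "Clc1cccc(Cl)c1{}",          # dichlorobenzene
    "c1cc({})cs1",               # thiophene
    "c1csc({})n1",               # thiazole
    "NS(=O)(=O)c1ccc({})cc1",    # benzenesulfonamide
    "CS(=O)(=O)N({})C",          # methanesulfonamide
    "O=P(O)(O)OC{}",             # phosphate monoester
    "CCOP(=O)(OCC)C{}",          # phosphonate diester
    "Clc1ccc2nc({})ccc2c1",      # chloroquinoline
    "Fc1ccc(C(=O)N{})cc1",       # fluorobenzamide
    "S=C(N)N{}",                 # thiourea
)
PLAIN_SCAFFOLDS: tuple[str, ...] = (
    "c1ccc({})cc1",              # benzene
    "c1ccnc({})c1",              # pyridine
    "c1ccc2[nH]c({})cc2c1",      # indole
    "c1ccc2nc({})ccc2c1",        # quinoline
    "c1cnc2c(n1)cc(cc2){}",      # quinoxaline
    "O=C(N{})c1ccccc1",          # benzamide
    "O=C(O)c1ccc({})cc1",        # benzoic acid
    "C1CCN({})CC1",              # piperidine
    "C1CN(CCN1C)C{}",            # methylpiperazine
    "O1CCN(CC1)C{}",             # morpholine
    "c1ccc(OC{})cc1",            # phenyl ether
    "CC(=O)Nc1ccc({})cc1",       # acetanilide
    "c1ccc(N{})nc1",             # aminopyridine... substituted amine
    "O=C1NC(=O)c2ccccc2N1{}",    # quinazolinedione-like
)
SUBSTITUENTS: tuple[str, ...] = (
    "C", "CC", "CCC", "CCCC", "C(C)C", "CO", "CCO", "CCN", "CN(C)C",
    "C(=O)O", "C(=O)N", "C(=O)C", "C#N", "OC", "OCC", "N", "NC",
    "CCOC", "C=C", "CC(=O)O", "c9ccccc9", "C9CCCCC9", "CC9CCNCC9",
)

DEFAULT_SCAFFOLD_POOL: tuple[str, ...] = HETERO_SCAFFOLDS + PLAIN_SCAFFOLDS

_HETERO_ATOMS = {"F", "Cl", "Br", "I", "S", "P"}


def _is_hetero(template: str) -> bool:
    mol = Chem.MolFromSmiles(template.format("C"))
    return any(a.GetSymbol() in _HETERO_ATOMS for a in mol.GetAtoms())


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic library."""

    n_compounds: int = 60
    positive_fraction: float = 0.3
    signal_views: frozenset = frozenset({"structure", "invitro"})
    scaffold_pool: tuple[str, ...] = DEFAULT_SCAFFOLD_POOL
    activity_effect: float = 1.5
    activity_base: float = 5.0
    noise_sd: float = 1.0
    missing_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 8:
            raise ValueError("n_compounds must be >= 8")
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must be in (0, 1)")
        if self.activity_effect < 0 or self.noise_sd <= 0:
            raise ValueError("activity_effect must be >= 0 and noise_sd > 0")
        if not self.scaffold_pool:
            raise ValueError("scaffold pool is empty")
        unknown = set(self.signal_views) - {"structure", "invitro"}
        if unknown:
            raise ValueError(f"unknown signal views: {sorted(unknown)}")


def _assemble(rng: np.random.Generator, templates: list[str], seen: set[str]) -> str:
    """One new molecule: scaffold + substituent (+ optional alkyl prefix)."""
    for attempt in range(500):
        template = templates[rng.integers(len(templates))]
        sub = SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))]
        tail = "C" * int(rng.integers(0, 4))
        if tail and sub.startswith(("c9", "C9")):
            candidate = template.format(tail + sub)
        else:
            candidate = template.format(sub + tail)
        mol = Chem.MolFromSmiles(candidate)
        if mol is None:
            continue
        can = Chem.MolToSmiles(mol)
        if can not in seen:
            return can
    raise RuntimeError("could not assemble a new unique molecule from the scaffold pool")


def generate(spec: SyntheticSpec) -> LabeledDataset:
    """Generate a :class:`LabeledDataset` fully reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_compounds
    n_pos = int(round(n * spec.positive_fraction))
    labels = np.zeros(n, dtype=bool)
    labels[rng.choice(n, size=n_pos, replace=False)] = True

    hetero = [t for t in spec.scaffold_pool if _is_hetero(t)]
    plain = [t for t in spec.scaffold_pool if not _is_hetero(t)]
    pool = list(spec.scaffold_pool)
    structure_signal = "structure" in spec.signal_views and hetero and plain

    seen: set[str] = set()
    records: list[CompoundRecord] = []
    for i in range(n):
        positive = bool(labels[i])
        if structure_signal:
            if positive:
                templates = hetero if rng.random() < 0.8 else plain
            else:
                templates = plain if rng.random() < 0.8 else hetero
        else:
            templates = pool
        smiles = _assemble(rng, templates, seen)
        seen.add(smiles)

        base = spec.activity_base
        shift = spec.activity_effect if (positive and "invitro" in spec.signal_views) else 0.0
        activities: dict[str, float] = {}
        missing: dict[str, bool] = {}
        for assay in ASSAYS:
            if rng.random() < spec.missing_fraction:
                missing[assay] = True
            else:
                activities[assay] = float(rng.normal(base + shift, spec.noise_sd))
                missing[assay] = False
        records.append(
            CompoundRecord(
                compound_id=f"SYN{i:04d}",
                smiles=smiles,
                dili_positive=positive,
                activities=activities,
                activity_missing=missing,
            )
        )
    ds = LabeledDataset(records=records, name=f"synthetic_n{n}_seed{spec.seed}")
    ds.validate()
    return ds


def make_fixtures(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a small (n=60) and a medium (n=471) synthetic table as CSV.

    The medium table is a synthetic stand-in for a 471-compound curated
    hepatotoxicity library; file names mark it as synthetic.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for tag, n in (("small", 60), ("medium", 471)):
        ds = generate(SyntheticSpec(n_compounds=n, seed=seed))
        paths[tag] = write_compound_table(ds, out_dir / f"synthetic_dili_{tag}_n{n}.csv")
    return paths
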