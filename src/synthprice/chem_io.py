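"""Catalog ingestion and preprocessing.

Reads supplier catalogs of purchasable (easy-to-synthesize, ES) molecules
with market prices, canonicalizes structures, normalizes prices to USD per
mmol, and applies a five-step cleaning pipeline:

1. drop structures the toolkit cannot parse;
2. normalize prices to USD/mmol, dropping entries with missing or
   unrecognized units;
3. collapse duplicate molecules, keeping the minimum USD/mmol price
   across suppliers;
4. transform prices to the natural-log scale;
5. drop molecules whose raw price falls below a cutoff (default
   2 USD/mmol) — these are typically stabilizing salts, metals or solvents.

Dot-disconnected (salt/mixture) SMILES are kept if parsable; the price
filter, not fragment stripping, is what removes cheap commodity species.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

from .errors import (
    ConfigError,
    EmptyDatasetError,
    InvalidStructureError,
    UnitError,
)

RDLogger.DisableLog("rdApp.*")

#: Conversion factors: price[unit] * factor(unit, mw) -> USD per mmol.
#: A price per gram times MW (g/mol) gives USD/mol; divide by 1000 for mmol.
_UNIT_TOKENS = ("per-gram", "per-mg", "per-mmol", "per-mol")

SPLIT_NAMES = ("train", "val", "test")
DEFAULT_FRACTIONS = (0.9, 0.05, 0.05)


@dataclasses.dataclass(frozen=True)
class RawCatalogEntry:
    """One supplier offer: a SMILES with a price in some unit."""

    smiles: str
    price: float
    unit: str | None
    supplier_id: str = ""
    mol_weight: float | None = None


@dataclasses.dataclass(frozen=True)
class MoleculeRecord:
    """A canonicalized molecule with an optional natural-log USD/mmol price.

    ``log_price`` is ``None`` for hard-to-synthesize (HS) and unlabeled
    molecules, which carry no market price.
    """

    canonical_smiles: str
    log_price: float | None
    n_heavy_atoms: int
    source: str = "ES"  # one of {"ES", "HS", "unlabeled"}


@dataclasses.dataclass
class FilterReport:
    """Per-step removal counts for :func:`preprocess_catalog`."""

    n_input: int
    n_unparsable: int
    n_bad_unit: int
    n_duplicates: int
    n_below_min_price: int
    n_survivors: int

    def conserved(self) -> bool:
        removed = (
            self.n_unparsable
            + self.n_bad_unit
            + self.n_duplicates
            + self.n_below_min_price
        )
        return removed + self.n_survivors == self.n_input

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclasses.dataclass
class PricedDataset:
    """Ordered molecule records plus an optional train/val/test assignment."""

    records: list[MoleculeRecord]
    split_assignment: dict[str, str] = dataclasses.field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, split: str) -> list[MoleculeRecord]:
        return [
            r for r in self.records if self.split_assignment.get(r.canonical_smiles) == split
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "canonical_smiles": [r.canonical_smiles for r in self.records],
                "log_price": [r.log_price for r in self.records],
                "n_heavy_atoms": [r.n_heavy_atoms for r in self.records],
                "source": [r.source for r in self.records],
                "split": [
                    self.split_assignment.get(r.canonical_smiles, "") for r in self.records
                ],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PricedDataset":
        records = []
        split: dict[str, str] = {}
        for row in df.itertuples(index=False):
            lp = getattr(row, "log_price", None)
            lp = None if lp is None or (isinstance(lp, float) and np.isnan(lp)) else float(lp)
            rec = MoleculeRecord(
                canonical_smiles=row.canonical_smiles,
                log_price=lp,
                n_heavy_atoms=int(getattr(row, "n_heavy_atoms", 0)),
                source=str(getattr(row, "source", "ES")),
            )
            records.append(rec)
            s = str(getattr(row, "split", "") or "")
            if s:
                split[rec.canonical_smiles] = s
        return cls(records=records, split_assignment=split)

    @classmethod
    def read_csv(cls, path: str | Path) -> "PricedDataset":
        return cls.from_frame(pd.read_csv(path))


def parse_and_canonicalize(
    smiles: str,
    log_price: float | None = None,
    source: str = "ES",
) -> MoleculeRecord:
    """Parse a SMILES and return a record with the toolkit-canonical form.

    Raises :class:`InvalidStructureError` for empty or unparsable input.
    Two spellings of the same molecule map to the same canonical SMILES.
    """
    if not smiles or not isinstance(smiles, str):
        raise InvalidStructureError(str(smiles), "empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidStructureError(smiles)
    return MoleculeRecord(
        canonical_smiles=Chem.MolToSmiles(mol),
        log_price=log_price,
        n_heavy_atoms=mol.GetNumHeavyAtoms(),
        source=source,
    )


def normalize_price(price: float, unit: str | None, mol_weight: float) -> float:
    """Convert a price in the given unit to USD per mmol.

    Supported units: ``per-gram``, ``per-mg``, ``per-mmol``, ``per-mol``.
    The molar basis correlates better with synthesis effort than a mass
    basis, so everything downstream works in USD/mmol.
    """
    if unit not in _UNIT_TOKENS:
        raise UnitError(f"missing or unrecognized unit: {unit!r}")
    if price <= 0:
        raise ValueError(f"price must be positive, got {price}")
    if unit == "per-mmol":
        return float(price)
    if unit == "per-mol":
        return float(price) / 1000.0
    if mol_weight is None or mol_weight <= 0:
        raise ValueError(f"mol_weight must be positive, got {mol_weight}")
    if unit == "per-gram":
        # USD/g * g/mol = USD/mol; /1000 -> USD/mmol
        return float(price) * float(mol_weight) / 1000.0
    # per-mg: USD/mg * 1000 mg/g = USD/g
    return float(price) * 1000.0 * float(mol_weight) / 1000.0


def preprocess_catalog(
    entries: Iterable[RawCatalogEntry],
    min_price: float = 2.0,
) -> tuple[PricedDataset, FilterReport]:
    """Apply the five-step cleaning pipeline to a raw catalog.

    The minimum-price cutoff is applied to the *raw* USD/mmol price (the
    log transform in step 4 only changes the stored scale). Returns the
    surviving records, log-priced, together with a conservation-checked
    :class:`FilterReport`.
    """
    entries = list(entries)
    n_input = len(entries)
    n_unparsable = 0
    n_bad_unit = 0

    # steps 1-2: parse + unit normalization
    normalized: list[tuple[str, int, float]] = []  # (canonical, heavy, usd_per_mmol)
    for e in entries:
        try:
            rec = parse_and_canonicalize(e.smiles)
        except InvalidStructureError:
            n_unparsable += 1
            continue
        mw = e.mol_weight
        if mw is None and e.unit in ("per-gram", "per-mg"):
            mol = Chem.MolFromSmiles(rec.canonical_smiles)
            mw = Descriptors.MolWt(mol)
        try:
            usd_mmol = normalize_price(e.price, e.unit, mw if mw is not None else -1.0)
        except (UnitError, ValueError):
            n_bad_unit += 1
            continue
        normalized.append((rec.canonical_smiles, rec.n_heavy_atoms, usd_mmol))

    # step 3: keep the minimum USD/mmol price per molecule
    best: dict[str, tuple[int, float]] = {}
    for smi, heavy, p in normalized:
        if smi not in best or p < best[smi][1]:
            best[smi] = (heavy, p)
    n_duplicates = len(normalized) - len(best)

    # steps 4-5: log transform, then drop cheap commodity species (raw scale)
    records: list[MoleculeRecord] = []
    n_below = 0
    for smi, (heavy, p) in best.items():
        if p < min_price:
            n_below += 1
            continue
        records.append(
            MoleculeRecord(
                canonical_smiles=smi,
                log_price=float(np.log(p)),
                n_heavy_atoms=heavy,
                source="ES",
            )
        )

    report = FilterReport(
        n_input=n_input,
        n_unparsable=n_unparsable,
        n_bad_unit=n_bad_unit,
        n_duplicates=n_duplicates,
        n_below_min_price=n_below,
        n_survivors=len(records),
    )
    if not records:
        raise EmptyDatasetError(
            f"no molecules survived preprocessing (report: {report.to_json()})"
        )
    return PricedDataset(records=records), report


def split_dataset(
    dataset: PricedDataset,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> PricedDataset:
    """Randomly assign records to train/val/test splits, in place.

    Deterministic under a fixed seed; split sizes follow the fractions
    exactly up to integer rounding (largest-remainder on the first splits).
    """
    if len(fractions) != 3:
        raise ConfigError(f"expected 3 fractions, got {len(fractions)}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError(f"fractions must sum to 1, got {sum(fractions)}")
    n = len(dataset.records)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    assignment: dict[str, str] = {}
    for rank, idx in enumerate(order):
        if rank < n_train:
            split = "train"
        elif rank < n_train + n_val:
            split = "val"
        else:
            split = "test"
        assignment[dataset.records[idx].canonical_smiles] = split
    dataset.split_assignment = assignment
    return dataset


def read_catalog_csv(path: str | Path) -> list[RawCatalogEntry]:
    """Read a delimited catalog with columns smiles, price, unit[, mol_weight, supplier_id]."""
    df = pd.read_csv(path)
    required = {"smiles", "price", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"catalog missing columns: {sorted(missing)}")
    entries = []
    for row in df.itertuples(index=False):
        unit = getattr(row, "unit", None)
        if isinstance(unit, float) and np.isnan(unit):
            unit = None
        mw = getattr(row, "mol_weight", None)
        if mw is not None and (isinstance(mw, float) and np.isnan(mw)):
            mw = None
        entries.append(
            RawCatalogEntry(
                smiles=str(row.smiles),
                price=float(row.price),
                unit=unit,
                supplier_id=str(getattr(row, "supplier_id", "")),
                mol_weight=None if mw is None else float(mw),
            )
        )
    return entries


def read_smiles_file(path: str | Path, source: str = "unlabeled") -> list[MoleculeRecord]:
    """Read a .smi file (one SMILES per line, optional trailing name field)."""
    records = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smi = line.split()[0]
        records.append(parse_and_canonicalize(smi, source=source))
    return records


def write_smiles_file(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    Path(path).write_text("".join(r.canonical_smiles + "\n" for r in records))
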