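"""Virtual-screening post-processing: Pareto fronts and purchasability.

After an SA-aware screen, candidate ligands are reduced to the Pareto
front over the declared objectives (e.g., two docking scores to minimize
and a predicted price to minimize), and the front is characterized by
how purchasable its members are: for each ligand, the maximum Tanimoto
similarity to a reference library of purchasable molecules, summarized
as the fractions exceeding 0.70 and 0.90 and the fraction with an exact
(canonical-SMILES) match.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs

from .chem_io import parse_and_canonicalize
from .errors import ConfigError, InvalidStructureError
from .featurize import DEFAULT_N_BITS, DEFAULT_RADIUS, fingerprint


@dataclasses.dataclass
class ObjectiveTable:
    """Molecules with named objective columns and per-objective directions."""

    table: pd.DataFrame  # must contain a "smiles" column
    directions: dict[str, str]  # objective name -> "minimize" | "maximize"

    def __post_init__(self) -> None:
        if "smiles" not in self.table.columns:
            raise ConfigError('ObjectiveTable requires a "smiles" column')
        if len(self.directions) < 2:
            raise ConfigError("need at least 2 objectives")
        for name, d in self.directions.items():
            if name not in self.table.columns:
                raise ConfigError(f"objective column missing: {name!r}")
            if d not in ("minimize", "maximize"):
                raise ConfigError(f"direction must be minimize/maximize, got {d!r}")
        if self.table[list(self.directions)].isna().any().any():
            raise ConfigError("objective table contains missing values")


def pareto_front(table: ObjectiveTable) -> np.ndarray:
    """Indices (positional) of the non-dominated rows.

    Row ``i`` is dominated if some row is weakly better on every objective
    and strictly better on at least one, after orienting all objectives to
    minimization.  Duplicated front points are all retained (a duplicate
    never strictly improves on its twin).
    """
    if len(table.table) == 0:
        raise ConfigError("empty objective table")
    cols = list(table.directions)
    V = table.table[cols].to_numpy(dtype=np.float64).copy()
    for k, name in enumerate(cols):
        if table.directions[name] == "maximize":
            V[:, k] = -V[:, k]
    n = V.shape[0]
    # vectorized pairwise dominance: dom[k, i] = row k dominates row i
    le = (V[:, None, :] <= V[None, :, :]).all(axis=2)
    lt = (V[:, None, :] < V[None, :, :]).any(axis=2)
    dominated = (le & lt).any(axis=0)
    del n
    return np.flatnonzero(~dominated)


@dataclasses.dataclass
class PurchasabilityReport:
    frac_above_070: float
    frac_above_090: float
    frac_exact: float
    n_ligands: int
    n_reference: int
    n_reference_skipped: int
    fp_scheme: str
    radius: int
    n_bits: int

    def __post_init__(self) -> None:
        assert self.frac_exact <= self.frac_above_090 + 1e-12
        assert self.frac_above_090 <= self.frac_above_070 + 1e-12


def purchasability_stats(
    ligands: Sequence[str],
    reference: Sequence[str],
    fp_scheme: str = "morgan",
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> PurchasabilityReport:
    """Max-Tanimoto purchasability statistics for a ligand set.

    Unparsable reference entries are skipped (and counted); unparsable
    ligands raise, since the ligand list is the analysis target.
    """
    if not ligands or not reference:
        raise ConfigError("both ligand and reference lists must be non-empty")
    ref_fps = []
    ref_smiles = set()
    skipped = 0
    for s in reference:
        try:
            rec = parse_and_canonicalize(s)
        except InvalidStructureError:
            skipped += 1
            continue
        ref_smiles.add(rec.canonical_smiles)
        ref_fps.append(_bitvect(rec.canonical_smiles, fp_scheme, radius, n_bits))
    if not ref_fps:
        raise ConfigError("no parsable reference molecules")
    n70 = n90 = nexact = 0
    for s in ligands:
        rec = parse_and_canonicalize(s)
        fp = _bitvect(rec.canonical_smiles, fp_scheme, radius, n_bits)
        best = max(DataStructs.BulkTanimotoSimilarity(fp, ref_fps))
        if rec.canonical_smiles in ref_smiles:
            nexact += 1
        if best > 0.70:
            n70 += 1
        if best > 0.90:
            n90 += 1
    n = len(ligands)
    return PurchasabilityReport(
        frac_above_070=n70 / n,
        frac_above_090=n90 / n,
        frac_exact=nexact / n,
        n_ligands=n,
        n_reference=len(ref_fps),
        n_reference_skipped=skipped,
        fp_scheme=fp_scheme,
        radius=radius,
        n_bits=n_bits,
    )


def _bitvect(smiles: str, scheme: str, radius: int, n_bits: int):
    arr = fingerprint(smiles, scheme, radius=radius, n_bits=n_bits).values
    bv = DataStructs.ExplicitBitVect(len(arr))
    bv.SetBitsFromList([int(i) for i in np.flatnonzero(arr)])
    return bv
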