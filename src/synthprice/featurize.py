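"""Molecular featurization: fingerprints and complexity descriptors.

Four fingerprint families are supported, all hashed to a fixed-length
binary vector:

* ``morgan`` — circular (ECFP-style) environments up to a radius;
* ``secfp`` — SMILES-extended circular environments (the MinHash-family
  construction, folded to a binary vector);
* ``atom_pair`` — atom pairs with their topological (shortest-path)
  distance;
* ``path`` — linear atom paths up to a maximum length.

Circular fingerprints capture functional-group substructures well but
miss global 3D-complexity cues (stereocentres, macrocycles, fused ring
systems).  The *hybrid* schemes therefore append a small panel of
real-valued complexity descriptors to the bit vector; descriptors are
z-scored on the training split so they do not dominate the 0/1 bits.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator, rdMHFPFingerprint, rdMolDescriptors

from .chem_io import MoleculeRecord
from .errors import ConfigError, InvalidStructureError

FP_SCHEMES = ("morgan", "secfp", "atom_pair", "path")
HYBRID_SCHEMES = ("morgan_hybrid", "secfp_hybrid")

#: Fixed, versioned order of the complexity-descriptor panel.
DESCRIPTOR_NAMES = (
    "n_stereocentres",
    "n_rings",
    "n_macrocycles",  # rings with more than 8 atoms
    "frac_sp3_carbons",
    "n_heavy_atoms",
    "n_rotatable_bonds",
    "n_spiro_atoms",
    "n_bridgehead_atoms",
)

DEFAULT_RADIUS = 3
DEFAULT_N_BITS = 2048


def _as_mol(mol: "MoleculeRecord | str") -> Chem.Mol:
    smi = mol.canonical_smiles if isinstance(mol, MoleculeRecord) else mol
    m = Chem.MolFromSmiles(smi)
    if m is None:
        raise InvalidStructureError(smi)
    return m


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    """A fixed-length numeric feature vector with its scheme provenance."""

    values: np.ndarray
    scheme: str

    @property
    def length(self) -> int:
        return int(self.values.shape[0])


def fingerprint(
    mol: "MoleculeRecord | str",
    scheme: str = "morgan",
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> FeatureVector:
    """Compute a binary fingerprint for one molecule.

    ``n_bits`` must be a power of two (hashing convention).  The output is
    deterministic for a given canonical SMILES and parameter set.
    """
    if scheme not in FP_SCHEMES:
        raise ConfigError(f"unknown fingerprint scheme: {scheme!r}")
    if n_bits <= 0 or (n_bits & (n_bits - 1)) != 0:
        raise ConfigError(f"n_bits must be a power of two, got {n_bits}")
    m = _as_mol(mol)
    if scheme == "morgan":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
        bv = gen.GetFingerprint(m)
    elif scheme == "secfp":
        enc = rdMHFPFingerprint.MHFPEncoder(0, 42)
        bv = enc.EncodeSECFPMol(
            m, radius=radius, rings=True, kekulize=True, min_radius=1, length=n_bits
        )
    elif scheme == "atom_pair":
        gen = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=n_bits)
        bv = gen.GetFingerprint(m)
    else:  # path
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(maxPath=7, fpSize=n_bits)
        bv = gen.GetFingerprint(m)
    arr = np.zeros(n_bits, dtype=np.float64)
    arr[list(bv.GetOnBits())] = 1.0
    return FeatureVector(values=arr, scheme=scheme)


def complexity_descriptors(mol: "MoleculeRecord | str") -> np.ndarray:
    """The fixed 8-descriptor complexity panel, in :data:`DESCRIPTOR_NAMES` order."""
    m = _as_mol(mol)
    ring_info = m.GetRingInfo()
    n_macro = sum(1 for ring in ring_info.AtomRings() if len(ring) > 8)
    return np.array(
        [
            rdMolDescriptors.CalcNumAtomStereoCenters(m),
            rdMolDescriptors.CalcNumRings(m),
            n_macro,
            rdMolDescriptors.CalcFractionCSP3(m),
            m.GetNumHeavyAtoms(),
            rdMolDescriptors.CalcNumRotatableBonds(m),
            rdMolDescriptors.CalcNumSpiroAtoms(m),
            rdMolDescriptors.CalcNumBridgeheadAtoms(m),
        ],
        dtype=np.float64,
    )


class DescriptorScaler:
    """Z-score scaler for the descriptor tail, fit on the training split.

    Constant descriptors get unit scale so they pass through centred at 0.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, desc_matrix: np.ndarray) -> "DescriptorScaler":
        self.mean_ = desc_matrix.mean(axis=0)
        sd = desc_matrix.std(axis=0)
        sd[sd == 0] = 1.0
        self.scale_ = sd
        return self

    def transform(self, desc: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise ConfigError("DescriptorScaler used before fit()")
        return (desc - self.mean_) / self.scale_


def hybrid_fingerprint(fp: FeatureVector, desc: np.ndarray) -> FeatureVector:
    """Append the (scaled) descriptor tail to a circular fingerprint.

    The concatenation is lossless: slicing ``values[:fp.length]`` recovers
    the fingerprint bits and ``values[fp.length:]`` the descriptors.
    """
    if fp.scheme not in ("morgan", "secfp"):
        raise ConfigError(
            f"hybrid fingerprints are defined for circular schemes, got {fp.scheme!r}"
        )
    return FeatureVector(
        values=np.concatenate([fp.values, np.asarray(desc, dtype=np.float64)]),
        scheme=f"{fp.scheme}_hybrid",
    )


def featurize_dataset(
    records: Sequence[MoleculeRecord] | Iterable[str],
    scheme: str = "morgan",
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
    scaler: DescriptorScaler | None = None,
) -> np.ndarray:
    """Feature matrix for a collection of molecules.

    For the ``*_hybrid`` schemes a fitted :class:`DescriptorScaler` must be
    supplied (fit it on the training split with :func:`fit_descriptor_scaler`).
    """
    records = list(records)
    hybrid = scheme in HYBRID_SCHEMES
    base_scheme = scheme.removesuffix("_hybrid")
    rows = []
    for rec in records:
        fp = fingerprint(rec, base_scheme, radius=radius, n_bits=n_bits)
        if hybrid:
            if scaler is None:
                raise ConfigError("hybrid scheme requires a fitted DescriptorScaler")
            desc = scaler.transform(complexity_descriptors(rec))
            fp = hybrid_fingerprint(fp, desc)
        rows.append(fp.values)
    return np.vstack(rows)


def fit_descriptor_scaler(
    records: Sequence[MoleculeRecord] | Iterable[str],
) -> DescriptorScaler:
    mat = np.vstack([complexity_descriptors(r) for r in records])
    return DescriptorScaler().fit(mat)
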