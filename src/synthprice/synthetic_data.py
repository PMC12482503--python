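"""Seeded synthetic ES/HS libraries for end-to-end testing without external data.

Real purchasable-compound catalogs are proprietary, so this module
emulates the two data sources every stage needs:

* an **ES library** of drug-like molecules assembled from a fragment
  grammar (alkyl chains, small rings, common linkers and functional
  groups), with a log-price that is a linear function of structural
  counts (heavy atoms, rings, heteroatoms, stereocentres) plus Gaussian
  noise, affinely mapped into a target price range (default [0, 12] on
  the natural-log USD/mmol scale);
* an **HS library** produced by applying three or more structure-
  complexifying edits to ES molecules — grafting spiro, bridged, fused,
  macrocyclic and stereocentre-rich fragments onto the molecular graph —
  in the spirit of published molecular-complexification procedures.  HS
  molecules carry no price labels.

The fragment grammar guarantees chemical validity by construction; HS
edits are performed on the molecular graph (combine + bond + sanitize)
with retries, so every output parses.  HS molecules are grown from the
smaller half of the ES library so that their sizes land inside the ES
size range and class separation cannot rest on atom count alone.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from rdkit import Chem

from .featurize import complexity_descriptors

DEFAULT_PRICE_COEFFS = {
    "heavy_atoms": 0.25,
    "rings": 0.8,
    "heteroatoms": 0.4,
    "stereocentres": 1.0,
}


@dataclasses.dataclass
class SyntheticSpec:
    """Study conditions for the synthetic libraries."""

    n_es: int = 2000
    n_hs: int = 2000
    price_coeffs: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PRICE_COEFFS)
    )
    noise_sd: float = 0.2
    price_range: tuple[float, float] = (0.0, 12.0)
    n_edits: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_es <= 0 or self.n_hs <= 0:
            raise ValueError("library sizes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_edits < 3:
            raise ValueError("HS construction applies at least 3 edits")


# ---- ES fragment grammar ----------------------------------------------------

_RINGS = (
    "c1ccccc1", "C1CCCCC1", "c1ccncc1", "C1CCOC1",
    "c1ccsc1", "C1CCNCC1", "c1ccoc1", "C1CCCC1",
)
_LINKERS = ("", "O", "N", "C(=O)", "C(=O)N", "S", "OC", "CC")
_TERMINALS = ("", "O", "N", "Cl", "F", "C(=O)O", "C#N", "OC", "C(F)(F)F", "Br", "C(=O)N", "S")
_STEREO = ("[C@@H](C)O", "[C@H](N)C")


def _assemble_es_smiles(rng: np.random.Generator) -> str:
    parts = ["C" * rng.integers(1, 9)]
    for _ in range(rng.integers(0, 4)):
        parts.append(_LINKERS[rng.integers(len(_LINKERS))])
        parts.append(_RINGS[rng.integers(len(_RINGS))])
    if rng.random() < 0.15:
        parts.append("C" * rng.integers(1, 4))
        parts.append(_STEREO[rng.integers(len(_STEREO))])
    else:
        if rng.random() < 0.5:
            parts.append("C" * rng.integers(1, 5))
        parts.append(_TERMINALS[rng.integers(len(_TERMINALS))])
    return "".join(parts)


def _structural_counts(mol: Chem.Mol) -> dict[str, float]:
    desc = complexity_descriptors(Chem.MolToSmiles(mol))
    n_hetero = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() not in (1, 6))
    return {
        "heavy_atoms": float(mol.GetNumHeavyAtoms()),
        "rings": float(desc[1]),
        "heteroatoms": float(n_hetero),
        "stereocentres": float(desc[0]),
    }


def generate_es_library(spec: SyntheticSpec) -> list[tuple[str, float]]:
    """Generate ``spec.n_es`` unique (canonical SMILES, log-price) pairs.

    The raw score ``sum_k coeff_k * count_k + noise`` is affinely mapped
    so the library's prices span ``spec.price_range`` exactly; with
    ``noise_sd == 0`` the price is a deterministic function of structure.
    """
    rng = np.random.default_rng(spec.seed)
    seen: set[str] = set()
    smiles: list[str] = []
    raw: list[float] = []
    attempts = 0
    while len(smiles) < spec.n_es:
        attempts += 1
        if attempts > 200 * spec.n_es:
            raise RuntimeError("fragment grammar exhausted before reaching n_es unique molecules")
        s = _assemble_es_smiles(rng)
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            continue
        can = Chem.MolToSmiles(mol)
        if can in seen:
            continue
        seen.add(can)
        counts = _structural_counts(mol)
        score = sum(spec.price_coeffs[k] * counts[k] for k in spec.price_coeffs)
        score += rng.normal(0.0, spec.noise_sd)
        smiles.append(can)
        raw.append(score)
    raw_arr = np.array(raw)
    lo, hi = spec.price_range
    span = raw_arr.max() - raw_arr.min()
    if span == 0:
        prices = np.full_like(raw_arr, (lo + hi) / 2.0)
    else:
        prices = lo + (raw_arr - raw_arr.min()) * (hi - lo) / span
    return list(zip(smiles, prices.tolist()))


# ---- HS complexification edits ----------------------------------------------

#: Complexity-raising graft fragments: spiro, bridged, fused and macrocyclic
#: ring systems, stereocentre-rich chains, and less common heterocycles.
_COMPLEX_FRAGMENTS = (
    "C1CC2(C1)CC2",            # spiro[2.3]
    "C1CC2(CCC2)CC1",          # spiro[3.4]-like
    "C1CC2CCC1C2",             # norbornane (bridged)
    "C1C2CC3CC1CC(C2)C3",      # adamantane (bridged cage)
    "C1CCC2CCCCC2C1",          # decalin (fused)
    "C1CCCCCCCCCCC1",          # 12-membered macrocycle
    "C[C@H](F)[C@@H](O)C",     # stereocentre pair
    "C[C@@H]1CC[C@H](C)CC1",   # stereo-defined ring
    "C1CSCCS1",                # dithiane (unusual heteroatoms)
    "C1COCCO1",                # dioxane
)


def _attach_fragment(
    mol: Chem.Mol, frag_smiles: str, rng: np.random.Generator
) -> Chem.Mol | None:
    """Graft a fragment onto the molecule by a single bond at random
    free-valence atoms; returns None if no valid attachment is found."""
    frag = Chem.MolFromSmiles(frag_smiles)
    combo = Chem.RWMol(Chem.CombineMols(mol, frag))
    n_base = mol.GetNumAtoms()
    base_sites = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetTotalNumHs() > 0 and a.GetAtomicNum() == 6
    ]
    frag_sites = [
        a.GetIdx() + n_base
        for a in frag.GetAtoms()
        if a.GetTotalNumHs() > 0 and a.GetAtomicNum() == 6
    ]
    if not base_sites or not frag_sites:
        return None
    i = base_sites[rng.integers(len(base_sites))]
    j = frag_sites[rng.integers(len(frag_sites))]
    combo.AddBond(int(i), int(j), Chem.BondType.SINGLE)
    out = combo.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def generate_hs_library(
    base: list[tuple[str, float]] | list[str],
    spec: SyntheticSpec,
) -> tuple[list[str], int]:
    """Complexify ES molecules into an unlabeled HS library.

    Each HS molecule starts from an ES molecule drawn from the smaller
    half of the base library (by heavy-atom count) and receives
    ``spec.n_edits`` fragment grafts.  Returns the list of canonical
    SMILES (all parsable, none present in the base library) and the
    number of construction attempts that were skipped after retries.
    """
    if not base:
        raise ValueError("base ES library must be non-empty")
    base_smiles = [b[0] if isinstance(b, tuple) else b for b in base]
    base_set = {Chem.MolToSmiles(Chem.MolFromSmiles(s)) for s in base_smiles}
    sizes = np.array([Chem.MolFromSmiles(s).GetNumHeavyAtoms() for s in base_smiles])
    median = np.median(sizes)
    pool = [s for s, n in zip(base_smiles, sizes) if n <= median] or base_smiles

    rng = np.random.default_rng(spec.seed + 1)
    out: list[str] = []
    out_set: set[str] = set()
    skipped = 0
    while len(out) < spec.n_hs:
        start = pool[rng.integers(len(pool))]
        mol = Chem.MolFromSmiles(start)
        ok = True
        for _ in range(spec.n_edits):
            edited = None
            for _retry in range(5):
                frag = _COMPLEX_FRAGMENTS[rng.integers(len(_COMPLEX_FRAGMENTS))]
                edited = _attach_fragment(mol, frag, rng)
                if edited is not None:
                    break
            if edited is None:
                ok = False
                break
            mol = edited
        if not ok:
            skipped += 1
            if skipped > 10 * spec.n_hs:
                raise RuntimeError("HS construction failing persistently")
            continue
        can = Chem.MolToSmiles(mol)
        if can in base_set or can in out_set:
            skipped += 1
            continue
        out.append(can)
        out_set.add(can)
    if skipped:
        warnings.warn(f"HS construction skipped {skipped} attempts", stacklevel=2)
    return out, skipped
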