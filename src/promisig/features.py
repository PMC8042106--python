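"""Circular atom-environment fingerprints with feature-to-atom bookkeeping.

Molecules are encoded as folded binary Morgan ("extended connectivity")
fingerprints.  Besides the bit vector itself, :func:`fingerprint` returns a
:class:`FeatureAtomIndex` recording, for every set bit, each atom environment
that hashed onto it (its center atom, radius and atom indices).  That
correspondence is what allows SVM feature weights to be redistributed onto
atoms later on; fingerprints computed without it (:func:`fingerprint_matrix`)
are cheaper and sufficient for model training.

The Tanimoto coefficient doubles as the SVM kernel, so it is defined here once
and reused everywhere (model training, cross-pair prediction, attribution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "FingerprintParams",
    "Fingerprint",
    "Occurrence",
    "FeatureAtomIndex",
    "fingerprint",
    "fingerprint_matrix",
    "tanimoto",
    "tanimoto_matrix",
]


class FingerprintInputError(ValueError):
    """Raised for unparseable SMILES or mismatched fingerprint shapes."""


@dataclass(frozen=True)
class FingerprintParams:
    """Radius / length of the folded circular fingerprint.

    Radius 2 with 2048 bits is the ECFP4-equivalent standard for binary
    atom-environment fingerprints.
    """

    radius: int = 2
    n_bits: int = 2048

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.n_bits < 1:
            raise ValueError("n_bits must be >= 1")


@dataclass(frozen=True)
class Occurrence:
    """One atom environment hashing onto a fingerprint bit."""

    center: int
    radius: int
    atoms: tuple[int, ...]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass
class Fingerprint:
    """A folded binary fingerprint as a dense 0/1 uint8 vector."""

    bits: np.ndarray
    params: FingerprintParams

    @property
    def n_bits(self) -> int:
        return int(self.bits.shape[0])

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    @property
    def on_bits(self) -> np.ndarray:
        return np.flatnonzero(self.bits)


@dataclass
class FeatureAtomIndex:
    """Maps every set bit of a fingerprint to its atom environments.

    ``occurrences[d]`` lists each environment that folded onto bit ``d``; hash
    collisions and symmetry-equivalent environments (e.g. the six identical
    carbon environments of benzene) are all kept as separate occurrences,
    because the atom-mapping formula divides each feature's weight by the
    occurrence count.
    """

    occurrences: dict[int, tuple[Occurrence, ...]] = field(default_factory=dict)

    def n_occ(self, d: int) -> int:
        return len(self.occurrences[d])

    def bits(self) -> frozenset[int]:
        return frozenset(self.occurrences)

    def __contains__(self, d: int) -> bool:
        return d in self.occurrences

    def __getitem__(self, d: int) -> tuple[Occurrence, ...]:
        return self.occurrences[d]


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FingerprintInputError(f"unparseable SMILES: {smiles!r}")
    return mol


def _generator(params: FingerprintParams):
    return rdFingerprintGenerator.GetMorganGenerator(
        radius=params.radius, fpSize=params.n_bits
    )


def _env_atoms(mol: Chem.Mol, center: int, radius: int) -> tuple[int, ...]:
    """Atom indices of the environment of `radius` bonds around `center`."""
    if radius == 0:
        return (center,)
    bond_ids = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, center)
    atoms = {center}
    for bid in bond_ids:
        bond = mol.GetBondWithIdx(bid)
        atoms.add(bond.GetBeginAtomIdx())
        atoms.add(bond.GetEndAtomIdx())
    return tuple(sorted(atoms))


def fingerprint(
    smiles: str, params: FingerprintParams = FingerprintParams()
) -> tuple[Fingerprint, FeatureAtomIndex]:
    """Fingerprint one molecule, keeping the bit-to-atom correspondence.

    Returns the folded bit vector together with a :class:`FeatureAtomIndex`
    covering exactly the set bits.
    """
    mol = _mol_from_smiles(smiles)
    gen = _generator(params)
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    bv = gen.GetFingerprint(mol, additionalOutput=ao)

    bits = np.zeros(params.n_bits, dtype=np.uint8)
    bits[list(bv.GetOnBits())] = 1

    occurrences: dict[int, tuple[Occurrence, ...]] = {}
    for bit, envs in ao.GetBitInfoMap().items():
        occurrences[int(bit)] = tuple(
            Occurrence(center=int(a), radius=int(r), atoms=_env_atoms(mol, int(a), int(r)))
            for a, r in envs
        )
    return Fingerprint(bits=bits, params=params), FeatureAtomIndex(occurrences)


def fingerprint_matrix(
    smiles_list: Sequence[str], params: FingerprintParams = FingerprintParams()
) -> np.ndarray:
    """Stack fingerprints of many molecules into an (n, n_bits) uint8 matrix."""
    gen = _generator(params)
    X = np.zeros((len(smiles_list), params.n_bits), dtype=np.uint8)
    for i, smi in enumerate(smiles_list):
        mol = _mol_from_smiles(smi)
        bv = gen.GetFingerprint(mol)
        X[i, list(bv.GetOnBits())] = 1
    return X


def _as_bits(x) -> np.ndarray:
    if isinstance(x, Fingerprint):
        return x.bits
    return np.asarray(x)


def tanimoto(x, y) -> float:
    """Tanimoto similarity |x AND y| / |x OR y| of two binary vectors.

    Both-empty vectors are assigned similarity 1 by convention (identical
    objects), which also keeps the kernel Gram matrix well defined.
    """
    xb = _as_bits(x)
    yb = _as_bits(y)
    if xb.shape != yb.shape:
        raise FingerprintInputError(
            f"fingerprint length mismatch: {xb.shape} vs {yb.shape}"
        )
    inter = int(np.minimum(xb, yb).sum())
    union = int(xb.sum()) + int(yb.sum()) - inter
    if union == 0:
        return 1.0
    return inter / union


def tanimoto_matrix(X, Y=None) -> np.ndarray:
    """Pairwise Tanimoto similarities between the rows of X and Y.

    The (i, j) entry is T(X[i], Y[j]).  With ``Y=None`` the symmetric Gram
    matrix of X is returned; this is the SVM kernel.
    """
    Xf = np.asarray(X, dtype=np.float64)
    Yf = Xf if Y is None else np.asarray(Y, dtype=np.float64)
    if Xf.shape[1] != Yf.shape[1]:
        raise FingerprintInputError(
            f"fingerprint length mismatch: {Xf.shape[1]} vs {Yf.shape[1]}"
        )
    inter = Xf @ Yf.T
    px = Xf.sum(axis=1)[:, None]
    py = Yf.sum(axis=1)[None, :]
    union = px + py - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    return sim
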