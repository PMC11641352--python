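"""Compound libraries, binary molecular fingerprints and Tanimoto similarity.

A library is a plain-text ``.smi`` file, one record per line::

    SMILES<whitespace>id[<whitespace>name ...]

Blank lines and lines starting with ``#`` are ignored.  Two fingerprint
schemes are supported: the 166-key MACCS substructure keys (``maccs``,
default) and a 2048-bit hashed circular fingerprint (``hashed``, Morgan
radius 2).  Similarity between fingerprints is the Tanimoto coefficient
|A∩B| / |A∪B| on the set bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .errors import FingerprintError, LibraryParseError

RDLogger.DisableLog("rdApp.*")

SCHEMES = ("maccs", "hashed")
SCHEME_LENGTHS = {"maccs": 166, "hashed": 2048}

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


@dataclass(frozen=True)
class Molecule:
    """A single compound record: unique id, display name, SMILES string."""

    id: str
    name: str
    smiles: str

    @property
    def canonical_smiles(self) -> str:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise FingerprintError(f"unparseable SMILES for {self.id!r}: {self.smiles!r}")
        return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary key vector for one molecule.

    ``bits`` is a boolean vector of length 166 (maccs) or 2048 (hashed).
    All-zero fingerprints are rejected at construction: they carry no
    substructure information and would make the Tanimoto coefficient 0/0.
    """

    bits: np.ndarray = field(repr=False)
    scheme: str = "maccs"

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=bool)
        object.__setattr__(self, "bits", bits)
        if self.scheme not in SCHEMES:
            raise FingerprintError(f"unknown scheme {self.scheme!r}")
        expected = SCHEME_LENGTHS[self.scheme]
        if bits.ndim != 1 or bits.size != expected:
            raise FingerprintError(
                f"scheme {self.scheme!r} requires {expected} bits, got shape {bits.shape}"
            )
        if not bits.any():
            raise FingerprintError("all-zero fingerprint (degenerate molecule)")

    def __len__(self) -> int:
        return int(self.bits.size)

    @property
    def on_bits(self) -> frozenset[int]:
        return frozenset(np.flatnonzero(self.bits).tolist())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Fingerprint)
            and self.scheme == other.scheme
            and bool(np.array_equal(self.bits, other.bits))
        )

    def __hash__(self) -> int:
        return hash((self.scheme, self.bits.tobytes()))


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square, symmetric, unit-diagonal matrix of Tanimoto coefficients."""

    ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        n = len(self.ids)
        if vals.shape != (n, n):
            raise FingerprintError(f"similarity matrix shape {vals.shape} != ({n}, {n})")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")


def parse_library(path: str | Path) -> list[Molecule]:
    """Parse a ``.smi`` compound library into :class:`Molecule` records.

    Records are returned in file order.  Every malformed line (unparseable
    SMILES, missing id) and every duplicate id is reported with its line
    number in a single :class:`LibraryParseError`.
    """
    path = Path(path)
    molecules: list[Molecule] = []
    problems: list[str] = []
    seen: set[str] = set()
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                problems.append(f"line {lineno}: expected 'SMILES id [name]', got {line!r}")
                continue
            smiles, mol_id = fields[0], fields[1]
            name = " ".join(fields[2:]) if len(fields) > 2 else mol_id
            if Chem.MolFromSmiles(smiles) is None:
                problems.append(f"line {lineno}: unparseable SMILES {smiles!r}")
                continue
            if mol_id in seen:
                problems.append(f"line {lineno}: duplicate id {mol_id!r}")
                continue
            seen.add(mol_id)
            molecules.append(Molecule(id=mol_id, name=name, smiles=smiles))
    if problems:
        raise LibraryParseError(problems)
    return molecules


def compute_fingerprint(mol: Molecule | str, scheme: str = "maccs") -> Fingerprint:
    """Compute the binary fingerprint of a molecule under the given scheme.

    The SMILES is parsed into a molecular graph first, so different entry
    forms of the same structure (e.g. ``OCC`` vs ``CCO``) give identical
    fingerprints.
    """
    if scheme not in SCHEMES:
        raise FingerprintError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    smiles = mol.smiles if isinstance(mol, Molecule) else mol
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise FingerprintError(f"unparseable SMILES {smiles!r}")
    if scheme == "maccs":
        # RDKit's MACCS vector has a dummy bit 0; keys 1..166 are the real keys.
        bv = MACCSkeys.GenMACCSKeys(rdmol)
        bits = np.zeros(166, dtype=bool)
        for b in bv.GetOnBits():
            if b >= 1:
                bits[b - 1] = True
    else:
        bv = _MORGAN.GetFingerprint(rdmol)
        bits = np.zeros(2048, dtype=bool)
        bits[list(bv.GetOnBits())] = True
    if not bits.any():
        raise FingerprintError(f"all-zero {scheme} fingerprint for {smiles!r}")
    return Fingerprint(bits=bits, scheme=scheme)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a∧b| / (|a| + |b| − |a∧b|) of two fingerprints."""
    if a.scheme != b.scheme or len(a) != len(b):
        raise FingerprintError(
            f"incompatible fingerprints: {a.scheme}/{len(a)} vs {b.scheme}/{len(b)}"
        )
    inter = int(np.count_nonzero(a.bits & b.bits))
    union = int(np.count_nonzero(a.bits)) + int(np.count_nonzero(b.bits)) - inter
    return inter / union


def similarity_matrix(fps: list[Fingerprint], ids: list[str] | None = None) -> SimilarityMatrix:
    """All-pairs Tanimoto similarity matrix for a list of fingerprints."""
    if not fps:
        raise FingerprintError("cannot build a similarity matrix from an empty library")
    schemes = {fp.scheme for fp in fps}
    if len(schemes) > 1:
        raise FingerprintError(f"mixed fingerprint schemes: {sorted(schemes)}")
    if ids is None:
        ids = [f"M{i}" for i in range(len(fps))]
    if len(ids) != len(fps):
        raise FingerprintError("ids and fingerprints differ in length")
    bits = np.stack([fp.bits for fp in fps]).astype(np.int64)
    inter = bits @ bits.T
    counts = bits.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    values = inter / union
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(ids=tuple(ids), values=values)


def jaccard_distance_matrix(fps: list[Fingerprint]) -> np.ndarray:
    """Pairwise Jaccard distances 1 − Tanimoto, as a dense square matrix."""
    return 1.0 - similarity_matrix(fps).values
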