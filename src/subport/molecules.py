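"""Molecule canonicalization, fingerprints, similarities and embeddings.

Substrates are represented either as extended-connectivity fingerprints
(ECFP, radius 3, 1024 bits by default — circular-neighborhood hashes of the
molecular graph), as learned embeddings from a pluggable backend (a SMILES
language model in full deployments; a deterministic mock here), or as
one-hot indicator vectors over the training substrate vocabulary (an
identity-only baseline).  Fingerprint similarity is the Tanimoto
coefficient, used both as a feature-space diagnostic and to steer negative
sampling toward structurally plausible decoys.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from typing import Mapping, Protocol, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

from .records import MoleculeRecord

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MoleculeParseError",
    "UnseenSubstrateError",
    "canonicalize_molecule",
    "compute_ecfp",
    "fingerprint_similarity",
    "similarity_matrix",
    "MoleculeSimilarityMatrix",
    "MoleculeEmbedder",
    "MockMoleculeEmbedder",
    "embed_molecule",
    "one_hot_encode",
]


class MoleculeParseError(ValueError):
    """Raised when a structure string cannot be parsed."""


class UnseenSubstrateError(KeyError):
    """Raised by the one-hot encoder for substrates outside the vocabulary.

    The one-hot baseline can only be applied to substrates that were present
    in the training set; there is no index for anything else.
    """


def _mol_from_record(record: MoleculeRecord) -> Chem.Mol:
    if record.smiles is not None:
        mol = Chem.MolFromSmiles(record.smiles)
        if mol is None:
            raise MoleculeParseError(
                f"{record.chebi_id}: unparseable SMILES {record.smiles!r}"
            )
        return mol
    if record.inchi is not None:
        mol = Chem.MolFromInchi(record.inchi, treatWarningAsError=False)
        if mol is None:
            raise MoleculeParseError(
                f"{record.chebi_id}: unparseable InChI {record.inchi!r}"
            )
        return mol
    raise MoleculeParseError(f"{record.chebi_id}: no structure string (InChI/SMILES)")


def canonicalize_molecule(record: MoleculeRecord) -> MoleculeRecord:
    """Return a copy of ``record`` with a canonical SMILES attached.

    Two records describing the same structure — regardless of atom ordering
    or of whether they arrived as SMILES or InChI — receive identical
    canonical SMILES strings.
    """
    mol = _mol_from_record(record)
    return replace(record, canonical_smiles=Chem.MolToSmiles(mol, canonical=True))


def compute_ecfp(
    record: MoleculeRecord, radius: int = 3, n_bits: int = 1024
) -> np.ndarray:
    """Extended-connectivity fingerprint of a canonicalized molecule.

    Returns a uint8 0/1 vector of length ``n_bits``.  Defaults (radius 3,
    1024 bits) match the configuration under which the pipeline was tuned;
    the fingerprint is invariant to input atom ordering because it is
    computed from the canonical structure.
    """
    if record.canonical_smiles is None:
        raise ValueError(
            f"{record.chebi_id}: record must be canonicalized before fingerprinting"
        )
    mol = Chem.MolFromSmiles(record.canonical_smiles)
    if mol is None:  # canonical SMILES should always round-trip
        raise MoleculeParseError(
            f"{record.chebi_id}: canonical SMILES failed to parse"
        )
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def fingerprint_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| of two bit vectors.

    The degenerate all-zero/all-zero case (vanishing denominator) is defined
    as 1.0: two structure-identical empty fingerprints count as identical.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 1.0
    return int(np.count_nonzero(a & b)) / union


@dataclass(frozen=True)
class MoleculeSimilarityMatrix:
    """Symmetric pairwise Tanimoto similarities over an ordered molecule set."""

    molecule_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.molecule_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match molecule_ids")

    def similarity(self, id_a: str, id_b: str) -> float:
        i = self.molecule_ids.index(id_a)
        j = self.molecule_ids.index(id_b)
        return float(self.values[i, j])

    def index(self, chebi_id: str) -> int:
        return self.molecule_ids.index(chebi_id)


def similarity_matrix(
    fingerprints: Mapping[str, np.ndarray],
    order: Sequence[str] | None = None,
    canonical_smiles: Mapping[str, str] | None = None,
) -> MoleculeSimilarityMatrix:
    """All-pairs Tanimoto matrix from a fingerprint table.

    When ``canonical_smiles`` is supplied, the degenerate pair of two
    all-zero fingerprints resolves to 1 only for structure-identical
    records and 0 otherwise (the raw Tanimoto denominator vanishes there,
    so bit counting alone cannot distinguish the two cases).
    """
    ids = tuple(order) if order is not None else tuple(fingerprints)
    n = len(ids)
    values = np.ones((n, n), dtype=float)
    empty = {i for i in ids if not np.any(fingerprints[i])}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = ids[i], ids[j]
            if a in empty and b in empty and canonical_smiles is not None:
                s = 1.0 if canonical_smiles[a] == canonical_smiles[b] else 0.0
            else:
                s = fingerprint_similarity(fingerprints[a], fingerprints[b])
            values[i, j] = values[j, i] = s
    return MoleculeSimilarityMatrix(molecule_ids=ids, values=values)


class MoleculeEmbedder(Protocol):
    """A molecule-embedding backend: declares a dimension, embeds SMILES."""

    dimension: int

    def embed(self, canonical_smiles: str) -> np.ndarray: ...


def _stable_bucket(token: str, n_buckets: int, salt: int) -> int:
    digest = hashlib.blake2b(
        token.encode(), digest_size=8, salt=salt.to_bytes(8, "little")
    ).digest()
    return int.from_bytes(digest, "little") % n_buckets


@dataclass(frozen=True)
class MockMoleculeEmbedder:
    """Deterministic structure-sensitive stand-in molecule embedder.

    Hashes character n-grams of the canonical SMILES into a bucketed count
    vector, applies a seeded Gaussian random projection to ``dimension``
    components and L2-normalizes.  Runs offline, is bitwise reproducible for
    a fixed seed, and molecules sharing substructure share n-grams, so
    related structures land near each other in embedding space.
    """

    dimension: int = 64
    n_buckets: int = 512
    ngram: int = 3
    seed: int = 2024

    def embed(self, canonical_smiles: str) -> np.ndarray:
        counts = np.zeros(self.n_buckets, dtype=float)
        s = f"^{canonical_smiles}$"
        for i in range(max(1, len(s) - self.ngram + 1)):
            token = s[i : i + self.ngram]
            counts[_stable_bucket(token, self.n_buckets, self.seed)] += 1.0
        rng = np.random.default_rng(self.seed)
        projection = rng.standard_normal((self.n_buckets, self.dimension))
        vec = counts @ projection
        norm = np.linalg.norm(vec)
        return (vec / norm if norm > 0 else vec).astype(np.float64)


def embed_molecule(record: MoleculeRecord, backend: MoleculeEmbedder) -> np.ndarray:
    """Embed a canonicalized molecule with the given backend."""
    if record.canonical_smiles is None:
        raise ValueError(
            f"{record.chebi_id}: record must be canonicalized before embedding"
        )
    if backend is None:
        raise ValueError(
            "no molecule-embedding backend supplied; pass MockMoleculeEmbedder() "
            "for an offline deterministic backend"
        )
    vec = np.asarray(backend.embed(record.canonical_smiles), dtype=np.float64)
    if vec.shape != (backend.dimension,):
        raise ValueError(
            f"backend returned shape {vec.shape}, declared dimension {backend.dimension}"
        )
    return vec


def one_hot_encode(chebi_id: str, vocabulary: Sequence[str]) -> np.ndarray:
    """Indicator vector of ``chebi_id`` over an ordered substrate vocabulary."""
    if len(vocabulary) == 0:
        raise ValueError("vocabulary must be nonempty")
    if len(set(vocabulary)) != len(vocabulary):
        raise ValueError("vocabulary contains duplicates")
    try:
        idx = list(vocabulary).index(chebi_id)
    except ValueError:
        raise UnseenSubstrateError(
            f"{chebi_id!r} is not in the vocabulary: one-hot encoding can only "
            "be applied to substrates that were present in the training set"
        ) from None
    vec = np.zeros(len(vocabulary), dtype=np.uint8)
    vec[idx] = 1
    return vec
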