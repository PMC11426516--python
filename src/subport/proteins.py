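"""Protein sequence identity, identity clustering and embeddings.

Percent identity between two transporters is computed from an optimal global
(Needleman-Wunsch) alignment — BLOSUM62 scoring, gap open 10, gap extend 0.5
— as 100 x identical columns / alignment length, gaps included.  Greedy
longest-first clustering at a configurable identity threshold (60% by
default) provides the leakage-control unit for cross-validation folds.
Protein embeddings come from a pluggable backend: in full deployments a
protein language model producing 1280-dimensional mean-pooled residue
representations; bundled here, a deterministic k-mer projection mock that
preserves sequence locality without any model download.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Protocol, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .records import VALID_RESIDUES, TransporterRecord

__all__ = [
    "AlignmentScoring",
    "pairwise_identity",
    "IdentityProvider",
    "PairwiseIdentityCache",
    "ClusterAssignment",
    "cluster_sequences",
    "ProteinEmbedder",
    "MockProteinEmbedder",
    "embed_protein",
    "max_identity_to_reference",
]


@dataclass(frozen=True)
class AlignmentScoring:
    """Global-alignment parameters (EMBOSS-needle-style conventions)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def _validate_sequence(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    for pos, res in enumerate(seq):
        if res not in VALID_RESIDUES:
            raise ValueError(f"{name}: invalid residue {res!r} at position {pos}")


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> float:
    """Percent identity of the optimal global alignment of two sequences.

    Identity is 100 x (identical aligned columns) / (alignment length with
    gap columns counted).  Symmetric; identical sequences score 100.
    """
    _validate_sequence(seq_a, "seq_a")
    _validate_sequence(seq_b, "seq_b")
    if seq_a == seq_b:
        return 100.0
    aligner = _make_aligner(scoring)
    alignment = aligner.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    return 100.0 * counts.identities / alignment.length


class IdentityProvider(Protocol):
    """Anything that answers percent-identity queries for accession pairs."""

    def identity(self, id_a: str, id_b: str) -> float: ...

    def known_ids(self) -> Sequence[str]: ...


class PairwiseIdentityCache:
    """Identity provider backed by sequences, computing alignments lazily.

    Results are memoized per unordered accession pair so the all-pairs cost
    is paid at most once however many pipeline stages query it.
    """

    def __init__(
        self,
        records: Sequence[TransporterRecord],
        scoring: AlignmentScoring = AlignmentScoring(),
    ) -> None:
        self._sequences = {r.uniprot_id: r.sequence for r in records}
        if len(self._sequences) != len(records):
            raise ValueError("duplicate accessions in identity provider input")
        self._scoring = scoring
        self._cache: dict[tuple[str, str], float] = {}

    def known_ids(self) -> list[str]:
        return list(self._sequences)

    def identity(self, id_a: str, id_b: str) -> float:
        for i in (id_a, id_b):
            if i not in self._sequences:
                raise KeyError(f"unknown transporter {i!r} in identity query")
        key = (id_a, id_b) if id_a <= id_b else (id_b, id_a)
        if key not in self._cache:
            self._cache[key] = pairwise_identity(
                self._sequences[key[0]], self._sequences[key[1]], self._scoring
            )
        return self._cache[key]


@dataclass(frozen=True)
class ClusterAssignment:
    transporter_id: str
    cluster_id: int
    is_representative: bool


def cluster_sequences(
    records: Sequence[TransporterRecord],
    threshold: float = 60.0,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> list[ClusterAssignment]:
    """Greedy incremental identity clustering (longest sequence first).

    Sequences are visited longest-first (ties broken by accession for
    determinism); each joins the first existing cluster whose representative
    it matches at >= ``threshold`` percent identity, otherwise it founds a
    new cluster and becomes its representative.  Representatives are
    therefore pairwise below the threshold; every member is within the
    threshold of its representative.  Non-representative cross-cluster pairs
    are not bounded by construction — use an exhaustive verification pass at
    fixture scale when that guarantee matters.
    """
    if not records:
        raise ValueError("records must be nonempty")
    if not (0 < threshold <= 100):
        raise ValueError("threshold must be in (0, 100]")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.uniprot_id))
    representatives: list[TransporterRecord] = []
    assignments: list[ClusterAssignment] = []
    for rec in ordered:
        joined = False
        for cluster_id, rep in enumerate(representatives):
            if pairwise_identity(rec.sequence, rep.sequence, scoring) >= threshold:
                assignments.append(
                    ClusterAssignment(rec.uniprot_id, cluster_id, is_representative=False)
                )
                joined = True
                break
        if not joined:
            assignments.append(
                ClusterAssignment(rec.uniprot_id, len(representatives), True)
            )
            representatives.append(rec)
    return assignments


class ProteinEmbedder(Protocol):
    dimension: int

    def embed(self, sequence: str) -> np.ndarray: ...


@dataclass(frozen=True)
class MockProteinEmbedder:
    """Deterministic locality-preserving stand-in protein embedder.

    Counts overlapping k-mers (k=3), applies a seeded Gaussian random
    projection of the count vector to ``dimension`` components and
    L2-normalizes.  Sequences that share most of their k-mers (close
    variants) map to nearby vectors; unrelated random sequences share few
    k-mers and map far apart — the locality property the pipeline's
    recovery tests rely on.
    """

    dimension: int = 64
    k: int = 3
    n_buckets: int = 2048
    seed: int = 2024

    def embed(self, sequence: str) -> np.ndarray:
        from .molecules import _stable_bucket  # same stable hashing helper

        counts = np.zeros(self.n_buckets, dtype=float)
        if len(sequence) < self.k:
            counts[_stable_bucket(sequence, self.n_buckets, self.seed)] += 1.0
        else:
            for i in range(len(sequence) - self.k + 1):
                kmer = sequence[i : i + self.k]
                counts[_stable_bucket(kmer, self.n_buckets, self.seed)] += 1.0
        rng = np.random.default_rng(self.seed)
        projection = rng.standard_normal((self.n_buckets, self.dimension))
        vec = counts @ projection
        norm = np.linalg.norm(vec)
        return (vec / norm if norm > 0 else vec).astype(np.float64)


def embed_protein(record: TransporterRecord, backend: ProteinEmbedder) -> np.ndarray:
    """One fixed-length vector for a transporter via the embedding backend."""
    if backend is None:
        raise ValueError(
            "no protein-embedding backend supplied; pass MockProteinEmbedder() "
            "for an offline deterministic backend"
        )
    _validate_sequence(record.sequence, record.uniprot_id)
    vec = np.asarray(backend.embed(record.sequence), dtype=np.float64)
    if vec.shape != (backend.dimension,):
        raise ValueError(
            f"backend returned shape {vec.shape}, declared dimension {backend.dimension}"
        )
    if not np.all(np.isfinite(vec)):
        raise ValueError(f"{record.uniprot_id}: non-finite embedding entries")
    return vec


def max_identity_to_reference(
    query: TransporterRecord,
    reference_set: Sequence[TransporterRecord],
    scoring: AlignmentScoring = AlignmentScoring(),
) -> tuple[float, str]:
    """Maximum percent identity of ``query`` to any reference sequence.

    Returns ``(max_identity, argmax_accession)``; ties resolve to the first
    reference in input order.
    """
    if not reference_set:
        raise ValueError("reference_set must be nonempty")
    best_identity = -1.0
    best_id = ""
    for ref in reference_set:
        ident = pairwise_identity(query.sequence, ref.sequence, scoring)
        if ident > best_identity:
            best_identity = ident
            best_id = ref.uniprot_id
    return best_identity, best_id
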