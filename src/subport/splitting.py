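"""Sequence-aware train/test splitting and identity-constrained CV folds.

The split unit is the distinct amino-acid sequence: all transporters
sharing a sequence are co-assigned, so no test protein ever occurs verbatim
in training.  Cross-validation folds additionally treat identity clusters
as atomic, so no two proteins from different folds exceed the clustering
threshold (60% identity with the default greedy clustering) — the leakage
control under which hyperparameters are selected.  Test pairs are annotated
with their maximum identity to any training sequence and their substrate's
occurrence count among positive training pairs, the two axes of the
stratified evaluation.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .proteins import AlignmentScoring, ClusterAssignment, max_identity_to_reference
from .records import InteractionPair, Label, TransporterRecord

__all__ = [
    "SplitAssignment",
    "train_test_split",
    "make_cv_folds",
    "annotate_identity_and_occurrence",
    "IDENTITY_BIN_EDGES",
    "OCCURRENCE_BIN_EDGES",
]

#: Identity-bin edges (percent) used for stratified reporting:
#: [0,40), [40,50), [50,60), [60,70), [70,80), [80,90), [90,100].
IDENTITY_BIN_EDGES = (0.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 100.0)

#: Substrate-occurrence bins: 0, 1-10, 11-100, >100 occurrences in training.
OCCURRENCE_BIN_EDGES = (-0.5, 0.5, 10.5, 100.5, float("inf"))


@dataclass(frozen=True)
class SplitAssignment:
    transporter_id: str
    partition: str  # "train" | "test"
    fold_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.partition not in ("train", "test"):
            raise ValueError(f"invalid partition {self.partition!r}")
        if self.partition == "test" and self.fold_id is not None:
            raise ValueError("test assignments carry no fold_id")


def train_test_split(
    transporters: Sequence[TransporterRecord],
    fraction_test: float = 0.2,
    rng: np.random.Generator | int | None = None,
) -> list[SplitAssignment]:
    """Assign transporters to train/test at sequence-group granularity.

    Transporters with identical sequences are always co-assigned.  Groups
    are shuffled with the supplied generator and accumulated into the test
    partition until the achieved test fraction (by transporter count) is as
    close as possible to the target; with distinct sequences of equal group
    size this reduces to exact division.
    """
    if not (0 < fraction_test < 1):
        raise ValueError("fraction_test must be in (0, 1)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    groups: dict[str, list[str]] = defaultdict(list)
    for rec in transporters:
        groups[rec.sequence].append(rec.uniprot_id)
    if len(groups) < 2:
        raise ValueError("need at least 2 distinct sequences to split")
    keys = sorted(groups, key=lambda s: (groups[s][0]))  # deterministic base order
    order = rng.permutation(len(keys))
    total = sum(len(v) for v in groups.values())
    target = fraction_test * total
    test_sequences: set[str] = set()
    n_test = 0
    for idx in order:
        size = len(groups[keys[idx]])
        # take the group only if it moves the achieved count closer to target
        if abs((n_test + size) - target) <= abs(n_test - target):
            test_sequences.add(keys[idx])
            n_test += size
        if n_test >= target:
            break
    assignments = []
    for seq, ids in groups.items():
        partition = "test" if seq in test_sequences else "train"
        for tid in ids:
            assignments.append(SplitAssignment(tid, partition))
    assignments.sort(key=lambda a: a.transporter_id)
    return assignments


def make_cv_folds(
    train_assignments: Sequence[SplitAssignment],
    clusters: Sequence[ClusterAssignment],
    n_folds: int = 5,
    rng: np.random.Generator | int | None = None,
) -> list[SplitAssignment]:
    """Distribute identity clusters over CV folds, keeping clusters atomic.

    Clusters are assigned largest-first to the currently smallest fold
    (balancing by transporter count); ties between equally small folds break
    toward the lowest fold index after a seeded shuffle of equal-size
    clusters, so the layout is reproducible.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    train_ids = {a.transporter_id for a in train_assignments if a.partition == "train"}
    cluster_members: dict[int, list[str]] = defaultdict(list)
    clustered_ids = set()
    for c in clusters:
        clustered_ids.add(c.transporter_id)
        if c.transporter_id in train_ids:
            cluster_members[c.cluster_id].append(c.transporter_id)
    unclustered = train_ids - clustered_ids
    if unclustered:
        raise ValueError(f"train transporters missing a cluster: {sorted(unclustered)}")
    if n_folds > len(cluster_members):
        raise ValueError(
            f"cannot make {n_folds} folds from {len(cluster_members)} clusters"
        )
    cluster_ids = list(cluster_members)
    cluster_ids = [cluster_ids[i] for i in rng.permutation(len(cluster_ids))]
    cluster_ids.sort(key=lambda cid: -len(cluster_members[cid]))  # stable: keeps shuffle within size ties
    fold_sizes = [0] * n_folds
    fold_of_cluster: dict[int, int] = {}
    for cid in cluster_ids:
        fold = int(np.argmin(fold_sizes))
        fold_of_cluster[cid] = fold
        fold_sizes[fold] += len(cluster_members[cid])
    out = []
    for cid, members in cluster_members.items():
        for tid in members:
            out.append(SplitAssignment(tid, "train", fold_id=fold_of_cluster[cid]))
    out.sort(key=lambda a: a.transporter_id)
    return out


def annotate_identity_and_occurrence(
    test_pairs: Sequence[InteractionPair],
    train_pairs: Sequence[InteractionPair],
    transporters: dict[str, TransporterRecord],
    scoring: AlignmentScoring = AlignmentScoring(),
) -> pd.DataFrame:
    """Annotate test pairs for stratified evaluation.

    Returns one row per test pair with ``max_identity_to_train`` (percent
    identity of the test transporter to its closest training sequence) and
    ``substrate_occurrence_in_train`` (count of the molecule among positive
    training pairs).  Splits must be disjoint; a test sequence identical to
    a training sequence is a split violation upstream and will surface here
    as identity 100.
    """
    if not train_pairs:
        raise ValueError("train set must be nonempty")
    train_ids = sorted({p.transporter_id for p in train_pairs})
    test_ids = {p.transporter_id for p in test_pairs}
    overlap = test_ids & set(train_ids)
    if overlap:
        raise ValueError(f"transporters present in both splits: {sorted(overlap)}")
    train_records = [transporters[t] for t in train_ids]
    occurrence = defaultdict(int)
    for p in train_pairs:
        if p.label is Label.POSITIVE:
            occurrence[p.chebi_id] += 1
    identity_cache: dict[str, tuple[float, str]] = {}
    rows = []
    for pair in test_pairs:
        tid = pair.transporter_id
        if tid not in identity_cache:
            identity_cache[tid] = max_identity_to_reference(
                transporters[tid], train_records, scoring
            )
        max_ident, argmax_id = identity_cache[tid]
        rows.append(
            {
                "transporter_id": tid,
                "chebi_id": pair.chebi_id,
                "label": pair.label.value,
                "max_identity_to_train": max_ident,
                "closest_train_id": argmax_id,
                "substrate_occurrence_in_train": occurrence[pair.chebi_id],
            }
        )
    return pd.DataFrame(rows)
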