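"""Constrained random sampling of negative transporter-molecule pairs.

Experimental databases record substrates, not non-substrates, so negatives
must be sampled.  For each positive pair the sampler draws a quota of 1-4
decoy molecules for the same transporter from the observed substrate
vocabulary, preferring decoys structurally similar to the true substrate
(Tanimoto in [0.75, 0.95], with the lower bound relaxed in steps of 0.2
when no candidates exist).  To limit false negatives, any molecule that is
a true substrate of the transporter itself — or of any transporter with
sequence identity above 60% to it — is excluded; and each molecule's
negative occurrences are capped at three times its positive occurrences so
the negative set mirrors the substrate frequency distribution.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .molecules import MoleculeSimilarityMatrix
from .proteins import IdentityProvider
from .records import InteractionPair, Label, Provenance

logger = logging.getLogger(__name__)

__all__ = [
    "SamplingConfig",
    "ExclusionIndex",
    "build_exclusion_index",
    "sample_negatives_for_positive",
    "sample_dataset_negatives",
]


@dataclass(frozen=True)
class SamplingConfig:
    """Knobs of the negative-sampling procedure.

    ``quota_weights``, when given, re-weights the quota draw over
    {negatives_min..negatives_max}; the default is uniform (mean 2.5 per
    positive with the 1-4 default range).
    """

    sim_upper: float = 0.95
    sim_lower_start: float = 0.75
    sim_lower_step: float = 0.2
    identity_exclusion_threshold: float = 60.0
    negatives_min: int = 1
    negatives_max: int = 4
    frequency_cap_multiplier: float = 3.0
    seed: int = 0
    quota_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.sim_lower_start <= self.sim_upper <= 1):
            raise ValueError("require 0 <= sim_lower_start <= sim_upper <= 1")
        if self.negatives_min > self.negatives_max:
            raise ValueError("negatives_min must be <= negatives_max")
        if self.frequency_cap_multiplier <= 0:
            raise ValueError("frequency_cap_multiplier must be > 0")
        n_quotas = self.negatives_max - self.negatives_min + 1
        if self.quota_weights is not None and len(self.quota_weights) != n_quotas:
            raise ValueError(
                f"quota_weights must have {n_quotas} entries "
                f"(one per quota in [{self.negatives_min}, {self.negatives_max}])"
            )


@dataclass
class ExclusionIndex:
    """Per-transporter sets of molecules forbidden as negatives."""

    forbidden: dict[str, set[str]] = field(default_factory=dict)

    def excluded_for(self, transporter_id: str) -> set[str]:
        return self.forbidden.get(transporter_id, set())


def build_exclusion_index(
    positives: Sequence[InteractionPair],
    identities: IdentityProvider,
    threshold: float = 60.0,
) -> ExclusionIndex:
    """Forbid, for each transporter, the substrates of all close homologs.

    A molecule is excluded as a negative for transporter ``t`` when it is a
    positive substrate of ``t`` itself or of any transporter with percent
    identity strictly greater than ``threshold`` to ``t``.
    """
    if any(p.label is not Label.POSITIVE for p in positives):
        raise ValueError("build_exclusion_index expects positive pairs only")
    substrates: dict[str, set[str]] = defaultdict(set)
    for p in positives:
        substrates[p.transporter_id].add(p.chebi_id)
    transporter_ids = sorted(substrates)
    known = set(identities.known_ids())
    missing = [t for t in transporter_ids if t not in known]
    if missing:
        raise KeyError(f"transporters unknown to the identity provider: {missing}")
    forbidden = {t: set(substrates[t]) for t in transporter_ids}
    for i, t_a in enumerate(transporter_ids):
        for t_b in transporter_ids[i + 1 :]:
            if identities.identity(t_a, t_b) > threshold:
                forbidden[t_a] |= substrates[t_b]
                forbidden[t_b] |= substrates[t_a]
    return ExclusionIndex(forbidden=forbidden)


def sample_negatives_for_positive(
    pair: InteractionPair,
    candidate_vocabulary: Sequence[str],
    similarity: MoleculeSimilarityMatrix,
    exclusion: ExclusionIndex,
    quota: int,
    usage_counts: Counter,
    positive_counts: Mapping[str, int],
    config: SamplingConfig,
    rng: np.random.Generator,
    already_sampled: set[tuple[str, str]] | None = None,
) -> list[InteractionPair]:
    """Sample up to ``quota`` negatives for one positive pair.

    Candidates must (i) belong to the observed substrate vocabulary, (ii) not
    be excluded for the transporter, (iii) have Tanimoto similarity to the
    pair's true substrate within [lower, sim_upper] where lower starts at
    sim_lower_start and is relaxed downward in sim_lower_step decrements
    (floored at 0) until candidates exist, and (iv) remain under the
    frequency cap of ``frequency_cap_multiplier`` times their positive
    occurrence count.  Sampling is without replacement within the call; a
    shortfall is logged, never raised.
    """
    excluded = exclusion.excluded_for(pair.transporter_id)
    taken = already_sampled if already_sampled is not None else set()
    sim_row = similarity.values[similarity.index(pair.chebi_id)]

    def eligible(mol: str) -> bool:
        if mol in excluded:
            return False
        if (pair.transporter_id, mol) in taken:
            return False
        cap = config.frequency_cap_multiplier * positive_counts.get(mol, 0)
        return usage_counts[mol] < cap

    base = [m for m in candidate_vocabulary if eligible(m)]
    lower = config.sim_lower_start
    chosen: list[str] = []
    while True:
        window = [
            m
            for m in base
            if lower <= sim_row[similarity.index(m)] <= config.sim_upper
        ]
        if len(window) >= quota or lower <= 0:
            pool = window
            break
        lower = max(0.0, lower - config.sim_lower_step)
    if len(pool) <= quota:
        chosen = list(pool)
    else:
        chosen = list(rng.choice(np.array(pool, dtype=object), size=quota, replace=False))
    if len(chosen) < quota:
        logger.info(
            "shortfall for (%s, %s): wanted %d negatives, found %d",
            pair.transporter_id,
            pair.chebi_id,
            quota,
            len(chosen),
        )
    negatives = []
    for mol in chosen:
        usage_counts[mol] += 1
        taken.add((pair.transporter_id, mol))
        negatives.append(
            InteractionPair(
                transporter_id=pair.transporter_id,
                chebi_id=str(mol),
                label=Label.NEGATIVE,
                provenance=Provenance.SAMPLED,
            )
        )
    return negatives


def sample_dataset_negatives(
    positives: Sequence[InteractionPair],
    similarity: MoleculeSimilarityMatrix,
    identities: IdentityProvider,
    config: SamplingConfig = SamplingConfig(),
) -> list[InteractionPair]:
    """Sample the full negative set for a positive-pair dataset.

    The candidate vocabulary is restricted to molecules observed among the
    positives.  Quotas are drawn per positive pair from
    {negatives_min..negatives_max} (uniformly unless ``quota_weights`` is
    set); positives are processed in a seeded shuffled order so early pairs
    do not monopolize capped molecules.  Output carries label=negative,
    provenance=sampled, collides with no positive pair, contains no
    duplicates, and is byte-reproducible for a fixed seed.
    """
    if not positives:
        raise ValueError("positives must be nonempty")
    rng = np.random.default_rng(config.seed)
    positive_counts = Counter(p.chebi_id for p in positives)
    vocabulary = sorted(positive_counts)
    missing = [m for m in vocabulary if m not in similarity.molecule_ids]
    if missing:
        raise KeyError(f"molecules missing from the similarity matrix: {missing}")
    exclusion = build_exclusion_index(
        positives, identities, config.identity_exclusion_threshold
    )
    usage_counts: Counter = Counter()
    taken: set[tuple[str, str]] = set()
    order = rng.permutation(len(positives))
    quotas = list(range(config.negatives_min, config.negatives_max + 1))
    weights = None
    if config.quota_weights is not None:
        w = np.asarray(config.quota_weights, dtype=float)
        weights = w / w.sum()
    negatives: list[InteractionPair] = []
    for idx in order:
        pair = positives[idx]
        quota = int(rng.choice(quotas, p=weights))
        negatives.extend(
            sample_negatives_for_positive(
                pair,
                vocabulary,
                similarity,
                exclusion,
                quota,
                usage_counts,
                positive_counts,
                config,
                rng,
                already_sampled=taken,
            )
        )
    logger.info(
        "sampled %d negatives for %d positives (ratio %.2f)",
        len(negatives),
        len(positives),
        len(negatives) / len(positives),
    )
    return negatives
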