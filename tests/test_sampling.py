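"""Negative sampling: exclusion index, similarity windows, caps, determinism."""

from collections import Counter

import numpy as np
import pytest

from subport.molecules import MoleculeSimilarityMatrix
from subport.records import InteractionPair, Label, Provenance
from subport.sampling import (
    ExclusionIndex,
    SamplingConfig,
    build_exclusion_index,
    sample_dataset_negatives,
    sample_negatives_for_positive,
)


class FakeIdentity:
    """Identity provider with hand-set values (default 0, self 100)."""

    def __init__(self, ids, values=None):
        self._ids = list(ids)
        self._values = dict(values or {})

    def known_ids(self):
        return self._ids

    def identity(self, a, b):
        if a == b:
            return 100.0
        key = (a, b) if a <= b else (b, a)
        return self._values.get(key, 0.0)


def positive(t, m):
    return InteractionPair(t, m, Label.POSITIVE, Provenance.GO)


def toy_similarity(ids, values):
    return MoleculeSimilarityMatrix(tuple(ids), np.array(values, dtype=float))


class TestExclusionIndex:
    def test_identical_transporters_share_exclusions(self):
        positives = [positive("T1", "A"), positive("T2", "B")]
        ident = FakeIdentity(["T1", "T2"], {("T1", "T2"): 100.0})
        index = build_exclusion_index(positives, ident, threshold=60.0)
        assert index.excluded_for("T1") == {"A", "B"}
        assert index.excluded_for("T2") == {"A", "B"}

    def test_distant_transporters_exclude_own_only(self):
        positives = [positive("T1", "A"), positive("T2", "B")]
        ident = FakeIdentity(["T1", "T2"], {("T1", "T2"): 30.0})
        index = build_exclusion_index(positives, ident, threshold=60.0)
        assert index.excluded_for("T1") == {"A"}
        assert index.excluded_for("T2") == {"B"}

    def test_threshold_is_strict(self):
        """Identity exactly at the threshold does not trigger exclusion."""
        positives = [positive("T1", "A"), positive("T2", "B")]
        ident = FakeIdentity(["T1", "T2"], {("T1", "T2"): 60.0})
        index = build_exclusion_index(positives, ident, threshold=60.0)
        assert index.excluded_for("T1") == {"A"}

    def test_single_transporter(self):
        index = build_exclusion_index(
            [positive("T1", "A"), positive("T1", "B")], FakeIdentity(["T1"]), 60.0
        )
        assert index.excluded_for("T1") == {"A", "B"}

    def test_unknown_transporter_error(self):
        with pytest.raises(KeyError, match="T9"):
            build_exclusion_index([positive("T9", "A")], FakeIdentity(["T1"]), 60.0)

    def test_rejects_negative_pairs(self):
        neg = InteractionPair("T1", "A", Label.NEGATIVE, Provenance.SAMPLED)
        with pytest.raises(ValueError, match="positive"):
            build_exclusion_index([neg], FakeIdentity(["T1"]), 60.0)


class TestPerPositiveSampling:
    def _world(self):
        # molecule M0 is the true substrate; similarities to M1..M4 chosen so
        # M1, M2 sit in [0.75, 0.95], M3 in [0.55, 0.75), M4 above 0.95
        ids = ["M0", "M1", "M2", "M3", "M4"]
        sim = np.eye(5)
        row = {1: 0.80, 2: 0.90, 3: 0.60, 4: 0.97}
        for j, s in row.items():
            sim[0, j] = sim[j, 0] = s
        return ids, toy_similarity(ids, sim)

    def test_exact_window_no_relaxation(self):
        ids, sim = self._world()
        out = sample_negatives_for_positive(
            positive("T1", "M0"),
            ids,
            sim,
            ExclusionIndex({"T1": {"M0"}}),
            quota=2,
            usage_counts=Counter(),
            positive_counts={m: 1 for m in ids},
            config=SamplingConfig(seed=0),
            rng=np.random.default_rng(0),
        )
        assert {p.chebi_id for p in out} == {"M1", "M2"}
        assert all(p.label is Label.NEGATIVE and p.provenance is Provenance.SAMPLED for p in out)

    def test_one_relaxation_step(self):
        """No candidates in [0.75,0.95] -> bound drops to 0.55 and finds M3."""
        ids, sim = self._world()
        out = sample_negatives_for_positive(
            positive("T1", "M0"),
            ids,
            sim,
            ExclusionIndex({"T1": {"M0", "M1", "M2"}}),
            quota=1,
            usage_counts=Counter(),
            positive_counts={m: 1 for m in ids},
            config=SamplingConfig(seed=0),
            rng=np.random.default_rng(0),
        )
        assert {p.chebi_id for p in out} == {"M3"}

    def test_fully_excluded_vocabulary_gives_shortfall(self):
        ids, sim = self._world()
        out = sample_negatives_for_positive(
            positive("T1", "M0"),
            ids,
            sim,
            ExclusionIndex({"T1": set(ids)}),
            quota=3,
            usage_counts=Counter(),
            positive_counts={m: 1 for m in ids},
            config=SamplingConfig(seed=0),
            rng=np.random.default_rng(0),
        )
        assert out == []

    def test_frequency_cap_blocks_saturated_molecule(self):
        ids, sim = self._world()
        usage = Counter({"M1": 3, "M2": 0})  # cap = 3 x 1 occurrence
        out = sample_negatives_for_positive(
            positive("T1", "M0"),
            ids,
            sim,
            ExclusionIndex({"T1": {"M0"}}),
            quota=2,
            usage_counts=usage,
            positive_counts={m: 1 for m in ids},
            config=SamplingConfig(seed=0),
            rng=np.random.default_rng(0),
        )
        assert "M1" not in {p.chebi_id for p in out}


class TestDatasetSampling:
    def test_fixed_seed_reproducible(self, default_world, default_identity, default_molecule_features):
        _, _, sim = default_molecule_features
        config = SamplingConfig(seed=123)
        a = sample_dataset_negatives(default_world.positives, sim, default_identity, config)
        b = sample_dataset_negatives(default_world.positives, sim, default_identity, config)
        assert a == b

    def test_no_collision_with_positives_and_no_duplicates(self, default_world, default_negatives):
        positive_keys = {p.key for p in default_world.positives}
        negative_keys = [p.key for p in default_negatives]
        assert not positive_keys & set(negative_keys)
        assert len(negative_keys) == len(set(negative_keys))

    def test_frequency_cap_holds_over_full_output(self, default_world, default_negatives):
        positive_counts = Counter(p.chebi_id for p in default_world.positives)
        negative_counts = Counter(p.chebi_id for p in default_negatives)
        for mol, n in negative_counts.items():
            assert n <= int(np.ceil(3 * positive_counts[mol]))

    def test_exclusion_soundness_exhaustive(self, small_world, small_identity, small_molecule_features):
        """No sampled (t, m) where m is a substrate of any >60%-identity
        transporter (exhaustive at fixture scale)."""
        _, _, sim = small_molecule_features
        negatives = sample_dataset_negatives(
            small_world.positives, sim, small_identity, SamplingConfig(seed=5)
        )
        substrates = {}
        for p in small_world.positives:
            substrates.setdefault(p.transporter_id, set()).add(p.chebi_id)
        for neg in negatives:
            for other, subs in substrates.items():
                if neg.chebi_id in subs:
                    assert small_identity.identity(neg.transporter_id, other) <= 60.0

    def test_mean_quota_converges_to_uniform_mean(self):
        """Unconstrained world: mean negatives/positive -> 2.5 (uniform 1-4)."""
        n_transporters, per = 2000, 5
        vocab = [f"M{i}" for i in range(40)]
        rng = np.random.default_rng(0)
        positives = []
        for t in range(n_transporters):
            picks = rng.choice(40, size=per, replace=False)
            positives.extend(positive(f"T{t}", vocab[i]) for i in picks)
        sim = toy_similarity(vocab, np.ones((40, 40)) * 0.85)
        ident = FakeIdentity([f"T{t}" for t in range(n_transporters)])
        config = SamplingConfig(seed=1, frequency_cap_multiplier=100.0)
        negatives = sample_dataset_negatives(positives, sim, ident, config)
        assert len(negatives) / len(positives) == pytest.approx(2.5, abs=0.05)

    def test_quota_weights_shift_the_mean(self):
        vocab = [f"M{i}" for i in range(40)]
        rng = np.random.default_rng(0)
        positives = []
        for t in range(400):
            picks = rng.choice(40, size=5, replace=False)
            positives.extend(positive(f"T{t}", vocab[i]) for i in picks)
        sim = toy_similarity(vocab, np.ones((40, 40)) * 0.85)
        ident = FakeIdentity([f"T{t}" for t in range(400)])
        config = SamplingConfig(
            seed=1, frequency_cap_multiplier=100.0, quota_weights=(0.0, 0.0, 0.5, 0.5)
        )
        negatives = sample_dataset_negatives(positives, sim, ident, config)
        assert len(negatives) / len(positives) == pytest.approx(3.5, abs=0.1)

    def test_empty_positives_error(self, default_molecule_features):
        _, _, sim = default_molecule_features
        with pytest.raises(ValueError, match="nonempty"):
            sample_dataset_negatives([], sim, FakeIdentity([]), SamplingConfig())


def test_sampling_config_validation():
    with pytest.raises(ValueError):
        SamplingConfig(sim_lower_start=0.99, sim_upper=0.95)
    with pytest.raises(ValueError):
        SamplingConfig(negatives_min=5, negatives_max=4)
    with pytest.raises(ValueError):
        SamplingConfig(quota_weights=(1.0, 1.0))
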