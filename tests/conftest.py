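"""Shared fixtures: synthetic worlds and derived pipeline artifacts.

Heavy artifacts (the default world, its identity cache, fingerprints and
the fully trained pipeline) are session-scoped so acceptance-level tests
share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from subport.molecules import (
    MockMoleculeEmbedder,
    canonicalize_molecule,
    compute_ecfp,
    similarity_matrix,
)
from subport.proteins import MockProteinEmbedder, PairwiseIdentityCache, cluster_sequences, embed_protein
from subport.sampling import SamplingConfig, sample_dataset_negatives
from subport.splitting import make_cv_folds, train_test_split
from subport.synthetic import SyntheticWorldConfig, generate_world
from subport.training import (
    FeatureRecipe,
    HyperparameterSpace,
    assemble_features,
    cross_validate,
    predict,
    train_final,
)

WORLD_SEED = 7


@pytest.fixture(scope="session")
def default_world():
    """The standard test world: 10 families x 10 members, 5 groups x 8."""
    return generate_world(SyntheticWorldConfig(seed=WORLD_SEED))


@pytest.fixture(scope="session")
def small_world():
    """A <=50-sequence world for exhaustive pairwise verification."""
    return generate_world(
        SyntheticWorldConfig(
            n_families=8,
            members_per_family=6,
            ancestor_length=120,
            n_molecule_groups=4,
            molecules_per_group=6,
            substrates_per_family=3,
            seed=WORLD_SEED + 1,
        )
    )


@pytest.fixture(scope="session")
def default_identity(default_world):
    return PairwiseIdentityCache(default_world.transporters)


@pytest.fixture(scope="session")
def small_identity(small_world):
    return PairwiseIdentityCache(small_world.transporters)


@pytest.fixture(scope="session")
def default_molecule_features(default_world):
    mols = {m.chebi_id: canonicalize_molecule(m) for m in default_world.molecules}
    fps = {cid: compute_ecfp(m) for cid, m in mols.items()}
    sim = similarity_matrix(
        fps, canonical_smiles={c: m.canonical_smiles for c, m in mols.items()}
    )
    return mols, fps, sim


@pytest.fixture(scope="session")
def small_molecule_features(small_world):
    mols = {m.chebi_id: canonicalize_molecule(m) for m in small_world.molecules}
    fps = {cid: compute_ecfp(m) for cid, m in mols.items()}
    sim = similarity_matrix(
        fps, canonical_smiles={c: m.canonical_smiles for c, m in mols.items()}
    )
    return mols, fps, sim


@pytest.fixture(scope="session")
def default_negatives(default_world, default_identity, default_molecule_features):
    _, _, sim = default_molecule_features
    return sample_dataset_negatives(
        default_world.positives, sim, default_identity, SamplingConfig(seed=WORLD_SEED)
    )


@pytest.fixture(scope="session")
def default_split(default_world):
    return train_test_split(default_world.transporters, 0.2, rng=WORLD_SEED)


@pytest.fixture(scope="session")
def trained_pipeline(
    default_world, default_identity, default_molecule_features, default_negatives, default_split
):
    """Full curate->sample->split->train->evaluate run on the default world.

    Returns a dict with the trained model, train/test pairs, held-out labels
    and scores, and a label-shuffle control's scores.
    """
    world = default_world
    _, fps, _ = default_molecule_features
    part = {a.transporter_id: a.partition for a in default_split}
    all_pairs = list(world.positives) + list(default_negatives)
    train_pairs = [p for p in all_pairs if part[p.transporter_id] == "train"]
    test_pairs = [p for p in all_pairs if part[p.transporter_id] == "test"]
    records = {r.uniprot_id: r for r in world.transporters}
    train_records = [records[t] for t in sorted({p.transporter_id for p in train_pairs})]
    clusters = cluster_sequences(train_records, 60.0)
    folds = make_cv_folds(
        [a for a in default_split if a.partition == "train"], clusters, 5, rng=WORLD_SEED
    )
    fold_of = {a.transporter_id: a.fold_id for a in folds}
    embedder = MockProteinEmbedder()
    protein_vectors = {r.uniprot_id: embed_protein(r, embedder) for r in world.transporters}
    recipe = FeatureRecipe("mock-kmer", "ecfp")
    fold_data = [
        assemble_features(
            [p for p in train_pairs if fold_of[p.transporter_id] == f],
            protein_vectors,
            fps,
            recipe,
        )
        for f in range(5)
    ]
    space = HyperparameterSpace(n_rounds=(50, 150))
    best = cross_validate(space, fold_data, n_trials=3, metric="mcc", rng=WORLD_SEED)
    X_train, y_train = assemble_features(train_pairs, protein_vectors, fps, recipe)
    X_test, y_test = assemble_features(test_pairs, protein_vectors, fps, recipe)
    model = train_final(best.point, X_train, y_train, recipe, seed=WORLD_SEED)
    scores = predict(model, X_test)
    rng = np.random.default_rng(WORLD_SEED)
    shuffled_model = train_final(
        best.point, X_train, rng.permutation(y_train), recipe, seed=WORLD_SEED
    )
    shuffled_scores = predict(shuffled_model, X_test)
    return {
        "model": model,
        "clusters": clusters,
        "folds": folds,
        "train_pairs": train_pairs,
        "test_pairs": test_pairs,
        "train_records": train_records,
        "protein_vectors": protein_vectors,
        "y_test": y_test,
        "scores": scores,
        "shuffled_scores": shuffled_scores,
    }
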