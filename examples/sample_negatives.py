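"""Sample negative transporter-molecule pairs for a synthetic world.

Negatives are drawn from the observed substrate vocabulary, preferring
molecules with Tanimoto similarity 0.75-0.95 to the true substrate,
excluding substrates of >60%-identity homologs, and capping each molecule
at 3x its positive occurrence count.
"""

from collections import Counter

from subport.molecules import canonicalize_molecule, compute_ecfp, similarity_matrix
from subport.proteins import PairwiseIdentityCache
from subport.sampling import SamplingConfig, sample_dataset_negatives
from subport.synthetic import SyntheticWorldConfig, generate_world

world = generate_world(SyntheticWorldConfig(seed=7))
mols = {m.chebi_id: canonicalize_molecule(m) for m in world.molecules}
fingerprints = {cid: compute_ecfp(m) for cid, m in mols.items()}
similarity = similarity_matrix(
    fingerprints, canonical_smiles={c: m.canonical_smiles for c, m in mols.items()}
)
identities = PairwiseIdentityCache(world.transporters)

negatives = sample_dataset_negatives(
    world.positives, similarity, identities, SamplingConfig(seed=7)
)

positive_counts = Counter(p.chebi_id for p in world.positives)
negative_counts = Counter(p.chebi_id for p in negatives)
worst = max(negative_counts, key=lambda m: negative_counts[m] / (3 * positive_counts[m]))

print(f"positives: {len(world.positives)}  negatives: {len(negatives)}")
print(f"achieved negative:positive ratio: {len(negatives) / len(world.positives):.2f}")
print(f"(quota drawn uniformly from 1-4, so the unconstrained mean is 2.5)")
print(
    f"tightest frequency cap: {worst} with {negative_counts[worst]} negatives "
    f"vs cap {3 * positive_counts[worst]}"
)
collisions = {p.key for p in negatives} & {p.key for p in world.positives}
print(f"collisions with positive pairs: {len(collisions)} (guaranteed zero)")
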