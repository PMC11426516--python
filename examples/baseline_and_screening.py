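"""Homology-transfer baseline, McNemar comparison, screening projection.

Runs the k-most-similar-protein baseline on a synthetic world and shows
the expected outcome of screening a 50-compound candidate library with a
classifier of known false/true positive rates.
"""

import numpy as np

from subport.evaluation import (
    BaselineConfig,
    mcnemar_test,
    screening_projection,
    similarity_baseline,
)
from subport.proteins import PairwiseIdentityCache
from subport.records import Label
from subport.splitting import train_test_split
from subport.synthetic import SyntheticWorldConfig, generate_world

world = generate_world(SyntheticWorldConfig(seed=7))
identities = PairwiseIdentityCache(world.transporters)
split = train_test_split(world.transporters, 0.2, rng=7)
partition = {a.transporter_id: a.partition for a in split}
train_pairs = [p for p in world.positives if partition[p.transporter_id] == "train"]
test_pairs = [p for p in world.positives if partition[p.transporter_id] == "test"]
test_records = [r for r in world.transporters if partition[r.uniprot_id] == "test"]

for k in (1, 4, 40):
    _, m = similarity_baseline(
        test_records, test_pairs, train_pairs, identities, BaselineConfig(k=k)
    )
    print(f"k={k}: accuracy={m['accuracy']:.3f}  precision={m['precision']:.3f}  "
          f"recall={m['recall']:.3f}")
print("the predicted set is the substrate union of the k nearest training")
print("homologs: small k transfers the nearest family's substrates, large k")
print("keeps recall high but collapses precision by predicting everything.")

rng = np.random.default_rng(0)
correct_a = (rng.random(200) < 0.92).astype(int)  # stronger classifier
correct_b = (rng.random(200) < 0.80).astype(int)  # weaker classifier
p = mcnemar_test(correct_a, correct_b)
print(f"\nMcNemar on paired correctness vectors (92% vs 80% accurate): p={p:.4f}")

fp, tp = screening_projection(n_candidates=50, n_true=1, fpr=0.11, tpr=0.82)
print(f"\nscreening 50 candidates with 1 true substrate at FPR 11%, TPR 82%:")
print(f"expected false positives ~{fp}, expected true positives {tp:.2f} — a")
print(f"50-compound screen shrinks to ~{fp + 1} candidates worth testing.")
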