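"""Why fusing modalities helps: the complementarity benchmark, in small.

At complementarity 1 the generator makes the butachlor/quinclorac pair
identical in reflectance (separable only through fluorescence kinetics)
and the Cd/Cu pair identical in kinetics (separable only through
reflectance).  A classifier on any single modality is then structurally
capped near 80% accuracy, while a fusion model that sees all four
modalities can recover every class.
"""

import numpy as np

import spectrafuse as sf
from spectrafuse.data import FUSION_STRATEGIES, SINGLE_MODALITY_STRATEGIES, normalize_records
from spectrafuse.fusion import HighFusionModel
from spectrafuse.models import CNNSConfig, CNNSModel
from spectrafuse.synthetic import MODALITIES

cfg = sf.SyntheticConfig(
    n_per_class=(48,) * 5, class_effect_scale=1.0, noise_sd=0.005,
    complementarity=1.0, seed=0,
)
records = normalize_records(sf.generate_dataset(cfg))
split = sf.stratified_split(records, seed=0)
tc = sf.TrainConfig(epochs=30, seed=0)

print("single-modality CNN-S test accuracies:")
best = 0.0
for mod in MODALITIES:
    model = CNNSModel(
        CNNSConfig(input_length=len(records[0].modality(mod))),
        seed=0, strategy=SINGLE_MODALITY_STRATEGIES[mod],
    )
    res = sf.train(model, split, tc)
    acc = sf.evaluate(res.model, split.test).accuracy
    best = max(best, acc)
    print(f"  {mod:9s}: {acc:.3f}")

fusion = HighFusionModel(FUSION_STRATEGIES[5], seed=0)
res = sf.train(fusion, split, tc)
acc = sf.evaluate(res.model, split.test).accuracy
print(f"\nend-to-end high-level fusion (all four modalities): {acc:.3f}")
print(f"gain over the best single source: {acc - best:+.3f}")
print("\nEach single source is blind to one class pair, so it plateaus near "
      "0.8; decision fusion combines the submodels' beliefs and resolves "
      "both pairs.")
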