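"""Train the CNN-S base classifier on one modality and report accuracy.

Small-scale demo: 40 plants per class, 25 epochs.  The printed history
shows the scheduled learning rate and the per-epoch train/validation
accuracies; the selected model is the snapshot with the best validation
accuracy.
"""

import numpy as np

import spectrafuse as sf
from spectrafuse.data import SINGLE_MODALITY_STRATEGIES, normalize_records
from spectrafuse.models import CNNSConfig, CNNSModel

cfg = sf.SyntheticConfig(
    n_per_class=(40,) * 5, class_effect_scale=1.0, noise_sd=0.005,
    complementarity=0.0, seed=0,
)
records = normalize_records(sf.generate_dataset(cfg))
split = sf.stratified_split(records, seed=0)
print(f"train/validation/test sizes: {len(split.train)}/{len(split.validation)}/{len(split.test)}")

model = CNNSModel(
    CNNSConfig(input_length=396), seed=0,
    strategy=SINGLE_MODALITY_STRATEGIES["l_visnir"],
)
result = sf.train(model, split, sf.TrainConfig(epochs=25, seed=0))

print("\nepoch    lr      loss   train_acc  val_acc")
for h in result.history[::4]:
    print(f"{h.epoch:>5}  {h.lr:.4f}  {h.loss:6.3f}  {h.train_acc:9.3f}  {h.val_acc:7.3f}")
print(f"\nselected epoch {result.best_epoch} (validation accuracy {result.best_val_acc:.3f})")

report = sf.evaluate(result.model, split.test)
print(f"test accuracy: {report.accuracy:.3f}")
print("confusion matrix (rows = true class CK/Cd/Cu/DCA/ELK, cols = predicted):")
print(report.confusion)
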