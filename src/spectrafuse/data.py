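"""Dataset handling: fusion strategies, stratified splitting, assembly.

The five fusion strategies pick subsets of the four modalities:

=========  ========  ========  =====  =====
strategy   l_visnir  s_visnir  l_fkc  s_fkc
=========  ========  ========  =====  =====
Fusion 1      x         x
Fusion 2                         x      x
Fusion 3      x                  x
Fusion 4                x              x
Fusion 5      x         x        x      x
=========  ========  ========  =====  =====

Splitting follows the 4:1:1 train/validation/test protocol, stratified by
class: a class of n samples contributes floor(n/6) to validation,
floor(n/6) to test and the remainder to training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import MODALITIES, SampleRecord


@dataclass(frozen=True)
class FusionStrategy:
    """A named subset of the four modalities used for fusion."""

    name: str
    use_l_visnir: bool = False
    use_s_visnir: bool = False
    use_l_fkc: bool = False
    use_s_fkc: bool = False

    def __post_init__(self):
        if not any(self.flags()):
            raise ValueError("a fusion strategy must select at least one modality")

    def flags(self) -> tuple[bool, bool, bool, bool]:
        return (self.use_l_visnir, self.use_s_visnir, self.use_l_fkc, self.use_s_fkc)

    @property
    def modalities(self) -> tuple[str, ...]:
        """Selected modality names in the fixed concatenation order."""
        return tuple(m for m, used in zip(MODALITIES, self.flags()) if used)

    @property
    def n_modalities(self) -> int:
        return len(self.modalities)


FUSION_STRATEGIES: dict[int, FusionStrategy] = {
    1: FusionStrategy("Fusion 1", use_l_visnir=True, use_s_visnir=True),
    2: FusionStrategy("Fusion 2", use_l_fkc=True, use_s_fkc=True),
    3: FusionStrategy("Fusion 3", use_l_visnir=True, use_l_fkc=True),
    4: FusionStrategy("Fusion 4", use_s_visnir=True, use_s_fkc=True),
    5: FusionStrategy(
        "Fusion 5", use_l_visnir=True, use_s_visnir=True, use_l_fkc=True, use_s_fkc=True
    ),
}

SINGLE_MODALITY_STRATEGIES: dict[str, FusionStrategy] = {
    mod: FusionStrategy(mod, **{f"use_{mod}": True}) for mod in MODALITIES
}


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test record lists under the 4:1:1 ratio."""

    train: list[SampleRecord]
    validation: list[SampleRecord]
    test: list[SampleRecord]
    seed: int
    ratio: tuple[int, int, int] = (4, 1, 1)


def stratified_split(records: Sequence[SampleRecord], seed: int) -> DatasetSplit:
    """Randomly split records 4:1:1 per class.

    For each class of size n, validation and test each receive floor(n/6)
    samples and training the remainder; classes with fewer than 3 samples
    go entirely to training (with a warning).  Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[SampleRecord]] = {}
    for r in records:
        by_class.setdefault(r.label, []).append(r)

    train: list[SampleRecord] = []
    val: list[SampleRecord] = []
    test: list[SampleRecord] = []
    for label in sorted(by_class):
        group = by_class[label]
        n = len(group)
        if n < 3:
            warnings.warn(
                f"class {label} has only {n} sample(s); all assigned to training",
                stacklevel=2,
            )
            train.extend(group)
            continue
        k = n // 6
        order = rng.permutation(n)
        val.extend(group[i] for i in order[:k])
        test.extend(group[i] for i in order[k : 2 * k])
        train.extend(group[i] for i in order[2 * k :])
    return DatasetSplit(train=train, validation=val, test=test, seed=seed)


def assemble(
    records: Sequence[SampleRecord],
    strategy: FusionStrategy,
    mode: str = "stacked",
):
    """Build model inputs for the selected modalities.

    mode='stacked' returns one (n_samples, sum of lengths) matrix whose
    rows concatenate the selected modalities in the fixed order
    (l_visnir, s_visnir, l_fkc, s_fkc); mode='per_modality' returns a list
    with one (n_samples, length) matrix per selected modality, same row
    order.
    """
    if mode not in ("stacked", "per_modality"):
        raise ValueError("mode must be 'stacked' or 'per_modality'")
    mats = []
    for mod in strategy.modalities:
        vecs = []
        for r in records:
            v = r.modality(mod)
            if v is None:
                raise ValueError(f"record {r.sample_id} is missing modality {mod}")
            vecs.append(np.asarray(v, dtype=float))
        mats.append(np.stack(vecs))
    if mode == "per_modality":
        return mats
    return np.concatenate(mats, axis=1)


def labels_of(records: Sequence[SampleRecord]) -> np.ndarray:
    return np.array([r.label for r in records], dtype=int)


def normalize_records(records: Sequence[SampleRecord]) -> list[SampleRecord]:
    """Maximum-normalize every modality vector of every record.

    This is the final preprocessing step before modeling: each curve is
    divided by its own maximum.  Returns new records; inputs are left
    untouched.
    """
    from .preprocessing import max_normalize

    out = []
    for r in records:
        out.append(
            SampleRecord(
                sample_id=r.sample_id,
                label=r.label,
                **{m: max_normalize(r.modality(m)) for m in MODALITIES},
            )
        )
    return out


def write_split_manifest(split: DatasetSplit, path: str | Path) -> None:
    """Write a sample_id -> partition table as delimited text."""
    rows = []
    for part, recs in (
        ("train", split.train),
        ("validation", split.validation),
        ("test", split.test),
    ):
        rows.extend({"sample_id": r.sample_id, "partition": part} for r in recs)
    pd.DataFrame(rows).to_csv(path, index=False)
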