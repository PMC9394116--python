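"""Synthetic multimodal plant-stress datasets.

Real acquisitions of this kind pair, for each plant, a leaf and a stem
VIS/NIR reflectance spectrum (454-957 nm, 396 bands) with a leaf and a stem
chlorophyll-fluorescence kinetic curve (286 timepoints), labelled by
treatment: 0 = control (CK), 1 = cadmium (Cd), 2 = copper (Cu),
3 = butachlor (DCA), 4 = quinclorac (ELK).

The generator emulates that structure with analytically known class
templates, so every downstream model can be tested without any external
download:

* reflectance: a smooth vegetation baseline (low visible reflectance, a
  green peak near 550 nm, a chlorophyll absorption dip near 670 nm, a
  sigmoidal red edge rising to a NIR plateau) plus class- and
  organ-specific Gaussian bumps scaled by ``class_effect_scale``;
* fluorescence kinetics: a saturating rise from the minimal fluorescence
  F0 toward the maximum Fm followed by exponential relaxation to a steady
  state, with the rise amplitude and rate constants modulated per class;
* i.i.d. Gaussian noise with standard deviation ``noise_sd``, clipped at 0
  (both physical quantities are nonnegative).

The ``complementarity`` knob controls how the class signal is distributed
across modalities.  At 0 every class is distinct in every modality.  As it
rises toward 1, the reflectance template of class 4 is linearly morphed
onto class 3's and the kinetic template of class 2 onto class 1's, so that
at 1 the pair (3, 4) is separable only through the kinetic curves and the
pair (1, 2) only through reflectance — the regime in which fusing
modalities provably beats any single source.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

N_CLASSES = 5
CLASS_NAMES = ("CK", "Cd", "Cu", "DCA", "ELK")
MODALITIES = ("l_visnir", "s_visnir", "l_fkc", "s_fkc")
ORGANS = ("leaf", "stem")

# Per-treatment sample counts of the emulated experiment (CK, Cd, Cu, DCA, ELK).
DEFAULT_N_PER_CLASS = (240, 360, 360, 268, 358)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic dataset generator.

    Parameters
    ----------
    n_per_class:
        Number of samples per treatment class (CK, Cd, Cu, DCA, ELK).
    n_bands:
        Length of the reflectance vectors (bands spanning 454-957 nm).
    n_timepoints:
        Length of the fluorescence kinetic curves.
    class_effect_scale:
        Amplitude of the class-specific template perturbations; 0 makes all
        classes share one template.
    noise_sd:
        Standard deviation of the additive Gaussian measurement noise.
    complementarity:
        In [0, 1]; 0 = every modality carries the full class signal, 1 =
        class pair (3, 4) separable only in kinetics and (1, 2) only in
        reflectance.
    seed:
        Seed for the dataset random stream.
    """

    n_per_class: Sequence[int] = DEFAULT_N_PER_CLASS
    n_bands: int = 396
    n_timepoints: int = 286
    class_effect_scale: float = 1.0
    noise_sd: float = 0.01
    complementarity: float = 0.5
    seed: int = 0

    def __post_init__(self):
        counts = tuple(int(n) for n in self.n_per_class)
        if len(counts) != N_CLASSES:
            raise ValueError(f"n_per_class must have {N_CLASSES} entries")
        if any(n < 0 for n in counts):
            raise ValueError("n_per_class entries must be nonnegative")
        object.__setattr__(self, "n_per_class", counts)
        if self.n_bands < 1 or self.n_timepoints < 1:
            raise ValueError("n_bands and n_timepoints must be positive")
        if self.class_effect_scale < 0:
            raise ValueError("class_effect_scale must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.complementarity <= 1.0:
            raise ValueError("complementarity must lie in [0, 1]")


@dataclass
class SampleRecord:
    """One plant: four modality vectors plus the treatment label."""

    sample_id: str
    label: int
    l_visnir: np.ndarray
    s_visnir: np.ndarray
    l_fkc: np.ndarray
    s_fkc: np.ndarray

    def modality(self, name: str) -> np.ndarray:
        if name not in MODALITIES:
            raise ValueError(f"unknown modality {name!r}")
        return getattr(self, name)


def _check_label_organ(label: int, organ: str) -> None:
    if label not in range(N_CLASSES):
        raise ValueError(f"label must be in 0..{N_CLASSES - 1}, got {label}")
    if organ not in ORGANS:
        raise ValueError(f"organ must be 'leaf' or 'stem', got {organ!r}")


def _gauss(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / width) ** 2)


def wavelength_grid(n_bands: int, low: float = 454.0, high: float = 957.0) -> np.ndarray:
    """Band-center wavelengths in nm, evenly spaced over [low, high]."""
    return np.linspace(low, high, n_bands)


def _visnir_baseline(wl: np.ndarray, organ: str) -> np.ndarray:
    # Stems share the leaf shape with a slightly lower NIR plateau and a
    # small shift of the green peak — similar but not identical organs.
    shift = 0.0 if organ == "leaf" else 8.0
    plateau = 0.45 if organ == "leaf" else 0.38
    base = 0.05
    green = 0.08 * _gauss(wl, 550.0 + shift, 25.0)
    red_dip = -0.03 * _gauss(wl, 670.0, 18.0)
    red_edge = plateau / (1.0 + np.exp(-(wl - 715.0) / 12.0))
    return base + green + red_dip + red_edge


# Class bump sets (centers nm, amplitudes) for the reflectance signatures.
# Class 0 (control) is the bare baseline.
_VISNIR_BUMPS = {
    0: ((), ()),
    1: ((520.0, 690.0), (0.030, 0.025)),
    2: ((560.0, 730.0), (-0.025, 0.035)),
    3: ((600.0, 760.0), (0.035, -0.030)),
    4: ((640.0, 820.0), (-0.030, 0.030)),
}
_BUMP_WIDTH_NM = 20.0


def _visnir_class_effect(wl: np.ndarray, label: int, organ: str) -> np.ndarray:
    centers, amps = _VISNIR_BUMPS[label]
    shift = 0.0 if organ == "leaf" else 6.0
    scale = 1.0 if organ == "leaf" else 0.9
    effect = np.zeros_like(wl)
    for c, a in zip(centers, amps):
        effect += scale * a * _gauss(wl, c + shift, _BUMP_WIDTH_NM)
    return effect


def visnir_template(label: int, organ: str, cfg: SyntheticConfig) -> np.ndarray:
    """Noise-free mean reflectance spectrum of a class/organ.

    This is the exact class template: the sampled spectra are this vector
    plus clipped Gaussian noise, which makes it usable as an analytic
    oracle (e.g. for nearest-template classification).
    """
    _check_label_organ(label, organ)
    wl = wavelength_grid(cfg.n_bands)
    base = _visnir_baseline(wl, organ)

    def raw(lab: int) -> np.ndarray:
        return base + cfg.class_effect_scale * _visnir_class_effect(wl, lab, organ)

    c = cfg.complementarity
    if label == 4 and c > 0:
        # Morph class 4's reflectance onto class 3's: at c=1 the pair (3,4)
        # is indistinguishable from reflectance alone.
        return (1.0 - c) * raw(4) + c * raw(3)
    return raw(label)


# Kinetic base parameters: minimal fluorescence F0, rise amplitude A
# (Fm - F0), rise rate kr, relaxation rate kd, steady-state fraction s,
# on a unit time axis (timepoints are a uniform index; no claim is made
# about real induction-protocol timing).
_FKC_BASE = {"F0": 0.2, "A": 0.8, "kr": 60.0, "kd": 2.0, "s": 0.55}

# Per-class modulation (dA, dkr, dkd) applied as base + scale * delta.
_FKC_DELTAS = {
    0: (0.0, 0.0, 0.0),
    1: (0.10, 15.0, 0.5),
    2: (-0.08, -12.0, 0.8),
    3: (0.08, -18.0, -0.6),
    4: (-0.10, 20.0, -0.8),
}


def _fkc_curve(t: np.ndarray, label: int, organ: str, scale: float) -> np.ndarray:
    dA, dkr, dkd = _FKC_DELTAS[label]
    organ_A = 1.0 if organ == "leaf" else 0.9
    organ_kr = 1.0 if organ == "leaf" else 0.85
    F0 = _FKC_BASE["F0"]
    A = (_FKC_BASE["A"] + scale * dA) * organ_A
    kr = (_FKC_BASE["kr"] + scale * dkr) * organ_kr
    kd = _FKC_BASE["kd"] + scale * dkd
    s = _FKC_BASE["s"]
    rise = 1.0 - np.exp(-kr * t)
    relax = s + (1.0 - s) * np.exp(-kd * t)
    return F0 + A * rise * relax


def fkc_template(label: int, organ: str, cfg: SyntheticConfig) -> np.ndarray:
    """Noise-free mean fluorescence kinetic curve of a class/organ."""
    _check_label_organ(label, organ)
    t = np.linspace(0.0, 1.0, cfg.n_timepoints)

    def raw(lab: int) -> np.ndarray:
        return _fkc_curve(t, lab, organ, cfg.class_effect_scale)

    c = cfg.complementarity
    if label == 2 and c > 0:
        # Morph class 2's kinetics onto class 1's: at c=1 the pair (1,2) is
        # indistinguishable from the kinetic curves alone.
        return (1.0 - c) * raw(2) + c * raw(1)
    return raw(label)


def template(label: int, modality: str, cfg: SyntheticConfig) -> np.ndarray:
    """Class template for any of the four modalities."""
    organ = "leaf" if modality.startswith("l_") else "stem"
    if modality in ("l_visnir", "s_visnir"):
        return visnir_template(label, organ, cfg)
    if modality in ("l_fkc", "s_fkc"):
        return fkc_template(label, organ, cfg)
    raise ValueError(f"unknown modality {modality!r}")


def generate_visnir(
    label: int, organ: str, cfg: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw one noisy reflectance spectrum for a class/organ."""
    clean = visnir_template(label, organ, cfg)
    noisy = clean + rng.normal(0.0, cfg.noise_sd, size=clean.shape)
    return np.clip(noisy, 0.0, None)


def generate_fkc(
    label: int, organ: str, cfg: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw one noisy fluorescence kinetic curve for a class/organ."""
    clean = fkc_template(label, organ, cfg)
    noisy = clean + rng.normal(0.0, cfg.noise_sd, size=clean.shape)
    return np.clip(noisy, 0.0, None)


def generate_dataset(cfg: SyntheticConfig) -> list[SampleRecord]:
    """Generate the full labelled multimodal dataset.

    Returns ``sum(cfg.n_per_class)`` records with exact per-class counts,
    deterministically for a given config (including seed).
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[SampleRecord] = []
    for label, count in enumerate(cfg.n_per_class):
        for i in range(count):
            records.append(
                SampleRecord(
                    sample_id=f"{CLASS_NAMES[label]}_{i:04d}",
                    label=label,
                    l_visnir=generate_visnir(label, "leaf", cfg, rng),
                    s_visnir=generate_visnir(label, "stem", cfg, rng),
                    l_fkc=generate_fkc(label, "leaf", cfg, rng),
                    s_fkc=generate_fkc(label, "stem", cfg, rng),
                )
            )
    return records


def write_dataset(records: Sequence[SampleRecord], out_dir: str | Path, prefix: str = "synthetic") -> None:
    """Write one delimited-text table per modality plus a combined .npz.

    Table layout: rows = samples; columns = sample_id, label, then one
    column per feature.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for mod in MODALITIES:
        mat = np.stack([r.modality(mod) for r in records])
        df = pd.DataFrame(mat, columns=[f"f{j}" for j in range(mat.shape[1])])
        df.insert(0, "label", [r.label for r in records])
        df.insert(0, "sample_id", [r.sample_id for r in records])
        df.to_csv(out / f"{prefix}_{mod}.csv", index=False)
    arrays = {mod: np.stack([r.modality(mod) for r in records]) for mod in MODALITIES}
    arrays["label"] = np.array([r.label for r in records])
    arrays["sample_id"] = np.array([r.sample_id for r in records])
    np.savez(out / f"{prefix}_all.npz", **arrays)


def read_dataset(in_dir: str | Path, prefix: str = "synthetic") -> list[SampleRecord]:
    """Read a dataset previously written by :func:`write_dataset`."""
    indir = Path(in_dir)
    frames = {}
    for mod in MODALITIES:
        path = indir / f"{prefix}_{mod}.csv"
        if not path.exists():
            raise FileNotFoundError(path)
        frames[mod] = pd.read_csv(path)
    ids = frames["l_visnir"]["sample_id"].tolist()
    labels = frames["l_visnir"]["label"].astype(int).tolist()
    records = []
    for i, (sid, lab) in enumerate(zip(ids, labels)):
        vecs = {
            mod: frames[mod].iloc[i, 2:].to_numpy(dtype=float) for mod in MODALITIES
        }
        records.append(SampleRecord(sample_id=str(sid), label=lab, **vecs))
    return records
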