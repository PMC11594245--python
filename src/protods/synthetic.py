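"""Seeded synthetic hyperspectral datasets.

The generator emulates the statistical structure of near-infrared reflectance
cubes of granular food samples, which is exactly the structure the training
scheme relies on:

* each class has one smooth spectral signature over 900-1700 nm (a baseline
  plus a few Gaussian bumps), with a configurable minimum L2 separation
  between class signatures;
* each physical instance carries a multiplicative illumination factor
  (lognormal), and each pixel a further multiplicative jitter — so pixels of
  the same instance share a spectral shape but differ from other instances,
  the property the instance-wise contrastive pretext task exploits;
* iid Gaussian per-band noise is added per pixel;
* a configurable fraction of pixels is shadowed (scaled to a mean reflectance
  below the effective-pixel threshold of 0.1) so masking has work to do;
* class instance counts are set directly, giving controlled imbalance.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cube import CalibratedCube, InstanceRecord, RawCube, cube_to_instance, effective_mask, select_bands
from .errors import ConfigurationError
from .io import write_cube, write_manifest

__all__ = [
    "SignatureModel",
    "SimConfig",
    "SyntheticInstance",
    "SyntheticDataset",
    "make_signatures",
    "simulate_instance",
    "simulate_dataset",
    "dataset_to_records",
]

EFFECTIVE_THRESHOLD = 0.1
SHADOW_TARGET_MEAN = 0.06  # mean reflectance given to shadowed pixels; < 0.1


@dataclass
class SignatureModel:
    """Per-class smooth signature family over a common wavelength grid."""

    n_classes: int = 2
    n_bands: int = 256
    wavelength_lo: float = 900.0
    wavelength_hi: float = 1700.0
    baseline: float = 0.45
    n_bumps: int = 3
    bump_width_nm: tuple[float, float] = (40.0, 160.0)
    bump_amplitude: float = 0.18
    separation: float = 0.5  # minimum pairwise L2 distance between signatures
    max_retries: int = 200

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.n_bands < 1:
            raise ConfigurationError("n_classes and n_bands must be >= 1")
        if not 0.1 < self.baseline < 1.0:
            raise ConfigurationError("baseline must lie in (0.1, 1.0)")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wavelength_lo, self.wavelength_hi, self.n_bands)


@dataclass
class SimConfig:
    """Dataset-level simulation settings.

    ``n_majority`` / ``n_minority`` are *training* instance counts; the test
    set holds ``n_test_per_class`` instances of every class (a balanced test
    set keeps the per-class recall estimates equally precise; balanced
    accuracy is prevalence-immune either way).  If ``n_test_per_class`` is
    None the test counts are derived from ``test_fraction`` applied to the
    training counts.
    """

    seed: int = 0
    n_majority: int = 100
    n_minority: tuple[int, ...] = (5,)
    n_test_per_class: int | None = 25
    test_fraction: float = 0.5
    height: int = 8
    width: int = 8
    illumination_jitter_sd: float = 0.15  # lognormal sigma, instance level
    pixel_jitter_sd: float = 0.05  # lognormal sigma, pixel level
    noise_sd: float = 0.02  # additive iid Gaussian, per band
    shadow_fraction: float = 0.1
    clip_hi: float = 1.2  # calibrated reflectance may mildly exceed 1

    def __post_init__(self) -> None:
        self.n_minority = tuple(int(n) for n in np.atleast_1d(self.n_minority))
        if self.n_majority < 1:
            raise ConfigurationError("n_majority must be >= 1")
        if any(n < 0 for n in self.n_minority):
            raise ConfigurationError("minority counts must be >= 0")
        if not 0.0 <= self.shadow_fraction <= 1.0:
            raise ConfigurationError("shadow_fraction must be in [0, 1]")
        if not 0.0 <= self.test_fraction <= 1.0:
            raise ConfigurationError("test_fraction must be in [0, 1]")

    @property
    def n_classes(self) -> int:
        return 1 + len(self.n_minority)


@dataclass
class SyntheticInstance:
    """One simulated sample: a reflectance cube plus its ground-truth label."""

    instance_id: str
    label: int
    cube: CalibratedCube
    raw: RawCube | None = None
    dark: np.ndarray | None = None
    white: np.ndarray | None = None


@dataclass
class SyntheticDataset:
    signatures: np.ndarray
    wavelengths: np.ndarray
    train: list[SyntheticInstance] = field(default_factory=list)
    test: list[SyntheticInstance] = field(default_factory=list)


def _gaussian_bumps(
    wl: np.ndarray, centres: np.ndarray, widths: np.ndarray, amps: np.ndarray
) -> np.ndarray:
    return np.sum(
        amps[:, None] * np.exp(-0.5 * ((wl[None, :] - centres[:, None]) / widths[:, None]) ** 2),
        axis=0,
    )


def make_signatures(model: SignatureModel, rng: np.random.Generator) -> np.ndarray:
    """Draw a C x B matrix of smooth class signatures in (0.1, 1.0).

    Signatures are redrawn until every pair is at least ``model.separation``
    apart in L2; after ``model.max_retries`` failed draws a
    ConfigurationError is raised (the separation is unattainable with the
    configured amplitude budget).
    """
    wl = model.wavelengths
    for _ in range(model.max_retries):
        sigs = np.empty((model.n_classes, model.n_bands))
        for c in range(model.n_classes):
            centres = rng.uniform(model.wavelength_lo, model.wavelength_hi, model.n_bumps)
            widths = rng.uniform(*model.bump_width_nm, model.n_bumps)
            amps = rng.uniform(-model.bump_amplitude, model.bump_amplitude, model.n_bumps)
            sigs[c] = model.baseline + _gaussian_bumps(wl, centres, widths, amps)
        sigs = np.clip(sigs, 0.12, 0.98)
        if model.n_classes == 1:
            return sigs
        dists = np.linalg.norm(sigs[:, None, :] - sigs[None, :, :], axis=2)
        iu = np.triu_indices(model.n_classes, k=1)
        if np.all(dists[iu] >= model.separation):
            return sigs
    raise ConfigurationError(
        f"could not draw {model.n_classes} signatures with pairwise L2 "
        f"separation >= {model.separation} in {model.max_retries} attempts; "
        "lower `separation` or raise `bump_amplitude`"
    )


def simulate_instance(
    signature: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
    wavelengths: np.ndarray | None = None,
) -> CalibratedCube:
    """Simulate one instance cube from a class signature.

    Pixel p gets reflectance ``clip(scale_p * signature + eps_p, 0, clip_hi)``
    with ``scale_p`` the product of an instance-level and a pixel-level
    lognormal factor, and ``eps_p`` iid Gaussian per band.  A
    ``shadow_fraction`` of pixels (rounded to the nearest count) instead gets
    a scale putting its mean reflectance at ~0.06, below the effective-pixel
    threshold.
    """
    signature = np.asarray(signature, dtype=float)
    b = signature.size
    if wavelengths is None:
        wavelengths = np.linspace(900.0, 1700.0, b)
    h, w = cfg.height, cfg.width
    n_pix = h * w

    inst_scale = float(np.exp(rng.normal(0.0, cfg.illumination_jitter_sd))) if cfg.illumination_jitter_sd > 0 else 1.0
    pix_scale = (
        np.exp(rng.normal(0.0, cfg.pixel_jitter_sd, n_pix)) if cfg.pixel_jitter_sd > 0 else np.ones(n_pix)
    )
    scale = inst_scale * pix_scale

    n_shadow = int(round(cfg.shadow_fraction * n_pix))
    if n_shadow > 0:
        shadow_idx = rng.choice(n_pix, size=n_shadow, replace=False)
        scale[shadow_idx] = SHADOW_TARGET_MEAN / signature.mean()

    noise = rng.normal(0.0, cfg.noise_sd, (n_pix, b)) if cfg.noise_sd > 0 else 0.0
    pixels = np.clip(scale[:, None] * signature[None, :] + noise, 0.0, cfg.clip_hi)
    return CalibratedCube(
        reflectance=pixels.reshape(h, w, b), wavelengths=wavelengths
    )


def _raw_triplet(
    cube: CalibratedCube, rng: np.random.Generator
) -> tuple[RawCube, np.ndarray, np.ndarray]:
    """Invert calibration: raw = dark + R * (white - dark)."""
    shape = cube.shape
    dark = np.full(shape, 80.0) + rng.normal(0, 1.0, shape[2])[None, None, :]
    white = np.full(shape, 3500.0) + rng.normal(0, 20.0, shape[2])[None, None, :]
    raw = dark + cube.reflectance * (white - dark)
    return RawCube(values=raw, wavelengths=cube.wavelengths), dark, white


def simulate_dataset(
    model: SignatureModel,
    cfg: SimConfig,
    emit_raw: bool = False,
) -> SyntheticDataset:
    """Generate a full train/test dataset with the configured imbalance.

    Class 1 is the majority; classes 2..C are minorities with the configured
    training counts.  With ``emit_raw`` each instance also carries a
    raw/dark/white triplet satisfying ``calibrate(raw, refs) == reflectance``
    to numerical precision.
    """
    if model.n_classes != cfg.n_classes:
        raise ConfigurationError(
            f"signature model has {model.n_classes} classes but config implies "
            f"{cfg.n_classes} (1 majority + {len(cfg.n_minority)} minorities)"
        )
    rng = np.random.default_rng(cfg.seed)
    signatures = make_signatures(model, rng)
    train_counts = [cfg.n_majority, *cfg.n_minority]
    if cfg.n_test_per_class is not None:
        test_counts = [cfg.n_test_per_class] * cfg.n_classes
    else:
        ratio = cfg.test_fraction / max(1.0 - cfg.test_fraction, 1e-12)
        test_counts = [int(round(n * ratio)) for n in train_counts]

    ds = SyntheticDataset(signatures=signatures, wavelengths=model.wavelengths)
    for split, counts, bucket in (
        ("train", train_counts, ds.train),
        ("test", test_counts, ds.test),
    ):
        for cls_idx, count in enumerate(counts):
            label = cls_idx + 1
            for j in range(count):
                cube = simulate_instance(
                    signatures[cls_idx], cfg, rng, wavelengths=model.wavelengths
                )
                inst = SyntheticInstance(
                    instance_id=f"{split}_c{label}_{j:04d}", label=label, cube=cube
                )
                if emit_raw:
                    inst.raw, inst.dark, inst.white = _raw_triplet(cube, rng)
                bucket.append(inst)
    return ds


def dataset_to_records(
    dataset: SyntheticDataset,
    lo: float = 1000.0,
    hi: float = 1600.0,
    threshold: float = EFFECTIVE_THRESHOLD,
) -> tuple[list[InstanceRecord], list[InstanceRecord], np.ndarray]:
    """Run the preprocessing chain (band crop + masking) over a dataset.

    Returns (train records, test records, retained band indices).
    """
    band_idx = select_bands(dataset.wavelengths, lo, hi)
    out: list[list[InstanceRecord]] = []
    for bucket in (dataset.train, dataset.test):
        records = []
        for inst in bucket:
            cube = inst.cube
            cube.mask = effective_mask(cube, band_idx, threshold)
            records.append(
                cube_to_instance(cube, band_idx, inst.label, inst.instance_id)
            )
        out.append(records)
    return out[0], out[1], band_idx


def export_dataset(
    dataset: SyntheticDataset,
    out_dir: str,
    fmt: str = "npz",
    provenance: dict | None = None,
) -> None:
    """Write cubes, train/test manifests and a provenance JSON to ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    for split, bucket in (("train", dataset.train), ("test", dataset.test)):
        rows = []
        for inst in bucket:
            ext = ".npz" if fmt == "npz" else ".raw"
            path = os.path.join(out_dir, f"{inst.instance_id}{ext}")
            write_cube(
                RawCube(values=inst.cube.reflectance, wavelengths=inst.cube.wavelengths),
                path,
            )
            rows.append(
                {"instance_id": inst.instance_id, "label": inst.label, "cube_path": path}
            )
        write_manifest(pd.DataFrame(rows), os.path.join(out_dir, f"{split}_manifest.csv"))
    with open(os.path.join(out_dir, "provenance.json"), "w") as fh:
        json.dump(provenance or {}, fh, indent=2, default=str)
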