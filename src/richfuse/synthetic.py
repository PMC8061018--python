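"""Synthetic paired image+record cohorts with controllable per-modality signal.

The generator emulates the released cohort's layout — 185 patients (82
benign), 2-10 images per patient, 29 coded record features, image labels
equal to patient labels — while letting tests dial class signal per modality:

* ``record_signal`` tilts the class-conditional categorical distributions of a
  fixed set of informative features toward clinically concordant codes
  (harder texture, irregular morphology, ... under malignant).
* ``image_signal`` raises nucleus-blob density and shape irregularity in
  malignant images.

The two cues are independent given the class, so with moderate strengths the
Bayes-optimal fused classifier beats each unimodal one — the property the
fusion acceptance runs rely on.  With both signals at 0 the classes are
exchangeable in every modality.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .emr_schema import LABELS, StructuredRecord, load_schema, write_cohort_table

__all__ = [
    "CohortParams",
    "Cohort",
    "generate_record",
    "generate_image",
    "generate_cohort",
    "write_cohort",
    "read_cohort_dir",
    "TEST_PRESET",
    "PAPERSIZE_PRESET",
]

# (feature name, direction): +1 -> higher codes more likely under malignant,
# -1 -> higher codes more likely under benign.  Directions follow the
# schema's clinical descriptions; this is flavor, not a scientific claim.
_INFORMATIVE: tuple[tuple[str, int], ...] = (
    ("Tumor Border", +1),
    ("Tumor Morphology", +1),
    ("Tumor Texture", +1),
    ("Activity", +1),
    ("Smooth Surface", -1),
    ("Capsules", -1),
    ("Axillary Lymphadenectasis", +1),
    ("Tumor Size", +1),
)


@dataclasses.dataclass(frozen=True)
class CohortParams:
    n_patients: int = 185
    benign_fraction: float = 82 / 185
    images_per_patient: tuple[int, int] = (2, 10)
    image_side: int = 64
    image_signal: float = 1.0
    record_signal: float = 1.0
    n_informative_record_features: int = 8
    pixel_noise: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.benign_fraction < 1.0):
            raise ValueError("benign_fraction must lie strictly between 0 and 1")
        lo, hi = self.images_per_patient
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid images_per_patient range {self.images_per_patient}")
        if self.image_signal < 0 or self.record_signal < 0:
            raise ValueError("signal strengths must be non-negative")
        if not (1 <= self.n_informative_record_features <= len(_INFORMATIVE)):
            raise ValueError(
                f"n_informative_record_features must be in 1..{len(_INFORMATIVE)}"
            )


TEST_PRESET = CohortParams(
    n_patients=120, benign_fraction=0.5, images_per_patient=(4, 4), image_side=64,
    image_signal=1.0, record_signal=1.0,
)
PAPERSIZE_PRESET = CohortParams(image_side=2048)  # images are side x side*0.75


@dataclasses.dataclass
class Cohort:
    records: list[StructuredRecord]
    images: list[np.ndarray]  # one array per image, [0,1] floats
    manifest: pd.DataFrame  # columns: image_id, patient_id, label
    params: CohortParams

    def images_of(self, patient_id: str) -> list[np.ndarray]:
        idx = self.manifest.index[self.manifest["patient_id"] == patient_id]
        return [self.images[i] for i in idx]


def _class_probs(k: int, direction: int, strength: float) -> np.ndarray:
    codes = np.arange(k + 1)
    logits = strength * direction * (codes / k - 0.5)
    p = np.exp(logits - logits.max())
    return p / p.sum()


def generate_record(
    label: str, params: CohortParams, seed: int | np.random.Generator,
    patient_id: str = "p0",
) -> StructuredRecord:
    """Draw one schema-valid record whose informative features are tilted
    toward the class by ``record_signal``; other features are uniform."""
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    schema = load_schema()
    informative = dict(_INFORMATIVE[: params.n_informative_record_features])
    sign = 1.0 if label == "malignant" else -1.0
    values = []
    for spec in schema:
        k = spec.max_code
        if spec.name in informative:
            p = _class_probs(k, informative[spec.name], sign * params.record_signal)
        else:
            p = np.full(k + 1, 1.0 / (k + 1))
        values.append(int(rng.choice(k + 1, p=p)))
    return StructuredRecord(patient_id=patient_id, values=tuple(values), label=label)


def generate_image(
    label: str, params: CohortParams, seed: int | np.random.Generator,
    height: int | None = None, width: int | None = None,
) -> np.ndarray:
    """Draw one H x W x 3 image in [0,1]: pinkish background with dark
    elliptical nucleus blobs.

    Malignant images get higher blob density and more eccentric blobs in
    proportion to ``image_signal``; with ``image_signal == 0`` the two class
    distributions coincide.
    """
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    side = params.image_side
    if side < 16:
        raise ValueError(f"image_side must be >= 16, got {side}")
    h = height or side
    w = width or side
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    malignant = label == "malignant"
    area_scale = (h * w) / (64.0 * 64.0)
    base_blobs = 9.0
    tilt = 0.35 * params.image_signal
    lam = base_blobs * (1.0 + tilt if malignant else 1.0 - min(tilt, 0.9)) * area_scale
    n_blobs = int(rng.poisson(lam))
    ecc_max = 0.15 + (0.45 * params.image_signal if malignant else 0.0)

    img = np.empty((h, w, 3))
    img[..., 0] = 0.91
    img[..., 1] = 0.72
    img[..., 2] = 0.83
    img += rng.normal(0.0, 0.02, size=(h, w, 1))  # background texture

    yy, xx = np.mgrid[0:h, 0:w]
    blob_color = np.array([0.38, 0.18, 0.48])
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r = rng.uniform(1.8, 3.6) * np.sqrt((h / 64.0) * (w / 64.0))
        ecc = rng.uniform(0.0, ecc_max)
        theta = rng.uniform(0.0, np.pi)
        a, b = r * (1.0 + ecc), r * (1.0 - ecc)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        d2 = (u / a) ** 2 + (v / b) ** 2
        inside = np.clip(1.0 - d2, 0.0, 1.0)[..., None]
        img = img * (1.0 - 0.9 * inside) + blob_color * 0.9 * inside

    img += rng.normal(0.0, params.pixel_noise, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_cohort(params: CohortParams, seed: int | None = None) -> Cohort:
    """Generate a full paired cohort: records, images and the pairing manifest."""
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    n_benign = round(params.benign_fraction * params.n_patients)
    labels = ["benign"] * n_benign + ["malignant"] * (params.n_patients - n_benign)

    records: list[StructuredRecord] = []
    images: list[np.ndarray] = []
    rows = []
    width = len(str(params.n_patients))
    lo, hi = params.images_per_patient
    for i, label in enumerate(labels):
        pid = f"P{i:0{width}d}"
        records.append(generate_record(label, params, rng, patient_id=pid))
        n_img = int(rng.integers(lo, hi + 1))
        for j in range(n_img):
            images.append(generate_image(label, params, rng))
            rows.append({"image_id": f"{pid}_img{j}", "patient_id": pid, "label": label})
    manifest = pd.DataFrame(rows, columns=["image_id", "patient_id", "label"])
    return Cohort(records=records, images=images, manifest=manifest, params=params)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write a cohort in the on-disk layout: cohort.csv, manifest.csv,
    images/<image_id>.png and params.json."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    write_cohort_table(cohort.records, out / "cohort.csv")
    cohort.manifest.to_csv(out / "manifest.csv", index=False)
    for img, image_id in zip(cohort.images, cohort.manifest["image_id"]):
        arr = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
        Image.fromarray(arr).save(out / "images" / f"{image_id}.png")
    (out / "params.json").write_text(json.dumps(dataclasses.asdict(cohort.params), indent=2))


def read_cohort_dir(path: str | Path) -> Cohort:
    """Read back a directory written by :func:`write_cohort`."""
    from .emr_schema import read_cohort_table

    path = Path(path)
    records = read_cohort_table(path / "cohort.csv")
    manifest = pd.read_csv(path / "manifest.csv", dtype={"patient_id": str})
    images = []
    for image_id in manifest["image_id"]:
        arr = np.asarray(Image.open(path / "images" / f"{image_id}.png"))
        images.append(arr.astype(np.float64) / 255.0)
    params_file = path / "params.json"
    if params_file.exists():
        d = json.loads(params_file.read_text())
        d["images_per_patient"] = tuple(d["images_per_patient"])
        params = CohortParams(**d)
    else:
        params = CohortParams()
    return Cohort(records=records, images=images, manifest=manifest, params=params)
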