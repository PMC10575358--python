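"""Box-consistent training-set augmentation: flip, brightness, noise.

The three augmentations the part detector is trained with:

* horizontal flip — mirrors the image and boxes; a mirrored left wing is
  visually a right wing, so the wing labels are swapped by default
  (``swap_wings_on_flip``),
* brightness — multiplicative gain with clipping to [0, 255],
* additive Gaussian pixel noise — i.i.d. per channel, clipped to [0, 255].

Images are uint8 ``(H, W, 3)`` arrays; annotations are
:class:`~birdparts.voc_io.PartAnnotation` lists in the same pixel frame.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .voc_io import PartAnnotation, PartType

_WING_SWAP = {PartType.leftwing: PartType.rightwing,
              PartType.rightwing: PartType.leftwing}


@dataclass
class AugmentConfig:
    brightness_factor: float = 1.5
    noise_sigma: float = 10.0     # pixel-intensity units on the 0..255 scale
    seed: int = 0
    swap_wings_on_flip: bool = True

    def __post_init__(self):
        if self.brightness_factor <= 0:
            raise ValueError("brightness_factor must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def hflip(image: np.ndarray, annotations: list,
          swap_wings: bool = True) -> tuple[np.ndarray, list]:
    """Mirror image and boxes about the vertical axis."""
    width = image.shape[1]
    flipped = image[:, ::-1].copy()
    out = []
    for a in annotations:
        xmin, ymin, xmax, ymax = a.box
        part = _WING_SWAP.get(a.part, a.part) if swap_wings else a.part
        out.append(replace(a, part=part,
                           box=(width - xmax, ymin, width - xmin, ymax)))
    return flipped, out


def adjust_brightness(image: np.ndarray, factor: float) -> np.ndarray:
    """Scale pixel intensities by `factor`, clipped to [0, 255]."""
    if factor <= 0:
        raise ValueError("brightness factor must be > 0")
    out = np.rint(image.astype(np.float32) * factor)
    return np.clip(out, 0, 255).astype(np.uint8)


def add_gaussian_noise(image: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Add N(0, sigma²) noise per pixel and channel; deterministic in seed."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    noisy = np.rint(image.astype(np.float32) + rng.normal(0.0, sigma, image.shape))
    return np.clip(noisy, 0, 255).astype(np.uint8)


def augment_dataset(manifest, out_dir, config: AugmentConfig):
    """Offline augmentation: write the three copies of every training image.

    Produces ``<out_dir>/images/<id>_<tag>.png`` and matching VOC XML under
    ``<out_dir>/Annotations/``, and returns a manifest covering the originals
    plus the augmented copies.  Noise seeds derive from ``config.seed`` and
    the example index, so the run is deterministic.
    """
    from dataclasses import replace as dc_replace
    from pathlib import Path

    from PIL import Image

    from .voc_io import DatasetManifest, read_voc_xml, write_voc_xml

    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    ann_dir = out_dir / "Annotations"
    img_dir.mkdir(parents=True, exist_ok=True)
    ann_dir.mkdir(parents=True, exist_ok=True)
    entries = list(manifest.entries)
    for i, (img_path, ann_path) in enumerate(manifest.entries):
        image = np.asarray(Image.open(img_path).convert("RGB"))
        annotations = read_voc_xml(ann_path)
        cfg_i = replace(config, seed=config.seed + i)
        for tag, aug_img, aug_anns in augment_example(image, annotations, cfg_i):
            stem = f"{Path(img_path).stem}_{tag}"
            aug_anns = [dc_replace(a, image_id=stem) for a in aug_anns]
            ip = img_dir / f"{stem}.png"
            ap = ann_dir / f"{stem}.xml"
            Image.fromarray(aug_img).save(ip)
            h, w = aug_img.shape[:2]
            write_voc_xml(aug_anns, (w, h, 3), ap, image_filename=ip.name)
            entries.append((str(ip), str(ap)))
    return DatasetManifest(entries=entries, split=manifest.split,
                           class_names=manifest.class_names)


def augment_example(image: np.ndarray, annotations: list,
                    config: AugmentConfig) -> list:
    """Produce the three augmented copies of one training example.

    Returns a list of (tag, image, annotations) triples — one copy per
    transform, mirroring the multiplicity used for the training split.
    """
    flipped_img, flipped_ann = hflip(image, annotations,
                                     swap_wings=config.swap_wings_on_flip)
    bright = adjust_brightness(image, config.brightness_factor)
    noisy = add_gaussian_noise(image, config.noise_sigma, config.seed)
    return [("hflip", flipped_img, flipped_ann),
            ("bright", bright, list(annotations)),
            ("noise", noisy, list(annotations))]
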