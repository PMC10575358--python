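"""Synthetic desk-scale fixtures with the structure the method assumes.

Two generators:

* :func:`generate_scenes` draws schematic "birds" on small canvases: each
  bird is up to four part glyphs (head = disc, left wing = left-pointing
  triangle, right wing = right-pointing triangle, tail = square) whose colour
  encodes the species — a colour × shape product code, so distinct species
  are separable by construction and a tiny detector can learn the task on a
  CPU.  Boxes are tight around glyphs and written as VOC XML.

* :func:`generate_detection_table` emits part tables with planted per-part
  informativeness: each part record is correct with probability ``p_part``
  (otherwise a uniformly wrong species) and carries a confidence drawn from
  Beta(8, 2) when correct and Beta(2, 4) when incorrect, making confidence
  informative the way the fusion step implicitly assumes.

Everything is deterministic given the spec seed.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .detector import DetectionRecord
from .part_table import PartRecord, PartTable, write_truth_csv
from .voc_io import (DatasetManifest, PartAnnotation, PartType, class_names,
                     encode_class, write_voc_xml)


def species_palette(n_species: int) -> np.ndarray:
    """n distinct saturated RGB colours (uint8), one per species."""
    cols = []
    for i in range(n_species):
        r, g, b = colorsys.hsv_to_rgb(i / n_species, 0.85, 0.95)
        cols.append((int(r * 255), int(g * 255), int(b * 255)))
    return np.asarray(cols, dtype=np.uint8)


@dataclass
class SceneSpec:
    canvas_size: int = 160
    n_species: int = 8
    parts: tuple = tuple(PartType)
    glyph_size: tuple = (28, 44)        # min/max glyph extent in pixels
    occlusion_probability: float = 0.1  # chance a part is absent from a scene
    clutter: int = 3                    # achromatic distractor blobs per scene
    background: int = 190
    noise_sigma: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if not 0 <= self.occlusion_probability <= 1:
            raise ValueError("occlusion_probability must be in [0, 1]")
        # four quadrants with margins must hold the largest glyph
        if self.canvas_size // 2 - 8 < self.glyph_size[1]:
            raise ValueError(f"canvas {self.canvas_size} too small for glyphs "
                             f"up to {self.glyph_size[1]}")


_QUADRANT = {PartType.head: (0, 0), PartType.leftwing: (0, 1),
             PartType.rightwing: (1, 1), PartType.tail: (1, 0)}


def _draw_glyph(canvas: np.ndarray, part: PartType, box: tuple, color):
    x0, y0, x1, y1 = box
    h, w = y1 - y0, x1 - x0
    yy, xx = np.mgrid[y0:y1, x0:x1]
    cy, cx = (y0 + y1 - 1) / 2, (x0 + x1 - 1) / 2
    if part is PartType.head:
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= (min(h, w) / 2) ** 2
    elif part is PartType.leftwing:   # apex on the left edge
        mask = np.abs(yy - cy) <= (xx - x0) / max(w - 1, 1) * (h / 2)
    elif part is PartType.rightwing:  # apex on the right edge
        mask = np.abs(yy - cy) <= (x1 - 1 - xx) / max(w - 1, 1) * (h / 2)
    else:                             # tail: filled square
        mask = np.ones((h, w), dtype=bool)
    canvas[y0:y1, x0:x1][mask] = color


def render_scene(spec: SceneSpec, species_id: int,
                 rng: np.random.Generator, image_id: str):
    """One bird on one canvas; returns (uint8 image, annotations)."""
    s = spec.canvas_size
    palette = species_palette(spec.n_species)
    img = np.full((s, s, 3), spec.background, dtype=np.float32)
    if spec.noise_sigma > 0:
        img += rng.normal(0, spec.noise_sigma, img.shape)
    for _ in range(spec.clutter):
        shade = rng.integers(140, 230)
        bw, bh = rng.integers(10, 30, size=2)
        bx = rng.integers(0, s - bw)
        by = rng.integers(0, s - bh)
        img[by:by + bh, bx:bx + bw] = shade
    img = np.clip(img, 0, 255).astype(np.uint8)
    annotations = []
    half = s // 2
    for part in spec.parts:
        if rng.random() < spec.occlusion_probability:
            continue
        g = int(rng.integers(spec.glyph_size[0], spec.glyph_size[1] + 1))
        qx, qy = _QUADRANT[part]
        margin = 4
        x0 = qx * half + margin + int(rng.integers(0, half - g - 2 * margin + 1))
        y0 = qy * half + margin + int(rng.integers(0, half - g - 2 * margin + 1))
        box = (x0, y0, x0 + g, y0 + g)
        _draw_glyph(img, part, box, palette[species_id - 1])
        annotations.append(PartAnnotation(image_id=image_id, part=part,
                                          species_id=species_id,
                                          box=tuple(float(v) for v in box)))
    if not annotations:  # guarantee at least one part per scene
        part = spec.parts[int(rng.integers(len(spec.parts)))]
        g = spec.glyph_size[0]
        qx, qy = _QUADRANT[part]
        x0, y0 = qx * half + 8, qy * half + 8
        box = (x0, y0, x0 + g, y0 + g)
        _draw_glyph(img, part, box, palette[species_id - 1])
        annotations.append(PartAnnotation(image_id=image_id, part=part,
                                          species_id=species_id,
                                          box=tuple(float(v) for v in box)))
    return img, annotations


def generate_scenes(spec: SceneSpec, n_images: int, out_dir,
                    split: str = "train"):
    """Write scenes + VOC XML + manifest + truth CSV; returns (manifest, truth).

    Layout: ``<out_dir>/images/*.png``, ``<out_dir>/Annotations/*.xml``,
    ``<out_dir>/manifest_<split>.txt``, ``<out_dir>/truth_<split>.csv``.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    ann_dir = out_dir / "Annotations"
    img_dir.mkdir(parents=True, exist_ok=True)
    ann_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    entries, truth = [], {}
    for i in range(n_images):
        image_id = f"{split}_{i:04d}"
        species_id = int(rng.integers(1, spec.n_species + 1))
        img, anns = render_scene(spec, species_id, rng, image_id)
        img_path = img_dir / f"{image_id}.png"
        ann_path = ann_dir / f"{image_id}.xml"
        Image.fromarray(img).save(img_path)
        write_voc_xml(anns, (spec.canvas_size, spec.canvas_size, 3), ann_path,
                      image_filename=img_path.name)
        entries.append((str(img_path), str(ann_path)))
        truth[image_id] = species_id
    manifest = DatasetManifest(entries=entries, split=split,
                               class_names=class_names(spec.n_species))
    manifest.save(out_dir / f"manifest_{split}.txt")
    write_truth_csv(truth, out_dir / f"truth_{split}.csv")
    return manifest, truth


def nearest_color_species(pixel_mean: np.ndarray, palette: np.ndarray) -> int:
    """Species id whose palette colour is nearest in RGB (1-based)."""
    d = ((palette.astype(np.float64) - pixel_mean) ** 2).sum(axis=1)
    return int(np.argmin(d)) + 1


@dataclass
class TableSpec:
    """Planted-structure detection tables for the fusion stage."""

    n_images: int = 1000
    n_species: int = 200
    p_part: tuple = (0.95, 0.5, 0.5, 0.3)   # per-part correctness probability
    dropout: float = 0.1                    # chance a part record is missing
    conf_correct: tuple = (8.0, 2.0)        # Beta parameters, correct records
    conf_incorrect: tuple = (2.0, 4.0)      # Beta parameters, wrong records
    seed: int = 0

    def __post_init__(self):
        if not all(0 <= p <= 1 for p in self.p_part) or len(self.p_part) != 4:
            raise ValueError("p_part must be four probabilities")
        if not 0 <= self.dropout <= 1:
            raise ValueError("dropout must be in [0, 1]")


def generate_detection_table(spec: TableSpec,
                             truth: dict | None = None) -> PartTable:
    """Part table with planted per-part informativeness and ground truth."""
    rng = np.random.default_rng(spec.seed)
    if truth is None:
        truth = {f"img_{i:04d}": int(rng.integers(1, spec.n_species + 1))
                 for i in range(spec.n_images)}
    records: dict = {}
    for image_id in sorted(truth):
        true_sp = truth[image_id]
        recs = []
        for part in PartType:
            if rng.random() < spec.dropout:
                continue
            correct = rng.random() < spec.p_part[part.ordinal]
            if correct:
                species = true_sp
                conf = rng.beta(*spec.conf_correct)
            else:
                species = int(rng.integers(1, spec.n_species))
                if species >= true_sp:
                    species += 1
                conf = rng.beta(*spec.conf_incorrect)
            recs.append(PartRecord(image_id=image_id, part=part,
                                   species_id=species, confidence=float(conf)))
        records[image_id] = recs
    return PartTable(records=records, true_species=dict(truth))


def generate_detection_dump(n_images: int = 100, per_part: int = 3,
                            n_species: int = 8, canvas: int = 160,
                            seed: int = 0):
    """Raw multi-detection dump (several boxes per part per image).

    Emulates the detector's output before the per-part reduction: every part
    of every image gets `per_part` detections with random confidences and
    jittered boxes.  Returns (detections, truth).
    """
    rng = np.random.default_rng(seed)
    detections, truth = [], {}
    for i in range(n_images):
        image_id = f"img_{i:04d}"
        true_sp = int(rng.integers(1, n_species + 1))
        truth[image_id] = true_sp
        for part in PartType:
            for _ in range(per_part):
                species = true_sp if rng.random() < 0.8 else \
                    int(rng.integers(1, n_species + 1))
                x0 = float(rng.uniform(0, canvas - 40))
                y0 = float(rng.uniform(0, canvas - 40))
                w, h = rng.uniform(20, 40, size=2)
                detections.append(DetectionRecord(
                    image_id=image_id,
                    box=(x0, y0, x0 + float(w), y0 + float(h)),
                    confidence=float(rng.uniform(0.05, 0.99)),
                    class_id=encode_class(species, part)))
    return detections, truth
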