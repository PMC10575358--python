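"""PASCAL VOC XML part annotations and the species×part class encoding.

Each bird is annotated with up to four parts — head, leftwing, rightwing,
tail — and every (species, part) pair is its own detection class: 200 species
× 4 parts = 800 classes.  Class ids are species-major:
``class_id = (species_id − 1) * 4 + part.ordinal``, so the species is
recoverable by integer division by 4.

Coordinate conventions: VOC files on disk store 1-based inclusive pixel
coordinates; in memory all boxes are 0-based half-open ``(xmin, ymin, xmax,
ymax)`` with ``xmin < xmax`` and ``ymin < ymax``.  Object names use the
dialect ``"<species_id:03d>_<part>"``, e.g. ``"017_leftwing"``.
"""

from __future__ import annotations

import enum
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

N_SPECIES = 200
N_PARTS = 4
N_CLASSES = N_SPECIES * N_PARTS


class PartType(enum.IntEnum):
    """The four annotated bird parts; ordinal order is fixed package-wide."""

    head = 0
    leftwing = 1
    rightwing = 2
    tail = 3

    @property
    def ordinal(self) -> int:
        return int(self)

    @classmethod
    def from_token(cls, token: str) -> "PartType":
        try:
            return cls[token]
        except KeyError:
            raise ValueError(f"unknown part token {token!r}; "
                             f"expected one of {[p.name for p in cls]}") from None


def encode_class(species_id: int, part: PartType) -> int:
    """Map (species, part) to the flat class id, species-major."""
    if not 1 <= species_id <= N_SPECIES:
        raise ValueError(f"species_id must be in 1..{N_SPECIES}, got {species_id}")
    return (species_id - 1) * N_PARTS + PartType(part).ordinal


def decode_class(class_id: int) -> tuple[int, PartType]:
    """Inverse of :func:`encode_class`."""
    if not 0 <= class_id < N_CLASSES:
        raise ValueError(f"class_id must be in 0..{N_CLASSES - 1}, got {class_id}")
    return class_id // N_PARTS + 1, PartType(class_id % N_PARTS)


def class_names(n_species: int = N_SPECIES) -> list[str]:
    """The flat class-name list in class-id order."""
    return [f"{s:03d}_{p.name}" for s in range(1, n_species + 1) for p in PartType]


@dataclass(frozen=True)
class PartAnnotation:
    """One labelled part box (0-based half-open pixel coordinates)."""

    image_id: str
    part: PartType
    species_id: int
    box: tuple  # (xmin, ymin, xmax, ymax)

    def __post_init__(self):
        xmin, ymin, xmax, ymax = self.box
        if not (xmin < xmax and ymin < ymax):
            raise ValueError(f"degenerate box {self.box} on {self.image_id}")
        if not 1 <= self.species_id <= N_SPECIES:
            raise ValueError(f"species_id {self.species_id} out of range")

    @property
    def class_id(self) -> int:
        return encode_class(self.species_id, self.part)

    @property
    def object_name(self) -> str:
        return f"{self.species_id:03d}_{self.part.name}"


@dataclass
class DatasetManifest:
    """Image/annotation path pairs for one split, with the class-name table."""

    entries: list  # of (image_path, annotation_path)
    split: str = "train"
    class_names: list = field(default_factory=class_names)

    def __post_init__(self):
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("class_names contains duplicates")

    def __len__(self):
        return len(self.entries)

    def save(self, path):
        with open(path, "w") as fh:
            for img, ann in self.entries:
                fh.write(f"{img}\t{ann}\n")

    @classmethod
    def load(cls, path, split="train", names=None):
        entries = []
        for line in Path(path).read_text().splitlines():
            if line.strip():
                img, ann = line.split("\t")
                entries.append((img, ann))
        return cls(entries=entries, split=split,
                   class_names=names or class_names())


def _parse_object_name(name: str) -> tuple[int, PartType]:
    try:
        species_str, part_token = name.split("_", 1)
        species_id = int(species_str)
    except ValueError:
        raise ValueError(f"object name {name!r} is not '<species:03d>_<part>'") from None
    return species_id, PartType.from_token(part_token)


def read_voc_xml(path) -> list[PartAnnotation]:
    """Parse one VOC annotation file into part annotations.

    VOC 1-based inclusive boxes become 0-based half-open:
    ``(xmin−1, ymin−1, xmax, ymax)``.
    """
    path = Path(path)
    try:
        root = ET.parse(str(path)).getroot()
    except ET.ParseError as exc:
        raise ValueError(f"malformed VOC XML in {path}: {exc}") from exc
    image_id = path.stem
    fn = root.findtext("filename")
    if fn:
        image_id = Path(fn).stem
    annotations = []
    for obj in root.iter("object"):
        species_id, part = _parse_object_name(obj.findtext("name", ""))
        bb = obj.find("bndbox")
        xmin = float(bb.findtext("xmin")) - 1
        ymin = float(bb.findtext("ymin")) - 1
        xmax = float(bb.findtext("xmax"))
        ymax = float(bb.findtext("ymax"))
        annotations.append(PartAnnotation(image_id=image_id, part=part,
                                          species_id=species_id,
                                          box=(xmin, ymin, xmax, ymax)))
    return annotations


def write_voc_xml(annotations: list, image_meta: tuple, path,
                  image_filename: str | None = None) -> None:
    """Write annotations to VOC XML (coordinates back to 1-based inclusive)."""
    width, height, depth = image_meta
    for a in annotations:
        xmin, ymin, xmax, ymax = a.box
        if xmin < 0 or ymin < 0 or xmax > width or ymax > height:
            raise ValueError(f"box {a.box} outside image {width}x{height}")
    path = Path(path)
    root = ET.Element("annotation")
    if image_filename is None and annotations:
        image_filename = annotations[0].image_id + ".png"
    ET.SubElement(root, "filename").text = image_filename or path.stem + ".png"
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(int(width))
    ET.SubElement(size, "height").text = str(int(height))
    ET.SubElement(size, "depth").text = str(int(depth))
    for a in annotations:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = a.object_name
        ET.SubElement(obj, "difficult").text = "0"
        bb = ET.SubElement(obj, "bndbox")
        xmin, ymin, xmax, ymax = a.box
        ET.SubElement(bb, "xmin").text = str(int(round(xmin)) + 1)
        ET.SubElement(bb, "ymin").text = str(int(round(ymin)) + 1)
        ET.SubElement(bb, "xmax").text = str(int(round(xmax)))
        ET.SubElement(bb, "ymax").text = str(int(round(ymax)))
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(str(path), encoding="unicode")
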