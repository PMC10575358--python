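"""Per-image part tables: one best detection per part type.

The classification stage consumes, for every image, at most one record per
part — the highest-confidence detection of that part type — so each image
contributes up to four (part, species, confidence) triples.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

from .voc_io import PartType, decode_class


@dataclass(frozen=True)
class PartRecord:
    image_id: str
    part: PartType
    species_id: int
    confidence: float


@dataclass
class PartTable:
    """image_id → up to four :class:`PartRecord`; optional ground truth."""

    records: dict  # image_id -> list[PartRecord]
    true_species: dict | None = None  # image_id -> species_id

    def __len__(self):
        return len(self.records)

    def image_ids(self):
        return sorted(self.records)

    def max_records_per_image(self) -> int:
        return max((len(v) for v in self.records.values()), default=0)


def _box_area(box) -> float:
    xmin, ymin, xmax, ymax = box
    return max(xmax - xmin, 0.0) * max(ymax - ymin, 0.0)


def select_best_per_part(detections: list, truth: dict | None = None) -> PartTable:
    """Keep exactly the maximum-confidence detection per (image, part).

    Ties on confidence resolve deterministically to the lower class_id, then
    the smaller box area, so the result is independent of input order.
    """
    best: dict = {}  # (image_id, part) -> DetectionRecord
    for det in detections:
        part = decode_class(det.class_id)[1]
        key = (det.image_id, part)
        cur = best.get(key)
        if cur is None or _beats(det, cur):
            best[key] = det
    records: dict = {}
    for (image_id, part), det in best.items():
        species_id = decode_class(det.class_id)[0]
        records.setdefault(image_id, []).append(
            PartRecord(image_id=image_id, part=part,
                       species_id=species_id, confidence=float(det.confidence)))
    for recs in records.values():
        recs.sort(key=lambda r: r.part.ordinal)
    return PartTable(records=records, true_species=dict(truth) if truth else None)


def _beats(a, b) -> bool:
    ka = (-a.confidence, a.class_id, _box_area(a.box))
    kb = (-b.confidence, b.class_id, _box_area(b.box))
    return ka < kb


def write_part_table_csv(table: PartTable, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "part", "species_id", "confidence"])
        for image_id in table.image_ids():
            for r in table.records[image_id]:
                writer.writerow([image_id, r.part.name, r.species_id,
                                 f"{r.confidence:.6f}"])


def read_part_table_csv(path, truth: dict | None = None) -> PartTable:
    records: dict = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rec = PartRecord(image_id=row["image_id"],
                             part=PartType.from_token(row["part"]),
                             species_id=int(row["species_id"]),
                             confidence=float(row["confidence"]))
            records.setdefault(rec.image_id, []).append(rec)
    return PartTable(records=records, true_species=truth)


def read_truth_csv(path) -> dict:
    truth = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            truth[row["image_id"]] = int(row["species_id"])
    return truth


def write_truth_csv(truth: dict, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "species_id"])
        for image_id in sorted(truth):
            writer.writerow([image_id, truth[image_id]])
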