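"""The improved part detector: backbone + FPN/PAN neck + anchor head.

The layer graph follows the published network table exactly: a CSP backbone
(Conv/C3) with a Res2Net-CBAM unit after every backbone C3 stage and SPPF at
the end; a top-down (FPN) plus bottom-up (PAN) neck whose three output scales
each pass through a CBAM block; and an anchor-based Detect head over layers
(22, 26, 30) predicting, per anchor, 4 box offsets + objectness + one score
per class (805 channels for the 800 part×species classes).

Width/depth multipliers shrink the graph for desk-scale training: channel
counts scale to the nearest multiple of 8 (minimum 8) and C3 repeat counts
scale with rounding (minimum 1).  The full-multiplier graph reproduces the
published shape table for a 640×640×3 input.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image

from . import nn
from .attention_blocks import CBAM, Res2NetCBAM
from .autodiff import Adam, Tensor, no_grad, _sigmoid
from .metrics import box_iou
from .voc_io import decode_class, read_voc_xml

logger = logging.getLogger(__name__)

# Published layer table at full multipliers:
# (from, repeats, kind, args); Conv args (c1, c2, k, s[, p]), C3 (c1, c2[, shortcut]).
# The row-7 Conv prints no kernel/stride; (3, 2) follows from its shape halving.
# The row-25 C3 prints (320, 320, False) but its concat input is 640 channels;
# channel consistency (640, 640, False) is used instead.
LAYER_TABLE = [
    (-1, 1, "Conv", (3, 80, 6, 2, 2)),        # 0  P1/2
    (-1, 1, "Conv", (80, 160, 3, 2)),         # 1  P2/4
    (-1, 4, "C3", (160, 160)),                # 2
    (-1, 1, "Res2NetCBAM", (160, 160)),       # 3
    (-1, 1, "Conv", (160, 320, 3, 2)),        # 4  P3/8
    (-1, 8, "C3", (320, 320)),                # 5
    (-1, 1, "Res2NetCBAM", (320, 320)),       # 6
    (-1, 1, "Conv", (320, 640, 3, 2)),        # 7  P4/16
    (-1, 12, "C3", (640, 640)),               # 8
    (-1, 1, "Res2NetCBAM", (640, 640)),       # 9
    (-1, 1, "Conv", (640, 1280, 3, 2)),       # 10 P5/32
    (-1, 4, "C3", (1280, 1280)),              # 11
    (-1, 1, "Res2NetCBAM", (1280, 1280)),     # 12
    (-1, 1, "SPPF", (1280, 1280, 5)),         # 13
    (-1, 1, "Conv", (1280, 640, 1, 1)),       # 14
    (-1, 1, "Upsample", (2,)),                # 15
    ((-1, 9), 1, "Concat", (1,)),             # 16
    (-1, 4, "C3", (1280, 640, False)),        # 17
    (-1, 1, "Conv", (640, 320, 1, 1)),        # 18
    (-1, 1, "Upsample", (2,)),                # 19
    ((-1, 6), 1, "Concat", (1,)),             # 20
    (-1, 4, "C3", (640, 320, False)),         # 21
    (-1, 1, "CBAM", (320,)),                  # 22 -> P3 out
    (-1, 1, "Conv", (320, 320, 3, 2)),        # 23
    ((-1, 18), 1, "Concat", (1,)),            # 24
    (-1, 4, "C3", (640, 640, False)),         # 25
    (-1, 1, "CBAM", (640,)),                  # 26 -> P4 out
    (-1, 1, "Conv", (640, 640, 3, 2)),        # 27
    ((-1, 14), 1, "Concat", (1,)),            # 28
    (-1, 4, "C3", (1280, 1280, False)),       # 29
    (-1, 1, "CBAM", (1280,)),                 # 30 -> P5 out
    ((22, 26, 30), 1, "Detect", ()),          # 31
]

DEFAULT_ANCHORS = ((10, 13, 16, 30, 33, 23),
                   (30, 61, 62, 45, 59, 119),
                   (116, 90, 156, 198, 373, 326))

SPPF_INDEX = 13
DETECT_SOURCES = (22, 26, 30)


@dataclass
class NetworkConfig:
    num_classes: int = 800
    width_multiple: float = 1.0
    depth_multiple: float = 1.0
    input_size: int = 640
    anchors: tuple = DEFAULT_ANCHORS
    res2net_scale: int = 4
    reduction_ratio: int = 16
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.width_multiple <= 1 or not 0 < self.depth_multiple <= 1:
            raise ValueError("multipliers must be in (0, 1]")
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")

    def to_dict(self):
        d = asdict(self)
        d["anchors"] = [list(a) for a in self.anchors]
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d["anchors"] = tuple(tuple(a) for a in d["anchors"])
        return cls(**d)


def _round8(c: float) -> int:
    return max(int(round(c / 8)) * 8, 8)


@dataclass(frozen=True)
class DetectionRecord:
    """One decoded detection in image pixel coordinates."""

    image_id: str
    box: tuple
    confidence: float
    class_id: int

    @property
    def species_id(self) -> int:
        return decode_class(self.class_id)[0]

    @property
    def part(self):
        return decode_class(self.class_id)[1]


class Network(nn.Module):
    """Layer graph built from :data:`LAYER_TABLE` under a config."""

    def __init__(self, config: NetworkConfig):
        super().__init__()
        self.config = config
        wm, dm = config.width_multiple, config.depth_multiple
        layers, ch = [], []
        for idx, (frm, n, kind, args) in enumerate(LAYER_TABLE):
            n_eff = max(round(n * dm), 1) if n > 1 else n
            if kind == "Conv":
                c1d, c2, k, s = args[0], args[1], args[2], args[3]
                p = args[4] if len(args) > 4 else None
                c1 = 3 if idx == 0 else ch[frm]
                if idx > 0 and c1 != _round8(c1d * wm):
                    raise ValueError(f"layer {idx}: declared in-channels {c1d} "
                                     f"inconsistent with graph ({c1})")
                c2 = _round8(c2 * wm)
                mod = nn.Conv(c1, c2, k, s, p)
            elif kind == "C3":
                c1, c2 = ch[frm], _round8(args[1] * wm)
                if c1 != _round8(args[0] * wm):
                    raise ValueError(f"layer {idx}: C3 in-channel mismatch "
                                     f"({_round8(args[0] * wm)} vs {c1})")
                shortcut = args[2] if len(args) > 2 else True
                mod = nn.C3(c1, c2, n_eff, shortcut)
            elif kind == "Res2NetCBAM":
                c1 = ch[frm]
                scale = config.res2net_scale
                if c1 % scale:
                    raise ValueError(f"layer {idx}: channels {c1} not divisible "
                                     f"by res2net scale {scale}")
                mod = Res2NetCBAM(c1, c1, scale, config.reduction_ratio)
                c2 = c1
            elif kind == "SPPF":
                c1, c2 = ch[frm], _round8(args[1] * wm)
                mod = nn.SPPF(c1, c2, args[2])
            elif kind == "Upsample":
                mod = nn.Upsample(args[0])
                c2 = ch[frm]
            elif kind == "Concat":
                c2 = sum(ch[f] for f in frm)
                mod = nn.Concat(args[0])
            elif kind == "CBAM":
                c1 = ch[frm]
                mod = CBAM(c1, config.reduction_ratio)
                c2 = c1
            elif kind == "Detect":
                chs = [ch[f] for f in frm]
                mod = nn.Detect(config.num_classes, config.anchors, chs)
                c2 = (config.num_classes + 5) * 3
            else:
                raise ValueError(f"unknown module kind {kind}")
            layers.append((frm, kind, mod))
            ch.append(c2)
        self.out_channels = ch
        self.layers = nn.ModuleList([m for _, _, m in layers])
        self.froms = [frm for frm, _, _ in layers]
        self.kinds = [kind for _, kind, _ in layers]
        # layers whose outputs are consumed later than the next layer
        save = set()
        for frm in self.froms:
            if isinstance(frm, tuple):
                save.update(f for f in frm if f != -1)
        self.save = save
        self.strides = np.array([8, 16, 32], dtype=np.float64)
        self.anchors = np.asarray(config.anchors, dtype=np.float64).reshape(3, 3, 2)

    def forward(self, x, record: list | None = None):
        """Run the graph; `x` is (N, 3, H, W) in [0, 1].

        When `record` is a list, (index, kind, output shape) triples are
        appended for every layer — the hook used by the shape audit.
        """
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError("input height/width must be divisible by 32")
        saved: dict[int, Tensor] = {}
        out = x
        for idx, (frm, mod) in enumerate(zip(self.froms, self.layers)):
            if isinstance(frm, tuple):
                inputs = [out if f == -1 else saved[f] for f in frm]
                out = mod(inputs)
            else:
                out = mod(out if frm == -1 else saved[frm])
            if idx in self.save:
                saved[idx] = out
            if record is not None:
                shape = ([tuple(t.shape) for t in out] if isinstance(out, list)
                         else tuple(out.shape))
                record.append((idx, self.kinds[idx], shape))
        return out  # list of 3 raw grids (N, na, H, W, nc+5)


def build_network(config: NetworkConfig) -> Network:
    """Construct the detector with seeded weight initialisation."""
    nn.set_init_rng(np.random.default_rng(config.seed))
    net = Network(config)
    n_params = sum(p.data.size for p in net.parameters())
    logger.info("built network: %d layers, %.2fM parameters",
                len(net.layers), n_params / 1e6)
    return net


def forward_eval(net: Network, images: np.ndarray,
                 record: list | None = None) -> list:
    """Deterministic evaluation-mode forward pass; returns numpy grids."""
    net.eval()
    with no_grad():
        out = net(images, record=record)
    return [t.data for t in out]


# ---------------------------------------------------------------------------
# Decoding and non-maximum suppression
# ---------------------------------------------------------------------------

def decode_predictions(raw: list, anchors, strides, conf_threshold: float = 0.25,
                       image_ids: list | None = None,
                       image_size: int | None = None) -> list:
    """Map raw grids to image-space detection records.

    Per cell and anchor: ``xy = (2σ(t_xy) − 0.5 + cell) · stride`` and
    ``wh = (2σ(t_wh))² · anchor``; confidence is σ(objectness) times the best
    sigmoid class score; records below `conf_threshold` are dropped.
    """
    anchors = np.asarray(anchors, dtype=np.float64).reshape(len(raw), -1, 2)
    records = []
    n_images = raw[0].shape[0]
    if image_ids is None:
        image_ids = [str(i) for i in range(n_images)]
    for scale, (grid, stride) in enumerate(zip(raw, strides)):
        N, na, H, W, no = grid.shape
        sig = _sigmoid(np.asarray(grid, dtype=np.float64))
        gy, gx = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
        cx = (sig[..., 0] * 2 - 0.5 + gx) * stride
        cy = (sig[..., 1] * 2 - 0.5 + gy) * stride
        pw = (sig[..., 2] * 2) ** 2 * anchors[scale, :, 0].reshape(1, na, 1, 1)
        ph = (sig[..., 3] * 2) ** 2 * anchors[scale, :, 1].reshape(1, na, 1, 1)
        obj = sig[..., 4]
        cls_best = sig[..., 5:].argmax(axis=-1)
        conf = obj * np.take_along_axis(sig[..., 5:], cls_best[..., None],
                                        axis=-1)[..., 0]
        keep = np.argwhere(conf >= conf_threshold)
        for b, a, j, i in keep:
            x1 = cx[b, a, j, i] - pw[b, a, j, i] / 2
            y1 = cy[b, a, j, i] - ph[b, a, j, i] / 2
            x2 = x1 + pw[b, a, j, i]
            y2 = y1 + ph[b, a, j, i]
            if image_size is not None:
                x1, y1 = max(x1, 0.0), max(y1, 0.0)
                x2, y2 = min(x2, image_size), min(y2, image_size)
            if x2 <= x1 or y2 <= y1:
                continue
            records.append(DetectionRecord(
                image_id=image_ids[b], box=(x1, y1, x2, y2),
                confidence=float(conf[b, a, j, i]),
                class_id=int(cls_best[b, a, j, i])))
    return records


def nms(records: list, iou_threshold: float = 0.45) -> list:
    """Greedy per-class, per-image suppression by descending confidence."""
    if not 0 < iou_threshold < 1:
        raise ValueError("iou_threshold must be in (0, 1)")
    groups: dict = {}
    for r in records:
        groups.setdefault((r.image_id, r.class_id), []).append(r)
    kept = []
    for group in groups.values():
        group = sorted(group, key=lambda r: (-r.confidence, r.box))
        chosen: list = []
        for r in group:
            if all(box_iou(r.box, k.box) < iou_threshold for k in chosen):
                chosen.append(r)
        kept.extend(chosen)
    kept.sort(key=lambda r: (r.image_id, -r.confidence, r.class_id))
    return kept


def detect_images(net: Network, images: np.ndarray, image_ids: list,
                  conf_threshold: float = 0.25, iou_threshold: float = 0.45,
                  batch_size: int = 16) -> list:
    """Forward + decode + NMS over a stack of (N, 3, H, W) images in [0,1]."""
    records = []
    size = images.shape[2]
    for lo in range(0, images.shape[0], batch_size):
        chunk = images[lo:lo + batch_size]
        raw = forward_eval(net, chunk)
        records.extend(decode_predictions(
            raw, net.anchors, net.strides, conf_threshold,
            image_ids=image_ids[lo:lo + batch_size], image_size=size))
    return nms(records, iou_threshold)


def write_detections_csv(records: list, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "class_id", "species_id", "part",
                         "confidence", "xmin", "ymin", "xmax", "ymax"])
        for r in records:
            writer.writerow([r.image_id, r.class_id, r.species_id, r.part.name,
                             f"{r.confidence:.6f}"]
                            + [f"{v:.2f}" for v in r.box])


def read_detections_csv(path) -> list:
    import csv

    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(DetectionRecord(
                image_id=row["image_id"], class_id=int(row["class_id"]),
                confidence=float(row["confidence"]),
                box=(float(row["xmin"]), float(row["ymin"]),
                     float(row["xmax"]), float(row["ymax"]))))
    return records


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class Hyperparams:
    epochs: int = 50
    batch_size: int = 8
    lr: float = 0.01
    final_lr_fraction: float = 0.1   # cosine-decayed floor
    warmup_epochs: int = 3
    seed: int = 0
    box_weight: float = 0.05
    obj_weight: float = 1.0
    cls_weight: float = 2.0
    anchor_match_threshold: float = 4.0
    obj_balance: tuple = (4.0, 1.0, 0.4)

    def lr_at(self, epoch: int) -> float:
        """Linear warmup then cosine decay to `final_lr_fraction` of peak."""
        if epoch < self.warmup_epochs:
            return self.lr * (epoch + 1) / self.warmup_epochs
        span = max(self.epochs - self.warmup_epochs, 1)
        t = (epoch - self.warmup_epochs) / span
        lo = self.lr * self.final_lr_fraction
        return lo + 0.5 * (self.lr - lo) * (1 + np.cos(np.pi * t))


def load_dataset(manifest, input_size: int):
    """Load images (N, 3, S, S) float32 in [0, 1] and target rows.

    Targets: (image_index, class_id, cx, cy, w, h) in input pixels.  Images
    are letterboxed (aspect-preserving pad with mid-gray) when not already at
    the input size.
    """
    images, targets, image_ids = [], [], []
    for i, (img_path, ann_path) in enumerate(manifest.entries):
        arr = np.asarray(Image.open(img_path).convert("RGB"))
        anns = read_voc_xml(ann_path)
        arr, boxes = letterbox(arr, [a.box for a in anns], input_size)
        images.append(arr.transpose(2, 0, 1).astype(np.float32) / 255.0)
        image_ids.append(Path(img_path).stem)
        for a, box in zip(anns, boxes):
            x1, y1, x2, y2 = box
            targets.append((i, a.class_id, (x1 + x2) / 2, (y1 + y2) / 2,
                            x2 - x1, y2 - y1))
    return (np.stack(images),
            np.asarray(targets, dtype=np.float64).reshape(-1, 6),
            image_ids)


def letterbox(image: np.ndarray, boxes: list, size: int):
    """Resize with preserved aspect ratio onto a size×size mid-gray canvas."""
    h, w = image.shape[:2]
    if h == size and w == size:
        return image, list(boxes)
    scale = min(size / h, size / w)
    nh, nw = int(round(h * scale)), int(round(w * scale))
    resized = np.asarray(Image.fromarray(image).resize((nw, nh), Image.BILINEAR))
    top, left = (size - nh) // 2, (size - nw) // 2
    canvas = np.full((size, size, 3), 114, dtype=image.dtype)
    canvas[top:top + nh, left:left + nw] = resized
    out_boxes = [(x1 * scale + left, y1 * scale + top,
                  x2 * scale + left, y2 * scale + top)
                 for x1, y1, x2, y2 in boxes]
    return canvas, out_boxes


def build_targets(targets: np.ndarray, batch_indices: np.ndarray,
                  anchors: np.ndarray, strides: np.ndarray,
                  grid_sizes: list, match_threshold: float = 4.0):
    """Anchor-match ground truth to (scale, image, anchor, cell) positives.

    Per target and scale, anchors within a `match_threshold` size ratio are
    positive at the center cell and its up-to-two nearest neighbour cells.
    Returns per scale: (b, a, gj, gi, txy, twh, anchor_wh, tcls).
    """
    out = []
    pos = np.isin(targets[:, 0], batch_indices)
    t_all = targets[pos]
    remap = {int(img): k for k, img in enumerate(batch_indices)}
    for scale in range(len(strides)):
        stride = strides[scale]
        H, W = grid_sizes[scale]
        anc = anchors[scale] / stride  # grid units
        rows = []
        for trow in t_all:
            img, cls = int(trow[0]), int(trow[1])
            gx, gy = trow[2] / stride, trow[3] / stride
            gw, gh = trow[4] / stride, trow[5] / stride
            for a in range(len(anc)):
                rw, rh = gw / anc[a, 0], gh / anc[a, 1]
                if max(rw, 1 / rw, rh, 1 / rh) >= match_threshold:
                    continue
                cells = [(int(gx), int(gy))]
                fx, fy = gx - int(gx), gy - int(gy)
                if fx < 0.5 and gx > 1:
                    cells.append((int(gx) - 1, int(gy)))
                elif fx >= 0.5 and gx < W - 1:
                    cells.append((int(gx) + 1, int(gy)))
                if fy < 0.5 and gy > 1:
                    cells.append((int(gx), int(gy) - 1))
                elif fy >= 0.5 and gy < H - 1:
                    cells.append((int(gx), int(gy) + 1))
                for gi, gj in cells:
                    if 0 <= gi < W and 0 <= gj < H:
                        rows.append((remap[img], a, gj, gi,
                                     gx - gi, gy - gj, gw, gh,
                                     anc[a, 0], anc[a, 1], cls))
        if rows:
            arr = np.asarray(rows, dtype=np.float64)
            out.append((arr[:, 0].astype(int), arr[:, 1].astype(int),
                        arr[:, 2].astype(int), arr[:, 3].astype(int),
                        arr[:, 4:6], arr[:, 6:8], arr[:, 8:10],
                        arr[:, 10].astype(int)))
        else:
            out.append(None)
    return out


def _ciou(pxy: Tensor, pwh: Tensor, txy: np.ndarray, twh: np.ndarray) -> Tensor:
    """Complete IoU between predicted and target boxes (center/size form)."""
    eps = 1e-7
    px, py = pxy[:, 0:1], pxy[:, 1:2]
    pw, ph = pwh[:, 0:1], pwh[:, 1:2]
    tx = Tensor(txy[:, 0:1])
    ty = Tensor(txy[:, 1:2])
    tw, th = twh[:, 0:1], twh[:, 1:2]
    p_x1, p_x2 = px - pw * 0.5, px + pw * 0.5
    p_y1, p_y2 = py - ph * 0.5, py + ph * 0.5
    t_x1, t_x2 = tx - tw * 0.5, tx + tw * 0.5
    t_y1, t_y2 = ty - th * 0.5, ty + th * 0.5
    iw = (p_x2.minimum(t_x2) - p_x1.maximum(t_x1)).clamp_min(0.0)
    ih = (p_y2.minimum(t_y2) - p_y1.maximum(t_y1)).clamp_min(0.0)
    inter = iw * ih
    union = pw * ph + Tensor(tw * th) - inter + eps
    iou = inter / union
    cw = p_x2.maximum(t_x2) - p_x1.minimum(t_x1)
    chh = p_y2.maximum(t_y2) - p_y1.minimum(t_y1)
    c2 = cw * cw + chh * chh + eps
    rho2 = (px - tx) * (px - tx) + (py - ty) * (py - ty)
    v = (Tensor(np.arctan(tw / th)) - (pw / (ph + eps)).atan()) ** 2 \
        * (4.0 / np.pi ** 2)
    alpha = (v / ((1.0 - iou) + v + eps)).detach()
    return iou - rho2 / c2 - alpha * v


def detection_loss(preds: list, targets: np.ndarray, batch_indices: np.ndarray,
                   net: Network, hyp: Hyperparams):
    """Composite loss: CIoU box + BCE objectness + BCE classification."""
    nc = net.config.num_classes
    grid_sizes = [(p.shape[2], p.shape[3]) for p in preds]
    built = build_targets(targets, batch_indices, net.anchors, net.strides,
                          grid_sizes, hyp.anchor_match_threshold)
    lbox = Tensor(0.0)
    lobj = Tensor(0.0)
    lcls = Tensor(0.0)
    for scale, (pred, matched) in enumerate(zip(preds, built)):
        tobj = np.zeros(pred.shape[:-1], dtype=np.float64)
        if matched is not None:
            b, a, gj, gi, txy, twh, anc, tcls = matched
            ps = pred[(b, a, gj, gi)]                     # (n, no)
            pxy = ps[:, 0:2].sigmoid() * 2.0 - 0.5
            pwh = (ps[:, 2:4].sigmoid() * 2.0) ** 2 * Tensor(anc)
            ciou = _ciou(pxy, pwh, txy, twh)
            lbox = lbox + (1.0 - ciou).mean()
            tobj[(b, a, gj, gi)] = np.clip(ciou.data.reshape(-1), 0.0, 1.0)
            if nc > 1:
                t = np.zeros((len(b), nc))
                t[np.arange(len(b)), tcls] = 1.0
                lcls = lcls + ps[:, 5:].bce_with_logits(t).mean()
        lobj = lobj + pred[..., 4].bce_with_logits(tobj).mean() \
            * hyp.obj_balance[scale]
    return (hyp.box_weight * lbox + hyp.obj_weight * lobj
            + hyp.cls_weight * lcls), \
        {"box": float(lbox.data), "obj": float(lobj.data),
         "cls": float(lcls.data)}


@dataclass
class Checkpoint:
    config: NetworkConfig
    state: dict
    history: list = field(default_factory=list)

    def save(self, path):
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state)
        meta = {"config": self.config.to_dict(), "history": self.history}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path):
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        with np.load(path.with_suffix(".npz")) as z:
            state = {k: z[k] for k in z.files}
        return cls(config=NetworkConfig.from_dict(meta["config"]), state=state,
                   history=meta["history"])

    def restore(self) -> Network:
        net = build_network(self.config)
        net.load_state_dict(self.state)
        return net


def train(net: Network, manifest, hyp: Hyperparams | None = None,
          log_every: int = 10) -> Checkpoint:
    """Train the detector on a manifest; deterministic given the seed."""
    hyp = hyp or Hyperparams()
    if len(manifest) == 0:
        raise ValueError("empty training manifest")
    images, targets, _ = load_dataset(manifest, net.config.input_size)
    rng = np.random.default_rng(hyp.seed)
    opt = Adam(net.parameters(), lr=hyp.lr)
    net.train()
    history = []
    n = images.shape[0]
    t0 = time.time()
    for epoch in range(hyp.epochs):
        opt.lr = hyp.lr_at(epoch)
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for lo in range(0, n, hyp.batch_size):
            idx = order[lo:lo + hyp.batch_size]
            batch = Tensor(images[idx])
            preds = net(batch)
            loss, parts = detection_loss(preds, targets, idx, net, hyp)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        mean_loss = epoch_loss / n_batches
        history.append({"epoch": epoch, "loss": mean_loss, **parts})
        if epoch % log_every == 0 or epoch == hyp.epochs - 1:
            logger.info("epoch %3d  loss %.4f  (%.1fs elapsed)",
                        epoch, mean_loss, time.time() - t0)
    net.eval()
    return Checkpoint(config=net.config, state=net.state_dict(), history=history)
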