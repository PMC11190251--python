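"""Per-use-case project store.

A *project* owns everything one labeling use case needs: the imported ROI
images and instance masks, the derived objects (centroid, area, bounding
box), fixed-size patches cropped around each object center, the confirmed
labels with their full event history, and serialized model checkpoints.
Everything lives in a single embedded SQLite database file, so a project is a
fully portable, self-contained entity.

Conventions used throughout: 0-based (row, col) pixel coordinates, half-open
bounding boxes ``(r0, c0, r1, c1)``, centroid rounding half-away-from-zero,
and zero (black) padding for patches that extend past the image border.

Labels are either an integer class id in ``1..K`` (indexing
``ProjectConfig.class_names``) or a special string label such as ``"unsure"``;
special labels are stored and exported but excluded from supervised training.
"""

from __future__ import annotations

import io
import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from skimage.measure import regionprops

__all__ = [
    "ProjectConfig",
    "ObjectInstance",
    "PatchRecord",
    "Project",
    "crop_centered",
    "default_palette",
]

Label = int | str
ObjectKey = tuple[str, int]


def default_palette(k: int) -> dict[int, tuple[int, int, int]]:
    """A categorical RGB palette for class ids 1..k (tab10-style)."""
    base = [
        (31, 119, 180), (255, 127, 14), (44, 160, 44), (214, 39, 40),
        (148, 103, 189), (140, 86, 75), (227, 119, 194), (127, 127, 127),
        (188, 189, 34), (23, 190, 207),
    ]
    return {i + 1: base[i % len(base)] for i in range(k)}


@dataclass
class ProjectConfig:
    """User-facing configuration of one project."""

    name: str
    patch_size: int
    class_names: Sequence[str]
    special_labels: tuple[str, ...] = ("unsure",)
    colors: dict[int, tuple[int, int, int]] | None = None
    unlabeled_color: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if self.patch_size <= 0:
            raise ValueError("patch_size must be positive")
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("class names must be unique")
        if self.colors is None:
            self.colors = default_palette(len(self.class_names))

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def valid_label(self, label: Label) -> bool:
        if isinstance(label, (int, np.integer)):
            return 1 <= int(label) <= self.n_classes
        return label in self.special_labels

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProjectConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "colors" in raw and raw["colors"] is not None:
            raw["colors"] = {int(k): tuple(v) for k, v in raw["colors"].items()}
        if "special_labels" in raw:
            raw["special_labels"] = tuple(raw["special_labels"])
        if "unlabeled_color" in raw:
            raw["unlabeled_color"] = tuple(raw["unlabeled_color"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "name": self.name,
            "patch_size": self.patch_size,
            "class_names": list(self.class_names),
            "special_labels": list(self.special_labels),
            "colors": {int(k): list(v) for k, v in (self.colors or {}).items()},
            "unlabeled_color": list(self.unlabeled_color),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


@dataclass(frozen=True)
class ObjectInstance:
    """One segmented object derived from an instance mask."""

    image_id: str
    instance_id: int
    centroid: tuple[float, float]  # (row, col), arithmetic mean of pixels
    area: int
    bbox: tuple[int, int, int, int]  # (r0, c0, r1, c1), half-open

    @property
    def key(self) -> ObjectKey:
        return (self.image_id, self.instance_id)


@dataclass
class PatchRecord:
    """Fixed-size crop centered on one object, plus its label slots."""

    image_id: str
    instance_id: int
    patch: np.ndarray  # (patch_size, patch_size, 3) uint8
    ground_truth_label: Label | None = None
    predicted_label: int | None = None
    prediction_confidence: float | None = None

    @property
    def key(self) -> ObjectKey:
        return (self.image_id, self.instance_id)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def crop_centered(image: np.ndarray, centroid: tuple[float, float], size: int) -> np.ndarray:
    """Crop a ``size``x``size`` window centered on ``centroid``.

    The top-left corner is ``round(centroid) - size // 2`` per axis (rounding
    half away from zero), so the rounded centroid lands at patch index
    ``size // 2``.  Pixels outside the image are zero-filled; a window lying
    entirely outside the image is legal and comes back all zeros.
    """
    h, w = image.shape[:2]
    r0 = _round_half_away(centroid[0]) - size // 2
    c0 = _round_half_away(centroid[1]) - size // 2
    out_shape = (size, size) + image.shape[2:]
    out = np.zeros(out_shape, dtype=image.dtype)
    sr0, sr1 = max(r0, 0), min(r0 + size, h)
    sc0, sc1 = max(c0, 0), min(c0 + size, w)
    if sr0 < sr1 and sc0 < sc1:
        out[sr0 - r0:sr1 - r0, sc0 - c0:sc1 - c0] = image[sr0:sr1, sc0:sc1]
    return out


_SCHEMA = """
CREATE TABLE IF NOT EXISTS meta (key TEXT PRIMARY KEY, value TEXT);
CREATE TABLE IF NOT EXISTS images (
    image_id TEXT PRIMARY KEY, height INT, width INT, image BLOB, mask BLOB);
CREATE TABLE IF NOT EXISTS objects (
    image_id TEXT, instance_id INT,
    centroid_r REAL, centroid_c REAL, area INT,
    r0 INT, c0 INT, r1 INT, c1 INT,
    ground_truth_label TEXT, predicted_label INT, prediction_confidence REAL,
    PRIMARY KEY (image_id, instance_id));
CREATE TABLE IF NOT EXISTS patches (
    image_id TEXT, instance_id INT, size INT, data BLOB,
    PRIMARY KEY (image_id, instance_id));
CREATE TABLE IF NOT EXISTS events (
    event_id INTEGER PRIMARY KEY AUTOINCREMENT,
    timestamp REAL, label TEXT, source TEXT, iteration INT);
CREATE TABLE IF NOT EXISTS event_objects (
    event_id INT, image_id TEXT, instance_id INT);
CREATE TABLE IF NOT EXISTS checkpoints (name TEXT PRIMARY KEY, data BLOB);
"""


def _encode_png(arr: np.ndarray) -> bytes:
    return iio.imwrite("<bytes>", arr, extension=".png")


def _decode_png(blob: bytes) -> np.ndarray:
    return iio.imread(io.BytesIO(blob), extension=".png")


def _label_to_db(label: Label | None) -> str | None:
    return None if label is None else str(label)


def _label_from_db(raw: str | None) -> Label | None:
    if raw is None:
        return None
    try:
        return int(raw)
    except ValueError:
        return raw


class Project:
    """A labeling project backed by a single SQLite file.

    Parameters
    ----------
    path : database file path, or ``":memory:"`` for an ephemeral project.
    config : required when creating a new project; when reopening an
        existing database the stored config is loaded and ``config`` may be
        omitted.
    """

    def __init__(self, path: str | Path, config: ProjectConfig | None = None):
        self.path = str(path)
        self._db = sqlite3.connect(self.path)
        self._db.executescript(_SCHEMA)
        stored = self._get_meta("config")
        if stored is not None and config is None:
            raw = json.loads(stored)
            raw["colors"] = {int(k): tuple(v) for k, v in raw["colors"].items()}
            raw["special_labels"] = tuple(raw["special_labels"])
            raw["unlabeled_color"] = tuple(raw["unlabeled_color"])
            config = ProjectConfig(**raw)
        if config is None:
            raise ValueError("new project requires a ProjectConfig")
        self.config = config
        self._set_meta("config", json.dumps({
            "name": config.name,
            "patch_size": config.patch_size,
            "class_names": list(config.class_names),
            "special_labels": list(config.special_labels),
            "colors": {k: list(v) for k, v in (config.colors or {}).items()},
            "unlabeled_color": list(config.unlabeled_color),
        }))
        self._db.commit()

    # -- meta -------------------------------------------------------------
    def _get_meta(self, key: str) -> str | None:
        row = self._db.execute("SELECT value FROM meta WHERE key=?", (key,)).fetchone()
        return None if row is None else row[0]

    def _set_meta(self, key: str, value: str) -> None:
        self._db.execute(
            "INSERT OR REPLACE INTO meta (key, value) VALUES (?, ?)", (key, value)
        )

    def close(self) -> None:
        self._db.close()

    # -- import -----------------------------------------------------------
    def import_image(
        self, image_id: str, image: np.ndarray, mask: np.ndarray
    ) -> list[ObjectInstance]:
        """Register an ROI image + instance mask; derive one object per
        distinct nonzero mask id.

        The centroid is the arithmetic mean of the (row, col) coordinates of
        the id's pixels.  An empty (all-zero) mask yields an empty list.
        """
        image = np.asarray(image)
        mask = np.asarray(mask)
        if image.shape[:2] != mask.shape[:2]:
            raise ValueError(
                f"image {image.shape[:2]} and mask {mask.shape[:2]} differ in size"
            )
        if mask.ndim != 2:
            raise ValueError("mask must be a single-channel integer raster")
        if np.issubdtype(mask.dtype, np.signedinteger) and (mask < 0).any():
            raise ValueError("mask values must be non-negative")

        objects = [
            ObjectInstance(
                image_id=image_id,
                instance_id=int(p.label),
                centroid=(float(p.centroid[0]), float(p.centroid[1])),
                area=int(p.area),
                bbox=tuple(int(v) for v in p.bbox),
            )
            for p in regionprops(mask.astype(np.int64))
        ]
        self._db.execute(
            "INSERT OR REPLACE INTO images (image_id, height, width, image, mask) "
            "VALUES (?, ?, ?, ?, ?)",
            (image_id, image.shape[0], image.shape[1],
             _encode_png(image.astype(np.uint8)),
             _encode_png(mask.astype(np.uint16))),
        )
        self._db.executemany(
            "INSERT OR REPLACE INTO objects "
            "(image_id, instance_id, centroid_r, centroid_c, area, r0, c0, r1, c1) "
            "VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?)",
            [
                (o.image_id, o.instance_id, o.centroid[0], o.centroid[1], o.area,
                 *o.bbox)
                for o in objects
            ],
        )
        self._db.commit()
        return objects

    def image_ids(self) -> list[str]:
        return [r[0] for r in self._db.execute(
            "SELECT image_id FROM images ORDER BY image_id")]

    def get_image(self, image_id: str) -> np.ndarray:
        row = self._db.execute(
            "SELECT image FROM images WHERE image_id=?", (image_id,)).fetchone()
        if row is None:
            raise KeyError(image_id)
        img = _decode_png(row[0])
        return img

    def get_mask(self, image_id: str) -> np.ndarray:
        row = self._db.execute(
            "SELECT mask FROM images WHERE image_id=?", (image_id,)).fetchone()
        if row is None:
            raise KeyError(image_id)
        return _decode_png(row[0]).astype(np.uint16)

    def get_objects(self) -> list[ObjectInstance]:
        rows = self._db.execute(
            "SELECT image_id, instance_id, centroid_r, centroid_c, area, "
            "r0, c0, r1, c1 FROM objects ORDER BY image_id, instance_id"
        ).fetchall()
        return [
            ObjectInstance(r[0], int(r[1]), (r[2], r[3]), int(r[4]),
                           (int(r[5]), int(r[6]), int(r[7]), int(r[8])))
            for r in rows
        ]

    def get_object(self, key: ObjectKey) -> ObjectInstance:
        r = self._db.execute(
            "SELECT image_id, instance_id, centroid_r, centroid_c, area, "
            "r0, c0, r1, c1 FROM objects WHERE image_id=? AND instance_id=?",
            key).fetchone()
        if r is None:
            raise KeyError(key)
        return ObjectInstance(r[0], int(r[1]), (r[2], r[3]), int(r[4]),
                              (int(r[5]), int(r[6]), int(r[7]), int(r[8])))

    # -- patches ----------------------------------------------------------
    def extract_patches(self, patch_size: int | None = None) -> list[PatchRecord]:
        """Crop one centered patch per object and persist it.

        Idempotent: re-running produces byte-identical patches.  Returns the
        records ordered by (image_id, instance_id).
        """
        size = self.config.patch_size if patch_size is None else patch_size
        if size <= 0:
            raise ValueError("patch_size must be positive")
        for image_id in self.image_ids():
            image = self.get_image(image_id)
            objs = [o for o in self.get_objects() if o.image_id == image_id]
            self._db.executemany(
                "INSERT OR REPLACE INTO patches (image_id, instance_id, size, data) "
                "VALUES (?, ?, ?, ?)",
                [
                    (o.image_id, o.instance_id, size,
                     crop_centered(image, o.centroid, size).tobytes())
                    for o in objs
                ],
            )
        self._db.commit()
        return self.get_patches()

    def get_patches(self) -> list[PatchRecord]:
        rows = self._db.execute(
            "SELECT p.image_id, p.instance_id, p.size, p.data, "
            "o.ground_truth_label, o.predicted_label, o.prediction_confidence "
            "FROM patches p JOIN objects o "
            "ON p.image_id=o.image_id AND p.instance_id=o.instance_id "
            "ORDER BY p.image_id, p.instance_id"
        ).fetchall()
        records = []
        for image_id, inst, size, blob, gt, pred, conf in rows:
            patch = np.frombuffer(blob, dtype=np.uint8).reshape(size, size, 3)
            records.append(PatchRecord(
                image_id, int(inst), patch,
                ground_truth_label=_label_from_db(gt),
                predicted_label=None if pred is None else int(pred),
                prediction_confidence=conf,
            ))
        return records

    def get_context_patch(self, key: ObjectKey, context_size: int) -> np.ndarray:
        """A larger crop around the object for visual context only (never
        used for training); shares the centering/padding rule of
        :meth:`extract_patches`."""
        if context_size < self.config.patch_size:
            raise ValueError("context_size must be >= patch_size")
        obj = self.get_object(key)
        return crop_centered(self.get_image(obj.image_id), obj.centroid, context_size)

    # -- labels & events --------------------------------------------------
    def apply_label_event(
        self,
        keys: Iterable[ObjectKey],
        label: Label,
        timestamp: float,
        source: str,
        iteration: int = 0,
    ) -> int:
        """Record one confirmed label event covering ``keys`` and update each
        object's current ground-truth label (last write wins; history kept)."""
        keys = list(keys)
        if not keys:
            raise ValueError("label event requires a non-empty selection")
        if not self.config.valid_label(label):
            raise ValueError(f"unknown label {label!r}")
        for key in keys:
            self.get_object(key)  # KeyError for unknown objects
        cur = self._db.execute(
            "INSERT INTO events (timestamp, label, source, iteration) "
            "VALUES (?, ?, ?, ?)",
            (timestamp, _label_to_db(label), source, iteration),
        )
        event_id = int(cur.lastrowid)
        self._db.executemany(
            "INSERT INTO event_objects (event_id, image_id, instance_id) "
            "VALUES (?, ?, ?)",
            [(event_id, k[0], k[1]) for k in keys],
        )
        self._db.executemany(
            "UPDATE objects SET ground_truth_label=? "
            "WHERE image_id=? AND instance_id=?",
            [(_label_to_db(label), k[0], k[1]) for k in keys],
        )
        self._db.commit()
        return event_id

    def get_labels(self) -> dict[ObjectKey, Label]:
        rows = self._db.execute(
            "SELECT image_id, instance_id, ground_truth_label FROM objects "
            "WHERE ground_truth_label IS NOT NULL").fetchall()
        return {(r[0], int(r[1])): _label_from_db(r[2]) for r in rows}

    def set_predictions(
        self,
        keys: Sequence[ObjectKey],
        labels: Sequence[int],
        confidences: Sequence[float],
    ) -> None:
        self._db.executemany(
            "UPDATE objects SET predicted_label=?, prediction_confidence=? "
            "WHERE image_id=? AND instance_id=?",
            [(int(l), float(c), k[0], k[1])
             for k, l, c in zip(keys, labels, confidences)],
        )
        self._db.commit()

    # -- export -----------------------------------------------------------
    def export_label_masks(
        self, out_dir: str | Path | None = None
    ) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
        """Render per-image color label masks and the label table.

        Each object's footprint is painted with its class color; unlabeled
        objects get ``unlabeled_color`` (black by default, signalling
        "not yet labeled"); background stays black.  When ``out_dir`` is
        given, masks are written as PNG and the table as ``labels.csv`` with
        header ``image_id,instance_id,label``.
        """
        labels = self.get_labels()
        colors = self.config.colors or {}
        rendered: dict[str, np.ndarray] = {}
        for image_id in self.image_ids():
            mask = self.get_mask(image_id)
            out = np.zeros(mask.shape + (3,), dtype=np.uint8)
            for inst in np.unique(mask):
                if inst == 0:
                    continue
                label = labels.get((image_id, int(inst)))
                if isinstance(label, int) and label in colors:
                    color = colors[label]
                else:
                    color = self.config.unlabeled_color
                out[mask == inst] = color
            rendered[image_id] = out
        table = pd.DataFrame(
            [(k[0], k[1], str(v)) for k, v in sorted(labels.items())],
            columns=["image_id", "instance_id", "label"],
        )
        if out_dir is not None:
            out_path = Path(out_dir)
            out_path.mkdir(parents=True, exist_ok=True)
            for image_id, arr in rendered.items():
                iio.imwrite(out_path / f"{image_id}_labels.png", arr)
            table.to_csv(out_path / "labels.csv", index=False)
        return rendered, table

    def import_labels(
        self,
        table: pd.DataFrame,
        timestamp: float = 0.0,
        source: str = "review_edit",
    ) -> int:
        """Apply a label table (e.g. a previously exported ``labels.csv``)
        as confirmed events, one per distinct label value."""
        n = 0
        for label, group in table.groupby("label", sort=True):
            keys = [(str(r.image_id), int(r.instance_id))
                    for r in group.itertuples()]
            self.apply_label_event(keys, _label_from_db(str(label)),
                                   timestamp, source)
            n += len(keys)
        return n

    # -- checkpoints ------------------------------------------------------
    def save_checkpoint(self, name: str, data: bytes) -> None:
        self._db.execute(
            "INSERT OR REPLACE INTO checkpoints (name, data) VALUES (?, ?)",
            (name, data))
        self._db.commit()

    def load_checkpoint(self, name: str) -> bytes:
        row = self._db.execute(
            "SELECT data FROM checkpoints WHERE name=?", (name,)).fetchone()
        if row is None:
            raise KeyError(name)
        return row[0]
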