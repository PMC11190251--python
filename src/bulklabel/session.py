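"""The headless labeling loop.

This module reproduces, without a browser, what an annotator does with the
embedding plot: lasso a region of the 2-D embedding, assign one class to the
whole selection, periodically retrain/re-embed, and review individual labels.
A *simulated annotator* with a known ground truth stands in for the human,
with per-action time costs on a simulated clock, so labeling-efficiency
experiments are deterministic and reproducible.

Three annotator policies are provided:

``one_at_a_time``
    The unaided baseline: random single objects labeled at a fixed cost
    each, no model in the loop.
``peripheral_bulk``
    Bulk labeling starting at the periphery of the embedding (where the most
    cleanly clustered objects sit), each selection labeled with its majority
    true class; periodic fine-tune/re-embed; then a grid-review pass that
    corrects members of mixed selections one at a time.
``interface_refine``
    One-at-a-time labeling of the points the model is least confident about
    (the class interfaces), with periodic fine-tune/re-embed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from .embedding import embed_2d
from .project import Label, ObjectKey, Project
from .representation import (EncoderSpec, ModelState, TrainConfig,
                             compute_features, finetune_semisupervised,
                             predict_labels, train_selfsupervised)

__all__ = [
    "LabelEvent",
    "SessionLog",
    "AnnotatorPolicy",
    "lasso_select",
    "modify_selection",
    "bulk_label",
    "run_iteration",
    "simulate_session",
]

_POLICIES = ("peripheral_bulk", "interface_refine", "one_at_a_time")


@dataclass(frozen=True)
class LabelEvent:
    """One confirmed label assignment covering one or more objects."""

    timestamp: float
    label: Label
    source: str  # bulk_lasso | single | review_edit
    iteration: int
    object_ids: frozenset | None = None
    n_objects: int = 0

    def __post_init__(self):
        if self.object_ids is not None:
            object.__setattr__(self, "n_objects", len(self.object_ids))


@dataclass
class SessionLog:
    """Ordered label events plus training/embedding compute intervals —
    the substrate of every efficiency metric.

    ``human time = total span − Σ compute intervals``: the annotator can be
    dismissed while the model trains or the embedding is recomputed."""

    events: list[LabelEvent] = field(default_factory=list)
    compute_intervals: list[tuple[float, float, str]] = field(default_factory=list)
    start_time: float = 0.0
    end_time: float | None = None
    clock: float = 0.0

    @property
    def span(self) -> float:
        end = self.end_time if self.end_time is not None else self.clock
        return end - self.start_time

    @property
    def compute_seconds(self) -> float:
        return sum(e - s for s, e, _ in self.compute_intervals)

    @property
    def human_seconds(self) -> float:
        return self.span - self.compute_seconds

    def add_event(self, event: LabelEvent) -> None:
        if self.events and event.timestamp < self.events[-1].timestamp:
            raise ValueError("event timestamps must be non-decreasing")
        self.events.append(event)

    def add_compute(self, duration: float, kind: str) -> None:
        """Append a compute interval starting at the current clock and
        advance the clock past it."""
        self.compute_intervals.append((self.clock, self.clock + duration, kind))
        self.clock += duration

    def final_labels(self) -> dict[ObjectKey, Label] | None:
        """Replay the event history; last write wins.  Returns None when the
        log was loaded without per-object identities."""
        if any(e.object_ids is None for e in self.events):
            return None
        out: dict[ObjectKey, Label] = {}
        for e in self.events:
            for key in e.object_ids:
                out[key] = e.label
        return out

    def n_labeled(self) -> int:
        """Distinct objects holding a final confirmed label (relabels do not
        double-count); falls back to summed event sizes for logs loaded
        without object identities."""
        labels = self.final_labels()
        if labels is None:
            return sum(e.n_objects for e in self.events)
        return len(labels)

    # -- serialization ----------------------------------------------------
    def to_csv(self, events_path: str | Path, intervals_path: str | Path) -> None:
        pd.DataFrame(
            [(e.timestamp, e.source, e.n_objects, str(e.label), e.iteration)
             for e in self.events],
            columns=["timestamp", "event_kind", "n_objects", "class", "iteration"],
        ).to_csv(events_path, index=False)
        pd.DataFrame(
            self.compute_intervals + [(self.start_time, self.span, "session_span")],
            columns=["start", "end", "kind"],
        ).to_csv(intervals_path, index=False)

    @classmethod
    def from_csv(cls, events_path: str | Path,
                 intervals_path: str | Path) -> "SessionLog":
        log = cls()
        ev = pd.read_csv(events_path)
        for r in ev.itertuples():
            log.events.append(LabelEvent(
                timestamp=float(r.timestamp), label=str(r._4)
                if not str(r._4).isdigit() else int(r._4),
                source=str(r.event_kind), iteration=int(r.iteration),
                object_ids=None, n_objects=int(r.n_objects)))
        iv = pd.read_csv(intervals_path)
        for r in iv.itertuples():
            if r.kind == "session_span":
                log.start_time = float(r.start)
                log.end_time = float(r.end)
                log.clock = float(r.end)
            else:
                log.compute_intervals.append(
                    (float(r.start), float(r.end), str(r.kind)))
        return log


# ---------------------------------------------------------------------------
# selection primitives
# ---------------------------------------------------------------------------

def lasso_select(coordinates: np.ndarray, ids, polygon_vertices) -> set:
    """Ids whose embedding point lies inside or on the boundary of the
    closed polygon (on-edge points are selected)."""
    vertices = list(polygon_vertices)
    if len(vertices) < 3:
        raise ValueError("a lasso polygon needs at least 3 vertices")
    coords = np.asarray(coordinates, dtype=np.float64)
    poly = shapely.Polygon(vertices)
    pts = shapely.points(coords[:, 0], coords[:, 1])
    inside = shapely.covers(poly, pts)
    return {i for i, hit in zip(ids, inside) if hit}


def modify_selection(selection: set, action: str, universe: set) -> set:
    """Keyboard-shortcut selection algebra: select_all, invert, clear."""
    if not selection <= universe:
        raise ValueError("selection must be a subset of the universe")
    if action == "select_all":
        return set(universe)
    if action == "invert":
        return set(universe) - selection
    if action == "clear":
        return set()
    raise ValueError(f"unknown selection action {action!r}")


def bulk_label(project: Project, selection, label: Label, timestamp: float,
               source: str = "bulk_lasso", iteration: int = 0,
               log: SessionLog | None = None) -> LabelEvent:
    """Assign one class to every object in the selection in a single
    confirmed event (last write wins on relabeling)."""
    keys = sorted(selection)
    project.apply_label_event(keys, label, timestamp, source, iteration)
    event = LabelEvent(timestamp=timestamp, label=label, source=source,
                       iteration=iteration, object_ids=frozenset(keys))
    if log is not None:
        log.add_event(event)
        log.clock = max(log.clock, timestamp)
    return event


# ---------------------------------------------------------------------------
# the iterative refinement loop
# ---------------------------------------------------------------------------

def run_iteration(project: Project, state: ModelState, cfg: TrainConfig,
                  log: SessionLog, embed_method: str = "pca",
                  embed_seed: int = 0, train_seconds: float = 60.0,
                  embed_seconds: float = 15.0, iteration: int = 0,
                  ) -> tuple[ModelState, np.ndarray]:
    """One refine cycle: fine-tune on all confirmed labels, recompute
    features and predictions, re-embed.

    Special labels (e.g. "unsure") are stored but excluded from the
    supervised term.  Exactly one training and one embedding compute
    interval are appended to the log, with simulated durations."""
    records = project.get_patches()
    patches = [r.patch for r in records]
    labels = {
        i: r.ground_truth_label
        for i, r in enumerate(records)
        if isinstance(r.ground_truth_label, int)
    }
    state = finetune_semisupervised(state, patches, labels, cfg)
    log.add_compute(train_seconds, "training")
    feats = compute_features(state, patches)
    pred, conf = predict_labels(state, patches)
    project.set_predictions([r.key for r in records], pred, conf)
    coords = embed_2d(feats, method=embed_method, seed=embed_seed)
    log.add_compute(embed_seconds, "embedding")
    return state, coords


# ---------------------------------------------------------------------------
# simulated annotator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotatorPolicy:
    """Behaviour and time costs of the simulated annotator.

    ``seconds_per_action`` is the cost of one lasso + class-key bulk action;
    ``seconds_per_single_label`` the cost of labeling or reviewing a single
    object.  ``error_rate`` is the probability that any assignment decision
    picks a uniformly random wrong class."""

    kind: str
    error_rate: float = 0.0
    seconds_per_action: float = 8.0
    seconds_per_single_label: float = 2.0
    seed: int = 0
    bulk_size: int = 40
    events_per_iteration: int = 5
    labels_per_iteration: int = 50

    def __post_init__(self):
        if self.kind not in _POLICIES:
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")
        if min(self.seconds_per_action, self.seconds_per_single_label) <= 0:
            raise ValueError("per-action times must be positive")


def _truth_dict(truth: pd.DataFrame) -> dict[ObjectKey, int]:
    return {(str(r.image_id), int(r.instance_id)): int(r.class_id)
            for r in truth.itertuples()}


def _maybe_corrupt(class_id: int, n_classes: int, error_rate: float,
                   rng: np.random.Generator) -> int:
    if error_rate > 0 and rng.random() < error_rate:
        offset = int(rng.integers(1, n_classes))
        return (class_id - 1 + offset) % n_classes + 1
    return class_id


def simulate_session(project: Project, truth: pd.DataFrame,
                     policy: AnnotatorPolicy, budget_seconds: float,
                     encoder_spec: EncoderSpec | None = None,
                     train_cfg: TrainConfig | None = None,
                     embed_method: str = "pca",
                     train_seconds: float = 60.0,
                     embed_seconds: float = 15.0) -> SessionLog:
    """Run a virtual labeling session until the simulated clock would exceed
    ``budget_seconds``.

    All times — labeling actions and model compute alike — advance the same
    session clock; an action is taken only if it finishes within budget, so
    a budget smaller than one action yields an empty event list.
    """
    if budget_seconds <= 0:
        raise ValueError("budget_seconds must be positive")
    truth_map = _truth_dict(truth)
    rng = np.random.default_rng(policy.seed)
    log = SessionLog()
    k = project.config.n_classes

    records = project.get_patches()
    if not records:
        records = project.extract_patches()
    keys = [r.key for r in records]
    key_to_idx = {key: i for i, key in enumerate(keys)}

    def corrupt(c: int) -> int:
        return _maybe_corrupt(c, k, policy.error_rate, rng)

    if policy.kind == "one_at_a_time":
        order = [keys[i] for i in rng.permutation(len(keys))]
        for key in order:
            if log.clock + policy.seconds_per_single_label > budget_seconds:
                break
            log.clock += policy.seconds_per_single_label
            bulk_label(project, [key], corrupt(truth_map[key]), log.clock,
                       source="single", iteration=0, log=log)
        log.end_time = log.clock
        return log

    # Model-in-the-loop policies: self-supervised pre-training + first embedding.
    spec = encoder_spec or EncoderSpec(patch_size=records[0].patch.shape[0],
                                       encoder_size=16)
    cfg = train_cfg or TrainConfig(seed=policy.seed)
    patches = [r.patch for r in records]
    state = train_selfsupervised(patches, spec, cfg, n_classes=k)
    log.add_compute(train_seconds, "training")
    feats = compute_features(state, patches)
    pred, conf = predict_labels(state, patches)
    project.set_predictions(keys, pred, conf)
    coords = embed_2d(feats, method=embed_method, seed=policy.seed)
    log.add_compute(embed_seconds, "embedding")

    unlabeled = set(keys)
    iteration = 0

    def refine() -> None:
        nonlocal state, coords, iteration, conf
        iteration += 1
        state, coords = run_iteration(
            project, state, cfg, log, embed_method=embed_method,
            embed_seed=policy.seed, train_seconds=train_seconds,
            embed_seconds=embed_seconds, iteration=iteration)
        conf = np.asarray(
            [r.prediction_confidence for r in project.get_patches()])

    if policy.kind == "peripheral_bulk":
        n_bulk = 0
        center = coords.mean(axis=0)
        while unlabeled and log.clock + policy.seconds_per_action <= budget_seconds:
            # Start from the unlabeled point farthest from the embedding
            # center (the periphery holds the most cleanly clustered
            # objects), lasso its local neighborhood of unlabeled points.
            cand = sorted(unlabeled)
            idx = np.asarray([key_to_idx[key] for key in cand])
            d_center = np.linalg.norm(coords[idx] - center, axis=1)
            seed_pt = coords[idx[int(np.argmax(d_center))]]
            d_seed = np.linalg.norm(coords[idx] - seed_pt, axis=1)
            take = np.argsort(d_seed, kind="stable")[:policy.bulk_size]
            selection = [cand[i] for i in take]
            true_classes = np.asarray([truth_map[key] for key in selection])
            majority = int(np.bincount(true_classes).argmax())
            log.clock += policy.seconds_per_action
            bulk_label(project, selection, corrupt(majority), log.clock,
                       source="bulk_lasso", iteration=iteration, log=log)
            unlabeled -= set(selection)
            n_bulk += 1
            if n_bulk % policy.events_per_iteration == 0 and unlabeled:
                refine()
                center = coords.mean(axis=0)
        # Grid-review pass: inspect the assignments and correct the members
        # of mixed bulk selections one at a time.
        assigned = project.get_labels()
        wrong = sorted(key for key, lab in assigned.items()
                       if truth_map.get(key) != lab)
        for key in wrong:
            if log.clock + policy.seconds_per_single_label > budget_seconds:
                break
            log.clock += policy.seconds_per_single_label
            bulk_label(project, [key], corrupt(truth_map[key]), log.clock,
                       source="review_edit", iteration=iteration, log=log)
        log.end_time = log.clock
        return log

    # interface_refine: single labels at the class interfaces, lowest model
    # confidence first.
    n_single = 0
    while unlabeled and log.clock + policy.seconds_per_single_label <= budget_seconds:
        cand = sorted(unlabeled)
        idx = np.asarray([key_to_idx[key] for key in cand])
        key = cand[int(np.argmin(conf[idx]))]
        log.clock += policy.seconds_per_single_label
        bulk_label(project, [key], corrupt(truth_map[key]), log.clock,
                   source="single", iteration=iteration, log=log)
        unlabeled.discard(key)
        n_single += 1
        if n_single % policy.labels_per_iteration == 0 and unlabeled:
            refine()
    log.end_time = log.clock
    return log
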