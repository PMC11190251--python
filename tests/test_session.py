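"""Selection semantics, the labeling loop, and the simulated annotator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bulklabel as bl
from conftest import ENCODER_SPEC, TRAIN_CFG, make_project


# --------------------------------------------------------------------------
# independent point-in-polygon oracle (winding number + edge distance)
# --------------------------------------------------------------------------

def winding_inside(point, vertices):
    px, py = point
    verts = np.asarray(vertices, dtype=np.float64)
    n = len(verts)
    # on-edge check via point-segment distance
    for i in range(n):
        a, b = verts[i], verts[(i + 1) % n]
        ab = b - a
        t = 0.0 if ab @ ab == 0 else np.clip(((point - a) @ ab) / (ab @ ab), 0, 1)
        if np.linalg.norm(a + t * ab - point) < 1e-9:
            return True
    angle = 0.0
    for i in range(n):
        a = verts[i] - point
        b = verts[(i + 1) % n] - point
        angle += np.arctan2(a[0] * b[1] - a[1] * b[0], a @ b)
    return abs(angle) > np.pi


class TestLassoSelect:
    coords = np.random.default_rng(0).uniform(-10, 10, size=(500, 2))
    ids = list(range(500))

    def test_bounding_square_selects_everything(self):
        poly = [(-11, -11), (11, -11), (11, 11), (-11, 11)]
        assert bl.lasso_select(self.coords, self.ids, poly) == set(self.ids)

    def test_polygon_in_empty_region_selects_nothing(self):
        poly = [(100, 100), (101, 100), (101, 101)]
        assert bl.lasso_select(self.coords, self.ids, poly) == set()

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            bl.lasso_select(self.coords, self.ids, [(0, 0), (1, 1)])

    def test_on_edge_points_are_selected(self):
        coords = np.array([[0.0, 0.0], [0.5, 0.0], [2.0, 2.0]])
        poly = [(0, 0), (1, 0), (1, 1), (0, 1)]
        assert bl.lasso_select(coords, [0, 1, 2], poly) == {0, 1}

    def test_star_polygon_matches_winding_oracle(self):
        rng = np.random.default_rng(7)
        angles = np.sort(rng.uniform(0, 2 * np.pi, size=9))
        radii = rng.uniform(2, 9, size=9)
        poly = [(r * np.cos(a), r * np.sin(a)) for r, a in zip(radii, angles)]
        got = bl.lasso_select(self.coords, self.ids, poly)
        expected = {i for i in self.ids
                    if winding_inside(self.coords[i], poly)}
        assert got == expected

    def test_random_polygons_match_winding_oracle(self):
        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(10):  # 10 polygons x 100 points = 1000 cases
            k = int(rng.integers(3, 8))
            angles = np.sort(rng.uniform(0, 2 * np.pi, size=k))
            radii = rng.uniform(1, 10, size=k)
            poly = [(r * np.cos(a), r * np.sin(a))
                    for r, a in zip(radii, angles)]
            pts = rng.uniform(-10, 10, size=(100, 2))
            got = bl.lasso_select(pts, range(100), poly)
            expected = {i for i in range(100) if winding_inside(pts[i], poly)}
            assert got == expected
            checked += 100
        assert checked == 1000


class TestModifySelection:
    universe = frozenset(range(30))

    @given(st.sets(st.integers(0, 29)))
    @settings(max_examples=50, derandomize=True)
    def test_invert_is_an_involution(self, selection):
        u = set(self.universe)
        once = bl.modify_selection(selection, "invert", u)
        assert bl.modify_selection(once, "invert", u) == selection

    def test_shortcut_algebra(self):
        u = set(self.universe)
        assert bl.modify_selection(set(), "invert", u) == u
        sel = bl.modify_selection(set(), "select_all", u)
        assert bl.modify_selection(sel, "invert", u) == set()
        assert bl.modify_selection(sel, "clear", u) == set()

    def test_selection_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            bl.modify_selection({99}, "invert", {1, 2})


class TestBulkLabel:
    def test_bulk_event_sets_all_labels_at_once(self, project):
        keys = [o.key for o in project.get_objects()][:40]
        log = bl.SessionLog()
        event = bl.bulk_label(project, keys, 2, timestamp=5.0, log=log)
        assert event.n_objects == 40
        assert len(log.events) == 1
        labels = project.get_labels()
        assert all(labels[k] == 2 for k in keys)

    def test_relabel_is_last_write_wins(self, project):
        keys = [o.key for o in project.get_objects()][:40]
        bl.bulk_label(project, keys, 2, timestamp=5.0)
        bl.bulk_label(project, keys[:5], 1, timestamp=9.0)
        labels = project.get_labels()
        assert all(labels[k] == 1 for k in keys[:5])
        assert all(labels[k] == 2 for k in keys[5:])
        _, table = project.export_label_masks()
        assert len(table) == 40  # relabels do not add rows

    def test_unknown_class_rejected(self, project):
        keys = [o.key for o in project.get_objects()][:3]
        with pytest.raises(ValueError):
            bl.bulk_label(project, keys, 9, timestamp=1.0)
        with pytest.raises(ValueError):
            bl.bulk_label(project, [], 1, timestamp=1.0)


class TestRunIteration:
    def test_bookkeeping_one_training_one_embedding_interval(self, dataset,
                                                             pretrained):
        project = make_project(dataset)
        log = bl.SessionLog()
        cfg = bl.TrainConfig(seed=1, epochs_finetune=1)
        state, coords = bl.run_iteration(project, pretrained, cfg, log)
        kinds = [k for _, _, k in log.compute_intervals]
        assert kinds == ["training", "embedding"]
        assert coords.shape == (len(project.get_objects()), 2)
        # a second call appends exactly one more of each
        bl.run_iteration(project, state, cfg, log)
        kinds = [k for _, _, k in log.compute_intervals]
        assert kinds == ["training", "embedding"] * 2


class TestSimulateSession:
    def test_budget_below_one_action_yields_no_events(self, dataset, truth_map):
        project = make_project(dataset)
        _, _, truth = dataset
        policy = bl.AnnotatorPolicy(kind="one_at_a_time",
                                    seconds_per_single_label=5.0)
        log = bl.simulate_session(project, truth, policy, budget_seconds=4.0)
        assert log.events == []

    def test_one_at_a_time_clock_arithmetic(self, dataset):
        """100 single labels at 2 s each -> 200 s of human time, LPS 0.5."""
        images, masks, truth = dataset
        cfg = bl.ProjectConfig(name="t", patch_size=32,
                               class_names=["a", "b", "c"])
        project = bl.Project(":memory:", cfg)
        project.import_image("img_000", images[0], masks[0])
        project.import_image("img_001", images[1], masks[1])
        project.import_image("img_002", images[2], masks[2])
        project.import_image("img_003", images[3], masks[3])  # 120 objects
        project.extract_patches()
        policy = bl.AnnotatorPolicy(kind="one_at_a_time",
                                    seconds_per_single_label=2.0, seed=0)
        log = bl.simulate_session(project, truth, policy, budget_seconds=200.0)
        assert len(log.events) == 100
        assert log.human_seconds == pytest.approx(200.0)
        report = bl.efficiency_from_log(log)
        assert report.lps_human == pytest.approx(0.5)

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            bl.AnnotatorPolicy(kind="telepathy")

    def test_event_history_reproduces_stored_labels(self, dataset):
        """Auditability: replaying the session's events yields exactly the
        labels the project ends up holding."""
        _, _, truth = dataset
        project = make_project(dataset)
        policy = bl.AnnotatorPolicy(kind="peripheral_bulk", seed=2,
                                    error_rate=0.1)
        log = bl.simulate_session(project, truth, policy, budget_seconds=3600,
                                  encoder_spec=ENCODER_SPEC,
                                  train_cfg=bl.TrainConfig(seed=2,
                                                           epochs_pretrain=2,
                                                           epochs_finetune=1))
        assert log.final_labels() == project.get_labels()
        ts = [e.timestamp for e in log.events]
        assert ts == sorted(ts)

    def test_session_log_csv_round_trip(self, dataset, tmp_path):
        _, _, truth = dataset
        project = make_project(dataset)
        policy = bl.AnnotatorPolicy(kind="one_at_a_time", seed=1)
        log = bl.simulate_session(project, truth, policy, budget_seconds=100.0)
        log.to_csv(tmp_path / "e.csv", tmp_path / "i.csv")
        loaded = bl.SessionLog.from_csv(tmp_path / "e.csv", tmp_path / "i.csv")
        assert loaded.span == pytest.approx(log.span)
        assert loaded.human_seconds == pytest.approx(log.human_seconds)
        assert len(loaded.events) == len(log.events)
        assert loaded.n_labeled() == log.n_labeled()
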