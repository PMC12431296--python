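"""Decision-level fusion of motor-imagery and scene posteriors.

The joint task distribution over the 12 (MI class x scene) combinations is
the product measure ``P_task(i, j) = P_MI(i) * P_scene(j)``; the predicted
task is its argmax, mapped to a robot command through the bundled task map
(editable JSON: scene, MI class, task name, description).

Note on the shipped map: two bedroom tasks share the "BL" name prefix
(BL-Switch for left hand, BL-WakeSupport for legs) — the names are kept
verbatim from the command table and remain distinct strings.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

MI_CLASSES = ("left hand", "right hand", "legs", "tongue")
SCENES = ("kitchen", "living room", "bedroom")


@dataclass(frozen=True)
class TaskMap:
    """Bijection between (MI class, scene) pairs and the 12 task commands."""

    mi_classes: tuple[str, ...]
    scenes: tuple[str, ...]
    names: np.ndarray          # (n_mi, n_scenes) task names
    descriptions: np.ndarray   # (n_mi, n_scenes)

    @classmethod
    def from_dict(cls, d: dict) -> "TaskMap":
        mi = tuple(d["mi_classes"])
        scenes = tuple(d["scenes"])
        names = np.empty((len(mi), len(scenes)), dtype=object)
        desc = np.empty_like(names)
        for entry in d["tasks"]:
            i, j = mi.index(entry["mi"]), scenes.index(entry["scene"])
            names[i, j] = entry["name"]
            desc[i, j] = entry["description"]
        if any(n is None for n in names.ravel()):
            raise ValueError("task map does not cover every (MI, scene) pair")
        flat = list(names.ravel())
        if len(set(flat)) != len(flat):
            raise ValueError("task names must be distinct")
        return cls(mi, scenes, names, desc)

    @classmethod
    def from_json(cls, path) -> "TaskMap":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def default(cls) -> "TaskMap":
        with resources.files("neurointent.data").joinpath(
                "task_map.json").open() as fh:
            return cls.from_dict(json.load(fh))

    @property
    def task_names(self) -> list[str]:
        return list(self.names.ravel())

    def lookup(self, mi_idx: int, scene_idx: int) -> tuple[str, str]:
        return (str(self.names[mi_idx, scene_idx]),
                str(self.descriptions[mi_idx, scene_idx]))


@dataclass
class TaskDecision:
    p_mi: np.ndarray
    p_scene: np.ndarray
    p_task: np.ndarray           # (n_mi, n_scenes)
    mi_idx: int
    scene_idx: int
    task_name: str
    command: str


def _validate_dist(p: np.ndarray, length: int, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (length,):
        raise ValueError(f"{name} must have length {length}, got {p.shape}")
    if np.any(p < 0):
        raise ValueError(f"{name} has negative entries")
    s = p.sum()
    if s <= 0:
        raise ValueError(f"{name} sums to zero")
    if abs(s - 1.0) > 1e-6:
        warnings.warn(f"{name} sums to {s:.6f}; renormalizing", RuntimeWarning,
                      stacklevel=3)
        p = p / s
    return p


def fuse(p_mi, p_scene, task_map: TaskMap | None = None,
         reject_threshold: float = 0.0) -> TaskDecision:
    """Product-of-posteriors fusion with lexicographic tie-breaking.

    Ties on the joint argmax resolve to the lowest (MI index, scene index)
    pair.  With ``reject_threshold`` > 0, a joint maximum below the threshold
    yields the command "reject" (task name None-like sentinel "REJECT").
    """
    task_map = task_map or TaskMap.default()
    p_mi = _validate_dist(p_mi, len(task_map.mi_classes), "P_MI")
    p_scene = _validate_dist(p_scene, len(task_map.scenes), "P_scene")
    p_task = np.outer(p_mi, p_scene)
    flat = np.argmax(p_task)  # argmax takes the first (lexicographic) maximum
    i, j = np.unravel_index(flat, p_task.shape)
    if reject_threshold > 0 and p_task[i, j] < reject_threshold:
        return TaskDecision(p_mi, p_scene, p_task, int(i), int(j),
                            "REJECT", "confidence below threshold")
    name, desc = task_map.lookup(int(i), int(j))
    return TaskDecision(p_mi, p_scene, p_task, int(i), int(j), name, desc)


def evaluate_tasks(predicted: list[str], truth: list[str],
                   task_map: TaskMap | None = None) -> pd.DataFrame:
    """Per-task accuracy table plus macro average over the 12-task label set."""
    task_map = task_map or TaskMap.default()
    valid = set(task_map.task_names)
    for lbl in list(predicted) + list(truth):
        if lbl not in valid:
            raise ValueError(f"label {lbl!r} outside the task set")
    pred = np.asarray(predicted, dtype=object)
    true = np.asarray(truth, dtype=object)
    if pred.shape != true.shape:
        raise ValueError("prediction/truth lists must align")
    rows = []
    accs = []
    for i, mi in enumerate(task_map.mi_classes):
        for j, scene in enumerate(task_map.scenes):
            name = str(task_map.names[i, j])
            mask = true == name
            n = int(mask.sum())
            acc = float((pred[mask] == name).mean()) if n else np.nan
            rows.append({"task": name, "scene": scene, "mi": mi,
                         "n": n, "accuracy": acc})
            if n:
                accs.append(acc)
    df = pd.DataFrame(rows)
    df.loc[len(df)] = {"task": "Average", "scene": "-", "mi": "-",
                       "n": int(len(true)),
                       "accuracy": float(np.mean(accs)) if accs else np.nan}
    return df
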