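"""Keep/waste decision making: logic gates and a quadratic-SVM classifier.

Two strategies, mirroring how an image-activated sorter is programmed:

* **Logic gating** — a conjunction of simple comparisons on droplet and
  cell features (e.g. ``cell_count == 1 AND ellipse_ratio <= 4``).
  Gates are AND-composed and order-independent; the rationale of a
  waste decision names the first failing gate.  Comparators are
  inclusive at the threshold, so "reject ellipse ratio higher than 4"
  keeps a cell at exactly 4.

* **Supervised classification** — a quadratic (degree-2 polynomial
  kernel) support vector machine over (Heywood circularity, area),
  trained on expert-labelled droplets from an imaging-cytometry run and
  then used to drive sorting in a later run.  Features are z-scored
  before the kernel fit since raw area (um^2) dwarfs circularity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import DropletRecord

# features evaluated per cell (gate passes only if every cell passes)
_CELL_FEATURES = {
    "ellipse_ratio", "heywood_circularity", "cell_area_um2",
    "waddel_disk_diameter_um", "max_feret_um",
}
_CELL_ATTR = {
    "ellipse_ratio": "ellipse_ratio",
    "heywood_circularity": "heywood_circularity",
    "cell_area_um2": "area_um2",
    "waddel_disk_diameter_um": "waddel_disk_diameter_um",
    "max_feret_um": "max_feret_um",
}
_RECORD_FEATURES = {
    "cell_count", "volume_pL", "droplet_area_um2", "droplet_circularity",
    "droplet_length_um", "droplet_width_um", "hole_area_um2",
}

_OPS = {
    "eq": lambda v, t: v == t,
    "le": lambda v, t: v <= t,
    "ge": lambda v, t: v >= t,
    "lt": lambda v, t: v < t,
    "gt": lambda v, t: v > t,
    "between": lambda v, t: t[0] <= v <= t[1],
}


@dataclass
class GateRule:
    """One comparison; gates AND-compose into a gate set."""

    feature: str
    op: str
    value: float | tuple[float, float]

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValueError(f"unknown comparator {self.op!r}")
        if self.feature not in _CELL_FEATURES | _RECORD_FEATURES:
            raise KeyError(f"unknown feature {self.feature!r}")
        if self.op == "between":
            lo, hi = self.value
            if lo > hi:
                raise ValueError("between bounds must be ordered")

    @classmethod
    def from_dict(cls, d: dict) -> "GateRule":
        value = d["value"]
        if isinstance(value, (list, tuple)):
            value = tuple(value)
        return cls(d["feature"], d["op"], value)

    def passes(self, record: DropletRecord) -> bool:
        fn = _OPS[self.op]
        if self.feature in _RECORD_FEATURES:
            return bool(fn(getattr(record, self.feature), self.value))
        attr = _CELL_ATTR[self.feature]
        return all(fn(getattr(c, attr), self.value) for c in record.cells)


@dataclass
class Decision:
    decision: str           # keep | waste
    rationale: str


def apply_gates(record: DropletRecord, gates: list[GateRule]) -> Decision:
    """Keep iff all gates pass; an empty gate list keeps everything."""
    for gate in gates:
        if not gate.passes(record):
            return Decision("waste",
                            f"failed gate {gate.feature} {gate.op} {gate.value}")
    return Decision("keep", "all gates passed")


# ---------------------------------------------------------------------------
# Quadratic SVM on (circularity, area)
# ---------------------------------------------------------------------------

class SingleCellClassifier:
    """Quadratic-kernel SVM separating single cells from clusters.

    Parameters
    ----------
    feature_names : tuple of str
        Input features, by default (heywood_circularity, area_um2).
    C : float
        SVM regularization constant (recorded in the artifact).
    seed : int
        Training seed, stored for replayable decisions.
    """

    KEEP_LABEL = "single"

    def __init__(self, feature_names=("heywood_circularity", "area_um2"),
                 C: float = 1.0, seed: int = 0):
        self.feature_names = tuple(feature_names)
        self.C = float(C)
        self.seed = int(seed)
        self._pipeline: Pipeline | None = None
        self.training_accuracy_: float | None = None
        self.training_confusion_: np.ndarray | None = None
        self.classes_: np.ndarray | None = None

    # -- training -----------------------------------------------------------
    def fit(self, X, y) -> "SingleCellClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError(f"X must be (n, {len(self.feature_names)})")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("training data contains a single class")
        if counts.min() < 2:
            raise ValueError("need at least 2 examples per class")
        self._pipeline = Pipeline([
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="poly", degree=2, coef0=1.0, C=self.C,
                        random_state=self.seed)),
        ])
        self._pipeline.fit(X, y)
        pred = self._pipeline.predict(X)
        self.classes_ = classes
        self.training_accuracy_ = float(np.mean(pred == y))
        self.training_confusion_ = confusion_matrix(y, pred, labels=classes)
        return self

    # -- inference ----------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        if self._pipeline is None:
            raise RuntimeError("classifier is not fitted")
        return self._pipeline.predict(np.asarray(X, dtype=float))

    def decision_margin(self, X) -> np.ndarray:
        if self._pipeline is None:
            raise RuntimeError("classifier is not fitted")
        return self._pipeline.decision_function(np.asarray(X, dtype=float))

    def _record_features(self, record: DropletRecord) -> np.ndarray:
        if not record.cells:
            raise ValueError("record has no cells to classify")
        cell = max(record.cells, key=lambda c: c.area_px)
        vals = []
        for name in self.feature_names:
            if name in _RECORD_FEATURES:
                vals.append(getattr(record, name))
            else:
                vals.append(getattr(cell, name if name != "cell_area_um2"
                                    else "area_um2"))
        return np.asarray(vals, dtype=float)

    def classify(self, record: DropletRecord) -> Decision:
        """Keep iff the predicted label is 'single'; margin in the rationale."""
        x = self._record_features(record)[None, :]
        label = str(self.predict(x)[0])
        margin = float(self.decision_margin(x)[0])
        decision = "keep" if label == self.KEEP_LABEL else "waste"
        return Decision(decision, f"label={label} margin={margin:+.3f}")

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Versioned JSON metadata + a joblib binary sidecar."""
        if self._pipeline is None:
            raise RuntimeError("classifier is not fitted")
        path = Path(path)
        meta = {
            "schema_version": 1,
            "feature_names": list(self.feature_names),
            "C": self.C,
            "seed": self.seed,
            "classes": [str(c) for c in self.classes_],
            "training_accuracy": self.training_accuracy_,
            "sidecar": path.with_suffix(".joblib").name,
        }
        path.write_text(json.dumps(meta, indent=2))
        joblib.dump(self._pipeline, path.with_suffix(".joblib"))

    @classmethod
    def load(cls, path: str | Path) -> "SingleCellClassifier":
        path = Path(path)
        meta = json.loads(path.read_text())
        clf = cls(feature_names=meta["feature_names"], C=meta["C"],
                  seed=meta["seed"])
        clf._pipeline = joblib.load(path.parent / meta["sidecar"])
        clf.classes_ = np.asarray(meta["classes"])
        clf.training_accuracy_ = meta["training_accuracy"]
        return clf


def train_classifier(X, y, seed: int = 0, C: float = 1.0,
                     feature_names=("heywood_circularity", "area_um2")
                     ) -> SingleCellClassifier:
    """Fit the quadratic SVM; deterministic for a fixed seed."""
    return SingleCellClassifier(feature_names=feature_names, C=C,
                                seed=seed).fit(X, y)
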