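"""GrayMax baseline: ordinal thresholds on the slide maximum gray value.

The simplest slide-level HER2 score uses only the single strongest patch:
the maximum per-patch mean membrane DAB absorbance.  Two thresholds
``t1 < t2`` split that statistic into the three reported IHC levels
(0/1+, 2+, 3+).  Thresholds are fitted by exhaustive search over midpoints
of the sorted training values, maximizing training accuracy; the baseline is
deliberately information-poor and serves as the comparison point for the
map-based CNN.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np

__all__ = ["GrayMaxClassifier", "fit_graymax", "predict_graymax"]

N_CLASSES = 3  # 0/1+, 2+, 3+


@dataclass
class GrayMaxClassifier:
    """Fitted two-threshold ordinal classifier on a scalar slide statistic."""

    t1: float
    t2: float

    def __post_init__(self) -> None:
        if not self.t1 < self.t2:
            raise ValueError(f"thresholds must satisfy t1 < t2, got {self.t1}, {self.t2}")

    def predict(self, values) -> np.ndarray:
        """Map values to ordinal classes 0 (0/1+), 1 (2+), 2 (3+).

        Bins are ``v < t1``, ``t1 <= v < t2``, ``v >= t2`` (top bin closed on
        the left, so a value exactly at t2 is class 2).
        """
        v = np.atleast_1d(np.asarray(values, dtype=float))
        return (v >= self.t1).astype(int) + (v >= self.t2).astype(int)

    @classmethod
    def fit(cls, values, labels) -> "GrayMaxClassifier":
        """Exhaustive midpoint search maximizing training accuracy.

        Candidate thresholds are midpoints between consecutive distinct
        sorted values; all ordered pairs are scored and ties resolve to the
        smallest (t1, t2) lexicographically.  Every class must be present.
        """
        v = np.asarray(values, dtype=float)
        y = np.asarray(labels, dtype=int)
        if v.shape != y.shape or v.ndim != 1:
            raise ValueError("values and labels must be 1-D and same length")
        present = set(np.unique(y))
        if not present.issuperset(range(N_CLASSES)):
            missing = sorted(set(range(N_CLASSES)) - present)
            raise ValueError(f"missing training class(es): {missing}")
        uniq = np.unique(v)
        mids = (uniq[:-1] + uniq[1:]) / 2.0
        if mids.size < 2:
            raise ValueError("need at least 3 distinct values to place two thresholds")
        best = (-1.0, None)
        for i, j in itertools.combinations(range(mids.size), 2):
            t1, t2 = mids[i], mids[j]
            pred = (v >= t1).astype(int) + (v >= t2).astype(int)
            acc = float((pred == y).mean())
            if acc > best[0]:  # strict: first (smallest) pair wins ties
                best = (acc, (t1, t2))
        return cls(*best[1])

    def to_json(self) -> str:
        return json.dumps({"t1": self.t1, "t2": self.t2})

    @classmethod
    def from_json(cls, s: str) -> "GrayMaxClassifier":
        d = json.loads(s)
        return cls(float(d["t1"]), float(d["t2"]))


def fit_graymax(values, labels) -> GrayMaxClassifier:
    """Functional alias for :meth:`GrayMaxClassifier.fit`."""
    return GrayMaxClassifier.fit(values, labels)


def predict_graymax(model: GrayMaxClassifier, values) -> np.ndarray:
    """Functional alias for :meth:`GrayMaxClassifier.predict`."""
    return model.predict(values)
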