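"""Representational dissimilarity matrices over the four task states.

Model RDMs are hypothesis-derived: the affordance model counts shared signed
actions between states (subtracted from the maximum of 2), the magnitude
model counts shared unsigned action magnitudes, and the link-distance model
uses shortest-path distance on the state-transition graph.  Behavioral RDMs
(reaction time, gaze position) are built per subject from summary values.

All RDMs share a single canonical vectorization — the upper triangle in the
fixed order (1-2, 1-3, 1-4, 2-3, 2-4, 3-4) — used by every downstream
correlation.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import N_STATES, StateActionGraph, link_distance_matrix

__all__ = [
    "RDM",
    "affordance_rdm",
    "magnitude_rdm",
    "linkdist_rdm",
    "behavior_rdm",
    "shared_successor_rdm",
    "upper_triangle",
    "from_upper_triangle",
]

_TRIU = np.triu_indices(N_STATES, k=1)


def upper_triangle(values: np.ndarray) -> np.ndarray:
    """Canonical 6-vector of a 4x4 symmetric matrix (order 1-2 ... 3-4)."""
    return np.asarray(values, dtype=float)[_TRIU]


def from_upper_triangle(vector: np.ndarray) -> np.ndarray:
    m = np.zeros((N_STATES, N_STATES))
    m[_TRIU] = vector
    return m + m.T


@dataclass(frozen=True)
class RDM:
    """Symmetric, zero-diagonal 4x4 dissimilarity matrix over states 1..4.

    Model RDMs hold nonnegative counts or distances; cross-validated neural
    RDMs may carry negative entries and use the same container.
    """

    values: np.ndarray
    labels: tuple[int, ...] = (1, 2, 3, 4)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_STATES, N_STATES):
            raise ValueError(f"expected 4x4 matrix, got {v.shape}")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("RDM diagonal must be zero")
        object.__setattr__(self, "values", v)

    @property
    def vector(self) -> np.ndarray:
        return upper_triangle(self.values)

    def entry(self, i: int, j: int) -> float:
        """Dissimilarity between states i and j (1-based labels)."""
        return float(self.values[self.labels.index(i), self.labels.index(j)])

    @classmethod
    def from_vector(cls, vector: np.ndarray, **kwargs) -> "RDM":
        return cls(values=from_upper_triangle(np.asarray(vector, float)), **kwargs)

    def normalized(self, method: str = "rms") -> "RDM":
        """Scale-free copy: vector divided by its root mean square ('rms'),
        or z-scored ('zscore')."""
        v = self.vector
        if method == "rms":
            s = np.sqrt(np.mean(v**2))
            if s == 0:
                raise ValueError("cannot normalize an all-zero RDM")
            out = v / s
        elif method == "zscore":
            sd = v.std()
            if sd == 0:
                raise ValueError("cannot z-score a constant RDM")
            out = (v - v.mean()) / sd
        else:
            raise ValueError(f"unknown normalization {method!r}")
        m = from_upper_triangle(out)
        return RDM(values=m, labels=self.labels, meta={**self.meta, "normalized": method})

    def to_dataframe(self) -> pd.DataFrame:
        names = [f"state{s}" for s in self.labels]
        return pd.DataFrame(self.values, index=names, columns=names)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    def to_json(self) -> str:
        return json.dumps({"labels": list(self.labels), "vector": self.vector.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "RDM":
        d = json.loads(text)
        return cls.from_vector(np.asarray(d["vector"]), labels=tuple(d["labels"]))

    @classmethod
    def read_csv(cls, path) -> "RDM":
        df = pd.read_csv(path, index_col=0)
        labels = tuple(int(c.removeprefix("state")) for c in df.columns)
        return cls(values=df.to_numpy(), labels=labels)


MAX_SHARED_ACTIONS = 2


def affordance_rdm(graph: StateActionGraph) -> RDM:
    """Count-based affordance dissimilarity: 2 minus the number of signed
    actions two states share.

    States affording the same two actions (e.g., 1 and 4, both -2/+2) have
    dissimilarity 0; one shared action gives 1; none gives 2.
    """
    vals = np.zeros((N_STATES, N_STATES))
    for i in range(N_STATES):
        for j in range(N_STATES):
            if i != j:
                shared = len(graph.affordances[i + 1] & graph.affordances[j + 1])
                vals[i, j] = MAX_SHARED_ACTIONS - shared
    return RDM(values=vals, meta={"model": "affordance"})


def magnitude_rdm(graph: StateActionGraph, semantics: str = "multiset") -> RDM:
    """Action-magnitude dissimilarity: 2 minus the number of shared unsigned
    action magnitudes.

    With ``semantics='multiset'`` (default) repeated magnitudes count
    individually — a state affording -2/+2 has magnitude multiset {2, 2} and
    is identical to any other +-2 state but shares only one magnitude with a
    +1/+2 state.  ``semantics='set'`` collapses repeats.
    """
    def mags(state: int):
        m = [abs(a) for a in graph.affordances[state]]
        return Counter(m) if semantics == "multiset" else Counter(set(m))

    if semantics not in ("multiset", "set"):
        raise ValueError(f"unknown semantics {semantics!r}")
    vals = np.zeros((N_STATES, N_STATES))
    for i in range(N_STATES):
        for j in range(N_STATES):
            if i != j:
                shared = sum((mags(i + 1) & mags(j + 1)).values())
                vals[i, j] = MAX_SHARED_ACTIONS - shared
    return RDM(values=vals, meta={"model": "magnitude", "semantics": semantics})


def linkdist_rdm(graph: StateActionGraph) -> RDM:
    """Link-distance model: minimum number of afforded-action steps between
    states (breadth-first search on the state graph)."""
    return RDM(values=link_distance_matrix(graph), meta={"model": "linkdist"})


def shared_successor_rdm(graph: StateActionGraph) -> RDM:
    """Dissimilarity as 2 minus the number of successor *states* two states
    share.  A diagnostic model: under the default affordances its vector
    correlates negatively (but not perfectly) with the magnitude model."""
    vals = np.zeros((N_STATES, N_STATES))
    for i in range(N_STATES):
        for j in range(N_STATES):
            if i != j:
                shared = len(
                    graph.successor_states(i + 1) & graph.successor_states(j + 1)
                )
                vals[i, j] = MAX_SHARED_ACTIONS - shared
    return RDM(values=vals, meta={"model": "shared_successor"})


def behavior_rdm(per_state_values: dict, metric: str = "absdiff") -> RDM:
    """Subject-specific behavioral RDM.

    ``metric='absdiff'`` takes the absolute difference of scalar values
    (e.g., mean reaction time per state); ``metric='euclidean'`` the 2D
    Euclidean distance between (x, y) pairs (e.g., median gaze position).
    """
    missing = [s for s in range(1, N_STATES + 1) if s not in per_state_values]
    if missing:
        raise ValueError(f"missing states {missing}")
    vals = np.zeros((N_STATES, N_STATES))
    for i in range(N_STATES):
        for j in range(N_STATES):
            if i == j:
                continue
            vi, vj = per_state_values[i + 1], per_state_values[j + 1]
            if metric == "absdiff":
                vals[i, j] = abs(float(vi) - float(vj))
            elif metric == "euclidean":
                vals[i, j] = float(np.linalg.norm(np.asarray(vi) - np.asarray(vj)))
            else:
                raise ValueError(f"unknown metric {metric!r}")
    return RDM(values=vals, meta={"model": f"behavior_{metric}"})
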