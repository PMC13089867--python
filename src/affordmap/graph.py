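"""State-action graph on the number line, and experiment schedules.

The task structure is a repeating module of four states laid out on
consecutive integers, followed by one unused ("gap") number, so the module
tiles the number line with period 5.  Each state affords exactly two signed
numerical actions; applying an afforded action from a state-bearing number
always lands on another state-bearing number (graph closure, checked at
construction).  Participant counterbalancing shifts the module offset along
the number line without changing the state-level structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DEFAULT_AFFORDANCES",
    "StateActionGraph",
    "TrialSequence",
    "TrainingSchedule",
    "build_graph",
    "state_of",
    "successors",
    "link_distance_matrix",
    "generate_run_sequence",
    "sample_isi_sequence",
    "truncated_exponential_rate",
    "make_training_schedule",
    "write_events_tsv",
    "read_events_tsv",
]

#: Afforded signed actions per state, as used throughout the experiment.
DEFAULT_AFFORDANCES: dict[int, frozenset[int]] = {
    1: frozenset({-2, +2}),
    2: frozenset({+1, +2}),
    3: frozenset({-2, -1}),
    4: frozenset({-2, +2}),
}

PERIOD = 5
N_STATES = 4

#: Response windows (seconds) for probe trials by session type.
RESPONSE_WINDOW = {"fmri": 1.4, "eyetracker": 1.2}

#: Mean inter-stimulus interval (seconds) by session type.
ISI_MEAN = {"fmri": 3.0, "eyetracker": 2.5}


class InvalidOffsetError(ValueError):
    """Offset violates the numbers-greater-than-20 rule."""


class NotAStateError(ValueError):
    """The queried number does not carry a state (gap or out of range)."""


class InfeasibleDesignError(ValueError):
    """Trial counts cannot satisfy the counterbalancing contract."""


class ConstraintFailure(RuntimeError):
    """ISI permutation search could not satisfy the correlation bound."""

    def __init__(self, best_rho: float, n_tried: int):
        self.best_rho = best_rho
        self.n_tried = n_tried
        super().__init__(
            f"|rho| < bound unsatisfied after {n_tried} permutations "
            f"(best {best_rho:.4f})"
        )


@dataclass(frozen=True)
class StateActionGraph:
    """Repeating four-state module tiled along the number line.

    Parameters
    ----------
    offset:
        Smallest state-bearing number; must exceed 20 so that stimuli avoid
        overlearned single-digit associations.
    n_modules:
        Number of module repetitions.
    affordances:
        Map from state id (1..4) to its set of signed actions.
    """

    offset: int
    n_modules: int
    affordances: Mapping[int, frozenset[int]] = field(
        default_factory=lambda: dict(DEFAULT_AFFORDANCES)
    )
    period: int = PERIOD

    def __post_init__(self):
        if self.offset <= 20:
            raise InvalidOffsetError(
                f"offset must be > 20, got {self.offset}"
            )
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        if set(self.affordances) != {1, 2, 3, 4}:
            raise ValueError("affordances must cover states 1..4")
        self._check_closure()

    def _check_closure(self) -> None:
        # Closure lives at the residue level: action a from within-module
        # position j must land on position (j + a) mod period in 0..3.
        for state, actions in self.affordances.items():
            j = state - 1
            for a in actions:
                if (j + a) % self.period >= N_STATES:
                    raise ValueError(
                        f"action {a:+d} from state {state} lands on a gap "
                        "number; graph is not closed"
                    )

    @property
    def numbers(self) -> np.ndarray:
        """All state-bearing numbers, ascending."""
        mods = np.arange(self.n_modules) * self.period
        return (self.offset + (mods[:, None] + np.arange(N_STATES))).ravel()

    def numbers_of_state(self, state: int) -> np.ndarray:
        return self.offset + (state - 1) + self.period * np.arange(self.n_modules)

    def state_of(self, number: int) -> int | None:
        lo = self.offset
        hi = self.offset + self.period * self.n_modules - 1
        if number < lo or number > hi:
            return None
        j = (number - lo) % self.period
        return j + 1 if j < N_STATES else None

    def successors(self, number: int) -> tuple[int, int]:
        state = self.state_of(number)
        if state is None:
            raise NotAStateError(f"{number} is not a state-bearing number")
        a, b = sorted(self.affordances[state])
        return (number + a, number + b)

    def successor_states(self, state: int) -> frozenset[int]:
        j = state - 1
        return frozenset(
            (j + a) % self.period + 1 for a in self.affordances[state]
        )

    def state_graph(self, directed: bool = False) -> nx.Graph:
        """The 4-node state-transition graph induced by the affordances."""
        g = nx.DiGraph() if directed else nx.Graph()
        g.add_nodes_from(range(1, N_STATES + 1))
        for s in range(1, N_STATES + 1):
            for t in self.successor_states(s):
                g.add_edge(s, t)
        return g

    def to_json(self) -> str:
        return json.dumps(
            {
                "offset": self.offset,
                "n_modules": self.n_modules,
                "period": self.period,
                "affordances": {
                    str(s): sorted(a) for s, a in self.affordances.items()
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StateActionGraph":
        d = json.loads(text)
        return cls(
            offset=d["offset"],
            n_modules=d["n_modules"],
            affordances={int(s): frozenset(a) for s, a in d["affordances"].items()},
            period=d.get("period", PERIOD),
        )


def build_graph(
    offset: int,
    n_modules: int,
    affordances: Mapping[int, frozenset[int]] | None = None,
) -> StateActionGraph:
    """Construct a closed state-action graph starting at ``offset``."""
    kwargs = {}
    if affordances is not None:
        kwargs["affordances"] = {s: frozenset(a) for s, a in affordances.items()}
    return StateActionGraph(offset=offset, n_modules=n_modules, **kwargs)


def state_of(number: int, graph: StateActionGraph) -> int | None:
    """State id (1..4) of ``number``, or None for gap/out-of-range numbers."""
    return graph.state_of(number)


def successors(number: int, graph: StateActionGraph) -> tuple[int, int]:
    """The two numbers reachable from ``number``, ascending."""
    return graph.successors(number)


def link_distance_matrix(graph: StateActionGraph) -> np.ndarray:
    """Minimum number of afforded-action steps between every pair of states.

    Distances are computed on the undirected state-transition graph; under
    the default affordances the directed distances coincide.  Unreachable
    pairs (possible only under overridden affordances) are ``inf``.
    """
    g = graph.state_graph(directed=False)
    dist = np.full((N_STATES, N_STATES), np.inf)
    np.fill_diagonal(dist, 0.0)
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, d in lengths.items():
            dist[src - 1, dst - 1] = d
    return dist


# ---------------------------------------------------------------------------
# Trial sequences


@dataclass
class TrialSequence:
    """One run of the recall task: stimulus trials with interleaved probes."""

    trials: pd.DataFrame
    run_id: int
    session: str

    @property
    def stimulus_trials(self) -> pd.DataFrame:
        return self.trials[~self.trials["is_probe"]]

    @property
    def probe_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["is_probe"]]

    def transition_counts(self) -> np.ndarray:
        """Ordered condition-transition counts over consecutive stimulus trials."""
        states = self.stimulus_trials["state"].to_numpy()
        counts = np.zeros((N_STATES, N_STATES), dtype=int)
        for a, b in zip(states[:-1], states[1:]):
            counts[a - 1, b - 1] += 1
        return counts


def _eulerian_condition_sequence(n_stim: int, rng: np.random.Generator) -> np.ndarray:
    """Serially balanced condition sequence over 4 states.

    The n_stim-1 ordered transitions are distributed over the 16 ordered
    state pairs (self-transitions included) as evenly as possible — each
    pair occurs floor or ceil of (n_stim-1)/16 times — by walking a random
    Eulerian path on the corresponding transition multigraph.  Conditions
    themselves occur exactly n_stim/4 times each.

    Because n_stim is a multiple of 4, the shortfall relative to a uniform
    ceil allocation is 1 (mod 4): it is realized by removing k disjoint
    directed 4-cycles (which keeps every in/out degree balanced) plus one
    single edge (which creates the Eulerian-path endpoints).
    """
    if n_stim == N_STATES:
        return rng.permutation(N_STATES) + 1
    n_trans = n_stim - 1
    base, extra = divmod(n_trans, 16)
    deficit = 16 - extra  # == 1 (mod 4) whenever n_stim is a multiple of 4
    if deficit % 4 != 1:
        raise InfeasibleDesignError(
            f"{n_stim} stimulus trials cannot be balanced over 4 conditions"
        )
    k = (deficit - 1) // 4
    # Remove `deficit` arcs from the uniform (base+1)-multigraph so that the
    # remainder admits an Eulerian path visiting every condition exactly
    # n_stim/4 times: removed out-degree k everywhere except k+1 at the path
    # end; removed in-degree k everywhere except k+1 at the path start.
    for _attempt in range(500):
        start, end = rng.choice(N_STATES, size=2, replace=False)
        removed = _sample_removal(base + 1, k, int(start), int(end), rng)
        if removed is None:
            continue
        mult = (base + 1) - removed
        g = nx.MultiDiGraph()
        g.add_nodes_from(range(N_STATES))
        edges = [
            (a, b)
            for a in range(N_STATES)
            for b in range(N_STATES)
            for _ in range(mult[a, b])
        ]
        for i in rng.permutation(len(edges)):  # random order randomizes the walk
            g.add_edge(*edges[i])
        if not nx.has_eulerian_path(g, source=int(start)):
            continue
        path = list(nx.eulerian_path(g, source=int(start)))
        seq = [path[0][0]] + [v for _, v in path]
        return np.asarray(seq) + 1
    raise InfeasibleDesignError(
        f"could not balance {n_trans} transitions over 16 ordered pairs"
    )


def _sample_removal(
    cap: int, k: int, start: int, end: int, rng: np.random.Generator
) -> np.ndarray | None:
    """Random arc multiset with out-degrees k (k+1 at ``end``), in-degrees k
    (k+1 at ``start``), and per-pair multiplicity at most ``cap``."""
    o_target = np.full(N_STATES, k)
    o_target[end] += 1
    i_target = np.full(N_STATES, k)
    i_target[start] += 1
    for _ in range(50):
        o, i = o_target.copy(), i_target.copy()
        c = np.full((N_STATES, N_STATES), cap)
        r = np.zeros((N_STATES, N_STATES), dtype=int)
        while o.sum() > 0:
            cand = [
                (a, b)
                for a in range(N_STATES)
                for b in range(N_STATES)
                if o[a] > 0 and i[b] > 0 and c[a, b] > 0
            ]
            if not cand:
                break
            a, b = cand[rng.integers(len(cand))]
            r[a, b] += 1
            o[a] -= 1
            i[b] -= 1
            c[a, b] -= 1
        else:
            return r
    return None


def sample_isi_sequence(
    n: int,
    mean: float,
    bounds: tuple[float, float] = (0.5, 8.0),
    model_rdms: Sequence[np.ndarray] | None = None,
    condition_sequence: np.ndarray | None = None,
    max_rho: float = 0.1,
    seed: int | np.random.Generator = 0,
    max_tries: int = 10_000,
) -> tuple[np.ndarray, int]:
    """Draw ISIs from a truncated exponential and order them so that ISI
    length is decorrelated from model-based distance of the flanking trials.

    The exponential rate is chosen so the post-truncation mean equals
    ``mean``.  If model RDMs and a condition sequence are given, the drawn
    ISIs are permuted until, for every model, the Spearman correlation
    between the ISI separating trials (t, t+1) and the model distance
    between their conditions is below ``max_rho`` in magnitude.

    Returns the ISI sequence and the number of permutations tried.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo, hi = bounds
    if not (lo < mean < (lo + hi) / 2):
        raise ValueError(
            f"mean {mean} not attainable on [{lo}, {hi}] with a truncated exponential"
        )
    lam = truncated_exponential_rate(mean, bounds)
    # Inverse-CDF sampling of the truncated exponential.
    u = rng.random(n)
    flo, fhi = 1 - np.exp(-lam * lo), 1 - np.exp(-lam * hi)
    isis = -np.log(1 - (flo + u * (fhi - flo))) / lam

    if not model_rdms or condition_sequence is None:
        return isis, 0

    cond = np.asarray(condition_sequence)
    dists = [
        np.asarray(m)[cond[:-1] - 1, cond[1:] - 1] for m in model_rdms
    ]

    def ok(order: np.ndarray) -> tuple[bool, float]:
        worst = 0.0
        vals = order[: len(cond) - 1]
        for d in dists:
            if np.all(d == d[0]):  # constant distances: rho 0 by convention
                continue
            rho = stats.spearmanr(vals, d).statistic
            if np.isnan(rho):
                rho = 0.0
            worst = max(worst, abs(rho))
            if worst >= max_rho:
                return False, worst
        return True, worst

    best = np.inf
    for tried in range(1, max_tries + 1):
        good, worst = ok(isis)
        if good:
            return isis, tried
        best = min(best, worst)
        isis = rng.permutation(isis)
    raise ConstraintFailure(best_rho=best, n_tried=max_tries)


def truncated_exponential_rate(mean: float, bounds: tuple[float, float]) -> float:
    """Rate of an exponential truncated to ``bounds`` with the given mean."""
    lo, hi = bounds

    def m(lam: float) -> float:
        elo, ehi = np.exp(-lam * lo), np.exp(-lam * hi)
        return 1 / lam + (lo * elo - hi * ehi) / (elo - ehi)

    return optimize.brentq(lambda l: m(l) - mean, 1e-8, 100.0)


def generate_run_sequence(
    graph: StateActionGraph,
    session: str = "fmri",
    n_trials: int = 80,
    n_probe: int = 16,
    seed: int | np.random.Generator = 0,
    run_id: int = 0,
    stim_duration: float = 1.5,
    isi_mean: float | None = None,
    isi_bounds: tuple[float, float] = (0.5, 8.0),
    model_rdms: Sequence[np.ndarray] | None = None,
    start_time: float = 2.0,
) -> TrialSequence:
    """Generate one counterbalanced run of the recall task.

    Stimulus-trial conditions form a serially balanced sequence (ordered
    transition counts differ by at most one); one quarter of stimulus trials
    are followed by probe trials presenting a candidate successor pair, half
    of which are the true successors.
    """
    if session not in RESPONSE_WINDOW:
        raise ValueError(f"session must be one of {sorted(RESPONSE_WINDOW)}")
    n_stim = n_trials - n_probe
    if n_stim % N_STATES != 0:
        raise InfeasibleDesignError(
            f"{n_stim} stimulus trials not divisible by {N_STATES} conditions"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    states = _eulerian_condition_sequence(n_stim, rng)

    # Stimulus numbers: a random module instance of the required state.
    numbers = np.array(
        [rng.choice(graph.numbers_of_state(s)) for s in states]
    )

    # Probe placement: attach each probe to a distinct stimulus trial.
    probe_after = np.sort(rng.choice(n_stim, size=n_probe, replace=False))
    probe_correct = rng.permutation(
        np.repeat([True, False], [n_probe // 2, n_probe - n_probe // 2])
    )

    isi_mean = ISI_MEAN[session] if isi_mean is None else isi_mean
    isis, _ = sample_isi_sequence(
        n_trials,
        isi_mean,
        bounds=isi_bounds,
        model_rdms=model_rdms,
        condition_sequence=states,
        seed=rng,
    )

    rows = []
    t = start_time
    isi_iter = iter(isis)
    probe_set = {int(i): bool(c) for i, c in zip(probe_after, probe_correct)}
    window = RESPONSE_WINDOW[session]
    for i, (s, num) in enumerate(zip(states, numbers)):
        isi = float(next(isi_iter))
        rows.append(
            dict(
                onset=t,
                duration=stim_duration,
                trial_type=f"state{s}",
                state=int(s),
                number=int(num),
                isi=isi,
                is_probe=False,
                probe_pair="",
                probe_correct=np.nan,
                response_window=np.nan,
            )
        )
        t += stim_duration + isi
        if i in probe_set:
            correct = probe_set[i]
            true_pair = graph.successors(int(num))
            pair = true_pair if correct else _foil_pair(graph, int(num), rng)
            pair = tuple(rng.permutation(pair))  # presented ordering randomized
            isi = float(next(isi_iter))
            rows.append(
                dict(
                    onset=t,
                    duration=stim_duration,
                    trial_type="probe",
                    state=int(s),
                    number=int(num),
                    isi=isi,
                    is_probe=True,
                    probe_pair=f"{pair[0]},{pair[1]}",
                    probe_correct=correct,
                    response_window=window,
                )
            )
            t += stim_duration + isi
    trials = pd.DataFrame(rows)
    trials.insert(0, "index", np.arange(len(trials)))
    return TrialSequence(trials=trials, run_id=run_id, session=session)


def _foil_pair(
    graph: StateActionGraph, number: int, rng: np.random.Generator
) -> tuple[int, int]:
    """An incorrect successor pair: perturb one true successor by +-1 or +-2
    so the pair is plausible (within range two) but wrong."""
    a, b = graph.successors(number)
    for _ in range(20):
        which = rng.integers(2)
        delta = int(rng.choice([-2, -1, 1, 2]))
        pair = (a + delta, b) if which == 0 else (a, b + delta)
        pair = tuple(sorted(pair))
        if pair != (a, b) and pair[0] != pair[1]:
            return pair
    return (a - 1, b)  # unreachable in practice


# ---------------------------------------------------------------------------
# Training schedule


@dataclass(frozen=True)
class TrainingSchedule:
    """Interleaved exploration/test blocks with optional extended
    generalization tests on novel numbers."""

    n_blocks: int
    exploration_per_block: int = 16
    tests_per_block: int = 18
    extended_after: tuple[int, ...] = ()
    extended_n_trials: int = 24

    @property
    def total_test_trials(self) -> int:
        return self.n_blocks * self.tests_per_block

    @property
    def total_generalization_trials(self) -> int:
        return len(self.extended_after) * self.extended_n_trials


def make_training_schedule(
    n_blocks: int, extended_after: Sequence[int] = ()
) -> TrainingSchedule:
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    for b in extended_after:
        if not (1 <= b <= n_blocks):
            raise ValueError(f"extended test after block {b} out of range")
    return TrainingSchedule(n_blocks=n_blocks, extended_after=tuple(extended_after))


# ---------------------------------------------------------------------------
# Events IO (BIDS-style events.tsv)

EVENTS_COLUMNS = [
    "onset",
    "duration",
    "trial_type",
    "state",
    "number",
    "isi",
    "is_probe",
    "probe_pair",
    "probe_correct",
    "response_window",
]


def write_events_tsv(sequence: TrialSequence, path) -> None:
    sequence.trials[EVENTS_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events_tsv(path, run_id: int = 0, session: str = "fmri") -> TrialSequence:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    df["is_probe"] = df["is_probe"].astype(bool)
    df["probe_pair"] = df["probe_pair"].fillna("")
    df.insert(0, "index", np.arange(len(df)))
    return TrialSequence(trials=df, run_id=run_id, session=session)
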