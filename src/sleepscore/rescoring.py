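"""Manual re-evaluation of autoscored epochs.

The rescoring workflow selects epochs by state or by state transition
from an autoscored matrix, lets the user relabel individual epochs, and
records every change in an edit log so the rescored matrix can be
reproduced from the original plus the log.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import ScoredMatrix, State

__all__ = [
    "TransitionQuery",
    "RelabelEdit",
    "find_epochs",
    "apply_edits",
    "rescored_fraction",
    "read_edits",
]


@dataclass(frozen=True)
class TransitionQuery:
    """Select epochs by state and/or by the transition leading to them.

    With both ``from_state`` and ``to_state`` set, matches the first
    epoch of the new state (index i where state[i-1] = from and
    state[i] = to). With only ``to_state`` (or only ``from_state``)
    set, matches all epochs in that state. At least one side must be
    given.
    """

    from_state: State | None = None
    to_state: State | None = None

    def __post_init__(self) -> None:
        if self.from_state is None and self.to_state is None:
            raise ValueError("at least one of from_state/to_state required")


@dataclass(frozen=True)
class RelabelEdit:
    """One manual correction: set epoch ``epoch_index`` to ``new_state``."""

    epoch_index: int
    new_state: State

    def __post_init__(self) -> None:
        if self.epoch_index < 0:
            raise ValueError(f"negative epoch index {self.epoch_index}")
        if self.new_state is State.ARTIFACT:
            raise ValueError("manual relabeling assigns WAKE/NREMS/REMS only")


def find_epochs(
    m: ScoredMatrix, q: TransitionQuery, skip_artifacts: bool = False
) -> np.ndarray:
    """Indices of epochs matching a state or transition query.

    For transitions the reported index is the first epoch of the NEW
    state. ``skip_artifacts`` makes ARTIFACT epochs transparent: a
    transition is then detected between the nearest non-artifact
    neighbours; otherwise an intervening artifact breaks it.
    """
    states = m.states
    if q.from_state is None or q.to_state is None:
        single = q.to_state if q.to_state is not None else q.from_state
        return np.flatnonzero(states == single.value)

    if skip_artifacts:
        keep = np.flatnonzero(states != State.ARTIFACT.value)
        sub = states[keep]
        hits = np.flatnonzero(
            (sub[:-1] == q.from_state.value) & (sub[1:] == q.to_state.value)
        )
        return keep[hits + 1]
    hits = np.flatnonzero(
        (states[:-1] == q.from_state.value) & (states[1:] == q.to_state.value)
    )
    return hits + 1


def apply_edits(
    m: ScoredMatrix, edits: list[RelabelEdit]
) -> tuple[ScoredMatrix, list[tuple[int, State, State]]]:
    """Apply relabel edits in order; later edits to an index win.

    Only the state column changes; feature columns are untouched.
    Returns the rescored matrix and the edit log of effective
    (index, old_state, new_state) changes — replaying the log on the
    original matrix reproduces the rescored one.
    """
    states = m.states.copy()
    log: list[tuple[int, State, State]] = []
    for e in edits:
        if e.epoch_index >= m.n_epochs:
            raise IndexError(
                f"epoch index {e.epoch_index} out of range "
                f"(matrix has {m.n_epochs} epochs)"
            )
        old = State(int(states[e.epoch_index]))
        states[e.epoch_index] = e.new_state.value
        log.append((e.epoch_index, old, e.new_state))
    return m.with_states(states), log


def rescored_fraction(before: ScoredMatrix, after: ScoredMatrix) -> float:
    """Fraction of epochs whose state differs between two matrices."""
    if before.n_epochs != after.n_epochs:
        raise ValueError(
            f"epoch counts differ: {before.n_epochs} vs {after.n_epochs}"
        )
    return float(np.mean(before.states != after.states))


def read_edits(path: str | Path) -> list[RelabelEdit]:
    """Read an edit list: two tab-separated columns per line,
    epoch index and state (integer code or name)."""
    edits: list[RelabelEdit] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) != 2:
                raise ValueError(
                    f"{path}: expected 2 tab-separated columns on line {lineno}"
                )
            try:
                idx = int(cells[0])
                state = State.parse(cells[1])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            edits.append(RelabelEdit(idx, state))
    return edits
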