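"""Branch-level expression-state transitions and duplication-vs-speciation tests."""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import fisher_exact

from .trees import DUPLICATION, SPECIATION, GeneTree

__all__ = ["TransitionTally", "tally_transitions", "fisher_event_association"]


@dataclass
class TransitionTally:
    """Branch counts indexed by (parent state, child state, parent event).

    Each scored branch contributes exactly one cell; a branch is "changed"
    when parent and child states differ.  Branches inherit the event type of
    their parent node; the root itself has no branch above it.
    """

    counts: Counter = field(default_factory=Counter)

    def add(self, parent_state: str, child_state: str, parent_event: str) -> None:
        self.counts[(parent_state, child_state, parent_event)] += 1

    def update(self, other: "TransitionTally") -> None:
        self.counts.update(other.counts)

    @property
    def n_branches(self) -> int:
        return sum(self.counts.values())

    def n_changed(self) -> int:
        return sum(v for (p, c, _e), v in self.counts.items() if p != c)

    def states(self) -> set[str]:
        out: set[str] = set()
        for p, c, _e in self.counts:
            out.update((p, c))
        return out

    def table_for_state(self, state: str) -> pd.DataFrame:
        """2x2 table over branches whose child state is ``state``.

        Rows: parent event (duplication, speciation); columns: changed into
        the state (parent differs) vs unchanged (parent already in it).
        """
        data = {
            ev: [
                sum(
                    v
                    for (p, c, e), v in self.counts.items()
                    if c == state and e == ev and p != c
                ),
                sum(
                    v
                    for (p, c, e), v in self.counts.items()
                    if c == state and e == ev and p == c
                ),
            ]
            for ev in (DUPLICATION, SPECIATION)
        }
        return pd.DataFrame(data, index=["changed", "unchanged"]).T

    def overall_table(self) -> pd.DataFrame:
        """2x2 table over all branches: parent event x changed/unchanged."""
        data = {
            ev: [
                sum(v for (p, c, e), v in self.counts.items() if e == ev and p != c),
                sum(v for (p, c, e), v in self.counts.items() if e == ev and p == c),
            ]
            for ev in (DUPLICATION, SPECIATION)
        }
        return pd.DataFrame(data, index=["changed", "unchanged"]).T

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "parent_state": p,
                "child_state": c,
                "parent_event": e,
                "n": v,
                "changed": p != c,
            }
            for (p, c, e), v in sorted(self.counts.items())
        ]
        return pd.DataFrame(
            rows, columns=["parent_state", "child_state", "parent_event", "n", "changed"]
        )


def tally_transitions(tree: GeneTree, node_states: dict[str, str]) -> TransitionTally:
    """Score every branch of ``tree`` by (parent state, child state, parent event).

    ``node_states`` maps node labels (tips and internals) to expression
    states.  Every internal node must carry an event label.
    """
    tally = TransitionTally()
    for parent, child in tree.branches():
        if parent.event is None:
            raise ValueError(f"unlabeled internal node: {parent.label!r}")
        try:
            ps = node_states[parent.label]
            cs = node_states[child.label]
        except KeyError as exc:
            raise KeyError(f"missing state for node {exc.args[0]!r}") from exc
        tally.add(ps, cs, parent.event)
    return tally


def fisher_event_association(
    tally: TransitionTally,
    states: list[str] | None = None,
    include_overall: bool = False,
) -> pd.DataFrame:
    """Two-sided Fisher's exact tests of change-rate vs parent event type.

    One 2x2 table per focal child state (duplication/speciation x
    changed/unchanged), Bonferroni-corrected over the tests performed.  An
    empty margin (no branches for a row or column) yields p = 1 with a
    warning.  Returns a DataFrame with the table cells, p-value, Bonferroni-
    adjusted p, and significance call at 0.05.
    """
    if tally.n_branches == 0:
        raise ValueError("empty transition tally")
    if states is None:
        states = sorted({c for (_p, c, _e) in tally.counts})
    rows = []
    for state in states:
        tab = tally.table_for_state(state)
        rows.append((state, tab))
    if include_overall:
        rows.append(("__overall__", tally.overall_table()))

    records = []
    for state, tab in rows:
        arr = tab.to_numpy()
        if arr.sum(axis=1).min() == 0 or arr.sum(axis=0).min() == 0:
            warnings.warn(
                f"empty margin in Fisher table for state {state!r}; p set to 1",
                stacklevel=2,
            )
            p = 1.0
        else:
            _odds, p = fisher_exact(arr, alternative="two-sided")
        records.append(
            {
                "state": state,
                "dup_changed": int(arr[0, 0]),
                "dup_unchanged": int(arr[0, 1]),
                "spec_changed": int(arr[1, 0]),
                "spec_unchanged": int(arr[1, 1]),
                "p": float(p),
            }
        )
    out = pd.DataFrame(records)
    m = len(out)
    out["p_bonferroni"] = (out["p"] * m).clip(upper=1.0)
    out["significant"] = out["p_bonferroni"] < 0.05
    return out
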