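"""End-to-end evolutionary analysis of expression on gene trees.

For every eligible family: per-tissue BM ancestral reconstruction, node
state classification, branch transition scoring.  Globally: pooled
transition tally, per-gland Fisher duplication-vs-speciation tests with
Bonferroni correction, and D-statistics for the 2-fold-silk trait plus one
binary trait per gland.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .asr import MULTIPLE, NOT_SILK, bm_ancestral_states, classify_node_state
from .dstat import DStatResult, d_statistic
from .transitions import TransitionTally, fisher_event_association, tally_transitions
from .trees import GeneTree, label_events_species_overlap

__all__ = ["PhyloPipelineResult", "reconstruct_states", "run_phylo_pipeline"]


@dataclass
class PhyloPipelineResult:
    node_states: dict[str, dict[str, str]]  # cluster -> node label -> state
    node_values: dict[str, pd.DataFrame]  # cluster -> node x tissue ML values
    tally: TransitionTally
    per_tree_tallies: dict[str, TransitionTally]
    fisher: pd.DataFrame
    dstat: pd.DataFrame
    summary: dict = field(default_factory=dict)


def _tip_profile(
    tree: GeneTree, tissue_profiles: pd.DataFrame, cluster: str
) -> pd.DataFrame:
    """Tip-label x tissue matrix for one tree, from a (species, tissue) table."""
    rows = {}
    for tip in tree.tips():
        sp, tx = tip.species, tip.transcript
        if sp not in tissue_profiles.columns.get_level_values("species"):
            raise KeyError(f"cluster {cluster!r}: no profiles for species {sp!r}")
        prof = tissue_profiles[sp]
        if tx not in prof.index:
            raise KeyError(f"cluster {cluster!r}: missing profile for {tip.label!r}")
        rows[tip.label] = prof.loc[tx]
    return pd.DataFrame(rows).T


def reconstruct_states(
    tree: GeneTree,
    tip_profile: pd.DataFrame,
    silk_glands: list[str],
    non_silk: list[str],
) -> tuple[dict[str, str], pd.DataFrame]:
    """Per-tissue BM ancestral values and the resulting node states.

    ``tip_profile`` is tip-label x tissue observed mean FPKM.  Each tissue
    is reconstructed independently; classification floors negative
    estimates at 0 but the raw estimates are returned unmodified.
    """
    tissues = list(tip_profile.columns)
    values: dict[str, dict[str, float]] = {}
    for tissue in tissues:
        anc = bm_ancestral_states(tree, tip_profile[tissue].to_dict())
        for node, v in anc.values.items():
            values.setdefault(node, {})[tissue] = v
    value_df = pd.DataFrame(values).T.reindex(columns=tissues)
    states = {
        node: classify_node_state(value_df.loc[node], silk_glands, non_silk)
        for node in value_df.index
    }
    return states, value_df


def run_phylo_pipeline(
    trees: dict[str, GeneTree],
    tissue_profiles: pd.DataFrame,
    silk_glands: list[str],
    non_silk: list[str],
    eligible: list[str] | None = None,
    n_perm: int = 1000,
    n_bm: int = 1000,
    seed: int | None = 0,
    min_dstat_tips: int = 4,
    do_dstat: bool = True,
) -> PhyloPipelineResult:
    """Run reconstruction, transition tallying, Fisher and D-stat analyses.

    ``tissue_profiles`` is a transcript x (species, tissue) mean-FPKM table
    covering every tip of every tree.  ``eligible`` restricts the clusters
    analyzed (default: all trees).  Internal nodes without event labels are
    labeled by species overlap.
    """
    if eligible is None:
        eligible = sorted(trees)
    missing = [c for c in eligible if c not in trees]
    if missing:
        raise KeyError(f"no tree for clusters: {missing[:5]}")
    rng = np.random.default_rng(seed)

    node_states: dict[str, dict[str, str]] = {}
    node_values: dict[str, pd.DataFrame] = {}
    per_tree: dict[str, TransitionTally] = {}
    pooled = TransitionTally()
    dstat_rows = []

    for cluster in eligible:
        tree = trees[cluster]
        if any(nd.event is None for nd in tree.internal_nodes()):
            label_events_species_overlap(tree)
        profile = _tip_profile(tree, tissue_profiles, cluster)
        states, values = reconstruct_states(tree, profile, silk_glands, non_silk)
        node_states[cluster] = states
        node_values[cluster] = values
        tally = tally_transitions(tree, states)
        per_tree[cluster] = tally
        pooled.update(tally)

        if do_dstat and tree.n_tips >= min_dstat_tips:
            tip_states = {t.label: states[t.label] for t in tree.tips()}
            traits: dict[str, dict[str, int]] = {
                "silk_2fold": {
                    lbl: int(s != NOT_SILK) for lbl, s in tip_states.items()
                }
            }
            for gland in silk_glands:
                if any(s == gland for s in tip_states.values()):
                    traits[gland] = {
                        lbl: int(s == gland) for lbl, s in tip_states.items()
                    }
            for trait_name, trait in traits.items():
                res: DStatResult = d_statistic(tree, trait, n_perm=n_perm, n_bm=n_bm, seed=rng)
                dstat_rows.append(
                    {
                        "cluster": cluster,
                        "trait": trait_name,
                        "d": res.d,
                        "d_obs": res.d_obs,
                        "perm_mean": res.perm_mean,
                        "bm_mean": res.bm_mean,
                        "degenerate": res.degenerate,
                        "n_tips": res.n_tips,
                    }
                )

    fisher = fisher_event_association(pooled, include_overall=True)
    dstat = pd.DataFrame(
        dstat_rows,
        columns=["cluster", "trait", "d", "d_obs", "perm_mean", "bm_mean", "degenerate", "n_tips"],
    )

    n_trees = len(eligible)
    trees_changed = sum(1 for t in per_tree.values() if t.n_changed() > 0)
    summary = {
        "n_trees": n_trees,
        "n_branches": pooled.n_branches,
        "n_changed_branches": pooled.n_changed(),
        "share_trees_with_change": trees_changed / n_trees if n_trees else float("nan"),
        "share_unchanged_branches": (
            1.0 - pooled.n_changed() / pooled.n_branches if pooled.n_branches else float("nan")
        ),
        "states_observed": sorted(pooled.states()),
    }
    return PhyloPipelineResult(
        node_states=node_states,
        node_values=node_values,
        tally=pooled,
        per_tree_tallies=per_tree,
        fisher=fisher,
        dstat=dstat,
        summary=summary,
    )
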