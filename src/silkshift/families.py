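"""Cross-species gene-family handling.

Family membership (homology clusters) is an input: a table of
(cluster_id, species, transcript) rows produced by an external homology
tool.  Operations here filter to families represented in every study
species, aggregate per-tissue expression within families, class families by
how many species contribute an over-expressed silk transcript, and select
families eligible for tree-based analysis.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "FamilyMap",
    "three_species_filter",
    "family_tissue_sum",
    "oest_sharing_classes",
    "tree_eligibility",
]


class FamilyMap:
    """cluster_id -> set of (species, transcript), with uniqueness checks."""

    def __init__(self, table: pd.DataFrame):
        required = {"cluster_id", "species", "transcript"}
        if not required.issubset(table.columns):
            raise ValueError(f"family map needs columns {sorted(required)}")
        table = table[["cluster_id", "species", "transcript"]].copy()
        dup = table.duplicated(subset=["species", "transcript"], keep=False)
        if dup.any():
            multi = table.loc[dup].groupby(["species", "transcript"])["cluster_id"].nunique()
            if (multi > 1).any():
                bad = list(multi.index[multi > 1])[:5]
                raise ValueError(f"transcripts in more than one cluster: {bad}")
            table = table.drop_duplicates()
        self.table = table.reset_index(drop=True)

    @property
    def cluster_ids(self) -> list:
        return sorted(self.table["cluster_id"].unique())

    def members(self, cluster_id) -> set[tuple[str, str]]:
        sub = self.table[self.table["cluster_id"] == cluster_id]
        return set(zip(sub["species"], sub["transcript"]))

    def species_per_cluster(self) -> pd.Series:
        return self.table.groupby("cluster_id")["species"].nunique()

    def __len__(self) -> int:
        return self.table["cluster_id"].nunique()

    def __eq__(self, other) -> bool:
        if not isinstance(other, FamilyMap):
            return NotImplemented
        a = self.table.sort_values(list(self.table.columns)).reset_index(drop=True)
        b = other.table.sort_values(list(other.table.columns)).reset_index(drop=True)
        return a.equals(b)


def three_species_filter(fmap: FamilyMap, species) -> FamilyMap:
    """Keep clusters with at least one member from every listed species."""
    species = set(species)
    if not species:
        raise ValueError("empty species set")
    if len(fmap.table) == 0:
        return FamilyMap(fmap.table)
    per = fmap.table.groupby("cluster_id")["species"].agg(lambda s: species.issubset(set(s)))
    keep = set(per.index[per])
    return FamilyMap(fmap.table[fmap.table["cluster_id"].isin(keep)])


def family_tissue_sum(fmap: FamilyMap, tissue_profiles: pd.DataFrame) -> pd.DataFrame:
    """Summed member mean FPKM per cluster, species-specifically per tissue.

    ``tissue_profiles`` is transcript x (species, tissue) MultiIndex columns
    (one row per transcript, as produced by ``mean_tissue_fpkm``).  Returns
    cluster x (species, tissue).  A member transcript without a profile row
    in its species is an error naming the transcript.
    """
    records = []
    for cluster_id, sub in fmap.table.groupby("cluster_id"):
        row = {}
        for species, ssub in sub.groupby("species"):
            if species not in tissue_profiles.columns.get_level_values("species"):
                raise KeyError(f"no profiles for species {species!r}")
            prof = tissue_profiles[species]
            missing = set(ssub["transcript"]) - set(prof.index)
            if missing:
                raise KeyError(
                    f"cluster {cluster_id!r}: transcript {sorted(missing)[0]!r} "
                    f"missing from {species!r} profiles"
                )
            sums = prof.loc[list(ssub["transcript"])].sum(axis=0)
            for tissue, v in sums.items():
                row[(species, tissue)] = v
        records.append(pd.Series(row, name=cluster_id))
    out = pd.DataFrame(records)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["species", "tissue"])
    return out.fillna(0.0).sort_index()


def oest_sharing_classes(
    fmap: FamilyMap, oest_sets: dict[str, set[str]]
) -> tuple[pd.Series, pd.Series]:
    """Number of species contributing >= 1 OEST per cluster, plus leftovers.

    Returns ``(classes, unclustered)``: ``classes`` maps each cluster with
    at least one OEST to 1, 2 or 3 (distinct contributing species);
    clusters without OESTs are excluded.  ``unclustered`` tallies OESTs not
    in any cluster of ``fmap``, keyed by species.
    """
    classes = {}
    seen: set[tuple[str, str]] = set()
    for cluster_id, sub in fmap.table.groupby("cluster_id"):
        contributing = set()
        for species, ssub in sub.groupby("species"):
            hits = set(ssub["transcript"]) & oest_sets.get(species, set())
            if hits:
                contributing.add(species)
            seen.update((species, t) for t in ssub["transcript"])
        if contributing:
            classes[cluster_id] = len(contributing)
    unclustered = {
        species: sum(1 for t in oests if (species, t) not in seen)
        for species, oests in oest_sets.items()
    }
    return pd.Series(classes, dtype=int), pd.Series(unclustered, dtype=int)


def tree_eligibility(
    fmap: FamilyMap,
    flags: dict[str, pd.DataFrame],
    per_species: bool = True,
) -> list:
    """Clusters eligible for ancestral-state analysis.

    ``flags`` maps species -> DataFrame with boolean columns ``twofold`` and
    ``fpkm_gt1`` indexed by transcript (from ``twofold_silk_flag``).  With
    ``per_species=True`` (default) a cluster is eligible iff every species
    has >= 1 member transcript satisfying both flags in that same
    transcript; with ``per_species=False`` one qualifying transcript
    anywhere suffices.
    """
    eligible = []
    for cluster_id, sub in fmap.table.groupby("cluster_id"):
        ok_by_species = []
        for species, ssub in sub.groupby("species"):
            fl = flags.get(species)
            if fl is None:
                ok_by_species.append(False)
                continue
            members = [t for t in ssub["transcript"] if t in fl.index]
            ok = bool(
                members
                and (fl.loc[members, "twofold"] & fl.loc[members, "fpkm_gt1"]).any()
            )
            ok_by_species.append(ok)
        if (all(ok_by_species) if per_species else any(ok_by_species)):
            eligible.append(cluster_id)
    return sorted(eligible)
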