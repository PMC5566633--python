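"""Synthetic study generator with ground truth for every pipeline stage.

Generates gene trees by birth-death simulation along a species tree,
evolves tissue expression profiles by Brownian motion on log(FPKM + 1)
with planted gland-specific shifts, and draws negative-binomial counts
emulating expected-count estimates.  All randomness flows through a single
``numpy.random.Generator`` so the full bundle is bit-reproducible under a
fixed seed; draws occur in documented order (trees, then expression in
tree order, then counts library by library).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .families import FamilyMap
from .normalize import CountMatrix
from .phyloexpr.asr import classify_node_state
from .phyloexpr.trees import (
    DUPLICATION,
    SPECIATION,
    GeneTree,
    Node,
    read_gene_tree,
)

__all__ = [
    "StudyDesign",
    "ShiftSpec",
    "SimTruth",
    "StudyBundle",
    "SimulationError",
    "default_design",
    "simulate_gene_tree",
    "simulate_expression",
    "simulate_counts",
    "generate_study",
    "load_config",
]

# the study layout: 3 cobweb-weaver-like species, ((Lg,Lh),Sg)
DEFAULT_SPECIES_NEWICK = "((Lg:0.5,Lh:0.5):0.5,Sg:1.0);"
SILK_GLANDS = ["MA", "MI", "AcF", "Tu", "Py", "AGant", "AGpost"]
NON_SILK = ["cephalothorax", "ovary", "venom"]


class SimulationError(RuntimeError):
    pass


@dataclass
class StudyDesign:
    """Species, tissues and replication structure of a simulated study."""

    species_newick: str = DEFAULT_SPECIES_NEWICK
    silk_glands: list[str] = field(default_factory=lambda: list(SILK_GLANDS))
    non_silk: list[str] = field(default_factory=lambda: list(NON_SILK))
    replicates_per_tissue: dict[str, int] = field(default_factory=dict)
    library_size: int = 2_000_000

    def __post_init__(self):
        overlap = set(self.silk_glands) & set(self.non_silk)
        if overlap:
            raise ValueError(f"tissues in both classes: {sorted(overlap)}")
        if not self.silk_glands or not self.non_silk:
            raise ValueError("need both silk-gland and non-silk tissues")
        for t in self.tissues:
            self.replicates_per_tissue.setdefault(t, 2)
        bad = [t for t, r in self.replicates_per_tissue.items() if r < 1]
        if bad:
            raise ValueError(f"tissues with <1 replicate: {bad}")
        if self.library_size <= 0:
            raise ValueError("library size must be > 0")
        unknown = set(self.replicates_per_tissue) - set(self.tissues)
        if unknown:
            raise ValueError(f"replicate spec for unknown tissues: {sorted(unknown)}")

    @property
    def tissues(self) -> list[str]:
        return self.silk_glands + self.non_silk

    @property
    def species_tree(self) -> GeneTree:
        return read_gene_tree(self.species_newick)

    @property
    def species(self) -> list[str]:
        return [t.name for t in self.species_tree.tips()]

    def libraries(self, species: str) -> list[tuple[str, str, int]]:
        """(library id, tissue, replicate) triples for one species."""
        out = []
        for tissue in self.tissues:
            for rep in range(1, self.replicates_per_tissue[tissue] + 1):
                out.append((f"{species}_{tissue}_r{rep}", tissue, rep))
        return out


def default_design() -> StudyDesign:
    """Design emulating the study: ~2 replicates per tissue, some with 1."""
    reps = {t: 2 for t in SILK_GLANDS + NON_SILK}
    reps["Py"] = 1
    reps["Tu"] = 1
    return StudyDesign(replicates_per_tissue=reps)


@dataclass
class ShiftSpec:
    """A planted expression shift on the branch above ``node``.

    The profile of ``node`` (and, by inheritance, its descendants) has the
    target tissue(s) multiplied by ``multiplier`` on the FPKM scale.
    """

    node: str
    tissues: list[str]
    multiplier: float


@dataclass
class SimTruth:
    """Planted truth for one gene tree."""

    node_profiles: dict[str, pd.Series]  # node label -> tissue -> FPKM
    node_states: dict[str, str]
    shift_branches: list[str]  # child-node labels of shifted branches


@dataclass
class StudyBundle:
    count_matrices: dict[str, CountMatrix]  # per species
    family_map: FamilyMap
    trees: dict[str, GeneTree]
    truths: dict[str, SimTruth]
    tip_profiles: pd.DataFrame  # transcript x (species, tissue) true FPKM
    oest_truth: dict[str, set[str]]  # species -> truly silk-specific transcripts
    design: StudyDesign


# --------------------------------------------------------------------------
# gene trees


def _evolve_lineage(
    species_node: Node,
    t_remaining: float,
    birth_rate: float,
    loss_rate: float,
    rng: np.random.Generator,
) -> Node | None:
    """One gene lineage evolving down the species-tree branch above
    ``species_node``; returns the surviving gene subtree or None."""
    elapsed = 0.0
    total = birth_rate + loss_rate
    while True:
        wait = rng.exponential(1.0 / total) if total > 0 else np.inf
        if elapsed + wait >= t_remaining:
            break
        elapsed += wait
        if rng.random() < birth_rate / total:
            # duplication: two sublineages finish the branch independently
            left = _evolve_lineage(species_node, t_remaining - elapsed, birth_rate, loss_rate, rng)
            right = _evolve_lineage(species_node, t_remaining - elapsed, birth_rate, loss_rate, rng)
            if left is None and right is None:
                return None
            if left is None or right is None:
                survivor = left if left is not None else right
                survivor.length += elapsed
                return survivor
            dup = Node(event=DUPLICATION, length=elapsed)
            dup.add_child(left)
            dup.add_child(right)
            return dup
        return None  # loss

    # reached the species node
    if species_node.is_leaf:
        return Node(species=species_node.name, length=t_remaining)
    kids = [
        _evolve_lineage(ch, ch.length, birth_rate, loss_rate, rng)
        for ch in species_node.children
    ]
    kids = [k for k in kids if k is not None]
    if not kids:
        return None
    if len(kids) == 1:
        kids[0].length += t_remaining
        return kids[0]
    spec = Node(event=SPECIATION, length=t_remaining)
    for k in kids:
        spec.add_child(k)
    return spec


def simulate_gene_tree(
    species_tree: GeneTree,
    birth_rate: float,
    loss_rate: float,
    seed: int | np.random.Generator | None = None,
    max_retries: int = 100,
) -> GeneTree:
    """Birth-death gene-tree simulation along a rooted species tree.

    Duplications bifurcate a lineage in place; losses prune it.  Trees
    missing any species are discarded and resimulated (up to
    ``max_retries``); an all-extinct family after the retries raises
    :class:`SimulationError`.  With both rates 0 the result is
    topologically identical to the species tree with every internal node a
    speciation.
    """
    if birth_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be >= 0")
    if species_tree.n_tips < 2:
        raise ValueError("species tree needs >= 2 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    want = {t.name for t in species_tree.tips()}
    for _ in range(max_retries):
        root = _evolve_lineage(species_tree.root, 0.0, birth_rate, loss_rate, rng)
        if root is None:
            continue
        root.length = 0.0
        tree = GeneTree(root)
        if tree.species_set() == want and root.children:
            # name tips per species, assign internal-node ids
            counters = {sp: 0 for sp in want}
            for tip in tree.tips():
                counters[tip.species] += 1
                tip.transcript = f"t{counters[tip.species]}"
            tree.assign_node_ids()
            return tree
    raise SimulationError(
        f"no surviving gene tree covering all species after {max_retries} tries"
    )


# --------------------------------------------------------------------------
# expression


def simulate_expression(
    tree: GeneTree,
    root_profile: pd.Series,
    bm_sigma2: float,
    shifts: list[ShiftSpec] | None = None,
    seed: int | np.random.Generator | None = None,
    silk_glands: list[str] | None = None,
    non_silk: list[str] | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Evolve tissue expression along a gene tree by Brownian motion.

    Expression evolves on log(FPKM + 1) per tissue independently with
    variance ``bm_sigma2 * branch length``, then back-transforms, keeping
    FPKM non-negative.  Each :class:`ShiftSpec` multiplies its target
    tissues' FPKM by the effect multiplier at the branch's child node
    (inherited below).  Returns tip profiles (transcript label x tissue)
    and the per-node truth.
    """
    if bm_sigma2 < 0:
        raise ValueError("bm_sigma2 must be >= 0")
    if (root_profile < 0).any():
        raise ValueError("root profile must be non-negative")
    shifts = shifts or []
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tissues = list(root_profile.index)
    node_labels = {nd.label for nd in tree.preorder()}
    shift_by_node: dict[str, list[ShiftSpec]] = {}
    for s in shifts:
        if s.node not in node_labels:
            raise KeyError(f"shift branch {s.node!r} not in tree")
        unknown = set(s.tissues) - set(tissues)
        if unknown:
            raise KeyError(f"shift targets unknown tissues: {sorted(unknown)}")
        shift_by_node.setdefault(s.node, []).append(s)

    sd = np.sqrt(bm_sigma2)
    profiles: dict[str, pd.Series] = {}
    log_prof: dict[int, np.ndarray] = {id(tree.root): np.log1p(root_profile.to_numpy(float))}
    for nd in tree.preorder():
        if nd.parent is not None:
            step = rng.normal(0.0, sd * np.sqrt(max(nd.length, 0.0)), size=len(tissues))
            z = log_prof[id(nd.parent)] + step
            log_prof[id(nd)] = z
        fpkm = np.expm1(np.clip(log_prof[id(nd)], 0.0, None))
        for s in shift_by_node.get(nd.label, []):
            for t in s.tissues:
                fpkm[tissues.index(t)] *= s.multiplier
            # shifts are heritable: push the shifted value back to log scale
            log_prof[id(nd)] = np.log1p(fpkm)
        profiles[nd.label] = pd.Series(fpkm, index=tissues)

    if silk_glands is None or non_silk is None:
        silk_glands = [t for t in tissues if t in set(SILK_GLANDS)]
        non_silk = [t for t in tissues if t not in set(SILK_GLANDS)]
    states = {
        lbl: classify_node_state(prof, silk_glands, non_silk)
        for lbl, prof in profiles.items()
    }
    tips = pd.DataFrame({t.label: profiles[t.label] for t in tree.tips()}).T
    truth = SimTruth(
        node_profiles=profiles,
        node_states=states,
        shift_branches=sorted(shift_by_node),
    )
    return tips, truth


# --------------------------------------------------------------------------
# counts


def simulate_counts(
    profiles: pd.DataFrame,
    design: StudyDesign,
    species: str,
    effective_lengths: pd.Series,
    nb_dispersion: float,
    seed: int | np.random.Generator | None = None,
) -> CountMatrix:
    """Draw NB counts for one species' libraries from true FPKM profiles.

    ``profiles`` is transcript x tissue true FPKM.  The expected count is
    ``mu = FPKM * effective_length/1e3 * library_size/1e6``; counts are
    NB with variance ``mu + dispersion * mu^2`` (Poisson at dispersion 0).
    """
    if nb_dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    lens = effective_lengths.reindex(profiles.index)
    if lens.isna().any() or (lens <= 0).any():
        raise ValueError("every transcript needs an effective length > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    counts = {}
    sheet_rows = []
    for lib, tissue, rep in design.libraries(species):
        mu = (
            profiles[tissue].to_numpy(float)
            * lens.to_numpy(float)
            / 1e3
            * design.library_size
            / 1e6
        )
        if nb_dispersion == 0:
            draws = rng.poisson(mu)
        else:
            r = 1.0 / nb_dispersion
            p = r / (r + mu)
            draws = np.where(mu > 0, rng.negative_binomial(r, np.clip(p, 1e-12, 1.0)), 0)
        counts[lib] = draws
        sheet_rows.append({"library": lib, "species": species, "tissue": tissue, "replicate": str(rep)})

    counts_df = pd.DataFrame(counts, index=profiles.index)
    sheet = pd.DataFrame(sheet_rows).set_index("library")
    return CountMatrix(
        counts=counts_df,
        effective_length=lens,
        sample_sheet=sheet,
        library_size=pd.Series(design.library_size, index=counts_df.columns),
    )


# --------------------------------------------------------------------------
# full study


DEFAULT_CONFIG = {
    "n_families": 40,
    "birth_rate": 0.3,
    "loss_rate": 0.1,
    "bm_sigma2": 0.05,
    "nb_dispersion": 0.1,
    "base_fpkm_log_mean": 2.0,
    "base_fpkm_log_sd": 1.0,
    "n_shift_families": 15,
    "shift_multiplier": 12.0,
    "shift_on": "random",  # random | duplication | speciation
    "library_size": 2_000_000,
    "effective_length_range": [500, 4000],
}


def load_config(path) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    loaded = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(loaded) - set(DEFAULT_CONFIG) - {"replicates_per_tissue"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(loaded)
    return cfg


def _pick_shift_branches(
    tree: GeneTree, mode: str, rng: np.random.Generator
) -> list[str]:
    """Candidate child-node labels for a planted shift, by parent event.

    Branches hanging directly off the root are excluded when possible: a
    shift there is directionally unidentifiable (the root state itself is
    estimated mostly from the shifted clade).
    """
    candidates = []
    fallback = []
    for parent, child in tree.branches():
        if mode == "duplication" and parent.event != DUPLICATION:
            continue
        if mode == "speciation" and parent.event != SPECIATION:
            continue
        if parent.parent is None:
            fallback.append(child.label)
        else:
            candidates.append(child.label)
    return candidates or fallback


def generate_study(
    config: dict | None = None,
    seed: int = 0,
    design: StudyDesign | None = None,
) -> StudyBundle:
    """Simulate a full study: trees, expression, counts, families, truth.

    Deterministic under ``seed``.  Each family is one gene tree; the first
    ``n_shift_families`` families get one planted silk-gland shift each
    (target gland cycled deterministically, branch chosen per
    ``shift_on``).
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    design = design or default_design()
    if cfg.get("library_size"):
        design.library_size = int(cfg["library_size"])
    rng = np.random.default_rng(seed)
    species_tree = design.species_tree
    tissues = design.tissues
    glands = design.silk_glands

    trees: dict[str, GeneTree] = {}
    truths: dict[str, SimTruth] = {}
    fam_rows = []
    profile_blocks: dict[str, dict[str, pd.Series]] = {sp: {} for sp in design.species}

    n_shifted = int(cfg["n_shift_families"])
    if n_shifted > int(cfg["n_families"]):
        raise ValueError("n_shift_families exceeds n_families")

    for i in range(int(cfg["n_families"])):
        fam = f"fam{i:04d}"
        tree = simulate_gene_tree(species_tree, cfg["birth_rate"], cfg["loss_rate"], rng)
        tree.name = fam
        # globally unique transcript ids, shared by trees / family map / counts
        for tip in tree.tips():
            tip.transcript = f"{fam}_{tip.species}_{tip.transcript}"

        base = float(np.exp(rng.normal(cfg["base_fpkm_log_mean"], cfg["base_fpkm_log_sd"])))
        root_profile = pd.Series(base, index=tissues, dtype=float)

        shifts: list[ShiftSpec] = []
        if i < n_shifted:
            target = glands[i % len(glands)]
            candidates = _pick_shift_branches(tree, cfg["shift_on"], rng)
            if candidates:
                node = candidates[rng.integers(len(candidates))]
                shifts = [ShiftSpec(node=node, tissues=[target], multiplier=float(cfg["shift_multiplier"]))]
        tips, truth = simulate_expression(
            tree,
            root_profile,
            cfg["bm_sigma2"],
            shifts,
            rng,
            silk_glands=design.silk_glands,
            non_silk=design.non_silk,
        )
        trees[fam] = tree
        truths[fam] = truth
        for tip in tree.tips():
            sp, tx = tip.species, tip.transcript
            fam_rows.append({"cluster_id": fam, "species": sp, "transcript": tx})
            profile_blocks[sp][tx] = tips.loc[tip.label]

    lo, hi = cfg["effective_length_range"]
    count_matrices = {}
    tip_profile_cols = {}
    for sp in design.species:
        prof = pd.DataFrame(profile_blocks[sp]).T.reindex(columns=tissues)
        lengths = pd.Series(
            rng.integers(int(lo), int(hi) + 1, size=len(prof)).astype(float),
            index=prof.index,
        )
        count_matrices[sp] = simulate_counts(
            prof, design, sp, lengths, cfg["nb_dispersion"], rng
        )
        for tissue in tissues:
            tip_profile_cols[(sp, tissue)] = prof[tissue]

    tip_profiles = pd.DataFrame(tip_profile_cols)
    tip_profiles.columns = pd.MultiIndex.from_tuples(
        tip_profiles.columns, names=["species", "tissue"]
    )

    # truth OEST: tip's true state is silk-specific (a gland or MULTIPLE)
    oest_truth: dict[str, set[str]] = {sp: set() for sp in design.species}
    for fam, tree in trees.items():
        for tip in tree.tips():
            if truths[fam].node_states[tip.label] != "NOT_SILK":
                oest_truth[tip.species].add(tip.transcript)

    fmap = FamilyMap(pd.DataFrame(fam_rows))
    return StudyBundle(
        count_matrices=count_matrices,
        family_map=fmap,
        trees=trees,
        truths=truths,
        tip_profiles=tip_profiles,
        oest_truth=oest_truth,
        design=design,
    )


def write_bundle(bundle: StudyBundle, outdir) -> dict[str, Path]:
    """Write the real-data-mode input files plus truth JSON."""
    from . import io as sio  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    counts = pd.concat([cm.counts for cm in bundle.count_matrices.values()], axis=1)
    counts = counts.fillna(0).astype(int)
    lengths = pd.concat([cm.effective_length for cm in bundle.count_matrices.values()])
    lengths = lengths[~lengths.index.duplicated()]
    sheet = pd.concat([cm.sample_sheet for cm in bundle.count_matrices.values()])

    paths["counts"] = outdir / "counts.tsv"
    sio.write_counts(counts, paths["counts"])
    paths["effective_lengths"] = outdir / "effective_lengths.tsv"
    sio.write_effective_lengths(lengths, paths["effective_lengths"])
    paths["samples"] = outdir / "samples.tsv"
    sio.write_sample_sheet(sheet, paths["samples"])
    paths["families"] = outdir / "families.tsv"
    sio.write_family_map(bundle.family_map, paths["families"])
    paths["trees"] = outdir / "trees.nhx"
    sio.write_trees(bundle.trees, paths["trees"])

    truth = {
        fam: {
            "node_profiles": {
                lbl: {t: float(v) for t, v in prof.items()}
                for lbl, prof in tr.node_profiles.items()
            },
            "node_states": tr.node_states,
            "shift_branches": tr.shift_branches,
        }
        for fam, tr in bundle.truths.items()
    }
    truth["_oest_truth"] = {sp: sorted(v) for sp, v in bundle.oest_truth.items()}
    paths["truth"] = outdir / "truth.json"
    sio.write_json(truth, paths["truth"])
    return paths
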