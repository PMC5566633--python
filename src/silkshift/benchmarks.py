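"""Self-contained calibration and validation benchmarks.

Each function recomputes one property-based quality criterion from scratch
on synthetic data and returns a dict of measured quantities.  Oracles used
here (explicit GLS covariance inversion, conditional binomial enumeration)
are deliberately independent of the implementation paths they check.
"""

from __future__ import annotations

import itertools
import tempfile
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binom

from .cluster import bootstrap_support, hierarchical_cluster, spearman_matrix
from .de import call_oests, estimate_common_dispersion, nb_exact_test
from .normalize import CountMatrix
from .phyloexpr.asr import bm_ancestral_states, classify_node_state
from .phyloexpr.dstat import d_statistic
from .phyloexpr.pipeline import run_phylo_pipeline
from .phyloexpr.trees import GeneTree, Node
from .synthetic_data import generate_study, write_bundle

__all__ = [
    "asr_oracle_equivalence",
    "exact_test_binomial_agreement",
    "dispersion_recovery",
    "oest_calibration",
    "dstat_calibration",
    "transition_test_calibration",
    "determinism_and_truth",
    "clustering_recovery",
]


# --------------------------------------------------------------------------
# helpers

def _random_tree(n_tips: int, rng: np.random.Generator) -> GeneTree:
    nodes = [Node(name=f"T{i}", length=float(rng.uniform(0.1, 2.0))) for i in range(n_tips)]
    cnt = itertools.count()
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]
        p = Node(name=f"I{next(cnt)}", length=float(rng.uniform(0.1, 2.0)))
        p.add_child(a)
        p.add_child(b)
        nodes = [x for x in nodes if x not in (a, b)] + [p]
    nodes[0].length = 0.0
    return GeneTree(nodes[0])


def _gls_oracle(tree: GeneTree, tip_values: dict[str, float]) -> dict[str, float]:
    """Explicit covariance-inversion GLS ancestral states (brute force)."""

    def root_path(nd):
        out = []
        while nd is not None:
            out.append(nd)
            nd = nd.parent
        return out

    def dist_root(nd):
        d = 0.0
        while nd.parent is not None:
            d += nd.length
            nd = nd.parent
        return d

    def mrca_depth(a, b):
        ids_a = {id(x) for x in root_path(a)}
        mrca = next(x for x in root_path(b) if id(x) in ids_a)
        return dist_root(mrca)

    tips = tree.tips()
    n = len(tips)
    C = np.empty((n, n))
    for i, a in enumerate(tips):
        for j, b in enumerate(tips):
            C[i, j] = dist_root(a) if a is b else mrca_depth(a, b)
    y = np.array([tip_values[t.label] for t in tips])
    Ci = np.linalg.inv(C)
    one = np.ones(n)
    mu = float(one @ Ci @ y / (one @ Ci @ one))
    out = {}
    for nd in tree.internal_nodes():
        if nd.parent is None:
            out[nd.label] = mu
        else:
            cov = np.array([mrca_depth(nd, t) for t in tips])
            out[nd.label] = float(mu + cov @ Ci @ (y - mu * one))
    return out


# --------------------------------------------------------------------------
# criteria

def asr_oracle_equivalence(seed: int, n_trees: int = 100) -> dict:
    """Max |BM ML estimate - GLS oracle| over random trees (4-10 tips)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trees):
        tree = _random_tree(int(rng.integers(4, 11)), rng)
        x = {t.label: float(rng.normal(5, 3)) for t in tree.tips()}
        anc = bm_ancestral_states(tree, x)
        oracle = _gls_oracle(tree, x)
        for label, expected in oracle.items():
            worst = max(worst, abs(anc.values[label] - expected))
    return {"max_abs_error": worst, "n_trees": n_trees}


def exact_test_binomial_agreement(max_total: int = 200) -> dict:
    """Max |NB exact-test p (dispersion 0) - conditional binomial p|.

    Covers every count pair (a, b) with a + b <= ``max_total`` at equal
    library sizes, where the conditional distribution is binomial(n, 1/2).
    """
    worst = 0.0
    n_pairs = 0
    for total in range(1, max_total + 1):
        k = np.arange(total + 1)
        pmf = binom.pmf(k, total, 0.5)
        for a in range(total + 1):
            oracle = min(1.0, float(pmf[pmf <= pmf[a] * (1 + 1e-9)].sum()))
            p = nb_exact_test([a], [total - a], dispersion=0.0)
            worst = max(worst, abs(p - oracle))
            n_pairs += 1
    return {"max_abs_diff": worst, "n_pairs": n_pairs}


def dispersion_recovery(
    seed: int,
    phis=(0.1, 0.5, 1.5),
    n_transcripts: int = 2000,
    n_seeds: int = 3,
) -> dict:
    """Median relative error of common-dispersion estimates (2+2 design)."""
    out = {}
    for phi in phis:
        estimates = []
        for s in range(n_seeds):
            rng = np.random.default_rng(seed + 1000 * s + int(phi * 100))
            mu = rng.gamma(2.0, 40.0, size=n_transcripts)
            r = 1.0 / phi
            counts = pd.DataFrame(
                {f"L{i}": rng.negative_binomial(r, r / (r + mu)) for i in range(4)}
            )
            groups = pd.Series(
                {"L0": "silk", "L1": "silk", "L2": "non", "L3": "non"}
            )
            sizes = pd.Series(1e6, index=counts.columns)
            estimates.append(estimate_common_dispersion(counts, groups, sizes))
        med = float(np.median(estimates))
        out[phi] = {
            "median_estimate": med,
            "relative_error": abs(med - phi) / phi,
            "estimates": estimates,
        }
    return out


def _study_counts(
    rng: np.random.Generator,
    n_transcripts: int,
    phi: float,
    planted: int = 0,
    fold: float = 10.0,
    planted_min_mu: float = 50.0,
) -> tuple[CountMatrix, list[str]]:
    """Counts for a 7-gland + 3-non-silk design (2 reps each but 2 glands)."""
    silk = ["MA", "MI", "AcF", "Tu", "Py", "AGant", "AGpost"]
    non = ["ceph", "ovary", "venom"]
    reps = {t: 2 for t in silk + non}
    reps["Py"] = 1
    reps["Tu"] = 1
    mu = rng.gamma(2.0, 25.0, size=n_transcripts)
    planted_ids = [f"t{i}" for i in range(planted)]
    if planted:
        mu[:planted] = np.maximum(mu[:planted], planted_min_mu)
    cols, rows = {}, []
    r = 1.0 / phi if phi > 0 else None
    for tissue in silk + non:
        for rep in range(1, reps[tissue] + 1):
            m = mu
            if planted and tissue in silk:
                m = mu.copy()
                m[:planted] *= fold
            if r is None:
                draw = rng.poisson(m)
            else:
                draw = rng.negative_binomial(r, r / (r + m))
            lib = f"{tissue}_r{rep}"
            cols[lib] = draw
            rows.append({"library": lib, "species": "Lg", "tissue": tissue, "replicate": str(rep)})
    counts = pd.DataFrame(cols, index=[f"t{i}" for i in range(n_transcripts)])
    cm = CountMatrix(
        counts=counts,
        effective_length=pd.Series(1000.0, index=counts.index),
        sample_sheet=pd.DataFrame(rows).set_index("library"),
        library_size=pd.Series(1_000_000, index=counts.columns),
    )
    return cm, planted_ids


def oest_calibration(seed: int, n_transcripts: int = 2000, phi: float = 0.1) -> dict:
    """Null false-positive share and planted-gene recall of OEST calling."""
    silk = ["MA", "MI", "AcF", "Tu", "Py", "AGant", "AGpost"]
    rng = np.random.default_rng(seed)
    cm_null, _ = _study_counts(rng, n_transcripts, phi)
    res_null = call_oests(cm_null, silk)
    null_fdp = float(res_null["oest_flag"].mean())

    cm_pow, planted = _study_counts(rng, n_transcripts, phi, planted=200)
    res_pow = call_oests(cm_pow, silk)
    found = res_pow.index.intersection(planted)
    recall = float(res_pow.loc[found, "oest_flag"].sum() / len(planted))
    discoveries = res_pow["oest_flag"].sum()
    false_disc = int(res_pow.loc[~res_pow.index.isin(planted), "oest_flag"].sum())
    mixed_fdp = float(false_disc / discoveries) if discoveries else 0.0
    return {
        "null_false_positive_share": null_fdp,
        "recall": recall,
        "mixed_fdp": mixed_fdp,
        "n_transcripts": n_transcripts,
    }


def dstat_calibration(
    seed: int, n_trees: int = 200, n_tips: int = 20, n_null: int = 200
) -> dict:
    """Mean D under tip-shuffle generation (~1) and BM-threshold (~0)."""
    rng = np.random.default_rng(seed)
    shuffle_ds, bm_ds = [], []
    for _ in range(n_trees):
        tree = _random_tree(n_tips, rng)
        tips = [t.label for t in tree.tips()]
        k = int(rng.integers(4, n_tips - 3))

        ones = set(rng.choice(tips, size=k, replace=False))
        res = d_statistic(
            tree, {lbl: int(lbl in ones) for lbl in tips}, n_null, n_null, seed=rng
        )
        if res.d is not None:
            shuffle_ds.append(res.d)

        # BM-threshold generation at the same prevalence
        vals = {}
        stack = [(tree.root, 0.0)]
        while stack:
            nd, v = stack.pop()
            if nd.is_leaf:
                vals[nd.label] = v
            for ch in nd.children:
                stack.append((ch, v + rng.normal(0, np.sqrt(ch.length))))
        order = sorted(vals, key=vals.get)
        ones = set(order[-k:])
        res = d_statistic(
            tree, {lbl: int(lbl in ones) for lbl in tips}, n_null, n_null, seed=rng
        )
        if res.d is not None:
            bm_ds.append(res.d)
    return {
        "mean_d_shuffle": float(np.mean(shuffle_ds)),
        "mean_d_bm": float(np.mean(bm_ds)),
        "n_trees": n_trees,
    }


def _transition_rejects(bundle, seed: int) -> tuple[bool, int]:
    design = bundle.design
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_phylo_pipeline(
            bundle.trees,
            bundle.tip_profiles,
            design.silk_glands,
            design.non_silk,
            seed=seed,
            do_dstat=False,
        )
    n_shift = sum(len(t.shift_branches) for t in bundle.truths.values())
    return bool(result.fisher["significant"].any()), n_shift


def transition_test_calibration(
    seed: int, n_null_reps: int = 20, n_power_reps: int = 15
) -> dict:
    """Fisher duplication-vs-speciation test: null rejection rate and power."""
    base = {
        "n_families": 40,
        "birth_rate": 0.5,
        "loss_rate": 0.1,
        "bm_sigma2": 0.005,
        "shift_multiplier": 12.0,
    }
    null_rejects = []
    for i in range(n_null_reps):
        bundle = generate_study(
            {**base, "n_shift_families": 25, "shift_on": "random"}, seed=seed + i
        )
        rej, _ = _transition_rejects(bundle, seed=seed + i)
        null_rejects.append(rej)

    power_rejects, shift_counts = [], []
    for i in range(n_power_reps):
        # not every simulated tree has a duplication branch, so oversample
        # shift families to pool >= 30 planted shift branches per replicate
        bundle = generate_study(
            {
                **base,
                "n_families": 55,
                "birth_rate": 0.6,
                "n_shift_families": 55,
                "shift_on": "duplication",
            },
            seed=seed + 10_000 + i,
        )
        rej, n_shift = _transition_rejects(bundle, seed=seed + i)
        power_rejects.append(rej)
        shift_counts.append(n_shift)
    return {
        "null_rejection_rate": float(np.mean(null_rejects)),
        "power": float(np.mean(power_rejects)),
        "mean_shift_branches_power": float(np.mean(shift_counts)),
        "n_null_reps": n_null_reps,
        "n_power_reps": n_power_reps,
    }


def determinism_and_truth(seed: int) -> dict:
    """Bit-reproducibility and planted-truth self-consistency checks."""
    cfg = {"n_families": 15, "n_shift_families": 8}
    with tempfile.TemporaryDirectory() as tmp:
        b1 = generate_study(cfg, seed=seed)
        b2 = generate_study(cfg, seed=seed)
        p1 = write_bundle(b1, Path(tmp) / "a")
        p2 = write_bundle(b2, Path(tmp) / "b")
        identical = all(p1[k].read_bytes() == p2[k].read_bytes() for k in p1)

    design = b1.design
    consistent = all(
        truth.node_states[lbl]
        == classify_node_state(prof, design.silk_glands, design.non_silk)
        for truth in b1.truths.values()
        for lbl, prof in truth.node_profiles.items()
    )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_phylo_pipeline(
            b1.trees, b1.tip_profiles, design.silk_glands, design.non_silk,
            do_dstat=False,
        )
    conserved = all(
        result.per_tree_tallies[fam].n_branches == len(b1.trees[fam].branches())
        for fam in b1.trees
    ) and result.tally.n_branches == sum(
        len(t.branches()) for t in b1.trees.values()
    )
    return {
        "bit_identical": identical,
        "truth_consistent": consistent,
        "tally_conserved": conserved,
    }


def _adjusted_rand_index(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.special import comb

    a, b = np.asarray(a), np.asarray(b)
    classes, cls_idx = np.unique(a, return_inverse=True)
    clusters, clu_idx = np.unique(b, return_inverse=True)
    table = np.zeros((len(classes), len(clusters)), dtype=int)
    for i, j in zip(cls_idx, clu_idx):
        table[i, j] += 1
    sum_comb = comb(table, 2).sum()
    sum_a = comb(table.sum(axis=1), 2).sum()
    sum_b = comb(table.sum(axis=0), 2).sum()
    n = comb(len(a), 2)
    expected = sum_a * sum_b / n
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))


def clustering_recovery(
    seed: int, n_oests: int = 60, noise_sd: float = 0.3
) -> dict:
    """Recovery of a planted aggregate-like vs fiber-like tissue split."""
    fiber = ["MA", "MI", "AcF", "Tu", "Py"]
    glue = ["AGant", "AGpost"]
    tissues = fiber + glue
    rng = np.random.default_rng(seed)
    data = np.empty((len(tissues), n_oests))
    for j in range(n_oests):
        block = fiber if j < n_oests // 2 else glue
        for i, tissue in enumerate(tissues):
            base = 100.0 if tissue in block else 1.0
            data[i, j] = base * float(np.exp(rng.normal(0, noise_sd)))
    prof = pd.DataFrame(data, index=tissues)

    support = bootstrap_support(prof, n_boot=200, seed=int(rng.integers(2**31)))
    planted = [frozenset(glue), frozenset(fiber)]
    planted_support = {
        ";".join(sorted(c)): support.get(c, 0.0) for c in planted
    }
    dend = hierarchical_cluster(spearman_matrix(prof))
    groups = dend.cut(2)
    truth = np.array([0 if t in fiber else 1 for t in groups.index])
    ari = _adjusted_rand_index(truth, groups.to_numpy())
    return {
        "min_planted_support": min(planted_support.values()),
        "planted_support": planted_support,
        "ari": ari,
    }
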