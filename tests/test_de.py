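import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from silkshift.de import (
    bh_fdr,
    call_oests,
    estimate_common_dispersion,
    estimate_tagwise_dispersion,
    nb_exact_test,
    per_gland_contrast,
    twofold_silk_flag,
)
from silkshift.normalize import CountMatrix

SILK = ["MA", "MI"]


def binom_two_sided_oracle(a: int, b: int, p_success: float = 0.5) -> float:
    """Conditional binomial two-sided test, minimum-likelihood convention."""
    n = a + b
    pmf = binom.pmf(np.arange(n + 1), n, p_success)
    return float(min(1.0, pmf[pmf <= pmf[a] * (1 + 1e-9)].sum()))


def nb_counts(rng, mu, phi, size):
    if phi == 0:
        return rng.poisson(mu, size=size)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu), size=size)


def sim_cm(rng, n_transcripts=300, phi=0.1, silk_mu=None, base_mu=50):
    """Small simulated study: 2 silk tissues x2 reps, 2 non-silk x2 reps."""
    tissues = ["MA", "MI", "ceph", "ovary"]
    libs, cols = [], {}
    mu = rng.gamma(2.0, base_mu / 2.0, size=n_transcripts)
    sheet_rows = []
    for tissue in tissues:
        for rep in (1, 2):
            lib = f"{tissue}_r{rep}"
            m = mu.copy()
            if silk_mu is not None and tissue in SILK:
                m = silk_mu(m)
            cols[lib] = nb_counts(rng, m, phi, n_transcripts)
            sheet_rows.append(
                {"library": lib, "species": "Lg", "tissue": tissue, "replicate": str(rep)}
            )
    counts = pd.DataFrame(cols, index=[f"t{i}" for i in range(n_transcripts)])
    sheet = pd.DataFrame(sheet_rows).set_index("library")
    return CountMatrix(
        counts=counts,
        effective_length=pd.Series(1000.0, index=counts.index),
        sample_sheet=sheet,
        library_size=pd.Series(1_000_000, index=counts.columns),
    )


class TestExactTest:
    def test_zero_vs_ten_binomial_limit(self):
        p = nb_exact_test([0], [10], dispersion=0.0)
        assert p == pytest.approx(2 * 0.5**10, rel=1e-9)

    def test_identical_counts_p_one(self):
        assert nb_exact_test([5, 5], [5, 5], dispersion=0.3) == pytest.approx(1.0)

    def test_symmetry_under_group_swap(self, rng):
        for _ in range(10):
            a = list(rng.integers(0, 50, size=2))
            b = list(rng.integers(0, 50, size=2))
            p1 = nb_exact_test(a, b, dispersion=0.4)
            p2 = nb_exact_test(b, a, dispersion=0.4)
            assert p1 == pytest.approx(p2, rel=1e-12)

    def test_dispersion_widens_null(self):
        p0 = nb_exact_test([2], [40], dispersion=0.0)
        p4 = nb_exact_test([2], [40], dispersion=0.4)
        assert p4 > p0

    def test_matches_binomial_oracle_grid(self):
        # equal group sizes: conditional distribution is binomial(total, 1/2)
        for a in range(0, 30, 3):
            for b in range(0, 30, 4):
                if a + b == 0:
                    continue
                p = nb_exact_test([a], [b], dispersion=0.0)
                assert p == pytest.approx(binom_two_sided_oracle(a, b), abs=1e-10)

    def test_unequal_group_sizes_binomial_oracle(self):
        # 2 libraries vs 1 at dispersion 0: success prob 2/3
        p = nb_exact_test([3, 4], [9], dispersion=0.0)
        assert p == pytest.approx(binom_two_sided_oracle(7, 9, 2.0 / 3.0), abs=1e-10)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test([1], [1], dispersion=-0.1)


class TestBhFdr:
    def test_hand_step_up(self):
        out = bh_fdr([0.01, 0.02, 0.03])
        assert out == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(size=50)
        adj = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_fdr_at_least_p(self, rng):
        p = rng.uniform(size=50)
        assert (bh_fdr(p) >= p - 1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestCommonDispersion:
    def test_identical_replicates_zero(self):
        counts = pd.DataFrame({"A": [10, 20, 30], "B": [10, 20, 30]})
        groups = pd.Series({"A": "g", "B": "g"})
        sizes = pd.Series({"A": 100.0, "B": 100.0})
        phi = estimate_common_dispersion(counts, groups, sizes)
        assert phi == pytest.approx(0.0, abs=1e-4)

    def test_poisson_truth_small(self, rng):
        counts = pd.DataFrame(
            {f"L{i}": rng.poisson(rng.gamma(2, 25, size=800)) for i in range(4)}
        )
        # note: same mu vector across libraries
        mu = rng.gamma(2, 25, size=800)
        counts = pd.DataFrame({f"L{i}": rng.poisson(mu) for i in range(4)})
        groups = pd.Series("g", index=counts.columns)
        sizes = pd.Series(float(mu.sum()), index=counts.columns)
        phi = estimate_common_dispersion(counts, groups, sizes)
        assert phi < 0.02

    def test_nb_parameter_recovery(self, rng):
        true_phi = 1.5
        mu = rng.gamma(2, 40, size=2000)
        r = 1.0 / true_phi
        counts = pd.DataFrame(
            {f"L{i}": rng.negative_binomial(r, r / (r + mu)) for i in range(4)}
        )
        groups = pd.Series("g", index=counts.columns)
        sizes = pd.Series(1e6, index=counts.columns)
        phi = estimate_common_dispersion(counts, groups, sizes)
        assert phi == pytest.approx(true_phi, rel=0.10)

    def test_all_singletons_rejected(self):
        counts = pd.DataFrame({"A": [10], "B": [20]})
        groups = pd.Series({"A": "g1", "B": "g2"})
        sizes = pd.Series({"A": 100.0, "B": 100.0})
        with pytest.raises(ValueError):
            estimate_common_dispersion(counts, groups, sizes)


class TestTagwiseDispersion:
    def _setup(self, rng, phi=0.5, n=200):
        mu = rng.gamma(2, 40, size=n)
        r = 1.0 / phi
        counts = pd.DataFrame(
            {f"L{i}": rng.negative_binomial(r, r / (r + mu)) for i in range(4)}
        )
        groups = pd.Series("g", index=counts.columns)
        sizes = pd.Series(1e6, index=counts.columns)
        return counts, groups, sizes

    def test_infinite_prior_equals_common(self, rng):
        counts, groups, sizes = self._setup(rng)
        common = estimate_common_dispersion(counts, groups, sizes)
        tag = estimate_tagwise_dispersion(
            counts, groups, sizes, common, prior_weight=np.inf
        )
        assert (tag == common).all()

    def test_zero_prior_matches_single_transcript_grid_oracle(self, rng):
        counts, groups, sizes = self._setup(rng, n=5)
        common = estimate_common_dispersion(counts, groups, sizes)
        tag = estimate_tagwise_dispersion(counts, groups, sizes, common, prior_weight=0.0)

        # independent oracle: dense grid search of the conditional
        # log-likelihood for one transcript alone
        from scipy.special import gammaln

        def cond_ll(y, phi):
            r = 1.0 / max(phi, 1e-8)
            nlib = len(y)
            z = y.sum()
            return (
                gammaln(y + r).sum()
                + gammaln(nlib * r)
                - gammaln(z + nlib * r)
                - nlib * gammaln(r)
            )

        grid = np.exp(np.linspace(np.log(1e-6), np.log(50), 4001))
        for i, (t, row) in enumerate(counts.iterrows()):
            y = row.to_numpy(float)
            lls = np.array([cond_ll(y, g) for g in grid])
            oracle = grid[lls.argmax()]
            mine = tag.iloc[i]
            if oracle <= 2e-6:
                assert mine <= 1e-3
            else:
                assert np.log(mine + 1e-6) == pytest.approx(
                    np.log(oracle + 1e-6), abs=0.1
                )

    def test_monotone_in_replicate_disagreement(self):
        counts = pd.DataFrame(
            {
                "A": [100, 100],
                "B": [100, 300],
                "C": [100, 100],
                "D": [100, 300],
            },
            index=["quiet", "noisy"],
        )
        groups = pd.Series("g", index=counts.columns)
        sizes = pd.Series(1e4, index=counts.columns)
        tag = estimate_tagwise_dispersion(counts, groups, sizes, 0.2, prior_weight=2.0)
        assert tag["noisy"] >= tag["quiet"]


class TestPipelines:
    def test_filtered_transcript_absent(self, rng):
        cm = sim_cm(rng, n_transcripts=50)
        # zero out one transcript everywhere -> fails the CPM filter
        cm.counts.iloc[0] = 0
        cm = CountMatrix(cm.counts, cm.effective_length, cm.sample_sheet, cm.library_size)
        res = call_oests(cm, SILK)
        assert cm.counts.index[0] not in res.index

    def test_planted_silk_genes_detected(self, rng):
        def boost(m):
            m = m.copy()
            m[:20] *= 10
            return m

        cm = sim_cm(rng, n_transcripts=300, phi=0.05, silk_mu=boost, base_mu=80)
        res = call_oests(cm, SILK)
        planted = [f"t{i}" for i in range(20)]
        recall = res.loc[res.index.intersection(planted), "oest_flag"].mean()
        assert recall >= 0.9

    def test_oest_flag_consistency(self, rng):
        cm = sim_cm(rng, n_transcripts=100)
        res = call_oests(cm, SILK)
        flagged = res[res["oest_flag"]]
        assert (flagged["fdr"] < 0.05).all()
        assert (flagged["logFC"] > 0).all()

    def test_missing_tissue_class_raises(self, rng):
        cm = sim_cm(rng, n_transcripts=20)
        with pytest.raises(ValueError):
            call_oests(cm, ["MA", "MI", "ceph", "ovary"])

    def test_replicated_gland_uses_tagwise(self, rng):
        cm = sim_cm(rng, n_transcripts=60)
        res = per_gland_contrast(cm, "MA", SILK)
        assert res.attrs["gland_replicated"] is True
        assert res["dispersion"].nunique() > 1

    def test_unreplicated_gland_fixed_dispersion(self, rng):
        cm = sim_cm(rng, n_transcripts=60)
        keep = [c for c in cm.counts.columns if c != "MA_r2"]
        cm = cm.subset_libraries(keep)
        res = per_gland_contrast(cm, "MA", SILK)
        assert res.attrs["gland_replicated"] is False
        assert (res["dispersion"] == 0.4).all()

    def test_unknown_gland_raises(self, rng):
        cm = sim_cm(rng, n_transcripts=20)
        with pytest.raises(KeyError):
            per_gland_contrast(cm, "nope", SILK)


class TestTwofoldFlag:
    def test_exact_boundary_false(self):
        prof = pd.DataFrame(
            [[14, 0, 0, 0, 0, 0, 0, 1, 1, 1]],
            index=["t1"],
            columns=["MA", "MI", "AcF", "Tu", "Py", "AGant", "AGpost", "c", "o", "v"],
        )
        flags = twofold_silk_flag(prof, ["MA", "MI", "AcF", "Tu", "Py", "AGant", "AGpost"])
        assert not flags.loc["t1", "twofold"]  # ratio exactly 2, strict >

    def test_all_zero_silk_false(self):
        prof = pd.DataFrame([[0, 0, 1, 1]], index=["t1"], columns=["MA", "MI", "c", "o"])
        assert not twofold_silk_flag(prof, ["MA", "MI"]).loc["t1", "twofold"]

    def test_zero_denominator_true(self):
        prof = pd.DataFrame([[3, 0, 0, 0]], index=["t1"], columns=["MA", "MI", "c", "o"])
        flags = twofold_silk_flag(prof, ["MA", "MI"])
        assert flags.loc["t1", "twofold"]

    def test_fpkm_gt1_companion(self):
        prof = pd.DataFrame(
            [[0.5, 0.5, 0.1, 0.1], [5, 0.5, 0.1, 0.1]],
            index=["low", "high"],
            columns=["MA", "MI", "c", "o"],
        )
        flags = twofold_silk_flag(prof, ["MA", "MI"])
        assert not flags.loc["low", "fpkm_gt1"]
        assert flags.loc["high", "fpkm_gt1"]
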