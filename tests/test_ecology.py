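"""Community statistics: diversity, distances, perMANOVA, CAP, AVD, SPEC-OCCU."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from crcmicro import ecology, prep
from crcmicro.errors import InputError


def _profile(arr, prefix="S"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"t{j}" for j in range(arr.shape[1])],
    )


class TestShannon:
    def test_uniform_profile_is_log_richness(self):
        prof = _profile([[1 / 8] * 8])
        assert ecology.shannon(prof).iloc[0] == pytest.approx(np.log(8))

    def test_single_taxon_zero(self):
        prof = _profile([[1.0, 0.0]])
        assert ecology.shannon(prof).iloc[0] == 0.0

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(0)
        raw = rng.random((10, 30))
        prof = _profile(raw / raw.sum(axis=1, keepdims=True))
        ours = ecology.shannon(prof)
        direct = [-(p[p > 0] * np.log(p[p > 0])).sum()
                  for p in prof.to_numpy()]
        assert np.allclose(ours, direct)


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        prof = _profile([[0.5, 0.5, 0.0], [0.5, 0.5, 0.0], [0.0, 0.0, 1.0]])
        dm = ecology.bray_curtis(prof)
        assert dm["S0", "S1"] == pytest.approx(0.0)
        assert dm["S0", "S2"] == pytest.approx(1.0)

    def test_hand_computed_toy(self):
        prof = _profile([[3, 1], [1, 3], [2, 2]])
        dm = ecology.bray_curtis(prof)
        # |3-1| + |1-3| = 4 over 3+1+1+3 = 8
        assert dm["S0", "S1"] == pytest.approx(0.5)
        assert dm["S0", "S2"] == pytest.approx(2 / 8)

    def test_two_all_zero_samples_error(self):
        prof = _profile([[0, 0], [0, 0], [1, 1]])
        with pytest.raises(InputError):
            ecology.bray_curtis(prof)


def _brute_force_f(d, labels):
    """Independent pseudo-F from the within/total sum-of-squares identity."""
    labels = np.asarray(labels)
    n = len(labels)
    groups = np.unique(labels)
    sst = (d[np.triu_indices(n, 1)] ** 2).sum() / n
    ssw = 0.0
    for g in groups:
        idx = np.nonzero(labels == g)[0]
        sub = d[np.ix_(idx, idx)]
        ssw += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
    ssa = sst - ssw
    return (ssa / (len(groups) - 1)) / (ssw / (n - len(groups)))


class TestPermanova:
    @pytest.fixture()
    def toy(self):
        rng = np.random.default_rng(5)
        raw = rng.random((6, 12)) + np.repeat([[0.0], [0.6]], 3, axis=0)
        prof = _profile(raw / raw.sum(axis=1, keepdims=True))
        meta = pd.DataFrame(
            {"group": ["a"] * 3 + ["b"] * 3, "age": [30, 40, 50, 35, 45, 55],
             "gender": ["male", "female"] * 3},
            index=prof.index,
        )
        return ecology.bray_curtis(prof), meta

    def test_exact_p_matches_brute_force_enumeration(self, toy):
        dm, meta = toy
        res = ecology.permanova(dm, meta, ["group"], n_perm="exact")
        labels = meta["group"].to_numpy()
        d = dm.data
        f_obs = _brute_force_f(d, labels)
        fs = []
        for pat in itertools.permutations(range(6)):
            fs.append(_brute_force_f(d[np.ix_(pat, pat)], labels))
        p_exact = np.mean(np.array(fs) >= f_obs - 1e-12)
        assert res.table.loc["group", "p"] == pytest.approx(p_exact)
        assert res.table.loc["group", "f"] == pytest.approx(f_obs)

    def test_f_matches_skbio(self, toy):
        dm, meta = toy
        res = ecology.permanova(dm, meta, ["group"], n_perm=99, seed=0)
        ref = skbio_permanova(dm, meta, column="group", permutations=99)
        assert res.table.loc["group", "f"] == pytest.approx(ref["test statistic"])

    def test_single_term_r2_partition_sums_to_one(self, toy):
        dm, meta = toy
        res = ecology.permanova(dm, meta, ["group"], n_perm=9, seed=0)
        assert res.table["r2"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_sequential_partition_additive(self, toy):
        dm, meta = toy
        res = ecology.permanova(dm, meta, ["group", "age"], n_perm=9, seed=0,
                                by="terms")
        assert res.table["r2"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_factor_marginal_symmetry(self, toy):
        dm, meta = toy
        meta = meta.assign(group2=meta["group"])
        res = ecology.permanova(dm, meta, ["group", "group2"], n_perm=9, seed=0)
        assert res.table.loc["group", "r2"] == pytest.approx(
            res.table.loc["group2", "r2"]
        )

    def test_singleton_level_error_names_level(self, toy):
        dm, meta = toy
        meta = meta.copy()
        meta.loc[meta.index[0], "group"] = "solo"
        with pytest.raises(InputError, match="solo"):
            ecology.permanova(dm, meta, ["group"], n_perm=9)


class TestPairwisePermanova:
    def test_all_pairs_reported_with_bh(self, small_rarefied):
        rarefied, meta, _, _ = small_rarefied
        dm = ecology.bray_curtis(prep.to_relative(rarefied))
        out = ecology.pairwise_permanova(dm, meta, n_perm=49, seed=0)
        assert len(out) == 10  # C(5,2)
        ok = out.dropna()
        assert (ok["p_adj"] >= ok["p"] - 1e-12).all()


class TestCapOrdination:
    def _clusters(self, sep=4.0, n=8, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 0.3, (n, 10)) + 1.0
        b = rng.normal(0, 0.3, (n, 10)) + 1.0
        b[:, :5] += sep
        raw = np.abs(np.vstack([a, b]))
        prof = _profile(raw / raw.sum(axis=1, keepdims=True))
        meta = pd.DataFrame(
            {"group": ["a"] * n + ["b"] * n}, index=prof.index
        )
        return prof, meta

    def test_separable_clusters_perfect_loo(self):
        prof, meta = self._clusters()
        dm = ecology.bray_curtis(prof)
        res = ecology.cap_ordination(dm, meta)
        assert res.loo_success == 1.0
        assert res.scores.shape[0] == len(meta)

    def test_scores_invariant_to_sample_order(self):
        prof, meta = self._clusters(seed=3)
        dm = ecology.bray_curtis(prof)
        res1 = ecology.cap_ordination(dm, meta)
        order = list(reversed(prof.index))
        dm2 = ecology.bray_curtis(prof.loc[order])
        res2 = ecology.cap_ordination(dm2, meta.loc[order])
        a = res1.scores.sort_index()
        b = res2.scores.sort_index()
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-6)

    def test_random_labels_near_chance(self):
        rng = np.random.default_rng(7)
        raw = rng.random((24, 15))
        prof = _profile(raw / raw.sum(axis=1, keepdims=True))
        accs = []
        for seed in range(5):
            labels = np.random.default_rng(seed).permutation(
                ["a", "b"] * 12
            )
            meta = pd.DataFrame({"group": labels}, index=prof.index)
            res = ecology.cap_ordination(ecology.bray_curtis(prof), meta,
                                         max_axes=5)
            accs.append(res.loo_success)
        assert np.mean(accs) < 0.8  # far from the separable case's 1.0


class TestAvd:
    def _meta(self, profile, groups):
        return pd.DataFrame(
            {"group": groups, "age": 50, "gender": "male"}, index=profile.index
        )

    def test_degenerate_group_flagged_zero(self):
        prof = _profile([[0.5, 0.5]] * 4)
        meta = self._meta(prof, ["a", "a", "b", "b"])
        res = ecology.avd(prof, meta)
        assert (res.per_sample == 0).all()
        assert res.summary["no_variation"].all()

    def test_gaussian_limit_mean_abs_z(self):
        rng = np.random.default_rng(0)
        prof = _profile(rng.normal(10, 1, (40, 10000)))
        meta = self._meta(prof, ["a"] * 20 + ["b"] * 20)
        res = ecology.avd(prof, meta)
        assert res.per_sample.mean() == pytest.approx(
            np.sqrt(2 / np.pi), abs=0.01
        )

    def test_scale_invariance_per_taxon(self):
        rng = np.random.default_rng(1)
        prof = _profile(rng.random((12, 20)))
        meta = self._meta(prof, ["a"] * 6 + ["b"] * 6)
        scaled = prof.copy()
        scaled["t0"] *= 1000.0
        a = ecology.avd(prof, meta)
        b = ecology.avd(scaled, meta)
        assert np.allclose(a.per_sample, b.per_sample)

    def test_group_of_one_is_error(self):
        prof = _profile(np.random.default_rng(2).random((3, 5)))
        meta = self._meta(prof, ["a", "b", "b"])
        with pytest.raises(InputError):
            ecology.avd(prof, meta)

    def test_summary_letters_present(self, small_rarefied):
        rarefied, meta, _, _ = small_rarefied
        res = ecology.avd(prep.to_relative(rarefied), meta)
        assert set(res.summary.index) == set(meta["group"].unique())
        assert (res.summary["letters"].str.len() >= 1).all()
        # group mean equals mean over member samples
        g0 = res.summary.index[0]
        members = meta.index[meta["group"] == g0]
        assert res.summary.loc[g0, "mean"] == pytest.approx(
            res.per_sample[members].mean()
        )


class TestUpsetCounts:
    def test_two_group_enumeration(self):
        counts = pd.DataFrame(
            {"A": [3, 0], "B": [1, 2], "C": [0, 0]}, index=["s1", "s2"]
        )
        meta = pd.DataFrame(
            {"group": ["g1", "g2"], "age": 50, "gender": "male"},
            index=counts.index,
        )
        out = ecology.upset_counts(counts, meta)
        assert out.loc["g1", "n_taxa"] == 1        # A only in g1
        assert out.loc["g1&g2", "n_taxa"] == 1     # B in both
        assert "C" not in out.index

    def test_patterns_partition_nonzero_taxa(self, small_rarefied):
        rarefied, meta, _, _ = small_rarefied
        out = ecology.upset_counts(rarefied, meta)
        nonzero = int((rarefied.sum(axis=0) > 0).sum())
        assert out["n_taxa"].sum() == nonzero


class TestSpecOccu:
    @pytest.fixture()
    def toy(self):
        counts = pd.DataFrame(
            {
                "only_g1": [5, 5, 0, 0],
                "everywhere": [2, 2, 2, 2],
                "patchy": [4, 0, 1, 0],
            },
            index=["a1", "a2", "b1", "b2"],
        )
        meta = pd.DataFrame(
            {"group": ["g1", "g1", "g2", "g2"], "age": 50, "gender": "male"},
            index=counts.index,
        )
        return counts, meta

    def test_single_support_full_specificity(self, toy):
        counts, meta = toy
        out = ecology.spec_occu(counts, meta, top_n=10)
        rec = out[(out.taxon == "only_g1") & (out.group == "g1")].iloc[0]
        assert rec.specificity == pytest.approx(1.0)
        assert rec.occupancy == pytest.approx(1.0)
        assert rec.specialist

    def test_specificities_sum_to_one_across_groups(self, small_rarefied):
        rarefied, meta, _, _ = small_rarefied
        out = ecology.spec_occu(rarefied, meta, top_n=30)
        # recompute specificity for taxa appearing in every group's top list
        counts = out.groupby("taxon")["specificity"].count()
        full = counts.index[counts == meta["group"].nunique()]
        sums = out[out.taxon.isin(full)].groupby("taxon")["specificity"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_stable_under_sample_reordering(self, toy):
        counts, meta = toy
        out1 = ecology.spec_occu(counts, meta, top_n=10)
        order = list(reversed(counts.index))
        out2 = ecology.spec_occu(counts.loc[order], meta.loc[order], top_n=10)
        key = ["taxon", "group"]
        pd.testing.assert_frame_equal(
            out1.sort_values(key).reset_index(drop=True),
            out2.sort_values(key).reset_index(drop=True),
        )


class TestDifferentialAbundance:
    def _meta(self, profile, groups):
        return pd.DataFrame(
            {"group": groups, "age": 50, "gender": "male"}, index=profile.index
        )

    def test_planted_enrichment_detected_with_power(self):
        rng = np.random.default_rng(0)
        hits = 0
        n_rep = 20
        for _ in range(n_rep):
            base = rng.lognormal(0, 0.5, (40, 20))
            base[20:, 0] *= 4.0  # planted 4-fold enrichment
            prof = _profile(base / base.sum(axis=1, keepdims=True))
            meta = self._meta(prof, ["a"] * 20 + ["b"] * 20)
            out = ecology.differential_abundance(prof, meta)
            hits += int(out.loc["t0", "p_adj"] < 0.05)
        assert hits / n_rep > 0.8

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(1)
        base = rng.lognormal(0, 0.5, (40, 50))
        prof = _profile(base / base.sum(axis=1, keepdims=True))
        meta = self._meta(prof, ["a"] * 20 + ["b"] * 20)
        out = ecology.differential_abundance(prof, meta)
        assert 0.3 < out["p"].mean() < 0.7
        assert (out["p_adj"] >= out["p"] - 1e-12).all()

    def test_constant_taxon_flagged(self):
        prof = _profile([[0.5, 0.5]] * 6)
        meta = self._meta(prof, ["a"] * 3 + ["b"] * 3)
        out = ecology.differential_abundance(prof, meta)
        assert out["constant"].all()
        assert (out["p"] == 1.0).all()

    def test_two_group_direction_sign(self):
        prof = _profile([[1, 9], [1, 9], [9, 1], [9, 1]])
        prof = prof.div(prof.sum(axis=1), axis=0)
        meta = self._meta(prof, ["a", "a", "b", "b"])
        out = ecology.differential_abundance(prof, meta)
        assert out.loc["t0", "direction"] == 1.0   # higher in b
        assert out.loc["t1", "direction"] == -1.0
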