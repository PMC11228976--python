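"""Comparative statistics against independent oracles: studentized-range
Tukey rejects, Lance-Williams ward.D2, eigendecomposition PCA, brute-force
Venn regions."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from hypothesis import given, settings, strategies as st

from epep import (
    SampleDesign,
    anova_tukey,
    compact_letter_display,
    count_epeps,
    hcluster,
    pairwise_t_bonferroni,
    pca_lfq,
    prevalence_filter_and_scale,
    species_overlap,
    subset_analysis,
)
from epep.quant import LFQMatrix


# ------------------------------------------------------------ oracles

def tukey_rejects_oracle(values, groups, order, alpha=0.05):
    """Tukey-Kramer rejects from the studentized range distribution."""
    arrays = {g: values[groups == g] for g in order}
    k = len(order)
    n_total = sum(len(a) for a in arrays.values())
    dfw = n_total - k
    msw = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / dfw
    qcrit = sps.studentized_range.ppf(1 - alpha, k, dfw)
    rejects = {}
    for a, b in itertools.combinations(order, 2):
        xa, xb = arrays[a], arrays[b]
        se = np.sqrt(msw / 2 * (1 / len(xa) + 1 / len(xb)))
        rejects[(a, b)] = abs(xa.mean() - xb.mean()) / se > qcrit
    return rejects


def ward_d2_heights_oracle(X):
    """Naive agglomerative ward.D2 via the Lance-Williams recurrence."""
    n = len(X)
    d = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = float(np.linalg.norm(X[i] - X[j]))

    def dist(a, b):
        return d[(a, b)] if (a, b) in d else d[(b, a)]

    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    nxt = n
    heights = []
    while len(active) > 1:
        best = min(
            ((dist(a, b), a, b) for a, b in itertools.combinations(active, 2)),
            key=lambda t: t[0],
        )
        h, a, b = best
        heights.append(h)
        for c in active:
            if c in (a, b):
                continue
            na, nb, nc = sizes[a], sizes[b], sizes[c]
            d[(nxt, c)] = float(np.sqrt(
                ((na + nc) * dist(a, c) ** 2 + (nb + nc) * dist(b, c) ** 2
                 - nc * h ** 2) / (na + nb + nc)
            ))
        sizes[nxt] = sizes[a] + sizes[b]
        active = [c for c in active if c not in (a, b)] + [nxt]
        nxt += 1
    return np.array(heights)


def make_matrix(rng, n_rows=12, design=None, missing=0.2):
    if design is None:
        samples = [(f"s{i}", "spA" if i < 3 else "spB", f"cv{i}") for i in range(6)]
        reps = {s: [f"{s}_r{k}" for k in (1, 2, 3)] for s, _, _ in samples}
        design = SampleDesign(samples=samples, replicates=reps)
    vals = np.exp(rng.normal(14, 1, size=(n_rows, len(design.sample_ids))))
    mask = rng.random(vals.shape) < missing
    vals[mask] = np.nan
    idx = pd.Index([f"PEP{i:02d}" for i in range(n_rows)], name="sequence")
    values = pd.DataFrame(vals, index=idx, columns=design.sample_ids)
    ann = pd.DataFrame(
        {
            "epitopes": ["FS" if i % 2 == 0 else "QPY" for i in range(n_rows)],
            "match_kinds": ["complete"] * n_rows,
            "groups": ["" if i % 2 == 0 else "5" for i in range(n_rows)],
            "protein_types": ["glut-L" if i % 2 == 0 else "glia-gamma" for i in range(n_rows)],
        },
        index=idx,
    )
    return LFQMatrix(values=values, row_annotations=ann, design=design)


# ------------------------------------------------------------ counts

class TestCounts:
    def test_per_sample_counts_and_species_sd(self, rng):
        m = make_matrix(rng)
        summary = count_epeps(m)
        for _, row in summary.per_sample.iterrows():
            assert row["n_epeps"] == m.values[row["sample_id"]].notna().sum()
        sub = summary.per_sample.query("species == 'spA'")["n_epeps"]
        got = summary.per_species.set_index("species")
        assert got.loc["spA", "mean"] == pytest.approx(sub.mean())
        assert got.loc["spA", "sd"] == pytest.approx(sub.std(ddof=1))


# ------------------------------------------------------------ ANOVA / Tukey

class TestAnovaTukey:
    def test_identical_groups_share_a_letter(self, rng):
        base = rng.normal(0, 1, size=8)
        values = np.concatenate([base, base + 1e-3 * rng.normal(size=8)])
        groups = np.array(["a_grp"] * 8 + ["b_grp"] * 8)
        res = anova_tukey(values, groups)
        assert set(res["letters"]["a_grp"]) & set(res["letters"]["b_grp"])

    def test_separated_groups_get_distinct_letters(self, rng):
        values = np.concatenate([rng.normal(0, 0.1, 8), rng.normal(100, 0.1, 8)])
        groups = np.array(["lo"] * 8 + ["hi"] * 8)
        res = anova_tukey(values, groups)
        assert not set(res["letters"]["lo"]) & set(res["letters"]["hi"])

    def test_letters_match_independent_rejects(self, rng):
        # 5 groups x 8 values with a partial-separation structure
        means = [0.0, 0.5, 5.0, 5.5, 12.0]
        order = [f"g{i}" for i in range(5)]
        values = np.concatenate([rng.normal(mu, 1.0, 8) for mu in means])
        groups = np.repeat(order, 8)
        res = anova_tukey(values, groups, group_order=order)
        oracle = tukey_rejects_oracle(values, groups, order)
        # statsmodels Tukey agrees with the studentized-range computation
        for (a, b), rej in oracle.items():
            share = bool(set(res["letters"][a]) & set(res["letters"][b]))
            assert share == (not rej)

    def test_clearly_ordered_groups_get_alphabetical_letters(self, rng):
        order = [f"g{i}" for i in range(5)]
        values = np.concatenate([rng.normal(100 * i, 0.5, 8) for i in range(5)])
        res = anova_tukey(values, np.repeat(order, 8), group_order=order)
        assert [res["letters"][g] for g in order] == ["a", "b", "c", "d", "e"]

    def test_letters_symmetric_under_relabeling(self, rng):
        values = np.concatenate([rng.normal(mu, 1.0, 8) for mu in (0, 1, 8)])
        relabel = {"x": "w", "y": "u", "z": "v"}
        g1 = np.repeat(["x", "y", "z"], 8)
        g2 = np.array([relabel[g] for g in g1])
        r1 = anova_tukey(values, g1, group_order=["x", "y", "z"])
        r2 = anova_tukey(values, g2, group_order=["w", "u", "v"])
        for a, b in itertools.combinations(["x", "y", "z"], 2):
            s1 = bool(set(r1["letters"][a]) & set(r1["letters"][b]))
            s2 = bool(set(r2["letters"][relabel[a]]) & set(r2["letters"][relabel[b]]))
            assert s1 == s2

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            anova_tukey(np.array([1.0] * 6), np.repeat(["u", "v"], 3))

    def test_insert_absorb_chain(self):
        # classic chain: A<B<C with only A-C significant -> A:a, B:ab, C:b
        letters = compact_letter_display(
            ["A", "B", "C"], {("A", "B"): False, ("B", "C"): False, ("A", "C"): True}
        )
        assert letters == {"A": "a", "B": "ab", "C": "b"}


class TestBonferroni:
    def test_adjustment_times_number_of_pairs(self, rng):
        values = np.concatenate([rng.normal(i, 1.0, 6) for i in range(3)])
        groups = np.repeat(["u", "v", "w"], 6)
        res = pairwise_t_bonferroni(values, groups)
        assert len(res) == 3
        for _, row in res.iterrows():
            raw = sps.ttest_ind(values[groups == row["group1"]],
                                values[groups == row["group2"]]).pvalue
            assert row["p_raw"] == pytest.approx(raw, abs=1e-12)
            assert row["p_adj"] == pytest.approx(min(1.0, raw * 3), abs=1e-10)
            assert row["p_adj"] >= row["p_raw"]

    def test_capped_at_one(self, rng):
        values = rng.normal(0, 1, 30)
        groups = np.repeat([f"g{i}" for i in range(5)], 6)
        res = pairwise_t_bonferroni(values, groups)
        assert (res["p_adj"] <= 1.0).all()

    def test_singleton_group_undefined(self):
        values = np.array([1.0, 2.0, 3.0, 10.0])
        groups = np.array(["u", "u", "u", "v"])
        res = pairwise_t_bonferroni(values, groups)
        assert np.isnan(res["p_adj"]).all()


# ------------------------------------------------------------ overlaps

class TestOverlap:
    def test_two_set_example(self):
        res = species_overlap({"A": {"p1", "p2"}, "B": {"p2", "p3"}})
        lut = res.set_index("species")["count"]
        assert lut["A"] == 1 and lut["B"] == 1 and lut["A;B"] == 1

    def test_identical_sets_only_full_region(self):
        res = species_overlap({"A": {1, 2}, "B": {1, 2}, "C": {1, 2}})
        lut = res.set_index("species")["count"]
        assert lut["A;B;C"] == 2
        assert res["count"].sum() == 2

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.sets(st.integers(0, 99)), min_size=2, max_size=5))
    def test_region_counts_sum_to_union(self, sets):
        named = {f"S{i}": s for i, s in enumerate(sets)}
        res = species_overlap(named)
        assert res["count"].sum() == len(set().union(*named.values()))
        assert len(res) == 2 ** len(named) - 1

    def test_matches_bruteforce_membership(self, rng):
        named = {f"S{i}": set(rng.choice(100, size=rng.integers(5, 60), replace=False))
                 for i in range(5)}
        res = species_overlap(named)
        for _, row in res.iterrows():
            inside = set(row["species"].split(";"))
            expected = sum(
                1 for el in set().union(*named.values())
                if {n for n in named if el in named[n]} == inside
            )
            assert row["count"] == expected


# ------------------------------------------------------------ PCA / clustering

class TestPca:
    def test_single_direction_gives_full_first_component(self):
        base = np.exp(np.linspace(1, 2, 5))
        vals = pd.DataFrame(
            {f"s{j}": base ** (j + 1) for j in range(4)},
            index=[f"p{i}" for i in range(5)],
        )
        res = pca_lfq(vals, impute_policy="zero")
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_duplicate_samples_get_identical_scores(self, rng):
        m = make_matrix(rng, missing=0.0)
        vals = m.values.copy()
        vals["dup"] = vals[vals.columns[0]]
        res = pca_lfq(vals)
        np.testing.assert_allclose(
            res.scores.loc[vals.columns[0]], res.scores.loc["dup"], atol=1e-10
        )

    def test_variance_fractions_match_eigendecomposition(self, rng):
        m = make_matrix(rng, missing=0.0)
        res = pca_lfq(m)
        X = np.log(m.values.to_numpy()).T
        C = np.cov(X, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(C))[::-1]
        frac = eig[: len(res.explained_variance_ratio)] / eig.sum()
        np.testing.assert_allclose(res.explained_variance_ratio, frac, atol=1e-8)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-8)

    def test_fractions_nonincreasing(self, rng):
        m = make_matrix(rng)
        res = pca_lfq(m)
        assert (np.diff(res.explained_variance_ratio) <= 1e-12).all()

    def test_all_missing_row_dropped_with_warning(self, rng):
        m = make_matrix(rng, missing=0.0)
        m.values.iloc[0] = np.nan
        with pytest.warns(UserWarning, match="all-missing"):
            res = pca_lfq(m)
        assert res.scores.shape[0] == len(m.design.sample_ids)


class TestHcluster:
    def test_identical_columns_merge_first(self, rng):
        m = make_matrix(rng, missing=0.0)
        m.values["s1"] = m.values["s0"]
        res = hcluster(m, axis="columns")
        i, j = int(res.linkage[0, 0]), int(res.linkage[0, 1])
        assert {res.labels[i], res.labels[j]} == {"s0", "s1"}
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_heights_match_lance_williams_oracle(self, rng):
        m = make_matrix(rng, n_rows=6, missing=0.0)
        res = hcluster(m, axis="rows")
        X = np.log(m.values.to_numpy())
        np.testing.assert_allclose(res.heights, ward_d2_heights_oracle(X), atol=1e-8)

    def test_heights_nondecreasing(self, rng):
        m = make_matrix(rng)
        res = hcluster(m, axis="columns")
        assert (np.diff(res.heights) >= -1e-12).all()

    def test_flat_clusters_count(self, rng):
        m = make_matrix(rng)
        res = hcluster(m, axis="columns")
        assert len(set(res.flat_clusters(3).values())) == 3


# ------------------------------------------------------------ slicing / scaling

class TestSubset:
    def test_epitope_and_group_and_type_slices(self, rng):
        m = make_matrix(rng)
        assert len(subset_analysis(m, epitope="FS").values) == 6
        assert len(subset_analysis(m, group=5).values) == 6
        assert len(subset_analysis(m, protein_type="glia-gamma").values) == 6
        assert len(subset_analysis(m, epitope="QGY").values) == 0

    def test_unknown_selector_rejected(self, rng):
        m = make_matrix(rng)
        with pytest.raises(ValueError):
            subset_analysis(m, group=9)
        with pytest.raises(ValueError):
            subset_analysis(m, protein_type="nonsense")
        with pytest.raises(ValueError):
            subset_analysis(m, epitope="FS", group=5)


class TestPrevalenceScale:
    def _matrix_with_presence(self, rng, n_present_per_row):
        samples = [(f"s{i}", "sp", f"cv{i}") for i in range(40)]
        reps = {s: [f"{s}_r{k}" for k in (1, 2, 3)] for s, _, _ in samples}
        design = SampleDesign(samples=samples, replicates=reps)
        vals = np.exp(rng.normal(14, 1, size=(len(n_present_per_row), 40)))
        for r, n_present in enumerate(n_present_per_row):
            absent = rng.choice(40, size=40 - n_present, replace=False)
            vals[r, absent] = np.nan
        idx = pd.Index([f"PEP{r}" for r in range(len(n_present_per_row))], name="sequence")
        values = pd.DataFrame(vals, index=idx, columns=design.sample_ids)
        ann = pd.DataFrame({"epitopes": "FS", "match_kinds": "complete",
                            "groups": "", "protein_types": "glut-L"}, index=idx)
        return LFQMatrix(values=values, row_annotations=ann, design=design)

    def test_strict_threshold_30_of_40(self, rng):
        m = self._matrix_with_presence(rng, [31, 30, 40, 5])
        out = prevalence_filter_and_scale(m, min_samples=30)
        assert list(out.values.index) == ["PEP0", "PEP2"]

    def test_rows_scaled_to_mean0_sd1(self, rng):
        m = self._matrix_with_presence(rng, [31, 35, 40])
        out = prevalence_filter_and_scale(m)
        for _, row in out.values.iterrows():
            obs = row.dropna()
            assert abs(obs.mean()) < 1e-10
            assert abs(obs.std(ddof=1) - 1.0) < 1e-10

    def test_constant_row_becomes_zero_with_warning(self, rng):
        m = self._matrix_with_presence(rng, [40])
        m.values.iloc[0, :] = 123.0
        with pytest.warns(UserWarning, match="constant"):
            out = prevalence_filter_and_scale(m)
        assert (out.values.iloc[0].dropna() == 0).all()

    def test_missingness_preserved(self, rng):
        m = self._matrix_with_presence(rng, [31, 35])
        out = prevalence_filter_and_scale(m)
        pd.testing.assert_frame_equal(out.values.isna(), m.values.loc[out.values.index].isna())
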