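"""Trait statistics: RA, correlations, regression, ANOVA, h2, Duncan test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import magic_ratoon as mr
import magic_ratoon.simulate as sim
import magic_ratoon.traits as tr


class TestRatooningAbility:
    def test_printed_parent_example(self):
        assert tr.ratooning_ability(7.5, 12.0) == pytest.approx(1.6)

    def test_equal_counts_give_one(self):
        assert tr.ratooning_ability(9.3, 9.3) == pytest.approx(1.0)

    def test_zero_ratoon_tillers(self):
        assert tr.ratooning_ability(10, 0) == 0.0

    def test_nonpositive_main_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(tr.ratooning_ability(0.0, 5.0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        x=st.floats(0.1, 100), y=st.floats(0, 100), c=st.floats(0.01, 50),
    )
    def test_scale_invariance(self, x, y, c):
        assert tr.ratooning_ability(c * x, c * y) == pytest.approx(
            tr.ratooning_ability(x, y), rel=1e-9
        )


def _book_from_means(mc: pd.DataFrame, rc: pd.DataFrame) -> sim.PhenotypeBook:
    """Build a single-replicate book from per-line season means."""
    rows = []
    for season, df in (("MC", mc), ("RC", rc)):
        for line_id, r in df.iterrows():
            rows.append({"line_id": line_id, "season": season, "replicate": 1,
                         "batch": 1, **r.to_dict()})
    return sim.PhenotypeBook(frame=pd.DataFrame(rows))


class TestCorrelation:
    def test_identical_vectors_r_one(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {"TN": rng.uniform(5, 20, 30), "PL": rng.uniform(15, 30, 30),
             "SPP": rng.uniform(50, 300, 30), "GY": rng.uniform(5, 40, 30)},
            index=[f"L{i}" for i in range(30)],
        )
        book = _book_from_means(df, df)
        r, p = tr.cross_season_correlation(book, "PL")
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_independent_seasons_near_zero(self, panel_302, lines_302):
        """With no shared variance the cross-season r stays in the null band."""
        arch = mr.TraitArchitecture.default(panel_302)
        arch.traits["SPP"] = sim.TraitSpec(
            mean={"MC": 213.0, "RC": 59.0}, sd={"MC": 65.0, "RC": 18.0},
            shared_var=0.0, batch_var=0.0, residual_var=0.2,
        )
        rs = []
        for seed in range(6):
            book = mr.simulate_phenotypes(panel_302, lines_302, arch, seed=600 + seed)
            r, _ = tr.cross_season_correlation(book, "SPP")
            rs.append(r)
        # null sampling band: |r| < 0.12 covers ~95% of draws at n=302
        assert np.mean(np.abs(rs) < 0.12) >= 5 / 6
        assert abs(np.mean(rs)) < 0.08

    def test_zero_variance_flagged(self):
        df = pd.DataFrame({"TN": [1.0] * 5, "PL": [2.0] * 5, "SPP": [3.0] * 5,
                           "GY": [4.0] * 5}, index=[f"L{i}" for i in range(5)])
        book = _book_from_means(df, df)
        with pytest.warns(UserWarning, match="zero variance"):
            r, p = tr.cross_season_correlation(book, "TN")
        assert np.isnan(r)


class TestYieldRegression:
    def test_gy_equals_tn_exactly(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "TN": rng.normal(12, 3, 50), "PL": rng.normal(27, 3, 50),
            "SPP": rng.normal(213, 60, 50)}, index=[f"L{i}" for i in range(50)])
        df["GY"] = df["TN"]
        book = _book_from_means(df, df)
        m = tr.yield_component_regression(book, "MC")
        assert m.beta["TN"] == pytest.approx(1.0, abs=1e-8)
        assert abs(m.beta["SPP"]) < 1e-8 and abs(m.beta["PL"]) < 1e-8

    def test_composed_weights_recover_ordering(self, panel_302, lines_302):
        """Generator composition is TN-dominant; standardized betas order
        TN > SPP in the main crop and TN > SPP > PL in the ratoon crop."""
        book = mr.simulate_phenotypes(
            panel_302, lines_302, mr.TraitArchitecture.default(panel_302), seed=71
        )
        mc = tr.yield_component_regression(book, "MC")
        rc = tr.yield_component_regression(book, "RC")
        assert mc.beta["TN"] > mc.beta["SPP"] > 0
        assert rc.beta["TN"] > rc.beta["SPP"] > rc.beta["PL"] > 0
        assert mc.pvalues["TN"] < 1e-3 and rc.pvalues["TN"] < 1e-3

    def test_permuted_gy_null_pvalues(self):
        rng = np.random.default_rng(5)
        ps = []
        for rep in range(30):
            df = pd.DataFrame({
                "TN": rng.normal(size=80), "PL": rng.normal(size=80),
                "SPP": rng.normal(size=80), "GY": rng.normal(size=80)},
                index=[f"L{i}" for i in range(80)])
            book = _book_from_means(df, df)
            m = tr.yield_component_regression(book, "MC")
            ps.extend(m.pvalues.values())
        assert 0.2 < np.mean(np.asarray(ps) < 0.5) < 0.8  # roughly uniform


def _records(lines, seasons, reps, fn, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(lines):
        for s, season in enumerate(seasons):
            for rep in range(reps):
                v = fn(i, s, rng)
                rows.append({"line_id": f"L{i:03d}", "season": season,
                             "replicate": rep + 1, "batch": 1,
                             "TN": v, "PL": v, "SPP": v, "GY": v})
    return sim.PhenotypeBook(frame=pd.DataFrame(rows))


class TestAnova:
    def test_season_effect_only(self):
        book = _records(40, ("MC", "RC"), 2,
                        lambda i, s, rng: 10.0 + 5.0 * s + 0.1 * rng.normal())
        part = tr.anova_partition(book, "TN")
        assert part.percent["genotype"] < 2.0
        assert part.percent["environment"] > 95.0

    def test_components_sum_to_hundred(self, book_small):
        for trait in ("TN", "PL", "SPP", "GY"):
            part = tr.anova_partition(book_small, trait)
            assert sum(part.percent.values()) == pytest.approx(100.0, abs=1e-6)

    def test_single_replicate_degrades(self):
        book = _records(20, ("MC", "RC"), 1, lambda i, s, rng: rng.normal())
        part = tr.anova_partition(book, "TN")
        assert part.degraded
        assert part.percent["gxe"] == 0.0

    def test_recovers_planted_shares(self, panel_302, lines_302):
        """Expected sequential-SS shares from the planted variance
        components are recovered within 5 points."""
        arch = mr.TraitArchitecture.default(panel_302)
        v_sh, v_sp, v_e_lm, delta = 0.35, 0.5, 0.15, 1.0
        arch.traits["PL"] = sim.TraitSpec(
            mean={"MC": -delta, "RC": 0.0}, sd={"MC": 1.0, "RC": 1.0},
            shared_var=v_sh, batch_var=0.0, residual_var=v_e_lm, specific=v_sp,
        )
        book = mr.simulate_phenotypes(panel_302, lines_302, arch, n_replicates=2, seed=81)
        part = tr.anova_partition(book, "PL")
        a, r = 302, 2
        sg = v_sh                     # line main effect = cross-season shared
        sge = v_sp                    # season-specific term is all interaction
        se = v_e_lm * r               # per-record residual
        ss_g = (a - 1) * (se + r * sge + 2 * r * sg)
        ss_e = (se + r * sge) + r * a * delta ** 2 / 2
        ss_ge = (a - 1) * (se + r * sge)
        ss_res = a * 2 * (r - 1) * se
        total = ss_g + ss_e + ss_ge + ss_res
        expect = {"genotype": 100 * ss_g / total, "environment": 100 * ss_e / total,
                  "gxe": 100 * ss_ge / total, "residual": 100 * ss_res / total}
        for term, val in expect.items():
            assert abs(part.percent[term] - val) < 5.0


class TestHeritability:
    def test_pure_genetic_unity(self):
        book = _records(30, ("MC", "RC"), 2, lambda i, s, rng: float(i))
        part = tr.anova_partition(book, "TN")
        h = tr.heritability(part)
        assert h.h2 == pytest.approx(1.0, abs=1e-9)

    def test_no_genetic_zero(self):
        book = _records(30, ("MC", "RC"), 2, lambda i, s, rng: rng.normal())
        h = tr.heritability(tr.anova_partition(book, "TN"))
        assert h.h2 < 0.15  # Vg floors at 0 up to sampling noise

    def test_recovers_planted_half(self, panel_302, lines_302):
        """Planted Vg/(Vg+Vge+Ve) = 0.5 recovered within 0.1."""
        arch = mr.TraitArchitecture.default(panel_302)
        # Vg = shared = 0.4; Vge = specific = 0.1;
        # Ve = residual_var * n_rep = 0.3 -> h2 = 0.4 / 0.8 = 0.5
        arch.traits["PL"] = sim.TraitSpec(
            mean={"MC": 0.0, "RC": 0.0}, sd={"MC": 1.0, "RC": 1.0},
            shared_var=0.4, batch_var=0.0, residual_var=0.15, specific=0.1,
        )
        h2s = []
        for seed in range(5):
            book = mr.simulate_phenotypes(panel_302, lines_302, arch, seed=900 + seed)
            h2s.append(tr.heritability(tr.anova_partition(book, "PL")).h2)
        assert abs(np.mean(h2s) - 0.5) < 0.1


class TestDuncan:
    def test_overwhelming_separation(self):
        rng = np.random.default_rng(3)
        groups = {"A": rng.normal(0, 0.1, 20), "B": rng.normal(10, 0.1, 20)}
        out = tr.duncan_groups(groups)
        assert list(out["letters"]) == ["a", "b"]
        assert out.iloc[0]["class"] == "B"  # highest mean first

    def test_null_shares_letter_most_of_the_time(self):
        """Identical distributions end up in one letter group ~(1 - alpha)
        of the time; with two classes the range test is exact, with three
        Duncan's protection level admits slightly more separations."""
        rng = np.random.default_rng(4)
        reps = 200
        share2 = share3 = 0
        for _ in range(reps):
            g2 = {k: rng.normal(size=12) for k in "AB"}
            share2 += int(set(tr.duncan_groups(g2)["letters"]) == {"a"})
            g3 = {k: rng.normal(size=12) for k in "ABC"}
            share3 += int(set(tr.duncan_groups(g3)["letters"]) == {"a"})
        assert 0.91 < share2 / reps < 0.99
        assert share3 / reps > 0.80

    @pytest.mark.parametrize("k,seed", [(3, 0), (4, 1), (5, 2), (4, 3), (5, 4)])
    def test_exhaustive_pairwise_range_oracle(self, k, seed):
        """Letter sharing must match an independent oracle built from the
        same studentized-range quantiles: a pair is inseparable iff some
        covering span's range is below its least significant range."""
        rng = np.random.default_rng(seed)
        groups = {f"C{i}": rng.normal(rng.uniform(0, 2), 1.0, rng.integers(5, 15))
                  for i in range(k)}
        out = tr.duncan_groups(groups, alpha=0.05)
        order = list(out["class"])
        means = out.set_index("class")["mean"]
        ns = out.set_index("class")["n"]
        arrays = {c: np.asarray(groups[c], float) for c in order}
        sse = sum(((arrays[c] - arrays[c].mean()) ** 2).sum() for c in order)
        df_err = sum(ns) - k
        mse = sse / df_err
        n_h = k / sum(1.0 / ns[c] for c in order)
        m = means[order].to_numpy()

        def lsr(p):
            ap = 1 - (1 - 0.05) ** (p - 1)
            return stats.studentized_range.ppf(1 - ap, p, df_err) * np.sqrt(mse / n_h)

        def share_letter(i, j):
            return bool(set(out["letters"].iloc[i]) & set(out["letters"].iloc[j]))

        for i in range(k):
            for j in range(i + 1, k):
                covered = any(
                    m[a] - m[b] < lsr(b - a + 1)
                    for a in range(0, i + 1)
                    for b in range(j, k)
                )
                assert share_letter(i, j) == covered, (i, j)

    def test_relabel_and_shift_invariance(self):
        rng = np.random.default_rng(6)
        groups = {f"C{i}": rng.normal(i * 0.8, 1.0, 10) for i in range(4)}
        base = tr.duncan_groups(groups)
        shifted = tr.duncan_groups({k: v + 100.0 for k, v in groups.items()})
        assert list(base["letters"]) == list(shifted["letters"])
        renamed = tr.duncan_groups({f"X{k}": v for k, v in groups.items()})
        assert list(base["letters"]) == list(renamed["letters"])

    def test_zero_error_df_single_letter(self):
        out = tr.duncan_groups({"A": [1.0], "B": [2.0]})
        assert set(out["letters"]) == {"a"}


class TestEffectTable:
    def _hapset(self, labels, lines, parents=None):
        import magic_ratoon.haplotypes as hap

        assign = pd.Series(labels, index=lines)
        counts = assign.value_counts().to_dict()
        haps = {l: (i,) for i, l in enumerate(sorted(set(labels) - {"MISSING"}))}
        return hap.GeneHaplotypeSet(
            gene_id="g1", variant_sites=[("chr01", 1, "A", "T")],
            haplotypes=haps, assignment=assign, class_counts=counts,
            parents=parents or {},
        )

    def test_difference_is_internal_mean_subtraction(self, book_small):
        lines = list(book_small.line_means("MC").index)
        labels = ["Hap1" if i % 2 == 0 else "Hap2" for i in range(len(lines))]
        hs = self._hapset(labels, lines)
        table = tr.haplotype_effect_table("g1", hs, book_small)
        t = table.table.set_index(["row", "class"])
        for row in ("TN_MC", "TN_RC", "RA"):
            diff = t.loc[(row, "Hap2"), "diff_vs_ref"]
            means = t.loc[row]["mean"]
            assert diff == pytest.approx(means["Hap2"] - means["Hap1"], abs=1e-12)

    def test_reference_class_has_most_founders(self, book_small):
        lines = list(book_small.line_means("MC").index)
        labels = ["Hap1" if i % 3 else "Hap2" for i in range(len(lines))]
        hs = self._hapset(labels, lines,
                          parents={"Hap1": ["DA5", "Pra"], "Hap2": ["ZS97", "MH63", "YJSM"]})
        table = tr.haplotype_effect_table("g1", hs, book_small)
        assert table.reference == "Hap2"

    def test_shuffled_phenotype_shares_letters(self, book_small):
        rng = np.random.default_rng(8)
        frame = book_small.frame.copy()
        for trait in ("TN", "PL", "SPP", "GY"):
            frame[trait] = rng.permutation(frame[trait].to_numpy())
        shuffled = sim.PhenotypeBook(frame=frame)
        lines = list(shuffled.line_means("MC").index)
        labels = ["Hap1" if i % 2 else "Hap2" for i in range(len(lines))]
        table = tr.haplotype_effect_table("g1", self._hapset(labels, lines), shuffled)
        t = table.table
        share = 0
        rows = t["row"].unique()
        for row in rows:
            sub = t[t["row"] == row]
            share += int(bool(set(sub["letters"].iloc[0]) & set(sub["letters"].iloc[1])))
        assert share >= len(rows) - 1  # null phenotypes: classes inseparable

    def test_single_class_no_letters(self, book_small):
        lines = list(book_small.line_means("MC").index)
        hs = self._hapset(["Hap1"] * len(lines), lines)
        table = tr.haplotype_effect_table("g1", hs, book_small)
        assert (table.table["letters"] == "").all()
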