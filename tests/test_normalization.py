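import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from maxcounts.counting import CountMatrix
from maxcounts.normalization import (apply_size_factors, fq_between_lane,
                                     fq_within_lane, rpkm, tmm_factors)


def matrix(columns: dict, index=None, groups=None) -> CountMatrix:
    return CountMatrix(pd.DataFrame(columns, index=index), groups=groups)


# ---------------------------------------------------------------------------
# Independent literal oracle for the trimmed mean of M-values: plain loops
# over the published formula, no shared code with the implementation.
# ---------------------------------------------------------------------------

def tmm_oracle(df: pd.DataFrame, trim_m=0.30, trim_a=0.05) -> pd.Series:
    sizes = {lib: df[lib].sum() for lib in df.columns}
    uq = {lib: np.quantile(df[lib] / sizes[lib], 0.75) for lib in df.columns}
    mean_uq = sum(uq.values()) / len(uq)
    ref = min(df.columns, key=lambda lib: abs(uq[lib] - mean_uq))
    log_factors = {}
    for lib in df.columns:
        if lib == ref:
            log_factors[lib] = 0.0
            continue
        m_vals, a_vals, weights = [], [], []
        for y_k, y_r in zip(df[lib], df[ref]):
            if y_k > 0 and y_r > 0:
                p_k, p_r = y_k / sizes[lib], y_r / sizes[ref]
                m_vals.append(math.log2(p_k / p_r))
                a_vals.append(0.5 * math.log2(p_k * p_r))
                weights.append((sizes[lib] - y_k) / (sizes[lib] * y_k)
                               + (sizes[ref] - y_r) / (sizes[ref] * y_r))
        n = len(m_vals)
        if n == 0 or max(abs(v) for v in m_vals) < 1e-6:
            log_factors[lib] = 0.0
            continue
        def ranks(values):  # 1-based, ties get the average rank
            out = []
            for v in values:
                smaller = sum(1 for u in values if u < v)
                equal = sum(1 for u in values if u == v)
                out.append(smaller + (equal + 1) / 2)
            return out
        rm, ra = ranks(m_vals), ranks(a_vals)
        lo_m = math.floor(n * trim_m) + 1
        lo_a = math.floor(n * trim_a) + 1
        num = den = 0.0
        for i in range(n):
            if lo_m <= rm[i] <= n + 1 - lo_m and lo_a <= ra[i] <= n + 1 - lo_a:
                num += m_vals[i] / weights[i]
                den += 1.0 / weights[i]
        log_factors[lib] = num / den if den else 0.0
    factors = {lib: 2.0 ** f for lib, f in log_factors.items()}
    geo = math.exp(sum(math.log(f) for f in factors.values()) / len(factors))
    return pd.Series({lib: f / geo for lib, f in factors.items()})


TOY = pd.DataFrame({
    "A": [10, 20, 30, 40, 50, 60, 700, 80],
    "B": [12, 18, 33, 47, 55, 66, 650, 95],
}, index=[f"e{i}" for i in range(8)])


class TestTMM:
    def test_identical_libraries_give_unit_factors(self):
        m = matrix({"A": [5, 10, 15], "B": [5, 10, 15]})
        sf = tmm_factors(m)
        assert sf.factors.tolist() == pytest.approx([1.0, 1.0])

    def test_global_scaling_cancels(self):
        m = matrix({"A": [5, 10, 15, 20], "B": [10, 20, 30, 40]})
        assert tmm_factors(m).factors.tolist() == pytest.approx([1.0, 1.0])

    def test_toy_table_matches_literal_oracle(self):
        got = tmm_factors(CountMatrix(TOY)).factors
        want = tmm_oracle(TOY)
        assert np.allclose(got[want.index], want, atol=1e-9)

    def test_matches_edger(self, tmp_path):
        """Cross-check against the reference TMM implementation in edgeR."""
        counts = TOY.assign(C=[9, 25, 28, 35, 60, 50, 900, 70])
        csv = tmp_path / "counts.csv"
        counts.to_csv(csv, index=False)
        script = tmp_path / "tmm.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(edgeR))
            m <- as.matrix(read.csv("{csv}"))
            cat(sprintf("%.12f", calcNormFactors(m, method="TMM")), sep="\\n")
        """))
        res = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        want = [float(x) for x in res.stdout.split()]
        got = tmm_factors(CountMatrix(counts)).factors
        assert np.allclose(got.to_numpy(), want, rtol=1e-6)

    def test_invariant_to_rescaling(self):
        # exact under joint rescaling; approximate when one library is
        # rescaled (the inverse-variance weights see absolute counts)
        base = CountMatrix(TOY)
        joint = CountMatrix(TOY * 3)
        one = CountMatrix(TOY.assign(A=TOY["A"] * 7))
        f0 = tmm_factors(base).factors
        assert np.allclose(tmm_factors(joint).factors, f0, rtol=1e-12)
        assert np.allclose(tmm_factors(one).factors, f0, atol=0.01)

    def test_all_zero_library_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(matrix({"A": [1, 2], "B": [0, 0]}))

    def test_apply_equalizes_effective_sizes(self):
        # TMM sees only proportions, so re-estimation reproduces the same
        # factors; the fixed point is that effective library sizes
        # (factor × total) become equal after applying the correction
        m = CountMatrix(TOY)
        sf = tmm_factors(m)
        normed = apply_size_factors(m, sf)
        again = tmm_factors(normed)
        assert np.allclose(again.factors, sf.factors, atol=1e-4)
        eff = again.factors * normed.library_sizes()
        assert np.allclose(eff, eff.iloc[0], rtol=1e-3)


class TestApplySizeFactors:
    def test_unit_factors_equal_sizes_leave_values(self):
        m = matrix({"A": [1, 2, 3], "B": [3, 2, 1]})
        sf = tmm_factors(m)
        out = apply_size_factors(m, sf)
        ratio = out.data / m.data
        assert np.allclose(ratio.values, ratio.values[0, 0])

    def test_doubling_a_factor_halves_values(self):
        from maxcounts.normalization import SizeFactors
        m = matrix({"A": [4, 4], "B": [4, 4]})
        base = apply_size_factors(m, SizeFactors(pd.Series({"A": 1.0, "B": 1.0}), "A"))
        bumped = apply_size_factors(m, SizeFactors(pd.Series({"A": 2.0, "B": 1.0}), "A"))
        # relative change of A against B halves (up to the common rescaling)
        rel_base = base.data["A"] / base.data["B"]
        rel_bump = bumped.data["A"] / bumped.data["B"]
        assert np.allclose(rel_bump, rel_base / 2)

    def test_unknown_library_rejected(self):
        from maxcounts.normalization import SizeFactors
        m = matrix({"A": [1], "B": [2]})
        with pytest.raises(KeyError):
            apply_size_factors(m, SizeFactors(pd.Series({"A": 1.0}), "A"))


class TestRPKM:
    def test_hand_values(self):
        m = matrix({"lib": [1000, 0, 500]},
                   index=["a", "b", "c"])
        # library total is 1500; use a custom total by scaling lengths instead
        lengths = pd.Series({"a": 1000, "b": 500, "c": 2000})
        out = rpkm(m, lengths)
        total = 1500
        assert out.data.loc["a", "lib"] == pytest.approx(
            1000 / (1000 / 1e3 * total / 1e6))
        assert out.data.loc["b", "lib"] == 0.0
        assert out.data.loc["c", "lib"] == pytest.approx(
            500 / (2000 / 1e3 * total / 1e6))

    def test_printed_formula_example(self):
        # one exon of 2 kb with 500 reads in a library of 2e7 reads -> 12.5
        m = CountMatrix(pd.DataFrame({"lib": [500, 2 * 10**7 - 500]},
                                     index=["x", "rest"]))
        lengths = pd.Series({"x": 2000, "rest": 1000})
        assert rpkm(m, lengths).data.loc["x", "lib"] == pytest.approx(12.5)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            rpkm(matrix({"lib": [0, 0]}, index=["a", "b"]),
                 pd.Series({"a": 100, "b": 100}))


class TestFQBetweenLane:
    def test_mean_of_order_statistics(self):
        m = matrix({"A": [1, 2, 3], "B": [2, 4, 6]})
        out = fq_between_lane(m)
        assert out.data["A"].tolist() == pytest.approx([1.5, 3.0, 4.5])
        assert out.data["B"].tolist() == pytest.approx([1.5, 3.0, 4.5])

    def test_identical_columns_unchanged(self):
        m = matrix({"A": [5, 1, 9], "B": [5, 1, 9]})
        out = fq_between_lane(m)
        assert np.allclose(out.data.values, m.data.values)

    def test_sorted_columns_identical_afterwards(self, rng):
        m = matrix({f"L{j}": rng.lognormal(2, 1, 200) for j in range(4)})
        out = fq_between_lane(m)
        ref = np.sort(out.data.iloc[:, 0].to_numpy())
        for col in out.libraries:
            assert np.allclose(np.sort(out.data[col].to_numpy()), ref)

    def test_preserves_ranks_and_grand_mean(self, rng):
        m = matrix({f"L{j}": rng.lognormal(2, 1, 100) for j in range(3)})
        out = fq_between_lane(m)
        for col in m.libraries:
            assert (np.argsort(np.argsort(m.data[col])) ==
                    np.argsort(np.argsort(out.data[col]))).all()
        assert out.data.values.mean() == pytest.approx(m.data.values.mean())

    def test_ties_get_a_common_value(self):
        m = matrix({"A": [1, 1, 5], "B": [2, 3, 4]})
        out = fq_between_lane(m)
        assert out.data["A"].iloc[0] == out.data["A"].iloc[1]


class TestFQWithinLane:
    def test_scaled_strata_align_medians(self):
        stratum1 = [1.0, 2.0, 3.0, 4.0, 5.0]
        stratum2 = [10.0, 20.0, 30.0, 40.0, 50.0]
        m = matrix({"lib": stratum1 + stratum2, "lib2": stratum1 + stratum2})
        covariate = pd.Series([10] * 5 + [1000] * 5, index=m.exon_ids)
        out = fq_within_lane(m, covariate, n_strata=2)
        col = out.data["lib"].to_numpy()
        assert np.median(col[:5]) == pytest.approx(np.median(col[5:]))
        # each stratum maps onto the mean quantile profile
        assert sorted(col[:5]) == pytest.approx(sorted(col[5:]))

    def test_equal_stratum_distributions_left_unchanged(self, rng):
        # constant covariate -> arbitrary (consecutive) strata; when every
        # stratum already holds the same values the mapping is the identity
        base = rng.lognormal(1, 1, 10)
        values = np.tile(base, 5)
        m = matrix({"lib": values, "lib2": values})
        out = fq_within_lane(m, pd.Series(1.0, index=m.exon_ids), n_strata=5)
        assert np.allclose(out.data["lib"].to_numpy(), values)

    def test_stratum_distributions_match_afterwards(self, rng):
        from scipy.stats import ks_2samp
        n = 2000
        length = rng.lognormal(6, 1, n)
        counts = rng.lognormal(2, 1, n) * length / length.mean()  # length bias
        m = matrix({"lib": counts, "lib2": counts})
        out = fq_within_lane(m, pd.Series(length, index=m.exon_ids), n_strata=10)
        order = np.argsort(length)
        first, last = order[:n // 10], order[-(n // 10):]
        stat = ks_2samp(out.data["lib"].to_numpy()[first],
                        out.data["lib"].to_numpy()[last]).statistic
        assert stat < 0.05

    def test_too_many_strata_rejected(self):
        m = matrix({"A": [1, 2], "B": [1, 2]})
        with pytest.raises(ValueError):
            fq_within_lane(m, pd.Series([1, 2], index=m.exon_ids), n_strata=5)
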