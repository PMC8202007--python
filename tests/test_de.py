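"""Normalization, exact-test and QC behaviour of the DE stage."""

import math
import subprocess
import tempfile
import os

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from fflomics import de
from fflomics.de import (
    GROUPS,
    call_demirs,
    ddct,
    exact_test,
    qc_summaries,
    tmm_factors,
    tpm_normalize,
)


class TestTPM:
    def test_formula_and_zero(self):
        counts = pd.DataFrame(
            {g: [10, 999_990 if g == "MW" else 499_990, 0] for g in GROUPS},
            index=["a", "b", "c"],
        )
        tpm = tpm_normalize(counts)
        assert tpm.loc["a", "MW"] == pytest.approx(10.0)
        assert (tpm.loc["c"] == 0).all()

    def test_columns_sum_to_1e6(self, small_counts):
        sums = tpm_normalize(small_counts).sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-9)

    def test_zero_total_group_rejected(self, small_counts):
        bad = small_counts.copy()
        bad["FT"] = 0
        with pytest.raises(ValueError, match="zero total"):
            tpm_normalize(bad)


def _naive_tmm_factor(obs, ref, trim_m=0.30, trim_a=0.05):
    """Loop-based reference computation of one pairwise TMM factor."""
    n_obs, n_ref = sum(obs), sum(ref)
    ms, aas, ws = [], [], []
    for o, r in zip(obs, ref):
        if o > 0 and r > 0:
            po, pr = o / n_obs, r / n_ref
            ms.append(math.log2(po / pr))
            aas.append((math.log2(po) + math.log2(pr)) / 2)
            ws.append((n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r))
    if max(abs(m) for m in ms) < 1e-6:
        return 1.0

    def average_ranks(values):
        order = sorted(range(len(values)), key=lambda i: values[i])
        ranks = [0.0] * len(values)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    n = len(ms)
    lo_l, hi_l = math.floor(n * trim_m) + 1, n - math.floor(n * trim_m)
    lo_s, hi_s = math.floor(n * trim_a) + 1, n - math.floor(n * trim_a)
    rm, ra = average_ranks(ms), average_ranks(aas)
    num = den = 0.0
    for i in range(n):
        if lo_l <= rm[i] <= hi_l and lo_s <= ra[i] <= hi_s:
            num += ms[i] / ws[i]
            den += 1.0 / ws[i]
    return 2.0 ** (num / den)


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([100, 50, 10, 400, 3, 77])
        counts = pd.DataFrame({g: col for g in GROUPS}, index=list("abcdef"))
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_depth_scaling_does_not_change_factors(self):
        col = np.array([100, 50, 10, 400, 3, 77])
        counts = pd.DataFrame({g: col for g in GROUPS}, index=list("abcdef"))
        counts["MT"] = 2 * col  # pure depth change; M-values all zero
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_matches_naive_reimplementation(self, rng):
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.02, size=(100, 6)),
            index=[f"m{i}" for i in range(100)],
            columns=list(GROUPS),
        ) + 1
        ref = "MW"
        ours = tmm_factors(counts, ref_group=ref)
        naive = {
            g: 1.0 if g == ref else _naive_tmm_factor(
                list(counts[g]), list(counts[ref])
            )
            for g in GROUPS
        }
        naive_s = pd.Series(naive)[list(GROUPS)]
        naive_s /= np.exp(np.mean(np.log(naive_s)))
        assert np.allclose(ours, naive_s, atol=1e-10)

    def test_geometric_mean_is_one(self, small_counts):
        f = tmm_factors(small_counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_matches_edger_calcnormfactors(self, rng):
        """Independent Bioconductor cross-check of the TMM computation."""
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.01, size=(200, 6)),
            index=[f"m{i}" for i in range(200)],
            columns=list(GROUPS),
        )
        ours = tmm_factors(counts, ref_group="MW")
        with tempfile.TemporaryDirectory() as td:
            cpath = os.path.join(td, "c.tsv")
            counts.to_csv(cpath, sep="\t")
            script = (
                'suppressMessages(library(edgeR)); '
                f'x <- as.matrix(read.delim("{cpath}", row.names=1)); '
                'f <- calcNormFactors(x, method="TMM", refColumn=1); '
                'cat(sprintf("%.12f", f), sep="\\n")'
            )
            proc = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
            )
            if proc.returncode != 0:
                pytest.skip(f"edgeR unavailable: {proc.stderr[-200:]}")
            edger = np.array([float(v) for v in proc.stdout.split()])
        assert np.allclose(ours.to_numpy(), edger, atol=1e-8)


def _oracle_conditional_p(xa, xb, na, nb, phi):
    """Brute-force summation of the conditional NB mass over all splits."""
    s = xa + xb
    pa = na / (na + nb)
    mu_a, mu_b = s * pa, s * (1 - pa)
    r = 1.0 / phi

    def log_nb(k, mu):
        return (
            gammaln(k + r) - gammaln(r) - gammaln(k + 1)
            + r * math.log(r / (r + mu)) + k * math.log(mu / (r + mu))
        )

    logs = [log_nb(k, mu_a) + log_nb(s - k, mu_b) for k in range(s + 1)]
    m = max(logs)
    probs = [math.exp(v - m) for v in logs]
    total = sum(probs)
    lower = sum(probs[: xa + 1]) / total
    upper = sum(probs[xa:]) / total
    return min(1.0, 2 * min(lower, upper))


class TestExactTest:
    def _table(self, xa, xb, filler):
        counts = pd.DataFrame(
            {g: filler.copy() for g in GROUPS}, index=[f"m{i}" for i in range(len(filler))]
        )
        counts.loc["m0", "MT"] = xa
        counts.loc["m0", "MP"] = xb
        return counts

    def test_symmetry_gives_null_result(self):
        filler = list(range(10, 60))
        counts = self._table(30, 30, filler)
        unit = pd.Series(1.0, index=list(GROUPS))
        rec = exact_test(counts, "MT/MP", dispersion=0.05, factors=unit)
        row = rec[rec["mirna"] == "m0"].iloc[0]
        assert row["log2fc"] == pytest.approx(0.0)
        assert row["pvalue"] == pytest.approx(1.0)

    def test_poisson_closed_form_extreme_split(self):
        # equal effective libraries, observation (50, 0): p = 2 * 2^-50
        filler = [100] * 60
        counts = self._table(50, 0, filler)
        counts.loc["m1", "MT"] = 0  # rebalance totals so libraries stay equal
        counts.loc["m1", "MP"] = 50
        unit = pd.Series(1.0, index=list(GROUPS))
        rec = exact_test(counts, "MT/MP", dispersion=0.0, factors=unit)
        p = rec.loc[rec["mirna"] == "m0", "pvalue"].iloc[0]
        assert p == pytest.approx(2.0 * 2.0 ** -50, rel=1e-9)

    def test_matches_enumeration_oracle(self, rng):
        na, nb = 1.2e6, 0.8e6
        for _ in range(10):
            xa, xb = int(rng.integers(0, 200)), int(rng.integers(0, 200))
            ours = de._conditional_pvalue(xa, xb, na, nb, 0.05)
            oracle = _oracle_conditional_p(xa, xb, na, nb, 0.05)
            assert ours == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    def test_negative_dispersion_rejected(self, small_counts):
        with pytest.raises(ValueError, match="dispersion"):
            exact_test(small_counts, "MT/MP", dispersion=-1.0)

    def test_unknown_contrast_rejected(self, small_counts):
        with pytest.raises(ValueError, match="unknown group"):
            exact_test(small_counts, "MT/XX")

    def test_row_order_invariance(self, small_counts):
        a = exact_test(small_counts, "MT/MW", dispersion=0.05).set_index("mirna")
        shuffled = small_counts.sample(frac=1.0, random_state=1)
        b = exact_test(shuffled, "MT/MW", dispersion=0.05).set_index("mirna")
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_null_type_one_error_controlled(self):
        """Null NB data: empirical rejection at alpha=0.05 stays near-nominal."""
        alpha = 0.05
        rejections = total = 0
        for seed in range(20):
            g = np.random.default_rng(seed)
            mu = g.lognormal(6.5, 1.2, 500)
            r = 1 / 0.05
            counts = pd.DataFrame(
                {grp: g.negative_binomial(r, r / (r + mu)) for grp in GROUPS},
                index=[f"m{i}" for i in range(500)],
            )
            rec = exact_test(counts, "MT/MW", dispersion=0.05)
            rejections += int((rec["pvalue"] <= alpha).sum())
            total += len(rec)
        assert rejections / total <= 0.07


class TestDemirGate:
    def test_boundaries_inclusive(self):
        rec = pd.DataFrame(
            {
                "mirna": ["a", "b", "c"],
                "contrast": ["MT/MP"] * 3,
                "log2fc": [1.0, 1.0, 0.99],
                "pvalue": [0.01] * 3,
                "qvalue": [0.05, 0.051, 0.05],
            }
        )
        out = call_demirs(rec)
        assert out["significant"].tolist() == [True, False, False]
        assert out["direction"].tolist() == ["up", "none", "none"]

    def test_bh_qvalues_monotone_in_p(self, small_counts):
        rec = exact_test(small_counts, "MT/MW", dispersion=0.05)
        rec = rec.sort_values("pvalue")
        assert (np.diff(rec["qvalue"].to_numpy()) >= -1e-12).all()
        assert rec["qvalue"].between(0, 1).all()


class TestQC:
    def test_duplicate_columns_have_unit_r2(self, small_counts):
        counts = small_counts.copy()
        counts["MP"] = counts["MW"]
        qc = qc_summaries(counts, seed=0)
        assert qc["r2"].loc["MW", "MP"] == pytest.approx(1.0)

    def test_saturation_endpoints_and_monotonicity(self, small_counts):
        qc = qc_summaries(small_counts, depth_fractions=(0.0, 0.05, 0.2, 1.0), seed=0)
        sat = qc["saturation"]
        full = (small_counts >= 1).sum(axis=0)
        assert (sat.loc[1.0] == full).all()
        assert (sat.loc[0.0] == 0).all()
        assert (sat.diff().dropna() >= 0).all().all()

    def test_constant_group_flagged_not_crashed(self, small_counts):
        counts = small_counts.copy()
        counts["FT"] = 5  # constant column; log-TPM has zero variance
        qc = qc_summaries(counts, seed=0)
        assert qc["constant_groups"] == ["FT"]

    def test_pca_shape(self, small_counts):
        qc = qc_summaries(small_counts, seed=0)
        assert qc["pca_scores"].shape == (6, 3)
        assert all(0 <= v <= 1 for v in qc["pca_explained"])


@pytest.mark.parametrize(
    "ct_m, ct_ref, expected",
    [(25.0, 25.0, 1.0), (24.0, 25.0, 2.0), (28.0, 25.0, 0.125)],
)
def test_ddct_closed_forms(ct_m, ct_ref, expected):
    assert ddct(ct_m, ct_ref) == pytest.approx(expected)


def test_ddct_rejects_non_finite():
    with pytest.raises(ValueError):
        ddct(float("nan"), 25.0)
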