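"""Normalization and differential expression for pooled (no-replicate) miRNA libraries.

The design is one composite library per condition: six groups named by
sex x tissue stage, MW/MP/MT/FW/FP/FT, where W = wild-type normal liver,
P = peri-tumor precancerous tissue and T = hepatic tumor. Without replicates
a dispersion cannot be estimated, so a fixed negative-binomial dispersion
``phi`` (var = mu + phi mu^2) is supplied by configuration and the pairwise
test conditions on the two-group sum, in the style of edgeR's exact test for
unreplicated designs.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

GROUPS = ("MW", "MP", "MT", "FW", "FP", "FT")
#: Pairwise contrasts within each sex ("vertical" comparisons), numerator first.
WITHIN_SEX_CONTRASTS = ("MT/MP", "MT/MW", "MP/MW", "FT/FP", "FT/FW", "FP/FW")
#: Male-vs-female contrasts at matched stage ("horizontal" comparisons).
BETWEEN_SEX_CONTRASTS = ("MW/FW", "MP/FP", "MT/FT")
ALL_CONTRASTS = WITHIN_SEX_CONTRASTS + BETWEEN_SEX_CONTRASTS


def split_contrast(contrast: str) -> tuple[str, str]:
    try:
        num, den = contrast.split("/")
    except ValueError as exc:
        raise ValueError(f"malformed contrast {contrast!r}") from exc
    return num, den


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def tpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Reads-per-million scaling: tpm[i, g] = counts[i, g] * 1e6 / sum_j counts[j, g]."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"group(s) with zero total counts: {bad}")
    return counts * 1e6 / totals


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    trim_m: float,
    trim_a: float,
    weighted: bool,
) -> float:
    """Trimmed mean of M-values for one library against the reference library.

    M = log2((x_g/N_g)/(x_r/N_r)) and A = mean of the two log2 relative
    abundances; features in the extreme ``trim_m`` (each tail, by M rank) or
    ``trim_a`` (by A rank) are discarded and the remaining M are averaged with
    inverse delta-method variance weights. Features with a zero in either
    library are excluded up front.
    """
    n_obs = obs.sum()
    n_ref = ref.sum()
    finite = (obs > 0) & (ref > 0)
    obs = obs[finite].astype(float)
    ref = ref[finite].astype(float)
    if obs.size == 0:
        raise ValueError("no features with positive counts in both libraries")
    log_r = np.log2((obs / n_obs) / (ref / n_ref))
    abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
    var = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    rank_m = stats.rankdata(log_r)
    rank_a = stats.rankdata(abs_e)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 1.0
    if weighted:
        f = np.sum(log_r[keep] / var[keep]) / np.sum(1.0 / var[keep])
    else:
        f = np.mean(log_r[keep])
    return float(2.0 ** f)


def tmm_factors(
    counts: pd.DataFrame,
    ref_group: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    weighted: bool = True,
) -> pd.Series:
    """TMM scaling factors per group, rescaled to geometric mean 1.

    The reference library defaults to the group whose total count is closest
    to the mean total. Effective library size = raw total x factor.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two groups")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("group with zero total counts")
    if ref_group is None:
        ref_group = (totals - totals.mean()).abs().idxmin()
    if ref_group not in counts.columns:
        raise ValueError(f"unknown reference group {ref_group!r}")
    ref = counts[ref_group].to_numpy()
    factors = {}
    for g in counts.columns:
        if g == ref_group:
            factors[g] = 1.0
        else:
            factors[g] = _tmm_pair_factor(counts[g].to_numpy(), ref, trim_m, trim_a, weighted)
    f = pd.Series(factors)[counts.columns]
    f = f / np.exp(np.mean(np.log(f)))
    return f


def effective_library_sizes(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.Series:
    if factors is None:
        factors = tmm_factors(counts)
    return counts.sum(axis=0) * factors


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

def _conditional_pvalue(xa: int, xb: int, na: float, nb: float, phi: float) -> float:
    """Two-sided conditional exact p for one feature.

    Conditions on s = xa + xb. Under the null of equal relative abundance the
    expected split is proportional to the effective library sizes; for phi = 0
    the conditional law is Binomial(s, na/(na+nb)), for phi > 0 the NB
    conditional mass over all splits of s is summed directly. Two-sided p
    doubles the smaller tail (observed point counted once per tail) and caps
    at 1.
    """
    s = xa + xb
    if s == 0:
        return 1.0
    pa = na / (na + nb)
    if phi == 0.0:
        lower = stats.binom.cdf(xa, s, pa)
        upper = stats.binom.sf(xa - 1, s, pa)
        return float(min(1.0, 2.0 * min(lower, upper)))
    # conditional NB mass over all splits k of s:
    #   log f(k) ∝ lgamma(k+r) - lgamma(k+1) + lgamma(s-k+r) - lgamma(s-k+1)
    #              + k log(mu_a/(r+mu_a)) + (s-k) log(mu_b/(r+mu_b))
    # the reversed-index terms reuse the same gammaln arrays.
    r = 1.0 / phi
    k = np.arange(s + 1, dtype=np.float64)
    mu_a = s * pa
    mu_b = s - mu_a
    ga = gammaln(k + r) - gammaln(k + 1.0)
    logp = ga + ga[::-1] + k * (np.log(mu_a / (r + mu_a)) - np.log(mu_b / (r + mu_b)))
    logp -= logp.max()
    pmf = np.exp(logp)
    total = pmf.sum()
    lower = pmf[: xa + 1].sum() / total
    upper = pmf[xa:].sum() / total
    return float(min(1.0, 2.0 * min(lower, upper)))


def exact_test(
    counts: pd.DataFrame,
    contrast: str,
    dispersion: float = 0.05,
    factors: pd.Series | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Pairwise no-replicate exact test for one contrast across all miRNAs.

    Returns a DataFrame with one row per miRNA: log2fc (numerator over
    denominator, computed on TMM/library-adjusted abundances with a
    pseudo-count), the two-sided conditional p-value, and the BH q-value
    adjusted across all miRNAs of this contrast.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    num, den = split_contrast(contrast)
    for g in (num, den):
        if g not in counts.columns:
            raise ValueError(f"unknown group {g!r} in contrast {contrast!r}")
    if factors is None:
        factors = tmm_factors(counts)
    eff = effective_library_sizes(counts, factors)
    na, nb = float(eff[num]), float(eff[den])
    xa = counts[num].to_numpy()
    xb = counts[den].to_numpy()
    log2fc = np.log2(((xa + pseudocount) / na) / ((xb + pseudocount) / nb))
    pvals = np.array(
        [_conditional_pvalue(int(a), int(b), na, nb, dispersion) for a, b in zip(xa, xb)]
    )
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "mirna": counts.index,
            "contrast": contrast,
            "log2fc": log2fc,
            "pvalue": pvals,
            "qvalue": qvals,
        }
    )


def exact_test_all(
    counts: pd.DataFrame,
    contrasts: Sequence[str] = ALL_CONTRASTS,
    dispersion: float = 0.05,
    factors: pd.Series | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    if factors is None:
        factors = tmm_factors(counts)
    frames = [
        exact_test(counts, c, dispersion=dispersion, factors=factors, pseudocount=pseudocount)
        for c in contrasts
    ]
    return pd.concat(frames, ignore_index=True)


def call_demirs(
    records: pd.DataFrame, q_cut: float = 0.05, lfc_cut: float = 1.0
) -> pd.DataFrame:
    """Apply the DEMIR gate: significant iff q <= q_cut and |log2fc| >= lfc_cut.

    Both boundaries are inclusive. Adds ``significant`` and ``direction``
    (up/down/none, relative to the contrast numerator) columns.
    """
    out = records.copy()
    sig = (out["qvalue"] <= q_cut) & (out["log2fc"].abs() >= lfc_cut)
    out["significant"] = sig
    out["direction"] = np.where(~sig, "none", np.where(out["log2fc"] > 0, "up", "down"))
    return out


def demir_sets(records: pd.DataFrame) -> dict[str, set[str]]:
    """Significant miRNA set per contrast (records must carry ``significant``)."""
    out: dict[str, set[str]] = {}
    for contrast, grp in records.groupby("contrast"):
        out[contrast] = set(grp.loc[grp["significant"], "mirna"])
    return out


def overall_demirs(records: pd.DataFrame, contrasts: Iterable[str]) -> set[str]:
    """miRNAs significant in at least one of the given contrasts."""
    sets = demir_sets(records)
    out: set[str] = set()
    for c in contrasts:
        out |= sets.get(c, set())
    return out


# ---------------------------------------------------------------------------
# QC: correlation, PCA, saturation
# ---------------------------------------------------------------------------

def qc_summaries(
    counts: pd.DataFrame,
    depth_fractions: Sequence[float] = (0.02, 0.05, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0),
    seed: int = 0,
) -> dict:
    """Pairwise Pearson R^2, group PCA and a saturation curve.

    Correlation and PCA operate on log2(TPM + 1). Saturation counts distinct
    detected miRNAs (count >= 1) after binomial thinning of each library at
    the given depth fractions; thinning is nested (each shallower depth is a
    thinning of the next deeper one) so the curve is monotone by construction.
    """
    if counts.shape[1] < 2:
        raise ValueError("QC needs at least two groups")
    tpm = tpm_normalize(counts)
    logx = np.log2(tpm + 1.0)
    constant_groups = [g for g in logx.columns if logx[g].std(ddof=0) == 0.0]
    usable = [g for g in logx.columns if g not in constant_groups]
    r2 = pd.DataFrame(np.nan, index=logx.columns, columns=logx.columns)
    if len(usable) >= 2:
        r2.loc[usable, usable] = logx[usable].corr(method="pearson") ** 2
    for g in logx.columns:
        r2.loc[g, g] = 1.0

    # PCA on groups (rows = groups, features = miRNAs), top 3 components
    x = logx.T.to_numpy()
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(3, s.size)
    scores = pd.DataFrame(
        u[:, :k] * s[:k], index=logx.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    total_var = float((s ** 2).sum())
    explained = [float(v) / total_var if total_var > 0 else 0.0 for v in (s[:k] ** 2)]

    rng = np.random.default_rng(seed)
    fracs = sorted(set(float(f) for f in depth_fractions))
    if any(f < 0 or f > 1 for f in fracs):
        raise ValueError("depth fractions must lie in [0, 1]")
    sat = pd.DataFrame(0, index=fracs, columns=counts.columns)
    for g in counts.columns:
        current = counts[g].to_numpy().astype(np.int64)
        current_frac = 1.0
        for f in reversed(fracs):
            if f == 0.0:
                current = np.zeros_like(current)
            elif f < current_frac:
                current = rng.binomial(current, f / current_frac)
            current_frac = max(f, 1e-300)
            sat.loc[f, g] = int((current >= 1).sum())
    sat.index.name = "depth_fraction"
    return {
        "r2": r2,
        "pca_scores": scores,
        "pca_explained": explained,
        "saturation": sat,
        "constant_groups": constant_groups,
    }


def ddct(ct_mirna: float, ct_ref: float) -> float:
    """Relative expression by the ddCt rule: 2^-(Ct_mirna - Ct_reference)."""
    if not (np.isfinite(ct_mirna) and np.isfinite(ct_ref)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** (-(ct_mirna - ct_ref)))


def ddct_table(ct: pd.DataFrame) -> pd.DataFrame:
    """Relative expression per (miRNA, group) from a Ct table.

    Expects columns (mirna, group, ct_mirna, ct_ref).
    """
    out = ct.copy()
    out["rel_expr"] = [
        ddct(a, b) for a, b in zip(out["ct_mirna"], out["ct_ref"])
    ]
    return out
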