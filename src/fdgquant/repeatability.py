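"""Test-retest repeatability statistics.

Implements the variability indices used to compare quantification
approaches across paired PET sessions:

* absolute variability (AbsVar): 100 * |test - retest| / pair mean;
* a two-level variance decomposition: the within-subject (session-to-session)
  variance is estimated from paired differences, sigma2_intra =
  Var(d_i)/2 with df = N-1; the between-subject variance is deduced by
  subtraction from the total variance over all 2N values, clipped at zero
  when sampling fluctuation drives it negative.  Both are reported as
  coefficients of variation (percent of the grand mean) and as explained
  shares of the total variance;
* a 95% confidence interval mean +/- t_{0.975, 2N-1} * sd over all values,
  with the lower bound clipped at 0;
* the sample size needed to estimate a mean with a given relative
  precision, n = ceil((t * s / (precision * mean))^2);
* Spearman rank correlation with exact permutation p-values at small n, and
  an exact paired Wilcoxon signed-rank test by sign-assignment enumeration;
* a robustness check: the fraction of an independent group's values that
  fall inside the test-retest confidence intervals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .quantify import PARAMETERS, PLASMA_LABEL


@dataclass(frozen=True)
class VariabilityDecomposition:
    """Variability summary for one (parameter, region) cell.

    CVs and explained-variance shares are percentages; ``var_inter_raw`` is
    the between-subject variance component before clipping at zero (useful
    for unbiased parameter-recovery checks).
    """

    parameter: str
    region: str
    n_subjects: int
    mean: float
    sd: float
    ci95_low: float
    ci95_high: float
    absvar_mean: float
    absvar_sd: float
    cv_intra: float
    cv_inter: float
    ev_intra: float
    ev_inter: float
    var_total: float
    var_intra: float
    var_inter_raw: float


@dataclass(frozen=True)
class SampleSizeResult:
    parameter: str
    mean: float
    s: float
    precision: float
    t_coef: float
    n_required: int


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int


def abs_var(x1: float, x2: float) -> float:
    """Absolute test-retest variability, percent of the pair mean."""
    m = (x1 + x2) / 2.0
    if not m > 0:
        raise InputError("abs_var requires a positive pair mean")
    return 100.0 * abs(x1 - x2) / m


def ci95(mean: float, sd: float, n: int) -> tuple[float, float]:
    """mean +/- t_{0.975, n-1} * sd, lower bound clipped at 0.

    This is a population-dispersion interval (t quantile times the sample
    SD), not a standard-error interval.
    """
    if n < 2:
        raise InputError("ci95 requires n >= 2")
    if sd < 0:
        raise InputError("sd must be non-negative")
    t = stats.t.ppf(0.975, n - 1)
    return max(0.0, mean - t * sd), mean + t * sd


def decompose(pairs: pd.DataFrame, parameter: str = "", region: str = "") -> VariabilityDecomposition:
    """Two-level variance decomposition of paired test-retest values.

    ``pairs`` needs columns ``subject_id``, ``test_value``, ``retest_value``
    (one row per subject) for a single region and parameter.
    """
    if not {"subject_id", "test_value", "retest_value"} <= set(pairs.columns):
        raise InputError("pairs must have subject_id, test_value, retest_value columns")
    n = len(pairs)
    if n < 2:
        raise InputError("decompose requires at least 2 subjects")
    if pairs["subject_id"].duplicated().any():
        raise InputError("one row per subject expected")
    x1 = pairs["test_value"].to_numpy(dtype=float)
    x2 = pairs["retest_value"].to_numpy(dtype=float)
    if not np.all(np.isfinite(x1)) or not np.all(np.isfinite(x2)):
        raise InputError("non-finite paired values")

    values = np.concatenate([x1, x2])
    m = float(values.mean())
    var_total = float(values.var(ddof=1))           # df = 2N - 1
    var_intra = float(np.var(x1 - x2, ddof=1)) / 2  # df = N - 1
    var_inter_raw = var_total - var_intra
    var_inter = max(0.0, var_inter_raw)

    sd = np.sqrt(var_total)
    lo, hi = ci95(m, sd, 2 * n)
    absvals = 100.0 * np.abs(x1 - x2) / ((x1 + x2) / 2.0)
    cv_intra = 100.0 * np.sqrt(var_intra) / m
    cv_inter = 100.0 * np.sqrt(var_inter) / m
    denom = var_intra + var_inter
    ev_intra = 100.0 * var_intra / denom if denom > 0 else 0.0
    return VariabilityDecomposition(
        parameter=parameter, region=region, n_subjects=n,
        mean=m, sd=float(sd), ci95_low=lo, ci95_high=hi,
        absvar_mean=float(absvals.mean()),
        absvar_sd=float(absvals.std(ddof=1)) if n > 1 else 0.0,
        cv_intra=float(cv_intra), cv_inter=float(cv_inter),
        ev_intra=float(ev_intra),
        ev_inter=float(max(0.0, 100.0 - ev_intra)) if denom > 0 else 0.0,
        var_total=var_total, var_intra=float(var_intra), var_inter_raw=float(var_inter_raw),
    )


def explained_variance_from_cv(cv_intra: float, cv_inter: float) -> float:
    """Intra-subject share (%) of total variance from the two CVs."""
    denom = cv_intra**2 + cv_inter**2
    if denom <= 0:
        raise InputError("at least one CV must be positive")
    return 100.0 * cv_intra**2 / denom


def sample_size(mean: float, s: float, precision: float = 0.20,
                t_coef: float = 1.96, parameter: str = "") -> SampleSizeResult:
    """Subjects needed to estimate ``mean`` to +/- ``precision * mean``.

    n = ceil((t * s / a)^2) with a = precision * mean, floored at 1.
    """
    if not mean > 0:
        raise InputError("sample_size requires a positive mean")
    if s < 0:
        raise InputError("s must be non-negative")
    if not precision > 0:
        raise InputError("precision must be positive")
    a = precision * mean
    n = max(1, int(np.ceil((t_coef * s / a) ** 2)))
    return SampleSizeResult(parameter=parameter, mean=mean, s=s,
                            precision=precision, t_coef=t_coef, n_required=n)


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    return float(np.sum(rx * ry) / denom)


def spearman(x, y, exact_max_n: int = 8) -> CorrelationResult:
    """Spearman rank correlation; exact permutation p for n <= ``exact_max_n``.

    Ties receive average ranks.  For larger n the usual t approximation with
    n - 2 degrees of freedom is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise InputError("spearman needs two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("spearman undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _spearman_rho(rx, ry)
    n = x.size
    if n <= exact_max_n:
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = _spearman_rho(rx, np.asarray(perm))
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        # t approximation, guarding |rho| = 1
        r = min(max(rho, -1.0 + 1e-15), 1.0 - 1e-15)
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(rho=rho, p_value=min(1.0, p), n=n)


def wilcoxon_signed_rank(x1, x2=None, exact_max_n: int = 12) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Pass paired samples ``(x1, x2)`` or precomputed differences ``x1``.
    Zero differences are dropped; ties among |d| get average ranks.  For
    N <= ``exact_max_n`` the p-value is exact by enumeration of all 2^N sign
    assignments; beyond that the normal approximation (with tie correction)
    is used.
    """
    d = np.asarray(x1, dtype=float)
    if x2 is not None:
        d = d - np.asarray(x2, dtype=float)
    d = d[d != 0]
    n = d.size
    if n < 2:
        raise InputError("wilcoxon needs >= 2 non-zero differences")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    if n <= exact_max_n:
        lo, hi = min(w_pos, w_neg), max(w_pos, w_neg)
        count = 0
        for signs in itertools.product((0, 1), repeat=n):
            w = float(np.sum(ranks[np.asarray(signs, dtype=bool)]))
            if w <= lo + 1e-12 or w >= hi - 1e-12:
                count += 1
        return count / 2**n
    return float(stats.wilcoxon(d, correction=False, method="asymptotic").pvalue)


def pivot_pairs(quant: pd.DataFrame) -> pd.DataFrame:
    """Long quantification table -> one row per (parameter, region, subject) pair.

    Keeps only subjects having both a test and a retest value.
    """
    q = quant[quant["region"] != PLASMA_LABEL]
    wide = q.pivot_table(index=["parameter", "region", "subject_id"],
                         columns="session", values="value", aggfunc="first")
    if "test" not in wide.columns or "retest" not in wide.columns:
        raise InputError("quantification table lacks test/retest sessions")
    wide = wide.dropna(subset=["test", "retest"]).reset_index()
    return wide.rename(columns={"test": "test_value", "retest": "retest_value"})


def repeatability_table(quant: pd.DataFrame) -> pd.DataFrame:
    """Variability decomposition for every (parameter, region) cell.

    ``quant`` is the long-format quantification table of a test-retest
    study.  Returns one row per cell with all decomposition fields.
    """
    pairs = pivot_pairs(quant)
    rows = []
    for (parameter, region), grp in pairs.groupby(["parameter", "region"], sort=False):
        dec = decompose(grp, parameter=parameter, region=region)
        rows.append(dec.__dict__)
    table = pd.DataFrame(rows)
    order = {p: i for i, p in enumerate(PARAMETERS)}
    table["_o"] = table["parameter"].map(lambda p: order.get(p, len(order)))
    return (table.sort_values(["_o", "region"]).drop(columns="_o")
            .reset_index(drop=True))


def parameter_correlations(quant: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlations between outcome parameters.

    Values are aligned on (subject, session, region); rows with a missing
    value in either parameter (e.g. a reference region's own ratio) are
    dropped pairwise.  Returns a long table: parameter_a, parameter_b, rho,
    p_value, n.
    """
    q = quant[quant["region"] != PLASMA_LABEL]
    wide = q.pivot_table(index=["subject_id", "session", "region"],
                         columns="parameter", values="value", aggfunc="first")
    params = [p for p in PARAMETERS if p in wide.columns]
    rows = []
    for i, pa in enumerate(params):
        for pb in params[i + 1:]:
            sub = wide[[pa, pb]].dropna()
            res = spearman(sub[pa].to_numpy(), sub[pb].to_numpy())
            rows.append((pa, pb, res.rho, res.p_value, res.n))
    return pd.DataFrame(rows, columns=["parameter_a", "parameter_b", "rho", "p_value", "n"])


def robustness_check(decomps: pd.DataFrame, new_quant: pd.DataFrame) -> pd.DataFrame:
    """CI-membership of an independent group inside test-retest intervals.

    ``decomps`` is a `repeatability_table` output; ``new_quant`` the long
    quantification table of the independent group.  Returns per parameter
    the fraction of (subject x region) values inside [ci95_low, ci95_high],
    plus per-region counts.
    """
    new = new_quant[new_quant["region"] != PLASMA_LABEL]
    ci = decomps.set_index(["parameter", "region"])[["ci95_low", "ci95_high"]]
    missing = set(map(tuple, new[["parameter", "region"]].drop_duplicates().to_numpy())) - set(ci.index)
    if missing:
        raise InputError(f"no test-retest interval for: {sorted(missing)}")
    rows = []
    for (parameter, region), grp in new.groupby(["parameter", "region"], sort=False):
        lo, hi = ci.loc[(parameter, region)]
        v = grp["value"].to_numpy(dtype=float)
        rows.append((parameter, region, int(((v >= lo) & (v <= hi)).sum()), int(v.size)))
    per_region = pd.DataFrame(rows, columns=["parameter", "region", "within", "total"])
    summary = per_region.groupby("parameter", sort=False)[["within", "total"]].sum()
    per_region = per_region.merge(
        (summary["within"] / summary["total"]).rename("fraction_within_ci"),
        left_on="parameter", right_index=True)
    return per_region
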