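"""Cross-method agreement statistics: deep sequencing vs bulk pyrosequencing.

Per-CpG methylation levels measured by amplicon deep sequencing are paired
with the corresponding bulk pyrosequencing values and compared with the
standard method-comparison toolkit: Bland-Altman limits of agreement,
least-squares regression with a slope confidence interval, deviation-
threshold congruence fractions (|difference| below 2 / 5 / 10 percentage
points), the coverage above which every difference stays inside the 95%
band, and the correlation between amplicon length and read yield.

Sign convention everywhere: difference = deep - bulk.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .demultiplex import funnel_pct

__all__ = [
    "ConcordanceReport",
    "pair_measurements",
    "bland_altman",
    "regression",
    "congruence_fractions",
    "coverage_vs_congruence",
    "correlate_yield",
    "concordance_report",
]

DEFAULT_THRESHOLDS = (2.0, 5.0, 10.0)


def pair_measurements(
    deep_levels: pd.DataFrame,
    bulk_table: pd.DataFrame,
    exclude_bins: set[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inner-join deep and bulk per-CpG levels on (sample, locus, cpg_index).

    ``deep_levels`` needs columns sample, locus, cpg_index, level_pct and
    (optionally) coverage / low_coverage; bins flagged low_coverage, sites
    without coverage, and any (sample, locus) in ``exclude_bins`` are
    excluded before the join.  Returns (pairs, excluded-with-reason).
    """
    keys = ["sample", "locus", "cpg_index"]
    deep = deep_levels.copy()
    excluded = []

    def drop(mask: pd.Series, reason: str):
        nonlocal deep
        for _, row in deep[mask].iterrows():
            excluded.append({**{k: row[k] for k in keys}, "reason": reason})
        deep = deep[~mask]

    if exclude_bins:
        mask = deep.apply(lambda r: (r["sample"], r["locus"]) in exclude_bins, axis=1)
        drop(mask, "excluded_bin")
    if "low_coverage" in deep.columns:
        drop(deep["low_coverage"].astype(bool), "low_coverage")
    drop(deep["level_pct"].isna(), "no_coverage")

    pairs = deep.merge(bulk_table, on=keys, how="inner", suffixes=("_deep", "_bulk"))
    if pairs.empty:
        raise ValueError("deep and bulk tables share no (sample, locus, cpg_index) keys")
    pairs = pairs.rename(
        columns={"level_pct_deep": "level_deep", "level_pct_bulk": "level_bulk"}
    )
    if "coverage" in pairs.columns:
        pairs = pairs.rename(columns={"coverage": "coverage_deep"})
    cols = keys + ["level_deep", "level_bulk"]
    if "coverage_deep" in pairs.columns:
        cols.append("coverage_deep")
    return pairs[cols].reset_index(drop=True), pd.DataFrame(
        excluded, columns=keys + ["reason"]
    )


def bland_altman(pairs: pd.DataFrame, mode: str = "loa") -> dict:
    """Bland-Altman agreement of the two level series.

    diff = level_deep - level_bulk.  ``loa`` (default) gives the classical
    95% limits of agreement mean +/- 1.96*SD; ``tolerance`` gives a
    two-sided normal tolerance interval covering 95% of the population with
    95% confidence (wider, k from the chi-square/normal construction).
    Also returns the per-pair (mean_of_two, diff) table for plotting.
    """
    d = (pairs["level_deep"] - pairs["level_bulk"]).to_numpy(dtype=float)
    n = d.size
    if n < 3:
        raise ValueError("Bland-Altman needs at least 3 pairs")
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    if mode == "loa":
        k = 1.96
    elif mode == "tolerance":
        # Howe's two-sided (P=0.95, confidence=0.95) normal tolerance factor
        z = scipy.stats.norm.ppf(0.975)
        df = n - 1
        chi2 = scipy.stats.chi2.ppf(0.05, df)
        k = z * np.sqrt(df * (1 + 1 / n) / chi2)
    else:
        raise ValueError(f"unknown Bland-Altman mode {mode!r}")
    scatter = pd.DataFrame(
        {
            "mean_of_two": (pairs["level_deep"] + pairs["level_bulk"]) / 2.0,
            "diff": d,
        }
    )
    return {
        "n_pairs": n,
        "mean_diff": mean_diff,
        "sd_diff": sd_diff,
        "lower_95": mean_diff - k * sd_diff,
        "upper_95": mean_diff + k * sd_diff,
        "mode": mode,
        "scatter": scatter,
    }


def regression(pairs: pd.DataFrame, through_origin: bool = False) -> dict:
    """Least squares of level_deep on level_bulk.

    With an intercept by default; ``through_origin`` forces the fit through
    zero (r2 is then uncentred).  Returns r2, slope with its 95% CI,
    intercept and the slope p-value.
    """
    x = pairs["level_bulk"].to_numpy(dtype=float)
    y = pairs["level_deep"].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("regression needs at least 3 pairs")
    if np.ptp(x) == 0:
        raise ValueError("bulk levels have zero variance")
    X = x[:, None] if through_origin else sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    slope_idx = 0 if through_origin else 1
    ci = fit.conf_int(alpha=0.05)
    return {
        "r2": float(fit.rsquared),
        "slope": float(fit.params[slope_idx]),
        "slope_ci_low": float(ci[slope_idx][0]),
        "slope_ci_high": float(ci[slope_idx][1]),
        "intercept": 0.0 if through_origin else float(fit.params[0]),
        "p_value": float(fit.pvalues[slope_idx]),
        "through_origin": through_origin,
        "n_pairs": int(x.size),
    }


def congruence_fractions(
    pairs: pd.DataFrame, thresholds=DEFAULT_THRESHOLDS
) -> dict[float, dict]:
    """Fraction of pairs with |deep - bulk| strictly below each threshold.

    The 10-point band is the conventional acceptability criterion, matching
    the technical variability of the bulk assay (2-10 percentage points).
    """
    d = np.abs((pairs["level_deep"] - pairs["level_bulk"]).to_numpy(dtype=float))
    n = d.size
    if n < 1:
        raise ValueError("need at least one pair")
    out = {}
    for t in thresholds:
        count = int((d < t).sum())
        out[float(t)] = {"count": count, "n": n, "pct": funnel_pct(count, n)}
    return out


def coverage_vs_congruence(pairs: pd.DataFrame, ba: dict | None = None) -> dict:
    """Scatter of |difference| against sequencing coverage, plus the minimal
    coverage above which every pair stays inside the 95% Bland-Altman band.

    coverage_threshold is the smallest observed coverage c such that all
    pairs with coverage >= c satisfy |diff - mean_diff| <= 1.96*SD (band
    estimated from all pairs); None when even the deepest bin strays outside.
    """
    if "coverage_deep" not in pairs.columns or pairs["coverage_deep"].isna().any():
        raise ValueError("every pair needs coverage_deep")
    if ba is None:
        ba = bland_altman(pairs)
    d = (pairs["level_deep"] - pairs["level_bulk"]).to_numpy(dtype=float)
    cov = pairs["coverage_deep"].to_numpy(dtype=float)
    out_of_band = np.abs(d - ba["mean_diff"]) > 1.96 * ba["sd_diff"]
    table = pd.DataFrame({"coverage": cov, "abs_diff": np.abs(d), "out_of_band": out_of_band})
    if not out_of_band.any():
        threshold = float(cov.min())
    else:
        worst = cov[out_of_band].max()
        above = cov[cov > worst]
        threshold = float(above.min()) if above.size else None
    return {"table": table, "coverage_threshold": threshold}


def correlate_yield(per_amplicon: pd.DataFrame) -> dict:
    """Pearson correlation of amplicon length vs mean read count.

    ``per_amplicon`` needs columns length and mean_reads, one row per
    amplicon (>= 3 rows, non-constant in both variables).
    """
    x = per_amplicon["length"].to_numpy(dtype=float)
    y = per_amplicon["mean_reads"].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 amplicons")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("length or read counts have zero variance")
    r, p = scipy.stats.pearsonr(x, y)
    return {"r": float(r), "p_value": float(p), "n": int(x.size)}


@dataclass
class ConcordanceReport:
    """Bundle of all agreement statistics for one paired data set."""

    n_pairs: int
    bland_altman: dict
    regression: dict
    congruence: dict
    coverage_threshold: float | None

    def to_dict(self) -> dict:
        ba = {k: v for k, v in self.bland_altman.items() if k != "scatter"}
        return {
            "n_pairs": self.n_pairs,
            "diff_convention": "deep - bulk",
            "bland_altman": ba,
            "regression": self.regression,
            "congruence": {
                str(t): stats for t, stats in self.congruence.items()
            },
            "coverage_threshold": self.coverage_threshold,
        }


def concordance_report(
    pairs: pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
    through_origin: bool = False,
    ba_mode: str = "loa",
) -> ConcordanceReport:
    ba = bland_altman(pairs, mode=ba_mode)
    cov = (
        coverage_vs_congruence(pairs, ba if ba_mode == "loa" else bland_altman(pairs))
        if "coverage_deep" in pairs.columns
        else {"coverage_threshold": None}
    )
    return ConcordanceReport(
        n_pairs=len(pairs),
        bland_altman=ba,
        regression=regression(pairs, through_origin=through_origin),
        congruence=congruence_fractions(pairs, thresholds),
        coverage_threshold=cov["coverage_threshold"],
    )
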