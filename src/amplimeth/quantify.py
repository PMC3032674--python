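"""QC filtering and methylation quantification.

Reads pass quality control when their alignment identity is at least 90%
and their CpH conversion efficiency is 100% (both configurable); the
per-CpG methylation level of a bin is then the fraction of passing reads
carrying an unconverted (methylated) C at that site, with MISSING calls
(gaps, foreign bases, sites beyond the read end) excluded from the
denominator.  Single-molecule resolution is summarised through the
epiallele matrix: the per-read binary pattern over all CpG sites of the
locus, from which fully-methylated / fully-unmethylated allele fractions
and pattern counts are derived.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import METH, UNMETH, MISSING
from .demultiplex import funnel_pct

__all__ = [
    "FilterConfig",
    "MethylationProfile",
    "filter_alignments",
    "calls_matrix",
    "epiallele_matrix",
    "methylation_levels",
    "epiallele_summary",
    "render_profile_table",
]


@dataclass(frozen=True)
class FilterConfig:
    """QC thresholds.

    min_identity_pct / min_conversion_pct: reads strictly below either
    threshold are filtered out (a read at exactly the threshold passes).
    min_reads_per_bin: bins with fewer passing reads are flagged low-coverage
    and excluded from cross-method statistics; 100-150 reads per amplicon
    are recommended for stable per-CpG quantification.
    """

    min_identity_pct: float = 90.0
    min_conversion_pct: float = 100.0
    min_reads_per_bin: int = 10
    recommended_reads: tuple[int, int] = (100, 150)

    def __post_init__(self):
        for v in (self.min_identity_pct, self.min_conversion_pct):
            if not (0.0 <= v <= 100.0):
                raise ValueError("thresholds must lie in [0, 100]")


@dataclass
class MethylationProfile:
    """Per-CpG methylation summary for one sample x locus bin."""

    sample: str
    locus: str
    per_cpg: pd.DataFrame  # cpg_index, n_meth, n_unmeth, coverage, level_pct
    n_reads_passing: int
    low_coverage: bool

    @property
    def mean_level_pct(self) -> float:
        """Unweighted mean of per-CpG levels over sites with coverage."""
        covered = self.per_cpg[self.per_cpg["coverage"] > 0]
        if covered.empty:
            return float("nan")
        return float(covered["level_pct"].mean())


def filter_alignments(
    alignments: pd.DataFrame,
    config: FilterConfig = FilterConfig(),
    raw_total: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Split an alignment metrics table into passing / rejected reads.

    A read passes iff identity_pct >= min_identity_pct AND conversion_pct >=
    min_conversion_pct (thresholds compared before any rounding).  Rejected
    reads carry the first failing criterion as their reason.  The funnel
    reports the passing percentage against ``raw_total`` (the pre-demux read
    count) when given, else against the table size.
    """
    idn = alignments["identity_pct"].to_numpy(dtype=float)
    conv = alignments["conversion_pct"].to_numpy(dtype=float)
    ok_id = idn >= config.min_identity_pct
    ok_conv = conv >= config.min_conversion_pct
    passing = alignments[ok_id & ok_conv].copy()
    rejected = alignments[~(ok_id & ok_conv)].copy()
    rejected["reason"] = np.where(~ok_id[~(ok_id & ok_conv)], "identity", "conversion")
    total = len(alignments) if raw_total is None else int(raw_total)
    funnel = {
        "input_reads": len(alignments),
        "passing_reads": len(passing),
        "passing_pct": funnel_pct(len(passing), total),
    }
    return passing, rejected, funnel


def calls_matrix(calls: pd.Series | list[str]) -> np.ndarray:
    """Decode call strings over {M,U,.} into an int8 matrix (1/0/MISSING)."""
    decode = {"M": METH, "U": UNMETH, ".": MISSING}
    rows = [[decode[c] for c in s] for s in calls]
    if not rows:
        return np.empty((0, 0), dtype=np.int8)
    return np.array(rows, dtype=np.int8)


#: alias: the per-molecule binary pattern matrix IS the epiallele matrix
epiallele_matrix = calls_matrix


def methylation_levels(
    passing: pd.DataFrame,
    sample: str,
    locus: str,
    config: FilterConfig = FilterConfig(),
    n_cpg: int | None = None,
) -> MethylationProfile:
    """Per-CpG methylation levels for one bin of passing reads.

    level_pct = 100 * n_meth / (n_meth + n_unmeth); MISSING calls contribute
    to neither count.  Zero passing reads yield an empty, low-coverage
    profile rather than an exception.
    """
    sub = passing[(passing["sample"] == sample) & (passing["locus"] == locus)]
    mat = calls_matrix(sub["calls"])
    if mat.size == 0:
        k = n_cpg or 0
        per_cpg = pd.DataFrame(
            {
                "cpg_index": np.arange(k),
                "n_meth": np.zeros(k, dtype=int),
                "n_unmeth": np.zeros(k, dtype=int),
                "coverage": np.zeros(k, dtype=int),
                "level_pct": np.full(k, np.nan),
            }
        )
        return MethylationProfile(sample, locus, per_cpg, 0, True)
    n_meth = (mat == METH).sum(axis=0)
    n_unmeth = (mat == UNMETH).sum(axis=0)
    coverage = n_meth + n_unmeth
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(coverage > 0, 100.0 * n_meth / np.maximum(coverage, 1), np.nan)
    per_cpg = pd.DataFrame(
        {
            "cpg_index": np.arange(mat.shape[1]),
            "n_meth": n_meth,
            "n_unmeth": n_unmeth,
            "coverage": coverage,
            "level_pct": level,
        }
    )
    n = mat.shape[0]
    return MethylationProfile(sample, locus, per_cpg, n, n < config.min_reads_per_bin)


def all_profiles(
    passing: pd.DataFrame,
    config: FilterConfig = FilterConfig(),
    universe: list[tuple[str, str]] | None = None,
    n_cpg_by_locus: dict[str, int] | None = None,
) -> list[MethylationProfile]:
    """Profiles for every (sample, locus) bin present (or a given universe)."""
    if universe is None:
        universe = sorted(
            {(s, l) for s, l in zip(passing["sample"], passing["locus"])}
        )
    return [
        methylation_levels(
            passing,
            s,
            l,
            config,
            n_cpg=(n_cpg_by_locus or {}).get(l),
        )
        for s, l in universe
    ]


def epiallele_summary(matrix: np.ndarray, min_called_sites: int | None = None) -> dict:
    """Single-molecule pattern summary of an epiallele matrix.

    A read counts as fully methylated iff all its non-MISSING calls are
    methylated and at least ``min_called_sites`` sites are called (default:
    every site — short or gapped reads cannot inflate the fraction);
    fully unmethylated is the mirror case.  Percentages are over all rows.
    """
    matrix = np.asarray(matrix)
    if matrix.size == 0:
        raise ValueError("epiallele matrix is empty")
    n, k = matrix.shape
    need = k if min_called_sites is None else int(min_called_sites)
    called = matrix != MISSING
    n_called = called.sum(axis=1)
    enough = n_called >= need
    full_meth = enough & ((matrix == METH) | ~called).all(axis=1) & (n_called > 0)
    full_unmeth = enough & ((matrix == UNMETH) | ~called).all(axis=1) & (n_called > 0)
    patterns = Counter(
        "".join("M" if c == METH else "U" if c == UNMETH else "." for c in row)
        for row in matrix
    )
    return {
        "n_reads": n,
        "full_meth_pct": 100.0 * int(full_meth.sum()) / n,
        "full_unmeth_pct": 100.0 * int(full_unmeth.sum()) / n,
        "n_patterns": len(patterns),
        "pattern_counts": dict(patterns),
    }


def render_profile_table(profiles: list[MethylationProfile]) -> pd.DataFrame:
    """Locus x sample matrix of mean methylation levels, rendered as whole
    percent strings; low-coverage or absent bins render "N/A"."""
    loci = sorted({p.locus for p in profiles})
    samples = sorted({p.sample for p in profiles})
    table = pd.DataFrame("N/A", index=loci, columns=samples)
    for p in profiles:
        m = p.mean_level_pct
        if p.low_coverage or np.isnan(m):
            continue
        table.loc[p.locus, p.sample] = f"{int(np.floor(m + 0.5))}%"
    table.index.name = "locus"
    return table
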