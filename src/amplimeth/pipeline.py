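"""End-to-end pipeline: simulate -> demultiplex -> align -> quantify -> compare.

One :class:`PipelineConfig` (YAML-loadable) drives the whole run; every
stage writes its tables into the output directory with provenance headers,
and a run manifest records config, seed and version.  All randomness flows
from the single master seed through per-stage derived seeds, so a run is
reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .align import AlignParams, align_batch
from .concordance import concordance_report, correlate_yield, pair_measurements
from .demultiplex import demultiplex_batch, funnel_pct
from .io import (
    config_hash,
    read_fasta,
    read_loci_fasta,
    read_tag_table,
    write_fasta,
    write_loci_fasta,
    write_tag_table,
    write_tsv,
)
from .quantify import FilterConfig, all_profiles, epiallele_summary, filter_alignments, render_profile_table, calls_matrix
from .simulate import (
    EpiallelePatternModel,
    ErrorModel,
    build_locus,
    simulate_pyro,
    simulate_run,
)

log = logging.getLogger("amplimeth")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "design_study"]


class PipelineError(RuntimeError):
    pass


@dataclass
class SimulateConfig:
    """Study design for simulate mode; defaults mirror a 12-locus, 10-sample
    multiplexed amplicon run with length-dependent read yield."""

    n_loci: int = 12
    n_samples: int = 10
    length_min: int = 140
    length_max: int = 312
    n_cpg_min: int = 6
    n_cpg_max: int = 10
    gc_fraction: float = 0.55
    primer_len: int = 20
    base_reads_per_bin: int = 120
    yield_length_effect: float = 1.2  # relative yield drop from shortest to longest
    yield_noise_sd: float = 0.25  # lognormal SD of per-bin yield
    pyro_noise_sd: float = 3.0  # percentage points, bulk assay technical noise


@dataclass
class PipelineConfig:
    out_dir: str = "amplimeth_out"
    seed: int = 0
    # non-simulate mode inputs; ignored when simulate is set
    reads: str | None = None
    tag_table: str | None = None
    references: str | None = None
    bulk_table: str | None = None
    simulate: SimulateConfig | None = None
    error_model: ErrorModel = field(default_factory=ErrorModel)
    filter: FilterConfig = field(default_factory=FilterConfig)
    align: AlignParams = field(default_factory=AlignParams)
    max_primer_mismatch: int = 2
    scan_reverse: bool = False
    identity_mode: str = "filtered"
    regression_through_origin: bool = False
    ba_mode: str = "loa"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (
            ("simulate", SimulateConfig),
            ("error_model", ErrorModel),
            ("filter", FilterConfig),
            ("align", AlignParams),
        ):
            if isinstance(d.get(key), dict):
                d[key] = sub(**d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


def design_study(sim: SimulateConfig, seed) -> tuple[list, list[str], dict, dict]:
    """Draw the loci, per-bin epiallele mixtures and per-bin read counts.

    Amplicon lengths are spread across the configured range; the expected
    read yield of a locus decreases linearly with its length (on top of
    per-bin lognormal and Poisson noise), emulating the strong negative
    length/yield dependence of emulsion-PCR amplicon sequencing.  Each
    sample x locus bin gets its own epiallele mixture spanning dichotomous
    (all-or-nothing) to heterogeneous patterns.
    """
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:02d}" for i in range(sim.n_samples)]
    lengths = np.linspace(sim.length_min, sim.length_max, sim.n_loci).round().astype(int)
    loci = []
    for i, L in enumerate(lengths):
        n_cpg = int(rng.integers(sim.n_cpg_min, sim.n_cpg_max + 1))
        loci.append(
            build_locus(
                f"locus{i + 1:02d}",
                int(L),
                n_cpg,
                gc_fraction=sim.gc_fraction,
                seed=rng,
                primer_len=sim.primer_len,
            )
        )

    span = max(sim.length_max - sim.length_min, 1)
    models: dict[tuple[str, str], EpiallelePatternModel] = {}
    reads_per_bin: dict[tuple[str, str], int] = {}
    for s in samples:
        for loc in loci:
            mu = rng.uniform(0.02, 0.9)
            dichotomy = rng.uniform(0.0, 1.0)
            site = np.clip(rng.normal(mu, 0.1, size=loc.n_cpg), 0.0, 1.0)
            models[(s, loc.name)] = EpiallelePatternModel(
                p_full=dichotomy * mu,
                p_none=dichotomy * (1.0 - mu),
                site_probs=tuple(site),
            )
            rel = 1.0 + sim.yield_length_effect * (0.5 - (loc.length - sim.length_min) / span)
            lam = sim.base_reads_per_bin * rel * np.exp(rng.normal(0.0, sim.yield_noise_sd))
            reads_per_bin[(s, loc.name)] = int(max(2, rng.poisson(max(lam, 1.0))))
    return loci, samples, models, reads_per_bin


def _write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return a result bundle (paths plus key statistics).

    Raises :class:`PipelineError` on missing inputs; partial outputs written
    before a failure are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    meta = {"seed": config.seed, "config": config_hash(cfg_dict)}
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    results: dict = {"out_dir": str(out)}

    # ---- inputs: simulate or load -------------------------------------
    if config.simulate is not None:
        sim = config.simulate
        loci, samples, models, rpb = design_study(sim, seeds[0])
        run = simulate_run(
            loci, samples, models, config.error_model, rpb, seed=seeds[1]
        )
        write_fasta(run.reads, out / "reads.fasta")
        write_loci_fasta(loci, out / "references.fasta")
        write_tag_table(run.records, out / "tags.tsv", meta)
        write_tsv(run.truth.molecules, out / "truth_molecules.tsv", meta)
        write_tsv(run.truth.levels, out / "truth_levels.tsv", meta)
        bulk = simulate_pyro(run.truth.levels, sim.pyro_noise_sd, seed=seeds[2])
        write_tsv(bulk, out / "bulk_levels.tsv", meta)
        reads_path = out / "reads.fasta"
        records = run.records
        truth = run.truth
        log.info("simulate: %d reads, %d loci, %d samples", len(run.reads), len(loci), len(samples))
    else:
        if not config.reads or not Path(config.reads).exists():
            raise PipelineError(f"reads FASTA not found: {config.reads}")
        if not config.tag_table or not Path(config.tag_table).exists():
            raise PipelineError(f"tag table not found: {config.tag_table}")
        if not config.references or not Path(config.references).exists():
            raise PipelineError(f"reference FASTA not found: {config.references}")
        reads_path = Path(config.reads)
        records = read_tag_table(config.tag_table)
        loci = read_loci_fasta(config.references)
        truth = None
        bulk = None
        if config.bulk_table:
            if not Path(config.bulk_table).exists():
                raise PipelineError(f"bulk table not found: {config.bulk_table}")
            from .io import read_tsv

            bulk = read_tsv(config.bulk_table)

    # ---- demultiplex ---------------------------------------------------
    demux = demultiplex_batch(
        reads_path, records, config.max_primer_mismatch, config.scan_reverse
    )
    bins_dir = out / "bins"
    bins_dir.mkdir(exist_ok=True)
    bins = demux.bin_reads()
    for (sample, locus_name), pair_list in sorted(bins.items()):
        write_fasta(pair_list, bins_dir / f"{sample}_{locus_name}.fasta")
    write_tsv(demux.bin_counts(), out / "bin_counts.tsv", meta)
    write_tsv(
        pd.DataFrame(demux.unassigned, columns=["read_id", "reason"]),
        out / "unassigned.tsv",
        meta,
    )
    results["demux_funnel"] = demux.funnel
    log.info(
        "demux: %d/%d reads assigned (%.1f%%)",
        demux.funnel["assigned_reads"],
        demux.funnel["total_reads"],
        demux.funnel["assigned_pct"],
    )

    # ---- align ---------------------------------------------------------
    alignments = align_batch(bins, loci, config.align, config.identity_mode)
    write_tsv(alignments, out / "alignments.tsv", meta)
    log.info("align: %d reads aligned", len(alignments))

    # ---- quantify ------------------------------------------------------
    passing, rejected, qc_funnel = filter_alignments(
        alignments, config.filter, raw_total=demux.funnel["total_reads"]
    )
    write_tsv(rejected, out / "rejected_reads.tsv", meta)
    n_cpg_by_locus = {loc.name: loc.n_cpg for loc in loci}
    universe = sorted({(r.sample_id, r.locus_name) for r in records})
    profiles = all_profiles(passing, config.filter, universe, n_cpg_by_locus)

    level_rows = []
    for p in profiles:
        for _, row in p.per_cpg.iterrows():
            level_rows.append(
                {
                    "sample": p.sample,
                    "locus": p.locus,
                    "cpg_index": int(row["cpg_index"]),
                    "n_meth": int(row["n_meth"]),
                    "n_unmeth": int(row["n_unmeth"]),
                    "coverage": int(p.n_reads_passing),
                    "site_coverage": int(row["coverage"]),
                    "level_pct": row["level_pct"],
                    "low_coverage": p.low_coverage,
                }
            )
    levels = pd.DataFrame(
        level_rows,
        columns=[
            "sample",
            "locus",
            "cpg_index",
            "n_meth",
            "n_unmeth",
            "coverage",
            "site_coverage",
            "level_pct",
            "low_coverage",
        ],
    )
    write_tsv(levels, out / "cpg_levels.tsv", meta)

    epi_rows = []
    for p in profiles:
        if p.n_reads_passing == 0:
            continue
        sub = passing[(passing["sample"] == p.sample) & (passing["locus"] == p.locus)]
        summary = epiallele_summary(calls_matrix(sub["calls"]))
        for pattern, count in sorted(summary["pattern_counts"].items()):
            epi_rows.append(
                {"sample": p.sample, "locus": p.locus, "pattern": pattern, "count": count}
            )
    write_tsv(
        pd.DataFrame(epi_rows, columns=["sample", "locus", "pattern", "count"]),
        out / "epialleles.tsv",
        meta,
    )
    write_tsv(render_profile_table(profiles), out / "mean_level_table.tsv", meta, index=True)

    funnel = {
        "total_reads": demux.funnel["total_reads"],
        "assigned_reads": demux.funnel["assigned_reads"],
        "assigned_pct": demux.funnel["assigned_pct"],
        "passing_reads": qc_funnel["passing_reads"],
        "passing_pct": qc_funnel["passing_pct"],
    }
    _write_json(funnel, out / "funnel.json")
    results["funnel"] = funnel
    log.info(
        "quantify: %d/%d reads passed QC (%.1f%% of raw)",
        funnel["passing_reads"],
        funnel["total_reads"],
        funnel["passing_pct"],
    )

    # ---- compare -------------------------------------------------------
    if bulk is not None:
        pairs, excluded = pair_measurements(levels, bulk)
        write_tsv(pairs, out / "paired_levels.tsv", meta)
        write_tsv(excluded, out / "excluded_pairs.tsv", meta)
        report = concordance_report(
            pairs,
            through_origin=config.regression_through_origin,
            ba_mode=config.ba_mode,
        )
        _write_json(report.to_dict(), out / "concordance.json")
        write_tsv(report.bland_altman["scatter"], out / "bland_altman_points.tsv", meta)

        cov_table = report_coverage_table(pairs)
        if cov_table is not None:
            write_tsv(cov_table, out / "coverage_vs_diff.tsv", meta)

        # per-gene mean levels of both assays (bar-plot ready)
        merged = pairs.groupby(["sample", "locus"], as_index=False)[
            ["level_deep", "level_bulk"]
        ].mean()
        write_tsv(merged, out / "mean_levels_by_bin.tsv", meta)

        # read-yield vs amplicon-length correlation
        counts = demux.bin_counts()
        lengths = pd.DataFrame(
            [{"locus": loc.name, "length": loc.length} for loc in loci]
        )
        per_amp = (
            counts.groupby("locus", as_index=False)["n_reads"].mean()
            .rename(columns={"n_reads": "mean_reads"})
            .merge(lengths, on="locus")
        )
        try:
            results["yield_correlation"] = correlate_yield(per_amp)
        except ValueError:
            results["yield_correlation"] = None
        results["concordance"] = report.to_dict()
        log.info(
            "compare: %d pairs, r2=%.3f, within-10pt %.1f%%",
            report.n_pairs,
            report.regression["r2"],
            report.congruence[10.0]["pct"],
        )

    manifest = {
        "tool": "amplimeth",
        "version": __version__,
        "seed": config.seed,
        "config_hash": meta["config"],
        "config": cfg_dict,
    }
    _write_json(manifest, out / "manifest.json")
    results["profiles"] = profiles
    if truth is not None:
        results["truth"] = truth
    return results


def report_coverage_table(pairs: pd.DataFrame):
    from .concordance import coverage_vs_congruence

    if "coverage_deep" not in pairs.columns:
        return None
    return coverage_vs_congruence(pairs)["table"]
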