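"""End-to-end screen driver: noise calibration -> z-scores -> screening.

Given one library per column across the experimental conditions (an
uninjected control plus morpholino knockdowns), the pipeline

1. fits a replicate noise model from every condition sequenced in duplicate
   (SD curves averaged pointwise when several pairs exist), falling back to
   the theoretical random-sampling z with a warning when no replicate pair
   is available;
2. pools replicate libraries within each condition (counts and totals add)
   and computes M, A and the calibrated z for every knockdown condition
   against the pooled control;
3. applies tiering, artifact/contaminant flags and DGE class assignment;
4. writes per-comparison MA tables, the screen report and a run summary.

Same configuration and seed give byte-identical outputs.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import rsm, screen as screening
from .io import load_sim_config, read_count_table, write_count_table, write_truth_table
from .simulate import TagCountTable, evaluate_recovery, simulate_experiment

__all__ = [
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
    "screen_experiment",
    "pool_condition",
    "zscore_table",
]

logger = logging.getLogger("dgescreen")


@dataclass
class RunConfig:
    """Pipeline configuration."""

    counts: list[str] = field(default_factory=list)  # count-table TSV paths
    sim_config: str | None = None  # SimConfig JSON/YAML path (alternative)
    control: str = "uninjected"
    loose_z: float = screening.LOOSE_Z
    strict_z: float = screening.STRICT_Z
    pseudocount: float = rsm.DEFAULT_PSEUDOCOUNT
    window_size: int = 500
    outdir: str = "dge_out"
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self):
        if not 0 < self.loose_z <= self.strict_z:
            raise ValueError("cutoffs must satisfy 0 < loose <= strict")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


@dataclass
class PipelineResult:
    ma_tables: dict[str, pd.DataFrame]  # condition -> gene/M/A/z/p/low_count
    records: list[screening.ScreenRecord]
    noise_model: rsm.NoiseModel | None
    recovery: object | None
    outdir: Path


def _condition_of(library: str) -> str:
    return library.rsplit("_", 1)[0] if "_" in library else library


def pool_condition(tables: dict[str, TagCountTable], condition: str) -> TagCountTable:
    """Sum the counts and totals of a condition's replicate libraries."""
    libs = sorted(
        lib for t in tables.values() for lib in t.libraries if _condition_of(lib) == condition
    )
    if not libs:
        raise ValueError(f"no libraries for condition {condition!r}")
    by_lib = {lib: t for t in tables.values() for lib in t.libraries}
    first = by_lib[libs[0]]
    counts = sum(by_lib[lib].counts[lib].to_numpy() for lib in libs)
    frame = pd.DataFrame({condition: counts}, index=first.counts.index)
    total = sum(by_lib[lib].total(lib) for lib in libs)
    return TagCountTable(counts=frame, totals={condition: total})


def zscore_table(
    case: TagCountTable,
    control: TagCountTable,
    model: rsm.NoiseModel | None,
    pseudocount: float = rsm.DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene M, A, z, p for one condition against the control.

    Uses the replicate-calibrated z when ``model`` is given, otherwise the
    theoretical random-sampling z.  When library totals differ, M is centred
    at its null expectation ``log2(n1/n2)`` before calibration (the noise
    model is fitted from same-size replicate pairs, so its mean curve cannot
    absorb a library-size offset); the reported M stays the raw log2 count
    ratio.  Genes with combined count below ``LOW_COUNT_MIN_K`` are flagged
    ``low_count`` (they still get a z).
    """
    (case_lib,) = case.libraries
    (ctl_lib,) = control.libraries
    c1 = case.column(case_lib).astype(float)
    c2 = control.column(ctl_lib).astype(float)
    M, A = rsm.compute_ma(c1, c2, pseudocount=pseudocount)
    if model is not None:
        offset = np.log2(case.total(case_lib) / control.total(ctl_lib))
        z = rsm.matr_zscore(M - offset, A, model)
    else:
        z = rsm.rsm_zscore(c1, c2, case.total(case_lib), control.total(ctl_lib), pseudocount)
    return pd.DataFrame(
        {
            "M": M,
            "A": A,
            "z": z,
            "p": rsm.two_sided_p(z),
            "low_count": (c1 + c2) < rsm.LOW_COUNT_MIN_K,
        },
        index=case.counts.index,
    )


def screen_experiment(
    tables: dict[str, TagCountTable],
    control: str = "uninjected",
    loose: float = screening.LOOSE_Z,
    strict: float = screening.STRICT_Z,
    pseudocount: float = rsm.DEFAULT_PSEUDOCOUNT,
    window_size: int = 500,
) -> tuple[list[screening.ScreenRecord], dict[str, pd.DataFrame], rsm.NoiseModel | None]:
    """Library-level screen: calibration, per-condition z, tier/flag/classify.

    The in-memory core of :func:`run_pipeline` (no file output): fits the
    replicate noise model, computes per-condition z tables against the
    pooled control and runs the screen.  Returns the records, the MA tables
    and the (possibly absent) noise model.
    """
    libraries = sorted(lib for t in tables.values() for lib in t.libraries)
    by_lib = {lib: t for t in tables.values() for lib in t.libraries}
    conditions = sorted({_condition_of(lib) for lib in libraries})
    pairs = _replicate_pairs(libraries)
    model = None
    if pairs:
        model = rsm.average_noise_models(
            [
                rsm.fit_noise_model(
                    by_lib[a].column(a),
                    by_lib[b].column(b),
                    window_size=window_size,
                    pseudocount=pseudocount,
                )
                for a, b in pairs
            ]
        )
    pooled_control = pool_condition(tables, control)
    ma_tables = {
        cond: zscore_table(pool_condition(tables, cond), pooled_control, model, pseudocount)
        for cond in conditions
        if cond != control
    }
    z_tables = {cond: dict(zip(tab.index, tab["z"])) for cond, tab in ma_tables.items()}
    records = screening.run_screen(z_tables, loose=loose, strict=strict)
    return records, ma_tables, model


def _replicate_pairs(libraries: list[str]) -> list[tuple[str, str]]:
    by_cond: dict[str, list[str]] = {}
    for lib in sorted(libraries):
        by_cond.setdefault(_condition_of(lib), []).append(lib)
    pairs = []
    for cond, libs in sorted(by_cond.items()):
        for i in range(0, len(libs) - 1, 2):
            pairs.append((libs[i], libs[i + 1]))
    return pairs


def run_pipeline(config: RunConfig) -> PipelineResult:
    level = logging.WARNING if config.verbosity == 0 else logging.INFO
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    # --- stage: input ---------------------------------------------------
    truth = None
    if config.sim_config is not None:
        sim_cfg = load_sim_config(config.sim_config)
        sim_cfg.seed = config.seed
        tables, truth = simulate_experiment(sim_cfg)
        logger.info("[input] simulated %d genes, %d libraries", sim_cfg.n_genes, len(tables))
        for lib, table in tables.items():
            write_count_table(table, outdir / f"counts_{lib}.tsv")
        write_truth_table(truth, outdir / "truth.tsv")
    elif config.counts:
        tables = {}
        for path in config.counts:
            table = read_count_table(path)
            for lib in table.libraries:
                sub = TagCountTable(
                    counts=table.counts[[lib]], totals={lib: table.total(lib)}
                )
                tables[lib] = sub
        logger.info("[input] read %d libraries", len(tables))
    else:
        raise ValueError("[input] either counts or sim_config must be given")

    libraries = sorted(lib for t in tables.values() for lib in t.libraries)
    conditions = sorted({_condition_of(lib) for lib in libraries})
    if config.control not in conditions:
        raise ValueError(f"[input] control condition {config.control!r} not among {conditions}")

    # --- stages: noise calibration, z-scores, screening -------------------
    if not _replicate_pairs(libraries):
        logger.warning(
            "[noise] no replicate pair found; falling back to the theoretical "
            "random-sampling z-score"
        )
    records, ma_tables, model = screen_experiment(
        tables,
        control=config.control,
        loose=config.loose_z,
        strict=config.strict_z,
        pseudocount=config.pseudocount,
        window_size=config.window_size,
    )
    if model is not None:
        logger.info("[noise] replicate noise model: %d grid points", model.a_grid.size)
    for cond, tab in ma_tables.items():
        out = tab.copy()
        out.insert(0, "gene", out.index)
        out.to_csv(outdir / f"zscore_{cond}.tsv", sep="\t", index=False, float_format="%.6g")
        logger.info("[zscore] %s vs %s: %d genes", cond, config.control, len(tab))
    report = pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            **{
                f"z_{cond}": [r.z_by_condition.get(cond, float("nan")) for r in records]
                for cond in ma_tables
            },
            "tier": [r.tier for r in records],
            "artifact_flag": [int(r.artifact_flag) for r in records],
            "contaminant_flag": [int(r.contaminant_flag) for r in records],
            "dge_class": [r.dge_class for r in records],
        }
    )
    report.to_csv(outdir / "screen.tsv", sep="\t", index=False, float_format="%.6g")
    n_flag = sum(r.artifact_flag or r.contaminant_flag for r in records)
    logger.info("[screen] %d records, %d flagged", len(records), n_flag)

    # --- stage: recovery ---------------------------------------------------
    recovery = None
    if truth is not None:
        recovery = evaluate_recovery(records, truth)
        recovery.confusion.to_csv(outdir / "confusion.tsv", sep="\t")
        (outdir / "recovery.tsv").write_text(recovery.summary() + "\n", encoding="utf-8")
        logger.info("[recovery] written")

    # --- summary -----------------------------------------------------------
    tier_counts = pd.Series([r.tier for r in records]).value_counts().to_dict()
    class_counts = pd.Series([str(r.dge_class) for r in records]).value_counts().to_dict()
    lines = [
        f"libraries\t{len(libraries)}",
        f"genes\t{len(records)}",
        f"noise_model\t{'replicate' if model is not None else 'theoretical'}",
    ]
    lines += [f"tier_{k}\t{v}" for k, v in sorted(tier_counts.items())]
    lines += [f"class_{k}\t{v}" for k, v in sorted(class_counts.items())]
    lines += [
        f"artifact_flags\t{sum(r.artifact_flag for r in records)}",
        f"contaminant_flags\t{sum(r.contaminant_flag for r in records)}",
    ]
    (outdir / "summary.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    logger.info("[done] %.2fs", time.perf_counter() - t0)
    return PipelineResult(
        ma_tables=ma_tables, records=records, noise_model=model, recovery=recovery, outdir=outdir
    )
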