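"""Synthetic tag-count experiments with planted ground truth.

Emulates the design of a morpholino-knockdown DGE screen on early gastrula
embryos: an uninjected control condition sequenced in duplicate, a ``wnt3``
knockdown in duplicate, and single ``fz1``, ``fz3`` and ``stbm`` knockdown
libraries.  Per-gene baseline abundances are log2-normal; realised counts are
gamma-Poisson (negative binomial) with variance ``m + dispersion * m**2`` so
that ``dispersion = 0`` degenerates to Poisson sampling.

Planted gene labels and their condition effects (log2 fold changes of
magnitude ``effect_log2fc``):

=============  ===========================================================
label          effect
=============  ===========================================================
``class1``     depleted in wnt3 only
``class2``     depleted in wnt3, fz1 and stbm (PCP-sensitive)
``class3``     elevated in wnt3 only
``class4``     elevated in wnt3, fz1 and stbm
``artifact``   elevated in every morpholino condition (injection damage)
``contaminant``present at ``contaminant_factor`` of its abundance in every
               morpholino library (carried over at full strength only in
               uninjected embryos, e.g. bacterial reads from the jelly coat)
``null``       no effect anywhere
=============  ===========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_LABELS",
    "MO_CONDITIONS",
    "SimConfig",
    "SimTruth",
    "TagCountTable",
    "default_library_sizes",
    "simulate_experiment",
    "evaluate_recovery",
    "RecoveryReport",
]

CLASS_LABELS = ("class1", "class2", "class3", "class4", "artifact", "contaminant", "null")
MO_CONDITIONS = ("wnt3", "fz1", "fz3", "stbm")
CONDITIONS = ("uninjected",) + MO_CONDITIONS

#: replicate layout of the emulated experiment
DEFAULT_REPLICATES = {"uninjected": 2, "wnt3": 2, "fz1": 1, "fz3": 1, "stbm": 1}


def default_library_sizes(n_genes: int, mean_depth: float = 100.0) -> dict[str, int]:
    """Library totals giving ``mean_depth`` mapped reads per gene per library."""
    size = int(round(mean_depth * n_genes))
    return {
        f"{cond}_{r + 1}": size
        for cond in CONDITIONS
        for r in range(DEFAULT_REPLICATES[cond])
    }


def _default_fractions() -> dict[str, float]:
    return {
        "class1": 0.005,
        "class2": 0.005,
        "class3": 0.005,
        "class4": 0.005,
        "artifact": 0.001,
        "contaminant": 0.001,
        "null": 0.978,
    }


@dataclass
class SimConfig:
    """Configuration of a synthetic screen.

    Defaults describe the study conditions the downstream statistics assume:
    20,000 reference transcripts, mean depth 100 mapped reads per transcript
    per library, log2-normal baselines with SD 1 (narrower than a real
    transcriptome's spread, keeping planted effects above the binomial
    detection floor at this depth), mild replicate overdispersion (0.05),
    strong planted effects (|log2FC| = 4), and small planted
    class/artifact/contaminant fractions.
    """

    n_genes: int = 20_000
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.0
    library_sizes: dict[str, int] | None = None
    dispersion: float = 0.05
    planted_fractions: dict[str, float] = field(default_factory=_default_fractions)
    effect_log2fc: float = 4.0
    contaminant_factor: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ValueError("n_genes must be strictly positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.effect_log2fc <= 0:
            raise ValueError("effect_log2fc must be positive")
        if not 0 < self.contaminant_factor <= 1:
            raise ValueError("contaminant_factor must lie in (0, 1]")
        if self.library_sizes is None:
            self.library_sizes = default_library_sizes(self.n_genes)
        for lib, n in self.library_sizes.items():
            if n <= 0:
                raise ValueError(f"library size for {lib!r} must be strictly positive")
        unknown = set(self.planted_fractions) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown planted labels: {sorted(unknown)}")
        total = sum(self.planted_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"planted fractions sum to {total!r}, expected 1")
        if any(f < 0 for f in self.planted_fractions.values()):
            raise ValueError("planted fractions must be non-negative")


@dataclass
class SimTruth:
    """Planted ground truth: baselines, labels and per-condition log2FCs."""

    genes: list[str]
    baseline: np.ndarray
    label: np.ndarray  # one of CLASS_LABELS per gene
    log2fc: pd.DataFrame  # genes x MO_CONDITIONS

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"baseline": self.baseline, "label": self.label},
            index=pd.Index(self.genes, name="gene"),
        )
        return out.join(self.log2fc.add_prefix("log2fc_"))


@dataclass
class TagCountTable:
    """Transcript-by-library count matrix plus library totals.

    ``counts`` has genes in rows and libraries in columns; ``totals`` are the
    declared library totals (the realised column sums unless genes were
    filtered out after counting).
    """

    counts: pd.DataFrame
    totals: dict[str, int]

    def __post_init__(self):
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        for lib in self.counts.columns:
            if lib not in self.totals:
                raise ValueError(f"missing library total for {lib!r}")
            if int(self.counts[lib].sum()) > int(self.totals[lib]):
                raise ValueError(f"column sum exceeds declared total for {lib!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    def column(self, library: str) -> np.ndarray:
        return self.counts[library].to_numpy()

    def total(self, library: str) -> int:
        return int(self.totals[library])


def _condition_log2fc(label: str, effect: float) -> dict[str, float]:
    fc = dict.fromkeys(MO_CONDITIONS, 0.0)
    if label == "class1":
        fc["wnt3"] = -effect
    elif label == "class2":
        fc.update(wnt3=-effect, fz1=-effect, stbm=-effect)
    elif label == "class3":
        fc["wnt3"] = effect
    elif label == "class4":
        fc.update(wnt3=effect, fz1=effect, stbm=effect)
    elif label == "artifact":
        fc = dict.fromkeys(MO_CONDITIONS, effect)
    return fc


def simulate_experiment(config: SimConfig) -> tuple[dict[str, TagCountTable], SimTruth]:
    """Draw one synthetic experiment.

    Returns one single-library :class:`TagCountTable` per library (keyed by
    library name, e.g. ``wnt3_1``) plus the planted truth.  Expected counts
    in a library are the label-adjusted relative abundances scaled to the
    configured library total; realised counts are independent negative
    binomial draws.  Identical seeds give bit-identical output: every
    library draws from its own substream spawned deterministically from the
    master seed.
    """
    cfg = config
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    master = np.random.SeedSequence(cfg.seed)
    # fixed spawn order: truth stream first, then one stream per library
    streams = master.spawn(1 + len(cfg.library_sizes))
    rng_truth = np.random.default_rng(streams[0])

    labels_pool = [lab for lab in CLASS_LABELS if cfg.planted_fractions.get(lab, 0) > 0]
    probs = np.array([cfg.planted_fractions[lab] for lab in labels_pool])
    label = rng_truth.choice(labels_pool, size=cfg.n_genes, p=probs / probs.sum())
    baseline = 2.0 ** rng_truth.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes)

    log2fc = pd.DataFrame(
        0.0, index=pd.Index(genes, name="gene"), columns=list(MO_CONDITIONS)
    )
    for lab in labels_pool:
        mask = label == lab
        if not mask.any():
            continue
        fc = _condition_log2fc(lab, cfg.effect_log2fc)
        for cond in MO_CONDITIONS:
            log2fc.loc[mask, cond] = fc[cond]
    # contaminants: residual abundance in every morpholino library
    contam = label == "contaminant"
    if contam.any():
        log2fc.loc[contam, :] = float(np.log2(cfg.contaminant_factor))

    truth = SimTruth(genes=genes, baseline=baseline, label=label, log2fc=log2fc)

    tables: dict[str, TagCountTable] = {}
    for stream, (lib, size) in zip(streams[1:], sorted(cfg.library_sizes.items())):
        rng = np.random.default_rng(stream)
        cond = lib.rsplit("_", 1)[0]
        if cond == "uninjected":
            abundance = baseline
        else:
            abundance = baseline * 2.0 ** log2fc[cond].to_numpy()
        mean = size * abundance / abundance.sum()
        if cfg.dispersion == 0:
            counts = rng.poisson(mean)
        else:
            # gamma-Poisson mixture: var = m + dispersion * m^2
            shape = 1.0 / cfg.dispersion
            counts = rng.poisson(rng.gamma(shape, mean / shape))
        frame = pd.DataFrame({lib: counts}, index=pd.Index(genes, name="gene"))
        tables[lib] = TagCountTable(counts=frame, totals={lib: int(counts.sum())})
    return tables, truth


@dataclass
class RecoveryReport:
    """Per-label precision/recall plus the assigned-vs-true confusion matrix."""

    confusion: pd.DataFrame  # rows: true label, columns: assigned label
    precision: dict[str, float]
    recall: dict[str, float]

    def summary(self) -> str:
        lines = ["label\tprecision\trecall"]
        for lab in self.confusion.index:
            p = self.precision.get(lab)
            r = self.recall.get(lab)
            fmt = lambda x: "NA" if x is None else f"{x:.4f}"
            lines.append(f"{lab}\t{fmt(p)}\t{fmt(r)}")
        return "\n".join(lines)


def _assigned_label(record) -> str:
    if record.contaminant_flag:
        return "contaminant"
    if record.artifact_flag:
        return "artifact"
    if record.dge_class in (1, 2, 3, 4):
        return f"class{record.dge_class}"
    return "null"


def evaluate_recovery(screen, truth: SimTruth) -> RecoveryReport:
    """Compare screen output with planted labels.

    ``screen`` is a sequence of :class:`~dgescreen.screen.ScreenRecord`.
    Flags take precedence over class labels on the assigned side
    (a flagged gene is never classified); unflagged, unclassified genes are
    assigned ``null``.  Precision/recall are reported only for labels with a
    non-empty denominator.
    """
    by_gene = {rec.gene: rec for rec in screen}
    if set(by_gene) != set(truth.genes):
        raise ValueError("screen and truth cover different gene sets")
    assigned = np.array([_assigned_label(by_gene[g]) for g in truth.genes])
    labels = list(CLASS_LABELS)
    confusion = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    confusion.index.name = "true"
    confusion.columns.name = "assigned"
    for t, a in zip(truth.label, assigned):
        confusion.loc[t, a] += 1
    precision, recall = {}, {}
    for lab in labels:
        tp = int(confusion.loc[lab, lab])
        n_assigned = int(confusion[lab].sum())
        n_true = int(confusion.loc[lab].sum())
        if n_assigned > 0:
            precision[lab] = tp / n_assigned
        if n_true > 0:
            recall[lab] = tp / n_true
    return RecoveryReport(confusion=confusion, precision=precision, recall=recall)
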