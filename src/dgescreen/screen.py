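"""Significance tiers, cross-condition filters and DGE class assignment.

A transcript's screening verdict is driven by its z-scores against the
uninjected control in up to four knockdown conditions (wnt3, fz1, fz3,
stbm).  Tiers follow the two z cutoffs (default |z| >= 3.3 "loose" and
|z| >= 5.0 "strict").  Two cross-condition filters remove transcripts whose
response cannot be specific to the targeted pathway:

* **injection artifact** — elevated (z > strict) in wnt3, fz1 *and* fz3,
  conditions with opposite phenotypes responding identically;
* **contaminant** — depleted (z < -strict) in both wnt3 and fz3, the
  signature of material carried over preferentially in uninjected embryos.

Unflagged transcripts at the strict tier are then placed in one of four DGE
classes from the (wnt3, fz1) z pair: class 1/2 split the wnt3-depleted
transcripts by weak/strong fz1 depletion, class 3/4 split the wnt3-elevated
ones by weak/strong fz1 elevation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LOOSE_Z",
    "STRICT_Z",
    "Tier",
    "ScreenRecord",
    "tier_transcript",
    "flag_injection_artifact",
    "flag_contaminant",
    "assign_dge_class",
    "run_screen",
]

LOOSE_Z = 3.3
STRICT_Z = 5.0

TIERS = ("none", "loose_under", "loose_over", "strict_under", "strict_over")
Tier = str


@dataclass
class ScreenRecord:
    """Per-transcript screening verdict."""

    gene: str
    z_by_condition: dict[str, float] = field(default_factory=dict)
    tier: Tier = "none"
    artifact_flag: bool = False
    contaminant_flag: bool = False
    dge_class: int | str = "unclassified"

    def __post_init__(self):
        if self.artifact_flag and self.contaminant_flag:
            raise ValueError("a record cannot be both artifact and contaminant")


def _check_finite(name: str, z: float) -> float:
    z = float(z)
    if not math.isfinite(z):
        raise ValueError(f"non-finite z-score for {name}")
    return z


def tier_transcript(z_wnt3: float, loose: float = LOOSE_Z, strict: float = STRICT_Z) -> Tier:
    """Tier from the wnt3 z-score; boundaries go to the more significant tier."""
    if not 0 < loose <= strict:
        raise ValueError("cutoffs must satisfy 0 < loose <= strict")
    z = _check_finite("wnt3", z_wnt3)
    if z <= -strict:
        return "strict_under"
    if z >= strict:
        return "strict_over"
    if z <= -loose:
        return "loose_under"
    if z >= loose:
        return "loose_over"
    return "none"


def _require(z_by_condition: dict[str, float], conditions: tuple[str, ...]) -> dict[str, float]:
    out = {}
    for cond in conditions:
        if cond not in z_by_condition:
            raise ValueError(f"z-score for condition {cond!r} is required")
        out[cond] = _check_finite(cond, z_by_condition[cond])
    return out


def flag_injection_artifact(z_by_condition: dict[str, float], strict: float = STRICT_Z) -> bool:
    """True iff z > +strict in wnt3, fz1 and fz3 simultaneously."""
    z = _require(z_by_condition, ("wnt3", "fz1", "fz3"))
    return all(z[c] > strict for c in ("wnt3", "fz1", "fz3"))


def flag_contaminant(z_by_condition: dict[str, float], strict: float = STRICT_Z) -> bool:
    """True iff z < -strict in both wnt3 and fz3 (fz1 not required)."""
    z = _require(z_by_condition, ("wnt3", "fz3"))
    return z["wnt3"] < -strict and z["fz3"] < -strict


def assign_dge_class(z_wnt3: float, z_fz1: float, strict: float = STRICT_Z) -> int | str:
    """Four-way class from the (wnt3, fz1) z pair at the strict cutoff.

    Exact-boundary fz1 values go to the strongly affected side (classes 2/4).
    """
    zw = _check_finite("wnt3", z_wnt3)
    zf = _check_finite("fz1", z_fz1)
    if zw <= -strict:
        return 2 if zf <= -strict else 1
    if zw >= strict:
        return 4 if zf >= strict else 3
    return "unclassified"


def run_screen(
    z_tables: dict[str, "np.ndarray | list[float] | dict[str, float]"],
    genes: list[str] | None = None,
    loose: float = LOOSE_Z,
    strict: float = STRICT_Z,
) -> list[ScreenRecord]:
    """Apply tiering, flags and class assignment to per-condition z tables.

    ``z_tables`` maps condition name -> per-gene z (either a mapping keyed by
    gene or an array aligned with ``genes``).  wnt3 and fz1 are required;
    fz3/stbm are used when present (both filters need fz3 — without it no
    gene is flagged).  Order-independent across genes.
    """
    if "wnt3" not in z_tables or "fz1" not in z_tables:
        raise ValueError("z tables for wnt3 and fz1 are required")

    per_cond: dict[str, dict[str, float]] = {}
    universe: list[str] | None = None
    for cond, table in z_tables.items():
        if isinstance(table, dict):
            mapping = {g: float(v) for g, v in table.items()}
        else:
            if genes is None:
                raise ValueError("genes must be given when z tables are arrays")
            arr = np.asarray(table, dtype=float)
            if arr.shape[0] != len(genes):
                raise ValueError(f"z table for {cond!r} does not match the gene list")
            mapping = dict(zip(genes, arr))
        if universe is None:
            universe = list(mapping)
        elif set(mapping) != set(universe):
            raise ValueError(f"z table for {cond!r} covers a different gene set")
        per_cond[cond] = mapping

    has_fz3 = "fz3" in per_cond
    records = []
    for gene in universe:
        z = {cond: per_cond[cond][gene] for cond in per_cond}
        tier = tier_transcript(z["wnt3"], loose, strict)
        contaminant = has_fz3 and flag_contaminant(z, strict)
        # contaminant wins if both rules ever matched (impossible at default
        # cutoffs: they need opposite wnt3 signs)
        artifact = (not contaminant) and has_fz3 and flag_injection_artifact(z, strict)
        if artifact or contaminant:
            dge_class: int | str = "unclassified"
        elif tier in ("strict_under", "strict_over"):
            dge_class = assign_dge_class(z["wnt3"], z["fz1"], strict)
        else:
            dge_class = "unclassified"
        records.append(
            ScreenRecord(
                gene=gene,
                z_by_condition=z,
                tier=tier,
                artifact_flag=artifact,
                contaminant_flag=contaminant,
                dge_class=dge_class,
            )
        )
    return records
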