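"""Rare-cell capture metrics for spike-in and enumeration experiments.

Immunomagnetic capture performance is characterized by spiking a known
number of tumor cells (e.g. LNCaP) into healthy donor blood and counting
what comes back: live cells, membrane-compromised (dead) cells, and
carried-over leukocytes.  Purity follows the protocol definition

    purity = recovered spiked cells / (recovered spiked cells + leukocytes)

where recovered spiked cells include dead ones (a live-only mode exists).
Enumeration comparisons against a reference platform substitute 1 for zero
counts for log-scale plotting, without touching the raw counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpikeExperiment",
    "EnumerationPair",
    "capture_efficiency",
    "dead_fraction",
    "purity",
    "attrition_estimate",
    "comparison_table",
    "replicate_summary",
]


@dataclass(frozen=True)
class SpikeExperiment:
    """Counts from one spike-in recovery experiment."""

    n_spiked: int
    recovered_live: int
    recovered_dead: int
    wbc_contaminating: int
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if min(self.n_spiked, self.recovered_live, self.recovered_dead,
               self.wbc_contaminating) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class EnumerationPair:
    """CTC counts for one patient sample on two enumeration platforms."""

    sample_id: str
    magsweeper_ctcs: int
    cellsearch_ctcs: int

    def __post_init__(self) -> None:
        if self.magsweeper_ctcs < 0 or self.cellsearch_ctcs < 0:
            raise ValueError("counts must be non-negative")


def capture_efficiency(exp: SpikeExperiment) -> float:
    """Fraction of spiked cells recovered alive.

    A value above 1 (a counting inconsistency) is returned as-is with a
    warning rather than raised, so batch summaries do not abort.
    """
    if exp.n_spiked <= 0:
        raise ValueError("n_spiked must be > 0")
    eff = exp.recovered_live / exp.n_spiked
    if eff > 1.0:
        warnings.warn(
            f"replicate {exp.replicate_id!r}: recovered_live > n_spiked "
            f"(efficiency {eff:.3g})",
            stacklevel=2,
        )
    return eff


def dead_fraction(exp: SpikeExperiment) -> float:
    """Fraction of spiked cells recovered membrane-compromised (dead)."""
    if exp.n_spiked <= 0:
        raise ValueError("n_spiked must be > 0")
    return exp.recovered_dead / exp.n_spiked


def purity(exp: SpikeExperiment, live_only: bool = False) -> float:
    """Recovered spiked cells over recovered spiked cells plus leukocytes.

    The numerator counts all recovered spiked cells, dead included
    (``live_only`` restricts both numerator and denominator to live cells).
    """
    recovered = exp.recovered_live + (0 if live_only else exp.recovered_dead)
    denom = recovered + exp.wbc_contaminating
    if denom == 0:
        raise ValueError("no cells recovered: purity undefined")
    return recovered / denom


def attrition_estimate(exp: SpikeExperiment, dead_fraction_pre_spike: float) -> float:
    """Cell attrition attributable to the isolation procedure.

    Interpreted as the recovered dead-cell fraction minus the dead fraction
    already present in the spike (an interpretation: the exact bookkeeping
    behind a published attrition figure is rarely printed).  Can be slightly
    negative by sampling noise.
    """
    return dead_fraction(exp) - dead_fraction_pre_spike


def comparison_table(
    pairs: Sequence[EnumerationPair], low_count_max: int = 5
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Platform-comparison table with log-plot-ready values.

    Raw counts are preserved; the ``*_plot`` columns substitute 1 for 0 so
    samples with zero CTCs remain visible on a log axis.  The accompanying
    summary covers the low-count stratum (reference platform count
    <= ``low_count_max``), where platform differences matter most.
    """
    df = pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in pairs],
            "magsweeper": [p.magsweeper_ctcs for p in pairs],
            "cellsearch": [p.cellsearch_ctcs for p in pairs],
        }
    )
    df["magsweeper_plot"] = df["magsweeper"].where(df["magsweeper"] > 0, 1)
    df["cellsearch_plot"] = df["cellsearch"].where(df["cellsearch"] > 0, 1)
    df["difference"] = df["magsweeper"] - df["cellsearch"]
    low = df[df["cellsearch"] <= low_count_max]
    summary = {
        "low_count_max": float(low_count_max),
        "n_low_count": float(len(low)),
        "mean_difference_low_count": float(low["difference"].mean()) if len(low) else float("nan"),
    }
    return df, summary


def replicate_summary(exps: Iterable[SpikeExperiment]) -> pd.DataFrame:
    """Mean +/- sample (n-1) standard deviation of efficiency, dead fraction
    and purity over replicates.  With a single replicate the sd is absent
    (NaN), matching the error-bar convention for replicate experiments.
    """
    exps = list(exps)
    if not exps:
        raise ValueError("need at least 1 replicate")
    metrics = {
        "efficiency": [capture_efficiency(e) for e in exps],
        "dead_fraction": [dead_fraction(e) for e in exps],
        "purity": [purity(e) for e in exps],
    }
    rows = {}
    for name, values in metrics.items():
        arr = np.asarray(values, dtype=float)
        rows[name] = {
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if arr.size > 1 else float("nan"),
            "n": int(arr.size),
        }
    return pd.DataFrame(rows).T
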