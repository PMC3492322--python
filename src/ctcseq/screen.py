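"""Over-expression screen, marker calls and expression-content summaries.

The screen compares circulating tumor cells (CTCs) with a normal-tissue
reference using a rank-based fold-change rule designed to be robust to
single-cell dropout and RNA degradation: for each gene the 2nd-highest FPKM
among the CTCs (so a single aberrant cell cannot drive a call) is divided
by the normal-tissue FPKM, and genes with a ratio of at least 100x that are
backed by at least 10 mapped reads in at least one CTC are selected.

Marker-based origin calling uses prostate markers (AR, KLK3, TMPRSS2) and
the pan-leukocyte marker CD45 (PTPRC): a cell is prostate-like when at
least one prostate marker exceeds 1 FPKM and CD45 does not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenConfig",
    "ScreenResult",
    "MarkerPanel",
    "overexpression_screen",
    "variable_gene_count",
    "marker_call",
    "origin_call",
    "transcript_count_summary",
    "pairwise_count_correlation",
    "round_half_up",
]


def round_half_up(x):
    """Round to nearest integer with ties away from zero-half (0.5 -> 1)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


@dataclass(frozen=True)
class ScreenConfig:
    """Parameters of the rank-based over-expression screen.

    rank
        Which order statistic of CTC FPKM forms the numerator (1 = highest;
        default 2, i.e. 2nd highest, so one aberrant cell cannot drive a call).
    ratio_threshold
        Minimal CTC/normal fold change; selection uses >= (default 100).
    min_reads
        Minimal rounded read count in at least one single CTC (default 10).
    denominator_floor
        FPKM substituted for a zero normal reference so genes absent from
        normal tissue can still pass; surfaced in the result table.
    """

    rank: int = 2
    ratio_threshold: float = 100.0
    min_reads: float = 10.0
    denominator_floor: float = 0.01

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.ratio_threshold <= 0 or self.min_reads <= 0 or self.denominator_floor <= 0:
            raise ValueError("thresholds and denominator floor must be > 0")


@dataclass(frozen=True)
class ScreenResult:
    gene: str
    ratio: float
    second_highest_fpkm: float
    normal_fpkm: float
    max_ctc_reads: float
    selected: bool


@dataclass(frozen=True)
class MarkerPanel:
    """Positive (tissue) and negative (leukocyte) marker genes with the
    positivity threshold (FPKM, strict >)."""

    positive_markers: tuple[str, ...] = ("AR", "KLK3", "TMPRSS2")
    negative_marker: str = "CD45"
    positive_threshold: float = 1.0
    strong_threshold: float = 5.0

    def __post_init__(self) -> None:
        if self.negative_marker in self.positive_markers:
            raise ValueError("positive and negative marker sets must be disjoint")


def overexpression_screen(
    ctc_fpkm: pd.DataFrame,
    ctc_counts: pd.DataFrame,
    normal_fpkm: pd.Series,
    config: ScreenConfig = ScreenConfig(),
) -> pd.DataFrame:
    """Rank-based CTC-vs-normal over-expression screen.

    Parameters
    ----------
    ctc_fpkm, ctc_counts
        Genes x CTC-sample frames with identical shape and order.
    normal_fpkm
        Normal-reference FPKM per gene (e.g. the mean over normal-tissue
        profiles), aligned to the same gene index.

    Returns
    -------
    pandas.DataFrame
        One row per gene, sorted by gene name, with columns ``ratio``,
        ``second_highest_fpkm`` (the rank-th highest CTC FPKM),
        ``normal_fpkm`` (after the zero floor), ``max_ctc_reads`` (rounded)
        and ``selected``.
    """
    if ctc_fpkm.shape[1] < config.rank:
        raise ValueError(
            f"need at least {config.rank} CTC samples, got {ctc_fpkm.shape[1]}"
        )
    if not ctc_fpkm.index.equals(ctc_counts.index) or not ctc_fpkm.columns.equals(
        ctc_counts.columns
    ):
        raise ValueError("ctc_fpkm and ctc_counts must be aligned")
    normal = normal_fpkm.reindex(ctc_fpkm.index)
    if normal.isna().any():
        raise ValueError("normal reference missing genes present in the CTC matrix")

    vals = np.sort(ctc_fpkm.to_numpy(), axis=1)  # ascending
    rank_th = vals[:, -config.rank]  # rank-th highest per gene
    denom = np.maximum(normal.to_numpy(dtype=float), config.denominator_floor)
    ratio = rank_th / denom
    max_reads = round_half_up(ctc_counts.to_numpy()).max(axis=1)
    selected = (ratio >= config.ratio_threshold) & (max_reads >= config.min_reads)

    out = pd.DataFrame(
        {
            "gene": ctc_fpkm.index,
            "ratio": ratio,
            "second_highest_fpkm": rank_th,
            "normal_fpkm": denom,
            "max_ctc_reads": max_reads,
            "selected": selected,
        }
    )
    return out.sort_values("gene", kind="stable").reset_index(drop=True)


def variable_gene_count(
    fpkm: pd.DataFrame, hi: float = 10.0, lo: float = 0.1
) -> int:
    """Count genes that are both very high and very low within a sample group.

    A gene is counted when its maximal FPKM across the given samples is
    strictly above ``hi`` and its minimal FPKM strictly below ``lo`` — a
    simple census of cell-to-cell expression heterogeneity.
    """
    if fpkm.shape[1] < 2:
        raise ValueError("variable-gene counting needs at least 2 samples")
    arr = fpkm.to_numpy()
    return int(((arr.max(axis=1) > hi) & (arr.min(axis=1) < lo)).sum())


def marker_call(fpkm_value: float, panel: MarkerPanel = MarkerPanel()) -> tuple[bool, str]:
    """Positive/negative marker call with a strength tier.

    Positive iff FPKM strictly exceeds the panel threshold (default 1);
    tier is ``strong`` above the strong threshold (default 5), ``weak`` in
    between, ``negative`` otherwise — mirroring a two-tone expression
    heatmap shading.
    """
    if fpkm_value < 0:
        raise ValueError("FPKM must be non-negative")
    positive = fpkm_value > panel.positive_threshold
    if not positive:
        return False, "negative"
    return True, ("strong" if fpkm_value > panel.strong_threshold else "weak")


def origin_call(sample_fpkm: pd.Series, panel: MarkerPanel = MarkerPanel()) -> str:
    """Tissue-of-origin call for one sample from the marker panel.

    ``leukocyte-flagged`` when the negative (leukocyte) marker is positive;
    ``prostate-like`` when at least one positive marker is positive and the
    leukocyte marker is not; ``indeterminate`` otherwise.  Panel genes
    missing from the index are treated as unexpressed (and logged).
    """
    def value(g: str) -> float:
        if g not in sample_fpkm.index:
            logger.warning("marker %s absent from sample index; treating as 0 FPKM", g)
            return 0.0
        return float(sample_fpkm[g])

    neg_positive, _ = marker_call(value(panel.negative_marker), panel)
    if neg_positive:
        return "leukocyte-flagged"
    if any(marker_call(value(g), panel)[0] for g in panel.positive_markers):
        return "prostate-like"
    return "indeterminate"


def transcript_count_summary(
    fpkm: pd.DataFrame, threshold: float = 10.0
) -> tuple[pd.Series, dict[str, float]]:
    """Per-sample counts of transcripts at or above an FPKM threshold.

    The comparison is non-strict (>= threshold).  Returns the per-sample
    counts and a summary with mean, sample (n-1) standard deviation, min
    and max.
    """
    per_sample = (fpkm >= threshold).sum(axis=0)
    per_sample.name = f"n_ge_{threshold:g}_fpkm"
    if len(per_sample) == 0:
        return per_sample, {"mean": 0.0, "sd": float("nan"), "min": 0.0, "max": 0.0}
    summary = {
        "mean": float(per_sample.mean()),
        "sd": float(per_sample.std(ddof=1)) if len(per_sample) > 1 else float("nan"),
        "min": float(per_sample.min()),
        "max": float(per_sample.max()),
    }
    return per_sample, summary


def pairwise_count_correlation(raw_counts: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between samples over per-gene raw read counts.

    Returns a symmetric samples x samples matrix with unit diagonal.
    Raises on a zero-variance sample (its correlations are undefined).
    """
    if raw_counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    variances = raw_counts.var(axis=0, ddof=0)
    dead = list(variances.index[variances == 0.0])
    if dead:
        raise ValueError(f"zero-variance samples: {dead}")
    arr = raw_counts.corr(method="pearson").to_numpy()
    np.fill_diagonal(arr, 1.0)
    return pd.DataFrame(arr, index=raw_counts.columns, columns=raw_counts.columns)
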