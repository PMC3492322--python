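"""Synthetic single-cell mRNA-Seq cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, for a cohort modeled on a single-CTC prostate-cancer study:
20 CTCs from 4 patients, 4 fresh and 4 immunomagnetically isolated
("MagSwept") LNCaP cells, 3 bulk normal-prostate profiles, and one white
blood cell.  Structure generated:

* per-gene baseline FPKM drawn log-normally (a heavy-tailed expression
  distribution), shared across groups;
* log-normal multiplicative cell-to-cell heterogeneity (natural-log sd
  ``heterogeneity_sd``) on every gene of every cell;
* a per-(gene, patient) log-normal effect on background genes of CTCs, so
  cells cluster by patient when the effect is large;
* marker genes (prostate: AR, KLK3, TMPRSS2; leukocyte: CD45) expressed
  only in their designated groups;
* planted over-expressed genes whose FPKM in a chosen number of CTCs
  exceeds the normal-prostate baseline by a stated fold;
* raw counts consistent with FPKM through gene length and a per-sample
  library size;
* per-base coverage with exponential 3'-retention decay (rate lambda per
  base) emulating degradation of oligo-dT-primed libraries;
* binomial spike-in recovery experiments for capture metrics.

Every operation draws all randomness from one generator seeded per call,
so identical configurations and seeds give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .capture import SpikeExperiment
from .coverage_qc import CoverageVector, write_bedgraph
from .quantify import ExpressionMatrix

__all__ = [
    "GroupSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_expression",
    "simulate_coverage",
    "simulate_spike",
    "write_simulation",
]

#: natural-log-scale parameters of the background baseline-FPKM distribution
BASELINE_LOG_MEAN = 0.5
BASELINE_LOG_SD = 1.5

#: FPKM baseline of planted over-expressed genes in normal prostate
PLANTED_NORMAL_BASELINE = 2.0

#: degradation-rate classes (per-base lambda) and their cohort frequencies,
#: mirroring the observed good / partially degraded / degraded RNA breakout
DEGRADATION_CLASSES = (0.0, 0.002, 0.01)
DEGRADATION_FREQS = (0.21, 0.37, 0.42)


@dataclass(frozen=True)
class GroupSpec:
    """One sample group: name, number of samples, optional patient id."""

    name: str
    n_samples: int
    patient: str | None = None


def default_groups() -> tuple[GroupSpec, ...]:
    """The emulated cohort: 20 CTCs over 4 patients, 4+4 LNCaP, 3 normal
    prostate, 1 WBC."""
    return (
        GroupSpec("ctc", 3, "P1"),
        GroupSpec("ctc", 9, "P2"),
        GroupSpec("ctc", 4, "P3"),
        GroupSpec("ctc", 4, "P4"),
        GroupSpec("lncap_fresh", 4),
        GroupSpec("lncap_magswept", 4),
        GroupSpec("normal_prostate", 3),
        GroupSpec("wbc", 1),
    )


PROSTATE_GROUPS = ("ctc", "lncap_fresh", "lncap_magswept", "normal_prostate")


def default_markers() -> dict[str, tuple[tuple[str, ...], float]]:
    """gene -> (groups expressing it, baseline FPKM).

    Prostate markers span the prostate-lineage groups; CD45 marks the WBC
    and — because bulk normal prostate contains resident leukocytes — the
    normal-tissue profiles.
    """
    return {
        "AR": (PROSTATE_GROUPS, 20.0),
        "KLK3": (PROSTATE_GROUPS, 150.0),
        "TMPRSS2": (PROSTATE_GROUPS, 40.0),
        "CD45": (("wbc", "normal_prostate"), 50.0),
    }


def default_planted() -> tuple[tuple[str, float, int], ...]:
    """(gene, fold vs normal prostate, number of CTCs expressing it):
    ten genes at fold 200 and ten below-threshold decoys at fold 50."""
    strong = tuple((f"OVEXP{i:03d}", 200.0, 3) for i in range(1, 11))
    weak = tuple((f"OVEXP{i:03d}", 50.0, 3) for i in range(11, 21))
    return strong + weak


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    heterogeneity_sd
        Natural-log sd of per-cell per-gene multiplicative noise (default
        1.0: order-of-magnitude cell-to-cell swings, as seen in single-cell
        data).
    patient_effect_sd
        Natural-log sd of the per-(gene, patient) effect applied to
        background genes of CTC samples (default 1.0).
    degradation_rates
        Optional explicit per-sample lambda (sample id -> rate).  When
        absent, CTC lambdas are drawn from the degradation classes
        according to ``degradation_mode`` and all other samples get 0.
    degradation_mode
        ``per_cell`` draws a class per CTC; ``per_patient`` draws one class
        per patient (RNA quality in patient cohorts tends to be
        patient-correlated); neither mode is canonical.
    """

    n_genes: int = 1000
    groups: Sequence[GroupSpec] = field(default_factory=default_groups)
    heterogeneity_sd: float = 1.0
    patient_effect_sd: float = 1.0
    marker_spec: Mapping[str, tuple[tuple[str, ...], float]] = field(
        default_factory=default_markers
    )
    planted_overexpression: Sequence[tuple[str, float, int]] = field(
        default_factory=default_planted
    )
    degradation_rates: Mapping[str, float] | None = None
    degradation_mode: str = "per_cell"
    read_length: int = 50
    seed: int = 0

    def validate(self) -> None:
        named = list(self.marker_spec) + [g for g, _, _ in self.planted_overexpression]
        if len(named) != len(set(named)):
            raise ValueError("duplicate gene names across markers and planted genes")
        if self.n_genes < len(named):
            raise ValueError("n_genes smaller than the number of named genes")
        for spec in self.groups:
            if spec.n_samples <= 0:
                raise ValueError(f"group {spec.name!r} has no samples")
        for gene, fold, n_ctcs in self.planted_overexpression:
            if fold <= 0:
                raise ValueError(f"planted gene {gene}: fold must be > 0")
            if n_ctcs <= 0:
                raise ValueError(f"planted gene {gene}: must be expressed in >= 1 CTC")
        if self.degradation_rates is not None:
            if any(lam < 0 for lam in self.degradation_rates.values()):
                raise ValueError("degradation rates must be >= 0")
        if self.degradation_mode not in ("per_cell", "per_patient"):
            raise ValueError("degradation_mode must be 'per_cell' or 'per_patient'")
        if self.heterogeneity_sd < 0 or self.patient_effect_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort, for downstream validation."""

    true_overexpressed: dict[str, dict]  # gene -> {fold, expressing_ctcs}
    true_markers: dict[str, tuple[str, ...]]  # gene -> groups
    true_lambda: dict[str, float]  # sample -> degradation rate
    true_cluster_labels: dict[str, str]  # CTC sample -> patient

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "true_overexpressed": self.true_overexpressed,
            "true_markers": {g: list(v) for g, v in self.true_markers.items()},
            "true_lambda": self.true_lambda,
            "true_cluster_labels": self.true_cluster_labels,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GroundTruth":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            true_overexpressed=payload["true_overexpressed"],
            true_markers={g: tuple(v) for g, v in payload["true_markers"].items()},
            true_lambda=payload["true_lambda"],
            true_cluster_labels=payload["true_cluster_labels"],
        )


def _sample_table(groups: Sequence[GroupSpec]) -> pd.DataFrame:
    """Sample ids, group and patient labels for the configured groups."""
    rows = []
    counters: dict[str, int] = {}
    for spec in groups:
        for _ in range(spec.n_samples):
            key = spec.patient or spec.name
            counters[key] = counters.get(key, 0) + 1
            if spec.patient is not None:
                sid = f"{spec.patient}.{counters[key]}"
            else:
                sid = f"{spec.name}.{counters[key]}"
            rows.append({"sample_id": sid, "group": spec.name, "patient": spec.patient or ""})
    df = pd.DataFrame(rows).set_index("sample_id")
    if df.index.has_duplicates:
        raise ValueError("duplicate sample ids generated from group specification")
    return df


def _draw_lambdas(
    config: SimulationConfig, meta: pd.DataFrame, rng: np.random.Generator
) -> dict[str, float]:
    if config.degradation_rates is not None:
        return {s: float(config.degradation_rates.get(s, 0.0)) for s in meta.index}
    lam: dict[str, float] = {}
    classes = np.asarray(DEGRADATION_CLASSES)
    if config.degradation_mode == "per_patient":
        patients = sorted({p for p in meta["patient"] if p})
        per_patient = {
            p: float(rng.choice(classes, p=DEGRADATION_FREQS)) for p in patients
        }
        for s in meta.index:
            group, patient = meta.loc[s, "group"], meta.loc[s, "patient"]
            lam[s] = per_patient[patient] if group == "ctc" else 0.0
    else:
        for s in meta.index:
            lam[s] = (
                float(rng.choice(classes, p=DEGRADATION_FREQS))
                if meta.loc[s, "group"] == "ctc"
                else 0.0
            )
    return lam


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate an FPKM/count matrix with planted markers, over-expressed
    genes and patient structure, plus the ground truth behind it.

    FPKM values are log-normal around group baselines; raw counts are
    ``FPKM * (length/1000) * (library_size/1e6)`` with a per-sample library
    size, kept as reals (integerized only where a read threshold applies
    downstream).  Identical configs and seeds give identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    meta = _sample_table(config.groups)
    n_samples = len(meta)

    marker_genes = list(config.marker_spec)
    planted_genes = [g for g, _, _ in config.planted_overexpression]
    n_background = config.n_genes - len(marker_genes) - len(planted_genes)
    background_genes = [f"G{i:05d}" for i in range(1, n_background + 1)]
    genes = marker_genes + planted_genes + background_genes
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene names in simulated gene set")

    lengths = rng.integers(500, 5001, size=config.n_genes)
    library_size = rng.integers(1_000_000, 3_000_001, size=n_samples)
    baseline = np.exp(rng.normal(BASELINE_LOG_MEAN, BASELINE_LOG_SD, size=config.n_genes))
    noise = np.exp(rng.normal(0.0, config.heterogeneity_sd, size=(config.n_genes, n_samples)))

    groups = meta["group"].to_numpy()
    patients = meta["patient"].to_numpy()
    is_ctc = groups == "ctc"
    ctc_ids = list(meta.index[is_ctc])

    fpkm = baseline[:, None] * noise

    # per-(gene, patient) effect on background genes of CTC cells
    unique_patients = sorted({p for p in patients[is_ctc] if p})
    if unique_patients and config.patient_effect_sd > 0:
        effect = np.exp(
            rng.normal(0.0, config.patient_effect_sd,
                       size=(config.n_genes, len(unique_patients)))
        )
        p_index = {p: j for j, p in enumerate(unique_patients)}
        bg_slice = slice(len(marker_genes) + len(planted_genes), config.n_genes)
        for i, sample in enumerate(meta.index):
            if is_ctc[i]:
                fpkm[bg_slice, i] *= effect[bg_slice, p_index[patients[i]]]

    # markers: expressed only in their groups, at their stated baseline
    true_markers: dict[str, tuple[str, ...]] = {}
    for row, gene in enumerate(marker_genes):
        mgroups, mbaseline = config.marker_spec[gene]
        in_group = np.isin(groups, list(mgroups))
        fpkm[row, :] = np.where(in_group, mbaseline * noise[row, :], 0.0)
        true_markers[gene] = tuple(mgroups)

    # planted over-expression: baseline everywhere, fold x baseline in the
    # chosen CTCs
    true_overexpressed: dict[str, dict] = {}
    for k, (gene, fold, n_ctcs) in enumerate(config.planted_overexpression):
        row = len(marker_genes) + k
        if n_ctcs > len(ctc_ids):
            raise ValueError(f"planted gene {gene}: {n_ctcs} expressing CTCs "
                             f"but only {len(ctc_ids)} CTC samples")
        chosen = sorted(rng.choice(ctc_ids, size=n_ctcs, replace=False).tolist())
        fpkm[row, :] = PLANTED_NORMAL_BASELINE * noise[row, :]
        for sample in chosen:
            i = meta.index.get_loc(sample)
            fpkm[row, i] = fold * PLANTED_NORMAL_BASELINE * noise[row, i]
        true_overexpressed[gene] = {"fold": float(fold), "expressing_ctcs": chosen}

    counts = fpkm * (lengths[:, None] / 1000.0) * (library_size[None, :] / 1e6)

    meta = meta.assign(
        read_length=config.read_length,
        mapped_fragments=library_size,
    )
    matrix = ExpressionMatrix(
        fpkm=pd.DataFrame(fpkm, index=genes, columns=meta.index),
        counts=pd.DataFrame(counts, index=genes, columns=meta.index),
        sample_meta=meta,
    )
    truth = GroundTruth(
        true_overexpressed=true_overexpressed,
        true_markers=true_markers,
        true_lambda=_draw_lambdas(config, meta, rng),
        true_cluster_labels={s: meta.loc[s, "patient"] for s in ctc_ids},
    )
    return matrix, truth


def simulate_coverage(
    transcript_length: int,
    n_fragments: int,
    lam: float,
    read_length: int = 50,
    seed: int | np.random.Generator = 0,
    transcript_id: str = "tx",
) -> CoverageVector:
    """Per-base coverage of one transcript under 3'-biased degradation.

    Each fragment's 3'-end is placed at distance ``d`` from the transcript
    3' end with probability proportional to ``exp(-lam * d)`` (uniform when
    ``lam = 0``, up to edge effects), and the fragment covers the
    ``read_length`` bases 5' of that point.  Models oligo-dT-primed
    libraries, where degraded molecules retain only their 3' portion.
    """
    if transcript_length <= 0 or n_fragments <= 0:
        raise ValueError("transcript_length and n_fragments must be > 0")
    if transcript_length <= read_length:
        raise ValueError("transcript_length must exceed read_length")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    max_d = transcript_length - read_length  # 3'-end distance keeping the read on-transcript
    d_values = np.arange(max_d + 1)
    weights = np.exp(-lam * d_values)
    probs = weights / weights.sum()
    d = rng.choice(d_values, size=n_fragments, p=probs)

    # fragment covers [L-1-d-read_length+1, L-1-d]
    starts = transcript_length - d - read_length
    depth = np.zeros(transcript_length + 1)
    np.add.at(depth, starts, 1.0)
    np.add.at(depth, starts + read_length, -1.0)
    depth = np.cumsum(depth[:-1])
    return CoverageVector(transcript_id=transcript_id, depth=depth)


def simulate_spike(
    n_spiked: int,
    p_capture_live: float,
    dead_fraction_in: float,
    n_wbc_carryover: float,
    seed: int | np.random.Generator = 0,
    replicate_id: str = "",
) -> SpikeExperiment:
    """One spike-in recovery experiment.

    The spike splits binomially into live and dead cells
    (``dead_fraction_in``); each class is recovered binomially with
    ``p_capture_live`` (immunomagnetic capture targets a surface epitope
    and is indifferent to viability); contaminating leukocytes are drawn
    Poisson with mean ``n_wbc_carryover`` (the binomial limit for a large
    leukocyte pool at a small carryover probability).
    """
    if not (0.0 <= p_capture_live <= 1.0 and 0.0 <= dead_fraction_in <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    if n_spiked <= 0:
        raise ValueError("n_spiked must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_dead_in = int(rng.binomial(n_spiked, dead_fraction_in))
    n_live_in = n_spiked - n_dead_in
    return SpikeExperiment(
        n_spiked=n_spiked,
        recovered_live=int(rng.binomial(n_live_in, p_capture_live)),
        recovered_dead=int(rng.binomial(n_dead_in, p_capture_live)),
        wbc_contaminating=int(rng.poisson(n_wbc_carryover)),
        replicate_id=replicate_id,
    )


def write_simulation(
    matrix: ExpressionMatrix,
    truth: GroundTruth,
    out_dir: str | Path,
    *,
    n_coverage_transcripts: int = 0,
    transcript_length: int = 1000,
    n_fragments: int = 200,
    coverage_seed: int = 0,
) -> None:
    """Write a simulated cohort to disk: ``fpkm.tsv``, ``counts.tsv``,
    ``samples.tsv``, ``truth.yaml`` and (optionally) per-sample bedGraph
    coverage for ``n_coverage_transcripts`` panel transcripts drawn at each
    sample's true degradation rate."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix.to_dir(out)
    truth.to_yaml(out / "truth.yaml")
    if n_coverage_transcripts > 0:
        covdir = out / "coverage"
        covdir.mkdir(exist_ok=True)
        rng = np.random.default_rng(coverage_seed)
        read_length = int(matrix.sample_meta["read_length"].iloc[0])
        for sample in matrix.sample_ids:
            lam = truth.true_lambda.get(sample, 0.0)
            covs = [
                simulate_coverage(
                    transcript_length, n_fragments, lam, read_length,
                    seed=rng, transcript_id=f"QC{t:04d}",
                )
                for t in range(n_coverage_transcripts)
            ]
            write_bedgraph(covs, covdir / f"{sample}.bedgraph")
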