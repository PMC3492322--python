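"""Gene-level quantification from transcript-level abundance records.

Upstream isoform quantification (e.g. a cufflinks ``isoform.fpkm_tracking``
table) reports, per transcript, a length, a mean per-base coverage, and an
FPKM.  Gene-level values are obtained by grouping transcripts that share a
gene name and taking

* raw count  = sum over transcripts of ``coverage * length / read_length``
* gene FPKM  = sum over transcripts of the transcript FPKM

Raw counts are kept as reals; the coverage-based formula is non-integer by
construction.  They are rounded (half-up) only where a read-count threshold
is applied downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "TranscriptQuant",
    "ExpressionMatrix",
    "gene_raw_count",
    "gene_fpkm",
    "build_matrix",
    "read_fpkm_tracking",
]

#: required columns of the tab-separated isoform tracking dialect
TRACKING_COLUMNS = {
    "tracking_id": "transcript_id",
    "gene_short_name": "gene_name",
    "length": "length",
    "coverage": "coverage",
    "FPKM": "fpkm",
}


@dataclass(frozen=True)
class TranscriptQuant:
    """One transcript's quantification record.

    Parameters
    ----------
    transcript_id : str
        Transcript accession (unique within a sample).
    gene_name : str
        Gene symbol the transcript belongs to; gene identity is keyed by
        this name.
    length : int
        Transcript length in bases (> 0).
    coverage : float
        Mean per-base coverage (x units, >= 0).
    fpkm : float
        Fragments per kilobase of exon per million mapped fragments (>= 0).
    """

    transcript_id: str
    gene_name: str
    length: int
    coverage: float
    fpkm: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"transcript {self.transcript_id}: length must be > 0")
        if self.coverage < 0 or self.fpkm < 0:
            raise ValueError(f"transcript {self.transcript_id}: negative abundance")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression container with FPKM and raw-count layers.

    Attributes
    ----------
    fpkm, counts : pandas.DataFrame
        Same shape, same gene (row) and sample (column) order.  Counts are
        non-negative reals.
    sample_meta : pandas.DataFrame
        Indexed by sample id; carries at least ``group``, ``patient`` and
        ``read_length`` columns (``mapped_fragments`` when known).
    """

    fpkm: pd.DataFrame
    counts: pd.DataFrame
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not self.fpkm.index.equals(self.counts.index) or not self.fpkm.columns.equals(
            self.counts.columns
        ):
            raise ValueError("fpkm and counts must share index and columns")
        if self.fpkm.index.has_duplicates:
            raise ValueError("duplicate gene names in matrix")
        if self.fpkm.columns.has_duplicates:
            raise ValueError("duplicate sample ids in matrix")
        # normalize axis names so written-then-read matrices compare equal
        for frame in (self.fpkm, self.counts):
            frame.index.name = None
            frame.columns.name = None
        if len(self.sample_meta) and not self.sample_meta.index.equals(self.fpkm.columns):
            self.sample_meta = self.sample_meta.reindex(self.fpkm.columns)

    @property
    def gene_names(self) -> list[str]:
        return list(self.fpkm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fpkm.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.sample_meta.index[self.sample_meta["group"] == group])

    # ------------------------------------------------------------------ I/O

    def to_dir(self, out_dir: str | Path) -> None:
        """Write ``fpkm.tsv``, ``counts.tsv`` and ``samples.tsv`` into a directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.fpkm.to_csv(out / "fpkm.tsv", sep="\t", index_label="gene")
        self.counts.to_csv(out / "counts.tsv", sep="\t", index_label="gene")
        self.sample_meta.to_csv(out / "samples.tsv", sep="\t", index_label="sample_id")

    @classmethod
    def from_dir(cls, in_dir: str | Path) -> "ExpressionMatrix":
        src = Path(in_dir)
        fpkm = pd.read_csv(src / "fpkm.tsv", sep="\t", index_col="gene")
        counts = pd.read_csv(src / "counts.tsv", sep="\t", index_col="gene")
        meta_path = src / "samples.tsv"
        meta = (
            pd.read_csv(meta_path, sep="\t", index_col="sample_id")
            if meta_path.exists()
            else pd.DataFrame(index=fpkm.columns)
        )
        return cls(fpkm=fpkm, counts=counts, sample_meta=meta)


def gene_raw_count(transcripts: Iterable[TranscriptQuant], read_length: float) -> float:
    """Gene-level raw fragment count from member transcripts.

    Sums ``coverage * length / read_length`` over the transcripts of one
    gene.  An empty transcript list yields 0 (unexpressed gene).
    """
    if read_length <= 0:
        raise ValueError("read_length must be > 0")
    return sum(t.coverage * t.length / read_length for t in transcripts)


def gene_fpkm(transcripts: Iterable[TranscriptQuant]) -> float:
    """Gene-level FPKM: the sum of member-transcript FPKMs.

    Raises if the records span more than one gene name.
    """
    transcripts = list(transcripts)
    names = {t.gene_name for t in transcripts}
    if len(names) > 1:
        raise ValueError(f"transcripts span multiple genes: {sorted(names)}")
    return sum(t.fpkm for t in transcripts)


def build_matrix(
    per_sample_tables: Mapping[str, Iterable[TranscriptQuant]],
    meta: pd.DataFrame,
) -> ExpressionMatrix:
    """Assemble an :class:`ExpressionMatrix` from per-sample transcript tables.

    The gene set is the union of gene names over all samples; gene-sample
    pairs absent from a sample's table are 0 in both layers (the upstream
    quantifier omits unexpressed transcripts).  ``meta`` must be indexed by
    sample id and provide a ``read_length`` column for every sample.
    """
    missing = [s for s in per_sample_tables if s not in meta.index]
    if missing:
        raise KeyError(f"samples absent from metadata: {missing}")

    fpkm_cols: dict[str, dict[str, float]] = {}
    count_cols: dict[str, dict[str, float]] = {}
    for sample, table in per_sample_tables.items():
        table = list(table)
        seen_tx = [t.transcript_id for t in table]
        if len(seen_tx) != len(set(seen_tx)):
            raise ValueError(f"duplicate transcript_id in sample {sample!r}")
        read_length = float(meta.loc[sample, "read_length"])
        by_gene: dict[str, list[TranscriptQuant]] = {}
        for t in table:
            by_gene.setdefault(t.gene_name, []).append(t)
        fpkm_cols[sample] = {g: gene_fpkm(ts) for g, ts in by_gene.items()}
        count_cols[sample] = {g: gene_raw_count(ts, read_length) for g, ts in by_gene.items()}

    samples = list(per_sample_tables)
    genes = sorted({g for col in fpkm_cols.values() for g in col})
    fpkm = pd.DataFrame(
        {s: [fpkm_cols[s].get(g, 0.0) for g in genes] for s in samples}, index=genes
    )
    counts = pd.DataFrame(
        {s: [count_cols[s].get(g, 0.0) for g in genes] for s in samples}, index=genes
    )
    return ExpressionMatrix(fpkm=fpkm, counts=counts, sample_meta=meta.loc[samples].copy())


def read_fpkm_tracking(path: str | Path) -> list[TranscriptQuant]:
    """Read a tab-separated isoform tracking table into transcript records.

    Requires a header with columns ``tracking_id``, ``gene_short_name``,
    ``length``, ``coverage`` and ``FPKM``; extra columns are ignored.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(TRACKING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return [
        TranscriptQuant(
            transcript_id=str(row.tracking_id),
            gene_name=str(row.gene_short_name),
            length=int(row.length),
            coverage=float(row.coverage),
            fpkm=float(row.FPKM),
        )
        for row in df.itertuples(index=False)
    ]
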