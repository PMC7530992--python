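"""Readers, writers and validated containers for every external format the
pipeline touches.

All expression values are FPKM (fragments per kilobase of transcript per
million mapped reads), stored as a genes x samples :class:`pandas.DataFrame`
with a sample -> developmental-stage mapping drawn from a controlled stage
vocabulary. Sequences are handled in the DNA alphabet (U -> T) and genomic
intervals follow the BED convention (0-based, half-open).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

#: Controlled vocabulary of developmental stages, in temporal order.
STAGE_VOCABULARY = (
    "GV",
    "MII",
    "zygote",
    "2-cell",
    "4-cell",
    "8-cell",
    "morula",
    "blastocyst",
)

#: Allowed sample treatments.
TREATMENTS = ("none", "alpha-amanitin", "verteporfin")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ValidationError(ValueError):
    """An input file violated a structural invariant of the pipeline."""


@dataclass
class StageExpressionMatrix:
    """Genes x samples FPKM matrix with per-sample stage labels.

    Parameters
    ----------
    values
        Non-negative FPKM, index = unique gene ids, columns = sample names.
    sample_to_stage
        Maps every sample (column) to a stage in :data:`STAGE_VOCABULARY`.
    sample_meta
        Optional per-sample attributes (patient id, genotype, treatment).
    """

    values: pd.DataFrame
    sample_to_stage: dict[str, str]
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        for sample in self.values.columns:
            if sample not in self.sample_to_stage:
                raise ValidationError(f"sample without stage label: {sample!r}")
        for sample, stage in self.sample_to_stage.items():
            if stage not in STAGE_VOCABULARY:
                raise ValidationError(
                    f"unknown stage {stage!r} for sample {sample!r}; "
                    f"expected one of {STAGE_VOCABULARY}"
                )
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression matrix contains non-numeric values")
        bad = ~np.isfinite(arr) | (arr < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"negative or non-finite FPKM at gene {idx[i]!r}, "
                f"sample {self.values.columns[j]!r}: {arr[i, j]}"
            )
        if self.sample_meta is not None:
            treatments = self.sample_meta.get("treatment")
            if treatments is not None:
                unknown = set(treatments) - set(TREATMENTS)
                if unknown:
                    raise ValidationError(f"unknown treatment(s): {sorted(unknown)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def stages(self) -> list[str]:
        """Stages present, in vocabulary (temporal) order."""
        present = set(self.sample_to_stage.values())
        return [s for s in STAGE_VOCABULARY if s in present]

    def samples_of_stage(self, stage: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_to_stage[s] == stage]

    def stage_mean(self, stage: str) -> pd.Series:
        """Arithmetic mean FPKM across the replicates of one stage."""
        cols = self.samples_of_stage(stage)
        if not cols:
            raise ValidationError(f"stage {stage!r} absent from matrix")
        return self.values[cols].mean(axis=1)

    def treatment_of(self, sample: str) -> str:
        if self.sample_meta is None or "treatment" not in self.sample_meta:
            return "none"
        return str(self.sample_meta.loc[sample, "treatment"])


@dataclass
class QPCRTable:
    """Cycle-threshold values per (gene, sample) with a reference gene."""

    ct: pd.DataFrame
    reference_gene: str
    replicate_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reference_gene not in self.ct.index:
            raise ValidationError(
                f"reference gene {self.reference_gene!r} absent from Ct table"
            )
        ref = self.ct.loc[self.reference_gene]
        if ref.isna().any():
            sample = ref.index[ref.isna()][0]
            raise ValidationError(
                f"reference gene {self.reference_gene!r} has no Ct in sample {sample!r}"
            )
        arr = self.ct.to_numpy(dtype=float)
        finite = np.isfinite(arr) | np.isnan(arr)
        if not finite.all():
            raise ValidationError("Ct table contains non-finite values")


@dataclass
class UTRAnnotation:
    """Per-gene 3'-UTR genomic intervals, BED convention (0-based half-open)."""

    intervals: pd.DataFrame  # columns: chrom, start, end, gene, strand
    source_genome_id: str = ""

    def __post_init__(self) -> None:
        bad = self.intervals["start"] >= self.intervals["end"]
        if bad.any():
            row = self.intervals[bad].iloc[0]
            raise ValidationError(
                f"empty/inverted interval for gene {row['gene']!r}: "
                f"{row['chrom']}:{row['start']}-{row['end']}"
            )
        unknown = ~self.intervals["strand"].isin(["+", "-"])
        if unknown.any():
            raise ValidationError(
                f"strand must be '+' or '-', got {self.intervals['strand'][unknown].iloc[0]!r}"
            )


def read_expression_matrix(
    path: str | Path, stage_map: Mapping[str, str], sample_meta: pd.DataFrame | None = None
) -> StageExpressionMatrix:
    """Parse a tab-separated FPKM matrix (first column gene ids, header row
    sample names) and validate it against ``stage_map``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                gene = df.index[bad][0]
                raise ValidationError(
                    f"non-numeric value {df.loc[gene, col]!r} at gene {gene!r}, sample {col!r}"
                )
            df[col] = coerced
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise ValidationError(f"missing expression value for gene {gene!r}")
    return StageExpressionMatrix(df, dict(stage_map), sample_meta)


def normalize_sequence(seq: str) -> str:
    """Upper-case, map RNA to DNA (U -> T), and check the IUPAC alphabet.

    Only {A, C, G, T, N} survive; anything else is rejected.
    """
    s = seq.upper().replace("U", "T")
    extra = set(s) - set("ACGTN")
    if extra:
        raise ValidationError(f"sequence contains non-IUPAC characters: {sorted(extra)}")
    return s


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_utr_sequences(
    fasta_path: str | Path,
    bed_path: str | Path | None = None,
    keep: str = "longest",
) -> dict[str, str]:
    """Load 3'-UTR sequences keyed by gene id.

    Two modes:

    * ``bed_path is None`` — ``fasta_path`` is a FASTA of UTR sequences keyed
      by gene id.
    * ``bed_path`` given — ``fasta_path`` is a genome FASTA and the BED6 file
      supplies per-gene UTR intervals; minus-strand intervals are
      reverse-complemented so every returned sequence reads 5'->3' of the
      transcript.

    When a gene has several annotated UTRs the longest is kept (``keep``
    currently admits only ``"longest"``).
    """
    if keep != "longest":
        raise ValueError("only keep='longest' is supported")
    sequences: dict[str, str] = {}
    if bed_path is None:
        for record in SeqIO.parse(str(fasta_path), "fasta"):
            seq = normalize_sequence(str(record.seq))
            gene = record.id
            if gene not in sequences or len(seq) > len(sequences[gene]):
                sequences[gene] = seq
        return sequences

    from pyfaidx import Fasta

    genome = Fasta(str(fasta_path))
    bed = pd.read_csv(
        bed_path,
        sep="\t",
        header=None,
        comment="#",
        usecols=range(6),
        names=["chrom", "start", "end", "gene", "score", "strand"],
    )
    UTRAnnotation(bed[["chrom", "start", "end", "gene", "strand"]])  # validates
    for row in bed.itertuples(index=False):
        if row.chrom not in genome:
            raise ValidationError(f"BED chromosome {row.chrom!r} absent from genome")
        chrom_len = len(genome[row.chrom])
        if row.end > chrom_len:
            raise ValidationError(
                f"interval {row.chrom}:{row.start}-{row.end} exceeds chromosome "
                f"length {chrom_len}"
            )
        seq = normalize_sequence(str(genome[row.chrom][row.start : row.end]))
        if row.strand == "-":
            seq = reverse_complement(seq)
        if row.gene not in sequences or len(seq) > len(sequences[row.gene]):
            sequences[row.gene] = seq
    return sequences


def read_ct_table(
    path: str | Path,
    reference_gene: str,
    replicate_groups: Mapping[str, str] | None = None,
    undetermined: str = "error",
    ceiling_ct: float = 40.0,
) -> QPCRTable:
    """Parse a tab-separated Ct table (genes x samples).

    Non-numeric entries such as ``Undetermined`` raise by default;
    ``undetermined="ceiling"`` imputes them at ``ceiling_ct`` (default 40),
    the conventional detection limit of a 40-cycle run.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            if undetermined == "ceiling":
                coerced[bad] = ceiling_ct
            else:
                gene = df.index[bad][0]
                raise ValidationError(
                    f"undetermined Ct for gene {gene!r}, sample {col!r} "
                    f"(pass undetermined='ceiling' to impute Ct={ceiling_ct})"
                )
        df[col] = coerced
    return QPCRTable(df.astype(float), reference_gene, dict(replicate_groups or {}))


# ---------------------------------------------------------------------------
# Result writers (round-trip stable)

def write_classification(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-gene decay classification table as TSV."""
    table.to_csv(path, sep="\t", index_label="gene")


def read_classification(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    df.index = df.index.astype(str)
    return df


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
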