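"""3'-UTR length and CPE/PAS motif features, compared between decay classes.

The cytoplasmic polyadenylation element (CPE, consensus UUUUAU / UUUUAAU)
and the polyadenylation signal (PAS, AAUAAA / AUUAAA) are scanned as exact
DNA-alphabet matches (U -> T). Matching is strand-specific and counts every
start position, so overlapping occurrences all count.

M-decay transcripts are Cluster I, Z-decay transcripts Cluster II.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Exact-match motif sets, DNA alphabet.
CPE_MOTIFS = ("TTTTAT", "TTTTAAT")
PAS_MOTIFS = ("AATAAA", "ATTAAA")

FEATURES = ("length", "cpe_count", "pas_count")


@dataclass
class ClassComparison:
    """Two-group feature comparison in figure-legend form."""

    feature: str
    groups: tuple[str, str]
    n: dict[str, int]
    mean: dict[str, float]
    sem: dict[str, float]
    median: dict[str, float]
    quantiles: dict[str, dict[str, float]]  # keys "2.5", "25", "75", "97.5"
    t_statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")


def count_motifs(sequence: str, motif_set: tuple[str, ...]) -> int:
    """Number of start positions where any motif matches exactly.

    Overlapping occurrences are all counted; a position matching several
    motif variants counts once per variant. ``N`` never matches.
    """
    if not motif_set:
        raise ValueError("empty motif set")
    total = 0
    for motif in motif_set:
        k = len(motif)
        total += sum(
            1 for i in range(len(sequence) - k + 1) if sequence[i : i + k] == motif
        )
    return total


def annotate_utrs(
    sequences: dict[str, str],
    classification,
    clusters: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Join UTR features onto the decay classification.

    Returns ``(records, report)``: records has one row per classified gene
    with a UTR (columns gene, cluster, length, cpe_count, pas_count);
    the report counts genes without a UTR, zero-length UTRs (both excluded)
    and UTRs for genes absent from the classification (kept aside).
    """
    table = classification.table if hasattr(classification, "table") else classification
    rows = []
    missing_utr = []
    zero_length = []
    for gene in table.index:
        seq = sequences.get(gene)
        if seq is None:
            missing_utr.append(gene)
            continue
        if len(seq) == 0:
            zero_length.append(gene)
            continue
        rows.append(
            {
                "gene": gene,
                "cluster": table.loc[gene, "cluster"],
                "length": len(seq),
                "cpe_count": count_motifs(seq, CPE_MOTIFS),
                "pas_count": count_motifs(seq, PAS_MOTIFS),
            }
        )
    records = pd.DataFrame(
        rows, columns=["gene", "cluster", "length", "cpe_count", "pas_count"]
    ).set_index("gene")
    if clusters is not None:
        records = records[records["cluster"].isin(clusters)]
    unmatched = sorted(set(sequences) - set(table.index))
    report = {
        "n_annotated": len(records),
        "n_without_utr": len(missing_utr),
        "n_zero_length": len(zero_length),
        "n_unmatched_utrs": len(unmatched),
        "unmatched_utrs": unmatched,
    }
    return records, report


_QUANT_KEYS = {"2.5": 0.025, "25": 0.25, "75": 0.75, "97.5": 0.975}


def compare_classes(
    records: pd.DataFrame,
    feature: str,
    groups: tuple[str, str] = ("I", "II"),
    welch: bool = False,
) -> ClassComparison:
    """Two-sample two-tailed t-test on a UTR feature between two clusters.

    Student's pooled-variance test by default; ``welch=True`` drops the
    equal-variance assumption. Summary statistics follow box-plot
    conventions (median, quartiles, 2.5/97.5 percentile whiskers).
    """
    if feature not in FEATURES:
        raise ValueError(f"feature must be one of {FEATURES}")
    a = records.loc[records["cluster"] == groups[0], feature].to_numpy(dtype=float)
    b = records.loc[records["cluster"] == groups[1], feature].to_numpy(dtype=float)
    for name, arr in zip(groups, (a, b)):
        if len(arr) < 2:
            raise ValueError(f"group {name!r} has n < 2")
    if a.std() == 0 and b.std() == 0 and np.allclose(a.mean(), b.mean()):
        t, p = 0.0, 1.0  # identical degenerate groups: no difference
    else:
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return ClassComparison(
        feature=feature,
        groups=groups,
        n={g: len(arr) for g, arr in zip(groups, (a, b))},
        mean={g: float(arr.mean()) for g, arr in zip(groups, (a, b))},
        sem={g: float(stats.sem(arr)) for g, arr in zip(groups, (a, b))},
        median={g: float(np.median(arr)) for g, arr in zip(groups, (a, b))},
        quantiles={
            g: {k: float(np.quantile(arr, q)) for k, q in _QUANT_KEYS.items()}
            for g, arr in zip(groups, (a, b))
        },
        t_statistic=float(t),
        p_value=float(p),
    )
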