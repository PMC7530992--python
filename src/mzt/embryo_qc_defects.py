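"""Single-embryo transcriptome QC and decay-defect diagnosis.

Concordance of individual embryo transcriptomes is assessed with Pearson
correlation and PCA on log2(FPKM + 1); fold-change tables against reference
embryos use pseudocounted mean ratios; set overlaps are scored with an
upper-tail hypergeometric test; and two decay-defect callers diagnose
failure of the maternal (M-) or zygotic (Z-) clearance pathway:

* M-decay defect — a marker panel (six maternal transcripts in the default
  design) is compared between a test patient's arrested zygotes and control
  zygotes; a marker counts as accumulated when its mean fold change exceeds
  1 and a one-way ANOVA across the groups is significant; the defect is
  called when at least 4 of the 6 detected markers accumulate.
* Z-decay defect — transcripts degraded 2-fold during the normal
  zygote-to-8-cell transition but stable in an arrested 8-cell embryo
  (Group A) are tested for enrichment among that embryo's stabilized
  transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFECT_CALLS = ("M_DECAY_DEFECT", "Z_DECAY_DEFECT", "NO_DEFECT", "INDETERMINATE")


@dataclass
class OverlapResult:
    """Hypergeometric enrichment of |A ∩ B| inside a finite universe."""

    n_a: int
    n_b: int
    n_overlap: int
    universe_size: int
    p_value: float
    fold_enrichment: float

    def __post_init__(self) -> None:
        if self.n_overlap > min(self.n_a, self.n_b):
            raise ValueError("overlap exceeds set sizes")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class DefectCall:
    subject_id: str
    call: str
    evidence: dict = field(default_factory=dict)
    group_a: list[str] = field(default_factory=list)
    group_b: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.call not in DEFECT_CALLS:
            raise ValueError(f"unknown call {self.call!r}")

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "call": self.call,
            "evidence": self.evidence,
            "group_a": self.group_a,
            "group_b": self.group_b,
        }


def _log2p1(df: pd.DataFrame) -> pd.DataFrame:
    return np.log2(df + 1.0)


def pairwise_correlation(
    profiles: pd.DataFrame, groups: Mapping[str, str] | None = None
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Pearson correlation between embryo profiles on log2(FPKM + 1).

    ``profiles`` is genes x embryos. Returns the full correlation matrix and
    the mean off-diagonal r within each group (all samples form one group
    when ``groups`` is None). Zero-variance profiles yield NaN for their
    pairs and are excluded from group means.
    """
    if profiles.shape[1] < 2:
        raise ValueError("need at least two profiles")
    log = _log2p1(profiles)
    corr = log.corr(method="pearson")  # pandas leaves NaN for zero variance
    if groups is None:
        groups = {s: "all" for s in profiles.columns}
    means: dict[str, float] = {}
    for group in sorted(set(groups.values())):
        members = [s for s in profiles.columns if groups[s] == group]
        vals = []
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                vals.append(corr.loc[a, b])
        finite = [v for v in vals if not np.isnan(v)]
        means[group] = float(np.mean(finite)) if finite else float("nan")
    return corr, means


def pca(
    profiles: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of embryo profiles with R ``prcomp`` conventions.

    Observations are embryos (columns of ``profiles``), features are genes
    on log2(FPKM + 1), centered per gene and not scaled. Each component's
    loading vector is oriented so its largest-magnitude entry is positive.
    Returns (coordinates: embryos x PCs, explained variance per PC).
    """
    n_samples = profiles.shape[1]
    max_rank = min(n_samples - 1, profiles.shape[0])
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds rank bound {max_rank}"
        )
    X = _log2p1(profiles).to_numpy().T  # samples x genes
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic orientation: largest-|loading| entry of each PC positive
    for k in range(len(s)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]
    coords = U * s
    explained = s**2 / (n_samples - 1)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(coords[:, :n_components], index=profiles.columns, columns=cols),
        explained[:n_components],
    )


def fold_changes(
    test_profiles: pd.DataFrame,
    ref_profiles: pd.DataFrame,
    thresholds: Sequence[float] = (2.0, 5.0),
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Pseudocounted fold-change table of test vs reference embryo means.

    ratio = (mean FPKM_test + 1)/(mean FPKM_ref + 1); per threshold t a gene
    is labeled "up" iff ratio > t and "down" iff ratio < 1/t. Returns a
    genes-indexed frame with ``ratio``, ``log2_ratio`` and one ``label_<t>x``
    column per threshold.
    """
    if ref_profiles.shape[1] == 0:
        raise ValueError("empty reference set")
    if test_profiles.shape[1] == 0:
        raise ValueError("empty test set")
    genes = test_profiles.index
    if not genes.equals(ref_profiles.index):
        raise ValueError("test and reference profiles must share the gene universe")
    ratio = (test_profiles.mean(axis=1) + pseudocount) / (
        ref_profiles.mean(axis=1) + pseudocount
    )
    out = pd.DataFrame({"ratio": ratio, "log2_ratio": np.log2(ratio)})
    for t in thresholds:
        label = np.where(ratio > t, "up", np.where(ratio < 1.0 / t, "down", ""))
        out[f"label_{t:g}x"] = label
    return out


def fold_change_counts(table: pd.DataFrame) -> dict[str, dict[str, int]]:
    """Up/down gene counts per threshold of a fold-change table."""
    counts = {}
    for col in table.columns:
        if col.startswith("label_"):
            counts[col.removeprefix("label_")] = {
                "up": int((table[col] == "up").sum()),
                "down": int((table[col] == "down").sum()),
            }
    return counts


def overlap_enrichment(
    set_a: set | Sequence, set_b: set | Sequence, universe: set | Sequence
) -> OverlapResult:
    """Upper-tail hypergeometric probability of the observed overlap.

    P(X >= |A ∩ B|) where X counts elements of A in a size-|B| draw without
    replacement from the universe.
    """
    universe = set(universe)
    a, b = set(set_a), set(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("A and B must be subsets of the universe")
    k = len(a & b)
    M, n, N = len(universe), len(a), len(b)
    p = float(stats.hypergeom.sf(k - 1, M, n, N))
    expected = n * N / M if M else float("nan")
    fold = k / expected if expected else float("inf") if k else float("nan")
    return OverlapResult(n, N, k, M, min(p, 1.0), float(fold))


def _one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA robust to zero within-group variance.

    All-identical data give F = 0, p = 1; nonzero between-group with zero
    within-group variance gives F = inf, p = 0.
    """
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = sum(len(g) for g in groups) - len(groups)
    if df_within <= 0 or df_between <= 0:
        raise ValueError("degenerate group sizes for ANOVA")
    if ss_within == 0.0:
        return (0.0, 1.0) if ss_between == 0.0 else (float("inf"), 0.0)
    F = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(F, df_between, df_within))
    return float(F), p


def call_m_decay_defect(
    marker_levels: pd.DataFrame,
    groups: Mapping[str, str],
    test_group: str = "test",
    control_group: str = "control",
    k: int = 4,
    n: int = 6,
    alpha: float = 0.05,
    fold_threshold: float = 1.0,
    subject_id: str = "",
) -> DefectCall:
    """k-of-n marker rule for maternal-decay failure.

    ``marker_levels`` is markers x samples (relative expression levels);
    ``groups`` maps each sample to a group label. A marker is "accumulated"
    when its test/control mean fold change exceeds ``fold_threshold`` and a
    one-way ANOVA across the two groups is significant at ``alpha``.
    M_DECAY_DEFECT requires accumulation of at least ``k`` of the ``n``
    detected markers; with fewer than ``n`` markers detected the threshold
    scales proportionally, and fewer than 4 detected markers is
    INDETERMINATE.
    """
    test_cols = [s for s in marker_levels.columns if groups[s] == test_group]
    ctrl_cols = [s for s in marker_levels.columns if groups[s] == control_group]
    if len(test_cols) < 3 or len(ctrl_cols) < 3:
        raise ValueError("need >= 3 replicates per group")
    detected = marker_levels.index[(marker_levels > 0).any(axis=1)]
    evidence = {}
    n_accumulated = 0
    for marker in detected:
        tv = marker_levels.loc[marker, test_cols].to_numpy(dtype=float)
        cv = marker_levels.loc[marker, ctrl_cols].to_numpy(dtype=float)
        fold = tv.mean() / cv.mean() if cv.mean() > 0 else float("inf")
        F, p = _one_way_anova([tv, cv])
        accumulated = bool(fold > fold_threshold and p < alpha)
        n_accumulated += accumulated
        evidence[str(marker)] = {
            "fold_change": float(fold),
            "anova_F": F,
            "anova_p": p,
            "accumulated": accumulated,
        }
    n_detected = len(detected)
    if n_detected < 4:
        call = "INDETERMINATE"
    else:
        k_required = k if n_detected >= n else int(np.ceil(k * n_detected / n))
        call = "M_DECAY_DEFECT" if n_accumulated >= k_required else "NO_DEFECT"
    return DefectCall(
        subject_id=subject_id,
        call=call,
        evidence={
            "markers": evidence,
            "n_detected": n_detected,
            "n_accumulated": n_accumulated,
            "k": k,
            "n": n,
            "alpha": alpha,
        },
    )


def call_z_decay_groups(
    normal_zygote: pd.Series,
    normal_8cell: pd.Series,
    arrested_8cell: pd.Series,
    margin: float = 1.0,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    subject_id: str = "",
) -> tuple[list[str], list[str], DefectCall]:
    """Partition transcripts into Group A / Group B and call a Z-decay defect.

    Inputs are mean FPKM per gene for normal zygotes, normal 8-cell embryos
    and the arrested 8-cell embryo(s); E = log2(mean + 1).

    Group A: degraded >2-fold zygote -> 8-cell in normal embryos
    (E_norm(zyg) > E_norm(8c) + margin) but stable in the arrested embryo
    (E_arr(8c) >= E_norm(zyg) - margin). Group B: zygotically increased
    >2-fold in normal embryos but not in the arrested embryo.

    A Z-decay defect is called when the normally-degraded set is enriched
    (hypergeometric, at ``alpha``) among the embryo's stabilized
    transcripts — genes accumulated above normal 8-cell levels
    (E_arr(8c) > E_norm(8c) + margin), mirroring the Venn overlap of
    up-regulated arrested transcripts with normally-degraded transcripts.
    """
    for name, s in (
        ("normal_zygote", normal_zygote),
        ("normal_8cell", normal_8cell),
        ("arrested_8cell", arrested_8cell),
    ):
        if s is None or len(s) == 0:
            raise ValueError(f"missing condition: {name}")
    genes = normal_zygote.index
    e_zy = np.log2(normal_zygote + pseudocount)
    e_8c = np.log2(normal_8cell.reindex(genes) + pseudocount)
    e_arr = np.log2(arrested_8cell.reindex(genes) + pseudocount)

    degraded_normal = e_zy > e_8c + margin
    stable_in_arrested = e_arr >= e_zy - margin
    group_a = genes[degraded_normal & stable_in_arrested]
    group_b = genes[(e_8c > e_zy + margin) & (e_arr <= e_zy + margin)]

    accumulated = e_arr > e_8c + margin
    enrich = overlap_enrichment(
        set(genes[degraded_normal]), set(genes[accumulated]), set(genes)
    )
    call = "Z_DECAY_DEFECT" if enrich.p_value < alpha and len(group_a) else "NO_DEFECT"
    defect = DefectCall(
        subject_id=subject_id,
        call=call,
        evidence={
            "n_group_a": len(group_a),
            "n_group_b": len(group_b),
            "n_degraded_normal": int(degraded_normal.sum()),
            "n_accumulated": int(accumulated.sum()),
            "enrichment_p": enrich.p_value,
            "fold_enrichment": enrich.fold_enrichment,
            "alpha": alpha,
        },
        group_a=list(group_a),
        group_b=list(group_b),
    )
    return list(group_a), list(group_b), defect


def concordant_subset(
    profiles: pd.DataFrame, r_min: float = 0.7
) -> tuple[list[str], float]:
    """Largest embryo subset whose mean pairwise r reaches ``r_min``.

    Greedy heuristic: repeatedly drop the embryo with the lowest mean
    correlation to the rest until the subset's mean pairwise r >= r_min or
    only two embryos remain. Returns (kept embryos, their mean pairwise r).
    """
    corr, _ = pairwise_correlation(profiles)
    kept = list(profiles.columns)

    def mean_r(members: list[str]) -> float:
        sub = corr.loc[members, members].to_numpy()
        off = sub[np.triu_indices(len(members), k=1)]
        return float(np.nanmean(off))

    while len(kept) > 2 and mean_r(kept) < r_min:
        per_sample = {
            s: np.nanmean([corr.loc[s, o] for o in kept if o != s]) for s in kept
        }
        kept.remove(min(per_sample, key=per_sample.get))
    return kept, mean_r(kept)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional multiple-testing correction)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(p_values, method="fdr_bh")[1]
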