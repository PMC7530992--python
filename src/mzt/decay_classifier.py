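"""Maternal-transcript selection and decay-cluster classification.

Maternal transcripts (mean GV FPKM strictly above a threshold, default 2)
are partitioned by their log2(FPKM + 1) profiles E(stage) across the
GV -> zygote -> 8-cell triplet, using a 2-fold margin m (1.0 in log2 space):

* Cluster I   (M-decay):      E(GV) > E(zyg)+m  and  E(zyg) <= E(8c)+m
* Cluster II  (Z-decay):      |E(GV)-E(zyg)| within m  and  E(zyg) > E(8c)+m
* Cluster III (both phases):  E(GV) > E(zyg)+m  and  E(zyg) > E(8c)+m
* Cluster IV  (stable):       both transitions within the margin

Genes matching no formula (e.g. zygotically up-regulated maternal genes)
are UNCLASSIFIED; the four cluster predicates are mutually exclusive by
construction. Cluster IV genes may additionally be flagged as degraded
between the 8-cell and morula stages, and Cluster II/III genes are tested
for dependence of their decay on zygotic genome activation (ZGA) by
comparing control embryos with alpha-amanitin-treated embryos in which
RNA-polymerase-II transcription is blocked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import StageExpressionMatrix, ValidationError

CLUSTERS = ("I", "II", "III", "IV")
M_DECAY_CLUSTER = "I"
Z_DECAY_CLUSTER = "II"


@dataclass
class ClassifierConfig:
    """Thresholds of the decay classifier.

    maternal_fpkm_threshold
        Minimum (strict) mean GV FPKM for a gene to count as maternal.
    log_margin
        Fold-change margin m on the log2 scale; 1.0 means 2-fold.
    pseudocount
        Added to mean FPKM before the log2 transform.
    stage_triplet
        (early, mid, late) stages of the clustering; the human convention is
        (GV, zygote, 8-cell), the mouse convention (GV, zygote, 2-cell).
    decay_ratio_threshold
        Pre-selection for ZGA analysis: control pseudocounted
        FPKM(post)/FPKM(zygote) must fall below this (default 0.5 = 2-fold).
    stabilization_margin
        A transcription-blocked drop below this (log2) counts as stabilized.
    post_zga_stage
        Stage compared against the zygote in the alpha-amanitin analysis.
    ratio_orientation
        "post/zygote" (default, select ratio < threshold) or "zygote/post"
        (select ratio > threshold).
    """

    maternal_fpkm_threshold: float = 2.0
    log_margin: float = 1.0
    pseudocount: float = 1.0
    stage_triplet: tuple[str, str, str] = ("GV", "zygote", "8-cell")
    decay_ratio_threshold: float = 0.5
    stabilization_margin: float = 1.0
    post_zga_stage: str = "8-cell"
    ratio_orientation: str = "post/zygote"
    morula_stage: str = "morula"

    def __post_init__(self) -> None:
        for name in (
            "maternal_fpkm_threshold",
            "log_margin",
            "pseudocount",
            "decay_ratio_threshold",
            "stabilization_margin",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.ratio_orientation not in ("post/zygote", "zygote/post"):
            raise ValueError("ratio_orientation must be 'post/zygote' or 'zygote/post'")


@dataclass
class DecayClassification:
    """Per-gene cluster label, stage E values, and tri-state flags.

    ``table`` columns: ``cluster`` in {I, II, III, IV, UNCLASSIFIED,
    NOT_MATERNAL}; one ``E_<stage>`` column per stage used;
    ``zga_dependent`` and ``morula_degraded`` tri-states.
    """

    table: pd.DataFrame
    config: ClassifierConfig = field(default_factory=ClassifierConfig)

    def genes_in(self, *clusters: str) -> pd.Index:
        return self.table.index[self.table["cluster"].isin(clusters)]

    def counts(self) -> dict[str, int]:
        return self.table["cluster"].value_counts().to_dict()


def log_transform(
    matrix: StageExpressionMatrix,
    pseudocount: float = 1.0,
    stages: Sequence[str] | None = None,
) -> pd.DataFrame:
    """E(stage) = log2(mean FPKM(stage) + pseudocount), genes x stages.

    Replicates within a stage are averaged (arithmetic mean of FPKM) before
    the transform.
    """
    stages = list(stages) if stages is not None else matrix.stages
    cols = {stage: np.log2(matrix.stage_mean(stage) + pseudocount) for stage in stages}
    return pd.DataFrame(cols, index=matrix.gene_ids)


def select_maternal(matrix: StageExpressionMatrix, threshold: float = 2.0) -> pd.Index:
    """Genes with mean GV FPKM strictly greater than ``threshold``."""
    gv = matrix.stage_mean("GV")
    return matrix.gene_ids[gv.to_numpy() > threshold]


def _cluster_predicates(
    gv: np.ndarray, zy: np.ndarray, late: np.ndarray, m: float
) -> dict[str, np.ndarray]:
    """The four cluster membership predicates on E-value triples.

    Inequalities are exactly as strict/non-strict as the selection rules
    demand, so boundary genes classify deterministically.
    """
    return {
        "I": (gv > zy + m) & (zy <= late + m),
        "II": (gv <= zy + m) & (gv > zy - m) & (zy > late + m),
        "III": (gv > zy + m) & (zy > late + m),
        "IV": (gv <= zy + m) & (gv > zy - m) & (zy <= late + m) & (zy > late - m),
    }


def classify_decay(
    matrix: StageExpressionMatrix, config: ClassifierConfig | None = None
) -> DecayClassification:
    """Assign every gene to exactly one of I/II/III/IV/UNCLASSIFIED/NOT_MATERNAL."""
    config = config or ClassifierConfig()
    early, mid, late_stage = config.stage_triplet
    for stage in config.stage_triplet:
        if stage not in matrix.stages:
            raise ValidationError(f"required stage {stage!r} absent from matrix")
    if early != "GV":
        raise ValidationError("maternal selection requires the GV stage first in the triplet")

    E = log_transform(matrix, config.pseudocount, config.stage_triplet)
    maternal = select_maternal(matrix, config.maternal_fpkm_threshold)
    is_maternal = matrix.gene_ids.isin(maternal)

    gv = E[early].to_numpy()
    zy = E[mid].to_numpy()
    late = E[late_stage].to_numpy()
    preds = _cluster_predicates(gv, zy, late, config.log_margin)

    cluster = np.full(len(E), "UNCLASSIFIED", dtype=object)
    for name in CLUSTERS:
        cluster[preds[name] & (cluster == "UNCLASSIFIED")] = name
    cluster[~is_maternal] = "NOT_MATERNAL"

    table = E.rename(columns={s: f"E_{s}" for s in E.columns})
    table.insert(0, "cluster", cluster)
    table["zga_dependent"] = "not_applicable"
    table["morula_degraded"] = "not_applicable"
    return DecayClassification(table, config)


def classify_morula_extension(
    matrix: StageExpressionMatrix,
    classification: DecayClassification,
    config: ClassifierConfig | None = None,
) -> DecayClassification:
    """Flag Cluster IV genes degraded between the 8-cell and morula stages.

    Uses the same 2-fold rule as the main clustering:
    degraded iff E(8-cell) > E(morula) + log_margin. When the morula stage
    is absent, every gene stays ``not_applicable``.
    """
    config = config or classification.config
    table = classification.table.copy()
    if config.morula_stage not in matrix.stages:
        table["morula_degraded"] = "not_applicable"
        return DecayClassification(table, config)
    late_stage = config.stage_triplet[2]
    E = log_transform(matrix, config.pseudocount, [late_stage, config.morula_stage])
    iv = table["cluster"] == "IV"
    degraded = E[late_stage] > E[config.morula_stage] + config.log_margin
    table.loc[iv, "morula_degraded"] = np.where(degraded[iv], "degraded", "stable")
    table.loc[~iv, "morula_degraded"] = "not_applicable"
    if f"E_{config.morula_stage}" not in table.columns:
        table[f"E_{config.morula_stage}"] = E[config.morula_stage]
    return DecayClassification(table, config)


def zga_dependence(
    control: StageExpressionMatrix,
    treated: StageExpressionMatrix,
    classification: DecayClassification,
    config: ClassifierConfig | None = None,
) -> DecayClassification:
    """Call ZGA-dependent vs -independent decay for Cluster II/III genes.

    Pre-selection (control matrix): pseudocounted
    (FPKM(post) + 1)/(FPKM(zygote) + 1) < ``decay_ratio_threshold`` — i.e.
    the transcript actually decays at least 2-fold after the zygote stage.
    A selected gene is ``dependent`` iff blocking transcription abolishes
    the drop (treated E(zyg) - E(post) < stabilization_margin) while the
    control drop is >= the margin; otherwise ``independent``.
    """
    config = config or classification.config
    mid = config.stage_triplet[1]
    post = config.post_zga_stage
    for mat, name in ((control, "control"), (treated, "treated")):
        for stage in (mid, post):
            if stage not in mat.stages:
                raise ValidationError(f"{name} matrix lacks stage {stage!r}")
    treated_flags = {
        treated.treatment_of(s) for s in treated.values.columns
    }
    if "alpha-amanitin" not in treated_flags:
        raise ValidationError(
            "treated matrix has no samples flagged treatment='alpha-amanitin'"
        )

    pc = config.pseudocount
    c_zy = control.stage_mean(mid)
    c_post = control.stage_mean(post)
    ratio = (c_post + pc) / (c_zy + pc)
    if config.ratio_orientation == "post/zygote":
        selected = ratio < config.decay_ratio_threshold
    else:
        selected = (1.0 / ratio) > config.decay_ratio_threshold

    E_c = log_transform(control, pc, [mid, post])
    E_t = log_transform(treated, pc, [mid, post])
    control_drop = E_c[mid] - E_c[post]
    treated_drop = E_t[mid] - E_t[post]

    table = classification.table.copy()
    eligible = table["cluster"].isin([Z_DECAY_CLUSTER, "III"])
    table["zga_dependent"] = "not_applicable"
    idx = table.index[eligible & selected.reindex(table.index, fill_value=False)]
    dep = (treated_drop.loc[idx] < config.stabilization_margin) & (
        control_drop.loc[idx] >= config.stabilization_margin
    )
    table.loc[idx, "zga_dependent"] = np.where(dep, "dependent", "independent")
    return DecayClassification(table, config)
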