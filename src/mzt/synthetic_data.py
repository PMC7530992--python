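"""Synthetic datasets with planted ground truth for every pipeline input.

Every generator draws from a single :class:`numpy.random.Generator` seeded
explicitly, emits a truth record alongside the data, and is fully
deterministic under (seed, parameters).

The expression model is a log-normal baseline at the GV stage with
deterministic per-cluster fold drops at the planted transitions and
multiplicative log-normal noise (additive Gaussian on the log2 scale,
sigma = ``noise_sd``). Baselines of maternal-class genes are floored so
that, at noise 0, every planted decay transition clears the classifier's
2-fold margin and every maternal gene clears the GV FPKM > 2 selection —
planted truth is then recovered exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import StageExpressionMatrix
from .utr_features import CPE_MOTIFS, PAS_MOTIFS, count_motifs

#: Planted class labels and the classifier call each one should map to.
EXPECTED_CALL = {
    "I": "I",
    "II": "II",
    "III": "III",
    "IV": "IV",
    "up-regulated": "UNCLASSIFIED",
    "not-maternal": "NOT_MATERNAL",
}

#: Default class proportions: the four published cluster sizes
#: (2372, 2259, 1109, 1531) over the 7271 selected maternal genes.
DEFAULT_PROPORTIONS = {
    "I": 2372 / 7271,
    "II": 2259 / 7271,
    "III": 1109 / 7271,
    "IV": 1531 / 7271,
    "up-regulated": 0.0,
    "not-maternal": 0.0,
}

#: Fraction of stable (Cluster IV) transcripts degraded by the morula stage
#: (176 of 1531 in the published profiles).
DEFAULT_MORULA_FRACTION = 176 / 1531

M_DECAY_MARKERS = tuple(f"MDECAY_MARKER_{i}" for i in range(1, 7))
MACHINERY_GENES = ("BTG4", "CNOT7", "CNOT6L")


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted next to every generated dataset."""

    genes: pd.DataFrame
    params: dict = field(default_factory=dict)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _maternal_floor(decay_fold: float, maternal_threshold: float = 2.0) -> float:
    # cluster III decays twice from the baseline; its second transition
    # starts at B/d and must still clear the 2-fold log margin, which
    # requires B/d > d/(d-2); 5% safety keeps boundaries strict.
    if decay_fold <= 2.0:
        raise ValueError("decay_fold must exceed 2 to clear the 2-fold rule")
    return 1.05 * max(maternal_threshold, decay_fold**2 / (decay_fold - 2.0))


def _planted_profiles(
    classes: np.ndarray,
    baseline: np.ndarray,
    decay_fold: float,
    morula_degraded: np.ndarray,
) -> pd.DataFrame:
    """Noise-free FPKM per stage implied by the planted class labels."""
    d = decay_fold
    n = len(classes)
    gv = baseline.copy()
    zy = np.empty(n)
    ec = np.empty(n)
    mo = np.empty(n)
    for cls, (fz, fe, fm) in {
        "I": (1 / d, 1 / d, 1 / d),
        "II": (1.0, 1 / d, 1 / d),
        "III": (1 / d, 1 / d**2, 1 / d**2),
        "IV": (1.0, 1.0, 1.0),
        "up-regulated": (d, d, d),
        "not-maternal": (1.0, 1.0, 1.0),
    }.items():
        mask = classes == cls
        zy[mask] = baseline[mask] * fz
        ec[mask] = baseline[mask] * fe
        mo[mask] = baseline[mask] * fm
    mo[(classes == "IV") & morula_degraded] = baseline[
        (classes == "IV") & morula_degraded
    ] / d
    return pd.DataFrame(
        {"GV": gv, "zygote": zy, "8-cell": ec, "morula": mo}
    )


def _noisy_matrix(
    profiles: pd.DataFrame,
    gene_ids: Sequence[str],
    stages: Sequence[str],
    n_replicates: int,
    noise_sd: float,
    rng: np.random.Generator,
    treatment: str = "none",
) -> StageExpressionMatrix:
    cols = {}
    stage_map = {}
    meta_rows = {}
    for stage in stages:
        base = profiles[stage].to_numpy()
        for r in range(1, n_replicates + 1):
            name = f"{stage}_rep{r}"
            noise = rng.normal(0.0, noise_sd, size=len(base)) if noise_sd > 0 else 0.0
            cols[name] = base * 2.0**noise
            stage_map[name] = stage
            meta_rows[name] = {"treatment": treatment}
    values = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene"))
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    return StageExpressionMatrix(values, stage_map, meta)


def generate_stage_matrix(
    n_genes: int = 7271,
    class_proportions: Mapping[str, float] | None = None,
    baseline_log2_mean: float = 5.0,
    baseline_log2_sd: float = 1.5,
    decay_fold: float = 4.0,
    noise_sd: float = 0.25,
    n_replicates: int = 2,
    morula_degraded_fraction: float = DEFAULT_MORULA_FRACTION,
    maternal_threshold: float = 2.0,
    stages: Sequence[str] = ("GV", "zygote", "8-cell", "morula"),
    seed: int = 0,
) -> tuple[StageExpressionMatrix, SyntheticTruth]:
    """Stage-wise FPKM matrix with planted decay clusters.

    Class labels are drawn i.i.d. from ``class_proportions`` (defaults to
    the published cluster fractions); each gene gets a log-normal GV
    baseline (floored for maternal classes, see module docstring), the
    deterministic per-cluster fold drops, and per-sample multiplicative
    noise. Planted Cluster IV genes lose their transcript after the 8-cell
    stage with probability ``morula_degraded_fraction``.
    """
    props = dict(DEFAULT_PROPORTIONS)
    if class_proportions is not None:
        props = {k: 0.0 for k in DEFAULT_PROPORTIONS}
        props.update(class_proportions)
    total = sum(props.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class proportions sum to {total}, expected 1")

    rng = _rng(seed)
    names = list(props)
    classes = rng.choice(names, size=n_genes, p=[props[k] for k in names])
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]

    baseline = 2.0 ** rng.normal(baseline_log2_mean, baseline_log2_sd, size=n_genes)
    floor = _maternal_floor(decay_fold, maternal_threshold)
    maternal = classes != "not-maternal"
    baseline[maternal] = np.maximum(baseline[maternal], floor)
    # non-maternal genes sit strictly below the selection threshold
    baseline[~maternal] = rng.uniform(0.0, maternal_threshold, size=(~maternal).sum())

    morula_degraded = np.zeros(n_genes, dtype=bool)
    iv = classes == "IV"
    morula_degraded[iv] = rng.random(iv.sum()) < morula_degraded_fraction

    profiles = _planted_profiles(classes, baseline, decay_fold, morula_degraded)
    matrix = _noisy_matrix(profiles, gene_ids, stages, n_replicates, noise_sd, rng)

    truth_genes = pd.DataFrame(
        {
            "cluster": classes,
            "expected_call": [EXPECTED_CALL[c] for c in classes],
            "morula_degraded": morula_degraded,
            "baseline_fpkm": baseline,
            **{f"fpkm_{s}": profiles[s].to_numpy() for s in profiles.columns},
        },
        index=pd.Index(gene_ids, name="gene"),
    )
    params = {
        "n_genes": n_genes,
        "class_proportions": props,
        "baseline_log2_mean": baseline_log2_mean,
        "baseline_log2_sd": baseline_log2_sd,
        "decay_fold": decay_fold,
        "noise_sd": noise_sd,
        "n_replicates": n_replicates,
        "morula_degraded_fraction": morula_degraded_fraction,
        "seed": seed,
    }
    return matrix, SyntheticTruth(truth_genes, params)


def generate_amanitin_pair(
    truth: SyntheticTruth,
    zga_dependent_fraction: float = 0.9,
    noise_sd: float | None = None,
    n_replicates: int | None = None,
    seed: int = 0,
) -> tuple[StageExpressionMatrix, StageExpressionMatrix, SyntheticTruth]:
    """Control vs alpha-amanitin-treated matrices over the zygote and
    8-cell stages.

    Planted ZGA-dependent Cluster II/III genes lose their post-zygote drop
    in the treated matrix (transcription block abolishes Z-decay);
    ZGA-independent genes decay identically in both. The returned truth
    carries a tri-state ``zga_dependent`` column.
    """
    rng = _rng(seed)
    genes = truth.genes
    noise_sd = truth.params["noise_sd"] if noise_sd is None else noise_sd
    n_replicates = (
        truth.params.get("n_replicates", 2) if n_replicates is None else n_replicates
    )
    eligible = genes["cluster"].isin(["II", "III"]).to_numpy()
    dependent = np.zeros(len(genes), dtype=bool)
    dependent[eligible] = rng.random(eligible.sum()) < zga_dependent_fraction

    control_profiles = genes[["fpkm_zygote", "fpkm_8-cell"]].rename(
        columns={"fpkm_zygote": "zygote", "fpkm_8-cell": "8-cell"}
    )
    treated_profiles = control_profiles.copy()
    treated_profiles.loc[dependent, "8-cell"] = control_profiles.loc[
        dependent, "zygote"
    ]

    stages = ("zygote", "8-cell")
    control = _noisy_matrix(
        control_profiles, genes.index, stages, n_replicates, noise_sd, rng
    )
    treated = _noisy_matrix(
        treated_profiles,
        genes.index,
        stages,
        n_replicates,
        noise_sd,
        rng,
        treatment="alpha-amanitin",
    )
    out_genes = genes.copy()
    out_genes["zga_dependent"] = np.where(
        eligible, np.where(dependent, "dependent", "independent"), "not_applicable"
    )
    params = dict(truth.params)
    params.update(
        {"zga_dependent_fraction": zga_dependent_fraction, "amanitin_seed": seed}
    )
    return control, treated, SyntheticTruth(out_genes, params)


#: Per-class UTR design: mean length (nt) and expected planted motif counts
#: per UTR. Z-decay (Cluster II) UTRs are twice as long and carry twice the
#: motif load of M-decay (Cluster I) UTRs.
DEFAULT_UTR_DESIGN = {
    "I": {"mean_length": 500, "cpe_rate": 1.0, "pas_rate": 1.0},
    "II": {"mean_length": 1000, "cpe_rate": 2.0, "pas_rate": 2.0},
    "default": {"mean_length": 500, "cpe_rate": 1.0, "pas_rate": 1.0},
}


def _plant_motifs(
    seq: list[str], motifs: tuple[str, ...], n: int, occupied: list[tuple[int, int]],
    rng: np.random.Generator,
) -> list[int]:
    """Insert ``n`` motif copies at random non-overlapping positions."""
    positions = []
    length = len(seq)
    for _ in range(n):
        for _attempt in range(200):
            motif = motifs[rng.integers(len(motifs))]
            if length < len(motif):
                break
            start = int(rng.integers(0, length - len(motif) + 1))
            span = (start, start + len(motif))
            if all(span[1] <= a or span[0] >= b for a, b in occupied):
                seq[span[0] : span[1]] = list(motif)
                occupied.append(span)
                positions.append(start)
                break
    return positions


def generate_utrs(
    classification: pd.DataFrame | SyntheticTruth,
    design: Mapping[str, Mapping[str, float]] | None = None,
    min_length: int = 50,
    length_log2_sd: float = 0.5,
    seed: int = 0,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Synthetic 3'-UTRs with class-dependent lengths and motif densities.

    Background is uniform ACGT; CPE/PAS copies (Poisson counts with the
    class rate) are planted at recorded non-overlapping positions. Because
    random background can itself spell a motif, the truth records the
    post-hoc scanned count as authoritative alongside the planted count.
    """
    table = classification.genes if isinstance(classification, SyntheticTruth) else classification
    design = dict(DEFAULT_UTR_DESIGN) | dict(design or {})
    rng = _rng(seed)
    sequences: dict[str, str] = {}
    rows = []
    for gene in table.index:
        cls = str(table.loc[gene, "cluster"])
        d = design.get(cls, design["default"])
        length = max(
            min_length,
            int(round(d["mean_length"] * 2.0 ** rng.normal(0.0, length_log2_sd))),
        )
        seq = list(rng.choice(list("ACGT"), size=length))
        occupied: list[tuple[int, int]] = []
        cpe_pos = _plant_motifs(
            seq, CPE_MOTIFS, rng.poisson(d["cpe_rate"]), occupied, rng
        )
        pas_pos = _plant_motifs(
            seq, PAS_MOTIFS, rng.poisson(d["pas_rate"]), occupied, rng
        )
        s = "".join(seq)
        sequences[gene] = s
        rows.append(
            {
                "gene": gene,
                "cluster": cls,
                "length": length,
                "planted_cpe": len(cpe_pos),
                "planted_pas": len(pas_pos),
                "cpe_count": count_motifs(s, CPE_MOTIFS),
                "pas_count": count_motifs(s, PAS_MOTIFS),
                "cpe_positions": ",".join(map(str, sorted(cpe_pos))),
                "pas_positions": ",".join(map(str, sorted(pas_pos))),
            }
        )
    truth = pd.DataFrame(rows).set_index("gene")
    return sequences, SyntheticTruth(truth, {"design": {k: dict(v) for k, v in design.items()}, "seed": seed})


@dataclass
class ArrestedCohort:
    """Simulated arrested-embryo cohort with planted defect labels.

    ``marker_tables[embryo]`` is a markers x samples relative-level table
    (three test and three control replicates) for the M-decay qPCR panel
    plus the decay-machinery genes; ``groups`` maps its columns to
    test/control. Genome-wide arrested 8-cell profiles and the matching
    normal references support the Z-decay caller.
    """

    truth: pd.DataFrame
    marker_tables: dict[str, pd.DataFrame]
    groups: dict[str, str]
    profiles: pd.DataFrame
    normal_zygote: pd.Series
    normal_8cell: pd.Series
    gene_truth: pd.DataFrame
    params: dict


def generate_arrested_cohort(
    n_embryos: int = 200,
    defect_spec: Mapping[str, float] | None = None,
    n_genes: int = 1000,
    defect_fold: float = 4.0,
    noise_sd: float = 0.25,
    baseline_log2_mean: float = 5.0,
    baseline_log2_sd: float = 1.0,
    seed: int = 0,
) -> ArrestedCohort:
    """Cohort of arrested embryos with planted M- or Z-decay failure.

    ``defect_spec`` gives label proportions over {none, m_decay, z_decay}
    (default: half none, half m_decay). Defective embryos stabilize the
    planted decay-target transcript set at ``defect_fold`` above control
    and down-shift the decay-machinery genes (BTG4/CNOT7/CNOT6L-like) by
    the same fold; non-defective embryos match controls up to noise.
    """
    spec = dict(defect_spec or {"none": 0.5, "m_decay": 0.5})
    if abs(sum(spec.values()) - 1.0) > 1e-9:
        raise ValueError("defect_spec proportions must sum to 1")
    rng = _rng(seed)
    labels = rng.choice(list(spec), size=n_embryos, p=list(spec.values()))
    embryo_ids = [f"E{i:03d}" for i in range(n_embryos)]

    # gene universe for the Z-decay route: 30% M-decay targets, 30% Z-decay
    # targets, 20% zygotically activated, 20% stable
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    kinds = np.array(
        ["m_target"] * (3 * n_genes // 10)
        + ["z_target"] * (3 * n_genes // 10)
        + ["zga"] * (2 * n_genes // 10)
        + ["stable"] * (n_genes - 3 * n_genes // 10 - 3 * n_genes // 10 - 2 * n_genes // 10)
    )
    base = 2.0 ** rng.normal(baseline_log2_mean, baseline_log2_sd, size=n_genes)
    base = np.maximum(base, _maternal_floor(defect_fold))
    d = defect_fold
    norm_zy = np.where(kinds == "m_target", base / d, np.where(kinds == "zga", base / d**2, base))
    norm_8c = np.where(
        kinds == "z_target",
        base / d,
        np.where(kinds == "m_target", base / d, np.where(kinds == "zga", base, base)),
    )

    def noisy(vec: np.ndarray) -> np.ndarray:
        if noise_sd == 0:
            return vec.copy()
        return vec * 2.0 ** rng.normal(0.0, noise_sd, size=len(vec))

    marker_tables: dict[str, pd.DataFrame] = {}
    profile_cols: dict[str, np.ndarray] = {}
    test_cols = [f"test_rep{i}" for i in (1, 2, 3)]
    ctrl_cols = [f"control_rep{i}" for i in (1, 2, 3)]
    groups = {**{c: "test" for c in test_cols}, **{c: "control" for c in ctrl_cols}}
    panel = list(M_DECAY_MARKERS) + list(MACHINERY_GENES)

    for embryo, label in zip(embryo_ids, labels):
        marker_level = d if label == "m_decay" else 1.0
        machinery_level = 1.0 / d if label == "m_decay" else 1.0
        planted = np.array(
            [marker_level] * len(M_DECAY_MARKERS) + [machinery_level] * len(MACHINERY_GENES)
        )
        data = {c: noisy(planted) for c in test_cols}
        data.update({c: noisy(np.ones(len(panel))) for c in ctrl_cols})
        marker_tables[embryo] = pd.DataFrame(data, index=panel)

        arrested = norm_8c.copy()
        if label == "m_decay":
            arrested = np.where(kinds == "m_target", base, arrested)
        elif label == "z_decay":
            arrested = np.where(kinds == "z_target", base, arrested)
            arrested = np.where(kinds == "zga", base / d**2, arrested)
        profile_cols[embryo] = noisy(arrested)

    cohort_truth = pd.DataFrame(
        {"defect": labels}, index=pd.Index(embryo_ids, name="embryo")
    )
    gene_truth = pd.DataFrame(
        {
            "kind": kinds,
            "baseline_fpkm": base,
            "normal_zygote_fpkm": norm_zy,
            "normal_8cell_fpkm": norm_8c,
        },
        index=pd.Index(gene_ids, name="gene"),
    )
    return ArrestedCohort(
        truth=cohort_truth,
        marker_tables=marker_tables,
        groups=groups,
        profiles=pd.DataFrame(profile_cols, index=pd.Index(gene_ids, name="gene")),
        normal_zygote=pd.Series(norm_zy, index=gene_ids),
        normal_8cell=pd.Series(norm_8c, index=gene_ids),
        gene_truth=gene_truth,
        params={
            "n_embryos": n_embryos,
            "defect_spec": spec,
            "n_genes": n_genes,
            "defect_fold": defect_fold,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )


def generate_ct_table(
    relative_levels: pd.DataFrame,
    ref_ct: float = 20.0,
    noise_sd: float = 0.0,
    reference_gene: str = "GAPDH",
    replicate_groups: Mapping[str, str] | None = None,
    seed: int = 0,
):
    """Invert relative levels into a Ct table: Ct = ref_ct - log2(level).

    At ``noise_sd`` 0 the table round-trips exactly through
    :func:`mzt.qpcr.relative_expression`. The reference gene row is pinned
    at ``ref_ct`` in every sample.
    """
    from .io_formats import QPCRTable

    rng = _rng(seed)
    if (relative_levels <= 0).any().any():
        raise ValueError("relative levels must be positive")
    ct = ref_ct - np.log2(relative_levels)
    if noise_sd > 0:
        ct = ct + rng.normal(0.0, noise_sd, size=ct.shape)
    ct.loc[reference_gene] = ref_ct
    return QPCRTable(ct, reference_gene, dict(replicate_groups or {}))
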