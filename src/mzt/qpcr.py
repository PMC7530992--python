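"""Relative qPCR quantification (2^dCt against a reference gene) and group
comparison by t-test or one-way ANOVA.

Technical replicates are averaged on the Ct scale before exponentiation;
biological replicates are averaged on the linear (relative-level) scale.
The default sign convention is level = 2^(Ct_ref - Ct_gene), so one cycle
earlier means roughly 2-fold more template; the literal reading
2^(Ct_gene - Ct_ref) is available as ``convention="literal"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .embryo_qc_defects import _one_way_anova
from .io_formats import QPCRTable


@dataclass
class RelativeLevels:
    """Per-(gene, sample) relative expression with group summaries."""

    levels: pd.DataFrame  # genes x samples, reference gene row == 1
    reference_gene: str
    group_means: pd.DataFrame | None = None
    group_sems: pd.DataFrame | None = None
    fold_vs_control: pd.DataFrame | None = None
    convention: str = "reference_minus_gene"


def relative_expression(
    table: QPCRTable,
    technical_replicates: Mapping[str, Sequence[str]] | None = None,
    convention: str = "reference_minus_gene",
    control_group: str | None = None,
) -> RelativeLevels:
    """Compute 2^dCt relative levels normalized to the reference gene.

    ``technical_replicates`` maps a biological sample name to the Ct columns
    that are technical triplicates of it; those are averaged on the Ct scale
    first. When the table carries ``replicate_groups`` the group means/SEMs
    (linear scale) and fold changes vs ``control_group`` are attached.
    """
    if convention not in ("reference_minus_gene", "literal"):
        raise ValueError("convention must be 'reference_minus_gene' or 'literal'")
    ct = table.ct
    if technical_replicates:
        ct = pd.DataFrame(
            {bio: ct[list(cols)].mean(axis=1) for bio, cols in technical_replicates.items()}
        )
    ref = ct.loc[table.reference_gene]
    if ref.isna().any():
        sample = ref.index[ref.isna()][0]
        raise ValueError(f"missing reference Ct in sample {sample!r}")
    if convention == "reference_minus_gene":
        levels = 2.0 ** (ref - ct)
    else:
        levels = 2.0 ** (ct - ref)

    result = RelativeLevels(levels, table.reference_gene, convention=convention)
    groups = table.replicate_groups
    if groups:
        cols_by_group = {
            g: [s for s in levels.columns if groups.get(s) == g]
            for g in sorted(set(groups.values()))
        }
        result.group_means = pd.DataFrame(
            {g: levels[c].mean(axis=1) for g, c in cols_by_group.items()}
        )
        result.group_sems = pd.DataFrame(
            {g: levels[c].sem(axis=1) for g, c in cols_by_group.items()}
        )
        if control_group is not None:
            if control_group not in cols_by_group:
                raise ValueError(f"unknown control group {control_group!r}")
            ctrl = result.group_means[control_group]
            result.fold_vs_control = result.group_means.div(ctrl, axis=0)
    return result


def group_compare(
    levels: pd.DataFrame,
    groups: Mapping[str, str],
    test: str = "anova",
    control_group: str | None = None,
) -> pd.DataFrame:
    """Per-gene two-tailed pooled t-test or one-way ANOVA across groups.

    Returns a genes-indexed frame with ``statistic`` (t or F), ``p_value``
    and, when ``control_group`` is given, fold change of each non-control
    group mean against the control mean.
    """
    if test not in ("t_test", "anova"):
        raise ValueError("test must be 't_test' or 'anova'")
    names = sorted(set(groups.values()))
    cols = {g: [s for s in levels.columns if groups[s] == g] for g in names}
    if test == "t_test" and len(names) != 2:
        raise ValueError("t_test requires exactly two groups")
    for g, c in cols.items():
        if len(c) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")

    rows = {}
    for gene in levels.index:
        data = [levels.loc[gene, c].to_numpy(dtype=float) for g, c in cols.items()]
        if test == "t_test":
            if all(d.std() == 0 for d in data) and np.allclose(data[0].mean(), data[1].mean()):
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.ttest_ind(data[0], data[1], equal_var=True)
        else:
            stat, p = _one_way_anova(data)
        row = {"statistic": float(stat), "p_value": float(p)}
        if control_group is not None:
            ctrl_mean = levels.loc[gene, cols[control_group]].mean()
            for g in names:
                if g != control_group:
                    row[f"fold_{g}"] = float(
                        levels.loc[gene, cols[g]].mean() / ctrl_mean
                    )
        rows[gene] = row
    return pd.DataFrame.from_dict(rows, orient="index")
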