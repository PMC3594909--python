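"""Reference t-test ranking, rank-consistency matrices, biomarker selection.

Each classifier ranks variables with its own importance measure; the
two-sample Student's t-test rank (ascending P value) serves as an unbiased
univariate reference. Consistency between any two methods is the Pearson
correlation of their integer rank vectors (a Spearman-type statistic), at
two levels: over all variables, and recomputed within the subset of
identified metabolites.

Putative biomarkers are variables passing all three screens: t-test
P < 0.05, PLS VIP > 1, and scaled RF Gini score > 50 (strict inequalities,
thresholds configurable). No multiple-testing correction is applied to the
P-value screen by default; a Benjamini-Hochberg option is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classifiers import ClassifierSpec, RankList, compute_vip, fit_classifier, scale_gini
from .errors import ValidationError
from .preprocess import PreprocessConfig, preprocess_table
from .tables import FeatureTable

__all__ = [
    "ConsistencyMatrix",
    "BiomarkerSelection",
    "ttest_pvalues",
    "ttest_rank",
    "pearson_consistency",
    "select_biomarkers",
]


@dataclass(frozen=True)
class ConsistencyMatrix:
    """Pairwise Pearson correlations between methods' rank vectors."""

    methods: tuple[str, ...]
    matrix: np.ndarray
    level: str = "all_variables"

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float))
        m = self.matrix
        if m.shape != (len(self.methods), len(self.methods)):
            raise ValidationError("consistency matrix shape disagrees with method count")
        if not np.allclose(m, m.T, atol=1e-12) or not np.allclose(np.diag(m), 1.0):
            raise ValidationError("consistency matrix must be symmetric with unit diagonal")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.methods), columns=list(self.methods))


@dataclass(frozen=True)
class BiomarkerSelection:
    """Per-variable screening statistics and the threshold-selected sets."""

    variable_ids: tuple[str, ...]
    p_values: np.ndarray
    vip: np.ndarray
    gini: np.ndarray
    thresholds: dict
    selected_ttest: tuple[str, ...]
    selected_vip: tuple[str, ...]
    selected_gini: tuple[str, ...]

    @property
    def intersection(self) -> tuple[str, ...]:
        common = set(self.selected_ttest) & set(self.selected_vip) & set(self.selected_gini)
        return tuple(v for v in self.variable_ids if v in common)

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds,
            "selected_ttest": list(self.selected_ttest),
            "selected_vip": list(self.selected_vip),
            "selected_gini": list(self.selected_gini),
            "intersection": list(self.intersection),
        }


def ttest_pvalues(table: FeatureTable, equal_var: bool = True) -> np.ndarray:
    """Per-variable two-sample t-test P values (pooled variance by default)."""
    y = table.labels
    if np.bincount(y, minlength=2).min() < 2:
        raise ValidationError("each class needs at least 2 samples for a t-test")
    a = table.values[y == 0]
    b = table.values[y == 1]
    return stats.ttest_ind(a, b, axis=0, equal_var=equal_var).pvalue


def ttest_rank(table: FeatureTable, equal_var: bool = True) -> RankList:
    """Variables ranked by ascending t-test P value (ties: lexicographic id).

    The rank list's score column is -log10(P), so the usual higher-is-more-
    important convention holds; the raw P values ride along in ``pvalues``.
    """
    p = ttest_pvalues(table, equal_var=equal_var)
    ids = [str(v) for v in table.variable_ids]
    order = sorted(range(len(ids)), key=lambda j: (p[j], ids[j]))
    return RankList(
        method="ttest",
        variable_ids=tuple(ids[j] for j in order),
        scores=-np.log10(np.clip(p[order], 1e-300, None)),
        pvalues=p[order],
    )


def pearson_consistency(
    rank_lists: Mapping[str, RankList],
    subset: Sequence[str] | np.ndarray | None = None,
    level: str = "all_variables",
) -> ConsistencyMatrix:
    """Pearson correlation matrix of integer rank vectors.

    ``subset`` (ids, or a boolean mask over the first list's sorted ids)
    restricts the comparison: each ordering is filtered to the subset and
    ranks are recomputed within it, so both vectors stay full permutations
    of the same set — a slice of global ranks would not be.
    """
    if len(rank_lists) < 2:
        raise ValidationError("need at least two rank lists to compare")
    names = list(rank_lists)
    id_sets = [frozenset(rl.variable_ids) for rl in rank_lists.values()]
    if len(set(id_sets)) != 1:
        raise ValidationError("rank lists cover different variable sets")
    canonical = sorted(id_sets[0])
    if subset is not None:
        subset = np.asarray(subset)
        if subset.dtype == bool:
            if len(subset) != len(canonical):
                raise ValidationError(
                    f"subset mask covers {len(subset)} variables, expected {len(canonical)}"
                )
            chosen = {v for v, keep in zip(canonical, subset) if keep}
        else:
            chosen = set(str(v) for v in subset)
            unknown = chosen - set(canonical)
            if unknown:
                raise ValidationError(f"subset names unknown variables: {sorted(unknown)}")
    else:
        chosen = set(canonical)
    if len(chosen) < 3:
        raise ValidationError(f"subset has {len(chosen)} variables; need at least 3")

    vectors = []
    for rl in rank_lists.values():
        kept = [v for v in rl.variable_ids if v in chosen]  # induced order
        pos = {v: i + 1 for i, v in enumerate(kept)}
        vectors.append([pos[v] for v in sorted(chosen)])
    matrix = np.corrcoef(np.asarray(vectors, dtype=float))
    matrix = (matrix + matrix.T) / 2.0
    np.fill_diagonal(matrix, 1.0)
    return ConsistencyMatrix(methods=tuple(names), matrix=matrix, level=level)


def select_biomarkers(
    table: FeatureTable,
    p_cut: float = 0.05,
    vip_cut: float = 1.0,
    gini_cut: float = 50.0,
    pls_spec: ClassifierSpec | None = None,
    rf_spec: ClassifierSpec | None = None,
    preprocess: PreprocessConfig | None = None,
    fdr: bool = False,
) -> BiomarkerSelection:
    """Three-way biomarker screen: t-test P, PLS VIP, scaled RF Gini.

    All three statistics are computed on the (optionally pretreated) table;
    selections use strict inequalities (P < p_cut, VIP > vip_cut,
    Gini > gini_cut). With ``fdr=True`` the P-value screen uses
    Benjamini-Hochberg adjusted values instead of raw ones.
    """
    if preprocess is not None:
        table = preprocess_table(table, preprocess)
    ids = tuple(str(v) for v in table.variable_ids)
    p = ttest_pvalues(table)
    p_screen = stats.false_discovery_control(p) if fdr else p
    pls = fit_classifier(pls_spec or ClassifierSpec("pls"), table)
    vip = compute_vip(pls)
    rf = fit_classifier(rf_spec or ClassifierSpec("rf"), table)
    gini = scale_gini(rf.feature_importances_)
    sel_t = tuple(v for v, pv in zip(ids, p_screen) if pv < p_cut)
    sel_v = tuple(v for v, s in zip(ids, vip) if s > vip_cut)
    sel_g = tuple(v for v, s in zip(ids, gini) if s > gini_cut)
    return BiomarkerSelection(
        variable_ids=ids,
        p_values=p,
        vip=vip,
        gini=gini,
        thresholds={"p": p_cut, "vip": vip_cut, "gini": gini_cut, "fdr": fdr},
        selected_ttest=sel_t,
        selected_vip=sel_v,
        selected_gini=sel_g,
    )
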