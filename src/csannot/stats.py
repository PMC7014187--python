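"""Differential feature screening and metabolite-set over-representation analysis.

Features are screened between weight groups with the two-sided Wilcoxon
rank-sum test (exact enumeration for small tie-free groups, normal
approximation with tie correction otherwise); features at p < 0.01 are
considered associated with the contrast. The compounds annotated to the
significant features are then tested for over-representation in predefined
metabolite sets with the one-tailed hypergeometric test, adjusted for
multiple testing across sets (Benjamini-Hochberg by default, Holm
available). The reference metabolome (population) is the set of all
compounds accepted by the annotation stage.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .preprocess import AlignedPeakTable

logger = logging.getLogger(__name__)

__all__ = ["wilcoxon_screen", "ora", "run_comparisons"]


def _ranksum_p_rows(Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p-values for two F x n intensity blocks.

    Exact null distribution when both groups have <= 10 samples and the
    pooled row is tie-free; tie-corrected normal approximation otherwise;
    constant rows carry no ordering information and get p = 1.
    """
    Z = np.concatenate([Xa, Xb], axis=1)
    p = np.ones(Z.shape[0])
    const = np.all(Z == Z[:, :1], axis=1)
    Zs = np.sort(Z, axis=1)
    tied = np.any(np.diff(Zs, axis=1) == 0, axis=1)
    small = Xa.shape[1] <= 10 and Xb.shape[1] <= 10
    exact = ~const & ~tied & small
    asym = ~const & ~exact
    if exact.any():
        p[exact] = mannwhitneyu(Xa[exact], Xb[exact], axis=1,
                                alternative="two-sided", method="exact").pvalue
    if asym.any():
        p[asym] = mannwhitneyu(Xa[asym], Xb[asym], axis=1,
                               alternative="two-sided", method="asymptotic").pvalue
    return p


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p-value; exact when both groups <= 10 and tie-free."""
    return float(_ranksum_p_rows(np.atleast_2d(np.asarray(x, dtype=float)),
                                 np.atleast_2d(np.asarray(y, dtype=float)))[0])


def wilcoxon_screen(
    table: AlignedPeakTable,
    group_a: str,
    group_b: str,
    alpha: float = 0.01,
    stratum: str = "all",
) -> pd.DataFrame:
    """Per-feature two-sided Wilcoxon rank-sum test between two groups.

    Zeros are measured values and take part in the ranking. ``stratum``
    restricts the samples by sex ('all', 'M' or 'F'). Returns a frame with
    feature_id, comparison, stratum, p_value and significant (p < alpha).
    """
    if table.sample_meta is None:
        raise ValueError("table has no sample metadata; attach a manifest first")
    meta = table.sample_meta
    in_stratum = np.ones(len(meta), dtype=bool) if stratum == "all" \
        else (meta["sex"].to_numpy() == stratum)
    mask_a = (meta["group"].to_numpy() == group_a) & in_stratum
    mask_b = (meta["group"].to_numpy() == group_b) & in_stratum
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError(f"each group needs >= 2 samples "
                         f"({group_a}: {mask_a.sum()}, {group_b}: {mask_b.sum()})")
    Xa = np.asarray(table.intensities[:, mask_a], dtype=float)
    Xb = np.asarray(table.intensities[:, mask_b], dtype=float)
    pvals = _ranksum_p_rows(Xa, Xb)
    return pd.DataFrame({
        "feature_id": table.feature_ids,
        "comparison": f"{group_a} vs {group_b}",
        "stratum": stratum,
        "p_value": pvals,
        "significant": pvals < alpha,
    })


def ora(
    hit_compounds: list[str],
    sets: dict[str, list[str]],
    population: list[str],
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """One-tailed hypergeometric over-representation of metabolite sets.

    With population size M, set size K (after intersecting with the
    population), hit-list size n and overlap k, the raw p-value is
    P(X >= k) for X ~ Hypergeometric(M, K, n). Adjusted p-values are
    computed across all tested sets (Benjamini-Hochberg or 'holm').
    Returns rows sorted by raw p-value.
    """
    popset = set(population)
    hits = set(hit_compounds)
    if not hits <= popset:
        raise ValueError("hit compounds must be a subset of the population")
    M, n = len(popset), len(hits)
    rows = []
    for sid, members in sets.items():
        inset = set(members) & popset
        K = len(inset)
        k = len(inset & hits)
        raw = 1.0 if (n == 0 or K == 0) else float(hypergeom.sf(k - 1, M, K, n))
        rows.append({"set_id": sid, "population": M, "set_size": K,
                     "hits": n, "overlap": k, "raw_p": min(raw, 1.0)})
    df = pd.DataFrame(rows)
    if len(df):
        df["adjusted_p"] = multipletests(df["raw_p"].to_numpy(), method=adjust)[1]
        df = df.sort_values(["raw_p", "set_id"], kind="stable").reset_index(drop=True)
    else:
        df["adjusted_p"] = []
    return df


def run_comparisons(
    table: AlignedPeakTable,
    annotations: pd.DataFrame,
    sets: dict[str, list[str]],
    control_group: str = "normal",
    alpha: float = 0.01,
    strata: tuple[str, ...] = ("all", "M", "F"),
    adjust: str = "fdr_bh",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified contrasts against the control group, followed by ORA.

    For every stratum x contrast cell: features significant at ``alpha`` are
    mapped to their accepted annotated compounds; those compounds are tested
    for set over-representation against the population of all accepted
    annotated compounds. Returns (wide adjusted-p matrix with sets as rows
    and stratum/contrast columns, long differential results).
    """
    if table.sample_meta is None:
        raise ValueError("table has no sample metadata; attach a manifest first")
    feature_to_compounds: dict[str, list[str]] = {}
    for row in annotations.itertuples(index=False):
        feature_to_compounds.setdefault(row.feature_id, []).append(row.compound_id)
    population = sorted(set(annotations["compound_id"]))

    groups = [g for g in dict.fromkeys(table.sample_meta["group"]) if g != control_group]
    wide: dict[str, pd.Series] = {}
    diff_frames = []
    for stratum in strata:
        for case in groups:
            label = f"{stratum}:{control_group} vs {case}"
            diff = wilcoxon_screen(table, control_group, case, alpha=alpha,
                                   stratum=stratum)
            diff_frames.append(diff)
            sig = diff.loc[diff["significant"], "feature_id"]
            hits = sorted({c for f in sig for c in feature_to_compounds.get(f, [])})
            if not hits:
                logger.warning("%s: no significant annotated compounds", label)
                wide[label] = pd.Series(1.0, index=sorted(sets))
                continue
            enr = ora(hits, sets, population, adjust=adjust).set_index("set_id")
            wide[label] = enr["adjusted_p"].reindex(sorted(sets))
    matrix = pd.DataFrame(wide)
    matrix.index.name = "set_id"
    return matrix, pd.concat(diff_frames, ignore_index=True)
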