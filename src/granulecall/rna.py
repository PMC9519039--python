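"""Granule-component calling for RNAs from fraction count matrices.

Counts are normalized by median-of-ratios size factors, each granule
fraction is compared against tissue lysate within each genotype, and a
transcript is called a granule component when, in *both* granule fractions
independently, either

(i)  its granule-vs-lysate log2 fold change in wildtype exceeds the one in
     the mutant by more than ``delta_threshold`` (enrichment lost in the
     mutant), or
(ii) the wildtype fold change is positive and significant (raw p < alpha)
     while the mutant one is not positive-and-significant.

The differential-enrichment engine here is deliberately plain (Welch test
on log2 normalized counts); ``classify_rna_components`` consumes any table
with the same columns, so results from a dedicated DE package can be
substituted.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, ValidationError
from .protein import adjust_benjamini_hochberg, _two_sample_t

DE_COLUMNS = ("feature_id", "log2fc", "base_mean", "p_value", "p_adjusted")

CRITERION_I = "i"
CRITERION_II = "ii"
CRITERION_NONE = "none"


def estimate_size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    Each feature with nonzero counts in every sample contributes the ratio
    of its count to its geometric mean across samples; the per-sample factor
    is the median of these ratios. Features containing any zero are excluded.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = mat.to_numpy(dtype=float)
    usable = (arr > 0).all(axis=1)
    if not usable.any():
        raise ValidationError(
            "no feature has nonzero counts in all samples; size factors are "
            "undefined (pseudo-reference fallback is disabled)"
        )
    logs = np.log(arr[usable])
    log_geo_mean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geo_mean, axis=0))
    return pd.Series(factors, index=mat.columns, name="size_factor")


def normalized_counts(cm: CountMatrix, size_factors: pd.Series | None = None) -> pd.DataFrame:
    if size_factors is None:
        size_factors = estimate_size_factors(cm)
    return cm.counts / size_factors


def differential_enrichment(
    cm: CountMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-feature enrichment of sample group a over group b.

    log2fc = log2((mean normalized a + 0.5) / (mean normalized b + 0.5));
    p from a two-sided Welch test on log2(normalized count + 0.5);
    base_mean is the mean normalized count over *all* samples of the matrix;
    p_adjusted is Benjamini-Hochberg.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs >= 2 samples")
    if set(group_a) & set(group_b):
        raise ValidationError(f"groups overlap: {sorted(set(group_a) & set(group_b))}")
    for s in group_a + group_b:
        if s not in cm.counts.columns:
            raise ValidationError(f"unknown sample {s!r}")

    norm = normalized_counts(cm, size_factors)
    a = norm[group_a].to_numpy()
    b = norm[group_b].to_numpy()
    log2fc = np.log2(a.mean(axis=1) + 0.5) - np.log2(b.mean(axis=1) + 0.5)
    t, p = _two_sample_t(np.log2(a + 0.5), np.log2(b + 0.5), equal_var=False)
    out = pd.DataFrame(
        {
            "feature_id": cm.feature_ids,
            "log2fc": log2fc,
            "base_mean": norm.to_numpy().mean(axis=1),
            "p_value": p,
            "p_adjusted": adjust_benjamini_hochberg(p),
        }
    )
    return out.sort_values("feature_id", kind="mergesort").reset_index(drop=True)


def _check_de_table(df: pd.DataFrame, name: str) -> pd.DataFrame:
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"DE table {name} lacks column(s) {missing}")
    if df["feature_id"].duplicated().any():
        raise ValidationError(f"DE table {name} has duplicate feature ids")
    return df.set_index("feature_id")


def classify_rna_components(
    de_wt_g1: pd.DataFrame,
    de_mut_g1: pd.DataFrame,
    de_wt_g2: pd.DataFrame,
    de_mut_g2: pd.DataFrame,
    delta_threshold: float = 0.5,
    alpha: float = 0.05,
    min_base_mean: float = 10.0,
) -> pd.DataFrame:
    """Apply the two-criterion, both-fraction granule-component rule.

    Inputs are four granule-vs-lysate DE tables (wildtype and mutant, for
    each of the two granule fractions) over one shared feature universe.
    Only features whose mean base_mean across the four tables is strictly
    greater than ``min_base_mean`` are considered. Per fraction, criterion
    (i) is (log2fc_wt - log2fc_mut) > delta_threshold (strict, signed) and
    criterion (ii) is log2fc_wt > 0 and p_wt < alpha while not
    (log2fc_mut > 0 and p_mut < alpha). A feature is called iff one of the
    criteria holds in both fractions.
    """
    tables = {
        ("wildtype", "granules_1"): _check_de_table(de_wt_g1, "wt/granules_1"),
        ("mutant", "granules_1"): _check_de_table(de_mut_g1, "mut/granules_1"),
        ("wildtype", "granules_2"): _check_de_table(de_wt_g2, "wt/granules_2"),
        ("mutant", "granules_2"): _check_de_table(de_mut_g2, "mut/granules_2"),
    }
    universe = tables[("wildtype", "granules_1")].index.sort_values()
    for name, tab in tables.items():
        if not tab.index.sort_values().equals(universe):
            raise ValidationError(f"feature universe of {name} disagrees")
    tables = {k: v.loc[universe] for k, v in tables.items()}

    base_mean = sum(t["base_mean"] for t in tables.values()) / 4.0
    considered = base_mean > min_base_mean

    flags = {}
    for fraction in ("granules_1", "granules_2"):
        wt = tables[("wildtype", fraction)]
        mut = tables[("mutant", fraction)]
        crit_i = (wt["log2fc"] - mut["log2fc"]) > delta_threshold
        wt_sig = (wt["log2fc"] > 0) & (wt["p_value"] < alpha)
        mut_sig = (mut["log2fc"] > 0) & (mut["p_value"] < alpha)
        crit_ii = wt_sig & ~mut_sig
        flags[fraction] = np.where(
            ~considered.to_numpy(),
            CRITERION_NONE,
            np.where(crit_i, CRITERION_I, np.where(crit_ii, CRITERION_II, CRITERION_NONE)),
        )

    called = (flags["granules_1"] != CRITERION_NONE) & (flags["granules_2"] != CRITERION_NONE)
    out = pd.DataFrame(
        {
            "feature_id": universe,
            "called": called,
            "criterion_granules_1": flags["granules_1"],
            "criterion_granules_2": flags["granules_2"],
            "base_mean": base_mean.to_numpy(),
        }
    )
    for fraction in ("granules_1", "granules_2"):
        suffix = fraction.replace("granules_", "g")
        for genotype in ("wildtype", "mutant"):
            tab = tables[(genotype, fraction)]
            out[f"log2fc_{genotype}_{suffix}"] = tab["log2fc"].to_numpy()
            out[f"p_{genotype}_{suffix}"] = tab["p_value"].to_numpy()
    return out.reset_index(drop=True)


def call_rna_components_from_counts(
    cm: CountMatrix,
    delta_threshold: float = 0.5,
    alpha: float = 0.05,
    min_base_mean: float = 10.0,
) -> pd.DataFrame:
    """Full pipeline: size factors, four DE comparisons, classification.

    Size factors are estimated per genotype over that genotype's samples, and
    each granule fraction is tested against tissue lysate.
    """
    de = {}
    for genotype in ("wildtype", "mutant"):
        cols = cm.sample_ids(genotype=genotype)
        sub = CountMatrix(
            cm.counts[cols].copy(),
            cm.samples[cm.samples["sample_id"].isin(cols)].copy(),
        )
        sf = estimate_size_factors(sub)
        lysate = sub.sample_ids(fraction="tissue_lysate")
        for fraction in ("granules_1", "granules_2"):
            de[(genotype, fraction)] = differential_enrichment(
                sub, sub.sample_ids(fraction=fraction), lysate, size_factors=sf
            )
    return classify_rna_components(
        de[("wildtype", "granules_1")],
        de[("mutant", "granules_1")],
        de[("wildtype", "granules_2")],
        de[("mutant", "granules_2")],
        delta_threshold=delta_threshold,
        alpha=alpha,
        min_base_mean=min_base_mean,
    )
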