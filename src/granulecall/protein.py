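"""iBAQ processing and protein granule-component calling.

The pipeline mirrors a differential-centrifugation MS experiment: per
(genotype, fraction) condition with replicated log2 iBAQ intensities, it

1. imputes missing values (nearest-neighbour replicate for a single
   missing value, a low basement constant when two or more of a
   condition's replicates are missing),
2. removes proteins whose quantification is unreliable,
3. mean-normalizes sample columns,
4. calls granule components by the difference of the wildtype and mutant
   granule-versus-lysate log2 fold changes,
5. tests the global proteome (wildtype vs mutant lysate, pooled t), and
6. runs the RAP-MS style enrichment test (downshifted-normal imputation,
   two-sample t, Benjamini-Yekutieli).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ValidationError, validate_sample_sheet

logger = logging.getLogger(__name__)

FLAG_OBSERVED = "observed"
FLAG_MISSING = "missing"
FLAG_IMPUTED_NN = "imputed_nn"
FLAG_IMPUTED_BASEMENT = "imputed_basement"
FLAG_IMPUTED_DOWNSHIFT = "imputed_downshift"

ROUTE_DELTA = "delta_ge_4.8"
ROUTE_ABSENT = "absent_in_mutant"
ROUTE_NONE = "none"


@dataclass
class ProteinQuantTable:
    """Protein x sample log2 iBAQ intensities with per-cell provenance.

    ``values`` holds log2 intensities (NaN where missing), ``flags`` one of
    the ``FLAG_*`` provenance strings per cell, ``samples`` the sample sheet
    (genotype, fraction, replicate).
    """

    values: pd.DataFrame
    flags: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = validate_sample_sheet(self.samples)
        absent = [s for s in self.samples["sample_id"] if s not in self.values.columns]
        if absent:
            raise ValidationError(f"sample(s) absent from intensity columns: {absent}")
        self.values = self.values.loc[:, list(self.samples["sample_id"])].astype(float)
        if self.flags is None:
            self.flags = pd.DataFrame(
                np.where(self.values.isna(), FLAG_MISSING, FLAG_OBSERVED),
                index=self.values.index,
                columns=self.values.columns,
            )
        self.flags = self.flags.loc[self.values.index, self.values.columns]
        observed = (self.flags == FLAG_OBSERVED).to_numpy()
        if np.isnan(self.values.to_numpy()[observed]).any():
            raise ValidationError("cell flagged observed but value missing")

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    def condition_columns(self, genotype: str, fraction: str) -> list[str]:
        sel = self.samples
        sel = sel[(sel["genotype"] == genotype) & (sel["fraction"] == fraction)]
        return list(sel.sort_values("replicate")["sample_id"])

    def conditions(self) -> list[tuple[str, str]]:
        pairs = self.samples[["genotype", "fraction"]].drop_duplicates()
        return [tuple(r) for r in pairs.itertuples(index=False)]

    def copy(self) -> "ProteinQuantTable":
        return ProteinQuantTable(self.values.copy(), self.flags.copy(), self.samples.copy())

    def was_missing(self) -> pd.DataFrame:
        """Boolean mask of cells that were not observed (pre-imputation)."""
        return self.flags != FLAG_OBSERVED


def read_protein_quant_table(ibaq_path, sheet_path) -> ProteinQuantTable:
    """Read a protein x sample log2-iBAQ TSV (``NA`` = missing) plus sheet."""
    from .io import NA_VALUES, read_sample_sheet

    values = pd.read_csv(
        ibaq_path, sep="\t", index_col=0, na_values=NA_VALUES, keep_default_na=False
    )
    values.index = values.index.astype(str)
    if values.index.duplicated().any():
        dup = values.index[values.index.duplicated()][0]
        raise ValidationError(f"duplicate protein id {dup!r}")
    return ProteinQuantTable(values, None, read_sample_sheet(sheet_path))


def write_protein_quant_table(table: ProteinQuantTable, ibaq_path, sheet_path) -> None:
    df = table.values.copy()
    df.index.name = "protein_id"
    df.sort_index().to_csv(ibaq_path, sep="\t", na_rep="NA")
    table.samples.to_csv(sheet_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


def _column_distances(values: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    """Pairwise RMS distance between sample columns over co-observed proteins."""
    n = len(cols)
    dist = np.full((n, n), np.inf)
    arr = values[cols].to_numpy()
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(arr[:, i]) & ~np.isnan(arr[:, j])
            if both.any():
                d = float(np.sqrt(np.mean((arr[both, i] - arr[both, j]) ** 2)))
            else:
                d = np.inf
            dist[i, j] = dist[j, i] = d
    return pd.DataFrame(dist, index=cols, columns=cols)


def impute_ibaq(table: ProteinQuantTable, basement_value: float = 8.0) -> ProteinQuantTable:
    """Fill missing iBAQ cells condition by condition.

    Within each (genotype, fraction) condition: a protein with exactly one
    missing replicate takes that protein's value from the nearest replicate
    column (minimum RMS distance over co-observed proteins, ties broken by
    replicate order) and is flagged ``imputed_nn``; a protein missing two or
    more replicates takes ``basement_value`` in every missing cell and is
    flagged ``imputed_basement``. Observed cells are never altered.
    """
    out = table.copy()
    for genotype, fraction in table.conditions():
        cols = table.condition_columns(genotype, fraction)
        if len(cols) < 2:
            raise ValidationError(
                f"condition ({genotype}, {fraction}) has fewer than 2 replicates"
            )
        dist = _column_distances(table.values, cols)
        missing = table.values[cols].isna()
        n_missing = missing.sum(axis=1)

        # single missing replicate -> nearest-neighbour donor column
        for pid in table.protein_ids[n_missing == 1]:
            target = missing.columns[missing.loc[pid]][0]
            donors = [c for c in cols if c != target and not missing.loc[pid, c]]
            donor = min(donors, key=lambda c: (dist.loc[target, c], cols.index(c)))
            out.values.loc[pid, target] = table.values.loc[pid, donor]
            out.flags.loc[pid, target] = FLAG_IMPUTED_NN

        # two or more missing -> basement constant
        many = table.protein_ids[n_missing >= 2]
        for col in cols:
            hit = many[missing.loc[many, col]]
            out.values.loc[hit, col] = basement_value
            out.flags.loc[hit, col] = FLAG_IMPUTED_BASEMENT
    return out


# ---------------------------------------------------------------------------
# reliability filtering
# ---------------------------------------------------------------------------


def _granule_fraction(samples: pd.DataFrame) -> str:
    fracs = [f for f in samples["fraction"].unique() if f != "tissue_lysate"]
    if len(fracs) != 1:
        raise ValidationError(
            f"expected exactly one granule fraction besides tissue_lysate, got {fracs}"
        )
    return fracs[0]


def _replicate_pairs(table: ProteinQuantTable, genotype: str) -> list[tuple[str, str]]:
    """(granule_column, lysate_column) per replicate id, for one genotype."""
    gfrac = _granule_fraction(table.samples)
    sel = table.samples[table.samples["genotype"] == genotype]
    pairs = []
    for rep, sub in sel.groupby("replicate"):
        by_frac = dict(zip(sub["fraction"], sub["sample_id"]))
        if "tissue_lysate" not in by_frac or gfrac not in by_frac:
            raise ValidationError(
                f"replicate {rep} of {genotype} lacks a granule/lysate pair"
            )
        pairs.append((by_frac[gfrac], by_frac["tissue_lysate"]))
    return pairs


def filter_unreliable_proteins(
    table: ProteinQuantTable,
) -> tuple[ProteinQuantTable, pd.DataFrame]:
    """Drop proteins whose granule-vs-lysate comparison cannot be trusted.

    Rule (i): any wildtype replicate was missing in both its granule and its
    lysate column before imputation. Rule (ii): in either genotype, a
    replicate pair containing a nearest-neighbour-imputed value shows a
    granule-minus-lysate sign opposite to every fully observed replicate
    pair. Returns the filtered table and a log of (protein_id, rule).
    """
    was_missing = table.was_missing()
    removed: dict[str, str] = {}

    for g_col, l_col in _replicate_pairs(table, "wildtype"):
        both = was_missing[g_col] & was_missing[l_col]
        for pid in table.protein_ids[both]:
            removed.setdefault(pid, "i")

    nn = table.flags == FLAG_IMPUTED_NN
    observed = table.flags == FLAG_OBSERVED
    for genotype in table.samples["genotype"].unique():
        pairs = _replicate_pairs(table, genotype)
        diffs = np.stack(
            [(table.values[g] - table.values[l]).to_numpy() for g, l in pairs], axis=1
        )
        has_nn = np.stack(
            [(nn[g] | nn[l]).to_numpy() for g, l in pairs], axis=1
        )
        fully_obs = np.stack(
            [(observed[g] & observed[l]).to_numpy() for g, l in pairs], axis=1
        )
        signs = np.sign(diffs)
        for idx, pid in enumerate(table.protein_ids):
            if pid in removed:
                continue
            obs_signs = signs[idx][fully_obs[idx]]
            if obs_signs.size == 0:
                continue
            for k in range(len(pairs)):
                if has_nn[idx, k] and np.all(signs[idx, k] * obs_signs < 0):
                    removed[pid] = "ii"
                    break

    log = pd.DataFrame(
        sorted(removed.items()), columns=["protein_id", "rule"]
    )
    keep = [p for p in table.protein_ids if p not in removed]
    filtered = ProteinQuantTable(
        table.values.loc[keep].copy(), table.flags.loc[keep].copy(), table.samples.copy()
    )
    return filtered, log


# ---------------------------------------------------------------------------
# normalization and classification
# ---------------------------------------------------------------------------


def mean_normalize(table: ProteinQuantTable) -> ProteinQuantTable:
    """Center every sample column to mean 0 on the log2 scale."""
    if len(table.values) == 0:
        raise ValidationError("cannot normalize an empty table")
    out = table.copy()
    out.values = table.values - table.values.mean(axis=0, skipna=True)
    return out


def genotype_log2fc(table: ProteinQuantTable, genotype: str) -> pd.Series:
    """Granule-vs-lysate log2 fold change: mean over replicate pairs of
    (granule - lysate) on the log2 scale."""
    pairs = _replicate_pairs(table, genotype)
    diffs = pd.concat(
        [table.values[g] - table.values[l] for g, l in pairs], axis=1
    )
    return diffs.mean(axis=1)


def classify_protein_components(
    table: ProteinQuantTable, delta_threshold: float = 4.8
) -> pd.DataFrame:
    """Call granule-associated proteins via either of two routes.

    Route ``delta_ge_4.8``: mutant expression was observed and the wildtype
    granule-vs-lysate log2 fold change exceeds the mutant one by at least
    ``delta_threshold``. Route ``absent_in_mutant``: every mutant cell was
    missing before imputation and the wildtype log2 fold change is positive.
    """
    lfc_wt = genotype_log2fc(table, "wildtype")
    lfc_mut = genotype_log2fc(table, "mutant")
    mut_cols = list(table.samples[table.samples["genotype"] == "mutant"]["sample_id"])
    if not mut_cols:
        raise ValidationError("table has no mutant samples")
    mut_all_missing = table.was_missing()[mut_cols].all(axis=1)

    routes = []
    for pid in table.protein_ids:
        if mut_all_missing[pid]:
            route = ROUTE_ABSENT if lfc_wt[pid] > 0 else ROUTE_NONE
        else:
            route = ROUTE_DELTA if (lfc_wt[pid] - lfc_mut[pid]) >= delta_threshold else ROUTE_NONE
        routes.append(route)

    calls = pd.DataFrame(
        {
            "protein_id": table.protein_ids,
            "called": [r != ROUTE_NONE for r in routes],
            "route": routes,
            "log2fc_wildtype": lfc_wt.to_numpy(),
            "log2fc_mutant": lfc_mut.to_numpy(),
        }
    )
    return calls.sort_values("protein_id", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def adjust_benjamini_hochberg(p: Sequence[float]) -> np.ndarray:
    return multipletests(np.asarray(p, float), method="fdr_bh")[1]


def adjust_benjamini_yekutieli(p: Sequence[float]) -> np.ndarray:
    """FDR adjustment valid under arbitrary dependence (BH x harmonic factor)."""
    return multipletests(np.asarray(p, float), method="fdr_by")[1]


def _two_sample_t(
    a: np.ndarray, b: np.ndarray, equal_var: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sided t test with degenerate-variance handling.

    Rows where both groups have zero variance get p = 1 for equal means and
    p = 0 (with a warning) for unequal means.
    """
    import warnings

    with warnings.catch_warnings():
        # degenerate rows are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    var0 = (np.nanvar(a, axis=1) == 0) & (np.nanvar(b, axis=1) == 0)
    if var0.any():
        eq = np.nanmean(a, axis=1) == np.nanmean(b, axis=1)
        p = np.where(var0 & eq, 1.0, p)
        t = np.where(var0 & eq, 0.0, t)
        if (var0 & ~eq).any():
            logger.warning(
                "%d feature(s) with zero variance in both groups but unequal "
                "means; p reported as 0",
                int((var0 & ~eq).sum()),
            )
            p = np.where(var0 & ~eq, 0.0, p)
            t = np.where(var0 & ~eq, np.sign(np.nanmean(a, axis=1) - np.nanmean(b, axis=1)) * np.inf, t)
    return t, p


def global_proteome_de(
    table: ProteinQuantTable,
    alpha: float = 0.05,
    lfc_threshold: float = 0.5,
) -> pd.DataFrame:
    """Wildtype-vs-mutant tissue-lysate differential expression.

    Pooled-variance two-sided t test per protein on log2 intensities;
    a protein is significant when p < ``alpha`` and |log2fc| > ``lfc_threshold``.
    """
    cols_wt = table.condition_columns("wildtype", "tissue_lysate")
    cols_mut = table.condition_columns("mutant", "tissue_lysate")
    if len(cols_wt) < 2 or len(cols_mut) < 2:
        raise ValidationError("each genotype needs >= 2 tissue_lysate replicates")
    a = table.values[cols_wt].to_numpy()
    b = table.values[cols_mut].to_numpy()
    lfc = a.mean(axis=1) - b.mean(axis=1)
    t, p = _two_sample_t(a, b, equal_var=True)
    out = pd.DataFrame(
        {
            "protein_id": table.protein_ids,
            "log2fc": lfc,
            "base_mean": np.concatenate([a, b], axis=1).mean(axis=1),
            "t_statistic": t,
            "p_value": p,
            "p_adjusted": adjust_benjamini_hochberg(p),
            "significant": (p < alpha) & (np.abs(lfc) > lfc_threshold),
        }
    )
    return out.sort_values("protein_id", kind="mergesort").reset_index(drop=True)


def rapms_enrichment(
    values: pd.DataFrame,
    crosslinked: Sequence[str],
    control: Sequence[str],
    width: float = 0.5,
    downshift: float = 1.8,
    seed: int = 0,
    alpha: float = 0.05,
    lfc_threshold: float = 0.5,
    log_transform: bool = True,
) -> pd.DataFrame:
    """RNA-antisense-purification MS enrichment: cross-linked vs control.

    Proteins need at least two valid quantifications in one of the groups.
    Intensities are log2-transformed (pass ``log_transform=False`` for
    pre-transformed input), remaining missing values are imputed per sample
    from Normal(mu_s - downshift * sigma_s, (width * sigma_s)^2) where mu_s
    and sigma_s are that sample's observed mean and standard deviation, and
    a two-sided pooled t test with Benjamini-Yekutieli adjustment yields
    ``enriched`` = adjusted p <= ``alpha`` and log2fc > ``lfc_threshold``
    toward the cross-linked group. Complete rows make the result independent
    of ``seed``.
    """
    crosslinked, control = list(crosslinked), list(control)
    if len(crosslinked) < 2 or len(control) < 2:
        raise ValidationError("both groups need >= 2 samples")
    if set(crosslinked) & set(control):
        raise ValidationError("groups overlap")
    cols = crosslinked + control
    vals = values[cols].astype(float)

    valid_a = vals[crosslinked].notna().sum(axis=1)
    valid_b = vals[control].notna().sum(axis=1)
    vals = vals[(valid_a >= 2) | (valid_b >= 2)]

    mat = np.log2(vals.to_numpy()) if log_transform else vals.to_numpy().copy()
    rng = np.random.default_rng(seed)
    for j, _col in enumerate(cols):
        col = mat[:, j]
        miss = np.isnan(col)
        if miss.any():
            mu, sigma = np.nanmean(col), np.nanstd(col, ddof=1)
            mat[miss, j] = rng.normal(mu - downshift * sigma, width * sigma, miss.sum())

    na = len(crosslinked)
    lfc = mat[:, :na].mean(axis=1) - mat[:, na:].mean(axis=1)
    t, p = _two_sample_t(mat[:, :na], mat[:, na:], equal_var=True)
    p_adj = adjust_benjamini_yekutieli(p)
    out = pd.DataFrame(
        {
            "protein_id": vals.index,
            "log2fc": lfc,
            "t_statistic": t,
            "p_value": p,
            "p_adjusted": p_adj,
            "enriched": (p_adj <= alpha) & (np.abs(lfc) > lfc_threshold) & (lfc > 0),
        }
    )
    return out.sort_values("protein_id", kind="mergesort").reset_index(drop=True)
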