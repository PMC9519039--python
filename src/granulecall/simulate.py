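"""Synthetic pipeline inputs with planted ground truth.

Three generators emulate the three experimental inputs:

* :func:`simulate_fraction_counts` — bulk RNA-seq read counts for two
  genotypes (wildtype, mutant) across tissue lysate and two granule
  fractions. Counts are negative binomial with variance
  mu + dispersion * mu**2; planted granule components have their mean
  multiplied by ``2**enrichment_log2fc`` in the wildtype granule fractions
  only, so the enrichment disappears in the mutant exactly as when the
  granule scaffold is lost.
* :func:`simulate_ibaq_table` — log2 iBAQ protein intensities with
  missing-not-at-random dropout: the probability that a cell is missing is
  logistic in its log2 intensity, so low-abundance proteins drop out first.
* :func:`simulate_polya_read_ends` — a random genome carrying true poly(A)
  sites near annotated transcription end sites plus internal-priming decoy
  sites whose strand-specific upstream window lies inside a planted A-tract
  far from any TES, with per-sample Poisson read coverage.

Every output is a pure function of (config, seed): one
``numpy.random.Generator`` stream drives all draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .io import CountMatrix, Genome, ValidationError
from .protein import ProteinQuantTable

LABEL_COMPONENT = "granule_component"
LABEL_BACKGROUND = "background"
LABEL_TRUE_PAS = "true_pas"
LABEL_DECOY = "internal_priming_decoy"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for all three generators.

    Defaults mirror a three-replicate fractionation experiment: 2,000 genes
    or 1,000 proteins with 100 planted granule components, moderate bulk
    RNA-seq overdispersion (0.1), and a 3'-seq layout of 50 true poly(A)
    sites plus 200 A-tract decoys on a 150-kb genome.
    """

    seed: int = 0
    # RNA counts
    n_genes: int = 2000
    n_enriched: int = 100
    enrichment_log2fc: float = 2.0
    replicates: int = 3
    nb_dispersion: float = 0.1
    count_mean_low: float = 20.0
    count_mean_high: float = 2000.0
    # protein iBAQ
    n_proteins: int = 1000
    ibaq_log2_mean: float = 14.0
    ibaq_log2_sd: float = 2.0
    ibaq_noise_sd: float = 0.5
    dropout_rate: float = 0.1
    dropout_intensity_dependence: float = 2.0
    # 3'-seq
    genome_length: int = 150_000
    n_true_pas: int = 50
    n_decoy_sites: int = 200
    a_tract_length: int = 30
    reads_per_site: float = 20.0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_proteins, self.replicates) < 1:
            raise ValidationError("n_genes, n_proteins and replicates must be positive")
        if self.n_enriched < 0:
            raise ValidationError("n_enriched must be non-negative")
        if not 0 <= self.dropout_rate <= 1:
            raise ValidationError("dropout_rate must lie in [0, 1]")
        if self.nb_dispersion < 0 or self.ibaq_log2_sd <= 0 or self.ibaq_noise_sd < 0:
            raise ValidationError("dispersion/scale parameters must be non-negative")
        if not 0 < self.count_mean_low <= self.count_mean_high:
            raise ValidationError("count mean range must satisfy 0 < low <= high")
        if self.genome_length < 10 * (self.n_true_pas + self.n_decoy_sites):
            raise ValidationError(
                "genome_length must be at least 10 bp per planted site"
            )
        if self.a_tract_length < 10:
            raise ValidationError("a_tract_length must cover the 10-bp upstream window")
        if self.reads_per_site <= 0:
            raise ValidationError("reads_per_site must be positive")


def rna_preset(seed: int = 0) -> SimulationConfig:
    """Fraction-count conditions: 2,000 genes, 100 planted at +2 log2 units."""
    return SimulationConfig(seed=seed, enrichment_log2fc=2.0)


def protein_preset(seed: int = 0) -> SimulationConfig:
    """iBAQ conditions: 1,000 proteins, 100 planted at +6 log2 units, 10% MNAR."""
    return SimulationConfig(seed=seed, enrichment_log2fc=6.0)


def polya_preset(seed: int = 0) -> SimulationConfig:
    """3'-seq conditions: 50 true poly(A) sites, 200 decoys, coverage 20."""
    return SimulationConfig(seed=seed)


# ---------------------------------------------------------------------------
# fraction counts
# ---------------------------------------------------------------------------


def _fraction_sample_sheet(replicates: int) -> pd.DataFrame:
    rows = []
    for genotype in ("wildtype", "mutant"):
        for fraction in ("tissue_lysate", "granules_1", "granules_2"):
            for rep in range(1, replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{genotype}_{fraction}_r{rep}",
                        "genotype": genotype,
                        "fraction": fraction,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def _negative_binomial(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def simulate_fraction_counts(
    config: SimulationConfig, seed: int | None = None
) -> tuple[CountMatrix, pd.DataFrame]:
    """Negative-binomial fraction counts with planted wildtype-only enrichment.

    Baseline means are log-uniform over [count_mean_low, count_mean_high];
    the ``n_enriched`` planted genes have their mean multiplied by
    ``2**enrichment_log2fc`` in both wildtype granule fractions and nowhere
    else. Returns the count matrix and a truth table with columns
    feature_id, label, planted_log2fc, baseline_mean.
    """
    if config.n_enriched > config.n_genes:
        raise ValidationError("n_enriched exceeds n_genes")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sheet = _fraction_sample_sheet(config.replicates)
    ids = pd.Index([f"gene_{i:05d}" for i in range(config.n_genes)], name="feature_id")

    baseline = np.exp(
        rng.uniform(
            np.log(config.count_mean_low), np.log(config.count_mean_high), config.n_genes
        )
    )
    enriched = np.zeros(config.n_genes, dtype=bool)
    enriched[rng.choice(config.n_genes, size=config.n_enriched, replace=False)] = True

    cols = {}
    for _, row in sheet.iterrows():
        mean = baseline.copy()
        if row["genotype"] == "wildtype" and row["fraction"] != "tissue_lysate":
            mean[enriched] *= 2.0 ** config.enrichment_log2fc
        cols[row["sample_id"]] = _negative_binomial(rng, mean, config.nb_dispersion)
    counts = pd.DataFrame(cols, index=ids)

    truth = pd.DataFrame(
        {
            "feature_id": ids,
            "label": np.where(enriched, LABEL_COMPONENT, LABEL_BACKGROUND),
            "planted_log2fc": np.where(enriched, config.enrichment_log2fc, 0.0),
            "baseline_mean": baseline,
        }
    )
    return CountMatrix(counts=counts, samples=sheet), truth


# ---------------------------------------------------------------------------
# iBAQ intensities
# ---------------------------------------------------------------------------


def _ibaq_sample_sheet(replicates: int) -> pd.DataFrame:
    rows = []
    for genotype in ("wildtype", "mutant"):
        for fraction in ("tissue_lysate", "granules_1"):
            for rep in range(1, replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{genotype}_{fraction}_r{rep}",
                        "genotype": genotype,
                        "fraction": fraction,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def _mnar_midpoint(mean: float, sd: float, slope: float, rate: float) -> float:
    """Logistic midpoint m with E[expit(slope * (m - X))] = rate, X ~ N(mean, sd^2)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    x = mean + sd * nodes
    w = weights / weights.sum()

    def mean_dropout(m: float) -> float:
        return float(np.sum(w * expit(slope * (m - x))))

    lo, hi = mean - 20 * sd, mean + 20 * sd
    return brentq(lambda m: mean_dropout(m) - rate, lo, hi, xtol=1e-9)


def simulate_ibaq_table(
    config: SimulationConfig, seed: int | None = None
) -> tuple[ProteinQuantTable, pd.DataFrame]:
    """Log-normal iBAQ intensities with MNAR dropout and planted enrichment.

    Per-protein baselines are Normal(ibaq_log2_mean, ibaq_log2_sd) on the
    log2 scale, replicate noise Normal(0, ibaq_noise_sd). Planted proteins
    gain ``enrichment_log2fc`` in wildtype granule samples. Each cell is
    then dropped to missing with probability
    expit(slope * (midpoint - intensity)), the midpoint calibrated so the
    expected missing fraction of a baseline-distributed cell equals
    ``dropout_rate``.
    """
    if config.n_enriched > config.n_proteins:
        raise ValidationError("n_enriched exceeds n_proteins")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sheet = _ibaq_sample_sheet(config.replicates)
    ids = pd.Index(
        [f"protein_{i:04d}" for i in range(config.n_proteins)], name="protein_id"
    )

    baseline = rng.normal(config.ibaq_log2_mean, config.ibaq_log2_sd, config.n_proteins)
    enriched = np.zeros(config.n_proteins, dtype=bool)
    enriched[rng.choice(config.n_proteins, size=config.n_enriched, replace=False)] = True

    values = {}
    for _, row in sheet.iterrows():
        x = baseline + rng.normal(0.0, config.ibaq_noise_sd, config.n_proteins)
        if row["genotype"] == "wildtype" and row["fraction"] == "granules_1":
            x = x + np.where(enriched, config.enrichment_log2fc, 0.0)
        values[row["sample_id"]] = x
    table = pd.DataFrame(values, index=ids)

    if config.dropout_rate > 0:
        total_sd = float(np.hypot(config.ibaq_log2_sd, config.ibaq_noise_sd))
        slope = config.dropout_intensity_dependence
        if slope > 0:
            midpoint = _mnar_midpoint(
                config.ibaq_log2_mean, total_sd, slope, config.dropout_rate
            )
            p_miss = expit(slope * (midpoint - table.to_numpy()))
        else:
            p_miss = np.full(table.shape, config.dropout_rate)
        drop = rng.random(table.shape) < p_miss
        table = table.mask(drop)

    truth = pd.DataFrame(
        {
            "protein_id": ids,
            "label": np.where(enriched, LABEL_COMPONENT, LABEL_BACKGROUND),
            "planted_log2fc": np.where(enriched, config.enrichment_log2fc, 0.0),
            "baseline_log2": baseline,
        }
    )
    return ProteinQuantTable(values=table, flags=None, samples=sheet), truth


# ---------------------------------------------------------------------------
# 3'-end read positions
# ---------------------------------------------------------------------------

_POLYA_CONTIG = "chrSim"
_TES_MAX_OFFSET = 100  # true PAS lie within this many bp of their emitted TES
_MIN_SPACING = 460  # keeps decoys > 250 bp from any TES and tracts >= 50 bp from true PAS


def simulate_polya_read_ends(
    config: SimulationConfig, seed: int | None = None
) -> tuple[dict[str, pd.DataFrame], Genome, pd.DataFrame, pd.DataFrame]:
    """Random genome with true poly(A) sites and internal-priming decoys.

    True sites are placed within 250 bp of an emitted same-strand TES;
    decoy sites have their 10-bp strand-specific upstream window inside a
    planted homo-A tract (A on the read strand) and sit more than 250 bp
    from every TES. Per-sample coverage at each site is
    Poisson(reads_per_site); zero-coverage sites are absent from that
    sample's table. Returns (site tables by sample, genome, TES annotation,
    truth table).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_sites = config.n_true_pas + config.n_decoy_sites
    margin = _MIN_SPACING
    spacing = (config.genome_length - 2 * margin) // max(n_sites, 1)
    if spacing < _MIN_SPACING:
        raise ValidationError(
            "genome too short to place sites with the required spacing: "
            f"need >= {2 * margin + n_sites * _MIN_SPACING} bp, have {config.genome_length}"
        )
    jitter = (spacing - _MIN_SPACING) // 2

    seq = rng.choice(list("ACGT"), size=config.genome_length)
    labels = np.array(
        [LABEL_TRUE_PAS] * config.n_true_pas + [LABEL_DECOY] * config.n_decoy_sites
    )
    rng.shuffle(labels)

    records = []
    tes_records = []
    for k, label in enumerate(labels):
        base = margin + k * spacing
        position = int(base + (rng.integers(-jitter, jitter + 1) if jitter else 0))
        strand = "+" if rng.random() < 0.5 else "-"
        rec = {
            "site_id": f"site_{k:04d}",
            "contig": _POLYA_CONTIG,
            "position": position,
            "strand": strand,
            "label": label,
        }
        if label == LABEL_TRUE_PAS:
            offset = int(rng.integers(-_TES_MAX_OFFSET, _TES_MAX_OFFSET + 1))
            tes_pos = position + offset
            tes_records.append((_POLYA_CONTIG, tes_pos, strand))
            rec["tes_position"] = tes_pos
        else:
            # Homo-A tract on the read strand covering the upstream window.
            if strand == "+":
                start, end = position - config.a_tract_length, position
                seq[start:end] = "A"
            else:
                start, end = position + 1, position + 1 + config.a_tract_length
                seq[start:end] = "T"
            rec["tract_start"], rec["tract_end"] = start, end
        records.append(rec)

    truth = pd.DataFrame(records)
    tes = (
        pd.DataFrame(tes_records, columns=["contig", "position", "strand"])
        .drop_duplicates()
        .sort_values(["contig", "position", "strand"], kind="mergesort")
        .reset_index(drop=True)
    )

    # Construction guarantees, checked rather than trusted.
    decoys = truth[truth["label"] == LABEL_DECOY]
    if len(decoys) and len(tes):
        dists = np.abs(
            decoys["position"].to_numpy()[:, None] - tes["position"].to_numpy()[None, :]
        )
        if (dists.min(axis=1) <= 250).any():
            raise ValidationError("internal error: decoy within 250 bp of a TES")

    genome = Genome({_POLYA_CONTIG: "".join(seq)})

    sample_ids = [
        f"{genotype}_r{rep}"
        for genotype in ("wildtype", "mutant")
        for rep in range(1, config.replicates + 1)
    ]
    site_tables: dict[str, pd.DataFrame] = {}
    for sample in sample_ids:
        coverage = rng.poisson(config.reads_per_site, n_sites)
        tab = pd.DataFrame(
            {
                "contig": truth["contig"],
                "position": truth["position"],
                "strand": truth["strand"],
                "count": coverage,
            }
        )
        site_tables[sample] = (
            tab[tab["count"] > 0]
            .sort_values(["contig", "position", "strand"], kind="mergesort")
            .reset_index(drop=True)
        )
    return site_tables, genome, tes, truth


def polya_transcripts(tes: pd.DataFrame, length: int = 200) -> list[tuple[str, int, int, str, str]]:
    """Synthetic transcript intervals whose 3' ends reproduce the TES records.

    Used to write a GTF from which :func:`granulecall.io.extract_transcript_end_sites`
    recovers exactly the input annotation.
    """
    out = []
    for i, row in tes.reset_index(drop=True).iterrows():
        tid = f"tx_{i:04d}"
        if row["strand"] == "+":
            start0, end0 = max(0, row["position"] - length + 1), row["position"] + 1
        else:
            start0, end0 = row["position"], row["position"] + length
        out.append((row["contig"], int(start0), int(end0), row["strand"], tid))
    return out
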