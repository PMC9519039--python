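"""Poly(A)-site calling from single-base 3'-end read positions.

Oligo(dT) priming inside genomic A-rich stretches produces artifactual
3'-end signal ("internal priming"). Positions whose 10-bp strand-specific
upstream window is more than 70% adenosine on the read strand are
blacklisted, unless they lie within 250 bp of an annotated transcription
end site of the same strand (genuine poly(A) tails next to A-rich genome).
Surviving sites are coverage-filtered and merged into clusters by
single-linkage with a 15-bp gap.

All coordinates are 0-based; the site position is the single base of the
observed 3' end and its upstream window excludes the position itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io import Genome, ValidationError

logger = logging.getLogger(__name__)


def _min_a_count(a_fraction: float, window: int) -> int:
    """Smallest integer A-count that is strictly more than a_fraction of window."""
    t = a_fraction * window
    if abs(t - round(t)) < 1e-9:
        return int(round(t)) + 1
    return int(np.ceil(t))


@dataclass
class BlacklistMask:
    """Per (contig, strand) boolean arrays of internally-primed positions."""

    masks: dict[tuple[str, str], np.ndarray]

    def is_blacklisted(self, contig: str, position: int, strand: str) -> bool:
        key = (contig, strand)
        if key not in self.masks:
            raise KeyError(f"no mask for contig {contig!r} strand {strand!r}")
        mask = self.masks[key]
        if not 0 <= position < mask.size:
            raise IndexError(f"position {position} outside contig {contig!r}")
        return bool(mask[position])

    def lookup(self, sites: pd.DataFrame) -> np.ndarray:
        """Vectorized membership for a frame with contig/position/strand."""
        sites = sites.reset_index(drop=True)
        out = np.zeros(len(sites), dtype=bool)
        for (contig, strand), sub in sites.groupby(["contig", "strand"], sort=False):
            key = (contig, strand)
            if key not in self.masks:
                raise ValidationError(f"sites on unknown contig/strand {key}")
            pos = sub["position"].to_numpy()
            mask = self.masks[key]
            if (pos < 0).any() or (pos >= mask.size).any():
                raise ValidationError(f"site position outside contig {contig!r}")
            out[sub.index.to_numpy()] = mask[pos]
        return out


def build_internal_priming_blacklist(
    genome: Genome,
    tes: pd.DataFrame,
    a_fraction: float = 0.70,
    window: int = 10,
    tes_protect: int = 250,
) -> BlacklistMask:
    """Strand-specific blacklist of positions with an A-rich upstream window.

    Plus strand: the window is the ``window`` reference bases at
    [p - window, p). Minus strand: the read-strand upstream window maps to
    the reference interval [p + 1, p + 1 + window], where a read-strand A is
    a reference T. Windows truncated by a contig edge never blacklist
    (insufficient context). Positions within ``tes_protect`` bp of a
    same-strand annotated TES are exempt.
    """
    unknown = set(tes["contig"]) - set(genome.contigs)
    if unknown:
        raise ValidationError(f"TES annotation on contig(s) absent from genome: {sorted(unknown)}")
    need = _min_a_count(a_fraction, window)
    masks: dict[tuple[str, str], np.ndarray] = {}
    for contig, seq in genome.contigs.items():
        n = len(seq)
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_a = np.concatenate([[0], np.cumsum(arr == ord("A"))])
        is_t = np.concatenate([[0], np.cumsum(arr == ord("T"))])
        pos = np.arange(n)

        plus = np.zeros(n, dtype=bool)
        full = pos >= window  # window [p-window, p) fits inside the contig
        plus[full] = (is_a[pos[full]] - is_a[pos[full] - window]) >= need
        if (~full).any():
            logger.info("contig %s: %d plus-strand positions lack upstream context", contig, int((~full).sum()))

        minus = np.zeros(n, dtype=bool)
        full_m = pos + 1 + window <= n
        minus[full_m] = (is_t[pos[full_m] + 1 + window] - is_t[pos[full_m] + 1]) >= need
        if (~full_m).any():
            logger.info("contig %s: %d minus-strand positions lack upstream context", contig, int((~full_m).sum()))

        for strand, mask in (("+", plus), ("-", minus)):
            near = tes[(tes["contig"] == contig) & (tes["strand"] == strand)]
            for p in near["position"].to_numpy():
                mask[max(0, p - tes_protect) : min(n, p + tes_protect + 1)] = False
            masks[(contig, strand)] = mask
    return BlacklistMask(masks)


def filter_sites(
    site_tables: Mapping[str, pd.DataFrame],
    blacklist: BlacklistMask,
    min_coverage: int = 5,
) -> pd.DataFrame:
    """Merge per-sample site tables, drop blacklisted and low-coverage sites.

    Each input table has columns contig/position/strand/count. Blacklisted
    sites are removed unconditionally; a remaining site is retained when its
    coverage reaches ``min_coverage`` in at least one sample. The output
    carries one ``cov_<sample>`` column per input sample plus
    ``total_coverage``.
    """
    if not site_tables:
        raise ValidationError("no site tables given")
    samples = list(site_tables)
    pieces = []
    for sample, tab in site_tables.items():
        sub = tab[["contig", "position", "strand", "count"]].copy()
        if sub.duplicated(["contig", "position", "strand"]).any():
            raise ValidationError(f"sample {sample!r} lists a site twice")
        sub["sample"] = sample
        pieces.append(sub)
    long = pd.concat(pieces, ignore_index=True)
    wide = (
        long.pivot_table(
            index=["contig", "position", "strand"],
            columns="sample",
            values="count",
            fill_value=0,
            aggfunc="sum",
        )
        .reindex(columns=samples, fill_value=0)
        .astype(int)
    )
    wide = wide.reset_index()
    cov_cols = {s: f"cov_{s}" for s in samples}
    wide = wide.rename(columns=cov_cols)

    keep = ~blacklist.lookup(wide)
    wide = wide[keep]
    cov = wide[list(cov_cols.values())].to_numpy()
    wide = wide[(cov >= min_coverage).any(axis=1)]
    wide = wide.copy()
    wide["total_coverage"] = wide[list(cov_cols.values())].sum(axis=1)
    return wide.sort_values(["contig", "strand", "position"], kind="mergesort").reset_index(
        drop=True
    )


def cluster_polya_sites(sites: pd.DataFrame, max_gap: int = 15) -> pd.DataFrame:
    """Single-linkage merge of sites within ``max_gap`` bp on one strand.

    Scanning each contig+strand in ascending position, a site joins the open
    cluster when its distance to the most recently added member is at most
    ``max_gap``; merging therefore chains, so a cluster may span more than
    ``max_gap`` bp. Cluster intervals are 0-based half-open and coverage is
    summed per sample and in total.
    """
    cov_cols = [c for c in sites.columns if c.startswith("cov_")]
    rows = []
    for (contig, strand), sub in sites.groupby(["contig", "strand"], sort=True):
        sub = sub.sort_values("position", kind="mergesort")
        pos = sub["position"].to_numpy()
        if len(pos) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
        for chunk in np.split(np.arange(len(pos)), breaks):
            members = sub.iloc[chunk]
            row = {
                "contig": contig,
                "start": int(members["position"].min()),
                "end": int(members["position"].max()) + 1,
                "strand": strand,
                "n_sites": len(members),
            }
            for c in cov_cols:
                row[c] = int(members[c].sum())
            row["total_coverage"] = int(members[cov_cols].to_numpy().sum()) if cov_cols else int(
                members.get("total_coverage", pd.Series(dtype=int)).sum()
            )
            rows.append(row)
    out = pd.DataFrame(
        rows,
        columns=["contig", "start", "end", "strand", "n_sites", *cov_cols, "total_coverage"],
    )
    return out.sort_values(["contig", "start", "strand"], kind="mergesort").reset_index(drop=True)


def call_polya_clusters(
    site_tables: Mapping[str, pd.DataFrame],
    genome: Genome,
    tes: pd.DataFrame,
    a_fraction: float = 0.70,
    window: int = 10,
    tes_protect: int = 250,
    min_coverage: int = 5,
    max_gap: int = 15,
) -> pd.DataFrame:
    """Blacklist, filter and cluster in one call."""
    blacklist = build_internal_priming_blacklist(
        genome, tes, a_fraction=a_fraction, window=window, tes_protect=tes_protect
    )
    retained = filter_sites(site_tables, blacklist, min_coverage=min_coverage)
    return cluster_polya_sites(retained, max_gap=max_gap)
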