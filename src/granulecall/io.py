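"""Readers, writers and shared coordinate conventions.

Every genomic position inside this package is 0-based, half-open. The
conversion to and from 1-based inclusive (GTF) or 0-based half-open (BED)
happens exclusively in the functions of this module, so downstream logic
never sees more than one convention.

Missing values in quantification TSVs are written as ``NA``; on read the
aliases ``NA``, ``NaN`` and the empty field are accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

GENOTYPES = ("wildtype", "mutant")
FRACTIONS = ("tissue_lysate", "granules_1", "granules_2")

NA_VALUES = ["NA", "NaN", ""]
NA_REP = "NA"


class ValidationError(ValueError):
    """Raised when an input file violates the format contract."""


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------

SAMPLE_SHEET_COLUMNS = ("sample_id", "genotype", "fraction", "replicate")


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet; returns it with canonical column order."""
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValidationError(f"sample sheet lacks column(s) {missing}")
    sheet = sheet.loc[:, list(SAMPLE_SHEET_COLUMNS)].copy()
    dup = sheet["sample_id"][sheet["sample_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate sample_id(s): {sorted(set(dup))}")
    bad_g = set(sheet["genotype"]) - set(GENOTYPES)
    if bad_g:
        raise ValidationError(f"unknown genotype(s) {sorted(bad_g)}; expected {GENOTYPES}")
    bad_f = set(sheet["fraction"]) - set(FRACTIONS)
    if bad_f:
        raise ValidationError(f"unknown fraction(s) {sorted(bad_f)}; expected {FRACTIONS}")
    rep = pd.to_numeric(sheet["replicate"], errors="coerce")
    if rep.isna().any() or (rep < 1).any() or (rep != rep.astype(int)).any():
        raise ValidationError("replicate ids must be positive integers")
    sheet["replicate"] = rep.astype(int)
    return sheet.reset_index(drop=True)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return validate_sample_sheet(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Non-negative integer gene x sample read counts plus sample metadata.

    ``counts`` is indexed by feature id; its columns follow the sample-sheet
    row order of ``samples``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = validate_sample_sheet(self.samples)
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()]
            raise ValidationError(f"duplicate feature id(s): {sorted(set(dup))}")
        absent = [s for s in self.samples["sample_id"] if s not in self.counts.columns]
        if absent:
            raise ValidationError(
                f"sample(s) in sheet absent from counts columns: {absent}"
            )
        self.counts = self.counts.loc[:, list(self.samples["sample_id"])]
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("counts contain non-numeric values")
        if np.isnan(vals.astype(float)).any():
            raise ValidationError("counts contain missing values")
        if (vals < 0).any():
            bad = self.counts.index[(vals < 0).any(axis=1)][0]
            raise ValidationError(f"negative count at feature {bad!r}")
        if (vals != np.round(vals)).any():
            bad = self.counts.index[(vals != np.round(vals)).any(axis=1)][0]
            raise ValidationError(f"non-integer count at feature {bad!r}")
        self.counts = self.counts.astype(np.int64)

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    def sample_ids(self, genotype: str | None = None, fraction: str | None = None) -> list[str]:
        """Sample ids, optionally restricted to one genotype and/or fraction."""
        sel = self.samples
        if genotype is not None:
            sel = sel[sel["genotype"] == genotype]
        if fraction is not None:
            sel = sel[sel["fraction"] == fraction]
        return list(sel["sample_id"])


def read_count_matrix(counts_path: str | Path, sheet_path: str | Path) -> CountMatrix:
    """Read a feature x sample count TSV together with its sample sheet.

    The first column of the counts file holds feature ids; every sample in
    the sheet must appear as a column. Validation failures raise
    :class:`ValidationError` naming the offending row or column.
    """
    sheet = read_sample_sheet(sheet_path)
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    return CountMatrix(counts=counts, samples=sheet)


def write_count_matrix(cm: CountMatrix, counts_path: str | Path, sheet_path: str | Path) -> None:
    df = cm.counts.copy()
    df.index.name = "feature_id"
    df.sort_index().to_csv(counts_path, sep="\t")
    cm.samples.to_csv(sheet_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genome sequence
# ---------------------------------------------------------------------------


@dataclass
class Genome:
    """In-memory genome: contig name -> upper-case sequence over {A,C,G,T,N}."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        self.contigs = {name: seq.upper() for name, seq in self.contigs.items()}

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Sequence of [start, end) on the forward strand; bounds-checked."""
        if contig not in self.contigs:
            raise KeyError(f"unknown contig {contig!r}")
        seq = self.contigs[contig]
        if not (0 <= start <= end <= len(seq)):
            raise IndexError(
                f"range [{start}, {end}) outside contig {contig!r} of length {len(seq)}"
            )
        return seq[start:end]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        contigs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in contigs:
                raise ValidationError(f"duplicate contig {rec.id!r} in FASTA")
            contigs[rec.id] = str(rec.seq).upper()
        return cls(contigs)

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# transcript end sites (GTF)
# ---------------------------------------------------------------------------


def extract_transcript_end_sites(gtf_path: str | Path) -> pd.DataFrame:
    """Annotated transcription end sites from GTF transcript records.

    Returns a deduplicated frame with columns ``contig``, ``position``
    (0-based base of the 3' end) and ``strand``. For a plus-strand
    transcript the TES is its GTF end coordinate; for minus strand its
    start. Transcripts with strand ``.`` are skipped with a warning.
    """
    records: list[tuple[str, int, str]] = []
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise ValidationError(f"{gtf_path}: malformed GTF line {lineno}")
            contig, _source, feature, start, end, _score, strand = fields[:7]
            if feature != "transcript":
                continue
            if strand == ".":
                logger.warning("%s line %d: transcript without strand skipped", gtf_path, lineno)
                continue
            if strand not in "+-":
                raise ValidationError(f"{gtf_path} line {lineno}: bad strand {strand!r}")
            # GTF is 1-based inclusive; internal coordinates 0-based.
            tes = int(end) - 1 if strand == "+" else int(start) - 1
            records.append((contig, tes, strand))
    tes_df = pd.DataFrame(records, columns=["contig", "position", "strand"])
    tes_df = tes_df.drop_duplicates().sort_values(
        ["contig", "position", "strand"], kind="mergesort"
    )
    return tes_df.reset_index(drop=True)


def write_transcript_gtf(
    transcripts: Iterable[tuple[str, int, int, str, str]], path: str | Path
) -> None:
    """Write (contig, start0, end0_halfopen, strand, transcript_id) as GTF."""
    with open(path, "w") as fh:
        for contig, start, end, strand, tid in transcripts:
            attrs = f'gene_id "{tid}"; transcript_id "{tid}";'
            fh.write(
                "\t".join(
                    [contig, "granulecall", "transcript", str(start + 1), str(end),
                     ".", strand, ".", attrs]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# generic results tables
# ---------------------------------------------------------------------------

_SORT_KEYS = ("feature_id", "protein_id", "contig", "start", "position", "strand")


def _sort_records(df: pd.DataFrame) -> pd.DataFrame:
    keys = [c for c in _SORT_KEYS if c in df.columns]
    if keys:
        df = df.sort_values(keys, kind="mergesort")
    return df.reset_index(drop=True)


def write_results_table(records: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV dump: sorted by stable keys, ``NA`` for missing.

    Writing the same record set in any row order yields a byte-identical
    file, so result files diff cleanly across runs.
    """
    _sort_records(records).to_csv(path, sep="\t", index=False, na_rep=NA_REP)


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=NA_VALUES, keep_default_na=False)


# ---------------------------------------------------------------------------
# BED6 single-base 3'-end sites
# ---------------------------------------------------------------------------

BED_COLUMNS = ("contig", "start", "end", "name", "score", "strand")


def read_site_bed(path: str | Path) -> pd.DataFrame:
    """Read single-base 3'-end sites from BED6 (name = sample id, score = reads).

    Returns columns ``contig``, ``position`` (0-based), ``strand``, ``sample``,
    ``count``.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS, comment="#")
    if ((df["end"] - df["start"]) != 1).any():
        raise ValidationError(f"{path}: BED intervals must be single-base")
    out = pd.DataFrame(
        {
            "contig": df["contig"].astype(str),
            "position": df["start"].astype(int),
            "strand": df["strand"].astype(str),
            "sample": df["name"].astype(str),
            "count": df["score"].astype(int),
        }
    )
    if not set(out["strand"]) <= {"+", "-"}:
        raise ValidationError(f"{path}: strand must be + or -")
    return out


def read_site_beds(paths: Sequence[str | Path]) -> dict[str, pd.DataFrame]:
    """Read several per-sample BEDs; sample-id collisions across files error."""
    tables: dict[str, pd.DataFrame] = {}
    for path in paths:
        df = read_site_bed(path)
        for sample, sub in df.groupby("sample"):
            if sample in tables:
                raise ValidationError(f"sample id {sample!r} appears in more than one input")
            tables[str(sample)] = sub.drop(columns="sample").reset_index(drop=True)
    return tables


def write_site_bed(sites: pd.DataFrame, sample: str, path: str | Path) -> None:
    """Write per-sample sites (contig, position, strand, count) as BED6."""
    df = sites.sort_values(["contig", "position", "strand"], kind="mergesort")
    bed = pd.DataFrame(
        {
            "contig": df["contig"],
            "start": df["position"],
            "end": df["position"] + 1,
            "name": sample,
            "score": df["count"],
            "strand": df["strand"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def write_cluster_bed(clusters: pd.DataFrame, path: str | Path) -> None:
    """Write poly(A) clusters as BED6; score = total summed coverage."""
    df = clusters.sort_values(["contig", "start", "strand"], kind="mergesort")
    bed = pd.DataFrame(
        {
            "contig": df["contig"],
            "start": df["start"],
            "end": df["end"],
            "name": [f"cluster_{i}" for i in range(len(df))],
            "score": df["total_coverage"],
            "strand": df["strand"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)
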