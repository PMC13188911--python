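"""Readers and writers for the tabular formats the pipeline consumes.

Everything downstream works on validated in-memory tables: hmmsearch
per-target (``--tblout``) hit files, CoverM-style MAG x sample coverage
tables, GTDB-Tk-style taxonomy summaries, sample metadata, and plain
labelled matrices. All on-disk tables are tab-separated with a header row;
matrices are oriented rows = MAGs or HMMs, columns = samples.

Protein hits are attributed to MAGs either by a configurable separator
embedded in the target id (default ``"~"``, i.e. ``MAG0007~PROT0123``) or by
an explicit per-file MAG id, because upstream gene callers do not share a
single id scheme.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ValidationError",
    "HmmHitRecord",
    "SampleMetadata",
    "TaxonomyRecord",
    "GROUP_ALIASES",
    "read_hmm_hits",
    "write_hmm_hits",
    "read_coverage_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
    "read_matrix",
    "write_matrix",
    "read_profile_table",
    "write_profile_table",
    "read_mag_table",
    "write_mag_table",
]


class FormatError(ValueError):
    """A file does not conform to its expected on-disk format."""


class ValidationError(ValueError):
    """A parsed table violates a semantic invariant."""


# Canonical two-level encoding of host status. Files may carry the study
# labels (CRC / Healthy) or the canonical ones directly.
GROUP_ALIASES = {
    "CRC": "case",
    "case": "case",
    "Healthy": "control",
    "control": "control",
}


@dataclass(frozen=True)
class HmmHitRecord:
    """One significant hmmsearch match of a profile against a MAG protein."""

    target_id: str
    mag_id: str
    hmm_id: str
    full_seq_evalue: float
    full_seq_score: float

    def __post_init__(self) -> None:
        if not self.target_id or not self.mag_id or not self.hmm_id:
            raise ValidationError("hit identifiers must be non-empty")
        if self.full_seq_evalue < 0:
            raise ValidationError(
                f"negative E-value {self.full_seq_evalue!r} for {self.target_id}"
            )


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    group: str  # "case" or "control"


@dataclass(frozen=True)
class TaxonomyRecord:
    mag_id: str
    lineage: str
    genus: str


_GENUS_RE = re.compile(r"(?:^|;)\s*g__([^;]*)")

# hmmsearch --tblout: 18 whitespace-delimited columns, then a free-text
# description of target. Column indices used below follow the HMMER manual.
_TBLOUT_MIN_FIELDS = 18


def read_hmm_hits(
    path: str | Path,
    evalue_threshold: float = 1e-5,
    *,
    mag_id: str | None = None,
    mag_delimiter: str = "~",
) -> list[HmmHitRecord]:
    """Parse an hmmsearch per-target table, keeping significant hits only.

    A hit is retained when its full-sequence E-value is <= ``evalue_threshold``
    (inclusive). Lines starting with ``#`` are comments. The MAG id is either
    supplied for the whole file (``mag_id``) or split off the front of each
    target id at ``mag_delimiter``.

    Raises
    ------
    FormatError
        On a data line with fewer than 18 columns or a non-numeric E-value,
        naming the 1-based line number.
    """
    path = Path(path)
    records: list[HmmHitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < _TBLOUT_MIN_FIELDS:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {_TBLOUT_MIN_FIELDS} columns, "
                    f"found {len(fields)}"
                )
            target = fields[0]
            hmm = fields[2]
            try:
                evalue = float(fields[4])
                score = float(fields[5])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric E-value/score field: {exc}"
                ) from None
            if evalue > evalue_threshold:
                continue
            if mag_id is not None:
                mag = mag_id
            else:
                mag, sep, rest = target.partition(mag_delimiter)
                if not sep or not rest:
                    raise FormatError(
                        f"{path}:{lineno}: target id {target!r} lacks MAG "
                        f"delimiter {mag_delimiter!r} and no per-file mag_id given"
                    )
            records.append(
                HmmHitRecord(
                    target_id=target,
                    mag_id=mag,
                    hmm_id=hmm,
                    full_seq_evalue=evalue,
                    full_seq_score=score,
                )
            )
    return records


def write_hmm_hits(records: Iterable[HmmHitRecord], path: str | Path) -> None:
    """Write hits in hmmsearch ``--tblout`` layout (18 columns + description).

    Fields the pipeline does not model (bias, domain expectation numbers) are
    written as neutral placeholders; :func:`read_hmm_hits` round-trips the
    fields it parses.
    """
    with open(path, "w") as fh:
        fh.write("# target name        accession  query name accession  "
                 "full-E  full-score full-bias dom-E dom-score dom-bias "
                 "exp reg clu ov env dom rep inc description of target\n")
        for r in records:
            fh.write(
                f"{r.target_id} - {r.hmm_id} - {r.full_seq_evalue:.3g} "
                f"{r.full_seq_score:.1f} 0.0 {r.full_seq_evalue:.3g} "
                f"{r.full_seq_score:.1f} 0.0 1.0 1 0 0 1 1 1 1 -\n"
            )


def _check_matrix(df: pd.DataFrame, path: Path, kind: str) -> pd.DataFrame:
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: {kind} table has no sample columns")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate row ids {dups}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell in {kind} table: {exc}") from None
    if values.isna().any().any():
        raise ValidationError(f"{path}: missing cells in {kind} table")
    return values


def read_coverage_table(path: str | Path) -> pd.DataFrame:
    """Read a CoverM-style mean coverage table (rows MAGs, columns samples).

    Entries are mean per-base coverage depths and must be non-negative and
    complete; absence of a MAG from a sample is an explicit 0, never NaN.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    values = _check_matrix(df, path, "coverage")
    if (values.values < 0).any():
        bad = values.index[(values.values < 0).any(axis=1)].tolist()
        raise ValidationError(f"{path}: negative coverage for MAG(s) {bad}")
    values.index.name = "Genome"
    return values


def read_taxonomy(path: str | Path) -> list[TaxonomyRecord]:
    """Read a GTDB-Tk summary-style TSV (MAG id, ranked lineage string).

    Accepts the GTDB-Tk column names (``user_genome``, ``classification``) or
    any two-column table in that order. The genus is the ``g__`` token of the
    lineage; a lineage without one yields an empty genus and a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    mag_col = "user_genome" if "user_genome" in cols else cols[0]
    lin_col = "classification" if "classification" in cols else cols[1]
    records = []
    for _, row in df.iterrows():
        lineage = "" if pd.isna(row[lin_col]) else str(row[lin_col])
        m = _GENUS_RE.search(lineage)
        if m is None:
            logger.warning("MAG %s: lineage %r lacks a g__ rank", row[mag_col], lineage)
            genus = ""
        else:
            genus = m.group(1).strip()
        records.append(TaxonomyRecord(str(row[mag_col]), lineage, genus))
    if len({r.mag_id for r in records}) != len(records):
        raise ValidationError(f"{path}: duplicate MAG ids in taxonomy table")
    return records


def write_taxonomy(records: Iterable[TaxonomyRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.mag_id, r.lineage) for r in records],
        columns=["user_genome", "classification"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read sample metadata (sample id, host-status group).

    Group labels are mapped through :data:`GROUP_ALIASES`; anything else is
    rejected. Exactly two group levels are required downstream, so both levels
    need not be present here but unknown labels are fatal.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    sid_col = "sample_id" if "sample_id" in cols else cols[0]
    grp_col = "group" if "group" in cols else cols[1]
    records = []
    for _, row in df.iterrows():
        raw = str(row[grp_col])
        if raw not in GROUP_ALIASES:
            raise ValidationError(
                f"{path}: unknown group label {raw!r}; allowed: "
                f"{sorted(GROUP_ALIASES)}"
            )
        records.append(SampleMetadata(str(row[sid_col]), GROUP_ALIASES[raw]))
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate sample ids")
    return records


def write_metadata(records: Iterable[SampleMetadata], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.sample_id, r.group) for r in records], columns=["sample_id", "group"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a labelled numeric TSV matrix (first column = row ids)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return _check_matrix(df, path, "matrix")


def write_matrix(matrix: pd.DataFrame, path: str | Path, index_name: str | None = None) -> None:
    """Write a labelled matrix as TSV at full float precision (round-trip safe)."""
    out = matrix.copy()
    if index_name is not None:
        out.index.name = index_name
    elif out.index.name is None:
        out.index.name = "id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_profile_table(path: str | Path) -> pd.DataFrame:
    """Read a profile-HMM description table: hmm_id, length (match states).

    Returns a frame indexed by hmm_id with a ``length_kb`` column
    (match states / 1000), plus ``seed_family`` if present.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    if "length" not in df.columns:
        raise FormatError(f"{path}: expected a 'length' column (match states)")
    length = df["length"].astype(float)
    if (length <= 0).any():
        raise ValidationError(f"{path}: non-positive profile length")
    out = pd.DataFrame({"length_kb": length / 1000.0}, index=df.index)
    if "seed_family" in df.columns:
        out["seed_family"] = df["seed_family"].astype(str)
    return out


def write_profile_table(profiles, path: str | Path) -> None:
    """Write profiles (iterable of quantify.HmmProfileInfo) as TSV."""
    rows = [
        (p.hmm_id, int(round(p.length_kb * 1000)), p.seed_family or "")
        for p in profiles
    ]
    pd.DataFrame(rows, columns=["hmm_id", "length", "seed_family"]).to_csv(
        path, sep="\t", index=False
    )


def read_mag_table(path: str | Path) -> pd.DataFrame:
    """Read a MAG description table: mag_id, genome_length_bp.

    Returns a frame indexed by mag_id with a ``genome_length_mb`` column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    if "genome_length_bp" not in df.columns:
        raise FormatError(f"{path}: expected a 'genome_length_bp' column")
    size = df["genome_length_bp"].astype(float)
    if (size <= 0).any():
        raise ValidationError(f"{path}: non-positive genome length")
    return pd.DataFrame({"genome_length_mb": size / 1e6}, index=df.index)


def write_mag_table(mags, path: str | Path) -> None:
    """Write MAG records (iterable of quantify.MagRecord) as TSV."""
    rows = [(m.mag_id, int(round(m.genome_length_mb * 1e6))) for m in mags]
    pd.DataFrame(rows, columns=["mag_id", "genome_length_bp"]).to_csv(
        path, sep="\t", index=False
    )
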