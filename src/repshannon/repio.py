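"""Clonotype tables and sequence records: data model, validation, I/O.

A *clonotype* is the unit of TCR-beta repertoire diversity: the unique
combination of a TRBV gene, a CDR3 amino-acid sequence and a TRBJ gene.
:class:`ClonotypeTable` maps clonotypes to positive integer abundances and
is the currency every other module consumes. :class:`SequenceRecord` is one
annotated sequence (with its CDR3 at nucleotide resolution) feeding the
error-correction step, where nucleotide variants matter.

Tables are read and written as AIRR-Rearrangement-style tab-separated files
(columns ``v_call``, ``junction_aa``, ``j_call``, ``duplicate_count``, with
``junction`` optional); arbitrary column names are supported through a
dialect mapping.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .exceptions import FormatError, ValidationError

__all__ = [
    "ClonotypeKey",
    "SequenceRecord",
    "ClonotypeTable",
    "AIRR_DIALECT",
    "read_clonotype_table",
    "write_clonotype_table",
    "aggregate_records",
]

# 20 proteinogenic amino acids; '*' (stop) is rejected for productive tables.
_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_RE = re.compile(rf"^[{_AA_ALPHABET}]+$")
_NT_RE = re.compile(r"^[ACGT]+$")

#: Default column dialect: AIRR Rearrangement names.
AIRR_DIALECT: dict[str, str] = {
    "v_gene": "v_call",
    "cdr3_aa": "junction_aa",
    "j_gene": "j_call",
    "count": "duplicate_count",
}


class ClonotypeKey(NamedTuple):
    """Identity of a clonotype: (TRBV gene, CDR3 peptide, TRBJ gene)."""

    v_gene: str
    cdr3_aa: str
    j_gene: str


def _validate_key(key: ClonotypeKey) -> None:
    if not key.cdr3_aa:
        raise ValidationError(f"empty CDR3 amino-acid sequence in {key!r}")
    if not _AA_RE.match(key.cdr3_aa):
        raise ValidationError(
            f"CDR3 {key.cdr3_aa!r} contains characters outside the 20 "
            f"amino-acid letters"
        )


@dataclass(frozen=True)
class SequenceRecord:
    """One annotated TRB sequence with CDR3 at nucleotide resolution.

    ``cdr3_nt`` must be an in-frame encoding of ``cdr3_aa``: length
    divisible by 3 and translating exactly to the peptide.
    """

    v_gene: str
    j_gene: str
    cdr3_nt: str
    cdr3_aa: str
    count: int = 1

    def __post_init__(self) -> None:
        if not _NT_RE.match(self.cdr3_nt):
            raise ValidationError(
                f"CDR3 nucleotide sequence {self.cdr3_nt!r} has characters "
                f"outside A/C/G/T"
            )
        if not isinstance(self.count, (int, np.integer)) or self.count < 1:
            raise ValidationError(f"count must be a positive integer, got {self.count!r}")
        if self.cdr3_aa:
            if len(self.cdr3_nt) % 3 != 0:
                raise ValidationError(
                    f"cdr3_nt length {len(self.cdr3_nt)} not divisible by 3"
                )
            translated = str(Seq(self.cdr3_nt).translate())
            if translated != self.cdr3_aa:
                raise ValidationError(
                    f"cdr3_nt translates to {translated!r}, not {self.cdr3_aa!r}"
                )

    @property
    def key(self) -> ClonotypeKey:
        return ClonotypeKey(self.v_gene, self.cdr3_aa, self.j_gene)


def _canonical_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Sort count descending, then key (v, cdr3_aa, j) ascending."""
    return df.sort_values(
        ["count", "v_gene", "cdr3_aa", "j_gene"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)


@dataclass
class ClonotypeTable:
    """Clonotype identities with integer abundances for one sample.

    Rows are kept in the canonical order used by every rank-based operation
    in the package: count descending, ties broken by lexicographic
    (v_gene, cdr3_aa, j_gene). Counts are positive integers (sequences).

    Parameters
    ----------
    entries
        Mapping ``ClonotypeKey -> count`` or a DataFrame with columns
        ``v_gene, cdr3_aa, j_gene, count``.
    sample_id
        Free-text sample label.
    validate
        Check key alphabets (slow for very large tables that are known
        valid by construction, e.g. simulated ones).
    """

    entries: Mapping[ClonotypeKey, int] | pd.DataFrame
    sample_id: str = ""
    validate: bool = True
    _df: pd.DataFrame = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if isinstance(self.entries, pd.DataFrame):
            df = self.entries[["v_gene", "cdr3_aa", "j_gene", "count"]].copy()
        else:
            items = list(self.entries.items())
            df = pd.DataFrame(
                {
                    "v_gene": [k[0] for k, _ in items],
                    "cdr3_aa": [k[1] for k, _ in items],
                    "j_gene": [k[2] for k, _ in items],
                    "count": [c for _, c in items],
                }
            )
        if len(df):
            counts = df["count"].to_numpy()
            if not np.issubdtype(counts.dtype, np.integer):
                if not np.all(np.equal(np.mod(counts, 1), 0)):
                    raise ValidationError("clonotype counts must be integers")
                counts = counts.astype(np.int64)
            if counts.min() < 1:
                raise ValidationError("clonotype counts must be >= 1")
            df["count"] = counts.astype(np.int64)
            if self.validate:
                bad = ~df["cdr3_aa"].str.fullmatch(_AA_RE.pattern.strip("^$"))
                if bad.any():
                    example = df.loc[bad, "cdr3_aa"].iloc[0]
                    raise ValidationError(
                        f"invalid CDR3 amino-acid sequence {example!r}"
                    )
            if df.duplicated(["v_gene", "cdr3_aa", "j_gene"]).any():
                df = (
                    df.groupby(["v_gene", "cdr3_aa", "j_gene"], as_index=False, sort=False)
                    .agg(count=("count", "sum"))
                )
        else:
            df = pd.DataFrame(
                {"v_gene": [], "cdr3_aa": [], "j_gene": [], "count": []}
            ).astype({"count": np.int64})
        self._df = _canonical_frame(df)
        # keep `entries` from holding a second copy
        object.__setattr__(self, "entries", None)

    # -- accessors ---------------------------------------------------------

    @property
    def df(self) -> pd.DataFrame:
        """Canonical-order view (do not mutate)."""
        return self._df

    @property
    def counts(self) -> np.ndarray:
        """Abundances in canonical order (int64, sequences)."""
        return self._df["count"].to_numpy()

    @property
    def frequencies(self) -> np.ndarray:
        """Relative clonotype frequencies in canonical order."""
        return self.counts / self.total

    @property
    def total(self) -> int:
        """Total number of sequences."""
        return int(self._df["count"].sum())

    @property
    def richness(self) -> int:
        """Number of distinct clonotypes."""
        return len(self._df)

    def keys(self) -> list[ClonotypeKey]:
        return [
            ClonotypeKey(v, a, j)
            for v, a, j in zip(
                self._df["v_gene"], self._df["cdr3_aa"], self._df["j_gene"]
            )
        ]

    def to_dict(self) -> dict[ClonotypeKey, int]:
        return dict(zip(self.keys(), (int(c) for c in self.counts)))

    def key_strings(self) -> pd.Series:
        """Joined 'v|cdr3|j' identifiers in canonical order."""
        d = self._df
        return d["v_gene"] + "|" + d["cdr3_aa"] + "|" + d["j_gene"]

    def __len__(self) -> int:
        return self.richness

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClonotypeTable):
            return NotImplemented
        return self._df.equals(other._df)

    def head_table(self, n: int, sample_id: str | None = None) -> "ClonotypeTable":
        """Table of the first *n* clonotypes in canonical order."""
        return ClonotypeTable(
            self._df.iloc[:n], sample_id or self.sample_id, validate=False
        )

    def tail_table(self, n: int, sample_id: str | None = None) -> "ClonotypeTable":
        """Table of everything after the first *n* clonotypes (may be empty)."""
        return ClonotypeTable(
            self._df.iloc[n:], sample_id or self.sample_id, validate=False
        )


def read_clonotype_table(
    path,
    dialect: Mapping[str, str] | None = None,
    sample_id: str | None = None,
) -> ClonotypeTable:
    """Read a tab-separated clonotype table.

    Duplicate-key rows are summed. ``dialect`` maps the internal field
    names (``v_gene``, ``cdr3_aa``, ``j_gene``, ``count``) to the file's
    column headers; the default is the AIRR Rearrangement dialect.
    """
    dialect = dict(dialect or AIRR_DIALECT)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for internal, column in dialect.items():
        if column not in df.columns:
            raise FormatError(f"{path}: missing required column {column!r}")
    renamed = df.rename(columns={v: k for k, v in dialect.items()})
    counts = pd.to_numeric(renamed["count"], errors="coerce")
    bad = counts.isna() | (counts % 1 != 0) | (counts < 1)
    if bad.any():
        line = int(bad.idxmax()) + 2  # 1-based, after header
        raise ValidationError(
            f"{path}: line {line}: count {renamed['count'][bad.idxmax()]!r} "
            f"is not a positive integer"
        )
    renamed["count"] = counts.astype(np.int64)
    return ClonotypeTable(
        renamed[["v_gene", "cdr3_aa", "j_gene", "count"]],
        sample_id=sample_id or str(path),
    )


def write_clonotype_table(table: ClonotypeTable, path) -> None:
    """Write a table as AIRR-style TSV, one row per clonotype.

    Output is deterministic: canonical row order, UTF-8, LF line endings.
    """
    out = table.df.rename(columns=AIRR_DIALECT)
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        out.to_csv(handle, sep="\t", index=False, lineterminator="\n")


def aggregate_records(records: Iterable[SequenceRecord], sample_id: str = "") -> ClonotypeTable:
    """Aggregate sequence records into a clonotype table.

    Counts are summed over records sharing (v_gene, cdr3_aa, j_gene);
    nucleotide variants of one clonotype merge into a single entry.
    """
    acc: dict[ClonotypeKey, int] = {}
    for rec in records:
        key = rec.key
        _validate_key(key)
        acc[key] = acc.get(key, 0) + int(rec.count)
    return ClonotypeTable(acc, sample_id=sample_id)
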