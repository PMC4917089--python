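"""On-disk tables: gene x library tag counts and gene -> GO annotations.

The canonical format is plain TSV ('.' decimals, no thousands separators).
Gene identifiers are opaque strings; absent expression must be written as 0,
missing cells are not permitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import TableFormatError

#: Library roles of the five-library design: two maternal inbreds (AA, BB),
#: the shared paternal inbred (CC) and the two F1 hybrids (AC = AA x CC,
#: BC = BB x CC).
ROLES = ("AA", "BB", "CC", "AC", "BC")

ONTOLOGIES = ("biological_process", "molecular_function", "cellular_component")

#: GAF 2.x Aspect column -> ontology.
GAF_ASPECTS = {"P": "biological_process", "F": "molecular_function",
               "C": "cellular_component"}


@dataclass(frozen=True)
class CountTable:
    """Raw integer tag counts, one column per sequencing library.

    ``counts`` is a gene x library DataFrame with a unique string index of
    gene ids and non-negative integer cells. ``library_totals`` are the exact
    column sums (the "clean tag" totals TPM is computed against).
    """

    counts: pd.DataFrame

    def __post_init__(self):
        c = self.counts
        if c.index.size == 0:
            raise TableFormatError("count table has no genes")
        if c.index.has_duplicates:
            dup = c.index[c.index.duplicated()][0]
            raise TableFormatError(f"duplicate gene id {dup!r}")
        if c.columns.has_duplicates:
            raise TableFormatError("duplicate library ids")
        if not all(np.issubdtype(dt, np.integer) for dt in c.dtypes):
            raise TableFormatError("counts must be integers")
        if (c.to_numpy() < 0).any():
            raise TableFormatError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def __eq__(self, other) -> bool:
        return isinstance(other, CountTable) and self.counts.equals(other.counts)


@dataclass(frozen=True)
class AnnotationTable:
    """Deduplicated (gene_id, term_id, ontology, term_name) records."""

    records: pd.DataFrame

    def __post_init__(self):
        r = self.records
        expected = ["gene_id", "term_id", "ontology", "term_name"]
        if list(r.columns) != expected:
            raise TableFormatError(f"annotation columns must be {expected}")
        bad = set(r["ontology"]) - set(ONTOLOGIES)
        if bad:
            raise TableFormatError(f"unknown ontology {sorted(bad)[0]!r}")
        if r.duplicated(["gene_id", "term_id"]).any():
            raise TableFormatError("duplicate (gene_id, term_id) pair")

    def term_to_genes(self) -> dict[str, set]:
        out: dict[str, set] = {}
        for term, sub in self.records.groupby("term_id"):
            out[term] = set(sub["gene_id"])
        return out

    def term_info(self) -> pd.DataFrame:
        """One row per term: ontology and name."""
        return (self.records.drop_duplicates("term_id")
                .set_index("term_id")[["ontology", "term_name"]])

    def __len__(self) -> int:
        return len(self.records)


_INT_RE = r"\d+"


def read_count_table(path) -> CountTable:
    """Read a TSV count matrix (header ``gene_id<TAB>lib1<TAB>...``).

    Raises :class:`TableFormatError` naming the offending line for duplicate
    gene ids, non-integer/negative cells, or ragged rows.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str,
                     keep_default_na=False, na_values=[], skip_blank_lines=False)
    if df.shape[1] < 2:
        raise TableFormatError("count table needs a gene id column and at "
                               "least one library column")
    gene_col = df.columns[0]
    genes = df[gene_col]
    if genes.duplicated().any():
        i = int(np.flatnonzero(genes.duplicated())[0])
        raise TableFormatError(
            f"line {i + 2}: duplicate gene id {genes.iloc[i]!r}")
    body = df.drop(columns=gene_col)
    empty = body.isna() | (body == "")
    if empty.to_numpy().any():
        i = int(np.flatnonzero(empty.any(axis=1))[0])
        raise TableFormatError(f"line {i + 2}: ragged row")
    ok = body.apply(lambda col: col.str.fullmatch(_INT_RE).fillna(False))
    if not ok.to_numpy().all():
        i = int(np.flatnonzero(~ok.all(axis=1))[0])
        col = ok.columns[int(np.flatnonzero(~ok.iloc[i])[0])]
        raise TableFormatError(
            f"line {i + 2}: non-integer count {body.loc[body.index[i], col]!r} "
            f"in library {col!r}")
    counts = body.astype(np.int64)
    counts.index = pd.Index(genes, name="gene_id")
    return CountTable(counts)


def write_count_table(table: CountTable, path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_annotations(path, dialect: str = "tsv") -> AnnotationTable:
    """Read gene -> GO annotations from a 4-column TSV or a GAF 2.x file.

    GAF Aspect codes P/F/C map onto the three ontologies; comment lines
    (leading '!') are skipped; (gene, term) pairs are deduplicated. An empty
    file yields an empty table with a warning, not an error.
    """
    if dialect == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", header=None,
                             names=["gene_id", "term_id", "ontology",
                                    "term_name"],
                             dtype=str, keep_default_na=False, na_values=[])
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=["gene_id", "term_id", "ontology",
                                       "term_name"], dtype=str)
    elif dialect == "gaf":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("!"):
                    continue
                fields = line.split("\t")
                if len(fields) < 9:
                    raise TableFormatError(
                        f"line {lineno}: GAF row has {len(fields)} fields, "
                        "expected >= 9")
                aspect = fields[8]
                if aspect not in GAF_ASPECTS:
                    raise TableFormatError(
                        f"line {lineno}: unknown GAF aspect {aspect!r}")
                rows.append((fields[1], fields[4], GAF_ASPECTS[aspect], ""))
        df = pd.DataFrame(rows, columns=["gene_id", "term_id", "ontology",
                                         "term_name"], dtype=str)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if df.empty:
        warnings.warn(f"annotation file {path} is empty", stacklevel=2)
    df = df.drop_duplicates(["gene_id", "term_id"]).reset_index(drop=True)
    return AnnotationTable(df)


def write_annotations(annotations: AnnotationTable, path) -> None:
    annotations.records.to_csv(path, sep="\t", index=False, header=False)
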