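"""Readers and writers for every external representation the pipeline touches.

Matrices are CSV/TSV with a header row of sample identifiers and gene symbols
in the first column (genes-as-rows is the internal orientation); gene sets use
the MSigDB GMT dialect; transcription-factor lists are plain text, one symbol
per line.  Gene symbols from all sources are canonicalised identically —
uppercased and whitespace-stripped — because DepMap, MSigDB and tumour WTS
symbol namespaces differ only in case/whitespace at this fidelity.

Missing values: "" / "NA" / "NaN" (any case) are accepted on read; "NA" is
written, covering DepMap CSV and R-exported TSV dialects.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, ValidationError

MISSING_TOKENS = {"", "na", "nan"}
_ENTREZ_SUFFIX = re.compile(r"\s*\([^()]*\)\s*$")


def canonical_symbol(symbol: str, strip_suffix: bool = False) -> str:
    """Uppercase + strip; optionally drop a trailing parenthesised token
    (DepMap "SYMBOL (ENTREZ)" headers)."""
    s = str(symbol).strip()
    if strip_suffix:
        s = _ENTREZ_SUFFIX.sub("", s)
    return s.upper()


@dataclass(frozen=True)
class MatrixTable:
    """Genes x samples table of real values with missing cells allowed.

    ``data`` is a float DataFrame whose index holds canonical gene symbols and
    whose columns hold sample / cell-line identifiers.  NaN encodes missing;
    infinities are rejected.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise IntegrityError(f"duplicate gene identifiers: {dup[:5]}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise IntegrityError(f"duplicate sample identifiers: {dup[:5]}")
        vals = df.to_numpy(dtype=float, copy=False)
        if np.isinf(vals).any():
            raise IntegrityError("matrix contains infinite values")

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_cols(self, cols: Iterable[str]) -> "MatrixTable":
        cols = list(cols)
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise ValidationError(f"unknown sample identifiers: {missing[:5]}")
        return MatrixTable(self.data.loc[:, cols])

    def row(self, gene: str) -> np.ndarray:
        if gene not in self.data.index:
            raise ValidationError(f"gene {gene!r} not in matrix")
        return self.data.loc[gene].to_numpy(dtype=float)

    def equals(self, other: "MatrixTable") -> bool:
        if self.row_ids != other.row_ids or self.col_ids != other.col_ids:
            return False
        a, b = self.values, other.values
        return bool(np.all((a == b) | (np.isnan(a) & np.isnan(b))))


def read_matrix(
    path: str | Path,
    orientation: str = "genes-as-rows",
    delimiter: str | None = None,
    strip_suffix: bool = False,
) -> MatrixTable:
    """Parse a delimited matrix into the genes-as-rows internal orientation.

    ``delimiter`` defaults by extension (.tsv/.txt -> tab, else comma).
    A malformed numeric cell raises :class:`FormatError` naming row and
    column; duplicate gene symbols after canonicalisation raise
    :class:`IntegrityError`.
    """
    path = Path(path)
    if orientation not in ("genes-as-rows", "genes-as-cols"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str,
                      keep_default_na=False, comment="#")
    if orientation == "genes-as-cols":
        raw = raw.T
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        cells = raw[col].str.strip()
        is_missing = cells.str.lower().isin(MISSING_TOKENS).to_numpy()
        present = cells.to_numpy()[~is_missing]
        try:
            # numpy's str->float64 conversion is correctly rounded, so the
            # round-trip with the shortest-repr writer is bit-exact
            parsed = present.astype(np.float64)
        except ValueError:
            for gene, token, miss in zip(raw.index, cells, is_missing):
                if miss:
                    continue
                try:
                    float(token)
                except ValueError:
                    raise FormatError(
                        f"{path}: cell at row {gene!r}, column {col!r} is not "
                        f"numeric: {token!r}") from None
            raise  # pragma: no cover - unreachable
        vals = np.full(len(cells), np.nan)
        vals[~is_missing] = parsed
        numeric[col] = vals
    numeric.index = [canonical_symbol(g, strip_suffix) for g in numeric.index]
    numeric.columns = [str(c).strip() for c in numeric.columns]
    if pd.Index(numeric.index).has_duplicates:
        dup = pd.Index(numeric.index)
        dup = dup[dup.duplicated()].unique().tolist()
        raise IntegrityError(f"{path}: duplicate gene symbols after canonicalization: {dup[:5]}")
    numeric.index.name = raw.index.name or "gene"
    return MatrixTable(numeric)


def write_matrix(m: MatrixTable, path: str | Path, delimiter: str | None = None) -> Path:
    """Write a MatrixTable; read_matrix(write_matrix(m)) reproduces m exactly.

    Values are serialised with pandas' shortest round-trip float repr; missing
    cells become "NA".
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = m.data.copy()
    df.index.name = df.index.name or "gene"
    df.to_csv(path, sep=delimiter, na_rep="NA")
    return path


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise IntegrityError(f"gene set {self.name!r} has duplicate members")


@dataclass
class GeneSetCollection:
    """Ordered mapping of set name -> GeneSet."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def add(self, gs: GeneSet) -> None:
        if gs.name in self.sets:
            raise IntegrityError(f"duplicate gene-set name {gs.name!r}")
        self.sets[gs.name] = gs

    @property
    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse an MSigDB-style GMT file (name TAB description TAB members...).

    Member symbols are canonicalised; duplicates within a set collapse to the
    first occurrence.  A line with fewer than three fields raises
    :class:`FormatError` with its line number.
    """
    path = Path(path)
    coll = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >= 3 tab-separated "
                                  f"fields, got {len(fields)}")
            name, desc = fields[0].strip(), fields[1]
            seen: dict[str, None] = {}
            for tok in fields[2:]:
                sym = canonical_symbol(tok)
                if sym and sym not in seen:
                    seen[sym] = None
            if not seen:
                raise FormatError(f"{path}: line {lineno}: set {name!r} has no members")
            coll.add(GeneSet(name, desc, tuple(seen)))
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for gs in coll:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")
    return path


def read_symbol_list(path: str | Path) -> list[str]:
    """One symbol per line; '#' comments and blanks allowed; uppercased,
    deduplicated, first-appearance order."""
    path = Path(path)
    out: dict[str, None] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            out[canonical_symbol(line)] = None
    if not out:
        raise ValidationError(f"{path}: no symbols found")
    return list(out)


def write_symbol_list(symbols: Iterable[str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for s in symbols:
            fh.write(f"{s}\n")
    return path


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    provenance: Mapping[str, object] | None = None,
    index: bool = True,
) -> Path:
    """Write a result table as TSV with a '#'-prefixed provenance block."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if provenance:
            for key, val in provenance.items():
                fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", na_rep="NA", index=index)
    return path


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table` (comments skipped)."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
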