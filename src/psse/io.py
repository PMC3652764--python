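"""Reading and writing the formats the tool touches.

Supported formats
-----------------
* SS-FASTA: ordinary FASTA whose sequence letters are the 3-state alphabet
  {H, E, C} (a predicted secondary structure per record).
* PSIPRED ``.ss2`` VFORMAT: comment/blank header lines followed by rows of
  ``index  residue  ss-letter  confC confH confE``.  Only the ss-letter
  column is used; the confidence columns are parsed but discarded.
* Label tables: two-column TSV/CSV mapping sequence id to structural class.
* Feature tables: CSV with an ``id`` column, one named feature per column,
  and the producing recipe embedded as a ``# recipe:`` comment line.

The 3-state alphabet is strict: 8-state DSSP letters (G, I, T, S, B, ...)
are rejected rather than silently reduced.
"""

from __future__ import annotations

import io as _io
import json
from os import PathLike
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlphabetError, FormatError, ParseError
from .features import FeatureMatrix
from .sequence import LabeledDataset, SSSequence, normalize_class


def read_ss_fasta(path: str | PathLike) -> list[SSSequence]:
    """Read an SS-FASTA file into a list of :class:`SSSequence`.

    Whitespace inside sequence lines is stripped and letters are upper-cased
    before validation; any symbol outside {H, E, C} raises
    :class:`~psse.errors.AlphabetError` naming the record and position.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip() == "":
            continue
        if not line.startswith(">"):
            raise ParseError(
                f"{path}: line {lineno}: expected a '>' header before "
                "sequence data"
            )
        break
    else:
        raise ParseError(f"{path}: no FASTA records found")
    out = []
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        seq = "".join(str(rec.seq).split())
        try:
            out.append(SSSequence(id=rec.id, seq=seq))
        except AlphabetError as exc:
            raise AlphabetError(f"{path}: {exc}") from None
    if not out:
        raise ParseError(f"{path}: no FASTA records found")
    return out


def write_ss_fasta(
    sequences: Iterable[SSSequence], path: str | PathLike, wrap: int = 60
) -> None:
    """Write sequences as SS-FASTA (line-wrapped at ``wrap`` columns)."""
    records = [
        SeqRecord(Seq(s.seq), id=s.id, description="") for s in sequences
    ]
    writer = SeqIO.FastaIO.FastaWriter(Path(path).open("w"), wrap=wrap)
    writer.write_file(records)


def read_psipred_ss2(
    path: str | PathLike, id: str | None = None
) -> SSSequence:
    """Read a PSIPRED vertical-format ``.ss2`` prediction.

    The secondary-structure letter (third column) of every data row is
    concatenated in row order.  The record id defaults to the file stem.

    Raises
    ------
    FormatError
        On non-monotone residue indices, missing columns, or an empty data
        section.
    """
    path = Path(path)
    letters: list[str] = []
    prev_index = 0
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if line == "" or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise FormatError(
                f"{path}: line {lineno}: expected at least 3 columns "
                f"(index, residue, ss), got {len(fields)}"
            )
        try:
            index = int(fields[0])
        except ValueError:
            raise FormatError(
                f"{path}: line {lineno}: residue index {fields[0]!r} "
                "is not an integer"
            ) from None
        if index <= prev_index:
            raise FormatError(
                f"{path}: line {lineno}: residue index {index} does not "
                f"increase (previous was {prev_index})"
            )
        prev_index = index
        ss = fields[2].upper()
        if ss not in ("H", "E", "C"):
            raise FormatError(
                f"{path}: line {lineno}: secondary-structure letter "
                f"{fields[2]!r} is not in {{H, E, C}}"
            )
        letters.append(ss)
    if not letters:
        raise FormatError(f"{path}: no data rows found")
    return SSSequence(id=id if id is not None else path.stem,
                      seq="".join(letters))


def read_labels(path: str | PathLike) -> dict[str, str]:
    """Read a two-column (id, class) table; classes are normalized.

    The delimiter is sniffed from the header (tab if present, else comma);
    duplicate ids and unknown class names raise :class:`FormatError`.
    """
    path = Path(path)
    labels: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if line == "" or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split(",")
        if len(fields) != 2:
            raise FormatError(
                f"{path}: line {lineno}: expected 2 columns, got {len(fields)}"
            )
        sid, cls = fields[0].strip(), fields[1].strip()
        if sid in labels:
            raise FormatError(f"{path}: line {lineno}: duplicate id {sid!r}")
        try:
            labels[sid] = normalize_class(cls)
        except Exception as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from None
    if not labels:
        raise FormatError(f"{path}: no label rows found")
    return labels


def read_dataset(
    fasta_path: str | PathLike, labels_path: str | PathLike
) -> LabeledDataset:
    """Read sequences plus labels into a :class:`LabeledDataset`."""
    return LabeledDataset(
        sequences=read_ss_fasta(fasta_path), labels=read_labels(labels_path)
    )


_RECIPE_PREFIX = "# recipe: "


def write_feature_table(fm: FeatureMatrix, path: str | PathLike) -> None:
    """Write a feature matrix as CSV (17 significant digits), recipe embedded."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_RECIPE_PREFIX + json.dumps(fm.recipe, sort_keys=True) + "\n")
        fm.values.to_csv(fh, index_label="id", float_format="%.17g")


def read_feature_table(path: str | PathLike) -> FeatureMatrix:
    """Read a CSV feature matrix written by :func:`write_feature_table`."""
    path = Path(path)
    recipe: dict = {}
    with path.open() as fh:
        pos = fh.tell()
        first = fh.readline()
        if first.startswith(_RECIPE_PREFIX):
            recipe = json.loads(first[len(_RECIPE_PREFIX):])
        else:
            fh.seek(pos)
        try:
            df = pd.read_csv(fh, index_col="id", comment="#")
        except Exception as exc:
            raise FormatError(f"{path}: {exc}") from None
    df.index = df.index.astype(str)
    if len(df) == 0:
        df = df.astype(float)
    bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if bad:
        raise FormatError(f"{path}: non-numeric values in columns {bad}")
    if df.isna().any().any():
        raise FormatError(f"{path}: missing values in feature table")
    return FeatureMatrix(values=df, recipe=recipe)
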