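"""Expression-dataset container and plain-text I/O.

One :class:`ExpressionDataset` holds a single study's probe- or gene-level
intensity matrix (rows = probes/genes, columns = samples) together with a
``scale`` flag recording whether the values are raw linear intensities or
log2-transformed ones.  Two on-disk dialects are supported:

* plain TSV: first column holds row identifiers, header row holds sample
  identifiers;
* a GEO-Series-Matrix-like dialect: ``!``-prefixed metadata lines, with the
  data table enclosed between ``!series_matrix_table_begin`` and
  ``!series_matrix_table_end`` markers and values optionally double-quoted.
"""
from __future__ import annotations

import logging
import pathlib
from dataclasses import dataclass, replace

import pandas as pd

logger = logging.getLogger(__name__)

LINEAR = "linear"
LOG2 = "log2"

#: float format used by every TSV writer in the package; fixed so that
#: repeated runs with the same seed are byte-identical.
FLOAT_FORMAT = "%.10g"
NA_REP = "NA"

TABLE_BEGIN = "!series_matrix_table_begin"
TABLE_END = "!series_matrix_table_end"


@dataclass
class ExpressionDataset:
    """A single study's expression matrix.

    Parameters
    ----------
    dataset_id :
        Identifier of the study (e.g. a simulated ``DS003`` or a GEO-style
        accession).
    values :
        Rows indexed by probe or gene identifier, columns by sample
        identifier.  Identifiers must be unique along both axes.
    scale :
        ``"linear"`` for raw intensities, ``"log2"`` after log transformation.
    """

    dataset_id: str
    values: pd.DataFrame
    scale: str = LINEAR

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG2):
            raise ValueError(
                f"dataset {self.dataset_id!r}: scale must be "
                f"{LINEAR!r} or {LOG2!r}, got {self.scale!r}"
            )
        if self.values.index.has_duplicates:
            raise ValueError(
                f"dataset {self.dataset_id!r}: duplicate row identifiers"
            )
        if self.values.columns.has_duplicates:
            raise ValueError(
                f"dataset {self.dataset_id!r}: duplicate sample identifiers"
            )

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def with_values(self, values: pd.DataFrame, scale: str) -> "ExpressionDataset":
        """Return a copy holding ``values`` on the given scale."""
        return replace(self, values=values, scale=scale)


# ---------------------------------------------------------------------------
# plain TSV dialect
# ---------------------------------------------------------------------------

def read_expression_tsv(path, dataset_id: str | None = None,
                        scale: str = LINEAR) -> ExpressionDataset:
    """Read a plain TSV expression matrix (row-ID column + sample columns)."""
    path = pathlib.Path(path)
    values = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    values.index = values.index.astype(str)
    if dataset_id is None:
        dataset_id = path.stem
    return ExpressionDataset(dataset_id, values, scale=scale)


def write_expression_tsv(dataset: ExpressionDataset, path) -> None:
    df = dataset.values.copy()
    df.index.name = df.index.name or "id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, na_rep=NA_REP)


# ---------------------------------------------------------------------------
# GEO-Series-Matrix-like dialect
# ---------------------------------------------------------------------------

def _unquote(token: str) -> str:
    token = token.strip()
    if len(token) >= 2 and token[0] == '"' and token[-1] == '"':
        token = token[1:-1]
    return token


def read_series_matrix(path, dataset_id: str | None = None,
                       scale: str = LINEAR) -> ExpressionDataset:
    """Read the series-matrix dialect.

    Metadata lines start with ``!``; the table sits between the
    ``!series_matrix_table_begin`` / ``!series_matrix_table_end`` markers.
    The first table row is the header (``ID_REF`` + sample ids); fields may
    be double-quoted.
    """
    path = pathlib.Path(path)
    metadata: dict[str, str] = {}
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            low = line.strip().lower()
            if low == TABLE_BEGIN:
                in_table = True
                continue
            if low == TABLE_END:
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!"):
                key, _, value = line[1:].partition("\t")
                metadata[key.strip()] = _unquote(value)
    if not table_lines:
        raise ValueError(f"{path}: no table between {TABLE_BEGIN} and {TABLE_END}")
    header = [_unquote(t) for t in table_lines[0].split("\t")]
    rows = []
    index = []
    for line in table_lines[1:]:
        fields = [_unquote(t) for t in line.split("\t")]
        index.append(fields[0])
        rows.append([float("nan") if f in ("", "null", NA_REP) else float(f)
                     for f in fields[1:]])
    values = pd.DataFrame(rows, index=pd.Index(index, name=header[0]),
                          columns=header[1:])
    if dataset_id is None:
        dataset_id = metadata.get("Series_geo_accession") or path.stem
    return ExpressionDataset(dataset_id, values, scale=scale)


def write_series_matrix(dataset: ExpressionDataset, path,
                        metadata: dict[str, str] | None = None) -> None:
    """Write the series-matrix dialect (used mainly for round-trip tests)."""
    with open(path, "w") as fh:
        fh.write(f'!Series_geo_accession\t"{dataset.dataset_id}"\n')
        for key, value in (metadata or {}).items():
            fh.write(f'!{key}\t"{value}"\n')
        fh.write(TABLE_BEGIN + "\n")
        fh.write("\t".join(['"ID_REF"'] + [f'"{s}"' for s in dataset.sample_ids]))
        fh.write("\n")
        for rid, row in dataset.values.iterrows():
            cells = [f'"{rid}"'] + [FLOAT_FORMAT % v for v in row.to_numpy()]
            fh.write("\t".join(cells) + "\n")
        fh.write(TABLE_END + "\n")


# ---------------------------------------------------------------------------
# probe → gene mapping
# ---------------------------------------------------------------------------

def read_probe_map(path) -> pd.Series:
    """Read a two-column (probe, gene) TSV into a probe→gene Series.

    Each probe must map to exactly one gene; conflicting rows raise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (probe, gene)")
    probe, gene = df.columns[:2]
    df = df.drop_duplicates()
    if df[probe].duplicated().any():
        bad = df.loc[df[probe].duplicated(), probe].iloc[0]
        raise ValueError(f"{path}: probe {bad!r} maps to more than one gene")
    mapping = pd.Series(df[gene].to_numpy(), index=df[probe].to_numpy())
    mapping.index.name = "probe"
    mapping.name = "gene"
    return mapping


def write_probe_map(mapping: pd.Series, path) -> None:
    df = pd.DataFrame({"probe": mapping.index, "gene": mapping.to_numpy()})
    df.to_csv(path, sep="\t", index=False)
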