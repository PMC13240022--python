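"""Readers and writers for the exchanged formats.

Expression matrices are accepted as dense TSV (cells × genes) or as a
Matrix-Market triplet directory (matrix.mtx genes × cells with genes.tsv and
barcodes.tsv, the usual single-cell convention); gene sets as GMT (set name =
TF); cell tables, driver tables and cohorts as TSV; networks as GraphML plus
an edge-list TSV. All float output is written at 6 significant digits so
re-exports of identical results are byte-identical.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .errors import InputError, ValidationError

logger = logging.getLogger("regfate")

FLOAT_FORMAT = "%.6g"


# --------------------------------------------------------------------------
# expression
# --------------------------------------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a cells × genes expression matrix from dense TSV or an MTX directory."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"expression input not found: {path}")
    if path.is_dir():
        mtx = path / "matrix.mtx"
        genes_file = path / "genes.tsv"
        barcodes_file = path / "barcodes.tsv"
        for f in (mtx, genes_file, barcodes_file):
            if not f.exists():
                raise InputError(f"MTX directory is missing {f.name}")
        matrix = np.asarray(mmread(str(mtx)).todense())
        genes = pd.read_csv(genes_file, sep="\t", header=None)[0].tolist()
        cells = pd.read_csv(barcodes_file, sep="\t", header=None)[0].tolist()
        if matrix.shape != (len(genes), len(cells)):
            raise ValidationError(
                f"MTX shape {matrix.shape} does not match genes×barcodes "
                f"({len(genes)}, {len(cells)})")
        frame = pd.DataFrame(matrix.T, index=cells, columns=genes)
    else:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.duplicated().any():
        raise ValidationError("duplicated cell ids in expression matrix")
    if frame.columns.duplicated().any():
        dup = frame.columns[frame.columns.duplicated()]
        logger.warning("dropping %d duplicated gene columns", len(dup))
        frame = frame.loc[:, ~frame.columns.duplicated()]
    return frame


def write_expression_mtx(expression: pd.DataFrame, outdir: str | Path) -> None:
    """Write genes × cells matrix.mtx + genes.tsv + barcodes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sparse = csr_matrix(expression.to_numpy(dtype=float).T)
    mmwrite(str(outdir / "matrix.mtx"), sparse)
    pd.Series(expression.columns).to_csv(outdir / "genes.tsv", sep="\t",
                                         index=False, header=False)
    pd.Series(expression.index).to_csv(outdir / "barcodes.tsv", sep="\t",
                                       index=False, header=False)


def write_expression_tsv(expression: pd.DataFrame, path: str | Path) -> None:
    expression.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


# --------------------------------------------------------------------------
# gene sets (GMT) and tables
# --------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from GMT: name <tab> description <tab> genes..."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"GMT file not found: {path}")
    sets: dict[str, list[str]] = {}
    with open(path) as handle:
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            name = parts[0]
            if name in sets:
                raise ValidationError(f"duplicate gene-set name in GMT: {name}")
            sets[name] = [g for g in parts[2:] if g]
    if not sets:
        raise InputError(f"no gene sets parsed from {path}")
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              description: str = "regfate") -> None:
    with open(path, "w") as handle:
        for name, genes in sets.items():
            handle.write("\t".join([name, description, *genes]) + "\n")


def read_cell_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"cell table not found: {path}")
    table = pd.read_csv(path, sep="\t", index_col=0)
    if table.index.duplicated().any():
        raise ValidationError("duplicated cell ids in cell table")
    return table


def read_drivers(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"driver table not found: {path}")
    table = pd.read_csv(path, sep="\t")
    missing = {"gene", "fate", "fdr"} - set(table.columns)
    if missing:
        raise ValidationError(f"driver table missing columns: {sorted(missing)}")
    return table


def read_cohort(expression_path: str | Path, survival_path: str | Path
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    for p in (expression_path, survival_path):
        if not Path(p).exists():
            raise InputError(f"cohort input not found: {p}")
    expression = pd.read_csv(expression_path, sep="\t", index_col=0)
    survival = pd.read_csv(survival_path, sep="\t", index_col=0)
    missing = {"time", "event"} - set(survival.columns)
    if missing:
        raise ValidationError(f"survival table missing columns: {sorted(missing)}")
    return expression, survival


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


# --------------------------------------------------------------------------
# alignment / harmonisation
# --------------------------------------------------------------------------

def align_inputs(expression: pd.DataFrame, cell_table: pd.DataFrame,
                 regulons: dict[str, list[str]]
                 ) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]]]:
    """Intersect identifiers consistently across the three single-cell inputs.

    Cell-table rows are aligned to the matrix rows (an annotated cell missing
    from the matrix is an error naming the id); regulon targets absent from
    the matrix are dropped with a logged count; regulons left empty are
    removed.
    """
    unknown = cell_table.index.difference(expression.index)
    if len(unknown) > 0:
        raise ValidationError(f"cell id not in expression matrix: {unknown[0]!r}")
    cells = expression.index.intersection(cell_table.index)
    if cells.empty:
        raise ValidationError("no overlapping cells between matrix and cell table")
    expression = expression.loc[cells]
    cell_table = cell_table.loc[cells]

    genes = set(expression.columns)
    cleaned: dict[str, list[str]] = {}
    dropped = 0
    for tf, targets in regulons.items():
        kept = [g for g in targets if g in genes]
        dropped += len(targets) - len(kept)
        if kept:
            cleaned[tf] = kept
        else:
            logger.warning("regulon %s has no targets in the matrix; removed", tf)
    if dropped:
        logger.warning("dropped %d regulon targets absent from the expression matrix", dropped)
    if not cleaned:
        raise ValidationError("zero overlapping genes between regulons and matrix")
    return expression, cell_table, cleaned


# --------------------------------------------------------------------------
# networks
# --------------------------------------------------------------------------

def write_network(graph: nx.DiGraph, basepath: str | Path) -> None:
    """Write GraphML plus an edge-list TSV next to it (basepath without suffix)."""
    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(graph, str(basepath.with_suffix(".graphml")))
    edges = pd.DataFrame(list(graph.edges), columns=["tf", "target"])
    write_table(edges, basepath.with_suffix(".edges.tsv"), index=False)


def read_network(path: str | Path) -> nx.DiGraph:
    if not Path(path).exists():
        raise InputError(f"network file not found: {path}")
    return nx.read_graphml(str(path))


def ensure_writable(outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not os.access(outdir, os.W_OK):
        raise InputError(f"output directory is not writable: {outdir}")
    return outdir
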