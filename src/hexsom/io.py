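"""Tabular input/output: matrix reading and result serialisation.

TSV is the canonical on-disk format (CSV accepted on read; delimiter can be
auto-sniffed from the header line).  The matrix layout is one header row of
sample identifiers and one leading column of gene identifiers.  Rows with
any missing or non-numeric cell are dropped with a logged count — training
cannot use incomplete vectors.  Numbers are serialised with 17 significant
digits, which round-trips float64 values exactly (well inside the 1e-12
round-trip contract).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .hexgrid import HexMapSpec
from .landscape import SampleLandscape
from .mapstats import Mapping, NodeScalarField
from .overlay import OverlayResult
from .partition import MetaClustering
from .trainer import Codebook, InputMatrix, TrainResult

logger = logging.getLogger("hexsom")

__all__ = ["read_matrix", "read_codebook", "write_results"]

_FLOAT_FMT = "%.17g"


def _sniff_delimiter(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_matrix(path, delimiter: str = "auto") -> InputMatrix:
    """Read a genes x samples matrix from a TSV/CSV file.

    First row: sample ids; first column: gene ids.  Rows containing any
    non-numeric or missing cell are dropped (count logged); duplicated gene
    ids are an error.
    """
    path = Path(path)
    if delimiter == "auto":
        sep = _sniff_delimiter(path)
    elif delimiter in ("tab", "\t"):
        sep = "\t"
    elif delimiter in ("comma", ","):
        sep = ","
    else:
        raise ValueError(f"unknown delimiter {delimiter!r}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - message wrapper
        raise ValueError(f"could not parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate gene id(s): {dup[:10]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    keep = numeric.notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("%s: dropped %d row(s) with missing/non-numeric cells",
                       path.name, dropped)
    numeric = numeric.loc[keep]
    if numeric.shape[0] == 0:
        raise ValueError(f"{path}: no usable (fully numeric) rows")
    return InputMatrix(
        values=numeric.to_numpy(dtype=float),
        row_ids=[str(g) for g in numeric.index],
        col_ids=[str(s) for s in numeric.columns],
    )


def _write_tsv(df: pd.DataFrame, path, index_label: str) -> None:
    df.to_csv(path, sep="\t", index=True, index_label=index_label,
              float_format=_FLOAT_FMT)


def write_codebook(codebook: Codebook, path) -> None:
    df = pd.DataFrame(
        codebook.prototypes,
        index=np.arange(1, codebook.spec.node_count + 1),
        columns=codebook.col_ids,
    )
    _write_tsv(df, path, "node")


def read_codebook(path, spec: HexMapSpec) -> Codebook:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return Codebook(
        prototypes=df.to_numpy(dtype=float),
        spec=spec,
        col_ids=[str(c) for c in df.columns],
    )


def write_mapping(mapping: Mapping, path, clustering: MetaClustering | None = None) -> None:
    data = {
        "bmu": mapping.bmu,
        "ties": [",".join(map(str, t)) for t in mapping.ties],
    }
    if clustering is not None:
        data["meta_cluster"] = clustering.gene_labels(mapping.bmu)
    df = pd.DataFrame(data, index=mapping.gene_ids)
    _write_tsv(df, path, "gene")


def write_node_stats(
    umatrix_field: NodeScalarField, mapping: Mapping, path,
    clustering: MetaClustering | None = None,
) -> None:
    data = {"umatrix": umatrix_field.values, "hits": mapping.hits}
    if clustering is not None:
        data["meta_cluster"] = clustering.labels
        seedset = set(clustering.seeds)
        data["is_seed"] = [int(j in seedset) for j in
                           range(1, len(clustering.labels) + 1)]
    df = pd.DataFrame(data, index=np.arange(1, mapping.node_count + 1))
    _write_tsv(df, path, "node")


def write_landscape(landscape: SampleLandscape, path) -> None:
    rows = [
        {"sample": s, "cell_x": landscape.placement[s][0],
         "cell_y": landscape.placement[s][1],
         "order": landscape.order.index(s)}
        for s in sorted(landscape.placement)
    ]
    pd.DataFrame(rows).set_index("sample").to_csv(path, sep="\t")


def write_overlay(result: OverlayResult, path) -> None:
    df = pd.DataFrame(
        result.values,
        index=np.arange(1, result.values.shape[0] + 1),
        columns=result.col_ids,
    )
    df["weighted_hits"] = result.weighted_hits
    df["undefined"] = result.undefined_mask.astype(int)
    _write_tsv(df, path, "node")


def write_results(result, prefix) -> list[Path]:
    """Serialise any result object under ``<prefix>_<kind>.tsv``.

    Accepts a TrainResult (codebook + mapping + node stats), MetaClustering
    paired with a TrainResult via :func:`write_train_with_clusters`, a
    SampleLandscape or an OverlayResult.  Returns the written paths.
    """
    from .mapstats import umatrix as _umx

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if isinstance(result, TrainResult):
        p = prefix.parent / f"{prefix.name}_codebook.tsv"
        write_codebook(result.codebook, p)
        written.append(p)
        p = prefix.parent / f"{prefix.name}_mapping.tsv"
        write_mapping(result.mapping, p)
        written.append(p)
        p = prefix.parent / f"{prefix.name}_nodestats.tsv"
        write_node_stats(_umx(result.codebook), result.mapping, p)
        written.append(p)
    elif isinstance(result, SampleLandscape):
        p = prefix.parent / f"{prefix.name}_landscape.tsv"
        write_landscape(result, p)
        written.append(p)
    elif isinstance(result, OverlayResult):
        p = prefix.parent / f"{prefix.name}_overlay.tsv"
        write_overlay(result, p)
        written.append(p)
    else:
        raise TypeError(f"cannot serialise {type(result).__name__}")
    return written


def write_train_with_clusters(
    result: TrainResult, clustering: MetaClustering, prefix
) -> list[Path]:
    from .mapstats import umatrix as _umx

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    p1 = prefix.parent / f"{prefix.name}_mapping.tsv"
    write_mapping(result.mapping, p1, clustering)
    p2 = prefix.parent / f"{prefix.name}_nodestats.tsv"
    write_node_stats(_umx(result.codebook), result.mapping, p2, clustering)
    return [p1, p2]
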