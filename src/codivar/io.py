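"""Labelled-matrix I/O (TSV with a header row and an index column) and
export of decomposition artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import Block, Decomposition, MultiBlock
from .exceptions import InvalidInputError


def read_labeled_matrix(path, block_id: str = "1", sep: str = "\t") -> Block:
    """Read a delimited text matrix: first row variable labels, first
    column object labels.  Errors name the offending row."""
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, header=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise InvalidInputError(f"{path}: cannot parse as a labelled matrix: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise InvalidInputError(f"{path}: empty data region")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise InvalidInputError(f"{path}: duplicate object labels {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise InvalidInputError(f"{path}: duplicate variable labels {dups}")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise InvalidInputError(
            f"{path}: non-numeric or missing cell at data row {i + 1} "
            f"(object {df.index[i]!r}, variable {df.columns[j]!r})"
        )
    return Block(
        values=values,
        object_labels=tuple(str(x) for x in df.index),
        variable_labels=tuple(str(x) for x in df.columns),
        block_id=block_id,
    )


def write_labeled_matrix(path, values: np.ndarray, row_labels, col_labels, sep: str = "\t") -> None:
    df = pd.DataFrame(np.asarray(values), index=list(row_labels), columns=list(col_labels))
    df.to_csv(path, sep=sep, float_format="%.17g")


def write_block(path, block: Block, sep: str = "\t") -> None:
    write_labeled_matrix(path, block.values, block.object_labels, block.variable_labels, sep=sep)


def _component_labels(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1}" for i in range(n)]


def write_decomposition(dec: Decomposition, data: MultiBlock, outdir) -> None:
    """Write every part, the scores/loadings and a JSON summary under
    ``outdir``.  One TSV per matrix, same dialect as the inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    obj = data.object_labels
    for k, blk in enumerate(data.blocks):
        var = blk.variable_labels
        tag = f"block{k + 1}"
        write_labeled_matrix(outdir / f"common_{tag}.tsv", dec.common[k], obj, var)
        write_labeled_matrix(outdir / f"distinct_{tag}.tsv", dec.distinct[k], obj, var)
        write_labeled_matrix(outdir / f"residual_{tag}.tsv", dec.residual[k], obj, var)
        cc = dec.common_loadings[k].shape[1]
        write_labeled_matrix(
            outdir / f"common_loadings_{tag}.tsv",
            dec.common_loadings[k], var, _component_labels("c", cc),
        )
        ck = dec.distinct_scores[k].shape[1]
        write_labeled_matrix(
            outdir / f"distinct_scores_{tag}.tsv",
            dec.distinct_scores[k], obj, _component_labels(f"d{k + 1}_", ck),
        )
        write_labeled_matrix(
            outdir / f"distinct_loadings_{tag}.tsv",
            dec.distinct_loadings[k], var, _component_labels(f"d{k + 1}_", ck),
        )
        T_ck = dec.block_common_scores(k)
        write_labeled_matrix(
            outdir / f"common_scores_{tag}.tsv",
            T_ck, obj, _component_labels("c", T_ck.shape[1]),
        )


def write_summary(path, summary: dict) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
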