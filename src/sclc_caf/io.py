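"""Readers and writers for the plain-text formats the pipeline touches.

Expression matrices are TSV/CSV with genes as rows and a header of sample
ids; gene sets are GMT; per-gene weights are two-column TSV; score and
comparison tables round-trip through CSV/TSV/JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, GeneSet, SignatureLibrary

logger = logging.getLogger(__name__)

_SEPS = {"tsv": "\t", "csv": ","}

#: significant digits used for all table output; enough for a lossless
#: round-trip at the precision the analysis needs
FLOAT_FORMAT = "%.10g"


def read_expression_matrix(
    path: Union[str, Path],
    format: str = "tsv",
    scale: str = "linear",
    collapse: str = "max",
) -> ExpressionMatrix:
    """Read a genes x samples expression table.

    First column holds gene symbols, header row holds sample ids.
    Duplicate gene rows are collapsed per-sample by ``collapse``
    (``max``, the probe/symbol collapse convention, or ``mean``);
    the number collapsed is logged. Duplicate sample ids are an error.

    Parameters
    ----------
    scale
        Declared scale of the stored values (``linear`` or ``log2p1``).
        Never inferred from the data.
    """
    path = Path(path)
    if format not in _SEPS:
        raise ValueError(f"format must be one of {list(_SEPS)}")
    if collapse not in ("max", "mean"):
        raise ValueError("collapse must be 'max' or 'mean'")
    sep = _SEPS[format]

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dup = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"duplicate sample ids in header of {path}: {dup}")

    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {raw.iat[i, j]!r} at gene {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r} in {path}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"missing value at gene {raw.index[i]!r}, sample {raw.columns[j]!r}")

    if numeric.index.has_duplicates:
        n_dup = int(numeric.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene row(s) by %s", n_dup, collapse)
        order = numeric.index.drop_duplicates()
        grouped = numeric.groupby(level=0, sort=False)
        numeric = (grouped.max() if collapse == "max" else grouped.mean()).loc[order]

    if scale == "linear" and (numeric.to_numpy() < 0).any():
        i, j = np.argwhere(numeric.to_numpy() < 0)[0]
        raise ValueError(
            f"negative value at gene {numeric.index[i]!r}, sample "
            f"{numeric.columns[j]!r} but scale declared 'linear'"
        )
    return ExpressionMatrix(numeric.astype(float), scale=scale)


def write_expression_matrix(m: ExpressionMatrix, path: Union[str, Path], format: str = "tsv") -> None:
    m.data.to_csv(path, sep=_SEPS[format], float_format=FLOAT_FORMAT)


def read_gmt(path: Union[str, Path]) -> SignatureLibrary:
    """Read a GMT file: ``name <tab> description <tab> gene...`` per line.

    Duplicate genes within a line are dropped with a warning; duplicate
    set names across lines are an error.
    """
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has {len(fields)} fields, expected >= 3")
            name, _desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            seen: dict[str, None] = {}
            for g in genes:
                if g in seen:
                    logger.warning("%s line %d: duplicate gene %r dropped", path, lineno, g)
                seen[g] = None
            if name in sets:
                raise ValueError(f"{path}: duplicate gene-set name {name!r} at line {lineno}")
            sets[name] = GeneSet(name, tuple(seen))
    return SignatureLibrary(sets)


def write_gmt(lib: SignatureLibrary, path: Union[str, Path], description: str = "na") -> None:
    with open(path, "w") as fh:
        for gs in lib:
            fh.write("\t".join([gs.name, description, *gs.genes]) + "\n")


def read_weights(path: Union[str, Path]) -> pd.Series:
    """Read a two-column (gene, weight) TSV into a Series keyed by gene."""
    tab = pd.read_csv(path, sep="\t", header=None, names=["gene", "weight"], comment="#")
    if tab["gene"].duplicated().any():
        raise ValueError(f"duplicate genes in weight table {path}")
    w = pd.to_numeric(tab["weight"], errors="coerce")
    if w.isna().any():
        raise ValueError(f"non-numeric weight in {path}")
    return pd.Series(w.to_numpy(), index=tab["gene"].astype(str).to_numpy(), name="weight")


def write_table(obj, path: Union[str, Path], format: str = "csv") -> None:
    """Write a score/comparison table losslessly (>= 6 significant digits).

    Accepts a DataFrame or Series; ``format`` is ``csv``, ``tsv`` or
    ``json`` (pandas *split* orientation, index preserved).
    """
    if isinstance(obj, pd.Series):
        obj = obj.to_frame()
    if not isinstance(obj, pd.DataFrame):
        raise TypeError("write_table accepts a DataFrame or Series")
    path = Path(path)
    if format in _SEPS:
        obj.to_csv(path, sep=_SEPS[format], float_format=FLOAT_FORMAT)
    elif format == "json":
        path.write_text(obj.to_json(orient="split", double_precision=12))
    else:
        raise ValueError("format must be 'csv', 'tsv' or 'json'")


def read_table(path: Union[str, Path], format: str = "csv") -> pd.DataFrame:
    """Inverse of :func:`write_table`."""
    if format in _SEPS:
        return pd.read_csv(path, sep=_SEPS[format], index_col=0)
    if format == "json":
        payload = json.loads(Path(path).read_text())
        return pd.DataFrame(payload["data"], index=payload["index"], columns=payload["columns"])
    raise ValueError("format must be 'csv', 'tsv' or 'json'")
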