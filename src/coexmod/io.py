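"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts travel as TSV (gene rows x sample columns), phenotypes as CSV
(sample id index), gene modules as GMT (one set per line:
``name<TAB>description<TAB>gene1<TAB>gene2...``), and run metadata as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples raw count matrix from TSV."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.index.has_duplicates:
        raise ValueError("duplicate gene ids in count matrix")
    if counts.columns.has_duplicates:
        raise ValueError("duplicate sample ids in count matrix")
    return counts


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def read_phenotypes_csv(path: str | Path) -> pd.DataFrame:
    """Read a phenotype table indexed by sample id."""
    pheno = pd.read_csv(path, index_col=0)
    if pheno.index.has_duplicates:
        raise ValueError("duplicate sample ids in phenotype table")
    return pheno


def write_phenotypes_csv(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a samples x genes expression matrix from TSV."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file into ``{set name: [gene, ...]}``."""
    sets: dict[str, list[str]] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:50]!r}")
            name = fields[0]
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r}")
            sets[name] = [g for g in fields[2:] if g]
    if not sets:
        raise ValueError("empty GMT file")
    return sets


def write_gmt(
    gene_sets: Mapping[str, Sequence[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    with open(path, "w") as handle:
        for name, genes in gene_sets.items():
            desc = descriptions.get(name, "") if descriptions else ""
            handle.write("\t".join([str(name), desc, *map(str, genes)]) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.Series,)):
        return obj.to_dict()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(payload: Mapping, path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True, default=_jsonable)
        handle.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as handle:
        return json.load(handle)
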