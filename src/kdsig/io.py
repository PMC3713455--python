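"""Readers and writers for the interchange formats used by the pipeline.

GCT (versioned ``#1.2``) carries expression matrices, CLS carries
two-class phenotype labels, GMT carries gene sets and RNK carries ranked
gene lists.  All are plain-text, tab-separated formats; writers are
deterministic (fixed float formatting) so that identical inputs produce
byte-identical files.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


# ----------------------------------------------------------------------
# GCT
def write_gct(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, matrix.sample_ids)) + "\n")
        for gene, row in matrix.values.iterrows():
            vals = "\t".join(FLOAT_FORMAT % v for v in row.to_numpy())
            fh.write(f"{gene}\tna\t{vals}\n")
    logger.info("wrote GCT %s (%d genes, %d samples)", path, matrix.n_genes, matrix.n_samples)


def read_gct(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    with path.open() as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"{path}: unsupported GCT version line {version!r}")
        dims = fh.readline().split()
        n_genes, n_samples = int(dims[0]), int(dims[1])
        table = pd.read_csv(fh, sep="\t", index_col=0)
    table = table.drop(columns=["Description"])
    if table.shape != (n_genes, n_samples):
        raise ValueError(
            f"{path}: dimensions line says {n_genes}x{n_samples}, found {table.shape}"
        )
    table.index.name = None
    return ExpressionMatrix(table)


# ----------------------------------------------------------------------
# CLS (categorical: "<n> <k> 1" header, names line, label line)
def write_cls(labels: Sequence[str], path: str | Path) -> None:
    labels = list(labels)
    classes = list(dict.fromkeys(labels))  # first-appearance order
    index = {c: i for i, c in enumerate(classes)}
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{len(labels)} {len(classes)} 1\n")
        fh.write("# " + " ".join(classes) + "\n")
        fh.write(" ".join(str(index[l]) for l in labels) + "\n")


def read_cls(path: str | Path) -> list[str]:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().split()
        n = int(header[0])
        names = fh.readline().split()
        if names[0] != "#":
            raise ValueError(f"{path}: malformed CLS class-name line")
        classes = names[1:]
        tokens = fh.readline().split()
    if len(tokens) != n:
        raise ValueError(f"{path}: expected {n} labels, found {len(tokens)}")
    # labels may be written as indices or as class names
    if all(t in classes for t in tokens):
        return tokens
    return [classes[int(t)] for t in tokens]


# ----------------------------------------------------------------------
# GMT (one set per line: name <tab> description <tab> genes...)
def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name, genes in sets.items():
            fh.write(name + "\tna\t" + "\t".join(map(str, genes)) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: malformed GMT line {line!r}")
        sets[fields[0]] = fields[2:]
    return sets


# ----------------------------------------------------------------------
# RNK (two columns: gene, score; ordered by score descending)
def write_rnk(scores: pd.Series, path: str | Path) -> None:
    ordered = scores.sort_values(ascending=False, kind="mergesort")
    with Path(path).open("w") as fh:
        for gene, score in ordered.items():
            fh.write(f"{gene}\t{FLOAT_FORMAT % score}\n")


def read_rnk(path: str | Path) -> pd.Series:
    table = pd.read_csv(path, sep="\t", header=None, index_col=0)
    series = table.iloc[:, 0].astype(float)
    series.index.name = None
    series.name = None
    return series
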