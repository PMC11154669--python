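"""Text-format plumbing: expression/metadata TSV, GMT gene sets, model bundles.

All matrices travel as plain TSV (genes as rows, a header row of sample or
column ids), optionally gzip-compressed by file suffix.  Floats are written
with 10 significant digits; re-reading a file the package wrote and writing it
again reproduces the bytes exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

FLOAT_FORMAT = "%.10g"

METADATA_COLUMNS = ("sample_id", "study_id", "condition", "age_months", "cell_type")


@dataclass
class GeneSet:
    """One GMT record: a named gene set with a free-text description."""

    name: str
    description: str
    genes: list[str]


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_expression(path: str | Path, state: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups[:10]}")
    if df.columns.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    if not all(np.issubdtype(t, np.number) for t in df.dtypes):
        bad = [c for c, t in df.dtypes.items() if not np.issubdtype(t, np.number)]
        raise ValueError(f"non-numeric expression column(s) in {path}: {bad[:5]}")
    return ExpressionMatrix.from_frame(df, state=state)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata file {path} is missing column(s): {missing}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in {path}: {dups[:10]}")
    meta["age_months"] = pd.to_numeric(meta["age_months"], errors="raise")
    return meta


def write_gmt(gene_sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, description, *genes = fields
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            seen.add(name)
            sets.append(GeneSet(name, description, [g for g in genes if g]))
    return sets


def read_gene_lengths(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "length"], comment="#")
    # Tolerate a header row.
    if df.iloc[0]["gene_id"] == "gene_id":
        df = df.iloc[1:]
    lengths = {str(g): float(ln) for g, ln in zip(df["gene_id"], df["length"])}
    if len(lengths) != len(df):
        raise ValueError(f"duplicate gene ids in gene length file {path}")
    return lengths


def write_gene_lengths(lengths: dict[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlength\n")
        for g, ln in lengths.items():
            fh.write(f"{g}\t{FLOAT_FORMAT % ln}\n")


def read_hierarchy(path: str | Path) -> list[tuple[str, str]]:
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: hierarchy line needs parent\\tchild")
            edges.append((fields[0], fields[1]))
    return edges


def write_hierarchy(edges: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for parent, child in edges:
            fh.write(f"{parent}\t{child}\n")


def _write_labeled_matrix(
    values: np.ndarray, index: Sequence[str], columns: Sequence[str],
    index_name: str, path: Path,
) -> None:
    df = pd.DataFrame(values, index=list(index), columns=list(columns))
    df.index.name = index_name
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def save_model(model, directory: str | Path) -> None:
    """Serialize a fitted model to a directory of TSVs plus ``config.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _write_labeled_matrix(model.Z, model.gene_ids, model.lv_ids, "gene_id", directory / "Z.tsv")
    _write_labeled_matrix(model.B, model.lv_ids, model.sample_ids, "lv_id", directory / "B.tsv")
    _write_labeled_matrix(model.U, model.set_ids, model.lv_ids, "set_id", directory / "U.tsv")
    with open(directory / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(model.config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    trace = pd.DataFrame({"iteration": range(len(model.objective_trace)),
                          "objective": model.objective_trace})
    trace.to_csv(directory / "objective_trace.tsv", sep="\t", index=False,
                 float_format="%.15g")


def load_model(directory: str | Path):
    from .plier import PlierConfig, PlierModel

    directory = Path(directory)
    Z = pd.read_csv(directory / "Z.tsv", sep="\t", index_col=0)
    B = pd.read_csv(directory / "B.tsv", sep="\t", index_col=0)
    U = pd.read_csv(directory / "U.tsv", sep="\t", index_col=0)
    with open(directory / "config.json") as fh:
        config = PlierConfig(**json.load(fh))
    trace = pd.read_csv(directory / "objective_trace.tsv", sep="\t")
    return PlierModel(
        Z=Z.to_numpy(),
        B=B.to_numpy(),
        U=U.to_numpy(),
        config=config,
        objective_trace=list(trace["objective"]),
        gene_ids=list(Z.index.astype(str)),
        sample_ids=list(B.columns.astype(str)),
        set_ids=list(U.index.astype(str)),
    )
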