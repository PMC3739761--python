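"""Readers and writers for every external table the pipeline touches.

All tables are tab-separated UTF-8 with a single header line; feature ids are
case-sensitive strings.  Supported dialects:

* Cufflinks-style ``.fpkm_tracking`` (``tracking_id``, ``FPKM``,
  ``FPKM_conf_lo``, ``FPKM_conf_hi``; extra columns ignored, any
  ``FPKM_status`` column is ignored — reliability is recomputed from the
  confidence bounds downstream).
* genes × samples expression matrix TSV plus a sample-metadata TSV
  (``sample_id``, ``stage``, ``replicate``).
* GMT gene-set collections, edge-list TSV/SIF, and an annotation TSV using
  the one-letter location codes E/P/C/N/O and a Y/N drug flag.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    LOCATION_CODES,
    LOCATIONS,
    EdgeList,
    ExpressionStudy,
    FormatError,
    GeneSetCollection,
    ValidationError,
    validate_annotation,
)

_TRACKING_COLS = ("tracking_id", "FPKM", "FPKM_conf_lo", "FPKM_conf_hi")


def read_fpkm_tracking(
    path, sample_id: str, stage: str, replicate: int
) -> ExpressionStudy:
    """Read one Cufflinks-style tracking file into a single-sample study.

    Rows with non-numeric FPKM are rejected with a :class:`FormatError`;
    a lower confidence bound above the estimate raises a
    :class:`ValidationError` naming the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _TRACKING_COLS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    num = {}
    for col in _TRACKING_COLS[1:]:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # 1-based incl. header
            raise FormatError(f"{path}: non-numeric {col} value near line {row}")
        num[col] = converted.to_numpy()
    over = num["FPKM_conf_lo"] > num["FPKM"] + 1e-12
    if over.any():
        row = int(np.flatnonzero(over)[0]) + 2
        raise ValidationError(f"{path}: FPKM_conf_lo exceeds FPKM at line {row}")
    idx = pd.Index(df["tracking_id"].astype(str), name="feature")
    if not idx.is_unique:
        raise ValidationError(f"{path}: duplicate tracking_id values")
    mk = lambda col: pd.DataFrame({sample_id: num[col]}, index=idx)
    samples = pd.DataFrame(
        {"stage": [stage], "replicate": [int(replicate)]},
        index=pd.Index([sample_id], name="sample_id"),
    )
    return ExpressionStudy(
        values=mk("FPKM"), samples=samples, ci_lo=mk("FPKM_conf_lo"), ci_hi=mk("FPKM_conf_hi")
    )


def write_fpkm_tracking(study: ExpressionStudy, directory) -> list[Path]:
    """Write one ``<sample_id>.fpkm_tracking`` file per sample."""
    if not study.has_ci():
        raise ValidationError("study has no confidence bounds to write")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for sid in study.values.columns:
        out = pd.DataFrame(
            {
                "tracking_id": study.values.index,
                "FPKM": study.values[sid].to_numpy(),
                "FPKM_conf_lo": study.ci_lo[sid].to_numpy(),
                "FPKM_conf_hi": study.ci_hi[sid].to_numpy(),
            }
        )
        p = directory / f"{sid}.fpkm_tracking"
        out.to_csv(p, sep="\t", index=False)
        paths.append(p)
    return paths


def read_sample_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "stage": str})
    for col in ("sample_id", "stage", "replicate"):
        if col not in meta.columns:
            raise FormatError(f"{path}: missing metadata column {col!r}")
    meta = meta.set_index("sample_id")
    meta["replicate"] = meta["replicate"].astype(int)
    return meta


def read_expression_matrix(path, metadata: pd.DataFrame) -> ExpressionStudy:
    """Read a genes × samples TSV; header sample ids must match ``metadata``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "feature"
    df.columns = [str(c) for c in df.columns]
    unknown = set(df.columns) - set(metadata.index)
    if unknown:
        raise ValidationError(
            f"{path}: samples absent from metadata: {sorted(unknown)}"
        )
    if (df.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative expression value")
    return ExpressionStudy(values=df, samples=metadata.loc[list(df.columns)])


def write_expression_matrix(study: ExpressionStudy, path, metadata_path=None):
    study.values.to_csv(path, sep="\t", index_label="feature")
    if metadata_path is not None:
        study.samples.to_csv(metadata_path, sep="\t", index_label="sample_id")


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, "
                                  "description and at least one gene")
            name, desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_edge_list(path) -> EdgeList:
    """Read an edge TSV (``gene_a  gene_b  [interaction]``) or SIF
    (``gene_a  type  gene_b``); duplicates and orientation collapse."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    first = str(df.iloc[0, 0]).lower()
    if first in ("gene_a", "genea", "source"):
        df = df.iloc[1:]
    if df.shape[1] < 2:
        raise FormatError(f"{path}: edge list needs at least two columns")
    if str(path).endswith(".sif") and df.shape[1] >= 3:
        pairs = list(zip(df.iloc[:, 0], df.iloc[:, 2]))
        labels = list(df.iloc[:, 1])
    else:
        pairs = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
        labels = list(df.iloc[:, 2]) if df.shape[1] >= 3 else None
    return EdgeList.from_pairs(pairs, labels)


def write_edge_list(edges: EdgeList, path) -> None:
    edges.edges.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    """Annotation TSV: gene id, location code/token, Y/N drug flag."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene", "location", "has_drug"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing annotation column {col!r}")

    def _loc(tok: str) -> str:
        if tok in LOCATION_CODES:
            return LOCATION_CODES[tok]
        if tok in LOCATIONS:
            return tok
        raise ValidationError(
            f"{path}: unknown location token {tok!r}; allowed tokens: "
            f"{sorted(LOCATION_CODES)} or {list(LOCATIONS)}"
        )

    out = pd.DataFrame(
        {
            "location": [_loc(t) for t in df["location"]],
            "has_drug": [t.upper() in ("Y", "TRUE", "1") for t in df["has_drug"]],
        },
        index=pd.Index(df["gene"].astype(str), name="gene"),
    )
    return validate_annotation(out)


def write_annotation(annotations: pd.DataFrame, path) -> None:
    codes = {v: k for k, v in LOCATION_CODES.items()}
    out = pd.DataFrame(
        {
            "gene": annotations.index,
            "location": [codes[loc] for loc in annotations["location"]],
            "has_drug": ["Y" if d else "N" for d in annotations["has_drug"]],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_tsv(table: pd.DataFrame, path, index: bool = False) -> None:
    table.to_csv(path, sep="\t", index=index)
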