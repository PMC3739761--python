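"""Core in-memory containers shared across the pipeline.

The central object is :class:`ExpressionStudy`, a features × samples FPKM
matrix with per-sample stage/replicate metadata and optional 95% confidence
bound matrices.  Gene- and isoform-level studies share the container; an
isoform study additionally carries an isoform→gene map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

LOCATIONS = (
    "extracellular_space",
    "plasma_membrane",
    "cytoplasm",
    "nucleus",
    "other",
)

#: one-letter codes used in annotation tables (Table S4 style)
LOCATION_CODES = {
    "E": "extracellular_space",
    "P": "plasma_membrane",
    "C": "cytoplasm",
    "N": "nucleus",
    "O": "other",
}


class FormatError(ValueError):
    """Raised when an input file violates its expected dialect."""


class ValidationError(ValueError):
    """Raised when parsed data violates a container invariant."""


@dataclass
class ExpressionStudy:
    """Expression estimates (FPKM) for a set of features across samples.

    Parameters
    ----------
    values
        Non-negative FPKM matrix, features in rows, samples in columns.
    samples
        Sample metadata indexed by sample id with columns ``stage`` and
        ``replicate``.  Stage order follows first appearance unless
        ``stage_order`` is given.
    ci_lo, ci_hi
        Optional 95% confidence bound matrices, same shape as ``values``.
    feature_kind
        ``"gene"`` or ``"isoform"``.
    isoform_to_gene
        Mapping isoform id -> gene id; required when ``feature_kind`` is
        ``"isoform"`` and must cover every feature.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    ci_lo: pd.DataFrame | None = None
    ci_hi: pd.DataFrame | None = None
    feature_kind: str = "gene"
    isoform_to_gene: pd.Series | None = None
    stage_order: list[str] = field(default_factory=list)
    #: False for derived studies (e.g. floored values) where the CI matrices
    #: intentionally describe the raw estimates, not the transformed values
    validate_ci_brackets: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if not self.samples.index.is_unique:
            raise ValidationError("sample ids must be unique")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValidationError(f"samples missing metadata: {sorted(missing)}")
        self.samples = self.samples.loc[list(self.values.columns)]
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression values must be non-negative")
        if (self.ci_lo is None) != (self.ci_hi is None):
            raise ValidationError("ci_lo and ci_hi must be given together")
        if self.ci_lo is not None:
            for name, ci in (("ci_lo", self.ci_lo), ("ci_hi", self.ci_hi)):
                if ci.shape != self.values.shape:
                    raise ValidationError(f"{name} shape differs from values")
            self.ci_lo = self.ci_lo.astype(float)
            self.ci_hi = self.ci_hi.astype(float)
            v, lo, hi = (df.to_numpy() for df in (self.values, self.ci_lo, self.ci_hi))
            if (lo < 0).any():
                raise ValidationError("ci_lo must be non-negative")
            if self.validate_ci_brackets and (
                (lo > v + 1e-12).any() or (hi < v - 1e-12).any()
            ):
                raise ValidationError("confidence bounds must bracket the estimate")
        if self.feature_kind not in ("gene", "isoform"):
            raise ValidationError("feature_kind must be 'gene' or 'isoform'")
        if self.feature_kind == "isoform":
            if self.isoform_to_gene is None:
                raise ValidationError("isoform study requires isoform_to_gene map")
            unmapped = set(self.values.index) - set(self.isoform_to_gene.index)
            if unmapped:
                raise ValidationError(
                    f"isoforms without gene mapping: {sorted(unmapped)[:5]}"
                )
        if not self.stage_order:
            seen: list[str] = []
            for s in self.samples["stage"]:
                if s not in seen:
                    seen.append(s)
            self.stage_order = seen
        extra = set(self.samples["stage"]) - set(self.stage_order)
        if extra:
            raise ValidationError(f"stages outside stage_order: {sorted(extra)}")

    # ------------------------------------------------------------------
    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def stages(self) -> list[str]:
        return list(self.stage_order)

    def has_ci(self) -> bool:
        return self.ci_lo is not None

    def samples_of_stage(self, stage: str) -> list[str]:
        if stage not in self.stage_order:
            raise KeyError(f"unknown stage {stage!r}; stages are {self.stage_order}")
        return list(self.samples.index[self.samples["stage"] == stage])

    def stage_means(self, floor: float | None = None) -> pd.DataFrame:
        """Per-stage mean FPKM (features × stages), optionally floored first."""
        vals = self.values
        if floor is not None:
            vals = vals.clip(lower=floor)
        cols = {s: vals[self.samples_of_stage(s)].mean(axis=1) for s in self.stage_order}
        return pd.DataFrame(cols)[self.stage_order]

    def with_values(self, values: pd.DataFrame) -> "ExpressionStudy":
        return replace(self, values=values)

    def canonical(self) -> "ExpressionStudy":
        """Return a copy with features sorted lexicographically."""
        order = self.values.index.sort_values()
        return replace(
            self,
            values=self.values.loc[order],
            ci_lo=None if self.ci_lo is None else self.ci_lo.loc[order],
            ci_hi=None if self.ci_hi is None else self.ci_hi.loc[order],
        )


def combine_fragments(fragments: list[ExpressionStudy]) -> ExpressionStudy:
    """Merge single-sample fragments (e.g. one per ``.fpkm_tracking`` file)."""
    if not fragments:
        raise ValueError("no fragments to combine")
    idx = fragments[0].values.index
    for frag in fragments[1:]:
        if not frag.values.index.equals(idx):
            raise ValidationError("fragments disagree on feature ids")
    values = pd.concat([f.values for f in fragments], axis=1)
    samples = pd.concat([f.samples for f in fragments])
    has_ci = all(f.has_ci() for f in fragments)
    ci_lo = pd.concat([f.ci_lo for f in fragments], axis=1) if has_ci else None
    ci_hi = pd.concat([f.ci_hi for f in fragments], axis=1) if has_ci else None
    first = fragments[0]
    return ExpressionStudy(
        values=values,
        samples=samples,
        ci_lo=ci_lo,
        ci_hi=ci_hi,
        feature_kind=first.feature_kind,
        isoform_to_gene=first.isoform_to_gene,
    )


@dataclass
class EdgeList:
    """Undirected interaction edges between genes.

    Edges are normalized to sorted unordered pairs; duplicates collapse and
    self-loops are dropped with a warning (interaction databases give no
    self-interaction semantics here).
    """

    edges: pd.DataFrame  # columns gene_a, gene_b[, interaction]

    @classmethod
    def from_pairs(cls, pairs, labels=None) -> "EdgeList":
        rows, seen = [], set()
        n_loops = 0
        labels = labels if labels is not None else [""] * len(list(pairs))
        for (a, b), lab in zip(pairs, labels):
            a, b = str(a), str(b)
            if a == b:
                n_loops += 1
                continue
            key = (a, b) if a < b else (b, a)
            if key in seen:
                continue
            seen.add(key)
            rows.append((*key, lab))
        if n_loops:
            warnings.warn(f"dropped {n_loops} self-loop edge(s)", stacklevel=2)
        df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "interaction"])
        return cls(df.sort_values(["gene_a", "gene_b"]).reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.edges)

    def genes(self) -> set[str]:
        return set(self.edges["gene_a"]) | set(self.edges["gene_b"])

    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.edges["gene_a"], self.edges["gene_b"]))


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets (GMT semantics)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def validate_annotation(annotations: pd.DataFrame) -> pd.DataFrame:
    """Check an annotation table (index gene id; location, has_drug columns)."""
    if not annotations.index.is_unique:
        raise ValidationError("one annotation record per gene required")
    bad = set(annotations["location"]) - set(LOCATIONS)
    if bad:
        raise ValidationError(
            f"unknown location token(s) {sorted(bad)}; allowed: {list(LOCATIONS)}"
        )
    annotations = annotations.copy()
    annotations["has_drug"] = annotations["has_drug"].astype(bool)
    return annotations


def annotation_for(
    genes, annotations: pd.DataFrame | None
) -> pd.DataFrame:
    """Annotation rows for ``genes``; unannotated genes default to
    location ``other`` / no drug so prioritization can still run."""
    genes = list(genes)
    base = pd.DataFrame(
        {"location": "other", "has_drug": False},
        index=pd.Index(genes, name="gene"),
    )
    if annotations is not None:
        known = [g for g in genes if g in annotations.index]
        base.loc[known, "location"] = annotations.loc[known, "location"]
        base.loc[known, "has_drug"] = annotations.loc[known, "has_drug"].astype(bool)
    return base
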