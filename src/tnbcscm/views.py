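"""Multi-omics view containers and the learning-matrix assembly.

A cohort is observed through several *views* (RNA isoform expression,
miRNA expression, methylation beta values from two array platforms).
This module turns them into a single dense sample-by-attribute matrix:

1. :func:`fuse_methylation` merges the two methylation platforms into one
   ``methyl_fusion`` view over the union of probes, preferring the
   higher-resolution platform where both report a value.
2. :func:`impute_label_conditional` fills missing entries with the mean of
   the observed values *within the sample's class* (TNBC vs non-TNBC),
   falling back to the overall column mean, then to zero.
3. :func:`assemble_feature_space` concatenates the imputed views, with
   globally unique view-prefixed attribute ids and a registry mapping every
   column back to its (view, attribute, gene symbol) provenance.

Imputation statistics are computed on the full cohort before any
train/test split; the class-conditional fill leaks label information into
the matrix by construction, which is inherent to the procedure being
modelled and is documented rather than altered.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AttributeInfo",
    "OmicsView",
    "FeatureSpace",
    "fuse_methylation",
    "impute_label_conditional",
    "assemble_feature_space",
    "read_view_tsv",
    "write_view_tsv",
    "write_feature_space",
    "read_feature_space",
]

GLOBAL_ID_SEP = "::"


class AttributeInfo(NamedTuple):
    """Provenance of one matrix column."""

    view: str
    attribute: str
    gene: str | None


@dataclass
class OmicsView:
    """One named feature matrix (samples x attributes) with a missing mask.

    Parameters
    ----------
    name
        View identifier, e.g. ``"isoform"`` or ``"methyl_fusion"``.
    sample_ids, attribute_ids
        Ordered row / column labels; attribute ids must be unique.
    values
        Float matrix of shape ``(n_samples, n_attributes)``. Entries under
        the missing mask carry no value semantics.
    missing_mask
        Boolean matrix of the same shape; ``True`` marks a missing entry.
    gene_map
        Optional map attribute id -> gene symbol (``None`` entries allowed).
    """

    name: str
    sample_ids: list[str]
    attribute_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray | None = None
    gene_map: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, d = self.values.shape
        if len(self.sample_ids) != n or len(self.attribute_ids) != d:
            raise ValueError(
                f"view {self.name!r}: matrix shape {self.values.shape} does not "
                f"match {len(self.sample_ids)} samples x {len(self.attribute_ids)} attributes"
            )
        if self.missing_mask.shape != self.values.shape:
            raise ValueError(f"view {self.name!r}: missing mask shape mismatch")
        if len(set(self.attribute_ids)) != d:
            raise ValueError(f"view {self.name!r}: duplicate attribute ids")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]

    def has_missing(self) -> bool:
        return bool(self.missing_mask.any())

    def registry(self) -> dict[str, AttributeInfo]:
        """Map attribute id -> (view, attribute, gene)."""
        return {
            a: AttributeInfo(self.name, a, self.gene_map.get(a))
            for a in self.attribute_ids
        }


@dataclass
class FeatureSpace:
    """The assembled learning matrix: dense, no missing values.

    Attribute ids are globally unique, ``"<view>::<attribute>"``. ``registry``
    maps each global id back to its :class:`AttributeInfo`.
    """

    sample_ids: list[str]
    attribute_ids: list[str]
    values: np.ndarray
    registry: dict[str, AttributeInfo]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.attribute_ids)):
            raise ValueError("feature space shape does not match id lists")
        if np.isnan(self.values).any():
            raise ValueError("feature space contains missing values")

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def column_index(self, attribute_id: str) -> int:
        try:
            return self._index[attribute_id]
        except AttributeError:
            self._index = {a: j for j, a in enumerate(self.attribute_ids)}
            return self._index[attribute_id]


def fuse_methylation(
    view450: OmicsView,
    view27: OmicsView,
    name: str = "methyl_fusion",
    prefer: str = "450",
) -> OmicsView:
    """Merge two methylation platforms into a single view over the probe union.

    For a probe assayed on both platforms, the preferred platform's value is
    used where observed; the other platform fills its missing entries; the
    fused entry is missing only where both are. Samples are aligned by id and
    must form the same set in both views.

    ``prefer`` selects which platform wins on shared probes ("450" or "27").
    """
    s450, s27 = set(view450.sample_ids), set(view27.sample_ids)
    if s450 != s27:
        only450 = sorted(s450 - s27)
        only27 = sorted(s27 - s450)
        raise ValueError(
            "methylation views cover different samples; "
            f"only in {view450.name}: {only450[:5]}{'...' if len(only450) > 5 else ''}; "
            f"only in {view27.name}: {only27[:5]}{'...' if len(only27) > 5 else ''}"
        )
    if prefer not in ("450", "27"):
        raise ValueError("prefer must be '450' or '27'")
    primary, secondary = (view450, view27) if prefer == "450" else (view27, view450)

    # Align the secondary view's rows to the primary's sample order.
    row_of = {s: i for i, s in enumerate(secondary.sample_ids)}
    sec_rows = np.array([row_of[s] for s in primary.sample_ids])
    sec_vals = secondary.values[sec_rows]
    sec_miss = secondary.missing_mask[sec_rows]

    primary_set = set(primary.attribute_ids)
    extra = [a for a in secondary.attribute_ids if a not in primary_set]
    attribute_ids = list(primary.attribute_ids) + extra

    n = primary.n_samples
    values = np.empty((n, len(attribute_ids)), dtype=float)
    missing = np.ones_like(values, dtype=bool)
    values[:, : primary.n_attributes] = primary.values
    missing[:, : primary.n_attributes] = primary.missing_mask

    sec_col = {a: j for j, a in enumerate(secondary.attribute_ids)}
    # shared probes: fall back to the secondary platform where primary is missing
    for j, a in enumerate(primary.attribute_ids):
        k = sec_col.get(a)
        if k is None:
            continue
        fill = missing[:, j] & ~sec_miss[:, k]
        if fill.any():
            values[fill, j] = sec_vals[fill, k]
            missing[fill, j] = False
    for offset, a in enumerate(extra):
        j = primary.n_attributes + offset
        k = sec_col[a]
        values[:, j] = sec_vals[:, k]
        missing[:, j] = sec_miss[:, k]

    gene_map = dict(secondary.gene_map)
    gene_map.update(primary.gene_map)
    return OmicsView(
        name=name,
        sample_ids=list(primary.sample_ids),
        attribute_ids=attribute_ids,
        values=values,
        missing_mask=missing,
        gene_map=gene_map,
    )


def impute_label_conditional(view: OmicsView, labels: Sequence[int]) -> OmicsView:
    """Fill missing entries with the class-conditional column mean.

    Each missing entry ``(sample, attribute)`` is replaced by the mean of the
    attribute's observed values among samples sharing the sample's binary
    label. Columns with no observed value in a class fall back to the overall
    observed mean; entirely unobserved columns are filled with 0. Observed
    entries are never altered, so the operation is idempotent.
    """
    y = np.asarray(labels)
    if y.shape != (view.n_samples,):
        raise ValueError("labels must align with the view's samples")
    uniq = set(np.unique(y).tolist())
    if not uniq <= {0, 1}:
        raise ValueError(f"labels must be binary 0/1, got values {sorted(uniq)}")
    if not view.has_missing():
        return OmicsView(
            name=view.name,
            sample_ids=list(view.sample_ids),
            attribute_ids=list(view.attribute_ids),
            values=view.values.copy(),
            missing_mask=np.zeros_like(view.missing_mask),
            gene_map=dict(view.gene_map),
        )

    obs = ~view.missing_mask
    vals = np.where(obs, view.values, 0.0)

    n_obs_all = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_all = np.where(n_obs_all > 0, vals.sum(axis=0) / n_obs_all, 0.0)

    filled = view.values.copy()
    for cls in (0, 1):
        rows = y == cls
        if not rows.any():
            continue
        n_obs = obs[rows].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_cls = np.where(n_obs > 0, vals[rows].sum(axis=0) / n_obs, mean_all)
        miss = view.missing_mask & rows[:, None]
        fill_matrix = np.broadcast_to(mean_cls, filled.shape)
        filled[miss] = fill_matrix[miss]

    return OmicsView(
        name=view.name,
        sample_ids=list(view.sample_ids),
        attribute_ids=list(view.attribute_ids),
        values=filled,
        missing_mask=np.zeros_like(view.missing_mask),
        gene_map=dict(view.gene_map),
    )


def assemble_feature_space(views: Sequence[OmicsView]) -> FeatureSpace:
    """Concatenate imputed views horizontally into one :class:`FeatureSpace`.

    All views must share the same sample set; rows are aligned to the first
    view's sample order. Column order follows the input view order, attributes
    in their original order within each view. Width = sum of view widths.
    """
    if not views:
        raise ValueError("need at least one view")
    for v in views:
        if v.has_missing():
            raise ValueError(f"view {v.name!r} still has missing values; impute first")
    ref = views[0]
    ref_set = set(ref.sample_ids)
    blocks = []
    attribute_ids: list[str] = []
    registry: dict[str, AttributeInfo] = {}
    for v in views:
        if set(v.sample_ids) != ref_set:
            raise ValueError(f"view {v.name!r} covers a different sample set")
        row_of = {s: i for i, s in enumerate(v.sample_ids)}
        order = np.array([row_of[s] for s in ref.sample_ids])
        blocks.append(v.values[order])
        for a in v.attribute_ids:
            gid = f"{v.name}{GLOBAL_ID_SEP}{a}"
            if gid in registry:
                raise ValueError(f"duplicate global attribute id {gid!r}")
            attribute_ids.append(gid)
            registry[gid] = AttributeInfo(v.name, a, v.gene_map.get(a))
    values = np.concatenate(blocks, axis=1) if len(blocks) > 1 else blocks[0].copy()
    return FeatureSpace(
        sample_ids=list(ref.sample_ids),
        attribute_ids=attribute_ids,
        values=values,
        registry=registry,
    )


# ---------------------------------------------------------------------------
# delimited-text I/O


def write_view_tsv(view: OmicsView, path) -> None:
    """Samples x attributes TSV; first column sample id, missing as "NA"."""
    vals = view.values.astype(object)
    vals[view.missing_mask] = "NA"
    df = pd.DataFrame(vals, index=view.sample_ids, columns=view.attribute_ids)
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_view_tsv(path, name: str, gene_map: dict[str, str | None] | None = None) -> OmicsView:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    values = df.to_numpy(dtype=float)
    return OmicsView(
        name=name,
        sample_ids=[str(s) for s in df.index],
        attribute_ids=[str(a) for a in df.columns],
        values=values,
        missing_mask=np.isnan(values),
        gene_map=gene_map or {},
    )


def write_feature_space(fs: FeatureSpace, matrix_path, registry_path) -> None:
    """Write the matrix as TSV plus a (global id, view, attribute, gene) sidecar."""
    pd.DataFrame(fs.values, index=fs.sample_ids, columns=fs.attribute_ids).to_csv(
        matrix_path, sep="\t", index_label="sample_id"
    )
    with open(registry_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["attribute_id", "view", "attribute", "gene_symbol"])
        for gid in fs.attribute_ids:
            info = fs.registry[gid]
            w.writerow([gid, info.view, info.attribute, info.gene or ""])


def read_feature_space(matrix_path, registry_path) -> FeatureSpace:
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    reg = pd.read_csv(registry_path, sep="\t", dtype=str).fillna("")
    registry = {
        r.attribute_id: AttributeInfo(r.view, r.attribute, r.gene_symbol or None)
        for r in reg.itertuples()
    }
    return FeatureSpace(
        sample_ids=[str(s) for s in df.index],
        attribute_ids=[str(a) for a in df.columns],
        values=df.to_numpy(dtype=float),
        registry=registry,
    )
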