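"""Anchor-based batch standardisation.

The emulated study ran its assays in two batches with the same control
samples included in both. Those shared controls act as anchors: per gene, the
batch offset is the mean difference between an anchor's value in that batch
and its value in the reference batch, and correction subtracts the offset.
The additive correction is on the log2 scale only; no variance rescaling.
Batch may alternatively (or additionally — forbidden for the same data) be
handled as a covariate in the differential-expression design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SampleTable, ValidationError
from .normalization import ExpressionMatrix

__all__ = ["BatchOffsets", "estimate_batch_offsets", "correct_batches"]


@dataclass
class BatchOffsets:
    """Per-gene additive log2 offsets per batch; reference batch is all-zero."""

    offsets: pd.DataFrame  # genes x batch labels
    reference_batch: str

    def __post_init__(self) -> None:
        if self.reference_batch not in self.offsets.columns:
            raise ValidationError(
                f"reference batch {self.reference_batch!r} not in offsets")
        ref = self.offsets[self.reference_batch]
        if not np.allclose(ref.to_numpy(), 0.0):
            raise ValidationError("reference-batch offsets must be zero")
        if not np.isfinite(self.offsets.to_numpy()).all():
            raise ValidationError("offsets must be finite")


def estimate_batch_offsets(expr: ExpressionMatrix, meta: SampleTable,
                           anchors: list[str] | None = None,
                           reference_batch: str | None = None) -> BatchOffsets:
    """Estimate per-gene batch offsets from anchor samples assayed in every batch.

    offset(gene, batch) = mean over anchors of (anchor value in batch -
    anchor value in the reference batch). The reference batch is the
    lexicographically first unless given.
    """
    if anchors is None:
        anchors = meta.anchors()
    if not anchors:
        raise ValidationError("no anchor samples assayed in more than one batch")
    batches = meta.batches
    if reference_batch is None:
        reference_batch = batches[0]
    if reference_batch not in batches:
        raise ValidationError(f"unknown reference batch {reference_batch!r}")

    frame = meta.frame
    # anchor sample -> batch -> mean expression column
    anchor_cols: dict[str, dict[str, pd.Series]] = {}
    for s in anchors:
        rows = frame[frame["sample_id"] == s]
        per_batch: dict[str, pd.Series] = {}
        for b in batches:
            assays = [a for a in rows.loc[rows["batch"].astype(str) == b,
                                          "assay_id"] if a in expr.values.columns]
            if not assays:
                raise ValidationError(
                    f"anchor sample {s!r} has no assay in batch {b!r}")
            per_batch[b] = expr.values[assays].mean(axis=1)
        anchor_cols[s] = per_batch

    offsets = pd.DataFrame(0.0, index=expr.values.index, columns=batches)
    for b in batches:
        if b == reference_batch:
            continue
        diffs = [anchor_cols[s][b] - anchor_cols[s][reference_batch]
                 for s in anchors]
        offsets[b] = pd.concat(diffs, axis=1).mean(axis=1)
    return BatchOffsets(offsets=offsets, reference_batch=reference_batch)


def correct_batches(expr: ExpressionMatrix, offsets: BatchOffsets,
                    meta: SampleTable) -> ExpressionMatrix:
    """Subtract each assay's batch offset; appends to provenance."""
    batch_of = meta.batch_of()
    missing_assays = [a for a in expr.assay_ids if a not in batch_of.index]
    if missing_assays:
        raise ValidationError(
            f"assays missing from metadata: {missing_assays[:5]}")
    used_batches = set(batch_of.loc[expr.assay_ids])
    uncovered = used_batches - set(offsets.offsets.columns)
    if uncovered:
        raise ValidationError(f"no offsets for batch(es): {sorted(uncovered)}")
    missing_genes = expr.values.index.difference(offsets.offsets.index)
    if len(missing_genes):
        raise ValidationError(
            f"no offsets for gene(s): {list(missing_genes[:5])}")
    shift = offsets.offsets.loc[
        expr.values.index, [batch_of[a] for a in expr.assay_ids]]
    shift.columns = expr.assay_ids
    corrected = expr.values - shift
    step = {"step": "batch_anchor_correction",
            "reference_batch": offsets.reference_batch,
            "batches": sorted(offsets.offsets.columns)}
    return expr.with_values(corrected, step)
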