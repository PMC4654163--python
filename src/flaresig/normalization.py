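"""Positive-control scaling, background filtering, log2 and quantile normalisation.

The chain mirrors standard practice for digital-counting (nCounter-style)
panels: per-lane scale factors from the geometric mean of the positive
spike-in ladder; exclusion of endogenous probes whose signal is not at least
``sd_multiplier`` (default 2) sample standard deviations above the mean of the
negative-control probes; log2 transformation with a pseudocount; and classic
rank-mean quantile normalisation across assays.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, ValidationError

__all__ = [
    "FilterParams",
    "ExpressionMatrix",
    "positive_control_factors",
    "background_filter",
    "quantile_normalize",
    "normalize_pipeline",
]


@dataclass
class FilterParams:
    """Background-filter settings: threshold = mean + sd_multiplier * SD of
    the (scale-adjusted) negative-control counts."""

    sd_multiplier: float = 2.0
    pooling: str = "pooled"  # or "per_sample"

    def __post_init__(self) -> None:
        if self.sd_multiplier < 0:
            raise ValueError("sd_multiplier must be >= 0")
        if self.pooling not in ("pooled", "per_sample"):
            raise ValueError(f"unknown pooling mode: {self.pooling!r}")


@dataclass
class ExpressionMatrix:
    """Filtered, normalised log2-scale gene-by-assay values with provenance.

    ``provenance`` is an ordered list of ``{"step": ..., **params}`` records,
    one per transform applied, so downstream stages can refuse to re-apply a
    correction twice.
    """

    values: pd.DataFrame
    provenance: list[dict] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.values.columns)

    def with_values(self, values: pd.DataFrame, step: dict) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values,
                                provenance=copy.deepcopy(self.provenance) + [step])

    def has_step(self, name: str) -> bool:
        return any(p.get("step") == name for p in self.provenance)


def positive_control_factors(counts: CountMatrix) -> pd.Series:
    """Per-assay scale factors from the positive spike-in controls.

    factor(assay) = GM_ref / GM(assay), where GM(assay) is the geometric mean
    of that assay's positive-probe counts and GM_ref the geometric mean of
    those per-assay means. The returned factors have geometric mean 1.
    """
    pos = counts.positive
    arr = pos.to_numpy(dtype=float)
    if (arr <= 0).any():
        bad = pos.columns[(arr <= 0).any(axis=0)][0]
        raise ValidationError(
            f"assay {bad!r} has a non-positive positive-control count; "
            "geometric mean undefined")
    log_gm = np.log(arr).mean(axis=0)  # per assay
    factors = np.exp(log_gm.mean() - log_gm)
    return pd.Series(factors, index=pos.columns, name="scale_factor")


def background_filter(counts: CountMatrix, factors: pd.Series,
                      params: FilterParams | None = None) -> pd.Series:
    """Boolean keep-mask over endogenous probes.

    Pooled mode (default): one threshold ``mean + k*SD`` (sample SD, n-1) from
    all scale-adjusted negative-control counts across all assays; a gene is
    kept iff its mean scale-adjusted count across assays is >= the threshold.
    Per-sample mode: an assay-specific threshold from that assay's negatives;
    a gene is kept iff it clears its threshold in at least half of the assays.
    """
    params = params or FilterParams()
    neg = counts.negative.to_numpy(dtype=float) * factors.to_numpy()[None, :]
    endo = counts.endogenous.to_numpy(dtype=float) * factors.to_numpy()[None, :]
    if np.isnan(neg).any() or np.isnan(endo).any():
        raise ValidationError("NaN counts encountered in background filter")
    if params.pooling == "pooled":
        flat = neg.ravel()
        if flat.size < 2:
            raise ValidationError(
                "background filter needs >=2 negative-control values")
        threshold = flat.mean() + params.sd_multiplier * flat.std(ddof=1)
        keep = endo.mean(axis=1) >= threshold
    else:
        if neg.shape[0] < 2:
            raise ValidationError(
                "per-sample background filter needs >=2 negative probes")
        thresholds = neg.mean(axis=0) + params.sd_multiplier * neg.std(axis=0,
                                                                       ddof=1)
        keep = (endo >= thresholds[None, :]).mean(axis=1) >= 0.5
    return pd.Series(keep, index=counts.endogenous.index, name="keep")


def background_threshold(counts: CountMatrix, factors: pd.Series,
                         params: FilterParams | None = None) -> float:
    """The pooled-mode threshold value (mean + k*SD of adjusted negatives)."""
    params = params or FilterParams()
    neg = counts.negative.to_numpy(dtype=float) * factors.to_numpy()[None, :]
    flat = neg.ravel()
    if flat.size < 2:
        raise ValidationError("background threshold needs >=2 negative values")
    return float(flat.mean() + params.sd_multiplier * flat.std(ddof=1))


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Classic rank-mean quantile normalisation across columns.

    Sort each column, average across columns at each rank, and assign the
    averages back by original ranks; tied values within a column receive the
    mean of the rank means over their tied positions. After the transform the
    sorted vector of every column is identical.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("quantile normalisation needs >=2 assays")
    arr = matrix.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValidationError("quantile normalisation input contains NaN")
    rank_means = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = rank_means
        # ties: average the rank means over tied positions
        sorted_vals = col[order]
        i = 0
        while i < len(col):
            k = i
            while k + 1 < len(col) and sorted_vals[k + 1] == sorted_vals[i]:
                k += 1
            if k > i:
                assigned[order[i:k + 1]] = rank_means[i:k + 1].mean()
            i = k + 1
        out[:, j] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def apply_quantile(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalise an expression matrix, appending to provenance.

    Exists as a separate step so batch correction can be interleaved before
    it: additive gene-wise batch offsets widen a batch's marginal
    distribution, and equalising marginals first would attenuate the offsets
    an anchor-based estimator is trying to measure.
    """
    done = any(p.get("step") == "quantile_normalization"
               and not p.get("skipped") for p in expr.provenance)
    if done:
        raise ValidationError("expression is already quantile-normalised")
    return expr.with_values(quantile_normalize(expr.values),
                            {"step": "quantile_normalization"})


def normalize_pipeline(counts: CountMatrix,
                       params: FilterParams | None = None,
                       pseudocount: float = 1.0,
                       quantile: bool = True) -> ExpressionMatrix:
    """Full normalisation chain on a raw count matrix.

    Order: positive-control scaling -> negative-control background filter ->
    log2(x + pseudocount) -> quantile normalisation. Control probes are
    dropped from the result; provenance records the four steps in order.
    With ``quantile=False`` (or a single assay) the last step is recorded as
    skipped so that anchor-based batch correction can run first, followed by
    :func:`apply_quantile`.
    """
    params = params or FilterParams()
    factors = positive_control_factors(counts)
    keep = background_filter(counts, factors, params)
    scaled = counts.endogenous.loc[keep] * factors
    logged = np.log2(scaled + pseudocount)
    provenance = [
        {"step": "positive_scaling", "n_positive_probes": int(counts.positive.shape[0])},
        {"step": "background_filter", "sd_multiplier": params.sd_multiplier,
         "pooling": params.pooling, "n_kept": int(keep.sum()),
         "n_dropped": int((~keep).sum())},
        {"step": "log2", "pseudocount": pseudocount},
    ]
    if quantile and logged.shape[1] >= 2:
        values = quantile_normalize(logged)
        provenance.append({"step": "quantile_normalization"})
    else:
        values = logged
        provenance.append({"step": "quantile_normalization", "skipped": True,
                           "reason": ("deferred" if not quantile
                                      else "single assay")})
    return ExpressionMatrix(values=values, provenance=provenance)
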