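"""Per-gene linear models with empirical-Bayes variance smoothing.

Model
-----
For each gene g, a linear model on the log2 expression values,

    y_g = X beta_g + eps_g,    eps_g ~ N(0, sigma_g^2 I),

with X encoding the response group (control reference) and, optionally, the
assay batch. The per-gene sample variances s_g^2 (residual df d) are smoothed
towards a common prior by the standard empirical-Bayes construction: the
prior is scaled inverse chi-square with df d0 and scale s0^2, whose
hyperparameters are estimated by moment-matching the log sample variances
against the scaled-F law (digamma/trigamma moments, trigamma inverted by
Newton iteration). The posterior variance

    s~_g^2 = (d0 s0^2 + d s_g^2) / (d0 + d)

yields a moderated t statistic with d + d0 degrees of freedom.

Multiple testing follows the expected-number-of-false-positives rule: the
per-comparison threshold alpha = k/m makes the expected count of false
positives among m true nulls equal k (e.g. 4 of 400 genes -> alpha 0.01).
Differential expression additionally requires at least a two-fold change;
fold changes are reported on the linear scale with down-regulation as a
fraction below 1 (a halving is 0.5, not -2).

The statsmodels-style entry point is :class:`ExpressionLinearModel`, whose
``fit`` returns an :class:`ExpressionLMResults` carrying the smoothed fits
and producing per-contrast tables and a text summary.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, special, stats

from .io import SampleTable, ValidationError
from .normalization import ExpressionMatrix

__all__ = [
    "DesignSpec", "GeneFits", "ModeratedFits",
    "fit_linear_models", "smooth_variances", "moderated_test",
    "enfp_alpha", "call_significant", "venn_partition", "rtpcr_concordance",
    "ExpressionLinearModel", "ExpressionLMResults",
    "MAIN_GATE", "ENRICHMENT_GATE",
]

#: (fold threshold, alpha) gates: the main differential-expression call and
#: the looser gate used to feed gene-set enrichment
MAIN_GATE = (2.0, 0.01)
ENRICHMENT_GATE = (1.5, 0.05)

_D0_CAP = 1e6  # finite sentinel for an infinite prior df


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass
class DesignSpec:
    """Group (+ optional batch) design with control as the reference level."""

    include_batch: bool = True
    reference_group: str = "control"
    reference_batch: str | None = None

    def build(self, meta: SampleTable) -> pd.DataFrame:
        f = meta.frame
        groups = sorted(set(f["group"]))
        if self.reference_group not in groups:
            raise ValidationError(
                f"reference group {self.reference_group!r} absent from metadata")
        cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(f))}
        for g in groups:
            if g == self.reference_group:
                continue
            cols[f"group_{g}"] = (f["group"] == g).to_numpy(dtype=float)
        if self.include_batch:
            batches = sorted(set(f["batch"].astype(str)))
            ref_b = self.reference_batch or batches[0]
            for b in batches:
                if b == ref_b:
                    continue
                cols[f"batch_{b}"] = (
                    f["batch"].astype(str) == b).to_numpy(dtype=float)
        design = pd.DataFrame(cols, index=f["assay_id"])
        _check_full_rank(design)
        return design

    def contrast_vector(self, name: str, design_columns: list[str]) -> np.ndarray:
        """Resolve 'A-B' (e.g. 'CR-control', 'CR-NR') to a coefficient vector."""
        try:
            a, b = name.split("-", 1)
        except ValueError:
            raise ValidationError(f"contrast {name!r} is not of the form 'A-B'")
        vec = np.zeros(len(design_columns))
        for label, sign in ((a, 1.0), (b, -1.0)):
            if label == self.reference_group:
                continue
            col = f"group_{label}"
            if col not in design_columns:
                raise ValidationError(
                    f"contrast {name!r} refers to missing coefficient {col!r}")
            vec[design_columns.index(col)] = sign
        if not vec.any():
            raise ValidationError(f"contrast {name!r} is identically zero")
        return vec


def _check_full_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, pivot = linalg.qr(X, pivoting=True)
        confounded = [design.columns[j] for j in pivot[rank:]]
        raise ValidationError(
            f"design matrix is rank deficient; confounded column(s): "
            f"{sorted(confounded)}")


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

@dataclass
class GeneFits:
    """OLS fits for every gene under one shared design."""

    coef: pd.DataFrame          # genes x design columns
    s2: pd.Series               # residual variance per gene
    df_resid: int
    xtx_inv: np.ndarray         # (X'X)^-1, shared
    design_columns: list[str] = field(default_factory=list)


@dataclass
class ModeratedFits:
    """GeneFits plus the empirical-Bayes prior and posterior variances."""

    fits: GeneFits
    d0: float                   # prior df (may be inf, capped in tests at 1e6)
    s0_sq: float                # prior variance
    post_var: pd.Series         # posterior (moderated) variances

    def __post_init__(self) -> None:
        if self.s0_sq <= 0:
            raise ValidationError("prior variance must be > 0")
        if self.d0 < 0:
            raise ValidationError("prior df must be >= 0")


def fit_linear_models(expr: ExpressionMatrix,
                      design: pd.DataFrame) -> GeneFits:
    """Ordinary least squares per gene; residual df = n - rank(X)."""
    missing = [a for a in expr.assay_ids if a not in design.index]
    if missing:
        raise ValidationError(f"design missing assay(s): {missing[:5]}")
    X = design.loc[expr.assay_ids].to_numpy(dtype=float)
    _check_full_rank(design.loc[expr.assay_ids])
    Y = expr.values.to_numpy(dtype=float).T  # assays x genes
    n, p = X.shape
    df_resid = n - p
    if df_resid <= 0:
        raise ValidationError(
            f"no residual degrees of freedom (n={n}, p={p})")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y                 # p x genes
    resid = Y - X @ beta
    s2 = (resid ** 2).sum(axis=0) / df_resid
    return GeneFits(
        coef=pd.DataFrame(beta.T, index=expr.values.index,
                          columns=list(design.columns)),
        s2=pd.Series(s2, index=expr.values.index, name="s2"),
        df_resid=df_resid,
        xtx_inv=xtx_inv,
        design_columns=list(design.columns),
    )


# ---------------------------------------------------------------------------
# empirical-Bayes variance smoothing
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse needs x > 0")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = special.polygamma(1, y)
        step = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += step
        if abs(step) / y < 1e-10:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) of the scaled inverse chi-square prior.

    Under the hierarchical model the sample variances follow s0^2 F(d, d0);
    matching the mean and variance of log s^2 via digamma/trigamma moments
    gives the estimates. Returns d0 = inf when the observed log-variance
    spread does not exceed the chi-square sampling spread.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise ValidationError("variance smoothing needs >=2 positive variances")
    z = np.log(s2)
    if np.allclose(z, z[0]):
        # degenerate ensemble: no spread to moment-match; the prior is the
        # common variance itself and moderation leaves it untouched
        return np.inf, float(np.exp(z[0]))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(emean)
    return float(d0), float(s0_sq)


def smooth_variances(fits: GeneFits) -> ModeratedFits:
    """Empirical-Bayes moderation of the per-gene residual variances."""
    s2 = fits.s2.to_numpy(dtype=float)
    if len(s2) < 10:
        raise ValidationError(
            "variance smoothing needs >=10 genes for moment estimation")
    if not (s2 > 0).any():
        raise ValidationError("all residual variances are zero")
    if fits.df_resid <= 0:
        raise ValidationError("residual df must be positive")
    d0, s0_sq = estimate_prior(s2, fits.df_resid)
    post = posterior_variances(s2, fits.df_resid, d0, s0_sq)
    return ModeratedFits(
        fits=fits, d0=d0, s0_sq=s0_sq,
        post_var=pd.Series(post, index=fits.s2.index, name="post_var"))


def posterior_variances(s2: np.ndarray, df: float, d0: float,
                        s0_sq: float) -> np.ndarray:
    """(d0 s0^2 + d s^2) / (d0 + d); returns s0^2 everywhere when d0 = inf."""
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(d0):
        return np.full_like(s2, s0_sq)
    if d0 == 0:
        return s2.copy()
    return (d0 * s0_sq + df * s2) / (d0 + df)


# ---------------------------------------------------------------------------
# moderated tests and calls
# ---------------------------------------------------------------------------

def moderated_test(mfits: ModeratedFits, contrast: np.ndarray | str,
                   spec: DesignSpec | None = None,
                   fold_threshold: float = MAIN_GATE[0],
                   alpha: float = MAIN_GATE[1],
                   contrast_name: str | None = None) -> pd.DataFrame:
    """Moderated t-test of one contrast for every gene.

    Returns a table with columns gene, contrast, log2fc, fold, t, p,
    significant. p is two-sided from a t distribution with d + d0 degrees of
    freedom (d0 capped at 1e6, effectively the normal limit when infinite).
    """
    fits = mfits.fits
    if isinstance(contrast, str):
        spec = spec or DesignSpec()
        contrast_name = contrast_name or contrast
        cvec = spec.contrast_vector(contrast, fits.design_columns)
    else:
        cvec = np.asarray(contrast, dtype=float)
        if cvec.shape != (len(fits.design_columns),):
            raise ValidationError(
                f"contrast length {cvec.shape} does not match design "
                f"({len(fits.design_columns)} coefficients)")
        contrast_name = contrast_name or "custom"
    log2fc = fits.coef.to_numpy() @ cvec
    c_var = float(cvec @ fits.xtx_inv @ cvec)
    se = np.sqrt(mfits.post_var.to_numpy() * c_var)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, 0.0)
    df_total = min(fits.df_resid + mfits.d0, _D0_CAP)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    table = pd.DataFrame({
        "gene": fits.coef.index,
        "contrast": contrast_name,
        "log2fc": log2fc,
        "fold": np.exp2(log2fc),
        "t": t,
        "p": p,
    }).reset_index(drop=True)
    table["significant"] = _gate_mask(table, fold_threshold, alpha)
    return table


def enfp_alpha(m: int, k: float) -> float:
    """Per-comparison alpha with expected false positives k among m nulls."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    if not 0 < k <= m:
        raise ValidationError(f"k must satisfy 0 < k <= m (got k={k}, m={m})")
    return k / m


def _gate_mask(table: pd.DataFrame, fold_threshold: float,
               alpha: float) -> pd.Series:
    if fold_threshold < 1:
        raise ValidationError("fold threshold must be >= 1")
    fold = table["fold"]
    return ((fold >= fold_threshold) | (fold <= 1.0 / fold_threshold)) & \
        (table["p"] < alpha)


def call_significant(table: pd.DataFrame, fold_threshold: float,
                     alpha: float) -> set[str]:
    """Genes passing the double gate: |fold| beyond threshold and p < alpha."""
    if table.empty:
        return set()
    mask = _gate_mask(table, fold_threshold, alpha)
    return set(table.loc[mask, "gene"])


def venn_partition(named_sets: dict[str, set[str]]) -> dict[str, set[str]]:
    """Exact region decomposition of named gene sets.

    Region labels join member set names with an intersection sign; proper
    subsets get an ' only' suffix (e.g. 'CR only', 'CR∩PR only', 'CR∩PR∩NR').
    Regions are pairwise disjoint and cover the union; empty regions are
    omitted.
    """
    names = list(named_sets)
    if len(names) < 2:
        raise ValidationError("venn partition needs >=2 named sets")
    if len(set(names)) != len(names):
        raise ValidationError("duplicate set names")
    regions: dict[str, set[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(named_sets[n] for n in combo))
            for other in names:
                if other not in combo:
                    inside = inside - named_sets[other]
            if not inside:
                continue
            label = "∩".join(combo)
            if len(combo) < len(names):
                label += " only"
            regions[label] = inside
    return regions


def rtpcr_concordance(de: pd.DataFrame,
                      pcr: pd.Series | dict[str, float]) -> pd.DataFrame:
    """Direction agreement between platform fold changes and RT-PCR ddCt.

    ``pcr`` maps gene -> delta-delta-Ct (cycles) for the same contrast; the
    PCR fold change is 2**(-ddCt). A gene is concordant when the sign of its
    platform log2 fold change matches the sign of -ddCt. The returned frame
    has one row per overlapping gene plus attrs['concordance'] with the
    overall concordant fraction.
    """
    pcr = pd.Series(pcr, dtype=float)
    if not np.isfinite(pcr.to_numpy()).all():
        raise ValidationError("PCR table contains non-finite ddCt values")
    de_fc = de.set_index("gene")["log2fc"]
    genes = [g for g in pcr.index if g in de_fc.index]
    if not genes:
        raise ValidationError("no genes shared between DE table and PCR table")
    rows = []
    for g in genes:
        pcr_log2 = -float(pcr[g])
        rows.append({
            "gene": g,
            "log2fc_platform": float(de_fc[g]),
            "ddct": float(pcr[g]),
            "fold_pcr": float(2.0 ** pcr_log2),
            "concordant": bool(np.sign(de_fc[g]) == np.sign(pcr_log2)),
        })
    out = pd.DataFrame(rows)
    out.attrs["concordance"] = float(out["concordant"].mean())
    return out


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class ExpressionLinearModel:
    """Per-gene linear model of log2 expression on response group (+ batch).

    Parameters
    ----------
    expr : ExpressionMatrix
        Normalised log2 expression (genes x assays).
    meta : SampleTable
        Assay-level metadata aligned with ``expr``.
    include_batch : bool
        Add the assay batch as a covariate. Refused (double correction) when
        the expression matrix has already been anchor-corrected for batch.
    """

    def __init__(self, expr: ExpressionMatrix, meta: SampleTable,
                 include_batch: bool = True,
                 reference_group: str = "control"):
        if include_batch and expr.has_step("batch_anchor_correction"):
            raise ValidationError(
                "expression was already anchor-corrected for batch; "
                "refusing to also fit batch as a covariate")
        self.expr = expr
        self.meta = meta
        self.spec = DesignSpec(include_batch=include_batch,
                               reference_group=reference_group)
        meta_ids = set(meta.assay_ids)
        missing = [a for a in expr.assay_ids if a not in meta_ids]
        if missing:
            raise ValidationError(f"assays missing from metadata: {missing[:5]}")
        sub = meta.frame[meta.frame["assay_id"].isin(expr.assay_ids)]
        self._meta_used = SampleTable(sub)
        self.design = self.spec.build(self._meta_used)

    def fit(self, smooth: bool = True) -> "ExpressionLMResults":
        fits = fit_linear_models(self.expr, self.design)
        if smooth:
            mfits = smooth_variances(fits)
        else:
            d0, s0 = 0.0, float(np.mean(fits.s2[fits.s2 > 0]))
            mfits = ModeratedFits(
                fits=fits, d0=d0, s0_sq=s0,
                post_var=fits.s2.copy())
        return ExpressionLMResults(self, mfits)


class ExpressionLMResults:
    """Fitted moderated models; produces contrast tables and a summary."""

    def __init__(self, model: ExpressionLinearModel, mfits: ModeratedFits):
        self.model = model
        self.mfits = mfits

    @property
    def d0(self) -> float:
        return self.mfits.d0

    @property
    def s0_sq(self) -> float:
        return self.mfits.s0_sq

    @property
    def df_resid(self) -> int:
        return self.mfits.fits.df_resid

    def contrast(self, name: str,
                 fold_threshold: float = MAIN_GATE[0],
                 alpha: float = MAIN_GATE[1]) -> pd.DataFrame:
        return moderated_test(self.mfits, name, spec=self.model.spec,
                              fold_threshold=fold_threshold, alpha=alpha)

    def significant(self, name: str,
                    fold_threshold: float = MAIN_GATE[0],
                    alpha: float = MAIN_GATE[1]) -> set[str]:
        return call_significant(self.contrast(name, fold_threshold, alpha),
                                fold_threshold, alpha)

    def summary(self, contrasts: list[str] | None = None,
                fold_threshold: float = MAIN_GATE[0],
                alpha: float = MAIN_GATE[1]) -> str:
        groups = sorted(set(self.model._meta_used.frame["group"])
                        - {self.model.spec.reference_group})
        contrasts = contrasts or [
            f"{g}-{self.model.spec.reference_group}" for g in groups]
        lines = [
            "Moderated linear model of log2 expression",
            "=" * 48,
            f"genes: {len(self.mfits.fits.s2)}    assays: "
            f"{len(self.model.expr.assay_ids)}",
            f"design columns: {', '.join(self.mfits.fits.design_columns)}",
            f"residual df: {self.df_resid}    prior df d0: "
            f"{'inf' if np.isinf(self.d0) else f'{self.d0:.3g}'}    "
            f"prior variance s0^2: {self.s0_sq:.4g}",
            f"gate: fold >= {fold_threshold:g} (or <= {1 / fold_threshold:.3g})"
            f" and p < {alpha:g}",
            "-" * 48,
        ]
        for c in contrasts:
            n_sig = len(self.significant(c, fold_threshold, alpha))
            lines.append(f"{c:>16}: {n_sig:5d} significant genes")
        return "\n".join(lines)
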