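"""Gene-set overrepresentation and activation scoring.

Overrepresentation uses the one-sided Fisher / hypergeometric tail
P(X >= overlap) on the 2x2 table (in-set vs out-of-set, DE vs not-DE) against
a stated background, reported with -log10 p; no multiple-testing correction
is applied (results are unadjusted by design). When a gene set carries
expected member directions (+1/-1), the activation z-score

    z = (n_consistent - n_inconsistent) / sqrt(N)

over the N direction-annotated DE members predicts an activated (z >= 2),
suppressed (z <= -2) or undetermined state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSet, GeneSetCollection, ValidationError

__all__ = ["EnrichmentRow", "fisher_enrichment", "activation_zscore"]


@dataclass
class EnrichmentRow:
    set_id: str
    overlap: int
    set_size: int
    background_size: int
    de_size: int
    p: float
    neg_log10_p: float
    z: float | None = None
    state: str | None = None


def fisher_enrichment(de_genes: set[str], sets: GeneSetCollection,
                      background: set[str],
                      alternative: str = "greater") -> pd.DataFrame:
    """Per-set overrepresentation p-values, sorted ascending.

    Set members are intersected with the background first; ``alternative``
    may be 'greater' (one-sided overrepresentation, default) or 'two-sided'.
    """
    if not background:
        raise ValidationError("background gene set is empty")
    stray = set(de_genes) - set(background)
    if stray:
        raise ValidationError(
            f"DE genes outside the background: {sorted(stray)[:5]}")
    if alternative not in ("greater", "two-sided"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    N = len(background)
    n = len(de_genes)
    rows = []
    for gs in sets:
        members = set(gs.members) & set(background)
        if not members:
            continue
        K = len(members)
        k = len(members & set(de_genes))
        if alternative == "greater":
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        else:
            table = [[k, K - k], [n - k, N - K - (n - k)]]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        p = min(max(p, np.finfo(float).tiny), 1.0)
        rows.append({
            "set_id": gs.set_id,
            "overlap": k,
            "set_size": K,
            "background_size": N,
            "de_size": n,
            "p": p,
            "neg_log10_p": float(-np.log10(p)),
        })
    out = pd.DataFrame(rows, columns=["set_id", "overlap", "set_size",
                                      "background_size", "de_size", "p",
                                      "neg_log10_p"])
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def activation_zscore(de: pd.DataFrame, gene_set: GeneSet,
                      state_threshold: float = 2.0) -> tuple[float, str]:
    """Direction-consistency z and predicted state for one signed gene set.

    ``de`` is a differential-expression table (columns gene, log2fc,
    significant); only significant genes are scored. A member is consistent
    when the sign of its log2 fold change equals its annotated direction.
    """
    if gene_set.directions is None:
        raise ValidationError(
            f"gene set {gene_set.set_id!r} has no direction annotations")
    sig = de.loc[de["significant"]].set_index("gene")["log2fc"]
    annotated = [g for g in gene_set.members
                 if g in sig.index and g in gene_set.directions]
    if not annotated:
        raise ValidationError(
            f"no significant DE genes with directions in set "
            f"{gene_set.set_id!r}")
    signs = np.sign([sig[g] for g in annotated])
    expected = np.array([gene_set.directions[g] for g in annotated])
    n_consistent = int((signs == expected).sum())
    n_inconsistent = len(annotated) - n_consistent
    z = (n_consistent - n_inconsistent) / np.sqrt(len(annotated))
    if z >= state_threshold:
        state = "activated"
    elif z <= -state_threshold:
        state = "suppressed"
    else:
        state = "undetermined"
    return float(z), state
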