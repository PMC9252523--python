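"""Single-sample gene-set enrichment scores from the weighted running sum.

For each sample, genes are ranked by expression (descending; ties broken
by gene id so results are platform-independent) and assigned rank
magnitudes r = N, N-1, ..., 1. Walking down the ranked list, the
in-set cumulative mass P_in(i) (r^alpha weighted, normalized by the
total in-set r^alpha mass) and the out-of-set cumulative count P_out(i)
(normalized by N - |S|) are accumulated; the raw enrichment score is the
integral form sum_i (P_in(i) - P_out(i)), not the maximum deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ExpressionCohort, GeneSet, ValidationError


@dataclass
class SsgseaScores:
    """Per-sample enrichment scores for one signature."""

    signature_name: str
    alpha: float
    sample_ids: tuple[str, ...]
    raw_es: np.ndarray
    normalized_es: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "raw_es": self.raw_es,
                "normalized_es": self.normalized_es,
                "alpha": self.alpha,
                "signature": self.signature_name,
            }
        )


def _sample_raw_es(order: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Raw ES for one sample given its gene ordering (best rank first)."""
    n = order.size
    in_ordered = in_set[order]
    n_in = int(in_ordered.sum())
    # rank magnitude at position i (0-based): N - i
    r = (n - np.arange(n)).astype(float)
    w = np.where(in_ordered, r**alpha, 0.0)
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~in_ordered) / float(n - n_in)
    return float(np.sum(p_in - p_out))


def ssgsea(cohort: ExpressionCohort, signature: GeneSet, alpha: float = 0.25) -> SsgseaScores:
    """Score every sample in ``cohort`` against ``signature``.

    Raises if the signature has no overlap with the cohort's genes or
    covers them all (the out-of-set walk would be undefined).
    """
    genes = np.array(cohort.gene_ids)
    in_set = np.isin(genes, list(signature.genes))
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValidationError(
            f"signature {signature.name!r} shares no genes with the cohort"
        )
    if n_in == cohort.n_genes:
        raise ValidationError(
            f"signature {signature.name!r} covers every gene in the cohort; "
            "out-of-set normalization is undefined"
        )
    # deterministic ordering: expression descending, gene id ascending on ties
    by_id = np.argsort(genes, kind="stable")
    id_order = np.empty_like(by_id)
    id_order[by_id] = np.arange(genes.size)  # lexicographic rank of each gene id

    raw = np.empty(cohort.n_samples)
    for j in range(cohort.n_samples):
        col = cohort.values[:, j]
        order = np.lexsort((id_order, -col))
        raw[j] = _sample_raw_es(order, in_set, alpha)

    span = raw.max() - raw.min()
    normalized = raw / span if span > 0 else np.full_like(raw, np.nan)
    return SsgseaScores(
        signature_name=signature.name,
        alpha=alpha,
        sample_ids=cohort.sample_ids,
        raw_es=raw,
        normalized_es=normalized,
    )


def dichotomize_scores(scores: SsgseaScores) -> pd.DataFrame:
    """Median split of raw scores: > median -> 'high', <= median -> 'low'."""
    if len(scores.sample_ids) < 2:
        raise ValidationError("need >= 2 samples to dichotomize scores")
    raw = scores.raw_es
    if np.all(raw == raw[0]):
        raise ValidationError("all scores equal; high/low groups undefined")
    med = float(np.median(raw))
    group = np.where(raw > med, "high", "low")
    return pd.DataFrame(
        {"sample_id": scores.sample_ids, "raw_es": raw, "group": group}
    )
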