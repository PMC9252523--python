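"""Two-marker sex inference and housekeeping-ratio trend comparison.

Sex is inferred by 2-means clustering on (log2(XIST+1), log2(RPS4Y1+1));
the cluster with the higher mean XIST is called female. The trend
comparison expresses each signature gene as a ratio to a housekeeping
gene and runs Student's t test (pooled variance by default) between each
cohort pair.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .types import COHORT_LABELS, ExpressionCohort, GeneSet, ValidationError

XIST = "XIST"
RPS4Y1 = "RPS4Y1"

_PAIRS = tuple(itertools.combinations(COHORT_LABELS, 2))


@dataclass
class SexCall:
    sample_id: str
    inferred_sex: str  # 'male' | 'female'
    cluster_distance_margin: float


def infer_sex(
    cohort: ExpressionCohort,
    xist_gene: str = XIST,
    rps4y1_gene: str = RPS4Y1,
    n_restarts: int = 50,
    random_state: int = 0,
) -> list[SexCall]:
    """Call sample sex from the two marker genes by 2-means clustering."""
    for marker in (xist_gene, rps4y1_gene):
        if not cohort.has_gene(marker):
            raise ValidationError(f"marker gene {marker!r} absent from cohort")
    if cohort.n_samples < 2:
        raise ValidationError("need >= 2 samples to form two clusters")
    x = np.log2(cohort.gene_values(xist_gene) + 1.0)
    y = np.log2(cohort.gene_values(rps4y1_gene) + 1.0)
    pts = np.column_stack([x, y])
    if np.allclose(pts, pts[0]):
        raise ValidationError("all samples identical on both markers; clusters undefined")
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=random_state)
    labels = km.fit_predict(pts)
    female_cluster = int(np.argmax(km.cluster_centers_[:, 0]))  # higher mean XIST
    d = np.linalg.norm(pts[:, None, :] - km.cluster_centers_[None, :, :], axis=2)
    margin = np.abs(d[:, 0] - d[:, 1])
    return [
        SexCall(
            sample_id=s,
            inferred_sex="female" if lab == female_cluster else "male",
            cluster_distance_margin=float(m),
        )
        for s, lab, m in zip(cohort.sample_ids, labels, margin)
    ]


@dataclass
class TrendResult:
    gene_id: str
    ratio_means: dict[str, float]  # cohort -> mean(gene / housekeeping)
    t_statistics: dict[tuple[str, str], float]
    p_values: dict[tuple[str, str], float]
    monotone_decreasing: bool


def _pair_t(a: np.ndarray, b: np.ndarray, welch: bool) -> tuple[float, float]:
    if len(a) < 2 or len(b) < 2:
        return float("nan"), float("nan")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def ratio_trend(
    cohort: ExpressionCohort,
    signature: GeneSet,
    housekeeping: str = "GAPDH",
    welch: bool = False,
) -> list[TrendResult]:
    """Per-gene housekeeping-ratio means and cohort-pair t tests.

    A cohort pair with fewer than 2 samples on either side gets NaN
    statistics (undefined, not an exception). The monotone flag is true
    iff the ratio means are strictly ordered ref_normal > adj_normal > tumor.
    """
    if not cohort.has_gene(housekeeping):
        raise ValidationError(f"housekeeping gene {housekeeping!r} absent from cohort")
    hk = cohort.gene_values(housekeeping)
    if np.any(hk <= 0):
        raise ValidationError(
            f"housekeeping gene {housekeeping!r} has non-positive values; ratios undefined"
        )
    cohort_masks = {c: np.array([x == c for x in cohort.cohort]) for c in COHORT_LABELS}
    results: list[TrendResult] = []
    for gene in signature.genes:
        if not cohort.has_gene(gene):
            continue
        ratio = cohort.gene_values(gene) / hk
        means: dict[str, float] = {}
        per_cohort: dict[str, np.ndarray] = {}
        for c, mask in cohort_masks.items():
            per_cohort[c] = ratio[mask]
            means[c] = float(np.mean(ratio[mask])) if mask.any() else float("nan")
        tstats: dict[tuple[str, str], float] = {}
        pvals: dict[tuple[str, str], float] = {}
        for a, b in _PAIRS:
            t, p = _pair_t(per_cohort[a], per_cohort[b], welch)
            tstats[(a, b)] = t
            pvals[(a, b)] = p
        mono = (
            np.isfinite(means["ref_normal"])
            and np.isfinite(means["adj_normal"])
            and np.isfinite(means["tumor"])
            and means["ref_normal"] > means["adj_normal"] > means["tumor"]
        )
        results.append(TrendResult(gene, means, tstats, pvals, bool(mono)))
    return results


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs pass through)."""
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    q = p[ok]
    n = q.size
    if n == 0:
        return out
    order = np.argsort(q)
    ranked = q[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(n)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def trend_frame(results: list[TrendResult]) -> pd.DataFrame:
    """Flatten trend results to one row per gene, with raw and BH-adjusted p."""
    rows = []
    for r in results:
        row: dict[str, object] = {"gene_id": r.gene_id, "monotone_decreasing": r.monotone_decreasing}
        for c in COHORT_LABELS:
            row[f"mean_{c}"] = r.ratio_means[c]
        for a, b in _PAIRS:
            row[f"t_{a}_vs_{b}"] = r.t_statistics[(a, b)]
            row[f"p_{a}_vs_{b}"] = r.p_values[(a, b)]
        rows.append(row)
    df = pd.DataFrame(rows)
    for a, b in _PAIRS:
        df[f"p_adj_{a}_vs_{b}"] = bh_adjust(df[f"p_{a}_vs_{b}"].to_numpy())
    return df
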