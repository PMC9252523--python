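"""Five-filter gene-screening cascade with per-stage provenance.

Stage order (each stage filters the previous stage's survivors):

1. differential between high/low obesity-score groups in the tumor
   cohort (score groups from the ssGSEA median split),
2. female-over-male differential in the reference-normal cohort,
3. reference-normal-female over tumor-female differential,
4. univariate Cox screen for protective genes (HR < 1) in female tumor
   samples,
5. Pearson correlation against the signature genes in the tumor cohort
   (pass needs r > corr_min with p < corr_p_max for at least
   min_correlated_signature_genes of them),
6. (optional) intersection with user-supplied annotation gene sets.

logFC is log2(mean(A)+1) - log2(mean(B)+1) on linear-scale expression;
the numerator convention for stage 1 is configurable and stated in the
report. The default (low-over-high < threshold) keeps genes HIGHER in
high-obesity-score tumors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sex_trend import bh_adjust, infer_sex
from .ssgsea import SsgseaScores, dichotomize_scores, ssgsea
from .survival import screen_protective
from .types import ExpressionCohort, GeneSet, SurvivalTable, ValidationError


@dataclass
class CascadeConfig:
    logfc_obesity_max: float = -0.3
    logfc_sex_min: float = 0.3
    logfc_tumor_min: float = 0.0
    hr_max: float = 1.0
    corr_min: float = 0.5
    corr_p_max: float = 0.05
    min_correlated_signature_genes: int = 12
    annotation_sets: Optional[list[GeneSet]] = None
    stage1_numerator: str = "low_over_high"  # or "high_over_low"
    corr_method: str = "pearson"             # or "spearman"
    ssgsea_alpha: float = 0.25

    def __post_init__(self) -> None:
        if not (0 < self.corr_min < 1):
            raise ValidationError("corr_min must lie in (0, 1)")
        if self.stage1_numerator not in ("low_over_high", "high_over_low"):
            raise ValidationError(f"unknown stage1_numerator {self.stage1_numerator!r}")
        if self.corr_method not in ("pearson", "spearman"):
            raise ValidationError(f"unknown corr_method {self.corr_method!r}")

    def validate_against(self, signature: GeneSet) -> None:
        if self.min_correlated_signature_genes > len(signature):
            raise ValidationError(
                "min_correlated_signature_genes exceeds the signature size"
            )


def logfc(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """log2(mean(A)+1) - log2(mean(B)+1) on linear-scale expression."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("logfc requires both groups non-empty")
    return float(np.log2(a.mean() + 1.0) - np.log2(b.mean() + 1.0))


def _logfc_table(
    expr: ExpressionCohort, mask_a: np.ndarray, mask_b: np.ndarray,
    genes: Sequence[str],
) -> pd.Series:
    if not mask_a.any() or not mask_b.any():
        raise ValidationError("logfc requires both groups non-empty")
    mean_a = expr.values[:, mask_a].mean(axis=1)
    mean_b = expr.values[:, mask_b].mean(axis=1)
    lfc = np.log2(mean_a + 1.0) - np.log2(mean_b + 1.0)
    s = pd.Series(lfc, index=list(expr.gene_ids))
    return s.loc[list(genes)]


def stage1_obesity_de(
    tumor_expr: ExpressionCohort,
    scores: SsgseaScores,
    config: CascadeConfig,
    genes: Sequence[str] | None = None,
) -> tuple[list[str], pd.Series]:
    """Genes differential between the ssGSEA high/low score groups."""
    groups = dichotomize_scores(scores)
    group_of = dict(zip(groups["sample_id"], groups["group"]))
    hi = np.array([group_of[s] == "high" for s in tumor_expr.sample_ids])
    lo = ~hi
    genes = list(genes) if genes is not None else list(tumor_expr.gene_ids)
    if config.stage1_numerator == "low_over_high":
        lfc = _logfc_table(tumor_expr, lo, hi, genes)
    else:
        lfc = _logfc_table(tumor_expr, hi, lo, genes)
    keep = lfc.index[lfc < config.logfc_obesity_max]
    return list(keep), lfc


def stage2_sex_de(
    ref_expr: ExpressionCohort, config: CascadeConfig, genes: Sequence[str]
) -> tuple[list[str], pd.Series]:
    """Genes higher in females than males in the reference-normal cohort."""
    fem = np.array([s == "female" for s in ref_expr.sex])
    male = np.array([s == "male" for s in ref_expr.sex])
    lfc = _logfc_table(ref_expr, fem, male, genes)
    keep = lfc.index[lfc > config.logfc_sex_min]
    return list(keep), lfc


def stage3_female_tumor_de(
    expr: ExpressionCohort, config: CascadeConfig, genes: Sequence[str]
) -> tuple[list[str], pd.Series]:
    """Genes higher in reference-normal females than tumor females (strict)."""
    ref_f = np.array(
        [c == "ref_normal" and s == "female" for c, s in zip(expr.cohort, expr.sex)]
    )
    tum_f = np.array(
        [c == "tumor" and s == "female" for c, s in zip(expr.cohort, expr.sex)]
    )
    lfc = _logfc_table(expr, ref_f, tum_f, genes)
    keep = lfc.index[lfc > config.logfc_tumor_min]
    return list(keep), lfc


def stage5_signature_correlation(
    tumor_expr: ExpressionCohort,
    candidates: Sequence[str],
    signature: GeneSet,
    config: CascadeConfig,
) -> tuple[list[str], pd.DataFrame]:
    """Correlate each candidate against every signature gene in tumor samples.

    A candidate passes iff at least ``min_correlated_signature_genes``
    signature genes give r > corr_min with two-sided p < corr_p_max.
    Correlations are computed on log2(x + 1) (Pearson on the linear
    lognormal scale is attenuated). Zero-variance candidates fail with
    the reason recorded.
    """
    sig_genes = [g for g in signature.genes if tumor_expr.has_gene(g)]
    if len(sig_genes) < len(signature.genes):
        missing = sorted(set(signature.genes) - set(sig_genes))
        raise ValidationError(f"signature genes absent from expression: {missing}")
    n = tumor_expr.n_samples
    sig_mat = np.log2(np.vstack([tumor_expr.gene_values(g) for g in sig_genes]) + 1.0)
    if config.corr_method == "spearman":
        sig_mat = np.apply_along_axis(stats.rankdata, 1, sig_mat)

    rows = []
    keep: list[str] = []
    for cand in candidates:
        x = np.log2(tumor_expr.gene_values(cand) + 1.0)
        if config.corr_method == "spearman":
            x = stats.rankdata(x)
        if np.ptp(x) == 0:
            rows.append({"gene_id": cand, "n_correlated": 0, "passed": False,
                         "reason": "zero_variance"})
            continue
        xc = x - x.mean()
        sc = sig_mat - sig_mat.mean(axis=1, keepdims=True)
        denom = np.sqrt((xc**2).sum() * (sc**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (sc @ xc) / denom
        r = np.clip(r, -1.0, 1.0)
        # two-sided p from the exact t transform of Pearson's r
        with np.errstate(invalid="ignore", divide="ignore"):
            t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
        p = 2.0 * stats.t(df=n - 2).sf(np.abs(t))
        ok = (r > config.corr_min) & (p < config.corr_p_max) & np.isfinite(r)
        n_corr = int(ok.sum())
        passed = n_corr >= config.min_correlated_signature_genes
        row: dict[str, object] = {"gene_id": cand, "n_correlated": n_corr,
                                  "passed": passed, "reason": ""}
        for g, rv, pv in zip(sig_genes, r, p):
            row[f"r_{g}"] = float(rv)
            row[f"p_{g}"] = float(pv)
        rows.append(row)
        if passed:
            keep.append(cand)
    table = pd.DataFrame(
        rows, columns=None if rows else ["gene_id", "n_correlated", "passed", "reason"])
    pcols = [c for c in table.columns if c.startswith("p_")]
    if pcols:
        flat = table[pcols].to_numpy(dtype=float).ravel()
        table_adj = bh_adjust(flat).reshape(len(table), len(pcols))
        for j, c in enumerate(pcols):
            table[f"adj_{c}"] = table_adj[:, j]
    return keep, table


@dataclass
class StageRecord:
    name: str
    threshold: str
    n_input: int
    survivors: list[str]

    @property
    def n_output(self) -> int:
        return len(self.survivors)


@dataclass
class CascadeReport:
    stages: list[StageRecord] = field(default_factory=list)
    final_genes: list[str] = field(default_factory=list)
    audit: dict[str, list[dict]] = field(default_factory=dict)
    stage1_numerator: str = "low_over_high"

    def record(self, name: str, threshold: str, input_genes: Sequence[str],
               survivors: Sequence[str], stats_by_gene: dict[str, object]) -> None:
        surv_set = set(survivors)
        if not surv_set <= set(input_genes):
            raise AssertionError(f"{name}: survivors are not nested within input")
        self.stages.append(StageRecord(name, threshold, len(input_genes), list(survivors)))
        for g in input_genes:
            self.audit.setdefault(g, []).append(
                {"stage": name, "passed": g in surv_set, "stat": stats_by_gene.get(g)}
            )

    def eliminated_at(self, gene: str) -> Optional[str]:
        for entry in self.audit.get(gene, []):
            if not entry["passed"]:
                return entry["stage"]
        return None

    def to_json(self) -> str:
        payload = {
            "stage1_numerator": self.stage1_numerator,
            "stages": [
                {"name": s.name, "threshold": s.threshold,
                 "n_input": s.n_input, "n_output": s.n_output,
                 "survivors": s.survivors}
                for s in self.stages
            ],
            "final_genes": self.final_genes,
            "audit": self.audit,
        }
        return json.dumps(payload, sort_keys=True, default=_jsonable)


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return float(v)
    raise TypeError(f"not JSON-serializable: {type(v)}")


def run_cascade(
    expr: ExpressionCohort,
    survival: SurvivalTable,
    signature: GeneSet,
    config: CascadeConfig | None = None,
    genes: Sequence[str] | None = None,
) -> CascadeReport:
    """Execute stages 1-5 (and optional stage 6) in order with provenance.

    Samples with unknown sex get calls from the two-marker clustering
    before the sex-dependent stages run. The default candidate universe is
    every gene except the signature itself (the scoring instrument is not
    a candidate; pass ``genes`` explicitly to override). Per-gene failures
    inside a stage are recorded, never fatal; a stage-level precondition
    failure aborts with the stage named.
    """
    config = config or CascadeConfig()
    config.validate_against(signature)
    if any(s == "unknown" for s in expr.sex):
        calls = {c.sample_id: c.inferred_sex for c in infer_sex(expr)}
        expr = expr.with_sex(
            tuple(calls[s] if sx == "unknown" else sx
                  for s, sx in zip(expr.sample_ids, expr.sex))
        )

    tumor = expr.select_cohort("tumor")
    ref = expr.select_cohort("ref_normal")
    if genes is not None:
        universe = list(genes)
    else:
        universe = [g for g in expr.gene_ids if g not in signature.genes]
    report = CascadeReport(stage1_numerator=config.stage1_numerator)

    try:
        scores = ssgsea(tumor, signature, alpha=config.ssgsea_alpha)
        s1, lfc1 = stage1_obesity_de(tumor, scores, config, universe)
    except ValidationError as exc:
        raise ValidationError(f"stage1 failed: {exc}") from exc
    report.record(
        "stage1_obesity_de",
        f"logFC({config.stage1_numerator}) < {config.logfc_obesity_max}",
        universe, s1, lfc1.to_dict(),
    )

    try:
        s2, lfc2 = stage2_sex_de(ref, config, s1)
    except ValidationError as exc:
        raise ValidationError(f"stage2 failed: {exc}") from exc
    report.record("stage2_sex_de", f"logFC(female/male) > {config.logfc_sex_min}",
                  s1, s2, lfc2.to_dict())

    try:
        s3, lfc3 = stage3_female_tumor_de(expr, config, s2)
    except ValidationError as exc:
        raise ValidationError(f"stage3 failed: {exc}") from exc
    report.record("stage3_female_tumor_de",
                  f"logFC(ref_normal_female/tumor_female) > {config.logfc_tumor_min}",
                  s2, s3, lfc3.to_dict())

    female_tumor = expr.subset_samples(
        np.array([c == "tumor" and s == "female"
                  for c, s in zip(expr.cohort, expr.sex)])
    )
    try:
        retained, fits = screen_protective(female_tumor, survival, s3)
    except ValidationError as exc:
        raise ValidationError(f"stage4 failed: {exc}") from exc
    converged = dict(zip(fits["gene_id"], fits["converged"]))
    hr_of = dict(zip(fits["gene_id"], fits["hr"]))
    s4 = [g for g in s3
          if converged.get(g, False) and hr_of.get(g, np.inf) < config.hr_max]
    report.record("stage4_protective_cox", f"HR < {config.hr_max} (female tumor samples)",
                  s3, s4, hr_of)

    try:
        s5, corr_table = stage5_signature_correlation(tumor, s4, signature, config)
    except ValidationError as exc:
        raise ValidationError(f"stage5 failed: {exc}") from exc
    ncorr_of = dict(zip(corr_table["gene_id"], corr_table["n_correlated"]))
    report.record(
        "stage5_signature_correlation",
        f">= {config.min_correlated_signature_genes} signature genes with "
        f"r > {config.corr_min} and p < {config.corr_p_max}",
        s4, s5, ncorr_of,
    )

    final = s5
    if config.annotation_sets is not None:
        if not config.annotation_sets:
            raise ValidationError("stage6 enabled with an empty annotation_sets list")
        member: set[str] = set()
        for gs in config.annotation_sets:
            member |= set(gs.genes)
        s6 = [g for g in s5 if g in member]
        report.record("stage6_annotation_intersect",
                      f"member of {len(config.annotation_sets)} annotation set(s)",
                      s5, s6, {})
        final = s6

    report.final_genes = list(final)
    return report
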