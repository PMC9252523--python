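"""Synthetic cohort generator with full ground-truth bookkeeping.

Generates (i) three expression cohorts (reference normal, adjacent
normal, tumor) on a log2-additive / linear-lognormal scale with a
housekeeping gene, bimodal XIST/RPS4Y1 sex markers, a latent per-sample
obesity factor driving signature co-expression, cohort-ordered signature
decline, planted screening hits and single-violation decoys; (ii)
proportional-hazards survival for the tumor cohort; (iii) exposure /
outcome GWAS summary tables with a planted causal slope and optional
directional pleiotropy (InSIDE holds by construction).

Seed policy: one root seed; each output consumes an independent
substream derived with a fixed spawn key, so regenerating one output
never perturbs another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .data_io import packaged_signature
from .types import (
    COHORT_LABELS,
    ExpressionCohort,
    GeneSet,
    GwasSummaryTable,
    SurvivalTable,
    ValidationError,
)

HOUSEKEEPING = "GAPDH"
MARKER_XIST = "XIST"
MARKER_RPS4Y1 = "RPS4Y1"

STAGES = ("stage1", "stage2", "stage3", "stage4", "stage5")

_NONPALINDROMIC = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"), ("G", "A"), ("T", "C")]
_PALINDROMIC = [("A", "T"), ("C", "G"), ("G", "C"), ("T", "A")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SimulationConfig:
    """Knobs for all three synthetic outputs. See module docstring."""

    seed: int = 0
    # expression
    n_per_group: int = 200          # samples per (cohort, sex) cell
    n_genes: int = 600              # total genes, incl. signature/markers/housekeeping
    signature_genes: GeneSet = field(default_factory=packaged_signature)
    n_planted_hits: int = 5
    n_decoys_per_type: int = 40     # per violated stage (5 types)
    obesity_factor_sd: float = 1.0
    signature_loading: float = 1.0
    cohort_shift: tuple[float, float, float] = (1.0, 0.5, 0.0)
    sexmarker_log_separation: float = 6.0
    housekeeping_cv: float = 0.1
    noise_sd: float = 0.7
    baseline_log2_range: tuple[float, float] = (4.0, 9.0)
    hit_sex_log2fc: float = 1.0     # female-over-male shift for hits/decoys
    hit_tumor_log2fc: float = -1.0  # tumor-over-normal shift for hits
    stage4_decoy_loading: float = 0.7   # stage-4 decoys' obesity-factor loading
    harm_loading: float = 1.3       # stage-4 decoys' loading on the harm factor
    harm_noise_sd: float = 0.3
    stage5_decoy_loading: float = 0.45
    stage5_decoy_noise_sd: float = 1.05
    # survival
    hit_log_hr: float = -0.5        # target univariate per-SD log HR of each hit
    harmful_log_hr: float = 0.6     # target univariate per-SD log HR of stage-4 decoys
    baseline_hazard: float = 1.0 / 1000.0   # events per day
    hazard_calibration: float = 1.4   # scales both thetas; compensates the
                                      # attenuation of univariate Cox fits by
                                      # unexplained hazard heterogeneity
    censoring_fraction: float = 0.2
    round_times_to_days: bool = False
    # gwas
    n_snps: int = 50
    causal_beta: float = 0.0
    causal_beta_female: Optional[float] = None
    causal_beta_male: Optional[float] = None
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    instrument_strength_sd: float = 0.1
    exposure_se: float = 0.005
    outcome_se: float = 0.03
    strand_flip_fraction: float = 0.0
    allele_swap_fraction: float = 0.0
    palindromic_fraction: float = 0.0
    orient_instruments: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        sds = {
            "obesity_factor_sd": self.obesity_factor_sd,
            "noise_sd": self.noise_sd,
            "housekeeping_cv": self.housekeeping_cv,
            "pleiotropy_sd": self.pleiotropy_sd,
            "instrument_strength_sd": self.instrument_strength_sd,
            "exposure_se": self.exposure_se,
            "outcome_se": self.outcome_se,
            "harm_noise_sd": self.harm_noise_sd,
            "stage5_decoy_noise_sd": self.stage5_decoy_noise_sd,
        }
        for name, v in sds.items():
            if v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")
        if self.n_planted_hits >= self.n_genes:
            raise ValidationError("n_planted_hits must be < n_genes")
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")
        if not (0 <= self.censoring_fraction < 1):
            raise ValidationError("censoring_fraction must be in [0, 1)")
        if len(self.cohort_shift) != 3:
            raise ValidationError("cohort_shift needs one value per cohort")
        if self.n_genes < self._min_genes():
            raise ValidationError(
                f"n_genes={self.n_genes} too small for signature + markers + "
                f"{self.n_planted_hits} hits + {5 * self.n_decoys_per_type} decoys "
                f"(need >= {self._min_genes()})"
            )
        for frac in (self.strand_flip_fraction, self.allele_swap_fraction,
                     self.palindromic_fraction):
            if not (0 <= frac <= 1):
                raise ValidationError("fractions must lie in [0, 1]")

    def _min_genes(self) -> int:
        return len(self.signature_genes) + 3 + self.n_planted_hits + 5 * self.n_decoys_per_type


@dataclass
class GroundTruth:
    """Everything a recovery test needs to score the pipeline's output."""

    planted_hits: Optional[GeneSet] = None
    decoy_primary: dict[str, str] = field(default_factory=dict)
    decoy_violations: dict[str, tuple[str, ...]] = field(default_factory=dict)
    sex: dict[str, str] = field(default_factory=dict)
    obesity_factor: Optional[pd.Series] = None
    harm_factor: Optional[pd.Series] = None
    true_mean_log2: Optional[pd.DataFrame] = None
    # survival
    theta_obesity: Optional[float] = None
    theta_harm: Optional[float] = None
    target_log_hr: dict[str, float] = field(default_factory=dict)
    # gwas
    causal_beta: Optional[float] = None
    gamma_true: Optional[np.ndarray] = None
    pleiotropy: Optional[np.ndarray] = None
    outcome_effect_aligned: Optional[np.ndarray] = None
    strand_flipped: Optional[np.ndarray] = None
    alleles_swapped: Optional[np.ndarray] = None

    def to_json(self) -> str:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, pd.Series):
                return v.to_dict()
            if isinstance(v, pd.DataFrame):
                return v.to_dict(orient="list")
            if isinstance(v, GeneSet):
                return {"name": v.name, "genes": list(v.genes)}
            return v

        return json.dumps({k: conv(v) for k, v in self.__dict__.items()},
                          sort_keys=True, default=float)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def _gene_roster(config: SimulationConfig) -> tuple[list[str], dict[str, list[str]]]:
    sig = list(config.signature_genes.genes)
    hits = [f"PROT{i:02d}" for i in range(1, config.n_planted_hits + 1)]
    decoys = {
        s: [f"DEC{k}_{i:03d}" for i in range(1, config.n_decoys_per_type + 1)]
        for k, s in enumerate(STAGES, start=1)
    }
    n_named = len(sig) + 3 + len(hits) + sum(len(v) for v in decoys.values())
    background = [f"BGR_{i:03d}" for i in range(1, config.n_genes - n_named + 1)]
    genes = sig + [HOUSEKEEPING, MARKER_XIST, MARKER_RPS4Y1] + hits
    for s in STAGES:
        genes += decoys[s]
    genes += background
    groups = {"signature": sig, "hits": hits, "background": background, **decoys}
    return genes, groups


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionCohort, GroundTruth]:
    """Generate the three-cohort expression matrix and its ground truth."""
    rng = _rng(config, 0)
    genes, groups = _gene_roster(config)
    gi = {g: i for i, g in enumerate(genes)}

    sample_ids: list[str] = []
    cohorts: list[str] = []
    sexes: list[str] = []
    for cohort in COHORT_LABELS:
        for sex in ("female", "male"):
            for i in range(config.n_per_group):
                sample_ids.append(f"{cohort[:3]}_{sex[0]}_{i:04d}")
                cohorts.append(cohort)
                sexes.append(sex)
    n_s = len(sample_ids)
    cohort_idx = np.array([COHORT_LABELS.index(c) for c in cohorts])
    female = np.array([s == "female" for s in sexes])
    tumor = cohort_idx == 2

    lo, hi = config.baseline_log2_range
    baseline = rng.uniform(lo, hi, size=len(genes))
    baseline[gi[HOUSEKEEPING]] = 10.0
    baseline[gi[MARKER_XIST]] = 2.0
    baseline[gi[MARKER_RPS4Y1]] = 2.0

    f_factor = rng.normal(0.0, config.obesity_factor_sd, size=n_s)
    h_factor = rng.normal(0.0, 1.0, size=n_s)

    gene_sd = np.full(len(genes), config.noise_sd)
    gene_sd[gi[HOUSEKEEPING]] = np.sqrt(np.log1p(config.housekeeping_cv**2)) / np.log(2)
    for g in groups["stage4"]:
        gene_sd[gi[g]] = config.harm_noise_sd
    for g in groups["stage5"]:
        gene_sd[gi[g]] = config.stage5_decoy_noise_sd
    noise = rng.normal(0.0, 1.0, size=(len(genes), n_s)) * gene_sd[:, None]

    mu = np.tile(baseline[:, None], (1, n_s)).astype(float)
    lam = config.signature_loading
    shift = np.asarray(config.cohort_shift, dtype=float)
    sex_fc = config.hit_sex_log2fc
    tum_fc = config.hit_tumor_log2fc

    # per-gene fixed effects (recorded for the ground-truth mean table)
    loading = np.zeros(len(genes))
    sex_eff = np.zeros(len(genes))      # added for female samples
    tum_eff = np.zeros(len(genes))      # added for tumor samples
    uses_cohort_shift = np.zeros(len(genes), dtype=bool)
    for g in groups["signature"]:
        loading[gi[g]] = lam
        uses_cohort_shift[gi[g]] = True
    for g in groups["hits"]:
        loading[gi[g]], sex_eff[gi[g]], tum_eff[gi[g]] = lam, sex_fc, tum_fc
    for g in groups["stage1"]:
        loading[gi[g]], sex_eff[gi[g]], tum_eff[gi[g]] = -lam, sex_fc, tum_fc
    for g in groups["stage2"]:
        # decisively male-high: at finite n a merely sex-neutral decoy can
        # drift past the soft logFC threshold
        loading[gi[g]], sex_eff[gi[g]], tum_eff[gi[g]] = lam, -sex_fc, tum_fc
    for g in groups["stage3"]:
        loading[gi[g]], sex_eff[gi[g]], tum_eff[gi[g]] = lam, sex_fc, -tum_fc
    for g in groups["stage4"]:
        loading[gi[g]] = config.stage4_decoy_loading
        sex_eff[gi[g]], tum_eff[gi[g]] = sex_fc, tum_fc
        mu[gi[g]] += config.harm_loading * h_factor
    for g in groups["stage5"]:
        loading[gi[g]] = config.stage5_decoy_loading
        sex_eff[gi[g]], tum_eff[gi[g]] = sex_fc, tum_fc

    mu += sex_eff[:, None] * female[None, :]
    mu += tum_eff[:, None] * tumor[None, :]
    mu += uses_cohort_shift[:, None] * shift[cohort_idx][None, :]
    mu[gi[MARKER_XIST]] += config.sexmarker_log_separation * female
    mu[gi[MARKER_RPS4Y1]] += config.sexmarker_log_separation * (~female)

    log2 = mu + loading[:, None] * f_factor[None, :] + noise
    values = np.exp2(log2)

    cohort_obj = ExpressionCohort(
        gene_ids=tuple(genes),
        sample_ids=tuple(sample_ids),
        values=values,
        cohort=tuple(cohorts),
        sex=tuple(sexes),
    )

    decoy_primary: dict[str, str] = {}
    decoy_violations: dict[str, tuple[str, ...]] = {}
    for stage in STAGES:
        for g in groups[stage]:
            decoy_primary[g] = stage
            # factor-loading coupling: stage-1 decoys (negative loading) and
            # stage-4 decoys (weak loading, strong harm factor) would also
            # fail the stage-5 positive-correlation rule if ever reached
            if stage in ("stage1", "stage4"):
                decoy_violations[g] = (stage, "stage5")
            else:
                decoy_violations[g] = (stage,)
    for g in groups["background"]:
        decoy_primary[g] = "stage1"
        decoy_violations[g] = ("stage1", "stage2", "stage5")

    mean_rows = []
    for cohort in COHORT_LABELS:
        for sex in ("female", "male"):
            c = COHORT_LABELS.index(cohort)
            fem = sex == "female"
            tum = cohort == "tumor"
            for g in genes:
                k = gi[g]
                m = baseline[k]
                m += shift[c] if uses_cohort_shift[k] else 0.0
                m += sex_eff[k] * fem + tum_eff[k] * tum
                if g == MARKER_XIST:
                    m += config.sexmarker_log_separation * fem
                elif g == MARKER_RPS4Y1:
                    m += config.sexmarker_log_separation * (not fem)
                mean_rows.append({"gene_id": g, "cohort": cohort, "sex": sex, "mean_log2": m})

    truth = GroundTruth(
        planted_hits=GeneSet("planted_hits", tuple(groups["hits"])),
        decoy_primary=decoy_primary,
        decoy_violations=decoy_violations,
        sex=dict(zip(sample_ids, sexes)),
        obesity_factor=pd.Series(f_factor, index=sample_ids),
        harm_factor=pd.Series(h_factor, index=sample_ids),
        true_mean_log2=pd.DataFrame(mean_rows),
    )
    return cohort_obj, truth


def _hazard_thetas(config: SimulationConfig) -> tuple[float, float]:
    """Latent-factor hazard coefficients hitting the target univariate log-HRs."""
    lam = config.signature_loading
    var_f = config.obesity_factor_sd**2
    s_hit = np.sqrt(lam**2 * var_f + config.noise_sd**2)
    if lam == 0 or var_f == 0:
        theta_f = 0.0 if config.hit_log_hr == 0 else np.nan
        if np.isnan(theta_f):
            raise ValidationError(
                "hit_log_hr != 0 requires a nonzero signature loading and obesity factor"
            )
    else:
        theta_f = config.hit_log_hr * s_hit / (lam * var_f)
    c = config.harm_loading
    lam4 = config.stage4_decoy_loading
    s4 = np.sqrt(lam4**2 * var_f + c**2 + config.harm_noise_sd**2)
    theta_h = (config.harmful_log_hr * s4 - lam4 * var_f * theta_f) / c if c > 0 else 0.0
    k = config.hazard_calibration
    return float(k * theta_f), float(k * theta_h)


def simulate_survival(
    config: SimulationConfig, expression: ExpressionCohort, truth: GroundTruth
) -> SurvivalTable:
    """Exponential-baseline proportional-hazards times for the tumor cohort.

    The log hazard is theta_F * (obesity factor) + theta_H * (harm factor),
    scaled so planted hits' univariate per-SD log-HR targets
    ``hit_log_hr`` and stage-4 decoys' targets ``harmful_log_hr``.
    Censoring is independent uniform, calibrated to the target fraction.
    """
    for g in (truth.planted_hits.genes if truth.planted_hits else ()):
        if not expression.has_gene(g):
            raise ValidationError(f"expression cohort lacks planted hit {g!r}")
    rng = _rng(config, 1)
    tumor_mask = np.array([c == "tumor" for c in expression.cohort])
    ids = [s for s, m in zip(expression.sample_ids, tumor_mask) if m]
    sex = [s for s, m in zip(expression.sex, tumor_mask) if m]
    f = truth.obesity_factor.loc[ids].to_numpy()
    h = truth.harm_factor.loc[ids].to_numpy()

    theta_f, theta_h = _hazard_thetas(config)
    eta = theta_f * f + theta_h * h
    rate = config.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / rate)

    if config.censoring_fraction > 0:
        # censored iff C < T with C ~ U(0, m): P = E[min(T/m, 1)]; solve for m
        target = config.censoring_fraction

        def frac(m: float) -> float:
            return float(np.mean(np.minimum(t_event / m, 1.0)))

        lo_m, hi_m = 1e-6, float(t_event.max()) * 2
        while frac(hi_m) > target:
            hi_m *= 2
        for _ in range(200):
            mid = 0.5 * (lo_m + hi_m)
            if frac(mid) > target:
                lo_m = mid
            else:
                hi_m = mid
        c_time = rng.uniform(0.0, hi_m, size=len(ids))
    else:
        c_time = np.full(len(ids), np.inf)

    time = np.minimum(t_event, c_time)
    event = (t_event <= c_time).astype(int)
    if config.round_times_to_days:
        time = np.maximum(np.ceil(time), 1.0)

    truth.theta_obesity = theta_f
    truth.theta_harm = theta_h
    truth.target_log_hr = {}
    if truth.planted_hits:
        for g in truth.planted_hits.genes:
            truth.target_log_hr[g] = config.hit_log_hr
    for g, stage in truth.decoy_primary.items():
        if stage == "stage4" and g in truth.decoy_violations and truth.decoy_violations[g] == ("stage4",):
            truth.target_log_hr[g] = config.harmful_log_hr

    return SurvivalTable(
        pd.DataFrame(
            {"sample_id": ids, "time_days": time, "event": event, "sex": sex}
        )
    )


def simulate_gwas(
    config: SimulationConfig, causal_beta: Optional[float] = None, stream: int = 2
) -> tuple[GwasSummaryTable, GwasSummaryTable, GroundTruth]:
    """Exposure/outcome summary tables with a planted causal slope.

    True instrument effects gamma_j ~ N(0, instrument_strength_sd^2)
    (oriented positive by default, as exported instruments are); true
    outcome effect = causal_beta * gamma_j + alpha_j with alpha_j drawn
    independently of gamma_j (InSIDE). Observed effects add their own
    standard-error noise. A configurable fraction of outcome rows is
    emitted strand-flipped and/or allele-swapped to exercise harmonization.
    """
    rng = _rng(config, stream)
    beta = config.causal_beta if causal_beta is None else causal_beta
    n = config.n_snps
    gamma = rng.normal(0.0, config.instrument_strength_sd, size=n)
    if config.orient_instruments:
        gamma = np.abs(gamma)
    alpha = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=n)
    beta_x = gamma + rng.normal(0.0, config.exposure_se, size=n)
    gamma_out = beta * gamma + alpha
    beta_y = gamma_out + rng.normal(0.0, config.outcome_se, size=n)

    n_pal = int(round(config.palindromic_fraction * n))
    pal_pick = rng.permutation(n) < n_pal
    pair_idx = rng.integers(0, len(_NONPALINDROMIC), size=n)
    pal_idx = rng.integers(0, len(_PALINDROMIC), size=n)
    ea = np.where(pal_pick,
                  [ _PALINDROMIC[i][0] for i in pal_idx],
                  [ _NONPALINDROMIC[i][0] for i in pair_idx])
    oa = np.where(pal_pick,
                  [ _PALINDROMIC[i][1] for i in pal_idx],
                  [ _NONPALINDROMIC[i][1] for i in pair_idx])
    eaf = rng.uniform(0.1, 0.9, size=n)

    snp = np.array([f"rs{i:06d}" for i in range(1, n + 1)])
    se_x = np.full(n, config.exposure_se)
    se_y = np.full(n, config.outcome_se)

    def pvals(b, se):
        z = np.abs(b) / se
        from scipy.stats import norm

        return np.clip(2 * norm.sf(z), np.finfo(float).tiny, 1.0)

    exposure = GwasSummaryTable(pd.DataFrame({
        "snp_id": snp, "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta_x, "se": se_x, "pval": pvals(beta_x, se_x),
        "n": np.full(n, 300000),
    }))

    flip = rng.random(n) < config.strand_flip_fraction
    swap = rng.random(n) < config.allele_swap_fraction
    ea_o = np.array([_COMPLEMENT[a] if f else a for a, f in zip(ea, flip)])
    oa_o = np.array([_COMPLEMENT[a] if f else a for a, f in zip(oa, flip)])
    beta_y_emit = beta_y.copy()
    eaf_o = eaf.copy()
    ea_o2 = ea_o.copy()
    for j in range(n):
        if swap[j]:
            ea_o2[j], oa_o[j] = oa_o[j], ea_o[j]
            beta_y_emit[j] = -beta_y_emit[j]
            eaf_o[j] = 1.0 - eaf_o[j]
    outcome = GwasSummaryTable(pd.DataFrame({
        "snp_id": snp, "effect_allele": ea_o2, "other_allele": oa_o, "eaf": eaf_o,
        "beta": beta_y_emit, "se": se_y, "pval": pvals(beta_y_emit, se_y),
        "n": np.full(n, 50000),
    }))

    truth = GroundTruth(
        causal_beta=beta,
        gamma_true=gamma,
        pleiotropy=alpha,
        outcome_effect_aligned=beta_y,
        strand_flipped=flip,
        alleles_swapped=swap,
    )
    return exposure, outcome, truth


def simulate_gwas_stratified(
    config: SimulationConfig,
) -> dict[str, tuple[GwasSummaryTable, GwasSummaryTable, GroundTruth]]:
    """Per-stratum GWAS pairs (all / female / male) on independent substreams."""
    betas = {
        "all": config.causal_beta,
        "female": config.causal_beta_female
        if config.causal_beta_female is not None else config.causal_beta,
        "male": config.causal_beta_male
        if config.causal_beta_male is not None else config.causal_beta,
    }
    return {
        stratum: simulate_gwas(config, causal_beta=b, stream=2 + k)
        for k, (stratum, b) in enumerate(betas.items())
    }
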