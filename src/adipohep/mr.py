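"""Two-sample Mendelian randomization from summary statistics.

Harmonization aligns outcome effects to the exposure's effect allele
(sign flips for swapped alleles, strand complementation, eaf-based
resolution of palindromic SNPs), then IVW (weighted regression through
the origin, weights 1/se_y^2, multiplicative random-effects inflation
when Cochran's Q overdisperses) and MR-Egger (weighted regression with
intercept after orienting every instrument to gamma >= 0; the intercept
tests directional pleiotropy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .types import GwasSummaryTable, ValidationError

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: eaf window inside which a palindromic SNP is considered ambiguous
PALINDROMIC_EAF_WINDOW = (0.42, 0.58)


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT[ea] == oa


@dataclass
class HarmonizedInstruments:
    """Per-SNP aligned exposure/outcome effects; dropped rows keep a reason."""

    df: pd.DataFrame = field(repr=False)

    def retained(self) -> pd.DataFrame:
        return self.df.loc[~self.df["dropped"]].reset_index(drop=True)

    @property
    def n_retained(self) -> int:
        return int((~self.df["dropped"]).sum())


def harmonize(
    exposure: GwasSummaryTable,
    outcome: GwasSummaryTable,
    eaf_window: tuple[float, float] = PALINDROMIC_EAF_WINDOW,
) -> HarmonizedInstruments:
    """Align outcome effect sizes to the exposure's effect alleles."""
    ex = exposure.df.set_index("snp_id")
    out = outcome.df.set_index("snp_id")
    shared = ex.index.intersection(out.index)
    if len(shared) == 0:
        raise ValidationError("exposure and outcome tables share no SNP ids")
    lo, hi = eaf_window
    rows = []
    for snp in shared:
        e = ex.loc[snp]
        o = out.loc[snp]
        ea, oa = e["effect_allele"], e["other_allele"]
        gamma, se_x = float(e["beta"]), float(e["se"])
        beta_y, se_y = float(o["beta"]), float(o["se"])
        oea, ooa = o["effect_allele"], o["other_allele"]
        dropped, reason, flip = False, "", False

        if _is_palindromic(ea, oa):
            if {oea, ooa} != {ea, oa}:
                dropped, reason = True, "allele_mismatch"
            else:
                eaf_x, eaf_y = e["eaf"], o["eaf"]
                both = pd.notna(eaf_x) and pd.notna(eaf_y)
                unambiguous = both and (
                    (eaf_x < lo and eaf_y < lo) or (eaf_x > hi and eaf_y > hi)
                )
                if not unambiguous:
                    dropped, reason = True, "palindromic_ambiguous"
                else:
                    # strand is unresolvable for palindromes; orient by eaf
                    flip = (eaf_x < 0.5) != (eaf_y < 0.5)
        else:
            if (oea, ooa) == (ea, oa):
                flip = False
            elif (oea, ooa) == (oa, ea):
                flip = True
            elif (_COMPLEMENT[oea], _COMPLEMENT[ooa]) == (ea, oa):
                flip = False  # opposite strand, same orientation
            elif (_COMPLEMENT[oea], _COMPLEMENT[ooa]) == (oa, ea):
                flip = True
            else:
                dropped, reason = True, "allele_mismatch"

        if not dropped and (not np.isfinite(gamma) or not np.isfinite(beta_y)):
            dropped, reason = True, "missing"
        rows.append(
            {
                "snp_id": snp,
                "gamma": gamma,
                "se_x": se_x,
                "Gamma": -beta_y if flip else beta_y,
                "se_y": se_y,
                "dropped": dropped,
                "reason": reason,
            }
        )
    return HarmonizedInstruments(pd.DataFrame(rows))


@dataclass
class MrResult:
    method: str  # 'ivw' | 'egger'
    slope: float
    se_slope: float
    p_slope: float
    n_snps: int
    cochran_q: float
    i_squared: float
    intercept: float | None = None
    se_intercept: float | None = None
    p_intercept: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _retained_arrays(instr: HarmonizedInstruments):
    df = instr.retained()
    return (
        df["gamma"].to_numpy(dtype=float),
        df["Gamma"].to_numpy(dtype=float),
        df["se_y"].to_numpy(dtype=float),
    )


def ivw(instr: HarmonizedInstruments) -> MrResult:
    """Inverse-variance-weighted estimate: regression of Gamma on gamma
    through the origin with weights 1/se_y^2."""
    g, G, se_y = _retained_arrays(instr)
    n = len(g)
    if n < 1:
        raise ValidationError("IVW requires >= 1 retained instrument")
    if np.all(g == 0):
        raise ValidationError("all exposure effects are zero; IVW slope undefined")
    w = 1.0 / se_y**2
    denom = float(np.sum(w * g**2))
    slope = float(np.sum(w * g * G)) / denom
    q = float(np.sum(w * (G - slope * g) ** 2))
    se_fixed = 1.0 / np.sqrt(denom)
    inflation = max(1.0, q / (n - 1)) if n > 1 else 1.0
    se = se_fixed * np.sqrt(inflation)
    p = float(2.0 * stats.norm.sf(abs(slope) / se))
    i2 = max(0.0, (q - (n - 1)) / q) if n > 1 and q > 0 else 0.0
    return MrResult("ivw", slope, float(se), max(p, np.finfo(float).tiny), n, q, i2)


def egger(instr: HarmonizedInstruments) -> MrResult:
    """MR-Egger: weighted least squares of Gamma on gamma with intercept,
    after orienting every instrument so gamma >= 0."""
    g, G, se_y = _retained_arrays(instr)
    n = len(g)
    if n < 3:
        raise ValidationError(f"MR-Egger requires >= 3 instruments, got {n}")
    sign = np.where(g < 0, -1.0, 1.0)
    g, G = g * sign, G * sign
    if np.ptp(g) == 0:
        raise ValidationError("all exposure effects equal; Egger regression collinear")
    w = 1.0 / se_y**2
    sw = w.sum()
    swx = float(np.sum(w * g))
    swxx = float(np.sum(w * g**2))
    swy = float(np.sum(w * G))
    swxy = float(np.sum(w * g * G))
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    resid = G - intercept - slope * g
    q = float(np.sum(w * resid**2))
    inflation = max(1.0, q / (n - 2))
    var_slope = inflation * sw / det
    var_intercept = inflation * swxx / det
    se_slope = float(np.sqrt(var_slope))
    se_intercept = float(np.sqrt(var_intercept))
    tdist = stats.t(df=n - 2)
    p_slope = float(2.0 * tdist.sf(abs(slope) / se_slope))
    p_intercept = float(2.0 * tdist.sf(abs(intercept) / se_intercept))
    i2 = max(0.0, (q - (n - 2)) / q) if q > 0 else 0.0
    return MrResult(
        "egger",
        float(slope),
        se_slope,
        max(p_slope, np.finfo(float).tiny),
        n,
        q,
        i2,
        intercept=float(intercept),
        se_intercept=se_intercept,
        p_intercept=max(p_intercept, np.finfo(float).tiny),
    )


def mr_stratified(
    pairs: Mapping[str, tuple[GwasSummaryTable, GwasSummaryTable]],
) -> dict[str, dict]:
    """Run harmonize + IVW + Egger per stratum (e.g. all/female/male).

    A stratum failing any precondition is reported as unavailable with
    the error message; other strata are unaffected.
    """
    results: dict[str, dict] = {}
    for stratum, (exp_tab, out_tab) in pairs.items():
        entry: dict = {"available": True, "error": None, "ivw": None, "egger": None}
        try:
            instr = harmonize(exp_tab, out_tab)
            entry["n_retained"] = instr.n_retained
            entry["ivw"] = ivw(instr)
            entry["egger"] = egger(instr)
        except ValidationError as exc:
            entry["available"] = False
            entry["error"] = str(exc)
        results[stratum] = entry
    return results


def stratified_comparison(results: Mapping[str, dict]) -> pd.DataFrame:
    """Flatten stratified MR results to one row per (stratum, method)."""
    rows = []
    for stratum, entry in results.items():
        if not entry["available"]:
            rows.append({"stratum": stratum, "method": "unavailable", "error": entry["error"]})
            continue
        for method in ("ivw", "egger"):
            r: MrResult = entry[method]
            rows.append(
                {
                    "stratum": stratum,
                    "method": method,
                    "slope": r.slope,
                    "se_slope": r.se_slope,
                    "p_slope": r.p_slope,
                    "intercept": r.intercept,
                    "p_intercept": r.p_intercept,
                    "n_snps": r.n_snps,
                    "cochran_q": r.cochran_q,
                }
            )
    return pd.DataFrame(rows)
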