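"""Two-sample MR causal estimators and heterogeneity statistics.

Given J harmonized instruments with SNP-exposure effects γⱼ (SE σ_γⱼ) and
SNP-outcome effects Γⱼ (SE σ_Γⱼ), the per-SNP Wald ratio Γⱼ/γⱼ estimates the
causal effect under instrument validity.  The estimators differ in how they
pool ratios and which validity violations they tolerate:

* IVW — inverse-variance-weighted combination, algebraically the weighted
  regression of Γ on γ through the origin with weights 1/σ_Γⱼ²; assumes all
  instruments valid.  Cochran's Q and I² quantify residual heterogeneity.
* MR-Egger — the same weighted regression with a free intercept; the
  intercept estimates average directional pleiotropy, the slope remains a
  consistent causal estimate when pleiotropy is independent of instrument
  strength (InSIDE).
* Weighted median — the weight-interpolated 50th percentile of ordered Wald
  ratios; consistent when valid instruments carry >= 50% of the weight.

P-values and confidence intervals use the standard normal throughout (a
t-based option with J-2 df exists for Egger); IVW standard errors are
fixed-effect by default with an optional multiplicative random-effects
inflation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    EmptyInstrumentError,
    InsufficientInstrumentsError,
    ScaleError,
    ValidationError,
)
from .harmonize import HarmonizedInstrument

#: Scale labels carried by estimates.
LOG_ODDS = "log_odds"
LINEAR = "linear"
ODDS_RATIO = "odds_ratio"

MIN_EGGER_INSTRUMENTS = 3
MIN_MEDIAN_INSTRUMENTS = 3


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate with normal-theory CI and p-value."""

    method: str  # wald | ivw | egger_slope | egger_intercept | weighted_median
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    scale: str = LINEAR

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "n_snps": self.n_snps,
            "scale": self.scale,
        }


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q across per-instrument estimates and the derived I² percentage."""

    Q: float
    df: int
    i2: float

    @classmethod
    def from_q(cls, Q: float, df: int) -> "HeterogeneityStats":
        i2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
        return cls(Q=Q, df=df, i2=i2)


def wald_ci_p(estimate: float, se: float, alpha: float = 0.05) -> tuple[float, float, float]:
    """Normal-approximation CI bounds and two-sided p-value."""
    if not se > 0:
        raise ValidationError(f"standard error must be > 0, got {se}")
    z = stats.norm.ppf(1 - alpha / 2)
    p = 2 * stats.norm.sf(abs(estimate) / se)
    return estimate - z * se, estimate + z * se, min(p, 1.0) if p > 0 else float(np.nextafter(0, 1))


def _finish(method: str, estimate: float, se: float, n_snps: int, scale: str) -> MREstimate:
    lo, hi, p = wald_ci_p(estimate, se)
    return MREstimate(
        method=method, estimate=estimate, se=se, ci_low=lo, ci_high=hi,
        pval=p, n_snps=n_snps, scale=scale,
    )


def _arrays(instruments: Sequence[HarmonizedInstrument]):
    insts = [i for i in instruments if i.action != "dropped"]
    g = np.array([i.gamma for i in insts], dtype=float)
    sg = np.array([i.se_gamma for i in insts], dtype=float)
    G = np.array([i.Gamma for i in insts], dtype=float)
    sG = np.array([i.se_Gamma for i in insts], dtype=float)
    return insts, g, sg, G, sG


def wald_ratio(inst: HarmonizedInstrument, scale: str = LINEAR) -> MREstimate:
    """Single-instrument ratio estimate Γ/γ with first-order delta SE σ_Γ/|γ|.

    Exposure-side uncertainty is ignored at first order (standard practice;
    it enters the weighted-median bootstrap instead).
    """
    if inst.gamma == 0:
        raise ValidationError(f"{inst.snp_id}: SNP-exposure effect is zero, ratio undefined")
    est = inst.Gamma / inst.gamma
    se = inst.se_Gamma / abs(inst.gamma)
    return _finish("wald", est, se, 1, scale)


def ivw_estimate(
    instruments: Sequence[HarmonizedInstrument],
    scale: str = LINEAR,
    random_effects: bool = False,
) -> tuple[MREstimate, HeterogeneityStats]:
    """Fixed-effect IVW estimate with Cochran's Q / I² heterogeneity.

    β̂ = Σ γⱼΓⱼ/σ_Γⱼ² / Σ γⱼ²/σ_Γⱼ², SE = (Σ γⱼ²/σ_Γⱼ²)^(-1/2);
    Q = Σ (Γⱼ - β̂γⱼ)²/σ_Γⱼ² on J-1 df.  With ``random_effects`` the SE is
    inflated by √(Q/df) when Q > df (multiplicative overdispersion model).
    A single instrument reduces to the Wald ratio with Q = 0.
    """
    insts, g, _, G, sG = _arrays(instruments)
    if len(insts) == 0:
        raise EmptyInstrumentError("IVW requires at least one non-dropped instrument")
    if np.any(g == 0):
        bad = [i.snp_id for i, gj in zip(insts, g) if gj == 0]
        raise ValidationError(f"zero SNP-exposure effect for {bad}, Wald ratios undefined")
    w = 1.0 / sG**2
    denom = float(np.sum(w * g**2))
    est = float(np.sum(w * g * G)) / denom
    se = 1.0 / np.sqrt(denom)
    df = len(insts) - 1
    # A single instrument has no heterogeneity; avoid a spurious fp residual.
    Q = float(np.sum(w * (G - est * g) ** 2)) if df > 0 else 0.0
    het = HeterogeneityStats.from_q(Q, df)
    if random_effects and df > 0 and Q > df:
        se *= np.sqrt(Q / df)
    return _finish("ivw", est, float(se), len(insts), scale), het


def egger_estimate(
    instruments: Sequence[HarmonizedInstrument],
    scale: str = LINEAR,
    dispersion: bool = False,
    t_dist: bool = False,
) -> tuple[MREstimate, MREstimate]:
    """MR-Egger weighted regression of Γ on γ with a free intercept.

    Instruments must be oriented so all γ >= 0 (see
    :func:`~tsmr.harmonize.orient_for_egger`).  Weighted least squares with
    weights 1/σ_Γⱼ², solved from the normal equations.  Returns (slope,
    intercept); the intercept estimates mean directional pleiotropy.  With
    ``dispersion`` the SEs are inflated by √(max(1, Q_e/(J-2))); with
    ``t_dist`` CIs and p-values use Student's t on J-2 df instead of the
    normal.
    """
    insts, g, _, G, sG = _arrays(instruments)
    if len(insts) < MIN_EGGER_INSTRUMENTS:
        raise InsufficientInstrumentsError(
            f"MR-Egger needs >= {MIN_EGGER_INSTRUMENTS} instruments, got {len(insts)}"
        )
    if np.any(g < 0):
        raise ValidationError("MR-Egger requires orientation with all gamma >= 0")
    w = 1.0 / sG**2
    # Weighted normal equations for Γ = α + βγ.
    sw, swx, swy = np.sum(w), np.sum(w * g), np.sum(w * G)
    swxx, swxy = np.sum(w * g**2), np.sum(w * g * G)
    det = sw * swxx - swx**2
    if det <= 0:
        raise ValidationError("degenerate design: all gamma identical")
    slope = float((sw * swxy - swx * swy) / det)
    intercept = float((swxx * swy - swx * swxy) / det)
    var_slope = sw / det
    var_intercept = swxx / det
    if dispersion:
        resid = G - intercept - slope * g
        q_e = float(np.sum(w * resid**2))
        phi = max(1.0, q_e / (len(insts) - 2))
        var_slope *= phi
        var_intercept *= phi
    se_slope = float(np.sqrt(var_slope))
    se_intercept = float(np.sqrt(var_intercept))

    def finish(method: str, est: float, se: float) -> MREstimate:
        if t_dist:
            df = len(insts) - 2
            tq = stats.t.ppf(0.975, df)
            p = 2 * stats.t.sf(abs(est) / se, df)
            return MREstimate(method, est, se, est - tq * se, est + tq * se,
                              min(p, 1.0), len(insts), scale)
        return _finish(method, est, se, len(insts), scale)

    return finish("egger_slope", slope, se_slope), finish("egger_intercept", intercept, se_intercept)


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weight-interpolated 50th percentile of the ratios.

    With ratios sorted ascending and Sⱼ the running weight sum, each ratio
    sits at percentile pⱼ = 100 (Sⱼ - wⱼ/2)/S; the estimate linearly
    interpolates the ordered ratios against pⱼ at p = 50.
    """
    order = np.argsort(ratios, kind="stable")
    r = np.asarray(ratios, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    s = np.cumsum(w)
    p = 100.0 * (s - w / 2.0) / s[-1]
    return float(np.interp(50.0, p, r))


def weighted_median_estimate(
    instruments: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int | None = None,
    scale: str = LINEAR,
) -> MREstimate:
    """Weighted-median causal estimate with a parametric-bootstrap SE.

    Ratios βⱼ = Γⱼ/γⱼ are weighted by the inverse Wald-ratio variance
    wⱼ = γⱼ²/σ_Γⱼ².  The SE resamples Γⱼ ~ N(Γⱼ, σ_Γⱼ²) and γⱼ ~ N(γⱼ, σ_γⱼ²)
    and takes the standard deviation of the recomputed weighted medians over
    ``n_boot`` replicates; the seed is mandatory in the pipeline so runs are
    reproducible.
    """
    insts, g, sg, G, sG = _arrays(instruments)
    if len(insts) < MIN_MEDIAN_INSTRUMENTS:
        raise InsufficientInstrumentsError(
            f"weighted median needs >= {MIN_MEDIAN_INSTRUMENTS} instruments, got {len(insts)}"
        )
    if np.any(g == 0):
        raise ValidationError("zero SNP-exposure effect, Wald ratios undefined")
    if n_boot < 2:
        raise ValidationError("n_boot must be >= 2 to estimate a bootstrap SE")
    est = weighted_median_point(G / g, g**2 / sG**2)
    rng = np.random.default_rng(seed)
    J = len(insts)
    boots = np.empty(n_boot)
    g_rep = rng.normal(g, sg, size=(n_boot, J))
    G_rep = rng.normal(G, sG, size=(n_boot, J))
    for b in range(n_boot):
        gb = g_rep[b]
        gb = np.where(gb == 0, np.finfo(float).tiny, gb)
        boots[b] = weighted_median_point(G_rep[b] / gb, gb**2 / sG**2)
    se = float(np.std(boots, ddof=1))
    if se == 0:
        se = float(np.finfo(float).tiny)  # degenerate: all ratios identical and noise-free
    return _finish("weighted_median", est, se, J, scale)


def to_odds_ratio(est: MREstimate) -> MREstimate:
    """Exponentiate a log-odds estimate (and its CI) onto the odds-ratio scale.

    The SE and p-value remain on the log scale, as conventionally reported.
    """
    if est.scale != LOG_ODDS:
        raise ScaleError(
            f"cannot exponentiate an estimate on scale {est.scale!r}; expected {LOG_ODDS!r}"
        )
    return replace(
        est,
        estimate=float(np.exp(est.estimate)),
        ci_low=float(np.exp(est.ci_low)),
        ci_high=float(np.exp(est.ci_high)),
        scale=ODDS_RATIO,
    )
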