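"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generative model for instrument j is

    Γⱼ = θ·γⱼ + αⱼ + εⱼ,    εⱼ ~ N(0, σ_Γⱼ²)

with true SNP-exposure effects γⱼ, causal effect θ, and horizontal
pleiotropy αⱼ assigned to a configurable fraction of "invalid" instruments
(directional when μ_α ≠ 0, balanced when μ_α = 0 and σ_α > 0, and
correlated with γⱼ when the InSIDE assumption is deliberately violated).
Observed exposure effects carry their own sampling noise.  Allele metadata
— including palindromic variants and strand/label corruptions of the
outcome copy — exercises the harmonization stage.

Defaults mirror the operating point of a consortium-scale analysis of an
externalizing phenotype on smoking initiation: 14 instruments jointly
explaining ~2% of exposure variance (per-SNP γ ≈ 0.06 in trait-SD units
with exposure GWAS n ≈ 55k), and a binary outcome GWAS of n ≈ 74k with a
28% case fraction, which sets σ_Γ ≈ 0.013 on the log-odds scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .harmonize import complement_allele
from .summary_io import SummaryDataset, SummaryRecord

_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]

# Floors keeping records valid in the noise-free limit (se scale = 0);
# the SE floor must survive squaring in inverse-variance weights.
_SE_FLOOR = 1e-12
_P_FLOOR = 1e-300


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic exposure/outcome pair."""

    n_snps: int = 14
    theta: float = 0.0
    gamma_mean: float = 0.06
    gamma_sd: float = 0.015
    se_gamma: float = 0.0066
    se_Gamma: float = 0.0126
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    frac_invalid: float = 0.0
    inside_violation: bool = False
    inside_slope: float = 0.5
    outcome_type: str = "binary"
    eaf_low: float = 0.05
    eaf_high: float = 0.95
    frac_palindromic: float = 0.0
    frac_strand_flipped: float = 0.0
    frac_allele_swapped: float = 0.0
    n_exposure: int = 55354
    n_outcome: int = 74053
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValidationError("need at least one instrument")
        for name in ("frac_invalid", "frac_palindromic", "frac_strand_flipped",
                     "frac_allele_swapped"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} = {v} outside [0, 1]")
        if self.se_gamma < 0 or self.se_Gamma < 0 or self.pleio_sd < 0:
            raise ValidationError("noise scales must be >= 0")
        if not (0 < self.eaf_low < self.eaf_high < 1):
            raise ValidationError("EAF range must satisfy 0 < low < high < 1")
        if self.outcome_type not in ("binary", "continuous"):
            raise ValidationError("outcome_type must be binary|continuous")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth behind one simulated pair, for estimator validation."""

    theta: float
    gamma: tuple[float, ...]
    alpha: tuple[float, ...]
    valid: tuple[bool, ...]
    seed: int

    def to_dict(self) -> dict:
        return {
            "theta": self.theta,
            "gamma": list(self.gamma),
            "alpha": list(self.alpha),
            "valid": list(self.valid),
            "seed": self.seed,
        }


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2 * stats.norm.sf(np.abs(beta) / np.maximum(se, _SE_FLOOR))
    return np.clip(p, _P_FLOOR, 1.0)


def _records(
    ids: Sequence[str],
    eas: Sequence[str],
    oas: Sequence[str],
    eaf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    n: int,
) -> list[SummaryRecord]:
    pv = _pvals(beta, se)
    se = np.maximum(se, _SE_FLOOR)
    return [
        SummaryRecord(
            snp_id=ids[j], effect_allele=eas[j], other_allele=oas[j],
            eaf=float(eaf[j]), beta=float(beta[j]), se=float(se[j]),
            pval=float(pv[j]), n=n,
        )
        for j in range(len(ids))
    ]


def simulate_pair(
    config: SimulationConfig,
) -> tuple[SummaryDataset, SummaryDataset, TruthRecord]:
    """Draw one exposure/outcome summary-statistic pair from the generative model.

    Identical configs (including seed) give bit-identical datasets.  The
    outcome copy's allele metadata is corrupted per the config's corruption
    fractions via :func:`corrupt_alleles`.
    """
    rng = np.random.default_rng(config.seed)
    J = config.n_snps

    gamma = rng.normal(config.gamma_mean, config.gamma_sd, J)
    gamma = np.where(gamma == 0, np.finfo(float).tiny, gamma)  # all-nonzero contract
    eaf = rng.uniform(config.eaf_low, config.eaf_high, J)

    pal = rng.random(J) < config.frac_palindromic
    pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), J)
    nonpal_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), J)
    eas, oas = [], []
    for j in range(J):
        ea, oa = (
            _PALINDROMIC_PAIRS[pal_idx[j]] if pal[j] else _NONPALINDROMIC_PAIRS[nonpal_idx[j]]
        )
        eas.append(ea)
        oas.append(oa)

    se_g = np.broadcast_to(np.asarray(config.se_gamma, dtype=float), (J,)).copy()
    se_G = np.broadcast_to(np.asarray(config.se_Gamma, dtype=float), (J,)).copy()

    beta_exp = gamma + rng.normal(0.0, 1.0, J) * se_g

    invalid = rng.random(J) < config.frac_invalid
    alpha = np.zeros(J)
    if invalid.any():
        direct = config.pleio_mean + config.pleio_sd * rng.normal(0.0, 1.0, int(invalid.sum()))
        if config.inside_violation:
            direct = direct + config.inside_slope * gamma[invalid]
        alpha[invalid] = direct

    beta_out = config.theta * gamma + alpha + rng.normal(0.0, 1.0, J) * se_G

    ids = [f"rs{j + 1}" for j in range(J)]
    exposure = SummaryDataset(
        records=_records(ids, eas, oas, eaf, beta_exp, se_g, config.n_exposure),
        trait_name="exposure",
        trait_type="continuous",
        sample_size=config.n_exposure,
    )
    outcome = SummaryDataset(
        records=_records(ids, eas, oas, eaf, beta_out, se_G, config.n_outcome),
        trait_name="outcome",
        trait_type=config.outcome_type,
        sample_size=config.n_outcome,
    )
    outcome, _ = corrupt_alleles(outcome, config)
    truth = TruthRecord(
        theta=config.theta,
        gamma=tuple(float(x) for x in gamma),
        alpha=tuple(float(x) for x in alpha),
        valid=tuple(bool(v) for v in ~invalid),
        seed=config.seed,
    )
    return exposure, outcome, truth


def corrupt_alleles(
    dataset: SummaryDataset, config: SimulationConfig
) -> tuple[SummaryDataset, list[tuple[str, str]]]:
    """Re-express a fraction of records under a swapped or strand-flipped reading.

    Both corruptions preserve the physical association: a label swap
    exchanges the alleles, negates beta and complements the frequency; a
    strand flip replaces both alleles by their complements (beta and the
    frequency, which follow the physical allele, are unchanged).  A correct
    harmonization pass therefore inverts every corruption except palindromic
    variants with ambiguous frequencies.  Returns the corrupted dataset and
    a ledger of (snp_id, corruption) pairs.
    """
    rng = np.random.default_rng(np.uint32(config.seed) ^ np.uint32(0x9E3779B9))
    u = rng.random(len(dataset))
    records: list[SummaryRecord] = []
    ledger: list[tuple[str, str]] = []
    for j, rec in enumerate(dataset):
        if u[j] < config.frac_allele_swapped:
            records.append(
                replace(
                    rec,
                    effect_allele=rec.other_allele,
                    other_allele=rec.effect_allele,
                    beta=-rec.beta,
                    eaf=1 - rec.eaf if rec.eaf is not None else None,
                )
            )
            ledger.append((rec.snp_id, "allele_swapped"))
        elif u[j] < config.frac_allele_swapped + config.frac_strand_flipped:
            records.append(
                replace(
                    rec,
                    effect_allele=complement_allele(rec.effect_allele),
                    other_allele=complement_allele(rec.other_allele),
                )
            )
            ledger.append((rec.snp_id, "strand_flipped"))
        else:
            records.append(rec)
    return (
        SummaryDataset(
            records=records,
            trait_name=dataset.trait_name,
            trait_type=dataset.trait_type,
            sample_size=dataset.sample_size,
        ),
        ledger,
    )
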