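"""Allele harmonization between exposure and outcome summary statistics.

Two-sample MR combines a SNP-exposure effect (γ) and a SNP-outcome effect
(Γ) per instrument; both must refer to the same effect allele.  The exposure
dataset is the reference frame (instruments are defined by the exposure
GWAS and are never modified); the outcome effect is re-oriented to the
exposure's effect allele, resolving allele swaps, strand flips, and
palindromic (A/T, C/G) variants whose strand is only identifiable through
allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .summary_io import SummaryRecord, SummaryDataset

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement_allele(allele: str) -> str:
    """Watson-Crick complement of a single base."""
    try:
        return _COMPLEMENT[allele]
    except KeyError:
        raise ValidationError(f"invalid allele {allele!r}") from None


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for A/T and C/G pairs, whose strand cannot be told from alleles alone."""
    return complement_allele(effect_allele) == other_allele


@dataclass(frozen=True)
class HarmonizationPolicy:
    """Tunable harmonization behavior.

    ``palindromic_eaf_window`` is the half-width of the ambiguous zone around
    EAF = 0.5: a palindromic SNP whose frequency falls inside
    (0.5 - w, 0.5 + w) on either side cannot be oriented reliably.  With
    ``drop_ambiguous`` (default) such SNPs are excluded; otherwise they are
    aligned by allele labels as if both datasets reported the same strand.
    """

    palindromic_eaf_window: float = 0.08
    drop_ambiguous: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.palindromic_eaf_window < 0.5):
            raise ValidationError("palindromic EAF window must be in [0, 0.5)")


@dataclass(frozen=True)
class HarmonizedInstrument:
    """One instrument's aligned (γ, Γ) pair, ready for estimation.

    ``action`` records how the outcome effect was brought onto the exposure's
    effect allele; ``dropped`` instruments carry a ``reason`` and must be
    excluded from estimation.
    """

    snp_id: str
    gamma: float
    se_gamma: float
    Gamma: float
    se_Gamma: float
    palindromic: bool = False
    action: str = "aligned"  # aligned|sign_flipped|strand_flipped|freq_resolved|dropped
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.action != "dropped":
            if not self.se_gamma > 0:
                raise ValidationError(f"{self.snp_id}: se_gamma must be > 0")
            if not self.se_Gamma > 0:
                raise ValidationError(f"{self.snp_id}: se_Gamma must be > 0")


def _ambiguous(eaf: float | None, window: float) -> bool:
    return eaf is None or abs(eaf - 0.5) <= window


def harmonize_pair(
    exposure_rec: SummaryRecord,
    outcome_rec: SummaryRecord,
    policy: HarmonizationPolicy = HarmonizationPolicy(),
) -> HarmonizedInstrument:
    """Align one outcome record to the exposure record's effect allele.

    Non-palindromic variants are resolved from allele labels alone: an
    identical pair is already aligned, a swapped pair flips the sign of Γ,
    and a complementary-strand pair is strand-flipped then re-compared.
    Palindromic variants are label-uninformative, so orientation comes from
    comparing the effect-allele frequency on both sides; when either
    frequency is missing or too close to 0.5 the SNP is dropped under the
    default policy.  Irreconcilable allele sets drop with reason
    ``allele_mismatch``.
    """
    exp_ea, exp_oa = exposure_rec.effect_allele, exposure_rec.other_allele
    out_ea, out_oa = outcome_rec.effect_allele, outcome_rec.other_allele
    pal = is_palindromic(exp_ea, exp_oa)

    def build(action: str, flip: bool, reason: str | None = None) -> HarmonizedInstrument:
        return HarmonizedInstrument(
            snp_id=exposure_rec.snp_id,
            gamma=exposure_rec.beta,
            se_gamma=exposure_rec.se,
            Gamma=-outcome_rec.beta if flip else outcome_rec.beta,
            se_Gamma=outcome_rec.se,
            palindromic=pal,
            action=action,
            reason=reason,
        )

    def dropped(reason: str) -> HarmonizedInstrument:
        return HarmonizedInstrument(
            snp_id=exposure_rec.snp_id,
            gamma=exposure_rec.beta,
            se_gamma=exposure_rec.se,
            Gamma=outcome_rec.beta,
            se_Gamma=outcome_rec.se,
            palindromic=pal,
            action="dropped",
            reason=reason,
        )

    same = (out_ea, out_oa) == (exp_ea, exp_oa)
    swapped = (out_ea, out_oa) == (exp_oa, exp_ea)
    comp_same = (complement_allele(out_ea), complement_allele(out_oa)) == (exp_ea, exp_oa)
    comp_swapped = (complement_allele(out_ea), complement_allele(out_oa)) == (exp_oa, exp_ea)

    if pal:
        # For A/T and C/G pairs "same" and "comp_swapped" (and "swapped" and
        # "comp_same") are indistinguishable strand readings; only EAF decides.
        if not (same or swapped):
            return dropped("allele_mismatch")
        w = policy.palindromic_eaf_window
        if _ambiguous(exposure_rec.eaf, w) or _ambiguous(outcome_rec.eaf, w):
            if policy.drop_ambiguous:
                return dropped("ambiguous_palindromic")
            # Fall back to label alignment, assuming a shared strand.
            return build("sign_flipped" if swapped else "aligned", flip=swapped)
        # Labels are strand-uninformative for palindromes: the reported
        # frequencies identify the shared physical allele directly.  Both on
        # the same side of 0.5 means the two datasets measured the same
        # allele; opposite sides mean opposite alleles.
        flip = (exposure_rec.eaf < 0.5) != (outcome_rec.eaf < 0.5)
        return build("freq_resolved", flip=flip)

    if same:
        return build("aligned", flip=False)
    if swapped:
        return build("sign_flipped", flip=True)
    if comp_same:
        return build("strand_flipped", flip=False)
    if comp_swapped:
        return build("strand_flipped", flip=True)
    return dropped("allele_mismatch")


def harmonize_datasets(
    instruments: SummaryDataset,
    outcome: SummaryDataset,
    policy: HarmonizationPolicy = HarmonizationPolicy(),
) -> list[HarmonizedInstrument]:
    """Harmonize every instrument found in the outcome dataset.

    Instruments absent from the outcome dataset (no proxy substituted) are
    returned as dropped with reason ``missing_in_outcome``.  Dropped entries
    are kept in the result so reports can account for every instrument;
    filter on ``action != "dropped"`` before estimation.
    """
    out_by_id = {r.snp_id: r for r in outcome}
    result: list[HarmonizedInstrument] = []
    for rec in instruments:
        out = out_by_id.get(rec.snp_id)
        if out is None:
            result.append(
                HarmonizedInstrument(
                    snp_id=rec.snp_id,
                    gamma=rec.beta,
                    se_gamma=rec.se,
                    Gamma=0.0,
                    se_Gamma=1.0,
                    palindromic=is_palindromic(rec.effect_allele, rec.other_allele),
                    action="dropped",
                    reason="missing_in_outcome",
                )
            )
            continue
        result.append(harmonize_pair(rec, out, policy))
    return result


def orient_for_egger(
    instruments: Iterable[HarmonizedInstrument],
) -> list[HarmonizedInstrument]:
    """Negate (γ, Γ) jointly so every γ >= 0; Wald ratios are unchanged.

    MR-Egger regression is not invariant to the arbitrary choice of effect
    allele: the conventional orientation codes each SNP so its exposure
    effect is positive before fitting the intercept.
    """
    oriented = []
    for inst in instruments:
        if inst.gamma < 0:
            oriented.append(replace(inst, gamma=-inst.gamma, Gamma=-inst.Gamma))
        else:
            oriented.append(inst)
    if not oriented:
        raise ValidationError("cannot orient an empty instrument collection")
    return oriented


def harmonization_report(instruments: Sequence[HarmonizedInstrument]) -> pd.DataFrame:
    """Tabular report (snp_id, action, reason) of a harmonization pass."""
    return pd.DataFrame(
        {
            "snp_id": [i.snp_id for i in instruments],
            "action": [i.action for i in instruments],
            "reason": [i.reason if i.reason is not None else "" for i in instruments],
        }
    )
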