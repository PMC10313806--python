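"""Allele harmonization between exposure and outcome summary statistics.

Two GWAS may report the same variant with the effect allele on either side
and on either strand. Harmonization re-expresses every outcome association
on the exposure's effect allele: swapped alleles negate the outcome beta and
complement its frequency; reverse-complement alleles are a strand flip and
leave the numbers alone.

Palindromic variants (A/T or C/G) are their own reverse complement, so
allele labels cannot reveal the strand. They are resolved by allele
frequency agreement between the two datasets, and dropped outright when the
minor-allele frequency exceeds the ambiguity band (default 0.40, i.e. EAF in
(0.40, 0.60)) in either dataset or when a frequency is missing — frequency
then carries no strand information.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .summary_io import SummaryStats, VariantAssociation

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_PAIRS = (frozenset({"A", "T"}), frozenset({"C", "G"}))

#: action labels that exclude an instrument from estimation
DROPPED_ACTIONS = frozenset({"dropped_palindromic", "dropped_incompatible", "dropped_missing"})

ALIGNED = "aligned"
SIGN_FLIPPED = "sign_flipped"
STRAND_FLIPPED = "strand_flipped"
STRAND_AND_SIGN_FLIPPED = "strand_and_sign_flipped"
DROPPED_INCOMPATIBLE = "dropped_incompatible"


@dataclass(frozen=True)
class HarmonizedInstrument:
    """One variant carrying aligned exposure (gamma) and outcome (alpha) effects."""

    variant_id: str
    gamma: float
    se_gamma: float
    alpha: float
    se_alpha: float
    action: str
    eaf_exposure: Optional[float] = None
    eaf_outcome: Optional[float] = None

    @property
    def retained(self) -> bool:
        return self.action not in DROPPED_ACTIONS


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is {A,T} or {C,G} (single nucleotides only)."""
    if len(effect_allele) != 1 or len(other_allele) != 1:
        logger.debug("indel alleles (%s/%s) are not palindromizable", effect_allele, other_allele)
        return False
    return frozenset({effect_allele, other_allele}) in _PALINDROMIC_PAIRS


def _revcomp_allele(allele: str) -> Optional[str]:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(allele))
    except KeyError:
        return None


def align_alleles(exp: VariantAssociation, out: VariantAssociation) -> str:
    """Classify how the outcome record's alleles relate to the exposure's.

    Returns one of ``aligned``, ``sign_flipped``, ``strand_flipped``,
    ``strand_and_sign_flipped`` or ``dropped_incompatible``. For palindromic
    pairs ``aligned``/``strand_and_sign_flipped`` (and ``sign_flipped``/
    ``strand_flipped``) coincide on allele labels; this returns the
    no-strand-flip reading — :func:`harmonize` disambiguates by frequency.
    """
    if exp.variant_id != out.variant_id:
        raise ValueError(
            f"variant_id mismatch: {exp.variant_id!r} vs {out.variant_id!r}"
        )
    e = (exp.effect_allele, exp.other_allele)
    o = (out.effect_allele, out.other_allele)
    if o == e:
        return ALIGNED
    if o == (e[1], e[0]):
        return SIGN_FLIPPED
    rc = (_revcomp_allele(e[0]), _revcomp_allele(e[1]))
    if None not in rc:
        if o == rc:
            return STRAND_FLIPPED
        if o == (rc[1], rc[0]):
            return STRAND_AND_SIGN_FLIPPED
    return DROPPED_INCOMPATIBLE


@dataclass
class HarmonizationReport:
    """Counts of every harmonization action; retained + dropped = instruments in."""

    actions: Counter

    @property
    def n_total(self) -> int:
        return sum(self.actions.values())

    @property
    def n_retained(self) -> int:
        return sum(c for a, c in self.actions.items() if a not in DROPPED_ACTIONS)

    @property
    def n_dropped(self) -> int:
        return self.n_total - self.n_retained


def _minor_freq(eaf: float) -> float:
    return min(eaf, 1.0 - eaf)


def _freq_usable(eaf: Optional[float]) -> bool:
    return eaf is not None and not math.isnan(eaf)


def _dropped(exp: VariantAssociation, out: Optional[VariantAssociation], action: str) -> HarmonizedInstrument:
    return HarmonizedInstrument(
        variant_id=exp.variant_id,
        gamma=exp.beta,
        se_gamma=exp.se,
        alpha=float("nan") if out is None else out.beta,
        se_alpha=float("nan") if out is None else out.se,
        action=action,
        eaf_exposure=exp.eaf,
        eaf_outcome=None if out is None else out.eaf,
    )


def _harmonize_one(
    exp: VariantAssociation, out: VariantAssociation, band: float
) -> HarmonizedInstrument:
    palindromic = is_palindromic(exp.effect_allele, exp.other_allele)
    if palindromic:
        if frozenset({out.effect_allele, out.other_allele}) != frozenset(
            {exp.effect_allele, exp.other_allele}
        ):
            return _dropped(exp, out, DROPPED_INCOMPATIBLE)
        # frequency is the only strand signal; without it (or inside the
        # ambiguity band) the variant is unusable
        if not (_freq_usable(exp.eaf) and _freq_usable(out.eaf)):
            return _dropped(exp, out, "dropped_palindromic")
        if _minor_freq(exp.eaf) > band or _minor_freq(out.eaf) > band:
            return _dropped(exp, out, "dropped_palindromic")
        swapped = (out.effect_allele, out.other_allele) != (exp.effect_allele, exp.other_allele)
        alpha = -out.beta if swapped else out.beta
        eaf_out = 1.0 - out.eaf if swapped else out.eaf
        if (exp.eaf < 0.5) == (eaf_out < 0.5):
            action = SIGN_FLIPPED if swapped else ALIGNED
        else:
            # frequencies disagree: the outcome was reported on the other
            # strand, which for a palindrome is an additional allele swap
            alpha = -alpha
            eaf_out = 1.0 - eaf_out
            action = STRAND_FLIPPED if swapped else STRAND_AND_SIGN_FLIPPED
        return HarmonizedInstrument(
            variant_id=exp.variant_id,
            gamma=exp.beta,
            se_gamma=exp.se,
            alpha=alpha,
            se_alpha=out.se,
            action=action,
            eaf_exposure=exp.eaf,
            eaf_outcome=eaf_out,
        )

    action = align_alleles(exp, out)
    if action == DROPPED_INCOMPATIBLE:
        return _dropped(exp, out, DROPPED_INCOMPATIBLE)
    sign_flip = action in (SIGN_FLIPPED, STRAND_AND_SIGN_FLIPPED)
    alpha = -out.beta if sign_flip else out.beta
    eaf_out = out.eaf
    if eaf_out is not None and sign_flip:
        eaf_out = 1.0 - eaf_out
    return HarmonizedInstrument(
        variant_id=exp.variant_id,
        gamma=exp.beta,
        se_gamma=exp.se,
        alpha=alpha,
        se_alpha=out.se,
        action=action,
        eaf_exposure=exp.eaf,
        eaf_outcome=eaf_out,
    )


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    palindromic_eaf_band: float = 0.40,
) -> tuple[list[HarmonizedInstrument], HarmonizationReport]:
    """Align every exposure instrument with its outcome record.

    Matching is by variant_id only (no chr:pos fallback — silently matching
    across genome builds is worse than dropping). Returns one
    :class:`HarmonizedInstrument` per exposure instrument, dropped ones
    included with their drop reason, plus a report counting every action.
    """
    instruments: list[HarmonizedInstrument] = []
    for exp in exposure:
        out = outcome.get(exp.variant_id)
        if out is None:
            instruments.append(_dropped(exp, None, "dropped_missing"))
        else:
            instruments.append(_harmonize_one(exp, out, palindromic_eaf_band))
    report = HarmonizationReport(actions=Counter(i.action for i in instruments))
    return instruments, report


def retained_instruments(instruments: list[HarmonizedInstrument]) -> list[HarmonizedInstrument]:
    return [i for i in instruments if i.retained]


def instruments_to_frame(instruments: list[HarmonizedInstrument]) -> pd.DataFrame:
    """Export as the canonical harmonized-instrument table."""
    return pd.DataFrame(
        [
            {
                "variant_id": i.variant_id,
                "gamma": i.gamma,
                "se_gamma": i.se_gamma,
                "alpha": i.alpha,
                "se_alpha": i.se_alpha,
                "eaf_exposure": i.eaf_exposure,
                "eaf_outcome": i.eaf_outcome,
                "action": i.action,
            }
            for i in instruments
        ]
    )


__all__ = [
    "DROPPED_ACTIONS",
    "HarmonizationReport",
    "HarmonizedInstrument",
    "align_alleles",
    "harmonize",
    "instruments_to_frame",
    "is_palindromic",
    "retained_instruments",
]
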