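"""Allele harmonization between exposure and outcome summary statistics.

Every estimator consumes per-variant pairs (beta_x, se_x, beta_y, se_y) that
must refer to the same effect allele.  Outcome records can disagree with the
exposure orientation in three reconcilable ways:

* allele swap — the outcome's effect allele is the exposure's other allele:
  negate beta_y, complement eaf_y;
* strand flip — the outcome reports the opposite strand (A<->T, C<->G):
  relabel only;
* both — relabel, negate, complement.

Palindromic variants (A/T or C/G) are strand-ambiguous: labels cannot
distinguish a swap from a flip.  The default policy drops them; the optional
``infer-by-eaf`` policy aligns on allele frequency when both studies place
the frequency on the same side of 0.5 by more than a tolerance (default
0.08), and drops otherwise.  No operation ever alters a standard error.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

from .instruments import InstrumentSet
from .sumstats_io import EmptyInputError, SummaryStatRecord, SummaryStatTable

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_PAIRS = (frozenset("AT"), frozenset("CG"))

POLICIES = ("drop", "infer-by-eaf")
DEFAULT_EAF_TOLERANCE = 0.08

ACTIONS = (
    "none",
    "swap_sign",
    "strand_flip",
    "strand_flip_and_swap",
    "dropped_palindromic",
)


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure and outcome effects expressed on the same effect allele."""

    variant_id: str
    effect_allele: str
    other_allele: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    eaf_x: float | None
    eaf_y: float | None
    action_taken: str

    def __post_init__(self) -> None:
        if self.se_x <= 0 or self.se_y <= 0:
            raise ValueError("standard errors must be positive")


@dataclass(frozen=True)
class DroppedVariant:
    """Marker for an instrument that could not be harmonized."""

    variant_id: str
    action: str
    reason: str


def _is_palindromic(a: str, b: str) -> bool:
    return frozenset((a, b)) in PALINDROMIC_PAIRS


def _complement_eaf(eaf: float | None) -> float | None:
    return None if eaf is None else 1.0 - eaf


def _harmonize_palindromic(
    exposure_rec: SummaryStatRecord,
    outcome_rec: SummaryStatRecord,
    policy: str,
    eaf_tolerance: float,
):
    ea, oa = exposure_rec.effect_allele, exposure_rec.other_allele
    out_pair = (outcome_rec.effect_allele, outcome_rec.other_allele)
    if set(out_pair) != {ea, oa}:
        return DroppedVariant(
            exposure_rec.variant_id, "dropped_palindromic", "alleles irreconcilable"
        )
    if policy == "drop":
        return DroppedVariant(
            exposure_rec.variant_id, "dropped_palindromic", "palindromic (drop policy)"
        )
    # Label-aligned tentative orientation; the strand part must come from eaf.
    if out_pair == (ea, oa):
        beta_y, eaf_y, swapped = outcome_rec.beta, outcome_rec.eaf, False
    else:
        beta_y, eaf_y, swapped = -outcome_rec.beta, _complement_eaf(outcome_rec.eaf), True
    if exposure_rec.eaf is None or eaf_y is None:
        return DroppedVariant(
            exposure_rec.variant_id, "dropped_palindromic", "palindromic, eaf missing"
        )
    dx, dy = exposure_rec.eaf - 0.5, eaf_y - 0.5
    if abs(dx) <= eaf_tolerance or abs(dy) <= eaf_tolerance:
        return DroppedVariant(
            exposure_rec.variant_id,
            "dropped_palindromic",
            f"palindromic, eaf within {eaf_tolerance} of 0.5",
        )
    if dx * dy > 0:
        action = "swap_sign" if swapped else "none"
    else:
        beta_y, eaf_y = -beta_y, 1.0 - eaf_y
        action = "strand_flip_and_swap" if swapped else "strand_flip"
    return HarmonizedInstrument(
        variant_id=exposure_rec.variant_id,
        effect_allele=ea,
        other_allele=oa,
        beta_x=exposure_rec.beta,
        se_x=exposure_rec.se,
        beta_y=beta_y,
        se_y=outcome_rec.se,
        eaf_x=exposure_rec.eaf,
        eaf_y=eaf_y,
        action_taken=action,
    )


def harmonize_pair(
    exposure_rec: SummaryStatRecord,
    outcome_rec: SummaryStatRecord,
    palindromic_policy: str = "drop",
    eaf_tolerance: float = DEFAULT_EAF_TOLERANCE,
) -> HarmonizedInstrument | DroppedVariant:
    """Express one outcome record on the exposure record's effect allele."""
    if exposure_rec.variant_id != outcome_rec.variant_id:
        raise ValueError(
            f"variant_id mismatch: {exposure_rec.variant_id!r} vs {outcome_rec.variant_id!r}"
        )
    if palindromic_policy not in POLICIES:
        raise ValueError(f"unknown palindromic policy {palindromic_policy!r}")

    ea, oa = exposure_rec.effect_allele, exposure_rec.other_allele
    if _is_palindromic(ea, oa):
        # Swap and strand-flip interpretations coincide here; the
        # strand-ambiguity branch governs.
        return _harmonize_palindromic(
            exposure_rec, outcome_rec, palindromic_policy, eaf_tolerance
        )

    out_pair = (outcome_rec.effect_allele, outcome_rec.other_allele)
    if out_pair == (ea, oa):
        beta_y, eaf_y, action = outcome_rec.beta, outcome_rec.eaf, "none"
    elif out_pair == (oa, ea):
        beta_y, eaf_y, action = (
            -outcome_rec.beta,
            _complement_eaf(outcome_rec.eaf),
            "swap_sign",
        )
    elif out_pair == (COMPLEMENT[ea], COMPLEMENT[oa]):
        beta_y, eaf_y, action = outcome_rec.beta, outcome_rec.eaf, "strand_flip"
    elif out_pair == (COMPLEMENT[oa], COMPLEMENT[ea]):
        beta_y, eaf_y, action = (
            -outcome_rec.beta,
            _complement_eaf(outcome_rec.eaf),
            "strand_flip_and_swap",
        )
    else:
        return DroppedVariant(
            exposure_rec.variant_id, "dropped", "alleles irreconcilable"
        )
    return HarmonizedInstrument(
        variant_id=exposure_rec.variant_id,
        effect_allele=ea,
        other_allele=oa,
        beta_x=exposure_rec.beta,
        se_x=exposure_rec.se,
        beta_y=beta_y,
        se_y=outcome_rec.se,
        eaf_x=exposure_rec.eaf,
        eaf_y=eaf_y,
        action_taken=action,
    )


@dataclass(frozen=True)
class AuditEntry:
    variant_id: str
    action: str
    reason: str


@dataclass
class HarmonizationResult:
    instruments: list[HarmonizedInstrument]
    audit: list[AuditEntry]

    def action_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for entry in self.audit:
            counts[entry.action] = counts.get(entry.action, 0) + 1
        return counts


def harmonize_tables(
    instruments: InstrumentSet,
    outcome: SummaryStatTable,
    palindromic_policy: str = "drop",
    eaf_tolerance: float = DEFAULT_EAF_TOLERANCE,
) -> HarmonizationResult:
    """Harmonize every instrument present in the outcome table, in order.

    Instruments absent from the outcome table are logged and skipped (proxy
    substitution should have handled them upstream).  Raises
    :class:`EmptyInputError` when nothing survives, since every estimator
    needs at least one instrument.
    """
    harmonized: list[HarmonizedInstrument] = []
    audit: list[AuditEntry] = []
    for rec in instruments:
        if rec.variant_id not in outcome:
            audit.append(AuditEntry(rec.variant_id, "skipped", "absent from outcome table"))
            continue
        result = harmonize_pair(
            rec, outcome.get(rec.variant_id), palindromic_policy, eaf_tolerance
        )
        if isinstance(result, DroppedVariant):
            audit.append(AuditEntry(result.variant_id, result.action, result.reason))
        else:
            harmonized.append(result)
            audit.append(AuditEntry(result.variant_id, result.action_taken, ""))
    counts: dict[str, int] = {}
    for entry in audit:
        counts[entry.action] = counts.get(entry.action, 0) + 1
    logger.info("harmonize_tables(%s): actions %s", instruments.exposure_label, counts)
    if not harmonized:
        raise EmptyInputError("no instruments survived harmonization")
    return HarmonizationResult(harmonized, audit)


def write_audit(result: HarmonizationResult, path) -> None:
    """Harmonization audit as TSV (variant, action, reason)."""
    lines = ["variant_id\taction\treason"]
    for entry in result.audit:
        lines.append(f"{entry.variant_id}\t{entry.action}\t{entry.reason}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
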