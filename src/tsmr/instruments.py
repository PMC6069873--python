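"""Instrument selection for the exposure GWAS.

Selection follows the usual two-sample MR recipe: keep genome-wide
significant variants (p < 5e-8, strict), greedily prune correlated pairs
(r-squared > 0.05 discarded, the variant with the larger p-value losing),
and, for instruments absent from the outcome study, substitute the best
available proxy (r-squared > 0.8, strict) from the variants present in both
studies.  All comparisons against thresholds are strict inequalities.

Pairs with unknown r-squared are treated as independent by default — LD
tables typically list linked pairs only.  ``strict=True`` turns an unknown
pair into an error instead.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from .sumstats_io import LDTable, SummaryStatRecord, SummaryStatTable

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
DEFAULT_R2_PRUNE = 0.05
DEFAULT_R2_PROXY = 0.8


class UnknownLDError(ValueError):
    """Raised in strict mode when a required pairwise r-squared is unknown."""


@dataclass(frozen=True)
class Provenance:
    """How a variant entered the instrument set."""

    kind: str  # "original" | "proxy"
    original_id: str | None = None
    r2: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("original", "proxy"):
            raise ValueError(f"unknown provenance kind {self.kind!r}")
        if self.kind == "proxy" and (self.original_id is None or self.r2 is None):
            raise ValueError("proxy provenance requires original_id and r2")


ORIGINAL = Provenance("original")


@dataclass
class InstrumentSet:
    """Ordered instruments for one exposure plus per-variant provenance."""

    exposure_label: str
    records: list[SummaryStatRecord]
    provenance: dict[str, Provenance] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rec in self.records:
            self.provenance.setdefault(rec.variant_id, ORIGINAL)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def variant_ids(self) -> list[str]:
        return [rec.variant_id for rec in self.records]


def filter_genomewide(
    table: SummaryStatTable, threshold: float = GENOME_WIDE_P
) -> SummaryStatTable:
    """Keep exactly the records with ``pval < threshold`` (strict), in order."""
    kept = [rec for rec in table.records if rec.pval < threshold]
    if len(kept) < len(table.records):
        logger.info(
            "filter_genomewide(%s): %d of %d records below p < %g",
            table.trait_label,
            len(kept),
            len(table.records),
            threshold,
        )
    if not kept:
        logger.warning("filter_genomewide(%s): no significant records", table.trait_label)
    return SummaryStatTable(
        kept, trait_label=table.trait_label, source_label=table.source_label
    )


def prune_ld(
    table: SummaryStatTable,
    ld: LDTable,
    r2_max: float = DEFAULT_R2_PRUNE,
    strict: bool = False,
) -> InstrumentSet:
    """Greedy LD pruning: smallest p-value wins within each correlated group.

    Records are visited in ascending (pval, variant_id) order; a variant is
    kept iff its r-squared with every already-kept variant is <= ``r2_max``
    or unknown.  The output order is that visiting order, which makes the
    result invariant to the input row order.
    """
    if not table.records:
        raise ValueError("prune_ld requires a nonempty table")
    kept: list[SummaryStatRecord] = []
    dropped = 0
    for rec in sorted(table.records, key=lambda r: (r.pval, r.variant_id)):
        conflict = False
        for other in kept:
            r2 = ld.lookup(rec.variant_id, other.variant_id)
            if r2 is None:
                if strict:
                    raise UnknownLDError(
                        f"unknown r2 for pair ({rec.variant_id}, {other.variant_id})"
                    )
                continue
            if r2 > r2_max:
                conflict = True
                break
        if conflict:
            dropped += 1
        else:
            kept.append(rec)
    if dropped:
        logger.info(
            "prune_ld(%s): dropped %d variant(s) at r2 > %g",
            table.trait_label,
            dropped,
            r2_max,
        )
    return InstrumentSet(
        exposure_label=table.trait_label,
        records=kept,
        provenance={rec.variant_id: ORIGINAL for rec in kept},
    )


def substitute_proxies(
    instruments: InstrumentSet,
    outcome: SummaryStatTable,
    exposure: SummaryStatTable,
    ld: LDTable,
    r2_min: float = DEFAULT_R2_PROXY,
) -> InstrumentSet:
    """Replace instruments absent from the outcome study by their best proxy.

    The candidate pool is the exposure/outcome intersection (a proxy is
    useless without both effect estimates).  The proxy with maximal known
    r-squared to the missing instrument wins, requiring r2 > ``r2_min``
    (strict); ties break on smaller exposure p-value, then variant id.  An
    instrument with no qualifying proxy is dropped with a logged reason.
    """
    present_ids = {rec.variant_id for rec in instruments if rec.variant_id in outcome}
    pool = [
        rec
        for rec in exposure.records
        if rec.variant_id in outcome and rec.variant_id not in present_ids
    ]
    taken: set[str] = set(present_ids)
    records: list[SummaryStatRecord] = []
    provenance: dict[str, Provenance] = {}
    for rec in instruments:
        if rec.variant_id in outcome:
            records.append(rec)
            provenance[rec.variant_id] = instruments.provenance[rec.variant_id]
            continue
        best: SummaryStatRecord | None = None
        best_key: tuple | None = None
        for cand in pool:
            if cand.variant_id in taken:
                continue
            r2 = ld.lookup(rec.variant_id, cand.variant_id)
            if r2 is None or not r2 > r2_min:
                continue
            key = (-r2, cand.pval, cand.variant_id)
            if best_key is None or key < best_key:
                best, best_key = cand, key
        if best is None:
            logger.info(
                "substitute_proxies: dropping %s (absent from outcome, no proxy with r2 > %g)",
                rec.variant_id,
                r2_min,
            )
            continue
        taken.add(best.variant_id)
        records.append(best)
        provenance[best.variant_id] = Provenance("proxy", rec.variant_id, -best_key[0])
        logger.info(
            "substitute_proxies: %s -> proxy %s (r2 = %g)",
            rec.variant_id,
            best.variant_id,
            -best_key[0],
        )
    return InstrumentSet(instruments.exposure_label, records, provenance)


def exclude_variants(
    instruments: InstrumentSet, exclusion_list: Iterable[str]
) -> InstrumentSet:
    """Set difference by variant id, order preserved; ids not present are ignored."""
    excluded = set(exclusion_list)
    records = [rec for rec in instruments if rec.variant_id not in excluded]
    n_removed = len(instruments.records) - len(records)
    logger.info(
        "exclude_variants(%s): removed %d, %d instrument(s) left",
        instruments.exposure_label,
        n_removed,
        len(records),
    )
    return InstrumentSet(
        instruments.exposure_label,
        records,
        {rec.variant_id: instruments.provenance[rec.variant_id] for rec in records},
    )


def read_exclusion_list(path) -> list[str]:
    """One variant id per line; blank lines and ``#`` comments ignored."""
    ids = []
    with open(path) as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                ids.append(token)
    return ids
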