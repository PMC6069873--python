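"""Containers and I/O for GWAS summary statistics, LD tables and MR results.

The on-disk formats are deliberately plain:

* summary statistics — tab-delimited text, one variant per row, with the
  canonical header ``SNP CHR POS A1 A2 Freq1 b se p N`` (consortium files
  with other headers are read through a user-supplied ``column_map``);
* pairwise LD — three-column text ``(id1, id2, r2)``;
* MR results — a human-readable TSV (numbers to 3 significant figures, CIs
  rendered ``low to high``) plus a machine-readable JSON mirror.

Effect sizes (``b``) are per effect-allele copy on the standardized-trait
scale (trait SD units); ``Freq1`` is the effect-allele frequency.  Validation
never silently repairs a record: rows violating the invariants are dropped
and counted in the log.
"""
from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: standard field -> canonical column name written by :func:`write_sumstats`
CANONICAL_COLUMNS: dict[str, str] = {
    "variant_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "A1",
    "other_allele": "A2",
    "eaf": "Freq1",
    "beta": "b",
    "se": "se",
    "pval": "p",
    "n": "N",
}

# Header spellings accepted when the caller relies on the defaults.  GIANT
# and EGG releases disagree on most of these, hence the alternates.
_COLUMN_ALTERNATES: dict[str, tuple[str, ...]] = {
    "variant_id": ("SNP", "MarkerName", "RSID", "rsid"),
    "chrom": ("CHR", "Chr", "chr", "chromosome"),
    "pos": ("POS", "Pos", "BP", "position"),
    "effect_allele": ("A1", "Allele1", "effect_allele", "EA"),
    "other_allele": ("A2", "Allele2", "other_allele", "OA"),
    "eaf": ("Freq1", "eaf", "EAF", "FreqAllele1HapMapCEU"),
    "beta": ("b", "beta", "BETA", "Effect"),
    "se": ("se", "SE", "StdErr"),
    "pval": ("p", "pval", "P", "P-value", "Pvalue"),
    "n": ("N", "n"),
}

_REQUIRED_FIELDS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pval")
_OPTIONAL_FIELDS = ("chrom", "pos", "eaf", "n")

REQUIRED_ESTIMATORS = ("IVW", "weighted_median", "mr_egger")


class ColumnMappingError(ValueError):
    """A mapped column is absent from the file header."""


class EmptyInputError(ValueError):
    """An operation received (or produced) zero usable records."""


class IncompleteGroupError(ValueError):
    """A result group is missing one of the required estimators."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SummaryStatRecord:
    """One variant's association estimate in one GWAS."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int | None

    def validation_error(self) -> str | None:
        """Return a reason string if any invariant is violated, else None."""
        if not self.variant_id:
            return "empty variant_id"
        if self.effect_allele not in VALID_ALLELES:
            return f"invalid effect allele {self.effect_allele!r}"
        if self.other_allele not in VALID_ALLELES:
            return f"invalid other allele {self.other_allele!r}"
        if self.effect_allele == self.other_allele:
            return "effect and other allele identical"
        if not (math.isfinite(self.beta)):
            return "non-finite beta"
        if not (math.isfinite(self.se) and self.se > 0):
            return "se not > 0"
        if not (0 < self.pval <= 1):
            return "pval outside (0, 1]"
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            return "eaf outside [0, 1]"
        if self.n is not None and self.n <= 0:
            return "n not positive"
        if self.pos < 0:
            return "negative position"
        return None


@dataclass
class SummaryStatTable:
    """An ordered collection of records from one GWAS (variant ids unique)."""

    records: list[SummaryStatRecord]
    trait_label: str = ""
    source_label: str = ""

    def __post_init__(self) -> None:
        self._reindex()

    def _reindex(self) -> None:
        by_id: dict[str, SummaryStatRecord] = {}
        for rec in self.records:
            if rec.variant_id in by_id:
                raise ValueError(f"duplicate variant_id {rec.variant_id!r}")
            by_id[rec.variant_id] = rec
        self._by_id = by_id

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SummaryStatRecord]:
        return iter(self.records)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._by_id

    def get(self, variant_id: str) -> SummaryStatRecord:
        return self._by_id[variant_id]

    def variant_ids(self) -> list[str]:
        return [rec.variant_id for rec in self.records]

    def subset(self, variant_ids: Iterable[str]) -> "SummaryStatTable":
        wanted = set(variant_ids)
        return SummaryStatTable(
            [rec for rec in self.records if rec.variant_id in wanted],
            trait_label=self.trait_label,
            source_label=self.source_label,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = list(CANONICAL_COLUMNS)
        return pd.DataFrame(
            {CANONICAL_COLUMNS[f]: [getattr(r, f) for r in self.records] for f in cols}
        )


class LDTable:
    """Symmetric pairwise r-squared lookup over variant ids.

    An absent pair means "r-squared unknown"; ``lookup(v, v)`` is 1 by
    definition and self-pairs cannot be stored.
    """

    def __init__(self, entries: Iterable[tuple[str, str, float]] | None = None):
        self._r2: dict[frozenset, float] = {}
        if entries is not None:
            for a, b, r2 in entries:
                self.add(a, b, r2)

    def add(self, a: str, b: str, r2: float) -> None:
        if a == b:
            raise ValueError(f"self-pair ({a!r}) cannot be stored; r2(v,v) = 1 implicitly")
        if not (0 <= r2 <= 1):
            raise ValueError(f"r2 outside [0, 1]: {r2!r} for pair ({a!r}, {b!r})")
        key = frozenset((a, b))
        if key in self._r2 and not math.isclose(self._r2[key], r2):
            raise ValueError(
                f"conflicting r2 for pair ({a!r}, {b!r}): {self._r2[key]} vs {r2}"
            )
        self._r2[key] = float(r2)

    def lookup(self, a: str, b: str) -> float | None:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)))

    def known_pairs(self) -> Iterator[tuple[str, str, float]]:
        for key, r2 in self._r2.items():
            a, b = sorted(key)
            yield a, b, r2

    def __len__(self) -> int:
        return len(self._r2)


@dataclass(frozen=True)
class MRResult:
    """One estimator's output; the intercept block is MR-Egger only."""

    estimator_name: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_ci_low: float | None = None
    intercept_ci_high: float | None = None
    intercept_pval: float | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("CI does not bracket the point estimate")
        if not (0 < self.pval <= 1):
            raise ValueError("pval outside (0, 1]")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.estimator_name == "mr_egger":
            if self.n_snps < 3:
                raise ValueError("mr_egger requires >= 3 instruments")
            if self.intercept is None or self.intercept_se is None:
                raise ValueError("mr_egger result must carry an intercept block")

    def to_dict(self) -> dict:
        d = {
            "estimator": self.estimator_name,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "n_snps": self.n_snps,
        }
        if self.intercept is not None:
            d["intercept"] = {
                "beta": self.intercept,
                "se": self.intercept_se,
                "ci_low": self.intercept_ci_low,
                "ci_high": self.intercept_ci_high,
                "pval": self.intercept_pval,
            }
        return d


# ---------------------------------------------------------------------------
# summary-statistic files


def _resolve_columns(
    header: Sequence[str], column_map: Mapping[str, str] | None
) -> dict[str, str | None]:
    """Map each standard field to a source column, or None if absent/optional."""
    header_set = set(header)
    resolved: dict[str, str | None] = {}
    explicit = dict(column_map or {})
    for field in _REQUIRED_FIELDS + _OPTIONAL_FIELDS:
        if field in explicit:
            col = explicit[field]
            if col not in header_set:
                raise ColumnMappingError(
                    f"mapped column {col!r} for field {field!r} not in header"
                )
            resolved[field] = col
            continue
        col = next((c for c in _COLUMN_ALTERNATES[field] if c in header_set), None)
        if col is None and field in _REQUIRED_FIELDS:
            raise ColumnMappingError(
                f"no column found for required field {field!r}; "
                f"tried {_COLUMN_ALTERNATES[field]} (supply a column_map)"
            )
        resolved[field] = col
    return resolved


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s in ("", "NA", "nan", "NaN", "."):
        return None
    return float(s)


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = "\t",
    trait_label: str = "",
    source_label: str = "",
) -> SummaryStatTable:
    """Read a delimited summary-statistics file into a validated table.

    ``column_map`` maps standard field names (``variant_id``, ``chrom``,
    ``pos``, ``effect_allele``, ``other_allele``, ``eaf``, ``beta``, ``se``,
    ``pval``, ``n``) to the file's column names; unmapped fields fall back to
    common consortium spellings.  Rows failing the record invariants are
    dropped with a logged count; row order is preserved.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    cols = _resolve_columns(df.columns, column_map)

    records: list[SummaryStatRecord] = []
    n_dropped = 0
    for _, row in df.iterrows():
        try:
            eaf = _opt_float(row[cols["eaf"]]) if cols["eaf"] else None
            n_raw = _opt_float(row[cols["n"]]) if cols["n"] else None
            rec = SummaryStatRecord(
                variant_id=str(row[cols["variant_id"]]).strip(),
                chrom=str(row[cols["chrom"]]).strip() if cols["chrom"] else "0",
                pos=int(float(row[cols["pos"]])) if cols["pos"] else 0,
                effect_allele=str(row[cols["effect_allele"]]).strip().upper(),
                other_allele=str(row[cols["other_allele"]]).strip().upper(),
                eaf=eaf,
                beta=float(row[cols["beta"]]),
                se=float(row[cols["se"]]),
                pval=float(row[cols["pval"]]),
                n=int(n_raw) if n_raw is not None else None,
            )
        except (ValueError, TypeError):
            n_dropped += 1
            continue
        reason = rec.validation_error()
        if reason is not None:
            logger.debug("dropping %s: %s", rec.variant_id, reason)
            n_dropped += 1
            continue
        records.append(rec)
    if n_dropped:
        logger.warning("read_sumstats(%s): dropped %d invalid row(s)", path, n_dropped)
    if not records:
        raise EmptyInputError(f"no valid summary-statistic rows in {path}")
    return SummaryStatTable(records, trait_label=trait_label, source_label=source_label)


def _fmt_opt(value) -> str:
    return "NA" if value is None else str(value)


def write_sumstats(table: SummaryStatTable, path) -> Path:
    """Write a table in the canonical tab-delimited format (round-trip safe)."""
    if not table.records:
        raise EmptyInputError("refusing to write an empty summary-statistics table")
    path = Path(path)
    lines = ["\t".join(CANONICAL_COLUMNS.values())]
    for r in table.records:
        lines.append(
            "\t".join(
                (
                    r.variant_id,
                    r.chrom,
                    str(r.pos),
                    r.effect_allele,
                    r.other_allele,
                    _fmt_opt(r.eaf),
                    str(r.beta),
                    str(r.se),
                    str(r.pval),
                    _fmt_opt(r.n),
                )
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# LD files


def read_ld_table(path) -> LDTable:
    """Read a 3-column ``(id1, id2, r2)`` text file into a symmetric lookup.

    A header line is tolerated (detected by a non-numeric third field).
    Duplicate pairs with conflicting r-squared raise; values outside [0, 1]
    raise.
    """
    ld = LDTable()
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{i + 1}: expected (id1, id2, r2)")
            if i == 0:
                try:
                    float(parts[2])
                except ValueError:
                    continue  # header
            ld.add(parts[0], parts[1], float(parts[2]))
    return ld


def write_ld_table(ld: LDTable, path) -> Path:
    path = Path(path)
    lines = ["id1\tid2\tr2"]
    for a, b, r2 in sorted(ld.known_pairs()):
        lines.append(f"{a}\t{b}\t{r2}")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# result tables


def format_sig(x: float, digits: int = 3) -> str:
    """Format to ``digits`` significant figures the way the tables print them."""
    return f"{x:.{digits}g}"


def format_beta_ci(beta: float, lo: float, hi: float) -> str:
    return f"{format_sig(beta)} ({format_sig(lo)} to {format_sig(hi)})"


_BETA_CI_RE = re.compile(
    r"^\s*(?P<beta>[-+0-9.eE]+)\s*\(\s*(?P<lo>[-+0-9.eE]+)\s+to\s+(?P<hi>[-+0-9.eE]+)\s*\)\s*$"
)


def parse_beta_ci(cell: str) -> tuple[float, float, float]:
    """Inverse of :func:`format_beta_ci` (to the printed precision)."""
    m = _BETA_CI_RE.match(cell)
    if m is None:
        raise ValueError(f"cannot parse beta/CI cell {cell!r}")
    return float(m["beta"]), float(m["lo"]), float(m["hi"])


RESULT_COLUMNS = (
    "exposure",
    "outcome",
    "n_snps",
    "IVW_beta_ci",
    "IVW_pval",
    "weighted_median_beta_ci",
    "weighted_median_pval",
    "mr_egger_beta_ci",
    "mr_egger_pval",
    "egger_intercept_ci",
    "egger_intercept_pval",
)


def _check_group(pair, group: Mapping[str, MRResult]) -> None:
    missing = [e for e in REQUIRED_ESTIMATORS if e not in group or group[e] is None]
    if missing:
        raise IncompleteGroupError(f"pair {pair}: missing estimator(s) {missing}")


def write_results(
    results: Mapping[tuple[str, str], Mapping[str, MRResult]], path
) -> Path:
    """Write one row per exposure-outcome pair with all three estimators.

    Each estimator contributes a ``beta (low to high)`` cell and a p-value
    cell; MR-Egger additionally contributes the intercept block.  Numbers are
    formatted to 3 significant figures.
    """
    if not results:
        raise EmptyInputError("no result groups to write")
    path = Path(path)
    lines = ["\t".join(RESULT_COLUMNS)]
    for pair, group in results.items():
        _check_group(pair, group)
        ivw, wm, egger = (group[e] for e in REQUIRED_ESTIMATORS)
        lines.append(
            "\t".join(
                (
                    pair[0],
                    pair[1],
                    str(ivw.n_snps),
                    format_beta_ci(ivw.beta, ivw.ci_low, ivw.ci_high),
                    format_sig(ivw.pval),
                    format_beta_ci(wm.beta, wm.ci_low, wm.ci_high),
                    format_sig(wm.pval),
                    format_beta_ci(egger.beta, egger.ci_low, egger.ci_high),
                    format_sig(egger.pval),
                    format_beta_ci(
                        egger.intercept, egger.intercept_ci_low, egger.intercept_ci_high
                    ),
                    format_sig(egger.intercept_pval),
                )
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def results_to_json(
    results: Mapping[tuple[str, str], Mapping[str, MRResult]]
) -> list[dict]:
    """Machine-readable mirror of :func:`write_results` (full precision)."""
    out = []
    for (exposure, outcome), group in results.items():
        _check_group((exposure, outcome), group)
        out.append(
            {
                "exposure": exposure,
                "outcome": outcome,
                "estimates": {name: res.to_dict() for name, res in group.items()},
            }
        )
    return out


def write_results_json(results, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(results_to_json(results), indent=2, sort_keys=True) + "\n")
    return path
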