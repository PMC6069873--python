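"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the shape of a consortium exposure study paired with
a consortium outcome study: per-SNP exposure effects gamma_j with their
standard errors, outcome effects generated under a linear causal model with
optional pleiotropy, block LD structure, palindromic allele pairs, and
deliberate allele-coding corruption (swaps and strand flips) of the outcome
table.  Every observed quantity is reconstructable from the truth record and
the seed.

Generative model, per SNP j:

    gamma_j   ~ Uniform(gamma_range)                (true exposure effect, > 0)
    alpha_j   =  0                                  (no pleiotropy)
              ~  N(0, tau^2)                        (balanced)
              ~  N(mu, tau^2) on an invalid subset  (directional; drawn
                 independently of gamma_j, so InSIDE holds)
    beta_x_j  ~  N(gamma_j, se_x_j^2)
    beta_y_j  ~  N(beta_causal * gamma_j + alpha_j, se_y_j^2)

p-values come from the observed beta/se; the default gamma_range and se_x
are chosen so every instrument passes the genome-wide 5e-8 filter by
construction.  One global seed drives independent per-purpose streams
(effects, exposure noise, outcome noise, pleiotropy, alleles, corruption),
so toggling corruption does not change the effect draws.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats

from .sumstats_io import LDTable, SummaryStatRecord, SummaryStatTable

_TINY_P = float(np.finfo(float).tiny)

# Non-palindromic ordered allele pairs a simulated SNP may carry.
_ALLELE_PAIRS = (
    ("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"),
    ("A", "C"), ("C", "A"), ("G", "T"), ("T", "G"),
)
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

CORRUPTION_ACTIONS = ("swap_sign", "strand_flip", "strand_flip_and_swap")


@dataclass(frozen=True)
class PleiotropyScenario:
    """Pleiotropy regime: none, balanced(tau), or directional(mu, tau).

    ``frac_invalid`` is the fraction of SNPs receiving the directional
    effect (1.0 = all); it lets a scenario place a minority of the
    inverse-variance weight on invalid instruments.
    """

    kind: str = "none"  # none | balanced | directional
    mu: float = 0.0
    tau: float = 0.0
    frac_invalid: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy kind {self.kind!r}")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if not 0 <= self.frac_invalid <= 1:
            raise ValueError("frac_invalid must be in [0, 1]")


def balanced(tau: float) -> PleiotropyScenario:
    return PleiotropyScenario("balanced", 0.0, tau)


def directional(mu: float, tau: float, frac_invalid: float = 1.0) -> PleiotropyScenario:
    return PleiotropyScenario("directional", mu, tau, frac_invalid)


@dataclass(frozen=True)
class SimScenario:
    """Generative parameters for one synthetic two-sample dataset.

    Defaults mirror the scale of a large anthropometric exposure GWAS
    (n = 224,459; per-SNP SE ~ 1/sqrt(2p(1-p)n) ~ 0.0033 at MAF 0.3) paired
    with an early-growth outcome GWAS (SEs 0.01-0.03), with 35 instruments
    whose true effects (0.04-0.16 SD/allele) clear genome-wide significance
    by a wide margin.
    """

    n_snps: int = 35
    beta_causal: float = 0.2
    pleiotropy: PleiotropyScenario = field(default_factory=PleiotropyScenario)
    gamma_range: tuple[float, float] = (0.04, 0.16)
    se_x: float | tuple[float, float] = 0.0033
    se_y: float | tuple[float, float] = (0.01, 0.03)
    n_ld_blocks: int = 0
    block_r2: float = 0.9
    frac_palindromic: float = 0.0
    frac_allele_corrupted: float = 0.0
    seed: int = 0
    n_exposure: int = 224_459
    n_outcome: int = 153_781

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        lo, hi = self.gamma_range
        if not (0 < lo <= hi):
            raise ValueError("gamma_range must be positive and ordered")
        for frac in (self.frac_palindromic, self.frac_allele_corrupted):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if self.n_ld_blocks < 0 or self.n_ld_blocks > self.n_snps:
            raise ValueError("n_ld_blocks must be in [0, n_snps]")
        if not 0 <= self.block_r2 <= 1:
            raise ValueError("block_r2 must be in [0, 1]")


class TwoSampleSim(NamedTuple):
    exposure: SummaryStatTable
    outcome: SummaryStatTable
    ld: LDTable
    truth: dict


def _resolve_se(spec, n: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec, (tuple, list)):
        lo, hi = spec
        if not (0 < lo <= hi):
            raise ValueError("SE range must be positive and ordered")
        return rng.uniform(lo, hi, n)
    if spec <= 0:
        raise ValueError("SE must be positive")
    return np.full(n, float(spec))


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, _TINY_P, 1.0)


def simulate_two_sample(scn: SimScenario) -> TwoSampleSim:
    """Generate (exposure, outcome, ld, truth) for a scenario, reproducibly."""
    ss = np.random.SeedSequence(scn.seed)
    r_eff, r_nx, r_ny, r_plei, r_all, r_corr = (
        np.random.default_rng(c) for c in ss.spawn(6)
    )
    n = scn.n_snps

    gamma = r_eff.uniform(*scn.gamma_range, n)
    se_x = _resolve_se(scn.se_x, n, r_eff)
    se_y = _resolve_se(scn.se_y, n, r_eff)

    alpha = np.zeros(n)
    invalid_idx: np.ndarray = np.array([], dtype=int)
    if scn.pleiotropy.kind == "balanced":
        alpha = r_plei.normal(0.0, scn.pleiotropy.tau, n)
        invalid_idx = np.arange(n)
    elif scn.pleiotropy.kind == "directional":
        k = int(round(scn.pleiotropy.frac_invalid * n))
        invalid_idx = np.sort(r_plei.choice(n, size=k, replace=False))
        alpha[invalid_idx] = r_plei.normal(scn.pleiotropy.mu, scn.pleiotropy.tau, k)

    beta_x = gamma + r_nx.normal(0.0, 1.0, n) * se_x
    beta_y = scn.beta_causal * gamma + alpha + r_ny.normal(0.0, 1.0, n) * se_y

    # alleles, frequencies, palindromes
    n_pal = int(round(scn.frac_palindromic * n))
    pal_idx = set(np.sort(r_all.choice(n, size=n_pal, replace=False)).tolist())
    pair_choice = r_all.integers(0, 8, n)  # palindromic SNPs use choice % 4
    eaf = r_all.uniform(0.1, 0.9, n)

    variant_ids = [f"rs{j + 1:05d}" for j in range(n)]
    alleles = [
        _PALINDROMIC_PAIRS[pair_choice[j] % 4] if j in pal_idx else _ALLELE_PAIRS[pair_choice[j]]
        for j in range(n)
    ]

    # corruption of the outcome table's allele coding (non-palindromic SNPs
    # only: for palindromes a flip is label-invisible by definition)
    eligible = [j for j in range(n) if j not in pal_idx]
    n_corrupt = min(int(round(scn.frac_allele_corrupted * n)), len(eligible))
    corrupt_idx = (
        np.sort(r_corr.choice(eligible, size=n_corrupt, replace=False))
        if n_corrupt
        else np.array([], dtype=int)
    )
    corrupt_action = {
        int(j): CORRUPTION_ACTIONS[int(a)]
        for j, a in zip(corrupt_idx, r_corr.integers(0, 3, n_corrupt))
    }

    p_x = _pvalues(beta_x, se_x)
    p_y = _pvalues(beta_y, se_y)

    exp_records = []
    out_records = []
    for j in range(n):
        ea, oa = alleles[j]
        exp_records.append(
            SummaryStatRecord(
                variant_id=variant_ids[j],
                chrom=str(j % 22 + 1),
                pos=(j + 1) * 10_000,
                effect_allele=ea,
                other_allele=oa,
                eaf=float(eaf[j]),
                beta=float(beta_x[j]),
                se=float(se_x[j]),
                pval=float(p_x[j]),
                n=scn.n_exposure,
            )
        )
        o_ea, o_oa, o_beta, o_eaf = ea, oa, float(beta_y[j]), float(eaf[j])
        action = corrupt_action.get(j)
        if action in ("swap_sign", "strand_flip_and_swap"):
            o_ea, o_oa = o_oa, o_ea
            o_beta = -o_beta
            o_eaf = 1.0 - o_eaf
        if action in ("strand_flip", "strand_flip_and_swap"):
            o_ea, o_oa = _COMPLEMENT[o_ea], _COMPLEMENT[o_oa]
        out_records.append(
            SummaryStatRecord(
                variant_id=variant_ids[j],
                chrom=str(j % 22 + 1),
                pos=(j + 1) * 10_000,
                effect_allele=o_ea,
                other_allele=o_oa,
                eaf=o_eaf,
                beta=o_beta,
                se=float(se_y[j]),
                pval=float(p_y[j]),
                n=scn.n_outcome,
            )
        )

    ld = LDTable()
    blocks: list[list[str]] = []
    if scn.n_ld_blocks > 0:
        for block in np.array_split(np.arange(n), scn.n_ld_blocks):
            blocks.append([variant_ids[j] for j in block])
            for i, a in enumerate(block):
                for b in block[i + 1 :]:
                    ld.add(variant_ids[a], variant_ids[b], scn.block_r2)

    truth = {
        "scenario": dataclasses.asdict(scn),
        "variant_ids": variant_ids,
        "gamma": gamma.tolist(),
        "alpha": alpha.tolist(),
        "beta_x": beta_x.tolist(),
        "beta_y": beta_y.tolist(),
        "se_x": se_x.tolist(),
        "se_y": se_y.tolist(),
        "eaf": eaf.tolist(),
        "invalid_ids": [variant_ids[j] for j in invalid_idx],
        "palindromic_ids": sorted(variant_ids[j] for j in pal_idx),
        "corruption": {variant_ids[j]: a for j, a in corrupt_action.items()},
        "ld_blocks": blocks,
    }
    exposure = SummaryStatTable(exp_records, trait_label="exposure", source_label="synthetic")
    outcome = SummaryStatTable(out_records, trait_label="outcome", source_label="synthetic")
    return TwoSampleSim(exposure, outcome, ld, truth)


class WorkedFixture(NamedTuple):
    exposure: SummaryStatTable
    outcome: SummaryStatTable
    ld: LDTable
    expected: dict


def _p_from_z(beta: float, se: float) -> float:
    return float(np.clip(2.0 * stats.norm.sf(abs(beta / se)), _TINY_P, 1.0))


def make_worked_fixture() -> WorkedFixture:
    """Deterministic 5-SNP fixture exercising every selection/harmonization branch.

    Construction (all values fixed by hand):

    * rs1 — baseline instrument, alleles match the outcome (action ``none``);
    * rs2 — outcome coded on the swapped allele with negated beta
      (``swap_sign``);
    * rs3 — absent from the outcome study; rs5 is its proxy (r2 = 0.9);
    * rs4 — palindromic A/T at eaf 0.5, dropped under the default policy;
    * rs5 — in LD with rs1 (r2 = 0.2 > 0.05), so pruned from the instrument
      set, but re-enters as rs3's proxy; the outcome reports the opposite
      strand (``strand_flip``).

    The ``expected`` record carries the hand-traced decisions for each stage.
    """

    def rec(vid, chrom, pos, ea, oa, eaf, beta, se, n):
        return SummaryStatRecord(vid, chrom, pos, ea, oa, eaf, beta, se, _p_from_z(beta, se), n)

    exposure = SummaryStatTable(
        [
            rec("rs1", "1", 1000, "A", "G", 0.30, 0.100, 0.008, 224_459),
            rec("rs2", "2", 2000, "A", "C", 0.25, 0.080, 0.008, 224_459),
            rec("rs3", "3", 3000, "G", "T", 0.40, 0.070, 0.008, 224_459),
            rec("rs4", "4", 4000, "A", "T", 0.50, 0.060, 0.008, 224_459),
            rec("rs5", "1", 1500, "C", "T", 0.35, 0.055, 0.008, 224_459),
        ],
        trait_label="central_obesity_sim",
        source_label="synthetic",
    )
    outcome = SummaryStatTable(
        [
            rec("rs1", "1", 1000, "A", "G", 0.30, 0.022, 0.020, 153_781),
            rec("rs2", "2", 2000, "C", "A", 0.75, -0.017, 0.018, 153_781),
            rec("rs4", "4", 4000, "A", "T", 0.50, 0.013, 0.020, 153_781),
            rec("rs5", "1", 1500, "G", "A", 0.35, 0.010, 0.020, 153_781),
        ],
        trait_label="birth_weight_sim",
        source_label="synthetic",
    )
    ld = LDTable([("rs1", "rs5", 0.2), ("rs3", "rs5", 0.9)])
    expected = {
        "significant": ["rs1", "rs2", "rs3", "rs4", "rs5"],
        "pruned": ["rs5"],
        "instruments_after_prune": ["rs1", "rs2", "rs3", "rs4"],
        "proxy": {"rs3": ("rs5", 0.9)},
        "instruments_after_proxy": ["rs1", "rs2", "rs5", "rs4"],
        "actions": {
            "rs1": "none",
            "rs2": "swap_sign",
            "rs5": "strand_flip",
            "rs4": "dropped_palindromic",
        },
        "harmonized_ids": ["rs1", "rs2", "rs5"],
        "harmonized_beta_y": {"rs1": 0.022, "rs2": 0.017, "rs5": 0.010},
    }
    return WorkedFixture(exposure, outcome, ld, expected)
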