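"""Burden hypothesis tests for trio callsets.

Two complementary framings are covered:

* rate-based: observed de novo counts against the trimer-model expectation,
  with a one-sided Poisson upper-tail p-value, the enrichment ratio, and an
  observed-minus-expected estimate whose lower confidence bound shifts the
  exact (Garwood) Poisson limit of the observed count by the expectation;
* case/control: two-sided Fisher exact tests on subject-level carrier
  status (a subject counts once however many qualifying calls it has), with
  the odds ratio reported as the conditional maximum-likelihood estimate of
  the noncentral hypergeometric model - the estimate that belongs with the
  exact test - and its exact-test-inversion confidence interval.

Screen-style filters (ACMG gene list, ClinVar pathogenic missense, LOEUF
constraint strata) and the diagnostic-yield arithmetic live here too. No
multiple-testing adjustment is applied; reports carry nominal p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import GeneSet, NONSYNONYMOUS_EFFECTS, Trio


# ---------------------------------------------------------------------------
# Poisson rate tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BurdenResult:
    geneset: str
    effect_class: str
    observed: int
    expected: float
    enrichment: float
    obs_minus_exp: float
    obs_minus_exp_lower: float
    p_value: float


def poisson_burden_test(
    observed: int,
    expected: float,
    geneset: str = "",
    effect_class: str = "",
    level: float = 0.95,
) -> BurdenResult:
    """One-sided Poisson test of an observed count against its expectation.

    p = P(X >= observed | X ~ Poisson(expected)), exact tail sum; the
    obs-exp lower bound uses the exact Poisson lower limit of the observed
    count (see :func:`obs_minus_exp_ci`).
    """
    if expected <= 0:
        raise ValueError("expected count must be positive")
    if observed < 0:
        raise ValueError("observed count must be non-negative")
    p = float(stats.poisson.sf(observed - 1, expected))
    est, lower = obs_minus_exp_ci(observed, expected, level=level)
    return BurdenResult(
        geneset=geneset,
        effect_class=effect_class,
        observed=observed,
        expected=expected,
        enrichment=observed / expected,
        obs_minus_exp=est,
        obs_minus_exp_lower=lower,
        p_value=p,
    )


def poisson_lower_limit(observed: int, level: float = 0.95) -> float:
    """Exact (Garwood) lower confidence limit for a Poisson count, at the
    lower tail probability (1-level)/2 of a two-sided interval."""
    if observed == 0:
        return 0.0
    alpha = (1.0 - level) / 2.0
    return float(stats.chi2.ppf(alpha, 2 * observed) / 2.0)


def obs_minus_exp_ci(observed: int, expected: float, level: float = 0.95) -> tuple[float, float]:
    """Observed-minus-expected estimate and its lower confidence bound.

    The bound is the exact Poisson lower limit for the observed count
    shifted down by the expectation; the expectation itself is treated as
    known (it is a model constant, not an estimate).
    """
    if expected <= 0:
        raise ValueError("expected count must be positive")
    return observed - expected, poisson_lower_limit(observed, level) - expected


# ---------------------------------------------------------------------------
# Fisher carrier tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CarrierTable:
    cases_with: int
    cases_without: int
    controls_with: int
    controls_without: int

    def __post_init__(self) -> None:
        if min(self.cases_with, self.cases_without, self.controls_with, self.controls_without) < 0:
            raise ValueError("carrier counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.cases_with + self.cases_without

    @property
    def n_controls(self) -> int:
        return self.controls_with + self.controls_without

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.cases_with, self.cases_without], [self.controls_with, self.controls_without]]
        )


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    degenerate: bool = False


def fisher_carrier_test(table: CarrierTable, level: float = 0.95) -> FisherResult:
    """Two-sided Fisher exact test with conditional-MLE odds ratio.

    The p-value conditions on both margins and sums all tables at most as
    probable as the observed one (the minimum-likelihood two-sided rule);
    the odds ratio maximizes the noncentral hypergeometric likelihood and
    its interval inverts the exact test. Degenerate margins (an all-zero
    row or column) leave the odds ratio undefined and are flagged.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return FisherResult(float("nan"), float("nan"), float("nan"), 1.0, degenerate=True)
    p = float(stats.fisher_exact(arr, alternative="two-sided")[1])
    orr = stats.contingency.odds_ratio(arr, kind="conditional")
    ci = orr.confidence_interval(confidence_level=level)
    return FisherResult(
        odds_ratio=float(orr.statistic),
        ci_lower=float(ci.low),
        ci_upper=float(ci.high),
        p_value=min(p, 1.0),
    )


def carrier_counts(
    calls: pd.DataFrame,
    trios: Sequence[Trio],
    geneset: GeneSet | Iterable[str] | None,
    effect_class: str,
    include_mosaics: bool = False,
    excluded_trio_ids: Iterable[str] = (),
) -> CarrierTable:
    """Subject-level carrier contingency table.

    A subject carries iff it has >= 1 call matching the effect class within
    the gene set; mosaic calls count only when ``include_mosaics`` is set
    (they are only comparable when cases and controls were called the same
    way). Trios excluded by the outlier rule leave both margins.
    """
    excluded = set(excluded_trio_ids)
    roster = {t.family_id: t.is_case for t in trios if t.family_id not in excluded}
    unknown = set(calls["trio_id"]) - set(t.family_id for t in trios)
    if unknown:
        raise ValueError(f"calls reference subjects missing from roster: {sorted(unknown)[:3]}")
    members: set[str] | None = None
    if geneset is not None:
        members = set(geneset.members) if isinstance(geneset, GeneSet) else set(geneset)

    qualifying = calls[calls["trio_id"].isin(roster)]
    if not include_mosaics:
        qualifying = qualifying[qualifying["kind"] != "mosaic"]
    effect_mask = np.fromiter(
        (effect_matches(e, effect_class) for e in qualifying["effect"]),
        dtype=bool, count=len(qualifying),
    )
    qualifying = qualifying[effect_mask]
    if members is not None:
        qualifying = qualifying[qualifying["gene"].isin(members)]
    carriers = set(qualifying["trio_id"])
    cases = [fid for fid, is_case in roster.items() if is_case]
    controls = [fid for fid, is_case in roster.items() if not is_case]
    cw = sum(1 for fid in cases if fid in carriers)
    ow = sum(1 for fid in controls if fid in carriers)
    return CarrierTable(
        cases_with=cw,
        cases_without=len(cases) - cw,
        controls_with=ow,
        controls_without=len(controls) - ow,
    )


def effect_matches(effect: str, effect_class: str) -> bool:
    if effect_class == "nonsynonymous":
        return effect in NONSYNONYMOUS_EFFECTS
    if effect_class == "all":
        return True
    return effect == effect_class


# ---------------------------------------------------------------------------
# screens and yield
# ---------------------------------------------------------------------------

SCREEN_CRITERIA = (
    "ACMG-59",
    "ClinVar-pathogenic-missense",
    "LOEUF<0.35",
    "LOEUF<0.35+denovo-db",
)


def screen_subset(
    calls: pd.DataFrame,
    criterion: str,
    acmg_genes: GeneSet | Iterable[str] | None = None,
    denovodb_genes: GeneSet | Iterable[str] | None = None,
    loeuf_threshold: float = 0.35,
) -> pd.DataFrame:
    """Deterministic screen-style filters over an annotated callset.

    - "ACMG-59": calls in the supplied actionable-gene list;
    - "ClinVar-pathogenic-missense": missense calls labelled pathogenic or
      likely pathogenic;
    - "LOEUF<0.35": LoF calls in LoF-intolerant genes (strict inequality);
    - "LOEUF<0.35+denovo-db": additionally restricted to genes with a prior
      LoF de novo observation (user-supplied list).
    """
    if criterion not in SCREEN_CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; choose from {SCREEN_CRITERIA}")
    if calls.empty:
        return calls.copy()
    if criterion == "ACMG-59":
        if acmg_genes is None:
            raise ValueError("ACMG-59 screen requires the gene list")
        members = set(acmg_genes.members) if isinstance(acmg_genes, GeneSet) else set(acmg_genes)
        return calls[calls["gene"].isin(members)].copy()
    if criterion == "ClinVar-pathogenic-missense":
        if "clinvar" not in calls.columns:
            raise ValueError("callset lacks the 'clinvar' annotation column")
        return calls[
            (calls["effect"] == "missense")
            & calls["clinvar"].isin(["pathogenic", "likely_pathogenic"])
        ].copy()
    if "loeuf" not in calls.columns:
        raise ValueError("callset lacks the 'loeuf' annotation column")
    subset = calls[(calls["effect"] == "LoF") & (calls["loeuf"] < loeuf_threshold)]
    if criterion == "LOEUF<0.35+denovo-db":
        if denovodb_genes is None:
            raise ValueError("denovo-db screen requires the hit-gene list")
        members = (
            set(denovodb_genes.members) if isinstance(denovodb_genes, GeneSet) else set(denovodb_genes)
        )
        subset = subset[subset["gene"].isin(members)]
    return subset.copy()


def diagnostic_yield(n_classified: int, n_trios: int) -> float:
    """Percent of trios with a (likely) contributory genotype, 1 decimal."""
    if n_trios <= 0:
        raise ValueError("n_trios must be positive")
    if not 0 <= n_classified <= n_trios:
        raise ValueError("classified count must be between 0 and n_trios")
    return round(100.0 * n_classified / n_trios, 1)


def format_report_row(result: BurdenResult) -> dict:
    """Rounded report formatting: 2 decimals for counts/ratios, 2
    significant figures for p-values."""
    return dict(
        geneset=result.geneset,
        effect_class=result.effect_class,
        observed=round(result.observed, 2),
        expected=round(result.expected, 2),
        enrichment=round(result.enrichment, 2),
        obs_minus_exp=round(result.obs_minus_exp, 2),
        obs_minus_exp_lower=round(result.obs_minus_exp_lower, 2),
        p_value=float(f"{result.p_value:.2g}"),
    )
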