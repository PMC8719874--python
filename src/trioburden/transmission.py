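"""Overtransmission of deleterious parental heterozygotes.

If a heterozygous parental variant plays no role in the child's phenotype,
transmission to the child is a fair coin: each qualifying variant is an
independent Bernoulli(0.5) trial under the null, and an excess of
transmitted variants is evidence that some contribute to the phenotype.

Qualifying variants are deleterious on one of two rules: (1) loss of
function in a LoF-intolerant gene (LOEUF < 0.35), or (2) missense with a
ClinVar pathogenic or likely-pathogenic label. Each (variant, carrier
parent) pair is one trial; a variant carried by both parents contributes
two trials. Children with a missing genotype at a qualifying site drop out
of the denominator rather than being imputed.

A companion test asks whether recessive biallelic genotypes form more often
than the 1-in-4 Mendelian expectation when both parents are carriers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .variant_io import Genotype, Trio, TrioVariantRecord

QUALIFYING_RULES = ("LoF-in-LOEUF<0.35", "ClinVar-pathogenic-missense")
AUTOSOMES = {str(c) for c in range(1, 23)}


@dataclass(frozen=True)
class QualifyingVariant:
    variant_key: str
    trio_id: str
    carrier_parent: str  # "mother" | "father"
    gene: str
    rule: str
    transmitted: bool | None  # None = child genotype indeterminate

    def __post_init__(self) -> None:
        if self.rule not in QUALIFYING_RULES:
            raise ValueError(f"unknown qualifying rule {self.rule!r}")


@dataclass(frozen=True)
class TransmissionResult:
    n_qualifying: int
    n_transmitted: int
    fraction: float
    p_value: float


def _qualifies(ann: pd.Series, loeuf_threshold: float = 0.35) -> str | None:
    effect = ann["effect"]
    if effect == "LoF" and pd.notna(ann["loeuf"]) and ann["loeuf"] < loeuf_threshold:
        return "LoF-in-LOEUF<0.35"
    if effect == "missense" and ann["clinvar"] in ("pathogenic", "likely_pathogenic"):
        return "ClinVar-pathogenic-missense"
    return None


def enumerate_qualifying(
    records_by_trio: Mapping[str, Sequence[TrioVariantRecord]],
    trios: Sequence[Trio],
    annotations: pd.DataFrame,
    loeuf_threshold: float = 0.35,
) -> list[QualifyingVariant]:
    """Enumerate qualifying deleterious parental heterozygotes across trios.

    Only autosomal, parentally heterozygous sites count (the 0.5 null
    assumes biparental autosomal inheritance, and de novo sites have no
    transmitting parent by definition). The transmitted flag is whether the
    child carries the allele; ``None`` marks an indeterminate (missing)
    child genotype, excluded from the test denominator downstream.
    """
    ann = annotations.set_index("variant_key")
    out: list[QualifyingVariant] = []
    for trio in trios:
        for rec in records_by_trio.get(trio.family_id, ()):  # type: ignore[arg-type]
            if rec.chrom.removeprefix("chr") not in AUTOSOMES:
                continue
            if rec.variant_key not in ann.index:
                continue
            rule = _qualifies(ann.loc[rec.variant_key], loeuf_threshold)
            if rule is None:
                continue
            for parent_name, call in (("mother", rec.mother), ("father", rec.father)):
                if call.gt is not Genotype.HET:
                    continue
                if rec.child.gt is Genotype.MISSING:
                    transmitted: bool | None = None
                else:
                    transmitted = rec.child.gt in (Genotype.HET, Genotype.HOM_ALT)
                out.append(
                    QualifyingVariant(
                        variant_key=rec.variant_key,
                        trio_id=trio.family_id,
                        carrier_parent=parent_name,
                        gene=str(ann.loc[rec.variant_key, "gene"]),
                        rule=rule,
                        transmitted=transmitted,
                    )
                )
    return out


def overtransmission_test(n_transmitted: int, n_qualifying: int) -> TransmissionResult:
    """Exact one-sided binomial test of transmission against the 0.5 null.

    p = P(X >= n_transmitted | X ~ Binomial(n_qualifying, 0.5)).
    """
    if n_qualifying < 1:
        raise ValueError("need at least one qualifying variant")
    if not 0 <= n_transmitted <= n_qualifying:
        raise ValueError("transmitted count must be between 0 and n_qualifying")
    p = float(stats.binom.sf(n_transmitted - 1, n_qualifying, 0.5))
    return TransmissionResult(
        n_qualifying=n_qualifying,
        n_transmitted=n_transmitted,
        fraction=round(n_transmitted / n_qualifying, 2),
        p_value=p,
    )


def overtransmission_from_qualifying(variants: Iterable[QualifyingVariant]) -> TransmissionResult:
    """Run the overtransmission test on an enumerated qualifying set,
    dropping indeterminate entries from the denominator."""
    determinate = [v for v in variants if v.transmitted is not None]
    if not determinate:
        raise ValueError("no determinate qualifying variants")
    return overtransmission_test(
        sum(1 for v in determinate if v.transmitted), len(determinate)
    )


def recessive_formation_test(
    n_formed: int, n_opportunities: int, per_opportunity_p: float = 0.25
) -> float:
    """Exact one-sided binomial test for excess recessive genotype formation.

    An opportunity is a trio where both parents are heterozygous carriers at
    biallelic-compatible sites of one gene; under Mendelian segregation the
    biallelic genotype forms with probability 0.25.
    """
    if n_opportunities < 1:
        raise ValueError("need at least one opportunity")
    if not 0 <= n_formed <= n_opportunities:
        raise ValueError("formed count must be between 0 and n_opportunities")
    if not 0.0 < per_opportunity_p < 1.0:
        raise ValueError("per-opportunity probability must be in (0, 1)")
    return float(stats.binom.sf(n_formed - 1, n_opportunities, per_opportunity_p))


def count_recessive_opportunities(
    records_by_trio: Mapping[str, Sequence[TrioVariantRecord]],
    trios: Sequence[Trio],
    annotations: pd.DataFrame,
    loeuf_threshold: float = 0.35,
) -> tuple[int, int]:
    """Count biallelic-formation opportunities and formed genotypes.

    A trio contributes one opportunity per gene where its mother and father
    each carry a qualifying heterozygote at distinct sites (trans-capable
    compound het) or the same site (hom formation); the genotype counts as
    formed when the child carries both parental alleles.
    """
    ann = annotations.set_index("variant_key")
    opportunities = formed = 0
    for trio in trios:
        per_gene: dict[str, dict[str, list[TrioVariantRecord]]] = {}
        for rec in records_by_trio.get(trio.family_id, ()):  # type: ignore[arg-type]
            if rec.variant_key not in ann.index:
                continue
            if _qualifies(ann.loc[rec.variant_key], loeuf_threshold) is None:
                continue
            gene = str(ann.loc[rec.variant_key, "gene"])
            slot = per_gene.setdefault(gene, {"mother": [], "father": []})
            if rec.mother.gt is Genotype.HET:
                slot["mother"].append(rec)
            if rec.father.gt is Genotype.HET:
                slot["father"].append(rec)
        for gene, slot in per_gene.items():
            maternal_sites = {r.variant_key for r in slot["mother"]}
            paternal_sites = {r.variant_key for r in slot["father"]}
            if not maternal_sites or not paternal_sites:
                continue
            trans_capable = bool(maternal_sites ^ paternal_sites) or bool(
                maternal_sites & paternal_sites
            )
            if not trans_capable:
                continue
            opportunities += 1
            child_carries = {
                r.variant_key
                for r in slot["mother"] + slot["father"]
                if r.child.gt in (Genotype.HET, Genotype.HOM_ALT)
            }
            hom_formed = any(
                r.child.gt is Genotype.HOM_ALT for r in slot["mother"] + slot["father"]
            )
            # formed = child homozygous at a shared site, or carries a maternal
            # and a distinct paternal allele (compound het)
            maternal_hit = child_carries & maternal_sites
            paternal_hit = child_carries & paternal_sites
            compound = bool(maternal_hit) and bool(paternal_hit) and len(maternal_hit | paternal_hit) >= 2
            if hom_formed or compound:
                formed += 1
    return formed, opportunities
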