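"""De novo and transmitted parental-mosaic variant calling from trio records.

A de novo mutation (DNM) call requires a heterozygous child with both
parents homozygous reference, a child alternate allele fraction of at least
0.30, minimum depths in all three members, essentially no alternate
evidence in either parent, and absence from a control carrier index. Trios
with six or more DNM calls are excluded outright as likely sample-quality
artifacts.

A transmitted parental-mosaic call is a heterozygous child passing the same
child-side QC whose site shows exactly one parent genotyped homozygous
reference but carrying an alternate allele fraction inside the mosaic band
(0.03-0.20) - too much support to be sequencing noise, too little to be a
constitutional heterozygote.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .variant_io import Genotype, SampleCall, Trio, TrioVariantRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    """Hard-call QC thresholds for trio-based calling."""

    min_child_alt_allele_fraction: float = 0.30
    min_depth_child: int = 10
    min_depth_parent: int = 10
    #: a parent counts as clean hom-ref if alt reads <= max(1, tol * depth);
    #: a zero-tolerance rule would reject real DNMs at realistic error rates
    parent_alt_fraction_tolerance: float = 0.02
    max_control_carriers: int = 0
    #: trios with >= this many DNM calls are excluded entirely
    max_dnms_per_trio: int = 6
    mosaic_band: tuple[float, float] = (0.03, 0.20)
    #: minimum alt reads for mosaic-band parental evidence; keeps the mosaic
    #: band disjoint from the DNM parent-tolerance rule at any depth
    min_parent_alt_reads_mosaic: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.min_child_alt_allele_fraction <= 0.5:
            raise ValueError("min_child_alt_allele_fraction must be in (0, 0.5]")
        lo, hi = self.mosaic_band
        if not 0.0 < lo < hi < self.min_child_alt_allele_fraction:
            raise ValueError("mosaic band must sit below the child het threshold")
        for name in ("min_depth_child", "min_depth_parent", "max_control_carriers",
                     "max_dnms_per_trio", "min_parent_alt_reads_mosaic"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class DNMCall:
    trio_id: str
    variant_key: str
    chrom: str
    pos: int
    variant_type: str  # "snv" | "indel"
    child_alt_fraction: float


@dataclass(frozen=True)
class MosaicCall:
    trio_id: str
    variant_key: str
    chrom: str
    pos: int
    mosaic_parent: str  # "mother" | "father"
    parental_alt_fraction: float
    child_alt_fraction: float


def _parent_clean(call: SampleCall, thresholds: QCThresholds) -> bool:
    limit = max(1.0, thresholds.parent_alt_fraction_tolerance * call.depth)
    return call.alt_reads <= limit


def _child_passes(rec: TrioVariantRecord, thresholds: QCThresholds) -> bool:
    c = rec.child
    return (
        c.gt is Genotype.HET
        and c.depth >= thresholds.min_depth_child
        and c.alt_fraction >= thresholds.min_child_alt_allele_fraction
    )


def _in_mosaic_band(call: SampleCall, thresholds: QCThresholds) -> bool:
    lo, hi = thresholds.mosaic_band
    return (
        call.gt is Genotype.HOM_REF
        and call.alt_reads >= thresholds.min_parent_alt_reads_mosaic
        and lo <= call.alt_fraction <= hi
    )


def call_dnms(
    records: Iterable[TrioVariantRecord],
    trio: Trio,
    thresholds: QCThresholds = QCThresholds(),
    control_carrier_index: Mapping[str, int] | None = None,
) -> list[DNMCall]:
    """Screen one trio's records for de novo mutations.

    Sites with a missing genotype in any member are skipped with a logged
    reason rather than raised, mirroring how hard-filtered pipelines drop
    no-call sites.
    """
    controls = control_carrier_index or {}
    calls: list[DNMCall] = []
    for rec in records:
        if any(c.gt is Genotype.MISSING for c in (rec.child, rec.mother, rec.father)):
            log.info("%s %s: skipped (missing genotype)", trio.family_id, rec.variant_key)
            continue
        if rec.child.gt is not Genotype.HET:
            continue
        if rec.mother.gt is not Genotype.HOM_REF or rec.father.gt is not Genotype.HOM_REF:
            continue
        if not _child_passes(rec, thresholds):
            continue
        if min(rec.mother.depth, rec.father.depth) < thresholds.min_depth_parent:
            continue
        if not (_parent_clean(rec.mother, thresholds) and _parent_clean(rec.father, thresholds)):
            continue
        if controls.get(rec.variant_key, 0) > thresholds.max_control_carriers:
            continue
        calls.append(
            DNMCall(
                trio_id=trio.family_id,
                variant_key=rec.variant_key,
                chrom=rec.chrom,
                pos=rec.pos,
                variant_type="snv" if rec.is_snv else "indel",
                child_alt_fraction=rec.child.alt_fraction,
            )
        )
    calls.sort(key=lambda c: (c.chrom, c.pos, c.variant_key))
    return calls


def call_transmitted_mosaics(
    records: Iterable[TrioVariantRecord],
    trio: Trio,
    thresholds: QCThresholds = QCThresholds(),
) -> list[MosaicCall]:
    """Screen one trio's records for transmitted parental-mosaic variants."""
    calls: list[MosaicCall] = []
    for rec in records:
        if any(c.gt is Genotype.MISSING for c in (rec.child, rec.mother, rec.father)):
            log.info("%s %s: skipped (missing genotype)", trio.family_id, rec.variant_key)
            continue
        if not _child_passes(rec, thresholds):
            continue
        if min(rec.mother.depth, rec.father.depth) < thresholds.min_depth_parent:
            continue
        mother_band = _in_mosaic_band(rec.mother, thresholds)
        father_band = _in_mosaic_band(rec.father, thresholds)
        if mother_band and father_band:
            log.info(
                "%s %s: skipped (mosaic-band evidence in both parents)",
                trio.family_id, rec.variant_key,
            )
            continue
        if not (mother_band or father_band):
            continue
        mosaic, other = (
            (rec.mother, rec.father) if mother_band else (rec.father, rec.mother)
        )
        if other.gt is not Genotype.HOM_REF or not _parent_clean(other, thresholds):
            continue
        calls.append(
            MosaicCall(
                trio_id=trio.family_id,
                variant_key=rec.variant_key,
                chrom=rec.chrom,
                pos=rec.pos,
                mosaic_parent="mother" if mother_band else "father",
                parental_alt_fraction=mosaic.alt_fraction,
                child_alt_fraction=rec.child.alt_fraction,
            )
        )
    calls.sort(key=lambda c: (c.chrom, c.pos, c.variant_key))
    return calls


def exclude_outlier_trios(
    calls: Sequence[DNMCall], thresholds: QCThresholds = QCThresholds()
) -> tuple[list[DNMCall], list[str]]:
    """Drop every trio with >= max_dnms_per_trio DNM calls, calls and all."""
    per_trio = Counter(c.trio_id for c in calls)
    excluded = sorted(t for t, n in per_trio.items() if n >= thresholds.max_dnms_per_trio)
    retained = [c for c in calls if c.trio_id not in set(excluded)]
    return retained, excluded


def combine_callsets(
    dnms: Sequence[DNMCall], mosaics: Sequence[MosaicCall]
) -> tuple[list[DNMCall | MosaicCall], float]:
    """Concatenate DNM and mosaic calls and report the mosaic percentage.

    The two callsets must be disjoint on (trio, variant); the mosaic share
    is |mosaics| / (|dnms| + |mosaics|) as a percent rounded to 1 decimal.
    """
    dnm_keys = {(c.trio_id, c.variant_key) for c in dnms}
    clash = [(c.trio_id, c.variant_key) for c in mosaics if (c.trio_id, c.variant_key) in dnm_keys]
    if clash:
        raise ValueError(f"calls present in both DNM and mosaic sets: {clash[:3]}")
    combined: list[DNMCall | MosaicCall] = [*dnms, *mosaics]
    total = len(combined)
    pct = round(100.0 * len(mosaics) / total, 1) if total else 0.0
    return combined, pct


def build_control_carrier_index(
    records_by_trio: Mapping[str, Sequence[TrioVariantRecord]],
    control_trio_ids: Iterable[str],
) -> dict[str, int]:
    """Count, per variant key, control-cohort members carrying the allele."""
    index: dict[str, int] = defaultdict(int)
    for trio_id in control_trio_ids:
        for rec in records_by_trio.get(trio_id, ()):  # type: ignore[arg-type]
            carriers = sum(
                1
                for c in (rec.child, rec.mother, rec.father)
                if c.gt in (Genotype.HET, Genotype.HOM_ALT)
            )
            if carriers:
                index[rec.variant_key] += carriers
    return dict(index)


def annotate_calls(
    calls: Sequence[DNMCall | MosaicCall], annotations: pd.DataFrame
) -> pd.DataFrame:
    """Join calls to the annotation table into the tabular callset used by
    all burden analyses (one row per call)."""
    ann = annotations.set_index("variant_key")
    rows = []
    for c in calls:
        if c.variant_key not in ann.index:
            raise KeyError(f"no annotation for {c.variant_key}")
        a = ann.loc[c.variant_key]
        rows.append(
            dict(
                trio_id=c.trio_id,
                variant_key=c.variant_key,
                kind="mosaic" if isinstance(c, MosaicCall) else "dnm",
                variant_type=getattr(c, "variant_type", "snv"),
                gene=a["gene"],
                effect=a["effect"],
                score=a["score"],
                clinvar=a["clinvar"],
                loeuf=a["loeuf"],
                alt_fraction=c.child_alt_fraction,
                mosaic_parent=getattr(c, "mosaic_parent", ""),
            )
        )
    columns = ["trio_id", "variant_key", "kind", "variant_type", "gene", "effect",
               "score", "clinvar", "loeuf", "alt_fraction", "mosaic_parent"]
    return pd.DataFrame(rows, columns=columns)


def validate_against_truth(
    dnm_calls: Sequence[DNMCall],
    truth: pd.DataFrame,
    records_by_trio: Mapping[str, Sequence[TrioVariantRecord]],
    min_depth: int = 20,
) -> dict[str, float]:
    """Caller performance against a simulated truth table.

    Sensitivity is measured over true DNM events where all three members
    have depth >= min_depth (shallower sites are legitimately unsalvageable
    by a hard-filter caller); the false discovery rate is over all calls.
    """
    depth_ok: dict[tuple[str, str], bool] = {}
    for trio_id, recs in records_by_trio.items():
        for rec in recs:
            depth_ok[(trio_id, rec.variant_key)] = (
                min(rec.child.depth, rec.mother.depth, rec.father.depth) >= min_depth
            )
    truth_dnm = truth[truth["kind"].isin(["dnm-snv", "dnm-indel"])]
    truth_keys = {(r.family_id, r.variant_key) for r in truth_dnm.itertuples(index=False)}
    eligible = {k for k in truth_keys if depth_ok.get(k, False)}
    called = {(c.trio_id, c.variant_key) for c in dnm_calls}
    tp_eligible = len(eligible & called)
    fp = len(called - truth_keys)
    sensitivity = tp_eligible / len(eligible) if eligible else float("nan")
    fdr = fp / len(called) if called else 0.0
    return dict(
        sensitivity=sensitivity,
        fdr=fdr,
        n_eligible_truth=len(eligible),
        n_calls=len(called),
        n_false_positives=fp,
    )
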