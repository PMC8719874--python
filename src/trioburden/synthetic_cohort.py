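"""Synthetic trio-cohort generator.

Generates trio genotype data (per-member genotype, allele depths, total
depth), variant annotations and a ground-truth event table with the
statistical structure the downstream analysis assumes:

* per-trio coding de novo SNV and indel counts are Poisson, by default ~1
  coding SNV and ~0.1 coding indel per trio;
* a configurable fraction (default 3.8%) of de novo-like events are
  transmitted parental-mosaic in origin, with the mosaic parent's blood
  allele fraction drawn uniformly from the mosaic band (0.03-0.20), below
  the 0.30 heterozygous allele-balance threshold used by the caller;
* de novo SNVs land on (gene, position, alt) proportionally to the trimer
  rate table, so observed counts are directly comparable to the rate-model
  expectations; a nonsynonymous enrichment factor can inflate case rates in
  a designated gene set;
* qualifying deleterious parental heterozygotes (LoF in a LOEUF<0.35 gene,
  or ClinVar-labelled pathogenic missense) are transmitted with probability
  ``transmission_bias`` (null 0.5);
* read depths follow a gamma-Poisson with mean ~89x (matching typical deep
  exomes), allele fractions at true heterozygous sites are Binomial(depth,
  0.5)/depth, and sequencing noise places error reads (rate 0.5% per read,
  spread over the three non-reference bases) on genuinely homozygous
  reference samples so the caller's false-positive filters are exercised.

Deleteriousness scores are rank-based: a rank fraction is drawn per effect
class and converted with the standard -10*log10(rank) scaling, so LoF and
most missense events exceed the conventional deleteriousness cutoff of 15
while synonymous events rarely do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import BASES, CLASS_NAMES, LOF, MISSENSE, SYNONYMOUS, GeneModel
from .genome import classify_substitutions, encode_sequence, toy_genome
from .rate_model import TrimerRateTable, calibrate_rate_table, default_rate_table
from .variant_io import (
    Genotype,
    SampleCall,
    Trio,
    TrioVariantRecord,
    read_annotations,
    read_ped,
    read_rate_table,
    read_table,
    read_trio_vcf,
    record_sort_key,
    write_annotations,
    write_ped,
    write_rate_table,
    write_table,
    write_trio_vcf,
)

EVENT_KINDS = ("dnm-snv", "dnm-indel", "parental-mosaic", "inherited-het", "inherited-biallelic")

TRUTH_COLUMNS = [
    "family_id", "kind", "variant_key", "chrom", "pos", "ref", "alt", "gene",
    "effect", "score", "carrier_parent", "parental_allele_fraction",
    "transmitted", "qualifying_rule", "pair_id",
]


@dataclass(frozen=True)
class DepthModel:
    """Gamma-Poisson per-site read depth; mean/dispersion parameterization."""

    mean: float = 89.0
    dispersion: float = 8.0  # gamma shape; larger = tighter around the mean

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        lam = rng.gamma(self.dispersion, self.mean / self.dispersion, size=size)
        return np.maximum(rng.poisson(lam), 1)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a simulated trio cohort."""

    n_case_trios: int = 124
    n_control_trios: int = 573
    mean_coding_snv_dnms_per_trio: float = 1.0
    mean_coding_indel_dnms_per_trio: float = 0.1
    mosaic_fraction: float = 0.038
    enriched_geneset: tuple[str, ...] = ()
    nonsyn_enrichment_factor: float = 1.0
    transmission_bias: float = 0.5
    # ~14 qualifying deleterious parental heterozygotes per 124 trios
    mean_qualifying_het_per_trio: float = 0.113
    mean_background_het_per_trio: float = 3.0
    mean_biallelic_opportunities_per_trio: float = 0.016
    depth_model: DepthModel = field(default_factory=DepthModel)
    error_rate: float = 0.005
    missing_rate: float = 0.001
    noise_sites_per_trio: int = 8
    seed: int = 0

    def validate(self) -> None:
        if self.n_case_trios + self.n_control_trios < 1:
            raise ValueError("at least one trio must be requested")
        for name in (
            "mean_coding_snv_dnms_per_trio", "mean_coding_indel_dnms_per_trio",
            "mean_qualifying_het_per_trio", "mean_background_het_per_trio",
            "mean_biallelic_opportunities_per_trio",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.mosaic_fraction <= 1.0:
            raise ValueError("mosaic_fraction must be in [0, 1]")
        if not 0.0 <= self.transmission_bias <= 1.0:
            raise ValueError("transmission_bias must be in [0, 1]")
        if self.nonsyn_enrichment_factor < 1.0:
            raise ValueError("nonsyn_enrichment_factor must be >= 1")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")


@dataclass
class Cohort:
    """A simulated (or re-loaded) trio cohort with its provenance objects."""

    trios: list[Trio]
    records: dict[str, list[TrioVariantRecord]]
    annotations: pd.DataFrame
    truth: pd.DataFrame
    genes: dict[str, GeneModel]
    rate_table: TrimerRateTable
    config: CohortConfig | None = None

    @property
    def case_trios(self) -> list[Trio]:
        return [t for t in self.trios if t.is_case]

    @property
    def control_trios(self) -> list[Trio]:
        return [t for t in self.trios if not t.is_case]


# ---------------------------------------------------------------------------
# genome-wide substitution space
# ---------------------------------------------------------------------------

@dataclass
class _SubstitutionSpace:
    """All coding single-base substitutions of a gene catalogue, flattened."""

    symbols: list[str]
    gene_idx: np.ndarray     # index into symbols
    cds_pos: np.ndarray      # 0-based position within the CDS
    gpos: np.ndarray         # 1-based genomic position
    chrom: np.ndarray        # chromosome label per substitution (object)
    ref: np.ndarray          # reference base index
    alt: np.ndarray          # alternate base index
    klass: np.ndarray        # SYNONYMOUS/MISSENSE/LOF
    rate: np.ndarray         # per-chromosome per-generation probability
    loeuf: np.ndarray        # per-substitution gene LOEUF

    @classmethod
    def build(cls, genes: dict[str, GeneModel], table: TrimerRateTable) -> "_SubstitutionSpace":
        symbols = list(genes)
        parts = {k: [] for k in ("gene_idx", "cds_pos", "gpos", "chrom", "ref", "alt", "klass", "rate", "loeuf")}
        for gi, sym in enumerate(symbols):
            gene = genes[sym]
            gene.require_frame()
            pos, alt, klass = classify_substitutions(gene.cds)
            seq_idx = encode_sequence(gene.cds)
            rates = table.rates_for(seq_idx, pos, alt)
            n = pos.size
            parts["gene_idx"].append(np.full(n, gi, dtype=np.int32))
            parts["cds_pos"].append(pos)
            parts["gpos"].append(gene.start + pos)
            parts["chrom"].append(np.full(n, gene.chrom, dtype=object))
            parts["ref"].append(seq_idx[pos])
            parts["alt"].append(alt)
            parts["klass"].append(klass)
            parts["rate"].append(rates)
            parts["loeuf"].append(np.full(n, gene.loeuf if gene.loeuf is not None else np.nan))
        return cls(symbols=symbols, **{k: np.concatenate(v) for k, v in parts.items()})

    def weighted_sample(self, rng: np.random.Generator, weights: np.ndarray, size: int) -> np.ndarray:
        if size == 0:
            return np.empty(0, dtype=np.int64)
        p = weights / weights.sum()
        return rng.choice(weights.size, size=size, p=p)


class _CategoricalSampler:
    """O(log n) repeated draws from a fixed weight vector (inverse CDF)."""

    def __init__(self, weights: np.ndarray):
        self._cum = np.cumsum(weights)
        self.total = float(self._cum[-1])

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if size == 0:
            return np.empty(0, dtype=np.int64)
        u = rng.random(size) * self.total
        return np.searchsorted(self._cum, u, side="right")


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _score_rank_fraction(rng: np.random.Generator, effect: str) -> float:
    """Draw a deleteriousness rank fraction; log-uniform ranges per class."""
    ranges = {
        "synonymous": (0.02, 1.0),
        "missense": (1e-4, 0.1),
        "inframe-indel": (1e-4, 0.1),
        "LoF": (1e-5, 3e-3),
    }
    lo, hi = ranges[effect]
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _scaled_score(rank_fraction: float) -> float:
    return round(-10.0 * np.log10(rank_fraction), 2)


class _TrioBuilder:
    """Accumulates truth events for one trio and renders read evidence."""

    def __init__(self, trio: Trio, config: CohortConfig, rng: np.random.Generator):
        self.trio = trio
        self.config = config
        self.rng = rng
        self.events: list[dict] = []
        self.sites: list[dict] = []
        self._keys: set[str] = set()

    def add_site(self, *, chrom, pos, ref, alt, genotypes, mosaic_af=None, mosaic_parent=None) -> bool:
        key = f"{chrom}-{pos}-{ref}-{alt}"
        if key in self._keys:
            return False
        self._keys.add(key)
        self.sites.append(
            dict(chrom=chrom, pos=int(pos), ref=ref, alt=alt, genotypes=genotypes,
                 mosaic_af=mosaic_af, mosaic_parent=mosaic_parent, key=key)
        )
        return True

    def render(self) -> list[TrioVariantRecord]:
        cfg = self.config
        rng = self.rng
        records = []
        for site in self.sites:
            calls = {}
            depths = cfg.depth_model.draw(rng, 3)
            for member, depth in zip(("child", "mother", "father"), depths):
                gt = site["genotypes"][member]
                depth = int(depth)
                if gt is Genotype.HET:
                    p_alt = 0.5
                elif gt is Genotype.HOM_ALT:
                    p_alt = 1.0 - cfg.error_rate / 3
                elif member == site["mosaic_parent"]:
                    p_alt = site["mosaic_af"]
                else:
                    # errors are spread over the three non-reference bases
                    p_alt = cfg.error_rate / 3
                alt_reads = int(rng.binomial(depth, p_alt))
                other = int(rng.binomial(depth - alt_reads, cfg.error_rate * 2 / 3))
                recorded = Genotype.MISSING if rng.random() < cfg.missing_rate else gt
                calls[member] = SampleCall(
                    gt=recorded, ref_reads=depth - alt_reads - other,
                    alt_reads=alt_reads, depth=depth,
                )
            records.append(
                TrioVariantRecord(
                    chrom=site["chrom"], pos=site["pos"], ref=site["ref"],
                    alt=site["alt"], **calls,
                )
            )
        records.sort(key=record_sort_key)
        return records


def _snv_alleles(space: _SubstitutionSpace, idx: int) -> tuple[str, str]:
    return BASES[space.ref[idx]], BASES[space.alt[idx]]


def simulate_cohort(
    config: CohortConfig,
    genes: dict[str, GeneModel] | None = None,
    rate_table: TrimerRateTable | None = None,
) -> Cohort:
    """Simulate a full trio cohort under the configured study conditions.

    The rate table defaults to the bundled trimer spectrum calibrated so the
    whole-catalogue expected coding de novo SNV count equals the configured
    per-trio mean; the simulator then samples events from exactly that
    distribution, so rate-model expectations are the true event means.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if genes is None:
        genes = toy_genome()
    unknown = [s for s in config.enriched_geneset if s not in genes]
    if unknown:
        raise ValueError(f"enriched_geneset references unknown genes: {unknown[:5]}")
    if rate_table is None:
        rate_table = calibrate_rate_table(
            default_rate_table(), genes, config.mean_coding_snv_dnms_per_trio or 1.0
        )
    space = _SubstitutionSpace.build(genes, rate_table)

    trios = [
        Trio(f"CASE{i + 1:04d}", f"CASE{i + 1:04d}-C", f"CASE{i + 1:04d}-M", f"CASE{i + 1:04d}-F", True)
        for i in range(config.n_case_trios)
    ] + [
        Trio(f"CTRL{i + 1:04d}", f"CTRL{i + 1:04d}-C", f"CTRL{i + 1:04d}-M", f"CTRL{i + 1:04d}-F", False)
        for i in range(config.n_control_trios)
    ]

    # per-substitution sampling weights; cases may carry nonsynonymous
    # enrichment within the designated gene set
    base_w = space.rate * 2.0  # two parental chromosomes
    enriched_gi = {space.symbols.index(s) for s in config.enriched_geneset}
    if enriched_gi and config.nonsyn_enrichment_factor > 1.0:
        in_set = np.isin(space.gene_idx, sorted(enriched_gi))
        boost = np.where(in_set & (space.klass != SYNONYMOUS), config.nonsyn_enrichment_factor, 1.0)
        case_w = base_w * boost
    else:
        case_w = base_w

    samp_base = _CategoricalSampler(base_w)
    samp_case = _CategoricalSampler(case_w) if case_w is not base_w else samp_base
    builders = {t.family_id: _TrioBuilder(t, config, rng) for t in trios}
    annotations: dict[str, dict] = {}
    gene_lengths = np.array([genes[s].coding_length for s in space.symbols], dtype=float)
    constrained_lof = np.flatnonzero((space.klass == LOF) & (space.loeuf < 0.35))
    missense_idx = np.flatnonzero(space.klass == MISSENSE)
    samp_lof = _CategoricalSampler(space.rate[constrained_lof]) if constrained_lof.size else None
    samp_mis = _CategoricalSampler(space.rate[missense_idx]) if missense_idx.size else None

    def annotate(key: str, gene_sym: str, effect: str, clinvar: str = "none", score: float | None = None) -> float:
        if key in annotations:
            return annotations[key]["score"]
        if score is None:
            score = _scaled_score(_score_rank_fraction(rng, effect))
        annotations[key] = dict(
            variant_key=key, gene=gene_sym, effect=effect, score=score,
            clinvar=clinvar, loeuf=genes[gene_sym].loeuf,
        )
        return score

    def snv_event(builder, idx: int, kind: str, genotypes, *, clinvar="none",
                  carrier_parent="", mosaic_af=np.nan, transmitted=np.nan,
                  rule="", pair_id="") -> None:
        ref, alt = _snv_alleles(space, idx)
        chrom = str(space.chrom[idx])
        pos = int(space.gpos[idx])
        gene_sym = space.symbols[space.gene_idx[idx]]
        effect = CLASS_NAMES[int(space.klass[idx])]
        key = f"{chrom}-{pos}-{ref}-{alt}"
        if not builder.add_site(
            chrom=chrom, pos=pos, ref=ref, alt=alt, genotypes=genotypes,
            mosaic_af=None if np.isnan(mosaic_af) else mosaic_af,
            mosaic_parent=carrier_parent if kind == "parental-mosaic" else None,
        ):
            return
        score = annotate(key, gene_sym, effect, clinvar)
        builder.events.append(
            dict(family_id=builder.trio.family_id, kind=kind, variant_key=key,
                 chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene_sym,
                 effect=effect, score=score, carrier_parent=carrier_parent,
                 parental_allele_fraction=mosaic_af, transmitted=transmitted,
                 qualifying_rule=rule, pair_id=pair_id)
        )

    n_trios = len(trios)
    is_case = np.array([t.is_case for t in trios])

    # --- de novo SNVs ------------------------------------------------------
    lam_case = 0.5 * config.mean_coding_snv_dnms_per_trio * case_w.sum() / (0.5 * base_w.sum()) \
        if base_w.sum() > 0 else 0.0
    lam_base = config.mean_coding_snv_dnms_per_trio
    lam = np.where(is_case, lam_case if case_w is not base_w else lam_base, lam_base)
    dnm_counts = rng.poisson(lam)
    for t_i, trio in enumerate(trios):
        sampler = samp_case if trio.is_case else samp_base
        idxs = sampler.draw(rng, int(dnm_counts[t_i]))
        for idx in idxs:
            snv_event(
                builders[trio.family_id], int(idx), "dnm-snv",
                {"child": Genotype.HET, "mother": Genotype.HOM_REF, "father": Genotype.HOM_REF},
            )

    # --- de novo indels ----------------------------------------------------
    indel_counts = rng.poisson(config.mean_coding_indel_dnms_per_trio, size=n_trios)
    gene_p = gene_lengths / gene_lengths.sum()
    for t_i, trio in enumerate(trios):
        builder = builders[trio.family_id]
        for _ in range(int(indel_counts[t_i])):
            gi = int(rng.choice(gene_p.size, p=gene_p))
            gene = genes[space.symbols[gi]]
            frameshift = rng.random() < 0.75
            del_len = 1 if frameshift else 3
            cpos = int(rng.integers(0, gene.coding_length - del_len - 1))
            ref = gene.cds[cpos : cpos + del_len + 1]
            alt = gene.cds[cpos]
            chrom, pos = gene.chrom, gene.start + cpos
            key = f"{chrom}-{pos}-{ref}-{alt}"
            effect = "LoF" if frameshift else "inframe-indel"
            if not builder.add_site(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                genotypes={"child": Genotype.HET, "mother": Genotype.HOM_REF, "father": Genotype.HOM_REF},
            ):
                continue
            score = annotate(key, gene.symbol, effect)
            builder.events.append(
                dict(family_id=trio.family_id, kind="dnm-indel", variant_key=key,
                     chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene.symbol,
                     effect=effect, score=score, carrier_parent="",
                     parental_allele_fraction=np.nan, transmitted=np.nan,
                     qualifying_rule="", pair_id="")
            )

    # --- transmitted parental mosaics -------------------------------------
    mf = config.mosaic_fraction
    if mf > 0:
        mean_dn = config.mean_coding_snv_dnms_per_trio + config.mean_coding_indel_dnms_per_trio
        lam_mosaic = mf / (1.0 - mf) * mean_dn if mf < 1 else mean_dn
        mosaic_counts = rng.poisson(lam_mosaic, size=n_trios)
        for t_i, trio in enumerate(trios):
            idxs = samp_base.draw(rng, int(mosaic_counts[t_i]))
            for idx in idxs:
                parent = "mother" if rng.random() < 0.5 else "father"
                af = float(rng.uniform(0.03, 0.20))
                genotypes = {"child": Genotype.HET, "mother": Genotype.HOM_REF, "father": Genotype.HOM_REF}
                snv_event(
                    builders[trio.family_id], int(idx), "parental-mosaic", genotypes,
                    carrier_parent=parent, mosaic_af=af, transmitted=True,
                )

    # --- inherited heterozygous variants -----------------------------------
    qual_counts = rng.poisson(config.mean_qualifying_het_per_trio, size=n_trios)
    bg_counts = rng.poisson(config.mean_background_het_per_trio, size=n_trios)
    for t_i, trio in enumerate(trios):
        builder = builders[trio.family_id]
        for _ in range(int(qual_counts[t_i])):
            lof_rule = rng.random() < 0.5 and constrained_lof.size > 0
            if lof_rule:
                idx = int(constrained_lof[samp_lof.draw(rng, 1)[0]])
                rule, clinvar = "LoF-in-LOEUF<0.35", "none"
            else:
                idx = int(missense_idx[samp_mis.draw(rng, 1)[0]])
                rule = "ClinVar-pathogenic-missense"
                clinvar = "pathogenic" if rng.random() < 0.5 else "likely_pathogenic"
            parent = "mother" if rng.random() < 0.5 else "father"
            transmitted = bool(rng.random() < config.transmission_bias)
            genotypes = {
                "child": Genotype.HET if transmitted else Genotype.HOM_REF,
                "mother": Genotype.HET if parent == "mother" else Genotype.HOM_REF,
                "father": Genotype.HET if parent == "father" else Genotype.HOM_REF,
            }
            snv_event(builder, idx, "inherited-het", genotypes, clinvar=clinvar,
                      carrier_parent=parent, transmitted=transmitted, rule=rule)
        for _ in range(int(bg_counts[t_i])):
            idx = int(samp_base.draw(rng, 1)[0])
            parent = "mother" if rng.random() < 0.5 else "father"
            transmitted = bool(rng.random() < 0.5)
            genotypes = {
                "child": Genotype.HET if transmitted else Genotype.HOM_REF,
                "mother": Genotype.HET if parent == "mother" else Genotype.HOM_REF,
                "father": Genotype.HET if parent == "father" else Genotype.HOM_REF,
            }
            snv_event(builder, idx, "inherited-het", genotypes,
                      carrier_parent=parent, transmitted=transmitted)

    # --- biallelic (compound heterozygous) opportunities -------------------
    if constrained_lof.size >= 2:
        bi_counts = rng.poisson(config.mean_biallelic_opportunities_per_trio, size=n_trios)
        for t_i, trio in enumerate(trios):
            builder = builders[trio.family_id]
            for k in range(int(bi_counts[t_i])):
                cand_genes = np.unique(space.gene_idx[constrained_lof])
                gi = int(rng.choice(cand_genes))
                in_gene = constrained_lof[space.gene_idx[constrained_lof] == gi]
                if in_gene.size < 2:
                    continue
                i1, i2 = rng.choice(in_gene, size=2, replace=False)
                pair_id = f"{trio.family_id}-bi{k}"
                for idx, parent in ((int(i1), "mother"), (int(i2), "father")):
                    transmitted = bool(rng.random() < 0.5)
                    genotypes = {
                        "child": Genotype.HET if transmitted else Genotype.HOM_REF,
                        "mother": Genotype.HET if parent == "mother" else Genotype.HOM_REF,
                        "father": Genotype.HET if parent == "father" else Genotype.HOM_REF,
                    }
                    snv_event(builder, idx, "inherited-biallelic", genotypes,
                              carrier_parent=parent, transmitted=transmitted,
                              rule="LoF-in-LOEUF<0.35", pair_id=pair_id)

    # --- sequencing-noise candidate sites ----------------------------------
    if config.noise_sites_per_trio > 0:
        hom = {"child": Genotype.HOM_REF, "mother": Genotype.HOM_REF, "father": Genotype.HOM_REF}
        for trio in trios:
            builder = builders[trio.family_id]
            idxs = rng.integers(0, space.rate.size, size=config.noise_sites_per_trio)
            for idx in idxs:
                ref, alt = _snv_alleles(space, int(idx))
                chrom = str(space.chrom[idx])
                pos = int(space.gpos[idx])
                gene_sym = space.symbols[space.gene_idx[idx]]
                key = f"{chrom}-{pos}-{ref}-{alt}"
                if builder.add_site(chrom=chrom, pos=pos, ref=ref, alt=alt, genotypes=hom):
                    annotate(key, gene_sym, CLASS_NAMES[int(space.klass[idx])])

    records = {fam: b.render() for fam, b in builders.items()}
    truth = pd.DataFrame(
        [e for b in builders.values() for e in b.events], columns=TRUTH_COLUMNS
    )
    ann_frame = pd.DataFrame(sorted(annotations.values(), key=lambda d: d["variant_key"]))
    return Cohort(
        trios=trios, records=records, annotations=ann_frame, truth=truth,
        genes=genes, rate_table=rate_table, config=config,
    )


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write a cohort as per-trio VCFs + PED + annotation/truth/rate TSVs
    and a FASTA + TSV gene catalogue."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    for trio in cohort.trios:
        write_trio_vcf(vcf_dir / f"{trio.family_id}.vcf", cohort.records[trio.family_id], trio)
    write_ped(outdir / "cohort.ped", cohort.trios)
    write_annotations(outdir / "annotations.tsv", cohort.annotations)
    write_table(outdir / "truth.tsv", cohort.truth)
    write_rate_table(outdir / "rate_table.tsv", cohort.rate_table)
    with open(outdir / "genes.fasta", "w") as fh:
        for gene in cohort.genes.values():
            fh.write(f">{gene.symbol}\n{gene.cds}\n")
    write_table(
        outdir / "genes.tsv",
        pd.DataFrame(
            [dict(symbol=g.symbol, chrom=g.chrom, start=g.start, loeuf=g.loeuf)
             for g in cohort.genes.values()]
        ),
    )


def read_cohort(outdir: str | Path) -> Cohort:
    """Re-load a cohort written by :func:`write_cohort`."""
    outdir = Path(outdir)
    trios = read_ped(outdir / "cohort.ped")
    records = {
        t.family_id: read_trio_vcf(outdir / "vcf" / f"{t.family_id}.vcf", t) for t in trios
    }
    genes: dict[str, GeneModel] = {}
    index = read_table(outdir / "genes.tsv").set_index("symbol")
    for symbol, cds in _read_fasta(outdir / "genes.fasta"):
        row = index.loc[symbol]
        genes[symbol] = GeneModel(
            symbol=symbol, chrom=str(row["chrom"]), start=int(row["start"]),
            cds=cds, loeuf=float(row["loeuf"]),
        )
    truth = read_table(outdir / "truth.tsv")
    for col in ("qualifying_rule", "carrier_parent", "pair_id"):
        truth[col] = truth[col].fillna("")
    return Cohort(
        trios=trios, records=records,
        annotations=read_annotations(outdir / "annotations.tsv"),
        truth=truth,
        genes=genes, rate_table=read_rate_table(outdir / "rate_table.tsv"),
    )


def _read_fasta(path: Path) -> list[tuple[str, str]]:
    out: list[tuple[str, str]] = []
    name, chunks = None, []
    for line in path.read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                out.append((name, "".join(chunks)))
            name, chunks = line[1:].split()[0], []
        else:
            chunks.append(line.strip())
    if name is not None:
        out.append((name, "".join(chunks)))
    return out
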