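"""Readers and writers for the pipeline's standard formats.

Trio genotype data travel as multi-sample VCF 4.2 (FORMAT GT:AD:DP) plus a
6-column PED pedigree; gene sets, trimer rate tables, variant annotations,
truth tables and interaction networks are tab-delimited text with a header
row. The canonical variant identifier used as the join key across all files
is the "chrom-pos-ref-alt" string (1-based position).

VCF parsing goes through cyvcf2; multi-allelic sites are decomposed into one
biallelic record per alternate allele.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from cyvcf2 import VCF

from .rate_model import TrimerRateTable

EFFECTS = ("synonymous", "missense", "inframe-indel", "LoF")
#: protein-altering classes; "LoF" covers stop-gain, frameshift and splice
#: donor/acceptor annotations
NONSYNONYMOUS_EFFECTS = frozenset({"missense", "inframe-indel", "LoF"})
CLINVAR_LABELS = ("none", "pathogenic", "likely_pathogenic")
#: severity order used when annotations for one variant conflict
EFFECT_PRECEDENCE = {"LoF": 3, "missense": 2, "inframe-indel": 1, "synonymous": 0}


class Genotype(enum.Enum):
    HOM_REF = "hom-ref"
    HET = "het"
    HOM_ALT = "hom-alt"
    MISSING = "missing"

    @property
    def n_alt(self) -> int:
        return {"hom-ref": 0, "het": 1, "hom-alt": 2, "missing": 0}[self.value]


_GT_STRING = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


@dataclass(frozen=True)
class SampleCall:
    """Per-sample evidence at one site: genotype call and read support."""

    gt: Genotype
    ref_reads: int
    alt_reads: int
    depth: int

    def __post_init__(self) -> None:
        if self.ref_reads < 0 or self.alt_reads < 0 or self.depth < 0:
            raise ValueError("read counts must be non-negative")
        if self.ref_reads + self.alt_reads > self.depth:
            raise ValueError("ref + alt reads exceed total depth")

    @property
    def alt_fraction(self) -> float:
        """Allele balance: alt reads over informative (ref + alt) reads."""
        informative = self.ref_reads + self.alt_reads
        return self.alt_reads / informative if informative > 0 else 0.0


@dataclass(frozen=True)
class TrioVariantRecord:
    """One biallelic site in one trio."""

    chrom: str
    pos: int
    ref: str
    alt: str
    child: SampleCall
    mother: SampleCall
    father: SampleCall

    def __post_init__(self) -> None:
        if not self.alt or self.alt == self.ref:
            raise ValueError(f"invalid alt allele {self.alt!r} (ref {self.ref!r})")
        if self.pos < 1:
            raise ValueError("positions are 1-based")

    @property
    def variant_key(self) -> str:
        return f"{self.chrom}-{self.pos}-{self.ref}-{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class Trio:
    family_id: str
    child_id: str
    mother_id: str
    father_id: str
    is_case: bool = True


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate symbols")

    def __contains__(self, symbol: str) -> bool:
        return symbol in set(self.members)


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

def write_ped(path: str | Path, trios: Sequence[Trio]) -> None:
    lines = []
    for t in trios:
        pheno = "2" if t.is_case else "1"
        lines.append(f"{t.family_id}\t{t.father_id}\t0\t0\t1\t1")
        lines.append(f"{t.family_id}\t{t.mother_id}\t0\t0\t2\t1")
        lines.append(f"{t.family_id}\t{t.child_id}\t{t.father_id}\t{t.mother_id}\t0\t{pheno}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ped(path: str | Path) -> list[Trio]:
    """Parse a 6-column PED into trios (one child with both parents listed)."""
    rows: dict[str, list[list[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 6:
            raise ValueError(f"{path}:{lineno}: expected 6 PED columns, got {len(fields)}")
        rows.setdefault(fields[0], []).append(fields)
    trios = []
    for fam, members in rows.items():
        children = [m for m in members if m[2] != "0" and m[3] != "0"]
        if len(children) != 1:
            raise ValueError(f"family {fam}: expected exactly one offspring row")
        child = children[0]
        ids = {m[1] for m in members}
        if child[2] not in ids or child[3] not in ids:
            raise ValueError(f"family {fam}: parent ids not present as samples")
        trios.append(
            Trio(
                family_id=fam,
                child_id=child[1],
                father_id=child[2],
                mother_id=child[3],
                is_case=child[5] == "2",
            )
        )
    return trios


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{child}\t{mother}\t{father}
"""


def record_sort_key(rec: TrioVariantRecord) -> tuple:
    return (_chrom_order(rec.chrom), rec.pos, rec.alt)


def write_trio_vcf(path: str | Path, records: Iterable[TrioVariantRecord], trio: Trio) -> None:
    """Write one trio's sites as an uncompressed multi-sample VCF 4.2."""
    def fmt(call: SampleCall) -> str:
        return f"{_GT_STRING[call.gt]}:{call.ref_reads},{call.alt_reads}:{call.depth}"

    records = sorted(records, key=record_sort_key)
    contigs = "".join(
        f"##contig=<ID={c}>\n"
        for c in sorted({r.chrom for r in records}, key=_chrom_order)
    )
    lines = [
        _VCF_HEADER.format(
            contigs=contigs, child=trio.child_id,
            mother=trio.mother_id, father=trio.father_id,
        )
    ]
    for rec in records:
        lines.append(
            f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t.\tGT:AD:DP\t"
            f"{fmt(rec.child)}\t{fmt(rec.mother)}\t{fmt(rec.father)}\n"
        )
    Path(path).write_text("".join(lines))


def _chrom_order(chrom: str) -> tuple[int, str]:
    c = chrom.removeprefix("chr")
    return (int(c), "") if c.isdigit() else (99, c)


def _decode_gt(alleles: list[int], alt_index: int) -> Genotype:
    if any(a < 0 for a in alleles):
        return Genotype.MISSING
    n = sum(1 for a in alleles if a == alt_index)
    return (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)[n]


def read_trio_vcf(path: str | Path, trio: Trio) -> list[TrioVariantRecord]:
    """Read a trio VCF into biallelic records.

    Multi-allelic sites are decomposed: each alternate allele yields one
    record sharing chrom/pos; for that record any genotype allele other than
    the focal alt counts as reference, and per-allele depths come from the
    matching entries of the AD vector.
    """
    vcf = VCF(str(path))
    sample_pos = {s: i for i, s in enumerate(vcf.samples)}
    for sid in (trio.child_id, trio.mother_id, trio.father_id):
        if sid not in sample_pos:
            raise ValueError(f"sample {sid!r} missing from {path}")
    records: list[TrioVariantRecord] = []
    for var in vcf:
        ad = var.format("AD")
        dp = var.format("DP")
        for alt_i, alt in enumerate(var.ALT):
            calls = {}
            for member, sid in (
                ("child", trio.child_id),
                ("mother", trio.mother_id),
                ("father", trio.father_id),
            ):
                i = sample_pos[sid]
                alleles = var.genotypes[i][:-1]
                depth = int(dp[i][0]) if dp is not None else 0
                ref_reads = max(int(ad[i][0]), 0) if ad is not None else 0
                alt_reads = max(int(ad[i][alt_i + 1]), 0) if ad is not None else 0
                calls[member] = SampleCall(
                    gt=_decode_gt(alleles, alt_i + 1),
                    ref_reads=ref_reads,
                    alt_reads=alt_reads,
                    depth=max(depth, ref_reads + alt_reads),
                )
            records.append(
                TrioVariantRecord(
                    chrom=var.CHROM, pos=var.POS, ref=var.REF, alt=alt, **calls
                )
            )
    return records


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene list (optional 'gene' header).

    Duplicate symbols are collapsed: curated source lists routinely overlap
    (e.g. a gene implicated in both a cardiac and an epilepsy source set),
    so the union is deduplicated rather than rejected.
    """
    symbols: list[str] = []
    seen: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        sym = line.strip()
        if not sym or sym.startswith("#") or (lineno == 1 and sym.lower() == "gene"):
            continue
        if any(ch.isspace() for ch in sym):
            raise ValueError(f"{path}:{lineno}: gene symbol contains whitespace")
        if sym not in seen:
            seen.add(sym)
            symbols.append(sym)
    if not symbols:
        raise ValueError(f"{path}: empty gene set")
    return GeneSet(name=name or Path(path).stem, members=tuple(symbols))


def write_gene_set(path: str | Path, geneset: GeneSet) -> None:
    Path(path).write_text("gene\n" + "\n".join(geneset.members) + "\n")


# ---------------------------------------------------------------------------
# rate table / annotations / truth tables
# ---------------------------------------------------------------------------

def read_rate_table(path: str | Path) -> TrimerRateTable:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return TrimerRateTable.from_frame(frame)


def write_rate_table(path: str | Path, table: TrimerRateTable) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


ANNOTATION_COLUMNS = ["variant_key", "gene", "effect", "score", "clinvar", "loeuf"]


def validate_annotations(frame: pd.DataFrame, source: str = "annotations") -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{source}: missing columns {missing}")
    for i, row in enumerate(frame.itertuples(index=False), 2):  # 2 = first data line
        if row.effect not in EFFECTS:
            raise ValueError(f"{source}:{i}: unknown effect class {row.effect!r}")
        if row.clinvar not in CLINVAR_LABELS:
            raise ValueError(f"{source}:{i}: unknown ClinVar label {row.clinvar!r}")
        if not pd.isna(row.loeuf) and row.loeuf < 0:
            raise ValueError(f"{source}:{i}: LOEUF must be >= 0")
    return frame


def read_annotations(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"variant_key": str, "gene": str})
    return validate_annotations(frame, source=str(path))


def write_annotations(path: str | Path, frame: pd.DataFrame) -> None:
    validate_annotations(frame)[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# interaction network
# ---------------------------------------------------------------------------

def read_network(path: str | Path, nodes_path: str | Path | None = None) -> nx.Graph:
    """Read a TSV edge list (gene_a, gene_b[, channel]) into a simple graph.

    Self-loops are dropped and duplicate/reversed edges collapsed. An
    optional node file retains isolated genes that have no listed edge.
    """
    graph = nx.Graph()
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    if not lines:
        raise ValueError(f"{path}: empty network file")
    start = 1 if lines[0].lower().startswith(("gene_a", "gene1", "source")) else 0
    for lineno, line in enumerate(lines[start:], start + 1):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected at least 2 columns")
        a, b = fields[0].strip(), fields[1].strip()
        if a == b:
            graph.add_node(a)
            continue
        channel = fields[2].strip() if len(fields) > 2 else None
        graph.add_edge(a, b, channel=channel)
    if graph.number_of_nodes() == 0:
        raise ValueError(f"{path}: network has no nodes")
    if nodes_path is not None:
        for lineno, line in enumerate(Path(nodes_path).read_text().splitlines(), 1):
            sym = line.strip()
            if sym and not sym.startswith("#") and sym.lower() != "gene":
                graph.add_node(sym)
    return graph


def write_network(path: str | Path, graph: nx.Graph) -> None:
    lines = ["gene_a\tgene_b\tchannel"]
    for a, b, data in sorted(graph.edges(data=True)):
        lines.append(f"{a}\t{b}\t{data.get('channel') or ''}")
    Path(path).write_text("\n".join(lines) + "\n")
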