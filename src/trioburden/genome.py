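"""Gene models and coding-sequence substitution space.

A gene is represented by its spliced coding sequence (CDS) on the sense
strand, anchored at a genomic coordinate. The single-nucleotide substitution
space of a CDS of length L has exactly 9L/3 codpositions x 3 alternate bases
= 3L entries; every entry is classified against the standard genetic code as
synonymous, missense or loss-of-function (stop-gain). Stop-loss changes are
treated as missense for burden purposes.

A deterministic toy genome (a catalogue of random-sequence genes with
realistic coding-length spread and per-gene LOEUF constraint values) is
provided so the whole pipeline can run without any external reference data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# substitution effect classes
SYNONYMOUS = 0
MISSENSE = 1
LOF = 2

CLASS_NAMES = {SYNONYMOUS: "synonymous", MISSENSE: "missense", LOF: "LoF"}

_STOP = 20  # amino-acid code for a stop codon


def _codon_aa_array() -> np.ndarray:
    """(4,4,4) int array mapping codon base indices to an amino-acid code."""
    table = CodonTable.unambiguous_dna_by_id[1]
    aa_codes: dict[str, int] = {}
    arr = np.empty((4, 4, 4), dtype=np.int8)
    for i, a in enumerate(BASES):
        for j, b in enumerate(BASES):
            for k, c in enumerate(BASES):
                codon = a + b + c
                if codon in table.stop_codons:
                    arr[i, j, k] = _STOP
                else:
                    aa = table.forward_table[codon]
                    arr[i, j, k] = aa_codes.setdefault(aa, len(aa_codes))
    return arr


CODON_AA = _codon_aa_array()


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an ACGT string as int8 indices; raises on other characters."""
    idx = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(idx.shape, -1, dtype=np.int8)
    for base, i in BASE_INDEX.items():
        out[idx == ord(base)] = i
    if (out < 0).any():
        bad = seq[int(np.argmax(out < 0))]
        raise ValueError(f"non-ACGT base {bad!r} in coding sequence")
    return out


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene reduced to its CDS.

    Attributes
    ----------
    symbol : gene symbol used as join key everywhere.
    chrom, start : genomic anchor; coding base i (0-based in the CDS) sits
        at 1-based genomic position ``start + i``.
    cds : spliced coding sequence, sense strand, length a multiple of 3.
    loeuf : gnomAD-style LoF observed/expected upper bound fraction
        (lower = more LoF-intolerant); optional.
    """

    symbol: str
    chrom: str
    start: int
    cds: str
    loeuf: float | None = None

    def __post_init__(self) -> None:
        if len(self.cds) == 0:
            raise ValueError(f"{self.symbol}: empty coding sequence")
        if self.loeuf is not None and self.loeuf < 0:
            raise ValueError(f"{self.symbol}: LOEUF must be >= 0")

    @property
    def coding_length(self) -> int:
        return len(self.cds)

    def require_frame(self) -> None:
        if len(self.cds) % 3 != 0:
            raise ValueError(
                f"{self.symbol}: CDS length {len(self.cds)} is not a multiple of 3"
            )


def classify_substitutions(cds: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Enumerate and classify all 3L single-base substitutions of a CDS.

    Returns ``(pos, alt, klass)`` arrays of length 3L: 0-based CDS position,
    alternate base index, and effect class (SYNONYMOUS/MISSENSE/LOF).
    The reading frame is taken from the CDS start.
    """
    seq = encode_sequence(cds)
    L = seq.size
    if L % 3 != 0:
        raise ValueError(f"CDS length {L} is not a multiple of 3")
    codons = seq.reshape(-1, 3)
    aa_ref = CODON_AA[codons[:, 0], codons[:, 1], codons[:, 2]]

    pos_parts, alt_parts, cls_parts = [], [], []
    n_codons = L // 3
    codon_pos = 3 * np.arange(n_codons)
    for w in range(3):
        refw = codons[:, w]
        for delta in (1, 2, 3):
            altb = (refw + delta) % 4
            mutated = codons.copy()
            mutated[:, w] = altb
            aa_alt = CODON_AA[mutated[:, 0], mutated[:, 1], mutated[:, 2]]
            klass = np.where(
                aa_alt == aa_ref,
                SYNONYMOUS,
                np.where((aa_alt == _STOP) & (aa_ref != _STOP), LOF, MISSENSE),
            ).astype(np.int8)
            pos_parts.append(codon_pos + w)
            alt_parts.append(altb)
            cls_parts.append(klass)
    pos = np.concatenate(pos_parts)
    order = np.argsort(pos, kind="stable")
    return (
        pos[order].astype(np.int64),
        np.concatenate(alt_parts)[order].astype(np.int8),
        np.concatenate(cls_parts)[order],
    )


# ---------------------------------------------------------------------------
# toy genome
# ---------------------------------------------------------------------------

TOY_GENOME_SEED = 20210  # fixed: the toy genome is a constant catalogue
_GENE_SPACING = 100_000


def toy_genome(
    n_genes: int = 200,
    seed: int = TOY_GENOME_SEED,
    min_length: int = 300,
    max_length: int = 15_000,
) -> dict[str, GeneModel]:
    """Deterministic catalogue of random-sequence genes.

    Coding lengths are log-uniform on [min_length, max_length] and rounded to
    a multiple of 3, matching the heavy right tail of real coding-length
    distributions. Genes are laid out on chromosomes 1-22 with wide spacing
    so variant coordinates never collide between genes. Per-gene LOEUF values
    are uniform on [0.03, 2.0], so roughly one gene in six falls below the
    0.35 LoF-intolerance cutoff.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    genes: dict[str, GeneModel] = {}
    per_chrom: dict[str, int] = {}
    for i in range(n_genes):
        length = int(np.exp(rng.uniform(np.log(min_length), np.log(max_length))))
        length -= length % 3
        seq = "".join(BASES[b] for b in rng.integers(0, 4, size=length))
        chrom = str(i % 22 + 1)
        slot = per_chrom.get(chrom, 0)
        per_chrom[chrom] = slot + 1
        symbol = f"TG{i + 1:04d}"
        genes[symbol] = GeneModel(
            symbol=symbol,
            chrom=chrom,
            start=1_000_000 + slot * _GENE_SPACING,
            cds=seq,
            loeuf=round(float(rng.uniform(0.03, 2.0)), 3),
        )
    return genes


def select_gene_set(
    genes: dict[str, GeneModel], size: int, seed: int, name: str = "set"
) -> list[str]:
    """Reproducibly pick ``size`` distinct gene symbols from a catalogue."""
    symbols = sorted(genes)
    if size > len(symbols):
        raise ValueError(f"cannot pick {size} genes from {len(symbols)}")
    rng = np.random.default_rng(seed)
    return sorted(rng.choice(symbols, size=size, replace=False).tolist())
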