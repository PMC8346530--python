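"""Per-gene T2-A2 and GRAVY, and their per-genome correlation.

The amino-acid-level winner (A at the second codon position scoring -1, T
scoring +1, G/C scoring 0 against hydropathy) collapses, when aggregated
over all codons of a gene, to the difference between the relative
frequencies of T and A at the second codon position: T2-A2.  GRAVY (grand
average of hydropathy) is the arithmetic mean of the Kyte-Doolittle index
over the translated protein's residues.  Across the genes of a genome the
two are strongly correlated, typically more strongly than the underlying
20-amino-acid association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from scipy import stats

from .aa_tables import CodonTable, STANDARD_TABLE, load_property_scale, translate_cds

__all__ = [
    "GeneRecord",
    "GenomeSummary",
    "compute_gene_record",
    "genome_assoc",
    "gravy",
    "read_cds_fasta",
    "t2_a2",
    "write_gene_tsv",
    "write_summary_tsv",
]

_KD = load_property_scale("hydropathy index").values

#: Below this many genes the genome-level correlation is flagged unstable.
QUALITY_MIN_GENES = 500


@dataclass
class GeneRecord:
    """One CDS with its derived codon statistics."""

    id: str
    cds: str
    n_codons: int = 0
    t2_a2: float = float("nan")
    gravy: float = float("nan")
    protein: str = ""
    valid: bool = False
    reason: str = ""


@dataclass(frozen=True)
class GenomeSummary:
    """Pearson association of T2-A2 vs GRAVY across the genes of one genome."""

    genome: str
    n_genes: int
    r: float
    p: float
    n_invalid: int = 0


def read_cds_fasta(path: str | Path) -> list[GeneRecord]:
    """Read a nucleotide CDS FASTA (.ffn dialect) into gene-record stubs.

    IDs are the first whitespace-delimited header token; sequences are
    upper-cased with U normalized to T.  Metrics are left unset — pass the
    stubs through :func:`compute_gene_record`.
    """
    path = Path(path)
    records = [
        GeneRecord(id=rec.id, cds=str(rec.seq).upper().replace("U", "T"))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        warnings.warn(f"no FASTA records in {path}", stacklevel=2)
    return records


def _sense_codons(cds: str, table: CodonTable) -> list[str]:
    """Frame-0 codons after trailing-stop trim, N-containing codons skipped."""
    seq = cds.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} is not a multiple of 3")
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in table.stop_codons:
        codons = codons[:-1]
    return [c for c in codons if "N" not in c]


def t2_a2(cds: str, table: CodonTable = STANDARD_TABLE) -> float:
    """(count of T - count of A) at codon position 2, per sense codon.

    The trailing stop is trimmed and N-containing codons are skipped before
    counting; the denominator is the gene's usable codon count, so the value
    lies in [-1, 1].  Stop codons are included in the count only if internal
    (the caller's validity policy decides whether such genes survive).
    """
    codons = _sense_codons(cds, table)
    if not codons:
        raise ValueError("no usable codons")
    n_t = sum(1 for c in codons if c[1] == "T")
    n_a = sum(1 for c in codons if c[1] == "A")
    return (n_t - n_a) / len(codons)


def gravy(protein: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue.

    Residues outside the 20 standard letters (ambiguity codes, stops) are
    excluded from numerator and denominator alike, following the convention
    of the classic codon-analysis tools.
    """
    vals = [_KD[a] for a in protein.upper() if a in _KD]
    if not vals:
        raise ValueError("no standard residues in protein")
    return float(np.mean(vals))


def compute_gene_record(
    stub: GeneRecord,
    table: CodonTable = STANDARD_TABLE,
    internal_stop_policy: str = "drop",
) -> GeneRecord:
    """Fill in codon counts, T2-A2, translation and GRAVY for one stub.

    ``internal_stop_policy`` is ``"drop"`` (gene marked invalid) or
    ``"truncate"`` (analyse up to the first internal stop).  Frame errors
    and empty translations also invalidate the record; invalid records carry
    a ``reason`` and NaN metrics.
    """
    if internal_stop_policy not in ("drop", "truncate"):
        raise ValueError(f"bad internal_stop_policy: {internal_stop_policy!r}")
    rec = GeneRecord(id=stub.id, cds=stub.cds)
    try:
        trans = translate_cds(stub.cds, table=table, on_internal_stop="truncate")
    except ValueError as exc:
        rec.reason = str(exc)
        return rec
    if trans.internal_stop and internal_stop_policy == "drop":
        rec.reason = "internal stop codon"
        return rec
    cds = stub.cds
    if trans.internal_stop:  # truncate: re-derive the analysed prefix
        seq = cds.upper().replace("U", "T")
        codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
        prefix = []
        for c in codons:
            if "N" not in c and c in table.stop_codons:
                break
            prefix.append(c)
        cds = "".join(prefix)
    try:
        codons = _sense_codons(cds, table)
        if not codons:
            raise ValueError("no usable codons")
        rec.n_codons = len(codons)
        rec.t2_a2 = t2_a2(cds, table)
        rec.protein = trans.protein
        rec.gravy = gravy(trans.protein)
    except ValueError as exc:
        rec.reason = str(exc)
        return rec
    rec.valid = True
    return rec


def genome_assoc(
    genes: Sequence[GeneRecord],
    genome: str = "genome",
    min_genes: int = 3,
) -> GenomeSummary:
    """Pearson correlation of T2-A2 vs GRAVY across a genome's genes.

    Invalid genes are excluded and counted.  Raises ``ValueError`` below
    ``min_genes`` valid genes; warns (without failing) below 500 genes,
    where the genome-level correlation becomes unstable.  Zero variance in
    either variable yields NaN r/p with a warning.
    """
    valid = [g for g in genes if g.valid]
    n_invalid = len(genes) - len(valid)
    if len(valid) < min_genes:
        raise ValueError(
            f"{len(valid)} valid genes < min_genes={min_genes} for {genome!r}"
        )
    if len(valid) < QUALITY_MIN_GENES:
        warnings.warn(
            f"{genome!r}: only {len(valid)} genes; genome-level r is "
            f"unstable below {QUALITY_MIN_GENES}",
            stacklevel=2,
        )
    x = np.array([g.t2_a2 for g in valid])
    y = np.array([g.gravy for g in valid])
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        warnings.warn(f"{genome!r}: zero variance; correlation undefined", stacklevel=2)
        return GenomeSummary(genome, len(valid), float("nan"), float("nan"), n_invalid)
    r, p = stats.pearsonr(x, y)
    return GenomeSummary(genome, len(valid), float(r), float(p), n_invalid)


def write_gene_tsv(genes: Iterable[GeneRecord], path: str | Path) -> None:
    lines = ["id\tn_codons\tt2_a2\tgravy\tvalid\treason"]
    for g in genes:
        lines.append(
            f"{g.id}\t{g.n_codons}\t{g.t2_a2!r}\t{g.gravy!r}\t{int(g.valid)}\t{g.reason}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_summary_tsv(summaries: Iterable[GenomeSummary], path: str | Path) -> None:
    lines = ["genome\tn_genes\tr\tp\tn_invalid"]
    for s in summaries:
        lines.append(f"{s.genome}\t{s.n_genes}\t{s.r!r}\t{s.p!r}\t{s.n_invalid}")
    Path(path).write_text("\n".join(lines) + "\n")
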