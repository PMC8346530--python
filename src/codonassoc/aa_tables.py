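"""Genetic-code and amino-acid property-scale constants, plus CDS translation.

The genetic code is the standard code (NCBI translation table 1), taken from
Biopython and frozen into a :class:`CodonTable` with the 61 sense codons and
the three stops (TAA, TAG, TGA).  Thirteen physicochemical property scales —
one numeric value per standard amino acid — are bundled as versioned
constants with a source citation each; they are never fetched at run time.
Users can export any scale to a two-column TSV, edit or replace it, and read
it back to run the same association analysis on a custom property.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "AMINO_ACIDS",
    "NUCLEOTIDES",
    "CodonTable",
    "PropertyScale",
    "PROPERTY_NAMES",
    "STANDARD_TABLE",
    "TranslationResult",
    "load_property_scale",
    "read_scale_tsv",
    "standardize",
    "translate_cds",
    "write_scale_tsv",
]

NUCLEOTIDES = ("A", "C", "G", "T")

#: The 20 standard amino acids, alphabetical by one-letter code.
AMINO_ACIDS = tuple(sorted("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class CodonTable:
    """The sense-codon -> amino-acid map of one genetic code.

    Only the 61 sense codons appear in ``codon_to_aa``; stop codons are kept
    separately and are excluded from every association statistic.
    """

    codon_to_aa: Mapping[str, str]
    stop_codons: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) + len(self.stop_codons) != 64:
            raise ValueError("codon table must cover all 64 codons")
        if set(self.codon_to_aa.values()) != set(AMINO_ACIDS):
            raise ValueError("codon table must encode all 20 standard amino acids")

    def codons_for(self, aa: str) -> tuple[str, ...]:
        """Synonymous sense codons of one amino acid, in lexicographic order."""
        if aa not in set(AMINO_ACIDS):
            raise KeyError(f"not a standard amino acid: {aa!r}")
        return tuple(sorted(c for c, a in self.codon_to_aa.items() if a == aa))


STANDARD_TABLE = CodonTable(
    codon_to_aa=dict(standard_dna_table.forward_table),
    stop_codons=frozenset(standard_dna_table.stop_codons),
)


# ---------------------------------------------------------------------------
# Property scales
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PropertyScale:
    """One named physicochemical property with a value per amino acid."""

    name: str
    values: Mapping[str, float]
    source: str

    def __post_init__(self) -> None:
        if set(self.values) != set(AMINO_ACIDS):
            missing = set(AMINO_ACIDS) - set(self.values)
            extra = set(self.values) - set(AMINO_ACIDS)
            raise ValueError(
                f"scale {self.name!r} must cover exactly the 20 standard amino "
                f"acids (missing={sorted(missing)}, extra={sorted(extra)})"
            )
        if not all(math.isfinite(v) for v in self.values.values()):
            raise ValueError(f"scale {self.name!r} contains non-finite values")

    def vector(self, order: Iterable[str] = AMINO_ACIDS) -> list[float]:
        return [float(self.values[a]) for a in order]


def _scale(name: str, source: str, **values: float) -> PropertyScale:
    return PropertyScale(name=name, values=dict(values), source=source)


_SCALES: dict[str, PropertyScale] = {}

_SCALES["hydropathy index"] = _scale(
    "hydropathy index",
    "Kyte & Doolittle (1982) J Mol Biol 157:105-132",
    A=1.8, R=-4.5, N=-3.5, D=-3.5, C=2.5, Q=-3.5, E=-3.5, G=-0.4, H=-3.2,
    I=4.5, L=3.8, K=-3.9, M=1.9, F=2.8, P=-1.6, S=-0.8, T=-0.7, W=-0.9,
    Y=-1.3, V=4.2,
)

_SCALES["polarity"] = _scale(
    "polarity",
    "Grantham (1974) Science 185:862-864, polarity p",
    A=8.1, R=10.5, N=11.6, D=13.0, C=5.5, Q=10.5, E=12.3, G=9.0, H=10.4,
    I=5.2, L=4.9, K=11.3, M=5.7, F=5.2, P=8.0, S=9.2, T=8.6, W=5.4, Y=6.2,
    V=5.9,
)

_SCALES["molecular weight"] = _scale(
    "molecular weight",
    "Fasman (1976) Handbook of Biochemistry and Molecular Biology, residue MW (Da)",
    A=89.09, R=174.20, N=132.12, D=133.10, C=121.16, Q=146.15, E=147.13,
    G=75.07, H=155.16, I=131.17, L=131.17, K=146.19, M=149.21, F=165.19,
    P=115.13, S=105.09, T=119.12, W=204.23, Y=181.19, V=117.15,
)

_SCALES["melting point"] = _scale(
    "melting point",
    "Fasman (1976) Handbook of Biochemistry and Molecular Biology, melting point (deg C)",
    A=297.0, R=238.0, N=236.0, D=270.0, C=178.0, Q=185.0, E=249.0, G=290.0,
    H=277.0, I=284.0, L=337.0, K=224.0, M=283.0, F=284.0, P=222.0, S=228.0,
    T=253.0, W=282.0, Y=344.0, V=293.0,
)

_SCALES["isoelectric point"] = _scale(
    "isoelectric point",
    "Zimmerman, Eliezer & Simha (1968) J Theor Biol 21:170-201, pI",
    A=6.00, R=10.76, N=5.41, D=2.77, C=5.05, Q=5.65, E=3.22, G=5.97, H=7.59,
    I=6.02, L=5.98, K=9.74, M=5.74, F=5.48, P=6.30, S=5.68, T=5.66, W=5.89,
    Y=5.66, V=5.96,
)

_SCALES["chemical composition of the side chain"] = _scale(
    "chemical composition of the side chain",
    "Grantham (1974) Science 185:862-864, composition c "
    "(atomic weight ratio of non-carbon elements to carbons in the side chain)",
    A=0.0, R=0.65, N=1.33, D=1.38, C=2.75, Q=0.89, E=0.92, G=0.74, H=0.58,
    I=0.0, L=0.0, K=0.33, M=0.0, F=0.0, P=0.39, S=1.42, T=0.71, W=0.13,
    Y=0.20, V=0.0,
)

_SCALES["molecular volume"] = _scale(
    "molecular volume",
    "Grantham (1974) Science 185:862-864, molecular volume V",
    A=31.0, R=124.0, N=56.0, D=54.0, C=55.0, Q=85.0, E=83.0, G=3.0, H=96.0,
    I=111.0, L=111.0, K=119.0, M=105.0, F=132.0, P=32.5, S=32.0, T=61.0,
    W=170.0, Y=136.0, V=84.0,
)

_SCALES["refractivity"] = _scale(
    "refractivity",
    "Jones (1975) J Theor Biol 50:167-183, refractivity",
    A=4.34, R=26.66, N=13.28, D=12.00, C=35.77, Q=17.56, E=17.26, G=0.00,
    H=21.81, I=19.06, L=18.78, K=21.29, M=21.64, F=29.40, P=10.93, S=6.35,
    T=11.01, W=42.53, Y=31.53, V=13.92,
)

_SCALES["aromaticity"] = _scale(
    "aromaticity",
    "Sneath (1966) J Theor Biol 12:157-195, aromaticity",
    A=-0.110, R=0.079, N=-0.136, D=-0.285, C=-0.184, Q=-0.067, E=-0.246,
    G=-0.073, H=0.320, I=0.001, L=-0.008, K=0.049, M=-0.041, F=0.438,
    P=-0.016, S=-0.153, T=-0.208, W=0.493, Y=0.381, V=-0.155,
)

_SCALES["aliphaticity"] = _scale(
    "aliphaticity",
    "Sneath (1966) J Theor Biol 12:157-195, aliphaticity",
    A=0.239, R=0.211, N=0.249, D=0.171, C=0.220, Q=0.260, E=0.187, G=0.160,
    H=0.205, I=0.273, L=0.281, K=0.228, M=0.253, F=0.234, P=0.165, S=0.236,
    T=0.213, W=0.183, Y=0.193, V=0.255,
)

_SCALES["hydrogenation"] = _scale(
    "hydrogenation",
    "Sneath (1966) J Theor Biol 12:157-195, hydrogenation",
    A=0.330, R=-0.176, N=-0.233, D=-0.371, C=0.074, Q=-0.254, E=-0.409,
    G=0.370, H=-0.078, I=0.149, L=0.129, K=0.118, M=-0.092, F=-0.011,
    P=0.370, S=0.022, T=0.136, W=-0.011, Y=-0.138, V=0.245,
)

_SCALES["hydroxythiolation"] = _scale(
    "hydroxythiolation",
    "Sneath (1966) J Theor Biol 12:157-195, hydroxythiolation",
    A=-0.062, R=-0.167, N=0.166, D=-0.079, C=0.380, Q=-0.025, E=-0.184,
    G=-0.017, H=0.056, I=-0.309, L=-0.264, K=-0.371, M=0.077, F=-0.287,
    P=-0.036, S=0.470, T=0.348, W=-0.270, Y=0.220, V=-0.212,
)

_SCALES["polar requirement"] = _scale(
    "polar requirement",
    "Woese et al. (1966) Cold Spring Harb Symp Quant Biol 31:723-736, polar requirement",
    A=7.0, R=9.1, N=10.0, D=13.0, C=4.8, Q=8.6, E=12.5, G=7.9, H=8.4, I=4.9,
    L=4.9, K=10.1, M=5.3, F=5.0, P=6.6, S=7.5, T=6.6, W=5.2, Y=5.4, V=5.6,
)

#: The 13 bundled property names, in a stable, documented order.
PROPERTY_NAMES = (
    "molecular weight",
    "melting point",
    "isoelectric point",
    "hydropathy index",
    "chemical composition of the side chain",
    "molecular volume",
    "polarity",
    "refractivity",
    "aromaticity",
    "aliphaticity",
    "hydrogenation",
    "hydroxythiolation",
    "polar requirement",
)

assert set(PROPERTY_NAMES) == set(_SCALES)


def load_property_scale(name: str) -> PropertyScale:
    """Return one of the 13 bundled property scales by name.

    Raises ``KeyError`` listing the valid names for an unknown property.
    """
    try:
        return _SCALES[name]
    except KeyError:
        raise KeyError(
            f"unknown property {name!r}; valid names: {', '.join(PROPERTY_NAMES)}"
        ) from None


def standardize(scale: PropertyScale) -> PropertyScale:
    """Z-standardize a scale (mean 0, sd 1 over the 20 amino acids).

    Pearson correlation is invariant under this affine rescaling; the helper
    exists so that tests and plots can put heterogeneous scales on one axis.
    """
    vals = scale.vector()
    mean = sum(vals) / len(vals)
    var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
    sd = math.sqrt(var)
    if sd == 0:
        raise ValueError(f"scale {scale.name!r} is constant; cannot standardize")
    return PropertyScale(
        name=scale.name,
        values={a: (scale.values[a] - mean) / sd for a in AMINO_ACIDS},
        source=scale.source + " (z-standardized)",
    )


def write_scale_tsv(scale: PropertyScale, path: str | Path) -> None:
    """Write a scale as a two-column TSV (amino-acid letter, value)."""
    lines = [f"{a}\t{scale.values[a]!r}" for a in AMINO_ACIDS]
    Path(path).write_text("\n".join(lines) + "\n")


def read_scale_tsv(path: str | Path, name: str | None = None,
                   source: str = "user-supplied TSV") -> PropertyScale:
    """Read a two-column TSV into a :class:`PropertyScale`.

    Lines starting with ``#`` are ignored.  The file must cover exactly the
    20 standard amino acids.
    """
    path = Path(path)
    values: dict[str, float] = {}
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{i}: expected 2 tab-separated fields")
        aa, val = parts
        if aa in values:
            raise ValueError(f"{path}:{i}: duplicate amino acid {aa!r}")
        values[aa] = float(val)
    return PropertyScale(name=name or path.stem, values=values, source=source)


# ---------------------------------------------------------------------------
# CDS translation
# ---------------------------------------------------------------------------

@dataclass
class TranslationResult:
    """Protein translation of a frame-0 CDS with bookkeeping.

    ``skipped_codons`` counts codons containing N (excluded from the protein
    entirely, numerator and denominator alike).  ``internal_stop`` marks a
    premature stop; whether that invalidates or truncates the record is the
    caller's policy.
    """

    protein: str
    skipped_codons: int = 0
    internal_stop: bool = False
    trimmed_stop: bool = False


def translate_cds(
    cds: str,
    table: CodonTable = STANDARD_TABLE,
    on_internal_stop: str = "flag",
) -> TranslationResult:
    """Translate a frame-0 coding sequence to amino acids.

    A single terminal stop codon is trimmed silently; codons containing N
    yield no residue but are counted as skipped.  ``on_internal_stop`` is
    ``"flag"`` (translate through, mark the result), ``"truncate"`` (stop at
    the first internal stop) or ``"error"``.

    Raises ``ValueError`` for a length not divisible by 3 or characters
    outside ``{A, C, G, T, N}``.
    """
    if on_internal_stop not in ("flag", "truncate", "error"):
        raise ValueError(f"bad on_internal_stop: {on_internal_stop!r}")
    seq = cds.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} is not a multiple of 3")
    if set(seq) - {"A", "C", "G", "T", "N"}:
        bad = sorted(set(seq) - {"A", "C", "G", "T", "N"})
        raise ValueError(f"CDS contains non-nucleotide characters: {bad}")
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    trimmed = False
    if codons and codons[-1] in table.stop_codons:
        codons = codons[:-1]
        trimmed = True
    residues: list[str] = []
    skipped = 0
    internal_stop = False
    for codon in codons:
        if "N" in codon:
            skipped += 1
            continue
        if codon in table.stop_codons:
            internal_stop = True
            if on_internal_stop == "error":
                raise ValueError(f"internal stop codon {codon}")
            if on_internal_stop == "truncate":
                break
            continue
        residues.append(table.codon_to_aa[codon])
    return TranslationResult(
        protein="".join(residues),
        skipped_codons=skipped,
        internal_stop=internal_stop,
        trimmed_stop=trimmed,
    )
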