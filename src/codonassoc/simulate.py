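"""Synthetic CDS, annotation and location fixtures with tunable codon bias.

Genes are sampled codon-by-codon from the 61 sense codons, so every output
sequence is a valid frame-0 CDS (ATG start, single terminal stop, no
internal stops).  A per-gene bias parameter beta in [-1, 1] tilts the
second-position nucleotide distribution: beta = -1 forces A at every second
position, +1 forces T, 0 leaves all four positions uniform.  Given the
second-position nucleotide, the codon is drawn uniformly from the sense
codons carrying it, so the bias acts on the one axis the downstream
statistics measure.

A configurable fraction of genes is labelled informational and receives a
negative shift delta on beta (A2-enrichment), reproducing the qualitative
regime in which informational genes are more hydrophilic; location labels
correlate with the super-class with stated probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .aa_tables import CodonTable, STANDARD_TABLE

__all__ = ["SimulationConfig", "SimulatedGenome", "simulate_genome", "write_genome"]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic genome generator.

    Gene lengths (in codons, excluding start and stop) are drawn from a
    normal with the given mean, clipped to [min, max] and rounded.  Per-gene
    beta is uniform on [-beta_range, beta_range]; informational genes get
    beta + delta_informational (clipped back to [-1, 1]).
    """

    n_genes: int = 1000
    length_min: int = 50
    length_mean: float = 300.0
    length_max: int = 1000
    beta_range: float = 0.8
    beta_fixed: float | None = None  # overrides the uniform draw when set
    fraction_informational: float = 0.2
    delta_informational: float = -0.3
    p_cytoplasmic_informational: float = 0.984
    p_cytoplasmic_operational: float = 0.755
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not (10 <= self.length_min <= self.length_mean <= self.length_max):
            raise ValueError("need 10 <= length_min <= length_mean <= length_max")
        if not 0.0 <= self.fraction_informational <= 1.0:
            raise ValueError("fraction_informational must lie in [0, 1]")
        if not 0.0 <= self.beta_range <= 1.0:
            raise ValueError("beta_range must lie in [0, 1]")
        if self.beta_fixed is not None and not -1.0 <= self.beta_fixed <= 1.0:
            raise ValueError("beta_fixed must lie in [-1, 1]")
        if not -2.0 <= self.delta_informational <= 0.0:
            raise ValueError("delta_informational must be <= 0")
        for p in (self.p_cytoplasmic_informational, self.p_cytoplasmic_operational):
            if not 0.0 <= p <= 1.0:
                raise ValueError("location probabilities must lie in [0, 1]")


@dataclass
class SimulatedGenome:
    """In-memory result of one simulation run."""

    config: SimulationConfig
    ids: list[str]
    sequences: list[str]
    super_classes: list[str]  # informational | operational, per gene
    betas: list[float]
    locations: list[str]  # cytoplasmic | cytoplasmic membrane

    def fasta_text(self) -> str:
        chunks = []
        for gid, seq in zip(self.ids, self.sequences):
            body = "\n".join(seq[i:i + 60] for i in range(0, len(seq), 60))
            chunks.append(f">{gid} synthetic CDS\n{body}")
        return "\n".join(chunks) + "\n"

    def annotation_text(self) -> str:
        # NCBI-ish dialect: protein_id, cog_id, letters, description
        lines = []
        for i, (gid, sc) in enumerate(zip(self.ids, self.super_classes)):
            letter = "J" if sc == "informational" else "E"
            lines.append(f"{gid}\tCOG{i:04d}\t{letter}\tsynthetic {sc} gene")
        return "\n".join(lines) + "\n"

    def location_text(self) -> str:
        lines = [f"{gid}\t{loc}" for gid, loc in zip(self.ids, self.locations)]
        return "\n".join(lines) + "\n"


def _second_position_probs(beta: float) -> np.ndarray:
    """P(A, C, G, T at codon position 2) under bias beta.

    Linear interpolation between the uniform distribution (beta = 0) and the
    degenerate all-T (beta = +1) or all-A (beta = -1) distribution.
    """
    base = np.full(4, 0.25)
    if beta >= 0:
        target = np.array([0.0, 0.0, 0.0, 1.0])  # T
        return (1 - beta) * base + beta * target
    target = np.array([1.0, 0.0, 0.0, 0.0])  # A
    return (1 + beta) * base + (-beta) * target


def simulate_genome(
    config: SimulationConfig, table: CodonTable = STANDARD_TABLE
) -> SimulatedGenome:
    """Generate one synthetic genome; deterministic for a fixed config+seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    nucs = "ACGT"
    codons_by_n2 = {
        n: sorted(c for c in table.codon_to_aa if c[1] == n) for n in nucs
    }
    sd = max(config.length_mean / 4.0, 1.0)
    lengths = np.clip(
        np.rint(rng.normal(config.length_mean, sd, size=config.n_genes)),
        config.length_min,
        config.length_max,
    ).astype(int)
    n_info = int(round(config.fraction_informational * config.n_genes))
    info_mask = np.zeros(config.n_genes, dtype=bool)
    info_mask[rng.choice(config.n_genes, size=n_info, replace=False)] = True
    if config.beta_fixed is not None:
        betas = np.full(config.n_genes, config.beta_fixed)
    else:
        betas = rng.uniform(-config.beta_range, config.beta_range, config.n_genes)
    betas = np.clip(betas + np.where(info_mask, config.delta_informational, 0.0), -1, 1)

    ids, seqs, classes, locs = [], [], [], []
    stop_codons = sorted(table.stop_codons)
    for i in range(config.n_genes):
        L = lengths[i]
        probs = _second_position_probs(float(betas[i]))
        n2_idx = rng.choice(4, size=L, p=probs)
        codon_list = []
        for idx in n2_idx:
            pool = codons_by_n2[nucs[idx]]
            codon_list.append(pool[rng.integers(len(pool))])
        stop = stop_codons[rng.integers(len(stop_codons))]
        seqs.append("ATG" + "".join(codon_list) + stop)
        ids.append(f"gene{i:05d}")
        is_info = bool(info_mask[i])
        classes.append("informational" if is_info else "operational")
        p_cyto = (
            config.p_cytoplasmic_informational
            if is_info
            else config.p_cytoplasmic_operational
        )
        locs.append(
            "cytoplasmic" if rng.random() < p_cyto else "cytoplasmic membrane"
        )
    return SimulatedGenome(
        config=config,
        ids=ids,
        sequences=seqs,
        super_classes=classes,
        betas=[float(b) for b in betas],
        locations=locs,
    )


def write_genome(
    genome: SimulatedGenome, out_dir: str | Path, prefix: str = "synthetic"
) -> dict[str, Path]:
    """Write FASTA + annotation + location tables; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cds": out_dir / f"{prefix}.ffn",
        "annotation": out_dir / f"{prefix}.cog.tsv",
        "location": out_dir / f"{prefix}.loc.tsv",
    }
    paths["cds"].write_text(genome.fasta_text())
    paths["annotation"].write_text(genome.annotation_text())
    paths["location"].write_text(genome.location_text())
    return paths
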