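# codonassoc

Quantitative analysis of how nucleotide identity at each codon position
associates with physicochemical properties of the encoded amino acids —
and how that association propagates from single codons to whole genes and
to protein functional classes.

The package is for sequence analysts studying genetic-code structure and
genome-scale codon composition. It provides:

1. **An exhaustive association catalogue.** The four nucleotides at one
   codon position are partitioned into 2–4 groups with numeric values per
   group (value sets {−1,+1}, {−1,0,+1}, {−2,−1,+1,+2}); there are exactly
   74 such assignments per position (24 four-group + 36 three-group +
   8 two-group 1v3 + 6 two-group 2v2). Each amino acid gets a position
   value — the mean assignment value over its sense codons — and the
   association with a property scale is the Pearson correlation over the
   20 amino acids (two-sided p, t distribution, 18 df). Over 3 positions
   and 13 bundled property scales the catalogue holds 74 × 3 × 13 = 2886
   records; a summary keeps the strongest association per (property,
   position) cell (39 records). The headline cell is hydropathy at the
   second codon position under A:−1 / T:+1 / G,C:0, with r = 0.864.

2. **Gene-level metrics.** Per gene, T₂−A₂ — the difference between the
   relative frequencies of T and A at the second codon position — and
   GRAVY, the grand average of Kyte–Doolittle hydropathy over the
   translated protein. Per genome, the Pearson correlation of the two
   across genes, which amplifies the amino-acid-level association.

3. **Functional super-class comparisons.** Genes split by COG/KOG letters
   into informational (A, B, J, K, L) vs operational (the rest);
   group differences in GRAVY and T₂−A₂ tested with the unpaired Student
   t-test, subcellular-location contrasts with a 2×2 chi-square.

4. **A synthetic genome generator** producing valid CDS FASTA, annotation
   and location tables with a controllable second-position bias per gene,
   so the entire pipeline is testable without any downloads.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

```python
from codonassoc import (SimulationConfig, simulate_genome, GeneRecord,
                        compute_gene_record, genome_assoc, pearson_assoc,
                        load_property_scale)
from codonassoc.catalogue import parse_assignment_string

# amino-acid level: the strongest single-position association
rec = pearson_assoc(parse_assignment_string("A:-1,T:1,GC:0", position=2),
                    load_property_scale("hydropathy index"))
print(f"position 2, A:-1/T:+1/GC:0 vs hydropathy: "
      f"r = {rec.r:.3f}, p = {rec.p:.2e}, n = {rec.n}")

# gene level: the association amplifies across a (synthetic) genome
genome = simulate_genome(SimulationConfig(n_genes=1000, seed=7))
genes = [compute_gene_record(GeneRecord(id=g, cds=s))
         for g, s in zip(genome.ids, genome.sequences)]
summary = genome_assoc(genes, genome="synthetic-7")
print(f"{summary.genome}: n_genes = {summary.n_genes}, "
      f"r(T2-A2, GRAVY) = {summary.r:.3f}, p = {summary.p:.3g}")
```

prints

```
position 2, A:-1/T:+1/GC:0 vs hydropathy: r = 0.864, p = 9.42e-07, n = 20
synthetic-7: n_genes = 1000, r(T2-A2, GRAVY) = 0.993, p = 0
```

The first line is the amino-acid-level association: amino acids with A in
the middle codon position are the most hydrophilic, those with T the most
hydrophobic, G/C intermediate — r = 0.864 over the 20 amino acids. The
second line shows the same signal aggregated per gene across a 1000-gene
synthetic genome: the correlation between T₂−A₂ frequency and GRAVY rises
well above the amino-acid-level value (a population effect of averaging
many codons per gene; p underflows to 0 at double precision).

## Command line

```sh
codonassoc catalogue --out-dir out/            # 2886-row catalogue + 39-row summary
codonassoc simulate  --out-dir out/ --seed 7   # synthetic .ffn + COG + location tables
codonassoc genome    out/synthetic.ffn --out-dir out/
codonassoc compare   --cds out/synthetic.ffn \
                     --annotation out/synthetic.cog.tsv \
                     --location out/synthetic.loc.tsv --out-dir out/
```

Every subcommand writes TSV outputs plus a JSON manifest sidecar
(inputs, parameters, version, seed) so runs are traceable and repeatable.

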