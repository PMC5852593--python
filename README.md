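# tfssr

A toolkit for developing **transcription-factor gene SSR markers (TFSSRs)**
from assembled plant transcriptomes and analysing the resulting codominant
genotype data — built around the marker-development workflow used for
*Lilium* (lily) germplasm characterisation.

Simple sequence repeats (SSRs, microsatellites) inside transcripts that
encode transcription factors make attractive markers: they are length-
polymorphic, codominant, transferable across related taxa, and sit in genes
that often drive stress responses. `tfssr` covers the whole desk side of
that workflow:

1. **Mine** perfect 2–6 bp microsatellite tracts (≥ 12 nt by default) from a
   transcriptome FASTA and classify them — Class I (≥ 20 nt) vs
   Class II (12–19 nt), AT-rich / GC-rich / AT/GC-balanced motifs.
2. **Annotate**: restrict SSR-bearing transcripts to TF candidates using
   homology hits against a plant TF protein database
   (E ≤ 10⁻¹⁰, query coverage ≥ 65 %, identity ≥ 40 %) and assign TF
   families.
3. **Design primers** flanking each tract with a native Primer3-default-style
   enumerator and penalty scorer (nearest-neighbour Tm, GC, 3′
   self-complementarity, 100–300 bp products).
4. **Genotype statistics** on fragment-size tables: allele frequencies,
   Ho/He, Shannon *I*, PIC, pairwise F_ST (Weir–Cockerham θ and Nei G_ST),
   two-level AMOVA with Φ_PT, allele-sharing distances, neighbour-joining
   trees, PCoA, a Bayesian clustering Gibbs sampler, and Evanno's ΔK.
5. **Expression tagging** of marker-associated genes from FPKM time courses
   (log₂ fold change, UP/DOWN/FLAT calls, Venn-style time-course partitions,
   hierarchical clustering for heat maps).
6. **Synthetic data** generators with exact ground truth for every input, so
   the full pipeline is testable offline.

## Core statistics

For allele frequencies *p₁ … p_k* at a locus:

- expected heterozygosity  He = 1 − Σ pᵢ²
- polymorphism information content (PowerMarker form)
  PIC = 1 − Σ pᵢ² − Σ_{i<j} 2 pᵢ² pⱼ²
- Shannon information index  I = −Σ pᵢ ln pᵢ
- Weir–Cockerham θ from the a/b/c variance components summed over alleles
  and loci; Nei G_ST = (H_T − H_S)/H_T averaged over loci
- AMOVA partitions Σ d²/n of individual allele-sharing distances into
  among/within-population strata; Φ_PT = σ²_among / σ²_total
- Evanno ΔK(K) = mean(|L(K+1) − 2L(K) + L(K−1)|) / sd(L(K)) over
  independent clustering runs, maximised at the supported number of
  populations

## Worked example

```python
from tfssr.io_formats import SequenceRecord
from tfssr.ssr_mining import find_ssrs
from tfssr.primer_design import design_primers, PrimerConstraints
from tfssr import marker_stats as ms

rec = SequenceRecord("unigene_00042",
    "ATGGCTGACCGTTGTAGCTGACCATTGGCAGCTACGAGTCCAGTGGCTTCAAGGTACGTT"
    "GGCGGCGGCGGCGGC"
    "TACGATCCGGATTCAAGCTGGATCGATTACGCCGCTTGGATCCGTTAGCCTTAGCGGATC")
locus = find_ssrs(rec)[0]
print(locus.motif, locus.n_repeats, locus.tract_length_nt,
      locus.length_class.value, locus.composition.value)

pair = design_primers(rec, locus, PrimerConstraints(
    tm_min=45, tm_opt=52, tm_max=62,
    product_size_min=80, product_size_max=135,
    primer_len_min=18, primer_len_opt=20, primer_len_max=24))[0]
print(pair.forward_seq, round(pair.forward_tm, 1))
print(pair.reverse_seq, round(pair.reverse_tm, 1))
print(pair.product_size, round(pair.penalty, 2))

f = ms.AlleleFrequencies({178: 0.5, 182: 0.3, 186: 0.2}, 78)
print(round(ms.expected_heterozygosity(f), 4),
      round(ms.pic(f), 4), round(ms.shannon_index(f), 4))
```

prints

```
GGC 5 15 CLASS_II GC_RICH
GACCGTTGTAGCTGACCATT 52.2
ATCGATCCAGCTTGAATCCG 52.1
96 0.25
0.62 0.5478 1.0297
```

i.e. a (GGC)₅ tract of 15 nt — a Class II, GC-rich trinucleotide SSR — with
a primer pair amplifying a 96 bp product spanning it, and a three-allele
locus (frequencies 0.5/0.3/0.2 over 78 gene copies) whose He is 0.62,
PIC 0.548 and Shannon index 1.03.

The same steps are available from the shell:

```bash
tfssr mine --fasta transcripts.fa --min-len 12 --units 2,3,4,5,6 --out loci.tsv
tfssr annotate --loci loci.tsv --blast hits.tsv --fasta transcripts.fa \
               --family-map fams.tsv --out tf_markers.tsv
tfssr primers --fasta transcripts.fa --loci tf_markers.tsv --out primers.tsv
tfssr stats --genotypes genotypes.tsv --out-dir stats/ --k-max 5
tfssr expression --fpkm fpkm.tsv --baseline 0h --out-dir expr/
tfssr run --config config.json        # the whole pipeline + manifest
```

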