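# vrflp

Virtual RFLP analysis of aligned 16S rRNA gene sequences.

The package chains the "dry lab" half of a ribotyping study into one tested
pipeline:

1. **In-silico restriction digestion** (`vrflp.digestion`) — degenerate
   IUPAC recognition-site scanning (subset matching, so an `N` in a
   sequence never certifies a definite site), cut-position computation and
   virtual-gel fragment profiles for ten classic 4/5-cutters (AluI, BstUI,
   DdeI, HaeIII, HhaI, HinfI, MboI, MspI, RsaI, TaqI) or any user-supplied
   enzyme table.
2. **Binary profiling** — site-level presence/absence matrices (one column
   per enzyme) and band-level matrices (one column per enzyme x
   fragment-length bin, with optional gel-resolution tolerance).
3. **Clustering** (`vrflp.rflp_compare`) — Jaccard similarity between
   binary profiles, distance conversion, deterministic unweighted
   average-linkage (UPGMA) dendrograms with newick output.
4. **Ordination and consistency** (`vrflp.ordination_stats`) — PCA of the
   binary profiles and Mandel h/k consistency statistics with closed-form
   critical values (validated against Monte-Carlo null simulations).
5. **Population genetics** (`vrflp.popgen`) — complete deletion of
   gap/ambiguous columns, segregating sites, total mutations, singleton and
   parsimony-informative sites, haplotype number and diversity, nucleotide
   diversity, within/between-group average pairwise differences, and the
   Hudson-Kaplan four-gamete minimum recombination count.
6. **Synthetic data** (`vrflp.synthetic_data`) — a seeded generator for
   group-structured aligned datasets with controllable within/between-group
   divergence, injected gap columns and planted/knocked-out restriction
   sites, plus a packaged 19-strain x 10-enzyme site-presence fixture.

## CLI

The console script `vrflp` exposes each stage and an end-to-end runner:

```sh
# generate a synthetic aligned dataset (FASTA + group map + truth JSON)
vrflp simulate --seed 1 --out data/

# full pipeline: digestion -> matrices -> Jaccard/UPGMA -> PCA -> Mandel -> popgen
vrflp run-all --aln data/alignment.fasta --groups data/groups.tsv --out out/

# individual stages
vrflp digest data/alignment.fasta --out fragments.tsv
vrflp matrix data/alignment.fasta --level band --out bands.tsv
vrflp cluster --input bands.tsv --out upgma.nwk
vrflp pca --input bands.tsv --out pca.tsv
vrflp mandel --aln data/alignment.fasta --groups data/groups.tsv --out mandel.tsv
vrflp popgen --aln data/alignment.fasta --groups data/groups.tsv \
    --pair pseudomonas,actinobacteria --out popgen.json
```

`run-all` writes `site_matrix.tsv`, `fragments.tsv`, `band_matrix.tsv`,
`similarity.tsv`, `upgma.nwk`, `pca_scores.tsv`, `mandel.tsv`,
`popgen.json` and `run.log`; the whole bundle is deterministic for a fixed
seed and configuration.  A matrix-only mode (`--matrix sites.tsv`) starts
from a site-presence TSV — e.g. one transcribed from a published
restriction map — and runs the clustering/ordination stages.

## Conventions

* Alphabet: IUPAC nucleotide codes plus `-` (`.` is normalized to `-`);
  case-insensitive input, uppercase canonical form.
* Coordinates: 0-based half-open internally, 1-based inclusive in
  human-facing reports.
* Gaps are alignment artifacts: stripped before digestion (sites are
  physical), removed column-wise (complete deletion) before polymorphism
  statistics.
* Sequences are linear; only the given strand is scanned (all built-in
  recognition patterns are self-reverse-complementary, and non-palindromic
  user enzymes trigger a warning).
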