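# srnakit

Classification of plant small RNAs (18–26 nt) into the five major classes —
miRNA, repeat-associated siRNA (ra-siRNA), phased siRNA (pha-siRNA), and
cis-/trans-natural-antisense-transcript siRNA — plus a synthetic
genome/read generator with ground truth so the whole pipeline is verifiable
end to end.

## What it does

Stages run in a strict sequential exclusion order; each stage only sees
sRNAs not claimed by an earlier one:

1. **Ingest** — collapse reads per library (FASTA with `_xN` count suffixes
   or two-column TSV), keep 18–26 nt, map exactly to the genome on both
   strands (no mismatches).
2. **miRNA discovery** — abundance (≥10 reads) and copy-number (≤5000 hits)
   pre-filter, locus clustering, strand bias ≥0.8 and abundance bias ≥0.6,
   then mature/star duplex validation on a folded precursor: same strand,
   ≤450 nt apart, 2-nt 3′-overhang geometry within a ±3 nt shift, ≤4 duplex
   mismatches. Folding is a pluggable contract; the bundled default is a
   stacking-aware weighted Nussinov, with ViennaRNA used automatically when
   its python bindings are importable.
3. **miRNA context** — conserved (≤3 substitutions against a known
   catalogue) vs lineage-specific split, family assignment (single-linkage
   for novel families), precursor gene context
   (intron/exon/junction/intron-exon) against transcript models, and
   origin-sharing Venn counts.
4. **ra-siRNA** — remaining sRNAs intersected with repeat annotations
   (≥1 nt overlap), summarized per repeat class × sub-genome
   (A2-only / D5-only / both / total).
5. **pha-siRNA** — 21-nt phasing scan on transcripts with an exact
   hypergeometric upper-tail p-value (p < 1e-3), post-filtered by ≥2
   phased siRNAs, ≥5 reads for at least one, and in-register read fraction
   ≥0.6; miRNA initiators predicted by seed-weighted complementarity
   scoring (mismatch 1, G:U 0.5, doubled at positions 2–13; length 18,
   expectation ≤4.0, site within 148 nt, cleavage within 1 nt of the phase
   register).
6. **nat-siRNA** — cis-NAT pairs (opposite strands, ≥50 nt genomic
   overlap) classified as convergent/divergent/enclosed/coincided;
   trans-NAT pairs (≥100 nt complementary alignment forming a ≥50 nt
   duplex with ≥90% paired positions, G:U allowed); per-read
   overlap/non-overlap, exon/intron, strand enrichment.
7. **Profiles** — length and 5′-nucleotide composition per class.

## CLI

```sh
# generate a synthetic dataset with a ground-truth manifest
srnakit simulate --seed 42 --out data/

# run the classification pipeline on it (or on your own files)
srnakit classify \
    --genome data/genome.fasta \
    --reads L1 data/reads_L1.tsv --reads L2 data/reads_L2.tsv \
    --transcripts-fasta data/transcripts.fasta \
    --transcripts-gff3 data/transcripts.gff3 \
    --repeats data/repeats.gff3 \
    --known-mirnas data/known_mirnas.fasta \
    --out out/

# simulate + classify + score recovery against the truth manifest
srnakit evaluate --dataset data/ --out eval/
```

All thresholds live in a YAML config (`--config`); defaults are the values
listed above. Exit codes: 0 success, 2 configuration error, 1 runtime
error.

## Layout

```
src/srnakit/
  sequence_io.py     read collapsing, length filter, exact mapping, file formats
  fold.py            pluggable folding contract + bundled fallback folder
  mirna_discovery.py clustering, bias filters, duplex/hairpin validation
  mirna_context.py   conservation, families, gene context, origin sharing
  rasirna.py         repeat intersection and taxonomy table
  phasing.py         hypergeometric phasing statistic, PYT calling, initiators
  nat.py             cis/trans NAT pairs, duplex filter, enrichment
  profiling.py       length / 5'-nucleotide / overlap-length profiles
  synthetic.py       ground-truth simulator and recovery scoring
  cli.py             pipeline orchestration and click commands
```
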