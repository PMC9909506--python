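# t2tkit

A desk-scale toolkit for the last mile of telomere-to-telomere (T2T)
genome assembly. Chromosome-scale plant assemblies built from long
reads and Hi-C scaffolding typically arrive with residual N-run gaps,
occasional mis-oriented contigs, and uncharacterized telomeres and
centromeres. `t2tkit` implements the finishing computation for that
situation as a reusable, fully tested library:

1. **Reference-guided anchoring** — contigs are re-mapped against guide
   pseudochromosomes and ordered/oriented along them *without ever
   splitting a contig* (long-read contigs outrank scaffolding joins),
   emitting an AGP v2.1 plan plus an unplaced set.
2. **Donor gap filling** — each remaining N-run is bridged by donor
   contigs (e.g. from an independent ONT assembly) that align to *both*
   gap flanks with block length ≥ 1000 bp and identity ≥ 0.80; the best
   donor's spanning segment replaces the gap-tied sequence.
3. **Telomere detection** — exact scanning for the 7-bp plant telomeric
   units (5′ CCCATTT / 3′ TTTAGGG, normalized query AAACCCT) within
   50 kb of each chromosome end; a single isolated unit is never called.
4. **Centromere localization and monomer characterization** — tandem
   arrays are detected genome-wide under TRF-style weights
   (match 2, mismatch 7, indel 7, minscore 50, maxperiod 500), monomers
   of 100–200 bp are retained, clustered greedily at 80% identity, the
   cluster representatives are mapped back per 10-kb bin, and the single
   continuous high-frequency region per chromosome is called; the
   monomer occupying the majority of the call is its centromeric
   monomer, and the modal dominant length across chromosomes is the
   representative monomer length.

A seeded synthetic-genome generator (`t2tkit.synthetic`) plants
telomere arrays, a centromeric satellite array (optionally a
two-monomer mixture or a higher-order repeat unit), N-gaps, contig
fragments and spanning donors — all recorded in a ground-truth
manifest — so every stage is testable with no external data.

## Core methods

**Alignment identity.** `pairwise.global_align` is a Needleman–Wunsch
global alignment under match +2 / mismatch −7 / gap −7 (the same
weights as the tandem-repeat scoring). Among optimal-score alignments
it reports the one maximizing matched columns; with these weights that
pins all four column counts, so identity = matches / block_length is a
canonical, symmetric function of the pair. N matches nothing.

**Mapping.** `mapper.map_query` chains exact 15-mer anchors per
(target, strand), reporting PAF-semantics records; externally produced
PAF (e.g. from minimap2) can be imported anywhere a mapping is
consumed.

**Tandem arrays.** The period of an array equals the distance between
consecutive occurrences of any intact k-mer inside it, so the integer
mode of those distances recovers the period exactly even at a few
percent divergence. Candidate regions are validated by stepping a
consensus monomer copy-by-copy (banded edit distance), rebuilding the
consensus by column-wise majority, and scoring each copy against it.

## Worked example

Generate a toy diploid genome (two 1-Mb chromosomes, 300-unit
telomeres, a 120-kb centromeric array of a 153-bp monomer at 2%
divergence, two hidden 5-kb gaps with spanning donors), then fill,
scan and locate:

```bash
t2t sim --config demo.yaml --seed 11 --n-chroms 2 --chrom-len 1000000 \
        --n-breaks 3 --n-gaps 2 --outdir demo
t2t fill --object demo/gapped.fa --donors demo/donors.fa \
         --out-fasta demo/filled.fa --report-tsv demo/fill.tsv
t2t telo --fasta demo/hapP.fa --out-tsv demo/telo.tsv
t2t cen locate --fasta demo/hapP.fa --out-bed demo/cen.bed \
               --monomers-out demo/monomers.fa
```

The fill report shows both gaps closed by their donors at mean flank
identity 1.0 (4000 aligned flank bases each), restoring the original
haplotype byte-for-byte:

```
gap_id      status  donor_id       mean_flank_identity  total_flank_block  inserted_length
Chr01_gap1  filled  donor_Chr01_1  1.0                  4000               5000
Chr02_gap1  filled  donor_Chr02_1  1.0                  4000               5000
```

The telomere scan finds all four arrays (`telomeres: 4  T2T
chromosomes: 2`); the 3′ calls start a few bases into the array because
the scan counts whole-unit occurrences in a fixed phase:

```
chrom  end          start   stop    units  span  offset
Chr01  five_prime   0       2100    300    2100  0
Chr01  three_prime  997903  999996  299    2093  4
Chr02  five_prime   0       2100    300    2100  0
Chr02  three_prime  997903  999996  299    2093  4
```

Centromere localization prints `centromeres: 2  representative monomer
length: 153 bp` and writes the calls to BED — each matching the planted
120-kb array (truth intervals 440 031–559 968 and 440 018–559 981) with
a dominant cluster covering 100% of the region:

```
Chr01   440031  559968  cl0001
Chr02   440031  559988  cl0002
```

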