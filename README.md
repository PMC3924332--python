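# famfinder

Family-profile-driven discovery and structural annotation of small one- and
two-exon genes.

Small secreted peptides — defensins and other cysteine-rich peptides (CRPs)
in plants, cyclic peptide toxins in fungi — are routinely missed by
general-purpose gene finders: their coding regions are short (often under
100 codons), family members are numerous and scattered, and the typical
architecture of a signal-peptide first exon separated from the mature
peptide by an intron defeats statistical models trained on average genes.
famfinder takes the opposite approach: given a curated multiple sequence
alignment of a protein family, it finds *all* members of that family in a
genome and predicts their exact gene structures.

## How it works

The pipeline runs four stages:

1. **Pre-processing.** The genome is translated in all six reading frames
   and split at stop codons into ORFs of at least 15 residues.  If a GFF3
   annotation is supplied, its protein sequences join the search database
   (the proteome search is complementary: it recovers exons whose
   translated-genome hits are individually too weak).
2. **Motif mining.** A profile HMM with match/insert/delete states per
   alignment column is built from each family alignment and searched
   against the database with the forward algorithm, at a deliberately
   generous E-value (10).  E-values come from a decoy calibration: forward
   scores of i.i.d. background sequences are fitted with a right-tail
   censored maximum-likelihood Gumbel, and `E = N_db * P(S >= s)`.  Hits are
   projected back to genomic coordinates, filtered at E <= 0.1, reduced to
   one best hit per overlapping cluster, and nearby partial hits of one
   family are merged into *extended hits* — but only when each neighbor
   covers a different (collinear) segment of the profile, the signature of
   exons split by an intron.
3. **Model prediction.** Around each extended hit a window (2500 bp
   upstream, 1500 bp downstream) is cut and every complete one- or two-exon
   gene model compatible with the hit reading frames is enumerated: ORFs
   are extended to reachable in-frame start codons and the nearest in-frame
   stop, and all GT..AG intron placements within configurable length bounds
   are tried, ranked by donor/acceptor position-weight-matrix scores.  An
   adapter seam lets external gene predictors contribute candidates.
4. **Model evaluation & selection.**  Each candidate protein is scored by
   its mean pairwise BLOSUM80 alignment score against the family alignment
   (MSA score), the sum of per-residue posterior alignment probabilities
   against the profile (HmmProb score), and a signal-peptide propensity
   score.  The selected model must pass the signal gate (score >= 0.4,
   optional), have proper start/stop codons and no premature stop, and
   maximize MSA + HmmProb.  Surviving models are rescored against the
   profile and reported at a final E-value cutoff of 0.001 (use 1 for a
   maximally sensitive search).

Sensitivity `Sn = TP/(TP+FN)` and specificity `Sp = TP/(TP+FP)` are
reported at nucleotide and exact-exon-boundary level; true negatives are
not defined for a family-restricted search and are not used.

## Worked example

famfinder ships a synthetic-genome generator that plants family members,
pseudogene decoys and hard-masked repeats with a truth annotation, so the
whole pipeline can be exercised without downloads:

```sh
$ famfinder make-fixture --out fixture --seed 7 --genome-length 50000 \
      --single-exon 3 --two-exon 3 --pseudogenes 2
fixture with 8 planted features -> fixture

$ famfinder run --genome fixture/genome.fa --family fixture/family.afa \
      --annotation fixture/truth.gff3 --out results --seed 7
...
6 models -> results

$ famfinder evaluate --pred results/models.gff3 --truth fixture/truth.gff3 \
      --genome fixture/genome.fa
level       TP      FP      FN      Sn      Sp
nucleotide  1368    0       0       1.0000  1.0000
exon        9       0       0       1.0000  1.0000
category    count
exact       6
```

All six real planted genes (three single-exon, three two-exon) are
recovered with exact boundaries; the two pseudogene decoys are rejected
because every candidate model at their loci carries a premature stop codon.
`results/` contains the models as GFF3, protein and CDS FASTA, a per-family
alignment of the predictions with the family consensus, and a TSV of all
scores:

```
synchr1  famfinder  gene  9215  9442  .  +  .  ID=gene:fm0000
synchr1  famfinder  mRNA  9215  9442  .  +  .  ID=fm0000;Parent=gene:fm0000
synchr1  famfinder  CDS   9215  9442  .  +  0  ID=cds:fm0000.0;Parent=fm0000
```

`famfinder scan` and `famfinder predict` run the mining and prediction
stages separately from serialized intermediates; `famfinder build-profile`
writes a calibrated profile HMM as JSON.

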