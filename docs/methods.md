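# Methods

This note documents the models and procedures implemented in famfinder, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Profile HMM and scoring

The search model is a local-alignment profile HMM: one match state per
consensus column (columns with >= 50% residues), with insert and delete
states per node, uniform entry into any match state (probability `1/M`),
a constant exit probability `p_exit = 0.05` from every internal match state
(the last match state always exits), and flanking states that emit
background residues on both sides of the aligned core.  Emission
probabilities are observed column frequencies blended with
background-proportional pseudocounts of total weight 1; insert states emit
the background, so inserted residues are score-neutral; transition
probabilities are counted from the members' match/insert/delete paths with
+1 pseudocounts.  The exact generative semantics, including the flank loop
probability `r = L/(L+2)`, are specified in the `famfinder.hmm` module
docstring; the test suite holds the dynamic programming to that definition
by exhaustive path enumeration at 1e-9 tolerance.

**Length-conditioned score.**  Bit scores are
`log2(Odds(x) / Odds0(L))`, where `Odds(x)` is the forward path mass with
emission odds `em/bg` and `Odds0(L)` is the same mass for an all-wildcard
sequence of equal length.  The second term is the model's bare length
preference; dividing it out makes a sequence with no emission information
score exactly 0 and removes the length dependence that otherwise skews
E-values across the very heterogeneous ORF lengths of a translated genome.
A plain geometric-null score does not have this property: the model's
length distribution can exceed the geometric null at its mode, so even an
uninformative sequence could score positively.

**`X` handling.**  Codons containing `N` translate to `X`, which does not
terminate an ORF but carries emission odds 1 in every state: hard masking
suppresses signal without fragmenting open reading frames.

**E-value calibration.**  Forward scores of `decoy_n = 4000` i.i.d.
background decoys, generated at the median ORF length of the actual search
database, are fitted with a maximum-likelihood Gumbel.  The fit is
right-tail censored (top 5% of decoys observed, the rest censored at the
quantile): forward scores of local alignments follow the Gumbel law only in
their upper tail, and a full-sample fit measurably misestimates exactly the
deep tail that E-value thresholds extrapolate into.  The fitted tail slope
approaches the theoretical value of ~0.69 nats per bit.  `E = N_db * P(S >=
s)` with `N_db` the number of database entries.  The final model filter
rescores each completed protein and multiplies by the same `N_db`, so the
reported E-value expresses significance relative to the original genomic
search space; the pipeline defaults are scan E = 10, keep E <= 0.1
and final E <= 0.001.

## HmmProb and MSA scores

The HmmProb score is the sum of per-residue **match-state** posterior
probabilities over the Viterbi local alignment (0 when the Viterbi score is
not positive).  Insert-state posteriors are deliberately excluded: a wrong
candidate that retains translated intron between two well-matching exons
accumulates insert posterior mass near 1 per junk residue and would
otherwise outscore the correct spliced model.

The MSA score aligns the candidate protein to the family alignment columns
with a profile-guided global affine aligner (position-specific column
scores = mean BLOSUM80 against the column's residues), then scores every
(candidate, member) row pair columnwise with BLOSUM80: gap opening -8,
each further residue-gap column -1, gap-gap columns 0; the mean over
members is returned.  The MSA and HmmProb scores are summed on their native
scales without normalization when ranking candidates — deliberately: the
MSA term (matrix units, typically hundreds) dominates overall fit while the
HmmProb term (probability units, bounded by protein length) discriminates
between structurally near-identical candidates.  An optional z-score mode
(`select_best(..., normalize=True)`, off by default) equalizes the two
units across the candidates of one hit for families where the native
scales are uninformative.

Three adapter seams allow external engines to stand in for built-in
components without changing the pipeline contract: a search engine
(`hmm.set_search_engine`), a signal-peptide scorer
(`selection.set_signal_scorer`), and external gene predictors
(`models.register_external_predictor`); adapter failures are contained
with a warning.

## Signal-peptide score

The built-in scorer is an explicit stand-in for an external signal-peptide
predictor, not a reimplementation of one.  It combines three classic
signal-peptide features mapped to [0, 1]: positive charge in residues 2-5
(n-region; weight 0.25), the best mean Kyte-Doolittle hydropathy of an
8-residue window in residues 6-20 (h-region; weight 0.55), and an
[AGS]-x-[AGS] cleavage-like motif in residues 10-30 (c-region; weight
0.20).  Proteins shorter than 15 residues score 0.  The selection gate
(default 0.4) applies to whatever scorer is plugged into the seam, and can
be disabled for non-secreted families.

## Model builder

Candidate enumeration is exhaustive within documented constraints (verified
against brute-force combinatorial enumeration on small windows):

* Start codons: **all** in-frame ATGs reachable upstream of the hit before
  the first in-frame stop are enumerated, each as its own candidate, and
  selection arbitrates.  The more obvious nearest-ATG rule truncates any
  family whose mature peptide itself begins with methionine (the model then
  loses its signal peptide and fails the gate), while junk start-extensions
  are eliminated by the gate and the alignment scores.
* Stop codon: the first in-frame stop downstream of the hit span; stops
  inside the span flag the candidate (`has_internal_stop`) rather than
  truncating it, which is what rejects pseudogenes at selection
  (criterion: proper start/stop and no premature stop).
* Two-exon candidates pair donors in or near the inter-block gap with
  acceptors before block 2 (a splice may cut up to 9 nt into a block —
  alignment jitter at exon boundaries), requiring GT..AG (GC donors
  optional), intron length within [40, 2500] nt, and a total exonic length
  that keeps both blocks in frame.
* **In-block introns.** A frame-preserving, stop-free intron does not
  interrupt the ORF, so the homology search reports one contiguous block
  with the translated intron absorbed as inserts.  For single-block hits
  the builder therefore also enumerates intron placements *inside* the
  block (length = 0 mod 3); the spliced candidate wins at selection because
  removing translated intron raises the MSA score.  This mirrors what a
  protein-to-genome aligner does within one contiguous alignment.
* Splice sites are ranked by built-in donor (9 nt) and acceptor (15 nt)
  position weight matrices (log-odds vs. uniform background) encoding the
  canonical GT-AAGT donor context and pyrimidine-tract + CAG acceptor;
  two-exon candidates are capped at the top 50 (donor, acceptor) pairs per
  hit.  The matrices are configuration, not biology learned from data.

Extended hits with three or more blocks are trimmed to their two longest
blocks with a warning: the native builder targets one- and two-exon genes.

## Synthetic benchmark

`famfinder.fixtures` generates genomes that emulate the target situation:
i.i.d. background of configurable GC (default 0.40), planted genes of the
form ATG + signal-peptide-like prefix (M-K-10 hydrophobics-A-X-A, no
internal Met) + a fresh draw from the family profile (40 members x 60
columns at 0.85 conservation with a fixed 6-cysteine scaffold, by default)
+ stop codon; two-exon genes are split at a random in-frame point in the
central portion of the family-coding region (>= 12 codons per side) by a
GT..AG intron of 80-300 nt with consensus-like donor context and
pyrimidine-tract acceptor; pseudogene decoys carry one induced premature
stop early in the family region; optional diverged decoys (0.45
conservation) populate the E-value twilight zone between the strict and
relaxed cutoffs; repeat tracts are `N` runs.  Output is byte-deterministic
given the seed.

What passing the benchmark shows: the pipeline's machinery — search,
projection, merging, splice-aware reconstruction, selection, filtering —
recovers planted structures at >= 90% nucleotide Sn/Sp with exact two-exon
boundaries for >= 80% of genes, rejects pseudogenes, and makes no calls on
background-only genomes.  What it does not show: performance on real
genomes, whose backgrounds are not i.i.d. (repeats, paralogs, GC isochores,
codon bias), whose intron boundaries are far more variable than the
consensus-context introns planted here, and whose families are older and
gappier than the synthetic alignments.  The headline percentages measured
on fixtures are therefore properties of the machinery, not predictions of
field accuracy.

Benchmark problem sizes (200 kb genome, 30 genes, 10 decoys, one profile)
were chosen so the full acceptance suite replays the entire study in a few
minutes on one CPU.

## Numerical choices and degenerate inputs

* Forward recursions run in probability space with per-row rescaling;
  delete-state columns use a cumulative-product scan with an exact loop
  fallback if the scan underflows.  Posterior decoding stores log2-domain
  forward/backward matrices.
* Coordinates are 0-based half-open forward-strand internally; GFF3 I/O is
  1-based inclusive.  Frames are numbered +1..+3 / -1..-3 by offset on each
  strand; trailing partial codons are dropped silently.
* Selection ties break by higher HmmProb, then shorter model, then leftmost
  position, then model id — fully deterministic and order-invariant.
* Empty sequences are scoring errors; sequences shorter than one codon
  translate to six empty frames; metrics with empty denominators report
  `None`, never silent 0/0.
* Cluster representatives: lowest E-value, then highest bit score, then
  smallest start.

## Known limitations

* No more than two exons in the native builder; no UTRs, no alternative
  splicing, no non-GT/GC..AG introns.
* E-values are calibrated per profile against an i.i.d. decoy model; they
  are internally consistent but not comparable to another engine's
  E-values.  Thresholds are configuration.
* The signal-peptide scorer is a feature-based stand-in; for production
  use on real secretomes, plug an external predictor into the seam.
* Chaining never crosses contigs; a gene split across assembly gaps is
  reported as partial hits.
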