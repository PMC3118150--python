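# Methods

`belpao` re-creates, as a tested pipeline on synthetic genomes, the classic
workflow for characterising BEL/Pao-type LTR retrotransposons in metazoan
assemblies: de novo structural detection, protein-evidence validation,
class assignment, merging of two detector passes, Markov clustering into
families, consensus-based concatenated-domain phylogeny with superfamily
assignment, and screens for horizontal transfer and abundance. Every stage
is scored against planted ground truth, so the whole chain is verifiable
without any external databases or genome downloads.

## The synthetic genomes

An LTR retrotransposon is modelled as `LTR + internal + LTR`: two long
terminal repeats (0.2–1.2 kb) that are identical at insertion time flanking
an internal region that carries gag and the pol domains in their natural
order (protease, then reverse transcriptase, then integrase). Full elements
are 4.2–10 kb. The coding region is a single stop-free reading frame; gag
(140 aa), protease (110 aa), RT (180 aa) and integrase (130 aa) are
contiguous, with family-specific non-coding filler and LTRs around them.

Protein sequences are generated hierarchically so that each downstream stage
has a recoverable signal: a root ancestor per domain; class ancestors for
Ty1/Copia, Ty3/Gypsy, BEL/Pao and DIRS (Copia and Gypsy descend from a
common non-BEL ancestor, which makes them a genuine outgroup *pair* for
rooting, mirroring the use of the canonical Copia and Gypsy elements as
outgroups); superfamily ancestors inside BEL/Pao (default 30% amino-acid
divergence from the class ancestor); and family ancestors inside each
superfamily (default 15%). Amino-acid replacements are drawn from the
codon-usage background composition, so composition is stationary along the
hierarchy — this is what keeps profile E-values calibrated (below).
Nucleotide sequences are independent random back-translations per family,
so between-family nucleotide identity decays much faster than amino-acid
identity, as in real repeat families.

Copies are planted by replacing a background window (top-level insertions;
the contig keeps its specified length) or by true insertion inside an
earlier copy (nesting, which expands the host and shifts coordinates).
Copies can be reverse-complemented and fragmented (a fragment always loses
at least one complete LTR). Per-copy divergence applies substitutions
(uniform over the three alternatives) and indel events (geometric lengths,
mean 2 bp); the realized divergence of every copy is recorded in the ground
truth. Background sequence is i.i.d. nucleotides at the requested GC — a
null that cannot produce LTR-like repeat pairs by chance at these scales.

What the generator does *not* emulate: target-site duplications, solo-LTR
recombination products, substitution-rate heterogeneity or
transition/transversion bias, tandem element arrays (top-level copies are
planted with a ≥300 bp background gap), and assembly artefacts. Passing
tests therefore demonstrate correctness of the decision logic under clean,
well-separated signals, not performance on degraded real assemblies.

## Detection

Genomes are filtered like real assemblies: contigs under 10 kb are dropped
and a genome whose retained contigs total under 1.5 Mbp is excluded.
Candidates are direct-repeat pairs found by exact k-mer seeding (default
k=16) between positions 2–15 kb apart, union-find clustering of seed pairs
that are close both in position (≤ max LTR length) and diagonal (spacing
within ±25 bp, tolerating indel drift between the two repeat copies), X-drop
ungapped extension of the seed cover (match +1 / mismatch −2, drop 12), and
a final gapped-alignment identity check of the two repeat copies (edlib,
identity = 1 − distance/length). A candidate needs both repeats in
200–1200 bp, spacing within 2000–15000 bp, and identity at or above the
configured threshold. Two parameterizations are run as independent
detector passes: A (k=16, identity ≥ 0.75) and B (k=20, identity ≥ 0.85);
B is the higher-precision pass and plays the preferred role during merging.
Only direct repeat pairs are sought: the structure is strand-symmetric, so
elements inserted in reverse orientation are detected identically and no
strand is called.

## Validation and class assignment

Each candidate must contain at least one stop-to-stop ORF longer than
300 bp (6 frames) and at least one protein-domain hit with E < 0.01.
Domains are modelled as ungapped log-odds PSSMs over a reference alignment:
column scores are log2(frequency with pseudocount 1/20 over the codon-usage
background). E-values come from a Gumbel fitted by the method of moments to
the scores of decoys drawn from the training-sequence residue composition
(`E(S) = n_windows · exp(−λ(S−μ))`, with `n_windows` the number of windows
actually scanned — reported in the hit metadata). Scans run over all
six-frame translations with stop codons kept as neutral `X` columns (a
local similarity search should pay one column for a nonsense mutation, not
the whole window); windows shorter than the profile are completed with the
profile's expected null score so that partial-coverage scores remain
comparable with the full-length calibration.

The reference panels stand in for a curated repeat library: per class and
domain, lightly diverged members of each family ancestor (≥ 8 per class).
Panel members passing the pooled-generic scan at E < 1e-4 are grouped into
lineage subprofiles (greedy clustering at 80% identity) because one class
profile averaged over deeply diverged superfamilies would dilute all
columns; a class's E-value is the best over its subprofiles, which keeps the
canonical decision rule ("smallest E among the four classes, require
E < 1e-20, otherwise unclassified, ties broken in fixed class order")
intact while remaining sharp. Validation scans the full library
(pooled-generic plus subprofiles), mirroring a multi-model domain library.

## Merging

Within each detector pass, nested candidates resolve to the innermost
element (containment judged with a 30 bp boundary tolerance and a 200 bp
minimum length difference, since detector boundaries jitter by a few
bases — this also removes the repeat-pair artefacts that arise between
neighbouring copies of the same family), and remaining overlaps are
resolved by a seeded uniform-random choice. Across the two passes:
a locus found by one pass is kept; if both ends agree within 20 bp, pass
B's coordinates win; otherwise-overlapping pairs are decided by the
2,000–15,000 bp full-length gate (both in range → seeded random choice;
neither → both dropped). The gate is also applied to single-pass loci, so
every final element lies within it. The merge is idempotent and its output
overlap-free; every random decision draws from a named substream of the
pipeline seed.

## Families

Elements become nodes of a similarity graph. All element pairs sharing
enough 14-mers on either strand are aligned semi-globally (shorter inside
longer, both orientations tried); matches need ≥ 500 aligned bp. The raw
score (matches − 2·mismatches/gaps) maps to a Karlin–Altschul-style
E-value whose absolute scale is unimportant because only
`score = min(−log10 E, 200)/200` enters the graph (E = 1 → 0,
E ≤ 1e-200 → 1). Markov clustering then partitions the graph: raw weights
are raised to the pre-inflation power (3.0), self-loops are set to each
node's maximum incident weight, and the column-stochastic matrix is
iterated with expansion (squaring), inflation (entry-wise power 4.0 with
renormalisation) and pruning (entries < 1e-5 of the stochastic matrix —
pruning must follow renormalisation or uniform columns of large cliques
vanish) until the largest entry change is below 1e-6 (cap 200 iterations;
non-convergence is flagged, not fatal). Clusters are read from attractor
rows, overlaps go to the lowest-indexed cluster, isolated nodes are
singleton families (smallest reported cluster size 1). Clustering can run
globally or per species.

## Consensus, tree, superfamilies

For each family of the focal class (majority vote of its members' class
labels), the best-matching window per pol domain is extracted from each
member, aligned (progressive profile–profile alignment: 3-mer distances →
average-linkage guide tree → affine-gap DP with BLOSUM62, gap open 11 /
extend 1), and condensed to a majority consensus: the most common residue
per column, seeded random tie-break, required in at least ⌈n/3⌉ and at
least 2 rows, else `X`. Alignments with mean pairwise similarity below 70%
or consensuses with more than five `X` are flagged for review (the
automated stand-in for manual curation).

Families with all three pol-domain consensuses enter the supermatrix: one
cross-family alignment per domain, concatenated protease–RT–integrase
(aligned first, concatenated after, to avoid aligning across domain
boundaries). Distances are Poisson-corrected p-distances
(`−ln(1−p)`, p capped at 0.98) with gap/`X` columns excluded pairwise; the
tree is neighbor joining (dendropy), rooted on the branch to the outgroup
pair, with support from a seeded nonparametric bootstrap over columns
(default 100 replicates). Superfamilies are the subtrees below deep,
well-supported branches: internal ingroup branches whose length reaches the
0.95 order-statistic quantile of internal branch lengths, is at least twice
their median and at least 0.1 substitutions/site, with support ≥ 0.5. The
quantile uses the lower order statistic so the threshold is an attained
branch length; the median and absolute floors make a star-like tree yield a
single superfamily. A within/between average percent-similarity matrix
(identity over mutually resolved columns, averaged over row pairs)
summarises the partition; singleton superfamilies have no within value.

## Screens

The horizontal-transfer screen compares every cross-species element pair
(both strands): the largest shared-k-mer diagonal cluster delimits the
candidate conserved region, which is aligned to give identity and span. A
pair is flagged when identity ≥ 80% over at least 20% of the shorter
element's length and at least 300 bp; the fraction is anchored to the
shorter element, the conservative reading that flags more candidates. Pairs
are annotated by the rank at which the species diverge (same genus / same
phylum / cross phylum); same-genus pairs are the expected positive control,
cross-phylum pairs are transfer candidates.

Abundance summaries report per-species counts, densities (copies per Mbp of
retained assembly) and per-class fractions of classified elements. The
Spearman rank correlation (average ranks for ties) uses an exact
permutation p-value for n ≤ 10 and a t-approximation above.

## Reference study conditions and problem sizes

The packaged scenarios (in `belpao.scenarios`) define the conditions under
which everything is scored:

- **recovery** — 3 same-genus species, 2×760 kb contigs each (every genome
  clears the 1.5 Mbp assembly gate), 50 full-length BEL/Pao copies per
  species over 9 families in 3 superfamilies, substitutions 5% per site,
  indels 0.002 per site (about one indel event per 25 substitutions, the
  usual order of magnitude for neutral indel/substitution ratios).
- **class** — one species, zero-divergence copies of all 15 families across
  the four classes (45 elements), for class-assignment accuracy.
- **ht** — four small genomes in two phyla, one planted cross-phylum
  transfer at 95% identity plus a 70%-identity decoy; these toy genomes are
  far below a real assembly's size, so their config lowers only the
  assembly-size gate (recorded in the bundle).

All analysis thresholds keep their standard defaults everywhere
(`PipelineConfig`): contig ≥ 10 kb, genome ≥ 1.5 Mbp, LTR spacing
2000–15000 bp, LTR length 200–1200 bp, ORF > 300 bp, domain keep E < 0.01,
profile-build gate E < 1e-4, classification E < 1e-20, match span ≥ 500 bp,
score cap 200, inflation 4.0 / pre-inflation 3.0, minimum cluster 1,
consensus ⅓-and-2 rule, 70%/5-X flags, HT 80%/20%/300 bp, merge tolerance
20 bp, element length 2000–15000 bp.

## Numerical and degenerate-input choices

- Single pipeline seed, named substreams per stage (overlap resolution,
  merge, consensus tie-breaks, calibration, bootstrap), so changing one
  stage's knobs never perturbs another's random decisions; bundles are
  byte-identical across reruns.
- E-values are clamped to ≥ 1e-300 (they only enter decisions through
  thresholds and a log capped at 200).
- MCL raises on edge weights outside (0, 1] and on inflation ≤ 1; the
  undefined-distance case (no mutually resolved columns between two
  supermatrix rows) raises an error naming the pair.
- Empty genomes/element sets flow through cleanly: the bundle is written
  with empty tables and the tree stage is skipped below 3 eligible
  families.

## Known limitations

- The tree is distance-based NJ with bootstrap support, not
  maximum-likelihood with approximate likelihood-ratio support; support
  semantics remain a [0,1] branch confidence but the values are not
  comparable to aLRT probabilities.
- The profile scorer is an ungapped PSSM; a true profile HMM tolerates
  indels inside a domain hit. Here indel-split domains are recovered only
  through their in-frame fragments.
- The superfamily cut formalises by thresholds (quantile, median multiple,
  absolute stem depth, support) what was originally a judgement call on a
  drawn tree; very unbalanced deep clades can shift the quantile.
- Solo LTRs, fragments under 2 kb and tandem arrays are out of scope by
  construction.
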