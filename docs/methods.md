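# Methods

## The problem

Tyrosine-based site-specific recombinases (TBSSRs) catalyse DNA
breaking–rejoining through a catalytic tyrosine, activated by a
conserved arginine roughly 30 residues upstream. They are the
integrases of phages, prophages, plasmids, genomic islands (GIs),
integrative conjugative elements (ICEs), integrons, and of composite
elements built from several recombinase genes (RIT trios, Tn554-like
tandems, BIM pairs). Because annotation of these enzymes in public
genomes is erratic, grouping them into sequence families and reading
the family's MGE composition is a practical route to better
annotation: a family whose members all come from plasmids is strong
evidence that an unannotated member is plasmid-associated too.

This package implements that analysis as a reproducible pipeline over
a desk-scale protein set (hundreds of sequences), with a synthetic
corpus generator providing planted ground truth for every stage.

## Similarity search

All ordered sequence pairs are aligned with exact Smith–Waterman local
alignment under affine gaps (BLOSUM62, gap open 11, gap extend 1; a
gap of length *k* costs 11 + *k*). There is no heuristic seeding: at N
≤ ~500 sequences the full dynamic program (a numba kernel) is fast
enough, and exactness makes the engine testable against a brute-force
oracle. Traceback prefers diagonal, then up, then left, and the best
cell is the first maximum in row-major order, so alignments are fully
deterministic. `X` is treated as fully ambiguous and scores 0 against
everything.

E-values use the Karlin–Altschul closed form, E = m·n·2^(−bit) with
bit = (λS − ln K)/ln 2 and fixed gapped-BLOSUM62(11,1) constants
λ = 0.267 nats, K = 0.041. Dedicated search tools estimate these
statistics empirically per query; here only the rank order and the
cutoff behaviour of E matter downstream, so fixed constants are the
simpler, fully reproducible choice (both are configurable). E-values
are floored at 1e−200 to keep −log₁₀(E) finite.

Hits at E ≤ 0.01 become edges of an undirected graph weighted by
−log₁₀(E), capped at 200. The two directions of a pair (which differ
only through the query length in E) are merged by maximum. Isolated
proteins are kept as nodes so the final partition covers the input.

## Markov clustering and inflation selection

The similarity graph becomes a column-stochastic matrix: self-loops at
each node's maximum incident edge weight (unit for isolated nodes) —
standard practice for E-value graphs, preventing trivial attractor
artifacts — then column normalisation. MCL alternates expansion
(matrix squaring) and inflation (entrywise power + renormalisation),
pruning entries below 1e−5 with renormalisation after pruning to keep
the iteration sparse; convergence is declared when the largest entry
change falls below 1e−8 (cap 200 iterations, with a warning and a
best-effort partition beyond that). Clusters are read from the limit
matrix: rows with non-negligible diagonal mass are attractors,
attractors connected through each other's supports form one attractor
system, and every remaining node joins the system holding its largest
limit weight (ties to the lower-numbered system). An independent,
unpruned dense reference implementation in the test suite bounds the
approximation: on 100 seeded random graphs the two agree exactly.

The inflation factor is swept over the inclusive grid 1.2–8.0 in steps
of 0.2 (35 points). Each partition is scored by the intra-cluster
clustering coefficient (ICCC): intra-cluster edges are binarised, and
for every node in a cluster of size ≥ 3 the local clustering
coefficient is computed on the cluster subgraph (intra-cluster degree
< 2 contributes 0); the ICCC is the mean over these nodes, 0 if no
cluster qualifies. The partition with the highest ICCC wins, ties
going to the lowest inflation. The literature definition of the ICCC
underdetermines weighting; a size-weighted edge-density variant is
available behind `iccc(variant="density")` and the variant used is
recorded in every sweep result. Families are numbered by decreasing
size (ties by smallest member id), the community convention for
"family 0 is the largest".

## Per-family alignment and motif calling

Families are aligned progressively: a UPGMA guide tree on distances
d = 1 − w/w_max from the similarity graph (missing edges at distance
1, ties resolved by id order), then profile–profile global alignment
with average sum-of-pairs substitution scores and the same affine gap
costs, merged bottom-up. Gap removal from any row reproduces the input
sequence exactly (asserted in tests). An external command-line aligner
(e.g. MAFFT) can be substituted through a FASTA-in/aligned-FASTA-out
adapter; the internal aligner keeps the package dependency-free and
deterministic.

The catalytic-motif scan formalises what is traditionally read off an
alignment by eye. Candidate Y columns must lie in the C-terminal
window (last 35% of columns — the catalytic domain is C-terminal but
no sharp boundary exists, so the window is configurable), with
consensus Y at ≥ 0.9 conservation among non-gap rows and ≤ 0.2 gaps.
For each Y (rightmost first), upstream conserved R columns are tested
nearest-first; the spacing is measured **ungapped per row** and
summarised by the median — "around 30 residues" is a sequence-space
statement, so gappy rows must not distort it — and must fall in
[20, 40] (the printed "around 30" has no published tolerance; ±10 is a
declared default). The label is "R", then the consensus residues of
the consecutive conserved columns immediately after the R (at most 4,
covering the longest printed label), then "-Y"; families with no
qualifying pair report "no obvious one". Families below 4 rows are not
called: conservation of a 2–3-row alignment is not meaningful.

## Specificity annotation

Phage and prophage counts are merged into one "(pro)phage" class (a
prophage is an integrated phage). A family of ≥ 4 members is
"specific:<class>" when the largest merged-class fraction reaches 0.9,
otherwise "mixed"; smaller families are "small". The 0.9 threshold
reproduces the bulk of the published manual labels; families near the
threshold are reported with their computed purity so the caller can
judge. Members shorter than 200 aa are flagged as likely defective
(too short for a complete recombinase fold). The report emits two
headline percentages: proteins in specific families of qualifying size
over all proteins, and over proteins in qualifying-size families —
published headline numbers have been read both ways, so both are
computed.

## Element detection

Detection is geometry- and length-driven, so it works on a plain GFF3
without prior clustering:

- **RIT**: three consecutive recombinase genes, co-oriented, both
  pairwise CDS overlaps in 4–8 bp (nucleotide-interval overlap), total
  span 3,300–3,700 bp (±200 around the ~3.5 kb element, since the ends
  vary). Both overlaps are required (published element tables list
  both inter-CDS distances). Members are labelled A/B/C in
  transcription order. Windows sharing a gene are all reported with a
  conflict flag.
- **Tn554-like**: adjacent co-oriented recombinase pair with one
  product in 611–828 aa and one in 275–425 aa (±75 around the "around
  350 aa" partner), intergenic gap ≤ 500 bp. The next co-oriented
  non-recombinase gene downstream (in transcription direction) within
  the same limit is attached as putative TnpC. The long member's
  N-terminal extension over a canonical ~350 aa recombinase is
  reported and flagged at ≥ 400 aa.
- **BIM**: a recombinase adjacent (gap ≤ 300 bp) to a member of a
  designated conserved partner family.

Every call's diagnostics re-validate against the rules
(`validate_call`), and detection is invariant under
reverse-complementing the replicon (coordinates flipped, strands
inverted) — asserted in tests.

The repeat scanner reports exact maximal direct and inverted repeats
of ≥ 9 bp with both copies within 600 bp, seeded on k-mers and
extended to non-extendability. Near-homopolymeric segments (≥ 90% one
base) are flagged low-complexity and dropped by default, since a
homopolymer generates one "maximal repeat" per offset.

## Host network

Host strings are grouped at the genus level (first binomial token, a
"Candidatus" prefix skipped) unless the genus has a single
representative, which keeps its full species/strain label. Edge weight
between two host nodes is the raw number of families (size ≥ 2;
singleton families cannot be shared) present in both — no
normalisation, matching the shared-count convention; a Jaccard option
exists but is off by default. Components are ordered by size then
label, and `hub_impact` reports the component structure before and
after removing named nodes.

## Synthetic corpus: what it emulates, and what not

The generator emulates a desk-scale recombinase corpus: by default 8
families of 12–40 members plus 20 unrelated singletons, sequence
lengths 280–450 aa (typical full-length TBSSRs), uniform background
residues, and each member derived from its family's random ancestor by
per-site substitution at `within_family_identity = 0.6`
(member-vs-ancestor; pairwise identity between members is then ~0.37
at the site level, far above the ~0.05 background). The catalytic
R-H-...-Y residues are exempt from mutation in motif-carrying families
(spacing drawn from 28–32), so planted motif columns are perfectly
conserved. A confounder mode derives the second family's ancestor from
the first at 30% identity to exercise cluster splitting.

The identity parameter is defined member-vs-ancestor rather than
pairwise because it composes directly with the mutation operator and
keeps per-column conservation of non-motif sites low, which is what
makes the motif false-positive test sharp. The generator does **not**
emulate: realistic amino-acid composition, indel evolution,
phylogenetic correlation within families, codon-level realism of the
replicon CDSs (detector rules use lengths and coordinates only), or
shared domains between unrelated families. Passing recovery tests
therefore show that the machinery is correct under its stated model,
not that real corpora will separate as cleanly — on real data,
between-family homology (shared catalytic domains!) makes family
boundaries genuinely harder, which is exactly why the published
corpus's headline numbers are not reproducible from scratch here.

Synthetic replicons place planted elements and single-rule-violation
decoys left to right with ~800 bp spacing; each decoy violates exactly
one detector rule (wrong strand, overlap 12 bp, span 4.2 kb, long
member 500 aa, partner 1 kb away), making sensitivity and precision
exactly 1.0 the expected outcome for a correct detector.

## Numerical and determinism notes

- Coordinates are 0-based half-open internally; 1-based inclusive only
  in files (BLAST tabular, GFF3).
- One top-level seed fans out to per-stage seeds through
  `numpy.random.SeedSequence`; only the generator consumes randomness —
  the analysis itself is deterministic, including tie-breaks
  (alignment traceback order, family numbering, sweep ties, attractor
  assignment).
- Problem sizes in the acceptance script (a ~200-protein corpus, two
  30-family motif suites, one replicon suite) are chosen to exercise
  every stage at full fidelity while completing in a few minutes on
  one CPU; all sizes are parameters of `SynthParams`.
- MCL non-convergence is a warning, not an error: the best-effort
  partition is returned and flagged in the sweep report.

## Known limitations

- The E-value model is ungapped-theory with gapped constants; absolute
  E-values differ from SSEARCH/BLAST (rank order and cutoff behaviour
  are what the pipeline uses).
- The motif scan anchors on the R...Y pair plus adjacent conserved
  columns; it does not model the full catalytic pentad or structure.
- Attractor-overlap resolution (a node in two limit supports) follows
  a documented deterministic rule; genuinely overlapping MCL limit
  states are rare and the hard-partition choice is a convention.
- The host network inherits every sampling bias of the input corpus;
  no significance testing is attempted.
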