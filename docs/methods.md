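# Methods

## Scope and model of the data

The package analyses coding-strand γ-gliadin transcript sets (cDNA/EST) from
allohexaploid bread wheat together with genomic reference genes cloned from
diploid relatives of its three subgenomes (A^b^ for A, S for B, D for D).
The mature protein model is the canonical γ-gliadin layout: signal peptide
(S), unique N-terminal domain (I), repetitive domain R1 (II), non-repetitive
NR1 (III, six conserved cysteines, opens with the NPC tripeptide),
repetitive R2 (IV), and non-repetitive NR2 (V, two conserved cysteines,
ends in the MCN tripeptide). All coordinates are 0-based half-open;
nucleotide positions refer to the input strand (inputs are coding-strand by
contract; no reverse-complement search).

## Contig assembly

Pairwise identity uses global alignment (match +1, mismatch −1, gap −2)
with terminal gaps scored at −1.1 per column: cheap enough that a partial
EST nests against a full-length cDNA essentially free, but more than half a
mismatch so the aligner never shifts an equal-length pair to clip a
terminal mismatch into the overhangs. Identity = matches / aligned columns,
terminal-gap columns excluded. Clustering is single linkage over edges with
identity ≥ 0.98 and mutual overlap ≥ 300 nt (the shortest credible shared
region); single linkage rather than centroid clustering because a 98–99%
identity band implies transitive merging. Clusters below 4 members go to a
reported "minor" bin. Consensus is a star alignment to the longest member
followed by per-column strict majority (ties A<C<G<T, never gap; columns
with a strict gap majority are dropped). Contig ids are assigned by
descending depth, then lexicographically smallest member id, so repeated
runs are byte-identical.

## Distances, trees, genome assignment

Distance models are the closed forms: p-distance; JC69 d = −¾ ln(1−4p/3);
K2P d = ½ ln 1/(1−2P−Q) + ¼ ln 1/(1−2Q) with P, Q the transition and
transversion proportions. Sites with gaps or ambiguity codes are excluded
per pair (pairwise deletion) or from the whole alignment (complete
deletion). Saturated pairs (log argument ≤ 0) are capped at 5.0 subs/site
with a warning and listed on the matrix rather than emitted as infinities.
The default model is K2P; it is an approximation to composite-likelihood
distances produced by older tools, so within-group figures computed here
are comparable only to ~±15% with values from those tools.

Neighbor joining is the Saitou–Nei agglomeration on the Q-criterion, ties
broken by the lowest (row, column) index pair; negative branch lengths are
clamped to zero with the deficit moved to the sister branch, preserving the
joined pair's path length. On additive matrices this recovers the
generating topology exactly (property-tested against the generating tree
and cross-checked against scikit-bio's NJ). Bootstrap resamples alignment
columns with replacement from a single seeded stream; support = % of
replicate trees containing each original internal bipartition.

Genome assignment replaces visual tree inspection with an explicit rule:
the contig consensus is aligned pairwise to every labeled reference, mean
model distance per genome is computed, and the contig takes the locus of
the nearest genome (A→Gli-A1, S/B→Gli-B1, D→Gli-D1) if the margin to the
runner-up is ≥ `min_margin` (default 0.01 subs/site), else "unassigned".
Contigs whose true relatives are absent from the reference panel (the
published analysis rescued such cases with an external homology search)
legitimately come out unassigned here.

## Epitope screening and annotation

The registry ships the nine canonical γ-gliadin cores with old and new
nomenclature; matching is exact and overlapping occurrences all count —
census semantics require instance counts, since the published per-transcript
totals exceed distinct-type counts. Deamidation rules, applied per
glutamine in order: (R1) QxP with x ≠ P → primary; (R2) Q immediately
before P → never deamidated; (R3) membership in a curated
(peptide, position) table of moderate targets → moderate; else none. The
moderate table is data, not a rule, deliberately: the published variant
annotations contain identical local contexts (e.g. two QQQ glutamines one
position apart) with different classifications, so no position-free
sequence rule can generate them, and generalisation is refused. Protease
rules: trypsin cleaves after K/R unless before P; chymotrypsin-high after
F/Y/W unless before P; chymotrypsin-low after F/L/M/W/Y/H unless before P,
with H additionally blocked before M/W. Pepsin is omitted from the defaults
(the published figure annotates only trypsin/chymotrypsin); the enzyme
table is overridable. Resistant fragments are the maximal intervals between
consecutive cleavage sites containing at least a configured number of
epitope matches.

## Census

Each transcript contributes its contig's consensus-protein matches, so a
cell of the epitope × group table is instances × depth; group and locus
frequencies are N_epitopes/N_transcripts rounded half-away-from-zero to one
decimal, shares to integer percent (half-away-from-zero reproduces the
printed 49/59/25/16/9% figures from the underlying ratios). Pseudogene
contigs are excluded by default and counted in a table note. The
`aggregate_printed_counts` entry point applies the same arithmetic to an
already-counted matrix; recomputed sums are authoritative and disagreements
with supplied printed marginals are flagged, never arbitrated (the shipped
published table has two such disagreements: one row sum and the grand
total; the printed shares are consistent with the recomputed grand total,
6126).

## Synthetic data generator

The generator emulates the study conditions so every stage is testable
offline: three genome groups (A, S, D), per-genome weighted repeat-unit
grammars that plant epitope cores with genome-specific composition (the D
grammar carries the 17-mer repeat and the resistant 26-mer, S a VIIa unit
and spacers), and the fixed domain scaffold described above. Proteins are
reverse-translated with a fixed codon table (one frequent wheat codon per
amino acid; Q = CAA so a single C→T transition creates a TAA stop).
Divergence is modelled as seeded per-site substitution with a 2:1
transition:transversion bias; the per-branch substitution probability q is
solved from the target *pairwise* p-distance D via
2q(1−q) + 0.625q² = D, because two lineages drawn independently from a
common ancestor otherwise undershoot the target. Substitutions are redrawn
if they would create an in-frame stop or a new cysteine codon, and the
start codon, NPC/MCN anchors and existing cysteines are protected — the
conserved-cysteine skeleton and the domain anchors survive any configured
divergence, everything else drifts. Transcript depths are log-uniform over
4–220 (heavily right-skewed, as in seed-storage EST sets); pseudogenes are
injected per gene at the configured rate by converting a CAA codon in R1
to TAA; optional 5′ truncation always keeps ≥300 nt of the 3′ region so
assignment over domains III–V stays possible.

Default divergences are 0.216 within genomes (the scale reported for
D-genome paralog families; S and A families are reported up to 0.423 and
0.789) and 0.43 between genome founders. Recovery analyses and the
acceptance checks use a 3:1 between:within ratio (0.24 / 0.08) with 2–4
genes per genome and depths 4–20, sizes at which the whole pipeline runs in
seconds per seed; accuracy is averaged over 10 seeds.

What the generator does not emulate — and hence what passing tests do not
show about real data: per-base indels inside the repeat domains (real
repeats expand and contract; here unit counts vary but unit-internal indels
do not occur), repeat homogenisation (uniform point substitution erodes
planted epitope cores faster than concerted evolution would in real
repeats, so high-divergence synthetic censuses are sparser than real ones),
allelic variation within a gene, and chimeric or low-quality reads.

## Numerical and design choices

- Signal peptide is a fixed-length prefix (default 19 residues), not
  predicted; no predictor is part of the contract.
- Repeat/non-repeat boundaries use a repeat-content heuristic: the first
  8-residue window ≥50% {P,Q} (after the signal for I/R1, after NR1's sixth
  cysteine for NR1/R2), snapped to the window's first P/Q residue so a rich
  window straddling a non-repetitive tail does not pull the boundary left.
  NR2 is a fixed-length region (default 33 aa) ending at MCN — no
  compositional signal separates R2 from NR2, so a length convention is
  used, and anchoring it on MCN alone keeps NR2 stable even when divergence
  erodes the repeat signal.
- Pseudogene proteins are cut at the first internal stop; the stop report
  carries the preceding 12 residues (the published truncations are
  recognisable by that motif).
- Rounding is decimal half-away-from-zero throughout the census.
- IUPAC ambiguity codes other than ACGTN are accepted on read and translate
  to X; X never matches an epitope core.
- All randomness (generator, bootstrap, acceptance simulations) flows from
  single integer seeds; derived seeds stay below 2³¹.

## Known limitations

Exact contig counts from the original EST snapshot are not reproducible
(the public EST set has drifted) and are not an acceptance surface; the
star alignment is adequate for near-identical contig members but is not a
general MSA; composite-likelihood distances are not replicated bit-exactly;
and the moderate-deamidation table covers only the curated variant
peptides — unknown peptides receive primary/none classifications only.
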