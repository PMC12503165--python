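# Methods

This note records the models, rules and numerical choices behind `ai2net`,
and what the synthetic test data do and do not establish.

## Genome ingestion and quality filtering

Genomes are consumed already annotated (Prokka-style GFF3 or GenBank plus a
protein FASTA keyed by locus tag) and already dereplicated to species
representatives. Coordinates are 1-based inclusive everywhere. Genes
without a translation (RNAs, pseudogenes) are kept for neighbourhood
analysis with an empty sequence and excluded from protein scans.

The quality rule is strict on both sides: a genome passes iff
completeness > 90 % **and** contamination < 5 %. "Over 90 %" is read as a
strict inequality, so a genome at exactly 90.0 % is rejected; both bounds
are configurable (`QualityThresholds`). Genus representatives prefer
isolates outright; within the preferred tier the highest completeness wins.
Completeness alone is used as the "genetic integrity" score — whether a
combined score would be more faithful is genuinely open, and the choice is
flagged here. The remaining tie-breaks (lowest contamination, then
lexicographic genome id) are purely for determinism.

## Synthase census

Detection is semantic, against a versioned lexicon
(`src/ai2net/data/lexicon.yaml`) rather than an opaque set of ad-hoc
greps: per signal class, exact case-insensitive gene names, whole-word
product keywords, and for the three multi-gene pathways (HAQs via
pqsABCD or phnAB, the aminophenol–thiazole signal via ambBCDE,
dialkylresorcinols via darABC) alternative gene sets of which one must be
complete anywhere in the genome — co-occurrence, not adjacency, because no
adjacency requirement is defensible from the biology of these operons
across taxa. Keyword matching guards token boundaries (so "tryptophanase"
does not match "tryptophanase-like") and rejects a trailing qualifier
blacklist ("inhibitor", "antagonist", ...). The AHL entry carries the 73
synthase gene names but no standardised product wordings; AHL keyword
recall is therefore weaker than gene-name recall, a known fidelity limit.

The genus presence matrix defaults to the union of calls over a genus
(each genus row is true if any member carries the signal); a
representative-only mode is available.

## Receptor detection

**LuxP / LsrB.** LuxP is a pure keyword call ("Autoinducer 2-binding
periplasmic protein LuxP", case-insensitive substring; partial matches
like "LuxP-like" do not contain the full keyword and are not called).
An lsrB annotation is *functional* only with (a) one gene each of
lsrA/C/D/B on one contig and strand, consecutive members separated by at
most 500 bp of intergenic sequence and at most 0 intervening genes, and
(b) lsrK and lsrR anywhere in the genome. All geometry knobs are
parameters (`OperonParams`), including a strict A-C-D-B order mode (off by
default — the permissive mode accepts any internal order). These defaults
are an interpretation: the operon concept fixes contiguity and
co-orientation but not exact distances.

**dCache_1 / GAPES1.** Candidates come from profile-HMM search. Because
the canonical profile databases cannot be redistributed here, the bundled
profiles are built at run time with pyhmmer from synthetic seed alignments
derived from the bundled reference ligand-binding domains and synthetic
output-domain bases; externally supplied HMMER3 files drop into the same
registry and are searched with their gathering cutoffs when present.
Synthetic profiles use a conditional E-value ≤ 1e-5.

The transmembrane filter is a deterministic Kyte–Doolittle sliding window
(window 19, threshold 1.6, overlapping windows merged), chosen so the
tests need no external predictor; precomputed TM tables from an external
tool can be injected instead. The default topology rule keeps a dCache_1
hit only when the protein has ≥ 2 predicted TM segments and the domain
envelope lies between two of them (10 residues of edge overlap tolerated —
hydropathy windows bleed slightly into domain boundaries); a permissive
≥ 1-segment mode exists. GAPES1 candidates are **not** TM-filtered by
default: the class is defined within one protein family of
*Enterobacteriaceae* c-di-GMP synthases and the sensible default is to let
the residue screen decide; a flag applies the filter.

**Residue screen.** The screened positions are R126, W128, Y144, D146,
D173 in PctA numbering (dCache_1) and Y210, D239 in YeaJ numbering
(GAPES1). The candidate envelope is aligned globally against the reference
domain window with BLOSUM62, gap open 10, gap extend 0.5; Biopython's
PairwiseAligner supplies a deterministic first traceback, which is this
package's tie-break. A screened position aligned to a gap fails; residue
comparison is exact identity, with no conservative-substitution allowance
— the screen counts domains that carry *exactly* the documented residues.
An MSA mode (external mafft) aligns all candidates together with the
reference and reads residues off the reference-anchored columns; pairwise
is the default because it is per-candidate deterministic and
order-independent, and the two modes are tested to agree on candidates
within 40 % divergence of the reference. The conservation profile uses the
MSA route, drops columns gapped in the reference, and reports per-position
residue frequencies (gaps counted separately; rows sum to 1).

**Reference fixtures.** The bundled PctA and YeaJ sequences are synthetic
stand-ins (no database access is assumed): full-length sequences
constructed with the documented residues at the documented full-length
positions, a sensory domain window (PctA 40–280, YeaJ 35–300) flanked by
two hydrophobic helices, and a realistic globular composition elsewhere.
Loading asserts the residue layout, which guards against off-by-one
fixture errors. Conclusions that depend on the *real* PctA/YeaJ sequences
(e.g. exact alignment coordinates against natural homologs) are outside
what these fixtures can establish.

## Functional typing

Modules are assigned from the full-protein domain scan by first match in
the precedence order MCP → CSP → HK → STK → SP → AC/GC (manifest:
`src/ai2net/data/modules.yaml`; HK requires the DHp-family *and* ATPase
domains together). Real architectures rarely co-match; the order puts the
chemotaxis output first, and all co-matches are preserved in the call
evidence. LuxP → LuxPQ, LsrB → Lsr-import and GAPES1 → CSP are canonical.
Module counts are registry-sensitive: with a different accession manifest
the per-module split would shift, which is why the manifest is editable
and shipped as data.

## Expression

TPM uses genome-wide denominators (every gene in the count table, not just
QS genes). Aggregation over a state's samples is the mean by default (max
optional) — the aggregation level is not prescribed by the thresholds
themselves, so it is a recorded parameter. Flags: *expressed* means
aggregated TPM > 0; *high* means > 0.2 (luxS), > 0.1 (LsrB), > 0.01
(dCache_1, also used for GAPES1 and as the LuxP floor, which have no
separate stated threshold). Co-expression requires the synthase and at
least one receptor kind expressed in the same state. Raising any threshold
can only shrink the corresponding flagged set (tested).

## Networks

Roles partition species exactly: both / producer_only / receiver_only /
none. The bipartite network uses an explicit AI-2 signal node; per species
there is one `produce` edge and one `sense:<module>` edge per distinct
module, encoded as a comma-joined edge-type attribute on the single
species–signal edge so the graph stays a simple `networkx.Graph` that
survives a GraphML round trip. A directed producer→receiver projection is
exported as a derived view, since the species–species formulation of the
bipartite figure is underdetermined. The summary verifies
`both + receiver_only = receptor species` and
`both + producer_only = synthase species` on every run.

## Synthetic data

The generator is the package's study-condition definition, not a test
convenience dial. The default community has 60 species across seven gut
phyla: 40 luxS⁺ species (three dual-copy, one copy planted by product
wording alone), 12 dCache_1 receptor proteins of mixed modules (4 with one
screened residue mutated), 3 GAPES1 (1 mutated), 6 complete and 4 broken
lsr operons (missing lsrK / lsrR / lsrD, and one 2000-bp gap), 2 LuxP
genes, 30 decoys (soluble intact domains, composition-preserving shuffles,
random proteins) and a background of housekeeping genes. Receptor proteins
are head + TM helix + sensory domain (reference domain with background
substitutions kept ≥ 3 residues away from screened positions, so the
alignment mapping is unambiguous) + TM helix + output domain. Identical
plan + seed reproduces every file byte for byte.

Counts are negative-binomial (dispersion 0.3, the standard overdispersed
RNA-count model) with expected TPM equal to the plan target: per state the
focal QS genes take their planned targets, every other gene shares the
residual TPM budget uniformly, and the mean count is
`target × length_kb × depth` with depth 50 (≈ 30 M reads/sample over the
default community, a realistic metatranscriptome depth). Targets in the
default two-state design keep at least a twofold margin from every
decision threshold so sampled flags equal analytic flags at any fixed
seed; the design plants healthy-state co-expression in Lachnospiraceae and
unhealthy-state co-expression in Enterobacteriaceae.

What the generator does *not* emulate: phylogenetic sequence divergence
(variants are i.i.d. substitutions from the references, not tree-shaped),
annotation noise, assembly artefacts, read-level error, or
abundance–expression coupling. Passing tests therefore demonstrate
correctness of the rules and their implementations on clean inputs with
known truth; they do not measure sensitivity on diverged natural
sequences, where HMM recall and alignment mapping would be the binding
constraints.

## Problem sizes

The shipped tests and the acceptance script run the full pipeline on the
60-species community (≈ 1 500 proteins), 100 randomized operon fixtures
of ≤ 50 genes, exhaustive 19-substitution scans at all 7 screened
positions, and 20–400-sample count simulations; this keeps a complete run
in the tens of seconds while exercising every rule, and the community
composition (not its size) carries the study conditions.
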