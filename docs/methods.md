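# Methods

This note documents the models and procedures implemented in `metaptgx`,
the parameters that matter, the numerical and design choices made where the
design was genuinely open, and what the synthetic fixtures do and do not
demonstrate.

## Six-frame ORF source

The in silico annotation source scans all six frames of each replicon for
open reading frames bounded by an in-frame stop codon, with start codons
{ATG, CTG, TTG, GTG} (bacterial initiator tRNA reads the alternatives as
formyl-Met, so the initiator is always translated as M). Genetic code:
NCBI translation table 11, pluggable.

* **One maximal ORF per (strand, stop)** is emitted by default — the
  5'-most qualifying start. Internal-start proteoforms are representable
  through the annotation-cluster variant mechanism, which keeps the
  database minimally redundant; `emit_internal_starts=True` enumerates
  them for sensitivity studies.
* **`min_len` = 18 aa, inclusive** (protein length = codon count − 1 ≥ 18).
  The size threshold is user-selectable.
* **N handling:** a codon containing N is neither start nor stop, and any
  ORF that would span it is dropped. Rationale: a translated X residue
  would poison peptide-level uniqueness logic silently.
* **Circular replicons:** ORFs spanning the origin are found only with
  `wrap_origin=True`, by scanning a doubled sequence and deduplicating on
  (strand, stop key); reference annotations rarely annotate such ORFs, so
  the default is off. Wrap ORFs keep `stop_end > len(replicon)` so the
  interval stays divisible by 3; the stop key is reduced modulo the
  replicon length.
* **Coordinates** are 0-based half-open on the forward strand everywhere
  (`start` = leftmost base, `stop_end` = one past the rightmost); GFF3 I/O
  converts to and from 1-based inclusive at the boundary. The **stop key**
  that annotation clustering groups on is the forward-strand coordinate of
  the stop codon's 3'-most base: `stop_end − 1` on the plus strand, and
  `start` (the interval's low side) on the minus strand, which is
  unambiguous under either CDS-includes-stop dialect after normalization.

## Annotation clusters, anchors, variants

Gene models from all sources are partitioned by (replicon, strand, stop
key). The anchor is the member from the earliest source in the configured
hierarchy; ties within one source break by longest proteoform, then
5'-most start, then locus id — a total order, so anchor selection is
invariant under input order (property-tested over 100 shuffles). Members
sharing the anchor's exact interval become provenance notes on the anchor
rather than variant entries.

**Variant sequences.** A variant entry carries the proteoform's N-terminal
sequence from its own initiator through the **(1 + k)-th cleavage boundary
at or 3' of the divergence point**, where k = `extra_cleavage_sites`
(default 1) and the divergence point is the 3'-most of the anchor and
variant starts in the variant's protein coordinates (for an extension, the
position where the anchor's sequence begins; for a reduction, its own
N-terminus). If the proteoform has fewer boundaries, the full proteoform is
emitted — e.g. a small protein with no Asp-N site is representable only in
full.

This prefix is exactly sufficient in the following sense: every fully
specific peptide with ≤ k missed cleavages that distinguishes the variant
proteoform from the anchor (i.e. occurs in the variant's digest but not
the anchor's) is a digest product of the emitted entry. Sketch: a
distinguishing peptide must start at a boundary strictly before the
divergence point d (a peptide starting at or after d has the same sequence
and boundary context in the anchor); with ≤ k missed cleavages it ends no
later than the (1+k)-th boundary after the last boundary before d, which
is the (1+k)-th boundary ≥ d — the emitted prefix end. The k = 2 case is
asserted wholesale in the acceptance suite on randomized clusters for both
proteases. The default k = 1 trades database size against missed-cleavage
coverage: the distinguishing zero-missed-cleavage peptide is always
covered, while fully covering a 2-missed-cleavage search requires k = 2.

**Reductions are emitted by default** (`emit_reductions=True`): a shorter
proteoform's N-terminal peptide is enzymatic only by virtue of being a
protein N-terminus, so "Full"-specificity searches can only find it if the
reduction has its own entry. They are labeled separately from extensions
in all reports.

**Pseudogenes** are excluded by default; `keep_pseudo=True` loads the
proteoform up to the first internal stop, for expressed-pseudogene
studies.

Variant entries whose emitted sequence duplicates another entry of the
same cluster are merged with a provenance union; identical-start models
from different sources likewise merge, so within a species database no two
entries share (sequence, cluster).

## Search databases

Databases are protease-specific. Entry headers follow the grammar
`{species}|{replicon}|{strand}{stop_key}|{source}|{role}[|{variant_start}]`
with a bit-exact codec, and round-trip through FASTA with metadata intact.
Decoys (one per target, `DECOY_` prefix, same length) are reversed
(involution-stable) or seed-shuffled, appended after the targets.

**Composition statistics** count, per species and combined: clusters
anchored by the reference source (and the subset ≤ 100 aa), extension
variant entries of reference-anchored sProtein clusters, clusters anchored
by each non-reference source with anchor ≤ 100 aa ("additional" sProteins
— mutually exclusive by anchor source), and totals. A cluster's
sProtein status is decided by its **anchor's** full proteoform length
(`sprotein_max_len` = 100, configurable); this makes the per-source rows
additive and the combined row a column-wise sum, which is asserted.

**Identifiability** is the fraction of target entries with ≥ 1 class-1a
peptide under the digestion window (≤ 2 missed cleavages, 6–50 aa, I/L
equivalent, no mass filter — typical engine defaults, configurable). On
synthetic databases it is tested for exact agreement with a brute-force
digest-and-count oracle; the small stop-rich fixtures typically come out
at 100%, far above what a real genome-scale database shows, because the
generator plants few and dissimilar sequences.

## Digestion and peptide classes

Fully specific ("Full") digestion: trypsin cleaves after K/R with cleavage
before P suppressed (the common SequestHT convention; configurable,
because engines differ), Asp-N cleaves before D (not E; configurable).
Protein termini count as boundaries; peptides retain start offsets and
missed-cleavage counts. The digest is cross-checked against
`pyteomics.parser.cleave` with matching rules.

Classification precedence, pinned by tests: a peptide mapping to > 1 entry
is **2a** whenever all entries lie in one cluster — even if their
sequences are identical; the identity-group test (**3a**) applies only
across clusters; anything else is **3b**. I/L equivalence is on by default
(collapsing to the joint symbol J) since MS/MS cannot distinguish them;
collapsing can only merge peptides, so it never increases the 1a count
(property-tested).

## PSM filtering

Engine exports are normalized (flank notation `K.AAAR.D` stripped,
peptides upper-cased; dialect maps provided for two common layouts plus a
generic one). Target-decoy q-values use the standard construction: FDR at
threshold t = (#decoys ≥ t)/(#targets ≥ t) with tied scores counted
together, q = the minimum FDR over thresholds accepting the PSM, capped at
1 — monotone non-increasing in score and equal to a brute-force threshold
sweep (acceptance-tested). Protein-level scores are best-PSM per entry;
protein FDR is estimated **per engine** (engines score on incommensurable
scales), falling back to engine-provided q-values when a table carries no
decoys.

Identification requires, within at least one engine: ≥ 1 class-1a/3a
peptide, protein q ≤ 0.01, and the engine gate (sequest: summed score ≥ 2;
msgf and unknown engines: ≥ 2 PSMs). Novelty is a **cluster-level**
property — no reference-source member (including merged provenance) — so
peptides from proteolytic maturation of annotated proteins, which map to
reference-anchored entries, can never create a novel candidate (asserted
end to end with planted maturation-style evidence). Source thresholds
(reference 2, ab initio predictors 3, in silico 4) apply to the class-1a/3a
PSM count **summed over proteases and engines**; a per-protease mode is
available. Raising any threshold can only shrink the passing set
(property-tested).

The candidate report mirrors the published evidence-table layout
(candidate, species, source, size, peptides/PSMs per protease); the
summary counts candidates with evidence per protease and reports
overlap% = 100·|both|/|Asp-N| (None when no Asp-N identifications exist).

## Spectral validation

The match factor is a √-intensity normalized dot product:
peaks are paired greedily by nearest m/z within ± 0.02 Th (each peak used
once, ties broken by larger intensity product), similarity =
(Σ√(I_q·I_r))² / (ΣI_q · ΣI_r), scaled to 0–999. The reverse match is the
same score after discarding query peaks with no reference partner, hence
reverse ≥ match always. Precursor agreement (± 0.01 Th) is reported but
does not gate. The widely used library-search software computes an
undocumented, possibly m/z-weighted variant; this formula is an
approximation that preserves the scale and the ≥ 500 / ≥ 700
(match/reverse) validation semantics, and the tests pin this module's
formula, not the proprietary one. Scores are invariant under joint
intensity scaling and the forward match is symmetric (both asserted).

Predicted reference spectra use singly charged b/y ions from monoisotopic
residue masses (proton 1.007276), carbamidomethyl-C (+57.02146) fixed, no
variable modifications, unit intensities.

Validation status per candidate: *validated* iff any tested peptide meets
both thresholds, *rejected* if all tested fail, *not testable* when no
spectrum could be acquired (synthetic peptides that fail to ionize).

## Characterization

* **pI**: bisection of the Henderson–Hasselbalch net charge on pH ∈ [0, 14]
  to 0.001, Bjellqvist pKa set with residue-specific terminal values
  (ProtParam-compatible; alternative sets pluggable — switching sets moves
  pI by up to ~0.5 pH for cysteine-rich sequences). The returned pH has
  |net charge| < 0.01 by construction; agreement with the biopython
  ProtParam implementation is within 0.05 when its search bracket is
  widened to [0, 14] (its default bracket clamps strongly acidic
  proteins).
* **GRAVY**: mean Kyte–Doolittle hydropathy. **Aliphatic index**:
  X(Ala) + 2.9·X(Val) + 3.9·(X(Ile)+X(Leu)) in mole percent. Both depend
  on composition only.
* **NSAF**: (PSM_i/L_i)/Σ_j(PSM_j/L_j), sums to 1 (tested to 1e-12).
  **TPM**: 1e6·rate_i/Σrate, sums to 1e6 (tested to 1e-6). Multi-mapping
  reads over duplicated gene copies are resolved by adding
  multimapped/n_copies to each copy's unique count.

## Synthetic communities

`generate_community` plants, per species, n_genes reference genes (default
20, 40–150 aa, both strands), of which n_start_variants (default 2) get an
upstream in-frame start visible only to the predictor source, and
n_hidden_sorfs (default 3) small ORFs of 18–100 aa present in the genome
and predictor source but absent from the reference — the ground-truth
novel sProteins. Intergenic spacers (30–60 bp) are drawn from a codon pool
of the three stop codons and their reverse complements, so spurious
six-frame ORFs stay rare and desk-scale; defaults (2 species, ~12–14 kb
genomes) keep the full pipeline in seconds. Everything is deterministic
per seed (byte-identical outputs, tested).

Simulated PSM tables realize a per-entry spectral-count plan using the
entry's own class-1a/3a peptides, with target scores ~ Normal(gap, 1) and
decoy PSMs ~ Normal(0, 1) at a configurable rate — two overlapping
location families, sufficient to exercise target-decoy estimation without
modeling engine internals. The expected filter outcome is computed
analytically from the plan, never from the pipeline under test.

**What passing these tests shows — and does not.** The fixtures verify the
combinatorial and statistical machinery exactly: clustering, variant
coverage, class logic, FDR, thresholds, recovery. They do not emulate real
genomes (GC skew, overlapping genes, Shine–Dalgarno context, realistic
intergenic ORF density), real spectra (isotopes, co-isolation, intensity
structure), or engine score distributions; absolute figures such as the
fixtures' 100% identifiability or clean FDR separation therefore do not
transfer to real communities, where the published workflow's
genome-scale databases show >90% class-1a identifiability and require the
full multi-tier filter.

The package also ships digitized copies of two published worked-example
tables (eight-species community database composition; 31 novel sProtein
candidates with per-protease evidence). The extracted table text is
undelimited digit runs; the digitization was resolved against the tables'
own row/column identities (every column of the composition table sums
exactly to its printed Combined row; the evidence table reproduces the
stated 31 rows, 28 trypsin-supported rows, and the three trypsin-free
candidates). One candidate's protease attribution differs between the
source's narrative and its printed table; the printed table is shipped
verbatim, and summary statistics are always recomputed from the rows
rather than asserted.

## Problem sizes

Defaults used by the test suite and acceptance script: 2-species
communities with 20 (tests: 12–20) genes and 3–4 hidden sORFs per species,
genomes ≤ 14 kb; six-frame oracle checks on 1–5 kb random sequences;
class-logic oracle on a 200-entry database; plant-recovery across 3 seeds
and 4 threshold settings. The entire suite runs in a few seconds on one
CPU.
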