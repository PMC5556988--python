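# Methods

`tepaleo` implements the standard comparative-genomics workflow for
reconstructing the history of a DNA-transposon family across genome
assemblies: census the copies, characterise their structure, rebuild the
ancestral element per species, date the amplification waves, and ask
whether the cross-species pattern is compatible with vertical descent.
This note records the models, the defaults and why, the numerical choices,
and what the simulation-based validation does and does not show.

## The substitution model and dating convention

All divergences are Kimura two-parameter (K2P) distances,

    d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)),

with `P` the transition and `Q` the transversion fraction over usable
sites.  Sites where either row carries a gap or an ambiguity code are
pairwise-deleted — complete deletion would discard most sites when MITEs
(internally deleted derivatives) are aligned to full-length elements.  When
the log argument is non-positive the distance is *saturated*; this is
raised as a distinct `SaturationError` and flagged in divergence tables,
never returned as a silent NaN.

Insertion ages follow `T = k / (2 r)`: after insertion, a copy and the
(reconstructed ancestral) consensus are separated by two evolving lineages,
so the copy-to-consensus distance `k` accrues at twice the per-lineage
neutral rate `r` (substitutions/site/My).  The same convention is applied
consistently everywhere a time appears: a pair of lineages separated `T` My
ago is expected to show pairwise divergence `2 r T`.  The bundled rate
table carries the published per-species neutral rates for the study system
(chicken 1.9e-3, turkey 2.0e-3, hornbill 2.3e-3, black grouse 1.9e-3,
bobwhite 1.9e-3, plus the water-bird lower bound 1.6e-3 used for
rate-sensitivity re-dating via `rescale_ages`).

## The simulator

The synthetic-data generator is the generative inverse of the estimators.

- **Elements.** A random-composition ~1.3-kb element whose first and last
  28 bp form a perfect inverted repeat (the mariner-family bauplan);
  MITE derivatives keep configurable 5'/3' termini (default 275 + 275 =
  550 bp) and record the internal deletion.
- **Mutation.** Sites evolve under the exact continuous-time K2P process:
  for branch length `d` the transition/transversion probabilities are the
  closed-form P(t) entries with rates scaled so one unit of `d` is one
  expected substitution per site and alpha/beta = kappa (default 2).  The
  K2P estimator applied to an input/output pair is therefore unbiased;
  tests verify recovery within three binomial standard errors up to
  d = 0.3.  Substitution-only: lengths are preserved, so simulated
  families exercise the gap handling of the aligners only through MITE
  deletions, not through small indels.
- **Planting.** Copies are spliced between background bases (so copies can
  never overlap) flanked by a duplicated `TA` target site, on either
  strand, with expected divergence `2 r age` — the dating convention
  inverts exactly.  Insertion points keep >=300 bp of background spacing so
  distinct copies are not merged into one locus by the hit merger.  Truth
  tables record exact 0-based half-open intervals.
- **Two-lineage scenarios.**  Ortholog pairs (default 50, the published
  design) diverge by `2 r Td` scaled by a per-gene lognormal(0, 0.25)
  rate multiplier, reproducing the bulk-plus-tail shape of real host-gene
  distance distributions.  The element masters of the two lineages diverge
  by `2 r min(Th_A, Th_B)`: for a transfer this is the transfer age; for
  the vertical control (`Th = Td`) it equals the gene expectation.  Each
  lineage's copies then diverge from their master by `2 r Th`.  This is the
  only convention under which (i) dating recovers the invasion ages,
  (ii) the vertical control puts the TE consensus distance inside the gene
  bulk, and (iii) a transfer puts it in the extreme lower tail.
- One seeded `numpy` generator threads through every step; identical seeds
  give byte-identical genomes, truth tables and ortholog sets.

What the simulator does **not** emulate: selection, recombination, nested
insertions, codon structure in "genes", small indels (available behind the
deletion machinery only as MITE derivation), assembly artifacts, and
low-complexity sequence.  Passing the validation experiments therefore
shows the chain of estimators is self-consistent and correctly inverts its
own generative model at realistic parameter values — not that it is robust
to assembly error or compositional heterogeneity in real assemblies.

## Homology search

The copy census re-implements a blastn-like screen so the package is
self-contained and its statistics are testable: exact 11-mer seeds on both
strands, clustering of seeds by diagonal, an ungapped X-drop triage
extension, and a gapped affine extension (match +2, mismatch -3, gap open
5, extend 2 — the blastn defaults) anchored at the seed and terminated by
row drop-off.  E-values use Karlin–Altschul `E = K m n exp(-lambda S)` with
`lambda` solved numerically from the scoring scheme and the observed genome
composition, `n` doubled for the two strands, and `K = 0.1` (conventional
default; K has no closed form, enters only linearly, and every decision at
the published `E <= 1e-10` cutoff has enormous margin — a planted 1.3-kb
copy at 10% divergence scores ~2000 while the random-background maximum on
5 Mb is ~40).  Gapped statistics reuse the ungapped `lambda`, the standard
approximation.  HSPs on the same contig and strand within 100 bp are
merged into loci (one MITE yields two HSPs against a full-length query —
its two retained termini — and must come back as one locus); copies are
extracted with up to 200 bp of flanking sequence, minus-strand copies
reverse-complemented to element orientation with genomic coordinates kept.

Low-complexity masking is off by default (mirroring the published search);
random-background specificity is instead guaranteed by the E cutoff and
verified by the 20-genome null experiment.

## Structural annotation

- **TIRs.**  The first and last 60 bp of a copy are compared (one side
  reverse-complemented) over all ungapped offsets; the best segment with
  length in [20, 40] bp and identity >= 0.8 is reported, scored as matches
  minus mismatches so a full imperfect TIR beats a shorter perfect core.
  The false-positive rate on random 1-kb sequence is under 5%.  Detection
  compares two *independently* diverged termini, so per-site agreement is
  roughly `(1-p)^2 + p^2/3`; TIR detectability consequently decays from
  ~99% at copy divergence 0.05 to ~2/3 at 0.15.  This is a property of the
  data, not the detector — it bounds what any terminus-vs-terminus method
  can call "conserved TIRs" in old families.
- **TSD.**  The `TA` duplication is called iff the 5' flank ends with it
  and the 3' flank begins with it.  Because local-alignment copy
  boundaries can be off by a base or two at diverged termini, TSD recovery
  degrades with copy age; the TSD is annotated but deliberately not used
  in classification.
- **ORFs.**  Six-frame ATG-to-stop scan, getorf-like semantics: the
  minimum (default 300 aa, i.e. `-minsize 900`) applies to the translated
  peptide excluding the stop; degenerate bases translate to X and never
  form a start or stop.  Ties at exactly 300 aa count as coding-capable.
- **Classes.**  TIR and a >=300-aa ORF -> potential autonomous; TIR only
  -> potential non-autonomous (MITEs); ORF only -> potential coding;
  neither -> partial.  Size classes by length band: 1200–1400 full-length,
  450–650 MITE, otherwise partial — the published census-table bands.
- **Conservation.**  Sequence-logo figures are replaced by their numeric
  content: per-column base frequencies and information content
  `IC = 2 + sum f log2 f` bits, gaps/N excluded from column totals, no
  small-sample correction by default.

## Consensus and distances

Per-species consensus elements are built by star alignment: every copy is
semiglobally aligned (affine gaps, free terminal gaps) to a reference —
the search query by default — rather than by a full multiple alignment.
For majority voting over a family derived from one reference this is
adequate and keeps the package dependency-free; it is *not* a general MSA
and will not recover alignments that require copy-to-copy information.
Columns are reference positions plus insertion columns supported by more
than half the copies; a column is emitted when its non-gap coverage is at
least 20% of the copies (so an all-MITE family yields a MITE-length
consensus); majority ties break alphabetically and a gap wins only by
strict majority (dropping the column).  Rebuilding a consensus from itself
is the identity.

The neighbor-joining utility is a deterministic textbook implementation
(Q criterion, ties by label order, negative branch lengths clamped to 0)
intended for clustering consensus matrices, not for publication-grade
phylogenetics; tests cross-check it against an independent NJ
implementation on additive matrices.

## The transfer test

For a species pair, the TE distance is the K2P between the two consensus
elements and the reference distribution is the K2P of single-copy ortholog
pairs.  `fraction_greater` is the share of genes strictly more diverged
than the TE (ties count against transfer).  The published analysis judged
"shorter than 92% of host genes" to indicate transfer; the package makes
that implicit rule explicit: HT at `fraction_greater >= 0.90`, vertical
in [0.25, 0.90), and *inconclusive* below 0.25 — a TE far above the gene
bulk is anomalous (possible alignment or consensus failure) and should not
be silently called vertical.  Both thresholds are configurable.

Age histograms default to 6.25-My bins, chosen so the landmark ages of the
study system (18.75, 37.5, 87.5 My) fall on bin edges; peaks are strict
local maxima holding at least 5% of copies, with runs of equal-count
adjacent maxima merged.

## Validation experiments and problem sizes

`tepaleo.experiments` fixes the desk-scale study conditions used by the
tests and the reproduction script: mining recall on a 5-Mb genome with 200
planted copies (3:1 full-length:MITE, divergences uniform up to 0.25);
specificity on twenty unplanted 1-Mb genomes; burst dating with 50 copies
planted at 30 My in 300 kb; transfer discrimination over 20 replicate
two-lineage scenarios (split 90 My, invasion 25 My, 15 copies per lineage
in 120-kb windows — copy numbers comparable to the minor species of the
real census — with 50 ortholog pairs); and MITE classification with 40
copies at divergences up to 0.15.

## Known limitations

- Gapped E-values inherit the ungapped `lambda` and a fixed `K`; absolute
  E-values are order-of-magnitude, decisions at 1e-10 are robust.
- Copy boundaries come from local alignment and can be a few bases short
  at diverged termini; this slightly deflates `k` (sub-percent at the ages
  studied) and degrades TSD recovery with age.
- The star-alignment consensus assumes all copies descend from something
  alignable to the reference; families with large reference-absent
  insertions would need a true MSA.
- The quantile test needs a reasonable number of ortholog pairs (the
  published design used 50) and assumes they evolve neutrally up to a
  lognormal rate spread.
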