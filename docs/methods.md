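# Methods

`panrep` characterizes scFv antibody repertoires around a phage-display
panning step: it assigns Kabat position codes to heavy and lambda variable
domains, partitions them into framework (FW) and complementarity-determining
(CDR) regions, classifies the non-H3 hypervariable loops into canonical
structure classes by strict Chothia-SDR template matching, profiles
per-position amino-acid variability, and compares conserved sites between
pre- and post-selection repertoires. A synthetic repertoire generator with
recorded ground truth makes every stage testable without deposited data.

## Kabat numbering by profile alignment

Each query is globally aligned (affine gaps, BLOSUM62, gap open −10 /
extend −1 — configurable; the values only matter for pathological inputs)
against an embedded, hand-annotated, sheep-consensus-like reference profile
per chain type (a two-column text file mapping Kabat code → residue;
user-overridable). Residues matched to the reference inherit its codes.
Inserted runs are attached as letter suffixes at the nearest permitted
insertion anchor — heavy 35, 52, 82, 100; lambda 27, 95, 106 — with
letters continuing past any reference-borne letters (the heavy reference
already carries 82A–82C, so further insertions there would start at 82D).
Anchor attachment is a numbering convention rather than an alignment
artefact: the run is spliced immediately after its anchor code, so codes
are strictly increasing and the concatenated numbered residues always
reproduce the input exactly. Deletions relative to the reference leave
codes absent (never placeholder residues), which is what makes Kabat CDR
length counting truthful.

Numerical choices: sequences outside 80–150 residues are rejected before
alignment; an alignment score below 50 (raw BLOSUM units; the references
self-score ≈ 600) is reported as "not an antibody variable domain"; an
inserted run farther than 14 Kabat numbers from every anchor is an error
(14 is the smallest bound letting any run inside Kabat CDR H2, 50–65,
reach its anchor at 52); ties in anchor choice break to the smaller
anchor, giving deterministic, leftmost placement. On insertion-only
variants up to reference+6 the tests check the whole procedure against an
oracle that exhaustively scores every legal anchor placement.

## Regions and CDR lengths

Kabat boundaries are hard-coded and exposed for audit: heavy CDR1 31–35,
CDR2 50–65, CDR3 95–102 (FW4 to 113); lambda CDR1 24–34, CDR2 50–56,
CDR3 89–97 (FW4 to 108). Insertion-lettered codes inherit the region of
their base number. Under these boundaries the scaffold classes imply the
invariant lengths H1 = 5, H2 = 16 and L2 = 7 that dominate real sheep
repertoires, which is the consistency check for the table.

## Canonical classes

Canonical loop lengths are measured over Chothia-style windows distinct
from the Kabat CDR boundaries (H1 26–35, H2 50–58, L1 24–34, L2 50–56,
L3 89–97). A loop is labelled:

* **a class** — exactly one template shares the observed window length and
  has every key residue satisfied;
* **"X"** — no template of that loop has the observed length (e.g. a
  10-residue lambda L3, which falls in the gap between the 9-residue class
  4 and 11-residue class 5);
* **"unmatched"** — a length-compatible template exists but each one has at
  least one violated key residue (strict matching: one violation
  disqualifies). A flag collapses "unmatched" into "X" for comparison with
  conventions that lump all non-classified loops together.

Two fully matched length-compatible templates are a hard error: the
template set must be discriminating. Templates live in a YAML data file
(window, length, key residues with allowed sets) so the rule base is
auditable and replaceable; the shipped key-residue sets are curated from
published Chothia/SDR compilations and deliberately permissive. CDR H3 is
not classified. Classification is checked against an independent
brute-force template scan on the synthetic corpus.

## Variability and conserved sites

Per Kabat position, variability = 100 × (1 − modal-residue frequency), a
frequency-based (not entropy-based) measure, binned into five classes with
edges 10, 25, 50, 75 %. The outer edges (10 % for "well conserved", 50 %
for "highly variable") are the conventional reporting thresholds;
the intermediate edges are a documented choice. Positions covered by fewer
than 5 chains are flagged "insufficient" and not binned (percentages from
fewer observations are noise). Region summaries report the percentage of
binnable positions per bin for FW1–4, CDR1–3 and FW-vs-CDR overall.

Conservative substitutions are judged with a seven-group biophysical
partition (aliphatic AVLI, aromatic FWY, polar-neutral STNQ, acidic DE,
basic KRH, sulfur CM, conformational GP), shipped as a data file: the
group count is the established convention, the exact membership a curated
choice. A position is conserved in a test repertoire iff **every** chain
carries a residue there and each residue equals the pre-selection
consensus (modal residue, alphabetical tie-break) or shares its group.
Positions deleted in any chain are never conserved — a site cannot be
unchanged where it does not exist. Both the pre and the post set are judged
against the *pre* consensus, so "post conserved ⊇ signal of selection".
An alternative, laxer reading (match *any* residue the pre set showed at
the position) is available behind a flag. The conservation report
organizes counts per chain and region with totals that always sum exactly.

## Selection statistics

Frequency tables (CDR lengths, canonical combinations) carry exact counts
with percents recomputed from them; rendering rounds to one decimal, all
comparisons use unrounded values. Post-selection tables can deduplicate
identical clones first (copies of one founder count once). Uniformity of
canonical-class representation is tested with a chi-square goodness of fit
against a uniform null over the *observed* categories (k = categories with
count > 0); no multiple-testing correction is applied across libraries.
Pre/post enrichment reports per-category percent fold changes, flagging
categories absent pre-selection as "novel" with an undefined fold change.

## The synthetic generator

`generate_pre_library` draws, per clone, a canonical combination from a
configured mixture, CDR H3 (and non-template "X" L3) lengths from
configured distributions, resizes the scaffold loops at the Kabat anchors,
sets canonical key residues, and applies per-site substitution at
region-specific rates (defaults: FW 0.01, CDR 0.15 per site — framework
positions are overwhelmingly conserved in immune repertoires while CDRs
carry the diversity). Scaffold construction is deterministic; all noise is
in the mutation model, so zero rates reproduce the scaffold exactly. Key
residues mutate only within their class-allowed sets, which keeps planted
class labels exactly recoverable — recovery tests are exact, not
statistical. The default three-library design mirrors the emulated study:
110+80, 77+30 and 196+95 heavy+lambda pre-selection sequences with
post-selection panels of 6/3, 8 and 6 founder clones (three copies each),
targets SQA/POR, COP and HSL, heavy chains dominated by the 1-1
combination and lambda chains led by 6-1-X.

`simulate_selection` contracts the library to a handful of founders
(sampled without replacement, weighted 1/(1 + Hamming distance to the pre
consensus), i.e. biased toward scaffold-faithful clones), optionally
overwrites *planted* positions with the pre-consensus residue
("identical" mode) or a random same-group residue ("group" mode), and
replicates founders without further mutation. Identical-mode planting
consumes no randomness, so a planted run differs from its unplanted
control only at the planted positions; the conserved set of the planted
run then equals the control's baseline union the planted set exactly,
which is the generator's strongest recovery property.

What the generator does **not** emulate: nucleotide-level V(D)J
recombination and junctional diversity, somatic hypermutation hotspots,
clonal lineage structure, phage amplification bias, and real germline gene
usage (scaffolds are synthetic consensus-like sequences, not database
germlines). Passing tests therefore demonstrate that the analysis recovers
what the generative model encodes — mixtures, lengths, planted
conservation, repertoire contraction — not that it would reproduce every
idiosyncrasy of wet-lab repertoires.

## Problem sizes and degenerate inputs

The test suite runs the full three-library emulation (≈ 600 sequences) and
smaller 40–70-clone libraries for property checks; statistical recovery is
checked at n = 500 within 3 % absolute, binomial checks at n = 200 within
95 % bounds. Degenerate inputs are defined errors, not silent results:
empty clone sets, single-category chi-square, post-selection clones without
targets, ambiguous scFv constructs (two exact linker matches), linkers
below 80 % window identity, and requests for more founders than distinct
two-chain clones. Empty report tables are written header-only with a
warning. CLI runs refuse non-empty output directories unless forced, so a
rerun with identical inputs is byte-identical and nothing is appended to
stale reports.

## Known limitations

* Numbering assumes profile-alignable variable domains; heavily truncated
  or chimeric constructs fail the score floor rather than being rescued.
* Insertions are only representable at the scheme's anchors; a genuine
  framework insertion beyond the anchor window is an error by design.
* Canonical key-residue sets are curated and permissive; users wanting a
  specific published template compilation should supply their own YAML.
* Kappa chains are carried by the data model but excluded from canonical
  and conservation analyses by default (the analyses target lambda-only
  repertoires).
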