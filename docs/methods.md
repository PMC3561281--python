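# Methods

This note documents the models and procedures `ubigain` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not demonstrate.

## Inputs and coordinate conventions

Sites arrive as TSV rows (accession, 1-based position, ≤13-mer peptide with
the modified lysine at the center). Peptides shorter than 13 residues are
accepted only in the form symmetric terminal truncation produces: odd
length, center K. Positions are interpreted on the coordinate system of the
accession as given; the package never remaps between accession namespaces,
because positions reported against retired namespaces (e.g. IPI) can differ
from current UniProt/NCBI records. When two experiments report the same
(protein, position) with different peptides, the longer peptide is kept and
the conflict logged.

Alignments are per-gene protein alignments in a multiz-style FASTA dialect.
Protein positions are 1-based; alignment columns are 0-based internally and
1-based in every emitted report. The pipeline operates entirely at the
amino-acid level; a codon-alignment translation pre-step is a documented
extension point, not implemented, because every decision the pipeline makes
is about amino-acid states.

**Missing-data semantics.** `-` (gap), `X` (unknown), `*` (stop codon), and
species absent from a file are all MISSING. A missing residue can neither
veto nor support a lysine call at any stage. This is deliberate: most
non-human mammal proteomes derive from draft genome assemblies, and treating
absence of evidence as evidence of absence would create false gains and
false losses. The corollary is that a column where an entire outgroup is
missing *passes* the corresponding filter, with a low-information flag on
the call rather than a discard.

## Mapping

A site maps to the alignment column of its reported position when that
position holds K and the ungapped reference context equals the reported
peptide (X wildcards on either side; truncated positions ignored). When the
position does not hold K — typically coordinate drift between database
versions of the same protein — the peptide is searched against the full
reference sequence; a unique center-K match relocates the site and the
correction is logged on the call. Zero or multiple matches fail with
`PEPTIDE_MISMATCH`. Requiring uniqueness avoids silently picking one of
several repeats.

## Screening filters

Four filters run in a fixed order (`MULTI_COPY`, `EUARCHONTOGLIRES_K`,
`MANY_NONPRIMATE_K`, `LOW_CONSERVATION`); each is an independent predicate
of the alignment, so order affects only the listing of reasons. All failing
reasons are collected — a discarded site says everything that is wrong with
it. Retention requires that none fail.

- **Multi-copy.** The ungapped human sequence is indexed across all loaded
  gene sets; a count > 1 discards every set involved. The criterion is
  exact full-length identity: near-identical paralogs are not detectable
  without external annotation, and a fuzzier criterion would need an
  arbitrary similarity cutoff with no principled value.
- **Euarchontoglires lysine.** Any observed K in a non-primate
  Euarchontoglires species (the eight-species outgroup closest to primates)
  means the lysine predates the primate lineage: hard discard, no
  threshold.
- **Many non-primate lysines** (`nonprimate_lysine_max_fraction`, default
  0.2). Fraction of non-primate species carrying K among non-primate
  species with an observed residue. A high fraction suggests the lysine is
  ancestral with scattered losses rather than a primate gain.
- **Regional conservation** (`conservation_window` = 10 residues each side,
  `conservation_min_identity` = 0.6). Per window column, the fraction of
  non-missing non-reference species matching the human residue; the filter
  value is the mean over informative columns, the site column excluded so
  the gain itself cannot depress its own context score.

The last two filters replace what was historically a manual-inspection
judgment. The defaults are deliberately permissive; both are exposed in the
run config and on the CLI, and tightening either is provably monotone (the
retained set shrinks). Reproducing any particular hand-curated published
set is explicitly not promised, and explicit `force_keep` / `force_drop`
lists exist so curation decisions can be reproduced, audited, and diffed
instead of being buried in thresholds.

## Dating: the minimal covering clade

The human-lineage ladder is a strictly nested chain of nine clades (human →
primates), each validated as monophyletic in the species tree at load time.
A retained gain is dated to the smallest ladder clade containing every
primate species observed with K at the site column. Patchy presence (e.g.
K in human and marmoset but not rhesus) dates to the minimal covering
clade; no loss-aware parsimony is attempted, because with eleven primate
taxa the data cannot distinguish one gain plus losses from independent
gains, and the covering-clade rule is at least reproducible and
conservative toward more recent origins.

Two annotations accompany the call:

- **Ambiguity.** Starting at the minimal clade, the call extends to each
  successively larger ladder clade so long as every species the larger
  clade adds is missing at the column. More than one consistent clade sets
  the ambiguity flag (the gibbon-missing situation: a great-ape-only K
  pattern with no gibbon row is consistent with a gain on either the
  great-ape or the ape branch; the reported clade is always the smallest).
- **Homoplasy.** An observed K in a non-primate species that survived
  screening (possible under the 0.2 fraction cap) is recorded on the call
  and ignored for dating — an independent appearance, not shared ancestry.
  Widening the clade to cover a lone dog K would require the gain to
  predate the Euarchontoglires screen that the site just passed, which is
  contradictory.

## Window classification

For offsets −5…+5 (site excluded), counted in *human residues* with gap
columns skipped — a lysine two residues upstream is at offset −2 regardless
of intervening alignment gaps — the analysis computes the fraction of
non-missing non-primate species with K at each offset's column. An offset
is conserved when that fraction is ≥ `conserved_min_fraction` (default
0.75; there is no canonical value, and 0.75 demands a clear outgroup
majority while tolerating draft-genome noise). Classification:

- **new** — no conserved offset;
- **additional** — some conserved offset retains its K in the human row;
- **shifted** — conserved offsets exist but none retains a human K.

The per-offset loss map additionally records the strict shifted pattern
(the ancestral K absent from *every* non-missing member of the origin
clade, not merely from the human row). Classification keys on the human
row so that the three classes always partition the retained set; the rare
configuration where an ancestral K disappeared from the human row but
persists in another member of the origin clade is thus reported as shifted,
with the strict flag left false — the loss map preserves the distinction
for downstream scrutiny. Raising the conservation threshold is monotone:
the *new* class can only grow. The origin clade (not the whole primate
clade) is used when testing ancestral-K loss, since the shift hypothesis is
about what happened on the branch where the novel lysine arose. Windows
clipped at a protein terminus proceed on the available offsets and are
flagged.

Acetylation cross-referencing marks a gain when its exact
(protein, position) occurs in the deduplicated acetylation table;
neighbouring positions never match, since both coordinates come from the
same accession namespace.

## Synthetic data

The simulator emulates the study conditions end to end: sequences evolve
down the 37-taxon mammal tree (11 primates including gibbon, 8 non-primate
Euarchontoglires, 10 Laurasiatheria, 3 Afrotheria, 2 Xenarthra, 2
Metatheria, platypus) and a lysine gain is planted on a chosen ladder
branch. Defaults, chosen once: sequence length 120 residues (a compact but
window-safe protein); substitution rate 0.01 expected substitutions per
site per branch-length unit with unit branch lengths (root-to-tip depth of
roughly 8–13 edges leaves background identity near 0.9, matching the
highly conserved regions the screen targets); the ancestral residue at the
planted column drawn from {Q, E, R}, the ancestral states repeatedly
observed at real gained sites. Substitutions are uniform over the other 19
residues — no stage of the pipeline depends on substitution-model realism,
so an empirical exchange matrix would add parameters without adding test
power. The classification window of the root sequence is kept lysine-free
so the planted window class is the ground truth rather than a draw.

Six patterns cover the decision space: a clean gain, the three window
classes, and the three discard modes (outgroup lysine, widespread
non-primate lysine, scrambled-window conservation). Missing-species masks
remove whole rows, reproducing the gibbon-style ambiguity. Everything is
reproducible: one integer seed per config, and identical configs produce
byte-identical files.

What the simulator does *not* emulate: indels and alignment error (the
emitted alignments are gap-free; gap handling is exercised by hand-written
fixtures), paralogy, assembly-quality artefacts correlated across columns,
and realistic among-site rate variation. Passing the synthetic recovery
tests therefore demonstrates the correctness of the decision logic under
the stated model, not the field error rate on real proteome-scale data,
where alignment and assembly quality dominate.

## Numerical and degenerate-input choices

- Filter thresholds compare with ≥/≤ exactly at the boundary (identity
  exactly at the minimum passes; lysine fraction exactly at the cap
  passes).
- Conservation columns with no informative species are dropped from the
  mean; a window with no informative columns passes with a flag.
- Deduplication sorts by (protein, position, kind), making it idempotent
  and order-insensitive; ties between conflicting peptides of equal length
  keep the first encountered.
- An empty site table runs cleanly end to end and produces empty outputs.
- The funnel invariant (input ≥ non-redundant ≥ mapped ≥ retained), the
  per-branch sum, and the window-class partition are asserted on every run;
  violation aborts rather than writing inconsistent reports.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run on simulated data sized for
quick, repeatable desk verification: 10,000 random lysine-presence sets for
the dating oracle, ~500 noise-free genes for exact branch/class recovery,
100-gene batches for confounder discard and the mixed-pipeline funnel, and
90 genes for the noisy-recovery curve. These sizes give exact (100 %/0 %)
expectations where the construction guarantees them and stable estimates
elsewhere.

## Known limitations

- Paralogy detection is exact-duplicate only.
- No codon-level input support; upstream translation is the user's job.
- The minimal-covering-clade rule cannot see gains masked by secondary
  loss inside the ladder, and deliberately does not try.
- Published curated site inventories blend automated screening with manual
  judgment; this package reproduces the automated, parameterized part and
  makes the manual part explicit input (`force_keep`/`force_drop`), so
  exact headline counts from such inventories are reproducible only given
  the same curation decisions.
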