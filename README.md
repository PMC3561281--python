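# ubigain

Detection, dating, and classification of lysine ubiquitylation sites gained
along the human lineage during primate evolution.

High-throughput diGly-remnant proteomics yields tens of thousands of
experimentally observed ubiquitylated lysines in human proteins. Most of
those lysines are ancient; a small subset appeared recently, on one of the
branches leading from the common ancestor of Euarchontoglires to humans.
Those lineage-specific gains are candidate substrates for recently evolved
regulation — degradation, localization, signalling — and `ubigain` finds
them: it maps each modified lysine into a per-gene orthologous mammalian
protein alignment, screens out everything that is not a primate-lineage gain
in a conserved region, dates each surviving gain, and asks whether the gain
created a genuinely new modification target.

The package is aimed at molecular-evolution and PTM-proteomics researchers.
It ships a species-tree-aware simulator with planted gains and full ground
truth, so every stage is testable without any external data.

## Method

For a modified lysine at position *p* of a human protein, with *C(p)* its
column in the orthologous alignment:

1. **Mapping.** The site maps to *C(p)* if the human residue at *p* is K and
   the reference context matches the reported 13-mer (X wildcards, terminal
   truncation allowed). If the coordinate has drifted between accession
   versions, a unique exact peptide match relocates the site with a logged
   correction; otherwise the site fails with `PEPTIDE_MISMATCH`.
2. **Screening.** A mapped site is discarded if any of these hold
   (all failing reasons are recorded):
   - `MULTI_COPY` — the human sequence occurs in more than one gene set
     (orthology uncertain);
   - `EUARCHONTOGLIRES_K` — a non-primate Euarchontoglires species
     (treeshrew, mouse, rat, kangaroo rat, guinea pig, squirrel, rabbit,
     pika) carries a lysine aligned with the site;
   - `MANY_NONPRIMATE_K` — the fraction of non-primate mammals with an
     aligned lysine, among those with an observed residue, exceeds a
     threshold (default 0.2);
   - `LOW_CONSERVATION` — mean per-column identity to the human sequence
     over the ±10-residue window falls below a threshold (default 0.6).
   Gaps, unknown residues (`X`), stop codons (`*`), and absent species are
   *missing data* and never count for or against any filter.
3. **Dating.** Let *S* be the primate species observed with K at *C(p)*.
   The gain is dated to the smallest clade of the nested human-lineage
   ladder (human ⊂ human+chimpanzee ⊂ African great apes ⊂ great apes ⊂
   apes ⊂ catarrhines ⊂ simians ⊂ haplorhines ⊂ primates) whose member set
   contains *S* — the minimal covering clade. If the species separating
   adjacent branches are missing, the call is flagged ambiguous and every
   consistent clade is listed.
4. **Window classification.** Within ±5 human residues of the site, an
   offset is *conserved* if ≥ 75 % of non-missing non-primate species carry
   K at its column. No conserved offset → **new** target; a conserved offset
   whose K is still present in the human row → **additional** target; a
   conserved offset whose K the gaining clade lost → **shifted** target.
5. **Acetylation cross-talk.** Gains whose exact (protein, position) also
   occurs in a deduplicated acetylation site table are flagged.

## Worked example

Simulate 18 genes (two per ladder branch, noise-free), run the pipeline,
and render the report:

```sh
ubigain simulate --out-dir demo/sim --genes 18 --rate 0.0 --seed 7
cat > demo/run.yaml <<EOF
site_tables:
  - path: demo/sim/sites.tsv
    source: sim
alignments_dir: demo/sim/alignments
tree_newick: demo/sim/tree.nwk
clade_config: demo/sim/clades.yaml
out_dir: demo/out
EOF
ubigain run --config demo/run.yaml
ubigain report --run-dir demo/out
```

prints

```
ubigain 0.1.0 — run report

Funnel
  input site records       18
  non-redundant sites      18
  mapped into alignments   18 (in 18 genes)
  retained after screening 18 (in 18 genes)

Gains per human-lineage branch (smallest clade first)
  human                2
  human-chimpanzee     2
  african-great-apes   2
  great-apes           2
  apes                 2
  catarrhines          2
  simians              2
  haplorhines          2
  primates             2

Window classes: additional=0, new=18, shifted=0
Acetylation overlaps among retained sites: 0

Human-specific gains
  g00_0000         NDCQINKFEITPI 107
  g00_0001         NDETSRKHHYRTC 99
```

The funnel counts each stage's survivors (they can only decrease); the
per-branch table recovers exactly the two gains planted on each of the nine
branches; both `human` rows are sites that arose after the human–chimpanzee
split, printed with their 13-mer context and position. Outputs land in
`demo/out/`: `site_calls.tsv` (one row per site with status, reason codes,
origin clade, window class), `gain_summary.tsv`, `window_reports.tsv`, and
`manifest.json` (config snapshot, input digests, all counts).

To run on real data, point `site_tables` at your diGly site TSVs
(`protein_id`, `position`, `peptide` columns), `alignments_dir` at per-gene
protein alignment FASTAs (species code as the first header token), and
optionally supply your own newick tree and clade YAML; the built-in 37-taxon
mammal configuration is used by default. Place full-scale inputs under
`data/fullscale/` to enable the full-scale regression test (see
`tests/test_acceptance.py`).

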