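# Methods

## Problem and model

The pipeline decides, from peptide-level MS identifications alone, which
proteins of a protein-existence (PE) annotated reference proteome are
present in each of three comparison groups, and which of those are
"missing proteins" (PE2–PE4 on the neXtProt five-tier scale: transcript
evidence only, homology inference, or prediction; PE1 is known, PE5 is
uncertain and excluded from the missing band). Presence follows the
standard conservative inference rule: a protein is present in a group when
at least two peptides *unique* to it are observed there. Spectrum-level
scoring, FDR estimation and parsimony grouping are deliberately out of
scope — the input is trusted peptide-level search output, and the only
matching criterion is 100% sequence identity.

## Digestion

Trypsin cleaves C-terminal to K or R, suppressed when the next residue is
P. Peptides with up to `max_missed_cleavages` (default 2) uncut internal
sites are enumerated by joining runs of consecutive fully-cleaved
fragments; the observable-length window (defaults 6–50 residues, the
conventional band for confident MS identification) is applied after
enumeration. Two exact combinatorial laws follow and are enforced by
tests: the zero-missed-cleavage peptides concatenate to the input sequence,
and a sequence with S internal cleavage sites yields exactly
max(0, S+1−k) peptides with k missed cleavages. The enumeration is
cross-checked in the test suite against an independent cleavage oracle
(pyteomics' `cleave` with the rule `[KR](?!P)`).

Protein N-terminal methionine clipping and semi-tryptic or modified
peptides are not modelled; this is a documented limitation, not an option.

## Matching and uniqueness

Two match modes exist. `substring` (default) calls a match whenever the
observed peptide occurs as an exact contiguous substring of a reference
sequence; it is the weaker, safer reading of "100% match" because it does
not assume the upstream search engine enforced tryptic boundaries.
`tryptic_index` restricts matches to in-silico tryptic peptides via the
index and is faster and search-engine-consistent. Every tryptic match is a
substring match, so the substring present set can only be equal or larger.

Uniqueness is evaluated *under the active match mode* — from the substring
match map, or from the tryptic index — at either protein or gene level.
The default is gene level: isoforms of one gene share most of their
sequence, and protein-level uniqueness would void otherwise perfectly
informative peptides (the packaged fixture itself carries two isoforms of
one kinase gene). Peptides are matched per group by pooling all samples
and replicates of the group before inference; per-sample inference is
available through the same functions.

The only ambiguity code admitted in reference sequences is X, and a
peptide containing X matches nothing — conservative under exact-identity
matching. Optionally I and L are collapsed (I → L) before matching and
uniqueness, since they are isobaric and indistinguishable by MS; the
default keeps them distinct because search engines emit a concrete
sequence. Unmatched peptides (contaminants, species-specific sequences)
are tallied and written to a spill file, never silently dropped.

## Duplicate peptide ratio

For one sample with replicate runs, the ratio is
|peptides seen in ≥2 replicates| / |peptides seen in ≥1 replicate|.
This denominator-union formalisation is this package's own definition of
replicate reproducibility; group and overall figures are unweighted means
over samples. Under independent Bernoulli(p) detection across 3
replicates the expected ratio is (3p²(1−p)+p³)/(1−(1−p)³) — 0.8058 at
p = 0.7 — and the simulator converges to this closed form (verified at
p ∈ {0.5, 0.7, 0.9} within ±0.02 with ≥2000 peptides). The analytic law
holds for pure detection noise, so that check runs with missed-cleavage
emission and contaminants disabled; both features lower the observed
ratio by adding peptides that rarely recur across replicates.

## Group regions and reporting

Present proteins are partitioned by their exact membership pattern over
the groups WT (wild type), KO_NT (knockout without tumor) and KO_T
(knockout with tumor) — the seven non-empty cells of a three-set Venn
diagram. The knockout-specific regions carry the labels III
(KO_NT ∩ KO_T ∖ WT, tumor-associated), IV (KO_NT only, candidates whose
expression falls after tumor formation) and V (KO_T only, tumor-specific);
the remaining four patterns are named by their pattern string. These label
assignments are an interpretation of the study design, not a formal
definition, and are therefore overridable in configuration.

Chromosome reports always use the fixed human axis 1–22, X, Y, MT plus
"unplaced", with zero-count entries retained — identifications from the
mouse model are projected onto human chromosomes, matching
chromosome-centric cataloguing practice. The normaliser accepts the
historical numeric convention (23 = X, 24 = Y; the packaged table prints
X-linked rows as "23×") and maps anything unrecognised to "unplaced" with
a warning rather than failing.

The region report mirrors the packaged fixture schema (group, accession,
chromosome, gene name, protein name, gene id, evidence label) plus an
`is_missing` flag, ordered by region, chromosome, accession; writing and
re-reading the fixture through this schema is lossless.

## Synthetic data generator

The generator emulates the study design end to end so that recovery can be
scored against known truth: a reference proteome of 300 random sequences
(mean length 450, geometric spread, floor 60), PE levels drawn from
(0.55, 0.25, 0.05, 0.10, 0.05) over PE1–PE5, chromosomes from a fixed
weight vector (autosomes and X equal, Y and MT rare), group content of
33 / 88 / 48 proteins for WT / KO_NT / KO_T (the emulated study's group
sizes) or an explicit region design, 3 replicate runs per pooled group
sample, per-peptide per-replicate detection probability 0.7 (putting the
expected duplicate ratio near 80%), 15% missed-cleavage emission and 5%
contaminant peptides.

Residue frequencies are deliberately crude — K and R at 5.5% each, the
other 18 residues uniform — which guarantees digestible sequences without
claiming to model real amino-acid composition. Abundance classes,
retention time, mass accuracy and any biological covariance between
groups are not modelled; detection is one global Bernoulli knob. Passing
recovery tests therefore demonstrates the correctness of the matching and
inference machinery under the stated noise model, not performance on real
tissue data, where shared-peptide structure and abundance bias are far
harsher.

Ground truth records, per group, both the designed content and the
*detectable* subset: proteins with at least two in-bounds
zero-missed-cleavage peptides that occur (as substrings, at gene level) in
exactly one gene's sequences. With detection probability 1 and no noise
the pipeline's present set equals this subset exactly; under default noise
sensitivity stays ≥ 0.95 across seeds. False discoveries are structurally
impossible in this design — every emitted real peptide is a true substring
of its source protein, so a peptide can never be unique to an absent
protein — and the suite asserts zero.

All randomness flows from one integer seed through fixed per-stage child
streams (proteome, truth assignment, observations), so the entire
generator and pipeline are byte-reproducible.

## Numerical and degenerate-input choices

- Ties and ordering: all outputs sort by explicit keys (group, accession,
  chromosome-axis position), so results are independent of input record
  order.
- Empty inputs: an empty FASTA parses to an empty database with a warning;
  an empty observation set yields empty reports; a sample with fewer than
  two replicates raises an error directing the caller to skip it in ratio
  computations (group means then average the remaining samples).
- Annotation gaps: strict mode refuses unannotated accessions; lenient
  mode defaults them to PE1 / unplaced with a warning, and a missing gene
  symbol falls back to the accession.
- Contaminant generation redraws any random peptide that happens to be a
  real reference substring, so simulated contaminants provably match
  nothing.

## Problem sizes used in the test and acceptance runs

The suite exercises digestion laws on random sequences up to length 2000,
index construction on 20-protein toy proteomes against brute-force
oracles, recovery on the default 300-protein design over ten seeds, and
the duplicate-ratio law on ≥2000-peptide samples; the acceptance script
runs three independently seeded full-pipeline recoveries plus one
150-protein ratio simulation. These sizes keep every stage's behaviour
observable while remaining quick to re-run.

## Known limitations

- No spectrum-level information: identification quality is inherited
  entirely from the upstream search engine.
- No N-terminal methionine clipping, modifications, or semi-tryptic
  peptides.
- The duplicate-ratio definition is this package's formalisation; other
  groups may report run-pairwise overlap instead.
- Region labels III/IV/V encode one reading of the three-group design;
  alternative readings are supported only through relabelling.
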