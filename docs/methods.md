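# Methods

## Problem setting and model

The package addresses interface prediction for complexes of a folded
receptor and a short linear motif (SLiM) embedded in an intrinsically
disordered ligand. Complex-structure predictors consume a *co-alignment* —
receptor and ligand MSAs concatenated row-wise — and emit models scored by
pTM, ipTM and per-residue pLDDT. Because disordered ligands are long and
their motifs short, prediction quality depends strongly on how the ligand
is delimited and on what evolutionary information accompanies it; the
package therefore treats delimitation, MSA mode and fragment tiling as
first-class, composable operations around a pluggable predictor.

### Co-alignment modes

Each per-chain MSA is query-anchored, one row per species (the first row
per taxon is kept at read time; taxon keys default to the UniProt `OX=`
tag, falling back to the suffix after the last underscore, and are
configurable by regex since header dialects vary). Three concatenation
modes are built:

- **mixed** — one *paired* row per species present in every block, rows
  ordered by ascending taxon key, followed by the remaining homologs
  *unpaired* (gaps in the other blocks; receptor blocks first in input
  order, then the ligand block);
- **unpaired** — every homolog contributes exactly one row with gaps
  outside its own block;
- **no-ligand-MSA** — the receptor side is joined as in mixed, the ligand
  block carries only the query, so no evolutionary information reaches the
  peptide.

Homomeric receptors repeat the same MSA object per subunit; a species'
single homolog row fills all copies simultaneously (self-pairing), both in
paired and unpaired rows. Conservation laws (width = Σ block widths; mixed
rows = |shared taxa| + block-only homologs + 1; unpaired rows =
Σ homologs + 1; mixed and unpaired carry the same homolog multiset) are
property-tested over randomized taxon overlaps. Upstream filtering
parameters (e.g. hhfilter id=100/qid=25/cov=50) are provenance metadata
only — the package never re-filters.

Row order within the paired block is not fixed by any convention we could
find for this pipeline shape; ascending taxon id was chosen for
deterministic, byte-identical output.

### Fragment tiling

Scanning windows are 100 residues with a minimum overlap of 30 (stride
70), which guarantees that any motif of ≤ 31 residues lies wholly inside
at least one window; the guarantee is verified exhaustively against a
brute-force placement oracle. The final window is re-anchored to end at
the chain terminus rather than shortened, keeping every fragment at
exactly the window length (a fixed input size for the predictor); its
effective overlap with the predecessor may then exceed 30 and is recorded,
never reduced. Chains no longer than the window yield the single fragment
(1, L).

Motif extensions ("+100", "+200") are interpreted as a *total* addition
split ⌊extra/2⌋ left / remainder right, with residues blocked by a chain
terminus redistributed to the other side; per-side extension is available
via the same function for sensitivity checks. The same engine extends
sub-5-residue ELM motifs up to 5.

A fragment "overlaps" a motif from one shared residue upward; the overlap
length is always reported so stricter thresholds can be imposed
downstream.

### Predictor contract and scores

A backend maps (co-alignment, seed) to `models_per_run` scored models; a
protocol is `n_runs` independent runs (defaults 5 × 5 = 25 models, no
relaxation). Per-run seeds derive from a base seed as
`base + crc32(protocol)·10007 + run (mod 2³¹)` so any protocol is
reproducible in isolation. Failed runs are skipped with a warning; a
protocol fails only when all runs do. The model confidence score is
`0.2·pTM + 0.8·ipTM`, enforced to 1e-9 on every model.

The bundled ColabFold-style adapter only writes the concatenated A3M,
builds the command line (3 recycles, multimer parameter tag, no
relaxation) and parses JSON score files; inference is out of scope by
design. The mock backend is the executable stand-in: its ipTM ceiling for
a fragment decays as `max_ipTM · exp(−gap/120)` with the sequence gap
between fragment and a planted motif (so a fragment 300 residues away
scores below half the ceiling), model-to-model variation is a
multiplicative U(0, 0.25) jitter plus N(0, 0.01) noise capped at the
ceiling, and the first model of a run is pinned at the ceiling so the
overlapping fragment attains the planted maximum exactly. When given a
reference toy complex the mock emits coordinates: the reference ligand
slid along the binding groove by `max(0, 0.82 − confidence)·60` Å (plus a
< 0.1 Å seeded jitter), making model quality a monotone function of
confidence — the property that pooling experiments rely on.

### Quality metrics

Model and reference are restricted to their common residues (numbers
shared per chain), mirroring the practice of cutting models to the
reference delimitation; `n_common_residues` is reported. Metrics use
heavy atoms for contacts and N/CA/C/O for superpositions:

- fnat — native (receptor, ligand) residue pairs within 5.0 Å recovered by
  the model; FRNNAT — fraction of model contacts that are non-native;
  FRIR — native 10 Å interface residues recalled;
- L-RMSD — ligand backbone RMSD after a Kabsch fit on the receptor
  backbone;
- iRMSD — backbone RMSD over interface residues after fitting on them;
  the interface is the 10 Å heavy-atom neighbourhood by default
  (`irmsd_interface="contact"` switches to the 5 Å contact residues, since
  assessment practice varies and the choice is worth a sensitivity check);
- DockQ with d1 = 1.5 Å, d2 = 8.5 Å;
- CAPRI protein-peptide classes: High when fnat ≥ 0.8 and (L-RMSD ≤ 1.0 or
  iRMSD ≤ 0.5); Medium when 0.5 ≤ fnat < 0.8 and (L-RMSD ≤ 2.0 or
  iRMSD ≤ 1.0), or fnat ≥ 0.8 with both RMSDs above the High cuts;
  Acceptable when 0.2 ≤ fnat < 0.5 and (L-RMSD ≤ 4.0 or iRMSD ≤ 2.0), or
  fnat ≥ 0.5 with both RMSDs above the Medium cuts; otherwise Incorrect.
  The printed fnat intervals share endpoints; lower bounds are taken
  inclusive and ties resolve to the higher class so the map is a
  partition. An empty native contact set leaves fnat undefined and the
  model Incorrect.

The 5/10 Å cutoffs and backbone atom set are the CAPRI community values;
the DockQ constants are from its definition. Superposition is the SVD
(Kabsch) solution constrained to a proper rotation; near-collinear point
sets are rejected as degenerate rather than silently fit.

When several references exist (homologous structures, or
symmetry-alternative arrangements of the same receptor), a model is scored
against all of them and the DockQ maximizer is kept.

### Selection, pooling, success rates

The best model of a pool is the confidence argmax (ipTM argmax in scan
mode, where the fold of the fragment should not influence ranking); ties
break to the lower run then model index, making ranking a total order. The
combined protocol concatenates per-protocol pools (4 × 25 by default) and
re-ranks by confidence; its best confidence therefore equals the maximum
of the per-protocol bests, but its *success* is not formally guaranteed to
dominate — a confident wrong model can win — so dominance is asserted only
on the mock benchmark, where quality is monotone in confidence by
construction.

A case succeeds when its best model is Acceptable or better; rates are
percentages rounded to one decimal. For unbalanced category sets the
stratified estimator draws one case per category uniformly, n_iter = 1000
times, and reports mean and standard deviation of the per-iteration rates
(the ± value is an sd; other dispersion measures would be computable from
the same draws).

Cross-partner specificity runs every receptor against candidate ligands of
the same bound-conformation cluster in no-ligand-MSA mode; a receptor
discriminates when its cognate ligand's confidence is the strict row
maximum (exact ties reported, not counted). Promiscuous ligands are
flagged as robust (median/MAD, threshold 3.5) outliers among column means.

### Benchmark construction rules

The sequence filter discards a candidate when any prior-release receptor
homolog at ≥ 30 % identity binds a partner in the same region ("same
region" operationalized as ≥ 1 shared receptor interface residue,
configurable, since no quantitative definition is standard). The
structural filter parses MM-align (-a) text output — three TM-scores and
the `:` marks line (residue pairs < 5.0 Å) — and declares redundancy only
when max TM > 0.5 *and* at least 5 consecutive ligand residues aligned
within 5 Å. ELM-style tables are filtered in order: class ∈ {LIG, DOC},
PubMed reference, defined delimitations, non-empty PDB references, unique
motif of the type in the ligand; exclusion tallies partition the input by
construction. Lists exceeding 2500 interfaces are expected to be supplied
pre-clustered; the package treats that as input selection, not a
clustering step it performs.

## Synthetic data: what it emulates and what it does not

The toy complex is two ideal α-helices (2.3 Å radius, 1.5 Å rise, 100°
twist) forming a groove that holds an extended peptide at 3.8 Å CA-CA
spacing; residues carry N, CA, C, O and a CB pseudo-atom — enough heavy
atoms for every metric without rotamers. Receptors are ≥ 20 residues and
peptides 6–39 residues, the size range the scanning protocol targets.
Decoys slide the peptide rigidly along the groove, so L-RMSD equals the
translation magnitude exactly and the default ladder
(0, 1, 2, 4, 50 Å) passes through all four CAPRI classes. MSA fixtures
control homolog counts and shared-taxon counts exactly; ELM-like tables
control exclusion counts exactly.

These fixtures validate *bookkeeping, metrics and decision logic* — they
say nothing about a real predictor's accuracy. In particular the mock's
confidence-quality coupling is planted, so mock success rates measure the
selection machinery, not predictive power; conclusions about real systems
require a GPU backend and experimental references. Problem sizes used in
tests and the acceptance script (toy complexes of ~40+12 residues, 12-case
mock benchmarks, 100 scan replicates, 200 randomized co-alignment
instances, containment checks to L = 2000) were chosen to exercise every
rule while keeping the default runs at desk scale.

## Numerical choices and degenerate inputs

- All residue intervals are 1-based inclusive; the BED-like fragment
  export alone is 0-based half-open. Author numbering is converted only at
  structure I/O.
- Score tables round-trip CSV at 1e-9; floats are written with 12
  significant digits.
- Altlocs resolve to highest occupancy, then alphabetical; hydrogens are
  dropped on reading, so atom counts are invariant to protonation.
- Ligand-chain inference takes the shortest polymer chain; equal-length
  chains are refused with a request for an explicit role map rather than
  guessed. Exactly one ligand chain per record.
- Modified or unknown residues are carried as `X` and excluded from
  nothing by default (contacts use coordinates, not identities); sequences
  admit the 20 standard letters plus `X`.
- fnat with an empty native interface is undefined; the model is classed
  Incorrect with dockq 0 and a warning path rather than a division error.
- Superposition requires ≥ 3 paired atoms and rejects collinear sets
  (second singular value below 1e-8 of the first).

## Known limitations

- The evaluation assumes residue-number correspondence (optionally via an
  explicit mapping table); it does not align sequences to build a mapping
  for numbering-shifted homologous references.
- No nucleic-acid chains; no protein-protein (non-peptide) CAPRI class
  set.
- The stratified estimator treats cases as exchangeable within a category;
  correlated cases (e.g. paralogs) inflate apparent precision.
- The ColabFold adapter is untested against a live engine in this
  repository; its contract is exercised through the mock only.
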