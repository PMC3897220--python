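# Methods

This note records the models, conventions and design choices behind each
analysis, what the synthetic generators do and do not emulate, and the
known limitations.

## Composition profiling

The fractional difference D_X = (C_X − C_order)/C_order compares the
frequency of amino acid X in a query residue pool against a reference pool
of ordered, globular proteins. Both pools are treated as i.i.d. draws of
residues, so the bootstrap resamples residues with replacement within each
pool — implemented as multinomial resampling of the letter counts, which is
exactly equivalent and vectorizes. Confidence intervals are percentile
intervals of the bootstrap distribution of D_X (default 10,000 iterations,
95% level). A letter absent from the reference pool makes D_X undefined;
it is flagged, never silently dropped, because a missing bar and a zero bar
mean different things. Display order is the Vihinen flexibility scale
(rigid → flexible), the convention of composition-profile plots.

The i.i.d. residue model ignores within-protein correlation; when the
query pool is a handful of related sequences the intervals are accordingly
slightly anti-conservative. Coverage of the true D_X is verified empirically
in the test suite at ~95% nominal on pools of 5,000 (query) and 50,000
(reference) residues — sizes chosen to mimic a protein-family-sized query
against a database-scale reference while keeping the suite fast.

## Charge–hydropathy classification

⟨H⟩ is the Kyte–Doolittle hydropathy, min–max normalized to [0, 1],
averaged over a 5-residue sliding window (plain mean below length 5). ⟨q⟩
is |Σ charges|/L with integer pH-7 charges K, R = +1 and D, E = −1;
histidine is neutral and termini are excluded, the standard convention of
CH plots. The default boundary is ⟨q⟩ = 2.785·⟨H⟩ − 1.151; the variant
2.743/−1.109 that circulates in the same literature is selectable
(`boundary="figure"`), and neither is "corrected" to the other. A point
exactly on the line is called disordered — the boundary itself belongs to
the disordered half-plane by construction here, since no published tie rule
exists. Because the source literature does not state the hydropathy scale
or window behind any particular published CH point, exact reproduction of
specific plotted coordinates is not promised; the classification rule is.

## Disorder tracks and segmentation

Per-residue disorder scores in [0, 1] are inputs (TSV), typically from
PONDR-family predictors. The bundled `disorder_track_standin` — windowed,
min–max-normalized Vihinen flexibility — exists so the pipeline is runnable
self-contained; it is a crude propensity, not a reimplementation of any
neural-network predictor, and pipelines default to user-supplied tracks.

Segmentation labels residues with score > 0.5 as disordered (the
training convention of those predictors) and merges runs shorter than
`min_len` (default 4, to suppress single-residue flicker) into the label of
the longer adjacent run, ties to the preceding run, processing the leftmost
shortest run first until all surviving runs are long enough. The output is
always a partition of [1, L] with alternating labels, and re-segmenting the
implied step track with `min_len=1` is idempotent.

## Hydrodynamics

Gel-filtration calibration fits log10(mass) on elution by least squares —
mass is the predicted quantity, so it is the regressand. Predictions
outside the standards' elution range are returned but flagged as
extrapolated. A non-negative slope warns (larger species elute earlier on a
correctly run size-exclusion column) but does not fail, since elution may
be expressed in units that reverse the sign.

Stokes radii come from the published log-linear calibrations
log10(Rs/Å) = a·log10(M/Da) + b per conformational class:

| state              | a     | b      |
|--------------------|-------|--------|
| native             | 0.369 | −0.254 |
| molten globule     | 0.334 | −0.053 |
| pre-molten globule | 0.392 | −0.210 |
| unfolded (urea)    | 0.521 | −0.649 |
| unfolded (GdmCl)   | 0.543 | −0.701 |

The native pair is verified in the test suite against its two reference
evaluations (≈26 Å at 34,020 Da, ≈35 Å at 75,000 Da) before anything else
trusts it. The conformational call uses the relative radius increase over
the native expectation: < 15% native, 15–20% molten globule (both ends
inclusive — the literature gives a range, not open/closed ends, and a
deterministic rule is required), > 20% pre-molten globule. The increase is
computed as 100·(Rapp − Rnat)/Rnat, which is exact at band edges where the
algebraically equivalent ratio form loses a ulp. The computed increase is
reported as computed (34.6% for the 26→35 Å pair, not a rounded 33%).
Column physics (void volume, non-globular standards) is out of scope.

## Substitution models and distances

The Dayhoff and JTT models are bundled as plain-text exchangeability/
frequency tables (published constants, checksummed on load). The generator
is Q_ij = S_ij·π_j off-diagonal, rows summing to zero, normalized to one
expected substitution per site per unit time. P(t) = exp(Qt) is evaluated
through the eigendecomposition of the π^(1/2)-symmetrized generator —
exact for reversible models and stable, with eigensystems cached per model.

Pairwise distances: the p-distance is the fraction of differing sites; the
ML distance maximizes Σ_sites log(π_a·P(t)_ab) over t ∈ [0, 10] by bounded
scalar minimization (xatol 1e-8). Gaps are excluded per pair (pairwise
deletion, wasting the least signal; complete deletion available via flag).
Pairs whose optimum reaches the cap of 10 substitutions/site are flagged
saturated and excluded from means with a warning, as are pairs with zero
comparable sites. The overall mean is the arithmetic mean over the
remaining unordered pairs.

One deliberately documented subtlety: "the correction never shortens" is
not a pointwise theorem. When the few observed differences concentrate on
high-exchangeability pairs (e.g. I↔V), the ML distance can fall slightly
below the p-distance — reference ML-distance implementations agree to five
decimals on such cases. The test suite asserts the statistical form
(violations rare and small), not the false pointwise form.

Region sub-alignments take the contiguous column block from the reference's
start-th to end-th non-gap column, keeping gap columns interior to the
block (they carry homolog residues aligned within the region) and excluding
gap columns outside it.

Alignment plumbing (global Needleman–Wunsch with affine gaps, BLOSUM62,
open −11 / extend −1, a gap of length L costing open + (L−1)·extend) and
neighbor joining (negative branches clamped to zero) are standard steps and
are delegated to established libraries behind this module's interface;
both are cross-checked against independent oracles (a hand-written Gotoh
DP; tree-additivity recovery) in the tests. The center-star MSA ("once a
gap, always a gap") is a stand-in for a production aligner and is only
adequate for closely related, indel-poor families; precomputed MSAs are the
intended input for real analyses. ML *tree search*, bootstrap support,
rate heterogeneity and indel models are out of scope.

## Motifs and phosphosites

GRAVY is the Kyte–Doolittle sum over length. The isoelectric point uses
the Bjellqvist pKa set (the ProtParam convention; side chains D 4.05,
E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0; C-terminus 3.55; N-terminal
pKa residue-specific) and bisection on [0, 14] narrowed to a 1e-5 pH
bracket; terminal groups are included by default and can be excluded for
"internal peptide" calculations. Charged-residue content counts K+R
positive (histidine only on request — published figures are ambiguous on
this convention) and D+E negative, as percentages of length.

Cdk consensus scanning is deliberately simple pattern matching: minimal =
S/T immediately followed by P; full = [S/T]-P-x-[K/R], a subset of minimal.
Kinase-preference scores are never computed internally — they are an input
column from whatever predictor the user trusts; the package contributes the
deterministic ranking (descending score, ties by ascending position,
rank 1 = earliest phosphorylated) and the motif bucketing (each site to the
unique containing motif, otherwise the inter-motif bucket; overlapping
motifs are rejected).

## Interactome shells

Levels are assigned constructively and minimally: level 1 = physical
partners of the focus (physical wins over genetic); level 2 = genetic
partners of the focus with a physical edge to level 1; level 3 = genetic
partners with a physical edge to level 2; outer = the rest of the focus's
genetic partners. Chains through outer-circle proteins do not qualify —
levels reference only already-leveled proteins. Edges are undirected,
self-loops dropped with a warning, duplicates collapsed. Equivalence with a
naive edge-scanning assigner is exhaustively tested on random ≤12-node
graphs.

Enrichment is the upper-tail hypergeometric test P(X ≥ k) with
Benjamini–Hochberg correction — a transparent, standard substitute for GUI
enrichment tools, labelled as such. Semantic-similarity treemaps are out of
scope; a user-supplied term-parent map can group terms downstream. Exports
(SIF + GraphML with level/function node attributes and etype edge
attributes) are byte-stable for fixed input.

## Synthetic generators

All generators are deterministic per seed (numpy `default_rng`).

* `sample_sequence` draws i.i.d. residues. The `globular` preset is the JTT
  equilibrium frequency vector (a published average over globular protein
  families); the `disordered` preset tilts it by ×0.35 on C, W, F, Y, V, I,
  ×1.9 on Q, S, P, E and ×1.3 on T, R before renormalizing — the
  directional signature of disordered sequences, including their elevated
  Thr/Arg content.
* `simulate_family` evolves a star phylogeny with no indels: per branch and
  region, sites substitute by P(t·k) where k is the region's rate
  multiplier. Defaults — 8 leaves, 400 residues, branch length 0.3
  (ordered-region rate), multiplier 3 on the disordered half — are the
  family-size and divergence regime of a small fungal homolog set; the star
  shape makes pairwise recovery have the closed expectation 2t. Indels are
  deliberately absent so rate estimation is not conflated with aligner
  error.
* `synth_interactome` plants exact shell structure (counts 5/8/6/10 by
  default) plus optional spurious physical edges; the returned truth is
  exact only at zero noise, and recovery degrades gracefully with noise.
* `synth_phospho_table` assigns a descending arithmetic score sequence in
  the planted temporal order plus Gaussian noise; `rhythm_recovery` reports
  the Spearman correlation of the recovered ranking.
* `synth_gf_standards` places standards on an exact log-linear law with
  optional log-normal mass noise.
* `whi5_like_sequence` is a deterministic synthetic stand-in for the yeast
  G1/S-inhibitor sequence, which is not bundled: 295 residues from the
  disordered preset carrying the documented architecture (twelve minimal
  S/T-P sites including T143/S154/S156/S161 in motif 1 [136–162],
  T215 between motifs 2 and 3, S262 in motif 3 [245–267]; no acceptor
  consensus in motif 2 [173–209]; six further sites in the variable
  N-terminal region). Tests on it exercise the scanning and assignment
  logic against documented coordinates; they say nothing about the natural
  residues themselves.

What passing tests on synthetic data do **not** show: robustness to
indels and alignment error, to non-i.i.d. composition, to heterotachy
beyond region multipliers, or to curation noise in real interaction
databases (curated interactor counts are database-snapshot-dependent and
are not asserted anywhere).

## Pipeline

One YAML config resolves to a full parameter set; every run logs that set,
sha256 checksums of all inputs, and per-stage headline numbers into
`report.json`, validated against the bundled structural schema. The single
timestamp field is the only run-to-run difference for identical inputs.
Problem sizes in the bundled synthetic demo (8-leaf / 400-residue family,
bootstrap capped at 2,000) keep a full demo run interactive.

## Known limitations

* The stand-in disorder track is compositional only; real predictor tracks
  are required for biologically meaningful segmentations.
* ML distances assume the empirical model and uniform rates within a
  region; saturation handling is a hard cap, not a rate-heterogeneity fix.
* The center-star MSA has no iterative refinement.
* The pI model treats pKa values as context-free; post-translational
  modifications (including phosphorylation) are not modelled.
* Enrichment treats annotations as flat sets; the term hierarchy is not
  propagated.
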