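# Methods

`saponet` implements rule-based dereplication of steroidal saponins from
high-resolution tandem mass spectra, together with modified-cosine
molecular networking and plant-part biodistribution reporting. This note
records the model, its parameters, the numerical conventions, and what
the synthetic validation does and does not demonstrate.

## The structural model

A steroidal saponin is modelled as

    M  =  aglycone  +  n_glc · Glc  +  n_ara · Ara  (+ H2O for furostanes)

where `Glc` (C6H10O5, 162.0528 Da) and `Ara` (C5H8O4, 132.0423 Da) are
dehydrated glycosyl residues and the aglycone is one of six sapogenin
backbone classes shipped in `data/aglycones.tsv`:

| class | formula | nominal [M+H]+ | E/F loss |
|---|---|---|---|
| diosgenin | C27H42O3 | 415 | C8H16O2 (144.1150) |
| laxogenin | C27H42O4 | 431 | C8H16O2 |
| sarsasapogenin/tigogenin | C27H44O3 | 417 | C8H16O2 |
| 27-OH sarsasapogenin/tigogenin | C27H44O4 | 433 | C8H14O2 (142.0994) |
| sieboldigenin | C27H42O5 | 447 | C8H14O2 |
| 3,6,27-trihydroxy furostane | C27H44O5 | 449 | C8H16O2 |

Assumptions encoded here, all deliberate simplifications of what tandem
MS can actually distinguish:

* **Composition, not sequence.** Sugar counts are reported, never
  linkage or order: sequential losses of identical residues are not
  orderable from MS/MS, and positional isomers share spectra.
* **cis/trans A/B fusion is not resolved** — sarsasapogenin and
  tigogenin are isobaric and form one combined class.
* **Arabinose is assumed for the pentose** (xylose is isobaric); the
  choice follows the sugar analysis of the source material.
* **Furostane vs (iso)spirostane** is an ion-species question: the open
  F-ring hemiketal carries a labile C-22 hydroxyl, so furostanes contain
  one extra water in the molecular formula and ionize as [M+H−H2O]+,
  while the closed-ketal (iso)spirostanes ionize intact. The classifier
  returns `furostane` exactly when the accepted decomposition required
  the extra water; a contradiction between that and the observed
  precursor species is surfaced as `ambiguous`, never silently resolved.
* The E/F-ring retro-cleavage of the sapogenin core loses C8H16O2 for
  methyl-substituted side chains and C8H14O2 for the 27-hydroxy series
  (the often-quoted 160 Da elimination equals C8H14O2 + H2O in mass and
  is represented that way in ladders). The 3,6,27-trihydroxy furostane
  class is assigned the 144 Da loss: its reference fragment series
  sheds the extra hydroxyls as water before the ring cleavage.

## Mass arithmetic

Element masses are pinned NIST most-abundant-isotope values (C 12,
H 1.00782503207, O 15.99491461956, N 14.0030740048, Na 22.9897692809);
the electron mass is included in every ion-species delta (proton
1.007276, not 1.007825 — required for 4-decimal agreement with QToF
reference values). Supported species: [M+H]+, [M+Na]+, [M+NH4]+,
[M+H−H2O]+, [M−H]−, [M+HCOO]−, [M+2HCOO]2− (the last computed as
(M + 2×44.9982)/2).

The signed ppm convention is `(theoretical − observed)/theoretical ×
1e6`; it reproduces the signs of the reference table and is reported at
1 decimal, with m/z at 4 decimals. All internal computation is double
precision.

## Annotation pipeline

1. **Neutral-mass inference** (`infer_neutral_mass`): every
   precursor-level ion observation (both polarities) is tried against
   every species of its polarity; implied neutral masses are clustered
   within the precursor tolerance and hypotheses supported by more ion
   species rank first.
2. **Decomposition** (`decompose_mass`): exhaustive enumeration of the
   grid (6 backbones × n_glc ≤ 4 × n_ara ≤ 2 × extra_water ∈ {0,1}),
   keeping combinations within tolerance, sorted by |ppm|. The bounds
   cover penta-glycosides, the largest reference saponins, and are
   configurable.
3. **Candidate refinement**: annotation generates candidates with a 2×
   tolerance margin, then recomputes each candidate's mass as the median
   over the ion species that corroborate it (any observed ion within the
   fragment tolerance of a species m/z of the candidate mass) and gates
   at the precursor tolerance. The margin exists because a single noisy
   ion must not mask the true composition; the median makes the final
   estimate robust to one outlying species.
4. **Ladder prediction and matching**: all sugar subsets × optional E/F
   loss × 0–4 waters from the [M+H]+ ion; peaks are assigned greedily
   nearest-first, one-to-one, within the fragment tolerance.
5. **Ranking.** Several reference masses are *exactly* degenerate across
   classes (aglycone + H2O equals the 27-oxygenated backbone of the next
   class, e.g. laxogenin + H2O = C27H44O5), so |ppm| alone cannot rank.
   Keys in order: matched fragment count; number of corroborating ion
   species; skeleton/ion-species consistency (furostanes must be seen
   dehydrated, (iso)spirostanes intact); |precursor ppm|. Surviving
   exact ties are all reported. Annotations with fewer than
   `min_matched` fragments are rejected.

Default parameters: precursor tolerance 5 ppm; fragment tolerance
0.02 Da (absolute, matching high-collision-energy QToF practice);
minimum matched fragments 3. All are overridable via
`AnnotationConfig`, a `key = value` config file, or CLI flags.

On the packaged 41-compound reference dataset the pipeline annotates
all 41 records with the published backbone and sugar composition,
resolving 6 classes (`analysis/01_reference_annotation.py`). Note the
skeleton column: the reference literature groups some intact-ionizing
27-hydroxy glycosides with the furostanes on biogenetic grounds; the
ion-evidence rule reported here calls them (iso)spirostane. The
disagreement is visible in the report rather than hidden.

## Molecular networking

`modified_cosine` pairs peaks directly (|Δm/z| ≤ tol) or shifted by the
precursor mass difference, square-root transforms intensities, and
builds the one-to-one assignment greedily by descending pair score;
the score is Σ√(I₁I₂) normalized to [0, 1]. Greedy assignment is
standard networking practice; tests compare it against an exhaustive
optimal assignment on ≤5-peak spectra (deviation rate < 2%) and against
an independent library implementation.

Network construction keeps an edge when cosine ≥ 0.6, matched peaks
≥ 3, and each endpoint ranks the other within its top-10 most similar
spectra (mutual top-K); singletons are retained as their own
components. The precursor tolerance (0.02 Da) enters only through the
shift; one spectrum is one node — no spectral pre-clustering.

Uniform-intensity spectra (e.g. the reference fixture, which prints no
intensities) make the cosine a matched-fraction statistic; that is
intentional and documented here.

## Biodistribution

Presence calls per compound and plant part (leaf/stem/root) use the
four-level vocabulary ND / t / + / ++. From measured data the
trace/strong boundaries default to 5 and 50 intensity units (an
LOD-equivalent scale) — explicitly arbitrary, as screening tables
rarely define them, and overridable. From the packaged reference
dataset the printed calls are taken verbatim; the published table does
not define its thresholds either, so the labels are categorical only.

## The synthetic-data generator

`generate_dataset` samples structures uniformly (configurable weights)
over the same space the annotator searches, with P(furostane) = 0.5,
and emits spectra with:

* minor glycosidic ions (partial sugar losses, relative intensity 0.15),
* a dominant sapogenin core series — full sugar loss, then up to three
  further waters and the E/F cleavage — decaying geometrically (factor
  0.7 per step),
* four skeleton-specific low-mass ring-cleavage ions per backbone class
  (relative intensities 1.2/0.9/0.7/0.5). These emulate the class-
  diagnostic low-mass ions of high-energy CID steroid spectra; their
  offsets are fixed, class-specific constants chosen so that they
  neither direct- nor shift-match across classes, unlike the loss
  ladder, which shifts rigidly with the backbone mass,
* multiplicative Gaussian mass noise (default 3 ppm s.d., matching
  low-ppm QToF accuracy), Poisson decoy peaks uniform in [100,
  precursor] (default rate 3 per spectrum ≈ 20% of peaks — the simplest
  null model), and negative-mode [M−H]−/[M+HCOO]− observations,
* per-part presence probabilities (leaf 0.85 / stem 0.9 / root 0.95,
  mirroring the near-ubiquitous distribution of the reference
  compounds), with independent noise per part.

Validation results computed by the tests and
`analysis/03_simulation_recovery.py` (500 compounds per condition):
noise-free recovery of (backbone, n_glc, n_ara, skeleton) is 100%;
under 3 ppm noise + ~20% decoys it stays above 95% (the residual
misses are precisely the exact mass degeneracies when noise flips the
corroboration evidence).

**What passing does not show.** The generator emits idealized ladders:
no co-isolation chimeras, no in-source fragmentation, no isotope
envelopes, no retention-time structure, uniform decoys rather than
correlated chemical noise, and an intensity model that is plausible but
uncalibrated (no public intensity data exists for the reference
compounds). Real-data recovery will be lower, particularly for the
furostane/spirostane call, which hinges on correctly reading the
precursor species.

`three_family_dataset` (used for the networking study) draws the
laxogenin, diosgenin and sarsasapogenin/tigogenin families with
*disjoint* glycoform sets and each family's free sapogenin as seed.
This is a deliberate choice: identical sugar compositions on different
backbones produce fully shift-aligned ladders whose modified cosine
approaches 1 — such analog pairs genuinely belong to one network
family, so separability can only be demonstrated where the glycoforms
differ. Mass noise is lowered to 1 ppm and decoys disabled so the
study isolates network topology rather than annotation robustness.

## Numerical choices and degenerate inputs

* Ladder ions are deduplicated at 1e-4 Da; ties in peak assignment
  break deterministically by smaller |Δm/z|, then index order.
* Mutual top-K neighbour ranking breaks cosine ties by node id, making
  network construction deterministic for a fixed input order.
* Empty spectra are an error for similarity but an empty annotation
  list (not an exception) for the pipeline; unknown adducts, elements,
  plant parts and config keys raise immediately.
* The reference TSV is guarded by a record-count checksum; two printed
  arithmetic slips in the source table (one calculated NH4+ adduct
  value 1 mDa off; a handful of fragment labels inconsistent with their
  own printed m/z) are kept verbatim and excluded from the
  corresponding golden checks by explicit, documented rules.

## Problem sizes

The test suite and acceptance script run the full 41-record reference
annotation, 1000-mass decomposition oracle comparisons, 1000 random
similarity-oracle pairs, 500-compound recovery experiments per noise
condition, and 15-node network studies; together they complete in a few
minutes on one CPU, the sizes at which the stochastic checks are
already tight (binomial 99% CIs, 10% tolerance on a 10k-peak noise
s.d.).
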