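# Methods

`ahlscreen` re-implements, as a reusable pipeline, the data-analysis side
of an LC-HRMS screen for acyl homoserine lactones (AHLs) — the canonical
quorum-sensing autoinducers of Gram-negative bacteria — in marine
*Vibrionaceae* isolates, together with the downstream profile and
phylogeny analysis.  This note records the models, the tunable parameters
and the design choices made where the method left them open.

## 1. Target library (`masslib`)

An AHL is a homoserine lactone ring amide-linked to an acyl chain of *n*
carbons, optionally 3-oxo or 3-hydroxy substituted, and either intact
("closed") or hydrolysed ("open", one H2O heavier).  Closed-ring
elemental formulas follow directly from this chemistry:

| class | formula |
|---|---|
| unsubstituted | C(n+4) H(2n+5) N O3 |
| 3-oxo | C(n+4) H(2n+3) N O4 |
| 3-hydroxy | C(n+4) H(2n+5) N O4 |

Monoisotopic masses use H 1.0078250319, C 12 (exact), N 14.0030740052,
O 15.9949146221, Na 22.98976928 Da.  Cation m/z values subtract one
electron mass (0.00054858 Da); this choice reproduces the reference
fragment masses (homoserine ring cation C4H8NO2+ at m/z 102.05495,
C3H6N+ at 56.04948, open-ring C4H10NO3+ at 120.06552) to the fifth
decimal, and OH-C6 [M+H]+ at 216.12303.  The adduct set is fixed to the
three singly charged positive adducts observed in positive-mode
acquisition ([M+H]+, [M+Na]+, [M+NH4]+); 13C isotopologues are spaced at
1.0033548 Da and only the one-13C satellite is used by default.

The default library crosses the three substitution classes with acyl
chain lengths 4–14 (closed ring only), i.e. 33 target species.  The
3 × 11 partition is the package's reading of a 33-species closed-ring
screen that detected species up to OH-C14 including odd chain lengths; it
is configurable (`build_library`).

## 2. Run model and EICs (`spectra`)

Runs are rt-ordered lists of centroided spectra (MS1 full scans; MS2
scans with precursor m/z and collision energy), read from and written to
mzML by a small built-in parser/serialiser (64-bit float arrays; reading
also accepts 32-bit and zlib-compressed arrays).  Profile-mode spectra
are rejected explicitly.  Retention times are minutes throughout.

Extracted ion chromatograms sum MS1 centroid intensities within an
**absolute** m/z window (default ±0.01 Da, the convention for narrow
extraction windows on QTOF data, not ppm).  MS2 spectra never contribute
to pseudomolecular-ion EICs; diagnostic-fragment mining reads MS2 scans
only — mirroring the separation between full-scan and MS/HRMS evidence.

## 3. Full-scan screening (`screen`)

**Peak detection.**  The s/n 1:10 integration rule needs a noise
definition, which the method convention leaves open; here noise is
1.4826 × the median absolute deviation (MAD) of the EIC, estimated in two
passes (candidate peak regions from a first pass are excluded before the
final estimate, so large peaks do not inflate their own noise floor).  A
peak is a contiguous region whose core exceeds `snr_min` × noise
(default 10), extended by hysteresis down to half that threshold so a
noisy chromatographic peak is reported once rather than once per flank
wiggle.  Regions narrower than `min_width` = 3 scans are treated as
electronic spikes, not chromatography — standard practice in peak
picking, and the guard that keeps single-scan noise excursions out of the
detection lists.  Height is the apex intensity; area is the trapezoid
integral between the local minima flanking the region.

**Grouping and tiers.**  Peaks of all ions of one species ([M+H]+,
[M+Na]+, [M+NH4]+ and their one-13C satellites) are grouped by
co-elution within ±0.02 min (the same window used for rt identity against
reference standards); within a group each ion keeps its largest-area peak
(tie: earlier rt), and grouping is anchored on the largest-area peak for
determinism.  Identification confidence:

* tier **b** — at least two distinct co-eluting ions.  13C satellites
  count as qualifier ions by default (`count_13c_for_tier`), since an
  isotope trace co-eluting with its parent is exactly the qualifier-ion
  evidence the two-tier convention describes;
* tier **c** — a single ion, and only if it is [M+H]+ or [M+Na]+;
* a lone [M+NH4]+ or lone satellite is reported as sub-threshold
  evidence, never as an identification.

Open-ring species are screened identically but always carry the open
flag and are never merged with their closed twin (extraction chemistry
closes most open forms, so the two are distinct observations).

**LOD.**  `estimate_lod` walks a descending dilution series and returns
the lowest concentration still detected (infinity if none) — an
operational, empirical limit of detection on synthetic series; the
instrument LODs of the original survey are inputs, not reproducible
quantities.

## 4. MS/MS mining (`fragmine`)

All MS2 scans are searched for the three diagnostic homoserine-ring ions
(±0.01); a scan with at least two of the three is a *candidate* — the
in-silico analogue of precursor-ion scanning, able to flag AHLs outside
the library.  Candidate precursors are matched against library [M+H]+
and [M+NH4]+ m/z (the sodium adduct does not survive CID and is
excluded); unmatched candidates are reported with the acyl-side
complement mass (precursor − 102.05495) and, optionally, an exhaustive
CHNO composition search (≤ C12H24N2O6, RDBE ≥ 0) to support manual
formula reasoning.  "Parent ions determined manually" is automated by
taking the precursor from the isolation metadata.

Spectral similarity is cosine with greedy m/z alignment (±0.01),
symmetric, 1.0 for identical spectra.  It is a reporting aid with a
default acceptance of 0.9, not an identification gate — the underlying
evidence for identity is visual/tiered, not a score threshold.
MS2-based evidence is always reported separately from full-scan
detections (MS/HRMS is less sensitive than full scan; silently merging
the two would hide that asymmetry).

## 5. Profiles, clustering, geography (`profiles`)

The packaged fixture transcribes the survey's strain table (32
AHL-positive strains + the *V. anguillarum* reference strain 90-11-287)
and its strain × AHL table (areas of two analytical runs, in 1000
counts, and the b/c tier per cell).  Transcription notes:

* The machine-readable source duplicated the OH-C4/OH-C6 columns in
  place of OH-C7/OH-C8 (headers, cells and tally row).  Presence of
  OH-C7/OH-C8 was therefore curated against the printed per-strain AHL
  counts and the prose description of the *Splendidus*-subclade profile
  (OH-C4/C6/C7/C8/C10/C12 conserved across four isolates); the
  duplicated areas are retained as the only available figures for those
  cells.  With this curation every per-strain count matches the printed
  column and the 21-species total holds.
* The O-C10 tally is 10 by cell count (and in the prose) though the
  printed tally row shows 11; the fixture follows the cells.
* When a cell carries different tiers in the two runs, the better tier
  (b over c) is stored.

Presence is detection in **either** run (the union, matching how the
strain totals count).  Occurrence tallies exclude the reference strain.

Profile clustering is agglomerative (average linkage, Jaccard distance
on binary presence profiles; both configurable).  The agglomeration is
implemented directly rather than via `scipy.cluster.hierarchy` because
merge ties are broken by the lexicographically smallest pair of cluster
representatives, making the dendrogram invariant to row permutation of
the input; scipy's linkage is the cross-check oracle on tie-free inputs.
Clade fingerprints are the AHL species present in ≥ q (default 1.0) of a
clade's or subclade's strains; fingerprints are exhibited for
user-specified subclades because the survey's own fingerprints describe
subgroups, not whole clades.

"No correlation between isolation site and AHL profile" is
operationalised as a Mantel test: Pearson correlation between the
Jaccard profile distances and great-circle (haversine) distances between
isolation sites, with a seeded row/column permutation null (default 999
permutations, p = (1 + exceedances)/(1 + permutations)).  The reference
strain has no recorded site and is excluded.  On the fixture this gives
r ≈ 0.09, p ≈ 0.08–0.10 depending on the permutation seed — no
significant association, in line with the survey's conclusion.

## 6. Phylogeny (`phylo`)

Jukes-Cantor distances d = −(3/4)·ln(1 − (4/3)p) with p the mismatch
fraction over pairwise-complete columns (gaps and N excluded per pair —
pairwise deletion, appropriate for partial gene fragments of unequal
coverage).  p ≥ 0.75 is reported as an error for that pair, never capped
silently.  Neighbor joining follows Saitou-Nei Q-minimisation with two
determinism rules: ties broken by the lexicographically smallest pair of
cluster representatives, and negative branch-length estimates clamped to
zero with the deficit moved to the sister branch (preserving the pair's
summed length).  Bootstrap support resamples alignment columns with
replacement (default 100 replicates, seeded) and scores each original
internal bipartition by the percentage of replicate trees containing it.
Rooting places the root at the midpoint of the outgroup's pendant edge
and is idempotent.  Clade labels are input metadata, not inferred.

## 7. Synthetic data (`synthetic_data`)

The generator produces exactly the features the pipeline consumes:

* **Chromatography** — Gaussian elution (sd 0.05 min) per planted adduct
  ion; no tailing model.
* **Adducts** — apex ratios per tune mode, H:Na:NH4 = 0.2:0.7:0.1 under
  the standard tune (sodium-dominant) and 0.7:0.2:0.1 under the
  small-molecule tune (proton-dominant).  The *orderings* encode the
  instrument behaviour the screen is designed around; the magnitudes are
  a modelling choice.
* **Isotopes** — one-13C satellites at natural abundance, 1.1% per
  carbon summed over the formula's carbons.
* **Noise** — folded-Gaussian (|N(0, sd)|, default sd 10 counts)
  baseline noise placed in every default-library extraction window each
  MS1 scan (so every screened EIC has a realistic noise floor for the
  MAD estimator) plus 100 random-m/z centroids per scan; m/z jitter
  sd 0.002 Da on all planted ions.
* **DDA** — per MS1 scan the top-3 eligible centroids (m/z 170–460,
  intensity ≥ 5 × noise sd, not dynamically excluded) are fragmented at
  10 and 20 eV; a selected precursor is excluded for 0.04 min.  Proton
  and ammonium adducts of planted AHLs yield the diagnostic ions (closed
  ring: ring 100, ring-loss 60, open-ring 20 relative; open ring:
  open-ring 100, ring 60, ring-loss 40, so open-ring dominance marks
  hydrolysed species) plus an acyl-side fragment; sodium adducts yield
  no CID products; decoys yield unrelated fragments, validated to avoid
  the diagnostic windows.  Only ion *presence* is asserted in tests —
  the yields are placeholders.
* **Determinism** — one `numpy` generator seeded per run spec; a fixed
  spec reproduces byte-identical mzML.

What this does **not** emulate — real resolution curves, in-source
fragmentation, matrix suppression, rt drift between runs — bounds what
green tests mean: they show the decision rules (windows, s/n cut-off,
tier logic, 2-of-3 mining, DDA bookkeeping) are implemented correctly,
not that the method's instrument-side sensitivity claims transfer to any
particular LC-MS system.

Sequence evolution (`simulate_jc_alignment`) draws i.i.d. sites on a
tree under the equal-rates model: along a branch of length t a base is
retained with probability 1/4 + 3/4·e^(−4t/3).

## 8. Problem sizes used in tests and the acceptance script

Planted-recovery properties run 20 seeded runs of 3 planted AHLs
(abundance 40 × noise sd) plus one decoy over a 4.2-min gradient,
screened against the full 33-species library.  Topology recovery runs 50
seeded 2000-site alignments on a 6-taxon tree with all branches
≥ 0.05 substitutions/site (recovery is ≥ 95% by construction of the
regime; observed 100%).  The Mantel permutation null uses 999
permutations.  These sizes keep the full suite and the acceptance script
each under a minute or two on one CPU while leaving the measured rates
far from their pass/fail boundaries.

## 9. Known limitations

* The OH-C7/OH-C8 fixture areas are duplicated transcription values (see
  §5); per-cell presence and tiers are curated, areas there are not
  trustworthy as magnitudes.
* `estimate_lod` depends on the planted-peak model; it is an ordering
  device for dilution series, not an instrument LOD.
* The formula enumerator searches CHNO only and ranks by mass error; it
  does not score isotope patterns.
* NJ is O(n^3) with a dense pair dictionary — fine for tens of taxa,
  not for thousands.
* The m/z 137 fragment of one novel open-chain AHL reported in the
  source survey is treated as a finding, not added as a fourth
  diagnostic ion; the default rule set stays at the three
  homoserine-ring ions.
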