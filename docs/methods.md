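# Methods

## Scope and model

`ltafrag` models the eight lipid classes that carry the signal in
direct-infusion spectra of *B. subtilis* polar-lipid extracts: the
diglucosyl-diacylglycerol LTA anchor, the LTA primer
(DAG-Glc-Glc-P-Gro) and its mono- and di-alanylated derivatives,
phosphatidylglycerol (PG), alanyl-PG, cardiolipin and lyso-cardiolipin.
Each species is a residue graph — acyl chains, a backbone glycerol, up to
two glucoses, a phosphate, a head glycerol, up to two alanines — condensed
with one water lost per covalent linkage. Acyl compositions are sum
compositions `(C:D)` optionally resolved per chain; every resolved split of
a sum composition yields the same neutral formula, so mass arithmetic never
depends on the split.

## Mass conventions

Monoisotopic masses use CODATA/IUPAC values for the closed element set
C, H, N, O, P, Na (C = 12 exactly, H = 1.007825, N = 14.003074,
O = 15.994915, Na = 22.989770, P = 30.973762; proton = 1.007276).
Ionisation conventions:

* `[M+Na]+` adds the sodium **atom** mass with no electron-mass correction —
  the convention under which the published sodiated-cation values reproduce;
* `[M−H]−` subtracts the **proton** mass. Published small-anion values were
  computed with H-atom subtraction instead, an internal inconsistency of
  ~0.5 mamu between the two conventions; one convention (proton) is used
  throughout and all comparisons carry an absolute 0.002 amu tolerance,
  which absorbs the difference. Tolerances are absolute amu, not ppm,
  because the reference data state their own agreement in amu.
* `[M−2H]2−` subtracts two protons and halves (cardiolipin dianions);
* `[M−OH]+` subtracts O + H atom masses — the acylium-like cation series
  ("MAG − OH") seen alongside sodiated fragments in positive mode.

## Fragmentation bookkeeping

Every linkage of the condensed structure owes one water. When a bond set
(1–3 bonds) is cut, each connected component is a candidate charge-retaining
fragment, and each of its cut boundaries independently either keeps that
water or loses it. Compounded with the terminal deprotonation this
generates the full `− H` / `− H3O` / `− H5O2` suffix family, and at acyl
esters it produces both the fatty-acid-loss and ketene-loss forms (one
water apart) — no fragment is hard-coded. In positive mode an ester cut on
the glycerol-retaining side may instead shed a bare hydroxyl, which yields
the allylic `CH2=CH-CH2-Glc-Glc + Na+` ion of the anchor from a b1 & b2
double cut. Fragments are deduplicated by (neutral composition, adduct) —
species with two identical chains therefore collapse their a1/a2 and b1/b2
cuts into single ions — and ions below m/z 50 are suppressed (no observed
fragment lies below ~79). `max_cuts` defaults to 2, or 3 for alanylated
classes whose observed spectra require triple cuts.

Two ions of the di-alanylated primer are not reachable by bond cutting and
are emitted as explicit rearrangement rules: the deprotonated
alanyl-alanine dipeptide (159.0775) from head-group transesterification,
and the decarboxylated molecular anion (M − CO2 − H, 1115.6613). They are
emitted only for the di-alanylated class; tests assert their absence from
every other catalogue.

Cardiolipin and lyso-cardiolipin are modelled at the molecular-ion level
only (their role in the survey scans is as precursor clusters: the default
(62:0)/(64:0) CL dianions at 661.5/675.5 in the observed 650–680 window,
lyso-CL anions near 1100).

Bond-label subscripts for asymmetric chain pairs are a convention: cutting
either ester of a (15:0/17:0) species produces fragments of identical
composition, so the catalogue keeps one representative whose subscript may
differ from a given hand-assignment. The alphabetic labels themselves map
(hydroxyl-retaining, dehydrating) cut pairs: a/b at acyl esters, c/d at the
glycerol–glucose linkage, f at the glycosidic bond, g–j at the
phosphodiester flanks, k–n at the alanyl esters. The second alanine is
attached as a second head-glycerol ester (labels m/n); its exact hydroxyl
position is not mass-distinguishable and only affects labels.

## Annotation and nomination

Observed peaks are matched greedily to the nearest catalogue ion within an
absolute tolerance (defaults: 0.005 amu for high-accuracy data, 0.3 amu for
unit-resolution data); ties go to the fewest-cuts, lexicographically
smallest assignment. Unmatched peaks are reported, never force-assigned.
Species nomination searches the classes compatible with a diagnostic
channel (347+ → anchors; 153− → terminal-phosphoglycerol PG and primer;
88− → alanylated classes) over acyl sum compositions C 24–40, 0–4 double
bonds, ranking candidates by |Δm|. Within the default 0.02 amu tolerance
the grid is collision-free: no two candidate species fall within tolerance
of one another.

## Synthetic data

The generator emulates the qualitative structure of the real survey and
precursor scans, not their absolute intensities. Signal peaks get Gaussian
m/z jitter (presets: 0.0005 amu high-accuracy, 0.2 amu unit-resolution) and
log-normal intensities (median `signal_scale` = 1000, log-sd 0.2); noise
peaks are uniform in m/z with intensities uniform on (0, 50]. The default
mixture reflects the published cluster structure — PG (30:0)/(32:0)
dominant at 693/721, cardiolipin dianions in 650–680, primer at 1017/1045,
alanyl-PG at 764/792, and the two alanylated-primer clusters at 1088/1116
and 1159/1187, 71 amu apart; relative abundances are order-of-magnitude
choices. Species whose phosphoglycerol is embedded or esterified
(cardiolipin, lyso-CL, alanyl-PG, alanylated primers) emit the 153
diagnostic at 5% of the signal scale; the emulated precursor scan uses an
absolute trace threshold of 150 intensity units, which sits between the
damped-diagnostic band (~50) and the signal floor (~550), reproducing the
observation that the 153 channel selects terminal-phosphoglycerol lipids
only. All draws are `numpy` `default_rng` streams fully determined by the
`NoiseModel` seed.

What the generator does **not** model — isotope envelopes, chromatography,
detector saturation, collision-energy dependence, charge states beyond 2−,
and quantitative intensity ratios — bounds what passing tests show: the
pipeline is validated for mass-arithmetic correctness and for
cluster/diagnostic logic, not for intensity-based inference on real data.

## Verification strategy and problem sizes

* The formula engine is cross-checked against an independent mass oracle
  (pyteomics) under property-based testing; condensation additivity and
  Hill round-tripping are property tests.
* The fragmenter is checked two ways: against the four curated reference
  fragment lists (every consistent reported calculated mass within
  0.002 amu), and against a brute-force generator on a 4-residue linear
  chain that tries every contiguous segment with every water state
  (exact set equality of m/z values).
* The simulate→annotate round trip is exact (100% recovery, zero delta) in
  the noiseless limit for all eight classes; with 0.001 amu jitter and 50
  noise peaks, per-run recovery stays ≥ 95% and species nomination is
  correct in ≥ 99% of 100 seeded runs. These sizes (10–100 seeds, catalogues
  of 50–105 ions) keep the full suite in single-digit seconds.

## Known data inconsistencies

Two rows of the curated reference tables are flagged rather than silently
matched:

* the `(15:0) MAG-Glc2-P − H3O` entry's reported calculated mass (701.3051)
  contradicts the neutral-loss arithmetic that accompanies it
  (943.5399 − 242.2246 = 701.3153, consistent with a single-digit
  misprint); the catalogue carries the arithmetically consistent value, and
  a dedicated test documents the discrepancy;
* the 223.1698 entry of the di-alanylated table is a background (14:2)
  free fatty acid, not a fragment of the species.

The anchor table's observed peaks deviate from the recomputed catalogue by
at most 0.0027 amu (the `b & f` double-cut row), slightly above the 0.002
amu agreement the source text claims for itself; the acceptance suite
asserts the claimed bound and therefore reports this row honestly as a
failure, while all rows remain matched at the 0.01 amu annotation
tolerance.
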