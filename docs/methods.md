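# Methods

`atomsort` implements the analysis chain used to profile and quantify
natural products in crude microbial extracts by NMR: identification of
known compounds from ¹H–¹³C HSQC peak lists, quantification from 1D-¹H
integrals against the residual-solvent internal standard, and validation of
candidate structures by formula mass and adduct m/z. This note records the
model, its assumptions, the defaults and why, the numerical choices, and
what the synthetic-data tests do and do not demonstrate.

## Identification: range-normalized nearest-neighbor distance

An HSQC spectrum is reduced to a peak list of (δ¹H, δ¹³C) pairs in ppm.
For a reference compound with peaks {q₁…q_n} and an extract spectrum with
peaks {t₁…t_m}, each compound peak is matched to its closest extract peak
under the range-normalized Euclidean metric

    d_AS(q, t) = √[ (Δδ¹H / R_H)² + (Δδ¹³C / R_C)² ]

where R_H and R_C are the max−min chemical-shift ranges of each dimension
of the searched list. Normalization makes the two dimensions commensurate
and expresses a distance as a fraction of the occupied shift space. The
per-compound score is the median of its n nearest-neighbor distances
(d̃_AS); the match fraction counts peaks with d_AS ≤ 0.25. Classification
of d̃_AS: < 0.1 → present, 0.1–0.2 (inclusive) → related compound,
> 0.2 → non-specific. Ranking a database ascending by d̃_AS (ties broken by
descending match fraction, then name) yields candidate identifications.

Assumptions and conventions:

* **Direction** is compound → extract: compound peaks are the queries and
  the culture spectrum is the searched set. The reverse comparison is not
  symmetric and is not computed.
* **Normalization ranges** come from the extract list by default, because
  the extract is the searched reference set. `MatchConfig.range_source`
  switches to compound-list ranges for the alternative convention.
* **Degenerate ranges** (≤ 1 distinct shift, e.g. a one-peak compound such
  as methanol when compound ranges are selected) fall back to floor ranges
  of 10 ppm ¹H / 160 ppm ¹³C — the full spectral windows of a routine
  HSQC — keeping distances defined and conservative.
* **Ties** in the nearest-neighbor search resolve to the lowest extract
  index, for determinism. Matching is many-to-one: several compound peaks
  may share one extract peak; no bijective assignment is attempted.
* **Even-count medians** are the mean of the central pair (standard
  convention).
* **Intensities** are carried through I/O but ignored in scoring; the
  distance uses chemical shifts only.
* Nearest neighbors are found by vectorised all-pairs search (numpy
  broadcasting). Peak lists here are a few hundred entries at most, where
  all-pairs is faster than tree structures and trivially exact; the test
  suite checks it against an independent exhaustive-loop oracle to 10⁻¹².

### The density floor on specificity

The median-distance statistic has an intrinsic specificity limit that users
should understand. Against an extract whose m peaks effectively fill the
normalized shift space, the nearest-neighbor distance of *any* query peak
has median ≈ √(ln 2 / (m π)); for m ≈ 225 peaks that is ≈ 0.031 — below
the 0.1 "present" threshold. In other words, at realistic crude-extract
peak densities an arbitrary compound whose peaks fall anywhere inside the
occupied region will score a "present"-range median by geometry alone, if
extract peaks were spread uniformly. Real spectra are far from uniform —
peaks concentrate on chemically allowed (δ¹H, δ¹³C) bands, leaving most of
the normalized square empty — which is what makes the thresholds usable in
practice on instrument data. The simulator's uniform decoys are therefore a
worst case for false positives, and under them the absolute present/related
labels lose specificity even though *ranking* remains informative: truly
present compounds score medians an order of magnitude below the density
floor (jitter-limited, ~0.002) and rank strictly above absent ones. The
test suite asserts both facts: the density law for absent compounds, and
the rank separation of present over absent.

## Quantification: residual-solvent internal standard

With an internal standard of known concentration c_s in the same tube, an
analyte's concentration follows from per-proton integral ratios in the
1D-¹H spectrum:

    c_a = (I_a / n_a) / (I_s / n_s) · c_s

* The standard here is the residual CHD₂OD methyl resonance of CD₃OD
  (n_s = 1). Its concentration is a required parameter with default
  150 mM, computed from the solvent's deuteration grade: 99.8 atom % D
  implies a singly protonated methyl isotopologue at ≈ 3 × 0.002 × 24.6 M
  ≈ 0.15 M in neat methanol-d4. Correctness of the package is defined by
  the formula; the constant should be calibrated per solvent lot for real
  work.
* `n_protons` per analyte resonance is caller-supplied — which resonance
  is integrated is an experimental choice the software cannot know.
* No relaxation or NOE corrections are applied; integrals are taken as
  proportional to proton count × concentration.

Downstream arithmetic (all linear, units reconciled):

* in-tube mass (µg) = c (mM) × V_tube (µL) × MW (g/mol) × 10⁻³, with
  V_tube defaulting to the 50 µL loading of a 1.7 mm tube;
* culture titer (mg/L) = mass_tube (µg) / V_equiv (mL), where the
  equivalent culture volume V_equiv = aliquot_fraction ×
  (V_tube/V_dissolved) × V_culture follows the sample chain (defaults: 2%
  extract aliquot, 50 of 200 µL loaded, 1 L culture → 5.0 mL);
* isolated yield (mg/L) = isolated mass / culture volume, reported to one
  decimal.

The production-run data this package reproduces are internally consistent
with a common equivalent volume of 7.25 mL rather than the 5.0 mL the
nominal chain implies (an effective aliquot fraction near 2.9%). Because
the chain parameters and the published ratios disagree, the package never
silently picks one: `SampleChain.equivalent_volume_override` makes the
calibrated value explicit, the default chain computes the nominal 5.0 mL,
and the tests calibrate the override from a single published
(mass, titer) pair before reproducing the others.

Report rounding: concentrations and masses to one decimal, titers to one
decimal, medians to three decimals — matching the precision of the tables
this mirrors.

## Formula masses and adduct m/z

Formula strings are parsed over the element set {C,H,D,N,O,S,P,Na,K,Cl}
(counts default 1; parenthesised groups supported). Monoisotopic masses sum
most-abundant-isotope masses and average masses sum IUPAC standard atomic
weights; both tables are pinned in `atomsort.masses` so values cannot drift
with an external dependency (the unit tests cross-check against pyteomics).
Adduct m/z uses the electron-corrected convention,

    m/z = (monoisotopic(ion) − z·mₑ) / |z|,   mₑ = 0.000549 Da,

which reproduces high-resolution "calcd." values to the printed 4 decimals
(the uncorrected sum is ~0.0005 high). Only |z| = 1 species are supported:
M+H, M+Na, M−H on a neutral formula, or an ion composition given directly.

## Synthetic data

`atomsort.simulate` generates study-shaped inputs with known truth:

* a reference database of compounds with 5–55 peaks uniform in 0–10 ppm
  ¹H × 0–160 ppm ¹³C and internally consistent synthetic formula/MW pairs;
* extract spectra = union of the present compounds' peaks, each dropped
  with probability 0.05 (weak/overlapped peaks) and jittered by Gaussian
  noise of 0.01 ppm ¹H / 0.1 ppm ¹³C (run-to-run referencing scatter),
  plus 125 uniform decoy peaks standing in for unassigned signals — with
  a handful of present compounds this lands extracts in the 200–250-peak
  range typical of crude-extract HSQC spectra, about half assignable;
* integral tables consistent with per-compound concentrations drawn
  uniformly from 2–30 mM (the scale of the quantified metabolites), with
  optional multiplicative Gaussian noise of configurable CV.

Everything is deterministic given the seed (independent substreams per
operation). What the simulator does **not** model: correlated ¹H/¹³C
chemical-shift statistics (real peaks live on compound-class bands, decoys
here are uniform — see the density-floor discussion), lineshapes and peak
overlap, intensity information, and solvent artifacts. Consequently,
passing synthetic-recovery tests demonstrates the scoring arithmetic and
ranking behavior, not field performance of the thresholds on real spectra.

## Packaged reference data

The packaged database holds the seven compounds profiled in the source
extracts. Didemnin B's 50-peak list is built from its tabulated ¹H/¹³C
assignments in CD₃OD under an explicit inheritance rule: a row lacking its
own ¹³C inherits its diastereotopic partner's carbon (same position label
up to a trailing a/b); N–H rows are excluded. The tabulated data give no
carbon for the Ist7 methylene pair, so those two correlations cannot be
placed — the published per-compound count (51) sits between this build's
zero-tolerance count (50 + the 2 unplaceable rows = 52 proton rows) and is
not reproducible exactly; tests assert the count relationships rather than
a fixed number. Peaks closer than 0.03 ppm ¹H and 0.3 ppm ¹³C in both
dimensions (≈ digital resolution of a routine HSQC) can be merged to their
centroid by the explicit merge operation; merging is never implicit. The
six other compounds ship as synthetic stand-in peak lists (typical
chemical-shift regions, literature peak counts) because their measured
lists are not public; filenames carry a `synthetic_` prefix.

## Numerical choices

* Merge clustering is single-linkage within per-dimension tolerances,
  iterated to a fixpoint so the operation is idempotent; comparisons allow
  a 10⁻⁹ ppm epsilon so decimal tolerance boundaries (e.g. |0.92 − 0.89|
  vs 0.03) are not broken by binary floating point. Zero tolerance is the
  exact identity, preserving duplicate coordinates.
* Peak-list csv I/O prints 4 decimals (0.1 mHz-scale precision, beyond any
  peak-picker), making write∘read the identity on coordinates.
* Classification boundaries: exactly 0.1 → related, exactly 0.2 → related,
  exactly 0.25 → matched.

## Known limitations

* The present/related thresholds are meaningful only when the searched
  spectrum's peaks do not fill the normalized shift space (see the density
  floor above); for dense or uniform target sets, use the ranking and the
  match fraction, not the absolute label.
* Quantification accuracy is bounded by the internal-standard
  concentration, which depends on the solvent lot's true deuteration grade.
* No peak picking: inputs are peak lists, and integral values are inputs,
  not computed from spectra.
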