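# Methods

## Ring puckering and conformer naming

Six-membered rings are described by the Cremer–Pople coordinates computed
from the original mean-plane construction: ring positions are centred,
the plane normal is taken from the two Fourier displacement vectors
R′ = Σ rⱼ sin(2πj/6) and R″ = Σ rⱼ cos(2πj/6), and the out-of-plane
displacements zⱼ are decomposed into

    q2 cos φ2 =  (1/3)^0.5 Σ zⱼ cos(4πj/6)
    q2 sin φ2 = −(1/3)^0.5 Σ zⱼ sin(4πj/6)
    q3        =  (1/6)^0.5 Σ zⱼ (−1)ʲ

with Q = (q2² + q3²)^0.5, θ = atan2(q2, q3). The ring cycle is ordered
ring-oxygen first (O5, C1…C5 for aldopyranoses; O6, C2…C6 for sialic
acid), which places the ⁴C₁ chair at θ ≈ 0 and ¹C₄ at θ ≈ 180.

Conformers are assigned to the nearest of the 38 canonical reference
points on the (θ, φ₂) sphere (2 chairs; boats at θ = 90°, φ₂ = 0°, 60°, …;
skew-boats at the odd multiples of 30°; half-chairs at θ = 50.8°/129.2°
and envelopes at θ = 54.7°/125.3°). The canonical positions were derived
analytically from the ideal displacement patterns (e.g. a boat is a pure
cos(φ₂ + 4πj/6) pattern) and are verified exhaustively in the test suite
by regenerating each pattern and checking the assigned name. Ties in the
nearest-point assignment resolve toward the chair poles. Names are
rendered with the residue's own ring labels, so sialic acid's chair
reports as ²C₅.

Numerical guards: rings with Q < 0.1 Å are reported planar and receive
no conformer name (θ is unstable there); the physically plausible
amplitude window is 0.4 Å ≤ Q ≤ 0.8 Å (configurable — the bounds of the
original survey software are not published).

## Stereochemistry checks

Anomeric (α/β) and absolute (D/L) configuration are compared against the
CCD code using conformation-robust signed-volume fingerprints: at the
anomeric carbon, sign(det[u(ring O), u(next ring C), u(exocyclic O)]),
and at C5, sign(det[u(O5), u(C4), u(C6)]). Expected signs per code are
tabulated from ideal-geometry constructions of each sugar. When the
anomeric oxygen has been replaced by a glycosidic bond the bridging
oxygen's position is used; if neither is available the check is reported
indeterminate rather than failed. A full mirror image flips both centres
and is classified as a D/L error.

A residue is *correct* when stereochemistry, amplitude and minimal-energy
chair (⁴C₁ for the D-sugars, ¹C₄ for fucose, ²C₅ for sialic acid) all
pass; failing only the conformer check is *high-energy*; anything else is
a geometry/nomenclature error.

## Torsion conventions

Dihedrals follow the IUPAC sign convention (clockwise positive viewed
along the central bond) and are reported in (−180°, 180°]. A torsion is
invariant under reversal of the four-atom chain; the implementation is
cross-checked against an independent library in the tests. Per linkage:

* sugar–sugar 1→x (x = 2, 3, 4): φ = O5(d)–C1(d)–Ox(a)–Cx(a),
  ψ = C1(d)–Ox(a)–Cx(a)–C(x−1)(a);
* 1→6: φ = O5(d)–C1(d)–O6(a)–C6(a), ψ = C1(d)–O6(a)–C6(a)–C5(a),
  ω = O6(a)–C6(a)–C5(a)–O5(a);
* 2→6 (sialic acid donor): as 1→6 with O6(d)/C2(d) as the donor frame;
* root linkage: φ = O5–C1–ND2–CG, ψ = C1–ND2–CG–CB.

The atom quadruples are calibrated so that fragments constructed at
published per-entry outlier torsions measure back to those values; real
deposited coordinates are the natural further check where available.

Summary statistics are circular by default (resultant-vector mean;
SD = √(−2 ln R) in degrees) because several linkages cluster near the
±180° wrap (the α1,6-mannobiose ψ, the root-linkage ψ). An arithmetic
mode is provided for comparability with tables computed linearly.

## The binned database and the Z-score

Records for each linkage type are binned on a 180×180 grid over
(φ, ψ) ∈ [−180°, 180°) with 2° half-open bins; ω is stored with the
records but never binned (the score is two-dimensional; ω acts as a
spread-increasing nuisance coordinate for 1→6 linkages). The score of a
measured linkage is z = (c − ⟨c⟩)/σ⟨c⟩ with ⟨c⟩ and σ⟨c⟩ the population
mean and SD of the **occupied** bin counts for that linkage type. The
occupied-bin convention is load-bearing: a 32 400-bin grid is
overwhelmingly empty at realistic sample sizes, so statistics over all
bins would pin every possible negative score to ≈ −√(f/(1−f)) (f the
occupied fraction), a few hundredths — no conformation could ever reach
the −1 standout threshold. Over occupied bins, an unobserved
conformation scores −⟨c⟩/σ⟨c⟩, which for realistic count distributions
lands near or below −1. Including empty bins remains available as an
option (`include_empty_bins`).

Thresholds: flagging is strict (z < −1; z = −1 exactly is not flagged);
linkage types with n < 50 observations are insufficient-data (grey);
global Z is the arithmetic mean of available linkage scores (the root
linkage participates like any other); |global Z| > 2 is annotated as
worth attention (very negative: possible serious problems; very
positive: possible torsion over-restraining). The quality Z standardises
a structure's global Z against a user-supplied reference set of global
Z values, using the reference sample mean and sample SD (ddof = 1) —
the minimal reading of "comparison to a reference set"; the original
construction is not published in detail.

Degenerate cases are errors, not silent zeros: σ⟨c⟩ = 0 (a single
distinct occupied count) and a zero-spread reference set both raise.

## Curation and the survey

A torsion record survives curation only if **both** monosaccharides of
the linkage pass RSCC > 0.80 (strict; RSCC = 0.80 exactly fails) and the
ring diagnostics above. The per-residue gating on both ends follows from
the observation that one poorly fitting residue invalidates the bond
geometry between them. Missing RSCC entries reject by default
(configurable pass-through). RSCC values are consumed from 4-column TSV
tables; computing them from maps is out of scope (a generic
masked-correlation helper is provided).

Summary tables are produced per linkage code and resolution shell
(breakpoints 1.50 Å and 3.00 Å, plus an "All" row; records without a
resolution contribute to "All" only). Two corpora are compared per
(code, angle) with Welch's unequal-variance two-sided t-test after
unwrapping both samples about their pooled circular mean — a naive
t-test is wrong whenever a cluster straddles ±180°. Significance is
p ≤ 0.05, two-sided, with no multiple-testing correction; the number of
simultaneous tests is reported so users can apply their own.

The modal-conformation estimate reported by `summarize_linkage` is the
per-angle marginal mode after summing each 2° bin with its circular
neighbours (a 6° window). A single raw cell of a sparse 2-D histogram
holds only a handful of counts, so its argmax is a noisy location
estimate; the windowed marginal is the standard stabilisation. The raw
hottest cell is reported alongside. The scoring grid itself is never
smoothed.

## Synthetic data: what it emulates, what it does not

The fixtures generator is the documented inverse of each measurement:

* `make_ring(Q, θ, φ₂)` inverts the puckering analysis exactly
  (zⱼ = √⅓ q₂ cos(φ₂ + 4πj/6) + √⅙ q₃(−1)ʲ on a regular hexagon
  traversed so the mean-plane normal is +z);
* `make_pyranose` adds substituents on tetrahedral slots chosen to
  preserve each stereocentre's canonical-chair chirality — so distorted
  rings keep correct stereochemistry, as real molecules do;
* `make_glycan` places each donor by internal coordinates so ψ is exact,
  then spins it about the glycosidic bond until φ matches (and sets ω by
  re-placing the acceptor's O6); round trips through bond perception and
  measurement are exact to 1e−6°;
* `make_database` samples wrapped-normal (φ, ψ) clusters.

Generated structures are geometrically exact but physically naive: no
clash relief, partial CCD atom inventories, idealised bond lengths, and
wrapped-normal torsion clusters where real survey data are clumpier
(restraint pile-ups, duplicated entries) and heavier-tailed. Passing
tests therefore demonstrate the correctness of the measurement and
scoring machinery, not the field realism of any particular database.
Demonstration databases use clusters at the modal core-glycan torsions
with σ = 8° (the tight end of observed per-linkage spreads) and 1000
observations per linkage: at that size the central bin of each cluster
expects ≈ 10 counts, so modal conformations score reliably positive
while displaced ones score below −1. At smaller corpus sizes the central
2° bin's count is Poisson with λ of a few, and even a modal-torsion
linkage can hit an empty cell — an inherent property of raw sparse-grid
scoring worth remembering when building small custom databases.

## Known limitations

* Connectivity is geometric (1.7 Å cutoff); file `struct_conn` records
  are not consulted. Severely distorted models could miss or mis-assign
  a bond.
* The stand-in fragments for the published outlier cases are synthetic
  constructions at the printed torsions; they pin the measurement
  conventions, but agreement with the actual deposited coordinates is
  only exercised when those files are supplied.
* Alternate locations keep the highest-occupancy conformer only; only
  the first model of multi-model files is read.
* The α/β sign table covers the six supported sugars; sialic acid's D/L
  centre is not checked.
* The tryptophan-mannosylation ¹C₄ special case is representable via the
  per-code minimal-conformer table but not auto-detected.
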