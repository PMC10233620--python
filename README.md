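# glycovalid

Conformational validation of N-glycans in glycoprotein structure models:
Cremer–Pople ring-puckering diagnostics, glycosidic torsion harvesting, a
2°×2°-binned torsion database with per-linkage Z-scores, and SNFG diagrams
that highlight standout linkages and distorted rings.

## The problem

N-glycans — oligosaccharides attached to the ND2 nitrogen of asparagine —
are hard to model well: their electron density is usually weaker than the
protein's, and deposited structures accumulate nomenclature errors,
impossible linkages and improbable high-energy ring conformations.
Torsion angles about glycosidic bonds are a sensitive fingerprint of these
problems, but judging them requires a trustworthy reference distribution,
which in turn requires curating away the very errors one wants to detect.

`glycovalid` implements that loop for structural biologists and model
validation pipelines:

1. **Curate.** Each pyranose ring is analysed with the Cremer–Pople
   puckering parameters (Q, θ, φ₂). A monosaccharide passes only if its
   anomeric and absolute (D/L) stereochemistry match its CCD three-letter
   code, its puckering amplitude is physical (0.4 Å ≤ Q ≤ 0.8 Å), it sits
   in its minimal-energy chair (⁴C₁ for the D-pyranosides, ¹C₄ for
   L-fucose), and its real-space correlation coefficient (RSCC) is
   strictly above 0.80 at both ends of the linkage.
2. **Harvest.** Glycosidic bonds are perceived geometrically
   (anomeric C → acceptor O/N within 1.7 Å), classified into the standard
   N-glycan linkage taxonomy (`NAG-ASN`, `NAG-1,4-NAG`, `MAN-1,3-BMA`,
   `SIA-2,6-GAL`, …), and measured: φ = O5–C1–Ox–Cx,
   ψ = C1–Ox–Cx–C(x−1), plus ω = O6–C6–C5–O5 for 1→6 / 2→6 linkages.
3. **Score.** Torsions for each linkage type *l* are accumulated on a
   180×180 grid of 2° bins. A measured linkage with bin count
   c<sub>l</sub><sup>φψ</sup> receives

   z = (c<sub>l</sub><sup>φψ</sup> − ⟨c<sub>l</sub>⟩) / σ⟨c<sub>l</sub>⟩

   where ⟨c<sub>l</sub>⟩ and σ⟨c<sub>l</sub>⟩ are the mean and SD of the
   occupied bin counts for that linkage type. Positive z: a well
   represented conformation; z < −1: a standout worth inspecting. Linkage
   types with fewer than 50 observations are reported as
   insufficient-data, never scored. Per glycan, the **global Z** is the
   mean of the linkage scores, and an optional **quality Z** standardises
   it against a reference set of trusted structures.
4. **Draw.** SNFG (3rd-edition) diagrams with orange backings behind
   standout linkages and non-chair rings, grey behind insufficient-data
   linkages.

A survey module compares two harvested corpora (e.g. as-deposited vs
re-refined models) per linkage and angle with Welch t-tests computed on
angles unwrapped about the pooled circular mean.

## Worked example

Every stage runs on synthetic structures with known ground truth — no
downloads needed. `examples/02_validate_glycan.py` builds a reference
database from wrapped-normal clusters at the modal core-glycan torsions
(σ = 8°, 1000 observations per linkage), then validates a glycan built at
those modal torsions and one whose 1,3-arm mannose is rotated into empty
torsion territory:

```
modal glycan: global Z = +3.03, 0 flagged linkage(s)
  NAG-ASN      phi    -97.0  psi    178.5  z = +2.26
  NAG-1,4-NAG  phi    -80.0  psi   -127.0  z = +2.22
  BMA-1,4-NAG  phi    -87.0  psi   -133.0  z = +2.95
  MAN-1,3-BMA  phi     76.0  psi    121.0  z = +5.49
  MAN-1,6-BMA  phi     72.0  psi    168.0  z = +2.24

displaced 1,3 arm: global Z = +1.71, 1 flagged linkage(s)
  ...
  MAN-1,3-BMA  phi   -170.0  psi    -20.0  z = -1.11 <- standout (orange)
```

Each linkage at its modal conformation scores strongly positive; the
displaced linkage falls in an unpopulated bin and scores −1.11, below the
−1 standout threshold, so the SNFG rendering backs it in orange. The
other examples cover ring puckering (`01`), corpus comparison with
wrap-aware Welch tests (`03`) and diagram rendering (`04`).

The same pipeline is available from the shell:

```sh
glycovalid build-db --corpus structures/ --rscc rscc.tsv --out db.json
glycovalid validate model.pdb --db db.json --svg model.svg --report report.json
glycovalid compare --a deposited/ --b rerefined/ --out ttests.tsv
```

`validate` exits 0 when clean, 2 when any linkage is flagged, 1 on error.

## Scope

RSCC values are consumed from per-residue TSV tables, not computed from
maps. Only ASN-rooted N-glycans are validated; orphan sugar clusters are
reported but never scored. O-, C- and S-glycosylation, furanose puckering,
restraint generation and interaction analysis of outliers are out of
scope. See `docs/methods.md` for the model, parameter defaults and known
limitations.
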