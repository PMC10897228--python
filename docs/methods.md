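# Methods

This note documents the models, numerical choices and limitations behind
each pipeline stage, and what the synthetic-data generators do and do not
emulate.

## Motif model

The ELF-pocket binding signature is deliberately minimal: an anchor residue
from a configurable set (default {F, L}) plus context flags rather than a
probabilistic model. Known clients are too divergent for a PSSM/HMM to be
honest — a literal probe such as `FADI` is neither sensitive (most known
clients do not match it) nor specific (most matches do not bind), and the
package surfaces that honestly through tiering rather than hiding it in a
score.

Parameters:

- **context window** (±5 residues, configurable): the acidic-residue
  criterion has no canonical distance; ±5 covers the D-at-+2 arrangement of
  `FADx` motifs and an acidic partner six residues downstream of the anchor
  as seen in some myosin-family clients.
- **disorder threshold** (50 on the 0–100 pLDDT-like scale): low predicted
  confidence correlates with disorder; anchors in confidently folded regions
  are down-weighted by criterion (iii).
- Coordinates are 1-based throughout sequence space, matching residue
  numbering conventions in the structural literature.
- `X` and other non-standard letters never match anchors or acidic checks.
- Nearest-acidic ties break downstream (C-terminal); biologically arbitrary
  but fixed and documented.

## Conservation

Per-column conservation is the Jensen–Shannon divergence (base-2) between
the column's residue distribution and a background, normalized by the
divergence of a point-mass column against the same background. JSD is
convex in the column distribution, so the point mass is the exact maximum:
the normalized score lies in [0, 1], equals 1 for any fully conserved
column and 0 for a background-like column. The background defaults to
uniform over the 20 residues; a BLOSUM62-derived background is available.

- Gaps are excluded from column distributions; columns with gap fraction
  > 0.5 are flagged low-coverage. Columns where the reference is gapped are
  skipped, so tracks index 1:1 onto the ungapped reference.
- Duplicate rows count at full weight (no redundancy reweighting); scores
  are invariant to row order.
- Homolog selection keeps the reference plus the top-N rows (N = 1000 by
  convention) ranked by percent identity to the reference over
  reference-ungapped columns; ties break by input order. Whether an input
  homolog set was redundancy-filtered upstream is recorded nowhere in the
  alignment itself, so the package does not guess — the ranked set is the
  caller's statement of the cohort.

Module co-occurrence across species is summarized as the agreement
fraction — identically 1 minus the normalized Hamming distance — plus the
φ coefficient of the 2×2 presence/absence table; φ is reported as undefined
whenever a margin is zero rather than coerced to 0.

## Interface featurization

- **SASA** is Shrake–Rupley sphere sampling: each atom's solvent-expanded
  sphere (Bondi van der Waals radius + 1.4 Å probe) is sampled at 960
  quasi-uniform (golden-spiral) points, with neighbor lookup via a k-d
  tree. A single isolated atom reproduces 4π(r+p)² exactly up to lattice
  discretization; doubling the point count changes peptide totals by
  < 1 %. Unknown elements get a 1.70 Å default radius with a warning.
- **Insertion** is operationalized as relative side-chain burial:
  (SASA of the side chain in the client chain alone − SASA in complex) /
  maximal side-chain exposure of that residue type in an extended
  Gly-X-Gly tripeptide (Miller et al., 1987, packaged). "Inserted" means
  relative burial ≥ 0.7 — "inserts extensively" read as near-complete
  burial; the threshold is configurable and reports always carry the raw
  number. Glycine has no side chain: its Cα is used as a proxy with its own
  isolated exposure as the reference, flagged in the result.
- **Salt bridges**: Arg {NH1, NH2, NE} or Lys {NZ} within 4.0 Å N–O of
  Asp/Glu carboxylate oxygens (side-chain kind) or backbone carbonyl
  oxygens (backbone-oxygen kind) on the other chain. Histidine is excluded
  by default (protonation unknown in predicted models). One bridge per
  (residue pair, kind) with the minimal distance; symmetric in chain order.
- **β-pairing** uses a geometric criterion, not a DSSP energy: candidate
  rungs need Cα–Cα ≤ 5.5 Å, ladders extend along ±1 diagonals, and each
  ladder must carry backbone N···O hydrogen bonds (≤ 3.5 Å with the
  approach angle at the carbonyl oxygen > 90°) on at least half of its
  rungs. Rungs H-bonded in both directions mark directly-opposite pairs
  and disambiguate the true registry from its offset diagonals; overlapping
  diagonals of one physical ladder are suppressed greedily. Orientation
  comes from the run direction and is cross-checked against the strand
  direction vectors. Minimum ladder length is 2 rungs.
- **Numbering** is author residue numbering everywhere so reports read like
  the structural literature; mmCIF label-space numbering is ignored in
  outputs. Alternate conformations collapse to the highest-occupancy one;
  waters and non-amino-acid hetero compounds are dropped at parse time;
  hydrogens are ignored.
- **Ramachandran classes** (favored/allowed/outlier for general, glycine,
  proline, pre-proline) come from a compact polygonal approximation of
  published torsion-density contours packaged as JSON. The polygons are
  coarse by construction — suitable for flagging clearly forbidden
  conformations (e.g. mirror-α in non-glycine residues), not for
  validation-grade percentile statistics.
- **Confidence**: per-residue model confidence is read from the B-factor
  field (the convention of structure-prediction servers); interface
  residues below 70 are flagged low-confidence in reports.

## Imaging statistics

- Mitochondrial enrichment = mean client intensity over the marker-derived
  mask / mean over (cell − mask). Masks always come from the marker
  channel, never the client channel, to avoid circular thresholding.
- Punctum enrichment = integrated client density in puncta / whole-cell
  integrated density, a fraction in [0, 1], monotone in mask growth.
- Crop CoV uses the population (N-denominator) standard deviation so the
  two-level toy example is exact; crop side = floor(√area / pixel size)
  pixels (minimum 2) for the canonical 8 µm² crop area. Crops are explicit
  caller inputs — no automated exclusion of confounding structures (e.g.
  perinuclear signal); choosing the crop is the analyst's documented act.
- No background subtraction by default; no segmentation, deconvolution or
  illumination correction (cell masks are inputs).

## f-Y2H normalization

normalized = (raw − mean of empty-vector wells) / plate divisor, where the
divisor is the mean of background-subtracted **non-empty** wells (default).
This makes the statistic dimensionless, pins the mean of normalized
interaction wells at exactly 1 per plate, maps empty-vector wells to ~0,
and is invariant to adding a constant to every well. The alternative
divisor including empty-vector wells is available behind a flag, since the
convention varies between labs. A non-positive divisor (no signal above
background) is a failed plate and raises rather than returning numbers.
Replicate summaries use sample SD over clones (n−1) / √n, matching
mean ± SEM with n = 3 clones.

## Synthetic generators: what they emulate, and what they do not

All generators are pure functions of parameters + seed (byte-identical
reruns) and their defaults define the test conditions:

- **Proteomes**: 100 proteins of 150–600 residues, i.i.d. uniform residue
  background (Swiss-Prot-like frequencies optional), 5 planted literals —
  mirroring the five-candidate scale of a real mitochondrial-inventory
  scan. Decoys are rejection-sampled to be literal-free, so planted
  sensitivity/specificity of 1.0 is a meaningful check of the scanner, not
  of the generator. Real proteomes have composition bias, repeats and
  homology that the generator does not emulate; passing these tests shows
  the scanner is exact, not that the motif is informative in real data.
- **MSAs**: rows are the reference with per-column i.i.d. substitutions,
  redrawn uniformly over all 20 letters; no indels by default, no
  phylogenetic correlation. Conservation tests therefore validate the
  statistic's response to column heterogeneity, not tree-aware inference.
- **Complexes**: idealized internal-coordinate geometry (standard bond
  lengths/angles, trans ω, sheet/helix φ/ψ). The β-ladder pose is refined
  by rigid-body least squares to textbook sheet geometry (N···O ≈ 2.9 Å on
  alternating rungs, Cα–Cα ≈ 5.0 Å) — physical targets independent of the
  detector's acceptance thresholds. The insertion fixture encloses a Phe
  side chain in a spherical carbon cage with a backbone opening. Planted
  confidence values are written to the B-factor field. No energy
  minimization and no emulation of prediction-error modes: detectors are
  geometric, so idealized geometry is the appropriate ground truth.
- **Images**: tubular structures are dilated random walks (or disk foci in
  punctate mode) inside an elliptical cell; client intensity is baseline ×
  enrichment on structure with Poisson shot noise (default baseline 200
  counts). No point-spread function, no illumination gradients, no
  camera noise model — recovery tests validate the estimators, not
  robustness to optics.
- **Plates**: raw = empty-vector signal + effect + Gaussian noise, with a
  charge-swap preset (wild-type pair high, charge-reversal single mutants
  reduced, double swap restored) for qualitative end-to-end runs.

## Problem sizes

Default test and acceptance runs use 100-protein proteomes, 100-row ×
200-column MSAs, ten complex fixtures with 20 random isometries each,
256×256-pixel images and 100 plates; SASA uses 960 sphere points (480 in
aggregate reports, 9600 in the brute-force oracle). These sizes make every
ground-truth comparison exact or tightly bounded while keeping the full
suite fast.

## Known limitations

- The motif scanner is exact string/anchor matching by design; no
  probabilistic scoring, homology search or isoform handling (the caller
  chooses the sequence set to scan).
- The burial threshold (0.7) and salt-bridge cutoff (4.0 Å) are
  operationalizations of qualitative structural descriptions; both are
  configurable and reported alongside raw values.
- The β-pairing detector assumes reasonably regular ladders; heavily bulged
  sheets may split into multiple short pairings.
- Conservation treats columns independently; shared phylogeny inflates
  apparent conservation in real alignments.
- The Ramachandran polygons are approximations; boundary-adjacent angles
  may classify differently than under the published density grids.
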