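# Methods

## Scope and model

`xpindex` implements an eigenvalue-based pair of molecular descriptors
(XP1, XP2) for xanthone and its polybrominated congeners, plus the
two-descriptor QSPR regression and leave-one-out validation used to relate
them to thermodynamic properties. The package treats the descriptor
construction, the congener combinatorics and the regression statistics as
first-class, testable components; quantum-chemical geometry optimization is
out of scope and replaced by an idealized-geometry generator.

## Molecular graphs and congener enumeration

Molecules are hydrogen-suppressed graphs: heavy atoms with implicit-H
counts and bonds with orders (orders are kept for file I/O but play no role
in the descriptors). The xanthone scaffold is hard-coded in a fixed atom
order — C1..C8, the four ring-fusion carbons, the ether oxygen, the
carbonyl carbon, the carbonyl oxygen — and bromination appends Br atoms in
ascending position order, so every matrix in the pipeline is deterministic.

The scaffold's C2v mirror maps position *i* to 9 − *i*. A substitution
pattern is canonicalized by taking the lexicographically smaller of itself
and its mirror image; enumerating canonical representatives of all
non-empty subsets of {1..8} yields exactly 135 congeners with size
distribution [4, 16, 28, 38, 28, 16, 4, 1], which matches the Burnside
count under the two-element group {id, σ}.

## Electronegativities

Group electronegativity is the stepwise equal-weight mean over a
substituent tree: a single atom contributes its Pauling value; an anchor
with *k* attached subgroups contributes (χ_anchor + Σ χ_subgroup)/(1 + k),
each subgroup averaged first. The equilibrium electronegativity of atom *i*
averages the atom's own Pauling value with one group term per attached
group, implicit hydrogens counting as single-atom groups:
χ_i = (χ_iA + Σ χ_G)/(1 + l).

Two choices here were genuinely open and are resolved as follows:

* **Rings.** The group-tree recursion is defined for acyclic substituents,
  but xanthone is polycyclic. Group trees are grown breadth-first away from
  the central atom, never revisiting an atom already on the current root
  path (cycles terminate naturally), and truncated at `depth_limit` levels
  (default 3, configurable). Deeper levels are damped by the product of the
  averaging weights, so truncation error shrinks geometrically; on an
  alternating-element chain the increment per extra level is exactly the
  electronegativity gap divided by 2 per level (asserted in the tests).
* **The denominator.** The "1 + l" denominator counts the directly
  attached groups only, with each implicit hydrogen one group. A
  methane-like carbon then gives (2.55 + 4·2.20)/5 = 2.27.

Pauling values: H 2.20, C 2.55, N 3.04, I 2.66 (the values used by the
construction's worked examples), O 3.44 and Br 2.96 from the standard
Pauling scale. All are overridable via `ElementTable` (or `--en-config` on
the CLI). Valence-electron counts are fixed: H 1, C 4, N 5, O 6, Br 7, I 7.

## Distances and the extension/correction matrices

The spatial topological distance std_ij is, by default, the shortest-path
distance through the bond network with each bond weighted by its Euclidean
length ("bond-path"); a through-space Euclidean mode is provided. Bond-path
distances are symmetric, zero-diagonal and satisfy the triangle inequality.

The stated product ³D × E × V is ambiguous, and the two defensible readings
differ qualitatively:

* **diagonal** (default): S_ij = std_ij · χ_j · v_j, i.e. E and V applied
  as column scalings. Q = S·Sᵀ is then a full-rank (generically) Gram
  matrix whose extreme eigenvalues carry independent information.
* **literal**: S = (³D·e)·vᵀ, the vector products read as written. S is
  rank one by construction, so Q has a single nonzero eigenvalue and
  |λ_min| is numerically zero — one of the two indices degenerates.

Both strategies are selectable; the default is the one that can support two
informative indices. In either case Q is symmetric positive semidefinite,
eigenvalues are computed with the symmetric solver (the general solver,
with a guarded imaginary-part check, covers externally supplied
non-symmetric matrices), sorted ascending, and XP1/XP2 are the absolute
values of the extremes. Scaling all distances by c scales every eigenvalue
by c²; permuting atoms leaves the spectrum unchanged.

Default numerical tolerance is 1e−8 (relative), used for the symmetry
check, the imaginary-part guard and the PSD assertions. Ties between
degenerate eigenvalues need no tie-break because only the extremes are
used.

## Idealized geometry

Since optimized 3-D structures for the congeners are not available, a
deterministic planar generator supplies coordinates: the central pyranone
ring is laid out mirror-symmetrically with exact 120° angles at the ether
oxygen and carbonyl carbon, the benzo rings are regular hexagons fused on
the shared edges, and bond lengths are idealized (aromatic C–C 1.39 Å,
aryl C–O 1.36 Å, C=O 1.22 Å, C–Br 1.89 Å, all exact by construction).
Bromines extend along the ray from the benzo-ring center through their
carbon.

This generator emulates the planarity, symmetry and realistic bond lengths
of the real molecules, but not substituent-induced distortions, steric
strain between peri bromines, or any electronic-structure relaxation.
Consequently the XP1/XP2 values computed from it are internally consistent
(they obey every structural invariant: PSD spectra, mirror invariance,
scaling law, a monotone mean-XP2 trend with bromination) but are **not**
expected to reproduce the bundled reference table's index values, and no
test asserts that they do. Passing tests demonstrate the correctness of
the construction, not agreement with quantum-chemically derived
geometries.

## QSPR regression and validation

`XPRegression.fit()` performs OLS (via statsmodels) of a property on the
two descriptors and reports R = √(1 − SSE/SST), R_adj, the standard error
of estimate S = √(SSE/(n − p − 1)), F, and coefficient standard errors
from the unscaled covariance. `loo()` computes leave-one-out residuals by
the hat-matrix identity (exactly equivalent to n refits, asserted against
a brute-force oracle), PRESS, q² = 1 − PRESS/SST and r_cv = √max(0, q²).
r_cv is reported in square-root form because cross-validated correlation
coefficients quoted alongside R in the QSPR literature are on R's scale;
the q² value is exposed as well. PRESS ≥ SSE and q² ≤ R² always hold.

The average relative error is (100/m)·Σ|y_pre − y_cal|/|y_cal| over rows
with |y_cal| ≥ eps (default 1e−6), with the excluded-row count reported —
relative error is undefined where the reference value is zero, which
affects the relative-Gibbs column (every group minimum is exactly 0).

Relative properties (ΔRG°-style) are computed within bromination-count
groups as y − min(y); singleton groups (the parent and the fully
substituted congener) are undefined.

## The bundled reference table and its known defects

The 136-row table ships verbatim (checksummed TSV) with a curation layer
that never edits calculated (Cal.) values:

* two unambiguous decimal-point typos in predicted columns are repaired
  and flagged ("2079" → 20.79 for congener 1,3,4,6; "5305" → 53.05 for
  1,2,3,4,8);
* two anomalous Cal. cells are flagged but kept (congener "2": ΔfG°
  inconsistent with its ΔRG°; congener "2,3,6,7": ΔfG° ≈ 90 kJ·mol⁻¹ below
  its group);
* rows where XP1 or XP2 fails to increase are flagged (`xp*_nonmonotone`);
* the congener list itself is inconsistent: "1,7" and "2,8" are mirror
  images of the same compound yet appear as two rows with different
  values, and the "3,4" (= "5,6") congener is absent. Both duplicate rows
  are flagged; nothing is merged.

Within each bromination group, ΔfG°(Cal.) − ΔRG°(Cal.) is constant to
±0.02 for 132 of the 134 defined rows; the two exceptions are exactly the
flagged anomalies.

**Irreproducible reference statistics.** The correlation coefficients
quoted with the table (R = 0.9971 for S°, 0.9965 for ΔfG°, 0.9982 for
ΔRG°, with r_cv ≈ R) are not reproducible from the table itself: honest
OLS refits of the Cal. columns on the tabulated XP1/XP2 give R = 0.9751,
0.9044 and 0.1844 respectively (r_cv = 0.9726 for S°). The residuals are
structured by bromination count — bromine count alone fits S° with
R = 0.998 — and R is invariant to any affine transformation of the
descriptors, so no rescaling can close the gap. Likewise the quoted model
coefficients do not regenerate the table's predicted columns (the S° model
applied to the parent compound gives 456.05 against a tabulated 416.32),
and the tabulated predicted values correlate with the calculated ones at
0.99999, far beyond what a two-descriptor model with these descriptors can
deliver. The package therefore always reports refitted statistics, keeps
the quoted ones as reference constants (`PRINTED_MODELS`), and the
acceptance tests that assert the quoted values fail by design, recording
the discrepancy. The shipped 17×17 reference correction matrix for
2,8-DBXTH is similarly inconsistent (non-symmetric as printed, with a
spectrum unrelated to the printed eigenvalue list, and negative printed
eigenvalues that no Gram matrix can produce); it is reference data, not a
pipeline output, and `spectrum_discrepancy_report()` quantifies the gap.

## Problem sizes

All computations are desk-scale: the largest molecule has 23 heavy atoms,
descriptor pipelines over all 136 congeners run in seconds, and the
regression/LOO work is on 136-row tables. Property tests run the full
congener set; randomized tests (hypothesis) are derandomized for
reproducibility.

## Known limitations

* Only the xanthone scaffold is generated internally; arbitrary molecules
  enter via XYZ (bond perception from covalent radii) or SDF/MOL (RDKit).
* The ΔfH° model family is supported as an ordinary fit, but no ΔfH° data
  are bundled, so it has no reference comparison.
* Descriptor selection, regularization and external test-set validation
  are out of scope; the model family is fixed at two descriptors.
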