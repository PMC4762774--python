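# xpindex

Quantum-topological **XP1/XP2** molecular descriptors and QSPR modelling for
xanthone (XTH, dibenzo-γ-pyrone, C13H8O2) and its 135 polybrominated
congeners (PBXTHs).

Xanthone carries eight substitutable CH positions; under the scaffold's
mirror symmetry (position *i* ↔ 9 − *i*) the 255 non-empty bromination
subsets collapse to 135 distinct congeners. Because measuring thermodynamic
properties for every congener is impractical, quantitative
structure–property relationship (QSPR) models predict them from descriptors
computed directly from molecular structure. This package is for
cheminformatics practitioners who want those descriptors, the congener
enumeration, and the associated regression/validation machinery in one
place.

## The descriptors and the model

For a molecule with *n* heavy atoms:

1. **³D** — the spatial topological distance matrix: pairwise distances in
   Å measured along the bond network (shortest path with real bond lengths
   as edge weights; through-space Euclidean mode available).
2. **E** — equilibrium electronegativities,
   χ<sub>i</sub> = (χ<sub>iA</sub> + Σ<sub>G</sub> χ<sub>G</sub>)/(1 + l),
   where χ<sub>G</sub> is the stepwise equal-weight group electronegativity
   of each attached group (e.g. χ(=CH₂) = (χ_C + 2χ_H)/3 = 2.3167) and *l*
   counts the attached groups, implicit hydrogens included.
3. **V** — branching degrees, v<sub>i</sub> = z<sub>i</sub> − h<sub>i</sub> + 1
   (valence electrons minus attached hydrogens, plus one).
4. **S** — the extension matrix combining the three
   (default: S<sub>ij</sub> = std<sub>ij</sub> · χ<sub>j</sub> · v<sub>j</sub>).
5. **Q = S Sᵀ** — the correction matrix, and
   **XP1 = |λ<sub>min</sub>(Q)|, XP2 = |λ<sub>max</sub>(Q)|**.

The QSPR model family is a two-descriptor ordinary least-squares fit,
*P* = a₁ + a₂·XP1 + a₃·XP2, validated by leave-one-out cross-validation
(PRESS via the hat-matrix identity e₍₋ᵢ₎ = eᵢ/(1 − hᵢᵢ), with
r<sub>cv</sub> = √(1 − PRESS/SST)).

The package also ships the literature's 136-row reference table (XP1, XP2
and calculated/predicted entropy S°, Gibbs energy of formation ΔfG° and
relative Gibbs energy ΔRG°) with a documented curation layer — see
`docs/methods.md` for the known inconsistencies of that table.

## Worked example

```python
>>> import xpindex as xp
>>> mol = xp.idealized_geometry(xp.SubstitutionPattern((2, 8)))
>>> res = xp.compute_indices(mol)        # diagonal strategy, bond-path distances
>>> res.name, round(res.xp2, 1)
('2,8-DBXTH', 1460960.8)
>>> table = xp.load_table1()
>>> print(xp.XPRegression.from_dataframe(table, "s_cal").fit().summary())
QSPR model: s_cal ~ xp1 + xp2
  n = 136
  intercept   406.952 +/- 12.3208
  xp1         1.78992 +/- 0.440632
  xp2         1.21914 +/- 0.276648
  R = 0.975094   R_adj = 0.974715   r_cv = 0.972604
  S = 12.8683   F = 1285.35   PRESS = 24195.4
```

The summary reads: over the 136 bundled congeners, the entropy model
explains the data with multiple correlation coefficient R = 0.975 and
cross-validates at r_cv = 0.973; the coefficients say each unit of XP1
(XP2) adds 1.79 (1.22) J·mol⁻¹·K⁻¹ of entropy on top of a 406.95 baseline.
These are honest refits of the bundled table; they differ from the
correlation coefficients quoted alongside that table in the literature,
which the bundled data do not support (`docs/methods.md` has the full
analysis, and `xpindex report` prints the side-by-side comparison).

The same is available from the shell:

```sh
xpindex index --pattern 2,8      # XP1/XP2 for one congener
xpindex index --all-pbxth        # all 136
xpindex enumerate                # the 135 symmetry-distinct patterns
xpindex fit --bundled s          # the summary shown above
xpindex loo --bundled s
xpindex report                   # all three properties + discrepancy notes
```

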