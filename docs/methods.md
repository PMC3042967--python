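# Methods

## Problem setting

A conformer generator produces, for one molecule, an ordered ensemble of
3-D geometries ("conformers"), often with energies. Two questions drive
this package: *how well can such an ensemble reproduce an experimentally
observed ligand geometry*, and *how many conformers must be kept* to
preserve that ability. Accuracy is measured per ensemble as the minimum
heavy-atom RMSD and the maximum Shape-Tanimoto (ST) between the reference
conformation and any single conformer. Hydrogens are excluded from every
descriptor, RMSD and shape computation.

## Molecular graphs and perception

Molecules are connected graphs of (element, formal charge) atoms and bonds
of order 1, 2, 3 or aromatic, read and written as V2000 SDF (multi-fragment
records are rejected: descriptors and superposition are single-molecule
concepts; consecutive SDF records with identical name and connectivity are
grouped into one ensemble, and a configurable data field — default
`ENERGY`, kcal/mol — populates conformer energies).

Perception rules are deliberately minimal and deterministic:

- **Rings**: minimum cycle basis (SSSR) via networkx.
- **Aromaticity**: a single SSSR ring is aromatic iff every ring atom
  carries a double/aromatic bond or is a lone-pair heteroatom (N, O, S, P)
  and the Hückel π count is 4n+2. Fused-system aromaticity beyond single
  rings is out of scope; adequate for the toy/test chemistry handled here.
- **sp³**: all incident bonds single and the atom not aromatic.
- **Rotatable bond**: single, acyclic, not aromatic-aromatic, both
  endpoints with ≥ 2 heavy neighbours. Amide C–N bonds are excluded by
  default (`include_amide_rotors=True` restores them); generators differ on
  this point and the flag records the ambiguity. Terminal bonds are never
  rotors.

The flexibility descriptor is `N_ER = N_R + N_NARA/5` (each qualifying ring
atom counted once even when shared between rings); `N_ER` is binned half-up
for reports. The fragment sampling count is
`round(10 + (n₃ − n₄)·startfact)` where `n₃`/`n₄` count atoms with exactly
3/4 ring bonds; spiro-heavy inputs can drive it negative, and since a
sample count must be positive the value is clamped to ≥ 1 with a warning
(the formula's behaviour below 1 is otherwise undefined).

The ligand-set filter keeps 2 ≤ N_NHA ≤ 50 and N_R ≤ 15, returning
machine-readable rejection reasons (`too_small`, `too_large`,
`too_flexible`).

## Symmetry-aware RMSD

Graph automorphisms (element-, charge- and bond-preserving permutations of
the heavy-atom graph) are enumerated with VF2, sorted lexicographically for
determinism, and capped at 10,000 with a warning flag on pathological
symmetric graphs. For each automorphism the conformer is permuted and
rigidly superposed onto the reference by closed-form SVD (Kabsch); the
reported RMSD is the minimum. Reflections are never allowed (det = +1):
mirror images are distinct molecules. Ties between automorphisms are broken
by permutation order. Degenerate point sets (< 3 non-collinear points)
return one of the minimisers. Identical coordinates reproduce RMSD 0 to
~1e-8 Å (SVD round-off), so exact-zero assertions use a 1e-6 Å tolerance.

## Gaussian shape model

Each heavy atom is an isotropic Gaussian `p·exp(−α|r−c|²)` with amplitude
p = 2.7 and exponent `α = π(3p/(4πr³))^(2/3)`, which makes an isolated
atom's density integral equal its hard-sphere volume (4/3)πr³. Radii are a
fixed Bondi-style table (C 1.70, N 1.55, O 1.52, S/P 1.80, F 1.47, Cl 1.75,
Br 1.85, I 1.98, default 1.70 Å); unknown elements warn and use the
default. Overlap volumes are first-order: the analytic Gaussian product
integral summed over atom pairs, with self-overlap including the diagonal
terms; higher-order intersection corrections are neglected (standard
soft-Gaussian practice). `ST = V_AB/(V_AA+V_BB−V_AB)`.

The overlay search maximising V_AB is a deterministic multi-start: identity
orientation plus the principal-axes alignment and its three 180° flips,
each refined by Nelder–Mead on (rotation vector, translation) with
tolerance 1e-6 and ≤ 500 iterations; the best start value is kept even if
refinement fails, so ST(a, a) = 1 exactly from the identity start.
Absolute ST values from this model are an approximation to
commercial shape-overlay codes whose parameters are unpublished; the
package's guarantees are therefore structural (range, symmetry,
optimisation dominance, agreement of analytic overlap with grid
integration), not reproduction of any published ST table.

## Ensemble evaluation pipeline

The pipeline order is fixed: generation → conformer cap → energy window.
The cap keeps the first `max_confs` conformers (default 100,000) in
generation order and flags the ensemble; the flag propagates into
evaluation results so capped ("100-k") cases can be excluded from
aggregates. The energy window keeps conformers with
`E ≤ E_min + ewindow` (inclusive — the window is a maximum energy *range*,
so a conformer exactly at the boundary survives; the global minimum always
survives). Window keep-sets are nested in the window size by construction.
Minimum RMSD and maximum ST are optimised independently and may come from
different conformers; both ordinals are reported. Binned aggregation
groups by `N_NHA` or half-up-rounded `N_ER`, omits empty bins, and always
reports per-bin counts (sparse bins at high size/flexibility carry little
information).

## Accuracy regression and sampling threshold

`RMSD_pred = b₀ + b_NHA·N_NHA + b_ER·N_ER`, ordinary least squares.
Published presets: the single model (0.029, 0.0099, 0.040; residual SD
0.19; R² 0.65) and a partitioned pair — (0.046, 0.0063, 0.050; SD 0.17)
for N_ER ≤ 10 and N_NHA ≤ 35, (−0.101, 0.0155, 0.035; SD 0.29) otherwise.
The partition predicate uses the complement ("N_ER > 10 **or**
N_NHA > 35") so the two groups tile the descriptor plane. Presets are
immutable; refits are new objects.

Refitting uses statsmodels OLS; `residual_sd = √(SS_res/(n−3))` (three
fitted parameters; the convention is a package choice) and requires ≥ 10
points and a full-rank design per partition. The sampling threshold is the
prediction plus one residual SD. On Gaussian residuals its one-sided
coverage converges to Φ(1) ≈ 0.8413; on right-skewed residuals (which real
accuracy data exhibits) coverage exceeds Φ(1), which is how a ~91%
empirical coverage arises from a +1 SD margin. The package documents this
and asserts the Gaussian value on Gaussian synthetic data only.

The estimator is scikit-learn compatible (`fit`/`predict`,
`get_params`/`set_params`, trailing-underscore fitted attributes), so it
composes with sklearn pipelines and model selection.

## Leader sampling

Conformers are scanned in energy-ascending order by default (input order
available for energy-free ensembles; energy ties break by input order), and
one is kept iff its symmetry-aware RMSD to every kept conformer exceeds the
threshold (strict `>`). Consequences asserted as invariants: kept pairs are
separated by more than the threshold; every discard is within the
threshold of its recorded blocker (the coverage map); the keep count is
non-increasing in the threshold. A threshold of exactly 0 disables
duplicate detection and keeps everything — the semantics of a zero
duplicate-RMSD setting in generator practice — rather than discarding
exact duplicates, which a literal strict-inequality scan would do.

## Synthetic data: what it emulates, and what it does not

`build_template` provides heavy-atom toys on ideal geometry (C–C 1.54 Å,
aromatic 1.39 Å, ring–chain 1.50 Å, tetrahedral angles; cyclohexane as a
solved ideal chair; decalin as two chairs related by inversion through the
fusion-bond midpoint, which reproduces trans-decalin geometry exactly with
all bonds 1.54 Å). `generate_torsion_ensemble` enumerates the Cartesian
product of per-rotor offsets `k·360°/S` from the anti geometry
(S = 3 gives anti/gauche±, the classic rotamer states; the count is exactly
`min(S^rotors, max_confs)` with the truncation flag on overflow, mirroring
the generator-side cap at desk scale), adds seeded Gaussian coordinate
noise (default 0.02 Å) to break exact degeneracies, and assigns a
pseudo-energy: 0 per anti state, 0.9 kcal/mol per gauche, 2.5 kcal/mol for
other (eclipsed-like) offsets, plus a steric term 10·(2.5 − d)² kcal/mol
for heavy-atom pairs ≥ 3 bonds apart closer than 2.5 Å. These numbers are
surrogates chosen once for plausibility (gauche–anti splits near the
n-butane value; eclipsed barriers a few kcal/mol); they are **not** a force
field, and their only contract is a deterministic, chemically sensible
total order for energy-window and sampling tests. No minimisation is
performed and ring puckering is not enumerated. Consequently, passing
tests demonstrate the correctness of the evaluation/reduction machinery on
controlled inputs — not the accuracy of any real generator or force field
on real ligands.

Regression datasets sample `N_NHA` uniformly over the integers 2–50 and
`N_ER` uniformly over 0–16 (flexibility above 16 effective rotors is rare
once the 15-rotor filter applies), then apply the stated linear model plus
noise and clip at zero. Gaussian noise targets the published residual
scale; the lognormal option produces right-skewed zero-mean residuals
(shape σ = 1, standardised, scaled) for coverage-skew experiments. The
zero-clipping censors ~2% of records at the default settings (small
molecules have means near 0.05 Å against a 0.19 Å noise SD), which biases
an OLS refit slightly — intercept up, slopes and residual-SD estimate down
by ~1–2% — a known property of censored responses that the tests document
rather than hide; the +1 SD coverage is insensitive to it.

## Numerical and scale choices

Automorphism cap 10,000; overlay tolerance 1e-6 with ≤ 500 Nelder–Mead
iterations per start; RMSD stored at full precision with rounding only at
the reporting layer (`--round 2` matches conventional table formatting).
Test problem sizes are chosen for completeness per minute: exhaustive
permutation oracles run on ≤ 8 heavy atoms, grid-integration oracles on
≤ 5-atom shapes at 0.1 Å spacing, sampler contracts on ensembles of ≤ 27
conformers, regression recovery at the full 25,972-record scale, and the
conformer-cap semantics on a 9-rotor chain (4⁹ = 262,144 attempted states)
with a reduced cap of 1,000 exercising the identical truncation logic.

## Known limitations

- Aromaticity and hybridisation rules are single-ring and valence-light;
  exotic chemistry (fused aromatics, charged delocalised systems,
  organometallics) is out of scope.
- Stereochemistry, tautomers and protonation states are not perceived.
- The Gaussian shape model's absolute ST values are parameterisation-
  dependent; compare STs only within one model.
- The rotatable-bond rule is one of several community conventions; rotor
  counts for amide- or conjugation-rich molecules depend on the flag
  settings.
- OLS on censored (zero-clipped) synthetic responses is slightly biased;
  see above.
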