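# Methods

This note records the models, numerical conventions and design choices
behind `saflex`, and what the synthetic study conditions do and do not
establish.

## Backbone model and masking

A chain is stored as per-residue N/CA/C/O coordinates, one-letter
sequence, Cα B-factor and a validity mask. Residues missing any backbone
atom, and both residues flanking a Cα–Cα gap ≥ 4.5 Å (trans peptide
≈ 3.8 Å), are masked rather than dropped; masks propagate through every
per-residue quantity so partial structures stay usable at full length.
PDB input goes through Biopython (first chain unless one is named;
alternate locations resolve to highest occupancy; one ensemble member per
MODEL). φ(i) is the C(i−1)–N(i)–CA(i)–C(i) torsion and ψ(i) the
N(i)–CA(i)–C(i)–N(i+1) torsion, in degrees wrapped to (−180, 180].
Superposition RMSD uses the SVD Kabsch rotation with the residual
evaluated on explicitly rotated coordinates (numerically exact near
zero, unlike the E₀ − 2Σσ shortcut).

## Alphabet assignment

**Protein Blocks (16 letters).** The bundled table holds the reference
dihedral prototypes, 8 angles per block in the order ψ(i−2), φ(i−1),
ψ(i−1), φ(i), ψ(i), φ(i+1), ψ(i+1), φ(i+2). Assignment minimizes the
angular RMSD `rmsda = sqrt(mean(min(|Δθ|, 360−|Δθ|)²))`; ties break to
the lowest prototype index; two residues at each terminus (and any window
touching a masked residue) are masked.

**Secondary structure (3/8 classes).** A simplified Kabsch–Sander
assigner: the amide H is placed 1.01 Å from N along the bisector opposite
the C(i−1)→N and CA→N directions; an H-bond exists when the electrostatic
energy 27.888·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol is below
−0.5. Two consecutive i→i+3/4/5 turns give G/H/I helices, bridge patterns
(parallel or antiparallel, partners ≥ 3 apart) give E in ladders and B
isolated, turns T, Cα bends (>70°) S, else C; priority
H > E > G > I > B > T > S > C; the 3-class collapse is {H,G,I}→H,
{E,B}→E, rest→C. Exact DSSP edge cases (termini, π-helix preference)
vary between DSSP versions, so precomputed DSSP files can be ingested as
an override. Note that an isolated extended strand has no bridge partner
and therefore reads as coil — relevant to the synthetic trend studies
below.

**Fragment alphabet (default 28 letters).** Centered 7-residue Cα
fragments are clustered k-means-style under superposed RMSD: assignments
go to the nearest prototype, and each prototype is rebuilt as the
Procrustes mean of its members, iterated to a fixed point (inner
tolerance 1e-10; empty clusters reseed with the worst-fit fragment).
Training is deterministic given the seed. This is a trainable stand-in in
the same geometry space (Cartesian Cα fragments, 28 prototypes × 7
residues) as published fragment alphabets whose prototype coordinates are
not redistributable; it is documented as "DW-style", not as a
reproduction.

## Entropy, thresholding, evaluation

Letter frequencies are computed per position across the ensemble with
masked symbols excluded from the denominator (support-aware). Entropy is
natural-log and never normalized — the ceiling ln m grows with alphabet
size by design, so thresholds are alphabet-specific. The flexibility
threshold T defaults to the pooled (residue-weighted) mean entropy of the
reference dataset; classification is strictly greater-than, so boundary
values are rigid. Flexible is the positive class throughout. The ROC
sweep groups tied scores into single steps and uses the trapezoidal
normalized area, which equals the Mann–Whitney pairwise statistic; the
test suite pins that equivalence to 1e-12. RMSD-uniform decoy selection
bins members by Cα RMSD to the native (default edges 3/4/5/6 Å) and
draws at most a per-bin cap without replacement, seeded — a cap, not
exact equalization, since real decoy sets fill bins unevenly.

## Dual-layer predictor

Layer 1 is L2-regularized multinomial logistic regression on a
15-residue window of PSSM features (log-odds squashed by the logistic
function to (0,1)); layer 2 is the same classifier family on a 9-residue
window of layer-1 distributions. Layer 2 trains on *cross-fitted* layer-1
outputs (grouped K-fold by protein, 5 folds) so it never sees
optimistically overfit inputs. Any sklearn probabilistic classifier can
replace the default via `base_estimator`; window sizes are configurable.
Letters absent from training receive probability zero at prediction. The
Q-score is the fraction of unmasked residues whose argmax letter matches
the assignment, with argmax ties broken to the lowest letter index.

## Synthetic study conditions

The generator perturbs *local conformation classes* rather than adding
Cartesian noise, so the generating per-position letter distribution — and
hence the true entropy and flexible/rigid labels — is exact. Four classes
are used: helix (−57, −47), strand (−119, 113), PPII-like coil
(−75, 145) and extended coil (−140, 150); a flexible position flips to
its alternative class (helix→coil, strand→extended coil, coil↔coil) with
its per-position probability. Backbones are rebuilt from the drawn
dihedrals with standard internal coordinates (N–CA 1.46 Å, CA–C 1.52 Å,
C–N 1.33 Å, ω = 180°), which reproduce helix i→i+4 O–N distances of
≈ 3.1 Å. B-factors are an affine function of true entropy
(B = 20·H + 10 Å²) plus Gaussian noise. Sequence profiles plant a fixed
20-dimensional pattern per letter, scaled by a signal strength, on unit
Gaussian noise.

Reference conditions, chosen once: 60-residue proteins mixing a helix,
two strands and coil linkers; flip probability 0.4 at every coil position
plus one helix-interior and one strand-interior position; 40 members for
trend studies and 1000 where estimator convergence is the question; the
predictor corpus is 20 proteins × 100 residues of random 4–12-residue
segments at signal strength 0.25, picked so the first layer is imperfect
and context can help. Held-out predictor scores are measured by grouped
4-fold cross-validation over the corpus, which is less variable than a
single split.

These conditions deliberately plant the mechanism the method claims:
coil↔coil and strand↔coil changes are invisible to a 3-class alphabet
(both read C) but resolvable by the 28-letter fragment alphabet, so the
finer alphabet detects more flexible residues. Passing trend tests
therefore show the pipeline *can* express that mechanism and that the
implementation is consistent end to end; they do not show that real
decoy ensembles have this structure, that real B-factors are affine in
entropy, or that PSSMs carry as clean a signal as the planted profiles.
Physically realistic decoys (energy-guided sampling) and real morph
trajectories are out of scope.

## Numerical conventions and degenerate inputs

0·ln 0 := 0 throughout; distribution rows must sum to 1 within 1e-6.
Correlation is undefined (raised, not returned) when either vector has
zero variance; ROC requires both classes; ratio metrics return NaN for a
zero denominator rather than failing the whole evaluation. All
randomness flows from explicit integer seeds (numpy `default_rng`);
training, selection and simulation are bit-reproducible given the seed.
Structures shorter than an assignment window yield all-mask encodings
rather than errors.

## Known limitations

The secondary-structure assigner approximates DSSP (no chain-break
bonus handling inside ladders, no π-helix preference toggle); PB cannot
distinguish the two synthetic coil classes (both fall nearest the
extended block), which is an honest property of a dihedral-basin
alphabet, not a defect of the assignment. The fragment-alphabet k-means
optimum depends on initialization; only seeded determinism, not global
optimality, is guaranteed. B-factor comparability across different real
crystal structures (resolution, refinement protocol) is outside the
model.
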