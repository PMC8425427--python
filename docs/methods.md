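# Methods

This note documents the models and procedures implemented in `c2contact`,
the parameters that matter, the synthetic data used to exercise them, and
the design choices made where the design was genuinely open. No empirical
claim here goes beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## Problem setting

A C2 homodimer is two identical chains related by a 180° rotation. Residues
i (chain A) and j (chain B) are *in contact* when any two heavy atoms of the
two residues are within 8 Å (inclusive; 6 Å is exposed as an alternative
cutoff). An ideal C2 contact map is diagonally symmetric, which motivates
the symmetrization steps below.

## Structure features

* **Parsing.** PDB/mmCIF via biotite; hydrogens and waters dropped; altloc
  duplicates resolved to the highest-occupancy copy. Gaps in author
  numbering become explicit unobserved placeholder residues so internal
  indices stay contiguous 0..L−1 and masks line up with the full chain.
* **Distance/contact maps.** Minimal heavy-atom distances, vectorized by
  block-minimum reduction over an atom-atom distance matrix; masks are False
  where either residue is unobserved.
* **SASA.** Shrake–Rupley point sampling (biotite backend) with
  Chothia-style element radii (C 1.76, N 1.65, O 1.40, S 1.85; fallback
  1.8 Å), probe 1.4 Å, 960 points per atom (isolated-sphere error < 2 %).
  A slice-based Lee–Richards area is **not** implemented; the second
  hydrophobicity channel duplicates the Shrake–Rupley one. The two-channel
  layout is kept so models trained here remain shape-compatible with inputs
  where both areas are available. SASA channels are fed in absolute Å²
  without rescaling.
* **Interface area.** (SASA(A) + SASA(B) − SASA(AB)) / 2.
* **Secondary structure.** Either ingested from a DSSP output file (the
  fidelity path) or assigned internally: Kabsch–Sander electrostatic
  hydrogen-bond energy (0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN),
  bond at E < −0.5 kcal/mol, amide H 1 Å from N along the preceding C=O),
  then helix/strand/turn/bend rules with priorities H > E/B > G > I > T > S.
  Exact parity with the DSSP program is not promised; an ideal α-helix
  (φ = −57°, ψ = −47°) is assigned ≥ 80 % H in the interior, which the test
  suite checks.
* **Dataset predicates.** The per-record curation filter (C2 label, 2
  chains, resolution < 3.0 Å strict, 50 ≤ L ≤ 500, chain identity > 0.99,
  interface > 1000 Å²) is a pure function returning the exact list of
  violated rules.

## Sequence features

* **Identity** = identical non-gap residues / full column count (a gapped
  column counts as mismatch). The alternative non-gap denominator is
  available as a parameter. **Meff** = Σ 1/mᵢ with mᵢ = #rows with identity
  > 0.7 to row i (a row always counts itself, so weights stay in (0, 1]).
* **PSSM**: redundancy-weighted column frequencies with λ/20 pseudocounts
  (λ = 1), gaps excluded from normalization; optional log-odds encoding
  against fixed Robinson–Robinson background frequencies. The profile
  construction behind the original method is unspecified; weighted
  frequencies with pseudocounts is the conventional choice.

## Coupling engine

Mean-field DCA over the 21-letter alphabet (20 amino acids + gap):
reweighted single and pair frequencies, pseudocount fraction λ = 0.5
(Morcos-style: λ/q on-site, λ/q² for pairs), covariance over q−1 = 20
states per column (gap is the gauge reference), matrix inversion, zero-sum
gauge per 20×20 block, Frobenius norm as the pair score. Sequence
reweighting reuses the 0.7 identity cutoff of Meff. The **raw** channel is
this un-corrected norm — a deliberate stand-in for a pseudo-likelihood
raw score, not the classical mutual-information-style DI integral. The
**APC** channel subtracts mean_i·mean_j/mean with means over the full
matrix; this convention makes the correction exactly annihilate rank-one
product structure (the defining property of APC), after which the matrix is
re-symmetrized and its diagonal zeroed. External CCMpred-style text
matrices can be ingested in place of the internal engine.

## Docking map

A C2 pose is parameterized by a two-fold axis **a** (the second copy is the
180° rotation about **a**) and a translation perpendicular to **a**. Axes
are the prefix of a fixed low-discrepancy hemisphere sequence (van der
Corput height, golden-angle azimuth); the count scales as 2π/θ² for an
angular interval θ, so 6° gives 573 axes and halving the interval roughly
quadruples the count. Prefix nesting makes the docking map monotone in the
rotation count by construction. How the original docking engine enumerates
"960 evenly distributed rotations" from a 6° interval is not derivable, so
the rotation count here is a parameter, not a promise.

Each monomer is rasterized on a cubic grid (spacing 1.2 Å): cells within
1.8 Å of an atom centre are *core*, a 1.5 Å shell around them *surface*.
For each rotation, all lattice translations are scored by FFT correlation

    score(t) = corr(surface_A, surface_B)(t) − 15 · corr(core_A, core_B)(t)

(ties broken lexicographically by signed (z, y, x) offset, so runs are
reproducible), the top 100 translations are kept, each translation is
projected onto the plane perpendicular to the axis (making the pose exactly
two-fold), and the pose's OR-symmetrized contact map is added to the union.
The union over all rotations × translations is the docking-map channel. At
the default sampling this union is intentionally permissive — on compact
synthetic fixtures it covers essentially all residue pairs — and acts as a
prior mask rather than a prediction.

## Network

Pre-activation residual blocks (norm → ELU → conv, twice, plus shortcut;
1×1 projection on channel mismatch). 1D stack: 6 blocks, kernel 17, filters
35/40/45/50/55/60, then 1×1 compression to 2 channels. Outer concatenation:
pairwise planes [v_i ; v_j] (4 planes), each averaged with its transpose.
2D stack: 36 blocks, 3×3, nine groups of 32/32/48/64/64/64/48/32/32
filters, then norm → ELU → 1×1 conv → sigmoid. The full preset has
1 985 797 parameters; a tiny preset (2 blocks 1D / 4 blocks 2D, 16 filters)
ships for tests and desk-scale runs.

Implementation choices, all hand-written in numpy with explicit backward
passes (verified against central finite differences):

* **Normalization.** With batch size 1 and variable L, batch statistics
  equal per-sample statistics; normalization is per-channel over the
  spatial axes of the single sample, identically in training and inference.
  This keeps inference deterministic and length-independent and sidesteps
  the question of frozen running statistics for variable-length inputs.
* **Outer concatenation.** The broadcast form [v_i ; v_j]; after the
  average-with-transpose step the i- and j-planes coincide pairwise, which
  is accepted redundancy (the citation chain for the original form does not
  pin it down).
* **Output symmetrization** (average with transpose) is applied at
  inference; inputs and labels are symmetrized for training.
* **Distance channel** clipped at 50 Å and divided by 50 (normalization
  unspecified upstream; configurable).
* **Loss reduction**: mean over unmasked pairs, so the loss scale is
  length-independent (sum vs mean is unspecified upstream).
* **Initialization**: seeded fan-in-scaled normal.
* Channel order is versioned in checkpoint metadata.

Focal loss: FL(p_t) = −α_t(1−p_t)^γ log p_t with α = 0.25, γ = 1.5; γ = 0
reduces exactly to α-weighted cross-entropy. Masked pairs contribute
nothing to value or gradient. Training: Adam (lr 10⁻³, β 0.9/0.999), L2
10⁻⁴ added to convolution-kernel gradients, plateau schedule (factor 0.2,
patience 2, floor 10⁻⁶, "improvement" = any decrease of the best validation
loss), random contiguous 400-residue crop applied jointly to the 1D axis
and both 2D axes.

## Baselines, metrics, pose filter

DCA baselines keep unique pairs with intra-monomer distance > 12 Å and rank
them by the raw or APC channel. Precision@n divides by min(n, list length);
top-L/K uses n = max(1, ⌊L/K⌋) so short chains stay defined; accuracy rate
is the fraction of targets with ≥ 1 hit in the top n; accuracy order is the
1-based rank of the first hit over L(L+1)/2 unique unordered pairs, in per
mille (the ordered/unordered convention is a documented choice). The pose
filter is a stable partition: poses whose contact map contains the top
predicted contact are promoted ahead of the rest with relative order
preserved and nothing deleted, so a top-5 report always has 5 poses.

## Synthetic data

`fixtures` generates fully self-contained targets:

* **Dimers.** Chain A is a bounded random walk at x ≥ 7.5 Å from the
  two-fold (z) axis; each planted pair (i, j) is moved to x = 3.5 Å,
  y = ±6.5 Å so that after the exact 180° rotation the pair sits at 7 Å
  between chains while every non-planted inter-chain pair exceeds 10 Å (a
  margin that keeps tests away from the 8 Å boundary). The pair members are
  13 Å apart *within* the chain, so true inter-chain pairs survive the
  12 Å intra-monomer filter of the DCA baseline — the regime that filter
  presumes. Residues carry a CA centre plus three dummy carbon atoms within
  0.25 Å; no realistic side chains, no backbone N/C/O (the secondary
  structure of fixture chains is therefore coil).
* **MSAs.** Query plus M−1 rows drawn i.i.d. per column from background
  frequencies, except planted column pairs, which with probability equal to
  the coupling strength are drawn jointly from a fixed set of five
  compatible amino-acid couples. Defaults: L = 40, M = 120–300, 3 planted
  pairs, strength 0.9 — depths where mean-field DCA recovers planted pairs
  reliably, as the acceptance checks measure.
* **Mini-datasets.** 20 targets, split 4:1 by a fixed hash of the target
  index; docking maps for training use coarse sampling (30°, top-30), the
  desk-scale setting.

What passing desk-scale tests shows — and what it does not: the pipeline is
internally consistent, the network can extract planted covariation and
geometric priors, and every statistic matches an independent oracle. It
does **not** show PDB-scale accuracy; real MSAs have phylogenetic
structure, gaps and intra-chain couplings that the generator does not
emulate, and real interfaces are packed surfaces rather than planted point
contacts.

## Numerical notes and limitations

* Float64 throughout; FFT scan equals direct-space correlation to ~1e-13.
* Probabilities are clipped to [1e-12, 1−1e-12] before the loss as a
  numerical guard; the loss itself rejects values outside (0, 1).
* The FFT translation unwrap assumes comparable grid extents for the two
  copies (always true for a homodimer).
* Mean-field DCA inverts an (L·20)² covariance matrix — fine for L ≤ a few
  hundred, not for very long chains.
* The simplified shape-complementarity score has no electrostatics or
  desolvation and no local refinement; Cn>2 symmetries are out of scope.
* Training at the published scale (thousands of targets, GPU, ~20 epochs)
  is out of scope; the architecture, loss and schedule are implemented
  faithfully and exercised at desk scale.
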