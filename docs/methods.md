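# Methods

## Problem and scope

`lsfgdl` models iridium-catalysed late-stage C–H borylation campaigns
recorded as SURF tables (simple user-friendly reaction format: flat,
tab-separated, one row per reaction).  Three prediction targets are
supported:

* **binary reaction outcome** — does the substrate give a detectable mono-
  or di-borylated product under the given conditions (success = conversion
  ≥ 1%; stricter thresholds of > 5/10/20% are available),
* **reaction yield** — the continuous conversion in [0, 100]%,
* **regioselectivity** — which non-quaternary carbon (carbon bearing at
  least one hydrogen) carries the pinacol-boronate group in the product,
  cast as per-atom binary classification.

## Molecular graphs

Molecules enter as SMILES and become explicit-hydrogen graphs in canonical
atom order (heavy atoms in canonical SMILES order, hydrogens appended);
every atom index in the package — graph nodes, regioselectivity labels,
ground-truth sites — refers to this ordering.

Atom features are a fixed 20-column one-hot scheme: 12 atom types
(H, C, N, O, F, P, S, Cl, Br, I, Si, Se), 2 ring flags, 2 aromaticity
flags, 4 hybridization types (sp3, sp2, sp, s; hydrogen occupies the s
slot).  Elements or hybridizations outside the scheme (e.g. boron in a
substrate, sp3d phosphorus) raise hard errors rather than falling into a
silent bucket, because the encoding has no spare slots.  The four graph
variants are:

| variant | edges | extra features |
|---------|-------|----------------|
| 2D | covalent bonds | — |
| 3D | all atom pairs within 4 Å (inclusive) of a conformer | Fourier distance features |
| 2DQM | covalent bonds | partial-charge column |
| 3DQM | 4 Å radius | distance features + charge column |

Interatomic distances are encoded as sine/cosine Fourier features with
linearly spaced frequencies `w_f = f·π/4 Å⁻¹`, `f = 1..16` by default (the
count is a config knob).  Since coordinates enter only through pairwise
distances, all 3D-derived features — and therefore all network outputs —
are invariant under rigid motions (E(3): rotations, translations,
reflections).  Covalent bonds are not added separately to 3D graphs; at a
4 Å cutoff every bonded pair is already connected.

Conformers come from RDKit distance-geometry embedding (ETKDGv3) followed
by UFF minimization, ten per molecule, bit-reproducible for a given seed.
Embedding failures retry a bounded number of times with perturbed seeds.

Partial charges are supplied by a pluggable provider registry.  Two
providers ship with the package: **gasteiger** (RDKit Gasteiger charges,
the default) and **electronegativity** (a simple Pauling-electronegativity
bond-increment scheme).  Higher-level (DFT-surrogate) providers can be
registered at run time; the provider id is recorded in run manifests and
checkpoints because charges are computed on the fly.  Provider output is
validated against charge conservation (sum equals the molecular formal
charge within 0.05 e).

## Network architectures

All graph models share an E(3)-invariant message-passing trunk,

    h_i^{l+1} = φ( h_i^l , Σ_{j∈N(i)} ψ(h_i^l, h_j^l [, r_ij]) ),

with three layers; `r_ij` (distance features) participates only for 3D
variants.  The per-layer atomic features `[h^1, h^2, h^3]` are
concatenated and mapped by an MLP to final atomic features `H`.

* **GNN** pools `H` by summation, transforms the pooled vector, and
  concatenates it with an embedded one-hot condition vector before the
  output MLP.
* **GTNN** replaces sum pooling with graph-multiset-transformer pooling:
  each of four attention heads owns a learned query vector `q` and two
  lightweight message-passing blocks producing keys and values from
  `(H, E)`; the head output is `Attn(Q, K, V) = QKᵀV`, heads are
  concatenated and projected by `W^o`.  Attention is the raw `QKᵀV`
  product by default; a scaled-softmax switch covers the common
  graph-multiset-transformer convention.  The key/value blocks do not
  share weights with the trunk.
* **aGNN** applies no pooling; `H` maps through a final MLP with a sigmoid
  to one reactivity score per atom.  Consumers read only the candidate
  (non-quaternary carbon) entries.
* **ECFP4NN** is the fingerprint baseline: a 256-bit ECFP4 (Morgan radius
  2) fingerprint MLP plus two condition-embedding MLPs (ligand, solvent)
  feeding a shared head.

MLP shape, where not otherwise fixed, is two hidden SiLU layers of width
320 (`mlp_hidden`, recorded in `ModelConfig`).  At the production dims —
internal width 128, embedding width 64, 256-wide first post-pooling layer,
three layers, four heads — this yields ≈1.9 M trainable parameters for the
GNN/aGNN and ≈2.7 M for the GTNN, auditable via `count_parameters`.

Yield is trained on the [0, 1] fraction scale (outputs are reported in %)
to keep the squared-error loss well scaled; the binary head passes through
a sigmoid.  Both reaction tasks train with mean squared error by default;
binary cross-entropy is available behind the `loss="bce"` flag.

The networks, a minimal reverse-mode automatic-differentiation engine and
the Adam optimizer are implemented in NumPy inside the package
(`autodiff.py`, `nn.py`, `networks.py`).  Correctness is established by
finite-difference gradient checks and by plain-loop re-implementations of
the message-passing update used as oracles in the test suite.

## Conditions

Categorical reaction conditions are one-hot encoded from a vocabulary
fitted on the dataset, lexicographically sorted for reproducibility.  The
experimental (plate) regime encodes ligand and solvent (6 × 4 = 24 joint
conditions); the literature regime additionally encodes reagent and
catalyst (12 × 9 × 2 × 4 = 864).  Numeric parameters (T = 80 °C, t = 16 h,
c = 0.2 M, scale) are fixed by the plate design and are not encoded; this
is an explicit extension point.  Unseen categories are load-time errors —
there is no "other" bucket — and vocabularies are serialized beside model
checkpoints so mismatches fail fast.

## Training and evaluation

Defaults (production scale): Adam, learning rate 1e-4, batch size 16, MSE
loss, learning-rate decay ×0.5 after every 100 epochs, early stopping on
the exponentially smoothed (factor 0.9) validation MAE within 1,000
epochs.  The smoothing is applied to the validation-error series, not to
the weights; both readings of "exponential smoothing factor" are
defensible and this one keeps the checkpoint criterion transparent
(arg-min of the smoothed series, verified in tests by replaying the
history).  For 3D variants one conformer is selected at random per
molecule per training step; per-epoch validation uses the first conformer
for speed, and test-time predictions average the full ten-conformer
ensemble, reported as mean ± population standard deviation (2D variants
have zero std by construction).

Splits: random k-fold, or substrate-based splits in which all reactions of
a held-out substrate move to the test side together (no substrate ever
straddles the split — asserted per fold).  Metrics: Pearson r and MAE (%)
for yield; confusion counts, PPV, TPR, balanced accuracy, accuracy and
F-score for classification.  The F-score is the harmonic mean of PPV and
TPR; a true ROC-AUC is reported separately from balanced accuracy since
the two are often conflated in this literature.  Degenerate cases (empty
positive class, zero-variance predictions) report missing values rather
than numbers.

## Synthetic data generator

The generator emulates a 24-well borylation HTE campaign so that every
pipeline stage is testable without external downloads:

* substrates are substituted (hetero)aromatics built from five cores
  (benzene, pyridine, thiophene, furan, naphthalene) and ten substituents
  including bulky (tert-butyl, isopropyl, trifluoromethyl) and flexible
  (alkoxy) groups, 1–3 substituents per molecule;
* the plate fixes the catalyst ([Ir(COD)OMe]₂) and boron source (B2Pin2)
  and crosses 6 ligands × 4 solvents per substrate (T = 80 °C, t = 16 h,
  c = 0.2 M); a literature-like regime samples 12 ligands, 9 solvents,
  2 reagents and 4 catalysts;
* ground-truth regioselectivity follows the mechanistic prior that
  borylation is dominated by sterics with a weaker electronic component:
  each candidate carbon is scored `−w_s · (heavy atoms within 4 Å on a
  reference conformer) + w_e · (ring-position parity proxy)` with default
  weights 1.0 and 0.3; the arg-max site (lowest index within its symmetry
  orbit; ties to the lowest index) is reactive and the emitted product
  carries Bpin there.  The resulting label imbalance across batches is
  ≈1:5–6 non-reactive candidates per reactive atom;
* yields are `clip(base(best site score) · ligand_effect · solvent_effect
  + N(0, 5%), 0, 100)` with multiplicative condition effects drawn once
  per dataset — simple and invertible for recovery tests.  The 5% noise
  default mirrors the reproducibility of miniaturized HTE conversions.

Because the steric score counts atoms that can be 4–6 bonds away yet
spatially close (e.g. the methyls of an ortho tert-butyl group), it is
directly visible to a 4 Å radius graph but only partially recoverable by a
three-layer 2D network — this is the designed learnable advantage of the
3D variants, and the package's substitute for the full-scale finding that
3D models generalize better to unseen substrates.

What the generator does **not** emulate: real reagent chemistry, directing
group effects beyond the parity proxy, inter-laboratory yield
heterogeneity, or sp3-rich drug topologies.  Passing the synthetic checks
therefore demonstrates that the pipeline can extract steric/electronic
structure–condition–outcome relationships at realistic scale and noise; it
does not certify accuracy on real screening data.

## Desk-scale verification runs

The acceptance checks that involve training use reduced dimensions
(hidden 32, embedding 16, MLP width 32, 8 Fourier frequencies), learning
rate 1e-3 and 30–40 epochs on 34 substrates × 24 conditions ≈ 800
reactions — sizes chosen so a complete verification runs on a laptop-class
CPU in minutes while leaving the architecture untouched.  Under these
conditions the GTNN3D recovers synthetic yields to a test MAE within
3 percentage points of the 5% noise floor, and the 3D binary-outcome model
beats its 2D twin by ≥ 5 balanced-accuracy points on a substrate-based
split of the steric task.

One caveat the tests make explicit only at their fixed seeds: the
3D-over-2D margin at desk scale is variable across dataset realizations.
Condition effects transfer perfectly across substrate splits (every
condition appears in training), and molecule-level steric aggregates are
partially inferable from topology (substituent counts proxy crowding), so
at some seeds the 2D model closes most of the gap.  The margin reported by
the acceptance script at an arbitrary seed should be read as one draw from
that distribution, not a guaranteed bound; establishing the advantage
robustly requires production-scale training.

## Numerical and design choices

* Float64 throughout; determinism favoured over speed.  One integer seed
  drives substrate generation, noise, conformers, initialization, batching
  and conformer selection.
* Dedup tie-break in the dataset filters keeps the highest-yield
  duplicate (deterministic, favours the informative datum).  The "occurs
  at least four times" condition filter counts on the post-dedup set and
  iterates to a fixed point, which makes the operation idempotent —
  a one-pass count is not, because dropping rows can push other
  categories below the threshold.
* Di-borylated products label both attachment carbons reactive.
* Reactive sites are canonicalized to the lowest atom index within the
  molecular automorphism orbit, so symmetry-equivalent atoms cannot cause
  spurious label mismatches.
* Empty neighbourhoods aggregate to a zero message vector; empty graphs
  are rejected at batch construction.
* Missing numeric SURF cells parse to missing (never zero); missing
  yields propagate to missing outcomes rather than failures.

## Known limitations

* The GTNN query is a learned per-head seed vector; formulations where
  queries are computed per atom would make pooling quadratic in atoms and
  are not implemented.
* Training runs on CPU via the in-package NumPy engine; wall-clock scales
  linearly with edges × hidden width and production-scale dims on
  thousands of reactions take hours, matching the method's original
  compute envelope only in architecture, not speed.
* Product-to-substrate mapping is constitutional only; stereochemistry is
  ignored.
* Catalyst and ligand structures are never graphed — conditions are
  strictly categorical.
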