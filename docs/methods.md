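# Methods

## Shape preprocessing

Digitized curves are resampled to a fixed number of equally spaced
semi-landmarks by linear interpolation along cumulative arc length; the
first and last points always coincide with the curve endpoints. The
semi-landmarks are then treated as ordinary fixed landmarks — no
bending-energy or Procrustes-distance sliding is applied. Equal arc-length
spacing is the only regularization, which matches workflows in which
semi-landmark files are converted to plain landmark files before analysis.
The package assumes curves are digitized in a consistent direction across
specimens and exposes a per-curve `reverse` flag for datasets where they
are not.

Superimposition is full Procrustes: every configuration is centered,
scaled to unit centroid size, and rotated (proper rotations only — no
reflection, since specimens are assumed digitized in consistent
orientation) to an iteratively updated consensus, until the consensus moves
by less than 1e−10 (at most 100 iterations; the `converged` flag records
the outcome). Because the Procrustes consensus is defined only up to
rotation, the final sample is rotated once more into a canonical frame
(principal axes of the consensus, signs fixed by the largest-magnitude
coordinate). This makes repeated alignment of already-aligned data an exact
fixed point and output coordinates reproducible across runs and machines.

Before any linear multivariate analysis the aligned rows are projected
orthogonally onto the tangent space at the consensus. All downstream
statistics (PCA, CVA, group means, ancestral reconstruction, Euclidean DR)
operate on these tangent coordinates.

## Ordination and discrimination

PCA is a singular value decomposition of the centered tangent coordinates
with a deterministic sign convention (the largest-magnitude loading of each
axis is positive), so scores are reproducible run to run.

Procrustes shape data are rank-deficient: 2k coordinates carry at most
2k − 4 informative dimensions, and with group structure the pooled
within-group covariance W has only n − g degrees of freedom. CVA is
therefore computed in a PCA-reduced subspace. The automatic choice keeps
min(n − g − 1, rank) components: one degree of freedom fewer than the
maximum so that W remains invertible when a specimen is withheld during
leave-one-out classification. If W is still numerically singular (this
happens when a between-group difference spans a direction with no
within-group spread), the error instructs the user to reduce further via
`prior_reduction`. Mahalanobis distances between group means use W in the
reduced space; Euclidean distances between group means are taken in the
full tangent space.

Confusion matrices assign each specimen to the nearest group mean under the
W metric. Because it is genuinely ambiguous whether published
total-correctness figures of this kind are cross-validated, both
resubstitution and leave-one-out rates are always computed and labeled;
leave-one-out refits the group means and W without the focal specimen while
keeping the PCA reduction fixed.

## Ancestral reconstruction

Continuous: internal-node shapes minimize Σ_edges ‖x_parent − x_child‖²/Δt
(weighted squared-change parsimony), solved exactly coordinate-by-coordinate
from the stationarity conditions as one linear system. With branch-length
weighting this is the maximum-likelihood point estimate under Brownian
motion; `weighting="equal"` gives the unweighted variant. Edges with
non-positive elapsed time receive Δt = 1e−8 Ma. Reconstruction operates on
terminal-group mean shapes in tangent space, not on per-specimen data.

Discrete (feeding types): the default is Sankoff parsimony with uniform
costs (equivalently Fitch). For every node the set of states participating
in at least one globally optimal assignment is computed by a down/up
dynamic program and reported as a set — ties are never silently broken. An
equal-rates Mk model is available as an alternative: the single rate is
fitted by bounded 1-D likelihood maximization (uniform root prior) and
per-node marginal posteriors come from the standard two-pass algorithm.

## DR and SGR

For each branch, both distance variants are always computed: Euclidean in
tangent coordinates, and Mahalanobis by projecting the two node shapes with
the CVA reduction fitted on terminal specimens and measuring under the
terminal pooled within-group covariance. Ancestral nodes have one
reconstructed shape each, so no within-node covariance of their own is
estimable; projecting them into the terminal CVA space is the convention
adopted here. Elapsed time is always the difference of mean node ages;
95% CI bounds on ages, where present, are carried into the per-edge output
(`dt_ci`) for reporting but are never propagated into DR.

SGR is computed per root-to-tip path, edges ordered from the root; shared
basal edges are repeated in every path that crosses them rather than
averaged, so each lineage's series is self-contained. A zero previous DR
makes the following SGR a missing value (never ±∞), with a logged warning.
Useful identities, enforced by tests: rescaling all ages by c multiplies
every DR by 1/c and leaves SGR unchanged; rescaling all distances leaves
SGR unchanged.

Step-chart tables give each edge's DR as a constant over [child age, parent
age] per lineage. Trend curves through (age, SGR) points are either
polynomial least squares (default, degree 2) or LOESS with a configurable
span; the choice and parameters are echoed in the run log since the
functional form of such published best-fit lines is generally unstated.

Window summaries report max, min and spread (max − min) of SGR values whose
edge-midpoint age falls inside each configured window, with characters
ranked by spread.

## Synthetic data

The generator's defaults describe a modest, realistic study: 8 terminal
groups on a 150-Ma balanced tree, 20 specimens per group, Brownian variance
1e−4 per coordinate per Ma in unit-centroid-size shape space, digitization
noise SD 0.005 (about the displacement a careless click produces on a
unit-size outline), and an equal-rates feeding-type character at 0.005
transitions per Ma. The root template is a regular polygon. Multi-character
fixtures use outline/landmark counts of 50/25/50/16
(mandible/pronotum/elytron/hindwing), the configuration sizes typical of
beetle datasets of this kind.

Simulation operates directly in shape coordinates: no rotation, translation
or scale nuisance is added by default, so alignment of a noise-free fixture
is nearly the identity and recovery statements are about the estimator, not
about GPA. An optional jitter mode applies random similarity transforms per
specimen to exercise the superimposition. What the generator does *not*
emulate: allometry, correlated landmark noise, missing landmarks,
digitization direction errors, and non-Brownian (OU, early-burst) dynamics —
so passing tests demonstrate correctness of the estimators under the BM
model, not robustness to these real-data complications.

Randomness flows from one integer seed through spawned substreams (tree,
each character, discrete trait), so sub-simulations are independently
reproducible and fixtures are byte-identical across reruns.

## Validation design

Recovery checks that compare true and estimated per-edge displacements use
random dated trees (lineage pairs joined at sorted uniform ages) rather
than balanced equal-depth trees: with equal branch lengths under a constant
rate, true displacement norms concentrate around a single value at high
landmark counts, and a correlation against them measures only noise.
Varying branch lengths spread the truth and make the correlation
informative. Problem sizes in tests and in `scripts/acceptance.py` (16-tip
trees, 25–100 landmarks, 200 seeded replicates) were chosen so the whole
validation suite runs in seconds while keeping Monte-Carlo bands narrow.

Known limitations: 2-D landmarks only; no sliding semi-landmarks; no
missing-landmark estimation; CVA requires ≥ 2 specimens per group (fixtures
without within-group variation fall back to Euclidean-only DR, with a
warning); the Mk optimizer fits a single global rate.
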