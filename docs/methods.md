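# Methods

## Network reconstruction

Reactions are read as unordered substrate and product *sets*: stoichiometry,
direction and reversibility carry no information for substrate–product
connectivity, so duplicate mentions collapse and every reaction is treated as
an undirected relation. Screening proceeds in three steps: (i) any reaction
containing a macromolecule or an R-group (unspecified-residue) compound is
deleted whole — such reactions describe polymer chemistry, not small-molecule
interconversion; (ii) currency metabolites (ubiquitous cofactors and carriers
such as ATP, NAD, water, metal ions) are removed from the substrate and
product sets of the remaining reactions, because keeping them would connect
most of the metabolome through biochemically meaningless shortcuts;
(iii) reactions left with an empty side are dropped. Currency species that
genuinely act as substrate or product in a particular reaction can be kept
via a per-reaction override list (reaction id → currency ids to keep); the
default is global removal. The override mechanism is this package's explicit
convention for the standard "except when they participate directly" caveat
of currency filtering — the literature states the caveat but not an
operational rule.

The graph expands each filtered reaction into the complete bipartite set of
(substrate, product) pairs, drops self-pairs, and merges parallel edges: the
network is a simple undirected graph and degree is the number of distinct
incident edges. Metabolites that survive filtering but acquire no edge (for
example, species appearing only in identity reactions) are not counted as
nodes; whether such isolates should count is genuinely ambiguous, and
excluding them keeps `sum(degree) = 2·|edges|` exact over the node set.

## Power-law fitting

Degree histograms are fit as `N = a·D^(−b)` by ordinary least squares of
log10(count) on log10(degree) over degrees with nonzero counts, reporting
`a = 10^intercept`, `b = −slope` and the r² of the log-log regression. This
is the classic presentation for metabolic-network degree data and is what
the package's scale-free checks quantify. It is *not* a rigorous power-law
estimator: no xmin search, no CCDF, no likelihood. The fit needs at least
three distinct degrees; fewer is an error, not a silent NaN.

## Descriptor panel

All descriptors are computed from the 2D structure with RDKit primitives, so
the panel is deterministic — no conformer generation, no 3D embedding.

* **logP** — Wildman–Crippen atomic contributions. Commercial ClogP/ALogP
  engines cannot be reproduced openly; a single Crippen-type logP stands in
  wherever a calculated partition coefficient is needed. Ionization-aware
  LogD is out of scope (it needs a pKa engine); logP is the proxy. Every
  downstream analysis depends on polarity *ordering*, not absolute values.
* **CPSA family** — hydrogens are made explicit, Gasteiger partial charges
  assigned, and per-atom Labute accessible surface areas used as the surface
  term: `PPSA3 = Σ_{q>0} q·SA`, `PNSA3 = Σ_{q<0} q·SA`,
  `FPSA3 = PPSA3/TMSA`, `FNSA3 = PNSA3/TMSA`,
  `RPCG = max(q>0)/Σ(q>0)`. A molecule with no positively charged atom has
  RPCG recorded as missing (the defining ratio is 0/0) and is excluded
  pairwise from statistics. Using topological (2D) surface areas rather than
  conformer-derived ones trades absolute CPSA accuracy for exact
  reproducibility; the polarity ordering the analyses rely on is preserved.
* **logS** — the ESOL linear model
  `logS = 0.16 − 0.63·logP − 0.0062·MW + 0.066·RB − 0.74·AP`
  (RB = rotatable bonds, AP = aromatic proportion), a transparent stand-in
  for proprietary solubility models.
* **Counts** — HBD/HBA from RDKit definitions; nitrogen count; amide count
  via the SMARTS `[NX3][CX3](=[OX1])`; six-membered-ring count from the
  smallest-set-of-smallest-rings; "hydrophobe" count = atoms matching
  `[$([#6;!$([#6]~[!#6;!#1])]),$([F,Cl,Br,I])]` (carbon bonded only to
  carbon/hydrogen, or halogen). The continuous Lipinski score is
  `Σ max(0, x/bound − 1)` over (MW, 500), (logP, 5), (HBD, 5), (HBA, 10) —
  zero for rule-of-five-compliant molecules. "Hydrophobe" and the Lipinski
  score have no canonical published formula; these SMARTS/penalty
  definitions are this package's documented conventions.

## Topology–chemistry statistics

Group summaries report n, mean and SE = sd/√n per degree interval
(SE = 0 by convention for singleton groups); missing property values are
excluded pairwise. Two grouping conventions ship as constants (degree
1 / 2–6 / >6 and 1–3 / 4–15 / >15); arbitrary interval schemes are a config
item because published analyses rarely print their bin edges. The trend
across ordered groups is the Pearson correlation of group means against the
ordinal group rank 1..k — rank, not interval midpoint, because unbounded top
groups (">6") have no midpoint. Concentration–degree analyses reuse the same
machinery with concentration deciles as groups. Rank tests are
scipy-backed: tie-corrected Kruskal–Wallis with the chi-square
approximation, and Mann–Whitney reported as `U = min(U_a, U_b)` with the
two-sided continuity-corrected normal approximation — the conventions of
mainstream statistics packages. All p-values are two-sided approximations;
exact permutation tests are deliberately not the default (the approximations
are what the classic analyses used), and the unit tests check the statistics
against exhaustive pair counting instead.

Early/late classification: the early-candidate set is the union of
metabolites attached to oldest-age-class enzymes minus aerobic metabolites;
early members are candidates present in the network, late members the rest.
Age classes are ordinals with 1 = oldest (traceable to eubacterial genomes);
the oldest class defaults to the minimum observed.

## Concentration models

Concentrations span orders of magnitude, so models target −Log10 C (molar).

**Stepwise MLR.** Forward selection enters the candidate whose partial-F
probability is smallest, if at most `p_enter`; after each entry a backward
sweep removes included variables whose partial-F probability exceeds
`p_remove` (the just-entered variable is protected within its own sweep, and
`p_remove ≥ p_enter` is enforced, preventing entry/removal cycles).
Defaults are `p_enter = 0.05`, `p_remove = 0.10`, the conventional stepwise
defaults of mainstream statistical software. Zero-variance candidates are
dropped with a warning; candidates that make a step's design singular are
skipped with a warning. A numerically saturated fit (residual sum of squares
below 1e-12 of the total sum of squares) stops selection — without this
floor, noiseless data would admit arbitrary spurious entries on
floating-point dust.

For *selection studies* — does the procedure recover a known generating
model among decoys? — the per-step default is the wrong yardstick: screening
k null candidates at α = 0.05 enters at least one decoy with probability
≈ 1 − 0.95^k (over half, at k = 16). The package's recovery protocol
therefore enters at the Bonferroni-adjusted probability 0.05/k (and removes
at 0.10/k), the standard family-wise control for a candidate pool; with it,
exact recovery of a four-descriptor generating model among 16 decoys
(n = 200, noise sd 0.5) succeeds in ≈95% of seeds, and the refitted
coefficients fall within 3 standard errors essentially always. The module
default remains 0.05/0.10 because that is what users of classic stepwise
expect interactively.

**ε-SVR.** `ConcentrationSVR` wraps an RBF-kernel ε-SVR
(`k(u,v) = exp(−γ‖u−v‖²)`) behind a feature z-standardisation fitted on the
training data only; an RBF over raw mixed-unit features (degree counts next
to CPSA fractions) is dominated by the widest-ranged feature, so scaling is
on by default. Parameter defaults γ = 0.01, ε = 0.22, C = 7.9 are the
reference grid-search optimum for −LogC prediction from degree plus ten
chemical descriptors. The quadratic program is solved by libsvm via
scikit-learn; an independent SLSQP solve of the same dual problem serves as
a cross-check in the test suite, never as the implementation.

**Scoring.** LOOCV refits a clone of the estimator n times; the report
carries the squared Pearson correlation between held-out predictions and
observations, and the plain mean of squared held-out residuals ("total mean
squared error" is read as exactly that). Squared Pearson r — not R² about
the identity line — is the default because that is what "squared correlation
coefficient" means; constant predictions are reported as 0 with a warning
rather than NaN. The through-origin calibration slope `Σŷy/Σy²` is reported
alongside. Grid search is exhaustive LOOCV over (γ, ε, C); ties break on
lower MSE, then smaller C (a preference for flatter models — the choice is a
declared convention, ties being common on small n). Default grids bracket
the reference optimum: γ ∈ 10^{−3..1}, ε ∈ 0.01–0.49 step 0.03,
C ∈ 0.1–9.7 step 0.3. Descriptor importance deletes one feature at a time,
re-tunes by grid search, and sorts ascending by LOOCV squared correlation:
the feature whose deletion hurts most ranks first.

The reference polarity equation
`−LogC = 6.105 + 0.431·ClogP + 15.595·FNSA3 + 16.727·FPSA3 − 5.333·RPCG`
ships as a constant evaluator only. Refitting it would require the original
measured E. coli concentrations and commercial descriptor values; neither is
bundled, and the package makes no claim to reproduce the printed
coefficients or the reference LOOCV metrics (r² = 0.5906, MSE = 0.5316) from
its own open descriptors.

## Growth simulator

One metabolite starts at concentration Ci = 10⁶ (arbitrary units). Step k
adds a metabolite with concentration `max(1, Ci − k·d + U)`,
U ~ Uniform(−f/2, +f/2), with d = 1000 and f = 1500 by default — the
fluctuation distribution is not canonical, and the symmetric bounded
mean-preserving uniform is this package's convention, giving
`E[C_k] = Ci − k·d` exactly. Each step then adds m edges (default 5) whose
endpoints are drawn with probability proportional to current concentration,
without replacement within an edge; the first edge of a step has the new
node forced as one endpoint so the graph stays connected (whether *every*
new edge must touch the newcomer is underdetermined — forcing only one
honours "higher concentration, higher reaction probability" for the rest
while guaranteeing a connected network). Self- and duplicate edges are
resampled up to 100 times, then skipped, so tiny graphs may gain fewer than
m edges per step. The floor of 1 keeps sampling weights positive near
termination. The run stops after the step in which a newly assigned
concentration reaches Cf = 10 or below (that node and the step's edges are
kept); existing concentrations never change during a run, so only newcomers
can trigger termination. Each run consumes a single seeded generator stream
and is bit-reproducible.

Consequences at the defaults: the concentration range spans exactly
log10(Ci/Cf) = 5 decades; with f = 0 termination happens at step 1000
(1001 nodes exactly); with f = 1500 the mean node count over seeds is
≈1000–1002; and the degree histograms fit `N = a·D^(−b)` with b ≈ 1.3 and
r² ≈ 0.84 (r² ≥ 0.8 in ≥18 of 20 seeds) — degree-preferential attachment
emerging from concentration alone.

## Synthetic data

The generators emulate the statistical *structure* the analyses assume, not
biochemical reality. Reaction sets embed known numbers of contaminated,
currency-only and clean reactions and emit the surviving reaction ids and
the substrate–product edge set by construction, so filter and graph code can
be checked against an independent enumeration. Molecules come from a small
fragment grammar (2–8-carbon backbones, 0–4 hydroxyl/amine/carboxyl/
phosphate decorations) whose polar-group count orders every polarity
descriptor by construction. Concentrations follow
`−LogC = β₀ + Σβx + ε`, ε ~ N(0, σ²) — log-normal concentrations, matching
the orders-of-magnitude spread of real metabolomes — with the reference
polarity equation as the default β, so recovery studies are a direct
analogue of the real fit; decoy descriptors are independent standard
normals. The synthetic descriptor table draws each descriptor from a
realistic marginal range but leaves them independent, unlike real panels
where logP and the CPSA fractions are strongly correlated: passing the
recovery study therefore shows the selection machinery works under the
assumed generating model, not that four descriptors are identifiable in a
collinear real panel. Each generator uses a salted seed stream, so equal
seeds across generators never couple their draws.

## Problem sizes and numerical choices

The test and acceptance workloads use 20 replicate simulator runs at the
default scale (~1000 nodes each), 50-seed recovery studies at n = 200 with
20 candidate descriptors, LOOCV cross-checks at n ≤ 30, and reduced SVR
grids for importance tests — sizes at which every check is exact or has wide
Monte-Carlo margins. Other numerical conventions: libsvm tolerance defaults
to 1e-3 and is an estimator parameter (the dual-QP cross-check tightens it);
power-law fits refuse fewer than three distinct degrees; LOOCV keeps the
caller's container type so it is bit-identical to a manual refit loop.

## Known limitations

* Descriptor values are open equivalents, not reproductions of Cerius2 /
  Sybyl / Pipeline Pilot output; only orderings and signs are comparable.
* No ionization modelling: logP is used where LogD would be more faithful
  for charged metabolites at physiological pH.
* The power-law fit is descriptive, not an MLE with model comparison.
* The simulator's nodes carry no structures; it tests the sufficiency of
  concentration-governed attachment for scale-free topology, nothing more.
* Stepwise selection inherits all classic caveats (post-selection inference,
  instability under collinearity); the Bonferroni protocol controls false
  entries, not selection bias in the retained coefficients.
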