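# Methods

This note documents the models, the numerical choices, what the synthetic
data do and do not emulate, and the known limitations. Everything stated
here is computed by the test suite or the acceptance script; nothing is an
external empirical claim.

## Penalized-likelihood dating

Branch lengths of the input phylogram (substitutions/site) are converted to
real-valued expected substitution counts n_k = length × sites (default
sites = 4000, the order of magnitude of a concatenated three-region plastid
matrix). Counts are deliberately not rounded: they are ML expectations and
rounding discards signal. The objective is the Poisson log-likelihood
Σ n_k log(r_k t_k) − r_k t_k (the log n_k! constant is dropped) minus
S × [Σ (r_k − r_parent(k))² + Var(rates of the root's children)]; the
root's children have no parent branch, so their penalty is the variance
term.

**Rate units matter.** Rates are carried as whole-alignment substitutions
per Myr, so the Poisson mean is r·t directly. In these units the penalty
and the likelihood are commensurable and the classic S ≈ 10 default is in
its binding regime. Had rates been per-site (~10⁻³), the squared-difference
penalty would be ~10⁶-fold weaker than the Poisson term and small S would
leave node ages essentially unidentified — at S → 0 the objective is
exactly flat in the ages, because each branch's free rate can absorb any
duration. S remains data-set specific; `cross_validate_smoothing` scores a
log grid by leave-one-terminal-out prediction, Σ (n − r̂_adj t̂)²/pred,
where the adjacent rate is the parent branch's (or the mean of the other
root children for a terminal hanging off the root).

Parameterization: each non-root internal age is h × parent age with
h ∈ (0,1) optimized on the logit scale (order constraints hold by
construction; tips are at 0), rates on the log scale; the crown age is
fixed by the single calibration (default 70.1 Ma). The optimizer is
L-BFGS-B on a numba-compiled objective with numerical gradients
(ftol 1e-12); the fit is deterministic given the data. Any outgroup is
pruned before fitting (`prune_taxa` / `--prune`).

Verified behavior: crown age exact; output ultrametric; zero penalty for
equal rates; saturated per-branch rates at S = 0; on strictly clock-like
data with sites = 50 000 and a tree whose internal nodes are ≥ 5 Ma, every
node age is recovered within 5% (younger nodes sit below the Poisson noise
floor of any finite alignment — at 0.5 Ma and plausible rates a branch
carries a handful of substitutions, so relative age error there is
irreducible); the fitted-rate coefficient of variation is nonincreasing in
S across 0.01–1000.

## DEC

Ranges are bitmasks over an ordered codebook (default 8 areas). The state
space holds all non-empty ranges up to `max_range_size` (default 3) plus
the absorbing empty range; an observed tip range larger than the cap is
appended together with its oversized loss-chain subsets, so the data stay
representable and the oversized state can decay by single losses — the
node constraint applies to internal nodes only (cladogenesis, root prior
and reported marginals are restricted to in-cap, non-empty states).

The generator has gains R → R∪{j} at rate d·|R| (uniform dispersal
multipliers; no adjacency or epoch structure) and losses R → R∖{j} at rate
e. exp(Qt) is computed by eigendecomposition with a validated
reconstruction (≤ 1e-10) and an `expm` fallback for ill-conditioned cases;
rows of every tested propagator sum to 1 within 1e-10 for t up to 100 Myr.
Cladogenesis enumerates the distinct ordered daughter pairs (vicariance
{a} vs R∖{a}; peripheral isolate {a} vs R; duplication for single-area
ranges) with uniform weights — equal weighting of isolate vs vicariance
outcomes is an assumption the original implementations do not document;
the weights are per-outcome uniform here and live in one function.

The likelihood is pruning with per-node rescaling; the root prior is flat
over permitted node states. Marginals condition the node state immediately
before the split (the range entering the cladogenetic event) and are
computed by a standard outside pass, not by n² re-pruning. Both the
likelihood and the marginals are checked against an exhaustive
enumeration oracle on all ≤ 4-tip shapes at 1e-8.

ML estimation is L-BFGS-B on log(d, e) from (0.01, 0.01), with a large
finite penalty (not ∞) for impossible regions so finite-difference
gradients stay clean, and optional random multistart.

**Known limitation (by design of the model, not of the code):** the
local-extinction rate e is chronically underestimated, typically to its
lower bound, even on data simulated from DEC itself. Profiling the
likelihood in e at the true d on simulated data shows it decreasing from
e = 0: cladogenetic inheritance can shed areas at zero rate cost, so
anagenetic loss is rarely the preferred explanation, and conditioning the
simulation on lineage survival (observed tips are extant) removes most
single-area loss signal. d is recovered within ~±10% at the simulated
settings; e estimates should not be interpreted quantitatively.

## Event scenarios

`best_range_per_node` takes the marginal argmax (ties broken toward the
canonically smallest state — fewest areas, then bit order — and flagged).
Each branch is compared against the parent's best range passed through the
cladogenetic outcome that exactly matches the two daughters' best ranges
when one exists (`cladogenesis_aware`, default on; the raw node-vs-node
diff inflates counts because DEC changes ranges at nodes too). The
difference decomposes into one dispersal per gained area and one
extinction per lost area — the minimal edit path under the single-step
generator; with m events on a branch, event k is dated at the k/(m+1)
quantile of the branch interval, extinctions oldest. Multi-area dispersal
sources are attributed fractionally (1/|source| per source area) so
directed-pair totals equal event totals exactly. Events on the root's own
branches can be excluded (the deepest optimization is rarely
interpretable), mirroring standard practice.

On simulated histories the inferred dispersal total correlates with the
truth (Spearman ≥ 0.7 across 50 replicates) and is an undercount in most
replicates — best-state reconstruction hides reversals — so absolute event
counts are lower bounds, while slice-to-slice contrasts are the robust
signal.

## GeoSSE

The three-state D/E ODE system is integrated per branch by an adaptive
Cash–Karp RK45 (rtol 1e-8, atol 1e-12) compiled with numba; D components
are renormalized per branch with an accumulated log-scaler; E is clipped
to [0,1] and D negatives beyond −1e-10 abort with an error. Tips start at
D = f (observed state) and E = 1 − f; a sister-E mismatch > 1e-5 aborts
(it indicates a non-ultrametric tree). Root options: observed-weights
(default, D-proportional), flat, or a given root state; no survival
conditioning. With all tips in A and dA = dB = sAB = 0 the likelihood
under a given-A root equals the closed-form constant-rate birth–death
likelihood to < 1e-6 for any (sB, xB) — note the D-weighted root does
*not* satisfy this identity when xB > 0, because a widespread ancestor can
extirpate its B part and still leave all-A tips.

ML fits are box-constrained L-BFGS-B on log-rates (bounds 1e-6–20/Myr,
finite-difference step 1e-6 — below that, ODE integration noise corrupts
the gradient). The reduced (sAB = 0) model is fit first and warm-starts
the full fit; since sAB = 0 lies in the full model's closed parameter
space, the reduced optimum is itself a valid full-model candidate, which
caps optimizer slop at LRT statistic exactly 0. The LRT uses χ²₁ despite
the boundary null, which makes it conservative (simulated type-I error
~2–5% at nominal 5%).

MCMC is an adaptive Metropolis random walk on log-rates, thinning 1,
proposal scale tuned toward ~25–40% acceptance during burn-in only (so the
post-burn-in chain is a fixed-kernel Markov chain), priors independent
exponentials with mean max(2 × ML, 0.01), chain started at the ML fit.
Prior-only runs recover the prior mean within Monte-Carlo error; chains
are bit-reproducible under a seed.

`per_area_scan` codes each area in turn as the focal region and skips
areas that cannot inform the focal/remainder contrast: unoccupied areas,
areas containing every tip, and areas harbouring only endemics (no
widespread tips). Sampling fractions default to 1 and accept a per-area
table (sampled/total per state).

## Synthetic data

All simulators are exact Gillespie-style forward simulations, deterministic
under a seed, with per-module substreams of one `SeedSequence` so adding a
simulator never perturbs existing outputs.

* Birth–death trees: crown-conditioned (both root children must survive;
  rejection capped at 1000); stopping either at a crown age or at a tip
  count — in the latter case the simulation extends by one exponential
  holding time past the nth tip so terminal branches have positive length,
  and the paper-shaped recipe rescales the tree so the crown is exactly
  70.1 Ma.
* DEC histories: anagenetic events drawn from the generator restricted to
  the state space; cladogenetic outcomes drawn with the model's weights;
  branches hitting the empty range are redrawn (observed lineages are
  extant), which is precisely the survival conditioning that biases ê
  downward in refitting.
* GeoSSE: state-dependent birth/death/transition with AB splitting into
  (A, AB), (B, AB) or — at rate sAB — (A, B), and AB contracting rather
  than dying.
* Rate variation: branch rates follow a parent × lognormal(0, σ)
  multiplicative walk; branch lengths are Poisson(r t sites)/sites.

The bundled recipe reproduces the empirical study's *shape*: exactly 256
tips, crown 70.1 Ma, 8 areas, ≥ 60% single-area tips, and one source area
(`C`) holding the majority of tip occurrences. Under the model's uniform
dispersal the occupancy skew is only robust at low dispersal, so the
recipe's defaults are d = 5 × 10⁻⁴, e = 0.01, root {C} (frozen after a
17-seed robustness scan); the price is sparser event lists than a real
radiation of this size would show. What passing tests on these data do
show: every algorithmic contract (oracle equality, conservation,
determinism, parameter-recovery behavior). What they do not show:
robustness to model violations real data carry — non-uniform dispersal,
area-dependent diversification feeding back on ranges, phylogenetic error,
and alignment-level noise.

## Pipeline

`run_pipeline` executes simulate/load → date → DEC → events → GeoSSE,
writing every table with a content hash into `manifest.json`. The manifest
contains no timestamps, so a rerun with the same config and seed is
bit-identical (asserted by the test suite). Species names are matched
between tree and range table after whitespace/underscore normalization;
any unmatched name on either side is a hard error listing all offenders
(silent drops would corrupt sampling fractions). The default focal area
for the single-area pipeline stage is the source area `C`, which the
recipe always populates; sparse focal areas should be analysed through
`per_area_scan`, which applies the suitability rules.
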