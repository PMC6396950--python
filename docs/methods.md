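# Methods

## Model class

A network is a collection of single-copy gene expression blocks.  Block
$i$ owns a promoter with binding set $B_i$: $\{0,1\}$ for constitutive or
one-site promoters, $\{00,01,10,11\}$ for two independent sites, with
configurations removable for competitive binding (no $11$) or ordered
binding (one singly-bound configuration absent, as in the PU.1/GATA.1
circuit).  The first digit of a configuration code is the first binding
site.  Global promoter states are indexed mixed-radix, first gene most
significant.

Reactions per block: reversible TF binding/unbinding for every allowed
single-site transition (TF-driven binding consumes one copy of the
regulating gene's output species; constitutive switching consumes
nothing), production $D^i_j \to D^i_j + X_i$ at $k_{ij}$, decay at
$k_{-i} > 0$, and for cooperativity $n_i > 1$ the $n$-merization
$n X_i \rightleftharpoons X_{ic}$ at $\beta_i, \beta_{-i}$.  Optional
reversible transport couplings $X \rightleftharpoons Y$ at rate $\Omega$
model protein exchange between cells.  Bound TF copies are represented by
the promoter configuration species, not as free molecules.

**Timescales.**  Promoter reactions are slow: their rates are multiplied
by $\varepsilon$.  We scale only the gene reactions by $\varepsilon$ and
leave protein rates unscaled (an equivalent formulation scales proteins
by $\varepsilon^{-1}$ instead; stationary laws are invariant under a
global rescaling of time, and a single knob keeps simulation simpler).

**Propensity convention.**  Stochastic propensities are combinatorial
mass action, $\kappa \prod_s \binom{x_s}{\nu_s}$.  This makes the
conditional multimer mean come out as
$b = (\beta/(n!\,\beta_-))\,a^n$; the deterministic backend uses rate
constants $\kappa/\prod_s \nu_s!$ so that its equilibria coincide with
the stochastic product-form means.

## Structural assumptions

Validation enforces: at most two binding sites per promoter; one fixed
cooperativity index per TF; single gene copies; a connected block graph
(regulatory edges plus diffusion couplings — a diffusion-coupled
population is one network); every referenced TF produced inside the
network; positive decay; multimerization rates present exactly when
$n > 1$.  Violations are returned as diagnostics, not raised.

## The slow-promoter limit

Conditioned on a frozen promoter state $d$, the protein network is a set
of independent birth–death chains plus reversible $n$-merization (and
linear transport when coupled): weakly reversible and deficiency zero,
hence product-Poisson stationary with means at the conditional
deterministic equilibrium.  Without transport the means are
$a_i = k_{i,d_i}/k_{-i}$ and $b_i = (\beta_i/(n_i!\beta_{-i}))a_i^{n_i}$;
with transport the monomer means solve the linear
production/decay/transport balance (decay diagonal plus transport
Laplacian; positive decay keeps it nonsingular) and the multimer means
follow from $n$-merization detailed balance.  Conditional laws never
depend on $\varepsilon$, $\alpha$ or $\alpha_-$.

The reduced generator $\Lambda_r$ over the $L$ promoter states assigns a
binding transition of gene $i$'s site the rate $\alpha\,\mathbb{E}[
\mathrm{TF} \mid D=d]$ with the expectation taken under the conditional
law of the *current* state, and $\alpha_-$ to unbinding; columns sum to
zero (the $\dot p = \Lambda p$ orientation, stated here to prevent
transpose bugs).  An independent construction — sandwiching the slow part
of the truncated CME between stacked conditional PMFs and block summation
— is implemented in `reduced_generator_direct` and agrees with the
transition-by-transition build to $10^{-8}$ on the desk-scale fixtures;
this is a cross-check, not the production path.

**Weights.**  $\lambda$ is the normalized kernel vector of $\Lambda_r$
(dense null-space solve; the chains here have $L \le 4096$).  Non-leaky
networks make the chain reducible because binding rates vanish with the
conditional TF means.  Policy: identify closed communicating classes; a
unique closed class carries the stationary law (this covers the
non-leaky self-activating gene and the toggle's unreachable doubly-bound
state); with several closed classes the weight is split by absorption
probabilities from a user-supplied initial promoter distribution, and
without one a `NonUniqueStationaryError` reports the kernel dimension.

**Modes.**  Each mixture component is a mode.  Component modes are
distinct component locations (coincident locations merged, weights
summed) above a weight floor, default $10^{-6}$ — small enough to
separate structurally-zero weights from numerically tiny ones.  Lattice
maxima are found by exhaustive scan of the mixture on its truncation box
(a point counts if it is $\ge$ all axis neighbours and $>$ at least one);
the scan is skipped automatically above $5\times 10^6$ lattice points.
Dominant-mode reports use a cumulative-weight threshold of $0.99$, stated
in the output.

**Synchronized populations.**  For $N$ identical diffusion-coupled toggle
switches the high-$\Omega$ stationary law depends only on the number of
unbound promoters per gene family; macro-state $(i, j)$ sits at
$(i\,k_0/(N k_-),\, j\,k_0/(N k_-))$.  The all-bound macro-state is
unreachable, so $(N+1)^2 - 1$ modes remain of the $4^N - 1$ finite-
coupling components.  The reported synchronization threshold
$\Omega_{\min} = (k_0 - k_-)/N$ makes the inter-cell component spread at
most one copy number ($\delta = k_0/(k_- + N\Omega) \le 1$); it is
reported, never silently applied.

## Finite-timescale backends

*Truncated CME.*  The generator is assembled sparse in explicit fast–slow
form $\Lambda_\varepsilon = \tilde\Lambda + \varepsilon\hat\Lambda$, the
fast part block-diagonal over promoter states.  Truncation boxes default
to per-species mean $+\,10\sqrt{\text{mean}}+20$ (Poisson tails beyond
this are negligible); columns at the box boundary keep their full outflow
on the diagonal so the leak is measurable, and a warning with a Poisson
tail estimate fires when any conditional mean exceeds half the box.

*Stationary solves.*  Reflecting closure (outflow discarded, columns
re-closed), then a sparse direct solve with one row replaced by the
normalization; residual $\|\Lambda\pi\|_\infty$ and the stationary leak
rate are reported.  Direct solves are used throughout (state spaces here
stay below $2\times 10^5$).

*Gillespie.*  Exact direct method over the expanded reaction list,
seeded; long runs are sampled on a regular grid to bound memory, and
occupancy histograms are time-weighted.  Oscillation analysis labels a
sample by its dominant protein when the leader exceeds twice the
runner-up, requires five consecutive samples (sampling interval
$1/k_-$) for a dominance episode, and counts episode changes as switches;
the dominance factor and run length are parameters, since no quantitative
criterion is standard.

*Deterministic states.*  Mass-action ODE with one promoter fraction per
gene eliminated by conservation.  Random starts (Dirichlet promoter
fractions, log-uniform protein levels, plus the origin) are relaxed by
LSODA integration and polished by a Newton solve whose promoter residuals
are rescaled by $1/\varepsilon$ — without the rescaling the slow–fast
imbalance defeats the root finder; a direct Newton attempt from each raw
start is kept because it is what finds unstable equilibria.  Stability:
all reduced-Jacobian eigenvalues with real part below $-10^{-9}$.
Equilibria are deduplicated at $10^{-3}$ relative tolerance and
non-convergent starts are counted in a warning.

## Fixtures and their provenance

Fixture rates printed in the source figure captions are used verbatim
(`provenance: paper`): the bursting gene ($\alpha_-=0.1$, $\alpha=1$,
$k_-=2$, $k=20$), the self-regulating gene ($\alpha=\alpha_-=1$ slow
units, $k_0=20$, $k_1=100$, $k_-=10$, $\beta=10$, $\beta_-=50$, $n=2$),
the toggle switch ($\alpha/\alpha_-=1/200$, $k_0/k_-=40$) and the
repressilator ($\alpha=5$, $\alpha_-=1$, $k=2000$, $k_-=20$,
$\beta_\pm=1$; $\varepsilon=0.1$ slow, $10^3$ fast).  The coupled-toggle
population and both cell-fate circuits were published without complete
rate tables; their shipped parameters are chosen once to satisfy every
published qualitative statement (mode ladders at multiples of
$k_0/(Nk_-) = 50$; silent singly-repressed configurations; low production
in unbound and doubly-bound PU.1/GATA.1 states) and are flagged
`provenance: reconstructed`.  The PU.1/GATA.1 bistable/tristable
binding-rate scenarios are likewise constructed: strong exclusive
self-activation leaves two dominant quadrants, weaker self-binding keeps
(low, low) as a third.  The quadrant grouping rule (boundary at half the
largest component mean per axis, dominance at weight $\ge 0.1$) is this
package's formalization of the verbal grouping and is exposed as
configuration.

The deterministic sweep behind the self-activating-gene comparison uses
three documented variants: the caption rates; a low-leak, weak-binding
set ($k_0=5$, $\alpha=0.4$, $\beta/\beta_-=0.2$) inside the bistable
regime of the cooperative gene; and a weak-multimerization set
($\alpha=0.2$, $\beta/\beta_-=0.02$) that pins the cooperative non-leaky
gene at the origin.  $\alpha=0.1$ is avoided deliberately: it puts the
non-leaky non-cooperative gene exactly on its transcritical point
($k_1\alpha/(k_-\alpha_-) = 1$), where no equilibrium is hyperbolic.

## What the tests show — and what they do not

All expected values are either closed forms derived independently
(birth–death detailed balance, the explicit 4-state toggle generator, the
displayed toggle mixture), brute-force solves of conditional generators,
or linear-algebra oracles constructed separately from the production
code.  Problem sizes are kept desk-scale on purpose: protein means up to
$\sim 100$, state spaces to a few $10^4$, simulation horizons of a few
hundred protein lifetimes.  Passing therefore demonstrates correctness of
the reduction and of the numerical backends on networks of this class; it
does not demonstrate anything about mRNA-level noise (transcription and
translation are lumped), multi-copy genes, heterodimer TFs, promoters
with more than two sites, or the accuracy of the $\varepsilon \to 0$
limit for a particular biological system — for that, the two-to-one rule
(largest reduced rate below half the protein decay rate, checked on the
toggle) is the practical guide.

## Known limitations

The first-order $\varepsilon$ correction to the stationary law is not
computed (no closed form is available).  FSP error control is limited to
leak reporting; there is no adaptive box refinement.  The SSA is a plain
direct method — adequate at these sizes, slow for stiff fast-kinetics
regimes far beyond the fixtures.  Reducible reduced chains with several
closed classes require the caller to supply an initial promoter
distribution; the package does not invent one.
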