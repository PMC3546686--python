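# Methods

## The model

Translation initiation is treated as the equilibrium assembly of the
30S subunit on an mRNA whose ribosome docking site (RDS) must be
completely unpaired.  Three species interact: mRNA (total m_T), a
trans-acting sRNA (s_T) and the pool of ribosomes available for
initiation (r_T).  Binding reactions are at thermodynamic equilibrium
with constants derived from free energies, K = exp(−ΔG/RT); the
structure of the mRNA enters only through the exposure probabilities
P_EF (free mRNA) and P_ES (sRNA-bound mRNA), which multiply the
concentration of ribosome-bindable substrate (m_F\* = P_EF·m_F,
m_S\* = P_ES·m_S).  Each successful initiation removes n ribosomes from
the free pool, accounting for the ribosomes elongating behind the
initiating one.

Two site topologies exist.  If the sRNA site shares bases with the RDS,
simultaneous binding is sterically impossible and the only active
species is m_R; eliminating the other species from the five balance
equations yields a cubic polynomial in m_F.  If the site is spatially
separate, the doubly bound complex M_SR also initiates
(m_TA = m_R + m_SR); the seven-equation system eliminates to a quintic.
We derived the quintic symbolically (resultant, in m_F, of the mRNA and
ribosome balances after substituting the mass-action laws); the
elimination produces one spurious factor (1 + K_R·P_ES·r_F), positive
for all physical states, which is dropped.  We solve for the free
ribosome concentration r_F rather than m_TA: species reconstruction
from r_F needs no subtractive cancellation.

The readout per site is the signed ratio α = m_TA(s_T)/m_TA(0),
reported as −m_TA(0)/m_TA(s_T) when activity falls, so |α| ≥ 1 always;
|α| > 2 calls a site (and its gene) putatively regulated.  At s_T = 0
the two systems are identical and α is returned as +1 exactly rather
than re-solved.

### Assumptions and deliberate simplifications

* Copy numbers per cell are used as dimensionless activities directly
  against exp(−ΔG/RT), with no volume or standard-state conversion.
  The model is qualitative; α is a classifier, not a prediction of
  measured fold change.
* The reaction M_R + S_F ⇌ M_SR (sRNA binding to an mRNA that already
  carries a ribosome) is not part of the network.
* One site at a time: multiple sites on a gene are evaluated
  independently, and no competition of several mRNAs for one sRNA pool
  is modelled.
* Equilibrium only: co-transcriptional folding kinetics, Hfq chaperone
  effects and initiation bursting are all outside the model.

## Numerical solution

Both eliminated polynomials are solved by Newton's method with the
analytic derivative, started at the center of the physical box
([0, m_T] for the cubic in m_F, [0, r_T] for the quintic in r_F).  Any
iterate leaving the box, or failure to converge within 100 steps,
falls back to bracketed root finding (Brent) on the *rational* form of
the same scalar equation — the balance equation before denominators
are cleared — which is monotone on the box and better conditioned than
the expanded polynomial when binding constants reach e^{40/RT} ≈ 10²⁸.
A converged Newton solution is polished on the rational form as well.
Scalar convergence tolerance is 10⁻¹² (relative + absolute); every
returned solution must satisfy all conservation laws to 10⁻⁹ of the
corresponding total, or an error carrying the residuals is raised.

A feasibility guard computes all polynomial roots (numpy eigenvalue
method), re-qualifies each candidate on the rational form (|residual| ≤
10⁻⁵ of its box-edge scale) and on species physicality (every species
within [0, its total]), and raises if more than one distinct feasible
root survives.  Re-qualification on the rational form matters: at
extreme constants the expanded polynomial's roots carry enough rounding
noise that clamped spurious roots would otherwise appear feasible.

An independent oracle (`oracle_solve`) never touches the eliminated
polynomials: it runs a damped log-space fixed-point iteration of the
conservation laws followed by a Levenberg–Marquardt / Powell-hybrid
polish with an analytic log-space Jacobian.  The test suite and the
acceptance script compare the production solvers against it on hundreds
of random parameter sets spanning K ∈ [1, e^{40/RT}], totals ∈ [1, 10⁵]
and n ∈ [1, 100]; observed agreement is ~10⁻¹³ relative, against a
10⁻⁸ requirement.

## Energy model

The bundled backend uses one simplified nearest-neighbor model for both
inter- and intra-molecular energetics, so that duplex energies, opening
energies and unpaired probabilities are mutually consistent and every
quantity is checkable against exhaustive enumeration:

* **Stacks.** A 21-entry published-style stack table over Watson–Crick
  and GU pairs (values in kcal/mol at 37 °C, two decimals), completed
  to all 36 ordered pair combinations by strand-flip symmetry.
* **Duplexes** (ribosome anti-RRS and sRNA sites): inter-molecular
  pairs only; initiation penalty 4.10 kcal/mol; bulges and interior
  loops with an affine penalty 3.20 + 0.60/nt, at most 6 unpaired nt
  per strand between consecutive pairs.  Dynamic programming over pair
  end points; sub-optimal sites are all traceback end points below the
  cutoff, deduplicated by the rule that two hits are the same site when
  their mRNA spans overlap by more than half of the shorter span and
  their sRNA spans intersect (the lower-energy hit is kept).
* **Intra-molecular folding**: nested structures, minimum hairpin loop
  3.  A structure's energy is the sum of its stacks plus a helix
  initiation penalty of 4.5 kcal/mol charged at each helix's innermost
  pair.  The per-helix (rather than per-pair) form is essential:
  isolated pairs are strongly suppressed (weight ≈ 7·10⁻⁴), so a
  30-nt interval in an unstructured background is genuinely accessible,
  while long stacked helices remain very stable — the qualitative shape
  of real loop-entropy penalties.  Neither sequence-dependent loop
  energies, dangles, nor coaxial stacking are modelled.
* **Partition function**: a McCaskill-style O(n³) recursion over the
  pair-containing partition function Zb and the unconstrained Z,
  splitting the inner ensemble on whether the adjacent inner pair
  exists (stack weight vs helix-open weight).  Constraint folding
  removes forbidden bases from pairing in both numerator and
  denominator; P_u(interval) = Z(interval unpaired)/Z.  Per-base
  rescaling (retry ladder 1, 4, 32) prevents overflow on ±250-nt
  windows; probabilities as small as e^{−100} are representable, well
  past the 60 kcal/mol opening energies the screening encounters.
* **Reference path**: exhaustive structure enumeration with the same
  energy function, for sequences ≤ 28 nt.  Partition-function and
  enumerated probabilities agree to ~10⁻¹³ (requirement 10⁻⁹),
  constrained and unconstrained.

Site energies are accessibility-corrected:
ΔG_S = ΔG_duplex + ΔE_open(mRNA site) + ΔE_open(sRNA site), each
opening energy computed as −RT·ln P_u of the bound interval in a
200-nt window centered on it with pair span limited to 150 nt (clipped
for short inputs).  RDS exposure uses a ±250-nt window around the RDS,
clipped at transcript ends without recentering.  An adapter backend
over the ViennaRNA bindings (duplexfold / duplex_subopt / constrained
partition functions with hard constraints) provides Turner-parameter
energetics behind the same interface; the bundled backend is the
default and the one all quantitative tests run against.

## Parameters

| parameter | default | meaning |
|---|---|---|
| anti-RRS | `UCACCUCCUU` | 3′-terminal 10 nt of *E. coli* 16S rRNA |
| RRS search window | −30..+3 | around the translation start |
| site window | −150..+20 | candidate sites fully inside (configurable semantics) |
| energy cutoff | −7 kcal/mol | accessibility-corrected ΔG_S, inclusive |
| minimum site length | 10 nt | mRNA span, interior bulges included |
| RDS length | 30 nt | from the RRS start |
| accessibility flank | ±250 nt | folding context around the RDS |
| temperature | 310.15 K | RT = 0.61633 kcal/mol |
| total 16S | 57,000 /cell | ribosome pool anchor |
| busy fraction | 0.80 | elongating ribosomes → r_T = 11,400 |
| occupancy n | 20 | ribosomes removed per initiation (sweepable 1..100) |
| [sRNA]/[mRNA] | 2/3 | default when the sRNA is unmeasured |
| α threshold | 2 | both directions; classification is pure in α |

Coordinates follow the biologist convention: no position 0, +1 is the
first base of the start codon, −1 the base upstream; intervals are
closed.  Windows beyond transcript ends are clipped silently and
flagged.  Ties in RRS energy resolve to the most 5′ site.

## Synthetic scenarios

The fixture generators produce the study conditions every end-to-end
test runs under.  Transcripts are 240 nt (160-nt 5′ leader, 80-nt CDS)
with the perfect anti-RRS complement at −12..−3 and AUG at +1; the
target is expressed at m_T = 150 copies/cell, chosen below the
ribosome-slot count r_T/n even at n = 100 so that the scenarios remain
sRNA-limited across the whole sensitivity sweep.  Backgrounds are
pairing-poor (A 0.70 / U 0.10 / G 0.10 / C 0.10): with sparse
complementary runs, the only stable structure in a scenario is the
planted one and the free RDS satisfies P_EF ≥ 0.1 in the repression
scenario.  Four mechanisms are planted:

* **repression** — a 24-nt perfect complement across the RDS and start
  codon; strong enough to outcompete the saturating ribosome, giving
  the sequestration-limit α ≈ −(1 − s_T/m_T)⁻¹ = −3.
* **activation** — a 14-bp GC-rich stem pairs an upstream arm
  (−94..−81) with the RDS core; the sRNA complements the upstream arm
  plus flanks only, so constraint folding releases the RDS
  (P_ES ≫ P_EF) and the doubly bound complex initiates.
* **null** — a random sRNA verified to have no site passing the
  filters.
* **upstream_weak** — two complements on one sRNA: a 28-nt decoy at
  −150..−123 whose occupancy leaves accessibility unchanged (α ≈ ±1)
  and a 16-nt site inside the RDS that represses; the gene is flagged
  only because every site is evaluated, not merely the energy-best.

Generation is a build–verify–retry loop on Python's integer Mersenne
Twister (platform-stable for a given seed): each candidate background
is pushed through the *actual* pipeline (RRS search, site search,
exposure, equilibrium) and emitted only if it shows its intended
behavior; after 40 failed attempts the generator raises and suggests a
new seed.  What passing these scenarios shows about real data is
limited: real transcripts have structured backgrounds, imperfect
duplexes, Hfq dependence and measured (not assumed) sRNA levels; the
scenarios establish that the machinery computes the model correctly and
that the two regulatory mechanisms are separable, not that the model's
calls on a real genome are accurate.

## Problem sizes in the standard checks

The test suite and acceptance script size their computations to run
comfortably on one CPU: 200 random parameter sets per topology for the
solver/oracle comparison; 30–50 random sequences of 10–25 nt for the
enumeration cross-check; 240-nt transcripts (so folding windows are
≤ 240 nt) for all end-to-end scenarios; a 6-gene cohort for the
multi-gene screen; the 3×3 grid n ∈ {1, 20, 100} × ratio ∈ {2/3, 1, 2}
for the sensitivity sweep.

## Known limitations

* The bundled energy model is qualitative; absolute ΔG values differ
  from Turner-parameter tools, so energy cutoffs calibrated there
  transfer only approximately.
* Accessibility uses "every RDS base unpaired" literally; partial
  exposure contributes nothing.
* The site-window rule is full containment of the site in −150..+20; a
  site straddling the window edge is excluded (documented alternative
  readings: 5′- or 3′-end containment).
* K ↔ P = K/(1+K) saturates in double precision near P = 1; round-trip
  identity holds for K ≲ 10³ at 10⁻¹² relative, and large constants
  should be kept as K (or ΔG), never stored as P.
* α can reach astronomically large positive values when P_EF is
  vanishingly small; it is a classification signal, and only its
  position relative to ±2 is meaningful.
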