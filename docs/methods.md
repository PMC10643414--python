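# Methods

## Model and assumptions

The market is a bilateral oligopoly in *reports*. Sellers (coastal states)
and buyers (distant-water fishing nations) simultaneously report endowments
— biomass b̂ᵢ and fleet gross tonnage t̂ⱼ — to a mechanism that clears the
access-fee market as if reports were truthful. With constant-elasticity
seller cost c(z) = η/(η+1)·z^((η+1)/η) and buyer value
v(z) = ε/(ε−1)·z^((ε−1)/ε), the clearing fee and quantity are
p = B̂^(−1/(ε+η)) T̂^(1/(ε+η)) and Q = B̂^(ε/(ε+η)) T̂^(η/(ε+η)); each agent
receives its reported share of Q. The mechanism is efficient *conditional
on reports*; strategic underreporting — larger for larger quantity shares —
is how market power distorts the outcome. Agents know rivals' report sums
but not rivals' true endowments.

Key structural facts the implementation exploits (and tests verify rather
than assumes):

* each side's best response depends on rivals only through the sum of their
  reports, and the two sides decouple — the seller polynomial contains no
  buyer terms and vice versa, so the buyer subgame is solved once per
  market and reused across all supply-side perturbations;
* the best-response root always lies in (0, true value]: the residual is
  negative near zero and positive at the truth, so a bracketed solve on
  (10⁻¹²·true, true] cannot pick a spurious root.

Biology is a one-stock-per-country Pella-Tomlinson surplus-production
model, growth(b) = (φ+1)/φ·g·b·(1−(b/k)^φ). Carrying capacity k is
calibrated by assuming the observed mean annual total catch h equals growth
at depletion d = b/b_MSY:

    k = h · φ (φ+1)^(1/φ) / (d g (φ+1 − d^φ)),   b = d·k/(φ+1)^(1/φ)

valid for 0 < d < (φ+1)^(1/φ) (≈2.5 at φ=0.188). The d = 0.8 case reduces
to the familiar 1.25/g closed form. Steady states only; no transient
dynamics between equilibria.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| η | seller opportunity-cost elasticity | 1.0 | swept over {0.5, 1, 1.5} |
| ε | buyer fishing-profit elasticity | 2.0 | swept over {1.5, 2, 2.5}; must exceed 1 |
| φ | growth-curve shape | 0.188 | puts b_MSY at 40% of k; per-stock override |
| d | depletion b/b_MSY | 0.8 | 0.4/0.6 robustness; 1.3 for healthy Pacific stocks |
| threshold | fishing-hours participation cutoff | 2,420 h | doubling is a config change |
| grid_pct | policy-grid step, % of carrying capacity | 1 | grid start 1% ("near-zero") |

Unit anchors are built from the solved status-quo market plus two observed
numbers: the anchor buyer's published agreement catch (tons/yr) pins tons
per quantity model unit via its equilibrium purchase share, and the
observed weighted-average fee (USD/ton) pins USD per fee model unit.
Profits convert with the product of both anchors. All conversions are
linear through the origin and exact inverses.

## Policy functions and equilibrium

A country's access policy function is tabulated by replacing its biomass
with each grid value (rescaling its model share proportionally — other
countries' shares stay fixed, so the model's total true endowment departs
from 1 under perturbation, by design), re-solving the Nash equilibrium, and
assigning the country its reported share of the total access quantity in
tons. Coalition variants grid the merged seller from 1% to 100% of the
*summed* carrying capacity and apportion access to members by status-quo
true biomass; regional variants do the same per bloc, holding other blocs
at their status-quo endowments, and apportion within the bloc.

We grid regional blocs to the regional carrying capacity (not the regional
status-quo biomass): counterfactual equilibria lie above status-quo
biomass, interpolation beyond the grid is forbidden, and only this choice
makes the nesting identities exact — all-singleton blocs reproduce the
status-quo curves and a single bloc reproduces the continental curves, both
to 1e-9.

Non-access catch (domestic plus unauthorized foreign) is linear through the
origin with slope (h − q*)/b frozen at the status-quo point — a zero-biomass
stock supports zero catch, and access + non-access reproduces observed
catch at the calibrated biomass. The slope is held fixed across scenarios
(the coalition is assumed not to change domestic/illegal-fishing behavior
at given biomass). A negative slope — modeled access exceeding observed
catch, which arises in the bloc-dissolution market — is replaced by the
mean slope of the unaffected countries; if all slopes are negative the
market is declared unrecoverable.

Equilibrium biomass is the *stable* crossing of growth and total-catch
policy (growth above harvest below the crossing, below it above), located
by a sign scan on a 20× refined grid and polished with Brent's method to
1e-6·k. No stable crossing, or more than one, raises a diagnostic error
rather than silently choosing — the analysis assumes a unique relevant
intersection and we surface any violation.

Counterfactual fees and profits are evaluated by re-solving the market once
at the scenario's equilibrium biomass shares (each merged seller's true
share = its equilibrium biomass ÷ status-quo total biomass); the status quo
needs no re-solve because its steady state recovers the calibrated market.
The continental coalition's true share (≈1.12 on the default synthetic
market) is an output of the growth/policy intersections, never an input.

## Numerical choices

* Best responses: vectorized bracketed bisection, 60 fixed steps
  (2⁻⁶⁰ relative width — below double precision); scipy's `brentq` has no
  vectorized bracketed counterpart and the fixed point calls one residual
  per side per iteration.
* Fixed point: synchronous best-response iteration from truthful reports,
  relative tolerance 1e-10 on the report vector, max 10,000 iterations,
  0.5 damping engaged only when the update direction reverses. Warm starts
  (neighbouring grid point) shorten policy-grid solves; tests confirm the
  fixed point is start-independent.
* Distant-water classification: a vessel is DWF only with *strictly* more
  than half its hours outside its flag EEZ; an exact tie is domestic.
  Zero-hour vessels are domestic with a warning.
* Bloc assignment: ascending order of selling-member count, alphabetical on
  ties (warned), explicit reassignment overrides, singleton fallback for
  countries in no bloc.
* Percent changes use the reference scenario as denominator and are not
  antisymmetric under swapping arguments.

## Synthetic data

The generator emulates the structure of the real inputs, not their values:
right-skewed country endowments (catch h ~ lognormal(ln 1.5e5, 1.3) tons/yr,
so a 32-country market averages ≈11 M tons/yr total with wide seed-to-seed
variation; buyer tonnage lognormal), growth g ~ U(0.1, 0.5)/yr, an anchor
buyer holding ≈13% of true tonnage so its equilibrium purchase share lands
near 11.5%, and total access catch tied to 21% of realized total catch (the
continent-scale access/total ratio) so that per-country access plausibly
stays below per-country catch. Fishing-hours and vessel tables are
generated with planted ground truth (which flags are buyers, which vessels
are distant-water) so identification and classification are assertable
without external data.

What the synthetic market does *not* emulate: real countries' actual
endowments, bloc memberships, or the spatial structure of fishing effort.
Passing tests therefore demonstrate the mechanics and the qualitative
comparative statics (cartel ⇒ lower reports and access catch, higher fee,
higher seller profit, higher biomass everywhere — verified across the full
(η, ε, d) grid), not the magnitude of any real-world estimate. Reproducing
the published continent-level magnitudes requires the study's deposited
country tables, which are deliberately out of scope here; on synthetic
markets of the same shape the aggregates land in the same qualitative
range.

Problem sizes used in the test suite are chosen to exercise every code
path at full grid resolution: 6×6 markets for the shared pipeline fixture,
8×8 for the 27-point robustness grid, 20 seeded markets of 2–12 sellers for
the recovery property, one 32×33 end-to-end smoke run.

## Known limitations

* One aggregate stock per country; no multi-stock or transboundary
  movement, no age structure.
* Non-access policy is exogenous and linear; behavioral responses of
  domestic/illegal fishing to the coalition are out of scope (the direction
  of the induced bias is discussed qualitatively above).
* Uniqueness of the Nash equilibrium is tested from multiple random
  initializations, not proven.
* Coalition formation itself (who joins, side payments, enforcement) is not
  modeled; scenarios compare exogenous market structures.
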