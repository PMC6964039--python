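# Methods

`bovsim` couples a compartmental model of glucose-insulin-glucagon
homeostasis in the dairy cow to a hormonal network of the bovine estrous
cycle, so that feeding scenarios (dietary glucose content, feed
restriction, lactation) propagate through insulin and IGF-1 into
gonadotropin dynamics, follicle growth and ovulation.

## Metabolic subsystem

Six states: blood glucose `Glu_blood` (g/L), hepatic glucose `Glu_liver`
(g), glycogen `Glu_store` (g), body fat `Fat` (kg), insulin `Ins` (mU/L)
and glucagon `Gluca` (ng/L).  Feed enters as dry-matter intake (DMI,
default 11 700 g/d for a 600-kg cow); a fraction `c0` (default 0.08) is
glucose plus glucogenic substances, of which a fraction `c1` (0.08) is
absorbed directly into the blood and the remainder is converted to
glucose by hepatic gluconeogenesis with no loss.  All regulation uses
Hill switches `H+(S,T,n) = S^n/(S^n+T^n)` and its complement: pancreatic
secretion responds to blood glucose around 0.5 g/L (exponents 10 and 2),
insulin routes glucose into the liver, glycogen (with a logistic store
factor `1 - Glu_store/K`, `K` = 1000 g) and fat, and glucagon mobilizes
glycogen and — once the store is depleted below ~10 g — body fat.
Sinks are a non-mammary maintenance term (`c12` = 1000 g/d at full
activation) and a mammary term `c13*Milk` with `c13` = 72 g of glucose
per kg of milk.  Blood glucose dynamics are scaled by the extracellular
volume `V` = 22.8 L; the fat state is carried in kg with an explicit
1000 g/kg factor so that summing the equations yields an exact glucose
mass balance (tested to machine precision).

Two structural properties matter for interpretation:

* **Fat is a quasi-neutral direction.**  At maintenance, lipolysis is
  fully gated off by the half-full glycogen store while lipogenesis
  remains marginally positive (~1 g/d against a 150-kg pool), so no
  exact interior equilibrium exists.  `find_steady_state` therefore
  solves the five fast states with `Fat` held fixed (default 150 kg) to
  a residual below 1e-8, and the long-time integration agrees with that
  root to four significant digits.
* **The mammary sink is unconditional.**  A diet whose glucose pool
  cannot cover `c13*Milk` drives blood glucose negative without bound;
  lactating scenarios are therefore only meaningful for glucose-rich
  diets (`c0` roughly 0.2-0.3), which is how they are run here.

The glycogen store is a fast, slaved variable: glycogenesis and
glycogenolysis are each of order 1e5 g/d and nearly cancel, so the store
equilibrates within hours.  Under 58% feed restriction it settles at
~11.5 g, just above the mobilization thresholds `T7 = T8` = 10 g — a
knife-edge that caps fat mobilization (~35 g/d) and fixes restricted
insulin at ~10.5 mU/L within days.  Several quantitative differences
from the reported restriction outcomes (see Limitations) trace to this
edge.

## Reproductive subsystem

Sixteen dimensionless states span the hypothalamus-pituitary-ovary axis:
GnRH (hypothalamic store and pituitary pool), FSH and LH (pituitary
store and blood), the lumped follicular function, corpus luteum (CL),
P4, E2, inhibin, the endometrial enzyme pool, oxytocin, PGF2a, an
interovarian factor (IOF) and IGF-1.  The published interaction topology
is retained — P4 suppresses GnRH/LH and the follicle, FSH drives
follicle growth, E2 at low P4 triggers the GnRH/LH surge, the surge
ovulates the follicle and induces a self-sustaining CL, and luteolysis
runs through an enzyme-plus-oxytocin gate onto PGF2a and the IOF — but
the right-hand sides were authored and calibrated for this package (the
reference equation set is not restated in the source article).  Design
choices that proved necessary for a robust limit cycle:

* **Surge excitability.**  The E2 trigger is a steep switch (exponent
  30) with an autocatalytic release term: once ignited, pituitary GnRH
  reinforces its own release until the hypothalamic store empties.  LH
  and FSH release are proportional to the GnRH release flux, so a full
  dump always delivers a fixed fraction of the pituitary stores as a
  bolus.
* **All-or-none ovulation.**  The IGF-gated ovarian response
  (`c20*H+(LH, T13, 2)` with `T13 = c21*H-(IGF, T14, 2)`) acts on the
  follicle only above a surge-level LH threshold; basal LH supports
  rather than destroys the dominant follicle.  Without this gate the
  system parks in a sub-surge pulsing state in which LH leakage shaves
  the follicle exactly at the trigger threshold.
* **Dominance runaway.**  Follicle growth self-amplifies above a
  dominance threshold, giving the E2 rise momentum through the surge
  trigger; luteal-phase P4 holds the follicle below that threshold.
* **Luteolysis timer.**  The endometrial enzyme integrates P4 exposure
  (shallow exponent 1, per the recalibrated parameterization) and is
  re-set around estrus when P4 is basal.  The oxytocin gate (steep
  exponent 10) is open whenever the luteal follicle is healthy and
  closes when follicular E2 collapses — which is what makes luteolysis
  fail under acute feed restriction.  A separate receptor-saturation
  route lets supra-physiological (injected) oxytocin advance luteolysis,
  reproducing the cycle-shortening effect of daily oxytocin
  administration from cycle day 2 (~10 vs ~20 days, with P4 rising
  normally for the first ~4-5 days).
* **Slow gonadotropin reserves.**  Pituitary FSH and LH are
  capacity-limited stores with slow basal turnover.  Because insulin
  gates their synthesis through steep Hill switches at `T15` = 15 and
  `T16` = 16 mU/L, feed restriction shuts synthesis within days, and the
  stores then drain over weeks — the model's mechanism for a gradual
  loss of cyclicity under chronic restriction, ending in a low-P4
  anestrus, and for its recovery after refeeding.

Nutritional coupling follows three routes: insulin multiplies LH/FSH
synthesis (`c23*H+(Ins,T16,10)`, `c22*H+(Ins,T15,10)`); insulin and P4
shape IGF-1 (`dIGF/dt = c17 + c18*H-(P4,T11,4)*H+(Ins,T12,10) -
c19*IGF`), which sets the LH threshold for the ovarian response; and a
glucose/insulin-gated basal LH pulsatility (a steep switch at 9 mU/L) is
permissive for follicular function, which distinguishes acute (~8 mU/L,
follicle collapses, luteolysis fails, P4 stays high) from chronic
(~10.5 mU/L, follicle function retained) restriction.  During lactation
an additional oxytocin source `c24*exp(-c25*t^2)` decays over the weeks
after calving.

The thirteen recalibrated constants of the reference cycle model
(clearances, exponents and thresholds of the CL/PGF2a/IOF loop) are
stored with both their reference and recalibrated values and are
individually toggleable (`ReproductiveParams.with_reference_values`);
one typographically ambiguous exponent was resolved as 2 -> 30, read as
a steep CL self-maintenance switch at its size threshold 0.2807.  The
remaining network constants are this package's own calibration, chosen
so that the default coupled model cycles regularly at ~20 days under
maintenance insulin (~15.3 mU/L).

## Scenarios and events

Scenarios carry piecewise-constant DMI schedules (the integrator
restarts at breakpoints), interpolated lactation inputs, a lactating
flag and optional exogenous-oxytocin pulse trains.  Restriction
protocols anchor their schedule at the first ovulation after a burn-in
(default 20 days), matching the experimental designs ("restriction
starts after ovulation"); the acute protocol can alternatively run at
absolute days 43-58.  The lactation fixture is a Wood gamma curve
`a*t^b*exp(-c*t)` for milk (shape 0.18) and DMI (shape 0.10), scaled to
hit 41 kg/d milk and 22 kg/d DMI exactly at week 8 postpartum — the two
printed anchors of the interpolated study data it emulates — with a
fresh-cow start of ~58% of peak milk; measured series can be loaded from
CSV or MATLAB files instead.  What the fixture does not emulate: day-to-
day intake variability, parity and seasonal effects, and the exact
early-lactation shape of the study data, so scenario outcomes that
depend on the first two weeks postpartum carry that caveat.

Events are detected on the dense output (0.05 d): luteal onset as the
first linear-interpolated crossing of relative P4 above 1; ovulations as
LH maxima with prominence at least half the largest surge, followed
within 7 days by P4 rising above its baseline plus 10% of amplitude;
cessation of cyclicity as a 35-day ovulation gap; undetected events
return a NaN sentinel rather than raising.  The energy-balance indicator
is the lipogenesis-minus-lipolysis flux difference `Delta_Fat` in g/d.
Local sensitivities use the one-sided relative finite-difference
quotient at 10% perturbations (5% and two-sided available); parameters
are enumerated by name in `docs/parameters.csv` rather than by position.

## Numerics

LSODA with `rtol` 1e-6, per-state `atol` (1e-9 g/L for blood glucose,
1e-6 g for masses, 1e-9 for the relative reproductive states) and a
0.1-day step cap, which resolves the sub-day pancreatic dynamics and
hormone surges; Hill inputs are clipped at zero inside rate laws to
tolerate solver micro-undershoot, while the state itself is never
modified.  A glycogen store probed more than 0.1% above its carrying
capacity raises a consistency error in direct evaluation; solver-facing
calls accept the overshoot and return the self-correcting negative
glycogenesis flux.  Runs are deterministic for fixed inputs and
tolerances; halving `rtol` moves event times by well under half a day.
Default problem sizes (100-day maintenance runs, 280-day restriction
runs, 200-day lactation runs) keep every scenario in the package's test
suite within seconds on one CPU.

## Known limitations

* Glucose is the only feed component; protein and lipid intake, rumen
  fermentation and body-weight dynamics are out of scope, and glucose
  converts to fat 1:1 with no efficiency loss.  Only the product
  `c0*DMI` enters the equations, so glucose content and total intake are
  interchangeable.  Milk volume and mass are treated as equal (1 kg = 1 L).
* Under chronic 58% restriction the simulated cyclicity ceases within a
  few weeks (followed by the observed low-P4 anestrus and refeeding
  recovery at ~30 weeks), not after ~15 weeks; restricted insulin falls
  to ~10.5 mU/L within days, and the re-derived cycle network does not
  sustain 15 further weeks of cycling at 2% gonadotropin synthesis.
  Likewise the restriction-phase fat loss is ~5% rather than ~10%
  (glycogen-store knife edge, above), and the postpartum onset of
  luteal activity at `c0` = 0.25 occurs near day 25-35 rather than near
  day 50.
* Above ~17 mU/L insulin the network enters a persistent-follicular
  anovulatory regime (continuous high E2 without surges); lactating
  scenarios with `c0` above ~0.27 pass through it, so the anestrus-vs-
  `c0` response is not monotone over the full 0.2-0.3 range.
* The single lumped follicle has no wave structure, no multi-follicle
  competition, and the model describes one representative cow with no
  between-animal variability.
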