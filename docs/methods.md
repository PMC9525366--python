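# Methods

## Model structure

The package implements a two-species (radioiodide I-131 + stable iodide)
compartmental model of iodine biokinetics in pregnancy. The topology has
23 well-mixed compartments: stomach, small intestine, upper/lower large
intestine, feces, blood, thyroid iodide, thyroid organic iodine, iodide in
other tissues, organic iodine in other tissues, salivary glands, gastric
secretory cells, kidneys, urinary bladder, urine, ovaries, uteroplacental
iodide and organic iodine, amniotic-fluid iodide and organic iodine, fetal
(extrathyroidal) iodide, fetal thyroid, and fetal organic iodine. Both
species flow through the same network; amounts are tracked in µmol and
time in days.

Most transfers are first order (flux k·m, k in d⁻¹). The transfers known
to be mediated by the sodium/iodide symporter — blood→thyroid iodide,
blood→thyroid organic, blood→salivary glands, blood→gastric mucosa,
blood→placenta, and fetal iodide→fetal thyroid — are saturable. Each
carrier is parametrised from its linear-regime first-order constant k and
the distribution volume V_d of its source compartment (7 l maternal blood;
50 % of fetal weight for the fetal pool) via

    T_max = K_m · k · V_d        K_m# = K_m · V_d

with the NIS Michaelis constant K_m = 9 µmol l⁻¹. Because the two iodide
species are chemically identical they share the carrier, giving the
competitive rate T₁ = T_max·m₁/(K_m# + m₁ + m₂). In the trace regime
(m ≪ K_m#) every carrier reduces exactly to k·m, so the saturable model
and the all-first-order model coincide — the basis of the linear-regime
equivalence tests. Intestinal iodide absorption stays first order: the
iodine distribution volume of gut content is not meaningfully defined.

Parameters are tabulated at post-conceptional weeks 0, 3, 8, 12, 16, 24,
32, 36, 38 and are frozen at the exposure week for a whole run; there is
no interpolation between weeks (gestational trajectories between the
tabulated ages would be invented, not derived). Fetal transfer routes
carry k = 0 before week 12, the age at which the fetal gland starts
concentrating iodide.

## Radioactive decay and dose

Decay (λ = ln 2 / 8.02 d⁻¹) removes radioiodine inside the thyroid
compartments, and the decayed amount is accumulated in one sink per gland
(maternal: thyroid iodide + organic; fetal: fetal thyroid). This
"thyroid-scope" decay is the formulation behind the model's published
dose tables and is the package default; `decay_scope="all"` applies decay
in every compartment (physically complete — elsewhere the nuclide decays
too, it merely contributes no thyroid dose) and lowers committed doses by
about 5 % by removing recirculating activity. Under thyroid-scope decay
the conserved quantity is live radio total + gland sinks; under `"all"`
the live total follows exp(−λt) exactly. Both balances are property-tested.

The committed β dose is the number of decays in the sink (Avogadro ×
µmol), times the mean β energy 0.18 MeV/decay, divided by the gland mass;
mGy equals mSv at quality factor 1. The γ contribution uses the
Marinelli/Quimby form with the Hine geometric factor ḡ = 3πr (valid for
sphere radii r < 10 cm, asserted): the γ fraction of the total dose is
f = 0.0346·Ƭ·ḡ/(73.8·Ē_β + 0.0346·Ƭ·ḡ) with Ƭ = 2.2 R mCi⁻¹ h⁻¹, and the
total dose is β/(1 − f) — the C_max·T_eff prefactor cancels in f and is
never needed, as the absolute dose always comes from the decay sink. At
the maternal lobe radii (1.27–1.364 cm) f is 6.4–6.9 %; the alternative
composition β·(1+f) was rejected because f is defined as the γ share *of
the total*. Model-to-model comparisons (saturable vs first-order) use the
β-only dose, where gland geometry cancels.

Committed doses are reported at the simulation horizon, default 100 d
(≈ 12 effective half-lives in the gland): the linear-regime committed dose
is then within 0.005 % of its t→∞ value, against 0.7 % low at 60 d. An
`at_time` option reports dose accrued to any earlier time.

## Wolff–Chaikoff switch

The uptake block engages when a gland's cumulative carrier influx of
iodine (both species, all routes into that gland) since the exposure
started exceeds the saturation increment — 350 µg (2.7581 µmol) above
basal content for the mature gland. The trigger uses influx-since-start
rather than net content because the model carries no 8,000 µg basal pool;
over the minutes-scale onset times, gland efflux is negligible, so the two
readings coincide. While the block is active every carrier flow *into*
that gland is gated to zero (both species, both maternal routes); efflux
and first-order flows continue. Placental, salivary and gastric carriers
are never gated.

Escape from the block is nominally 36 h after switch-on; because the
cumulative-uptake condition still holds at that moment (the counter never
decreases), the gland re-saturates instantly and the block effectively
persists for the rest of a single-bolus scenario. This reading — rather
than resetting the saturation counter at escape — was adopted because it
reproduces the model's published blocked-dose values across pregnancy
(e.g. week 24, 100 mg: 3.16 mSv) while the reset variant roughly doubles
them through repeated escape-and-reblock cycles.

No saturation amount is reported for the fetal gland. The default assumes
the block engages at the same *fraction* of gland iodine content as in the
adult (+4.375 %), with the fetal content estimated as the adult
concentration (500 µg per g of tissue) times the fetal gland weight. The
threshold is exposed as a configuration scalar (`wc.threshold_fetal_umol`)
and can be calibrated against observed onset times; fetal with-WC outputs
should be read as threshold-calibrated. With the default, fetal onset
times at 100 mg fall from ≈ 138 min (week 12) to ≈ 32 min at term,
matching the expected 126 → 30 min pattern within ~10 %.

## Efficacy analysis

Efficacy(D) = 1 − dose(blocked)/dose(unblocked), computed per gland from
paired simulations at the reference intake of 700 kBq (the activity
producing ≈ 300 mSv in a non-pregnant adult thyroid — the occupational
ceiling this scenario represents). The default sweep is 25 log-spaced
doses over the studied range 0.1–1000 mg. Dose–effect curves are fitted
with the Hill function E = a·D^b/(D50^b + D^b) by bounded least squares
(fit in log₁₀ D50; deterministic initialisation: b₀ = 1, D50 at the dose
nearest half-max). The amplitude is pinned at a = 1 by default: the
reference ED₅₀/Hill-coefficient values for this model are reproducible
only under that convention (their printed at-100-mg efficacies follow
from the printed (ED₅₀, b) pairs with a = 1 to ~0.3 %). A free-amplitude
fit (`amplitude=None`) is available; since simulated plateaus reach only
≈ 0.97–0.99, it yields a slightly smaller D50 and shallower slope.
ED₅₀ is the fitted D50 (dose at half of a). Non-convergence is flagged in
the returned fit, not raised.

## Numerical choices

Rate constants span 0.0063–18,000 d⁻¹, so the system is stiff; it is
integrated with LSODA (BDF available) at rtol 1e-8 and per-block absolute
tolerances scaled to each species' total (down to ~1e-24 µmol for
trace radioiodine). Halving the tolerances changes committed doses by
< 0.1 % (tested). Integration is segmented at bolus administration times
and Wolff–Chaikoff switch events; switch-on is located by the solver's
root-finding on the cumulative-influx counters, which are carried as
auxiliary ODE states alongside the two decay sinks (50 states total).
Boluses are instantaneous additions to maternal blood, simultaneous by
default. Carrier rates clip negative amounts to zero inside the flux
evaluation only; non-negativity of the integrated states is
property-tested under random carrier-parameter perturbations. The
first-order reference model reuses the carrier code path with K_m#
inflated by 1e12 (slope k held), and is independently checked against a
closed-form matrix-exponential solution of the linear system.

## Known limitations

* Single acute intravenous boluses only: no inhalation/ingestion
  front-end, no continuous exposure, no repeated stable-iodine dosing.
* Parameters are fixed at the exposure week; no within-run gestational
  progression, no interpolation between tabulated weeks, no individual
  variability (e.g. dietary down-regulation of uptake).
* The fetal Wolff–Chaikoff threshold is an assumption (see above), so
  fetal with-WC doses and ED₅₀ values are threshold-calibrated; fetal
  competition-only results do not depend on it.
* Equivalent dose only; no tissue weighting (effective dose) and no
  dosimetry for organs other than the thyroid.
* The saturation (>1e14 Bq) regime is far outside radiologically
  plausible intakes and is exercised mainly as a consistency check of the
  carrier kinetics.
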