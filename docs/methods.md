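# Methods

## Model structure

The model is a well-mixed compartment description of one glutamatergic
synapse enwrapped by an astrocytic perisynaptic cradle (PsC). Six
compartments: synaptic terminal (internal K⁺/Na⁺ clamped), perisynaptic
extracellular space (PsECS), the cradle, the thin astrocyte process, the
astrocyte soma and the global ECS (GECS). Soma and GECS concentrations are
clamped boundaries. Five concentrations are dynamic — cradle K⁺, Na⁺,
Ca²⁺ and PsECS K⁺, Na⁺ — plus the neuron voltage, three HH gates, and the
EAAT flux state. PsECS Ca²⁺ is clamped at 1.5 mM; extracellular glutamate
is never a state variable (each spike's 1 mM release binds instantaneously
and appears only as an EAAT flux impulse).

Geometry is cylindrical. Because the cradle wraps roughly half of the
synapse, all cradle-, PsECS- and synapse-facing lateral areas and shell
volumes carry a factor ½; the process is a full cylinder. Two quantities
(synapse volume, PsECS–GECS interface area) are not derivable from the
listed dimensions and are carried as literals. Volumes are in litres so
that I/(zF·Vol) is a molar rate.

Sign convention throughout: a positive transmembrane current carries the
ion out of its intracellular source compartment into the PsECS; the ODE
assembly recovers the standard five-equation bookkeeping under this
convention, and a mole-conservation audit (cradle+PsECS mole rate equals
the signed boundary fluxes) is checked in the test suite at ~1e-13
relative.

The astrocyte membrane potential V_A is held constant (the cradle is
isopotential with the syncytium); the PsC therefore has no voltage
equation, and all astrocyte pathway currents respond only to
concentrations.

## Pathways

* **EAAT1/2** — rapid glutamate binding, slow transport: dJ/dt = −J/τ with
  an additive impulse J₀ = 0.06 M/s per spike (impulses stack, which is
  what makes the Na⁺ load frequency-dependent). J is the PsECS depletion
  rate, so I_NaEAAT = −J·F·Vol_PsECS; K⁺ counter-transport is exactly
  −I_NaEAAT/3. τ is not given by the source tables; it is set by requiring
  the full-decay integral of one impulse, J₀τ, to equal the stated 3 mM
  per-spike Na⁺ uptake, giving τ = 50 ms. (The nominal 30 ms transporter
  cycle cannot move 3 mM at J₀ = 0.06 M/s — the maximum would be 1.8 mM —
  so the full-integral reading is the only consistent one.)
* **NCX** — the standard two-exponential antiporter form with γ = 0.5 and
  Ī = 1 A/m²; I_CaNCX = −⅔·I_NaNCX. Its zero crossing coincides
  analytically with E_NCX = 3E_Na − 2E_Ca, which the tests verify to
  <0.5 mV.
* **NKA** — Hill-saturating form, (Naᵢ/(Naᵢ+10 mM))³·(Kₒ/(Kₒ+1.5 mM))²,
  exact 3:2 stoichiometry. The neuron pump uses its clamped internal Na⁺.
* **Kir and backgrounds** — linear in driving force with concentration-
  dependent Nernst potentials (valence-free RT/F form for every ion, as in
  the source formulation; a z-aware option exists). A √[K]ₒ Kir variant is
  available behind a switch but is off by default since no richer form is
  specified.
* **PsECS→GECS leak** — purely diffusive, g·E·SA with E the PsECS/GECS
  Nernst-like potential and no membrane-potential term.
* **Process transport** — canonical Poole–Frenkel form: ohmic prefactor in
  ΔV/l times exp[−Q(φ_w − √(Q|ΔV|/lπε))/k_BT], with ΔV = −V_r because the
  cradle is isopotential with the soma. The barrier lowering uses |ΔV|;
  the sign of the current follows the prefactor. Hop charge is one
  electron charge for all ions (a z·e option exists). At φ_w = 0.267 eV
  and 310 K the zero-field escape factor is e⁻¹⁰, which semi-isolates the
  cradle; this is the mechanism that permits microdomains.
* **Neuron** — classic rest-at-zero HH gating with the tabulated reversal
  potentials as printed, plus leak, two concentration-dependent background
  channels and the pump. The voltage-gated Na⁺ current includes the h gate
  (m³h); the strictly-as-printed m³ form is available behind a switch.

## Parameters that matter most

| Parameter | Default | Units | Role |
|---|---|---|---|
| J₀ | 0.06 | M/s | EAAT impulse height; with τ fixes the 3 mM/spike load |
| τ_EAAT | 0.05 | s | EAAT decay; calibrated, not tabulated |
| Ī_NCX, γ | 1, 0.5 | A/m², – | exchanger scale and barrier partition |
| P_NKA,max (astro) | 1e-6 | mol/(m²·s) | cradle Na⁺ extrusion / K⁺ import |
| g_Kir | 144 | S/m² | stiff K⁺ coupling of cradle to PsECS |
| φ_w | 0.267 | eV | well depth; e⁻¹⁰ isolation at default |
| K_K, K_Na | 0.018 | S/m | process mobility constants (monovalent) |
| K_Ca | 0.0018 | S/m | set one order of magnitude below the monovalent value because cytosolic Ca²⁺ mobility is strongly reduced by buffering proteins — the same retention argument the model makes for the process |
| g_ECS | 3.3 | S/m² | the only drain of PsECS excursions; sets the slow recovery tail |
| V_A | calibrated, −85.81 | mV | fixed astrocyte potential |

## Resting-state calibration

The published tables do not form a consistent resting state: at the
printed V_A = −80.7 mV the resting Kir efflux (~0.75 A/m²) exceeds the
printed NKA K⁺ import (~0.022 A/m²) thirty-fold, and no **positive**
background conductance can close the K⁺ balance (a passive channel cannot
import K⁺ against its own driving force). The textbook recipe — solve the
background conductance for zero resting flux — is implemented and raises a
calibration error with the residual in exactly these cases. Inflating the
pump instead (tested) creates ion turnovers so large that their stimulus
sensitivity swamps the EAAT signal and destroys the model's headline
behaviour.

The default calibration therefore keeps every printed conductance and pump
rate and closes the system with four small moves:

1. **V_A** is placed where resting Kir+background K⁺ efflux equals the
   printed NKA import: V_A = E_K + 2FP·occ/(g_Kir+g_K) = −85.81 mV. This
   is ~5 mV below the quoted "~−80 mV" but inside the measured astrocyte
   range (−85…−90 mV), and it lands, self-consistently, almost exactly on
   the NCX equilibrium potential at the calibrated resting Ca²⁺ — the
   exchanger idles at rest, as the model narrative requires.
2. **Resting cradle Ca²⁺** is the joint fixed point of NCX and the process
   Ca²⁺ pathway: 83.1 nM, inside the 50–80 nM range the source assumes.
   The resting NCX is then marginally in **forward** mode
   (−1.4×10⁻⁶ A/m²), so stimulation produces a literal sign flip.
3. The **astrocyte Na⁺ background conductance** is solved from the Na⁺
   balance (0.229 S/m² versus 0.976 printed) — the one knob the source
   itself describes as chosen for zero steady-state flux.
4. The **neuron** rests at its leak reversal (+10.6 mV in the rest-frame;
   once each ion's flux is zeroed, the leak is the only charge carrier, so
   V_rest = E_L). The pump rate follows from the K⁺ balance and the Na⁺
   background conductance from the Na⁺ balance.

The result is an exact fixed point: a zero-stimulus 10 s run drifts at
machine precision, and every per-membrane resting flux is < 1e-15 M/s.

## Stimulation protocol

The HH neuron with the printed reversal values cannot fire sustained
10–30 Hz under constant current (one onset spike, then block — verified up
to 50 A/m²). The protocol therefore delivers brief current pulses (1 ms)
at the target rate; the amplitude is found by bisection to 1:1 entrainment
and verified to ±0.5 Hz. Pulses are kept near threshold deliberately:
injected charge leaves the neuron as K⁺ into the ~2×10⁻¹⁸ L PsECS, so an
over-driven stimulus floods the ECS by itself (3 ms × 20 A/m² pulses add
tens of mM per pulse). Constant-current and external spike-event drives
remain available; the event drive replaces the neuron entirely and is what
the deterministic test fixtures use.

## Numerics

Forward Euler, Δt = 10 µs (the reference scheme), compiled with numba;
states recorded every 100 steps by default. Spikes are upward crossings of
rest+50 mV with a 2 ms refractory guard, and the EAAT impulse lands on the
same step. Gates are clamped to [0,1]; concentrations are floored at
1e-12 M (a floored step flags the run non-physiological; it never triggers
in the shipped protocols). HH rate singularities use the analytic limits.
Halving Δt moves the endpoint of a stimulated protocol by <0.1%
(first-order convergence, checked in the suite with a fixed spike-event
drive so both runs see identical event times). Runs are bit-deterministic
for a fixed configuration; the only randomness in the package is the
optional jitter of generated spike-train fixtures, seeded explicitly.

Problem sizes: the test suite uses 2 s probe runs for stimulus
calibration, a 10 s rest run, and 17 s protocols (2 s settle, 10 s
stimulus, 5 s recovery); `scripts/acceptance.py` uses 6 s settle, 10 s
stimulus, 10 s recovery at 10/20/30 Hz, ~2.6M Euler steps per run.

## What the spike-train fixture does and does not emulate

The generated trains reproduce the timing statistics of the neuron drive
(regular, optionally jittered) and trigger identical EAAT impulses, but
carry none of the neuron's K⁺ efflux / Na⁺ influx into the PsECS. Tests
that pass on the fixture therefore validate the astrocyte-side transport
arithmetic, not the coupled ECS dynamics; the protocol tests use the full
neuron.

## Known limitations

* **Late-time ECS drift under long stimulation.** Recaptured spike K⁺
  costs 1.5 Na⁺ pushed into the PsECS (3:2 pump), and the printed GECS
  leak drains PsECS excursions on a ~100 s timescale. Over a full 60 s
  stimulus the accumulating PsECS Na⁺ weakens (Naᵢ/Naₒ)³ until the NCX can
  swing back toward forward mode at low rates: the Ca²⁺ microdomain is
  then an early-stimulus phenomenon. On 10 s stimulation all three
  microdomains are sustained and strictly rate-ordered.
* **Slow K⁺ recovery.** After stimulus offset, cradle K⁺ tracks the PsECS
  through the stiff Kir coupling (equilibrium ratio e^{|V_A|F/RT} ≈ 25)
  and keeps rising for several seconds before declining; full relaxation
  is leak-limited (~100 s). Na⁺ and Ca²⁺ recover much faster (pump- and
  NCX-driven).
* No glutamate, H⁺ or voltage dependence of EAAT; no ER or PMCA; no Cl⁻;
  no spatial resolution of the process (single lumped element); neuron
  internal concentrations clamped. Microdomain magnitudes therefore
  overstate what a cradle with additional efflux pathways would sustain;
  the qualitative mechanism (EAAT load → NCX reversal → trapped Ca²⁺) is
  the tested claim.
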