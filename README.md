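# pscradle

Compartmental simulation of ion microdomain formation at the astrocyte
**perisynaptic cradle** (PsC) — the thin astrocytic sheet that enwraps a
glutamatergic synapse.

## The problem

Astrocyte processes near synapses are too thin to hold an endoplasmic
reticulum, yet they show localized Ca²⁺ signals. The model implemented here
tests a minimal mechanism: neuronal glutamate release drives Na⁺ into the
cradle through the glutamate transporters (EAAT1/2); negatively charged
membrane lipids in the thin process trap cations in potential wells
(Poole–Frenkel well-hopping conduction), so the Na⁺ cannot diffuse to the
soma and a **Na⁺ microdomain** forms; the Na⁺/Ca²⁺ exchanger (NCX) then
reverses and imports Ca²⁺, which is likewise trapped — a **Ca²⁺
microdomain**, with EAAT, NKA and NCX as the only required machinery.

The package is for computational neuroscientists who want a tested,
reproducible implementation of this model: a library (`import pscradle`),
a CLI (`pscradle run|calibrate|sweep|summarize`), and narrative examples.

## The model

Six compartments: synaptic terminal, perisynaptic ECS (PsECS), cradle
(PsC), astrocyte process, soma and global ECS (the last two clamped).
Five dynamic concentrations obey, e.g. for cradle K⁺ and Ca²⁺:

```
d[K⁺]PsC/dt  = −(I_Kir + I_KNKA + I_KEAAT + I_KB + I_KPF) / (z_K F Vol_PsC)
d[Ca²⁺]PsC/dt = −(I_CaNCX + I_CaPF) / (z_Ca F Vol_PsC)
```

with pathway currents

* EAAT1/2: per spike, flux jumps by J₀ and decays, dJ/dt = −J/τ + J₀ δ(t−t_sp);
  one event moves 3 mM Na⁺ (and counter-transports 1 mM K⁺), I_KEAAT = −I_NaEAAT/3;
* NCX (3 Na⁺ : 1 Ca²⁺):
  I_NaNCX = Ī·[(Naᵢ/Naₒ)³ e^{γFV/RT} − (Caᵢ/Caₒ) e^{(γ−1)FV/RT}]·SA, I_CaNCX = −⅔ I_NaNCX;
* NKA: P = P_max (Naᵢ/(Naᵢ+K_Na))³ (Kₒ/(Kₒ+K_K))², 3 Na⁺ out : 2 K⁺ in;
* Kir and lumped backgrounds: g (V − E_ion) with concentration-dependent Nernst E;
* process hopping: I = K (ΔV/l) exp[−Q(φ_w − √(Q|ΔV|/lπε))/k_BT]·CSA_P, with
  ΔV = −V_r, V_r = (RT/F) ln([i]_soma/[i]_PsC);
* a Hodgkin–Huxley presynaptic neuron supplies spikes and K⁺/Na⁺ fluxes.

Integration is forward Euler at Δt = 10 µs, as in the reference study.
See `docs/methods.md` for assumptions, calibration and limitations.

## Worked example

```sh
python examples/frequency_sweep.py
```

prints (10 s stimulation per rate):

```
rate    K+ plateau    Na+ plateau    Ca2+ plateau
10 Hz    +18.99 mM     +12.12 mM        +217 nM
20 Hz    +36.47 mM     +26.37 mM        +680 nM
30 Hz    +52.59 mM     +42.71 mM       +1555 nM
```

Each row is the plateau elevation of the three cradle microdomains above
baseline (K⁺ 100 mM, Na⁺ 15 mM, Ca²⁺ 83 nM): faster firing stacks more
EAAT impulses and neuronal K⁺ load, and all three microdomains deepen.
`examples/ncx_reversal_protocol.py` shows the mechanism: the NCX current
density flips from −1.4×10⁻⁶ A/m² at rest (weak forward mode) to
+8.7×10⁻⁶ A/m² during 10 Hz drive (reverse mode, Ca²⁺ import), raising
cradle Ca²⁺ from 83 nM to ~300 nM.

The same protocol from the shell:

```sh
pscradle run --rate 10 --duration 10 --out runs/
pscradle summarize runs/run_rate10
```

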