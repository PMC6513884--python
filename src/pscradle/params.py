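"""Model parameters, baseline state, and small analytic utilities.

Every symbol appearing in the implemented equations lives here, in
:class:`~pscradle.geometry.Geometry`, or in the state containers of the
simulation engine.  Defaults reproduce the reference parameter set
(astrocyte variables/parameters and neuron parameters); quantities the
reference leaves implicit (EAAT decay time, resting-balance values) are
produced by :mod:`pscradle.calibrate`.

Sign convention used across the package: a positive transmembrane current
carries the ion OUT of its intracellular source compartment (cradle or
synaptic terminal) INTO the perisynaptic extracellular space.
"""

import math
from dataclasses import dataclass, field, replace, asdict

from .constants import PhysicalConstants, CONSTANTS
from .errors import DomainError, ValidationError


@dataclass(frozen=True)
class ModelVariants:
    """Switches between the literal published formulation and standard forms.

    The defaults are the forms used for all headline results; the alternates
    exist for sensitivity checks.
    """

    #: Include the inactivation gate h in the neuronal Na+ current (m^3 h).
    #: The printed current omits h; the standard HH model includes it.
    na_channel_h_gate: bool = True
    #: Include the astrocyte background K+ current in the cradle K+ balance
    #: (the printed cradle ODE omits it, but the background efflux is what
    #: restores the K+ baseline after stimulation).
    background_k_in_psc: bool = True
    #: Scale the Kir conductance by sqrt([K+]PsECS / [K+]PsECS,rest).
    kir_sqrt_k_out: bool = False
    #: Use z*e instead of e for the hopping charge of divalent ions in the
    #: Poole-Frenkel current.
    pf_charge_valence: bool = False
    #: Include the valence in channel Nernst potentials (the printed channel
    #: formulas use RT/F for all ions, including Ca2+).
    nernst_valence: bool = False


@dataclass(frozen=True)
class ModelParameters:
    """All physical constants, conductances and kinetic parameters.

    Units: conductances S/m^2, pump rates mol/(m^2 s), concentrations M,
    voltages V, Poole-Frenkel channel constants S/m, EAAT flux M/s.
    """

    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    variants: ModelVariants = field(default_factory=ModelVariants)

    # --- astrocyte membrane ---
    v_a: float = -0.0807           # astrocyte membrane potential (V), held fixed
    g_kir: float = 144.0           # Kir channel conductance
    g_k_bg: float = 17.9364        # astrocyte K+ background conductance
    g_na_bg: float = 0.9761        # astrocyte Na+ background conductance
    p_nka_max: float = 0.1e-5      # astrocyte NKA max pump rate, mol/(m^2 s)
    k_nai: float = 10e-3           # NKA Na+ half-saturation (M)
    k_ke: float = 1.5e-3           # NKA external-K+ half-saturation (M)
    i_bar_ncx: float = 1.0         # NCX exchanger conductance, A/m^2
    gamma_ncx: float = 0.5         # NCX energy-barrier partition parameter
    j0_eaat: float = 0.06          # max EAAT1/2 flux rate, M/s
    tau_eaat: float = 0.05         # EAAT flux decay time constant (s); = 3 mM / J0
    g_ecs_leak: float = 3.3        # PsECS->GECS leak conductance

    # --- process (Poole-Frenkel) ---
    phi_w: float = 0.267           # well activation energy, eV
    k_pf_k: float = 0.018          # K+ channel constant, S/m
    k_pf_na: float = 0.018         # Na+ channel constant, S/m
    #: Ca2+ channel constant.  Not part of the published table; set an order
    #: of magnitude below the monovalent value because cytosolic Ca2+
    #: mobility is strongly reduced by buffering proteins.
    k_pf_ca: float = 0.0018

    # --- valences ---
    z_k: int = 1
    z_na: int = 1
    z_ca: int = 2

    # --- baseline / clamped concentrations (M) ---
    k_psc_0: float = 0.1
    na_psc_0: float = 0.015
    ca_psc_0: float = 100e-9
    k_psecs_0: float = 0.004
    na_psecs_0: float = 0.135
    ca_psecs: float = 1.5e-3       # clamped throughout a run
    k_gecs: float = 0.004
    na_gecs: float = 0.135
    ca_gecs: float = 1.5e-3
    k_soma: float = 0.1
    na_soma: float = 0.015
    ca_soma: float = 100e-9
    glu_ecs: float = 25e-9
    glu_psc: float = 1.5e-3
    h_psc: float = 60e-9
    h_psecs: float = 40e-9

    # --- neuron (HH rest-at-zero frame) ---
    c_m: float = 0.01              # membrane capacitance, F/m^2
    g_k_neu: float = 360.0
    g_na_neu: float = 1200.0
    g_leak_neu: float = 3.0
    g_k_bg_neu: float = 1.0522
    g_na_bg_neu: float = 2.3217
    e_k_neu: float = -0.12
    e_na_neu: float = 0.115
    e_leak_neu: float = 0.010613
    p_nka_max_neu: float = 3.7863e-8   # magnitude; printed with a direction sign
    k_nai_neu: float = 10e-3
    k_ke_neu: float = 1.5e-3
    k_syn: float = 0.1             # clamped internal K+ (M)
    na_syn: float = 0.015          # clamped internal Na+ (M)

    # --- spike handling ---
    spike_threshold_offset: float = 0.05   # V above neuron rest
    spike_refractory: float = 0.002        # s

    # --- legacy fitting parameters: parsed and stored, used in no equation ---
    alpha_eaat: float = 0.0032     # A/m^2
    beta_eaat: float = 28.8        # 1/mV
    r_g: float = 5e-7              # 1/M
    s_g: float = 9e-6              # M

    # --- filled by calibration (see pscradle.calibrate) ---
    v_rest_neu: float = 0.010613   # neuron resting potential = e_leak_neu
    ca_psc_rest: float = 100e-9    # resting cradle Ca2+ (joint NCX/PF fixed point)
    calibrated: bool = False

    def __post_init__(self):
        if not (0.0 < self.gamma_ncx < 1.0):
            raise ValidationError(f"gamma_ncx must be in (0,1), got {self.gamma_ncx}")
        if (self.z_k, self.z_na, self.z_ca) != (1, 1, 2):
            raise ValidationError("ion valences must be (1, 1, 2) for (K, Na, Ca)")
        for name in ("k_psc_0", "na_psc_0", "ca_psc_0", "k_psecs_0",
                     "na_psecs_0", "ca_psecs", "k_gecs", "na_gecs",
                     "k_soma", "na_soma", "ca_soma", "k_syn", "na_syn"):
            if getattr(self, name) <= 0.0:
                raise ValidationError(f"concentration {name} must be positive")

    def evolve(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def nernst_potential(conc_out: float, conc_in: float, valence: int = 1,
                     T: float | None = None,
                     constants: PhysicalConstants = CONSTANTS) -> float:
    """Equilibrium (Nernst) potential (RT / zF) ln(out/in) in volts.

    The published channel formulas use ``z = 1`` for every ion (including
    Ca2+); pass ``valence=2`` where the proper divalent form is wanted (e.g.
    the Ca2+ term of the NCX equilibrium potential).

    Raises
    ------
    DomainError
        If either concentration is non-positive.
    """
    if conc_out <= 0.0 or conc_in <= 0.0:
        raise DomainError(
            f"non-positive concentration in Nernst potential: "
            f"out={conc_out!r}, in={conc_in!r}"
        )
    if valence == 0:
        raise DomainError("valence must be non-zero")
    R, F = constants.R, constants.F
    temp = constants.T if T is None else T
    return (R * temp) / (valence * F) * math.log(conc_out / conc_in)


def ncx_equilibrium_potential(e_na: float, e_ca: float, n: float = 3.0) -> float:
    """Reversal potential of an n Na+ : 1 Ca2+ exchanger.

    E_NCX = (n E_Na - 2 E_Ca) / (n - 2); for the physiological stoichiometry
    n = 3 this is 3 E_Na - 2 E_Ca.  At the membrane potential E_NCX the
    exchanger carries zero net current; above it the exchanger runs in
    reverse (Na+ out, Ca2+ in).

    Raises
    ------
    DomainError
        If n == 2 (the expression degenerates).
    """
    if n == 2:
        raise DomainError("NCX stoichiometry n=2 makes the equilibrium potential undefined")
    return (n * e_na - 2.0 * e_ca) / (n - 2.0)


def calibrate_eaat_tau(j0: float, target_uptake: float = 3e-3) -> float:
    """EAAT decay time constant from the per-spike uptake requirement.

    One glutamate-release event sets the transporter flux to ``j0`` and lets
    it decay exponentially; the total transported charge of the event is the
    full-decay integral ``j0 * tau``.  Choosing ``tau = target / j0`` makes a
    single event move exactly ``target_uptake`` (3 mM of Na+ out of the
    PsECS, and by the 3:1 stoichiometry 1 mM of K+ into it).
    """
    if j0 <= 0.0:
        raise ValidationError(f"j0 must be positive, got {j0}")
    if target_uptake < 0.0:
        raise ValidationError(f"target_uptake must be >= 0, got {target_uptake}")
    return target_uptake / j0
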