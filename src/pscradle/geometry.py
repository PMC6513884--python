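"""Compartment geometry of the perisynaptic cradle model.

The model idealises a single synapse enwrapped by an astrocytic sheet (the
perisynaptic cradle, PsC) as a set of coaxial cylindrical shells:

* the synaptic bouton — a cylinder of radius ``r_syn``;
* the perisynaptic extracellular space (PsECS) — the thin shell between the
  bouton and the inner face of the cradle;
* the cradle itself — the shell between ``r_ips`` and ``r_eps``;
* the astrocyte process — a long thin full cylinder connecting cradle and soma.

Because an astrocyte cradle enwraps roughly half of a synapse's perimeter, all
cradle-, PsECS- and synapse-facing lateral areas and shell volumes carry a
factor 1/2 ("half-wrap"); the process is a complete cylinder.

Two quantities cannot be reconstructed from the listed dimensions with any
simple cylindrical construction and are carried as literal constants:
the synapse volume ``vol_syn`` and the PsECS-to-global-ECS interface area
``sa_psecs_gecs``.

Volumes are expressed in litres (1 m^3 = 1000 L) so that dividing a current by
``z * F * Vol`` yields a concentration rate in M/s.
"""

import math
from dataclasses import dataclass

from .errors import ValidationError

M3_TO_L = 1000.0

#: Synapse volume (L), carried from the reference morphology; not derivable
#: from the listed synapse dimensions.
VOL_SYN_LITERAL = 8.5883e-16

#: Interface area between perisynaptic and global extracellular space (m^2);
#: carried as a literal for the same reason.
SA_PSECS_GECS_LITERAL = 1.5715e-14


@dataclass(frozen=True)
class Geometry:
    """Derived compartment geometry.

    Lengths in metres, areas in m^2, volumes in litres.
    """

    # input lengths
    r_ips: float
    r_eps: float
    l_ps: float
    r_p: float
    l_p: float
    r_syn: float
    l_syn: float
    # derived areas
    csa_ps: float
    sa_ps: float
    csa_p: float
    sa_p: float
    csa_syn: float
    sa_syn: float
    sa_psecs_gecs: float
    # derived volumes
    vol_ps: float
    vol_p: float
    vol_syn: float
    vol_psecs: float

    @property
    def d_ips(self) -> float:
        return 2.0 * self.r_ips

    @property
    def d_eps(self) -> float:
        return 2.0 * self.r_eps

    @property
    def d_p(self) -> float:
        return 2.0 * self.r_p

    @property
    def d_syn(self) -> float:
        return 2.0 * self.r_syn


def derive_geometry(
    r_ips: float = 150e-9,
    r_eps: float = 250e-9,
    l_ps: float = 300e-9,
    r_p: float = 50e-9,
    l_p: float = 25e-6,
    r_syn: float = 135e-9,
    l_syn: float = 300e-9,
    vol_syn: float = VOL_SYN_LITERAL,
    sa_psecs_gecs: float = SA_PSECS_GECS_LITERAL,
) -> Geometry:
    """Derive all compartment areas and volumes from the primitive lengths.

    Parameters default to the reference morphology (perisynaptic internal /
    external radius 150/250 nm, length 300 nm; process radius 50 nm, length
    25 um; synapse radius 135 nm, length 300 nm).

    Raises
    ------
    ValidationError
        If any length is non-positive (a zero-thickness shell ``r_ips ==
        r_eps`` is allowed and yields a zero cradle volume) or the radii are
        ordered inconsistently (``r_syn <= r_ips <= r_eps`` is required).
    """
    lengths = {
        "r_ips": r_ips, "r_eps": r_eps, "l_ps": l_ps,
        "r_p": r_p, "l_p": l_p, "r_syn": r_syn, "l_syn": l_syn,
    }
    bad = [k for k, v in lengths.items() if not (v > 0.0) or not math.isfinite(v)]
    if bad:
        raise ValidationError(f"non-positive or non-finite lengths: {', '.join(bad)}")
    if r_ips > r_eps:
        raise ValidationError(
            f"perisynaptic internal radius ({r_ips}) exceeds external radius ({r_eps})"
        )
    if r_syn > r_ips:
        raise ValidationError(
            f"synapse radius ({r_syn}) exceeds perisynaptic internal radius ({r_ips})"
        )

    half = 0.5  # half-wrap convention for cradle/PsECS/synapse lateral quantities
    csa_ps = half * math.pi * r_ips ** 2
    sa_ps = half * 2.0 * math.pi * r_ips * l_ps
    vol_ps = half * math.pi * (r_eps ** 2 - r_ips ** 2) * l_ps * M3_TO_L
    vol_psecs = half * math.pi * (r_ips ** 2 - r_syn ** 2) * l_ps * M3_TO_L

    csa_p = math.pi * r_p ** 2
    sa_p = 2.0 * math.pi * r_p * l_p
    vol_p = math.pi * r_p ** 2 * l_p * M3_TO_L

    csa_syn = half * math.pi * r_syn ** 2
    sa_syn = half * 2.0 * math.pi * r_syn * l_syn

    return Geometry(
        r_ips=r_ips, r_eps=r_eps, l_ps=l_ps, r_p=r_p, l_p=l_p,
        r_syn=r_syn, l_syn=l_syn,
        csa_ps=csa_ps, sa_ps=sa_ps, csa_p=csa_p, sa_p=sa_p,
        csa_syn=csa_syn, sa_syn=sa_syn, sa_psecs_gecs=sa_psecs_gecs,
        vol_ps=vol_ps, vol_p=vol_p, vol_syn=vol_syn, vol_psecs=vol_psecs,
    )
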