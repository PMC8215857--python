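"""Stimulation modes and their current patterns on the electrode array.

A biphasic charge-balanced pulse at a center electrode returns its current
either through the extracochlear casing ground (monopolar, MP), through one
intracochlear sink (bipolar, BP), through two flanking sinks at half current
each (tripolar, TP), or through a fraction sigma intracochlearly with the
remainder extracochlear (partial tripolar, pTP):

    MP  = pTP(sigma=0),    TP = pTP(sigma=1).

The sink offset n counts the electrodes skipped between the stimulating
contact and each sink (TP+0 = adjacent flanks).  Sinks are pulsed with the
opposite polarity to the center contact.  Only the leading phase is solved
(the network is purely resistive); peak-to-peak values are reported as twice
the single-phase voltage, signed so that the center contact's response is
positive and sink-dominated wires show the polarity inversion seen in
multipolar recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ArrayLayout, CochleaModel, ValidationError, N_ELECTRODES
from .metrics import SIVProfile
from .network import CurrentVector, Network, assemble, solve

__all__ = ["StimulusSpec", "make_currents", "siv_profile", "ConfigurationError"]

MODES = ("MP", "BP", "TP", "pTP")

#: Bench defaults: 800 uA per phase, 32 us phases, centered on contact 8.
DEFAULT_AMPLITUDE_UA = 800.0
DEFAULT_PHASE_US = 32.0
DEFAULT_CENTER = 8


class ConfigurationError(ValidationError):
    """The requested stimulus cannot be realized on the array."""


@dataclass(frozen=True)
class StimulusSpec:
    """One stimulation configuration.

    ``sigma`` is the intracochlear sinking fraction (pTP only; forced to 0
    for MP and 1 for BP/TP).  ``phase_duration_us`` and ``leading_polarity``
    are metadata: the solve is steady-state resistive, and the sign
    convention already fixes the reported polarity.
    """

    mode: str
    center_electrode: int = DEFAULT_CENTER
    sigma: float = 1.0
    n: int = 0
    amplitude_uA: float = DEFAULT_AMPLITUDE_UA
    phase_duration_us: float = DEFAULT_PHASE_US
    leading_polarity: str = "cathodic"
    bp_side: str = "basal"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"unknown mode {self.mode!r} (use {MODES})")
        if not 1 <= self.center_electrode <= N_ELECTRODES:
            raise ConfigurationError(
                f"center electrode {self.center_electrode} is off the array"
            )
        if not 0.0 <= self.sigma <= 1.0:
            raise ConfigurationError("sigma must lie in [0, 1]")
        if self.n < 0:
            raise ConfigurationError("sink offset n must be >= 0")
        if self.leading_polarity not in ("cathodic", "anodic"):
            raise ConfigurationError("leading_polarity must be cathodic|anodic")
        if self.bp_side not in ("apical", "basal"):
            raise ConfigurationError("bp_side must be apical|basal")
        if self.mode == "MP":
            object.__setattr__(self, "sigma", 0.0)
        elif self.mode in ("BP", "TP"):
            object.__setattr__(self, "sigma", 1.0)

    @property
    def effective_sigma(self) -> float:
        """Intracochlear sinking fraction actually applied."""
        return self.sigma

    def sink_electrodes(self) -> tuple[int, ...]:
        """Contacts that sink current intracochlearly for this spec."""
        c, off = self.center_electrode, self.n + 1
        if self.mode == "MP" or (self.mode == "pTP" and self.sigma == 0.0):
            return ()
        if self.mode == "BP":
            # contact numbers increase toward the base
            return (c + off,) if self.bp_side == "basal" else (c - off,)
        return (c - off, c + off)


def _check_on_array(electrode: int) -> None:
    if not 1 <= electrode <= N_ELECTRODES:
        raise ConfigurationError(
            f"sink electrode {electrode} is off the array (valid: 1..{N_ELECTRODES})"
        )


def make_currents(
    spec: StimulusSpec, layout: ArrayLayout, geometry
) -> CurrentVector:
    """Balanced per-node current vector (uA) realizing a stimulus spec.

    Electrodes are ideal point sources snapped to the nearest lumen node
    (exact ties toward the base).  The total over lumen nodes plus the
    ground return is zero for every mode and sigma.
    """
    amp = float(spec.amplitude_uA)
    currents = np.zeros(geometry.n_nodes)

    def node_of(electrode: int) -> int:
        return geometry.nearest_node(layout.electrode_position(electrode))

    currents[node_of(spec.center_electrode)] += amp

    sinks = spec.sink_electrodes()
    for e in sinks:
        _check_on_array(e)
    if spec.mode == "BP":
        currents[node_of(sinks[0])] -= amp
        ground = 0.0
    elif sinks:  # TP, or pTP with sigma > 0
        sink_total = spec.sigma * amp
        for e in sinks:
            currents[node_of(e)] -= sink_total / 2.0
        ground = -(amp - sink_total)
    else:  # MP or pTP(sigma=0)
        ground = -amp
    return CurrentVector(node_currents_uA=currents, ground_current_uA=ground)


def siv_profile(
    model: CochleaModel,
    layout: ArrayLayout,
    spec: StimulusSpec,
    network: Network | None = None,
) -> SIVProfile:
    """Simulate the signed peak-to-peak SIV at the 14 recording wires.

    The leading phase is solved once; V_SI,pp = 2 x (phase voltage) at each
    wire, signed with the center contact's response positive.  Pass a
    pre-assembled ``network`` to amortize factorization over sweeps.
    """
    if network is None:
        network = assemble(model)
    currents = make_currents(spec, layout, model.geometry)
    voltages = solve(network, currents)
    wire_nodes = [
        model.geometry.nearest_node(x) for x in layout.wire_positions
    ]
    v_pp = 2.0 * voltages.voltages_mV[wire_nodes]
    spec_with_pos = _with_center_position(spec, layout)
    return SIVProfile(
        wire_positions=np.asarray(layout.wire_positions, dtype=float),
        values=v_pp,
        stimulus=spec_with_pos,
    )


@dataclass(frozen=True)
class _AnnotatedSpec:
    """Stimulus spec plus the center contact's position, carried as profile
    metadata so metrics can break peak ties toward the stimulation site."""

    spec: StimulusSpec
    center_position: float

    def __getattr__(self, name):
        return getattr(object.__getattribute__(self, "spec"), name)


def _with_center_position(spec: StimulusSpec, layout: ArrayLayout) -> _AnnotatedSpec:
    return _AnnotatedSpec(
        spec=spec, center_position=layout.electrode_position(spec.center_electrode)
    )
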