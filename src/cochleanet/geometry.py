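"""Discretized geometry of the unwrapped cochlea and its electrical elements.

The cochlear duct is modelled as a straight, tapered tube of circular
cross-section ("unwrapped" cochlea): the spiral is uncurled into a line while
the cross-sectional dimensions and their base-to-apex gradient are preserved.
The tube is discretized into equally spaced nodes along its axis.  Each node
carries a transverse (through-the-wall) resistance to the surrounding bath,
and each inter-node segment of saline carries a longitudinal resistance
computed from the local cross-sectional area and the saline conductivity.

Coordinate convention: x = 0 at the basal opening (round window end),
increasing toward the apex.  Cochlear-implant electrodes are numbered
1 (apical) to 16 (basal), so electrode position *decreases* with electrode
number; recording wires are numbered 1 (basal) to 14 (apical).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LumenGeometry",
    "CochleaModel",
    "ArrayLayout",
    "ValidationError",
    "build_lumen",
    "longitudinal_resistances",
    "default_model",
    "default_layout",
    "fluid_column_resistance",
]


class ValidationError(ValueError):
    """A model parameter or configuration is physically or structurally invalid."""


# ---------------------------------------------------------------------------
# Default configuration (the reference "digital bench")
# ---------------------------------------------------------------------------

#: Total lumen length, mm (basal opening to apex).
DEFAULT_LENGTH_MM = 32.0
#: Lumen diameter at the basal opening, mm (linear-taper stand-in for the
#: digitized human cross-section profile).
DEFAULT_BASE_DIAMETER_MM = 2.0
#: Lumen diameter at the apex, mm.
DEFAULT_APEX_DIAMETER_MM = 1.0
#: Discretization step, mm.  Chosen so that electrode (~1 mm pitch) and wire
#: (2 mm pitch) positions land exactly on nodes.
DEFAULT_STEP_MM = 0.25
#: Conductivity of 1 % w/v NaCl (~0.171 mol/L) at 25 degC, S/m.
DEFAULT_CONDUCTIVITY_S_PER_M = 1.6
#: Transverse (cross-wall) resistance at every node, ohm.  47 kOhm discrete
#: resistors electrically mimic the bony-wall current pathway of a real
#: cochlea as judged by agreement with in-vivo EFI profiles.
DEFAULT_TRANSVERSE_R_OHM = 47_000.0
#: Basal opening fluid stub: length of the open saline column from the last
#: lumen node to the bath, mm.
BASAL_STUB_LENGTH_MM = 2.0
#: Apical flushing tubing: 0.011-inch bore, assumed 20 mm effective length.
APICAL_TUBE_BORE_MM = 0.011 * 25.4
APICAL_TUBE_LENGTH_MM = 20.0

#: Electrode pitch of the 16-contact intracochlear array, mm.
DEFAULT_ELECTRODE_PITCH_MM = 1.0
#: Recording wires: one every 2 mm, the first 1 mm from the basal opening.
WIRE_SPACING_MM = 2.0
FIRST_WIRE_MM = 1.0
N_ELECTRODES = 16
N_WIRES = 14
#: Electrode 8 of the array is aligned with recording wire 8.
ALIGN_ELECTRODE = 8
ALIGN_WIRE = 8


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LumenGeometry:
    """Discretized tapered lumen.

    Parameters
    ----------
    node_positions
        Axial positions, mm from the basal opening; uniform, strictly
        increasing, starting at 0.
    cross_sectional_areas
        Lumen cross-section at each node, mm^2, all positive.
    """

    node_positions: np.ndarray
    cross_sectional_areas: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.node_positions, dtype=float)
        areas = np.asarray(self.cross_sectional_areas, dtype=float)
        object.__setattr__(self, "node_positions", pos)
        object.__setattr__(self, "cross_sectional_areas", areas)
        if pos.ndim != 1 or pos.size < 2:
            raise ValidationError("need at least two lumen nodes")
        if areas.shape != pos.shape:
            raise ValidationError("one area per node required")
        if abs(pos[0]) > 1e-12:
            raise ValidationError("node positions must start at 0")
        steps = np.diff(pos)
        if np.any(steps <= 0):
            raise ValidationError("node positions must be strictly increasing")
        if np.ptp(steps) > 1e-9:
            raise ValidationError("node spacing must be uniform to 1e-9 mm")
        if np.any(areas <= 0):
            raise ValidationError("cross-sectional areas must be positive")

    @property
    def step(self) -> float:
        """Node spacing, mm."""
        return float(self.node_positions[1] - self.node_positions[0])

    @property
    def total_length(self) -> float:
        """Lumen length, mm."""
        return float(self.node_positions[-1])

    @property
    def n_nodes(self) -> int:
        return int(self.node_positions.size)

    def nearest_node(self, x_mm: float, *, warn: bool = True) -> int:
        """Index of the node nearest to ``x_mm``; exact ties snap basally.

        Positions that do not coincide with a node (beyond 1e-9 mm) trigger a
        warning, because element placement then moves by up to half a step.
        """
        # ceil(x/h - 1/2) rounds half-down, i.e. toward the base (x = 0)
        idx = int(np.ceil(x_mm / self.step - 0.5))
        idx = min(max(idx, 0), self.n_nodes - 1)
        if warn and abs(self.node_positions[idx] - x_mm) > 1e-9:
            warnings.warn(
                f"position {x_mm:g} mm is off-node; snapped to node {idx} at "
                f"{self.node_positions[idx]:g} mm",
                stacklevel=2,
            )
        return idx


@dataclass(frozen=True)
class CochleaModel:
    """Electrical identity of the artificial cochlea.

    ``transverse_resistances`` holds one cross-wall shunt per lumen node
    (ohm); ``np.inf`` means the pathway is absent.  The basal and apical
    boundary resistances are the unavoidable fluid columns connecting the
    lumen ends to the surrounding bath.
    """

    geometry: LumenGeometry
    saline_conductivity: float  # S/m
    transverse_resistances: np.ndarray  # ohm, per node
    basal_boundary_resistance: float  # ohm
    apical_boundary_resistance: float  # ohm

    def __post_init__(self) -> None:
        r = np.broadcast_to(
            np.asarray(self.transverse_resistances, dtype=float),
            (self.geometry.n_nodes,),
        ).copy()
        object.__setattr__(self, "transverse_resistances", r)
        if self.saline_conductivity <= 0:
            raise ValidationError("saline conductivity must be positive")
        for name in ("basal_boundary_resistance", "apical_boundary_resistance"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive or infinite")
        if np.any(r <= 0):
            raise ValidationError("transverse resistances must be positive or infinite")

    def with_transverse(self, resistances) -> "CochleaModel":
        """Copy of the model with replaced transverse resistances (ohm)."""
        return replace(self, transverse_resistances=np.broadcast_to(
            np.asarray(resistances, dtype=float), (self.geometry.n_nodes,)).copy())


@dataclass(frozen=True)
class ArrayLayout:
    """Positions of the 16 CI contacts and the 14 recording wires, mm.

    ``electrode_positions[k]`` is contact ``k+1`` (apex-to-base numbering:
    contact 1 is most apical).  ``wire_positions[k]`` is wire ``k+1``
    (base-to-apex numbering).  The alignment pair records which contact was
    registered to which wire when the array was inserted.
    """

    electrode_positions: np.ndarray
    wire_positions: np.ndarray
    alignment: tuple[int, int] = (ALIGN_ELECTRODE, ALIGN_WIRE)
    total_length: float = DEFAULT_LENGTH_MM

    def __post_init__(self) -> None:
        e = np.asarray(self.electrode_positions, dtype=float)
        w = np.asarray(self.wire_positions, dtype=float)
        object.__setattr__(self, "electrode_positions", e)
        object.__setattr__(self, "wire_positions", w)
        if e.size != N_ELECTRODES:
            raise ValidationError(f"expected {N_ELECTRODES} electrode positions")
        if w.size != N_WIRES:
            raise ValidationError(f"expected {N_WIRES} wire positions")
        for arr, what in ((e, "electrode"), (w, "wire")):
            if np.any(arr < 0) or np.any(arr > self.total_length):
                raise ValidationError(f"{what} positions must lie in [0, total_length]")

    def electrode_position(self, electrode: int) -> float:
        """Position (mm) of CI contact ``electrode`` (1-based, 1 = apical)."""
        if not 1 <= electrode <= N_ELECTRODES:
            raise ValidationError(
                f"electrode {electrode} is off the array (valid: 1..{N_ELECTRODES})"
            )
        return float(self.electrode_positions[electrode - 1])

    def wire_position(self, wire: int) -> float:
        if not 1 <= wire <= N_WIRES:
            raise ValidationError(f"wire {wire} does not exist (valid: 1..{N_WIRES})")
        return float(self.wire_positions[wire - 1])


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def build_lumen(
    total_length: float = DEFAULT_LENGTH_MM,
    base_diameter: float = DEFAULT_BASE_DIAMETER_MM,
    apex_diameter: float = DEFAULT_APEX_DIAMETER_MM,
    step: float = DEFAULT_STEP_MM,
    taper_shape: str = "linear-diameter",
    area_table: np.ndarray | None = None,
) -> LumenGeometry:
    """Discretize the tapered lumen.

    ``taper_shape='linear-diameter'`` interpolates the diameter linearly from
    ``base_diameter`` (x=0) to ``apex_diameter`` (x=total_length) and converts
    to area via A = pi d^2 / 4.  ``taper_shape='table'`` instead linearly
    interpolates a user-supplied ``area_table`` of shape (m, 2) with columns
    (position_mm, area_mm2), e.g. a digitized human cross-section profile;
    the table must cover [0, total_length].
    """
    if total_length <= 0 or step <= 0:
        raise ValidationError("total_length and step must be positive")
    n_steps = total_length / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValidationError("step must divide total_length")
    positions = np.arange(round(n_steps) + 1) * step

    if taper_shape == "linear-diameter":
        if base_diameter <= 0 or apex_diameter <= 0:
            raise ValidationError("diameters must be positive")
        d = base_diameter + (apex_diameter - base_diameter) * positions / total_length
        areas = np.pi * d**2 / 4.0
    elif taper_shape == "table":
        if area_table is None:
            raise ValidationError("taper_shape='table' requires area_table")
        table = np.asarray(area_table, dtype=float)
        if table.ndim != 2 or table.shape[1] != 2 or table.shape[0] < 2:
            raise ValidationError("area_table must be (m, 2): position_mm, area_mm2")
        order = np.argsort(table[:, 0])
        xs, As = table[order, 0], table[order, 1]
        if xs[0] > 1e-9 or xs[-1] < total_length - 1e-9:
            raise ValidationError("area_table must cover [0, total_length]")
        if np.any(As <= 0):
            raise ValidationError("table areas must be positive")
        areas = np.interp(positions, xs, As)
    else:
        raise ValidationError(f"unknown taper_shape {taper_shape!r}")

    return LumenGeometry(node_positions=positions, cross_sectional_areas=areas)


def longitudinal_resistances(
    geometry: LumenGeometry, conductivity: float
) -> np.ndarray:
    """Saline-column resistance of each inter-node segment, ohm.

    R = dx / (sigma * A_mid), A_mid the mean of the end-node areas.  With dx
    in mm, A in mm^2 and sigma in S/m the quotient comes out in kOhm
    (1 mm / (1 S/m * 1 mm^2) = 1 kOhm), hence the factor 1000.
    """
    if conductivity <= 0:
        raise ValidationError("conductivity must be positive")
    areas = geometry.cross_sectional_areas
    a_mid = 0.5 * (areas[:-1] + areas[1:])
    if np.any(a_mid <= 0):
        raise ValidationError("zero cross-sectional area in a segment")
    dx = np.diff(geometry.node_positions)
    return 1000.0 * dx / (conductivity * a_mid)


def fluid_column_resistance(
    length_mm: float, area_mm2: float, conductivity: float
) -> float:
    """Resistance (ohm) of a straight saline column."""
    if area_mm2 <= 0 or conductivity <= 0:
        raise ValidationError("column area and conductivity must be positive")
    return 1000.0 * length_mm / (conductivity * area_mm2)


def default_model(
    transverse_r_ohm: float | np.ndarray = DEFAULT_TRANSVERSE_R_OHM,
    conductivity: float = DEFAULT_CONDUCTIVITY_S_PER_M,
    step: float = DEFAULT_STEP_MM,
    **lumen_kwargs,
) -> CochleaModel:
    """The reference configuration of the artificial cochlea.

    47 kOhm cross-wall resistors at every node, default linear taper, and
    boundary resistances computed as fluid-column resistances of the basal
    opening stub and the apical flushing tubing.  Pass ``np.inf`` for
    ``transverse_r_ohm`` to obtain the no-resistor model used to show the
    flat-apex behaviour of an insulating-walled tube.
    """
    geometry = build_lumen(step=step, **lumen_kwargs)
    basal_r = fluid_column_resistance(
        BASAL_STUB_LENGTH_MM, geometry.cross_sectional_areas[0], conductivity
    )
    apical_r = fluid_column_resistance(
        APICAL_TUBE_LENGTH_MM, np.pi * APICAL_TUBE_BORE_MM**2 / 4.0, conductivity
    )
    return CochleaModel(
        geometry=geometry,
        saline_conductivity=conductivity,
        transverse_resistances=np.broadcast_to(
            np.asarray(transverse_r_ohm, dtype=float), (geometry.n_nodes,)
        ).copy(),
        basal_boundary_resistance=basal_r,
        apical_boundary_resistance=apical_r,
    )


def default_layout(
    electrode_pitch: float = DEFAULT_ELECTRODE_PITCH_MM,
    align_electrode: int = ALIGN_ELECTRODE,
    align_wire: int = ALIGN_WIRE,
    total_length: float = DEFAULT_LENGTH_MM,
) -> ArrayLayout:
    """Wires every 2 mm from 1 mm; electrodes placed by registering contact
    ``align_electrode`` to wire ``align_wire`` and fanning out at the array
    pitch (contact numbers increase basally, i.e. toward x = 0)."""
    wires = FIRST_WIRE_MM + WIRE_SPACING_MM * np.arange(N_WIRES)
    anchor = wires[align_wire - 1]
    numbers = np.arange(1, N_ELECTRODES + 1)
    electrodes = anchor + (align_electrode - numbers) * electrode_pitch
    return ArrayLayout(
        electrode_positions=electrodes,
        wire_positions=wires,
        alignment=(align_electrode, align_wire),
        total_length=total_length,
    )
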