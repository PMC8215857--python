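"""EFI / trans-impedance simulation and transverse-resistance calibration.

Electrical field imaging (EFI, also trans-impedance matrix, TIM) is the
back-telemetry measurement of a cochlear implant: each contact stimulates
monopolarly in turn while every contact records, yielding a 16x16 matrix of
trans-impedances.  The stimulating contact's own (diagonal) entry is
contaminated by the electrode-electrolyte interface voltage and is
unreliable; the simulator computes it from the network but flags it invalid
and every calibration objective excludes it.

Calibration tunes the transverse (cross-wall) resistances of a model so its
simulated EFI matches a target profile — the computational counterpart of
choosing physical resistors by comparison with an in-vivo measurement.
Profiles are compared after normalization to their largest valid entry (the
shape, not the absolute scale, is fitted by default), the figure of merit
being a root-mean-square error in percent of that normalized scale.
Optimization runs in log-resistance space (resistances span decades),
deterministically: a fixed coarse grid provides the multi-start, followed by
bounded local refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .geometry import ArrayLayout, CochleaModel
from .metrics import SIVProfile, normalize
from .network import CurrentVector, assemble, solve
from .stimulation import StimulusSpec, siv_profile

__all__ = [
    "EFIMatrix",
    "CalibrationResult",
    "simulate_efi",
    "rmse_percent",
    "calibrate",
]

#: Clinical EFI probe: 32 uA amplitude, 36 us phase.
EFI_PROBE_UA = 32.0
EFI_PROBE_US = 36.0


@dataclass(frozen=True)
class EFIMatrix:
    """Trans-impedance matrix, ohm; rows stimulate, columns record.

    ``diagonal_valid`` defaults to all-False: without an interface model the
    stimulating contact's own entry is not to be trusted, mirroring the
    clinical situation.
    """

    values: np.ndarray  # (16, 16) ohm
    diagonal_valid: np.ndarray | None = None
    probe_amplitude_uA: float = EFI_PROBE_UA
    probe_phase_us: float = EFI_PROBE_US

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("EFI matrix must be square")
        flags = (
            np.zeros(v.shape[0], dtype=bool)
            if self.diagonal_valid is None
            else np.asarray(self.diagonal_valid, dtype=bool)
        )
        object.__setattr__(self, "diagonal_valid", flags)

    @property
    def n_electrodes(self) -> int:
        return self.values.shape[0]

    def offdiagonal_mask(self) -> np.ndarray:
        """Entries usable for comparison: off-diagonal plus any validated
        diagonal entries."""
        mask = ~np.eye(self.n_electrodes, dtype=bool)
        mask[np.diag_indices(self.n_electrodes)] = self.diagonal_valid
        return mask


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of a transverse-resistance fit."""

    transverse_resistances: np.ndarray  # ohm; size 1 (shared) or per node
    rmse_percent: float
    iterations: int
    converged: bool
    mode: str  # shared | per-node
    objective_history: tuple = ()

    @property
    def shared_resistance(self) -> float:
        """Fitted resistance for a shared (scalar) fit, ohm."""
        return float(np.asarray(self.transverse_resistances).ravel()[0])


def simulate_efi(
    model: CochleaModel,
    layout: ArrayLayout,
    amplitude_uA: float = EFI_PROBE_UA,
) -> EFIMatrix:
    """Simulate the EFI a CI would report from this model.

    Row e: monopolar injection at contact e, voltage recorded at all 16
    contact positions, divided by the probe amplitude.  Impedances, so the
    result is amplitude-invariant.  Diagonal entries are computed (lumen
    potential at the stimulating node) but flagged invalid.
    """
    network = assemble(model)
    geom = model.geometry
    nodes = [geom.nearest_node(x) for x in layout.electrode_positions]
    n = len(nodes)
    values = np.empty((n, n))
    for row, src in enumerate(nodes):
        i = np.zeros(geom.n_nodes)
        i[src] = amplitude_uA
        v = solve(
            network,
            CurrentVector(node_currents_uA=i, ground_current_uA=-amplitude_uA),
        )
        values[row] = v.voltages_mV[nodes] / amplitude_uA * 1e3  # mV/uA -> ohm
    return EFIMatrix(values=values, probe_amplitude_uA=amplitude_uA)


def _normalized_valid(efi: EFIMatrix) -> tuple[np.ndarray, np.ndarray]:
    mask = efi.offdiagonal_mask()
    peak = np.abs(efi.values[mask]).max()
    if not np.isfinite(peak) or peak == 0:
        raise ValueError("EFI target has no finite nonzero valid entries")
    return efi.values / peak, mask


def rmse_percent(simulated, target) -> float:
    """Root-mean-square mismatch between two profiles, percent.

    Both inputs are normalized to their own largest (valid) magnitude before
    comparison, so the figure measures shape mismatch on a peak = 1 scale.
    EFI matrices are compared over off-diagonal (plus validated diagonal)
    entries; SIV profiles over all wires.
    """
    if isinstance(simulated, EFIMatrix) and isinstance(target, EFIMatrix):
        if simulated.values.shape != target.values.shape:
            raise ValueError("EFI matrices have different shapes")
        sim_n, mask_s = _normalized_valid(simulated)
        tgt_n, mask_t = _normalized_valid(target)
        mask = mask_s & mask_t
        diff = sim_n[mask] - tgt_n[mask]
    elif isinstance(simulated, SIVProfile) and isinstance(target, SIVProfile):
        if simulated.values.shape != target.values.shape:
            raise ValueError("profiles are on different wire grids")
        diff = normalize(simulated).values - normalize(target).values
    else:
        raise TypeError("rmse_percent compares two EFIMatrix or two SIVProfile")
    if not np.all(np.isfinite(diff)):
        raise ValueError("non-finite entries in comparison")
    return 100.0 * float(np.sqrt(np.mean(diff**2)))


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

DEFAULT_BOUNDS_OHM = (1e3, 1e6)
COARSE_GRID_POINTS = 25
DEFAULT_SMOOTHNESS = 0.1


def calibrate(
    target,
    model_template: CochleaModel,
    layout: ArrayLayout,
    mode: str = "shared",
    bounds_ohm: tuple[float, float] = DEFAULT_BOUNDS_OHM,
    smoothness: float = DEFAULT_SMOOTHNESS,
) -> CalibrationResult:
    """Fit transverse resistances so the model reproduces a target profile.

    ``target`` is an :class:`EFIMatrix` (objective: RMSE%% over valid
    entries) or an :class:`SIVProfile` carrying its stimulus metadata
    (objective: RMSE%% over wires).  ``mode='shared'`` fits one resistance
    for all nodes by coarse log-grid search plus bounded scalar refinement;
    ``mode='per-node'`` fits every node's resistance with an L-BFGS-B solve
    in log space, regularized by a smoothness penalty
    ``smoothness * sum((delta log R)^2)`` that keeps neighbouring wall
    segments electrically similar.  Fully deterministic: no random starts.
    """
    lo, hi = bounds_ohm
    if not (0 < lo < hi):
        raise ValueError("bounds must satisfy 0 < lo < hi")
    _validate_target(target)

    history: list[float] = []

    def objective_shared(log_r: float) -> float:
        model = model_template.with_transverse(10.0**log_r)
        return _objective(model, layout, target)

    # deterministic multi-start: coarse grid in log space
    grid = np.linspace(np.log10(lo), np.log10(hi), COARSE_GRID_POINTS)
    coarse = np.array([objective_shared(g) for g in grid])
    k0 = int(np.argmin(coarse))
    history.extend(np.minimum.accumulate(coarse[: k0 + 1]).tolist())
    left = grid[max(k0 - 1, 0)]
    right = grid[min(k0 + 1, grid.size - 1)]

    res = scipy.optimize.minimize_scalar(
        objective_shared, bounds=(left, right), method="bounded",
        options={"xatol": 1e-8},
    )
    shared_log = float(res.x) if res.fun <= coarse[k0] else float(grid[k0])
    shared_rmse = float(min(res.fun, coarse[k0]))
    history.append(shared_rmse)
    iterations = COARSE_GRID_POINTS + int(res.nfev)

    if mode == "shared":
        return CalibrationResult(
            transverse_resistances=np.array([10.0**shared_log]),
            rmse_percent=shared_rmse,
            iterations=iterations,
            converged=bool(res.success),
            mode=mode,
            objective_history=tuple(history),
        )
    if mode != "per-node":
        raise ValueError("mode must be 'shared' or 'per-node'")

    n = model_template.geometry.n_nodes

    def objective_pernode(log_r: np.ndarray) -> float:
        model = model_template.with_transverse(10.0**log_r)
        penalty = smoothness * float(np.sum(np.diff(log_r) ** 2))
        return _objective(model, layout, target) + penalty

    x0 = np.full(n, shared_log)
    opt = scipy.optimize.minimize(
        objective_pernode,
        x0,
        method="L-BFGS-B",
        bounds=[(np.log10(lo), np.log10(hi))] * n,
        options={"maxiter": 200, "ftol": 1e-12},
    )
    fitted = 10.0 ** opt.x
    final_rmse = _objective(model_template.with_transverse(fitted), layout, target)
    history.append(float(opt.fun))
    return CalibrationResult(
        transverse_resistances=fitted,
        rmse_percent=float(final_rmse),
        iterations=iterations + int(opt.nit),
        converged=bool(opt.success),
        mode=mode,
        objective_history=tuple(history),
    )


def _validate_target(target) -> None:
    values = target.values
    if not np.all(np.isfinite(values)):
        raise ValueError("target contains non-finite entries")


def _objective(model: CochleaModel, layout: ArrayLayout, target) -> float:
    if isinstance(target, EFIMatrix):
        sim = simulate_efi(model, layout, amplitude_uA=target.probe_amplitude_uA)
        sim = EFIMatrix(
            values=sim.values,
            diagonal_valid=target.diagonal_valid,
            probe_amplitude_uA=sim.probe_amplitude_uA,
        )
        return rmse_percent(sim, target)
    if isinstance(target, SIVProfile):
        spec = target.stimulus
        if spec is None:
            raise ValueError("SIV-profile target must carry its stimulus metadata")
        inner = getattr(spec, "spec", spec)
        sim = siv_profile(model, layout, inner)
        return rmse_percent(sim, target)
    raise TypeError("target must be an EFIMatrix or an SIVProfile")
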