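"""Synthetic telemetry with known ground truth.

No public dataset of in-vivo EFI profiles or bench SIV recordings exists to
ship with the package, so calibration and the metrics pipeline are
exercised end-to-end on generated stand-ins: an in-vivo-like EFI matrix
(inverted-V rows, flatter apically than basally — the shape real
trans-impedance telemetry shows) produced from a jittered copy of the
reference model, and wire-recorded SIV profiles with replicate averaging.

Noise model: log-normal and multiplicative throughout, because impedance
and SIV values are positive and span an order of magnitude.  Two sources
are distinguished: *resistor tolerance* perturbs the ground-truth model's
per-node transverse resistances once (component scatter), and *measurement
CV* perturbs every recorded entry independently per replicate (telemetry
noise).  Replicates are averaged as on the bench.  Every draw is governed
by the integer seed in the noise spec; identical specs give bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import EFIMatrix, simulate_efi
from .geometry import ArrayLayout, CochleaModel
from .metrics import SIVProfile
from .network import assemble
from .stimulation import StimulusSpec, siv_profile

__all__ = ["NoiseSpec", "make_invivo_like_efi", "make_noisy_siv"]

#: Defaults: 3 % measurement CV (visible yet recoverable), 5 % resistor
#: tolerance (typical discrete-resistor grade), 3 replicates as on the bench.
DEFAULT_CV = 0.03
DEFAULT_TOLERANCE = 0.05
DEFAULT_REPLICATES = 3


@dataclass(frozen=True)
class NoiseSpec:
    """Stochastic conditions for one synthetic measurement campaign."""

    multiplicative_cv: float = DEFAULT_CV
    resistor_tolerance: float = DEFAULT_TOLERANCE
    replicates: int = DEFAULT_REPLICATES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplicative_cv < 0 or self.resistor_tolerance < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _lognormal_factors(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Unit-mean multiplicative log-normal factors with the given CV."""
    if cv == 0:
        return np.ones(shape)
    s2 = np.log1p(cv**2)
    return rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=shape)


def make_invivo_like_efi(
    base_model: CochleaModel,
    layout: ArrayLayout,
    noise: NoiseSpec = NoiseSpec(),
) -> tuple[EFIMatrix, CochleaModel]:
    """Generate a noisy EFI target plus the ground-truth model behind it.

    The truth model is the base with each node's transverse resistance
    jittered by the resistor tolerance; its simulated EFI is then corrupted
    entry-wise by measurement noise in each replicate and the replicates are
    averaged.  Returning the truth model makes recovery error computable by
    construction.
    """
    rng = np.random.default_rng(noise.seed)
    jitter = _lognormal_factors(
        rng, noise.resistor_tolerance, base_model.geometry.n_nodes
    )
    truth = base_model.with_transverse(base_model.transverse_resistances * jitter)
    clean = simulate_efi(truth, layout)
    if noise.multiplicative_cv == 0:
        measured = clean.values  # replicates are identical; keep bit-exact
    else:
        reps = np.empty((noise.replicates,) + clean.values.shape)
        for r in range(noise.replicates):
            reps[r] = clean.values * _lognormal_factors(
                rng, noise.multiplicative_cv, clean.values.shape
            )
        measured = reps.mean(axis=0)
    return (
        EFIMatrix(values=measured, probe_amplitude_uA=clean.probe_amplitude_uA),
        truth,
    )


def make_noisy_siv(
    model: CochleaModel,
    layout: ArrayLayout,
    spec: StimulusSpec,
    noise: NoiseSpec = NoiseSpec(),
) -> SIVProfile:
    """Replicate-averaged SIV profile with per-wire standard deviations.

    Multiplicative noise acts on the signed values (sign is preserved; the
    bench's polarity inversions survive averaging)."""
    rng = np.random.default_rng(noise.seed)
    clean = siv_profile(model, layout, spec)
    n_wires = clean.values.size
    if noise.multiplicative_cv == 0:
        mean, sd = clean.values, np.zeros(n_wires)  # bit-exact degenerate case
    else:
        reps = clean.values * _lognormal_factors(
            rng, noise.multiplicative_cv, (noise.replicates, n_wires)
        )
        mean = reps.mean(axis=0)
        sd = reps.std(axis=0, ddof=1) if noise.replicates > 1 else np.zeros(n_wires)
    return SIVProfile(
        wire_positions=clean.wire_positions,
        values=mean,
        wire_indices=clean.wire_indices,
        stimulus=clean.stimulus,
        replicate_sd=sd,
    )
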