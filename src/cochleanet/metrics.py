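"""Figures of merit for spread-induced voltage (SIV) profiles.

Two numbers summarize a profile: the maximum peak-to-peak SIV (a proxy for
how much stimulus amplitude reaches the neural target — higher means lower
power to reach threshold), and the focusing parameter alpha (dB/mm), the
exponential decay rate of the profile away from its peak — higher means
spatially tighter stimulation.  Alpha is extracted by a least-squares fit,
on the decibel scale and constrained through the origin, of

    L(x) = 20 log10(|V(x)| / |V(x_peak)|)  ~  -alpha |x - x_peak|,

jointly over both sides of the peak by default (per-side fits are available
for asymmetric modes such as bipolar).  Magnitudes are used so that
polarity-inverted wires near current sinks contribute by size; the number
of sign flips relative to the peak is recorded.  Wires more than
``floor_db`` below the peak are excluded as numerical noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

__all__ = ["SIVProfile", "FocusingFit", "normalize", "max_siv", "fit_focusing"]


@dataclass(frozen=True)
class SIVProfile:
    """Signed peak-to-peak spread-induced voltages at the recording wires.

    ``values`` are V_SI,pp in mV (dimensionless after :func:`normalize`),
    signed: the center electrode's leading-phase response is positive and
    wires dominated by a current sink carry the opposite sign.
    """

    wire_positions: np.ndarray  # mm
    values: np.ndarray
    wire_indices: np.ndarray | None = None  # 1-based, base-to-apex
    stimulus: Any = None
    replicate_sd: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.wire_positions, dtype=float)
        val = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wire_positions", pos)
        object.__setattr__(self, "values", val)
        if val.shape != pos.shape:
            raise ValueError("one SIV value per wire position required")
        if self.wire_indices is None:
            object.__setattr__(self, "wire_indices", np.arange(1, pos.size + 1))
        else:
            object.__setattr__(
                self, "wire_indices", np.asarray(self.wire_indices, dtype=int)
            )
        if self.replicate_sd is not None:
            sd = np.asarray(self.replicate_sd, dtype=float)
            if sd.shape != val.shape:
                raise ValueError("replicate_sd shape mismatch")
            object.__setattr__(self, "replicate_sd", sd)


@dataclass(frozen=True)
class FocusingFit:
    """Exponential-decay fit of an SIV profile.

    ``alpha``: decay rate, dB/mm (>= 0).  ``v0``: peak magnitude (mV, or
    dimensionless for a normalized profile).  ``r_squared``: coefficient of
    determination on the dB scale.  ``flat`` marks a degenerate all-equal
    profile (alpha = 0, r_squared reported as 1).
    """

    alpha: float
    v0: float
    r_squared: float
    side: str  # apical | basal | joint
    points_used: int
    peak_wire: int
    flat: bool = False
    sign_flips: int = 0
    flip_positions: tuple = ()


def normalize(profile: SIVProfile) -> SIVProfile:
    """Divide by the largest magnitude so the peak becomes +/-1."""
    peak = float(np.max(np.abs(profile.values)))
    if peak == 0:
        raise ValueError("cannot normalize an all-zero profile")
    sd = None if profile.replicate_sd is None else profile.replicate_sd / peak
    return replace(
        profile, values=profile.values / peak, replicate_sd=sd, normalized=True
    )


def max_siv(profile: SIVProfile, center_position: float | None = None) -> tuple[float, int]:
    """Largest |V_SI,pp| and the 1-based wire index carrying it.

    Ties (to 1e-12 relative) resolve to the wire nearest ``center_position``
    (the stimulating electrode) when given, else to the basal-most tied wire.
    """
    if profile.values.size == 0:
        raise ValueError("empty profile")
    mags = np.abs(profile.values)
    peak = mags.max()
    tied = np.flatnonzero(mags >= peak * (1 - 1e-12))
    if center_position is None and profile.stimulus is not None:
        center_position = getattr(profile.stimulus, "center_position", None)
    if center_position is not None and tied.size > 1:
        best = tied[np.argmin(np.abs(profile.wire_positions[tied] - center_position))]
    else:
        best = tied[0]
    return float(mags[best]), int(profile.wire_indices[best])


def fit_focusing(
    profile: SIVProfile,
    floor_db: float = -40.0,
    side: str = "joint",
    include_peak: bool = True,
) -> FocusingFit:
    """Fit the dB-scale exponential decay away from the profile peak.

    ``side`` selects the wires used: ``'joint'`` pools both sides of the
    peak, ``'apical'``/``'basal'`` restrict to one.  If the peak sits on an
    end wire, the fit silently becomes one-sided and the side is recorded.
    Raises ``ValueError`` when fewer than 3 wires survive the floor.
    """
    mags = np.abs(profile.values)
    peak_val, peak_wire = max_siv(profile)
    peak_idx = int(np.flatnonzero(profile.wire_indices == peak_wire)[0])
    x_peak = profile.wire_positions[peak_idx]
    if peak_val == 0:
        raise ValueError("all-zero profile cannot be fitted")

    with np.errstate(divide="ignore"):
        level_db = 20.0 * np.log10(mags / peak_val)
    dist = np.abs(profile.wire_positions - x_peak)

    mask = level_db >= floor_db
    if side == "apical":
        mask &= profile.wire_positions >= x_peak
    elif side == "basal":
        mask &= profile.wire_positions <= x_peak
    elif side != "joint":
        raise ValueError(f"unknown side {side!r}")
    if not include_peak:
        mask[peak_idx] = False

    actual_side = side
    if side == "joint" and peak_idx in (0, profile.values.size - 1):
        actual_side = "apical" if peak_idx == 0 else "basal"

    n_used = int(mask.sum())
    if n_used < 3:
        raise ValueError(
            f"too few wires above the {floor_db:g} dB floor on side {side!r} "
            f"({n_used} < 3)"
        )

    L = level_db[mask]
    d = dist[mask]

    signs = np.sign(profile.values[mask])
    peak_sign = np.sign(profile.values[peak_idx])
    flipped = signs * peak_sign < 0
    flips = int(flipped.sum())
    flip_pos = tuple(profile.wire_positions[mask][flipped])

    if np.ptp(mags[mask]) <= 1e-12 * peak_val:
        # all-equal profile: no decay to fit; flag rather than divide by zero
        return FocusingFit(
            alpha=0.0, v0=peak_val, r_squared=1.0, side=actual_side,
            points_used=n_used, peak_wire=peak_wire, flat=True,
            sign_flips=flips, flip_positions=flip_pos,
        )

    denom = float(np.sum(d * d))
    alpha = max(0.0, -float(np.sum(L * d)) / denom) if denom > 0 else 0.0
    pred = -alpha * d
    ss_res = float(np.sum((L - pred) ** 2))
    ss_tot = float(np.sum((L - L.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FocusingFit(
        alpha=alpha, v0=peak_val, r_squared=r2, side=actual_side,
        points_used=n_used, peak_wire=peak_wire,
        sign_flips=flips, flip_positions=flip_pos,
    )
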