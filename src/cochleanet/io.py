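"""Configuration loading and tabular serialization.

File schemas carry fixed units, named in the column headers: positions in
mm, currents in uA, voltages in mV, resistances in ohm, focusing in dB/mm.
All tables are plain CSV ('.' decimal); model configuration is YAML.  Every
writer here has a matching reader and the pair round-trips exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import EFIMatrix
from .geometry import (
    ArrayLayout,
    CochleaModel,
    ValidationError,
    build_lumen,
    default_layout,
    default_model,
    fluid_column_resistance,
)
from .metrics import SIVProfile

__all__ = [
    "load_model_config",
    "read_area_table",
    "write_siv_csv",
    "read_siv_csv",
    "write_efi_csv",
    "read_efi_csv",
]


def read_area_table(path) -> np.ndarray:
    """Area table CSV with columns position_mm, area_mm2 -> (m, 2) array."""
    df = pd.read_csv(path)
    missing = {"position_mm", "area_mm2"} - set(df.columns)
    if missing:
        raise ValidationError(f"area table lacks columns: {sorted(missing)}")
    return df[["position_mm", "area_mm2"]].to_numpy(dtype=float)


def load_model_config(path) -> tuple[CochleaModel, ArrayLayout]:
    """Build a model and array layout from a YAML configuration file.

    Recognized keys (all optional; omissions fall back to the reference
    configuration)::

        geometry:
          length_mm, base_diameter_mm, apex_diameter_mm, step_mm,
          area_table_csv          # switches the taper to a lookup table
        conductivity_S_per_m
        transverse_R_ohm          # scalar or per-node list
        basal_R_ohm, apical_R_ohm # override computed boundary columns
        arrays:
          electrode_pitch_mm, align_electrode, align_wire
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}

    geo = cfg.get("geometry", {}) or {}
    length = float(geo.get("length_mm", 32.0))
    step = float(geo.get("step_mm", 0.25))
    conductivity = float(cfg.get("conductivity_S_per_m", 1.6))

    if "area_table_csv" in geo:
        table_path = Path(path).parent / geo["area_table_csv"]
        geometry = build_lumen(
            total_length=length,
            step=step,
            taper_shape="table",
            area_table=read_area_table(table_path),
        )
    else:
        geometry = build_lumen(
            total_length=length,
            base_diameter=float(geo.get("base_diameter_mm", 2.0)),
            apex_diameter=float(geo.get("apex_diameter_mm", 1.0)),
            step=step,
        )

    transverse = cfg.get("transverse_R_ohm", 47_000.0)
    transverse = np.asarray(transverse, dtype=float)

    basal = cfg.get("basal_R_ohm")
    apical = cfg.get("apical_R_ohm")
    ref = default_model(conductivity=conductivity)  # for computed boundary defaults
    basal = float(basal) if basal is not None else fluid_column_resistance(
        2.0, geometry.cross_sectional_areas[0], conductivity
    )
    apical = float(apical) if apical is not None else ref.apical_boundary_resistance

    model = CochleaModel(
        geometry=geometry,
        saline_conductivity=conductivity,
        transverse_resistances=np.broadcast_to(transverse, (geometry.n_nodes,)).copy(),
        basal_boundary_resistance=basal,
        apical_boundary_resistance=apical,
    )

    arr = cfg.get("arrays", {}) or {}
    layout = default_layout(
        electrode_pitch=float(arr.get("electrode_pitch_mm", 1.0)),
        align_electrode=int(arr.get("align_electrode", 8)),
        align_wire=int(arr.get("align_wire", 8)),
        total_length=length,
    )
    return model, layout


def write_siv_csv(profile: SIVProfile, path) -> None:
    pd.DataFrame(
        {
            "wire_index": profile.wire_indices,
            "position_mm": profile.wire_positions,
            "v_pp_mV_signed": profile.values,
            **(
                {"sd_mV": profile.replicate_sd}
                if profile.replicate_sd is not None
                else {}
            ),
        }
    ).to_csv(path, index=False)


def read_siv_csv(path) -> SIVProfile:
    df = pd.read_csv(path)
    return SIVProfile(
        wire_positions=df["position_mm"].to_numpy(dtype=float),
        values=df["v_pp_mV_signed"].to_numpy(dtype=float),
        wire_indices=df["wire_index"].to_numpy(dtype=int),
        replicate_sd=df["sd_mV"].to_numpy(dtype=float) if "sd_mV" in df else None,
    )


def write_efi_csv(efi: EFIMatrix, path) -> None:
    idx = pd.Index(range(1, efi.n_electrodes + 1), name="stim_electrode")
    df = pd.DataFrame(efi.values, index=idx, columns=[str(c) for c in idx])
    df.to_csv(path)


def read_efi_csv(path) -> EFIMatrix:
    df = pd.read_csv(path, index_col=0)
    return EFIMatrix(values=df.to_numpy(dtype=float))
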