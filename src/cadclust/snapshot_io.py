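"""Snapshot readers/writers: plain CSV, one monomer table and one actin
table per snapshot, fixed column order, lossless round-trip of ids and bond
topology and coordinates to 1e-6 nm.

``write_snapshot(state, prefix)`` produces ``<prefix>_monomers.csv`` and
``<prefix>_actin.csv``.  Angles are serialised in degrees, lengths in nm,
times in s; empty bond slots are ``-1``.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .geometry import PeriodicDomain
from .state import KineticParams, SystemState

__all__ = ["SnapshotFormatError", "write_snapshot", "read_snapshot", "state_from_tables"]

MONOMER_COLUMNS = [
    "id", "plane", "x_nm", "y_nm", "theta_deg",
    "trans_partner", "cis_donor_partner", "cis_acceptor_partner", "actin_segment",
]
ACTIN_COLUMNS = [
    "id", "plane", "ax_nm", "ay_nm", "bx_nm", "by_nm",
    "bind_start_frac", "bind_len_frac", "birth_s",
]

FLOAT_FORMAT = "%.6f"


class SnapshotFormatError(ValueError):
    pass


def monomer_frame(state: SystemState) -> pd.DataFrame:
    n = state.n_monomers
    return pd.DataFrame(
        {
            "id": np.arange(n, dtype=np.int64),
            "plane": state.plane.astype(np.int64),
            "x_nm": state.pos[:, 0],
            "y_nm": state.pos[:, 1],
            "theta_deg": np.degrees(state.theta),
            "trans_partner": state.trans.astype(np.int64),
            "cis_donor_partner": state.cis_donor.astype(np.int64),
            "cis_acceptor_partner": state.cis_acceptor.astype(np.int64),
            "actin_segment": state.actin_bond.astype(np.int64),
        },
        columns=MONOMER_COLUMNS,
    )


def actin_frame(state: SystemState) -> pd.DataFrame:
    m = state.n_filaments
    cos = np.cos(state.fil_angle)
    sin = np.sin(state.fil_angle)
    return pd.DataFrame(
        {
            "id": np.arange(m, dtype=np.int64),
            "plane": state.fil_plane.astype(np.int64),
            "ax_nm": state.fil_anchor[:, 0] if m else np.zeros(0),
            "ay_nm": state.fil_anchor[:, 1] if m else np.zeros(0),
            "bx_nm": (state.fil_anchor[:, 0] + state.fil_len * cos) if m else np.zeros(0),
            "by_nm": (state.fil_anchor[:, 1] + state.fil_len * sin) if m else np.zeros(0),
            "bind_start_frac": state.fil_b0,
            "bind_len_frac": state.fil_b1 - state.fil_b0,
            "birth_s": state.fil_birth,
        },
        columns=ACTIN_COLUMNS,
    )


def write_snapshot(state: SystemState, prefix) -> Tuple[Path, Path]:
    """Write the monomer and actin tables; returns the two paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mono_path = prefix.parent / f"{prefix.name}_monomers.csv"
    actin_path = prefix.parent / f"{prefix.name}_actin.csv"
    monomer_frame(state).to_csv(mono_path, index=False, float_format=FLOAT_FORMAT,
                                lineterminator="\n")
    actin_frame(state).to_csv(actin_path, index=False, float_format=FLOAT_FORMAT,
                              lineterminator="\n")
    return mono_path, actin_path


def _read_csv(path: Path, columns) -> pd.DataFrame:
    if not path.exists():
        raise SnapshotFormatError(f"snapshot file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as e:
        raise SnapshotFormatError(f"{path}: {e}") from e
    if list(df.columns) != columns:
        raise SnapshotFormatError(
            f"{path}: expected columns {columns}, found {list(df.columns)}"
        )
    return df


def read_snapshot(prefix) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Read back the monomer and actin tables written by
    :func:`write_snapshot`."""
    prefix = Path(prefix)
    mono = _read_csv(prefix.parent / f"{prefix.name}_monomers.csv", MONOMER_COLUMNS)
    act = _read_csv(prefix.parent / f"{prefix.name}_actin.csv", ACTIN_COLUMNS)
    return mono, act


def state_from_tables(
    mono: pd.DataFrame,
    act: pd.DataFrame,
    domain: PeriodicDomain,
    params: KineticParams,
    time: float = 0.0,
) -> SystemState:
    """Rebuild a :class:`SystemState` from snapshot tables."""
    n = len(mono)
    st = SystemState.empty(domain, params, n)
    order = np.argsort(mono["id"].to_numpy())
    mono = mono.iloc[order]
    if not np.array_equal(mono["id"].to_numpy(), np.arange(n)):
        raise SnapshotFormatError("monomer ids must be 0..n-1")
    st.pos[:, 0] = mono["x_nm"].to_numpy(float)
    st.pos[:, 1] = mono["y_nm"].to_numpy(float)
    st.theta[:] = np.radians(mono["theta_deg"].to_numpy(float)) % (2 * math.pi)
    st.plane[:] = mono["plane"].to_numpy(np.int64)
    st.trans[:] = mono["trans_partner"].to_numpy(np.int64)
    st.cis_donor[:] = mono["cis_donor_partner"].to_numpy(np.int64)
    st.cis_acceptor[:] = mono["cis_acceptor_partner"].to_numpy(np.int64)
    st.actin_bond[:] = mono["actin_segment"].to_numpy(np.int64)
    m = len(act)
    if m:
        ax = act["ax_nm"].to_numpy(float)
        ay = act["ay_nm"].to_numpy(float)
        bx = act["bx_nm"].to_numpy(float)
        by = act["by_nm"].to_numpy(float)
        st.fil_anchor = np.column_stack([ax, ay])
        st.fil_angle = np.arctan2(by - ay, bx - ax) % (2 * math.pi)
        st.fil_len = np.hypot(bx - ax, by - ay)
        st.fil_b0 = act["bind_start_frac"].to_numpy(float)
        st.fil_b1 = st.fil_b0 + act["bind_len_frac"].to_numpy(float)
        st.fil_birth = act["birth_s"].to_numpy(float)
        st.fil_plane = act["plane"].to_numpy(np.int64)
    st.time = time
    st.audit()
    return st
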