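"""Text-based readers and writers for every artifact the package handles.

All formats are plain delimited text (gzip-transparent where noted) with
YAML sidecars or headers for metadata:

* spectrum: two columns (frequency_kHz, intensity) at 9 significant
  digits, plus a ``<name>.meta.yaml`` sidecar (chi_kHz, dwell_time_s,
  n_points, ...); writer and reader round-trip the text representation
  bit-identically.
* order profile / phase model: CSV with columns
  (carbon, order, weight, line_broadening_Hz).
* bond-vector trajectory: CSV (frame, lipid_id, carbon, hydrogen_index,
  vx, vy, vz) with the bilayer normal in a sidecar.
* per-lipid order series: long CSV (lipid, frame, order).
* HMM model: a single YAML document (means, sds, matrices, seed).
* fit report: CSV table plus a YAML run log.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .hmm import HmmModel, StatePath
from .md_order import PerLipidOrderSeries, VectorTrajectory
from .profiles import OrderProfile
from .spectra import AcquisitionParams, Spectrum
from .fitting import TwoPhaseFit

__all__ = [
    "write_spectrum", "read_spectrum",
    "write_profile", "read_profile",
    "write_trajectory", "read_trajectory",
    "write_series", "read_series",
    "write_hmm_model", "read_hmm_model",
    "write_state_path",
    "write_fit_report",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def _open_text(path: Path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def write_spectrum(
    path: str | Path,
    spectrum: Spectrum,
    label: str = "",
    temperature_c: float | None = None,
) -> Path:
    """Write a spectrum as two-column text plus a YAML metadata sidecar."""
    path = Path(path)
    with _open_text(path, "w") as fh:
        for f, i in zip(spectrum.frequencies, spectrum.intensities):
            fh.write(f"{f:.9g} {i:.9g}\n")
    p = spectrum.params
    meta = {
        "chi_kHz": p.chi,
        "dwell_time_s": p.dwell_time,
        "n_points": p.n_points,
        "theta_increment_deg": p.theta_increment,
        "zero_fill_factor": p.zero_fill_factor,
        "label": label,
        "temperature_C": temperature_c,
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def read_spectrum(path: str | Path) -> tuple[Spectrum, dict[str, Any]]:
    """Read a spectrum file and its sidecar; returns (Spectrum, metadata)."""
    path = Path(path)
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValidationError(f"{path}: expected two columns (frequency, intensity)")
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise ValidationError(f"metadata sidecar {sidecar} not found")
    meta = yaml.safe_load(sidecar.read_text())
    params = AcquisitionParams(
        chi=float(meta["chi_kHz"]),
        dwell_time=float(meta["dwell_time_s"]),
        n_points=int(meta["n_points"]),
        theta_increment=float(meta.get("theta_increment_deg", 0.00625)),
        zero_fill_factor=int(meta.get("zero_fill_factor", 1)),
    )
    return Spectrum(data[:, 0], data[:, 1], params), meta


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def write_profile(
    path: str | Path,
    profile: OrderProfile,
    weights: np.ndarray | None = None,
    line_broadening: float | np.ndarray = 0.0,
) -> Path:
    path = Path(path)
    n = profile.carbons.size
    if weights is None:
        weights = np.ones(n)
    lb = np.broadcast_to(np.asarray(line_broadening, dtype=float), (n,))
    df = pd.DataFrame(
        {
            "carbon": profile.carbons,
            "order": profile.orders,
            "weight": np.asarray(weights, dtype=float),
            "line_broadening_Hz": lb,
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def read_profile(
    path: str | Path, chain_label: str = "", signed: bool = False
) -> tuple[OrderProfile, pd.DataFrame]:
    """Read a profile CSV; returns (OrderProfile, full table)."""
    df = pd.read_csv(path)
    required = {"carbon", "order"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: profile file needs columns {required}")
    profile = OrderProfile(
        chain_label or Path(path).stem,
        df["carbon"].to_numpy(),
        df["order"].to_numpy(),
        signed=signed,
    )
    return profile, df


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def write_trajectory(path: str | Path, traj: VectorTrajectory) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "frame": traj.frames,
            "lipid_id": traj.lipid_ids,
            "carbon": traj.carbons,
            "hydrogen_index": traj.hydrogens,
            "vx": traj.vectors[:, 0],
            "vy": traj.vectors[:, 1],
            "vz": traj.vectors[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")
    meta = {"normal": [float(v) for v in traj.normal]}
    _sidecar(path).write_text(yaml.safe_dump(meta))
    return path


def read_trajectory(path: str | Path) -> VectorTrajectory:
    """Read a bond-vector table (gzip-transparent via pandas)."""
    path = Path(path)
    df = pd.read_csv(path)
    needed = {"frame", "lipid_id", "carbon", "vx", "vy", "vz"}
    if not needed.issubset(df.columns):
        raise ValidationError(f"{path}: trajectory file needs columns {needed}")
    normal = np.array([0.0, 0.0, 1.0])
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text())
        if meta and "normal" in meta:
            normal = np.asarray(meta["normal"], dtype=float)
    return VectorTrajectory(
        frames=df["frame"].to_numpy(),
        lipid_ids=df["lipid_id"].to_numpy(),
        carbons=df["carbon"].to_numpy(),
        vectors=df[["vx", "vy", "vz"]].to_numpy(),
        normal=normal,
        hydrogens=(
            df["hydrogen_index"].to_numpy() if "hydrogen_index" in df else None
        ),
    )


# ---------------------------------------------------------------------------
# per-lipid order series
# ---------------------------------------------------------------------------

def write_series(path: str | Path, series: PerLipidOrderSeries) -> Path:
    path = Path(path)
    series.to_frame().to_csv(path, index=False, float_format="%.12g")
    return path


def read_series(path: str | Path) -> PerLipidOrderSeries:
    df = pd.read_csv(path)
    needed = {"lipid", "frame", "order"}
    if not needed.issubset(df.columns):
        raise ValidationError(f"{path}: series file needs columns {needed}")
    wide = df.pivot(index="lipid", columns="frame", values="order")
    if wide.isna().any().any():
        raise ValidationError(f"{path}: every lipid needs every frame")
    return PerLipidOrderSeries(
        wide.index.to_numpy(), wide.columns.to_numpy(), wide.to_numpy()
    )


# ---------------------------------------------------------------------------
# HMM model and state paths
# ---------------------------------------------------------------------------

def write_hmm_model(path: str | Path, model: HmmModel) -> Path:
    path = Path(path)
    doc = {
        "n_states": model.n_states,
        "initial_probs": model.initial_probs.tolist(),
        "transition_matrix": model.transition_matrix.tolist(),
        "emission_means": model.emission_means.tolist(),
        "emission_sds": model.emission_sds.tolist(),
        "log_likelihood": (
            None if np.isnan(model.log_likelihood) else float(model.log_likelihood)
        ),
        "seed": model.seed,
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def read_hmm_model(path: str | Path) -> HmmModel:
    doc = yaml.safe_load(Path(path).read_text())
    return HmmModel(
        n_states=int(doc["n_states"]),
        initial_probs=np.asarray(doc["initial_probs"], dtype=float),
        transition_matrix=np.asarray(doc["transition_matrix"], dtype=float),
        emission_means=np.asarray(doc["emission_means"], dtype=float),
        emission_sds=np.asarray(doc["emission_sds"], dtype=float),
        log_likelihood=(
            float(doc["log_likelihood"])
            if doc.get("log_likelihood") is not None
            else np.nan
        ),
        seed=doc.get("seed"),
    )


def write_state_path(path: str | Path, sp: StatePath) -> Path:
    """State labels + posteriors as a long table."""
    path = Path(path)
    n_l, n_t = sp.state_labels.shape
    cols = {
        "lipid": np.repeat(sp.lipid_ids, n_t),
        "frame": np.tile(sp.times, n_l),
        "state": sp.state_labels.ravel(),
    }
    names = (
        ("p_disordered", "p_intermediate", "p_ordered")
        if sp.n_states == 3
        else tuple(f"p_state_{k}" for k in range(sp.n_states))
    )
    for k, name in enumerate(names):
        cols[name] = sp.posterior_probs[:, :, k].ravel()
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")
    return path


# ---------------------------------------------------------------------------
# fit reports
# ---------------------------------------------------------------------------

def write_fit_report(
    path_prefix: str | Path, fit: TwoPhaseFit, extra: dict | None = None
) -> tuple[Path, Path]:
    """Write <prefix>.csv (per-phase table) and <prefix>.log.yaml."""
    prefix = Path(path_prefix)
    rows = [
        {
            "phase": "I",
            "fraction": fit.fraction_I,
            "plateau_order": float(fit.profile_I.orders[0]),
            "line_broadening_Hz": fit.lb_I,
        }
    ]
    if fit.profile_II is not None:
        rows.append(
            {
                "phase": "II",
                "fraction": fit.fraction_II,
                "plateau_order": float(fit.profile_II.orders[0]),
                "line_broadening_Hz": fit.lb_II,
            }
        )
    if fit.fraction_iso > 0:
        rows.append(
            {
                "phase": "isotropic",
                "fraction": fit.fraction_iso,
                "plateau_order": 0.0,
                "line_broadening_Hz": fit.lb_iso,
            }
        )
    table_path = prefix.with_suffix(".csv")
    pd.DataFrame(rows).to_csv(table_path, index=False, float_format="%.9g")
    log = {
        "seed": fit.seed,
        "residual_rms": float(fit.residual_rms),
        "n_evaluations": int(fit.n_evaluations),
        "cost": float(fit.cost),
        "start_costs": [float(c) for c in fit.start_costs],
        "scale": float(fit.scale),
        "offset": float(fit.offset),
    }
    if extra:
        log.update(extra)
    log_path = prefix.with_suffix(".log.yaml")
    log_path.write_text(yaml.safe_dump(log, sort_keys=False))
    return table_path, log_path
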