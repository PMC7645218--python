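"""Order parameters from C-H bond-vector trajectories.

The segmental order parameter is S_CD = <(3 cos^2 theta - 1)/2> with theta
the angle between a C-H (C-D) bond vector and the bilayer normal.  For
comparison with 2H NMR, magnitudes averaged over a chain are used; for
lipid-state classification, a per-lipid instantaneous mean over the chain
segments (the director order parameter observable) is extracted as a time
series.

Trajectory input is a pre-extracted bond-vector table (frame, lipid,
carbon, hydrogen, unit vector); a raw-trajectory adapter is a documented
extension point.  The bilayer normal is a fixed input vector (membranes
are planar here); no local-normal estimation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .profiles import OrderProfile

__all__ = [
    "VectorTrajectory",
    "PerLipidOrderSeries",
    "compute_scd_profile",
    "per_lipid_order",
    "chain_average_order",
]


def _p2(x: np.ndarray) -> np.ndarray:
    return 0.5 * (3.0 * x * x - 1.0)


@dataclass
class VectorTrajectory:
    """Flat table of C-H bond unit vectors plus the bilayer normal.

    One row per (frame, lipid, carbon, hydrogen).  Vectors must be unit
    norm within 1e-6.
    """

    frames: np.ndarray
    lipid_ids: np.ndarray
    carbons: np.ndarray
    vectors: np.ndarray
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    hydrogens: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.lipid_ids = np.asarray(self.lipid_ids, dtype=int)
        self.carbons = np.asarray(self.carbons, dtype=int)
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        n = self.frames.size
        if n == 0:
            raise ValidationError("trajectory must contain at least one frame")
        if not (
            self.lipid_ids.shape == (n,)
            and self.carbons.shape == (n,)
            and self.vectors.shape == (n, 3)
        ):
            raise ValidationError("trajectory column lengths are inconsistent")
        if self.hydrogens is None:
            self.hydrogens = np.ones(n, dtype=int)
        else:
            self.hydrogens = np.asarray(self.hydrogens, dtype=int)
            if self.hydrogens.shape != (n,):
                raise ValidationError("hydrogen column length mismatch")
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValidationError("bond vectors must be unit norm within 1e-6")
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-6:
            raise ValidationError("bilayer normal must be a unit vector")

    @property
    def n_rows(self) -> int:
        return self.frames.size

    def p2_values(self) -> np.ndarray:
        """P2(cos theta) of every bond vector against the normal."""
        return _p2(self.vectors @ self.normal)


@dataclass
class PerLipidOrderSeries:
    """Per-lipid instantaneous chain-order time series.

    ``order_values`` has shape (n_lipids, n_times); values lie in the
    geometric range [-0.5, 1] of a mean of P2 terms.
    """

    lipid_ids: np.ndarray
    times: np.ndarray
    order_values: np.ndarray

    def __post_init__(self) -> None:
        self.lipid_ids = np.asarray(self.lipid_ids, dtype=int)
        self.times = np.asarray(self.times)
        self.order_values = np.asarray(self.order_values, dtype=float)
        if self.order_values.shape != (self.lipid_ids.size, self.times.size):
            raise ValidationError(
                "order_values must have shape (n_lipids, n_times)"
            )
        if not np.all(np.isfinite(self.order_values)):
            raise ValidationError("order values must be finite")
        if np.any(self.order_values < -0.5 - 1e-9) or np.any(
            self.order_values > 1.0 + 1e-9
        ):
            raise ValidationError("order values must lie in [-0.5, 1]")

    @property
    def n_lipids(self) -> int:
        return self.lipid_ids.size

    @property
    def n_times(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        """Long-format (lipid, frame, order) table."""
        lipids = np.repeat(self.lipid_ids, self.n_times)
        frames = np.tile(self.times, self.n_lipids)
        return pd.DataFrame(
            {"lipid": lipids, "frame": frames, "order": self.order_values.ravel()}
        )


def compute_scd_profile(
    traj: VectorTrajectory,
    chain_label: str = "",
    carbons: np.ndarray | None = None,
) -> OrderProfile:
    """Per-carbon signed S_CD profile averaged over frames and lipids.

    Equivalent hydrogens on a carbon are averaged before the carbon-level
    mean.  Returns a signed profile; use ``.magnitudes`` for the NMR-style
    magnitude profile.
    """
    p2 = traj.p2_values()
    df = pd.DataFrame(
        {
            "frame": traj.frames,
            "lipid": traj.lipid_ids,
            "carbon": traj.carbons,
            "p2": p2,
        }
    )
    if carbons is not None:
        df = df[df["carbon"].isin(np.asarray(carbons))]
        if df.empty:
            raise ValidationError("carbon selection matched no trajectory rows")
    # hydrogens first, then frames/lipids
    site = df.groupby(["frame", "lipid", "carbon"], sort=True)["p2"].mean()
    prof = site.groupby("carbon").mean()
    return OrderProfile(
        chain_label=chain_label,
        carbons=prof.index.to_numpy(),
        orders=prof.to_numpy(),
        signed=True,
    )


def per_lipid_order(traj: VectorTrajectory, window: int = 1) -> PerLipidOrderSeries:
    """Instantaneous per-lipid chain order, optionally boxcar smoothed.

    For each lipid and frame the mean P2 over that lipid's chain segments
    (hydrogens averaged within each carbon first) is computed.  A boxcar
    of ``window`` frames (trailing, 'valid' convolution) reduces the time
    axis to n_frames - window + 1 points.
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    p2 = traj.p2_values()
    df = pd.DataFrame(
        {
            "frame": traj.frames,
            "lipid": traj.lipid_ids,
            "carbon": traj.carbons,
            "p2": p2,
        }
    )
    site = df.groupby(["frame", "lipid", "carbon"], sort=True)["p2"].mean()
    per = site.groupby(["lipid", "frame"]).mean().unstack("frame")
    if per.isna().any().any():
        raise ValidationError("every lipid must be present in every frame")
    lipids = per.index.to_numpy()
    frames = per.columns.to_numpy()
    values = per.to_numpy()
    n_frames = frames.size
    if window > n_frames:
        raise ValidationError(
            f"window ({window}) exceeds trajectory length ({n_frames})"
        )
    if window > 1:
        kernel = np.full(window, 1.0 / window)
        values = np.apply_along_axis(
            lambda r: np.convolve(r, kernel, mode="valid"), 1, values
        )
        frames = frames[window - 1 :]
    return PerLipidOrderSeries(lipids, frames, values)


def chain_average_order(
    profile: OrderProfile, carbons: np.ndarray | None = None
) -> float:
    """Mean |S_CD| over the selected carbons (all carbons by default)."""
    if carbons is None:
        carbons = profile.carbons
    carbons = np.asarray(carbons)
    if carbons.size == 0:
        raise ValidationError("carbon selection must be non-empty")
    mask = np.isin(profile.carbons, carbons)
    if mask.sum() != carbons.size:
        missing = np.setdiff1d(carbons, profile.carbons)
        raise ValidationError(f"carbons {missing.tolist()} not in profile")
    return float(np.mean(profile.magnitudes[mask]))
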