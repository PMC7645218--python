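"""Synthetic fixtures with known ground truth.

Generates the inputs the rest of the package consumes: two-phase powder
spectra of perdeuterated chains (smooth plateau+decay order profiles, line
broadening, optional isotropic line, additive frequency-domain Gaussian
noise), cone-geometry bond-vector trajectories with closed-form order
parameters, and Markov-switching per-lipid order time series for the state
classifier.  All randomness flows from explicit integer seeds.

The named presets emulate the lineshape scenarios of a POPC/PSM/Chol
(4/4/2) raft mixture with and without 9 mol% serotonin: a single-phase
disordered POPC spectrum, two-phase POPC (60/40 disordered/ordered) and
PSM (37/63) mixtures, and a serotonin-d4 scenario with an isotropic
contribution (28/65/7).  The percentages parameterize scenarios with known
ground truth; they are generator conventions, not re-derivations of any
experimental dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .profiles import ChainDescriptor, OrderProfile, get_chain
from .spectra import (
    AcquisitionParams,
    PhaseModel,
    Spectrum,
    build_chain_model,
    simulate_fid,
    fid_to_spectrum,
)

__all__ = [
    "ProfileSpec",
    "SpectrumScenario",
    "GroundTruth",
    "gen_profile",
    "gen_two_phase_spectrum",
    "gen_cone_trajectory",
    "gen_markov_order_series",
    "stationary_distribution",
    "PRESETS",
]


@dataclass(frozen=True)
class ProfileSpec:
    """Plateau + exponential-decay parameterization of an order profile.

    orders(c) = plateau                       for c <= knee
              = plateau * exp(-(c-knee)/decay) beyond,
    with an independently specified methyl order for CD3-terminated
    chains.
    """

    plateau: float
    knee: float = 8.0
    decay: float = 3.0
    methyl: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.plateau <= 0.5):
            raise ValidationError("plateau order must be in (0, 0.5]")
        if self.decay <= 0:
            raise ValidationError("decay constant must be positive")
        if self.methyl is not None and not (0 <= self.methyl <= 0.5):
            raise ValidationError("methyl order must be in [0, 0.5]")


def gen_profile(
    spec: ProfileSpec, chain: "str | ChainDescriptor"
) -> OrderProfile:
    """Smooth monotone order profile for a chain from a ProfileSpec."""
    chain = get_chain(chain)
    meth = chain.methylene_carbons.astype(float)
    orders = spec.plateau * np.exp(
        -np.maximum(0.0, meth - spec.knee) / spec.decay
    )
    if chain.methyl:
        if spec.methyl is None:
            raise ValidationError(
                f"chain {chain.label!r} has a terminal methyl; spec.methyl required"
            )
        if spec.methyl > orders[-1] + 1e-12:
            raise ValidationError(
                f"methyl order {spec.methyl} exceeds last methylene order "
                f"{orders[-1]:.4f}"
            )
        orders = np.append(orders, spec.methyl)
    return OrderProfile(chain.label, chain.carbons, orders)


@dataclass(frozen=True)
class SpectrumScenario:
    """Ground-truth description of one synthetic two-phase spectrum."""

    fraction_I: float
    fraction_II: float
    profile_I: ProfileSpec
    profile_II: ProfileSpec | None = None
    fraction_iso: float = 0.0
    lb_I: float = 100.0
    lb_II: float = 150.0
    lb_iso: float = 50.0
    snr: float = math.inf
    seed: int = 0
    temperature: float = 30.0
    chain: str = "palmitoyl-d31"

    def __post_init__(self) -> None:
        fr = (self.fraction_I, self.fraction_II, self.fraction_iso)
        if any(f < 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValidationError("fractions must be >= 0 and sum to 1")
        if self.fraction_II > 0 and self.profile_II is None:
            raise ValidationError("fraction_II > 0 requires profile_II")
        if not self.snr > 0:
            raise ValidationError("snr must be positive")

    @property
    def fractions(self) -> np.ndarray:
        return np.array([self.fraction_I, self.fraction_II, self.fraction_iso])


@dataclass
class GroundTruth:
    """What the generator actually put into a synthetic spectrum."""

    scenario: SpectrumScenario
    profile_I: OrderProfile
    profile_II: OrderProfile | None
    noise_sd: float

    def to_dict(self) -> dict:
        sc = self.scenario
        out = {
            "chain": sc.chain,
            "fraction_I": sc.fraction_I,
            "fraction_II": sc.fraction_II,
            "fraction_iso": sc.fraction_iso,
            "lb_I": sc.lb_I,
            "lb_II": sc.lb_II,
            "lb_iso": sc.lb_iso,
            "snr": None if math.isinf(sc.snr) else sc.snr,
            "seed": sc.seed,
            "temperature": sc.temperature,
            "noise_sd": self.noise_sd,
            "orders_I": self.profile_I.orders.tolist(),
        }
        if self.profile_II is not None:
            out["orders_II"] = self.profile_II.orders.tolist()
        return out


def gen_two_phase_spectrum(
    scenario: SpectrumScenario,
    params: AcquisitionParams | None = None,
) -> tuple[Spectrum, GroundTruth]:
    """Forward-simulate a scenario and add frequency-domain noise.

    Identical seeds give bit-identical output.  Noise sd is
    max(intensity)/snr; snr = inf reproduces the noiseless simulation.
    """
    params = params or AcquisitionParams()
    chain = get_chain(scenario.chain)
    prof_I = gen_profile(scenario.profile_I, chain)
    prof_II = (
        gen_profile(scenario.profile_II, chain)
        if scenario.profile_II is not None
        else None
    )
    phases: list[PhaseModel] = []
    fractions: list[float] = []
    if scenario.fraction_I > 0:
        phases.append(build_chain_model(prof_I, chain, scenario.lb_I, "phase-I"))
        fractions.append(scenario.fraction_I)
    if scenario.fraction_II > 0:
        phases.append(build_chain_model(prof_II, chain, scenario.lb_II, "phase-II"))
        fractions.append(scenario.fraction_II)
    if scenario.fraction_iso > 0:
        phases.append(
            PhaseModel(
                "isotropic", (), isotropic_weight=1.0, isotropic_lb=scenario.lb_iso
            )
        )
        fractions.append(scenario.fraction_iso)
    spectrum = fid_to_spectrum(simulate_fid(phases, params, fractions))
    noise_sd = 0.0
    if math.isfinite(scenario.snr):
        noise_sd = float(np.max(spectrum.intensities) / scenario.snr)
        rng = np.random.default_rng(scenario.seed)
        spectrum = Spectrum(
            spectrum.frequencies,
            spectrum.intensities + rng.normal(0.0, noise_sd, spectrum.intensities.size),
            params,
        )
    return spectrum, GroundTruth(scenario, prof_I, prof_II, noise_sd)


def gen_cone_trajectory(
    theta0: float,
    n_lipids: int = 10,
    n_frames: int = 100,
    seed: int = 0,
    carbons: tuple[int, ...] = (2,),
    normal: np.ndarray | None = None,
):
    """Bond vectors on a cone of fixed polar angle with random azimuth.

    Expected order parameter is exactly P2(cos theta0) =
    (3 cos^2 theta0 - 1)/2 for every carbon, lipid, and frame.
    """
    from .md_order import VectorTrajectory

    if not (0.0 <= theta0 <= 180.0):
        raise ValidationError("theta0 must be in [0, 180] degrees")
    rng = np.random.default_rng(seed)
    n = n_frames * n_lipids * len(carbons)
    frames = np.repeat(np.arange(n_frames), n_lipids * len(carbons))
    lipids = np.tile(np.repeat(np.arange(n_lipids), len(carbons)), n_frames)
    carb = np.tile(np.asarray(carbons, dtype=int), n_frames * n_lipids)
    az = rng.uniform(0.0, 2.0 * np.pi, n)
    th = math.radians(theta0)
    vecs = np.column_stack(
        [np.sin(th) * np.cos(az), np.sin(th) * np.sin(az), np.full(n, np.cos(th))]
    )
    if normal is None:
        normal = np.array([0.0, 0.0, 1.0])
    else:
        # place the cone about the requested normal: rotate z onto it
        normal = np.asarray(normal, dtype=float)
        normal = normal / np.linalg.norm(normal)
        rot = _rotation_from_z(normal)
        vecs = vecs @ rot.T
    return VectorTrajectory(frames, lipids, carb, vecs, normal)


def _rotation_from_z(target: np.ndarray) -> np.ndarray:
    """Rotation matrix taking the +z axis onto ``target`` (unit vector)."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, target)
    c = float(z @ target)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def stationary_distribution(transition_matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix."""
    p = np.asarray(transition_matrix, dtype=float)
    vals, vecs = np.linalg.eig(p.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def gen_markov_order_series(
    transition_matrix: np.ndarray,
    emission_means: np.ndarray,
    emission_sds: np.ndarray,
    n_lipids: int = 200,
    n_frames: int = 2000,
    seed: int = 0,
    initial_probs: np.ndarray | None = None,
):
    """Markov-switching Gaussian order series plus the true state paths.

    Each lipid is an independent chain started from ``initial_probs``
    (stationary distribution by default).  Returns
    (PerLipidOrderSeries, true_paths) with true_paths of shape
    (n_lipids, n_frames).
    """
    from .md_order import PerLipidOrderSeries

    p = np.asarray(transition_matrix, dtype=float)
    means = np.asarray(emission_means, dtype=float)
    sds = np.asarray(emission_sds, dtype=float)
    k = p.shape[0]
    if p.shape != (k, k) or np.any(p < 0) or np.any(np.abs(p.sum(axis=1) - 1) > 1e-9):
        raise ValidationError("transition_matrix must be row-stochastic")
    if means.shape != (k,) or sds.shape != (k,):
        raise ValidationError("means/sds must have one entry per state")
    if np.any(sds <= 0):
        raise ValidationError("emission sds must be positive")
    if initial_probs is None:
        initial_probs = stationary_distribution(p)
    rng = np.random.default_rng(seed)
    cum = np.cumsum(p, axis=1)
    states = np.empty((n_lipids, n_frames), dtype=int)
    states[:, 0] = rng.choice(k, size=n_lipids, p=initial_probs)
    u = rng.uniform(size=(n_lipids, n_frames - 1))
    for t in range(1, n_frames):
        states[:, t] = (u[:, t - 1, None] >= cum[states[:, t - 1]]).sum(axis=1)
    values = rng.normal(means[states], sds[states])
    # clip to the geometric range of a P2 mean; Gaussian tails may poke out
    values = np.clip(values, -0.5, 1.0)
    series = PerLipidOrderSeries(
        np.arange(n_lipids), np.arange(n_frames), values
    )
    return series, states


def _presets() -> dict[str, SpectrumScenario]:
    c16_ld = ProfileSpec(plateau=0.21, knee=8.0, decay=3.2, methyl=0.020)
    return {
        # single-phase disordered POPC (no serotonin)
        "popc_no5ht": SpectrumScenario(
            fraction_I=1.0,
            fraction_II=0.0,
            profile_I=c16_ld,
            lb_I=100.0,
        ),
        # POPC with serotonin: 60% disordered / 40% ordered
        "popc_5ht": SpectrumScenario(
            fraction_I=0.60,
            fraction_II=0.40,
            profile_I=ProfileSpec(plateau=0.19, knee=8.0, decay=3.0, methyl=0.018),
            profile_II=ProfileSpec(plateau=0.34, knee=10.0, decay=2.8, methyl=0.040),
            lb_I=100.0,
            lb_II=150.0,
        ),
        # PSM with serotonin: 37% disordered / 63% ordered
        "psm_5ht": SpectrumScenario(
            fraction_I=0.37,
            fraction_II=0.63,
            profile_I=ProfileSpec(plateau=0.23, knee=8.0, decay=3.0, methyl=0.022),
            profile_II=ProfileSpec(plateau=0.38, knee=10.0, decay=3.0, methyl=0.045),
            lb_I=100.0,
            lb_II=150.0,
        ),
        # serotonin-d4: 28% disordered / 65% ordered / 7% isotropic
        "5ht_d4": SpectrumScenario(
            fraction_I=0.28,
            fraction_II=0.65,
            fraction_iso=0.07,
            profile_I=ProfileSpec(plateau=0.045, knee=2.0, decay=2.5),
            profile_II=ProfileSpec(plateau=0.060, knee=2.0, decay=2.5),
            lb_I=60.0,
            lb_II=80.0,
            lb_iso=40.0,
            chain="serotonin-d4",
        ),
    }


#: Named scenario presets (see module docstring).
PRESETS: dict[str, SpectrumScenario] = _presets()
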