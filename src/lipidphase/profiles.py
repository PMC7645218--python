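"""Acyl-chain descriptors and per-carbon order-parameter profiles.

The order parameter S_CD of a methylene (or methyl) deuteron is the time
average of P2(cos theta) for the C-D bond relative to the bilayer normal;
its magnitude is at most 0.5 for a rotating all-trans chain segment.
Profiles follow the perdeuterated-chain assignment convention: the largest
quadrupolar splitting is assigned to the C-2 position, the next largest to
C-3, and so on toward the terminal methyl.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Tolerance used when checking the 0.5 methylene order ceiling.
ORDER_CEILING_TOL = 1e-9


@dataclass(frozen=True)
class ChainDescriptor:
    """A deuterated chain: which carbons carry deuterons and how many.

    Carbons are numbered 2..n_carbons (C-1 is the carbonyl/backbone carbon
    and carries no deuterons).  If ``methyl`` is True the last carbon is a
    terminal CD3 group (3 deuterons); all other carbons are CD2 groups
    (2 deuterons each).
    """

    label: str
    n_carbons: int = 16
    methyl: bool = True

    def __post_init__(self) -> None:
        min_c = 3 if self.methyl else 2
        if self.n_carbons < min_c:
            raise ValidationError(
                f"chain {self.label!r}: n_carbons must be >= {min_c}, "
                f"got {self.n_carbons}"
            )

    @property
    def carbons(self) -> np.ndarray:
        """Deuterated carbon indices, 2..n_carbons inclusive."""
        return np.arange(2, self.n_carbons + 1)

    @property
    def methylene_carbons(self) -> np.ndarray:
        last = self.n_carbons - 1 if self.methyl else self.n_carbons
        return np.arange(2, last + 1)

    @property
    def deuteron_weights(self) -> np.ndarray:
        """Relative deuteron count per carbon (2 per CD2, 3 for CD3)."""
        w = np.full(self.n_carbons - 1, 2.0)
        if self.methyl:
            w[-1] = 3.0
        return w

    @property
    def n_deuterons(self) -> int:
        return int(self.deuteron_weights.sum())

    @property
    def n_segments(self) -> int:
        """Number of C-C segments used in chain-extension bookkeeping."""
        return self.n_carbons - 1


#: Chains the command line and presets refer to by name.  palmitoyl-d31 is
#: a C16 perdeuterated chain (14 CD2 + CD3 = 31 deuterons); serotonin-d4
#: carries two labelled side-chain methylenes; cholesterol-d6 three CD2-like
#: sites.  The carbon numbering of the non-acyl chains is a bookkeeping
#: convention only.
CHAINS: dict[str, ChainDescriptor] = {
    "palmitoyl-d31": ChainDescriptor("palmitoyl-d31", 16, True),
    "serotonin-d4": ChainDescriptor("serotonin-d4", 3, False),
    "cholesterol-d6": ChainDescriptor("cholesterol-d6", 4, False),
}


def get_chain(chain: "str | ChainDescriptor") -> ChainDescriptor:
    """Resolve a chain given by name or descriptor."""
    if isinstance(chain, ChainDescriptor):
        return chain
    try:
        return CHAINS[chain]
    except KeyError:
        known = ", ".join(sorted(CHAINS))
        raise ValidationError(f"unknown chain {chain!r}; known chains: {known}")


@dataclass
class OrderProfile:
    """Per-carbon order parameters for one chain in one phase.

    ``orders`` are |S_CD| magnitudes by default.  Trajectory-derived
    profiles may carry signed values (``signed=True``), in which case the
    magnitude ceiling is relaxed to the geometric range [-0.5, 1].
    """

    chain_label: str
    carbons: np.ndarray
    orders: np.ndarray
    signed: bool = False

    def __post_init__(self) -> None:
        self.carbons = np.asarray(self.carbons, dtype=int)
        self.orders = np.asarray(self.orders, dtype=float)
        if self.carbons.ndim != 1 or self.carbons.size == 0:
            raise ValidationError("profile needs at least one carbon")
        if self.carbons.shape != self.orders.shape:
            raise ValidationError("carbons and orders must have equal length")
        if not np.all(np.isfinite(self.orders)):
            raise ValidationError("orders must be finite")
        if np.any(np.diff(self.carbons) <= 0):
            raise ValidationError("carbons must be strictly increasing")
        if self.signed:
            lo, hi = -0.5 - ORDER_CEILING_TOL, 1.0 + ORDER_CEILING_TOL
        else:
            lo, hi = -ORDER_CEILING_TOL, 0.5 + ORDER_CEILING_TOL
        if np.any(self.orders < lo) or np.any(self.orders > hi):
            raise ValidationError(
                f"orders outside [{lo:.3g}, {hi:.3g}] for "
                f"{'signed' if self.signed else 'magnitude'} profile"
            )

    @property
    def magnitudes(self) -> np.ndarray:
        return np.abs(self.orders)

    @property
    def is_monotone(self) -> bool:
        """True if magnitudes are non-increasing with carbon index."""
        return bool(np.all(np.diff(self.magnitudes) <= 1e-12))

    def order_at(self, carbon: int) -> float:
        idx = np.nonzero(self.carbons == carbon)[0]
        if idx.size == 0:
            raise ValidationError(f"carbon {carbon} not in profile")
        return float(self.orders[idx[0]])

    def missing_carbons(self, chain: ChainDescriptor) -> np.ndarray:
        return np.setdiff1d(chain.carbons, self.carbons)
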