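"""Core reaction-diffusion model of the JNK/AP-1 - JAK/STAT signalling field.

Four species live on a 1D compartmentalised domain: a diffusible wound
signal (EIG), the stress-pathway activity it drives (JNK), the cytokine
pathway (JAK) and its diffusible ligand (UPD).  JAK represses JNK in both
topologies; the *mutual* topology adds the reciprocal repression of JAK by
JNK.  All dynamics are expressed in nondimensional (characteristic) units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import numpy as np

from . import _kernels

__all__ = [
    "SPECIES",
    "PARAM_NAMES",
    "HILL_NAMES",
    "DimensionalParameters",
    "DimensionlessParameters",
    "ModelConfiguration",
    "SpeciesState",
    "nondimensionalize",
    "laplacian",
    "rhs",
]

SPECIES = ("EIG", "JNK", "JAK", "UPD")

#: canonical column order for parameter tables (CSV round-trips, sampling)
PARAM_NAMES = (
    "gamma",
    "k_deg_JNK",
    "k_deg_JAK",
    "k_deg_UPD",
    "k_act_EIG",
    "k_act_JNK",
    "k_act_JAK",
    "k_act_UPD",
    "K_m_EIG",
    "K_m_JNK",
    "K_m_JAK",
    "K_m_UPD",
    "k_inh_JAK_by_JNK",
    "k_inh_JNK_by_JAK",
    "d",
    "n1",
    "n2",
    "n3",
    "n4",
    "ni1",
    "ni2",
)

HILL_NAMES = ("n1", "n2", "n3", "n4", "ni1", "ni2")


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DimensionalParameters:
    """Rates and constants of the dimensional equation set.

    Units: productions ``b_*`` in concentration/time, degradations in 1/time,
    activations in concentration/time (``k_act_JAK`` in 1/time: it multiplies
    the UPD concentration), Michaelis constants in concentration, inhibition
    constants in 1/concentration**n, diffusion in length**2/time and the
    characteristic length ``L`` in length.
    """

    b_EIG: float = 1.0
    b_JNK: float = 1.0
    b_JAK: float = 1.0
    b_UPD: float = 1.0
    k_deg_EIG: float = 1.0
    k_deg_JNK: float = 1.0
    k_deg_JAK: float = 1.0
    k_deg_UPD: float = 1.0
    k_act_EIG: float = 1.0
    k_act_JNK: float = 1.0
    k_act_JAK: float = 1.0
    k_act_UPD: float = 1.0
    K_m_EIG: float = 1.0
    K_m_JNK: float = 1.0
    K_m_JAK: float = 1.0
    K_m_UPD: float = 1.0
    k_inh_JNK_by_JAK: float = 1.0
    k_inh_JAK_by_JNK: float = 1.0
    D_EIG: float = 1.0
    D_UPD: float = 1.0
    L: float = 1.0
    n1: float = 1.0
    n2: float = 1.0
    n3: float = 1.0
    n4: float = 1.0
    ni1: float = 1.0
    ni2: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v!r}")
            if f.name.startswith("b_"):
                if v < 0:
                    raise ValueError(f"{f.name} must be >= 0, got {v}")
            elif f.name in HILL_NAMES:
                if v < 1:
                    raise ValueError(f"Hill coefficient {f.name} must be >= 1, got {v}")
            elif v <= 0:
                raise ValueError(f"{f.name} must be > 0, got {v}")


@dataclass(frozen=True)
class DimensionlessParameters:
    """The scanned constants of the nondimensional system."""

    gamma: float = 1.0
    k_deg_JNK: float = 1.0
    k_deg_JAK: float = 1.0
    k_deg_UPD: float = 1.0
    k_act_EIG: float = 1.0
    k_act_JNK: float = 1.0
    k_act_JAK: float = 1.0
    k_act_UPD: float = 1.0
    K_m_EIG: float = 1.0
    K_m_JNK: float = 1.0
    K_m_JAK: float = 1.0
    K_m_UPD: float = 1.0
    k_inh_JAK_by_JNK: float = 1.0
    k_inh_JNK_by_JAK: float = 1.0
    d: float = 1.0
    n1: float = 1.0
    n2: float = 1.0
    n3: float = 1.0
    n4: float = 1.0
    ni1: float = 1.0
    ni2: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v!r}")
            if f.name in HILL_NAMES:
                if v < 1:
                    raise ValueError(f"Hill coefficient {f.name} must be >= 1, got {v}")
            elif f.name.startswith(("k_act", "k_inh")):
                # zero switches a feedback or repression off entirely; the
                # sampler never draws it but closed-form oracles rely on it
                if v < 0:
                    raise ValueError(f"{f.name} must be >= 0, got {v}")
            elif v <= 0:
                raise ValueError(f"{f.name} must be > 0, got {v}")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    def as_array(self) -> np.ndarray:
        """Values in PARAM_NAMES order (the kernel calling convention)."""
        return np.array([getattr(self, name) for name in PARAM_NAMES], dtype=float)

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "DimensionlessParameters":
        return cls(**{name: float(d[name]) for name in PARAM_NAMES})


def nondimensionalize(p: DimensionalParameters) -> DimensionlessParameters:
    """Map dimensional rates onto the scanned dimensionless constants.

    gamma = k_deg_EIG * L^2 / D_EIG compares EIG turnover with its diffusion
    time; degradations are expressed relative to EIG turnover; activation
    rates relative to the matching basal production (``k_act_JAK`` picks up
    the diffusion time and the UPD/JAK production ratio because it multiplies
    the UPD concentration); Michaelis constants are divided by the
    concentration scale b * L^2 / D_EIG of their species; inhibition
    constants are multiplied by that scale.  Hill coefficients and the
    diffusion ratio d = D_UPD / D_EIG pass through.
    """
    for name in ("b_EIG", "b_JNK", "b_JAK", "b_UPD"):
        if getattr(p, name) <= 0:
            raise ValueError(f"nondimensionalization requires {name} > 0")
    tau = p.L**2 / p.D_EIG  # diffusion time of EIG across the field
    return DimensionlessParameters(
        gamma=p.k_deg_EIG * tau,
        k_deg_JNK=p.k_deg_JNK / p.k_deg_EIG,
        k_deg_JAK=p.k_deg_JAK / p.k_deg_EIG,
        k_deg_UPD=p.k_deg_UPD / p.k_deg_EIG,
        k_act_EIG=p.k_act_EIG / p.b_EIG,
        k_act_JNK=p.k_act_JNK / p.b_JNK,
        k_act_JAK=p.k_act_JAK * tau * p.b_UPD / p.b_JAK,
        k_act_UPD=p.k_act_UPD / p.b_UPD,
        K_m_EIG=p.K_m_EIG / (tau * p.b_EIG),
        K_m_JNK=p.K_m_JNK / (tau * p.b_JNK),
        K_m_JAK=p.K_m_JAK / (tau * p.b_JAK),
        K_m_UPD=p.K_m_UPD / (tau * p.b_UPD),
        k_inh_JAK_by_JNK=p.k_inh_JAK_by_JNK * tau * p.b_JAK,
        k_inh_JNK_by_JAK=p.k_inh_JNK_by_JAK * tau * p.b_JNK,
        d=p.D_UPD / p.D_EIG,
        n1=p.n1,
        n2=p.n2,
        n3=p.n3,
        n4=p.n4,
        ni1=p.ni1,
        ni2=p.ni2,
    )


# ---------------------------------------------------------------------------
# spatial configuration
# ---------------------------------------------------------------------------

TOPOLOGIES = ("unidirectional", "mutual")
BOUNDARIES = ("zero-flux", "absorbing")


@dataclass(frozen=True)
class ModelConfiguration:
    """Topology, grid, wound geometry and integration controls."""

    topology: str = "mutual"
    n_compartments: int = 100
    domain: tuple[float, float] = (0.0, 1.0)
    wound: tuple[float, float] = (0.0, 0.05)
    initial_value: float = 0.1
    boundary: str = "zero-flux"
    tolerance: float = 1e-6
    horizon: float = 1e3

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"topology must be one of {TOPOLOGIES}, got {self.topology!r}")
        if self.boundary not in BOUNDARIES:
            raise ValueError(f"boundary must be one of {BOUNDARIES}, got {self.boundary!r}")
        if self.n_compartments < 2:
            raise ValueError("need at least 2 compartments")
        lo, hi = self.domain
        if not hi > lo:
            raise ValueError("domain must have positive extent")
        wlo, whi = self.wound
        if not (lo <= wlo <= whi <= hi):
            raise ValueError(f"wound {self.wound} must be a sub-interval of the domain {self.domain}")
        if self.initial_value < 0:
            raise ValueError("initial state must be >= 0")
        if self.tolerance <= 0 or self.horizon <= 0:
            raise ValueError("tolerance and horizon must be > 0")

    @property
    def dx(self) -> float:
        lo, hi = self.domain
        return (hi - lo) / self.n_compartments

    @property
    def centers(self) -> np.ndarray:
        """Compartment centres at (i + 1/2) * dx."""
        lo, _ = self.domain
        return lo + (np.arange(self.n_compartments) + 0.5) * self.dx

    @property
    def wound_indicator(self) -> np.ndarray:
        """1 where the compartment centre lies inside the wound, else 0."""
        c = self.centers
        wlo, whi = self.wound
        return ((c >= wlo) & (c <= whi)).astype(float)

    def with_topology(self, topology: str) -> "ModelConfiguration":
        return replace(self, topology=topology)


@dataclass
class SpeciesState:
    """Concentration of each species per compartment."""

    EIG: np.ndarray
    JNK: np.ndarray
    JAK: np.ndarray
    UPD: np.ndarray

    def __post_init__(self) -> None:
        arrs = [np.asarray(getattr(self, s), dtype=float) for s in SPECIES]
        n = arrs[0].shape
        for s, a in zip(SPECIES, arrs):
            if a.ndim != 1 or a.shape != n:
                raise ValueError("all species vectors must be 1D with a common length")
            object.__setattr__(self, s, a)

    @property
    def n_compartments(self) -> int:
        return self.EIG.shape[0]

    @classmethod
    def uniform(cls, value: float, n: int) -> "SpeciesState":
        return cls(*(np.full(n, float(value)) for _ in SPECIES))

    @classmethod
    def from_config(cls, cfg: ModelConfiguration) -> "SpeciesState":
        return cls.uniform(cfg.initial_value, cfg.n_compartments)

    def stack(self) -> np.ndarray:
        """(4, N) array in SPECIES order."""
        return np.stack([self.EIG, self.JNK, self.JAK, self.UPD])

    @classmethod
    def from_stack(cls, a: np.ndarray) -> "SpeciesState":
        return cls(*(np.array(a[i], dtype=float) for i in range(4)))

    def pack(self) -> np.ndarray:
        """Flat vector interleaved per compartment (bandwidth-4 Jacobian)."""
        return self.stack().T.reshape(-1).copy()

    @classmethod
    def unpack(cls, y: np.ndarray) -> "SpeciesState":
        return cls.from_stack(np.asarray(y).reshape(-1, 4).T)

    def copy(self) -> "SpeciesState":
        return SpeciesState(*(getattr(self, s).copy() for s in SPECIES))


# ---------------------------------------------------------------------------
# spatial operator
# ---------------------------------------------------------------------------


def laplacian(values: np.ndarray, cfg: ModelConfiguration, out: np.ndarray | None = None) -> np.ndarray:
    """Second-difference operator scaled by 1/dx^2.

    Zero-flux ends reflect the boundary compartment (so the output sums to
    zero: no mass enters or leaves); the absorbing variant uses zero-value
    ghost compartments.
    """
    u = np.asarray(values, dtype=float)
    if u.ndim != 1 or u.shape[0] != cfg.n_compartments:
        raise ValueError("field length must equal the compartment count")
    if cfg.n_compartments < 2:
        raise ValueError("need at least 2 compartments")
    inv_dx2 = 1.0 / cfg.dx**2
    if out is None:
        out = np.empty_like(u)
    out[1:-1] = (u[:-2] - 2.0 * u[1:-1] + u[2:]) * inv_dx2
    if cfg.boundary == "zero-flux":
        out[0] = (u[1] - u[0]) * inv_dx2
        out[-1] = (u[-2] - u[-1]) * inv_dx2
    else:  # absorbing
        out[0] = (u[1] - 2.0 * u[0]) * inv_dx2
        out[-1] = (u[-2] - 2.0 * u[-1]) * inv_dx2
    return out


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------


def _rhs_stack(s: np.ndarray, q: DimensionlessParameters, cfg: ModelConfiguration,
               wound: np.ndarray | None = None) -> np.ndarray:
    """Derivative of a (4, N) state stack; no validation, clips at 0.

    Clipping keeps fractional Hill powers defined when an adaptive solver
    probes slightly negative states; linear degradation still acts on the
    raw values so such excursions decay.
    """
    if wound is None:
        wound = cfg.wound_indicator
    eig, jnk, jak, upd = np.maximum(s, 0.0)
    g = q.gamma

    h1 = jnk ** q.n1
    d_eig = g * (wound - eig + q.k_act_EIG * h1 / (q.K_m_EIG ** q.n1 + h1))
    d_eig += laplacian(eig, cfg)

    h2 = eig ** q.n2
    inh_by_jak = 1.0 + q.k_inh_JNK_by_JAK ** q.ni1 * jak ** q.ni1
    d_jnk = g * (1.0 - q.k_deg_JNK * jnk
                 + q.k_act_JNK * h2 / ((q.K_m_JNK ** q.n2 + h2) * inh_by_jak))

    h3 = jak ** q.n3
    denom = q.K_m_JAK ** q.n3 + h3
    if cfg.topology == "mutual":
        denom = denom * (1.0 + q.k_inh_JAK_by_JNK ** q.ni2 * jnk ** q.ni2)
    d_jak = g * (1.0 - q.k_deg_JAK * jak + q.k_act_JAK * upd * h3 / denom)

    h4 = jnk ** q.n4
    d_upd = g * (1.0 - q.k_deg_UPD * upd + q.k_act_UPD * h4 / (q.K_m_UPD ** q.n4 + h4))
    d_upd += q.d * laplacian(upd, cfg)

    return np.stack([d_eig, d_jnk, d_jak, d_upd])


def rhs(state: SpeciesState, q: DimensionlessParameters, cfg: ModelConfiguration) -> SpeciesState:
    """Time derivative of ``state`` under the nondimensional equations.

    Diffusion applies to EIG and UPD only; the repression of JAK by JNK is
    active only in the mutual topology.
    """
    if state.n_compartments != cfg.n_compartments:
        raise ValueError("state and configuration disagree on the compartment count")
    stack = state.stack()
    if np.any(stack < 0):
        raise ValueError("state must be non-negative")
    if not np.all(np.isfinite(stack)):
        raise ValueError("state contains non-finite entries")
    return SpeciesState.from_stack(_rhs_stack(stack, q, cfg))


def make_packed_rhs(q: DimensionlessParameters, cfg: ModelConfiguration, compiled: bool = True):
    """Flat-vector RHS ``f(y, t)`` for LSODA, on the interleaved packing.

    Uses the compiled kernel when numba is importable; ``compiled=False``
    forces the readable numpy path (the reference implementation).
    """
    wound = cfg.wound_indicator
    if compiled and _kernels.HAVE_NUMBA:
        p = q.as_array()
        inv_dx2 = 1.0 / cfg.dx**2
        mutual = cfg.topology == "mutual"
        reflect = cfg.boundary == "zero-flux"

        def f(y: np.ndarray, t: float = 0.0) -> np.ndarray:
            return _kernels.rhs_packed(y, t, p, wound, inv_dx2, mutual, reflect)

        return f

    def f(y: np.ndarray, t: float = 0.0) -> np.ndarray:
        s = y.reshape(-1, 4).T
        return _rhs_stack(s, q, cfg, wound).T.reshape(-1)

    return f
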