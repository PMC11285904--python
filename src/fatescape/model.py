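"""Four-factor stem-cell differentiation network.

The model tracks four transcription factors — Nanog (N), the Oct4–Sox2
complex (O), Fgf4 (F) and Gata6 (G) — whose mutual activation and
repression produce two attracting cell states: a pluripotent state
(high Nanog, low Gata6) and a differentiated state (low Nanog, high
Gata6).  Each factor is produced at a saturating (Shea–Ackers / Hill)
rate and degrades linearly with rate ``gamma``.  The external cytokine
LIF sustains pluripotency by feeding into Nanog production through the
Oct4–Sox2-gated activation term; the inhibitor level ``I3`` and the
reprogramming rate ``alpha`` are carried as fields but fixed at zero in
this analysis.

The deterministic rate equations are

    dN/dt = k0·O·(c0 + c1·N² + c2·LIF)
            / (1 + k0·O·(c1·N² + c2·LIF + c3·F²) + c4·O·G²) − γ·N
    dO/dt = α + (e0 + e1·O) / (1 + e1·O + e2·G²) − γ·O
    dF/dt = (a0 + a1·O) / (1 + a1·O) − γ·F
    dG/dt = (b0 + b1·G² + b3·O) / (1 + b1·G² + b2·N² + b3·O) − γ·G

Abundances are treated as unit-scaled molecule counts (system size 1),
so the same rate laws serve directly as propensities of the underlying
jump process (one production and one degradation channel per species).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "SPECIES",
    "PARAM_NAMES",
    "ModelParameters",
    "true_parameters",
    "ode_rhs",
    "propensities",
    "stoichiometry",
    "load_parameters",
    "save_parameters",
]

#: Canonical species order used everywhere in the package.
SPECIES = ("Nanog", "Oct4-Sox2", "Fgf4", "Gata6")

#: The 16 kinetic constants, in a fixed order (the parameter vector layout).
PARAM_NAMES = (
    "a0", "a1", "b0", "b1", "b2", "b3",
    "c0", "c1", "c2", "c3", "c4",
    "e0", "e1", "e2", "k0", "gamma",
)

#: Full layout of the numeric parameter vector handed to the simulation
#: kernels: the 16 kinetic constants followed by the external signals.
VECTOR_FIELDS = PARAM_NAMES + ("LIF", "I3", "alpha")


@dataclass(frozen=True)
class ModelParameters:
    """Kinetic constants and external signals of the 4-gene network.

    Defaults are the published reference parameterization with LIF = 50
    and I3 = alpha = 0.  All fields must be nonnegative.
    """

    a0: float = 0.01
    a1: float = 1.0
    b0: float = 0.005
    b1: float = 0.005
    b2: float = 1.0
    b3: float = 1.0
    c0: float = 0.01
    c1: float = 0.4
    c2: float = 1.0
    c3: float = 0.1
    c4: float = 0.00135
    e0: float = 0.01
    e1: float = 1.0
    e2: float = 1.0
    k0: float = 0.005
    gamma: float = 0.01
    LIF: float = 50.0
    I3: float = 0.0
    alpha: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(
                    f"parameter {f.name!r} must be finite and >= 0, got {v}"
                )

    def to_vector(self) -> np.ndarray:
        """Flat float64 vector in :data:`VECTOR_FIELDS` order."""
        return np.array([getattr(self, k) for k in VECTOR_FIELDS], dtype=np.float64)

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "ModelParameters":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(VECTOR_FIELDS),):
            raise ValueError(f"expected vector of length {len(VECTOR_FIELDS)}")
        return cls(**dict(zip(VECTOR_FIELDS, vec.tolist())))

    def replace(self, **kw) -> "ModelParameters":
        return replace(self, **kw)

    def kinetic_vector(self) -> np.ndarray:
        """The 16 kinetic constants only, in :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=np.float64)


def true_parameters(LIF: float = 50.0) -> ModelParameters:
    """Reference ("true") parameter set used to generate synthetic data."""
    return ModelParameters(LIF=LIF)


def _check_state(state) -> np.ndarray:
    x = np.asarray(state, dtype=float)
    if x.shape != (4,):
        raise ValueError("state must have 4 components (N, O, F, G)")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError(f"state components must be finite and >= 0, got {x}")
    return x


def propensities(state, params: ModelParameters) -> np.ndarray:
    """Rates of the 8 reaction channels at ``state``.

    Entries 0–3 are the production terms of the four rate equations
    (everything except the linear decay); entries 4–7 are the
    degradation rates ``gamma * x``.  All entries are nonnegative.
    """
    x = _check_state(state)
    N, O, F, G = x
    p = params
    ko = p.k0 * O
    a = np.empty(8)
    num = ko * (p.c0 + p.c1 * N * N + p.c2 * p.LIF)
    den = 1.0 + ko * (p.c1 * N * N + p.c2 * p.LIF + p.c3 * F * F) + p.c4 * O * G * G
    a[0] = num / den
    a[1] = p.alpha + (p.e0 + p.e1 * O) / (1.0 + p.e1 * O + p.e2 * G * G)
    a[2] = (p.a0 + p.a1 * O) / (1.0 + p.a1 * O)
    a[3] = (p.b0 + p.b1 * G * G + p.b3 * O) / (1.0 + p.b1 * G * G + p.b2 * N * N + p.b3 * O)
    a[4:] = p.gamma * x
    return a


def stoichiometry() -> np.ndarray:
    """4×8 stoichiometric matrix: columns 0–3 are +e_j, columns 4–7 are −e_j."""
    S = np.zeros((4, 8), dtype=int)
    for j in range(4):
        S[j, j] = 1
        S[j, j + 4] = -1
    return S


def ode_rhs(state, params: ModelParameters) -> np.ndarray:
    """Deterministic right-hand side (dN/dt, dO/dt, dF/dt, dG/dt).

    Identical to ``stoichiometry() @ propensities(state, params)``.
    """
    a = propensities(state, params)
    return a[:4] - a[4:]


# -- flat key/value parameter files -----------------------------------------

def save_parameters(params: ModelParameters, path) -> None:
    """Write a parameter set as flat key: value text (YAML mapping)."""
    data = {k: float(getattr(params, k)) for k in VECTOR_FIELDS}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_parameters(path) -> ModelParameters:
    """Read a parameter set written by :func:`save_parameters`."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat key/value mapping")
    unknown = set(data) - set(VECTOR_FIELDS)
    if unknown:
        raise ValueError(f"{path}: unknown parameter keys {sorted(unknown)}")
    return ModelParameters(**{k: float(v) for k, v in data.items()})
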