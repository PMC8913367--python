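"""Parameter containers, bounds, and constrained/unconstrained transforms.

The legacy model's parameter vector mixes sign-constrained regression
coefficients (log-linear equilibrium surface), unit-interval legacy decay
rates, free interaction terms, observer random effects and two scale
parameters.  :class:`ModelParams` stores everything on the constrained
(scientific) scale; :class:`ParameterMap` maps the blocks that a given
:class:`ModelSpec` actually samples to an unconstrained real vector for the
sampler, with the associated log-Jacobian handled in the density.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

#: The five aggregated land-cover categories, in canonical order.
CLASSES = ("urban", "forest", "grassland", "wetland", "cropland")
N_CLASSES = len(CLASSES)

#: Direction slots for change covariates: index 0 = loss, 1 = gain.
DIRECTIONS = ("loss", "gain")

# Index pairs for the pairwise block (i <= k, row-major) and the
# linear x quadratic block (i != k, row-major).
PAIR_IDX = [(i, k) for i in range(N_CLASSES) for k in range(i, N_CLASSES)]
LINQUAD_IDX = [(i, k) for i in range(N_CLASSES) for k in range(N_CLASSES) if k != i]
PAIR_DIAG_POS = np.array([p for p, (i, k) in enumerate(PAIR_IDX) if i == k])
PAIR_OFF_POS = np.array([p for p, (i, k) in enumerate(PAIR_IDX) if i != k])

N_PAIR = len(PAIR_IDX)  # 15
N_LINQUAD = len(LINQUAD_IDX)  # 20
N_GAMMA = N_CLASSES * 2  # 10


@dataclass
class ModelParams:
    """Full parameter vector of the legacy model, on the constrained scale.

    Attributes
    ----------
    beta0:
        Intercept of the log-linear equilibrium surface, bounded below at 0.
    beta_lin:
        Linear land-cover effects, shape (5,), each >= 0.
    beta_pair:
        Pairwise second-order coefficients for i <= k, shape (15,).
        Diagonal (quadratic) entries are bounded above at 0; off-diagonal
        interactions are unbounded.
    beta_linquad:
        Linear x quadratic interaction coefficients for i != k, shape (20,),
        unbounded.
    gamma:
        Legacy decay rates, shape (5, 2): column 0 responds to losses,
        column 1 to gains; each entry lies in [0, 1].
    alpha_temp_lin, alpha_temp_quad:
        Linear (>= 0) and quadratic (<= 0) temperature effects.
    alpha_heterogeneity, alpha_time_of_day:
        Unbounded static-covariate effects.
    observer_effects:
        Per-observer deviations, shape (n_observers,).
    sigma_obs_re:
        Standard deviation of the observer random effect, >= 0.
    sigma:
        Residual standard deviation of the observation model, >= 0.
    """

    beta0: float = 0.0
    beta_lin: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES))
    beta_pair: np.ndarray = field(default_factory=lambda: np.zeros(N_PAIR))
    beta_linquad: np.ndarray = field(default_factory=lambda: np.zeros(N_LINQUAD))
    gamma: np.ndarray = field(default_factory=lambda: np.zeros((N_CLASSES, 2)))
    alpha_temp_lin: float = 0.0
    alpha_temp_quad: float = 0.0
    alpha_heterogeneity: float = 0.0
    alpha_time_of_day: float = 0.0
    observer_effects: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sigma_obs_re: float = 1.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        self.beta_lin = np.asarray(self.beta_lin, dtype=float)
        self.beta_pair = np.asarray(self.beta_pair, dtype=float)
        self.beta_linquad = np.asarray(self.beta_linquad, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float).reshape(N_CLASSES, 2)
        self.observer_effects = np.asarray(self.observer_effects, dtype=float)
        if self.beta_lin.shape != (N_CLASSES,):
            raise ValueError(f"beta_lin must have shape ({N_CLASSES},)")
        if self.beta_pair.shape != (N_PAIR,):
            raise ValueError(f"beta_pair must have shape ({N_PAIR},)")
        if self.beta_linquad.shape != (N_LINQUAD,):
            raise ValueError(f"beta_linquad must have shape ({N_LINQUAD},)")

    # -- bounds ---------------------------------------------------------
    def validate(self) -> None:
        """Raise ``ValueError`` if any stated bound is violated."""
        if self.beta0 < 0:
            raise ValueError("beta0 must be >= 0")
        if np.any(self.beta_lin < 0):
            raise ValueError("beta_lin entries must be >= 0")
        if np.any(self.beta_pair[PAIR_DIAG_POS] > 0):
            raise ValueError("quadratic (diagonal) beta_pair entries must be <= 0")
        if np.any((self.gamma < 0) | (self.gamma > 1)):
            raise ValueError("gamma entries must lie in [0, 1]")
        if self.alpha_temp_lin < 0:
            raise ValueError("alpha_temp_lin must be >= 0")
        if self.alpha_temp_quad > 0:
            raise ValueError("alpha_temp_quad must be <= 0")
        if self.sigma_obs_re < 0:
            raise ValueError("sigma_obs_re must be >= 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def in_bounds(self) -> bool:
        try:
            self.validate()
        except ValueError:
            return False
        return True

    @property
    def n_observers(self) -> int:
        return self.observer_effects.shape[0]

    def equilibrium_coefs(self) -> np.ndarray:
        """Concatenated coefficient vector [beta0, lin, pair, linquad]."""
        return np.concatenate(
            [[self.beta0], self.beta_lin, self.beta_pair, self.beta_linquad]
        )

    # -- flatten / unflatten --------------------------------------------
    _SCALARS = (
        "beta0",
        "alpha_temp_lin",
        "alpha_temp_quad",
        "alpha_heterogeneity",
        "alpha_time_of_day",
        "sigma_obs_re",
        "sigma",
    )

    def flatten(self) -> np.ndarray:
        """Full parameter vector (independent of any model-spec masking)."""
        return np.concatenate(
            [
                [self.beta0],
                self.beta_lin,
                self.beta_pair,
                self.beta_linquad,
                self.gamma.ravel(),
                [
                    self.alpha_temp_lin,
                    self.alpha_temp_quad,
                    self.alpha_heterogeneity,
                    self.alpha_time_of_day,
                ],
                self.observer_effects,
                [self.sigma_obs_re, self.sigma],
            ]
        )

    @classmethod
    def unflatten(cls, vec: np.ndarray, n_observers: int = 0) -> "ModelParams":
        vec = np.asarray(vec, dtype=float)
        expect = 1 + N_CLASSES + N_PAIR + N_LINQUAD + N_GAMMA + 4 + n_observers + 2
        if vec.shape != (expect,):
            raise ValueError(f"expected length {expect}, got {vec.shape}")
        pos = 0

        def take(n: int) -> np.ndarray:
            nonlocal pos
            out = vec[pos : pos + n]
            pos += n
            return out

        return cls(
            beta0=take(1)[0],
            beta_lin=take(N_CLASSES),
            beta_pair=take(N_PAIR),
            beta_linquad=take(N_LINQUAD),
            gamma=take(N_GAMMA).reshape(N_CLASSES, 2),
            alpha_temp_lin=take(1)[0],
            alpha_temp_quad=take(1)[0],
            alpha_heterogeneity=take(1)[0],
            alpha_time_of_day=take(1)[0],
            observer_effects=take(n_observers),
            sigma_obs_re=take(1)[0],
            sigma=take(1)[0],
        )

    def copy(self) -> "ModelParams":
        return ModelParams.unflatten(self.flatten(), self.n_observers)

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "beta_lin": self.beta_lin.tolist(),
            "beta_pair": self.beta_pair.tolist(),
            "beta_linquad": self.beta_linquad.tolist(),
            "gamma": self.gamma.tolist(),
            "alpha_temp_lin": self.alpha_temp_lin,
            "alpha_temp_quad": self.alpha_temp_quad,
            "alpha_heterogeneity": self.alpha_heterogeneity,
            "alpha_time_of_day": self.alpha_time_of_day,
            "observer_effects": self.observer_effects.tolist(),
            "sigma_obs_re": self.sigma_obs_re,
            "sigma": self.sigma,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**{k: d[k] for k in d})

    @classmethod
    def from_json(cls, path) -> "ModelParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class ModelSpec:
    """Structural configuration of the diversity regression.

    Parameters
    ----------
    equilibrium_form:
        ``"quadratic"`` for the second-order polynomial surface (per-class
        linear + quadratic terms only) or ``"pairwise"`` for the extended
        surface with pairwise and linear x quadratic interactions.
    legacy:
        If True the mean mixes the equilibria implied by both timepoints via
        the legacy weight; if False the model is the pure equilibrium
        (current-landscape-only) variant.
    include_t1:
        Include first-timepoint observations in the likelihood, with their
        mean taken as the t1 equilibrium plus static terms.
    observer_random_effect:
        Include per-observer deviations with a hierarchical SD.
    landcover_scale:
        Scale on which compositions enter the equilibrium surface:
        ``"fraction"`` (0-1, default) or ``"percent"`` (0-100).
    change_scale:
        Scale on which change magnitudes enter the legacy weight:
        ``"percent"`` (percentage points, default) or ``"fraction"``.
    sigma_re_prior:
        ``"gamma_sd"`` places Gamma(0.001, 0.001) directly on the
        random-effect SD; ``"gamma_precision"`` places it on the precision.
    """

    equilibrium_form: str = "pairwise"
    legacy: bool = True
    include_t1: bool = True
    observer_random_effect: bool = True
    landcover_scale: str = "fraction"
    change_scale: str = "percent"
    sigma_re_prior: str = "gamma_sd"

    def __post_init__(self) -> None:
        if self.equilibrium_form not in ("quadratic", "pairwise"):
            raise ValueError("equilibrium_form must be 'quadratic' or 'pairwise'")
        if self.landcover_scale not in ("fraction", "percent"):
            raise ValueError("landcover_scale must be 'fraction' or 'percent'")
        if self.change_scale not in ("percent", "fraction"):
            raise ValueError("change_scale must be 'percent' or 'fraction'")
        if self.sigma_re_prior not in ("gamma_sd", "gamma_precision"):
            raise ValueError("sigma_re_prior must be 'gamma_sd' or 'gamma_precision'")


# ---------------------------------------------------------------------------
# constrained <-> unconstrained transforms
# ---------------------------------------------------------------------------

# transform kinds: how an unconstrained u maps to the constrained theta
# lower0 / positive: theta = exp(u); upper0: theta = -exp(u);
# unit: theta = sigmoid(u); free: identity.
_KINDS = ("lower0", "upper0", "unit", "free")


@dataclass(frozen=True)
class Block:
    name: str
    size: int
    kind: str
    offset: int


class ParameterMap:
    """Ordered map between sampled blocks and the unconstrained vector.

    Only blocks active under ``spec`` are sampled; inactive blocks stay at
    their values in the template (zero for interaction terms under the
    quadratic form, for example).
    """

    def __init__(self, spec: ModelSpec, n_observers: int = 0):
        self.spec = spec
        self.n_observers = int(n_observers)
        blocks: list[Block] = []
        off = 0

        def add(name: str, size: int, kind: str) -> None:
            nonlocal off
            blocks.append(Block(name, size, kind, off))
            off += size

        add("beta0", 1, "lower0")
        add("beta_lin", N_CLASSES, "lower0")
        add("beta_pair_diag", N_CLASSES, "upper0")
        if spec.equilibrium_form == "pairwise":
            add("beta_pair_off", len(PAIR_OFF_POS), "free")
            add("beta_linquad", N_LINQUAD, "free")
        if spec.legacy:
            add("gamma", N_GAMMA, "unit")
        add("alpha_temp_lin", 1, "lower0")
        add("alpha_temp_quad", 1, "upper0")
        add("alpha_heterogeneity", 1, "free")
        add("alpha_time_of_day", 1, "free")
        if spec.observer_random_effect and self.n_observers > 0:
            # non-centered: the sampler works with z-scores, effects are
            # z * sigma_obs_re (avoids the hierarchical funnel)
            add("observer_z", self.n_observers, "free")
            add("sigma_obs_re", 1, "lower0")
        add("sigma", 1, "lower0")

        self.blocks = blocks
        self.size = off
        # precomputed per-kind index arrays (constrain is sampler-hot)
        kinds = np.empty(off, dtype="U6")
        for b in blocks:
            kinds[b.offset : b.offset + b.size] = b.kind
        self._idx = {k: np.flatnonzero(kinds == k) for k in _KINDS}

    def __iter__(self) -> Iterator[Block]:
        return iter(self.blocks)

    def block(self, name: str) -> Block:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)

    def slice(self, name: str) -> slice:
        b = self.block(name)
        return slice(b.offset, b.offset + b.size)

    @property
    def names(self) -> list[str]:
        """Flat per-element parameter names, in vector order."""
        out: list[str] = []
        for b in self.blocks:
            if b.size == 1:
                out.append(b.name)
            elif b.name == "beta_lin":
                out.extend(f"beta_lin[{c}]" for c in CLASSES)
            elif b.name == "beta_pair_diag":
                out.extend(f"beta_quad[{c}]" for c in CLASSES)
            elif b.name == "beta_pair_off":
                out.extend(
                    f"beta_pair[{CLASSES[i]},{CLASSES[k]}]"
                    for p, (i, k) in enumerate(PAIR_IDX)
                    if i != k
                )
            elif b.name == "beta_linquad":
                out.extend(
                    f"beta_linquad[{CLASSES[i]},{CLASSES[k]}]" for i, k in LINQUAD_IDX
                )
            elif b.name == "gamma":
                out.extend(
                    f"gamma[{c},{d}]" for c in CLASSES for d in DIRECTIONS
                )
            elif b.name == "observer_z":
                out.extend(f"observer_z[{o}]" for o in range(self.n_observers))
            else:  # pragma: no cover - exhaustive above
                out.extend(f"{b.name}[{j}]" for j in range(b.size))
        return out

    # -- packing --------------------------------------------------------
    def constrained_vector(self, params: ModelParams) -> np.ndarray:
        """Extract the active blocks of ``params`` as a constrained vector."""
        theta = np.empty(self.size)
        for b in self.blocks:
            sl = slice(b.offset, b.offset + b.size)
            if b.name == "beta_pair_diag":
                theta[sl] = params.beta_pair[PAIR_DIAG_POS]
            elif b.name == "beta_pair_off":
                theta[sl] = params.beta_pair[PAIR_OFF_POS]
            elif b.name == "gamma":
                theta[sl] = params.gamma.ravel()
            elif b.name == "observer_z":
                s_re = max(params.sigma_obs_re, 1e-12)
                theta[sl] = params.observer_effects / s_re
            elif b.size == 1:
                theta[sl] = getattr(params, b.name)
            else:
                theta[sl] = getattr(params, b.name)
        return theta

    def to_params(self, theta: np.ndarray, template: ModelParams | None = None) -> ModelParams:
        """Assemble a :class:`ModelParams` from a constrained active vector."""
        if template is None:
            template = ModelParams(observer_effects=np.zeros(self.n_observers))
        p = template.copy()
        obs_z = None
        for b in self.blocks:
            val = theta[b.offset : b.offset + b.size]
            if b.name == "beta_pair_diag":
                p.beta_pair[PAIR_DIAG_POS] = val
            elif b.name == "beta_pair_off":
                p.beta_pair[PAIR_OFF_POS] = val
            elif b.name == "gamma":
                p.gamma = val.reshape(N_CLASSES, 2).copy()
            elif b.name == "observer_z":
                obs_z = val.copy()
            elif b.name in ("beta_lin", "beta_linquad"):
                setattr(p, b.name, val.copy())
            else:
                setattr(p, b.name, float(val[0]))
        if obs_z is not None:
            p.observer_effects = obs_z * p.sigma_obs_re
        return p

    # -- transforms ------------------------------------------------------
    def kinds_vector(self) -> np.ndarray:
        kinds = np.empty(self.size, dtype="U6")
        for b in self.blocks:
            kinds[b.offset : b.offset + b.size] = b.kind
        return kinds

    def unconstrain(self, theta: np.ndarray) -> np.ndarray:
        u = np.empty_like(theta)
        kinds = self.kinds_vector()
        tiny = 1e-300
        for kind in _KINDS:
            m = kinds == kind
            if not m.any():
                continue
            t = theta[m]
            if kind == "lower0":
                u[m] = np.log(np.maximum(t, tiny))
            elif kind == "upper0":
                u[m] = np.log(np.maximum(-t, tiny))
            elif kind == "unit":
                tc = np.clip(t, 1e-12, 1 - 1e-12)
                u[m] = np.log(tc) - np.log1p(-tc)
            else:
                u[m] = t
        return u

    def constrain(self, u: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
        """Map unconstrained ``u`` to (theta, dtheta_du, dlogjac_du, logjac)."""
        theta = np.empty_like(u)
        dtheta = np.empty_like(u)
        dlogjac = np.zeros_like(u)
        logjac = 0.0
        m = self._idx["lower0"]
        if m.size:
            um = u[m]
            e = np.exp(np.clip(um, -300.0, 300.0))
            theta[m] = e
            dtheta[m] = e
            dlogjac[m] = 1.0
            logjac += um.sum()
        m = self._idx["upper0"]
        if m.size:
            um = u[m]
            e = np.exp(np.clip(um, -300.0, 300.0))
            theta[m] = -e
            dtheta[m] = -e
            dlogjac[m] = 1.0
            logjac += um.sum()
        m = self._idx["unit"]
        if m.size:
            s = 1.0 / (1.0 + np.exp(-u[m]))
            theta[m] = s
            dtheta[m] = s * (1 - s)
            dlogjac[m] = 1 - 2 * s
            logjac += np.sum(np.log(s) + np.log1p(-s))
        m = self._idx["free"]
        if m.size:
            theta[m] = u[m]
            dtheta[m] = 1.0
        return theta, dtheta, dlogjac, logjac


def perturb_within_bounds(
    truth: ModelParams, scale: float, rng: np.random.Generator
) -> ModelParams:
    """Jitter a parameter vector while respecting all bounds.

    Used to build synthetic posterior-like draw sets around a known truth
    without running a sampler (clearly labelled synthetic wherever used).
    Bounded components are jittered on their unconstrained scale.
    """
    pmap = ParameterMap(ModelSpec(), n_observers=truth.n_observers)
    theta = pmap.constrained_vector(truth)
    u = pmap.unconstrain(theta)
    u = u + rng.normal(0.0, scale, size=u.shape)
    new_theta, _, _, _ = pmap.constrain(u)
    return pmap.to_params(new_theta, template=truth)
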