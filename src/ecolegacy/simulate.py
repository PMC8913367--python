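"""Synthetic survey, landscape and community generator with known truth.

Emulates the structure of the study system — 50-stop roadside survey
routes subdivided into segments, five-class land-cover compositions at two
timepoints with sparse directional change, and community abundances whose
effective number of species (ENS) follows the legacy model — so that every
downstream stage can be exercised against known ground-truth parameters.

Default sizes mirror the study scale (960 routes, segments 1/3/5 retained,
3 survey years per timepoint); noise defaults (residual SD 1 ENS unit,
observer SD 0.5) and legacy decay rates are set so that a 10-point change
in a "strong-legacy" class leaves most of the mixture weight on the past
landscape, as the fitted model reports for urban/cropland gain and
grassland/cropland loss, with milder rates for forest loss and grassland
gain.

The generative direction (target ENS -> abundance vector) is an artifact
construction: a geometric-series abundance profile whose evenness
parameter is solved by 1-D root finding so that exp(Shannon) matches the
drawn ENS exactly; yearly replicates are Poisson around the expected
abundances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .model import Design, ModelInputs, ModelParams, assemble_inputs
from .params import CLASSES, ModelSpec, perturb_within_bounds

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "default_true_params",
    "simulate_landscapes",
    "simulate_statics",
    "simulate_communities",
    "generate_dataset",
    "abundance_for_target_ens",
    "make_toy_raster_fixture",
    "mock_posterior_draws",
]

_OTHER = "other"  # unmodelled remainder class (water/ice/barren analogue)


def default_true_params(n_observers: int = 0, rng: np.random.Generator | None = None) -> ModelParams:
    """Ground-truth parameters used as generator defaults.

    The equilibrium surface declines with urban and cropland cover, rises
    with wetland and (saturating) forest, and declines mildly with
    grassland — so urban/cropland gain and wetland loss seed extinction
    debts while grassland loss seeds colonization credits. Legacy decay
    rates gamma are set so the past landscape contributes >= 0.9 of the
    mixture at a 10-point change for the strong classes and ~ 0.68 for the
    mild ones. Observer deviations, if requested, are drawn from
    Normal(0, sigma_obs_re).
    """
    p = ModelParams(
        beta0=2.6,
        beta_lin=np.array([0.15, 0.8, 0.12, 1.2, 0.15]),
        beta_pair=np.zeros(15),
        beta_linquad=np.zeros(20),
        gamma=np.array(
            [
                [0.10, 0.24],  # urban: loss, gain
                [0.11, 0.18],  # forest
                [0.25, 0.11],  # grassland
                [0.15, 0.12],  # wetland
                [0.23, 0.24],  # cropland
            ]
        ),
        alpha_temp_lin=0.8,
        alpha_temp_quad=-0.5,
        alpha_heterogeneity=0.6,
        alpha_time_of_day=-0.4,
        observer_effects=np.zeros(n_observers),
        sigma_obs_re=0.5,
        sigma=1.0,
    )
    # quadratic optima: f declines in urban/cropland/grassland over the
    # realistic range, saturates in forest, keeps rising in wetland
    diag = {"urban": -2.2, "forest": -0.8, "grassland": -1.2, "wetland": -0.2, "cropland": -1.8}
    from .params import PAIR_DIAG_POS

    p.beta_pair[PAIR_DIAG_POS] = [diag[c] for c in CLASSES]
    if n_observers and rng is not None:
        p.observer_effects = rng.normal(0.0, p.sigma_obs_re, size=n_observers)
    p.validate()
    return p


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the study conditions."""

    n_routes: int = 960
    segments_per_route: int = 5  # subdivision; only retained_segments are kept
    retained_segments: tuple = (1, 3, 5)
    n_species_pool: int = 500
    #: Dirichlet concentration over the five classes plus the unmodelled rest
    landcover_profile: tuple = (1.2, 2.2, 2.6, 0.8, 1.6, 2.0)
    #: mean change magnitude (percentage points) per class when a change occurs
    change_intensity: tuple = (8.0, 8.0, 8.0, 6.0, 8.0)
    #: probability that a changing segment's change in a class is a gain
    gain_probability: tuple = (0.85, 0.45, 0.4, 0.45, 0.55)
    zero_change_fraction: float = 0.2
    max_change: float = 35.0
    total_abundance: float = 300.0
    richness_margin: int = 8
    poisson_replication: bool = True
    routes_per_observer: int = 8
    years_t1: tuple = (2000, 2001, 2002)
    years_t2: tuple = (2015, 2016, 2017)
    years_t3: tuple = (2018, 2019, 2020)
    #: fraction of the remaining equilibrium gap closed by t3 (None: no t3)
    relaxation: float | None = None
    true_params: ModelParams | None = None
    rng_seed: int = 0

    @property
    def n_segments(self) -> int:
        return self.n_routes * len(self.retained_segments)

    @property
    def n_observers(self) -> int:
        return max(1, self.n_routes // self.routes_per_observer)


@dataclass
class SyntheticDataset:
    """All generated tables plus the generating truth."""

    abundance: pd.DataFrame  # segment_id, species_id, year, count
    landcover_t1: pd.DataFrame
    landcover_t2: pd.DataFrame
    statics: pd.DataFrame
    truth: ModelParams
    config: SimulationConfig
    expected_ens: pd.DataFrame | None = None  # segment_id, timepoint, mu, r_target

    def inputs(self, diversity: pd.DataFrame) -> ModelInputs:
        return assemble_inputs(diversity, self.landcover_t1, self.landcover_t2, self.statics)

    def to_csv(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.abundance.to_csv(out / "abundance.csv", index=False)
        self.landcover_t1.to_csv(out / "landcover_t1.csv", index=False)
        self.landcover_t2.to_csv(out / "landcover_t2.csv", index=False)
        self.statics.to_csv(out / "statics.csv", index=False)
        self.truth.to_json(out / "truth.json")


# ---------------------------------------------------------------------------
# landscapes
# ---------------------------------------------------------------------------


def _segment_ids(config: SimulationConfig) -> list[str]:
    return [
        f"r{r:04d}_s{s}" for r in range(config.n_routes) for s in config.retained_segments
    ]


def simulate_landscapes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Five-class percent compositions at both timepoints per segment.

    Baseline compositions are Dirichlet over six classes (five modelled
    plus an unmodelled remainder) scaled to percent, which enforces the
    sum <= 100 simplex constraint by construction. Directional change hits
    one or two classes in a (1 - zero_change_fraction) share of segments,
    compensated in the remainder class; proposals leaving the simplex are
    rejected and resampled.
    """
    rng = rng or np.random.default_rng(config.rng_seed)
    ids = _segment_ids(config)
    n = len(ids)
    comp = rng.dirichlet(config.landcover_profile, size=n) * 100.0
    x1 = comp[:, :5]
    other1 = comp[:, 5]

    x2 = x1.copy()
    other2 = other1.copy()
    changing = rng.random(n) >= config.zero_change_fraction
    intensity = np.asarray(config.change_intensity)
    p_gain = np.asarray(config.gain_probability)
    n_reject = 0
    for s in np.flatnonzero(changing):
        for _ in range(100):
            k = rng.integers(1, 3)  # 1 or 2 classes change
            cls = rng.choice(5, size=k, replace=False)
            delta = np.zeros(5)
            for c in cls:
                mag = min(rng.exponential(intensity[c]), config.max_change)
                sign = 1.0 if rng.random() < p_gain[c] else -1.0
                delta[c] = sign * mag
            new_x = x1[s] + delta
            new_other = other1[s] - delta.sum()
            if np.all(new_x >= 0) and np.all(new_x <= 100) and 0 <= new_other <= 100:
                x2[s] = new_x
                other2[s] = new_other
                break
            n_reject += 1
        else:
            # keep unchanged if no feasible proposal was found
            changing[s] = False
    n_attempts = n_reject + int(changing.sum())
    if n_attempts and n_reject / n_attempts > 0.5:
        warnings.warn(
            f"high change rejection rate: {n_reject}/{n_attempts} proposals rejected",
            stacklevel=2,
        )

    def table(x: np.ndarray, tp: str) -> pd.DataFrame:
        df = pd.DataFrame(x, columns=list(CLASSES))
        df.insert(0, "segment_id", ids)
        df["timepoint"] = tp
        return df

    return table(x1, "t1"), table(x2, "t2")


def simulate_statics(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Observer assignment, survey time, temperature and coordinates."""
    rng = rng or np.random.default_rng(config.rng_seed + 1)
    rows = []
    n_obs = config.n_observers
    route_obs = rng.integers(0, n_obs, size=config.n_routes)
    route_xy = rng.uniform(0.0, 4000.0, size=(config.n_routes, 2))
    for r in range(config.n_routes):
        temp = rng.normal(15.0, 4.0)
        for j, s in enumerate(config.retained_segments):
            rows.append(
                {
                    "segment_id": f"r{r:04d}_s{s}",
                    "observer_id": f"obs{route_obs[r]:03d}",
                    "time_of_day": rng.uniform(280.0, 600.0),  # minutes after midnight
                    "temperature": temp + rng.normal(0.0, 0.3),
                    "x_coord": route_xy[r, 0] + 5.0 * j,
                    "y_coord": route_xy[r, 1] + rng.normal(0.0, 1.0),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------


def _geom_profile_ens(log_ratio: float, s: int) -> float:
    """exp(Shannon) of a geometric abundance profile p_k ~ exp(k*log_ratio)."""
    k = np.arange(s, dtype=float)
    logw = k * log_ratio
    logw -= logw.max()
    w = np.exp(logw)
    p = w / w.sum()
    from scipy.special import xlogy

    return float(np.exp(-np.sum(xlogy(p, p))))


def abundance_for_target_ens(
    target: float, richness_margin: int = 8, total: float = 300.0
) -> np.ndarray:
    """Expected abundance vector whose exp(Shannon) equals ``target``.

    Uses a geometric-series profile over ``ceil(target) + margin`` species;
    the log-ratio of the series is solved by 1-D root finding. The mapping
    from evenness to exp(Shannon) is monotone, from 1 (total dominance) to
    the richness (perfect evenness), so a root always exists for targets in
    that interval.
    """
    if target < 1.0:
        raise ValueError("target ENS must be >= 1")
    s = max(int(np.ceil(target)) + richness_margin, 2)
    if abs(target - s) < 1e-12:
        p = np.full(s, 1.0 / s)
        return total * p
    # ENS is monotone increasing in the log-ratio; bracket it
    lo, hi = -50.0, 0.0
    f_lo = _geom_profile_ens(lo, s) - target
    f_hi = _geom_profile_ens(hi, s) - target
    if f_lo > 0 or f_hi < 0:
        raise ValueError(f"target ENS {target} infeasible for richness {s}")
    r = brentq(lambda lr: _geom_profile_ens(lr, s) - target, lo, hi, xtol=1e-13)
    k = np.arange(s, dtype=float)
    logw = k * r
    logw -= logw.max()
    w = np.exp(logw)
    return total * w / w.sum()


def _draw_target_ens(mu: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """R ~ Normal(mu, sigma) truncated below at 1."""
    if sigma <= 0:
        return np.maximum(mu, 1.0)
    a = (1.0 - mu) / sigma
    return truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, random_state=rng)


def simulate_communities(
    landcover_t1: pd.DataFrame,
    landcover_t2: pd.DataFrame,
    statics: pd.DataFrame,
    truth: ModelParams,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the long abundance table for all timepoints.

    Per segment and timepoint: the legacy-model mean ENS is computed from
    the truth, a target ENS is drawn (truncated below at 1), an abundance
    vector matching it exactly is constructed, and each survey year gets a
    Poisson replicate around the expected abundances (or the exact vector
    when replication is off).

    Returns (abundance table, expected-ENS table with the model means).
    """
    rng = rng or np.random.default_rng(config.rng_seed + 2)
    truth.validate()
    spec = ModelSpec()  # scaling conventions; legacy mean uses full machinery
    dummy = pd.DataFrame(
        {
            "segment_id": landcover_t1["segment_id"],
            "timepoint": "t2",
            "q1": 1.0,
        }
    )
    inputs = assemble_inputs(dummy, landcover_t1, landcover_t2, statics)
    if truth.n_observers and inputs.n_observers > truth.n_observers:
        raise ValueError("truth has fewer observer effects than observers in statics")
    design = Design(inputs, spec)
    mu2, mu1 = design.mu(truth)

    if np.any(np.maximum(mu1, mu2) > config.n_species_pool - config.richness_margin):
        raise ValueError("expected ENS exceeds the species pool; enlarge n_species_pool")

    timepoints = {"t1": (mu1, config.years_t1), "t2": (mu2, config.years_t2)}
    if config.relaxation is not None:
        e2 = design.f_values(truth)[1] + design.static_term(truth)
        mu3 = mu2 + config.relaxation * (e2 - mu2)
        timepoints["t3"] = (mu3, config.years_t3)

    col_seg: list[np.ndarray] = []
    col_sp: list[np.ndarray] = []
    col_yr: list[np.ndarray] = []
    col_ct: list[np.ndarray] = []
    expected = []
    seg_ids = inputs.segment_ids
    pool = np.arange(config.n_species_pool)
    for tp, (mu, years) in timepoints.items():
        r_target = _draw_target_ens(np.asarray(mu, float), truth.sigma, rng)
        for i, seg in enumerate(seg_ids):
            a = abundance_for_target_ens(
                r_target[i], config.richness_margin, config.total_abundance
            )
            species = rng.choice(pool, size=len(a), replace=False)
            for yr in years:
                counts = rng.poisson(a) if config.poisson_replication else a
                keep = counts > 0
                if not keep.any():
                    keep = a > 0
                    counts = a
                nk = int(keep.sum())
                col_seg.append(np.repeat(seg, nk))
                col_sp.append(species[keep])
                col_yr.append(np.repeat(yr, nk))
                col_ct.append(counts[keep])
            expected.append(
                {"segment_id": seg, "timepoint": tp, "mu": mu[i], "r_target": r_target[i]}
            )
    abundance = pd.DataFrame(
        {
            "segment_id": np.concatenate(col_seg),
            "species_id": np.concatenate(col_sp),
            "year": np.concatenate(col_yr),
            "count": np.concatenate(col_ct),
        }
    )
    return abundance, pd.DataFrame(expected)


def generate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """End-to-end generation: landscapes, statics, truth, communities."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.rng_seed)
    lc1, lc2 = simulate_landscapes(config, rng)
    statics = simulate_statics(config, rng)
    truth = config.true_params
    if truth is None:
        truth = default_true_params(n_observers=config.n_observers, rng=rng)
    abundance, expected = simulate_communities(lc1, lc2, statics, truth, config, rng)
    return SyntheticDataset(
        abundance=abundance,
        landcover_t1=lc1,
        landcover_t2=lc2,
        statics=statics,
        truth=truth,
        config=config,
        expected_ens=expected,
    )


# ---------------------------------------------------------------------------
# toy raster fixture
# ---------------------------------------------------------------------------


def make_toy_raster_fixture(
    shape: tuple = (64, 64),
    n_segments: int = 4,
    codes: tuple = (11, 21, 22, 41, 42, 43, 52, 71, 81, 82, 90, 95),
    rng: np.random.Generator | None = None,
):
    """Small class-coded grid plus per-segment masks, with oracle percentages.

    Returns ``(grid, masks, truth)`` where ``truth`` holds exact per-mask
    class percentages obtained by brute-force cell counting — intended as
    the independent oracle for the aggregation path.
    """
    if shape[0] > 512 or shape[1] > 512:
        raise ValueError("toy raster limited to 512x512")
    rng = rng or np.random.default_rng(0)
    grid = rng.choice(codes, size=shape)
    masks = {}
    rows = np.array_split(np.arange(shape[0]), n_segments)
    from .landcover import DEFAULT_CLASS_MAP

    truth_rows = []
    for j, rr in enumerate(rows):
        mask = np.zeros(shape, dtype=bool)
        mask[rr] = True
        seg = f"toy_s{j}"
        masks[seg] = mask
        cells = grid[mask].ravel()
        tally: dict[str, float] = {c: 0.0 for c in list(CLASSES) + ["excluded"]}
        for cell in cells:  # deliberate brute force
            tally[DEFAULT_CLASS_MAP[int(cell)]] += 1
        total = float(len(cells))
        truth_rows.append(
            {"segment_id": seg, **{k: 100.0 * v / total for k, v in tally.items()}}
        )
    return grid, masks, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# synthetic posterior stand-in
# ---------------------------------------------------------------------------


def mock_posterior_draws(
    truth: ModelParams, n_draws: int, scale: float = 0.05, rng: np.random.Generator | None = None
) -> list[ModelParams]:
    """Synthetic posterior-like draw set jittered around a known truth.

    A stand-in for a fitted posterior in propagation experiments that do
    not need a sampler run: draws are the truth perturbed on the
    unconstrained scale, so all bounds hold. Clearly synthetic — it carries
    no information from any data fit.
    """
    rng = rng or np.random.default_rng(0)
    return [perturb_within_bounds(truth, scale, rng) for _ in range(n_draws)]
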