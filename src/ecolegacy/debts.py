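"""Extinction debts and colonization credits from posterior draws.

The debt/credit of a site is the difference between the ENS predicted at
equilibrium under the current landscape (legacy weight forced to 1) and
the ENS predicted by the fitted legacy model. Static terms cancel in the
subtraction, leaving the closed form

    delta_s = (1 - omega_s) * (f(x_{s,t2}) - f(x_{s,t1}))

per posterior draw: positive delta is a colonization credit (species gain
still owed), negative delta an extinction debt. Uncertainty is propagated
by repeating the prediction over posterior draws.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .inference import PosteriorDraws
from .model import Design, ModelInputs
from .params import ModelSpec

__all__ = [
    "predict_delta",
    "geometric_cv",
    "summarize",
    "over_under_estimate",
    "grid_aggregate",
]


def predict_delta(
    draws: PosteriorDraws,
    inputs: ModelInputs,
    n_rep: int = 1000,
    spec: ModelSpec | None = None,
    return_components: bool = False,
):
    """Per-site delta (equilibrium minus legacy prediction) per draw.

    Evaluates ``(1 - omega) (f(x_t2) - f(x_t1))`` for ``n_rep`` draws taken
    at evenly spaced positions of the flattened chains, returning a
    site x draw matrix. With ``return_components=True`` also returns the
    two mean predictions (equilibrium, legacy) whose subtraction it equals.
    """
    spec = spec or ModelSpec()
    if not spec.legacy:
        raise ValueError("delta predictions require a legacy-model fit")
    flat = draws.flat()
    if n_rep > flat.shape[0]:
        raise ValueError(f"n_rep={n_rep} exceeds available draws {flat.shape[0]}")
    idx = np.linspace(0, flat.shape[0] - 1, n_rep).round().astype(int)
    design = Design(inputs, spec)

    n = design.n
    delta = np.empty((n, n_rep))
    equil = np.empty((n, n_rep))
    legacy = np.empty((n, n_rep))
    for j, i in enumerate(idx):
        p = draws.pmap.to_params(flat[i], draws.template)
        f1, f2 = design.f_values(p)
        w = design.omega(p)
        g = design.static_term(p)
        delta[:, j] = (1.0 - w) * (f2 - f1)
        equil[:, j] = f2 + g
        legacy[:, j] = f2 * w + f1 * (1 - w) + g
    if return_components:
        return delta, equil, legacy
    return delta


def geometric_cv(sd: np.ndarray) -> np.ndarray:
    """Geometric coefficient of variation, ``sqrt(exp(ln(sd + 1)^2) - 1)``.

    Uses the published form with the "+1" inside the logarithm; the
    conventional form (with ``sd`` the SD of log-values) is available via
    ``summarize(..., cv_form='log_sd')``.
    """
    sd = np.asarray(sd, dtype=float)
    return np.sqrt(np.exp(np.log1p(sd) ** 2) - 1.0)


def summarize(
    delta_draws: np.ndarray,
    site_ids=None,
    coords: np.ndarray | None = None,
    cv_form: str = "printed",
    min_draws: int = 100,
) -> tuple[pd.DataFrame, dict]:
    """Posterior summaries of per-site delta draws.

    Returns a table (mean, 95% credible bounds, geometric CV,
    debt/credit classification) and the area shares of sites classified
    as debt vs credit.
    """
    delta_draws = np.atleast_2d(np.asarray(delta_draws, dtype=float))
    n_sites, n_draws = delta_draws.shape
    if n_draws < min_draws:
        raise ValueError(f"need >= {min_draws} draws per site, got {n_draws}")
    mean = delta_draws.mean(axis=1)
    sd = delta_draws.std(axis=1, ddof=1) if n_draws > 1 else np.zeros(n_sites)
    lo = np.percentile(delta_draws, 2.5, axis=1)
    hi = np.percentile(delta_draws, 97.5, axis=1)
    if cv_form == "printed":
        gcv = geometric_cv(sd)
    elif cv_form == "log_sd":
        gcv = np.sqrt(np.exp(sd**2) - 1.0)
    else:
        raise ValueError("cv_form must be 'printed' or 'log_sd'")
    cls = np.where(mean > 0, "credit", np.where(mean < 0, "debt", "neutral"))
    table = pd.DataFrame(
        {
            "site_id": site_ids if site_ids is not None else np.arange(n_sites),
            "mean_delta": mean,
            "ci_low": lo,
            "ci_high": hi,
            "gcv": gcv,
            "classification": cls,
        }
    )
    if coords is not None:
        table["x_coord"] = coords[:, 0]
        table["y_coord"] = coords[:, 1]
    shares = {
        "credit_share": float((mean > 0).mean()),
        "debt_share": float((mean < 0).mean()),
    }
    return table, shares


def over_under_estimate(equilibrium_pred, legacy_pred):
    """Relative mis-estimate in percent: ``100 (equil - legacy) / legacy``.

    The percentage by which current observed diversity over- or
    under-states what the landscape can sustain at equilibrium.
    """
    e = np.asarray(equilibrium_pred, dtype=float)
    l = np.asarray(legacy_pred, dtype=float)
    if np.any(l <= 0):
        raise ValueError("legacy predictions must be strictly positive")
    return 100.0 * (e - l) / l


def _hex_cell(x: np.ndarray, y: np.ndarray, size: float):
    """Axial hex-bin indices (pointy-top) via cube rounding."""
    qf = (np.sqrt(3) / 3 * x - 1.0 / 3 * y) / size
    rf = (2.0 / 3 * y) / size
    xf, zf = qf, rf
    yf = -xf - zf
    rx, ry, rz = np.round(xf), np.round(yf), np.round(zf)
    dx, dy, dz = np.abs(rx - xf), np.abs(ry - yf), np.abs(rz - zf)
    fix_x = (dx > dy) & (dx > dz)
    fix_z = ~fix_x & (dz > dy)
    rx = np.where(fix_x, -ry - rz, rx)
    rz = np.where(fix_z, -rx - ry, rz)
    return rx.astype(int), rz.astype(int)


def grid_aggregate(
    site_estimates: pd.DataFrame,
    cell_size: float = 10.0,
    kind: str = "square",
    value: str = "mean_delta",
) -> pd.DataFrame:
    """Average site values over a regular spatial grid.

    ``site_estimates`` needs ``x_coord``/``y_coord`` columns (sites without
    coordinates are excluded with a warning). ``kind='square'`` bins into
    cells of side ``cell_size``; ``kind='hex'`` into hexagons with
    ``cell_size`` the vertex-to-opposite-vertex diameter. Cell areas are
    reported alongside the per-cell mean.
    """
    df = site_estimates
    if not {"x_coord", "y_coord"}.issubset(df.columns):
        raise ValueError("site_estimates must carry x_coord and y_coord")
    has = df[["x_coord", "y_coord"]].notna().all(axis=1)
    if (~has).any():
        warnings.warn(f"{int((~has).sum())} site(s) without coordinates excluded", stacklevel=2)
        df = df[has]
    x = df["x_coord"].to_numpy(float)
    y = df["y_coord"].to_numpy(float)
    if kind == "square":
        cx = np.floor(x / cell_size).astype(int)
        cy = np.floor(y / cell_size).astype(int)
        area = cell_size**2
    elif kind == "hex":
        radius = cell_size / 2.0
        cx, cy = _hex_cell(x, y, radius)
        area = 3 * np.sqrt(3) / 2 * radius**2
    else:
        raise ValueError("kind must be 'square' or 'hex'")
    out = (
        pd.DataFrame({"cell_x": cx, "cell_y": cy, value: df[value].to_numpy()})
        .groupby(["cell_x", "cell_y"], as_index=False)
        .agg(**{value: (value, "mean"), "n_sites": (value, "size")})
    )
    out["cell_area"] = area
    return out
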