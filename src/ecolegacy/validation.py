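"""Model validation: predictive correlation and spatial autocorrelation.

Fitted-versus-observed agreement and the agreement between predicted
debts/credits and the observed diversity change toward a later timepoint
are tested with Pearson correlations; residual spatial structure is tested
with Moran's I under distance-band (binary, row-standardized) weights at a
list of neighbourhood radii.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

__all__ = ["correlate_predictions", "morans_i", "future_change_validation"]


def correlate_predictions(predicted, observed) -> tuple[float, int, float]:
    """Pearson correlation with t-based p-value; returns (r, dof, p)."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("predicted and observed must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in inputs")
    # numerically-zero spread (e.g. identical timepoints up to roundoff)
    # is as degenerate as exact zeros
    if (
        x.std() <= 1e-10 * max(1.0, float(np.abs(x).max()))
        or y.std() <= 1e-10 * max(1.0, float(np.abs(y).max()))
    ):
        raise ValueError("zero variance in predicted or observed values")
    r, p = stats.pearsonr(x, y)
    return float(r), len(x) - 2, float(p)


def morans_i(
    values,
    coordinates,
    radius_list=(0.5, 1.0, 5.0, 10.0, 100.0),
    permutations: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Moran's I per neighbourhood radius, with analytical p-values.

    Weights are binary within-radius, row-standardized; the expectation
    under no autocorrelation is -1/(n-1) and significance uses the
    normal approximation under the normality assumption (optionally a
    permutation test with ``permutations`` shuffles). Sites without any
    neighbour at a radius are excluded for that radius with a warning;
    a radius at which all sites are isolated is reported as undefined.
    """
    v = np.asarray(values, dtype=float)
    xy = np.asarray(coordinates, dtype=float)
    if len(v) != len(xy):
        raise ValueError("values and coordinates must align")
    if len(v) < 10:
        raise ValueError("need at least 10 sites")
    dist = cdist(xy, xy)
    rng = np.random.default_rng(seed)
    rows = []
    for radius in radius_list:
        if radius <= 0:
            raise ValueError("radii must be positive")
        A = (dist <= radius) & ~np.eye(len(v), dtype=bool)
        has_nb = A.any(axis=1)
        if not has_nb.any():
            rows.append({"radius": radius, "n": 0, "I": np.nan,
                         "expected_I": np.nan, "z": np.nan, "p_value": np.nan})
            continue
        if (~has_nb).any():
            warnings.warn(
                f"{int((~has_nb).sum())} site(s) without neighbours at radius "
                f"{radius} excluded", stacklevel=2,
            )
        Ak = A[np.ix_(has_nb, has_nb)].astype(float)
        # after exclusion some rows may have lost all their neighbours
        keep = Ak.sum(axis=1) > 0
        Ak = Ak[np.ix_(keep, keep)]
        vk = v[has_nb][keep]
        n = len(vk)
        if n < 3 or vk.std() == 0:
            rows.append({"radius": radius, "n": n, "I": np.nan,
                         "expected_I": np.nan, "z": np.nan, "p_value": np.nan})
            continue
        W = Ak / Ak.sum(axis=1, keepdims=True)  # row-standardized
        z = vk - vk.mean()
        s0 = W.sum()
        I = (n / s0) * float(z @ W @ z) / float(z @ z)
        e_i = -1.0 / (n - 1)
        s1 = 0.5 * np.sum((W + W.T) ** 2)
        s2 = np.sum((W.sum(axis=0) + W.sum(axis=1)) ** 2)
        var_i = (n**2 * s1 - n * s2 + 3 * s0**2) / ((n**2 - 1) * s0**2) - e_i**2
        zscore = (I - e_i) / np.sqrt(var_i) if var_i > 0 else np.nan
        if permutations > 0:
            count = 0
            for _ in range(permutations):
                vp = rng.permutation(vk)
                zp = vp - vp.mean()
                Ip = (n / s0) * float(zp @ W @ zp) / float(zp @ zp)
                if abs(Ip - e_i) >= abs(I - e_i):
                    count += 1
            p = (count + 1) / (permutations + 1)
        else:
            p = 2 * stats.norm.sf(abs(zscore)) if np.isfinite(zscore) else np.nan
        rows.append({"radius": radius, "n": n, "I": I, "expected_I": e_i,
                     "z": zscore, "p_value": p})
    return pd.DataFrame(rows)


def future_change_validation(
    predicted_delta: pd.Series,
    diversity: pd.DataFrame,
    from_timepoint: str = "t2",
    to_timepoint: str = "t3",
    response: str = "q1",
) -> dict:
    """Correlate predicted debts/credits with observed later ENS change.

    ``predicted_delta`` is indexed by segment_id (posterior-mean delta,
    computed without any land-cover information from the later period);
    ``diversity`` is the long per-timepoint Hill-number table including the
    later timepoint. Observed change is ENS(to) - ENS(from) per segment,
    inner-joined on segments; the join count is reported.
    """
    piv = diversity.pivot_table(index="segment_id", columns="timepoint", values=response)
    for tp in (from_timepoint, to_timepoint):
        if tp not in piv.columns:
            raise ValueError(f"diversity table lacks timepoint {tp!r}")
    obs = (piv[to_timepoint] - piv[from_timepoint]).dropna()
    common = obs.index.intersection(predicted_delta.index)
    if len(common) == 0:
        raise ValueError("no overlapping segments between predictions and observations")
    r, dof, p = correlate_predictions(
        predicted_delta.loc[common].to_numpy(), obs.loc[common].to_numpy()
    )
    return {
        "pearson_r": r,
        "dof": dof,
        "p_value": p,
        "n_matched": int(len(common)),
        "n_predicted": int(len(predicted_delta)),
        "n_observed": int(len(obs)),
    }
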