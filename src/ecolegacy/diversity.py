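"""Hill-number diversity and survey-table preparation.

Covers the observational side of the pipeline: quality filtering of 50-stop
survey routes, subdivision into five 10-stop segments with retention of
segments 1, 3 and 5, averaging of counts over a 3-year window centred on
each timepoint, and effective numbers of species (Hill numbers) at
arbitrary order q, with q = 1 — the exponential of the Shannon index — as
the response used by the legacy model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FilterRules",
    "filter_routes",
    "segment_and_select",
    "average_window",
    "hill_diversity",
    "diversity_table",
]


# ---------------------------------------------------------------------------
# Hill numbers
# ---------------------------------------------------------------------------


def hill_diversity(abundances, q: float = 1.0) -> float:
    """Effective number of species of order ``q``.

    Computed as ``(sum p_i^q)^(1/(1-q))`` on the relative abundances, with
    the limit ``exp(-sum p_i ln p_i)`` at q = 1 (branch taken for
    |q - 1| < 1e-9) and ``1 / max(p_i)`` at q = inf.  q = 0 counts species
    with positive abundance.  Scale-invariant in the abundances.
    """
    a = np.asarray(abundances, dtype=float)
    if a.ndim != 1:
        a = a.ravel()
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    total = a.sum()
    if total <= 0:
        raise ValueError("at least one abundance must be positive")
    p = a[a > 0] / total
    if np.isinf(q):
        return float(1.0 / p.max())
    if q < 0:
        raise ValueError("q must be >= 0")
    if abs(q - 1.0) < 1e-9:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


# ---------------------------------------------------------------------------
# route filtering
# ---------------------------------------------------------------------------


@dataclass
class FilterRules:
    """Configurable route-quality predicates.

    Defaults drop routes with fewer than ``min_stops`` point-count stops,
    with a route-type-detail code below ``min_route_type_detail``
    (incomplete survey length), or surveyed under a flagged protocol code
    (adverse conditions). Field semantics are survey-release dependent, so
    each rule is a plain threshold/code the caller can override.
    """

    min_stops: int = 50
    min_route_type_detail: int = 2
    flagged_protocols: tuple = (1,)
    required_columns: tuple = ("route_id", "n_stops", "route_type_detail", "run_protocol")


def filter_routes(
    raw: pd.DataFrame, rules: FilterRules | None = None
) -> tuple[pd.DataFrame, dict]:
    """Remove low-quality routes; return (filtered table, removal report)."""
    rules = rules or FilterRules()
    missing = [c for c in rules.required_columns if c not in raw.columns]
    if missing:
        raise KeyError(f"missing route-quality column(s): {missing}")
    report = {"input": len(raw), "incomplete_length": 0, "flagged_protocol": 0, "retained": 0}
    if raw.empty:
        return raw.copy(), report
    short = (raw["n_stops"] < rules.min_stops) | (
        raw["route_type_detail"] < rules.min_route_type_detail
    )
    flagged = raw["run_protocol"].isin(rules.flagged_protocols)
    report["incomplete_length"] = int(short.sum())
    report["flagged_protocol"] = int((flagged & ~short).sum())
    keep = raw.loc[~(short | flagged)].copy()
    report["retained"] = len(keep)
    return keep, report


def segment_and_select(
    route_stops: pd.DataFrame,
    stops_per_segment: int = 10,
    retained_segments: tuple = (1, 3, 5),
) -> pd.DataFrame:
    """Assign 50 stops per route to five 10-stop segments; keep 1, 3, 5.

    Adjacent segments share road frontage, so alternating segments are
    retained to avoid overlapping landscape buffers.
    """
    df = route_stops.copy()
    n_per_route = df.groupby("route_id")["stop"].nunique()
    expect = 5 * stops_per_segment
    bad = n_per_route[n_per_route != expect]
    if len(bad):
        raise ValueError(
            f"routes without exactly {expect} stops (should have been filtered): "
            f"{list(bad.index)[:5]}"
        )
    df["segment"] = (df["stop"] - 1) // stops_per_segment + 1
    df = df[df["segment"].isin(retained_segments)].copy()
    df["segment_id"] = df["route_id"].astype(str) + "_s" + df["segment"].astype(str)
    return df


# ---------------------------------------------------------------------------
# 3-year window averaging
# ---------------------------------------------------------------------------


def average_window(
    abundance: pd.DataFrame,
    center_year: int,
    width: int = 3,
    denominator: str = "surveyed",
) -> pd.DataFrame:
    """Mean count per (segment, species) over a ``width``-year window.

    ``denominator='surveyed'`` (default) averages over the years in which
    the segment was actually surveyed within the window; ``'fixed'``
    divides the summed counts by ``width`` regardless, which deflates
    abundances when surveys were missed.  Species absent in all window
    years are excluded. Segments with no surveys in the window are dropped
    with a warning.
    """
    if width % 2 != 1:
        raise ValueError("window width must be odd")
    if denominator not in ("surveyed", "fixed"):
        raise ValueError("denominator must be 'surveyed' or 'fixed'")
    half = width // 2
    lo, hi = center_year - half, center_year + half
    win = abundance[(abundance["year"] >= lo) & (abundance["year"] <= hi)]
    lost = set(abundance["segment_id"].unique()) - set(win["segment_id"].unique())
    if lost:
        warnings.warn(
            f"{len(lost)} segment(s) had no surveys in window {lo}-{hi}; dropped",
            stacklevel=2,
        )
    sums = (
        win.groupby(["segment_id", "species_id"], observed=True)["count"]
        .sum()
        .rename("total")
        .reset_index()
    )
    if denominator == "fixed":
        sums["mean_count"] = sums["total"] / width
    else:
        n_years = (
            win.groupby("segment_id", observed=True)["year"].nunique().rename("n_years")
        )
        sums = sums.merge(n_years, on="segment_id")
        sums["mean_count"] = sums["total"] / sums["n_years"]
    out = sums[sums["mean_count"] > 0][["segment_id", "species_id", "mean_count"]]
    return out.reset_index(drop=True)


def diversity_table(
    abundance: pd.DataFrame,
    center_years: dict,
    width: int = 3,
    q_values: tuple = (0.0, 1.0, np.inf),
    denominator: str = "surveyed",
) -> pd.DataFrame:
    """Per-segment Hill numbers for each timepoint.

    ``center_years`` maps timepoint labels (e.g. 't1', 't2') to centre
    years. Returns a long table with columns segment_id, timepoint, q0,
    q1, q_inf (columns named per requested q).
    """

    def qname(q: float) -> str:
        return "q_inf" if np.isinf(q) else f"q{int(q) if float(q).is_integer() else q}"

    rows = []
    for tp, year in center_years.items():
        mat = average_window(abundance, year, width=width, denominator=denominator)
        for seg, grp in mat.groupby("segment_id", observed=True):
            rec = {"segment_id": seg, "timepoint": tp}
            for q in q_values:
                rec[qname(q)] = hill_diversity(grp["mean_count"].to_numpy(), q)
            rows.append(rec)
    return pd.DataFrame(rows)
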