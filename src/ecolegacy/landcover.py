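"""Land-cover aggregation, composition change, and heterogeneity.

Raw 30 m land-cover class codes (NLCD-style) are aggregated to five
categories — urban, forest, grassland, wetland, cropland — as percentages
of total buffer area; open water, perennial ice and barren land stay in the
denominator but are reported only as remainder. Change between two
timepoints is decomposed into separate non-negative loss/gain magnitudes
per class, which the legacy weight consumes; landscape heterogeneity is the
effective number of land-cover types (Hill q = 1 over the composition).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .diversity import hill_diversity
from .params import CLASSES

__all__ = [
    "DEFAULT_CLASS_MAP",
    "load_class_map",
    "aggregate_classes",
    "composition_table",
    "decompose_change",
    "landscape_heterogeneity",
]

#: Default NLCD code -> category mapping. Codes 11 (open water), 12
#: (perennial ice/snow) and 31 (barren) are excluded from the modelled
#: classes but remain in the area denominator.
DEFAULT_CLASS_MAP: dict[int, str] = {
    11: "excluded",
    12: "excluded",
    21: "urban",
    22: "urban",
    23: "urban",
    24: "urban",
    31: "excluded",
    41: "forest",
    42: "forest",
    43: "forest",
    52: "grassland",
    71: "grassland",
    81: "grassland",
    82: "cropland",
    90: "wetland",
    95: "wetland",
}

_VALID_CATEGORIES = set(CLASSES) | {"excluded"}


def load_class_map(path) -> dict[int, str]:
    """Read a code->category mapping from JSON or YAML."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    cmap = {int(k): str(v) for k, v in raw.items()}
    bad = {v for v in cmap.values()} - _VALID_CATEGORIES
    if bad:
        raise ValueError(f"unknown categories in class map: {sorted(bad)}")
    return cmap


def aggregate_classes(
    codes: np.ndarray,
    class_map: dict[int, str] | None = None,
    mask: np.ndarray | None = None,
    denominator: str = "total",
) -> dict[str, float]:
    """Percent cover per aggregated category within ``mask``.

    ``codes`` is an integer grid (or flat array) of raw class codes.
    Excluded classes count toward the denominator under the default
    ``denominator='total'`` (percentages are of total buffer area); with
    ``'modelled'`` they are dropped from the denominator instead. The
    remainder (100 - sum of the five classes) is reported under
    ``'excluded'``.
    """
    class_map = class_map or DEFAULT_CLASS_MAP
    codes = np.asarray(codes)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != codes.shape:
            raise ValueError("mask shape must match the code grid")
        codes = codes[mask]
    codes = codes.ravel()
    if codes.size == 0:
        raise ValueError("empty mask: no cells to aggregate")
    unknown = sorted(set(np.unique(codes).tolist()) - set(class_map))
    if unknown:
        raise KeyError(f"unmapped land-cover code(s): {unknown}")
    lut_codes = np.array(sorted(class_map))
    cats = list(CLASSES) + ["excluded"]
    cat_of = {c: i for i, c in enumerate(cats)}
    lut = np.array([cat_of[class_map[c]] for c in lut_codes])
    idx = lut[np.searchsorted(lut_codes, codes)]
    counts = np.bincount(idx, minlength=len(cats)).astype(float)
    denom = counts.sum() if denominator == "total" else counts[:-1].sum()
    if denom == 0:
        raise ValueError("denominator is zero (all cells excluded)")
    pct = 100.0 * counts / denom
    out = {c: float(pct[i]) for c, i in cat_of.items()}
    if denominator == "modelled":
        out["excluded"] = 0.0
    return out


def composition_table(
    grids: dict,
    masks: dict,
    class_map: dict[int, str] | None = None,
    timepoint: str = "t1",
) -> pd.DataFrame:
    """Aggregate a raster per segment mask into a composition table."""
    rows = []
    for seg, mask in masks.items():
        comp = aggregate_classes(grids, class_map, mask=mask)
        rows.append({"segment_id": seg, "timepoint": timepoint, **{c: comp[c] for c in CLASSES}})
    return pd.DataFrame(rows)


def decompose_change(state_t1: pd.DataFrame, state_t2: pd.DataFrame) -> pd.DataFrame:
    """Split per-class composition change into loss and gain magnitudes.

    For each class i, with ``delta = x_t2 - x_t1`` in percentage points:
    a decrease fills the loss slot with |delta| and zeroes the gain slot;
    otherwise the gain slot holds delta (zero change leaves both at 0).
    ``gain - loss`` reconstructs delta exactly.
    """
    a = state_t1.set_index("segment_id").sort_index()
    b = state_t2.set_index("segment_id").sort_index()
    ids = a.index.intersection(b.index).sort_values()
    out = pd.DataFrame({"segment_id": ids})
    for c in CLASSES:
        delta = (b.loc[ids, c] - a.loc[ids, c]).to_numpy(float)
        out[f"{c}_loss"] = np.where(delta < 0, -delta, 0.0)
        out[f"{c}_gain"] = np.where(delta < 0, 0.0, delta)
    return out


def landscape_heterogeneity(state) -> float:
    """Effective number of land-cover types: Hill q = 1 on the composition.

    Accepts a mapping, Series or 5-vector of class percentages; the five
    modelled classes are renormalized to proportions before applying the
    same exponential-Shannon computation used for species.
    """
    if isinstance(state, dict):
        vals = np.array([state[c] for c in CLASSES], dtype=float)
    elif isinstance(state, pd.Series):
        vals = state[list(CLASSES)].to_numpy(float) if set(CLASSES) <= set(state.index) \
            else state.to_numpy(float)
    else:
        vals = np.asarray(state, dtype=float).ravel()
    if vals.sum() <= 0:
        raise ValueError("composition sums to zero")
    return hill_diversity(vals, q=1.0)
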