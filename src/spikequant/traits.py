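"""Trait-table handling: the nine analysed spike traits, threshold
classifications of awnedness and spike length, and per-species summary
statistics.

The nine traits characterise one spike image: four quadrangle-model
measurements (``xu2_mm``, ``ybm_mm``, ``xb2_mm``, ``yu2_mm``), two physical
dimensions of the ear body (``perimeter_mm``, ``rachis_length_mm``), two
dimensionless shape descriptors (``circularity``, ``roundness``) and the
total awn area (``awns_area_mm2``).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

#: The nine analysed traits, in canonical column order.
TRAIT_COLUMNS = [
    "xu2_mm",
    "ybm_mm",
    "xb2_mm",
    "yu2_mm",
    "perimeter_mm",
    "rachis_length_mm",
    "circularity",
    "roundness",
    "awns_area_mm2",
]

#: Metadata columns carried alongside the traits.
METADATA_COLUMNS = ["plant", "species", "ploidy", "protocol", "projection"]

# Class boundaries (mm^2 for awnedness, mm for spike length).  Boundary
# values fall in the middle class: "from 30 to 90" / "from 60 to 90" are
# read as closed intervals.
AWNLESS_MAX = 30.0
AWNED_MIN = 90.0
SHORT_MAX = 60.0
LONG_MIN = 90.0


def classify_awnedness(awns_area_mm2: float) -> str:
    """Classify a spike by total awn area (mm^2).

    Returns ``"awnless"`` (< 30), ``"moderately_awned"`` ([30, 90]) or
    ``"awned"`` (> 90).
    """
    a = float(awns_area_mm2)
    if not np.isfinite(a) or a < 0:
        raise ValueError(f"awns area must be a finite non-negative number, got {awns_area_mm2!r}")
    if a < AWNLESS_MAX:
        return "awnless"
    if a <= AWNED_MIN:
        return "moderately_awned"
    return "awned"


def classify_length(spike_length_mm: float) -> str:
    """Classify a spike by length (mm): short (< 60), medium ([60, 90]),
    long (> 90)."""
    length = float(spike_length_mm)
    if not np.isfinite(length) or length <= 0:
        raise ValueError(f"spike length must be a finite positive number, got {spike_length_mm!r}")
    if length < SHORT_MAX:
        return "short"
    if length <= LONG_MIN:
        return "medium"
    return "long"


def classify_table(records: pd.DataFrame) -> pd.DataFrame:
    """Append ``awnedness_class`` and ``length_class`` columns to a trait table.

    Length classification uses the rachis (body axis) length.
    """
    out = records.copy()
    out["awnedness_class"] = [classify_awnedness(v) for v in out["awns_area_mm2"]]
    out["length_class"] = [classify_length(v) for v in out["rachis_length_mm"]]
    return out


def _require_traits(records: pd.DataFrame) -> None:
    missing = [c for c in TRAIT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"trait table is missing columns: {missing}")


def summarize_species(records: pd.DataFrame) -> pd.DataFrame:
    """Per-species summary statistics of the nine traits.

    Returns one row per (species, trait) with the arithmetic mean, median,
    sample standard deviation and sample variance (n - 1 denominator), plus
    the image and plant counts for the species.  For a species represented
    by a single record the sd and variance are reported as missing (NaN),
    never as zero.
    """
    if records is None or len(records) == 0:
        raise ValueError("trait table is empty")
    _require_traits(records)
    if "species" not in records.columns:
        raise ValueError("trait table has no 'species' column")

    rows = []
    for species, grp in records.groupby("species", sort=True):
        n_images = len(grp)
        n_plants = grp["plant"].nunique() if "plant" in grp.columns else n_images
        for trait in TRAIT_COLUMNS:
            vals = grp[trait].to_numpy(dtype=float)
            sd = float(np.std(vals, ddof=1)) if n_images > 1 else np.nan
            rows.append(
                {
                    "species": species,
                    "trait": trait,
                    "mean": float(np.mean(vals)),
                    "median": float(np.median(vals)),
                    "sd": sd,
                    "variance": sd**2 if np.isfinite(sd) else np.nan,
                    "n_images": n_images,
                    "n_plants": n_plants,
                }
            )
    return pd.DataFrame(rows)


def species_mean_vectors(records: pd.DataFrame) -> pd.DataFrame:
    """Species-by-trait matrix of mean values (one 9-vector per species)."""
    _require_traits(records)
    return records.groupby("species", sort=True)[TRAIT_COLUMNS].mean()


def read_trait_table(path) -> pd.DataFrame:
    """Read a trait CSV and check the nine trait columns are present."""
    df = pd.read_csv(path)
    _require_traits(df)
    return df


def write_trait_table(records: Iterable[dict] | pd.DataFrame, path) -> pd.DataFrame:
    """Write trait records to CSV (one row per image) and return the frame."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    _require_traits(df)
    df.to_csv(path, index=False)
    return df
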