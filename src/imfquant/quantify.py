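"""From masks to measurements: percent fat per section, aggregated per slide.

The measurement is the fat-mask area as a percentage of the muscle
cross-section area.  The cross-section mask is the thresholded tissue mask
with the hull-clipped fat prediction added back — adipocytes are unstained
and therefore holes in the saturation mask, but they are part of the
cross-section the fraction refers to.  Slides (the statistical unit) are
the mean of their usable sections.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import UndefinedFractionError
from .segment import FatPrediction
from .synth import SectionSpec, SyntheticSection
from .tissue import TissueMaskConfig, tissue_pipeline

SECTION_COLUMNS = ["animal", "group", "side", "region", "slide", "section",
                   "method", "fat_percent", "n_pixels_fat", "n_pixels_tissue",
                   "usable"]


def fat_fraction(fat: np.ndarray, tissue: np.ndarray, hull: np.ndarray) -> float:
    """100 * |fat ∩ hull| / |tissue|.

    ``tissue`` is the cross-section (denominator) mask; pass the union of
    the lean tissue mask and the clipped fat mask for the standard
    measurement (see :func:`cross_section_mask`).
    """
    tissue = np.asarray(tissue, dtype=bool)
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise UndefinedFractionError("empty tissue mask: fraction undefined")
    n_fat = int((np.asarray(fat, dtype=bool) & np.asarray(hull, dtype=bool)).sum())
    return 100.0 * n_fat / n_tissue


def cross_section_mask(tissue: np.ndarray, fat: np.ndarray,
                       hull: np.ndarray) -> np.ndarray:
    """Muscle cross-section = lean tissue plus hull-clipped fat."""
    return np.asarray(tissue, dtype=bool) | (
        np.asarray(fat, dtype=bool) & np.asarray(hull, dtype=bool))


def measure_section(spec: SectionSpec, prediction: FatPrediction,
                    tissue: np.ndarray, hull: np.ndarray) -> dict:
    """One result row for a section given its masks and a fat prediction."""
    cross = cross_section_mask(tissue, prediction.fat, hull)
    pct = fat_fraction(prediction.fat, cross, hull)
    return dict(animal=spec.animal, group=spec.group, side=spec.side,
                region=spec.region, slide=spec.slide, section=spec.section,
                method=prediction.method, fat_percent=pct,
                n_pixels_fat=int((prediction.fat & hull).sum()),
                n_pixels_tissue=int(cross.sum()), usable=spec.usable)


def measure_sections(sections: list[SyntheticSection], segmenters: dict,
                     cfg: TissueMaskConfig | None = None) -> pd.DataFrame:
    """Run mask + each segmenter over sections; one row per (section, method).

    ``segmenters`` maps a method label to a callable
    ``(image, hull) -> FatPrediction``.
    """
    rows = []
    for sec in sections:
        tissue, hull = tissue_pipeline(sec.image, cfg)
        for _label, segment in segmenters.items():
            pred = segment(sec.image, hull)
            rows.append(measure_section(sec.spec, pred, tissue, hull))
    return pd.DataFrame(rows, columns=SECTION_COLUMNS)


def qc_filter(measurements: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split measurements into (retained, discarded) on the usable flag."""
    usable = measurements["usable"].astype(bool)
    retained = measurements[usable].reset_index(drop=True)
    discarded = measurements[~usable].reset_index(drop=True)
    if retained.empty and not measurements.empty:
        import warnings
        warnings.warn("QC discarded every section", stacklevel=2)
    return retained, discarded


def aggregate_slides(measurements: pd.DataFrame) -> pd.DataFrame:
    """Average usable sections to one data point per slide.

    Slides with no usable section simply do not appear (their sections were
    removed upstream).  Keeps the method column so the two segmenters stay
    separate.
    """
    keys = ["animal", "group", "side", "region", "slide", "method"]
    keys = [k for k in keys if k in measurements.columns]
    agg = (measurements.groupby(keys, sort=True, as_index=False)
           .agg(fat_percent=("fat_percent", "mean"),
                n_sections=("fat_percent", "size")))
    return agg
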