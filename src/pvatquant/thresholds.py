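"""Data-driven extent and abnormality thresholds and slice classification.

Two small-sample derivations drive the pipeline's cut-offs: the PVAT search
extent per vessel family (mean + 2 sample SD of PVAT measured on sample
images; the study's values were 20 mm for the aorta and 9 mm for the
carotid, from n = 15) and the abnormal-wall cut (mean + 3 sample SD of the
maximal wall thickness in a visually normal subsample).  Both use the n-1
divisor since they are estimated from small samples.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .core import DEFAULT_EXTENT_MM, RadialProfile, ThresholdSet


def _mean_plus_k_sd(values: Iterable[float], k: float, what: str) -> float:
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError(f"need at least 2 values to derive the {what}")
    if (v < 0).any():
        raise ValueError(f"{what} sample values must be nonnegative")
    return float(v.mean() + k * v.std(ddof=1))


def derive_extent_threshold(sample_pvat_mm: Iterable[float]) -> float:
    """PVAT search extent: mean + 2 sample SD of sample-image PVAT (mm)."""
    return _mean_plus_k_sd(sample_pvat_mm, 2.0, "extent threshold")


def derive_abnormal_cut(normal_slice_max_mm: Iterable[float]) -> float:
    """Abnormal-wall cut: mean + 3 sample SD of normal-subsample maxima (mm).

    One-sided upper cut — wall thickening is one-directional.
    """
    return _mean_plus_k_sd(normal_slice_max_mm, 3.0, "abnormal cut")


def build_threshold_set(extent_samples: dict[str, Iterable[float]] | None = None,
                        normal_slice_max_mm: Iterable[float] | None = None) -> ThresholdSet:
    """Assemble a ThresholdSet, falling back to the stored study defaults
    (aorta 20 mm, carotid 9 mm) for vessel families with no samples."""
    extent = dict(DEFAULT_EXTENT_MM)
    derivation: dict = {"extent_defaults": dict(DEFAULT_EXTENT_MM)}
    if extent_samples:
        for fam, samples in extent_samples.items():
            samples = list(samples)
            extent[fam] = derive_extent_threshold(samples)
            derivation[f"extent_{fam}"] = {
                "n": len(samples), "mean": float(np.mean(samples)),
                "sd": float(np.std(samples, ddof=1)), "rule": "mean + 2*SD",
            }
    cut = None
    if normal_slice_max_mm is not None:
        samples = list(normal_slice_max_mm)
        cut = derive_abnormal_cut(samples)
        derivation["abnormal_cut"] = {
            "n": len(samples), "mean": float(np.mean(samples)),
            "sd": float(np.std(samples, ddof=1)), "rule": "mean + 3*SD",
        }
    return ThresholdSet(extent_mm=extent, abnormal_cut_mm=cut, derivation=derivation)


def classify_slice(wall_profile: RadialProfile, cut_mm: float) -> str:
    """'abnormal' iff the maximal wall thickness over the 72 cords exceeds the cut."""
    return "abnormal" if float(wall_profile.values_mm.max()) > cut_mm else "normal"


def classify_cohort(cohort: pd.DataFrame, cut_mm: float,
                    wall_col: str = "wall_mm") -> pd.DataFrame:
    """Label every (patient, slice) in a long-format cohort table.

    Adds/overwrites ``normal_flag``: a slice is abnormal when its maximal
    wall thickness across angles exceeds ``cut_mm``.
    """
    out = cohort.copy()
    key = ["patient_id", "vessel_class", "slice_index"]
    slice_max = out.groupby(key)[wall_col].transform("max")
    out["normal_flag"] = ~(slice_max > cut_mm)
    return out
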