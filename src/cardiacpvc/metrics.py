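"""Figures of merit over noise realizations.

Conventions (fixed across the package):

* region means are computed per realization first, then averaged over
  realizations;
* ``noise`` of a region is the voxelwise standard deviation over
  realizations (sample, n-1), averaged over the region's voxels;
* contrast is ``r/BP - 1`` for the ventricles and ``1 - r/LV`` for lesions;
* RC = recovered mean / true mean (undefined for a zero-activity region);
* CRC = recovered contrast / true contrast (undefined at zero true contrast);
* CNR = recovered contrast / relative background noise, the background being
  the blood pool for the ventricles and the LV for the lesions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .image import Image


class UndefinedMetricError(ValueError):
    """The requested figure of merit is undefined for this region."""


def _stack(recons) -> np.ndarray:
    arrs = [np.asarray(r.data if isinstance(r, Image) else r, dtype=np.float64)
            for r in recons]
    return np.stack(arrs)


def region_means(recons, mask) -> np.ndarray:
    """Per-realization mean over a boolean mask."""
    stack = _stack(recons)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region mask")
    return stack[:, mask].mean(axis=1)


def bias_lv(recons, mask_lv, true_value: float) -> float:
    """Mean recovered LV activity minus the true LV activity (kBq/cc)."""
    return float(region_means(recons, mask_lv).mean() - true_value)


def noise_region(recons, mask) -> float:
    """Voxelwise stddev over realizations, averaged over the mask."""
    stack = _stack(recons)
    if stack.shape[0] < 2:
        raise ValueError("noise requires at least two realizations")
    mask = np.asarray(mask, dtype=bool)
    return float(stack[:, mask].std(axis=0, ddof=1).mean())


def contrast(region: str, means: dict) -> float:
    """Region contrast from mean activities.

    ``means`` maps region names to mean values and must contain the
    reference region (BP for LV/RV, LV for L1/L2).
    """
    if region in ("LV", "RV"):
        return float(means[region] / means["BP"] - 1.0)
    if region in ("L1", "L2"):
        return float(1.0 - means[region] / means["LV"])
    raise KeyError(f"unknown region {region!r}")


def rc(recons, mask, true_value: float) -> float:
    """Recovery coefficient: recovered mean / true mean."""
    if true_value == 0:
        raise UndefinedMetricError("RC is undefined for a zero-activity region")
    return float(region_means(recons, mask).mean() / true_value)


def crc(recon_contrast: float, true_contrast: float) -> float:
    """Contrast recovery coefficient."""
    if true_contrast == 0:
        raise UndefinedMetricError("CRC is undefined at zero true contrast")
    return float(recon_contrast / true_contrast)


def cnr(recon_contrast: float, recons, background_mask) -> float:
    """Contrast-to-noise ratio against the relative background noise."""
    nb = noise_region(recons, background_mask) / float(
        region_means(recons, background_mask).mean())
    return float(recon_contrast / nb)


@dataclass
class PairedTestResult:
    statistic: float
    p_value: float
    significant: bool
    alpha: float


def paired_test(values_a, values_b, alpha: float = 0.01) -> PairedTestResult:
    """Two-sided paired t test on per-realization values."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("paired test needs equal-length samples of size >= 2")
    t, p = stats.ttest_rel(a, b)
    if np.isnan(t):  # identical samples -> zero variance of differences
        t, p = 0.0, 1.0
    return PairedTestResult(float(t), float(p), bool(p < alpha), alpha)


# --------------------------------------------------------------- reporting

TRUE_BACKGROUND = {"LV": "BP", "RV": "BP", "L1": "LV", "L2": "LV"}


@dataclass
class MetricsReport:
    """Per-region figures of merit for one reconstruction ensemble."""
    algorithm: str
    n_realizations: int
    table: pd.DataFrame           # rows: region; cols: metric values
    per_realization: dict         # region -> {metric -> ndarray}
    mask_provenance: str = ""


def evaluate_ensemble(algorithm: str, recons, masks: dict, true_values: dict,
                      mask_provenance: str = "") -> MetricsReport:
    """All figures of merit for one algorithm over its noise realizations.

    ``masks`` maps region names (LV, RV, BP, L1, L2) to boolean masks on the
    reconstruction grid; ``true_values`` maps them to ground-truth activities.
    Undefined metrics are reported as NaN with a flag, never fabricated.
    """
    n = len(recons)
    means = {r: region_means(recons, m) for r, m in masks.items()}
    true_contrasts = {r: contrast(r, true_values) for r in TRUE_BACKGROUND}
    rows, per_real = [], {}
    for r in ("LV", "RV", "L1", "L2"):
        if r not in masks:
            continue
        bg = TRUE_BACKGROUND[r]
        c_bar = contrast(r, {k: v.mean() for k, v in means.items()})
        c_per = np.array([
            contrast(r, {k: v[i] for k, v in means.items()}) for i in range(n)])
        noise_bg = noise_region(recons, masks[bg]) / means[bg].mean() if n >= 2 else np.nan
        row = {"region": r, "mean": means[r].mean(),
               "contrast": c_bar, "true_contrast": true_contrasts[r]}
        try:
            row["rc"] = rc(recons, masks[r], true_values[r])
        except UndefinedMetricError:
            row["rc"] = np.nan
        try:
            row["crc"] = crc(c_bar, true_contrasts[r])
            crc_per = c_per / true_contrasts[r]
        except UndefinedMetricError:
            row["crc"] = np.nan
            crc_per = np.full(n, np.nan)
        if n >= 2 and noise_bg > 0:
            row["cnr"] = c_bar / noise_bg
            cnr_per = c_per / noise_bg
        else:  # undefined for a noise-free ensemble
            row["cnr"] = np.nan
            cnr_per = np.full(n, np.nan)
        for name, arr in (("crc", crc_per), ("cnr", cnr_per)):
            row[f"{name}_min"] = np.nanmin(arr) if np.isfinite(arr).any() else np.nan
            row[f"{name}_max"] = np.nanmax(arr) if np.isfinite(arr).any() else np.nan
        rows.append(row)
        per_real[r] = {"mean": means[r], "contrast": c_per,
                       "crc": crc_per, "cnr": cnr_per}
    extra = {
        "bias_lv": bias_lv(recons, masks["LV"], true_values["LV"]),
        "noise_lv": noise_region(recons, masks["LV"]) if n >= 2 else np.nan,
        "contrast_l1": contrast("L1", {k: v.mean() for k, v in means.items()}),
    }
    table = pd.DataFrame(rows).set_index("region")
    for k, v in extra.items():
        table.attrs[k] = v
    return MetricsReport(algorithm, n, table, per_real, mask_provenance)


def curve_assembly(runs) -> pd.DataFrame:
    """Bias-noise / contrast-noise curve points over a parameter grid.

    ``runs`` is an iterable of dicts with keys ``algorithm``, ``params``
    (a dict, e.g. {'beta': 10, 'n': 9}) and ``report`` (a MetricsReport).
    Returns one row per run with (noise_lv, bias_lv, contrast_l1), ordered by
    noise within each algorithm, ready to be written as CSV.
    """
    rows = []
    for run in runs:
        rep: MetricsReport = run["report"]
        rows.append({
            "algorithm": run["algorithm"],
            **{f"param_{k}": v for k, v in run.get("params", {}).items()},
            "noise_lv": rep.table.attrs["noise_lv"],
            "bias_lv": rep.table.attrs["bias_lv"],
            "contrast_l1": rep.table.attrs["contrast_l1"],
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["algorithm", "noise_lv"]).reset_index(drop=True)
    return df
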