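"""Per-organoid response scoring and invasion quantification.

Each organoid's *fraction affected* is the ratio of its dead-signal overlap
to its masked area, ``fa = green_area / bf_area`` (clipped to [0, 1]). The
fraction partitions organoids into three response classes:

* resistant — fa in [0, 0.15)
* sensitive — fa in [0.15, 0.34)
* highly_sensitive — fa in [0.34, 1]

Invasion is quantified from the invasive annulus: the *survival invasive
area* is ``inv_area − inv_green_area`` (the still-living part of the annulus), the
*invasive fraction* is ``inv_area / bf_area``, and an organoid is flagged
invasive when its invasive fraction exceeds a configurable threshold
(default 0.2). Crossing the invasive flag with the resistant/affected split
yields four quadrant categories (invasive-resistant, invasive-sensitive,
noninvasive-resistant, noninvasive-sensitive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .io import PlateLayout

logger = logging.getLogger(__name__)

__all__ = [
    "ResponseThresholds",
    "fraction_affected",
    "classify_response",
    "organoid_states",
    "class_fractions",
    "invasion_metrics",
    "classify_invasive",
]

RESPONSE_CLASSES = ("resistant", "sensitive", "highly_sensitive")


@dataclass(frozen=True)
class ResponseThresholds:
    """Cut points for the per-organoid classifiers."""

    resistant: float = 0.15  # fa below -> resistant
    highly_sensitive: float = 0.34  # fa at/above -> highly sensitive
    invasive: float = 0.2  # invasive fraction above -> invasive

    def validate(self) -> None:
        if not (0 < self.resistant < self.highly_sensitive <= 1):
            raise DataError(
                "response thresholds must satisfy 0 < resistant < highly_sensitive <= 1"
            )
        if self.invasive < 0:
            raise DataError("invasive threshold must be >= 0")


def fraction_affected(green_area, bf_area):
    """Dead fraction of an organoid, ``green/bf`` clipped to [0, 1].

    Vectorized; NaN where ``bf_area <= 0`` (the organoid is excluded, not
    imputed).
    """
    green = np.asarray(green_area, dtype=float)
    bf = np.asarray(bf_area, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.where(bf > 0, np.clip(green / np.where(bf > 0, bf, 1.0), 0.0, 1.0), np.nan)
    return fa if fa.ndim else float(fa)


def classify_response(fa, thresholds: ResponseThresholds = ResponseThresholds()):
    """Map fraction affected to resistant / sensitive / highly_sensitive.

    Half-open bins [0, r) / [r, hs) / [hs, 1] so the three classes
    partition [0, 1]; classification is monotone in fa.
    """
    thresholds.validate()
    fa_arr = np.asarray(fa, dtype=float)
    out = np.where(
        fa_arr < thresholds.resistant,
        "resistant",
        np.where(fa_arr < thresholds.highly_sensitive, "sensitive", "highly_sensitive"),
    ).astype(object)
    out = np.where(np.isnan(fa_arr), None, out)
    return out if fa_arr.ndim else out.item()


def classify_invasive(
    inv_fraction, fa=None, thresholds: ResponseThresholds = ResponseThresholds()
):
    """Invasive flag (inv_fraction > threshold) and optional quadrant label.

    With ``fa`` given, returns ``(flag, quadrant)`` where quadrant crosses
    invasiveness with the resistant split at fa < resistant-threshold:
    e.g. "invasive-resistant", "noninvasive-sensitive".
    """
    thresholds.validate()
    invf = np.asarray(inv_fraction, dtype=float)
    flag = invf > thresholds.invasive
    if fa is None:
        return flag if invf.ndim else bool(flag)
    fa_arr = np.asarray(fa, dtype=float)
    quad = np.where(flag, "invasive", "noninvasive").astype(object)
    quad = quad + np.where(fa_arr < thresholds.resistant, "-resistant", "-sensitive")
    if invf.ndim:
        return flag, quad
    return bool(flag), str(quad)


def organoid_states(
    measurements: pd.DataFrame,
    layout: PlateLayout | None = None,
    thresholds: ResponseThresholds = ResponseThresholds(),
) -> pd.DataFrame:
    """Per-organoid × timepoint response and invasion state table.

    Organoids with ``bf_area <= 0`` at a timepoint are dropped (logged).
    Columns: identity + fa, response_class, survival_inv_area, inv_fraction,
    invasive_flag, quadrant, and layout annotations when a layout is given.
    """
    df = measurements.copy()
    bad = df["bf_area"] <= 0
    if bad.any():
        logger.warning("excluding %d organoid-timepoint rows with bf_area <= 0", int(bad.sum()))
        df = df[~bad]
    if df.empty:
        raise DataError("no organoids with positive area")
    df["fa"] = fraction_affected(df["green_area"], df["bf_area"])
    df["response_class"] = classify_response(df["fa"].to_numpy(), thresholds)
    df["survival_inv_area"] = (df["inv_area"] - df["inv_green_area"]).clip(lower=0)
    df["inv_fraction"] = df["inv_area"] / df["bf_area"]
    flag, quad = classify_invasive(df["inv_fraction"].to_numpy(), df["fa"].to_numpy(), thresholds)
    df["invasive_flag"] = flag
    df["quadrant"] = quad
    if layout is not None:
        ann = layout.to_frame()[["well", "role", "regimen", "total_conc", "replicate_id"]]
        df = df.merge(ann, on="well", how="left")
        df = df[df["role"].notna()]  # wells absent from the layout are excluded
    return df.reset_index(drop=True)


def class_fractions(states: pd.DataFrame, group_keys: list[str]) -> pd.DataFrame:
    """Per-group response-class composition.

    Returns one row per group with ``frac_resistant``, ``frac_sensitive``,
    ``frac_highly_sensitive`` (summing to 1), counts, and
    ``ratio_sens_res`` = (sensitive + highly_sensitive) / resistant — the
    numerator pools both affected classes, treating sensitive vs resistant
    as a dichotomy. The ratio is +inf (flagged) when no organoid is
    resistant.
    """
    rows = []
    for keys, grp in states.groupby(group_keys):
        keys = keys if isinstance(keys, tuple) else (keys,)
        n = len(grp)
        counts = {c: int((grp["response_class"] == c).sum()) for c in RESPONSE_CLASSES}
        n_sens = counts["sensitive"] + counts["highly_sensitive"]
        row = dict(zip(group_keys, keys))
        row.update({
            "n_organoids": n,
            "frac_resistant": counts["resistant"] / n,
            "frac_sensitive": counts["sensitive"] / n,
            "frac_highly_sensitive": counts["highly_sensitive"] / n,
            "pct_sensitive": 100.0 * n_sens / n,
            "pct_resistant": 100.0 * counts["resistant"] / n,
            "ratio_sens_res": (n_sens / counts["resistant"]) if counts["resistant"] else np.inf,
            "ratio_undefined": counts["resistant"] == 0,
        })
        if "quadrant" in grp:
            for q in ("invasive-resistant", "invasive-sensitive",
                      "noninvasive-resistant", "noninvasive-sensitive"):
                row[f"frac_{q}"] = float((grp["quadrant"] == q).mean())
        rows.append(row)
    return pd.DataFrame(rows)


def invasion_metrics(states: pd.DataFrame, group_keys: list[str]) -> pd.DataFrame:
    """Per-group invasion summaries with the T0-normalized kinetic curve.

    For each group (e.g. well or regimen) and timepoint: total invasive
    area, total survival invasive area, mean invasive fraction, and
    ``kinetic_inv_norm(t)`` = sum inv_area(t) / sum inv_area(t₀). If the
    group's t₀ invasive area is 0, normalization falls back to a +1 µm²
    pseudo-area (flagged).
    """
    agg = (
        states.groupby(group_keys + ["time_h"])
        .agg(
            sum_inv_area=("inv_area", "sum"),
            sum_survival_inv_area=("survival_inv_area", "sum"),
            mean_inv_fraction=("inv_fraction", "mean"),
        )
        .reset_index()
        .sort_values(group_keys + ["time_h"])
    )
    parts = []
    for _, grp in agg.groupby(group_keys):
        grp = grp.copy()
        base = grp["sum_inv_area"].iloc[0]
        pseudo = base <= 0
        grp["kinetic_inv_norm"] = grp["sum_inv_area"] / (base if not pseudo else base + 1.0)
        grp["t0_pseudo_area"] = pseudo
        parts.append(grp)
    return pd.concat(parts, ignore_index=True)
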