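"""Well-level kinetic signal and control-anchored drug-response metrics.

The well signal at time *t* is the net live area
``S(t) = Σ bf_area − Σ green_area`` over the well's organoids; each well is
self-normalized to its first timepoint, ``F(t) = S(t)/S(t₀)``. Control
anchors are the per-timepoint mean fold changes of the vehicle
(negative-control) and staurosporine (positive-control) wells.

Three normalizations are computed from these fold changes:

* **% viability** — linear rescale placing the vehicle at 100% and the
  staurosporine control at 0%.
* **GR** — growth-rate inhibition metric normalized to the negative
  control only: ``GR = 2^(log2 F_trt / log2 F̄_neg) − 1``. 1 means
  control-like growth, 0 complete growth arrest, negative values net loss.
* **NDR** — normalized drug response using both controls:
  ``NDR = (2^(log2 F_trt / log2 F̄_neg) − 1) / (1 − 2^(log2 F̄_pos / log2 F̄_neg))``,
  anchored so a well matching the positive control scores exactly −1, a
  static well exactly 0, and a control-like well ≈ 1 (exactly 1 in the
  limit of a fully dead positive control). Values > 1 flag a proliferative
  effect. The double-control anchoring is what makes NDR robust to
  seeding-density differences between wells.

Dose-response curves of NDR over log10 concentration are summarized by a
span-normalized trapezoidal AUC (a constant curve has AUC equal to that
constant), and endpoint (NDR, % cell death) pairs are classified into
cytotoxic / mixed / cytostatic response signatures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, DegenerateWellError, SlowGrowthError
from .io import PlateLayout

__all__ = [
    "WellSeries",
    "ControlAnchors",
    "ResponseSignature",
    "well_signal",
    "control_anchors",
    "percent_viability",
    "gr_metric",
    "ndr_metric",
    "dose_response_auc",
    "auc_ratio",
    "classify_signature",
    "plate_well_metrics",
    "dose_response_table",
]


@dataclass
class WellSeries:
    """Aggregated kinetic signal of one well."""

    well: str
    time_h: np.ndarray
    signal: np.ndarray  # S(t) = Σ bf − Σ green, µm²
    fold_change: np.ndarray  # F(t) = S(t)/S(t0)
    cell_death_pct: np.ndarray  # 100 · Σ green / Σ bf


def well_signal(measurements: pd.DataFrame, well: str) -> WellSeries:
    """Assemble the per-timepoint net signal and fold change of one well."""
    sub = measurements[measurements["well"] == well]
    if sub.empty:
        raise DataError(f"well {well}: no measurements")
    agg = sub.groupby("time_h")[["bf_area", "green_area"]].sum().sort_index()
    if len(agg) < 2:
        raise DataError(f"well {well}: need >= 2 timepoints, got {len(agg)}")
    signal = (agg["bf_area"] - agg["green_area"]).to_numpy()
    if signal[0] <= 0:
        raise DegenerateWellError(f"well {well}: non-positive signal at first timepoint")
    bf = agg["bf_area"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        death = np.where(bf > 0, 100.0 * agg["green_area"].to_numpy() / bf, 0.0)
    return WellSeries(
        well=well,
        time_h=agg.index.to_numpy(dtype=float),
        signal=signal,
        fold_change=signal / signal[0],
        cell_death_pct=death,
    )


@dataclass
class ControlAnchors:
    """Per-timepoint mean fold change of the control wells of one plate."""

    time_h: np.ndarray
    f_neg: np.ndarray  # vehicle
    f_pos: np.ndarray | None  # staurosporine; None if not configured

    def at(self, t: float) -> tuple[float, float | None]:
        idx = np.flatnonzero(np.isclose(self.time_h, t))
        if len(idx) == 0:
            raise DataError(f"no control anchor at t = {t} h")
        i = int(idx[0])
        return float(self.f_neg[i]), None if self.f_pos is None else float(self.f_pos[i])


def control_anchors(
    measurements: pd.DataFrame, layout: PlateLayout, *, stat: str = "mean"
) -> ControlAnchors:
    """Average control-well fold changes per timepoint.

    ``stat`` may be "mean" (default) or "median" for robustness to a failed
    control well.
    """
    if stat not in ("mean", "median"):
        raise ConfigError(f"unknown control statistic {stat!r}")
    reduce = np.mean if stat == "mean" else np.median

    def pooled(wells: list[str]) -> tuple[np.ndarray, np.ndarray] | None:
        series = [well_signal(measurements, w) for w in wells
                  if w in set(measurements["well"])]
        if not series:
            return None
        times = series[0].time_h
        folds = np.vstack([s.fold_change for s in series])
        return times, reduce(folds, axis=0)

    neg = pooled(layout.negative_controls)
    if neg is None:
        raise DataError("no measured negative-control wells")
    pos = pooled(layout.positive_controls)
    return ControlAnchors(
        time_h=neg[0], f_neg=neg[1], f_pos=None if pos is None else pos[1]
    )


def percent_viability(f_trt: float, f_neg: float, f_pos: float | None = None) -> float:
    """Viability % anchored at vehicle = 100 and positive control = 0.

    Without a positive control, falls back to ``100 · F_trt / F̄_neg``.
    """
    if f_pos is None:
        if f_neg == 0:
            raise DataError("degenerate anchor: negative-control fold change is 0")
        return 100.0 * f_trt / f_neg
    if f_neg == f_pos:
        raise DataError("degenerate anchors: negative and positive control fold changes equal")
    return 100.0 * (f_trt - f_pos) / (f_neg - f_pos)


def _gr_exponent(f_trt: float, f_neg: float) -> float:
    if f_trt <= 0:
        raise DataError(f"fold change must be > 0 for GR/NDR (got {f_trt})")
    if f_neg <= 1:
        raise SlowGrowthError(
            f"negative-control fold change {f_neg} <= 1: growth-rate normalization "
            "undefined (slow-growing control)",
            fold_change=f_neg,
        )
    return np.log2(f_trt) / np.log2(f_neg)


def gr_metric(f_trt: float, f_neg: float) -> float:
    """Growth-rate inhibition metric: 1 control-like, 0 arrest, <0 net kill."""
    return float(2.0 ** _gr_exponent(f_trt, f_neg) - 1.0)


def ndr_metric(f_trt: float, f_neg: float, f_pos: float) -> float:
    """Normalized drug response on the −1 (killed) / 0 (static) / 1 (growing) scale.

    Exactly −1 when ``f_trt == f_pos`` and exactly 0 when ``f_trt == 1``,
    for any valid anchors.
    """
    if f_pos <= 0:
        raise DataError(f"positive-control fold change must be > 0 (got {f_pos})")
    num = 2.0 ** _gr_exponent(f_trt, f_neg) - 1.0
    den = 1.0 - 2.0 ** _gr_exponent(f_pos, f_neg)
    if den == 0:
        raise DataError("degenerate NDR anchors: positive control grew like the negative control")
    return float(num / den)


def dose_response_auc(concentrations, ndr_values) -> float:
    """Span-normalized trapezoidal AUC of NDR over log10 concentration.

    A constant NDR curve has AUC equal to that constant, so the value is
    comparable across regimens with different dose ranges.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(ndr_values, dtype=float)
    if len(c) < 2:
        raise DataError("need >= 2 concentrations for an AUC")
    if np.any(c <= 0):
        raise DataError("concentrations must be strictly positive")
    if np.any(np.diff(c) <= 0):
        raise DataError("concentrations must be strictly increasing without duplicates")
    x = np.log10(c)
    return float(np.trapezoid(y, x) / (x[-1] - x[0]))


def auc_ratio(combo_auc: float, alternative_auc: float) -> float:
    """AUC of a combination regimen over an alternative; < 1 reads as added benefit."""
    if alternative_auc == 0:
        raise DataError("AUC ratio undefined: alternative regimen AUC is 0")
    return float(combo_auc / alternative_auc)


@dataclass(frozen=True)
class ResponseSignature:
    """Joint NDR / % cell death response label of one condition."""

    label: str  # cytotoxic | mixed | cytostatic | indeterminate
    ndr_value: float
    cell_death_pct: float
    proliferative: bool = False


def classify_signature(
    ndr: float, cell_death_pct: float, *, death_threshold: float = 40.0,
    ndr_cytotoxic: float = -0.5,
) -> ResponseSignature:
    """Classify an endpoint (NDR, % cell death) pair.

    cytotoxic: NDR < −0.5 with cell death > 40%; mixed: cell death > 40%
    despite NDR ≥ −0.5; cytostatic: NDR ≥ 0 with little cell death (≤ 40%);
    anything else (negative NDR without measurable death) is indeterminate.
    Every input receives a label.
    """
    if cell_death_pct > death_threshold:
        label = "cytotoxic" if ndr < ndr_cytotoxic else "mixed"
    elif ndr >= 0:
        label = "cytostatic"
    else:
        label = "indeterminate"
    return ResponseSignature(
        label=label, ndr_value=float(ndr), cell_death_pct=float(cell_death_pct),
        proliferative=ndr > 1,
    )


def plate_well_metrics(
    measurements: pd.DataFrame, layout: PlateLayout, *, control_stat: str = "mean"
) -> pd.DataFrame:
    """All well × timepoint metrics of one plate as a tidy table.

    Columns: well, role, regimen, total_conc, replicate_id, time_h, signal,
    fold_change, cell_death_pct, viability_pct, gr, ndr, proliferative.
    GR/NDR are NaN where undefined (t₀, or a non-growing control).
    """
    anchors = control_anchors(measurements, layout, stat=control_stat)
    rows = []
    for well in sorted(set(measurements["well"]) & set(layout.wells)):
        entry = layout.wells[well]
        series = well_signal(measurements, well)
        for i, t in enumerate(series.time_h):
            f_neg, f_pos = anchors.at(t)
            f_trt = series.fold_change[i]
            try:
                viability = percent_viability(f_trt, f_neg, f_pos)
            except DataError:
                viability = np.nan
            try:
                gr = gr_metric(f_trt, f_neg)
            except DataError:
                gr = np.nan
            try:
                ndr = np.nan if f_pos is None else ndr_metric(f_trt, f_neg, f_pos)
            except DataError:
                ndr = np.nan
            rows.append({
                "well": well, "role": entry.role, "regimen": entry.regimen,
                "total_conc": entry.total_conc, "replicate_id": entry.replicate_id,
                "time_h": t, "signal": series.signal[i], "fold_change": f_trt,
                "cell_death_pct": series.cell_death_pct[i],
                "viability_pct": viability, "gr": gr, "ndr": ndr,
                "proliferative": bool(np.isfinite(ndr) and ndr > 1),
            })
    return pd.DataFrame(rows)


def dose_response_table(
    well_metrics: pd.DataFrame, *, endpoint_h: float | None = None
) -> pd.DataFrame:
    """Per-regimen dose-response profile with AUC at an endpoint timepoint.

    Replicate wells at the same concentration are averaged. ``endpoint_h``
    defaults to the final timepoint. Returns one row per regimen ×
    concentration with mean viability/GR/NDR/cell death plus the regimen's
    span-normalized NDR AUC (NaN for single-dose regimens).
    """
    if endpoint_h is None:
        endpoint_h = float(well_metrics["time_h"].max())
    trt = well_metrics[
        (well_metrics["role"] == "treatment")
        & np.isclose(well_metrics["time_h"], endpoint_h)
    ]
    if trt.empty:
        raise DataError(f"no treatment wells at endpoint {endpoint_h} h")
    prof = (
        trt.groupby(["regimen", "total_conc"])[
            ["viability_pct", "gr", "ndr", "cell_death_pct"]
        ]
        .mean()
        .reset_index()
        .sort_values(["regimen", "total_conc"])
    )
    aucs = {}
    for regimen, grp in prof.groupby("regimen"):
        aucs[regimen] = (
            dose_response_auc(grp["total_conc"], grp["ndr"]) if len(grp) >= 2 else np.nan
        )
    prof["auc"] = prof["regimen"].map(aucs)
    prof["endpoint_h"] = endpoint_h
    return prof
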