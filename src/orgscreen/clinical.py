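"""Exact small-sample Spearman correlation and clinical concordance.

Organoid cohorts are small (here, seven or eight patients), so the usual
large-sample approximations for the Spearman rank correlation are
inappropriate. For untied ranks with n ≤ 8 the permutation null is
enumerated in full (n! rank permutations), giving the exact two-sided
p-value ``#{|ρ*| ≥ |ρ|} / n!``. Tied ranks fall back to average ranks with
a seeded Monte-Carlo permutation p; larger n uses the t approximation,
with the method recorded on the result.

Cohort-level helpers correlate per-patient organoid readouts (% sensitive,
% resistant, sensitive:resistant ratio) with progression-free survival,
and score the concordance between well-level response signatures and the
categorical clinical response.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "spearman_exact",
    "correlate_with_pfs",
    "signature_concordance",
    "DEFAULT_SIGNATURE_MAP",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman coefficient with its permutation (or approximate) p-value."""

    rho: float
    p_two_sided: float
    n: int
    method: str  # exact | monte_carlo | approximate


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    """Moment (Pearson-on-ranks) Spearman coefficient; exact for tied ranks too."""
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise DataError("constant input: Spearman rho undefined")
    return float(rx @ ry / denom)


def spearman_exact(
    x, y, *, n_exact_max: int = 8, n_mc: int = 10_000, seed: int = 0
) -> CorrelationResult:
    """Spearman rank correlation with an exact permutation p for small n.

    For untied ranks and ``n <= n_exact_max`` (default 8: 40,320
    permutations), the two-sided p enumerates every rank permutation.
    Untied ranks use the classical ``ρ = 1 − 6Σd²/(n³−n)``. Tied ranks use
    average ranks with the moment formula and a seeded Monte-Carlo
    permutation p; untied ``n > n_exact_max`` uses the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 3:
        raise DataError(f"need n >= 3 pairs (got {n})")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise DataError("constant input: Spearman rho undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    tied = np.unique(x).size < n or np.unique(y).size < n

    if not tied:
        d2 = float(np.sum((rx - ry) ** 2))
        rho = 1.0 - 6.0 * d2 / (n**3 - n)
        if n <= n_exact_max:
            base = np.arange(1, n + 1, dtype=float)
            count = 0
            total = math.factorial(n)
            threshold = abs(rho) - 1e-12
            for perm in itertools.permutations(range(n)):
                d2p = float(np.sum((base - base[list(perm)]) ** 2))
                if abs(1.0 - 6.0 * d2p / (n**3 - n)) >= threshold:
                    count += 1
            return CorrelationResult(rho, count / total, n, "exact")
        t = rho * math.sqrt((n - 2) / max(1.0 - rho**2, 1e-300))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
        return CorrelationResult(rho, min(p, 1.0), n, "approximate")

    rho = _rho_from_ranks(rx, ry)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_mc):
        if abs(_rho_from_ranks(rx, rng.permutation(ry))) >= abs(rho) - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_mc)
    return CorrelationResult(rho, p, n, "monte_carlo")


def correlate_with_pfs(
    fractions: pd.DataFrame, clinical: pd.DataFrame, **spearman_kwargs
) -> pd.DataFrame:
    """Correlate per-patient organoid class fractions with PFS.

    ``fractions`` needs one row per patient with ``patient_id``,
    ``pct_sensitive``, ``pct_resistant`` and ``ratio_sens_res`` (as from
    :func:`orgscreen.singleorg.class_fractions` grouped by patient).
    Censored patients are excluded (count logged). Returns one row per
    readout with rho, p, n and method.
    """
    usable = clinical[~clinical["censored"]]
    n_censored = len(clinical) - len(usable)
    if n_censored:
        logger.info("excluding %d censored patient(s) from PFS correlation", n_censored)
    merged = fractions.merge(usable[["patient_id", "pfs_months"]], on="patient_id")
    if len(merged) < 3:
        raise DataError(f"need >= 3 patients with uncensored PFS (got {len(merged)})")
    rows = []
    for readout in ("pct_sensitive", "pct_resistant", "ratio_sens_res"):
        res = spearman_exact(merged[readout], merged["pfs_months"], **spearman_kwargs)
        rows.append({
            "readout": readout, "rho": res.rho, "p_two_sided": res.p_two_sided,
            "n": res.n, "method": res.method, "n_censored_excluded": n_censored,
        })
    return pd.DataFrame(rows)


#: ex vivo signature -> expected clinical response category
DEFAULT_SIGNATURE_MAP = {"cytotoxic": "good", "mixed": "mixed", "cytostatic": "bad"}


def signature_concordance(
    signatures: pd.DataFrame, clinical: pd.DataFrame,
    mapping: dict[str, str] = DEFAULT_SIGNATURE_MAP,
) -> tuple[pd.DataFrame, float]:
    """Match ex vivo response signatures to clinical response categories.

    ``signatures`` needs ``patient_id`` and ``label`` columns (one row per
    patient/regimen). Returns the per-patient table with a ``concordant``
    flag and the overall concordant fraction. Patients missing from either
    table are listed and excluded.
    """
    merged = signatures.merge(
        clinical[["patient_id", "response_category"]], on="patient_id", how="inner"
    )
    dropped = sorted(
        set(signatures["patient_id"]).symmetric_difference(clinical["patient_id"])
    )
    if merged.empty:
        raise DataError(f"no patients shared between signatures and clinical table: {dropped}")
    if dropped:
        logger.warning("unmatched patient keys excluded: %s", dropped)
    merged = merged.copy()
    merged["predicted"] = merged["label"].map(mapping)
    merged["concordant"] = merged["predicted"] == merged["response_category"]
    return merged, float(merged["concordant"].mean())
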