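"""Most Probable Number (MPN) estimation from multi-well dilution assays.

A water sample (possibly diluted by a factor ``d``) is distributed over
wells of one or more volume classes; a well turns positive when it received
at least one viable cell.  Under complete mixing the number of cells in a
well of volume ``v`` ml is Poisson with mean ``c * v / d`` where ``c`` is the
cell concentration per ml of undiluted sample, so

    P(positive) = 1 - exp(-c * v / d).

The MPN is the maximum-likelihood ``c`` given the observed pattern of
positive wells, reported per 100 ml.  Assays report censored values outside
their dynamic range; the defaults mirror a Colilert-18-style assay with
reporting limits <100 and >=242,000 per 100 ml.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["WellClass", "WellOutcome", "MPNEstimate", "mpn_loglik", "estimate_mpn"]

DEFAULT_LOD_PER_100ML = 100.0
DEFAULT_UOD_PER_100ML = 242_000.0

# log10 search bounds on concentration per ml
_LOG10_C_LO, _LOG10_C_HI = -6.0, 6.0


@dataclass(frozen=True)
class WellClass:
    volume_ml: float
    wells_total: int
    wells_positive: int

    def __post_init__(self):
        if self.volume_ml <= 0:
            raise ValueError("well volume must be > 0")
        if not 0 <= self.wells_positive <= self.wells_total:
            raise ValueError(
                f"wells_positive={self.wells_positive} outside "
                f"[0, {self.wells_total}]"
            )


@dataclass(frozen=True)
class WellOutcome:
    """Observed positives per volume class, plus the pre-plating dilution."""

    classes: tuple[WellClass, ...]
    dilution: float = 1.0
    sample_id: str = ""

    def __post_init__(self):
        if not self.classes:
            raise ValueError("at least one well class required")
        if self.dilution < 1.0:
            raise ValueError("dilution factor must be >= 1")
        object.__setattr__(self, "classes", tuple(self.classes))

    @property
    def all_negative(self) -> bool:
        return all(c.wells_positive == 0 for c in self.classes)

    @property
    def all_positive(self) -> bool:
        return all(c.wells_positive == c.wells_total for c in self.classes)


@dataclass(frozen=True)
class MPNEstimate:
    """MPN per 100 ml with censoring status at the assay's reporting limits."""

    mpn: float  # per 100 ml
    status: str  # point | below_lod | above_uod
    lod: float = DEFAULT_LOD_PER_100ML
    uod: float = DEFAULT_UOD_PER_100ML
    loglik_at_mpn: float = float("nan")
    sample_id: str = ""


def mpn_loglik(c: float, wells: WellOutcome) -> float:
    """Log-likelihood of concentration ``c`` (cells/ml, pre-dilution).

    ``sum_classes [ p*log(1 - e^(-c*v/d)) + (n-p)*(-c*v/d) ]``; returns
    ``-inf`` at c=0 when any well is positive.
    """
    if c < 0:
        raise ValueError("concentration must be >= 0")
    ll = 0.0
    d = wells.dilution
    for cl in wells.classes:
        lam = c * cl.volume_ml / d
        neg = cl.wells_total - cl.wells_positive
        if cl.wells_positive > 0:
            if lam == 0.0:
                return -math.inf
            # log(1 - exp(-lam)), stable for small lam
            ll += cl.wells_positive * math.log(-math.expm1(-lam))
        ll += neg * (-lam)
    return ll


def estimate_mpn(
    wells: WellOutcome,
    lod: float = DEFAULT_LOD_PER_100ML,
    uod: float = DEFAULT_UOD_PER_100ML,
    xatol: float = 1e-8,
) -> MPNEstimate:
    """Maximum-likelihood MPN per 100 ml.

    All-negative outcomes are censored below the lower reporting limit and
    all-positive outcomes above the upper one.  Otherwise the likelihood is
    maximised by Brent search on log10 concentration over [1e-6, 1e6] per ml;
    a point estimate falling outside the reporting limits is also censored
    (its value is still returned in ``mpn``).
    """
    if wells.all_negative:
        return MPNEstimate(0.0, "below_lod", lod, uod, 0.0, wells.sample_id)
    if wells.all_positive:
        return MPNEstimate(
            math.inf, "above_uod", lod, uod, 0.0, wells.sample_id
        )

    def neg_ll(log10_c: float) -> float:
        return -mpn_loglik(10.0**log10_c, wells)

    res = minimize_scalar(
        neg_ll,
        bounds=(_LOG10_C_LO, _LOG10_C_HI),
        method="bounded",
        options={"xatol": xatol},
    )
    c = 10.0**res.x
    mpn_100ml = c * 100.0
    if mpn_100ml <= lod:
        status = "below_lod"
    elif mpn_100ml >= uod:
        status = "above_uod"
    else:
        status = "point"
    return MPNEstimate(mpn_100ml, status, lod, uod, -res.fun, wells.sample_id)


def wells_to_json(outcomes: Sequence[WellOutcome], path) -> None:
    """Write well outcomes as a JSON sidecar."""
    import json

    payload = {
        "samples": [
            {
                "sample_id": w.sample_id,
                "dilution": w.dilution,
                "classes": [
                    [c.volume_ml, c.wells_total, c.wells_positive] for c in w.classes
                ],
            }
            for w in outcomes
        ]
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def wells_from_json(path) -> list[WellOutcome]:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    return [
        WellOutcome(
            tuple(WellClass(v, n, p) for v, n, p in s["classes"]),
            s.get("dilution", 1.0),
            s.get("sample_id", ""),
        )
        for s in payload["samples"]
    ]


def closed_form_single_volume(wells: WellOutcome) -> float:
    """MPN per 100 ml for a single-volume outcome, ``-ln((n-p)/n)/v * d * 100``.

    Only valid for one well class with 0 < p < n; used as an analytic
    cross-check of the optimiser.
    """
    if len(wells.classes) != 1:
        raise ValueError("closed form requires a single volume class")
    cl = wells.classes[0]
    if not 0 < cl.wells_positive < cl.wells_total:
        raise ValueError("closed form requires 0 < p < n")
    frac_neg = (cl.wells_total - cl.wells_positive) / cl.wells_total
    c = -math.log(frac_neg) / cl.volume_ml * wells.dilution
    return c * 100.0
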