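"""Evolutionary-rate alignment across lineages and event dating.

Lineages evolve at different speeds, so the same polyploidy or divergence
event produces Ks peaks at different positions in different genomes.  A
shared event gives the handle to align them: if the reference lineage shows
the shared event at mean Ks ``mu_ref`` and lineage i at ``mu_i``, then
``lambda_i = mu_ref / mu_i`` rescales lineage-i Ks onto the reference clock.
Paralog Ks is corrected by ``lambda_i``; ortholog Ks between lineages i and
j by the average ``(lambda_i + lambda_j) / 2`` (both lineages assumed to
contribute equal shares of the path since their split).  Two lineages that
share a later event can afterwards be re-aligned on that event, absorbing
rate change that postdates the first shared event.  Corrected peaks convert
to ages through the reference clock rate ``r_ref`` (Ks per Mya per lineage):
``T = mu' / (2 r_ref)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .peaks import GaussianComponent


class AssignmentError(KeyError):
    pass


@dataclass
class RateFactor:
    lineage: str
    reference: str
    shared_event: str
    value: float            # multiplicative Ks correction lambda_i
    sd_corrected: float     # sigma of the shared-event component after correction

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("rate factor must be positive")


@dataclass
class CalibratedDates:
    """Event dates (Mya) from corrected Ks peaks.

    ``table`` columns: event, mu, sd, date, lower, upper.  The interval is
    the ± one-component-sigma band mapped through the clock.
    """
    r_ref: float
    table: pd.DataFrame
    calibration: str


def _component(assignment: Mapping[str, GaussianComponent], event: str,
               lineage: str) -> GaussianComponent:
    if event not in assignment:
        raise AssignmentError(f"no component assigned to event {event!r} in {lineage}")
    return assignment[event]


def estimate_rate_factor(assignment_i: Mapping[str, GaussianComponent],
                         assignment_ref: Mapping[str, GaussianComponent],
                         shared_event: str, lineage: str = "i",
                         reference: str = "ref") -> RateFactor:
    """lambda_i aligning lineage i onto the reference via a shared event."""
    ci = _component(assignment_i, shared_event, lineage)
    cref = _component(assignment_ref, shared_event, reference)
    if ci.mean <= 0:
        raise ValueError(f"non-positive shared-event peak mean for {lineage}")
    lam = cref.mean / ci.mean
    return RateFactor(lineage=lineage, reference=reference, shared_event=shared_event,
                      value=lam, sd_corrected=ci.sd * lam)


def correct_ks(values, lineages, factors: Mapping[str, float]):
    """Correct Ks values for lineage rate differences.

    ``lineages`` is, per value, either a single lineage id (paralog pair:
    multiply by lambda_i) or a tuple (i, j) of the two lineages of an
    ortholog pair (multiply by the mean of the two lambdas).
    """
    values = np.asarray(values, dtype=float)
    single = isinstance(lineages, (str, tuple)) and (
        isinstance(lineages, str) or len(lineages) == 2 and all(isinstance(x, str) for x in lineages))
    items = [lineages] * len(values) if single else list(lineages)
    out = np.empty_like(values)
    for n, (v, lin) in enumerate(zip(values, items)):
        if isinstance(lin, str):
            if lin not in factors:
                raise KeyError(f"no rate factor for lineage {lin!r}")
            out[n] = v * factors[lin]
        else:
            i, j = lin
            for l in (i, j):
                if l not in factors:
                    raise KeyError(f"no rate factor for lineage {l!r}")
            out[n] = v * (factors[i] + factors[j]) / 2.0
    return out


def corrected_assignment(assignment: Mapping[str, GaussianComponent],
                         lam: float) -> dict:
    return {ev: GaussianComponent(c.weight, c.mean * lam, c.sd * lam)
            for ev, c in assignment.items()}


def recorrect_pair(corrected_slow: Mapping[str, GaussianComponent],
                   corrected_fast: Mapping[str, GaussianComponent],
                   shared_later_event: str, lam_fast: float,
                   lineage_fast: str = "fast") -> float:
    """Second-stage alignment of the faster of two lineages that share a
    later event, on first-stage-corrected peaks.  Returns the updated
    lambda for the faster lineage."""
    cs = _component(corrected_slow, shared_later_event, "slow lineage")
    cf = _component(corrected_fast, shared_later_event, lineage_fast)
    if cf.mean <= 0:
        raise ValueError("non-positive corrected peak mean")
    return lam_fast * (cs.mean / cf.mean)


def date_events(corrected: Mapping[str, GaussianComponent],
                r_ref: Optional[float] = None,
                anchor_event: Optional[str] = None,
                anchor_age: Optional[float] = None) -> CalibratedDates:
    """Convert corrected Ks peaks to absolute ages.

    Calibration is either a direct clock rate ``r_ref`` (Ks per Mya per
    lineage) or an anchored event age, which implies
    ``r_ref = mu_anchor / (2 * anchor_age)``.  Dating the anchor event
    returns the anchor age exactly.
    """
    if r_ref is None:
        if anchor_event is None or anchor_age is None:
            raise ValueError("need r_ref or (anchor_event, anchor_age)")
        if anchor_age <= 0:
            raise ValueError("anchor age must be positive")
        mu = _component(corrected, anchor_event, "calibration").mean
        r_ref = mu / (2.0 * anchor_age)
        calibration = f"anchor {anchor_event} at {anchor_age} Mya"
    else:
        calibration = f"r_ref = {r_ref}"
    if r_ref <= 0:
        raise ValueError("clock rate must be positive")
    rows = []
    for ev, c in sorted(corrected.items(), key=lambda kv: kv[1].mean):
        rows.append({
            "event": ev, "mu": c.mean, "sd": c.sd,
            "date": c.mean / (2.0 * r_ref),
            "lower": max(c.mean - c.sd, 0.0) / (2.0 * r_ref),
            "upper": (c.mean + c.sd) / (2.0 * r_ref),
        })
    return CalibratedDates(r_ref=r_ref, table=pd.DataFrame(rows), calibration=calibration)
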