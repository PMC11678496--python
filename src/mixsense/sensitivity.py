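"""Detection rates per eVAF group and probit-regression sensitivity.

For a cutoff condition (read-depth cutoff ``dp_cut``, VAF cutoff
``vaf_cut``) an observation counts as *detected* when the allele was called
at all (VAF > 0) and survives both thresholds — a call below a cutoff is
treated as null, exactly as a caller applying that cutoff would have
treated it. Detection rates per V-group (detected / total informative
pair-observations at that eVAF) form the dose–response curve of the
dilution series.

Sensitivity is the lowest eVAF at which at least 95% of diluted alleles are
detected. It is estimated by probit regression: group-level detected/total
counts are fit as Binomial with success probability Phi(a + b * eVAF) by
maximum likelihood, and the estimate is the eVAF where the fitted curve
crosses the target,

    eVAF_95 = (Phi^-1(0.95) - a) / b.

When every group already sits at or above the target the fit would have to
extrapolate below the data; the smallest observed eVAF is returned instead,
flagged as saturated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .errors import FitError
from .pairs import InformativePair, MixtureObservation

_SLOPE_TOL = 1e-6


@dataclass(frozen=True)
class CutoffCondition:
    """A (read depth, VAF) threshold pair under which detection is evaluated."""

    dp_cut: int = 0
    vaf_cut: float = 0.0

    def __post_init__(self) -> None:
        if self.dp_cut < 0:
            raise ValueError(f"dp_cut must be >= 0, got {self.dp_cut}")
        if not 0.0 <= self.vaf_cut <= 1.0:
            raise ValueError(f"vaf_cut must be in [0,1], got {self.vaf_cut}")

    def __str__(self) -> str:
        return f"DP{self.dp_cut}_VAF{self.vaf_cut:g}"


@dataclass(frozen=True)
class GroupRow:
    """Detected/total counts for one eVAF group."""

    label: str
    evaf: float
    n_total: int
    n_detected: int

    @property
    def rate(self) -> float:
        return self.n_detected / self.n_total if self.n_total else float("nan")


@dataclass(frozen=True)
class DetectionTable:
    """Per-group detection counts under one cutoff condition, ordered by eVAF."""

    condition: CutoffCondition
    rows: tuple[GroupRow, ...]
    empty: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": [r.label for r in self.rows],
                "evaf": [r.evaf for r in self.rows],
                "n_total": [r.n_total for r in self.rows],
                "n_detected": [r.n_detected for r in self.rows],
                "rate": [r.rate for r in self.rows],
            }
        )


@dataclass(frozen=True)
class SensitivityEstimate:
    """Probit fit summary and the eVAF reaching the target detection level."""

    intercept: float
    slope: float
    target: float
    sensitivity_evaf: float
    n_groups: int
    converged: bool
    saturated: bool = False

    @property
    def sensitivity_pct(self) -> float:
        """Sensitivity as a percentage, two decimals (e.g. 4.82)."""
        return round(100.0 * self.sensitivity_evaf, 2)


def is_detected(obs: MixtureObservation, condition: CutoffCondition) -> bool:
    """Whether one mixture observation counts as detected under the condition.

    Requires presence in the call set (VAF > 0) even at ``vaf_cut`` 0 — a
    zero cutoff means no extra thresholding, not detection of absent calls.
    An unknown depth (``None``) passes the depth test vacuously: missing
    coverage information is not evidence of low coverage.
    """
    if obs.vaf <= 0.0 or obs.vaf < condition.vaf_cut:
        return False
    if obs.depth is not None and obs.depth < condition.dp_cut:
        return False
    return True


def detection_table(
    pairs: Sequence[InformativePair], condition: CutoffCondition
) -> DetectionTable:
    """Tally detected/total pair-observations per eVAF group."""
    groups: dict[str, tuple[float, int, int]] = {}
    for pair in pairs:
        for obs in pair.observations:
            evaf, total, det = groups.get(obs.group_label, (obs.evaf, 0, 0))
            groups[obs.group_label] = (evaf, total + 1, det + int(is_detected(obs, condition)))
    rows = tuple(
        GroupRow(label=label, evaf=evaf, n_total=total, n_detected=det)
        for label, (evaf, total, det) in sorted(groups.items(), key=lambda kv: kv[1][0])
    )
    return DetectionTable(condition=condition, rows=rows, empty=not rows)


def probit_sensitivity(
    table: DetectionTable,
    target: float = 0.95,
    max_fit_evaf: float | None = None,
) -> SensitivityEstimate:
    """Estimate the eVAF at which the detection rate reaches ``target``.

    Groups with no observations are ignored; ``max_fit_evaf`` restricts the
    fit to groups at or below that eVAF (the near-saturated upper groups
    contribute almost no likelihood either way). Raises
    :class:`~mixsense.errors.FitError` on fewer than two usable groups, a
    non-positive fitted slope (no dose–response), or non-convergence.
    """
    import statsmodels.api as sm

    rows = [r for r in table.rows if r.n_total > 0]
    if max_fit_evaf is not None:
        rows = [r for r in rows if r.evaf <= max_fit_evaf + 1e-12]
    if len(rows) < 2:
        raise FitError(
            f"{table.condition}: need >= 2 non-empty eVAF groups, have {len(rows)}"
        )
    if all(r.rate >= target for r in rows):
        # Already above target everywhere observed: do not extrapolate below
        # the data; report the smallest observed eVAF.
        return SensitivityEstimate(
            intercept=float("nan"), slope=float("nan"), target=target,
            sensitivity_evaf=min(r.evaf for r in rows),
            n_groups=len(rows), converged=True, saturated=True,
        )

    endog = np.array([[r.n_detected, r.n_total - r.n_detected] for r in rows], dtype=float)
    exog = sm.add_constant(np.array([r.evaf for r in rows], dtype=float))
    model = sm.GLM(endog, exog, family=sm.families.Binomial(link=sm.families.links.Probit()))
    try:
        import warnings

        with warnings.catch_warnings():
            # Saturated upper groups (rate exactly 1) trigger a perfect-
            # separation warning; the slope is still identified by the
            # partially detected groups, so the fit is valid.
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=200)
    except Exception as exc:
        raise FitError(f"{table.condition}: probit fit failed: {exc}") from exc
    a, b = float(res.params[0]), float(res.params[1])
    if not np.isfinite(a) or not np.isfinite(b):
        raise FitError(f"{table.condition}: probit fit returned non-finite parameters")
    if b <= _SLOPE_TOL:
        raise FitError(
            f"{table.condition}: non-positive probit slope ({b:.3g}); "
            "detection does not increase with eVAF"
        )
    evaf95 = (ndtri(target) - a) / b
    return SensitivityEstimate(
        intercept=a, slope=b, target=target, sensitivity_evaf=float(evaf95),
        n_groups=len(rows), converged=bool(res.converged),
    )


def count_detected_variants(
    pairs: Sequence[InformativePair], conditions: Iterable[CutoffCondition]
) -> pd.DataFrame:
    """Detected observation and distinct-pair counts per cutoff condition.

    For each condition: ``n_observations`` is the number of pair-observations
    passing the detection rule across all mixtures; ``n_pairs`` the number of
    pairs detected in at least one mixture.
    """
    records = []
    for cond in conditions:
        n_obs = 0
        n_pairs = 0
        for pair in pairs:
            hits = sum(is_detected(o, cond) for o in pair.observations)
            n_obs += hits
            n_pairs += int(hits > 0)
        records.append(
            {"dp_cut": cond.dp_cut, "vaf_cut": cond.vaf_cut,
             "n_observations": n_obs, "n_pairs": n_pairs}
        )
    return pd.DataFrame.from_records(records)


def sensitivity_grid(
    pairs: Sequence[InformativePair],
    conditions: Iterable[CutoffCondition],
    target: float = 0.95,
    max_fit_evaf: float | None = None,
) -> pd.DataFrame:
    """Detection tables and probit estimates for a list of cutoff conditions.

    Returns one row per condition with fit parameters, the sensitivity in
    percent, and flags; conditions whose fit fails are reported with NaN
    estimates and the failure message rather than aborting the grid.
    """
    records = []
    for cond in conditions:
        table = detection_table(pairs, cond)
        rec: dict = {"dp_cut": cond.dp_cut, "vaf_cut": cond.vaf_cut}
        try:
            est = probit_sensitivity(table, target=target, max_fit_evaf=max_fit_evaf)
            rec.update(
                intercept=est.intercept, slope=est.slope,
                sensitivity_evaf=est.sensitivity_evaf,
                sensitivity_pct=est.sensitivity_pct,
                saturated=est.saturated, converged=est.converged, error="",
            )
        except FitError as exc:
            rec.update(
                intercept=float("nan"), slope=float("nan"),
                sensitivity_evaf=float("nan"), sensitivity_pct=float("nan"),
                saturated=False, converged=False, error=str(exc),
            )
        records.append(rec)
    return pd.DataFrame.from_records(records)
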