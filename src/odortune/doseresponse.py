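"""Hill dose-response fitting, EC50 censoring and the activity index.

The model is the three-parameter Hill equation with a zero lower
asymptote (responses are baseline-subtracted ΔF/F, so no basal offset is
fitted)::

    response(c) = amplitude * c**slope / (c**slope + EC50**slope)

parameterized as (log10 EC50, amplitude, slope) and fitted by unweighted
least squares on replicate-mean responses. Negative amplitudes are
permitted: inhibitory ligands suppress spontaneous channel activity and
produce negative ΔF/F.

Ligands whose curves never saturate inside the tested concentration range
cannot yield a meaningful EC50; such fits (non-converged, or fitted EC50
above the highest tested concentration) are *censored*: log10(EC50) is
assigned the fixed placeholder −2 (10 mM, more than an order of magnitude
above the 0.5 mM protocol top).

Two scalar summaries characterize each curve:

* max ΔF/F — the replicate-mean response at the highest tested
  concentration (sign preserved);
* activity index = −log10(EC50) × max ΔF/F, combining apparent affinity
  and maximal efficacy in one agonism score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import InsufficientDataError, InvalidParameterError
from .synth import hill_response

logger = logging.getLogger(__name__)

__all__ = [
    "CENSOR_LOG_EC50",
    "HillModel",
    "HillResults",
    "fit_hill",
    "apply_censoring",
    "max_dff",
    "activity_index",
    "fit_dose_response_table",
]

#: log10(EC50/M) placeholder assigned to censored (non-saturating) curves.
CENSOR_LOG_EC50 = -2.0

_SLOPE_BOUNDS = (0.2, 10.0)
_LOG_EC50_BOUNDS = (-12.0, 3.0)


@dataclass(frozen=True)
class HillResults:
    """Estimates and diagnostics of one Hill fit.

    Attributes
    ----------
    log_ec50, amplitude, slope : float
        Point estimates. When ``censored`` is true, ``log_ec50`` holds the
        censoring placeholder, not an estimate.
    converged : bool
        Whether the optimizer reported success.
    censored : bool
        Whether the censoring rule replaced the EC50.
    degenerate : bool
        All-zero response vector; amplitude pinned to 0.
    rss : float
        Residual sum of squares of the fitted curve on the fitted data.
    """

    log_ec50: float
    amplitude: float
    slope: float
    converged: bool
    censored: bool = False
    degenerate: bool = False
    rss: float = float("nan")
    nobs: int = 0

    @property
    def ec50(self) -> float:
        return 10.0 ** self.log_ec50

    def predict(self, concentrations):
        """Fitted curve evaluated at the given molar concentrations."""
        return hill_response(concentrations, self.log_ec50, self.amplitude, self.slope)

    def summary(self) -> str:
        state = (
            "censored" if self.censored
            else "converged" if self.converged
            else "not converged"
        )
        lines = [
            "Hill dose-response fit",
            "----------------------",
            f"  log10 EC50 : {self.log_ec50: .4f}" + ("  [censoring placeholder]" if self.censored else ""),
            f"  EC50 (M)   : {self.ec50: .4g}",
            f"  amplitude  : {self.amplitude: .4f}",
            f"  Hill slope : {self.slope: .4f}",
            f"  RSS        : {self.rss: .4g}  (n = {self.nobs})",
            f"  status     : {state}" + ("; degenerate (all-zero responses)" if self.degenerate else ""),
        ]
        return "\n".join(lines)


class HillModel:
    """Hill dose-response model for one receptor x ligand series.

    Parameters
    ----------
    concentrations : array-like
        Distinct molar concentrations (any order; at least 4).
    responses : array-like
        Mean normalized ΔF/F at each concentration (replicate means), or a
        2-D array (replicates x concentrations) whose column means are
        fitted.
    """

    def __init__(self, concentrations, responses):
        c = np.asarray(concentrations, dtype=float)
        y = np.asarray(responses, dtype=float)
        if y.ndim == 2:
            y = np.nanmean(y, axis=0)
        if c.ndim != 1 or c.shape != y.shape:
            raise InvalidParameterError("concentrations and responses must align")
        if np.any(c <= 0):
            raise InvalidParameterError("fit concentrations must be positive")
        if len(np.unique(c)) < 4:
            raise InsufficientDataError(
                f"need >= 4 distinct concentrations, got {len(np.unique(c))}"
            )
        order = np.argsort(c)
        self.concentrations = c[order]
        self.responses = y[order]

    def _initial_params(self) -> tuple[float, float, float]:
        c, y = self.concentrations, self.responses
        amp0 = float(y[-1])                       # response at top concentration
        if amp0 == 0.0:
            amp0 = float(y[np.argmax(np.abs(y))]) or 1e-3
        logc = np.log10(c)
        # log EC50 <- concentration of half-max crossing, linearly interpolated
        le0 = float(np.median(logc))
        rel = y / amp0                            # ascending toward 1 at the top
        for i in range(len(c) - 1):
            y0, y1 = rel[i], rel[i + 1]
            if (y0 - 0.5) * (y1 - 0.5) <= 0 and y0 != y1:
                frac = (0.5 - y0) / (y1 - y0)
                le0 = float(logc[i] + frac * (logc[i + 1] - logc[i]))
                break
        le0 = float(np.clip(le0, *_LOG_EC50_BOUNDS))
        return le0, amp0, 1.0

    def fit(self, censor: bool = True, censor_value: float = CENSOR_LOG_EC50) -> HillResults:
        """Least-squares fit; optionally apply the censoring rule.

        Non-convergence is reported through ``converged``/``censored``
        flags, never raised.
        """
        c, y = self.concentrations, self.responses
        if np.allclose(y, 0.0):
            res = HillResults(
                log_ec50=float(np.median(np.log10(c))),
                amplitude=0.0,
                slope=1.0,
                converged=False,
                degenerate=True,
                rss=float(np.sum(y**2)),
                nobs=len(y),
            )
            return apply_censoring(res, c, censor_value) if censor else res

        p0 = self._initial_params()
        lb = [_LOG_EC50_BOUNDS[0], -np.inf, _SLOPE_BOUNDS[0]]
        ub = [_LOG_EC50_BOUNDS[1], np.inf, _SLOPE_BOUNDS[1]]
        p0 = (
            float(np.clip(p0[0], lb[0], ub[0])),
            p0[1],
            float(np.clip(p0[2], lb[2], ub[2])),
        )
        try:
            popt, _ = curve_fit(
                hill_response,
                c,
                y,
                p0=p0,
                bounds=(lb, ub),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                maxfev=20000,
            )
            converged = bool(np.all(np.isfinite(popt)))
        except (RuntimeError, ValueError):
            popt, converged = p0, False

        pred = hill_response(c, *popt)
        res = HillResults(
            log_ec50=float(popt[0]),
            amplitude=float(popt[1]),
            slope=float(popt[2]),
            converged=converged,
            rss=float(np.sum((y - pred) ** 2)),
            nobs=len(y),
        )
        return apply_censoring(res, c, censor_value) if censor else res


def fit_hill(concentrations, responses, *, censor: bool = True,
             censor_value: float = CENSOR_LOG_EC50) -> HillResults:
    """Functional wrapper: ``HillModel(c, y).fit()``."""
    return HillModel(concentrations, responses).fit(censor, censor_value)


def apply_censoring(
    fit: HillResults, concentrations, censor_value: float = CENSOR_LOG_EC50
) -> HillResults:
    """Assign the placeholder log EC50 to non-saturating fits.

    A fit is censored when the optimizer did not converge or the fitted
    EC50 lies above the highest tested concentration (the curve cannot
    have reached saturation within the series). Converged, in-range fits
    pass through unchanged.
    """
    top = float(np.max(np.asarray(concentrations, dtype=float)))
    if fit.converged and not fit.degenerate and fit.ec50 <= top:
        return fit
    if not fit.censored:
        logger.info(
            "censoring fit (converged=%s, log_ec50=%.3f, top=%g M) at %g",
            fit.converged, fit.log_ec50, top, censor_value,
        )
    return replace(fit, log_ec50=float(censor_value), censored=True)


def max_dff(responses_at_top) -> float:
    """Replicate-mean response at the highest tested concentration."""
    vals = np.asarray(responses_at_top, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise InsufficientDataError("no responses at the top concentration")
    return float(vals.mean())


def activity_index(log_ec50: float, max_dff_value: float) -> float:
    """Agonism score: (−log10 EC50) × max ΔF/F."""
    if not (np.isfinite(log_ec50) and np.isfinite(max_dff_value)):
        raise InvalidParameterError("activity index requires finite arguments")
    return float(-log_ec50 * max_dff_value)


def fit_dose_response_table(
    bioreps: pd.DataFrame,
    *,
    mode: str = "pooled",
    censor_value: float = CENSOR_LOG_EC50,
) -> pd.DataFrame:
    """Fit every experimental receptor x ligand series in a replicate table.

    Parameters
    ----------
    bioreps : DataFrame
        Biological-replicate measurements with columns receptor_id,
        ligand_id, concentration, dff_norm, role and plate_id (one row per
        plate x concentration).
    mode : {"pooled", "per_replicate"}
        "pooled" (default) fits one curve to the across-replicate mean at
        each concentration. "per_replicate" additionally fits each plate's
        series alone and reports the per-replicate log EC50s (used for the
        mutant-vs-wild-type group comparisons).

    Returns
    -------
    DataFrame with one row per receptor x ligand: fit parameters, flags,
    max_dff, activity_index, n biological replicates, and (in
    per_replicate mode) the JSON-ish ';'-joined replicate log EC50 list.
    """
    if mode not in ("pooled", "per_replicate"):
        raise InvalidParameterError(f"unknown fit mode {mode!r}")
    exp = bioreps[bioreps["role"] == "experimental"]
    rows = []
    for (receptor, ligand), grp in exp.groupby(["receptor_id", "ligand_id"], sort=True):
        per_conc = grp.groupby("concentration")["dff_norm"].mean().sort_index()
        concs = per_conc.index.to_numpy(dtype=float)
        top = concs.max()
        fit = fit_hill(concs, per_conc.to_numpy(), censor_value=censor_value)
        md = max_dff(grp.loc[grp["concentration"] == top, "dff_norm"])
        n_bio = int(grp.loc[grp["concentration"] == top, "plate_id"].nunique())
        row = {
            "receptor_id": receptor,
            "ligand_id": ligand,
            "log_ec50": fit.log_ec50,
            "amplitude": fit.amplitude,
            "slope": fit.slope,
            "converged": fit.converged,
            "censored": fit.censored,
            "degenerate": fit.degenerate,
            "rss": fit.rss,
            "max_dff": md,
            "activity_index": activity_index(fit.log_ec50, md),
            "n_biological": n_bio,
        }
        if mode == "per_replicate":
            reps = []
            for _, plate_grp in grp.groupby("plate_id", sort=True):
                series = plate_grp.groupby("concentration")["dff_norm"].mean().sort_index()
                try:
                    rep_fit = fit_hill(
                        series.index.to_numpy(dtype=float),
                        series.to_numpy(),
                        censor_value=censor_value,
                    )
                    reps.append(rep_fit.log_ec50)
                except InsufficientDataError:
                    continue
            row["replicate_log_ec50"] = ";".join(f"{v:.6g}" for v in reps)
        rows.append(row)
    return pd.DataFrame(rows)
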