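"""Concentration-response assembly, AUCRC, 4PL fitting and potency ratios.

The per-assay response summary used throughout is the area under the
concentration-response curve (AUCRC) computed by trapezoid over log10-transformed
concentrations. Because the area is linear in the response, the mutant:WT AUCRC
ratio at matched potency equals the efficacy scale exactly — the property that
lets these ratios separate efficacy effects from potency (EC50) effects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import gmean

__all__ = [
    "ConcentrationResponse",
    "FitResult",
    "aucrc",
    "aucrc_ratio",
    "fit_4pl",
    "ec50_ratio",
    "four_pl",
]

HILL_BOUNDS = (0.3, 5.0)
N_STARTS = 8


@dataclass
class ConcentrationResponse:
    """Per-variant (concentration, response) points for one assay/experiment."""

    variant: str
    ligand: str
    assay: str
    concentrations: np.ndarray  # molar, strictly increasing, > 0
    responses: np.ndarray       # mean response per concentration
    sems: np.ndarray | None = None
    ns: np.ndarray | None = None
    experiment_id: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError(f"{self.variant}: concentration/response length mismatch")
        if np.any(self.concentrations <= 0):
            raise ValueError(f"{self.variant}: concentrations must be > 0")
        if not np.all(np.diff(self.concentrations) > 0):
            raise ValueError(f"{self.variant}: concentrations must be strictly increasing")

    @property
    def log_concs(self) -> np.ndarray:
        return np.log10(self.concentrations)


@dataclass
class FitResult:
    ec50: float
    hill: float
    floor: float
    ceiling: float
    converged: bool
    sse: float = np.nan
    covariance: np.ndarray | None = field(default=None, repr=False)


def aucrc(crc: ConcentrationResponse) -> float:
    """Trapezoidal area of mean response vs log10(concentration)."""
    if crc.concentrations.size < 3:
        raise ValueError(f"{crc.variant}: AUCRC needs >= 3 concentrations")
    return float(np.trapezoid(crc.responses, crc.log_concs))


def aucrc_ratio(mut_crc: ConcentrationResponse, wt_crc: ConcentrationResponse) -> float:
    """Mutant AUCRC divided by WT AUCRC from the same experiment."""
    if mut_crc.assay != wt_crc.assay:
        raise ValueError("AUCRC ratio requires matching assays")
    if not np.allclose(mut_crc.concentrations, wt_crc.concentrations):
        raise ValueError("AUCRC ratio requires a shared concentration grid")
    wt_area = aucrc(wt_crc)
    if wt_area <= 0:
        raise ValueError(f"WT AUCRC is non-positive ({wt_area:g}); ratio undefined")
    return aucrc(mut_crc) / wt_area


def four_pl(log_conc: np.ndarray, log_ec50: float, hill: float,
            floor: float, ceiling: float) -> np.ndarray:
    """4-parameter logistic on log10 concentration."""
    return floor + (ceiling - floor) / (1.0 + 10 ** (hill * (log_ec50 - log_conc)))


def fit_4pl(crc: ConcentrationResponse) -> FitResult:
    """Least-squares 4PL fit with multi-start initialization.

    Starts span a log-spaced EC50 grid across the tested range; the best SSE
    wins (deterministic ordering). Degenerate data (flat responses, or a fitted
    EC50 far outside the tested range) yields ``converged=False`` rather than
    an exception.
    """
    if crc.concentrations.size < 4:
        raise ValueError(f"{crc.variant}: 4PL fit needs >= 4 concentrations")
    x = crc.log_concs
    y = crc.responses
    span = y.max() - y.min()
    if span <= 1e-12 * max(abs(y).max(), 1.0):
        return FitResult(np.nan, np.nan, float(y.min()), float(y.max()), False)
    lo = (x.min() - 2, HILL_BOUNDS[0], 0.0, y.min())
    hi = (x.max() + 2, HILL_BOUNDS[1], y.max(), y.max() * 10 + 10)
    best: FitResult | None = None
    for log_ec50_start in np.linspace(x.min() - 1, x.max() + 1, N_STARTS):
        p0 = (log_ec50_start, 1.0, max(y.min(), 0.0), y.max())
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(four_pl, x, y, p0=p0, bounds=(lo, hi), maxfev=5000)
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((four_pl(x, *popt) - y) ** 2))
        if best is None or sse < best.sse - 1e-15:
            best = FitResult(
                ec50=float(10 ** popt[0]), hill=float(popt[1]),
                floor=float(popt[2]), ceiling=float(popt[3]),
                converged=True, sse=sse, covariance=pcov,
            )
    if best is None:
        return FitResult(np.nan, np.nan, np.nan, np.nan, False)
    cmin, cmax = crc.concentrations.min(), crc.concentrations.max()
    if not (cmin / 100 <= best.ec50 <= cmax * 100):
        best.converged = False
    return best


def ec50_ratio(mut_fits: "FitResult | list[FitResult]",
               wt_fits: "FitResult | list[FitResult]",
               average: str = "geometric") -> float:
    """Mutant:WT EC50 ratio, averaged across paired per-experiment fits.

    Ratios of potencies are log-normally distributed, so the default average is
    geometric; pass ``average='arithmetic'`` for a plain mean.
    """
    if isinstance(mut_fits, FitResult):
        mut_fits = [mut_fits]
    if isinstance(wt_fits, FitResult):
        wt_fits = [wt_fits]
    if len(mut_fits) != len(wt_fits):
        raise ValueError("need one WT fit per mutant fit (paired experiments)")
    ratios = []
    for m, w in zip(mut_fits, wt_fits):
        if not (m.converged and w.converged):
            raise ValueError("EC50 ratio requires converged fits on both sides")
        ratios.append(m.ec50 / w.ec50)
    if average == "geometric":
        return float(gmean(ratios))
    if average == "arithmetic":
        return float(np.mean(ratios))
    raise ValueError(f"unknown average {average!r}")
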