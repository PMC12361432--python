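"""Flow-cytometry binding math: surface-level and chemokine-binding ratios.

Both ratio definitions are quotients of log-MFI differences, which makes them
invariant to common multiplicative rescaling of all fluorescence values and
pins the wild-type ratio at exactly 1. Base-10 logarithms are used for stored
intermediates (the quotient itself is base-invariant).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import FlowRecord

__all__ = [
    "BindingRatio",
    "surface_ratio_eq1",
    "binding_ratio_eq2",
    "specific_binding_curve",
    "impact_binding_at_top",
]

EPS_DENOM = 1e-9
DEFAULT_TOP_CONC = 3.0e-7  # 300 nM readout concentration


@dataclass
class BindingRatio:
    variant: str
    ligand: str | None
    concentration: float
    ratio: float
    equation: str  # eq1_surface | eq2_binding
    n: int
    sem: float | None

    def __post_init__(self) -> None:
        if not np.isfinite(self.ratio):
            raise ValueError(f"{self.variant}: non-finite binding ratio")


def surface_ratio_eq1(mfi_mut: float, mfi_parental: float, mfi_wt: float) -> float:
    """Surface receptor level of a mutant line relative to WT:

        (log MFI_mut - log MFI_parental) / (log MFI_WT - log MFI_parental)

    1 means WT-level surface expression, 0 means indistinguishable from the
    receptor-negative parental line.
    """
    for name, v in (("mfi_mut", mfi_mut), ("mfi_parental", mfi_parental), ("mfi_wt", mfi_wt)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0 (log domain)")
    denom = math.log10(mfi_wt) - math.log10(mfi_parental)
    if abs(denom) < EPS_DENOM:
        raise ValueError("WT MFI indistinguishable from parental; ratio undefined")
    return (math.log10(mfi_mut) - math.log10(mfi_parental)) / denom


def binding_ratio_eq2(mfi_mut: float, af_mut: float, mfi_wt: float, af_wt: float) -> float:
    """Chemokine binding of a mutant line relative to WT:

        (log MFI_mut - log AF_mut) / (log MFI_WT - log AF_WT)

    where AF is the autofluorescence MFI of the same cell line without ligand.
    """
    for name, v in (("mfi_mut", mfi_mut), ("af_mut", af_mut),
                    ("mfi_wt", mfi_wt), ("af_wt", af_wt)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0 (log domain)")
    denom = math.log10(mfi_wt) - math.log10(af_wt)
    if denom <= EPS_DENOM:
        raise ValueError("WT signal does not exceed autofluorescence; ratio undefined")
    return (math.log10(mfi_mut) - math.log10(af_mut)) / denom


def _records_frame(records: list[FlowRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_line": r.cell_line, "ligand": r.ligand, "concentration": r.concentration,
                "mfi": r.mfi, "af": r.autofluorescence_mfi, "experiment_id": r.experiment_id,
            }
            for r in records
        ]
    )


def specific_binding_curve(records: list[FlowRecord], variant: str,
                           concs: list[float] | None = None) -> pd.DataFrame:
    """Receptor-specific binding: variant MFI minus parental MFI, per concentration.

    Negative values (possible under noise) are retained, not clipped, and
    flagged so downstream SEMs stay honest. Returns a table with columns
    concentration, mean_specific, sem, n, negative_flag.
    """
    frame = _records_frame(records)
    frame = frame[frame["ligand"].notna()]
    var = frame[frame["cell_line"] == variant]
    par = frame[frame["cell_line"] == "parental"]
    if concs is None:
        concs = sorted(var["concentration"].unique())
    rows = []
    for conc in concs:
        v = var[np.isclose(var["concentration"], conc, rtol=1e-6, atol=0)]
        p = par[np.isclose(par["concentration"], conc, rtol=1e-6, atol=0)]
        if p.empty:
            raise ValueError(f"no parental record at concentration {conc:g}")
        if v.empty:
            raise ValueError(f"no {variant} record at concentration {conc:g}")
        diffs = []
        for exp in v["experiment_id"].unique():
            ve = v[v["experiment_id"] == exp]["mfi"].mean()
            pe_rows = p[p["experiment_id"] == exp]
            if pe_rows.empty:
                raise ValueError(f"no parental record for experiment {exp} at {conc:g}")
            diffs.append(ve - pe_rows["mfi"].mean())
        diffs = np.asarray(diffs)
        rows.append({
            "concentration": conc,
            "mean_specific": diffs.mean(),
            "sem": diffs.std(ddof=1) / math.sqrt(len(diffs)) if len(diffs) > 1 else np.nan,
            "n": len(diffs),
            "negative_flag": bool((diffs < 0).any()),
        })
    return pd.DataFrame(rows)


def impact_binding_at_top(records: list[FlowRecord], variant: str,
                          top_conc: float = DEFAULT_TOP_CONC,
                          wt_line: str = "WT") -> BindingRatio:
    """Binding impact readout at the top tested concentration (default 300 nM).

    The mutant:WT log-ratio quotient is computed within each experiment, then
    averaged across experiments (mean +/- SEM on the ratio scale).
    """
    frame = _records_frame(records)
    ratios = []
    ligand = None
    for exp, grp in frame.groupby("experiment_id"):
        at_top = grp[grp["ligand"].notna() & np.isclose(grp["concentration"], top_conc, rtol=1e-6, atol=0)]
        mut = at_top[at_top["cell_line"] == variant]
        wt = at_top[at_top["cell_line"] == wt_line]
        if mut.empty or wt.empty:
            raise ValueError(
                f"experiment {exp}: missing {variant if mut.empty else wt_line} "
                f"record at top concentration {top_conc:g}"
            )
        ligand = mut["ligand"].iloc[0]
        ratios.append(
            binding_ratio_eq2(mut["mfi"].mean(), mut["af"].mean(),
                              wt["mfi"].mean(), wt["af"].mean())
        )
    arr = np.asarray(ratios)
    sem = arr.std(ddof=1) / math.sqrt(arr.size) if arr.size > 1 else None
    return BindingRatio(variant, ligand, top_conc, float(arr.mean()),
                        "eq2_binding", int(arr.size), sem)
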