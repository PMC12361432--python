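"""Cross-assay mutation-impact statistics.

Mutation effects are expressed as within-experiment mutant:WT response ratios
(AUCRC ratios for signaling, log-MFI binding ratios), aggregated across
independent experiments. Inference is one-way ANOVA on log-transformed ratios
with post-hoc comparisons against WT (and parental, for binding) corrected by
the Holm-Sidak step-down; signaling assays use the repeated-measures variant
with experiment as the blocking factor and a single pooled error variance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ImpactRecord",
    "RadarTable",
    "BasalRecord",
    "assemble_impacts",
    "log_ratio_anova",
    "holm_sidak",
    "radar_table",
    "render_radar",
    "bias_index",
    "basal_activity_analysis",
]

INTRACELLULAR_THRESHOLD = 0.5  # surface:total below this flags intracellular retention


@dataclass
class ImpactRecord:
    variant: str
    assay: str  # binding | ca | arr3
    per_experiment_ratios: list[float]
    mean_ratio: float = field(init=False)
    sem: float | None = field(init=False)
    n: int = field(init=False)
    p_vs_wt: float | None = None
    p_vs_parental: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.per_experiment_ratios, dtype=float)
        if arr.size == 0:
            raise ValueError(f"{self.variant}/{self.assay}: no ratios")
        # Near-zero responses can yield non-positive ratios under noise; they
        # are kept for descriptive statistics but reject the log transform
        # (log_ratio_anova raises on them).
        self.n = int(arr.size)
        self.mean_ratio = float(arr.mean())
        self.sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else None


@dataclass
class RadarTable:
    variants: list[str]                 # axis order (stable, configurable)
    groups: dict[str, list[str]]        # group label -> variants (bracket annotation)
    values: pd.DataFrame                # index variant, columns per assay (mean ratios)
    sems: pd.DataFrame                  # same shape; NaN where undefined


@dataclass
class BasalRecord:
    variant: str
    basal_bret: float
    donor_luminescence: float
    acceptor_level: float
    surface_level_eq1: float
    total_level_lum: float

    def __post_init__(self) -> None:
        for name in ("basal_bret", "donor_luminescence", "acceptor_level", "total_level_lum"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.variant}: {name} must be > 0")


def assemble_impacts(responses: pd.DataFrame, assay: str,
                     wt_variant: str = "WT") -> list[ImpactRecord]:
    """Within-experiment mutant:WT ratios, aggregated across experiments.

    ``responses`` needs columns variant, experiment_id, value (one summary
    response per variant per experiment). Experiments missing WT are excluded
    with a warning.
    """
    records: dict[str, list[float]] = {}
    for exp, grp in responses.groupby("experiment_id"):
        wt_rows = grp[grp["variant"] == wt_variant]
        if wt_rows.empty:
            warnings.warn(f"experiment {exp}: no WT response; excluded", stacklevel=2)
            continue
        wt_value = float(wt_rows["value"].mean())
        if wt_value <= 0:
            warnings.warn(f"experiment {exp}: non-positive WT response; excluded", stacklevel=2)
            continue
        for variant, vgrp in grp.groupby("variant"):
            records.setdefault(str(variant), []).append(float(vgrp["value"].mean()) / wt_value)
    return [ImpactRecord(v, assay, ratios) for v, ratios in sorted(records.items())]


def holm_sidak(p_values: np.ndarray) -> np.ndarray:
    """Holm-Sidak step-down adjustment of a family of raw p-values."""
    return multipletests(np.asarray(p_values, dtype=float), method="holm-sidak")[1]


def _pooled_anova(groups: dict[str, np.ndarray]) -> tuple[float, float, float, int]:
    """Plain one-way ANOVA: returns (F, p, MSE, df_error)."""
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    k = len(groups)
    n_total = all_vals.size
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups.values())
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    df_b, df_e = k - 1, n_total - k
    if df_e <= 0 or ss_within <= 0:
        bad = min(groups, key=lambda name: groups[name].var())
        raise ValueError(f"degenerate error variance (group {bad!r}); ANOVA undefined")
    mse = ss_within / df_e
    f = (ss_between / df_b) / mse
    p = float(stats.f.sf(f, df_b, df_e))
    return float(f), p, float(mse), df_e


def _repeated_anova(table: pd.DataFrame) -> tuple[float, float, float, int]:
    """Repeated-measures one-way ANOVA (variant x experiment blocks).

    Requires a balanced design: every variant observed in every experiment.
    Returns (F, p, MSE_residual, df_residual).
    """
    wide = table.pivot(index="experiment_id", columns="variant", values="log_ratio")
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any()].tolist()
        raise ValueError(f"repeated-measures ANOVA needs a balanced design; missing: {missing}")
    vals = wide.to_numpy(float)
    b, k = vals.shape  # blocks (experiments) x treatments (variants)
    grand = vals.mean()
    ss_treat = b * ((vals.mean(axis=0) - grand) ** 2).sum()
    ss_block = k * ((vals.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((vals - grand) ** 2).sum()
    ss_resid = ss_total - ss_treat - ss_block
    df_t, df_r = k - 1, (k - 1) * (b - 1)
    if df_r <= 0 or ss_resid <= 0:
        raise ValueError("degenerate residual variance in repeated-measures ANOVA")
    mse = ss_resid / df_r
    f = (ss_treat / df_t) / mse
    p = float(stats.f.sf(f, df_t, df_r))
    return float(f), p, float(mse), df_r


def log_ratio_anova(impacts: list[ImpactRecord], repeated: bool = False,
                    control: str = "WT",
                    extra_controls: tuple[str, ...] = ()) -> pd.DataFrame:
    """ANOVA on log10 ratios with Holm-Sidak-corrected comparisons vs control(s).

    Returns a long statistics table (comparison, raw_p, adjusted_p, test) plus
    one omnibus row. Post-hoc tests use the single pooled error variance from
    the ANOVA (two-sided t on the pooled MSE).
    """
    for rec in impacts:
        if np.any(np.asarray(rec.per_experiment_ratios) <= 0):
            raise ValueError(
                f"{rec.variant}/{rec.assay}: non-positive ratio; cannot log-transform"
            )
    groups = {
        rec.variant: np.log10(np.asarray(rec.per_experiment_ratios, dtype=float))
        for rec in impacts
    }
    for ctrl in (control, *extra_controls):
        if ctrl not in groups:
            raise ValueError(f"control group {ctrl!r} absent from impacts")
    for name, vals in groups.items():
        if name != control and vals.size < 2 and not repeated:
            raise ValueError(f"group {name!r} has n < 2; cannot run plain ANOVA")

    if repeated:
        long = pd.DataFrame(
            [
                {"variant": rec.variant, "experiment_id": f"E{i + 1}", "log_ratio": lr}
                for rec in impacts
                for i, lr in enumerate(np.log10(rec.per_experiment_ratios))
            ]
        )
        f, omnibus_p, mse, df_e = _repeated_anova(long)
        test_name = "repeated-measures one-way ANOVA / Holm-Sidak"
    else:
        f, omnibus_p, mse, df_e = _pooled_anova(groups)
        test_name = "one-way ANOVA / Holm-Sidak"

    rows = [{"comparison": "omnibus", "statistic": f, "raw_p": omnibus_p,
             "adjusted_p": np.nan, "test": test_name}]
    for ctrl in (control, *extra_controls):
        ctrl_vals = groups[ctrl]
        comps, raw = [], []
        for name, vals in groups.items():
            if name in (control, *extra_controls):
                continue
            se = math.sqrt(mse * (1 / vals.size + 1 / ctrl_vals.size))
            if se == 0:
                raise ValueError(f"zero standard error comparing {name!r} vs {ctrl!r}")
            t = (vals.mean() - ctrl_vals.mean()) / se
            comps.append((f"{name} vs {ctrl}", float(t)))
            raw.append(2 * float(stats.t.sf(abs(t), df_e)))
        adjusted = holm_sidak(raw) if raw else []
        for (comp, t), rp, ap in zip(comps, raw, adjusted):
            rows.append({"comparison": comp, "statistic": t, "raw_p": rp,
                         "adjusted_p": float(ap), "test": test_name})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Radar assembly and bias
# ---------------------------------------------------------------------------

ASSAY_ORDER = ("binding", "ca", "arr3")


def radar_table(impacts: list[ImpactRecord],
                variant_order: list[str] | None = None,
                groups: dict[str, list[str]] | None = None) -> RadarTable:
    """Assemble per-variant per-assay mean ratios (and SEMs) for radar plotting."""
    frame = pd.DataFrame(
        [
            {"variant": r.variant, "assay": r.assay,
             "mean_ratio": r.mean_ratio, "sem": r.sem if r.sem is not None else np.nan}
            for r in impacts
        ]
    )
    values = frame.pivot(index="variant", columns="assay", values="mean_ratio")
    sems = frame.pivot(index="variant", columns="assay", values="sem")
    order = variant_order or sorted(values.index)
    missing = set(order) - set(values.index)
    if missing:
        raise ValueError(f"variants without impact records: {sorted(missing)}")
    values = values.loc[order]
    sems = sems.loc[order]
    return RadarTable(list(order), groups or {}, values, sems)


def render_radar(table: RadarTable, path, title: str = "Mutation impact") -> None:
    """Polar radar plot: one contour per assay; SEM encoded as band width/alpha."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(table.variants)
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(7, 7))
    colors = {"binding": "purple", "ca": "darkorange", "arr3": "steelblue"}
    closed = np.concatenate([angles, angles[:1]])
    for assay in table.values.columns:
        vals = table.values[assay].to_numpy(float)
        sem = np.nan_to_num(table.sems[assay].to_numpy(float))
        v = np.concatenate([vals, vals[:1]])
        s = np.concatenate([sem, sem[:1]])
        color = colors.get(assay, None)
        ax.plot(closed, v, label=assay, color=color)
        ax.fill_between(closed, v - s, v + s, alpha=0.25, color=color)
    ax.plot(closed, np.ones_like(closed), color="lightgreen", lw=2, label="WT reference")
    ax.set_xticks(angles)
    ax.set_xticklabels(table.variants, fontsize=8)
    ax.set_title(title)
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1))
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def bias_index(ratio_ca: float, ratio_arr3: float) -> float:
    """Absolute log10 difference of the two signaling impact ratios.

    0 means the mutation affects both pathways proportionally; 1 means a
    ten-fold disproportionate effect on one pathway. This scalar quantifies the
    'scalene contour' visual criterion for biased mutants.
    """
    if ratio_ca <= 0 or ratio_arr3 <= 0:
        raise ValueError("signaling ratios must be > 0")
    return abs(math.log10(ratio_ca) - math.log10(ratio_arr3))


# ---------------------------------------------------------------------------
# Constitutive activity / expression diagnostics
# ---------------------------------------------------------------------------

def basal_activity_analysis(records: list[BasalRecord], wt_variant: str = "WT",
                            intracellular_threshold: float = INTRACELLULAR_THRESHOLD,
                            ) -> pd.DataFrame:
    """Basal-BRET constitutive-activity summary with confounder diagnostics.

    Per variant: basal BRET fold-change vs WT; surface:total expression ratio
    (flagging predominantly intracellular variants below the threshold). The
    returned frame's ``attrs`` carry Pearson/Spearman correlations of basal
    BRET against donor luminescence and acceptor level across variants — a
    check that elevated basal BRET is not an expression artifact.
    """
    wt = [r for r in records if r.variant == wt_variant]
    if not wt:
        raise ValueError(f"no {wt_variant} basal record")
    wt_bret = float(np.mean([r.basal_bret for r in wt]))
    wt_surface = float(np.mean([r.surface_level_eq1 for r in wt]))
    wt_total = float(np.mean([r.total_level_lum for r in wt]))
    rows = []
    for rec in records:
        surface_total = (rec.surface_level_eq1 / wt_surface) / (rec.total_level_lum / wt_total)
        rows.append({
            "variant": rec.variant,
            "basal_bret": rec.basal_bret,
            "basal_fold_change": rec.basal_bret / wt_bret,
            "surface_total_ratio": surface_total,
            "intracellular_flag": bool(surface_total < intracellular_threshold),
        })
    out = pd.DataFrame(rows)
    basal = np.array([r.basal_bret for r in records])
    donor = np.array([r.donor_luminescence for r in records])
    acceptor = np.array([r.acceptor_level for r in records])
    diag = {}
    if len(records) >= 3:
        for name, other in (("donor", donor), ("acceptor", acceptor)):
            if np.std(other) > 0 and np.std(basal) > 0:
                diag[f"pearson_basal_vs_{name}"] = float(stats.pearsonr(basal, other)[0])
                diag[f"spearman_basal_vs_{name}"] = float(stats.spearmanr(basal, other)[0])
    out.attrs["correlations"] = diag
    return out
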