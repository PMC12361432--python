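"""Synthetic data generation for every pipeline stage.

All generators are pure functions of their parameters and an explicit seed:
dual-injection plate-reader kinetic traces (calcium flux and BRET), flow
cytometry MFI tables with receptor-specific and proteoglycan-like nonspecific
binding components, and toy helical-bundle structural ensembles with planted
contacts, hydrogen bonds and activation geometry.

The kinetic functional forms (difference-of-exponentials calcium transient,
saturating BRET change) are deliberately simple emulations of plate-reader
traces; the analysis pipeline only ever consumes peak and area summaries of
them, which have closed forms used by the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_io import Ensemble, FlowRecord, KineticTrace, PlateMap, StructureModel, WellRole

__all__ = [
    "VariantTruth",
    "NoiseModel",
    "TraceGrid",
    "simulate_ca_trace",
    "simulate_bret_trace",
    "simulate_flow_table",
    "generate_toy_ensemble",
    "ToyEnsembleSpec",
    "default_truth_table",
    "simulate_experiment_plates",
    "ca_transient_shape",
    "ca_peak_closed_form",
    "bret_plateau_closed_form",
    "flow_mfi_closed_form",
]

# Emulation defaults for the calcium transient shape (seconds)
TAU_RISE = 3.0
TAU_DECAY = 40.0
BRET_TAU = 60.0       # approach-to-plateau time constant of the BRET change
BASAL_BRET_RATIO = 0.6
DONOR_LEVEL = 10000.0
FLOW_AF = 100.0       # autofluorescence MFI, arbitrary units
FLOW_BMAX = 5000.0    # specific-binding plateau for a WT-level line
FLOW_KNS = 2.0e9      # nonspecific (proteoglycan) slope, MFI per molar


@dataclass
class VariantTruth:
    """Ground-truth effect sizes for one receptor variant.

    Scales are relative to WT (WT == 1 everywhere, offset 0); ``parental`` is
    modelled as a line with no receptor (binding_bmax_scale = 0).
    """

    variant: str
    binding_bmax_scale: float = 1.0
    binding_kd: float = 3.0e-8
    ec50_ca: float = 1.0e-8
    emax_ca_scale: float = 1.0
    ec50_arr: float = 1.0e-8
    emax_arr_scale: float = 1.0
    basal_bret_offset: float = 0.0
    expression_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("binding_bmax_scale", "emax_ca_scale", "emax_arr_scale", "expression_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.variant}: {name} must be >= 0")
        for name in ("binding_kd", "ec50_ca", "ec50_arr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.variant}: {name} must be > 0")


@dataclass
class NoiseModel:
    trace_cv: float = 0.03       # multiplicative Gaussian CV on trace points
    mfi_log_sd: float = 0.05     # lognormal sd on MFI values (log10 units)
    baseline_drift: float = 0.0  # fractional drift per second
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trace_cv < 0 or self.mfi_log_sd < 0:
            raise ValueError("noise magnitudes must be >= 0")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class TraceGrid:
    """Acquisition grid: 0.5 s spacing by default, one or two injections."""

    dt: float = 0.5
    duration: float = 120.0
    injections: tuple[float, ...] = (30.0,)

    def times(self) -> np.ndarray:
        return np.arange(0.0, self.duration + self.dt / 2, self.dt)

    def n_pre_injection(self) -> int:
        return int(np.sum(self.times() < self.injections[0]))


def _occupancy(conc: float, ec50: float, hill: float = 1.0) -> float:
    if conc == 0:
        return 0.0
    return conc**hill / (conc**hill + ec50**hill)


def ca_transient_shape(t_after: np.ndarray) -> np.ndarray:
    """Unit-peak difference-of-exponentials transient, zero before injection."""
    shape = np.where(
        t_after >= 0,
        np.exp(-np.clip(t_after, 0, None) / TAU_DECAY) - np.exp(-np.clip(t_after, 0, None) / TAU_RISE),
        0.0,
    )
    return shape / _double_exp_peak()


def _double_exp_peak() -> float:
    t_star = math.log(TAU_DECAY / TAU_RISE) / (1 / TAU_RISE - 1 / TAU_DECAY)
    return math.exp(-t_star / TAU_DECAY) - math.exp(-t_star / TAU_RISE)


def ca_peak_closed_form(truth: VariantTruth, conc: float, hill: float = 1.0) -> float:
    """Noise-free normalized peak of a simulated calcium response (buffer = 1)."""
    return 1.0 + truth.emax_ca_scale * _occupancy(conc, truth.ec50_ca, hill)


def simulate_ca_trace(truth: VariantTruth, conc: float, noise: NoiseModel,
                      grid: TraceGrid | None = None, well_id: str = "W1",
                      hill: float = 1.0, stream: int = 0,
                      buffer_well: bool = False) -> KineticTrace:
    """Simulate a calcium-flux fluorescence trace for one well.

    The pre-injection signal sits at a baseline proportional to expression;
    after injection a transient with amplitude ``emax_ca_scale * occupancy``
    (relative to baseline) rises and decays. Buffer wells have amplitude 0.
    """
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    grid = grid or TraceGrid()
    if grid.n_pre_injection() < 20:
        raise ValueError("grid must include at least 20 pre-injection points")
    times = grid.times()
    baseline = 1000.0 * max(truth.expression_scale, 1e-6)
    amp = 0.0 if buffer_well else truth.emax_ca_scale * _occupancy(conc, truth.ec50_ca, hill)
    signal = baseline * (1.0 + amp * ca_transient_shape(times - grid.injections[0]))
    if noise.baseline_drift:
        signal = signal * (1.0 + noise.baseline_drift * times)
    if noise.trace_cv > 0:
        rng = noise.rng(stream)
        signal = signal * (1.0 + noise.trace_cv * rng.standard_normal(times.size))
    signal = np.clip(signal, 1e-9, None)
    return KineticTrace(well_id, times, {"fluo": signal}, list(grid.injections))


def bret_plateau_closed_form(truth: VariantTruth, conc: float, mode: str = "arrestin",
                             hill: float = 1.0) -> float:
    """Asymptotic BRET ratio at t >> injection, noise free."""
    occ = _occupancy(conc, truth.ec50_arr, hill)
    sign = 1.0 if mode == "arrestin" else -1.0
    scale = truth.emax_arr_scale if mode == "arrestin" else truth.emax_ca_scale
    return BASAL_BRET_RATIO + truth.basal_bret_offset + sign * 0.2 * scale * occ


def simulate_bret_trace(truth: VariantTruth, conc: float, noise: NoiseModel,
                        grid: TraceGrid | None = None, mode: str = "arrestin",
                        well_id: str = "W1", hill: float = 1.0, stream: int = 0,
                        buffer_well: bool = False) -> KineticTrace:
    """Simulate a dual-emission BRET trace (em540, em470 channels).

    ``mode='arrestin'`` produces a ratio that rises after injection (recruitment
    of the acceptor-tagged arrestin); ``mode='g_dissociation'`` a ratio that
    falls (separation of the tagged G protein subunits).
    """
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    if mode not in ("arrestin", "g_dissociation"):
        raise ValueError(f"unknown BRET mode {mode!r}")
    grid = grid or TraceGrid(dt=0.5, duration=630.0, injections=(30.0,))
    if grid.n_pre_injection() < 20:
        raise ValueError("grid must include at least 20 pre-injection points")
    times = grid.times()
    occ = 0.0 if buffer_well else _occupancy(conc, truth.ec50_arr, hill)
    sign = 1.0 if mode == "arrestin" else -1.0
    scale = truth.emax_arr_scale if mode == "arrestin" else truth.emax_ca_scale
    t_after = times - grid.injections[0]
    kinetic = np.where(t_after >= 0, 1.0 - np.exp(-np.clip(t_after, 0, None) / BRET_TAU), 0.0)
    ratio = BASAL_BRET_RATIO + truth.basal_bret_offset + sign * 0.2 * scale * occ * kinetic
    em470 = np.full_like(times, DONOR_LEVEL * max(truth.expression_scale, 1e-6))
    em540 = em470 * ratio
    if noise.trace_cv > 0:
        rng = noise.rng(stream)
        em470 = em470 * (1.0 + noise.trace_cv * rng.standard_normal(times.size))
        em540 = em540 * (1.0 + noise.trace_cv * rng.standard_normal(times.size))
    em470 = np.clip(em470, 1e-9, None)
    em540 = np.clip(em540, 1e-9, None)
    return KineticTrace(well_id, times, {"em540": em540, "em470": em470}, list(grid.injections))


def flow_mfi_closed_form(truth: VariantTruth, conc: float, af: float = FLOW_AF,
                         bmax: float = FLOW_BMAX, k_ns: float = FLOW_KNS) -> float:
    """Noise-free MFI: autofluorescence + specific saturation + nonspecific line."""
    specific = (bmax * truth.binding_bmax_scale * truth.expression_scale
                * _occupancy(conc, truth.binding_kd))
    return af + specific + k_ns * conc


def simulate_flow_table(truths: list[VariantTruth], ligand_concs: list[float],
                        noise: NoiseModel, n_experiments: int = 3,
                        ligand: str = "CCL25", events: int = 10000,
                        af: float = FLOW_AF, bmax: float = FLOW_BMAX,
                        k_ns: float = FLOW_KNS) -> list[FlowRecord]:
    """Simulate a chemokine-binding flow table across cell lines and experiments.

    Every line gets a paired no-ligand autofluorescence record per experiment.
    The nonspecific (proteoglycan) component is present in all lines including
    the receptor-negative parental line.
    """
    if not any(t.variant == "parental" for t in truths):
        raise ValueError("truth table must include a 'parental' entry")
    records: list[FlowRecord] = []
    for e in range(n_experiments):
        for v, truth in enumerate(truths):
            rng = noise.rng(stream=1_000_000 + e * 10_000 + v)
            af_e = af * 10 ** (noise.mfi_log_sd * rng.standard_normal())
            records.append(FlowRecord(truth.variant, None, 0.0, af_e, af_e, events, f"E{e + 1}"))
            for conc in ligand_concs:
                mfi = flow_mfi_closed_form(truth, conc, af, bmax, k_ns)
                mfi = mfi * 10 ** (noise.mfi_log_sd * rng.standard_normal())
                records.append(FlowRecord(truth.variant, ligand, conc, mfi, af_e, events, f"E{e + 1}"))
    return records


# ---------------------------------------------------------------------------
# Toy structural ensembles
# ---------------------------------------------------------------------------

HELIX_RADIUS = 11.0   # bundle radius, Angstrom
HELIX_RISE = 1.5      # per-residue rise of the idealized straight helices
HELIX_LEN = 30        # residues per helix

# Toy transmembrane layout: helix index -> (first residue number, angular slot).
# Residue numbers echo CCR9 conventions so positions like 126/208/211/271 land
# on the expected helices.
TM_STARTS = {1: 35, 2: 70, 3: 110, 4: 150, 5: 195, 6: 250, 7: 290}


@dataclass
class ToyEnsembleSpec:
    """Planted-feature description for a toy helical-bundle ensemble."""

    n_models: int = 5
    activation_distance: float | list[float] = 3.0   # Tyr-OH to Asn-amide separation
    activation_donor: int = 126
    activation_acceptor: int = 271
    contact_residues: tuple[int, ...] = (44, 208, 211, 296, 299)  # strong receptor contacts
    weak_contact_residues: tuple[int, ...] = (40, 126)            # sub-threshold contacts
    hbond_pairs: int = 3            # planted K211-style sidechain->backbone H-bonds
    hbond_center: int = 211
    tm5_shift: float = 6.0          # axial slide of TM5 between active and inactive
    tm5_shift_radial: float = 0.0   # optional radial component of the shift
    jitter_sd: float = 0.0          # per-atom Gaussian jitter across models
    confidence: float = 92.0


def _helix_coords(start_res: int, angle: float, n_res: int = HELIX_LEN) -> list[tuple[int, np.ndarray]]:
    cx, cy = HELIX_RADIUS * math.cos(angle), HELIX_RADIUS * math.sin(angle)
    out = []
    for i in range(n_res):
        # z runs intracellular (negative) to extracellular (positive)
        z = -22.0 + i * HELIX_RISE
        out.append((start_res + i, np.array([cx, cy, z])))
    return out


def _backbone_rows(chain: str, seq: int, resname: str, ca: np.ndarray, conf: float) -> list[tuple]:
    # minimal backbone: N, CA, C, O placed in a small rigid pattern around CA
    offsets = {"N": (-0.8, 0.6, -0.4), "CA": (0.0, 0.0, 0.0),
               "C": (0.9, -0.5, 0.4), "O": (1.3, -1.3, 1.0)}
    elem = {"N": "N", "CA": "C", "C": "C", "O": "O"}
    return [
        (chain, seq, resname, name, elem[name],
         ca[0] + dx, ca[1] + dy, ca[2] + dz, conf)
        for name, (dx, dy, dz) in offsets.items()
    ]


def generate_toy_ensemble(spec: ToyEnsembleSpec, seed: int = 0) -> tuple[Ensemble, dict]:
    """Build a toy receptor/chemokine ensemble with planted measurable features.

    Returns the ensemble (with an inactive reference model attached) and a
    ground-truth dictionary describing every planted feature, so downstream
    metrics can be validated against construction.
    """
    rng = np.random.default_rng(seed)
    dists = spec.activation_distance
    if np.isscalar(dists):
        dists = [float(dists)] * spec.n_models
    if len(dists) != spec.n_models:
        raise ValueError("activation_distance list length must equal n_models")
    if min(dists) < 1.0:
        raise ValueError(
            f"infeasible geometry: planted separation {min(dists):g} A would clash"
        )

    truth = {
        "activation_distances": list(map(float, dists)),
        "contact_residues": sorted(spec.contact_residues),
        "weak_contact_residues": sorted(spec.weak_contact_residues),
        "hbond_pairs": [],
        "tm5_shift": spec.tm5_shift,
        "disulfide": (7, 35),
    }

    def build_model(model_id: str, act_dist: float, tm5_offset: np.ndarray,
                    jitter: float) -> StructureModel:
        rows: list[tuple] = []
        conf = spec.confidence
        # receptor helices
        for tm, start in TM_STARTS.items():
            angle = 2 * math.pi * (tm - 1) / 7
            for seq, ca in _helix_coords(start, angle):
                if tm == 5:
                    ca = ca + tm5_offset
                resname = "GLY"
                if seq == spec.activation_donor:
                    resname = "TYR"
                elif seq == spec.activation_acceptor:
                    resname = "ASN"
                elif seq == spec.hbond_center:
                    resname = "LYS"
                elif seq in spec.contact_residues or seq in spec.weak_contact_residues:
                    resname = "LEU"
                rows.extend(_backbone_rows("R", seq, resname, ca, conf))
        rows_arr = rows

        def ca_of(seq: int) -> np.ndarray:
            for r in rows_arr:
                if r[0] == "R" and r[1] == seq and r[3] == "CA":
                    return np.array([r[5], r[6], r[7]])
            raise KeyError(seq)

        # activation-distance pair: Tyr OH at fixed point, Asn ND2/OD1 at act_dist
        donor_ca = ca_of(spec.activation_donor)
        oh = donor_ca + np.array([1.5, 0.5, 0.0])
        rows.append(("R", spec.activation_donor, "TYR", "OH", "O", *oh, conf))
        direction = np.array([0.0, 1.0, 0.2])
        direction /= np.linalg.norm(direction)
        nd2 = oh + act_dist * direction
        od1 = nd2 + np.array([0.0, 0.0, 1.2])  # strictly farther from OH
        rows.append(("R", spec.activation_acceptor, "ASN", "ND2", "N", *nd2, conf))
        rows.append(("R", spec.activation_acceptor, "ASN", "OD1", "O", *od1, conf))

        # chemokine chain: short 30s-loop-like strand above the bundle top
        chem_rows: list[tuple] = []
        loop_res = list(range(29, 40))
        for i, seq in enumerate(loop_res):
            ca = np.array([4.0 * math.cos(i * 0.5), 4.0 * math.sin(i * 0.5), 26.0 + 0.3 * i])
            resname = "CYS" if seq == 35 else "SER"
            chem_rows.extend(_backbone_rows("C", seq, resname, ca, conf))
        # chemokine N-terminal stub with C7 for the disulfide
        for seq, resname in ((5, "GLU"), (6, "ASP"), (7, "CYS"), (8, "CYS")):
            ca = np.array([2.0, -5.0 + seq * 0.8, 24.0])
            chem_rows.extend(_backbone_rows("C", seq, resname, ca, conf))

        def chem_ca(seq: int) -> np.ndarray:
            for r in chem_rows:
                if r[1] == seq and r[3] == "CA":
                    return np.array([r[5], r[6], r[7]])
            raise KeyError(seq)

        # disulfide: SG atoms of C7 and C35 at 2.05 A
        sg7 = chem_ca(7) + np.array([1.0, 0.4, 0.3])
        sg35 = sg7 + np.array([2.05, 0.0, 0.0])
        chem_rows.append(("C", 7, "CYS", "SG", "S", *sg7, conf))
        chem_rows.append(("C", 35, "CYS", "SG", "S", *sg35, conf))

        # planted strong receptor-chemokine contacts: receptor CB at 3.8 A from
        # a chemokine sidechain atom; weak contacts at 6.0 A (beyond cutoff)
        contact_targets = loop_res
        for j, seq in enumerate(sorted(spec.contact_residues)):
            rc = ca_of(seq)
            cb = rc + np.array([0.7, 0.7, 0.7])
            rows.append(("R", seq, "LEU", "CB", "C", *cb, conf))
            partner = contact_targets[j % len(contact_targets)]
            pc = cb + np.array([0.0, 0.0, 3.8])
            chem_rows.append(("C", partner, "SER", "OG", "O", *pc, conf))
        for j, seq in enumerate(sorted(spec.weak_contact_residues)):
            rc = ca_of(seq)
            cb = rc + np.array([-0.7, 0.7, 0.7])
            rows.append(("R", seq, "LEU", "CB", "C", *cb, conf))
            partner = contact_targets[(j + 7) % len(contact_targets)]
            pc = cb + np.array([0.0, 0.0, 6.0])
            chem_rows.append(("C", partner, "SER", "OG2", "O", *pc, conf))

        # planted H-bond network: hbond_center sidechain NZ to chemokine
        # backbone O atoms of residues 32, 33, 35, ... at 2.9 A
        nz = ca_of(spec.hbond_center) + np.array([1.2, 0.8, 0.5])
        rows.append(("R", spec.hbond_center, "LYS", "NZ", "N", *nz, conf))
        hb_partners = [32, 33, 35, 36, 37][: spec.hbond_pairs]
        chem_rows = [r for r in chem_rows
                     if not (r[3] == "O" and r[1] in hb_partners and r[0] == "C")]
        for j, seq in enumerate(hb_partners):
            theta = j * 2.0 * math.pi / max(spec.hbond_pairs, 1)
            offset = 2.9 * np.array([math.cos(theta), math.sin(theta), 0.15])
            offset *= 2.9 / np.linalg.norm(offset)
            o_pos = nz + offset
            chem_rows.append(("C", seq, "SER" if seq != 35 else "CYS", "O", "O", *o_pos, conf))

        all_rows = rows + chem_rows
        atoms = pd.DataFrame(all_rows, columns=list(StructureModel.ATOM_COLUMNS))
        if jitter > 0:
            atoms[["x", "y", "z"]] += jitter * rng.standard_normal((len(atoms), 3))
        # clash guard on planted geometry
        return StructureModel(model_id, atoms, {"R": "receptor", "C": "chemokine"})

    models = [
        build_model(f"model_{i + 1:02d}", dists[i], np.zeros(3), spec.jitter_sd)
        for i in range(spec.n_models)
    ]
    truth["hbond_pairs"] = [(spec.hbond_center, p) for p in [32, 33, 35, 36, 37][: spec.hbond_pairs]]

    # inactive reference: TM5 slid along +z (toward intracellular = -z means
    # active is *deeper*; the active->inactive difference is spec.tm5_shift)
    inactive = build_model(
        "inactive_ref", dists[0],
        np.array([spec.tm5_shift_radial, 0.0, spec.tm5_shift]),
        0.0,
    )
    ens = Ensemble(models=models, receptor_chain="R", chemokine_chain="C",
                   reference_inactive=inactive)
    return ens, truth


# ---------------------------------------------------------------------------
# Whole-experiment simulation (plates + flow + truth), the demo entry point
# ---------------------------------------------------------------------------

def default_truth_table() -> list[VariantTruth]:
    """A 13-line truth table emulating the study's mutant panel phenotypes:

    signaling-dead rim mutants, binding-enhanced pocket-floor mutants with
    constitutive activity, and pathway-biased TM5/TM6 mutants.
    """
    return [
        VariantTruth("parental", binding_bmax_scale=0.0),
        VariantTruth("WT"),
        VariantTruth("K40A", binding_bmax_scale=0.6, emax_ca_scale=0.1, emax_arr_scale=0.1),
        VariantTruth("R44A", binding_bmax_scale=0.05, emax_ca_scale=0.05, emax_arr_scale=0.05),
        VariantTruth("Y126A", binding_bmax_scale=2.5, emax_ca_scale=1.3, emax_arr_scale=1.3,
                     basal_bret_offset=0.05),
        VariantTruth("Y202A", binding_bmax_scale=0.8, emax_ca_scale=0.1, emax_arr_scale=0.12),
        VariantTruth("S207A", binding_bmax_scale=1.8, emax_ca_scale=1.6, emax_arr_scale=1.5),
        VariantTruth("T208A", binding_bmax_scale=1.0, emax_ca_scale=1.0, emax_arr_scale=0.05),
        VariantTruth("K211A", binding_bmax_scale=0.7, emax_ca_scale=0.1, emax_arr_scale=0.1),
        VariantTruth("Q267A", binding_bmax_scale=1.8, emax_ca_scale=1.0, emax_arr_scale=0.3,
                     basal_bret_offset=0.04),
        VariantTruth("N271A", binding_bmax_scale=1.0, emax_ca_scale=0.15, emax_arr_scale=1.4,
                     basal_bret_offset=0.04),
        VariantTruth("S292A", binding_bmax_scale=0.5, emax_ca_scale=0.48, emax_arr_scale=0.9),
        VariantTruth("D296A", binding_bmax_scale=1.0, emax_ca_scale=0.15, emax_arr_scale=0.46),
    ]


# Six half-log dilutions bracketing the WT EC50 (10 nM): 0.3 nM to ~95 nM
DEFAULT_CONCS = tuple(3e-10 * 10 ** (0.5 * i) for i in range(6))


def simulate_experiment_plates(truths: list[VariantTruth], noise: NoiseModel,
                               concs: tuple[float, ...] = DEFAULT_CONCS,
                               n_replicates: int = 3, n_experiments: int = 3,
                               assay: str = "ca") -> tuple[PlateMap, list[KineticTrace]]:
    """Simulate a full multi-experiment dose-response plate for one assay.

    Each experiment contains, per variant, ``n_replicates`` agonist wells at
    each concentration plus matched buffer wells. Every well draws from its own
    noise stream so replicates differ but the whole dataset is seed-determined.
    """
    if assay not in ("ca", "arrestin", "g_dissociation"):
        raise ValueError(f"unknown assay {assay!r}")
    # BRET plates are sampled at 1 s over the 10-min read to keep long-format
    # tables compact; the smoothing window covers 10 points either way.
    grid = TraceGrid() if assay == "ca" else TraceGrid(dt=1.0, duration=630.0)
    rows = []
    traces: list[KineticTrace] = []
    stream = 0
    for e in range(1, n_experiments + 1):
        for truth in truths:
            if truth.variant == "parental":
                continue
            for rep in range(1, n_replicates + 1):
                well = f"E{e}_{truth.variant}_buf_r{rep}"
                rows.append((well, truth.variant, "buffer", 0.0, WellRole.BUFFER.value, rep, f"E{e}"))
                stream += 1
                if assay == "ca":
                    traces.append(simulate_ca_trace(truth, 0.0, noise, grid, well,
                                                    stream=stream, buffer_well=True))
                else:
                    traces.append(simulate_bret_trace(truth, 0.0, noise, grid, assay,
                                                      well, stream=stream, buffer_well=True))
                for ci, conc in enumerate(concs):
                    well = f"E{e}_{truth.variant}_c{ci}_r{rep}"
                    rows.append((well, truth.variant, "CCL25", conc, WellRole.AGONIST.value, rep, f"E{e}"))
                    stream += 1
                    if assay == "ca":
                        traces.append(simulate_ca_trace(truth, conc, noise, grid, well, stream=stream))
                    else:
                        traces.append(simulate_bret_trace(truth, conc, noise, grid, assay,
                                                          well, stream=stream))
    plate = PlateMap(pd.DataFrame(rows, columns=list(PlateMap.COLUMNS)))
    return plate, traces


def truth_table_to_frame(truths: list[VariantTruth]) -> pd.DataFrame:
    return pd.DataFrame([asdict(t) for t in truths])
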