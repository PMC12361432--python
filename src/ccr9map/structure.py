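"""Structural-ensemble metrics for receptor activation and interface mapping.

Covers rigid least-squares superposition, per-residue ensemble variability
(RMSF + mean confidence), the Tyr(3.32)-Asn(6.52) activation-distance metric
and "most active" model ranking, active-vs-inactive helix displacement
decomposition, receptor-chemokine contact mapping with mutagenesis-site
selection, geometric hydrogen-bond and disulfide detection, and aggregation of
externally supplied per-atom interaction scores to residue backbones and side
chains.

Conventions (declared, configurable): heavy-atom contact cutoff 4.5 A;
H-bond donor-acceptor distance <= 3.5 A with a >= 120 deg D-H-A angle applied
only when hydrogens are present; disulfide SG-SG < 2.5 A; transmembrane helix
boundaries are supplied as a configuration table, never computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core_io import Ensemble, StructureModel

__all__ = [
    "ActivationMetrics",
    "ContactRecord",
    "HBond",
    "AtomScoreTable",
    "DEFAULT_TM_RANGES",
    "superpose",
    "ensemble_variability",
    "activation_distance",
    "compute_activation_metrics",
    "rank_by_activation",
    "tm_displacement",
    "contact_map",
    "select_mutagenesis_sites",
    "hbond_network",
    "disulfide_partners",
    "aggregate_atom_scores",
]

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})
CONTACT_CUTOFF = 4.5
HBOND_D_A_MAX = 3.5
HBOND_DHA_MIN = 120.0
DISULFIDE_CUTOFF = 2.5

# Helix boundary table used by the toy ensembles; real analyses supply their
# own via config.
DEFAULT_TM_RANGES = {tm: (start, start + 29) for tm, start in
                     {1: 35, 2: 70, 3: 110, 4: 150, 5: 195, 6: 250, 7: 290}.items()}


@dataclass
class ActivationMetrics:
    model_id: str
    y126_n271_distance: float
    tm6_ic_outward: float = math.nan
    cross_pocket_distance: float = math.nan
    tm5_depth: float = math.nan  # signed, intracellular-positive


@dataclass(frozen=True)
class ContactRecord:
    receptor_residue: int
    chemokine_residue: int
    min_heavy_atom_distance: float
    sidechain_contact: bool
    model_fraction: float
    mean_pair_count: float

    @property
    def strength(self) -> float:
        """Contact-strength score: ensemble persistence x mean atom-pair count."""
        return self.model_fraction * self.mean_pair_count


@dataclass(frozen=True)
class HBond:
    donor: tuple[str, int, str]     # (chain, residue, atom)
    acceptor: tuple[str, int, str]
    d_a_distance: float
    dha_angle: float | None         # None when no hydrogens are present
    donor_backbone: bool
    acceptor_backbone: bool


@dataclass
class AtomScoreTable:
    scores: pd.DataFrame  # chain, seq_number, atom_name, score
    provenance: str = ""


# ---------------------------------------------------------------------------
# Superposition and variability
# ---------------------------------------------------------------------------

def _select_coords(model: StructureModel, chain: str, residues, atom_names) -> np.ndarray:
    a = model.atoms
    mask = (a["chain"] == chain) & a["atom_name"].isin(atom_names)
    if residues is not None:
        mask &= a["seq_number"].isin(list(residues))
    sel = a[mask].sort_values(["seq_number", "atom_name"])
    return sel[["x", "y", "z"]].to_numpy(float)


def superpose(mobile: StructureModel, reference: StructureModel,
              selection=None, atom_names=("CA",), chain: str | None = None,
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation, translation, rmsd); ``rotation @ x + translation`` maps
    mobile coordinates into the reference frame. The selection (residue set and
    atom names, default Calpha) must resolve to >= 3 atoms in both models.
    """
    chain_m = chain or mobile.receptor_chain
    chain_r = chain or reference.receptor_chain
    xm = _select_coords(mobile, chain_m, selection, atom_names)
    xr = _select_coords(reference, chain_r, selection, atom_names)
    if len(xm) < 3 or len(xr) < 3:
        raise ValueError(f"superposition needs >= 3 atoms (got {len(xm)} / {len(xr)})")
    if len(xm) != len(xr):
        raise ValueError(f"selection size mismatch: {len(xm)} vs {len(xr)} atoms")
    result = gemmi.superpose_positions(
        [gemmi.Position(*p) for p in xr], [gemmi.Position(*p) for p in xm]
    )
    rot = np.array(result.transform.mat.tolist())
    trans = np.array(result.transform.vec.tolist())
    return rot, trans, float(result.rmsd)


def ensemble_variability(ensemble: Ensemble, selection=None) -> pd.DataFrame:
    """Per-residue Calpha RMSF across the ensemble, plus mean confidence.

    All models are superposed onto the first on receptor Calpha atoms before
    fluctuations are measured. RMSF(i) = sqrt(mean_m |x_mi - mean_x_i|^2).
    """
    if len(ensemble.models) < 2:
        raise ValueError("ensemble variability needs >= 2 models")
    chain = ensemble.receptor_chain
    ref = ensemble.models[0]
    ca_mask = (ref.atoms["chain"] == chain) & (ref.atoms["atom_name"] == "CA")
    if selection is not None:
        ca_mask &= ref.atoms["seq_number"].isin(list(selection))
    residues = ref.atoms[ca_mask].sort_values("seq_number")["seq_number"].to_numpy()
    stack = []
    for m in ensemble.models:
        rot, trans, _ = superpose(m, ref, selection=selection, chain=chain)
        coords = _select_coords(m, chain, residues, ("CA",))
        stack.append(coords @ rot.T + trans)
    arr = np.stack(stack)  # models x residues x 3
    mean = arr.mean(axis=0)
    rmsf = np.sqrt(((arr - mean) ** 2).sum(axis=2).mean(axis=0))
    conf = pd.concat([m.residue_confidence() for m in ensemble.models])
    conf = conf[conf["chain"] == chain].groupby("seq_number")["mean_confidence"].mean()
    return pd.DataFrame({
        "seq_number": residues,
        "rmsf": rmsf,
        "mean_confidence": conf.reindex(residues).to_numpy(),
    })


# ---------------------------------------------------------------------------
# Activation metrics
# ---------------------------------------------------------------------------

def activation_distance(model: StructureModel, donor_res: int = 126,
                        acceptor_res: int = 271) -> float:
    """Distance from the Tyr(3.32) hydroxyl oxygen to the nearer heavy atom of
    the Asn(6.52) side-chain carboxamide (ND2 or OD1).

    Using the nearer amide heavy atom makes the metric robust to amide flips.
    """
    chain = model.receptor_chain
    oh = model.atom_coord(chain, donor_res, "OH")
    dists = []
    for name in ("ND2", "OD1"):
        try:
            dists.append(float(np.linalg.norm(model.atom_coord(chain, acceptor_res, name) - oh)))
        except KeyError:
            pass
    if not dists:
        raise KeyError(
            f"model {model.model_id}: residue {acceptor_res} lacks side-chain amide atoms "
            "(ND2/OD1)"
        )
    return min(dists)


def _bundle_axis(model: StructureModel, tm_ranges: dict) -> tuple[np.ndarray, np.ndarray]:
    """Principal axis of the TM Calpha cloud, signed intracellular-positive.

    Intracellular markers default to the first two residues of each helix
    range (helix starts are the intracellular ends in the boundary table).
    """
    chain = model.receptor_chain
    tm_residues = [r for lo, hi in tm_ranges.values() for r in range(lo, hi + 1)]
    coords = _select_coords(model, chain, tm_residues, ("CA",))
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    axis = vt[0]
    markers = [r for lo, hi in tm_ranges.values() for r in (lo, lo + 1)]
    marker_coords = _select_coords(model, chain, markers, ("CA",))
    if marker_coords.size and np.dot(marker_coords.mean(axis=0) - centroid, axis) < 0:
        axis = -axis
    return axis, centroid


def compute_activation_metrics(model: StructureModel, donor_res: int = 126,
                               acceptor_res: int = 271,
                               tm_ranges: dict | None = None) -> ActivationMetrics:
    """Activation-distance metric plus secondary bundle-geometry diagnostics."""
    dist = activation_distance(model, donor_res, acceptor_res)
    metrics = ActivationMetrics(model.model_id, dist)
    if tm_ranges:
        chain = model.receptor_chain
        axis, centroid = _bundle_axis(model, tm_ranges)

        def ca_mean(residues) -> np.ndarray:
            return _select_coords(model, chain, residues, ("CA",)).mean(axis=0)

        tm6_lo, tm6_hi = tm_ranges[6]
        ic_end = ca_mean(range(tm6_lo, tm6_lo + 3))
        radial = ic_end - centroid
        radial = radial - np.dot(radial, axis) * axis
        metrics.tm6_ic_outward = float(np.linalg.norm(radial))
        tm5_lo, tm5_hi = tm_ranges[5]
        mid5 = ca_mean([(tm5_lo + tm5_hi) // 2])
        metrics.tm5_depth = float(np.dot(mid5 - centroid, axis))
        tm7_lo, tm7_hi = tm_ranges[7]
        pocket_a = ca_mean([donor_res])
        pocket_b = 0.5 * (ca_mean(range(tm6_hi - 2, tm6_hi + 1)) + ca_mean(range(tm7_hi - 2, tm7_hi + 1)))
        metrics.cross_pocket_distance = float(np.linalg.norm(pocket_a - pocket_b))
    return metrics


def rank_by_activation(ensemble: Ensemble, donor_res: int = 126,
                       acceptor_res: int = 271, tm_ranges: dict | None = None,
                       ) -> tuple[list[ActivationMetrics], ActivationMetrics]:
    """Rank ensemble models from most to least active.

    Primary key: the Tyr-Asn activation distance (largest = most active);
    ties broken by model_id for a stable total order. Returns (ranked metrics,
    most-active model's metrics).
    """
    metrics = [
        compute_activation_metrics(m, donor_res, acceptor_res, tm_ranges)
        for m in ensemble.models
    ]
    ranked = sorted(metrics, key=lambda m: (-m.y126_n271_distance, m.model_id))
    return ranked, ranked[0]


def tm_displacement(active: StructureModel, inactive: StructureModel,
                    segment: range | list[int], frame: range | list[int],
                    reference_residue: int | None = None,
                    tm_ranges: dict | None = None,
                    ) -> tuple[float, float, float]:
    """Decompose the inactive-to-active displacement of a helix segment.

    After superposing the inactive model onto the active one on the ``frame``
    Calpha selection (which must exclude the segment), the displacement vector
    of the segment's reference Calpha (default: midpoint residue) is split into
    a bundle-axis component (``along_axis``, intracellular-positive) and the
    perpendicular ``outward`` component. Returns (outward, along_axis, total).
    """
    segment = list(segment)
    frame = [r for r in frame if r not in set(segment)]
    if reference_residue is None:
        reference_residue = segment[len(segment) // 2]
    chain_a, chain_i = active.receptor_chain, inactive.receptor_chain
    rot, trans, _ = superpose(inactive, active, selection=frame)
    try:
        ref_active = active.atom_coord(chain_a, reference_residue, "CA")
        ref_inactive = inactive.atom_coord(chain_i, reference_residue, "CA")
    except KeyError as exc:
        raise ValueError(f"missing reference Calpha: {exc}") from exc
    ref_inactive = rot @ ref_inactive + trans
    v = ref_active - ref_inactive
    axis, _ = _bundle_axis(active, tm_ranges or DEFAULT_TM_RANGES)
    along = float(np.dot(v, axis))
    outward = float(np.linalg.norm(v - along * axis))
    return outward, along, float(np.linalg.norm(v))


# ---------------------------------------------------------------------------
# Contacts and mutagenesis-site selection
# ---------------------------------------------------------------------------

def _heavy(atoms: pd.DataFrame) -> pd.DataFrame:
    return atoms[atoms["element"] != "H"]


def contact_map(ensemble: Ensemble, cutoff: float = CONTACT_CUTOFF,
                sidechain_only: bool = False) -> list[ContactRecord]:
    """Receptor-chemokine residue contacts across the ensemble.

    A residue pair is in contact in a model when its minimum heavy-atom
    distance is <= cutoff; ``sidechain_only`` restricts the receptor side to
    side-chain atoms. Each record carries the fraction of models showing the
    contact and the mean number of atom pairs within the cutoff, whose product
    is the contact-strength score used for mutagenesis-site selection.
    """
    if ensemble.chemokine_chain is None:
        raise ValueError("ensemble has no chemokine chain")
    stats: dict[tuple[int, int], dict] = {}
    n_models = len(ensemble.models)
    for model in ensemble.models:
        rec = _heavy(model.atoms[model.atoms["chain"] == ensemble.receptor_chain])
        if sidechain_only:
            rec = rec[~rec["atom_name"].isin(BACKBONE_ATOMS)]
        chem = _heavy(model.atoms[model.atoms["chain"] == ensemble.chemokine_chain])
        if rec.empty or chem.empty or cutoff <= 0:
            continue
        d = cdist(rec[["x", "y", "z"]].to_numpy(float), chem[["x", "y", "z"]].to_numpy(float))
        rres = rec["seq_number"].to_numpy()
        cres = chem["seq_number"].to_numpy()
        within = np.argwhere(d <= cutoff)
        per_pair: dict[tuple[int, int], list] = {}
        for i, j in within:
            per_pair.setdefault((int(rres[i]), int(cres[j])), []).append(d[i, j])
        for pair, dists in per_pair.items():
            entry = stats.setdefault(pair, {"count": 0, "pairs": 0, "min": math.inf})
            entry["count"] += 1
            entry["pairs"] += len(dists)
            entry["min"] = min(entry["min"], min(dists))
    out = []
    for (r, c), entry in sorted(stats.items()):
        out.append(ContactRecord(
            receptor_residue=r, chemokine_residue=c,
            min_heavy_atom_distance=float(entry["min"]),
            sidechain_contact=sidechain_only,
            model_fraction=entry["count"] / n_models,
            mean_pair_count=entry["pairs"] / n_models,
        ))
    return out


def select_mutagenesis_sites(contacts: list[ContactRecord], k: int = 10,
                             restrict=None) -> list[int]:
    """Top-k receptor residues by total contact strength within a restriction set.

    ``restrict`` is typically the union of transmembrane residue ranges (the
    CRS2 "TM domains only" rule). Ties break toward the lower residue number.
    Returns fewer than k residues (with a warning) when candidates run out.
    """
    import warnings
    scores: dict[int, float] = {}
    for c in contacts:
        if restrict is not None and c.receptor_residue not in restrict:
            continue
        scores[c.receptor_residue] = scores.get(c.receptor_residue, 0.0) + c.strength
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) < k:
        warnings.warn(f"only {len(ranked)} candidate residues for k={k}", stacklevel=2)
    return [res for res, _ in ranked[:k]]


# ---------------------------------------------------------------------------
# Hydrogen bonds and disulfides
# ---------------------------------------------------------------------------

_POLAR_ELEMENTS = {"N", "O"}


def hbond_network(model: StructureModel, focus_residues,
                  d_a_max: float = HBOND_D_A_MAX,
                  dha_min: float = HBOND_DHA_MIN) -> list[HBond]:
    """Geometric hydrogen bonds touching any focus residue.

    Donor/acceptor candidates are N and O heavy atoms; a pair qualifies when
    the donor-acceptor distance is <= ``d_a_max`` and the atoms belong to
    different residues. When hydrogens are present on the donor the D-H-A angle
    must also be >= ``dha_min``; without hydrogens the angle criterion is
    skipped and the reported angle is None. N is preferred as the donor of a
    mixed pair; each unordered pair is reported once.
    """
    focus = {(c, int(r)) for c, r in focus_residues}
    atoms = model.atoms
    polar = atoms[atoms["element"].isin(_POLAR_ELEMENTS)].reset_index(drop=True)
    if polar.empty:
        return []
    coords = polar[["x", "y", "z"]].to_numpy(float)
    d = cdist(coords, coords)
    hydrogens = atoms[atoms["element"] == "H"]
    h_coords = hydrogens[["x", "y", "z"]].to_numpy(float) if not hydrogens.empty else None
    out = []
    n = len(polar)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] > d_a_max:
                continue
            ai, aj = polar.iloc[i], polar.iloc[j]
            if (ai["chain"], ai["seq_number"]) == (aj["chain"], aj["seq_number"]):
                continue
            key_i = (ai["chain"], int(ai["seq_number"]))
            key_j = (aj["chain"], int(aj["seq_number"]))
            if key_i not in focus and key_j not in focus:
                continue
            # donor preference: N over O; ties keep (i, j) order
            if ai["element"] == "N" or aj["element"] != "N":
                donor, acceptor, dc, acc_c = ai, aj, coords[i], coords[j]
            else:
                donor, acceptor, dc, acc_c = aj, ai, coords[j], coords[i]
            angle = None
            if h_coords is not None and len(h_coords):
                hd = np.linalg.norm(h_coords - dc, axis=1)
                near = hd < 1.3  # hydrogens covalently bonded to the donor
                if near.any():
                    best = None
                    for hpos in h_coords[near]:
                        v1 = dc - hpos
                        v2 = acc_c - hpos
                        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                        ang = math.degrees(math.acos(np.clip(cosang, -1, 1)))
                        best = ang if best is None else max(best, ang)
                    angle = best
                    if angle < dha_min:
                        continue
            out.append(HBond(
                donor=(donor["chain"], int(donor["seq_number"]), donor["atom_name"]),
                acceptor=(acceptor["chain"], int(acceptor["seq_number"]), acceptor["atom_name"]),
                d_a_distance=float(d[i, j]),
                dha_angle=angle,
                donor_backbone=donor["atom_name"] in BACKBONE_ATOMS,
                acceptor_backbone=acceptor["atom_name"] in BACKBONE_ATOMS,
            ))
    return out


def disulfide_partners(model: StructureModel, chain: str) -> list[tuple[int, int]]:
    """Cysteine SG-SG bridges (< 2.5 A), each Cys in at most one pair.

    Pairing is greedy by increasing SG-SG distance, which on small systems
    coincides with minimum-weight matching.
    """
    sg = model.atoms[
        (model.atoms["chain"] == chain)
        & (model.atoms["residue_name"] == "CYS")
        & (model.atoms["atom_name"] == "SG")
    ]
    if len(sg) < 2:
        return []
    res = sg["seq_number"].to_numpy()
    coords = sg[["x", "y", "z"]].to_numpy(float)
    d = cdist(coords, coords)
    candidates = [
        (d[i, j], int(res[i]), int(res[j]))
        for i in range(len(sg)) for j in range(i + 1, len(sg))
        if d[i, j] < DISULFIDE_CUTOFF
    ]
    candidates.sort()
    used: set[int] = set()
    pairs = []
    for _, ri, rj in candidates:
        if ri in used or rj in used:
            continue
        pairs.append((min(ri, rj), max(ri, rj)))
        used.update((ri, rj))
    return sorted(pairs)


# ---------------------------------------------------------------------------
# Per-atom score aggregation
# ---------------------------------------------------------------------------

def aggregate_atom_scores(models: StructureModel | list[StructureModel],
                          scores: AtomScoreTable | list[AtomScoreTable]) -> pd.DataFrame:
    """Sum per-atom scores to residue backbones and side chains.

    With lists of models and matching per-model score tables, the aggregates
    are averaged across models (e.g. the top-n models of an ensemble). Every
    scored atom must resolve in its model. Returns a frame with chain,
    seq_number, backbone_score, sidechain_score.
    """
    if isinstance(models, StructureModel):
        models = [models]
    if isinstance(scores, AtomScoreTable):
        scores = [scores] * len(models)
    if len(scores) != len(models):
        raise ValueError("need one score table per model")
    frames = []
    for model, score_table in zip(models, scores):
        merged = score_table.scores.merge(
            model.atoms[["chain", "seq_number", "atom_name"]],
            on=["chain", "seq_number", "atom_name"], how="left", indicator=True,
        )
        missing = merged[merged["_merge"] == "left_only"]
        if not missing.empty:
            items = [
                f"{r.chain}/{r.seq_number}/{r.atom_name}" for r in missing.itertuples()
            ]
            raise ValueError(
                f"model {model.model_id}: scored atoms not found: {', '.join(items[:5])}"
                + ("..." if len(items) > 5 else "")
            )
        tab = score_table.scores.copy()
        tab["is_backbone"] = tab["atom_name"].isin(BACKBONE_ATOMS)
        agg = (
            tab.groupby(["chain", "seq_number", "is_backbone"])["score"].sum().unstack(fill_value=0.0)
        )
        agg = agg.rename(columns={True: "backbone_score", False: "sidechain_score"})
        for col in ("backbone_score", "sidechain_score"):
            if col not in agg:
                agg[col] = 0.0
        frames.append(agg[["backbone_score", "sidechain_score"]])
    mean = sum(frames[1:], frames[0].copy()) / len(frames)
    return mean.reset_index()
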