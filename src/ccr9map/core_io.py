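"""Shared domain types, structure/table readers and writers, sequence utilities.

All residue positions use 1-based mature-protein numbering: position 1 is the
first residue of the processed chemokine/receptor chain, matching the numbering
used for mutant names such as K40A or S32. Ballesteros-Weinstein labels for
transmembrane positions are supplied as annotation tables, never computed.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "WellRole",
    "PlateMap",
    "KineticTrace",
    "FlowRecord",
    "SequenceRecord",
    "ResidueLabel",
    "StructureModel",
    "Ensemble",
    "CCR9_SEQUENCE",
    "CCL25_SEQUENCE",
    "CCL25_1P6_SEQUENCE",
    "read_structure",
    "write_structure",
    "find_subsequence",
    "n_terminal_region",
    "write_tables",
    "read_table",
    "traces_to_frame",
    "frame_to_traces",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX")

# Mature-protein sequences of the receptor and its chemokine ligands,
# 1-based numbering from the first printed residue.
CCR9_SEQUENCE = (
    "MTPTDFTSPIPNMADDYGSESTSSMEDYVNFNFTDFYCEKNNVRQFASHFLPPLYWLVFI"
    "VGALGNSLVILVYWYCTRVKTMTDMFLLNLAIADLLFLVTLPFWAIAAADQWKFQTFMCK"
    "VVNSMYKMNFYSCVLLIMCISVDRYIAIAQAMRAHTWREKRLLYSKMVCFTIWVLAAALC"
    "IPEILYSQIKEESGIAICTMVYPSDESTKLKSAVLTLKVILGFFLPFVVMACCYTIIIHT"
    "LIQAKKSSKHKALKVTITVLTVFVLSQFPYNCILLVQTIDAYAMFISNCAVSTNIDICFQ"
    "VTQTIAFFHSCLNPVLYVFVGERFRRDLVKTLKNLGCISQAQWVSFTRREGSLKLSSMLL"
    "ETTSGALSL"
)
CCL25_SEQUENCE = (
    "PGVFEDCCLAYHYPIGWAVLRRAWTYRIQEVSGSCNLPAAIFYLPKRHRKVCGNPKSREV"
    "QRAMKLLDARNKVFAKLHHNTQTFQAGPHAVKKLSSGNSKLSSSKFSNPISSSKRNVSLL"
    "ISANSGL"
)
CCL25_1P6_SEQUENCE = "YQAS" + CCL25_SEQUENCE[4:]


class WellRole(str, Enum):
    AGONIST = "agonist"
    BUFFER = "buffer"
    VEHICLE = "vehicle"
    ANTAGONIST_PROBE = "antagonist_probe"


@dataclass
class PlateMap:
    """Annotation of plate wells: which variant/ligand/concentration each holds."""

    wells: pd.DataFrame  # columns: well_id, variant, ligand, concentration, role, replicate, experiment_id

    COLUMNS = ("well_id", "variant", "ligand", "concentration", "role", "replicate", "experiment_id")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.wells.columns)
        if missing:
            raise ValueError(f"plate map missing columns: {sorted(missing)}")
        if self.wells["well_id"].duplicated().any():
            dup = self.wells.loc[self.wells["well_id"].duplicated(), "well_id"].iloc[0]
            raise ValueError(f"duplicate well_id {dup!r} in plate map")
        ag = self.wells[self.wells["role"] == WellRole.AGONIST.value]
        if (ag["concentration"] <= 0).any():
            bad = ag.loc[ag["concentration"] <= 0, "well_id"].iloc[0]
            raise ValueError(f"agonist well {bad!r} has non-positive concentration")
        for exp, grp in self.wells.groupby("experiment_id"):
            roles = set(grp["role"])
            if not roles & {WellRole.BUFFER.value, WellRole.VEHICLE.value}:
                raise ValueError(f"experiment {exp!r} has no buffer/vehicle well")

    def select(self, **kwargs) -> pd.DataFrame:
        out = self.wells
        for key, val in kwargs.items():
            out = out[out[key] == val]
        return out


@dataclass
class KineticTrace:
    """One well's time series: one or two emission channels plus injection times."""

    well_id: str
    times: np.ndarray  # seconds, strictly increasing
    channels: dict[str, np.ndarray]
    injections: list[float]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if not np.all(np.diff(self.times) > 0):
            raise ValueError(f"trace {self.well_id}: times must be strictly increasing")
        for name in list(self.channels):
            vals = np.asarray(self.channels[name], dtype=float)
            if vals.shape != self.times.shape:
                raise ValueError(f"trace {self.well_id}: channel {name!r} length mismatch")
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"trace {self.well_id}: channel {name!r} has non-finite values")
            self.channels[name] = vals
        for t in self.injections:
            if not (self.times[0] <= t <= self.times[-1]):
                raise ValueError(f"trace {self.well_id}: injection {t} outside time range")

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"trace {self.well_id}: missing channel {name!r}")
        return self.channels[name]

    def replace(self, **channels: np.ndarray) -> "KineticTrace":
        new = dict(self.channels)
        new.update({k: np.asarray(v, dtype=float) for k, v in channels.items()})
        return KineticTrace(self.well_id, self.times.copy(), new, list(self.injections))


@dataclass
class FlowRecord:
    """Per-sample flow-cytometry summary: median fluorescence of a cell line."""

    cell_line: str
    ligand: str | None
    concentration: float
    mfi: float
    autofluorescence_mfi: float
    events: int
    experiment_id: str

    def __post_init__(self) -> None:
        if self.mfi <= 0 or self.autofluorescence_mfi <= 0:
            raise ValueError(
                f"flow record ({self.cell_line}, {self.experiment_id}): MFI values must be > 0"
            )


@dataclass
class SequenceRecord:
    name: str
    residues: str
    numbering_offset: int = 1  # mature-sequence position of residues[0]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.name!r} is empty")
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise ValueError(f"sequence {self.name!r} has invalid letters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ResidueLabel:
    chain: str
    seq_number: int
    bw_label: str | None = None  # "T.NN" or loop tag (ECL2, ECL3, ...)


@dataclass
class StructureModel:
    """One structural model: flat atom table plus chain-role annotations.

    The atom table holds chain, residue number (mature numbering), residue and
    atom names, element, coordinates in Angstrom, and a per-atom confidence
    (pLDDT-like, carried in the B-factor column of PDB files).
    """

    model_id: str
    atoms: pd.DataFrame  # chain, seq_number, residue_name, atom_name, element, x, y, z, confidence
    chain_roles: dict[str, str] = field(default_factory=dict)  # chain -> receptor/chemokine
    rank_score: float | None = None
    bw_labels: dict[int, str] = field(default_factory=dict)  # receptor seq_number -> BW label

    ATOM_COLUMNS = ("chain", "seq_number", "residue_name", "atom_name", "element", "x", "y", "z", "confidence")

    def __post_init__(self) -> None:
        missing = set(self.ATOM_COLUMNS) - set(self.atoms.columns)
        if missing:
            raise ValueError(f"model {self.model_id}: atom table missing {sorted(missing)}")
        xyz = self.atoms[["x", "y", "z"]].to_numpy(float)
        if not np.all(np.isfinite(xyz)):
            raise ValueError(f"model {self.model_id}: non-finite coordinates")

    @property
    def receptor_chain(self) -> str:
        for chain, role in self.chain_roles.items():
            if role == "receptor":
                return chain
        raise ValueError(f"model {self.model_id}: no chain labeled receptor")

    @property
    def chemokine_chain(self) -> str | None:
        for chain, role in self.chain_roles.items():
            if role == "chemokine":
                return chain
        return None

    def coords(self, mask=None) -> np.ndarray:
        table = self.atoms if mask is None else self.atoms[mask]
        return table[["x", "y", "z"]].to_numpy(float)

    def atom_coord(self, chain: str, seq_number: int, atom_name: str) -> np.ndarray:
        sel = self.atoms[
            (self.atoms["chain"] == chain)
            & (self.atoms["seq_number"] == seq_number)
            & (self.atoms["atom_name"] == atom_name)
        ]
        if sel.empty:
            raise KeyError(
                f"model {self.model_id}: atom {atom_name} of {chain}/{seq_number} not found"
            )
        return sel[["x", "y", "z"]].to_numpy(float)[0]

    def residue_confidence(self) -> pd.DataFrame:
        """Per-residue confidence = mean of per-atom values."""
        return (
            self.atoms.groupby(["chain", "seq_number"], as_index=False)["confidence"]
            .mean()
            .rename(columns={"confidence": "mean_confidence"})
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        xyz = self.coords() @ np.asarray(rotation).T + np.asarray(translation)
        atoms = self.atoms.copy()
        atoms[["x", "y", "z"]] = xyz
        return StructureModel(self.model_id, atoms, dict(self.chain_roles), self.rank_score, dict(self.bw_labels))


@dataclass
class Ensemble:
    models: list[StructureModel]
    receptor_chain: str
    chemokine_chain: str | None = None
    reference_inactive: StructureModel | None = None

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("ensemble must contain at least one model")
        ref = self._topology(self.models[0])
        for m in self.models[1:]:
            if not ref.equals(self._topology(m)):
                raise ValueError(f"ensemble topology mismatch in model {m.model_id}")

    def _topology(self, model: StructureModel) -> pd.DataFrame:
        a = model.atoms
        rec = a[a["chain"] == self.receptor_chain]
        return rec[["chain", "seq_number", "atom_name"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Structure file I/O (PDB / mmCIF via gemmi)
# ---------------------------------------------------------------------------

def read_structure(path: str | Path, chain_roles: Mapping[str, str] | None = None,
                   model_id: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a flat atom table.

    ``chain_roles`` maps chain names to "receptor"/"chemokine"; declared chains
    must exist in the file. The B-factor column is interpreted as per-atom
    confidence (pLDDT convention for predicted models).
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    st.setup_entities()
    model = st[0]
    chains_present = {ch.name for ch in model}
    if chain_roles:
        missing = set(chain_roles) - chains_present
        if missing:
            raise ValueError(
                f"{path}: declared chain(s) {sorted(missing)} not present "
                f"(file has {sorted(chains_present)})"
            )
    rows = []
    for chain in model:
        for res in chain:
            for atom in res:
                rows.append(
                    (chain.name, res.seqid.num, res.name, atom.name,
                     atom.element.name.upper(), atom.pos.x, atom.pos.y, atom.pos.z,
                     atom.b_iso)
                )
    atoms = pd.DataFrame(rows, columns=list(StructureModel.ATOM_COLUMNS))
    return StructureModel(
        model_id=model_id or path.stem,
        atoms=atoms,
        chain_roles=dict(chain_roles or {}),
    )


def write_structure(model: StructureModel, path: str | Path, format: str = "pdb") -> Path:
    """Write a model as PDB or mmCIF; confidence goes to the B-factor column."""
    path = Path(path)
    st = gemmi.Structure()
    st.name = model.model_id
    gm = gemmi.Model("1")
    for chain_name, chain_atoms in model.atoms.groupby("chain", sort=False):
        chain = gemmi.Chain(str(chain_name))
        for (seq_number, residue_name), res_atoms in chain_atoms.groupby(
            ["seq_number", "residue_name"], sort=False
        ):
            res = gemmi.Residue()
            res.name = str(residue_name)
            res.seqid = gemmi.SeqId(int(seq_number), " ")
            for row in res_atoms.itertuples():
                atom = gemmi.Atom()
                atom.name = row.atom_name
                atom.element = gemmi.Element(row.element)
                atom.pos = gemmi.Position(row.x, row.y, row.z)
                atom.b_iso = float(row.confidence)
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    if format == "pdb":
        st.write_pdb(str(path))
    elif format in ("cif", "mmcif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown structure format {format!r}")
    return path


# ---------------------------------------------------------------------------
# Sequence utilities
# ---------------------------------------------------------------------------

def find_subsequence(seq: SequenceRecord, motif: str) -> int:
    """1-based mature-numbering start of the first occurrence of ``motif``.

    Multiple occurrences trigger a warning; the first is returned.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    idx = seq.residues.find(motif)
    if idx < 0:
        raise ValueError(f"motif {motif!r} not found in sequence {seq.name!r}")
    if seq.residues.find(motif, idx + 1) >= 0:
        warnings.warn(
            f"motif {motif!r} occurs more than once in {seq.name!r}; returning first",
            stacklevel=2,
        )
    return idx + seq.numbering_offset


def n_terminal_region(seq: SequenceRecord) -> int:
    """Number of residues strictly before the first cysteine."""
    idx = seq.residues.find("C")
    if idx < 0:
        raise ValueError(f"sequence {seq.name!r} contains no cysteine")
    return idx


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def write_tables(records, path: str | Path, record_type: type | None = None) -> Path:
    """Write domain records (or a DataFrame) as a header-carrying CSV.

    An empty record list yields a header-only file when ``record_type`` names
    the dataclass whose fields define the columns.
    """
    path = Path(path)
    if isinstance(records, PlateMap):
        frame = records.wells
    elif isinstance(records, pd.DataFrame):
        frame = records
    else:
        records = list(records)
        if records and not hasattr(records[0], "__dataclass_fields__"):
            raise TypeError(f"cannot serialize records of type {type(records[0])}")
        if records:
            cols = list(records[0].__dataclass_fields__)
        elif record_type is not None:
            cols = list(record_type.__dataclass_fields__)
        else:
            cols = []
        frame = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records],
                             columns=cols)
    frame.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_flow_records(path: str | Path) -> list[FlowRecord]:
    frame = pd.read_csv(path)
    out = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        if pd.isna(d.get("ligand")):
            d["ligand"] = None
        out.append(FlowRecord(**d))
    return out


def traces_to_frame(traces: Sequence[KineticTrace]) -> pd.DataFrame:
    """Long-format trace table: well_id, time_s, channel, value (+injections)."""
    parts = []
    for tr in traces:
        for name, vals in tr.channels.items():
            parts.append(pd.DataFrame({
                "well_id": tr.well_id,
                "time_s": tr.times,
                "channel": name,
                "value": vals,
                "injections": ";".join(f"{t:g}" for t in tr.injections),
            }))
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["well_id", "time_s", "channel", "value", "injections"])


def frame_to_traces(frame: pd.DataFrame) -> list[KineticTrace]:
    out = []
    for well_id, grp in frame.groupby("well_id", sort=False):
        channels = {}
        times = None
        for channel, cgrp in grp.groupby("channel", sort=False):
            cgrp = cgrp.sort_values("time_s")
            t = cgrp["time_s"].to_numpy(float)
            if times is None:
                times = t
            channels[channel] = cgrp["value"].to_numpy(float)
        inj_field = str(grp["injections"].iloc[0])
        injections = [float(x) for x in inj_field.split(";") if x]
        out.append(KineticTrace(str(well_id), times, channels, injections))
    return out
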