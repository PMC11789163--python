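"""Readers/writers: CIF structures, JSONL record/trajectory streams,
validated run configuration and run manifests.

JSONL (one JSON object per line) is used for all Monte Carlo archives:
it streams, appends and diffs.  Energies are serialized at full double
precision; non-finite energies use the JSON Infinity extension that the
standard library emits and accepts.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__ as _pkg_version
from .crystal import (
    PackingState,
    RigidMolecule,
    SpaceGroup,
    cell_matrix,
    expand_to_cell,
)
from .mc import StepRecord
from .search import PolymorphRecord, Provenance

SCHEMA_VERSION = 1

__all__ = [
    "write_cif",
    "write_records",
    "read_records",
    "write_trajectory",
    "read_trajectory",
    "RunConfig",
    "load_config",
    "write_manifest",
    "JsonlParseError",
]


class JsonlParseError(ValueError):
    """A JSONL stream could not be parsed; carries the 1-based line."""

    def __init__(self, path, line_no: int, why: str):
        super().__init__(f"{path}:{line_no}: {why}")
        self.line_no = line_no


# ---------------------------------------------------------------------------
# CIF
# ---------------------------------------------------------------------------

def write_cif(
    record: PolymorphRecord,
    mol: RigidMolecule,
    sg: SpaceGroup,
    path: Union[str, Path],
) -> Path:
    """Write a minimized structure as a P1-expanded CIF.

    All symmetry copies are emitted as explicit atom sites with
    fractional coordinates wrapped into [0, 1); the data block is named
    from the record's provenance.  The file round-trips through gemmi.
    """
    import gemmi

    path = Path(path)
    st = record.state
    atoms = expand_to_cell(st, mol, sg)
    A = cell_matrix(st.H)
    frac = (atoms @ np.linalg.inv(A)) % 1.0
    doc = gemmi.cif.Document()
    prov = record.provenance
    name = f"{prov.run_id or 'evccp'}_step{prov.step}_m{prov.batch_index}"
    block = doc.add_new_block(name.replace(" ", "_"))
    pairs = [
        ("_cell_length_a", st.H[0]),
        ("_cell_length_b", st.H[1]),
        ("_cell_length_c", st.H[2]),
        ("_cell_angle_alpha", st.H[3]),
        ("_cell_angle_beta", st.H[4]),
        ("_cell_angle_gamma", st.H[5]),
    ]
    for k, v in pairs:
        block.set_pair(k, f"{v:.6f}")
    block.set_pair("_symmetry_space_group_name_H-M", gemmi.cif.quote("P 1"))
    block.set_pair("_evccp_energy_kj_mol", f"{record.U_unb:.10g}")
    block.set_pair("_evccp_source_space_group", gemmi.cif.quote(sg.symbol))
    loop = block.init_loop(
        "_atom_site_", ["label", "fract_x", "fract_y", "fract_z"]
    )
    for i, f in enumerate(frac):
        loop.add_row(
            [f"X{i + 1}", f"{f[0]:.6f}", f"{f[1]:.6f}", f"{f[2]:.6f}"]
        )
    doc.write_file(str(path))
    return path


# ---------------------------------------------------------------------------
# JSONL records
# ---------------------------------------------------------------------------

def _record_to_obj(rec: PolymorphRecord) -> dict:
    p = rec.provenance
    return {
        "schema": SCHEMA_VERSION,
        "X": rec.state.X.tolist(),
        "H": rec.state.H.tolist(),
        "U_unb": rec.U_unb,
        "penalty": rec.penalty,
        "U_biased": rec.U_biased,
        "converged": rec.converged,
        "provenance": {
            "run_id": p.run_id, "step": p.step,
            "batch_index": p.batch_index, "replica": p.replica,
        },
        "seed": rec.seed,
    }


def _record_from_obj(o: dict) -> PolymorphRecord:
    p = o.get("provenance", {})
    return PolymorphRecord(
        state=PackingState(np.asarray(o["X"], float), np.asarray(o["H"], float)),
        U_unb=float(o["U_unb"]),
        penalty=float(o["penalty"]),
        U_biased=float(o["U_biased"]),
        converged=bool(o["converged"]),
        provenance=Provenance(
            run_id=p.get("run_id", ""), step=p.get("step", -1),
            batch_index=p.get("batch_index", -1), replica=p.get("replica", -1),
        ),
        seed=int(o.get("seed", 0)),
    )


def write_records(
    records: Sequence[PolymorphRecord], path: Union[str, Path],
    append: bool = False,
) -> Path:
    path = Path(path)
    mode = "a" if append else "w"
    with path.open(mode) as fh:
        for rec in records:
            fh.write(json.dumps(_record_to_obj(rec)) + "\n")
    return path


def _iter_jsonl(path: Path):
    with path.open() as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as err:
                raise JsonlParseError(path, i, f"bad JSON ({err.msg})") from err
            if obj.get("schema") != SCHEMA_VERSION:
                raise JsonlParseError(
                    path, i,
                    f"schema version {obj.get('schema')!r} != {SCHEMA_VERSION}",
                )
            yield i, obj


def read_records(path: Union[str, Path]) -> List[PolymorphRecord]:
    """Lossless inverse of :func:`write_records`."""
    out = []
    for i, obj in _iter_jsonl(Path(path)):
        try:
            out.append(_record_from_obj(obj))
        except (KeyError, ValueError) as err:
            raise JsonlParseError(path, i, f"bad record ({err})") from err
    return out


# ---------------------------------------------------------------------------
# JSONL trajectories
# ---------------------------------------------------------------------------

def _step_to_obj(s: StepRecord) -> dict:
    return {
        "schema": SCHEMA_VERSION,
        "iter": s.iter,
        "S": np.asarray(s.S, float).tolist(),
        "U_cond": s.U_cond,
        "U_min": s.U_min,
        "X_min": None if s.X_min is None else {
            "X": s.X_min.X.tolist(), "H": s.X_min.H.tolist()
        },
        "batch": [_record_to_obj(r) for r in s.batch],
        "accepted": s.accepted,
        "n_prefiltered": s.n_prefiltered,
    }


def _step_from_obj(o: dict) -> StepRecord:
    xm = o.get("X_min")
    return StepRecord(
        iter=int(o["iter"]),
        S=np.asarray(o["S"], float),
        U_cond=float(o["U_cond"]),
        U_min=float(o["U_min"]),
        X_min=None if xm is None else PackingState(
            np.asarray(xm["X"], float), np.asarray(xm["H"], float)
        ),
        batch=[_record_from_obj(b) for b in o.get("batch", [])],
        accepted=bool(o["accepted"]),
        n_prefiltered=int(o.get("n_prefiltered", 0)),
    )


def write_trajectory(
    steps: Sequence[StepRecord], path: Union[str, Path], append: bool = False
) -> Path:
    path = Path(path)
    with path.open("a" if append else "w") as fh:
        for s in steps:
            fh.write(json.dumps(_step_to_obj(s)) + "\n")
    return path


def read_trajectory(path: Union[str, Path]) -> List[StepRecord]:
    out = []
    for i, obj in _iter_jsonl(Path(path)):
        try:
            out.append(_step_from_obj(obj))
        except (KeyError, ValueError) as err:
            raise JsonlParseError(path, i, f"bad step ({err})") from err
    return out


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

class MoleculeConfig(BaseModel):
    """User molecule block; epsilon/sigma/charge may be scalars (uniform
    over sites) or per-site lists."""

    model_config = ConfigDict(extra="forbid")
    label: str
    sites: List[List[float]]
    epsilon: Union[float, List[float]] = 1.0
    sigma: Union[float, List[float]] = 3.4
    charge: Union[float, List[float]] = 0.0
    molar_mass: float = 100.0

    def build(self) -> RigidMolecule:
        n = len(self.sites)

        def _expand(v):
            return [float(v)] * n if isinstance(v, (int, float)) else list(v)

        params = np.column_stack(
            [_expand(self.epsilon), _expand(self.sigma), _expand(self.charge)]
        )
        return RigidMolecule(self.label, np.asarray(self.sites, float),
                             params, self.molar_mass)


class PotentialSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cutoff_radius: float = 8.0
    image_shell_margin: int = 0


class BoundsSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    length_min: float = 3.0
    length_max: float = 10.0
    angle_min: float = 60.0
    angle_max: float = 120.0
    density_min: float = 0.0
    density_max: float = 1e9


class EvccpSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k_com: float = 1000.0
    k_euler: float = 1000.0
    M: int = 10
    T: float = 300.0
    step_com: float = 0.5
    step_euler: float = 15.0
    E_threshold: Optional[float] = None
    n_steps: int = 100


class MreSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    variant: str = "MRE0"
    baths: List[float] = Field(default_factory=lambda: [263.0, 370.0, 574.0, 1142.0])
    steps: int = 200
    cycles: int = 1
    exchange_interval: int = 5


class RunConfig(BaseModel):
    """Top-level validated configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    molecule: MoleculeConfig
    space_group: str = "P1"
    z_prime: int = 1
    potential: PotentialSection = Field(default_factory=PotentialSection)
    bounds: BoundsSection = Field(default_factory=BoundsSection)
    evccp: EvccpSection = Field(default_factory=EvccpSection)
    mre: MreSection = Field(default_factory=MreSection)
    n: int = 100
    output_dir: str = "evccp_out"
    seed: int = 0
    log_level: str = "INFO"


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and schema-validate a YAML/JSON run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return RunConfig.model_validate(data)


def write_manifest(
    out_dir: Union[str, Path],
    config_text: str,
    seed: int,
    outputs: Sequence[Union[str, Path]],
) -> Path:
    """Record what produced a run directory: config hash, seed, package
    and numpy versions, output file list."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": seed,
        "evccp_version": _pkg_version,
        "numpy_version": np.__version__,
        "outputs": [str(Path(p).name) for p in outputs],
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
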