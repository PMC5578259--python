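"""File interfaces: structures (PDB/XYZ), sequences (FASTA), traces and
curves (CSV), configuration (YAML/JSON).

Units are fixed at the boundary: structure coordinates come in Angstrom
(both PDB and XYZ conventions) and are converted to nm on read; trace
CSVs use columns ``time_s`` plus ``f{n}_Hz`` / ``D{n}`` per overtone with
an optional events sidecar (``time_s,label``); mobility curves use
``pH,mobility_e-8_m2_Vs``; charge curves use ``pH,Q_e``.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.PDB import PDBParser

from .geometry import CoordinateSet, DensityProfile
from .electrokinetics import MobilityCurve
from .physchem import BufferSolution, default_buffer
from .qcm import QcmTrace
from .titration import ChargeCurve

__all__ = [
    "ELEMENT_MASSES",
    "VDW_RADII",
    "read_structure",
    "read_sequence",
    "read_qcm_trace",
    "write_qcm_trace",
    "read_mobility_curve",
    "write_mobility_curve",
    "read_charge_curve",
    "write_charge_curve",
    "write_density_profile",
    "load_config",
]

ANGSTROM_TO_NM = 0.1

#: Atomic masses [amu] for the elements common in proteins.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38,
}
#: Van der Waals radii [nm] (Bondi set) used for SASA.
VDW_RADII: dict[str, float] = {
    "H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152,
    "S": 0.180, "P": 0.180, "SE": 0.190, "FE": 0.200, "ZN": 0.139,
}
DEFAULT_MASS = 12.011
DEFAULT_RADIUS = 0.170
_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


def _element_props(element: str, context: str) -> tuple[float, float]:
    el = element.strip().upper()
    if el not in ELEMENT_MASSES:
        warnings.warn(
            f"unknown element {element!r} in {context}; using carbon-like defaults",
            stacklevel=3,
        )
        return DEFAULT_MASS, DEFAULT_RADIUS
    return ELEMENT_MASSES[el], VDW_RADII[el]


def _read_pdb(path: Path) -> list[CoordinateSet]:
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Biopython raises assorted types on bad records
        raise ValueError(f"malformed PDB file {path}: {exc}") from exc
    models = []
    for model in structure:
        pos, masses, radii, flags = [], [], [], []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    if atom.get_altloc() not in (" ", "A"):
                        continue  # keep the first alternate location only
                    m, r = _element_props(atom.element or "", f"{path}:{atom.get_full_id()}")
                    pos.append(atom.coord * ANGSTROM_TO_NM)
                    masses.append(m)
                    radii.append(r)
                    flags.append(atom.get_name() in _BACKBONE_NAMES)
        if not pos:
            continue
        models.append(
            CoordinateSet(
                positions=np.array(pos),
                masses=np.array(masses),
                radii=np.array(radii),
                backbone_flags=np.array(flags),
                label=f"{path.stem}/model{model.id}",
            )
        )
    if not models:
        raise ValueError(f"no atoms found in {path}")
    return models


def _read_xyz(path: Path) -> list[CoordinateSet]:
    lines = Path(path).read_text().splitlines()
    frames: list[CoordinateSet] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise ValueError(
                f"{path}:{i + 1}: expected an atom count, got {lines[i]!r}"
            ) from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}:{i + 1}: frame declares {n} atoms, file ends early")
        pos, masses, radii = [], [], []
        for j, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{i + 3 + j}: need 'element x y z'")
            try:
                xyz = [float(p) for p in parts[1:4]]
            except ValueError as exc:
                raise ValueError(f"{path}:{i + 3 + j}: bad coordinate in {line!r}") from exc
            m, r = _element_props(parts[0], f"{path}:{i + 3 + j}")
            pos.append(xyz)
            masses.append(m)
            radii.append(r)
        frames.append(
            CoordinateSet(
                positions=np.array(pos) * ANGSTROM_TO_NM,
                masses=np.array(masses),
                radii=np.array(radii),
                label=comment.strip() or path.stem,
            )
        )
        i += 2 + n
    if not frames:
        raise ValueError(f"no frames found in {path}")
    return frames


def read_structure(
    path: str | Path, fmt: str | None = None
) -> CoordinateSet | list[CoordinateSet]:
    """Read a PDB or XYZ structure; coordinates converted Angstrom -> nm.

    Returns a single CoordinateSet for a one-model file, a list for a
    multi-model PDB or multi-frame XYZ.  Masses and SASA radii are
    attached from the bundled element tables (unknown elements warn and
    fall back to carbon-like values).
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "pdb":
        frames = _read_pdb(path)
    elif fmt == "xyz":
        frames = _read_xyz(path)
    else:
        raise ValueError(f"unsupported structure format {fmt!r} (use pdb or xyz)")
    return frames[0] if len(frames) == 1 else frames


def write_xyz(coords: CoordinateSet, path: str | Path, comment: str = "") -> None:
    """Write a coordinate set as XYZ (Angstrom), all atoms as carbon."""
    with open(path, "w") as fh:
        fh.write(f"{len(coords)}\n{comment or coords.label}\n")
        for x, y, z in coords.positions / ANGSTROM_TO_NM:
            fh.write(f"C {x:.6f} {y:.6f} {z:.6f}\n")


def read_sequence(path: str | Path) -> str:
    """First sequence of a FASTA file as a one-letter string."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return str(records[0].seq)


def read_qcm_trace(path: str | Path, events_path: str | Path | None = None) -> QcmTrace:
    """Trace CSV with columns time_s, f{n}_Hz, D{n}; optional events sidecar."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required column 'time_s'")
    overtones = sorted(
        int(c[1:-3]) for c in df.columns if c.startswith("f") and c.endswith("_Hz")
    )
    if not overtones:
        raise ValueError(f"{path}: no overtone columns (f{{n}}_Hz) found")
    delta_f = {n: df[f"f{n}_Hz"].to_numpy() for n in overtones}
    delta_D = {
        n: (df[f"D{n}"].to_numpy() if f"D{n}" in df.columns else np.zeros(len(df)))
        for n in overtones
    }
    events: tuple[tuple[float, str], ...] = ()
    if events_path is not None:
        ev = pd.read_csv(events_path)
        events = tuple((float(r.time_s), str(r.label)) for r in ev.itertuples())
    return QcmTrace(
        time=df["time_s"].to_numpy(), delta_f=delta_f, delta_D=delta_D, events=events
    )


def write_qcm_trace(trace: QcmTrace, path: str | Path,
                    events_path: str | Path | None = None) -> None:
    cols = {"time_s": trace.time}
    for n in trace.overtones:
        cols[f"f{n}_Hz"] = trace.delta_f[n]
        cols[f"D{n}"] = trace.delta_D[n]
    pd.DataFrame(cols).to_csv(path, index=False)
    if events_path is not None and trace.events:
        pd.DataFrame(trace.events, columns=["time_s", "label"]).to_csv(
            events_path, index=False
        )


def read_mobility_curve(
    path: str | Path, buffers: Sequence[BufferSolution] | None = None
) -> MobilityCurve:
    """Mobility CSV (pH, mobility_e-8_m2_Vs); default buffers attached per pH."""
    df = pd.read_csv(path)
    needed = {"pH", "mobility_e-8_m2_Vs"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(needed)}")
    ph = df["pH"].to_numpy(dtype=float)
    if buffers is None:
        buffers = [default_buffer(float(p)) for p in ph]
    return MobilityCurve(
        pH=ph,
        mobility=df["mobility_e-8_m2_Vs"].to_numpy(dtype=float),
        buffers=tuple(buffers),
    )


def write_mobility_curve(curve: MobilityCurve, path: str | Path) -> None:
    pd.DataFrame({"pH": curve.pH, "mobility_e-8_m2_Vs": curve.mobility}).to_csv(
        path, index=False
    )


def read_charge_curve(path: str | Path) -> ChargeCurve:
    """Charge-curve CSV (pH, Q_e); pI interpolated from the sign change."""
    df = pd.read_csv(path)
    if not {"pH", "Q_e"}.issubset(df.columns):
        raise ValueError(f"{path}: need columns ['pH', 'Q_e']")
    ph = df["pH"].to_numpy(dtype=float)
    q = df["Q_e"].to_numpy(dtype=float)
    pi = None
    for i in range(len(ph) - 1):
        if q[i] == 0.0:
            pi = float(ph[i])
            break
        if q[i] * q[i + 1] < 0:
            pi = float(ph[i] - q[i] * (ph[i + 1] - ph[i]) / (q[i + 1] - q[i]))
            break
    return ChargeCurve(pH_grid=ph, net_charge=q, pI=pi)


def write_charge_curve(curve: ChargeCurve, path: str | Path) -> None:
    pd.DataFrame({"pH": curve.pH_grid, "Q_e": curve.net_charge}).to_csv(
        path, index=False
    )


def write_density_profile(profile: DensityProfile, path: str | Path) -> None:
    centers = 0.5 * (profile.bin_edges[:-1] + profile.bin_edges[1:])
    pd.DataFrame(
        {"distance_nm": centers, "probability": profile.probability}
    ).to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration and check referenced files exist."""
    path = Path(path)
    text = path.read_text()
    config = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(config, dict) or not config:
        raise ValueError(f"{path}: empty or non-mapping configuration")
    base = path.parent
    for key in ("structure", "trace", "events", "charge_curve", "mobility"):
        for section in config.values():
            if isinstance(section, dict) and key in section:
                ref = base / section[key]
                if not ref.exists():
                    raise FileNotFoundError(f"{path}: referenced file missing: {ref}")
                section[key] = str(ref)
    return config
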