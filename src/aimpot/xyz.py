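"""Multi-frame XYZ / extended-XYZ reading and writing.

The extended dialect carries per-frame ``energy=``, ``charge=``,
``dipole="x y z"``, ``quadrupole="..."``, ``Lattice="ax 0 0 0 by 0 0 0 cz"``
and a ``Properties=`` column declaration (species, positions and optional
per-atom forces/charges).  Units are Å / eV / e.  Roundtrips are lossless
to well below 1e-8 (values are written with repr-level precision).
"""

from __future__ import annotations

import re

import numpy as np

from .system import Dataset, LabeledSample, MolecularSystem, UnsupportedElementError
from .units import SYMBOLS, Z_FROM_SYMBOL

_FMT = "%.12g"


class XYZParseError(ValueError):
    pass


def _parse_comment(line: str) -> dict:
    """key=value pairs; values may be double-quoted strings."""
    out = {}
    for m in re.finditer(r'(\S+?)=(?:"([^"]*)"|(\S+))', line):
        key = m.group(1)
        out[key] = m.group(2) if m.group(2) is not None else m.group(3)
    return out


def _parse_properties(spec: str):
    """'species:S:1:pos:R:3:forces:R:3:...' -> [(name, kind, ncols), ...]"""
    toks = spec.split(":")
    if len(toks) % 3 != 0:
        raise XYZParseError(f"malformed Properties spec: {spec}")
    return [(toks[i], toks[i + 1], int(toks[i + 2]))
            for i in range(0, len(toks), 3)]


def read_xyz(path, dialect: str = "extended"):
    """Read a (multi-frame) XYZ file.

    Returns a list of :class:`LabeledSample` for frames carrying energy,
    forces and charges, otherwise a list of :class:`MolecularSystem`.
    Unknown per-frame keys are preserved in sample metadata.
    """
    records = []
    with open(path) as fh:
        lines = fh.readlines()
    pos = 0
    nline = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            nline += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError:
            raise XYZParseError(
                f"line {pos + 1}: expected atom count, got {lines[pos]!r}")
        if pos + 1 + natoms >= len(lines) + 1 and natoms > 0:
            pass
        comment = lines[pos + 1].rstrip("\n") if pos + 1 < len(lines) else ""
        info = _parse_comment(comment) if dialect == "extended" else {}
        props = _parse_properties(info["Properties"]) if "Properties" in info \
            else [("species", "S", 1), ("pos", "R", 3)]
        body = lines[pos + 2: pos + 2 + natoms]
        if len(body) != natoms:
            raise XYZParseError(
                f"line {pos + 1}: frame declares {natoms} atoms, "
                f"file ends after {len(body)}")
        symbols, columns = [], {name: [] for name, _, _ in props}
        for k, ln in enumerate(body):
            toks = ln.split()
            want = sum(nc for _, _, nc in props)
            if len(toks) < want:
                raise XYZParseError(
                    f"line {pos + 3 + k}: expected {want} columns, "
                    f"got {len(toks)}")
            c = 0
            for name, kind, ncols in props:
                vals = toks[c:c + ncols]
                c += ncols
                if kind == "S":
                    columns[name].append(vals[0])
                else:
                    columns[name].append([float(v) for v in vals])
        symbols = columns.pop("species")
        try:
            z = np.array([Z_FROM_SYMBOL[s] for s in symbols])
        except KeyError as e:
            raise UnsupportedElementError(
                f"unsupported element symbol {e.args[0]!r} at frame "
                f"starting line {pos + 1}")
        coords = np.array(columns.pop("pos"))
        cell = pbc = None
        if "Lattice" in info:
            lat = np.array([float(v) for v in info["Lattice"].split()])
            lat = lat.reshape(3, 3)
            if np.abs(lat - np.diag(np.diag(lat))).max() > 1e-10:
                raise XYZParseError("only orthorhombic lattices are supported")
            cell = np.diag(lat).copy()
            pbc = np.array([t in ("T", "1", "True") for t in
                            info.get("pbc", "T T T").split()])
        charge = int(float(info.get("charge", 0)))
        bonds = None
        if "bonds" in info and info["bonds"]:
            b = np.array([int(v) for v in info["bonds"].split()])
            bonds = b.reshape(-1, 2) if b.size else None
        system = MolecularSystem(coords=coords, atomic_numbers=z,
                                 charge=charge, cell=cell, pbc=pbc,
                                 bonds=bonds)
        known = {"Properties", "Lattice", "pbc", "charge", "energy",
                 "dipole", "quadrupole", "bonds"}
        extra = {k: v for k, v in info.items() if k not in known}
        if "energy" in info and "forces" in columns and "charges" in columns:
            quad = None
            if "quadrupole" in info:
                quad = np.array([float(v) for v in
                                 info["quadrupole"].split()]).reshape(3, 3)
            dip = None
            if "dipole" in info:
                dip = np.array([float(v) for v in info["dipole"].split()])
            records.append(LabeledSample(
                system=system,
                energy=float(info["energy"]),
                forces=np.array(columns["forces"]),
                charges=np.array(columns["charges"]).reshape(-1),
                dipole=dip, quadrupole=quad, metadata=extra))
        else:
            records.append(system)
        pos += 2 + natoms
    return records


def _fmt_arr(a) -> str:
    return " ".join(_FMT % v for v in np.asarray(a).ravel())


def write_xyz(records, path, dialect: str = "extended"):
    """Write systems or labeled samples as (extended) XYZ frames."""
    if isinstance(records, Dataset):
        records = records.samples
    if isinstance(records, (MolecularSystem, LabeledSample)):
        records = [records]
    records = list(records)
    if not records:
        raise ValueError("nothing to write: empty record list")
    out = []
    for rec in records:
        system = rec.system if isinstance(rec, LabeledSample) else rec
        labeled = isinstance(rec, LabeledSample) and dialect == "extended"
        n = system.n_atoms
        cols = [("species", "S", 1), ("pos", "R", 3)]
        if labeled:
            cols += [("forces", "R", 3), ("charges", "R", 1)]
        fields = []
        if dialect == "extended":
            fields.append("Properties=" + ":".join(
                f"{nm}:{kd}:{nc}" for nm, kd, nc in cols))
            if system.cell is not None:
                lat = np.diag(system.cell).ravel()
                fields.append(f'Lattice="{_fmt_arr(lat)}"')
                fields.append('pbc="' + " ".join(
                    "T" if b else "F" for b in system.pbc) + '"')
            fields.append(f"charge={system.charge}")
            if system.bonds is not None:
                fields.append(f'bonds="{" ".join(map(str, system.bonds.ravel()))}"')
            if labeled:
                fields.append(f"energy={_FMT % rec.energy}")
                if rec.dipole is not None:
                    fields.append(f'dipole="{_fmt_arr(rec.dipole)}"')
                if rec.quadrupole is not None:
                    fields.append(f'quadrupole="{_fmt_arr(rec.quadrupole)}"')
                for k, v in rec.metadata.items():
                    fields.append(f'{k}="{v}"')
        out.append(f"{n}\n{' '.join(fields)}\n")
        for i in range(n):
            row = [SYMBOLS[int(system.atomic_numbers[i])],
                   _FMT % system.coords[i, 0], _FMT % system.coords[i, 1],
                   _FMT % system.coords[i, 2]]
            if labeled:
                row += [_FMT % v for v in rec.forces[i]]
                row += [_FMT % rec.charges[i]]
            out.append(" ".join(row) + "\n")
    with open(path, "w") as fh:
        fh.writelines(out)
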