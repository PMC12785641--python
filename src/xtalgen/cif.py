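"""Minimal CIF output (and re-reading) for generated structures.

Writes a single data block with cell parameters, symmetry operator
strings, and a fractional-coordinate atom loop with isotropic U values.
The reader understands exactly this subset — enough for round-tripping
and for downstream tools that consume standard CIF.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import DomainError
from .oblique import CellParameters, vectors_from_parameters
from .placement import Atom, CrystalStructure
from .symmetry import SPECIAL, SiteKind, p1_group, p1bar_group

__all__ = ["write_cif", "read_cif", "cif_text"]


def cif_text(structure: CrystalStructure, name: str = "xtalgen") -> str:
    p = structure.parameters
    vol = structure.volume
    lines = [
        f"data_{name}",
        f"_cell_length_a     {p.a:.6f}",
        f"_cell_length_b     {p.b:.6f}",
        f"_cell_length_c     {p.c:.6f}",
        f"_cell_angle_alpha  {p.alpha:.6f}",
        f"_cell_angle_beta   {p.beta:.6f}",
        f"_cell_angle_gamma  {p.gamma:.6f}",
        f"_cell_volume       {vol:.6f}",
        f"_space_group_name_H-M_alt  '{structure.group.name}'",
        "loop_",
        "_space_group_symop_operation_xyz",
    ]
    lines += [f"  '{op}'" for op in structure.group.operator_strings()]
    lines += [
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
        "_atom_site_U_iso_or_equiv",
    ]
    for i, atom in enumerate(structure.atoms, start=1):
        x, y, z = atom.frac
        lines.append(
            f"{atom.element}{i} {atom.element} {x:.6f} {y:.6f} {z:.6f} {atom.u_iso:.6f}"
        )
    return "\n".join(lines) + "\n"


def write_cif(structure: CrystalStructure, destination) -> None:
    Path(destination).write_text(cif_text(structure))


def _parse_loop(lines: list[str], start: int) -> tuple[list[str], list[list[str]], int]:
    headers: list[str] = []
    i = start + 1
    while i < len(lines) and lines[i].strip().startswith("_"):
        headers.append(lines[i].strip())
        i += 1
    rows: list[list[str]] = []
    while i < len(lines):
        stripped = lines[i].strip()
        if not stripped or stripped.startswith(("_", "loop_", "data_")):
            break
        if stripped.startswith("'") and stripped.endswith("'"):
            rows.append([stripped.strip("'")])
        else:
            rows.append(stripped.split())
        i += 1
    return headers, rows, i


def read_cif(source) -> CrystalStructure:
    """Parse a CIF produced by :func:`write_cif` back into a structure."""
    text = Path(source).read_text() if not str(source).lstrip().startswith("data_") else str(source)
    lines = text.splitlines()
    scalars: dict[str, str] = {}
    loops: list[tuple[list[str], list[list[str]]]] = []
    i = 0
    while i < len(lines):
        stripped = lines[i].strip()
        if stripped.startswith("loop_"):
            headers, rows, i = _parse_loop(lines, i)
            loops.append((headers, rows))
            continue
        if stripped.startswith("_"):
            key, _, value = stripped.partition(" ")
            scalars[key] = value.strip().strip("'")
        i += 1

    try:
        params = CellParameters(
            *(float(scalars[f"_cell_length_{x}"]) for x in "abc"),
            *(float(scalars[f"_cell_angle_{x}"]) for x in ("alpha", "beta", "gamma")),
        )
    except KeyError as exc:
        raise DomainError(f"CIF missing cell item {exc}")
    name = scalars.get("_space_group_name_H-M_alt", "P1")
    n_ops = 1
    for headers, rows in loops:
        if "_space_group_symop_operation_xyz" in headers:
            n_ops = len(rows)
    group = p1bar_group() if (name == "P-1" or n_ops == 2) else p1_group()

    atoms: list[Atom] = []
    for headers, rows in loops:
        if "_atom_site_fract_x" not in headers:
            continue
        col = {h: j for j, h in enumerate(headers)}
        for row in rows:
            frac = np.array(
                [float(row[col[f"_atom_site_fract_{x}"]]) for x in "xyz"]
            )
            special = all(
                abs(((2 * c) % 1.0 + 0.5) % 1.0 - 0.5) < 1e-6 for c in frac
            ) and group.name == "P-1"
            atoms.append(
                Atom(
                    element=row[col["_atom_site_type_symbol"]],
                    frac=frac,
                    u_iso=float(row[col.get("_atom_site_U_iso_or_equiv", -1)])
                    if "_atom_site_U_iso_or_equiv" in col
                    else 0.03,
                    site=SiteKind(SPECIAL, None) if special else SiteKind(),
                )
            )
    return CrystalStructure(
        parameters=params,
        vectors=vectors_from_parameters(params),
        group=group,
        atoms=atoms,
    )
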