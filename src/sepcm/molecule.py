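"""Molecular structure container and XYZ/PDB input.

Coordinates are stored in bohr internally; all file formats use angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .units import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM, MASSES


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class Molecule:
    symbols: tuple
    coords: np.ndarray  # (N, 3) bohr
    charge: int = 0
    multiplicity: int = 1
    comment: str = ""

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float).reshape(len(self.symbols), 3)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "symbols", tuple(self.symbols))
        if self.multiplicity != 1:
            raise GeometryError("only restricted closed-shell (singlet) molecules are supported")

    @property
    def natoms(self) -> int:
        return len(self.symbols)

    @property
    def masses(self) -> np.ndarray:
        return np.array([MASSES[s] for s in self.symbols])

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        return replace(self, coords=np.asarray(coords, dtype=float).reshape(self.natoms, 3))

    def distance_matrix(self) -> np.ndarray:
        d = self.coords[:, None, :] - self.coords[None, :, :]
        return np.linalg.norm(d, axis=-1)

    @classmethod
    def from_xyz_string(cls, text: str) -> "Molecule":
        lines = text.strip().splitlines()
        n = int(lines[0].split()[0])
        comment = lines[1] if len(lines) > 1 else ""
        charge = 0
        for tok in comment.replace(",", " ").split():
            if tok.lower().startswith("charge="):
                charge = int(tok.split("=", 1)[1])
        symbols, coords = [], []
        for line in lines[2 : 2 + n]:
            parts = line.split()
            symbols.append(parts[0].capitalize())
            coords.append([float(x) for x in parts[1:4]])
        return cls(
            symbols=tuple(symbols),
            coords=np.array(coords) * ANGSTROM_TO_BOHR,
            charge=charge,
            comment=comment,
        )

    @classmethod
    def from_xyz(cls, path) -> "Molecule":
        with open(path) as fh:
            return cls.from_xyz_string(fh.read())

    def to_xyz_string(self, comment: str | None = None) -> str:
        if comment is None:
            comment = f"charge={self.charge}"
            if self.comment and "charge=" not in self.comment:
                comment = f"{self.comment} charge={self.charge}"
        out = [str(self.natoms), comment]
        for s, xyz in zip(self.symbols, self.coords * BOHR_TO_ANGSTROM):
            out.append(f"{s:2s} {xyz[0]:18.10f} {xyz[1]:18.10f} {xyz[2]:18.10f}")
        return "\n".join(out) + "\n"

    def to_xyz(self, path, comment: str | None = None) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_xyz_string(comment))

    @classmethod
    def from_pdb(cls, path, charge: int = 0) -> "Molecule":
        """Minimal PDB reader: ATOM/HETATM coordinates and element column only."""
        symbols, coords = [], []
        with open(path) as fh:
            for line in fh:
                if not line.startswith(("ATOM", "HETATM")):
                    continue
                elem = line[76:78].strip() or line[12:16].strip()[0]
                symbols.append(elem.capitalize())
                coords.append(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
        return cls(
            symbols=tuple(symbols),
            coords=np.array(coords) * ANGSTROM_TO_BOHR,
            charge=charge,
        )


def write_trajectory(path, frames, comments=None) -> None:
    """Write a multi-frame XYZ trajectory."""
    with open(path, "w") as fh:
        for i, mol in enumerate(frames):
            c = comments[i] if comments is not None else None
            fh.write(mol.to_xyz_string(c))
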