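"""Cartesian geometries and XYZ file input/output."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .constants import ATOMIC_NUMBERS


class ElementError(ValueError):
    """Raised when a geometry contains an unsupported element."""


class GeometryError(ValueError):
    """Raised for physically invalid geometries (overlapping atoms etc.)."""


@dataclass(frozen=True)
class Geometry:
    """A single molecular structure: element symbols plus coordinates in Angstrom."""

    symbols: tuple[str, ...]
    coords: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbols", tuple(self.symbols))
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise GeometryError(f"coords must be n x 3, got shape {coords.shape}")
        if len(self.symbols) != coords.shape[0]:
            raise GeometryError(
                f"{len(self.symbols)} symbols but {coords.shape[0]} coordinate rows"
            )
        if len(self.symbols) == 0:
            raise GeometryError("geometry must contain at least one atom")
        for s in self.symbols:
            if s not in ATOMIC_NUMBERS:
                raise ElementError(f"unsupported element {s!r} (supported: H, C, N, O)")
        if not np.all(np.isfinite(coords)):
            raise GeometryError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([ATOMIC_NUMBERS[s] for s in self.symbols], dtype=int)

    def distance_matrix(self) -> np.ndarray:
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    def permuted(self, order: Iterable[int]) -> "Geometry":
        order = list(order)
        return Geometry(tuple(self.symbols[i] for i in order), self.coords[order])


def write_xyz(path: str | Path, geometries: Iterable[Geometry], comments: Iterable[str] | None = None) -> None:
    """Write one or more geometries as a standard multi-record XYZ file."""
    geometries = list(geometries)
    comments = list(comments) if comments is not None else [""] * len(geometries)
    lines: list[str] = []
    for geom, comment in zip(geometries, comments):
        lines.append(str(geom.n_atoms))
        lines.append(comment)
        for sym, (x, y, z) in zip(geom.symbols, geom.coords):
            lines.append(f"{sym} {x:.8f} {y:.8f} {z:.8f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path: str | Path) -> list[Geometry]:
    """Read a (possibly multi-record) XYZ file."""
    return list(iter_xyz(path))


def iter_xyz(path: str | Path) -> Iterator[Geometry]:
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise GeometryError(f"truncated XYZ record at line {i + 1}")
        symbols = []
        coords = []
        for line in block:
            parts = line.split()
            symbols.append(parts[0])
            coords.append([float(p) for p in parts[1:4]])
        yield Geometry(tuple(symbols), np.array(coords))
        i += 2 + n
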