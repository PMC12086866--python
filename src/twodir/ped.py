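"""Harmonic normal-mode analysis and potential energy distribution (PED).

Given a geometry, a Cartesian Hessian and a set of internal coordinates
(bond stretches, angle bends), this module

1. diagonalizes the mass-weighted Hessian after Eckart projection of rigid
   translations/rotations -> harmonic frequencies and normal modes;
2. builds the Wilson B matrix for the internal set, transforms the Cartesian
   Hessian to an internal force-constant matrix F via the generalized
   inverse, and reports the diagonal-convention PED

       PED(k, mode) = F_kk * L_k^2 / sum_k' F_k'k' * L_k'^2

   with L_k the internal displacement of the mode along coordinate k.

The diagonal convention ignores off-diagonal internal force constants in the
numerator; it is the dominant community convention and keeps fractions
interpretable on [0, 1], at the price of row sums deviating from 1 for
strongly coupled coordinate pairs (flagged, not hidden).  PED here is
harmonic-only: the quantity localizes a *normal mode* on bond coordinates,
which is exactly the localization measure the anharmonicity analysis is
correlated against.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import constants

__all__ = [
    "MolecularSystem",
    "InternalCoordinate",
    "InternalCoordinateSet",
    "PEDTable",
    "normal_modes",
    "wilson_b_matrix",
    "ped_table",
    "read_xyz",
    "write_xyz",
    "read_hessian",
    "write_hessian",
    "atomic_mass",
    "WAVENUMBER_FACTOR",
]

_HESSIAN_UNITS = ("hartree/bohr^2", "mdyn/angstrom")

# conversion of sqrt(eigenvalue) to cm^-1 for Hessian in hartree/bohr^2, mass in u
_HARTREE = constants.physical_constants["Hartree energy"][0]
_BOHR = constants.physical_constants["Bohr radius"][0]
_U = constants.physical_constants["atomic mass constant"][0]
_C_CM = constants.c * 100.0
WAVENUMBER_FACTOR = {
    "hartree/bohr^2": np.sqrt(_HARTREE / (_BOHR**2 * _U)) / (2.0 * np.pi * _C_CM),
    # 1 mdyn/A = 100 N/m
    "mdyn/angstrom": np.sqrt(100.0 / _U) / (2.0 * np.pi * _C_CM),
}
_BOHR_PER_ANGSTROM = 1e-10 / _BOHR


def atomic_mass(symbol: str) -> float:
    """Standard atomic weight in unified atomic mass units."""
    from rdkit.Chem import GetPeriodicTable

    pt = GetPeriodicTable()
    mass = pt.GetAtomicWeight(symbol.capitalize())
    if mass <= 0:
        raise ValueError(f"unknown element symbol {symbol!r}")
    return float(mass)


@dataclass
class MolecularSystem:
    """Geometry (angstrom) + masses (u) + Cartesian Hessian.

    ``hessian_units`` declares the Hessian convention — either the native
    quantum-chemistry ``hartree/bohr^2`` or ``mdyn/angstrom``; there is no
    autodetection.  The Hessian must be symmetric to 1e-8 of its own norm.
    """

    symbols: list[str]
    coords: np.ndarray
    hessian: np.ndarray
    masses: np.ndarray | None = None
    hessian_units: str = "hartree/bohr^2"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.hessian = np.asarray(self.hessian, dtype=float)
        n = len(self.symbols)
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if self.hessian.shape != (3 * n, 3 * n):
            raise ValueError(
                f"hessian shape {self.hessian.shape} != ({3 * n}, {3 * n})"
            )
        if self.hessian_units not in _HESSIAN_UNITS:
            raise ValueError(
                f"hessian_units must be one of {_HESSIAN_UNITS}, "
                f"got {self.hessian_units!r}"
            )
        norm = np.linalg.norm(self.hessian)
        if norm > 0 and np.linalg.norm(self.hessian - self.hessian.T) > 1e-8 * norm:
            raise ValueError("Cartesian Hessian is not symmetric within tolerance")
        if self.masses is None:
            self.masses = np.array([atomic_mass(s) for s in self.symbols])
        else:
            self.masses = np.asarray(self.masses, dtype=float)
            if self.masses.shape != (n,):
                raise ValueError("need one mass per atom")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class InternalCoordinate:
    """A stretch (2 atoms) or bend (3 atoms, central atom second)."""

    kind: str
    atoms: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("stretch", "bend"):
            raise ValueError(f"kind must be 'stretch' or 'bend', got {self.kind!r}")
        want = 2 if self.kind == "stretch" else 3
        if len(self.atoms) != want:
            raise ValueError(f"{self.kind} needs {want} atom indices, got {self.atoms}")
        if len(set(self.atoms)) != len(self.atoms):
            raise ValueError(f"atom indices must be distinct: {self.atoms}")
        if not self.label:
            object.__setattr__(
                self, "label", self.kind[0] + "-".join(str(a) for a in self.atoms)
            )


class InternalCoordinateSet:
    def __init__(self, coordinates: Sequence[InternalCoordinate]) -> None:
        coords = list(coordinates)
        if not coords:
            raise ValueError("need at least one internal coordinate")
        labels = [c.label for c in coords]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate coordinate labels: {labels}")
        self.coordinates = coords

    def __len__(self) -> int:
        return len(self.coordinates)

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.coordinates]

    def validate(self, n_atoms: int) -> None:
        for c in self.coordinates:
            if any(not 0 <= a < n_atoms for a in c.atoms):
                raise ValueError(
                    f"coordinate {c.label} references atom outside 0..{n_atoms - 1}"
                )

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("kind\tatoms\tlabel\n")
            for c in self.coordinates:
                fh.write(f"{c.kind}\t{','.join(map(str, c.atoms))}\t{c.label}\n")

    @classmethod
    def from_tsv(cls, path) -> "InternalCoordinateSet":
        df = pd.read_csv(path, sep="\t")
        coords = [
            InternalCoordinate(
                str(r.kind),
                tuple(int(a) for a in str(r.atoms).split(",")),
                str(r.label),
            )
            for r in df.itertuples()
        ]
        return cls(coords)


@dataclass
class PEDTable:
    """Modes (ascending frequency) x internal coordinates fraction matrix."""

    frequencies: np.ndarray
    fractions: np.ndarray
    coordinate_labels: list[str]
    row_sum_ok: np.ndarray | None = None

    _OVERSHOOT = 0.05

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (self.frequencies.size, len(self.coordinate_labels)):
            raise ValueError("PED matrix shape mismatch")
        if np.any(self.fractions < -1e-12) or np.any(
            self.fractions > 1.0 + self._OVERSHOOT
        ):
            raise ValueError(
                "PED fractions outside [0, 1.05]; check coordinate set and units"
            )
        if self.row_sum_ok is None:
            sums = self.fractions.sum(axis=1)
            self.row_sum_ok = np.abs(sums - 1.0) <= self._OVERSHOOT

    def fraction(self, mode_index: int, label: str) -> float:
        return float(self.fractions[mode_index, self.coordinate_labels.index(label)])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.fractions, columns=self.coordinate_labels)
        df.insert(0, "freq_cm1", self.frequencies)
        df["row_sum_ok"] = self.row_sum_ok
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# normal-mode analysis


def _eckart_projector(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Projector removing mass-weighted rigid translations and rotations."""
    n = coords.shape[0]
    sq = np.sqrt(masses)
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    x = coords - com
    vecs = []
    for axis in range(3):
        t = np.zeros((n, 3))
        t[:, axis] = sq
        vecs.append(t.ravel())
    for axis in range(3):
        e = np.zeros(3)
        e[axis] = 1.0
        r = np.cross(x, e) * sq[:, None]
        vecs.append(r.ravel())
    V = np.array(vecs).T  # (3n, 6)
    # orthonormalize, dropping null rotations of linear molecules
    q, r = np.linalg.qr(V)
    keep = np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return np.eye(3 * n) - q @ q.T


def normal_modes(system: MolecularSystem) -> tuple[np.ndarray, np.ndarray]:
    """Harmonic frequencies (cm^-1, ascending) and mass-weighted eigenvectors.

    Translations/rotations are projected out (Eckart-style) before
    diagonalization; only the remaining 3N-6 (3N-5 for linear molecules)
    vibrations are returned.  Imaginary frequencies come back as negative
    numbers.  Eigenvector columns are orthonormal in the mass-weighted space.
    """
    n = system.n_atoms
    sq = np.sqrt(system.masses)
    inv_sq = 1.0 / np.repeat(sq, 3)
    H = system.hessian
    if system.hessian_units == "hartree/bohr^2":
        # geometry enters only via the projector; Hessian already per bohr^2
        pass
    Hmw = H * np.outer(inv_sq, inv_sq)
    P = _eckart_projector(system.coords, system.masses)
    Hproj = P @ Hmw @ P
    lam, vecs = np.linalg.eigh(Hproj)
    n_rigid = 3 * n - int(round(np.trace(P)))
    # drop the n_rigid eigenvalues closest to zero (the projected-out space)
    idx_by_mag = np.argsort(np.abs(lam), kind="stable")
    rigid = set(idx_by_mag[:n_rigid].tolist())
    keep = [k for k in range(3 * n) if k not in rigid]
    lam = lam[keep]
    vecs = vecs[:, keep]
    factor = WAVENUMBER_FACTOR[system.hessian_units]
    freqs = np.sign(lam) * np.sqrt(np.abs(lam)) * factor
    order = np.argsort(freqs, kind="stable")
    return freqs[order], vecs[:, order]


# ---------------------------------------------------------------------------
# Wilson B matrix and PED


def _stretch_row(coords: np.ndarray, a: int, b: int) -> np.ndarray:
    n = coords.shape[0]
    row = np.zeros((n, 3))
    d = coords[a] - coords[b]
    r = np.linalg.norm(d)
    if r < 1e-10:
        raise ValueError(f"coincident atoms {a}, {b} in stretch coordinate")
    e = d / r
    row[a] = e
    row[b] = -e
    return row.ravel()


def _bend_row(coords: np.ndarray, a: int, b: int, c: int) -> np.ndarray:
    """Valence-angle bend a-b-c with b central (standard Wilson s-vectors)."""
    n = coords.shape[0]
    row = np.zeros((n, 3))
    u = coords[a] - coords[b]
    v = coords[c] - coords[b]
    ru = np.linalg.norm(u)
    rv = np.linalg.norm(v)
    eu, ev = u / ru, v / rv
    cosphi = float(np.clip(eu @ ev, -1.0, 1.0))
    sinphi = np.sqrt(1.0 - cosphi**2)
    if sinphi < 1e-8:
        raise ValueError(f"bend {a}-{b}-{c} is (anti)linear; s-vectors undefined")
    sa = (cosphi * eu - ev) / (ru * sinphi)
    sc = (cosphi * ev - eu) / (rv * sinphi)
    row[a] = sa
    row[c] = sc
    row[b] = -sa - sc
    return row.ravel()


def wilson_b_matrix(
    coords: np.ndarray, internals: InternalCoordinateSet
) -> np.ndarray:
    """B such that delta(internal) = B @ delta(cartesian); shape (m, 3N).

    Coordinates in angstrom give stretch rows in angstrom/angstrom (pure
    direction cosines) and bend rows in rad/angstrom.
    """
    rows = []
    for c in internals.coordinates:
        if c.kind == "stretch":
            rows.append(_stretch_row(coords, *c.atoms))
        else:
            rows.append(_bend_row(coords, *c.atoms))
    return np.array(rows)


def ped_table(
    system: MolecularSystem,
    internals: InternalCoordinateSet,
    mode_selection: Sequence[int] | None = None,
    redundant: bool = False,
) -> PEDTable:
    """Diagonal-convention PED of the normal modes over an internal set.

    The internal force-constant matrix is F_int = A^T H A with
    A = M^-1 B^T (B M^-1 B^T)^-1 (generalized inverse for ``redundant=True``),
    and the internal displacement of mode q is L = B M^-1/2 q.  For a
    complete non-redundant set the PED rows sum to 1 within the tolerance
    recorded in ``row_sum_ok``; a redundant or partial set relaxes this and
    the flags mark affected rows.

    Raises if B is rank-deficient while ``redundant=False`` (naming the
    dependent coordinates is up to the caller's set; the error reports the
    rank defect).
    """
    internals.validate(system.n_atoms)
    coords = system.coords
    B = wilson_b_matrix(coords, internals)
    if system.hessian_units == "hartree/bohr^2":
        # work in bohr so B (dimensionless for stretches) matches the Hessian
        B = wilson_b_matrix(coords * _BOHR_PER_ANGSTROM, internals)
    m = B.shape[0]
    rank = np.linalg.matrix_rank(B, tol=1e-10)
    if rank < m and not redundant:
        raise ValueError(
            f"Wilson B matrix is rank-deficient (rank {rank} < {m} coordinates); "
            "the internal set is redundant — drop dependent coordinates or pass "
            "redundant=True"
        )
    Minv = np.diag(1.0 / np.repeat(system.masses, 3))
    G = B @ Minv @ B.T
    Ginv = np.linalg.pinv(G) if redundant else np.linalg.inv(G)
    A = Minv @ B.T @ Ginv
    F_int = A.T @ system.hessian @ A

    freqs, vecs = normal_modes(system)
    if mode_selection is not None:
        freqs = freqs[list(mode_selection)]
        vecs = vecs[:, list(mode_selection)]
    inv_sq = 1.0 / np.repeat(np.sqrt(system.masses), 3)
    L = B @ (vecs * inv_sq[:, None])  # internal displacements, (m, n_modes)
    fkk = np.diag(F_int)
    num = fkk[:, None] * L**2
    denom = num.sum(axis=0)
    denom[denom == 0] = np.nan
    fractions = (num / denom).T
    return PEDTable(freqs, np.nan_to_num(fractions), internals.labels)


# ---------------------------------------------------------------------------
# file formats


def read_xyz(path) -> tuple[list[str], np.ndarray]:
    """Standard XYZ: atom count, comment, then 'symbol x y z' lines (angstrom)."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValueError(f"{path}: empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as err:
        raise ValueError(f"{path}: first XYZ line must be the atom count") from err
    if len(lines) < n + 2:
        raise ValueError(f"{path}: expected {n} atom lines, file has {len(lines) - 2}")
    symbols, coords = [], []
    for ln in lines[2 : 2 + n]:
        parts = ln.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: malformed XYZ atom line {ln!r}")
        symbols.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return symbols, np.array(coords)


def write_xyz(path, symbols: Sequence[str], coords: np.ndarray, comment: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(symbols)}\n{comment}\n")
        for s, (x, y, z) in zip(symbols, np.asarray(coords)):
            fh.write(f"{s} {x:.10f} {y:.10f} {z:.10f}\n")


def read_hessian(path) -> tuple[np.ndarray, str]:
    """Plain-text lower-triangle Hessian, row-major, one-line unit header.

    Header: ``# units: hartree/bohr^2`` (or ``mdyn/angstrom``); then the
    lower triangle including the diagonal, whitespace-separated, any number
    of values per line.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].lstrip().startswith("#"):
        raise ValueError(f"{path}: first line must be a '# units: ...' header")
    header = lines[0].split(":", 1)
    units = header[1].strip() if len(header) == 2 else ""
    if units not in _HESSIAN_UNITS:
        raise ValueError(
            f"{path}: header declares units {units!r}; expected one of {_HESSIAN_UNITS}"
        )
    vals = [float(x) for ln in lines[1:] for x in ln.split()]
    # lower triangle of a d x d matrix has d(d+1)/2 entries
    d = int((np.sqrt(8 * len(vals) + 1) - 1) / 2)
    if d * (d + 1) // 2 != len(vals):
        raise ValueError(
            f"{path}: {len(vals)} values is not a triangular number — "
            "not a complete lower triangle"
        )
    H = np.zeros((d, d))
    it = iter(vals)
    for i in range(d):
        for j in range(i + 1):
            H[i, j] = H[j, i] = next(it)
    return H, units


def write_hessian(path, hessian: np.ndarray, units: str = "hartree/bohr^2") -> None:
    if units not in _HESSIAN_UNITS:
        raise ValueError(f"units must be one of {_HESSIAN_UNITS}")
    H = np.asarray(hessian)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# units: {units}\n")
        for i in range(H.shape[0]):
            fh.write(" ".join(f"{H[i, j]:.12e}" for j in range(i + 1)) + "\n")
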