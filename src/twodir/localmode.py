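"""Coupled anharmonic local-mode (vibrational exciton) model.

Each CO/CN ligand stretch is a local Morse-like oscillator with ladder
E_i(n) = omega_i * n - chi_i * n * (n + 1), so the uncoupled 1->2 transition
is red-shifted by exactly 2*chi_i from the fundamental.  Bilinear couplings
beta_ij mix the sites.  The Hamiltonian is number-conserving (rotating-wave),
hence exactly block diagonal in total quanta:

one-quantum block (site basis |1_i>):
    H1[i, i] = omega_i - 2 chi_i
    H1[i, j] = beta_ij

two-quantum block (basis |2_i> then |1_i 1_j>, i < j):
    H2[2_i, 2_i]         = 2 omega_i - 6 chi_i
    H2[1_i 1_j, 1_i 1_j] = (omega_i - 2 chi_i) + (omega_j - 2 chi_j)
    <2_i|H|1_i 1_j>      = sqrt(2) beta_ij        (harmonic scaling)
    <1_i 1_j|H|1_i 1_k>  = beta_jk                (shared excitation on i)

Diagonalizing the one-quantum block gives the eigen-fundamentals (the normal
modes of the cluster); diagonalizing the two-quantum block gives overtone
and combination levels.  Eigenstates of the two-quantum block are assigned to
zeroth-order character by maximal squared overlap with *exciton products* —
bosonic two-quantum products of the one-quantum eigenmodes — which is the
anharmonicity-free reference: for chi = 0 the exciton products are exact
eigenstates and every anharmonicity vanishes identically, for beta = 0 they
reduce to the local basis.  Differences between eigen and product energies
are exactly the intramode/intermode anharmonicities a 2D-IR experiment
measures.  Near degeneracy the 2-2 Darling-Dennison mechanism emerges from
the residual coupling between exciton-product states: it pushes the overtone
of the lower eigenmode down and that of the upper one up, making the two
intramode anharmonicities unequal even for identical sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ladder import (
    AnharmonicityMatrix,
    LadderError,
    TransitionTable,
    anharmonicities_from_table,
)

__all__ = [
    "LocalModeModel",
    "EigenLadder",
    "AssignmentError",
    "one_quantum_block",
    "two_quantum_block",
    "exciton_product_basis",
    "solve_ladder",
    "localization",
    "sweep_models",
    "SweepRecord",
]


class AssignmentError(LadderError):
    """Eigenstate-to-zeroth-order assignment is ambiguous."""


@dataclass(frozen=True)
class LocalModeModel:
    """Site frequencies omega_i, local anharmonicities chi_i, couplings beta_ij.

    All in cm^-1.  ``labels`` name the *sites* (local oscillators); the
    emitted :class:`~twodir.ladder.TransitionTable` reuses them for the
    eigenmodes via the dominant-site assignment.
    """

    site_freqs: tuple[float, ...]
    local_anh: tuple[float, ...]
    couplings: tuple[tuple[float, ...], ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.site_freqs)
        object.__setattr__(self, "site_freqs", tuple(float(w) for w in self.site_freqs))
        object.__setattr__(self, "local_anh", tuple(float(c) for c in self.local_anh))
        beta = np.asarray(self.couplings, dtype=float)
        if beta.shape != (n, n):
            raise ValueError(f"coupling matrix shape {beta.shape} != ({n}, {n})")
        if np.max(np.abs(beta - beta.T), initial=0.0) > 1e-9:
            raise ValueError("coupling matrix must be symmetric")
        if np.max(np.abs(np.diag(beta)), initial=0.0) > 0:
            raise ValueError("coupling matrix must have zero diagonal")
        object.__setattr__(self, "couplings", tuple(map(tuple, beta)))
        if len(self.local_anh) != n:
            raise ValueError("need one local anharmonicity per site")
        if any(w <= 0 for w in self.site_freqs):
            raise ValueError("site frequencies must be > 0")
        if any(c < 0 for c in self.local_anh):
            raise ValueError("local anharmonicities must be >= 0")
        if not self.labels:
            object.__setattr__(self, "labels", tuple(f"mode{i}" for i in range(n)))
        elif len(self.labels) != n:
            raise ValueError("need one label per site")

    @property
    def n(self) -> int:
        return len(self.site_freqs)

    @classmethod
    def dimer(
        cls,
        omega: tuple[float, float],
        chi: float | tuple[float, float],
        beta: float,
        labels: tuple[str, str] = ("low", "high"),
    ) -> "LocalModeModel":
        if np.isscalar(chi):
            chi = (float(chi), float(chi))
        return cls(tuple(omega), tuple(chi), ((0.0, beta), (beta, 0.0)), labels)


def _two_quantum_basis(n: int) -> list[tuple[int, int]]:
    """Local basis order: |2_0>..|2_{n-1}>, then |1_i 1_j> for i < j."""
    return [(i, i) for i in range(n)] + [
        (i, j) for i in range(n) for j in range(i + 1, n)
    ]


def one_quantum_block(model: LocalModeModel) -> np.ndarray:
    w = np.asarray(model.site_freqs)
    chi = np.asarray(model.local_anh)
    return np.diag(w - 2.0 * chi) + np.asarray(model.couplings)


def two_quantum_block(model: LocalModeModel) -> np.ndarray:
    n = model.n
    w = np.asarray(model.site_freqs)
    chi = np.asarray(model.local_anh)
    beta = np.asarray(model.couplings)
    basis = _two_quantum_basis(n)
    m = len(basis)
    H = np.zeros((m, m))
    e1 = w - 2.0 * chi
    for a, (i, j) in enumerate(basis):
        H[a, a] = 2.0 * w[i] - 6.0 * chi[i] if i == j else e1[i] + e1[j]
    for a in range(m):
        sa = basis[a]
        for b in range(a + 1, m):
            sb = basis[b]
            # overtone <-> combination sharing the doubly excited site
            if sa[0] == sa[1] and sb[0] != sb[1] and sa[0] in sb:
                other = sb[1] if sb[0] == sa[0] else sb[0]
                H[a, b] = H[b, a] = np.sqrt(2.0) * beta[sa[0], other]
            elif sb[0] == sb[1] and sa[0] != sa[1] and sb[0] in sa:
                other = sa[1] if sa[0] == sb[0] else sa[0]
                H[a, b] = H[b, a] = np.sqrt(2.0) * beta[sb[0], other]
            # combination <-> combination sharing exactly one site
            elif sa[0] != sa[1] and sb[0] != sb[1]:
                shared = set(sa) & set(sb)
                if len(shared) == 1:
                    (p,) = set(sa) - shared
                    (q,) = set(sb) - shared
                    H[a, b] = H[b, a] = beta[p, q]
    return H


def exciton_product_basis(vecs1: np.ndarray) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Two-quantum products of one-quantum eigenmodes, in the local basis.

    Returns an orthogonal matrix T whose columns are the zeroth-order states
    |2_k> (k-th eigenmode doubly excited) and |1_k 1_l> (k < l), expressed in
    the local two-quantum basis of :func:`two_quantum_block`, together with
    the (k, l) pair labels.  With b_k^+ = sum_i v_ik a_i^+:

        |2_k>     = sum_i v_ik^2 |2_i>  +  sum_{i<j} sqrt(2) v_ik v_jk |1_i 1_j>
        |1_k 1_l> = sum_i sqrt(2) v_ik v_il |2_i>
                    + sum_{i<j} (v_ik v_jl + v_jk v_il) |1_i 1_j>
    """
    n = vecs1.shape[0]
    basis = _two_quantum_basis(n)
    pairs = _two_quantum_basis(n)  # same ordering convention for exciton pairs
    T = np.zeros((len(basis), len(pairs)))
    for col, (k, l) in enumerate(pairs):
        for row, (i, j) in enumerate(basis):
            if k == l:
                T[row, col] = (
                    vecs1[i, k] ** 2
                    if i == j
                    else np.sqrt(2.0) * vecs1[i, k] * vecs1[j, k]
                )
            else:
                T[row, col] = (
                    np.sqrt(2.0) * vecs1[i, k] * vecs1[i, l]
                    if i == j
                    else vecs1[i, k] * vecs1[j, l] + vecs1[j, k] * vecs1[i, l]
                )
    return T, pairs


_TIE_TOL = 1e-6


def _assign(weights: np.ndarray, order: Sequence[int], what: str) -> dict[int, int]:
    """Assign eigenstates (columns) to zeroth-order states (rows), bijectively.

    Eigenstates are processed in ``order`` (ascending energy); each takes the
    still-unclaimed zeroth-order state of maximal weight.  If an eigenstate's
    globally dominant character is already claimed by a *strictly* larger
    margin than the tie tolerance, the assignment is genuinely ambiguous and
    an error asks for a symmetry-breaking perturbation; exact symmetric ties
    are resolved toward lower zeroth-order index (= lower energy ordering).
    """
    m = weights.shape[0]
    assign: dict[int, int] = {}
    unclaimed = set(range(m))
    for k in order:
        col = weights[:, k]
        best_un = min(unclaimed, key=lambda b: (-col[b], b))
        if col.max() - col[best_un] > _TIE_TOL:
            culprit = int(np.argmax(col))
            raise AssignmentError(
                f"{what}: eigenstate {k} is dominated by zeroth-order state "
                f"{culprit}, already claimed by eigenstate "
                f"{[e for e, b in assign.items() if b == culprit][0]}; apply a "
                "small symmetry-breaking perturbation to the model"
            )
        assign[k] = best_un
        unclaimed.remove(best_un)
    return assign


@dataclass
class EigenLadder:
    """Eigen-solution of the one- and two-quantum blocks.

    ``freqs1``/``vecs1``: one-quantum eigenfrequencies (ascending) and
    eigenvectors (columns, site basis).  ``energies2``/``vecs2``: two-quantum
    eigenenergies and eigenvectors (local two-quantum basis).  ``assign1``
    maps eigenmode index -> dominant site index; ``assign2`` maps two-quantum
    eigenstate index -> (k, l) eigenmode pair of its dominant exciton-product
    character (k == l for overtone character).  Both are bijections.
    """

    labels: tuple[str, ...]
    freqs1: np.ndarray
    vecs1: np.ndarray
    energies2: np.ndarray
    vecs2: np.ndarray
    basis2: list[tuple[int, int]] = field(default_factory=list)
    assign1: dict[int, int] = field(default_factory=dict)
    assign2: dict[int, tuple[int, int]] = field(default_factory=dict)


def solve_ladder(
    model: LocalModeModel, two_quantum_mixing: bool = True
) -> tuple[EigenLadder, TransitionTable]:
    """Diagonalize both blocks and emit the eigen transition table.

    The table names eigenmodes by the site label of their dominant one-quantum
    character; overtone and combination rows carry the two-quantum eigenvalues
    matched to the corresponding exciton-product character.

    ``two_quantum_mixing=False`` replaces the two-quantum eigenvalues by the
    deperturbed diagonal of the Hamiltonian in the exciton-product basis,
    i.e. it switches off the coupling among two-quantum zeroth-order states
    that drives the Darling-Dennison splitting — useful for isolating that
    mechanism.
    """
    H1 = one_quantum_block(model)
    f1, v1 = np.linalg.eigh(H1)
    assign1 = _assign(v1**2, range(model.n), "one-quantum block")

    H2 = two_quantum_block(model)
    basis2 = _two_quantum_basis(model.n)
    T, pairs = exciton_product_basis(v1)
    if two_quantum_mixing:
        e2, v2 = np.linalg.eigh(H2)
        weights = (T.T @ v2) ** 2  # exciton-product character of each eigenstate
        raw = _assign(weights, np.argsort(e2, kind="stable"), "two-quantum block")
        assign2 = {k: pairs[b] for k, b in raw.items()}
    else:
        e2 = np.diag(T.T @ H2 @ T).copy()
        v2 = T
        assign2 = dict(enumerate(pairs))

    ladder = EigenLadder(
        labels=model.labels,
        freqs1=f1,
        vecs1=v1,
        energies2=e2,
        vecs2=v2,
        basis2=basis2,
        assign1=assign1,
        assign2=assign2,
    )

    site_label_of_mode = {k: model.labels[s] for k, s in assign1.items()}
    rows: list[tuple[str, str, str | None, float]] = []
    for k in range(model.n):
        rows.append(("fundamental", site_label_of_mode[k], None, float(f1[k])))
    for state, (k, l) in assign2.items():
        if k == l:
            rows.append(("overtone", site_label_of_mode[k], None, float(e2[state])))
        else:
            rows.append(
                (
                    "combination",
                    site_label_of_mode[k],
                    site_label_of_mode[l],
                    float(e2[state]),
                )
            )
    table = TransitionTable(rows)
    table.validate_complete()
    return ladder, table


def localization(ladder: EigenLadder, mode_index: int, site_index: int) -> float:
    """Squared one-quantum eigenvector weight of ``site_index`` in eigenmode
    ``mode_index`` (eigenmodes in ascending frequency order).

    Fractions over all sites sum to 1 for each eigenmode; this is the
    eigenvector-weight analogue of a PED localization fraction.
    """
    n = ladder.vecs1.shape[0]
    if not (0 <= mode_index < n and 0 <= site_index < n):
        raise IndexError(
            f"mode/site index ({mode_index}, {site_index}) out of range for n={n}"
        )
    return float(ladder.vecs1[site_index, mode_index] ** 2)


@dataclass
class SweepRecord:
    """One grid point of a detuning/coupling sweep."""

    model: LocalModeModel
    detuning: float
    coupling: float
    anharmonicities: AnharmonicityMatrix
    localizations: dict[str, float]
    eigen_fundamentals: np.ndarray


def sweep_models(
    base: LocalModeModel,
    detunings: Sequence[float],
    couplings: Sequence[float],
) -> list[SweepRecord]:
    """Grid sweep over site detuning and coupling for a two-site model.

    For each grid point the base dimer is re-parameterized with site
    frequencies mean(omega) -/+ detuning/2 and coupling beta, solved, and
    summarized by its anharmonicity matrix and the localization of the low
    (high) eigenmode on site 0 (1).  This is the synthetic analogue of a
    structural-model series: detuning plays the role of active-site
    asymmetry.  Deterministic given the grids.
    """
    if base.n != 2:
        raise ValueError("sweep_models is defined for two-site models")
    if len(detunings) == 0 or len(couplings) == 0:
        raise ValueError("detuning and coupling grids must be non-empty")
    center = float(np.mean(base.site_freqs))
    records: list[SweepRecord] = []
    for beta in couplings:
        for d in detunings:
            model = LocalModeModel.dimer(
                (center - d / 2.0, center + d / 2.0),
                base.local_anh,
                float(beta),
                labels=base.labels,
            )
            try:
                ladder, table = solve_ladder(model)
            except AssignmentError as err:
                raise AssignmentError(
                    f"grid point (detuning={d}, coupling={beta}): {err}"
                ) from err
            anh = anharmonicities_from_table(table)
            loc = {
                base.labels[0]: localization(ladder, 0, 0),
                base.labels[1]: localization(ladder, 1, 1),
            }
            records.append(
                SweepRecord(model, float(d), float(beta), anh, loc, ladder.freqs1)
            )
    return records
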