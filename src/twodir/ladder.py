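"""Vibrational energy ladder and anharmonicity arithmetic.

The observables of a 2D-IR experiment on a set of n high-frequency
oscillators (here the CO/CN stretching modes of a metal-carbonyl cofactor)
live on the ladder of vibrational states with at most two quanta in total.
With fundamentals nu_i, intramode anharmonicities D_ii and intermode
anharmonicities D_ij the ladder energies (relative to the ground state) are

    E(1_i)     = nu_i
    E(2_i)     = 2 nu_i - D_ii
    E(1_i 1_j) = nu_i + nu_j - D_ij

so D_ii is the red-shift of the 1->2 sequence transition relative to the
fundamental, and D_ij the red-shift of the combination-band sequence
transition 1_j -> 1_i 1_j.  The sign convention throughout is
D = (0-1 frequency) - (1-2 frequency): positive D means normal anharmonic
softening; negative D (bond strengthening upon excitation of a partner
mode) is allowed and observed.

Modes are always ordered by increasing fundamental frequency, matching the
|abcde> occupation-label convention for a five-mode cluster.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VibrationalMode",
    "AnharmonicityMatrix",
    "StateLabel",
    "TransitionTable",
    "LadderEnergies",
    "LadderError",
    "build_ladder",
    "sequence_transitions",
    "anharmonicities_from_table",
    "anharmonicities_from_peaks",
    "round_half_away",
]

#: default pump-axis spectral resolution (cm^-1) used for peak pairing
PUMP_RESOLUTION = 2.8


class LadderError(ValueError):
    """Inconsistent ladder input (label mismatch, missing table rows, ...)."""


def round_half_away(x: float) -> int:
    """Round to the nearest integer with halves away from zero.

    Experimental peak positions are reported as integers in cm^-1; this is
    the convention used when comparing against printed values (numpy's
    bankers' rounding would map 0.5 -> 0).
    """
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class VibrationalMode:
    """One high-frequency oscillator as seen in the linear IR spectrum.

    Parameters
    ----------
    label:
        Short unique name, e.g. ``mu_CO``, ``tCO_low``.
    fundamental:
        0->1 transition frequency in cm^-1.
    dipole_mag:
        Transition-dipole magnitude in arbitrary units (>= 0); 2D-IR peak
        amplitudes scale with its fourth (diagonal) or squared-squared
        (cross) power.
    dipole_angle:
        Orientation relative to an arbitrary reference axis, degrees.
    width_pump, width_probe:
        Gaussian FWHM along the pump and probe axes, cm^-1.
    """

    label: str
    fundamental: float
    dipole_mag: float = 1.0
    dipole_angle: float = 0.0
    width_pump: float = 8.0
    width_probe: float = 8.0

    def __post_init__(self) -> None:
        if self.fundamental <= 0:
            raise ValueError(f"fundamental must be > 0 (mode {self.label!r})")
        if self.width_pump <= 0 or self.width_probe <= 0:
            raise ValueError(f"widths must be > 0 (mode {self.label!r})")
        if self.dipole_mag < 0:
            raise ValueError(f"dipole_mag must be >= 0 (mode {self.label!r})")


def check_unique_labels(modes: Sequence[VibrationalMode]) -> None:
    labels = [m.label for m in modes]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate mode labels: {labels}")


_SYM_TOL = 1e-9


class AnharmonicityMatrix:
    """Symmetric matrix of intramode (diagonal) and intermode anharmonicities.

    Entries are in cm^-1.  Missing (unobserved) entries are NaN, never zero;
    an optional per-entry provenance string records where each value came
    from (printed position, fit, model, "unobserved", "<1 qualifier", ...).
    """

    def __init__(
        self,
        labels: Sequence[str],
        values: np.ndarray,
        provenance: Mapping[tuple[str, str], str] | None = None,
    ) -> None:
        labels = list(labels)
        values = np.asarray(values, dtype=float)
        n = len(labels)
        if values.shape != (n, n):
            raise ValueError(f"matrix shape {values.shape} != ({n}, {n})")
        if len(set(labels)) != n:
            raise ValueError(f"duplicate labels: {labels}")
        finite = np.isfinite(values)
        if not np.array_equal(finite, finite.T):
            raise LadderError("missing-entry pattern is not symmetric")
        asym = np.nanmax(np.abs(values - values.T)) if finite.any() else 0.0
        if asym > _SYM_TOL:
            raise LadderError(f"matrix not symmetric (max asymmetry {asym:g} cm^-1)")
        self.labels = labels
        self.values = values
        self.provenance: dict[tuple[str, str], str] = dict(provenance or {})

    @property
    def n(self) -> int:
        return len(self.labels)

    def _idx(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown mode label {label!r}; have {self.labels}") from None

    def get(self, i: str, j: str) -> float:
        """Entry by label pair (NaN when unobserved)."""
        return float(self.values[self._idx(i), self._idx(j)])

    def is_observed(self, i: str, j: str) -> bool:
        return bool(np.isfinite(self.values[self._idx(i), self._idx(j)]))

    def provenance_of(self, i: str, j: str) -> str:
        key = (i, j) if (i, j) in self.provenance else (j, i)
        return self.provenance.get(key, "")

    def is_low_confidence(self, i: str, j: str) -> bool:
        """True when the extraction marked this entry as unreliable (e.g.
        built from partially cancelled, ill-defined components)."""
        return "low-confidence" in self.provenance_of(i, j)

    def __eq__(self, other: object) -> bool:  # value equality, NaN-aware
        if not isinstance(other, AnharmonicityMatrix):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(
            self.values, other.values, equal_nan=True
        )

    def __repr__(self) -> str:
        return f"AnharmonicityMatrix(labels={self.labels}, values=\n{self.values})"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        """Square tab-separated matrix, labels as header row/column, NaN as NA."""
        self.to_frame().to_csv(path, sep="\t", na_rep="NA", index_label="mode")

    @classmethod
    def from_tsv(cls, path) -> "AnharmonicityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        if list(df.index) != list(df.columns):
            raise LadderError(
                f"row labels {list(df.index)} != column labels {list(df.columns)}"
            )
        return cls(list(df.columns), df.to_numpy(dtype=float))


@dataclass(frozen=True, order=True)
class StateLabel:
    """Occupation-number label |ab...> over modes ordered by frequency."""

    occupations: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(o < 0 for o in self.occupations):
            raise ValueError(f"negative occupation in {self.occupations}")

    @property
    def total_quanta(self) -> int:
        return sum(self.occupations)

    @classmethod
    def ground(cls, n: int) -> "StateLabel":
        return cls((0,) * n)

    @classmethod
    def single(cls, n: int, i: int, quanta: int = 1) -> "StateLabel":
        occ = [0] * n
        occ[i] = quanta
        return cls(tuple(occ))

    @classmethod
    def pair(cls, n: int, i: int, j: int) -> "StateLabel":
        occ = [0] * n
        occ[i] += 1
        occ[j] += 1
        return cls(tuple(occ))

    def __str__(self) -> str:
        return "|" + "".join(str(o) for o in self.occupations) + ">"


class TransitionTable:
    """Anharmonic fundamental / overtone / combination frequencies.

    This is the shape of post-processed VPT2-style output: one fundamental
    (0 -> 1_i) and one overtone (0 -> 2_i) row per mode, and one combination
    row (0 -> 1_i 1_j) per unordered mode pair.  All frequencies in cm^-1.
    """

    KINDS = ("fundamental", "overtone", "combination")

    def __init__(self, rows: Iterable[tuple[str, str, str | None, float]]) -> None:
        recs = []
        for kind, mode_i, mode_j, freq in rows:
            if kind not in self.KINDS:
                raise LadderError(f"unknown transition kind {kind!r}")
            if freq <= 0:
                raise LadderError(f"non-positive frequency {freq} for {kind} {mode_i}")
            mode_j = mode_j or None
            if kind == "combination" and mode_j is None:
                raise LadderError(f"combination row for {mode_i} lacks second mode")
            if kind != "combination" and mode_j is not None:
                raise LadderError(f"{kind} row for {mode_i} must not name a second mode")
            recs.append((kind, mode_i, mode_j, float(freq)))
        self.rows = recs
        self._fund: dict[str, float] = {}
        self._over: dict[str, float] = {}
        self._comb: dict[frozenset[str], float] = {}
        for kind, mi, mj, f in recs:
            if kind == "fundamental":
                if mi in self._fund:
                    raise LadderError(f"duplicate fundamental for {mi}")
                self._fund[mi] = f
            elif kind == "overtone":
                if mi in self._over:
                    raise LadderError(f"duplicate overtone for {mi}")
                self._over[mi] = f
            else:
                key = frozenset((mi, mj))
                if len(key) != 2:
                    raise LadderError(f"combination row pairs {mi} with itself")
                if key in self._comb:
                    raise LadderError(f"duplicate combination for {sorted(key)}")
                self._comb[key] = f

    @property
    def labels(self) -> list[str]:
        """Mode labels ordered by increasing fundamental frequency."""
        return sorted(self._fund, key=self._fund.__getitem__)

    def fundamental(self, i: str) -> float:
        if i not in self._fund:
            raise LadderError(f"missing fundamental for mode {i!r}")
        return self._fund[i]

    def overtone(self, i: str) -> float:
        if i not in self._over:
            raise LadderError(f"missing overtone for mode {i!r}")
        return self._over[i]

    def combination(self, i: str, j: str) -> float:
        key = frozenset((i, j))
        if key not in self._comb:
            raise LadderError(f"missing combination for modes {i!r}, {j!r}")
        return self._comb[key]

    def validate_complete(self) -> None:
        """Exactly one fundamental+overtone per mode, one combination per pair."""
        modes = set(self._fund)
        missing_over = modes - set(self._over)
        if missing_over:
            raise LadderError(f"missing overtone rows for {sorted(missing_over)}")
        extra_over = set(self._over) - modes
        if extra_over:
            raise LadderError(f"overtone rows without fundamentals: {sorted(extra_over)}")
        want = {frozenset(p) for p in itertools.combinations(modes, 2)}
        missing_comb = want - set(self._comb)
        if missing_comb:
            raise LadderError(
                "missing combination rows for "
                + ", ".join(str(sorted(k)) for k in sorted(missing_comb, key=sorted))
            )
        extra_comb = set(self._comb) - want
        if extra_comb:
            raise LadderError(
                "combination rows referencing unknown modes: "
                + ", ".join(str(sorted(k)) for k in extra_comb)
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["kind", "mode_i", "mode_j", "freq_cm1"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TransitionTable":
        df = pd.read_csv(path, sep="\t")
        need = {"kind", "mode_i", "mode_j", "freq_cm1"}
        if not need.issubset(df.columns):
            raise LadderError(
                f"transition table needs columns {sorted(need)}, got {list(df.columns)}"
            )
        rows = [
            (
                str(r.kind),
                str(r.mode_i),
                None if pd.isna(r.mode_j) else str(r.mode_j),
                float(r.freq_cm1),
            )
            for r in df.itertuples()
        ]
        return cls(rows)


@dataclass
class LadderEnergies:
    """Energies (cm^-1, relative to the ground state) of all <=2-quantum states."""

    labels: list[str]
    energies: dict[StateLabel, float] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.labels)

    def energy(self, state: StateLabel) -> float:
        return self.energies[state]

    def states(self) -> list[StateLabel]:
        return sorted(self.energies, key=lambda s: (s.total_quanta, s.occupations))


# ---------------------------------------------------------------------------
# operations


def build_ladder(
    modes: Sequence[VibrationalMode], anh: AnharmonicityMatrix
) -> LadderEnergies:
    """Assemble all <=2-quantum state energies from fundamentals + anharmonicities.

    Unobserved (NaN) anharmonicity entries propagate to NaN energies of the
    affected doubly excited states; singly excited states are always defined.
    """
    check_unique_labels(modes)
    modes = sorted(modes, key=lambda m: m.fundamental)
    labels = [m.label for m in modes]
    if sorted(anh.labels) != sorted(labels):
        raise LadderError(
            f"anharmonicity labels {anh.labels} do not match mode labels {labels}"
        )
    n = len(modes)
    out = LadderEnergies(labels)
    out.energies[StateLabel.ground(n)] = 0.0
    for i, m in enumerate(modes):
        out.energies[StateLabel.single(n, i)] = m.fundamental
        out.energies[StateLabel.single(n, i, 2)] = (
            2.0 * m.fundamental - anh.get(m.label, m.label)
        )
    for i, j in itertools.combinations(range(n), 2):
        out.energies[StateLabel.pair(n, i, j)] = (
            modes[i].fundamental + modes[j].fundamental
            - anh.get(labels[i], labels[j])
        )
    return out


def table_from_ladder(ladder: LadderEnergies) -> TransitionTable:
    """Express a ladder as fundamental/overtone/combination rows (inverse of
    :func:`build_ladder` composed with :func:`anharmonicities_from_table`)."""
    n = ladder.n
    rows: list[tuple[str, str, str | None, float]] = []
    for i, lab in enumerate(ladder.labels):
        rows.append(("fundamental", lab, None, ladder.energy(StateLabel.single(n, i))))
        rows.append(("overtone", lab, None, ladder.energy(StateLabel.single(n, i, 2))))
    for i, j in itertools.combinations(range(n), 2):
        rows.append(
            (
                "combination",
                ladder.labels[i],
                ladder.labels[j],
                ladder.energy(StateLabel.pair(n, i, j)),
            )
        )
    return TransitionTable(rows)


def sequence_transitions(
    table: TransitionTable,
) -> list[tuple[StateLabel, StateLabel, float]]:
    """Frequencies of transitions between excited levels.

    Emits the 1_i -> 2_i ladder climb (overtone minus fundamental) and, for
    every ordered pair i != j, the 1_j -> 1_i 1_j combination climb
    (combination minus fundamental of j).  These are the probe frequencies of
    excited-state-absorption signals in a 2D-IR spectrum.
    """
    table.validate_complete()
    labels = table.labels
    n = len(labels)
    out: list[tuple[StateLabel, StateLabel, float]] = []
    for i, li in enumerate(labels):
        out.append(
            (
                StateLabel.single(n, i),
                StateLabel.single(n, i, 2),
                table.overtone(li) - table.fundamental(li),
            )
        )
    for j, lj in enumerate(labels):
        for i, li in enumerate(labels):
            if i == j:
                continue
            out.append(
                (
                    StateLabel.single(n, j),
                    StateLabel.pair(n, i, j),
                    table.combination(li, lj) - table.fundamental(lj),
                )
            )
    return out


def anharmonicities_from_table(table: TransitionTable) -> AnharmonicityMatrix:
    """Intramode/intermode anharmonicities from a complete transition table.

    D_ii = 2 nu_i - nu_overtone(i);  D_ij = nu_i + nu_j - nu_comb(i, j).
    """
    table.validate_complete()
    labels = table.labels
    n = len(labels)
    vals = np.zeros((n, n))
    for i, li in enumerate(labels):
        vals[i, i] = 2.0 * table.fundamental(li) - table.overtone(li)
    for i, j in itertools.combinations(range(n), 2):
        li, lj = labels[i], labels[j]
        d = table.fundamental(li) + table.fundamental(lj) - table.combination(li, lj)
        vals[i, j] = vals[j, i] = d
    prov = {(li, lj): "table" for li in labels for lj in labels}
    return AnharmonicityMatrix(labels, vals, prov)


def anharmonicities_from_peaks(
    peaks: Sequence,
    labels: Sequence[str],
    pump_tol: float = 0.5 * PUMP_RESOLUTION,
) -> AnharmonicityMatrix:
    """Anharmonicity matrix from an assigned signed 2D peak list.

    Each peak must expose ``pump_freq``, ``probe_freq``, ``sign`` (+1 ESA /
    -1 bleach), ``pumped_mode`` and ``probed_mode`` attributes (duck-typed;
    :class:`twodir.spectra.Peak2D` qualifies).  Peaks are grouped by pump
    frequency (within ``pump_tol``, half the pump spectral resolution by
    default); within a group, each ESA is paired with the bleach probing the
    same mode, and the entry is D = probe_bleach - probe_ESA.  An entry
    observed from both pump directions is averaged.  Entries never seen as a
    bleach/ESA pair are NaN with provenance "unobserved" — missing is not
    zero.  An ESA with no same-pump same-probed-mode bleach partner is an
    error (it cannot be turned into an anharmonicity).

    Parameters
    ----------
    labels:
        Mode labels in ascending-fundamental order; fixes the matrix layout.
    """
    labels = list(labels)
    n = len(labels)
    order = {lab: k for k, lab in enumerate(labels)}
    for p in peaks:
        for lab in (p.pumped_mode, p.probed_mode):
            if lab not in order:
                raise LadderError(f"peak references unknown mode {lab!r}")

    # group by pump frequency
    groups: list[list] = []
    centers: list[float] = []
    for p in sorted(peaks, key=lambda q: q.pump_freq):
        if centers and abs(p.pump_freq - centers[-1]) <= pump_tol:
            groups[-1].append(p)
            centers[-1] = float(np.mean([q.pump_freq for q in groups[-1]]))
        else:
            groups.append([p])
            centers.append(p.pump_freq)

    sums = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    orphans = []
    for group in groups:
        bleaches = {p.probed_mode: p for p in group if p.sign < 0}
        for p in group:
            if p.sign < 0:
                continue
            partner = bleaches.get(p.probed_mode)
            if partner is None:
                orphans.append(p)
                continue
            i = order[p.pumped_mode]
            j = order[p.probed_mode]
            delta = partner.probe_freq - p.probe_freq
            sums[i, j] += delta
            counts[i, j] += 1
    if orphans:
        desc = ", ".join(
            f"(pump {p.pump_freq:g}, probe {p.probe_freq:g}, {p.probed_mode})"
            for p in orphans
        )
        raise LadderError(f"ESA peaks without a bleach partner at the same pump: {desc}")

    vals = np.full((n, n), np.nan)
    prov: dict[tuple[str, str], str] = {}
    for i in range(n):
        for j in range(i, n):
            c = counts[i, j] + (counts[j, i] if j != i else 0)
            if c == 0:
                prov[(labels[i], labels[j])] = "unobserved"
                continue
            s = sums[i, j] + (sums[j, i] if j != i else 0.0)
            vals[i, j] = vals[j, i] = s / c
            prov[(labels[i], labels[j])] = f"peaks (n={c})"
    return AnharmonicityMatrix(labels, vals, prov)
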