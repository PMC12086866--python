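"""Forward simulation of linear and 2D-IR spectra in the Bloch limit.

The simulator works in the frequency domain: third-order signals are
enumerated as signed stick peaks on the pump x probe plane directly from the
energy ladder, then broadened with 2D Gaussians.  Conventions:

* negative peaks: ground-state bleach merged with stimulated emission (they
  are degenerate at fixed waiting time in this representation);
* positive peaks: excited-state absorption (1->2 ladder climbs and
  combination-band sequence transitions);
* the ESA magnitude equals the merged bleach magnitude (harmonic
  |mu_12|^2 = 2 |mu_01|^2 scaling balances the two bleach pathways), so all
  contrast in the rendered map comes from positional shifts — for vanishing
  anharmonicity bleach and ESA cancel exactly;
* peak amplitudes carry the orientational average over an isotropic sample
  for the chosen polarization scheme (parallel or perpendicular pump/probe).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from typing import Sequence

import numpy as np
import pandas as pd

from .ladder import (
    AnharmonicityMatrix,
    StateLabel,
    VibrationalMode,
    check_unique_labels,
)

__all__ = [
    "Peak2D",
    "Spectrum2D",
    "orientation_factor",
    "enumerate_peaks",
    "render_2d",
    "render_linear",
    "peaks_to_frame",
    "peaks_from_frame",
]

#: default grid step (cm^-1) for rendered spectra
GRID_STEP = 0.5
#: default Gaussian FWHM (cm^-1) when a mode does not specify one
DEFAULT_FWHM = 8.0


@dataclass(frozen=True)
class Peak2D:
    """One signed stick peak on the pump x probe plane.

    ``sign`` is +1 (excited-state absorption) or -1 (bleach / stimulated
    emission); ``amplitude`` is always >= 0, the sign is carried separately.
    ``assignment`` is the (initial, final) state pair of the probe-frequency
    transition; third-order assignments differ by exactly one quantum.
    """

    pump_freq: float
    probe_freq: float
    sign: int
    amplitude: float
    pumped_mode: str
    probed_mode: str
    assignment: tuple[StateLabel, StateLabel] | None = None
    order: str = "third"

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValueError(f"sign must be +-1, got {self.sign}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0 (sign is carried separately)")
        if self.order not in ("third", "fifth"):
            raise ValueError(f"order must be 'third' or 'fifth', got {self.order!r}")
        if self.order == "third" and self.assignment is not None:
            ini, fin = self.assignment
            if abs(fin.total_quanta - ini.total_quanta) != 1:
                raise ValueError(
                    f"third-order assignment {ini} -> {fin} must change the "
                    "total quanta by exactly one"
                )


@dataclass
class Spectrum2D:
    """Rendered pump x probe intensity map (rows = pump, columns = probe)."""

    pump: np.ndarray
    probe: np.ndarray
    intensity: np.ndarray
    polarization: str = "perpendicular"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pump = np.asarray(self.pump, dtype=float)
        self.probe = np.asarray(self.probe, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.pump.size, self.probe.size):
            raise ValueError(
                f"intensity shape {self.intensity.shape} != "
                f"({self.pump.size}, {self.probe.size})"
            )
        for name, ax in (("pump", self.pump), ("probe", self.probe)):
            if ax.size > 1 and not np.all(np.diff(ax) > 0):
                raise ValueError(f"{name} axis must be strictly increasing")
        if self.polarization not in ("parallel", "perpendicular"):
            raise ValueError(f"unknown polarization {self.polarization!r}")


def orientation_factor(theta: float, scheme: str = "parallel") -> float:
    """Isotropic four-wave-mixing orientational average.

    For transition dipoles at relative angle ``theta`` (degrees, 0..180):
    parallel pump/probe polarization weights the signal by (1+2cos^2)/15,
    perpendicular by (2-cos^2)/15.  The perpendicular/parallel ratio crosses
    1 at arccos(1/sqrt(3)) ~ 54.7 deg, so cross peaks between modes at larger
    relative angles gain contrast in the perpendicular scheme.
    """
    if not 0.0 <= theta <= 180.0:
        raise ValueError(f"theta must be in [0, 180] degrees, got {theta}")
    c2 = np.cos(np.deg2rad(theta)) ** 2
    if scheme == "parallel":
        return float((1.0 + 2.0 * c2) / 15.0)
    if scheme == "perpendicular":
        return float((2.0 - c2) / 15.0)
    raise ValueError(f"unknown polarization scheme {scheme!r}")


def enumerate_peaks(
    modes: Sequence[VibrationalMode],
    anh: AnharmonicityMatrix,
    polarization: str = "perpendicular",
    cross_threshold: float = 0.5,
    include_forbidden: bool = False,
    forbidden_rel_amplitude: float = 0.05,
) -> list[Peak2D]:
    """Enumerate third-order signed peaks from a mode set + anharmonicities.

    Per mode i: a diagonal bleach at (nu_i, nu_i) and a diagonal ESA at
    (nu_i, nu_i - D_ii), both with amplitude mu_i^4 * O(0 deg).  Per ordered
    pair (i pumped, j probed), i != j, when D_ij is observed and
    |D_ij| >= cross_threshold: a cross bleach at (nu_i, nu_j) and a cross ESA
    at (nu_i, nu_j - D_ij), amplitude mu_i^2 mu_j^2 * O(theta_ij).  Pairs
    with unobserved (NaN) coupling or |D_ij| below threshold emit nothing —
    their bleach and ESA would cancel.

    ``include_forbidden`` additionally emits the dipole-forbidden
    two-quantum-jump peaks (1_i -> 2_j type, probe nu_j - D_jj + (D_ij ...)):
    observed in strongly coupled pairs as faint features; their amplitude is
    ``forbidden_rel_amplitude`` times the corresponding cross-peak amplitude
    since the intensity is borrowed through eigenvector mixing.
    """
    check_unique_labels(modes)
    modes = sorted(modes, key=lambda m: m.fundamental)
    n = len(modes)
    labels = [m.label for m in modes]
    if sorted(anh.labels) != sorted(labels):
        raise ValueError(
            f"anharmonicity labels {anh.labels} do not match modes {labels}"
        )
    peaks: list[Peak2D] = []
    for i, m in enumerate(modes):
        amp = m.dipole_mag**4 * orientation_factor(0.0, polarization)
        g = StateLabel.ground(n)
        e1 = StateLabel.single(n, i)
        e2 = StateLabel.single(n, i, 2)
        peaks.append(
            Peak2D(m.fundamental, m.fundamental, -1, amp, m.label, m.label, (g, e1))
        )
        d = anh.get(m.label, m.label)
        peaks.append(
            Peak2D(m.fundamental, m.fundamental - d, +1, amp, m.label, m.label, (e1, e2))
        )
    for i, j in itertools.permutations(range(n), 2):
        mi, mj = modes[i], modes[j]
        d = anh.get(mi.label, mj.label)
        if not np.isfinite(d) or abs(d) < cross_threshold:
            continue
        theta = abs(mi.dipole_angle - mj.dipole_angle) % 360.0
        if theta > 180.0:
            theta = 360.0 - theta
        amp = mi.dipole_mag**2 * mj.dipole_mag**2 * orientation_factor(
            theta, polarization
        )
        g = StateLabel.ground(n)
        ei = StateLabel.single(n, i)
        ej = StateLabel.single(n, j)
        eij = StateLabel.pair(n, i, j)
        peaks.append(
            Peak2D(mi.fundamental, mj.fundamental, -1, amp, mi.label, mj.label, (g, ej))
        )
        peaks.append(
            Peak2D(
                mi.fundamental,
                mj.fundamental - d,
                +1,
                amp,
                mi.label,
                mj.label,
                (ei, eij),
            )
        )
        if include_forbidden:
            # 1_i -> 2_j double jump: probe at E(2_j) - E(1_i)
            djj = anh.get(mj.label, mj.label)
            probe = 2.0 * mj.fundamental - djj - mi.fundamental
            peaks.append(
                Peak2D(
                    mi.fundamental,
                    probe,
                    +1,
                    amp * forbidden_rel_amplitude,
                    mi.label,
                    mj.label,
                    None,
                    order="third",
                )
            )
    return peaks


def render_2d(
    peaks: Sequence[Peak2D],
    pump_axis: np.ndarray | tuple[float, float, float] | None = None,
    probe_axis: np.ndarray | tuple[float, float, float] | None = None,
    widths: dict[str, tuple[float, float]] | tuple[float, float] | None = None,
    polarization: str = "perpendicular",
    pad: float = 30.0,
) -> Spectrum2D:
    """Sum of signed 2D Gaussians centred at each peak.

    Axes are either explicit arrays, (start, stop, step) triples, or derived
    from the peak extent plus ``pad``.  ``widths`` maps the pumped-mode label
    to (pump FWHM, probe FWHM); a single (pump, probe) tuple applies to all
    peaks; None falls back to 8 cm^-1.  Rendering is linear in the peak
    amplitudes.
    """

    def _axis(spec, lo, hi):
        if spec is None:
            return np.arange(lo - pad, hi + pad + GRID_STEP / 2, GRID_STEP)
        if isinstance(spec, tuple):
            start, stop, step = spec
            if step <= 0:
                raise ValueError(f"axis step must be > 0, got {step}")
            return np.arange(start, stop + step / 2, step)
        ax = np.asarray(spec, dtype=float)
        if ax.size > 1 and np.any(np.diff(ax) <= 0):
            raise ValueError("axis must be strictly increasing")
        return ax

    if peaks:
        plo = min(p.pump_freq for p in peaks)
        phi = max(p.pump_freq for p in peaks)
        qlo = min(p.probe_freq for p in peaks)
        qhi = max(p.probe_freq for p in peaks)
    else:
        plo = phi = qlo = qhi = 2000.0
    pump = _axis(pump_axis, min(plo, qlo), max(phi, qhi))
    probe = _axis(probe_axis, min(plo, qlo), max(phi, qhi))

    four_ln2 = 4.0 * np.log(2.0)
    intensity = np.zeros((pump.size, probe.size))
    for p in peaks:
        if isinstance(widths, dict):
            wp, wq = widths.get(p.pumped_mode, (DEFAULT_FWHM, DEFAULT_FWHM))
        elif widths is not None:
            wp, wq = widths
        else:
            wp = wq = DEFAULT_FWHM
        gp = np.exp(-four_ln2 * ((pump - p.pump_freq) / wp) ** 2)
        gq = np.exp(-four_ln2 * ((probe - p.probe_freq) / wq) ** 2)
        intensity += p.sign * p.amplitude * np.outer(gp, gq)
    return Spectrum2D(pump, probe, intensity, polarization)


def render_linear(
    modes: Sequence[VibrationalMode],
    widths: dict[str, float] | float | None = None,
    axis: np.ndarray | None = None,
    pad: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear IR absorption: positive Gaussians at the fundamentals.

    Band areas scale with mu_i^2.  Returns (frequency, absorbance) arrays.
    """
    check_unique_labels(modes)
    if axis is None:
        if modes:
            lo = min(m.fundamental for m in modes) - pad
            hi = max(m.fundamental for m in modes) + pad
        else:
            lo, hi = 1800.0, 2200.0
        axis = np.arange(lo, hi + GRID_STEP / 2, GRID_STEP)
    axis = np.asarray(axis, dtype=float)
    four_ln2 = 4.0 * np.log(2.0)
    absorb = np.zeros_like(axis)
    for m in modes:
        if isinstance(widths, dict):
            w = widths.get(m.label, DEFAULT_FWHM)
        elif widths is not None:
            w = float(widths)
        else:
            w = m.width_probe
        # area proportional to mu^2: peak height = area / (w * sqrt(pi/4ln2))
        area = m.dipole_mag**2
        height = area / (w * np.sqrt(np.pi / four_ln2))
        absorb += height * np.exp(-four_ln2 * ((axis - m.fundamental) / w) ** 2)
    return axis, absorb


# ---------------------------------------------------------------------------
# tabular peak-list serialization


def peaks_to_frame(peaks: Sequence[Peak2D]) -> pd.DataFrame:
    rows = []
    for p in peaks:
        rows.append(
            {
                "pump_cm1": p.pump_freq,
                "probe_cm1": p.probe_freq,
                "sign": p.sign,
                "amplitude": p.amplitude,
                "pumped_mode": p.pumped_mode,
                "probed_mode": p.probed_mode,
                "assignment": (
                    f"{p.assignment[0]}->{p.assignment[1]}" if p.assignment else ""
                ),
                "order": p.order,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pump_cm1",
            "probe_cm1",
            "sign",
            "amplitude",
            "pumped_mode",
            "probed_mode",
            "assignment",
            "order",
        ],
    )


def peaks_from_frame(df: pd.DataFrame) -> list[Peak2D]:
    peaks = []
    for r in df.itertuples():
        peaks.append(
            Peak2D(
                float(r.pump_cm1),
                float(r.probe_cm1),
                int(r.sign),
                float(r.amplitude),
                str(r.pumped_mode),
                str(r.probed_mode),
                None,
                str(r.order) if hasattr(r, "order") else "third",
            )
        )
    return peaks
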