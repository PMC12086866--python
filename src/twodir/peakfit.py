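"""Peak-position recovery from 2D spectra by multi-Gaussian slice fitting.

The extraction procedure mirrors how experimental anharmonicities are
obtained: take a horizontal slice through the 2D spectrum at the pump
frequency of each fundamental, fit a sum of signed Gaussians plus a constant
baseline to the slice, classify the fitted components into bleaches and
excited-state absorptions, pair them, and convert the paired probe positions
to anharmonicities via the ladder arithmetic.

Component signs are fixed by their seeds (a component seeded negative stays
negative), which prevents bleach/ESA identity swaps during optimization.
Center uncertainties come from the linearized covariance at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize
from scipy.ndimage import gaussian_filter1d
from scipy.signal import argrelextrema

from .ladder import (
    AnharmonicityMatrix,
    LadderError,
    VibrationalMode,
    anharmonicities_from_peaks,
)
from .spectra import Peak2D, Spectrum2D

__all__ = [
    "SliceFitResult",
    "take_slice",
    "default_seeds",
    "fit_slice",
    "assemble_matrix",
    "extract_matrix",
]

#: default FWHM bounds for fitted components, cm^-1
WIDTH_BOUNDS = (2.0, 30.0)
#: ESA search window around its bleach: [below, above], cm^-1
PAIRING_WINDOW = (30.0, 6.0)

_FOUR_LN2 = 4.0 * np.log(2.0)


@dataclass
class SliceFitResult:
    """Multi-Gaussian fit of one pump slice.

    ``components`` are (center, FWHM, signed amplitude) sorted by center;
    ``center_unc`` the 1-sigma center uncertainties (NaN when the covariance
    could not be estimated); ``residual_rms`` the root-mean-square misfit.
    """

    pump_freq: float
    components: list[tuple[float, float, float]]
    center_unc: list[float]
    residual_rms: float
    converged: bool
    low_confidence: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        order = np.argsort([c[0] for c in self.components], kind="stable")
        self.components = [self.components[int(k)] for k in order]
        self.center_unc = [self.center_unc[int(k)] for k in order]
        if self.low_confidence:
            self.low_confidence = [self.low_confidence[int(k)] for k in order]
        else:
            self.low_confidence = [False] * len(self.components)
        for _, w, _ in self.components:
            if w <= 0:
                raise ValueError("fitted FWHM must be > 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pump_cm1": self.pump_freq,
                "center_cm1": [c[0] for c in self.components],
                "fwhm_cm1": [c[1] for c in self.components],
                "amplitude": [c[2] for c in self.components],
                "center_unc_cm1": self.center_unc,
                "low_confidence": self.low_confidence,
            }
        )


def take_slice(
    spec: Spectrum2D, pump_freq: float
) -> tuple[float, np.ndarray, np.ndarray]:
    """Row nearest to ``pump_freq`` (no interpolation).

    Returns (realized pump frequency, probe axis, intensity).  A pump
    frequency exactly between two grid rows resolves to the lower-index row.
    """
    if not spec.pump[0] <= pump_freq <= spec.pump[-1]:
        raise ValueError(
            f"pump frequency {pump_freq} outside axis "
            f"[{spec.pump[0]}, {spec.pump[-1]}]"
        )
    dist = np.abs(spec.pump - pump_freq)
    row = int(np.argmin(dist))  # argmin takes the first (lower) index on ties
    return float(spec.pump[row]), spec.probe, spec.intensity[row].copy()


def robust_noise(trace: np.ndarray) -> float:
    """Noise scale from the median absolute deviation of first differences.

    Differencing removes the smooth signal; the 1.4826/sqrt(2) factor maps
    the MAD of the differenced series onto the Gaussian sigma of the
    original one.
    """
    d = np.diff(trace)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def default_seeds(
    probe: np.ndarray,
    trace: np.ndarray,
    snr: float = 3.0,
    rel_floor: float = 0.01,
    smooth_fwhm: float = 3.0,
) -> list[tuple[float, int]]:
    """Signed local extrema exceeding ``snr`` times the robust noise estimate.

    Operator-free seeding: the trace is lightly smoothed (Gaussian,
    ``smooth_fwhm`` cm^-1 — well below the narrowest physical linewidth, so
    real bands survive while single-point noise spikes are suppressed);
    every local maximum of the smoothed trace above +threshold becomes a
    positive seed, every local minimum below -threshold a negative one.
    ``rel_floor`` additionally discards extrema below that fraction of the
    trace maximum — in noise-free synthetic data the noise estimate is
    numerically zero and far-tail wiggles would otherwise seed phantom
    components.
    """
    step = float(np.median(np.diff(probe))) if probe.size > 1 else 1.0
    sm_sigma_pts = smooth_fwhm / 2.3548 / step
    smooth = gaussian_filter1d(trace, sm_sigma_pts) if sm_sigma_pts > 0 else trace
    sigma = robust_noise(trace)  # raw-trace MAD: smoothing correlates samples
    thresh = max(snr * sigma if sigma > 0 else 0.0,
                 rel_floor * float(np.max(np.abs(smooth), initial=0.0)))
    seeds: list[tuple[float, int]] = []
    for idx in argrelextrema(smooth, np.greater)[0]:
        if smooth[idx] > thresh:
            seeds.append((float(probe[idx]), +1))
    for idx in argrelextrema(smooth, np.less)[0]:
        if smooth[idx] < -thresh:
            seeds.append((float(probe[idx]), -1))
    return sorted(seeds)


def _model(params: Parameters, x: np.ndarray, signs: Sequence[int]) -> np.ndarray:
    y = np.full_like(x, params["baseline"].value)
    for k, s in enumerate(signs):
        a = params[f"a{k}"].value
        c = params[f"c{k}"].value
        w = params[f"w{k}"].value
        y = y + s * a * np.exp(-_FOUR_LN2 * ((x - c) / w) ** 2)
    return y


def fit_slice(
    probe: np.ndarray,
    trace: np.ndarray,
    seeds: Sequence[tuple[float, int]],
    pump_freq: float = float("nan"),
    width_bounds: tuple[float, float] = WIDTH_BOUNDS,
    center_window: float = 6.0,
) -> SliceFitResult:
    """Nonlinear least squares of signed Gaussians + constant baseline.

    Each seed contributes one component whose sign is fixed; centers may move
    by at most ``center_window`` cm^-1 from their seed (keeps crowded fits
    from reshuffling components); amplitudes are bounded non-negative.
    Non-convergence and unreliable uncertainties are reported via
    ``converged`` / NaN uncertainties, never silently.
    """
    probe = np.asarray(probe, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if len(seeds) == 0:
        raise ValueError("need at least one seed")
    for c, _ in seeds:
        if not probe[0] <= c <= probe[-1]:
            raise ValueError(f"seed center {c} outside probe range")
    n_par = 3 * len(seeds) + 1
    if probe.size < n_par:
        raise ValueError(
            f"{probe.size} data points cannot constrain {n_par} parameters"
        )
    signs = [s for _, s in seeds]
    wlo, whi = width_bounds
    scale = float(np.max(np.abs(trace))) or 1.0
    params = Parameters()
    params.add("baseline", value=0.0)
    for k, (c, s) in enumerate(seeds):
        guess = abs(float(np.interp(c, probe, trace)))
        params.add(f"a{k}", value=max(guess, 1e-3 * scale), min=0.0)
        params.add(
            f"c{k}",
            value=c,
            min=max(c - center_window, probe[0]),
            max=min(c + center_window, probe[-1]),
        )
        params.add(f"w{k}", value=float(np.clip(8.0, wlo, whi)), min=wlo, max=whi)

    out = minimize(
        lambda p: _model(p, probe, signs) - trace, params, method="leastsq"
    )
    resid = _model(out.params, probe, signs) - trace
    rms = float(np.sqrt(np.mean(resid**2)))
    comps, uncs, lowconf = [], [], []
    noise = robust_noise(trace)
    for k, s in enumerate(signs):
        a = out.params[f"a{k}"].value
        c = out.params[f"c{k}"].value
        w = out.params[f"w{k}"].value
        cerr = out.params[f"c{k}"].stderr
        comps.append((float(c), float(w), float(s * a)))
        uncs.append(float(cerr) if cerr is not None else float("nan"))
        weak = a < 3.0 * noise if noise > 0 else a <= 0
        uncertain = cerr is None or not np.isfinite(cerr) or cerr > 1.0
        lowconf.append(bool(weak or uncertain))
    converged = bool(out.success)
    return SliceFitResult(pump_freq, comps, uncs, rms, converged, lowconf)


def _nearest_mode(freq: float, modes: Sequence[VibrationalMode], tol: float):
    best = min(modes, key=lambda m: abs(m.fundamental - freq))
    if abs(best.fundamental - freq) > tol:
        return None
    return best


def assemble_matrix(
    fits: Sequence[SliceFitResult],
    modes: Sequence[VibrationalMode],
    mode_tol: float = 10.0,
    pairing_window: tuple[float, float] = PAIRING_WINDOW,
) -> tuple[AnharmonicityMatrix, pd.DataFrame]:
    """Classify fitted components, pair bleach/ESA, build the matrix.

    Within each pump slice: negative components are bleaches and are assigned
    to the mode with the nearest fundamental (within ``mode_tol``); each
    positive component becomes the ESA of the bleach found inside an
    asymmetric window around it — up to ``pairing_window[0]`` above the ESA
    (normal red-shifted anharmonicity) and ``pairing_window[1]`` below it
    (negative anharmonicity), nearest bleach wins.  Pairs are then fed to the
    ladder-level extraction; entries whose members carry a low-confidence
    flag are marked in the provenance.  Every component appears in the audit
    table; the unassignable ones are rows flagged ``unassigned``, never
    silently dropped.
    """
    modes = sorted(modes, key=lambda m: m.fundamental)
    labels = [m.label for m in modes]
    audit_rows = []
    peaks: list[Peak2D] = []
    lowconf_pairs: set[tuple[str, str]] = set()
    for fit in fits:
        pumped = _nearest_mode(fit.pump_freq, modes, mode_tol)
        items = list(zip(fit.components, fit.center_unc, fit.low_confidence))
        bleaches = []  # (key, center, mode, low_confidence)
        for key, ((c, w, a), unc, lc) in enumerate(items):
            if a < 0:
                bleaches.append((key, c, _nearest_mode(c, modes, mode_tol), lc))
        used: set[int] = set()
        # strong components claim their partners first: a weak noise artifact
        # must not steal the bleach of a genuine ESA
        esa_order = sorted(
            (key for key, ((c, w, a), _, _) in enumerate(items) if a >= 0),
            key=lambda key: -items[key][0][2],
        )
        bleach_order = [key for key, _, _, _ in bleaches]
        for key in bleach_order + esa_order:
            (c, w, a), unc, lc = items[key]
            entry = {
                "pump_cm1": fit.pump_freq,
                "center_cm1": c,
                "fwhm_cm1": w,
                "amplitude": a,
                "center_unc_cm1": unc,
                "kind": "bleach" if a < 0 else "esa",
                "pumped_mode": pumped.label if pumped else "",
                "probed_mode": "",
                "status": "unassigned",
            }
            if pumped is None:
                entry["status"] = "unassigned (pump off any fundamental)"
                audit_rows.append(entry)
                continue
            if a < 0:
                probed = _nearest_mode(c, modes, mode_tol)
                if probed is None:
                    entry["status"] = "unassigned (bleach off any fundamental)"
                else:
                    entry["probed_mode"] = probed.label
                    entry["status"] = "assigned"
                    peaks.append(
                        Peak2D(fit.pump_freq, c, -1, abs(a), pumped.label, probed.label)
                    )
                    if lc:
                        lowconf_pairs.add(
                            tuple(sorted((pumped.label, probed.label)))
                        )
                audit_rows.append(entry)
                continue
            # ESA: find its bleach within [-above, +below] around the ESA center
            below, above = pairing_window
            candidates = [
                (k, bc, bm, blc)
                for k, bc, bm, blc in bleaches
                if k not in used
                and bm is not None
                and -above <= bc - c <= below
            ]
            if not candidates:
                entry["status"] = "unassigned (no bleach partner in window)"
                audit_rows.append(entry)
                continue
            k, bc, bm, blc = min(candidates, key=lambda t: abs(t[1] - c))
            used.add(k)
            entry["probed_mode"] = bm.label
            entry["status"] = "assigned"
            peaks.append(Peak2D(fit.pump_freq, c, +1, a, pumped.label, bm.label))
            if lc or blc:
                lowconf_pairs.add(tuple(sorted((pumped.label, bm.label))))
            audit_rows.append(entry)

    audit = pd.DataFrame(
        audit_rows,
        columns=[
            "pump_cm1",
            "center_cm1",
            "fwhm_cm1",
            "amplitude",
            "center_unc_cm1",
            "kind",
            "pumped_mode",
            "probed_mode",
            "status",
        ],
    )
    matrix = anharmonicities_from_peaks(peaks, labels, pump_tol=1e-6)
    for i, j in lowconf_pairs:
        key = (i, j) if (i, j) in matrix.provenance else (j, i)
        matrix.provenance[key] = matrix.provenance.get(key, "") + " [low-confidence]"
    return matrix, audit


def extract_matrix(
    spec: Spectrum2D,
    modes: Sequence[VibrationalMode],
    seeds_by_mode: dict[str, list[tuple[float, int]]] | None = None,
    width_bounds: tuple[float, float] = WIDTH_BOUNDS,
) -> tuple[AnharmonicityMatrix, list[SliceFitResult], pd.DataFrame]:
    """Full slice-fitting pipeline: slices at every fundamental -> matrix.

    Slices are taken at the grid rows nearest to each mode's fundamental.
    ``seeds_by_mode`` overrides the operator-free extremum seeding per pumped
    mode (useful for faint, partially cancelled features).
    """
    fits = []
    for m in sorted(modes, key=lambda x: x.fundamental):
        realized, probe, trace = take_slice(spec, m.fundamental)
        if seeds_by_mode and m.label in seeds_by_mode:
            seeds = seeds_by_mode[m.label]
        else:
            seeds = default_seeds(probe, trace)
        if not seeds:
            continue
        fits.append(
            fit_slice(probe, trace, seeds, pump_freq=realized, width_bounds=width_bounds)
        )
    matrix, audit = assemble_matrix(fits, modes)
    return matrix, fits, audit
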