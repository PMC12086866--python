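"""Synthetic ground-truth inputs for the whole pipeline.

Everything downstream code consumes can be generated here with known truth:

* the five-mode inhibited-state preset (fundamentals and anharmonicities as
  measured for the oxygen-stable H_inact state of the [FeFe]-hydrogenase
  H-cluster),
* rendered 2D spectra with optional seeded noise plus machine-readable truth
  sidecars (generating peak list + matrix + manifest),
* candidate-model ensembles from the coupled local-mode solver, emulating a
  series of structural models with one designated ground-truth member.

All randomness flows through explicit integer seeds; identical seeds give
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .ladder import AnharmonicityMatrix, VibrationalMode
from .localmode import LocalModeModel, localization, solve_ladder
from .ladder import anharmonicities_from_table
from .modelselect import CandidateModel
from .spectra import Peak2D, Spectrum2D, enumerate_peaks, peaks_to_frame, render_2d

__all__ = [
    "NoiseSpec",
    "hinact_preset",
    "hinact_printed_peaks",
    "make_spectrum",
    "make_ensemble",
]

MODE_LABELS = ("mu_CO", "tCO_low", "tCO_high", "tCN_low", "tCN_high")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise (sigma as a fraction of the spectrum maximum)
    plus an optional diagonal scatter ridge as an artifact stress test."""

    sigma: float = 0.0
    seed: int | None = None
    ridge_amplitude: float = 0.0
    ridge_width: float = 4.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if (self.sigma > 0 or self.ridge_amplitude > 0) and self.seed is None:
            raise ValueError("a seed is mandatory whenever noise is added")


def hinact_preset() -> tuple[list[VibrationalMode], AnharmonicityMatrix]:
    """Five-mode set and anharmonicity matrix of the H_inact state.

    Fundamentals (cm^-1): bridging CO 1847, terminal CO pair 1982/2007,
    cyanide pair 2087/2107.  Diagonal anharmonicities 24/23/14/24/24;
    observed couplings: 13 between the two terminal COs, 1 between the
    bridging CO and the high terminal CO, -3 between the low terminal CO and
    the low cyanide, 1 between the high terminal CO and the low cyanide.
    The bridging-CO / low-terminal-CO coupling is below the 1 cm^-1
    detection limit and stored as 0 with a "<1" qualifier; the high cyanide
    is vibrationally isolated — every entry involving it, and the undetected
    bridging-CO/cyanide couplings, are unobserved (NaN), not zero.

    Dipole magnitudes give the familiar linear-spectrum pattern (dominant
    terminal-CO pair, medium bridging CO, weaker cyanides); dipole angles
    put every observed cross pair above the 54.7 deg crossover so cross
    peaks gain contrast in perpendicular polarization.
    """
    mu, lo, hi, cnl, cnh = MODE_LABELS
    modes = [
        VibrationalMode(mu, 1847.0, dipole_mag=1.0, dipole_angle=0.0),
        VibrationalMode(lo, 1982.0, dipole_mag=1.3, dipole_angle=60.0),
        VibrationalMode(hi, 2007.0, dipole_mag=1.3, dipole_angle=120.0),
        VibrationalMode(cnl, 2087.0, dipole_mag=0.9, dipole_angle=175.0),
        VibrationalMode(cnh, 2107.0, dipole_mag=0.9, dipole_angle=90.0),
    ]
    nan = np.nan
    vals = np.array(
        [
            #  mu     lo     hi     cnl    cnh
            [24.0,   0.0,   1.0,   nan,   nan],
            [0.0,   23.0,  13.0,  -3.0,   nan],
            [1.0,   13.0,  14.0,   1.0,   nan],
            [nan,   -3.0,   1.0,  24.0,   nan],
            [nan,    nan,   nan,   nan,  24.0],
        ]
    )
    prov = {
        (mu, mu): "measured bleach/ESA pair 1847/1823",
        (lo, lo): "measured bleach/ESA pair 1982/1959",
        (hi, hi): "measured bleach/ESA pair 2007/1993",
        (cnl, cnl): "measured bleach/ESA pair 2087/2063",
        (cnh, cnh): "measured bleach/ESA pair 2107/2083",
        (lo, hi): "measured sequence transition 1983/1970",
        (mu, lo): "below detection limit (<1), stored as 0",
        (mu, hi): "measured, rounded printed positions",
        (lo, cnl): "measured, negative coupling",
        (hi, cnl): "measured, rounded printed positions",
        (mu, cnl): "unobserved (no detectable cross peaks)",
        (mu, cnh): "unobserved (isolated high cyanide)",
        (lo, cnh): "unobserved (isolated high cyanide)",
        (hi, cnh): "unobserved (isolated high cyanide)",
        (cnl, cnh): "unobserved (no cross peaks between the cyanides)",
    }
    return modes, AnharmonicityMatrix(list(MODE_LABELS), vals, prov)


def hinact_printed_peaks() -> list[Peak2D]:
    """The published third-order signal catalogue as an assigned peak list.

    Integer pump/probe positions of the bleach (negative) and excited-state
    absorption (positive) signals; amplitudes are placeholders (1.0) since
    only positions enter the anharmonicity arithmetic.  The ill-defined
    sequence signal between the terminal-CO bleaches and the fifth-order /
    dipole-forbidden features are excluded — they carry no reliable position.
    """
    mu, lo, hi, cnl, cnh = MODE_LABELS
    cat = [
        # (pump, probe, sign, pumped, probed)
        (1847, 1847, -1, mu, mu),
        (1847, 1823, +1, mu, mu),
        (2088, 2087, -1, cnl, cnl),
        (2107, 2107, -1, cnh, cnh),
        (2088, 2063, +1, cnl, cnl),
        (2107, 2083, +1, cnh, cnh),
        (1982, 1982, -1, lo, lo),
        (2007, 2007, -1, hi, hi),
        (1982, 1959, +1, lo, lo),
        (2007, 1993, +1, hi, hi),
        (1982, 2008, -1, lo, hi),
        (2007, 1983, -1, hi, lo),
        (2007, 1970, +1, hi, lo),
        (1847, 1983, -1, mu, lo),
        (1982, 1847, -1, lo, mu),
        (1982, 1846, +1, lo, mu),
        (1847, 2007, -1, mu, hi),
        (2007, 1847, -1, hi, mu),
        (1847, 2006, +1, mu, hi),
        (2007, 1846, +1, hi, mu),
        (2007, 2087, -1, hi, cnl),
        (2088, 2007, -1, cnl, hi),
        (2007, 2086, +1, hi, cnl),
        (2088, 2006, +1, cnl, hi),
        (1982, 2087, -1, lo, cnl),
        (2088, 1982, -1, cnl, lo),
        (1982, 2090, +1, lo, cnl),
        (2088, 1985, +1, cnl, lo),
    ]
    return [
        Peak2D(float(p), float(q), s, 1.0, pm, qm) for p, q, s, pm, qm in cat
    ]


def _apply_noise(spec: Spectrum2D, noise: NoiseSpec) -> Spectrum2D:
    if noise.sigma == 0 and noise.ridge_amplitude == 0:
        return spec
    rng = np.random.default_rng(noise.seed)
    scale = float(np.max(np.abs(spec.intensity))) or 1.0
    intensity = spec.intensity + rng.normal(
        0.0, noise.sigma * scale, size=spec.intensity.shape
    )
    if noise.ridge_amplitude > 0:
        # scatter ridge along the pump = probe diagonal
        four_ln2 = 4.0 * np.log(2.0)
        diff = spec.pump[:, None] - spec.probe[None, :]
        intensity = intensity + noise.ridge_amplitude * scale * np.exp(
            -four_ln2 * (diff / noise.ridge_width) ** 2
        )
    return Spectrum2D(spec.pump, spec.probe, intensity, spec.polarization, spec.metadata)


def make_spectrum(
    modes: list[VibrationalMode] | None = None,
    anh: AnharmonicityMatrix | None = None,
    polarization: str = "perpendicular",
    noise: NoiseSpec = NoiseSpec(),
    cross_threshold: float = 0.5,
    out_dir: str | Path | None = None,
) -> tuple[Spectrum2D, list[Peak2D]]:
    """Simulate a 2D spectrum (preset by default) with truth sidecars.

    Returns (spectrum, generating peak list).  With ``out_dir`` set, writes
    ``spectrum.tsv``, ``peaks.tsv``, ``matrix.tsv`` and ``manifest.yaml``
    into that directory; outputs are byte-identical for identical seeds.
    """
    if (modes is None) != (anh is None):
        raise ValueError("pass both modes and anh, or neither for the preset")
    if modes is None:
        modes, anh = hinact_preset()
    peaks = enumerate_peaks(modes, anh, polarization, cross_threshold)
    spec = render_2d(peaks, polarization=polarization)
    spec = _apply_noise(spec, noise)
    spec.metadata.update(
        {
            "waiting_time": "fixed (dynamics not modelled)",
            "noise_sigma": noise.sigma,
            "noise_seed": noise.seed,
        }
    )
    if out_dir is not None:
        from .interface import write_spectrum  # deferred: avoids import cycle

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_spectrum(spec, out / "spectrum.tsv")
        peaks_to_frame(peaks).to_csv(out / "peaks.tsv", sep="\t", index=False)
        anh.to_tsv(out / "matrix.tsv")
        manifest = {
            "modes": [
                {
                    "label": m.label,
                    "fundamental_cm1": m.fundamental,
                    "dipole_mag": m.dipole_mag,
                    "dipole_angle_deg": m.dipole_angle,
                    "width_pump_cm1": m.width_pump,
                    "width_probe_cm1": m.width_probe,
                }
                for m in modes
            ],
            "polarization": polarization,
            "cross_threshold_cm1": cross_threshold,
            "noise": {
                "sigma": noise.sigma,
                "seed": noise.seed,
                "ridge_amplitude": noise.ridge_amplitude,
                "ridge_width_cm1": noise.ridge_width,
            },
        }
        with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    return spec, peaks


def make_ensemble(
    n_models: int = 23,
    detuning_range: tuple[float, float] = (-35.0, 35.0),
    coupling_range: tuple[float, float] = (4.0, 18.0),
    chi: float = 12.5,
    center: float = 1994.5,
    seed: int = 0,
    true_index: int | None = None,
) -> tuple[list[CandidateModel], CandidateModel, AnharmonicityMatrix]:
    """Candidate-model ensemble emulating a structural-model series.

    Local-mode dimers are sampled on a seeded jittered grid of detunings
    (structural asymmetry) and couplings, solved exactly, and packaged as
    candidates with their anharmonicity matrices and localizations.  One
    member (``true_index``, seeded choice by default) is designated ground
    truth; its matrix doubles as the pseudo-experimental target (no
    perturbation by default, so the designated model scores exactly zero).

    Returns (candidates, designated true model, pseudo-experimental matrix).
    """
    if n_models < 2:
        raise ValueError("need at least 2 models for a meaningful ensemble")
    rng = np.random.default_rng(seed)
    lo_d, hi_d = detuning_range
    lo_b, hi_b = coupling_range
    detunings = np.linspace(lo_d, hi_d, n_models)
    detunings = detunings + rng.uniform(
        -0.25, 0.25, n_models
    ) * (hi_d - lo_d) / max(n_models - 1, 1)
    couplings = rng.uniform(lo_b, hi_b, n_models)
    candidates = []
    for k in range(n_models):
        model = LocalModeModel.dimer(
            (center - detunings[k] / 2.0, center + detunings[k] / 2.0),
            chi,
            float(couplings[k]),
            labels=("low", "high"),
        )
        ladder, table = solve_ladder(model)
        anh = anharmonicities_from_table(table)
        loc = {
            "low": localization(ladder, 0, 0),
            "high": localization(ladder, 1, 1),
        }
        candidates.append(
            CandidateModel(
                id=f"model_{k + 1:02d}",
                anharmonicities=anh,
                localizations=loc,
                descriptor=(
                    f"detuning {detunings[k]:+.1f} cm^-1, "
                    f"coupling {couplings[k]:.1f} cm^-1"
                ),
            )
        )
    if true_index is None:
        true_index = int(rng.integers(n_models))
    true_model = candidates[true_index]
    true_model.descriptor += " [designated ground truth]"
    return candidates, true_model, true_model.anharmonicities
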