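"""File formats, run configuration and logging for the pipeline.

Spectrum matrix dialect (text): tab-separated; cell [0,0] is the literal
header ``pump\\probe``, the rest of the first row is the probe axis, the
first column the pump axis, rows are pump — matching the vertical pump axis
of a conventional 2D-IR plot.  Transposition is the likeliest user error,
hence the mandatory corner marker.  Frequencies are always cm^-1; text
values carry 6 significant digits, the HDF5 container is exact.  All text
output is UTF-8 with '.' as the decimal separator regardless of locale.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .spectra import Spectrum2D

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "RunConfig",
    "setup_logging",
    "file_digest",
]

log = logging.getLogger("twodir")

_CORNER = "pump\\probe"


def setup_logging(verbosity: int = 0) -> None:
    level = logging.WARNING if verbosity <= 0 else (
        logging.INFO if verbosity == 1 else logging.DEBUG
    )
    logging.basicConfig(format="%(levelname)s %(name)s: %(message)s")
    log.setLevel(level)


def file_digest(path) -> str:
    """SHA-256 of a file, for reproducibility logging."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_spectrum(spec: Spectrum2D, path) -> None:
    """Write the matrix dialect; '.h5'/'.hdf5' suffixes use the exact binary
    container with identical semantics (datasets pump/probe/intensity)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("pump_cm1", data=spec.pump)
            fh.create_dataset("probe_cm1", data=spec.probe)
            fh.create_dataset("intensity", data=spec.intensity)
            fh.attrs["polarization"] = spec.polarization
            for k, v in spec.metadata.items():
                fh.attrs[f"meta_{k}"] = "" if v is None else v
        return
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# polarization: {spec.polarization}\n")
        fh.write(_CORNER + "\t" + "\t".join(f"{q:.6g}" for q in spec.probe) + "\n")
        for p, row in zip(spec.pump, spec.intensity):
            fh.write(f"{p:.6g}\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
    log.info("wrote spectrum %s (%d x %d)", path, spec.pump.size, spec.probe.size)


def read_spectrum(path) -> Spectrum2D:
    """Read either dialect back; errors carry line numbers for text files."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as fh:
            spec = Spectrum2D(
                fh["pump_cm1"][:],
                fh["probe_cm1"][:],
                fh["intensity"][:],
                str(fh.attrs.get("polarization", "perpendicular")),
            )
        return spec
    lines = path.read_text(encoding="utf-8").splitlines()
    polarization = "perpendicular"
    start = 0
    if lines and lines[0].startswith("#"):
        if "polarization:" in lines[0]:
            polarization = lines[0].split(":", 1)[1].strip()
        start = 1
    if start >= len(lines):
        raise ValueError(f"{path}:{start + 1}: missing header row")
    header = lines[start].split("\t")
    if header[0] != _CORNER:
        raise ValueError(
            f"{path}:{start + 1}: first cell must be {_CORNER!r} "
            f"(got {header[0]!r}); is the matrix transposed?"
        )
    try:
        probe = np.array([float(x) for x in header[1:]])
    except ValueError as err:
        raise ValueError(f"{path}:{start + 1}: non-numeric probe axis: {err}") from None
    if probe.size > 1 and np.any(np.diff(probe) <= 0):
        raise ValueError(f"{path}:{start + 1}: probe axis is not strictly increasing")
    pump, rows = [], []
    for ln_no, ln in enumerate(lines[start + 1 :], start=start + 2):
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) != probe.size + 1:
            raise ValueError(
                f"{path}:{ln_no}: ragged row — {len(parts) - 1} values, "
                f"expected {probe.size}"
            )
        try:
            pump.append(float(parts[0]))
            rows.append([float(x) for x in parts[1:]])
        except ValueError as err:
            raise ValueError(f"{path}:{ln_no}: non-numeric value: {err}") from None
    pump = np.array(pump)
    if pump.size > 1 and np.any(np.diff(pump) <= 0):
        raise ValueError(f"{path}: pump axis is not strictly increasing")
    return Spectrum2D(pump, np.asarray(probe), np.array(rows), polarization)


@dataclass
class RunConfig:
    """Structured run configuration (YAML); every CLI flag has a twin here
    and CLI values override config values.  Stochastic blocks carry seeds."""

    inputs: dict[str, str] = field(default_factory=dict)
    output_dir: str = "."
    verbosity: int = 0
    simulate: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    rank: dict = field(default_factory=dict)
    synth: dict = field(default_factory=dict)

    def validate(self) -> None:
        for key, p in self.inputs.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"config input {key!r}: {p} does not exist")
        for name, block in (("synth", self.synth), ("simulate", self.simulate)):
            sigma = block.get("noise_sigma", 0)
            if sigma and "seed" not in block:
                raise ValueError(
                    f"config block {name!r} adds noise but carries no seed"
                )

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "inputs": self.inputs,
                "output_dir": self.output_dir,
                "verbosity": self.verbosity,
                "simulate": self.simulate,
                "fit": self.fit,
                "rank": self.rank,
                "synth": self.synth,
            },
            sort_keys=True,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f: data.get(f) for f in (
            "inputs", "output_dir", "verbosity", "simulate", "fit", "rank", "synth"
        ) if data.get(f) is not None}
        return cls(**known)
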