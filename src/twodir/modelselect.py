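"""Trend analysis and ranking of candidate structural models.

Candidate active-site structures are compared to experiment through the
anharmonicity observables: the intramode anharmonicity of a mode varies
parabolically with its localization (minimal in the delocalized 50/50
limit), intramode and intermode anharmonicities are negatively related, and
the candidate whose tCO-block anharmonicities best match the measured ones
(smallest RMSD, cm^-1) is the structural best fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ladder import AnharmonicityMatrix

__all__ = [
    "CandidateModel",
    "RankingResult",
    "parabola_trend",
    "intra_inter_trend",
    "rank_models",
    "DEFAULT_SELECTION",
]

#: default entry selection: the terminal-CO block, the observables that vary
#: strongly with structure (mu-CO and CN diagonals are robust across models
#: and carry no discriminating power)
DEFAULT_SELECTION = (("low", "low"), ("high", "high"), ("low", "high"))


@dataclass
class CandidateModel:
    """One candidate structure summarized by its vibrational observables."""

    id: str
    anharmonicities: AnharmonicityMatrix
    localizations: dict[str, float] = field(default_factory=dict)
    descriptor: str = ""
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        vals = self.anharmonicities.values
        if np.isinf(vals).any():
            raise ValueError(f"candidate {self.id}: infinite matrix entries")
        for k, v in self.localizations.items():
            if not np.isfinite(v):
                raise ValueError(f"candidate {self.id}: non-finite localization {k}")
        if self.provenance not in ("synthetic", "imported-table"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclass
class RankingResult:
    """Ascending (id, RMSD score in cm^-1) list; ties broken by id."""

    ranking: list[tuple[str, float]]
    entries: list[tuple[str, str]]
    weights: list[float]
    skipped_entries: list[tuple[str, str]] = field(default_factory=list)

    @property
    def best(self) -> str:
        return self.ranking[0][0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.ranking, columns=["id", "score_cm1"])
        df.insert(0, "rank", np.arange(1, len(df) + 1))
        return df


def parabola_trend(
    points: Sequence[tuple[float, float]],
) -> tuple[np.ndarray, float, float]:
    """Least-squares quadratic through (localization, intramode anharmonicity).

    Returns (coefficients [c0, c1, c2] for c0 + c1 x + c2 x^2, vertex
    abscissa, R^2).  Positive c2 (upward curvature) with a vertex near 0.5 is
    the signature of anharmonicity being minimized in the delocalized limit.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct abscissae for a quadratic")
    coeffs = np.polynomial.polynomial.polyfit(x, y, 2)
    c0, c1, c2 = coeffs
    vertex = float("nan") if c2 == 0 else -c1 / (2.0 * c2)
    yhat = np.polynomial.polynomial.polyval(x, coeffs)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return coeffs, float(vertex), r2


def intra_inter_trend(
    points: Sequence[tuple[float, float]],
) -> tuple[float, float, float]:
    """Least-squares line through (intramode, intermode) pairs.

    Returns (slope, intercept, Pearson correlation); the model sweep
    produces strongly negative correlation — delocalization trades intramode
    softening for intermode coupling.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise ValueError("degenerate abscissae: all x identical")
    if np.unique(y).size == 1:
        slope, intercept = np.polyfit(x, y, 1)
        return float(slope), float(intercept), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def rank_models(
    candidates: Sequence[CandidateModel],
    experiment: AnharmonicityMatrix,
    entries: Sequence[tuple[str, str]] = DEFAULT_SELECTION,
    weights: Sequence[float] | None = None,
) -> RankingResult:
    """Rank candidates by weighted RMSD to the experimental matrix.

        score = sqrt( sum_e w_e (D_cand(e) - D_exp(e))^2 / sum_e w_e )

    over the selected entries, in cm^-1.  Entries the experiment does not
    provide (unobserved) are dropped from the selection and reported in
    ``skipped_entries``; every candidate must provide all remaining entries.
    Ascending by score, ties broken by id; deterministic.
    """
    if not candidates:
        raise ValueError("empty ensemble: no candidate models to rank")
    ids = [c.id for c in candidates]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate candidate ids: {ids}")
    entries = list(entries)
    if weights is None:
        weights = [1.0] * len(entries)
    weights = list(weights)
    if len(weights) != len(entries):
        raise ValueError("need one weight per selected entry")

    effective, w_eff, skipped = [], [], []
    for (i, j), w in zip(entries, weights):
        if experiment.is_observed(i, j):
            effective.append((i, j))
            w_eff.append(float(w))
        else:
            skipped.append((i, j))
    if not effective:
        raise ValueError(
            "empty effective selection: experiment observes none of the "
            f"requested entries {entries}"
        )

    scores = []
    wsum = sum(w_eff)
    for c in candidates:
        sq = 0.0
        for (i, j), w in zip(effective, w_eff):
            if not c.anharmonicities.is_observed(i, j):
                raise ValueError(
                    f"candidate {c.id} lacks selected entry ({i}, {j})"
                )
            dev = c.anharmonicities.get(i, j) - experiment.get(i, j)
            sq += w * dev * dev
        scores.append((c.id, float(np.sqrt(sq / wsum))))
    scores.sort(key=lambda t: (t[1], t[0]))
    return RankingResult(scores, effective, w_eff, skipped)
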