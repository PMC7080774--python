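"""Founder-event demographic trajectories and effective-size summaries.

A trajectory lists the effective population size at every generation from
the founding event forward to the present.  The drift-relevant average of
such a fluctuating history is the harmonic mean, which is dominated by the
smallest sizes — exactly the property that makes a brief founding bottleneck
leave a lasting signature.

Piecewise-constant founder models (a tiny introduction size held for some
generations, then an expanded contemporary size; optionally a secondary
island colonisation) are expanded to per-generation trajectories here.
Generations are counted founding-forward internally; model parameters given
in "generations ago" are converted on expansion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "NeTrajectory",
    "DemographicModel",
    "harmonic_mean_ne",
    "expand_model_to_trajectory",
]


@dataclass(frozen=True)
class NeTrajectory:
    """Per-generation effective sizes N_g, ordered founding -> present."""

    sizes: np.ndarray

    def __post_init__(self) -> None:
        sizes = np.asarray(self.sizes, dtype=float)
        if sizes.ndim != 1 or sizes.size == 0:
            raise ValueError("trajectory must be a non-empty 1-D sequence")
        if np.any(sizes < 1):
            raise ValueError("all per-generation sizes must be >= 1")
        object.__setattr__(self, "sizes", sizes)

    @property
    def n_generations(self) -> int:
        return int(self.sizes.size)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_generations

    @classmethod
    def constant(cls, n: float, t: int) -> "NeTrajectory":
        return cls(np.full(t, float(n)))

    @classmethod
    def from_json(cls, path: str | Path) -> "NeTrajectory":
        """Read an ordered list of ``{"generation": g, "N": n}`` records."""
        records = json.loads(Path(path).read_text())
        records = sorted(records, key=lambda r: r["generation"])
        gens = [r["generation"] for r in records]
        if gens != list(range(1, len(gens) + 1)):
            raise ValueError("trajectory JSON must cover generations 1..t")
        return cls(np.array([r["N"] for r in records], dtype=float))

    def to_json(self, path: str | Path) -> None:
        records = [
            {"generation": g + 1, "N": float(n)} for g, n in enumerate(self.sizes)
        ]
        Path(path).write_text(json.dumps(records, indent=1) + "\n")


def harmonic_mean_ne(traj: NeTrajectory) -> float:
    """Harmonic-mean effective size Ne(h) = t / sum_g 1/N_g.

    Always <= the arithmetic mean and especially sensitive to the smallest
    sizes, which is why it is the right single-number summary of a
    bottlenecked history when quantifying cumulative drift.
    """
    sizes = traj.sizes
    if np.any(sizes <= 0):
        raise ValueError("sizes must be positive")
    return float(sizes.size / np.sum(1.0 / sizes))


# Default parameter bounds for the founder models.  The introduction is a
# single documented human-mediated release, so the post-introduction size is
# bounded at a handful-to-a-hundred individuals; expansion timing and the
# secondary-colonisation window come from the documented population history.
_BOUNDS = {
    "N_intro": (2.0, 100.0),
    "t_exp": (19, 26),
    "N_contemporary": (1e4, 1e7),
    "t_col": (11, 14),
    "N_col": (2.0, 500.0),
    "t_change": (2, 11),
    "N_island": (5.0, 1000.0),
}


@dataclass(frozen=True)
class DemographicModel:
    """Two- or three-population founder model with bounded parameters.

    ``t_intro`` is the number of generations since introduction (fixed at 32:
    80 years at 2.5 years per generation).  Times other than ``t_intro`` are
    expressed in generations ago; ``expand_model_to_trajectory`` converts them
    to the founding-forward axis.
    """

    model_kind: str = "two-population"
    t_intro: int = 32
    bounds: dict = field(default_factory=lambda: dict(_BOUNDS))

    def __post_init__(self) -> None:
        if self.model_kind not in ("two-population", "three-population"):
            raise ValueError(f"unknown model_kind: {self.model_kind!r}")
        if self.t_intro < 1:
            raise ValueError("t_intro must be >= 1")

    def required_params(self) -> tuple[str, ...]:
        base = ("N_intro", "t_exp", "N_contemporary")
        if self.model_kind == "three-population":
            return base + ("t_col", "N_col", "t_change", "N_island")
        return base

    def check_point(self, point: dict) -> None:
        """Raise naming the violated bound if ``point`` is outside the model."""
        for name in self.required_params():
            if name not in point:
                raise ValueError(f"missing parameter: {name}")
            lo, hi = self.bounds[name]
            value = point[name]
            if not (lo <= value <= hi):
                raise ValueError(
                    f"{name}={value} outside bound [{lo}, {hi}]"
                )
        if not point["t_exp"] < self.t_intro:
            raise ValueError("t_exp must be < t_intro")
        if self.model_kind == "three-population":
            if not point["t_change"] < point["t_col"]:
                raise ValueError("t_change must be < t_col")


def expand_model_to_trajectory(
    model: DemographicModel, point: dict, population: str = "main"
) -> NeTrajectory:
    """Expand a bounded parameter point to a per-generation trajectory.

    The main lineage sits at ``N_intro`` from founding until the expansion
    ``t_exp`` generations ago, then at ``N_contemporary`` through the present
    (bottleneck duration = t_intro - t_exp generations).  For
    ``population="island"`` under the three-population model, the lineage
    follows the main trajectory until the island colonisation ``t_col``
    generations ago, then ``N_col`` until ``t_change`` ago, then ``N_island``.
    """
    model.check_point(point)
    t = model.t_intro
    sizes = np.empty(t, dtype=float)
    d_bottleneck = t - int(point["t_exp"])  # generations spent small
    sizes[:d_bottleneck] = point["N_intro"]
    sizes[d_bottleneck:] = point["N_contemporary"]
    if population == "island":
        if model.model_kind != "three-population":
            raise ValueError("island trajectory requires the three-population model")
        split = t - int(point["t_col"])
        change = t - int(point["t_change"])
        sizes[split:change] = point["N_col"]
        sizes[change:] = point["N_island"]
    elif population != "main":
        raise ValueError(f"unknown population: {population!r}")
    return NeTrajectory(sizes)
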