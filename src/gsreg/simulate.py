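"""Synthetic two-group expression cohorts with known dysregulated sets.

The generator emulates the statistical structure the GSR index is built
to detect: a control group whose within-set gene ordering is stable, and
a case group in which a chosen fraction of gene sets has lost that
ordering.  Every gene gets a distinct baseline intensity; controls are
baseline plus Gaussian measurement noise; cases are identical except
that, inside each dysregulated set and independently for every case
sample, a random subset of ceil(theta * m) of the set's m genes has its
baselines permuted among themselves before noise is added.  At
theta = 1 each case sample's within-set ordering is a fresh uniform
permutation, so its expected GSR against the control template is 0.5;
at theta = 0 cases and controls are exchangeable.

Scrambling is drawn per case sample, not once per group, so cases are
exchangeable draws from a disordered distribution rather than a cohort
with a fixed alternative ordering — lost regularity, not a new one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gsreg.io import ExpressionMatrix, GeneSet, GeneSetCollection

__all__ = ["SimulationConfig", "SimTruth", "simulate_cohort"]

CONTROL = "control"
CASE = "case"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic two-group cohort.

    ``frac_dysregulated`` (f) is the fraction of gene sets scrambled in
    cases; ``scramble_intensity`` (theta) controls how much of each
    dysregulated set is permuted per case sample; ``noise_sd`` (sigma)
    is additive Gaussian measurement noise on the baseline intensity
    scale.  Gene sets are disjoint blocks unless ``overlap`` is set, in
    which case consecutive sets share half their genes.
    """

    n_genes: int = 2000
    n_sets: int = 200
    set_size: int = 10
    n_controls: int = 30
    n_cases: int = 30
    frac_dysregulated: float = 0.2
    scramble_intensity: float = 1.0
    noise_sd: float = 0.1
    seed: int = 0
    overlap: bool = False

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_sets", "set_size", "n_controls", "n_cases"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.set_size < 2:
            raise ValueError("set_size must be >= 2")
        if not 0.0 <= self.frac_dysregulated <= 1.0:
            raise ValueError("frac_dysregulated must lie in [0, 1]")
        if not 0.0 <= self.scramble_intensity <= 1.0:
            raise ValueError("scramble_intensity must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        step = max(1, self.set_size // 2) if self.overlap else self.set_size
        needed = (self.n_sets - 1) * step + self.set_size
        if self.n_genes < needed:
            raise ValueError(
                f"infeasible geometry: {self.n_sets} sets of size {self.set_size} "
                f"need >= {needed} genes, got {self.n_genes}"
            )


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated cohort."""

    dysregulated: dict[str, bool]
    theta: dict[str, float] = field(default_factory=dict)

    @property
    def positives(self) -> frozenset[str]:
        return frozenset(s for s, flag in self.dysregulated.items() if flag)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "set_id": list(self.dysregulated),
                "dysregulated": [self.dysregulated[s] for s in self.dysregulated],
                "theta": [self.theta.get(s, 0.0) for s in self.dysregulated],
            }
        ).set_index("set_id")


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _set_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"SET{i:0{width}d}" for i in range(1, n + 1)]


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, GeneSetCollection, SimTruth]:
    """Draw one cohort; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    set_ids = _set_ids(config.n_sets)

    # Distinct baselines: evenly spaced levels shuffled over genes, plus a
    # jitter far smaller than the spacing, so the canonical ordering is
    # unambiguous and unrelated to the gene numbering.
    levels = np.linspace(4.0, 12.0, config.n_genes)
    spacing = levels[1] - levels[0] if config.n_genes > 1 else 1.0
    baselines = rng.permutation(levels) + rng.uniform(
        -0.25 * spacing, 0.25 * spacing, config.n_genes
    )

    if config.overlap:
        step = max(1, config.set_size // 2)
    else:
        step = config.set_size
    membership = [
        list(range(k * step, k * step + config.set_size))
        for k in range(config.n_sets)
    ]
    collection = GeneSetCollection(
        GeneSet(sid, f"synthetic set {sid}", tuple(genes[i] for i in idx))
        for sid, idx in zip(set_ids, membership)
    )

    n_dys = round(config.frac_dysregulated * config.n_sets)
    dys_positions = rng.choice(config.n_sets, size=n_dys, replace=False)
    dys_flags = np.zeros(config.n_sets, dtype=bool)
    dys_flags[dys_positions] = True
    truth = SimTruth(
        dysregulated={sid: bool(f) for sid, f in zip(set_ids, dys_flags)},
        theta={
            sid: (config.scramble_intensity if f else 0.0)
            for sid, f in zip(set_ids, dys_flags)
        },
    )

    n_total = config.n_controls + config.n_cases
    signal = np.tile(baselines[:, None], (1, n_total))

    n_scramble = math.ceil(config.scramble_intensity * config.set_size)
    if n_scramble >= 2:
        for k in np.flatnonzero(dys_flags):
            idx = np.asarray(membership[k])
            for s in range(config.n_controls, n_total):
                chosen = rng.choice(config.set_size, size=n_scramble, replace=False)
                signal[idx[chosen], s] = signal[idx[chosen[rng.permutation(n_scramble)]], s]

    values = signal + rng.normal(0.0, config.noise_sd, size=signal.shape)
    samples = [f"ctrl{i:03d}" for i in range(1, config.n_controls + 1)] + [
        f"case{i:03d}" for i in range(1, config.n_cases + 1)
    ]
    groups = pd.Series(
        [CONTROL] * config.n_controls + [CASE] * config.n_cases, index=samples
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), groups
    )
    return matrix, collection, truth
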