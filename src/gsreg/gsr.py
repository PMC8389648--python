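"""Gene set regularity (GSR) indices over control-derived ordering templates.

The core statistic is a rank-conservation measure in the DIRAC family.
For each gene set, the control cohort defines a pairwise-ordering
template: for every unordered pair of member genes, the direction
("gene *a* expressed below gene *b*") chosen by the majority of control
samples.  A sample's GSR index for that set is the fraction of gene
pairs whose in-sample ordering agrees with the template — 1 when the
sample reproduces the control ordering exactly, 0 when every pair is
reversed, and 0.5 in expectation for a uniformly random ordering.

The index depends on the sample's values only through their ranks, so
it is invariant under any strictly increasing per-sample transform
(background correction, log scaling, quantile normalisation).

Ties in expression are broken deterministically: the lexicographically
smaller gene symbol is deemed lower.  The same rule settles exact 50/50
template votes, whose support is recorded as 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from gsreg.io import ExpressionMatrix, GeneSet, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "PairOrderTemplate",
    "restrict_sets",
    "build_template",
    "build_templates",
    "gsr_index",
    "functionome",
]


@dataclass(frozen=True)
class PairOrderTemplate:
    """Majority expression ordering of every gene pair in one gene set.

    ``pairs[k] = (i, j)`` indexes into ``genes`` with ``i < j``;
    ``directions[k]`` is True when the template says ``genes[i]`` is
    expressed below ``genes[j]``; ``support[k]`` is the fraction of
    control samples voting for the stored direction (0.5 for an exact
    split, resolved lexicographically).
    """

    set_id: str
    genes: tuple[str, ...]
    pairs: tuple[tuple[int, int], ...]
    directions: np.ndarray  # bool, one per pair
    support: np.ndarray  # float in [0.5, 1], one per pair

    def __post_init__(self) -> None:
        m = len(self.genes)
        if len(self.pairs) != m * (m - 1) // 2:
            raise ValueError("template must cover every unordered gene pair")
        if np.any(self.support < 0.5 - 1e-12) or np.any(self.support > 1 + 1e-12):
            raise ValueError("pair support must lie in [0.5, 1]")

    def pair_table(self) -> pd.DataFrame:
        """Long-form view: one row per pair with symbols, direction, support."""
        rows = [
            {
                "set_id": self.set_id,
                "gene_low": self.genes[i] if d else self.genes[j],
                "gene_high": self.genes[j] if d else self.genes[i],
                "support": s,
            }
            for (i, j), d, s in zip(self.pairs, self.directions, self.support)
        ]
        return pd.DataFrame(rows)


def restrict_sets(
    collection: GeneSetCollection,
    matrix: ExpressionMatrix,
    min_set_size: int = 5,
) -> GeneSetCollection:
    """Intersect every set with the measured genes; drop undersized sets.

    Member order is preserved.  ``min_set_size`` must be at least 2 —
    the index is defined over gene pairs.
    """
    if min_set_size < 2:
        raise ValueError("min_set_size must be >= 2 (the index is pairwise)")
    measured = set(matrix.genes)
    kept: list[GeneSet] = []
    dropped = 0
    for set_id, gs in collection.items():
        members = tuple(g for g in gs.members if g in measured)
        if len(members) >= min_set_size:
            kept.append(GeneSet(set_id, gs.name, members))
        else:
            dropped += 1
    if dropped:
        logger.info("restrict_sets: dropped %d of %d sets below size %d",
                    dropped, len(collection), min_set_size)
    if not kept:
        raise ValueError("no gene sets remain after restriction to measured genes")
    return GeneSetCollection(kept)


def _pair_indices(m: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(m, k=1)


def _pair_directions(values: np.ndarray, genes: Sequence[str]) -> np.ndarray:
    """Per-sample pair directions with the lexicographic tie rule.

    ``values`` is (m genes x n samples); returns a boolean
    (n_pairs x n samples) array where entry (k, s) is True when the
    pair's first gene is expressed below its second in sample s.
    """
    iu, ju = _pair_indices(values.shape[0])
    lo, hi = values[iu], values[ju]
    lex = np.fromiter(
        (genes[i] < genes[j] for i, j in zip(iu, ju)), dtype=bool, count=len(iu)
    )
    return np.where(lo == hi, lex[:, None], lo < hi)


def build_template(
    controls: ExpressionMatrix | pd.DataFrame,
    gene_set: GeneSet | Sequence[str],
    set_id: str | None = None,
) -> PairOrderTemplate:
    """Derive the majority pairwise-ordering template from control samples.

    Every control votes on every pair by strict comparison (per-sample
    ties fall to the lexicographically smaller symbol); the stored
    direction is the majority, and an exact 50/50 split is stored with
    support 0.5 and the lexicographic direction.
    """
    if isinstance(gene_set, GeneSet):
        genes = gene_set.members
        set_id = set_id or gene_set.id
    else:
        genes = tuple(gene_set)
        set_id = set_id or "<unnamed>"
    frame = controls.values if isinstance(controls, ExpressionMatrix) else controls
    if frame.shape[1] == 0:
        raise ValueError("template requires at least one control sample")
    missing = [g for g in genes if g not in frame.index]
    if missing:
        raise ValueError(f"gene set {set_id!r}: unmeasured genes {missing}")
    if len(genes) < 2:
        raise ValueError(f"gene set {set_id!r}: need >= 2 genes for pair ordering")

    values = frame.loc[list(genes)].to_numpy(dtype=float)
    votes = _pair_directions(values, genes)  # n_pairs x n_controls
    frac_low = votes.mean(axis=1)

    iu, ju = _pair_indices(len(genes))
    lex = np.fromiter(
        (genes[i] < genes[j] for i, j in zip(iu, ju)), dtype=bool, count=len(iu)
    )
    tied = np.isclose(frac_low, 0.5)
    directions = np.where(tied, lex, frac_low > 0.5)
    support = np.where(tied, 0.5, np.maximum(frac_low, 1.0 - frac_low))
    return PairOrderTemplate(
        set_id=set_id,
        genes=genes,
        pairs=tuple(zip(iu.tolist(), ju.tolist())),
        directions=directions,
        support=support,
    )


def build_templates(
    matrix: ExpressionMatrix,
    collection: GeneSetCollection,
    control_label: str = "control",
) -> dict[str, PairOrderTemplate]:
    """One template per gene set, from the pooled control group."""
    controls = matrix.group_samples(control_label)
    if not controls:
        raise ValueError(f"no samples labelled {control_label!r}")
    sub = matrix.values[controls]
    return {
        set_id: build_template(sub, gs) for set_id, gs in collection.items()
    }


def gsr_index(
    sample_values: Mapping[str, float] | pd.Series,
    template: PairOrderTemplate,
) -> float:
    """Fraction of gene pairs whose in-sample ordering matches the template."""
    try:
        values = np.array([float(sample_values[g]) for g in template.genes])
    except KeyError as exc:
        raise ValueError(f"sample is missing a value for gene {exc.args[0]!r}") from None
    observed = _pair_directions(values[:, None], template.genes)[:, 0]
    return float(np.mean(observed == template.directions))


def functionome(
    matrix: ExpressionMatrix,
    collection: GeneSetCollection,
    templates: Mapping[str, PairOrderTemplate],
) -> pd.DataFrame:
    """GSR profile of every sample over every gene set in the collection.

    Returns a samples x sets DataFrame of GSR indices in [0, 1]; the
    column order follows the collection, the row order the matrix.
    """
    missing = [set_id for set_id in collection if set_id not in templates]
    if missing:
        raise ValueError(f"no template for gene sets: {missing[:5]}")
    out = np.empty((len(matrix.samples), len(collection)))
    for k, (set_id, gs) in enumerate(collection.items()):
        template = templates[set_id]
        if template.genes != gs.members:
            raise ValueError(
                f"template for {set_id!r} does not match the collection's members"
            )
        values = matrix.values.loc[list(template.genes)].to_numpy(dtype=float)
        observed = _pair_directions(values, template.genes)
        out[:, k] = (observed == template.directions[:, None]).mean(axis=0)
    return pd.DataFrame(out, index=matrix.samples, columns=list(collection))
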