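"""Cross-group target discovery and clinical-scoring utilities.

Three steps turn per-group dysregulation rankings into candidate
biomarkers:

* intersect the per-group top-k dysfunctional pathway lists to find
  pathways dysregulated in every tumour group;
* count how often each gene is annotated across a chosen collection of
  GO terms ("repetitive frequency") and flag members of the
  epithelial–mesenchymal transition (EMT) biomarker panel;
* score immunohistochemical staining with the composite
  Q = I x P (intensity grade 0–3 times percentage of positive cells
  0–100, maximum 300).

The package bundles the published reference rankings for serous
borderline ovarian tumours and serous ovarian carcinomas stages I–IV:
the five top-50 dysfunctional pathway lists (whose only common member
is aryl hydrocarbon receptor binding, GO:0017162), and the 25 common
dysregulated GO terms with their expert-assigned semantic categories
and most-repeated annotated genes.  The category assignment was expert
curation, so it ships as input data, never recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from gsreg.io import GeneSetCollection

__all__ = [
    "EMT_PANEL",
    "IHCScore",
    "intersect_top_pathways",
    "gene_frequency",
    "ihc_score",
    "load_reference_top50_lists",
    "load_reference_term_categories",
    "load_reference_category_genes",
]

#: EMT biomarker panel used for the cross-check of candidate genes.
EMT_PANEL: tuple[str, ...] = ("CDH1", "CTNNB1", "SNAI1", "SNAI2", "TWIST1")


@dataclass(frozen=True)
class IHCScore:
    """Immunohistochemistry composite score Q = I x P (max 300)."""

    intensity: int
    percent_positive: float
    q: float

    def __post_init__(self) -> None:
        if self.q != self.intensity * self.percent_positive:
            raise ValueError("Q must equal I x P")


def intersect_top_pathways(lists: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Pathways present in every group's ordered top-k list.

    ``lists`` maps group label -> ordered pathway identifiers (rank 1
    first, unique within a list).  Returns one row per common
    identifier with its 1-based rank in each group and the mean rank,
    sorted by mean rank ascending (ties by identifier).
    """
    if len(lists) < 2:
        raise ValueError("need at least two groups to intersect")
    rank_maps: dict[str, dict[str, int]] = {}
    for group, ids in lists.items():
        ids = list(ids)
        if not ids:
            raise ValueError(f"group {group!r} has an empty pathway list")
        if len(set(ids)) != len(ids):
            raise ValueError(f"group {group!r} has duplicate pathway identifiers")
        rank_maps[group] = {p: r for r, p in enumerate(ids, start=1)}

    common = set.intersection(*(set(m) for m in rank_maps.values()))
    rows = []
    for set_id in common:
        ranks = {g: rank_maps[g][set_id] for g in lists}
        rows.append({"set_id": set_id, **ranks, "mean_rank": float(np.mean(list(ranks.values())))})
    frame = pd.DataFrame(rows, columns=["set_id", *lists, "mean_rank"])
    return (
        frame.sort_values(["mean_rank", "set_id"], kind="mergesort")
        .reset_index(drop=True)
        .set_index("set_id")
    )


def gene_frequency(
    selected_terms: Iterable[str],
    annotations: GeneSetCollection,
    panel: Sequence[str] = EMT_PANEL,
) -> pd.DataFrame:
    """Annotation repetition count per gene across the selected terms.

    Each gene's count is the number of selected terms whose member list
    contains it.  The table is sorted by count descending, then symbol,
    and flags membership in ``panel`` (by default the EMT biomarker
    panel).  An identifier absent from the annotation collection is an
    error; an empty selection yields an empty table.
    """
    counts: dict[str, int] = {}
    for term in selected_terms:
        if term not in annotations:
            raise KeyError(f"unknown gene set identifier {term!r}")
        for gene in annotations[term].members:
            counts[gene] = counts.get(gene, 0) + 1
    frame = pd.DataFrame(
        {"gene": list(counts), "count": list(counts.values())}
    )
    if frame.empty:
        return pd.DataFrame(columns=["count", "in_panel"], index=pd.Index([], name="gene"))
    frame["in_panel"] = frame["gene"].isin(set(panel))
    return (
        frame.sort_values(["count", "gene"], ascending=[False, True], kind="mergesort")
        .set_index("gene")
    )


def ihc_score(intensity: int, percent_positive: float) -> IHCScore:
    """Composite immunohistochemistry score Q = I x P.

    ``intensity`` is the staining grade in {0, 1, 2, 3};
    ``percent_positive`` the percentage of positive cells in [0, 100].
    Q therefore ranges from 0 to 300.
    """
    if intensity not in (0, 1, 2, 3):
        raise ValueError(f"intensity grade must be one of 0..3, got {intensity!r}")
    if not 0.0 <= percent_positive <= 100.0:
        raise ValueError(
            f"percent positive cells must lie in [0, 100], got {percent_positive!r}"
        )
    return IHCScore(intensity, percent_positive, float(intensity * percent_positive))


def _data_path(name: str):
    return resources.files("gsreg.data").joinpath(name)


def load_reference_top50_lists() -> dict[str, list[str]]:
    """Published per-group top-50 dysfunctional pathway identifiers.

    Five ordered lists (serous borderline tumours and carcinoma stages
    I–IV), rank 1 first, as reported for the serous ovarian tumour
    cohorts the pipeline was developed on.
    """
    with resources.as_file(_data_path("serous_ovarian_top50_pathways.tsv")) as path:
        table = pd.read_csv(path, sep="\t")
    groups = [c[: -len("_id")] for c in table.columns if c.endswith("_id")]
    return {g: table[f"{g}_id"].tolist() for g in groups}


def load_reference_term_categories() -> pd.DataFrame:
    """The 25 common dysregulated GO terms with expert category labels."""
    with resources.as_file(_data_path("serous_ovarian_top25_terms.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def load_reference_category_genes() -> dict[str, list[str]]:
    """Most-repeated annotated genes per semantic category (reference)."""
    with resources.as_file(_data_path("serous_ovarian_category_genes.tsv")) as path:
        table = pd.read_csv(path, sep="\t")
    return {row.category: row.top_genes.split(",") for row in table.itertuples()}
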