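"""Per-gene-set dysregulation testing, group summaries, and term ranking.

Each gene set's per-sample GSR indices are compared between a case group
and the control group with a two-sided Mann–Whitney U test (exact
enumeration for small tie-free samples, normal approximation with tie
correction otherwise), followed by Benjamini–Hochberg step-up FDR
adjustment across all sets.

Two complementary rankings are produced from the same table:

* *dysregulated GO terms* — q-significant sets ranked by the cluster
  weight index (CWI), where each significant term's weight is
  w = -log10(max(q, eps)) and its CWI is that weight divided by the
  total weight of all clustered significant terms (clusters are
  connected components of the significant subgraph of the GO ``is_a``
  tree; one global cluster when no graph is supplied);
* *dysfunctional pathways* — sets ranked by ascending raw p-value at a
  configurable, less stringent threshold (default unadjusted p < 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GroupSummary",
    "mann_whitney",
    "compare_groups",
    "group_summary",
    "compute_cwi",
    "rank_pathways",
    "gsr_histogram",
]

EPS_Q = 1e-16


@dataclass(frozen=True)
class GroupSummary:
    """Grand-mean GSR of a case group, with the control mean alongside."""

    group: str
    mean_gsr: float
    control_mean_gsr: float
    n_samples: int
    n_control_samples: int
    n_sets: int


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U for one gene set.

    Uses exact enumeration when n1 + n2 <= 20 and the pooled values are
    tie-free, and the tie-corrected normal approximation otherwise.  The
    fully degenerate case — every value in both groups identical — is
    returned as (n1*n2/2, 1.0) rather than undefined, so that constant
    null profiles behave.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return len(x) * len(y) / 2.0, 1.0
    small = len(pooled) <= 20
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if small and not has_ties else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_groups(
    case_profiles: pd.DataFrame,
    control_profiles: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-set Mann–Whitney U with BH FDR between case and control profiles.

    Profiles are samples x sets DataFrames sharing one set index.
    Returns a table indexed by set id with columns ``case_mean``,
    ``control_mean``, ``U``, ``p``, ``q``, ``significant``.
    """
    if list(case_profiles.columns) != list(control_profiles.columns):
        raise ValueError("case and control profiles must share one set index")
    if len(case_profiles) < 2 or len(control_profiles) < 2:
        raise ValueError("each group needs >= 2 samples")

    records = []
    for set_id in case_profiles.columns:
        u, p = mann_whitney(
            case_profiles[set_id].to_numpy(), control_profiles[set_id].to_numpy()
        )
        records.append((set_id, u, p))
    table = pd.DataFrame(records, columns=["set_id", "U", "p"]).set_index("set_id")
    table.insert(0, "control_mean", control_profiles.mean(axis=0))
    table.insert(0, "case_mean", case_profiles.mean(axis=0))
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table["significant"] = table["q"] < alpha
    return table


def group_summary(
    profiles: pd.DataFrame,
    control_profiles: pd.DataFrame,
    group: str = "case",
) -> GroupSummary:
    """Grand mean GSR over all sets and samples, case and control."""
    if profiles.size == 0 or control_profiles.size == 0:
        raise ValueError("cannot summarise an empty profile collection")
    return GroupSummary(
        group=group,
        mean_gsr=float(profiles.to_numpy().mean()),
        control_mean_gsr=float(control_profiles.to_numpy().mean()),
        n_samples=len(profiles),
        n_control_samples=len(control_profiles),
        n_sets=profiles.shape[1],
    )


def compute_cwi(
    table: pd.DataFrame,
    graph: nx.DiGraph | None = None,
    alpha: float = 0.05,
    epsilon: float = EPS_Q,
    svm_weights: pd.Series | None = None,
) -> pd.DataFrame:
    """Fill ``weight``, ``cluster_id``, ``cwi`` and ``cwi_rank`` columns.

    Significant terms (q < alpha) get weight w = -log10(max(q, epsilon));
    when ``svm_weights`` is given, w is additionally multiplied by the
    term's absolute classifier weight.  Clusters are the connected
    components of the significant-term subgraph induced on the GO
    graph's undirected ``is_a`` edges (one global cluster without a
    graph).  CWI normalises each weight by the total weight of all
    significant terms, so significant CWIs sum to 1; non-significant
    terms get CWI 0 and no rank.  Rank order is CWI descending, ties by
    set identifier.
    """
    out = table.copy()
    sig = out.index[out["q"] < alpha]
    out["weight"] = 0.0
    out["cluster_id"] = pd.array([pd.NA] * len(out), dtype="Int64")
    out["cwi"] = 0.0
    out["cwi_rank"] = pd.array([pd.NA] * len(out), dtype="Int64")
    if len(sig) == 0:
        logger.info("compute_cwi: no significant terms at q < %g", alpha)
        return out

    weights = -np.log10(np.maximum(out.loc[sig, "q"].to_numpy(), epsilon))
    if svm_weights is not None:
        weights = weights * np.abs(svm_weights.reindex(sig).fillna(0.0).to_numpy())
    out.loc[sig, "weight"] = weights

    if graph is not None:
        sub = graph.to_undirected().subgraph([t for t in sig if t in graph])
        components = list(nx.connected_components(sub))
        known = set(sub.nodes)
        components.extend({t} for t in sig if t not in known)
    else:
        components = [set(sig)]
    components.sort(key=lambda comp: min(comp))
    for cid, comp in enumerate(components, start=1):
        out.loc[list(comp), "cluster_id"] = cid

    total = out.loc[sig, "weight"].sum()
    if total > 0:
        out.loc[sig, "cwi"] = out.loc[sig, "weight"] / total
    # mergesort is stable; pre-sorting by id makes ties deterministic
    ordered = (
        out.loc[sig]
        .sort_index()
        .sort_values("cwi", ascending=False, kind="mergesort")
    )
    out.loc[ordered.index, "cwi_rank"] = np.arange(1, len(ordered) + 1)
    return out


def rank_pathways(
    table: pd.DataFrame,
    k: int = 50,
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Top-k dysfunctional pathways ranked by ascending p-value.

    Sets passing the significance threshold (raw p < alpha by default;
    q < alpha when ``use_adjusted``) are sorted by ascending p, ties by
    set identifier, and truncated to k.  Fewer than k rows are returned
    when fewer are significant.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    column = "q" if use_adjusted else "p"
    sig = table[table[column] < alpha]
    ordered = sig.sort_index().sort_values("p", kind="mergesort").head(k)
    result = ordered[["p", "q"]].copy()
    result["rank"] = np.arange(1, len(result) + 1)
    return result


def gsr_histogram(profiles: pd.DataFrame, bin_width: float = 0.02) -> pd.DataFrame:
    """Counts of GSR indices in fixed-width bins over [0, 1].

    One row per bin with its left edge and the number of (sample, set)
    index values falling in [left, left + width); the final bin is
    closed at 1.
    """
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(profiles.to_numpy().ravel(), bins=edges)
    return pd.DataFrame({"bin_left": edges[:-1], "count": counts})
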