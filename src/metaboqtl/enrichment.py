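"""Mean-rank gene-set enrichment (MR-GSE) of pathway-grouped metabotypes.

Each profiled component (metabolite or protein) carries a Pearson correlation
with the target trait; a pathway is enriched when its members' correlation
statistics rank significantly higher than the remaining components
(one-sided Wilcoxon rank-sum on midranks).  Components of significantly
enriched pathways become the intermediate phenotypes taken forward to GWAS.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EXACT_ENUMERATION_LIMIT = 100_000


@dataclass
class Pathway:
    pathway_id: str
    name: str
    members: set[str]


@dataclass
class PathwayCatalog:
    """Named sets of component identifiers (GMT-style pathway catalog)."""

    pathways: dict[str, Pathway] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways.values())

    def add(self, pathway_id: str, name: str, members) -> None:
        members = set(members)
        if not members:
            raise ValueError(f"pathway {pathway_id} has no members")
        self.pathways[pathway_id] = Pathway(pathway_id, name, members)


def read_gmt(path) -> PathwayCatalog:
    catalog = PathwayCatalog()
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line needs id, description, >=1 member: {line!r}")
            catalog.add(fields[0], fields[1], [f for f in fields[2:] if f])
    return catalog


def write_gmt(catalog: PathwayCatalog, path) -> None:
    with open(path, "w") as fh:
        for pw in catalog:
            fh.write("\t".join([pw.pathway_id, pw.name, *sorted(pw.members)]) + "\n")


def rank_statistics(correlations: pd.Series, mode: str = "mixed") -> pd.Series:
    """Midranks of per-component correlation statistics (largest = top rank m).

    ``mode="mixed"`` ranks |r| (direction-agnostic enrichment, the default);
    ``mode="signed"`` ranks r itself.  NaN statistics are dropped.
    """
    if mode not in ("mixed", "signed"):
        raise ValueError(f"unknown mode {mode!r}")
    vals = correlations.dropna().astype(float)
    if len(vals) < 2:
        raise ValueError("need at least 2 finite statistics to rank")
    stat = vals.abs() if mode == "mixed" else vals
    ranks = stats.rankdata(stat.to_numpy(), method="average")
    return pd.Series(ranks, index=vals.index)


def mr_gse_pvalue(
    ranks: pd.Series | np.ndarray,
    member_mask: np.ndarray,
    exact_limit: int = EXACT_ENUMERATION_LIMIT,
) -> float:
    """One-sided rank-sum p for "member statistics rank higher than the rest".

    Exact enumeration over all C(m, k) member placements when that count is
    at most 1e5 (p = proportion of placements whose rank-sum reaches the
    observed one, so p is never 0); otherwise the normal approximation with
    tie and continuity corrections.
    """
    r = np.asarray(ranks, dtype=float)
    mask = np.asarray(member_mask, dtype=bool)
    m = len(r)
    k = int(mask.sum())
    if not 1 <= k < m:
        raise ValueError(f"member set size {k} must satisfy 1 <= k < {m}")
    w_obs = r[mask].sum()
    if math.comb(m, k) <= exact_limit:
        tol = 1e-9 * m
        n_ge = sum(1 for combo in combinations(r, k) if sum(combo) >= w_obs - tol)
        return n_ge / math.comb(m, k)
    mean = k * (m + 1) / 2.0
    _, tie_counts = np.unique(r, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (m * (m - 1.0))
    var = k * (m - k) / 12.0 * ((m + 1) - tie_term)
    if var <= 0:  # all statistics tied
        return 0.5
    z = (w_obs - mean - 0.5) / math.sqrt(var)
    return float(min(1.0, max(np.nextafter(0, 1), stats.norm.sf(z))))


def enrich_catalog(
    catalog: PathwayCatalog,
    correlations: pd.Series,
    alpha: float = 0.05,
    mode: str = "mixed",
) -> pd.DataFrame:
    """MR-GSE p-value per pathway; unadjusted p <= alpha flags significance.

    No cross-pathway multiple-testing correction is applied.  Members without
    a profiled correlation are dropped (logged); pathways left with no
    profiled member are skipped.  Result is sorted ascending by p.
    """
    ranks = rank_statistics(correlations, mode=mode)
    universe = list(ranks.index)
    rank_arr = ranks.to_numpy()
    pos = {c: i for i, c in enumerate(universe)}
    rows = []
    for pw in catalog:
        profiled = sorted(pw.members & set(universe))
        dropped = pw.members - set(universe)
        if dropped:
            logger.info(
                "pathway %s: dropping %d unprofiled member(s): %s",
                pw.pathway_id, len(dropped), ",".join(sorted(dropped)),
            )
        if not profiled:
            continue
        if len(profiled) == len(universe):
            logger.warning(
                "pathway %s equals the component universe; skipped", pw.pathway_id
            )
            continue
        mask = np.zeros(len(universe), dtype=bool)
        mask[[pos[c] for c in profiled]] = True
        p = mr_gse_pvalue(rank_arr, mask)
        rows.append(
            {
                "pathway_id": pw.pathway_id,
                "name": pw.name,
                "n_members_profiled": len(profiled),
                "members": ";".join(profiled),
                "p_value": p,
                "significant": p <= alpha,
            }
        )
    if not rows:
        raise ValueError("no pathway has a profiled member")
    out = pd.DataFrame(rows).sort_values(
        ["p_value", "pathway_id"], kind="mergesort", ignore_index=True
    )
    return out


def select_gwas_traits(enrichment: pd.DataFrame, target_trait: str) -> list[str]:
    """Union of members of significant pathways, plus the target trait.

    The target trait comes first, followed by member components sorted by id.
    With no significant pathway the list is just the target (warned).
    """
    sig = enrichment[enrichment.significant]
    members: set[str] = set()
    for mm in sig.members:
        members.update(mm.split(";"))
    members.discard(target_trait)
    if not members:
        logger.warning("no significant pathway; GWAS will run on the target trait only")
    return [target_trait, *sorted(members)]
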