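"""QTL condensation, cross-trait overlap, gene windowing and candidate genes.

Significant SNPs (q <= 0.1 by default) are chained into QTL regions per
chromosome: consecutive SNPs closer than 1 Mb belong to one region.  Genes
are read from GFF3; each significant SNP is classified against the gene
models (exonic / intronic / genic-unresolved when the gene carries no exon
records / within-1Mb neighbor), and candidate genes are those hit by a SNP
that is simultaneously (1) significant, (2) inside the per-trait top list
(Top 10 for metabotypes, Top 25 for the target trait) and (3) located inside
an annotated gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

QTL_GAP_BP = 1_000_000
GENE_WINDOW_BP = 1_000_000
IN_GENE_CLASSES = ("exonic", "intronic", "genic-unresolved")


@dataclass
class QTLRegion:
    trait_id: str
    chrom: str
    start_bp: int
    end_bp: int
    snp_ids: list[str]
    best_p: float
    best_q: float
    max_var_pct: float

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp > end_bp")


@dataclass
class GeneModel:
    gene_id: str
    symbol: str
    chrom: str
    start_bp: int
    end_bp: int
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"gene {self.gene_id}: invalid span")
        for es, ee in self.exons:
            if es > ee or es < self.start_bp or ee > self.end_bp:
                raise ValueError(f"gene {self.gene_id}: exon outside gene span")


@dataclass
class CandidateGene:
    gene_id: str
    trait_id: str
    supporting_snps: list[dict]  # snp_id, pos_bp, location_class, p, q, rank


def read_gff3(path) -> list[GeneModel]:
    """Load gene and exon features from GFF3 (1-based inclusive)."""
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = sorted(
            (e.start, e.end) for e in db.children(g, featuretype="exon")
        )
        name = g.attributes.get("Name", [g.id])[0]
        genes.append(
            GeneModel(
                gene_id=g.id, symbol=name, chrom=str(g.seqid),
                start_bp=g.start, end_bp=g.end, strand=g.strand or "+",
                exons=exons,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start_bp, g.gene_id))
    return genes


def condense_qtl(
    records: pd.DataFrame, gap_bp: int = QTL_GAP_BP
) -> list[QTLRegion]:
    """Chain one trait's significant SNPs into QTL regions per chromosome.

    Single-linkage: consecutive positions with distance < gap_bp join the
    same region.  Output ordered by (chrom, start).
    """
    regions: list[QTLRegion] = []
    if records.empty:
        return regions
    traits = records.trait_id.unique()
    if len(traits) != 1:
        raise ValueError("condense_qtl expects records of exactly one trait")
    trait = traits[0]
    for chrom, grp in records.groupby("chrom", sort=False):
        grp = grp.sort_values("pos_bp")
        pos = grp.pos_bp.to_numpy()
        breaks = np.flatnonzero(np.diff(pos) >= gap_bp) + 1
        for block in np.split(np.arange(len(pos)), breaks):
            sub = grp.iloc[block]
            regions.append(
                QTLRegion(
                    trait_id=trait,
                    chrom=str(chrom),
                    start_bp=int(sub.pos_bp.min()),
                    end_bp=int(sub.pos_bp.max()),
                    snp_ids=list(sub.snp_id),
                    best_p=float(sub.p_value.min()),
                    best_q=float(sub.q_value.min()),
                    max_var_pct=float(sub.var_explained_pct.max()),
                )
            )
    regions.sort(key=lambda r: (int(r.chrom) if r.chrom.isdigit() else 10**9,
                                r.chrom, r.start_bp))
    return regions


def regions_frame(regions: list[QTLRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trait_id": r.trait_id, "chrom": r.chrom,
                "start_bp": r.start_bp, "end_bp": r.end_bp,
                "n_snps": len(r.snp_ids), "snp_ids": ";".join(r.snp_ids),
                "best_p": r.best_p, "best_q": r.best_q,
                "max_var_pct": r.max_var_pct,
            }
            for r in regions
        ]
    )


def find_overlaps(
    significant: pd.DataFrame, regions_by_trait: dict[str, list[QTLRegion]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-trait shared SNPs and intersecting QTL regions.

    A SNP overlaps when significant for >= 2 traits; two regions overlap
    when they come from different traits, sit on the same chromosome and
    their [start, end] intervals intersect.
    """
    snp_traits = (
        significant.groupby("snp_id")
        .agg(chrom=("chrom", "first"), pos_bp=("pos_bp", "first"),
             traits=("trait_id", lambda t: sorted(set(t))))
        .reset_index()
    )
    snp_overlap = snp_traits[snp_traits.traits.str.len() >= 2].copy()
    snp_overlap["traits"] = snp_overlap.traits.str.join(";")
    snp_overlap = snp_overlap.sort_values(["chrom", "pos_bp"], ignore_index=True)

    rows = []
    traits = sorted(regions_by_trait)
    for i, ta in enumerate(traits):
        for tb in traits[i + 1:]:
            for ra in regions_by_trait[ta]:
                for rb in regions_by_trait[tb]:
                    if ra.chrom != rb.chrom:
                        continue
                    lo = max(ra.start_bp, rb.start_bp)
                    hi = min(ra.end_bp, rb.end_bp)
                    if lo <= hi:
                        rows.append(
                            {
                                "chrom": ra.chrom,
                                "trait_a": ta, "region_a": f"{ra.start_bp}-{ra.end_bp}",
                                "trait_b": tb, "region_b": f"{rb.start_bp}-{rb.end_bp}",
                                "overlap_start": lo, "overlap_end": hi,
                            }
                        )
    qtl_overlap = pd.DataFrame(
        rows, columns=["chrom", "trait_a", "region_a", "trait_b", "region_b",
                       "overlap_start", "overlap_end"],
    )
    return snp_overlap, qtl_overlap


def classify_snp_location(
    chrom: str,
    pos_bp: int,
    genes: list[GeneModel],
    window_bp: int = GENE_WINDOW_BP,
) -> list[dict]:
    """Classify one SNP against every gene on its chromosome.

    Inside an exon -> exonic; inside the gene span outside all exons ->
    intronic; inside a span with no exon records -> genic-unresolved;
    otherwise genes whose span lies within ``window_bp`` (inclusive) are
    reported as within-1Mb neighbors with their distance.
    """
    chrom_genes = [g for g in genes if g.chrom == str(chrom)]
    if not chrom_genes and genes:
        logger.warning("chromosome %s absent from annotation", chrom)
    out = []
    for g in chrom_genes:
        if g.start_bp <= pos_bp <= g.end_bp:
            if any(es <= pos_bp <= ee for es, ee in g.exons):
                cls = "exonic"
            elif g.exons:
                cls = "intronic"
            else:
                cls = "genic-unresolved"
            dist = 0
        else:
            dist = g.start_bp - pos_bp if pos_bp < g.start_bp else pos_bp - g.end_bp
            if dist > window_bp:
                continue
            cls = "within-1Mb"
        out.append({"gene_id": g.gene_id, "symbol": g.symbol,
                    "location_class": cls, "distance_bp": dist})
    return out


def significant_records(
    assoc: pd.DataFrame, q_threshold: float = 0.1
) -> pd.DataFrame:
    return assoc[assoc.q_value <= q_threshold].copy()


def select_candidates(
    assoc: pd.DataFrame,
    genes: list[GeneModel],
    target_trait: str,
    q_threshold: float = 0.1,
    top_n_metabotype: int = 10,
    top_n_target: int = 25,
    window_bp: int = GENE_WINDOW_BP,
) -> tuple[list[CandidateGene], pd.DataFrame]:
    """Apply the three candidate-gene criteria per trait.

    Per trait the significant SNPs (q <= q_threshold) are ranked ascending
    by p (ties by q, then position); ranks up to Top-N (25 for the target
    trait, 10 otherwise) that fall inside an annotated gene nominate that
    gene.  Returns candidates plus a report table ordered by chromosome and
    position, one row per supporting SNP x gene.
    """
    candidates: dict[tuple[str, str], CandidateGene] = {}
    report_rows = []
    for trait, grp in assoc.groupby("trait_id", sort=True):
        sig = grp[grp.q_value <= q_threshold].sort_values(
            ["p_value", "q_value", "pos_bp"], kind="mergesort"
        )
        top_n = top_n_target if trait == target_trait else top_n_metabotype
        for rank, (_, row) in enumerate(sig.head(top_n).iterrows(), start=1):
            hits = classify_snp_location(row.chrom, int(row.pos_bp), genes, window_bp)
            for h in hits:
                if h["location_class"] not in IN_GENE_CLASSES:
                    continue
                key = (h["gene_id"], trait)
                snp_info = {
                    "snp_id": row.snp_id, "pos_bp": int(row.pos_bp),
                    "location_class": h["location_class"],
                    "p_value": row.p_value, "q_value": row.q_value, "rank": rank,
                }
                if key not in candidates:
                    candidates[key] = CandidateGene(h["gene_id"], trait, [])
                candidates[key].supporting_snps.append(snp_info)
                report_rows.append(
                    {
                        "chrom": row.chrom, "trait_id": trait,
                        "gene_id": h["gene_id"], "symbol": h["symbol"],
                        "snp_id": row.snp_id, "pos_bp": int(row.pos_bp),
                        "location_class": h["location_class"],
                        "maf": row.maf, "effect": row.effect, "se": row.se,
                        "chi2": row.chi2, "p_value": row.p_value,
                        "q_value": row.q_value,
                        "var_explained_pct": row.var_explained_pct,
                        "top_rank": rank,
                    }
                )
    report = pd.DataFrame(
        report_rows,
        columns=["chrom", "trait_id", "gene_id", "symbol", "snp_id", "pos_bp",
                 "location_class", "maf", "effect", "se", "chi2", "p_value",
                 "q_value", "var_explained_pct", "top_rank"],
    )
    if not report.empty:
        report["_c"] = [int(c) if str(c).isdigit() else 10**9 for c in report.chrom]
        report = report.sort_values(["_c", "chrom", "pos_bp", "trait_id"],
                                    ignore_index=True).drop(columns="_c")
    ordered = sorted(candidates.values(),
                     key=lambda c: (c.trait_id, c.gene_id))
    return ordered, report
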