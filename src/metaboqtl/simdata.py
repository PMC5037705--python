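"""Synthetic genotype/metabotype/trait datasets with a truth ledger.

The generator emulates the statistical structure of an F2 pig meat-quality
study: ~97 animals genotyped at tens of thousands of SNPs on 18 autosomes,
163 metabolic components (128 metabolites + 35 proteins) grouped into ~219
pathways, and a drip-loss-like target trait (percent weight loss, realistic
range 0.4–5.3%) influenced by slaughter date, slaughter weight and, through
latent pathway activities, by a handful of causal SNPs.

Population structure is modelled as a two-subpopulation admixture (the
pedigree of a real reciprocal cross is simplified to the one property the
pipeline needs — PC-detectable stratification).  The causal chain is

    causal SNP dosage --(effect)--> pathway activity --(loading)--> member
    component abundance, and --(weight)--> target trait,

so planted signal is recoverable both through the metabotypes and through
the trait.  Every planted quantity is recorded in a :class:`TruthSet` for
parameter-recovery tests.  All output files are the same formats the
pipeline consumes (PED/MAP, TSV, GMT, GFF3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import PathwayCatalog, write_gmt
from .genotype import GenotypePanel, SNPRecord, write_ped_map

logger = logging.getLogger(__name__)

TARGET_TRAIT = "drip_loss"


@dataclass
class SimConfig:
    """All knobs of the generator; identical config (incl. seed) gives
    byte-identical output files."""

    n_samples: int = 97
    n_snps: int = 45_000
    n_chromosomes: int = 18
    chrom_length_bp: int = 150_000_000
    n_metabolites: int = 128
    n_proteins: int = 35
    n_pathways: int = 219
    components_per_pathway: tuple[int, int] = (2, 10)
    n_causal_snps: int = 3
    snp_effect_sd: float = 1.0       # |effect| of a causal SNP on its pathway activity
    activity_noise_sd: float = 0.5   # non-genetic noise in pathway activity
    component_loading: float = 1.0   # pathway activity -> member abundance
    component_noise_sd: float = 0.8  # per-component measurement noise
    pathway_weight_sd: float = 1.0   # |weight| of a causal pathway on the trait (%)
    stratification: str = "two_subpop"  # "off" or "two_subpop"
    divergence: float = 0.15         # founder allele-frequency separation in [0, 1]
    subpop_trait_shift: float = 0.0  # confounding shift of the trait (%) for subpop B
    n_slaughter_dates: int = 6
    date_effect_sd: float = 0.3      # sd of slaughter-date shifts (%)
    weight_beta: float = 0.05        # trait change per kg slaughter weight (%/kg)
    residual_sd: float = 0.8         # trait residual sd (%)
    missing_geno_rate: float = 0.01
    trait_range: tuple[float, float] = (0.4, 5.3)
    n_distractor_genes: int = 30
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_samples": self.n_samples, "n_snps": self.n_snps,
            "n_chromosomes": self.n_chromosomes, "chrom_length_bp": self.chrom_length_bp,
            "n_metabolites": self.n_metabolites, "n_proteins": self.n_proteins,
            "n_pathways": self.n_pathways, "n_slaughter_dates": self.n_slaughter_dates,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        for name, v in (("missing_geno_rate", self.missing_geno_rate),
                        ("divergence", self.divergence)):
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_snps < self.n_chromosomes:
            raise ValueError(
                f"n_snps ({self.n_snps}) < n_chromosomes ({self.n_chromosomes})"
            )
        if self.stratification not in ("off", "two_subpop"):
            raise ValueError(f"unknown stratification {self.stratification!r}")
        lo, hi = self.components_per_pathway
        if not 1 <= lo <= hi:
            raise ValueError("components_per_pathway must be a valid (lo, hi) range")
        if self.n_causal_snps < 0 or self.n_causal_snps > self.n_pathways:
            raise ValueError("n_causal_snps must be in [0, n_pathways]")


@dataclass
class TruthSet:
    """Ledger of everything the generator planted."""

    causal_snps: list[tuple[str, str, float]] = field(default_factory=list)
    pathway_weights: dict[str, float] = field(default_factory=dict)
    date_effects: dict[str, float] = field(default_factory=dict)
    weight_beta: float = 0.0
    subpop_assignment: dict[str, str] = field(default_factory=dict)
    trait_scale: tuple[float, float] = (0.0, 1.0)  # y_final = a + b * y_raw
    causal_genes: dict[str, str] = field(default_factory=dict)  # snp -> gene


@dataclass
class SimulatedDataset:
    config: SimConfig
    panel: GenotypePanel
    metabotypes: pd.DataFrame           # samples x components
    catalog: PathwayCatalog
    traits: pd.DataFrame                # sample_id, drip_loss, slaughter_date, slaughter_weight
    activities: pd.DataFrame            # samples x causal pathways (latent)
    truth: TruthSet


def simulate_panel(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypePanel, dict[str, str]]:
    """Genotype panel under a one- or two-subpopulation binomial model.

    Under ``two_subpop`` each SNP's base frequency p ~ Beta(2,2) (rescaled to
    [0.05, 0.95]) is split symmetrically into founder frequencies
    p ± divergence/2 (clipped), and samples are assigned half/half to the
    two subpopulations.  Dosages are Binomial(2, p_subpop) counts of the 'B'
    allele, then flipped where needed so dosage counts the realized minor
    allele.  Missing calls are injected MCAR at ``missing_geno_rate``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_snps
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]

    base = 0.05 + 0.90 * rng.beta(2.0, 2.0, size=m)
    if config.stratification == "two_subpop":
        half = config.divergence / 2.0
        p1 = np.clip(base + half, 0.01, 0.99)
        p2 = np.clip(base - half, 0.01, 0.99)
        labels = np.array(["A"] * (n - n // 2) + ["B"] * (n // 2))
        freq = np.where(labels[:, None] == "A", p1[None, :], p2[None, :])
    else:
        labels = np.array(["A"] * n)
        freq = np.broadcast_to(base, (n, m)).copy()
    dosages = rng.binomial(2, freq).astype(float)
    if config.missing_geno_rate > 0:
        miss = rng.random((n, m)) < config.missing_geno_rate
        dosages[miss] = np.nan

    # flip to minor-allele coding so a PED round trip reproduces the matrix;
    # at an exact 50/50 tie 'B' stays counted (it sorts after 'A')
    counted = np.nansum(dosages, axis=0)
    called = 2 * (~np.isnan(dosages)).sum(axis=0)
    flip = counted > called - counted
    dosages[:, flip] = 2.0 - dosages[:, flip]

    # SNP placement: spread evenly over chromosomes, random distinct positions
    per_chrom = np.full(config.n_chromosomes, m // config.n_chromosomes)
    per_chrom[: m % config.n_chromosomes] += 1
    snps: list[SNPRecord] = []
    j = 0
    for c in range(config.n_chromosomes):
        k = int(per_chrom[c])
        pos = np.sort(rng.choice(config.chrom_length_bp, size=k, replace=False)) + 1
        for p_bp in pos:
            alleles = ("B", "A") if flip[j] else ("A", "B")
            snps.append(SNPRecord(f"SNP{j + 1:05d}", str(c + 1), int(p_bp), alleles))
            j += 1
    panel = GenotypePanel(sample_ids=sample_ids, snps=snps, dosages=dosages)
    return panel, dict(zip(sample_ids, labels))


def simulate_catalog(config: SimConfig, rng: np.random.Generator) -> PathwayCatalog:
    """Pathway catalog over M###/P### component ids; overlap allowed."""
    comps = [f"M{i + 1:03d}" for i in range(config.n_metabolites)]
    comps += [f"P{i + 1:03d}" for i in range(config.n_proteins)]
    lo, hi = config.components_per_pathway
    hi = min(hi, len(comps))
    catalog = PathwayCatalog()
    for k in range(config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(comps, size=size, replace=False)
        catalog.add(f"map{k + 1:04d}", f"synthetic pathway {k + 1}", members)
    return catalog


def simulate_metabotypes(
    panel: GenotypePanel,
    catalog: PathwayCatalog,
    config: SimConfig,
    rng: np.random.Generator,
    truth: TruthSet | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthSet]:
    """Component abundances driven by causal-SNP-loaded pathway activities.

    ``n_causal_snps`` SNPs (drawn among intermediate-frequency SNPs so the
    MAF filter cannot remove them) each load one distinct pathway:
    activity = effect * dosage + N(0, activity_noise_sd).  Members of a
    causal pathway read ``loading * activity`` plus noise; all other
    components are pure noise.  Effects have magnitude ``snp_effect_sd``
    with random sign.  Returns (abundances, activities, truth).
    """
    if truth is None:
        truth = TruthSet()
    for pw in catalog:
        if not pw.members:
            raise ValueError(f"pathway {pw.pathway_id} has no members")
    n = panel.n_samples
    comps = sorted({c for pw in catalog for c in pw.members})
    freq = np.nansum(panel.dosages, axis=0) / (2 * (~np.isnan(panel.dosages)).sum(axis=0))
    eligible = np.flatnonzero((freq >= 0.3) & (freq <= 0.7))
    if config.n_causal_snps > 0 and len(eligible) < config.n_causal_snps:
        raise ValueError("not enough intermediate-frequency SNPs for causal planting")
    causal_idx = (
        np.sort(rng.choice(eligible, size=config.n_causal_snps, replace=False))
        if config.n_causal_snps
        else np.array([], dtype=int)
    )
    pathway_ids = sorted(catalog.pathways)
    causal_pw = (
        rng.choice(pathway_ids, size=config.n_causal_snps, replace=False)
        if config.n_causal_snps
        else np.array([], dtype=object)
    )

    activities: dict[str, np.ndarray] = {}
    truth.causal_snps = []
    for idx, pw_id in zip(causal_idx, causal_pw):
        g = panel.dosages[:, idx].copy()
        g[np.isnan(g)] = np.nanmean(g)  # missing calls read the mean dosage
        eff = config.snp_effect_sd * rng.choice([-1.0, 1.0])
        a = eff * g + rng.normal(0.0, config.activity_noise_sd, size=n)
        activities[str(pw_id)] = a
        truth.causal_snps.append((panel.snps[idx].snp_id, str(pw_id), float(eff)))

    abund = pd.DataFrame(
        rng.normal(10.0, config.component_noise_sd, size=(n, len(comps))),
        index=panel.sample_ids, columns=comps,
    )
    for pw_id, a in activities.items():
        for comp in sorted(catalog.pathways[pw_id].members):
            abund[comp] = abund[comp] + config.component_loading * a
    if not np.isfinite(abund.to_numpy()).all():
        raise ValueError("non-finite abundance generated")
    act_df = pd.DataFrame(activities, index=panel.sample_ids)
    return abund, act_df, truth


def simulate_target_trait(
    activities: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    truth: TruthSet,
    subpops: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Target trait plus slaughter covariates.

    trait = 2 + sum_p weight_p * activity_p + date effect + weight_beta *
    (centered slaughter weight) [+ subpop shift] + N(0, residual_sd), then
    affinely rescaled into ``trait_range`` only if the realized values stray
    outside it; the affine coefficients are recorded in the truth ledger.
    Slaughter dates are assigned round-robin; slaughter weights are
    N(86.5, 5) kg clipped to [73, 102].
    """
    n = len(activities.index)
    sample_ids = list(activities.index)
    dates = [f"D{(i % config.n_slaughter_dates) + 1}" for i in range(n)]
    levels = [f"D{j + 1}" for j in range(config.n_slaughter_dates)]
    date_eff = {lv: float(rng.normal(0.0, config.date_effect_sd)) for lv in levels}
    weights = np.clip(rng.normal(86.5, 5.0, size=n), 73.0, 102.0)

    pw_weights = {
        pw: config.pathway_weight_sd * float(rng.choice([-1.0, 1.0]))
        for pw in activities.columns
    }
    y = np.full(n, 2.0)
    for pw, w in pw_weights.items():
        y = y + w * activities[pw].to_numpy()
    y = y + np.array([date_eff[d] for d in dates])
    y = y + config.weight_beta * (weights - weights.mean())
    if subpops is not None and config.subpop_trait_shift:
        y = y + np.where(
            np.array([subpops[s] for s in sample_ids]) == "B",
            config.subpop_trait_shift, 0.0,
        )
    y = y + rng.normal(0.0, config.residual_sd, size=n)

    lo, hi = config.trait_range
    if y.min() < lo or y.max() > hi:
        span = y.max() - y.min()
        b = (hi - lo) / span if span > 0 else 1.0
        a = lo - b * y.min()
        y = a + b * y
    else:
        a, b = 0.0, 1.0

    truth.pathway_weights = pw_weights
    truth.date_effects = date_eff
    truth.weight_beta = config.weight_beta
    truth.trait_scale = (float(a), float(b))
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            TARGET_TRAIT: y,
            "slaughter_date": dates,
            "slaughter_weight": weights,
        }
    )


def _toy_gff3(panel: GenotypePanel, config: SimConfig,
              rng: np.random.Generator, truth: TruthSet) -> list[str]:
    """GFF3 lines: one gene spanning each causal SNP (SNP falls in an intron)
    plus distractor genes elsewhere."""
    pos_by_id = {s.snp_id: (s.chrom, s.pos_bp) for s in panel.snps}
    genes = []  # (chrom, start, end, gene_id, exons)
    for i, (snp_id, _, _) in enumerate(truth.causal_snps):
        chrom, pos = pos_by_id[snp_id]
        start = max(1, pos - 40_000)
        end = pos + 60_000
        exons = [(start, start + 10_000), (start + 20_000, start + 30_000),
                 (end - 10_000, end)]
        gid = f"GENE_C{i + 1:02d}"
        genes.append((chrom, start, end, gid, exons))
        truth.causal_genes[snp_id] = gid
    for i in range(config.n_distractor_genes):
        chrom = str(int(rng.integers(1, config.n_chromosomes + 1)))
        start = int(rng.integers(1, max(2, config.chrom_length_bp - 100_000)))
        end = start + 100_000
        exons = [(start, start + 8_000), (end - 8_000, end)]
        genes.append((chrom, start, end, f"GENE_D{i + 1:03d}", exons))
    genes.sort(key=lambda g: (int(g[0]), g[1]))
    lines = ["##gff-version 3"]
    for chrom, start, end, gid, exons in genes:
        lines.append(
            f"{chrom}\tsim\tgene\t{start}\t{end}\t.\t+\t.\tID={gid};Name={gid}"
        )
        for k, (es, ee) in enumerate(exons):
            lines.append(
                f"{chrom}\tsim\texon\t{es}\t{ee}\t.\t+\t.\t"
                f"ID={gid}.exon{k + 1};Parent={gid}"
            )
    return lines


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the full generator with one seed-derived random stream."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    panel, subpops = simulate_panel(config, rng)
    catalog = simulate_catalog(config, rng)
    truth = TruthSet(subpop_assignment=subpops)
    abund, activities, truth = simulate_metabotypes(panel, catalog, config, rng, truth)
    traits = simulate_target_trait(activities, config, rng, truth, subpops)
    return SimulatedDataset(config, panel, abund, catalog, traits, activities, truth)


def write_truth(truth: TruthSet, path) -> None:
    rows = []
    for snp, pw, eff in truth.causal_snps:
        rows.append(("causal_snp", snp, pw, eff))
    for pw, w in sorted(truth.pathway_weights.items()):
        rows.append(("pathway_weight", pw, "", w))
    for lv, e in sorted(truth.date_effects.items()):
        rows.append(("date_effect", lv, "", e))
    rows.append(("weight_beta", "slaughter_weight", "", truth.weight_beta))
    for sid, lab in sorted(truth.subpop_assignment.items()):
        rows.append(("subpop", sid, lab, ""))
    rows.append(("trait_scale", "a", "", truth.trait_scale[0]))
    rows.append(("trait_scale", "b", "", truth.trait_scale[1]))
    for snp, gid in sorted(truth.causal_genes.items()):
        rows.append(("causal_gene", snp, gid, ""))
    pd.DataFrame(rows, columns=["record_type", "id", "aux", "value"]).to_csv(
        path, sep="\t", index=False
    )


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"id": str, "aux": str})


def write_fixture_bundle(dataset: SimulatedDataset, directory) -> dict[str, Path]:
    """Write every artifact the pipeline consumes; returns name -> path.

    Files: genotypes.ped/.map, traits.tsv, metabotypes.tsv, pathways.gmt,
    genes.gff3, truth.tsv.  Numeric TSVs carry full float precision so a
    read-back reproduces the in-memory matrices bit for bit.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {name: directory / fname for name, fname in [
        ("ped", "genotypes.ped"), ("map", "genotypes.map"),
        ("traits", "traits.tsv"), ("metabotypes", "metabotypes.tsv"),
        ("gmt", "pathways.gmt"), ("gff3", "genes.gff3"), ("truth", "truth.tsv"),
    ]}
    write_ped_map(dataset.panel, paths["ped"], paths["map"])
    dataset.traits.to_csv(paths["traits"], sep="\t", index=False, float_format="%.17g")
    dataset.metabotypes.rename_axis("sample_id").to_csv(
        paths["metabotypes"], sep="\t", float_format="%.17g"
    )
    write_gmt(dataset.catalog, paths["gmt"])
    rng_gff = np.random.default_rng(dataset.config.seed + 987_654_321)
    lines = _toy_gff3(dataset.panel, dataset.config, rng_gff, dataset.truth)
    paths["gff3"].write_text("\n".join(lines) + "\n")
    write_truth(dataset.truth, paths["truth"])
    return paths
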