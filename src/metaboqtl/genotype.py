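"""Genotype panel I/O (PLINK text PED/MAP) and SNP quality control.

The panel stores allele-dosage genotypes (count of the minor allele, so
dosages lie in {0, 1, 2} with NaN for no-calls) together with per-SNP map
metadata.  QC applies the three standard marker filters — minor allele
frequency, call rate and Hardy–Weinberg equilibrium — with exclusive
thresholds: a SNP is removed when MAF < 1%, call rate < 95% or HWE p < 1e-3
(equality survives).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MISSING_ALLELE = "0"


@dataclass
class SNPRecord:
    """Map metadata plus QC statistics for one biallelic SNP.

    ``alleles`` is (major, minor); dosage counts the minor allele, hence
    ``maf`` <= 0.5 by construction.  QC fields are NaN until computed.
    """

    snp_id: str
    chrom: str
    pos_bp: int
    alleles: tuple[str, str] = ("0", "0")
    maf: float = np.nan
    call_rate: float = np.nan
    hwe_p: float = np.nan


@dataclass
class GenotypePanel:
    sample_ids: list[str]
    snps: list[SNPRecord]
    dosages: np.ndarray  # n_samples x n_snps, float, NaN = missing

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.snps):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids")
        by_chrom: dict[str, int] = {}
        for s in self.snps:
            last = by_chrom.get(s.chrom)
            if last is not None and s.pos_bp <= last:
                raise ValueError(
                    f"positions not strictly increasing on chrom {s.chrom} at {s.snp_id}"
                )
            by_chrom[s.chrom] = s.pos_bp
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be in {0, 1, 2} or NaN")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def subset_snps(self, keep: np.ndarray) -> "GenotypePanel":
        """Return a panel restricted to SNP indices ``keep`` (order preserved)."""
        keep = np.asarray(keep)
        return GenotypePanel(
            sample_ids=list(self.sample_ids),
            snps=[replace(self.snps[i]) for i in keep],
            dosages=self.dosages[:, keep].copy(),
        )


def _encode_snp(a1: np.ndarray, a2: np.ndarray) -> tuple[np.ndarray, tuple[str, str]]:
    """Encode one SNP's two allele columns to minor-allele dosage.

    Returns (dosage vector with NaN missing, (major, minor)).  The minor
    allele is the rarer of the two observed alleles; at an exact tie the
    alphabetically later allele is counted.  Monomorphic SNPs get dosage 0
    everywhere with the unobserved allele recorded as '0'.
    """
    called = (a1 != MISSING_ALLELE) & (a2 != MISSING_ALLELE)
    if (called != ((a1 != MISSING_ALLELE) | (a2 != MISSING_ALLELE))).any():
        raise ValueError("half-missing genotype (one allele '0')")
    obs = np.concatenate([a1[called], a2[called]])
    alleles, counts = np.unique(obs, return_counts=True)
    if len(alleles) > 2:
        raise ValueError(f"non-biallelic site: alleles {sorted(alleles)}")
    dose = np.full(a1.shape, np.nan)
    if len(alleles) == 0:  # all missing
        return dose, ("0", "0")
    if len(alleles) == 1:
        dose[called] = 0.0
        return dose, (str(alleles[0]), "0")
    # two observed alleles; alleles[] is sorted alphabetically
    if counts[0] < counts[1]:
        minor, major = alleles[0], alleles[1]
    else:  # tie -> alphabetically later counted
        minor, major = alleles[1], alleles[0]
    dose[called] = (a1[called] == minor).astype(float) + (a2[called] == minor).astype(float)
    return dose, (str(major), str(minor))


def read_ped_map(ped_path, map_path) -> GenotypePanel:
    """Read a PLINK-text PED/MAP pair into a minor-allele-dosage panel."""
    map_df = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos_bp"], dtype={"chrom": str},
    )
    m = len(map_df)
    sample_ids: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * m:
                raise ValueError(
                    f"PED line {lineno}: expected {6 + 2 * m} fields for "
                    f"{m} MAP SNPs, got {len(tok)}"
                )
            sample_ids.append(tok[1])
            allele_rows.append(np.array(tok[6:], dtype="U8"))
    if not allele_rows:
        raise ValueError("empty PED file")
    alleles = np.vstack(allele_rows)  # n x 2m
    a1 = alleles[:, 0::2]
    a2 = alleles[:, 1::2]
    dosages = np.empty((len(sample_ids), m))
    snps: list[SNPRecord] = []
    for j in range(m):
        try:
            dosages[:, j], pair = _encode_snp(a1[:, j], a2[:, j])
        except ValueError as exc:
            raise ValueError(f"SNP {map_df.snp_id[j]}: {exc}") from exc
        snps.append(
            SNPRecord(
                snp_id=str(map_df.snp_id[j]),
                chrom=str(map_df.chrom[j]),
                pos_bp=int(map_df.pos_bp[j]),
                alleles=pair,
            )
        )
    return GenotypePanel(sample_ids=sample_ids, snps=snps, dosages=dosages)


def write_ped_map(panel: GenotypePanel, ped_path, map_path) -> None:
    """Write the panel back to PED/MAP (dosage 2 -> minor/minor, NaN -> '0 0')."""
    with open(map_path, "w") as fh:
        for s in panel.snps:
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos_bp}\n")
    major = np.array([s.alleles[0] for s in panel.snps], dtype="U8")
    minor = np.array([s.alleles[1] for s in panel.snps], dtype="U8")
    # for monomorphic SNPs the 'minor' slot may be '0'; dosage there is 0
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(panel.sample_ids):
            d = panel.dosages[i]
            a1 = np.where(np.isnan(d), MISSING_ALLELE, np.where(d >= 1, minor, major))
            a2 = np.where(np.isnan(d), MISSING_ALLELE, np.where(d == 2, minor, major))
            pairs = " ".join(f"{x} {y}" for x, y in zip(a1, a2))
            fh.write(f"FAM {sid} 0 0 0 -9 {pairs}\n")


def hwe_chi2_pvalue(n0: int, n1: int, n2: int) -> float:
    """Pearson 1-df chi-square HWE p-value from genotype counts.

    ``n0/n1/n2`` count dosage 0/1/2 (major-hom, het, minor-hom).  Monomorphic
    counts give p = 1 (zero expected cells contribute nothing when the
    observed cell is also zero).
    """
    n = n0 + n1 + n2
    if n < 2:
        return np.nan
    q = (2 * n2 + n1) / (2 * n)  # minor allele frequency
    p = 1.0 - q
    exp = np.array([p * p * n, 2 * p * q * n, q * q * n])
    obs = np.array([n0, n1, n2], dtype=float)
    chi2 = 0.0
    for o, e in zip(obs, exp):
        if e > 0:
            chi2 += (o - e) ** 2 / e
        elif o > 0:
            return 0.0
    return float(stats.chi2.sf(chi2, df=1))


def hwe_exact_midp(n0: int, n1: int, n2: int) -> float:
    """Exact HWE mid-p (conditional on allele counts, summed over het counts).

    Enumerates all heterozygote counts with the observed parity given the
    minor-allele count, using the standard conditional distribution; mid-p
    counts half the probability of outcomes exactly as probable as observed.
    """
    n = n0 + n1 + n2
    if n < 2:
        return np.nan
    n_minor = 2 * n2 + n1
    n_minor = min(n_minor, 2 * n - n_minor)  # work with the rarer allele
    het_obs = n1
    hets = list(range(n_minor % 2, n_minor + 1, 2))
    # log unnormalized probabilities via the recurrence
    # P(h+2)/P(h) = (n_minor-h)(2n-n_minor-h) / ((h+2)(h+1)) ... derived from
    # the hypergeometric-type conditional pmf
    # pmf(h) prop. 2^h / (n_hom_minor! h! n_hom_major!), homs fixed by n_minor
    logp = {hets[0]: 0.0}
    for h in hets[:-1]:
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        ratio = (4.0 * hom_minor * hom_major) / ((h + 2.0) * (h + 1.0))
        logp[h + 2] = logp[h] + (np.log(ratio) if ratio > 0 else -np.inf)
    mx = max(logp.values())
    probs = {h: np.exp(v - mx) for h, v in logp.items()}
    total = sum(probs.values())
    p_obs = probs.get(het_obs, 0.0)
    p = sum(v for h, v in probs.items() if v < p_obs * (1 - 1e-12))
    p += 0.5 * sum(v for h, v in probs.items() if abs(v - p_obs) <= p_obs * 1e-12)
    return float(min(1.0, p / total))


def snp_stats(panel: GenotypePanel, hwe_method: str = "chi2") -> pd.DataFrame:
    """Compute per-SNP MAF, call rate and HWE p; fills the SNPRecord fields.

    ``hwe_method`` is ``"chi2"`` (asymptotic Pearson, default) or
    ``"exact"`` (mid-p exact test).  All-missing SNPs get call_rate 0 and
    NaN MAF/HWE (they will fail QC).
    """
    if hwe_method not in ("chi2", "exact"):
        raise ValueError(f"unknown hwe_method {hwe_method!r}")
    d = panel.dosages
    called = ~np.isnan(d)
    n_called = called.sum(axis=0)
    call_rate = n_called / panel.n_samples
    with np.errstate(invalid="ignore"):
        freq = np.nansum(d, axis=0) / (2 * n_called)
    maf = np.minimum(freq, 1 - freq)
    maf = np.where(n_called >= 2, maf, np.nan)
    hwe = np.full(panel.n_snps, np.nan)
    hwe_fn = hwe_chi2_pvalue if hwe_method == "chi2" else hwe_exact_midp
    for j in range(panel.n_snps):
        if n_called[j] < 2:
            continue
        col = d[called[:, j], j]
        n2 = int((col == 2).sum())
        n1 = int((col == 1).sum())
        n0 = int((col == 0).sum())
        hwe[j] = hwe_fn(n0, n1, n2)
    for j, s in enumerate(panel.snps):
        s.maf = float(maf[j]) if np.isfinite(maf[j]) else np.nan
        s.call_rate = float(call_rate[j])
        s.hwe_p = float(hwe[j]) if np.isfinite(hwe[j]) else np.nan
    return pd.DataFrame(
        {
            "snp_id": panel.snp_ids,
            "chrom": [s.chrom for s in panel.snps],
            "pos_bp": [s.pos_bp for s in panel.snps],
            "maf": maf,
            "call_rate": call_rate,
            "hwe_p": hwe,
        }
    )


def apply_qc(
    panel: GenotypePanel,
    maf_min: float = 0.01,
    call_min: float = 0.95,
    hwe_min: float = 1e-3,
    hwe_method: str = "chi2",
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Filter SNPs by MAF/call-rate/HWE; thresholds are inclusive on keep.

    Returns the filtered panel and an exclusion report with one row per input
    SNP (kept flag and semicolon-joined failure reasons).  Raises if no SNP
    survives.
    """
    st = snp_stats(panel, hwe_method=hwe_method)
    fail_maf = ~(st.maf.to_numpy() >= maf_min)  # NaN fails
    fail_call = ~(st.call_rate.to_numpy() >= call_min)
    fail_hwe = ~(st.hwe_p.to_numpy() >= hwe_min)
    kept = ~(fail_maf | fail_call | fail_hwe)
    reasons = [
        ";".join(
            r
            for r, f in (("maf", fail_maf[j]), ("call_rate", fail_call[j]), ("hwe", fail_hwe[j]))
            if f
        )
        for j in range(len(st))
    ]
    report = st.assign(kept=kept, reasons=reasons)
    if not kept.any():
        raise ValueError("no SNP survives QC")
    filtered = panel.subset_snps(np.flatnonzero(kept))
    logger.info("QC kept %d / %d SNPs", kept.sum(), len(kept))
    return filtered, report
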