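"""End-to-end orchestration: simulate -> qc -> adjust -> enrich -> gwas ->
annotate, with one config, a structured log and a hashed output manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import enrichment as enr
from . import gwas as gw
from . import qtl as qt
from . import simdata as sd
from . import traits as tr
from .genotype import apply_qc, read_ped_map

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat configuration for a full pipeline run."""

    out_dir: str = "run"
    # input paths (ignored when simulate=True, which writes them under out_dir)
    ped: str | None = None
    map: str | None = None
    traits: str | None = None
    metabotypes: str | None = None
    catalog: str | None = None
    gff3: str | None = None
    simulate: bool = True
    sim: sd.SimConfig = field(default_factory=sd.SimConfig)
    # thresholds
    maf_min: float = 0.01
    call_min: float = 0.95
    hwe_min: float = 1e-3
    alpha: float = 0.05
    enrichment_mode: str = "mixed"
    enrichment_gate: bool = True  # False -> GWAS on the target trait only
    q_threshold: float = 0.1
    window_bp: int = 1_000_000
    top_n_metabotype: int = 10
    top_n_target: int = 25
    k_max: int = 10
    empirical_p: bool = False
    n_permutations: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        for name, v, lo, hi in [
            ("maf_min", self.maf_min, 0, 0.5), ("call_min", self.call_min, 0, 1),
            ("hwe_min", self.hwe_min, 0, 1), ("alpha", self.alpha, 0, 1),
            ("q_threshold", self.q_threshold, 0, 1),
        ]:
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.k_max < 1 or self.window_bp < 0:
            raise ValueError("k_max >= 1 and window_bp >= 0 required")
        if not self.simulate:
            for name in ("ped", "map", "traits", "metabotypes", "catalog", "gff3"):
                if getattr(self, name) is None:
                    raise ValueError(f"simulate=False requires input path {name!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        cfg = cls(**raw)
        if sim_raw:
            cfg.sim = sd.SimConfig(**sim_raw)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk).

    Every output file is hashed into ``manifest.json``; identical config and
    inputs reproduce identical hashes.  The run log records the selected PC
    count and inflation factor per trait.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("metaboqtl")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    outputs: dict[str, Path] = {}
    try:
        logger.info("config: %s", json.dumps(config.to_dict(), default=str, sort_keys=True))

        # --- stage: inputs -------------------------------------------------
        if config.simulate:
            config.sim.seed = config.seed
            dataset = sd.simulate_dataset(config.sim)
            inp = sd.write_fixture_bundle(dataset, out / "inputs")
            ped, map_, traits_p = inp["ped"], inp["map"], inp["traits"]
            metab_p, gmt_p, gff_p = inp["metabotypes"], inp["gmt"], inp["gff3"]
            outputs.update({f"inputs/{p.name}": p for p in inp.values()})
        else:
            ped, map_, traits_p = Path(config.ped), Path(config.map), Path(config.traits)
            metab_p, gmt_p, gff_p = (
                Path(config.metabotypes), Path(config.catalog), Path(config.gff3)
            )

        # --- stage: qc -----------------------------------------------------
        try:
            panel = read_ped_map(ped, map_)
            panel, qc_report = apply_qc(
                panel, config.maf_min, config.call_min, config.hwe_min
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'qc' failed: {exc}") from exc
        outputs["qc_report.tsv"] = _write(qc_report, out / "qc_report.tsv")

        # --- stage: adjust -------------------------------------------------
        try:
            table = tr.TraitTable.from_files(traits_p, metab_p)
            adjusted = tr.residualize_all(table)
            correlations = tr.correlate_with_target(adjusted, table.target)
            descr = tr.descriptive_report(table, correlations)
        except Exception as exc:
            raise RuntimeError(f"stage 'adjust' failed: {exc}") from exc
        outputs["adjusted_residuals.tsv"] = _write(
            adjusted.residual_frame.rename_axis("sample_id"),
            out / "adjusted_residuals.tsv", index=True,
        )
        outputs["correlations.tsv"] = _write(
            descr, out / "correlations.tsv", index=True
        )

        # --- stage: enrich -------------------------------------------------
        try:
            catalog = enr.read_gmt(gmt_p)
            enriched = enr.enrich_catalog(
                catalog, correlations["r"], alpha=config.alpha,
                mode=config.enrichment_mode,
            )
            if config.enrichment_gate:
                gwas_traits = enr.select_gwas_traits(enriched, table.target)
            else:
                gwas_traits = [table.target]
        except Exception as exc:
            raise RuntimeError(f"stage 'enrich' failed: {exc}") from exc
        outputs["enrichment.tsv"] = _write(enriched, out / "enrichment.tsv")

        # --- stage: gwas ---------------------------------------------------
        try:
            residuals = adjusted.residual_frame
            gwas_traits = [t for t in gwas_traits if t in residuals.columns]
            gcfg = gw.GwasConfig(
                k_max=config.k_max, empirical_p=config.empirical_p,
                n_permutations=config.n_permutations, seed=config.seed,
            )
            result = gw.run_gwas(gwas_traits, residuals, panel, gcfg)
        except Exception as exc:
            raise RuntimeError(f"stage 'gwas' failed: {exc}") from exc
        outputs["associations.tsv"] = _write(
            result.associations, out / "associations.tsv"
        )
        outputs["gwas_summary.tsv"] = _write(result.summaries, out / "gwas_summary.tsv")

        # --- stage: annotate -----------------------------------------------
        try:
            genes = qt.read_gff3(gff_p)
            sig = qt.significant_records(result.associations, config.q_threshold)
            regions_by_trait = {
                t: qt.condense_qtl(grp) for t, grp in sig.groupby("trait_id")
            }
            all_regions = [r for rs in regions_by_trait.values() for r in rs]
            snp_ov, qtl_ov = qt.find_overlaps(sig, regions_by_trait)
            _, cand_report = qt.select_candidates(
                result.associations, genes, table.target,
                q_threshold=config.q_threshold,
                top_n_metabotype=config.top_n_metabotype,
                top_n_target=config.top_n_target,
                window_bp=config.window_bp,
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'annotate' failed: {exc}") from exc
        outputs["qtl_regions.tsv"] = _write(
            qt.regions_frame(all_regions), out / "qtl_regions.tsv"
        )
        outputs["snp_overlaps.tsv"] = _write(snp_ov, out / "snp_overlaps.tsv")
        outputs["qtl_overlaps.tsv"] = _write(qtl_ov, out / "qtl_overlaps.tsv")
        outputs["candidate_genes.tsv"] = _write(
            cand_report, out / "candidate_genes.tsv"
        )

        manifest = {
            "config": json.loads(json.dumps(config.to_dict(), default=str)),
            "files": {name: _sha256(p) for name, p in sorted(outputs.items())},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        logger.info("pipeline complete: %d output files", len(outputs))
        return manifest
    finally:
        root.removeHandler(handler)
        handler.close()
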