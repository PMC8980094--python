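"""End-to-end workflows tying the stages together.

Two workflows mirror the analysis structure of a multi-site tumor study:

* **relatedness** — per-patient mutation matrices (with deep-coverage
  rescue), trunk/branch/private classification, mutation and SCNA
  neighbor-joining trees, inter-sample copy-number correlations;
* **enrichment** — GSEA association + deregulation scoring of gene sets
  against a ranked fusion-association list, truncated-product combination,
  ROC/AUC benchmarking, and drug-target prioritization.

Every run is driven by a validated configuration and a single root seed and
writes a manifest sufficient to reproduce its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import io as psio
from .enrichment import (
    RankedGeneList,
    combine_pathway_pvalues,
    gsea_enrichment,
    prioritize_drug_targets,
    roc_auc,
)
from .phylogeny import (
    RescueRule,
    build_binary_matrix,
    classify_mutations,
    hamming_distance_matrix,
    mean_vaf_by_category,
    neighbor_joining,
    rescue_genotype,
)
from .qc import QCThresholds, filter_high_quality
from .scna import intersample_correlation, scna_tree, segments_to_site_matrix
from .simulate import SimulationConfig, simulate_cohort

log = logging.getLogger("phylosite")


class QCConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_t_depth: int = 30
    min_n_depth: int = 15
    min_t_vaf: float = 0.05
    max_n_vaf: float = 0.01
    driver_max_maf: float = 0.01

    def to_thresholds(self) -> QCThresholds:
        return QCThresholds(**self.model_dump())


class RescueConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    min_alt: int = 5
    min_vaf: float = 0.01


class ScnaConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    log2_cutoff: float = 0.25
    min_patients: int = 4
    de_p_cut: float = 0.05
    de_fc_cut: float = 1.5


class EnrichmentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_perm: int = 1000
    weight_exponent: float = 1.0
    tau: float = 0.05
    top_percentile: float = 15.0
    de_p_cut: float = 0.05
    de_fc_cut: float = 1.5


class SimulationBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_patients: int = 14
    sites_min: int = 2
    sites_max: int = 5
    n_mutations_per_patient: int = 40
    clone_fractions: tuple[float, float, float] = (0.60, 0.25, 0.15)
    tumor_purity: float = 0.4
    depth_wes: float = 228.0
    depth_deep: float = 3700.0
    sequencing_error: float = 0.001
    site_counts: tuple[int, ...] | None = None  # fixed per-patient site counts

    def to_config(self, seed: int) -> SimulationConfig:
        return SimulationConfig(
            n_patients=self.n_patients,
            sites_per_patient=(self.sites_min, self.sites_max),
            n_mutations_per_patient=self.n_mutations_per_patient,
            clone_fractions=self.clone_fractions,
            tumor_purity=self.tumor_purity,
            depth_wes=self.depth_wes,
            depth_deep=self.depth_deep,
            sequencing_error=self.sequencing_error,
            site_counts=self.site_counts,
            seed=seed,
        )


class PipelineConfig(BaseModel):
    """Schema-validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    log_level: str = "INFO"
    qc: QCConfig = Field(default_factory=QCConfig)
    rescue: RescueConfig = Field(default_factory=RescueConfig)
    scna: ScnaConfig = Field(default_factory=ScnaConfig)
    enrichment: EnrichmentConfig = Field(default_factory=EnrichmentConfig)
    simulation: SimulationBlock = Field(default_factory=SimulationBlock)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_simulate(config: PipelineConfig, out_dir: str | Path, force: bool = False) -> dict:
    """Simulate a cohort and write all fixtures plus a checksummed manifest."""
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"output directory {out_dir} is not empty (use force)")
    sim = config.simulation.to_config(config.seed)
    cohort = simulate_cohort(sim)
    psio.write_fixtures(cohort, out_dir)
    files = sorted(p for p in out_dir.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "parameters": config.model_dump(),
        "checksums": {p.name: _checksum(p) for p in files},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def analyze_patient_mutations(
    per_sample_variants: dict,
    deep_counts: pd.DataFrame | None,
    thresholds: QCThresholds,
    rescue_rule: RescueRule | None,
    patient_id: str = "",
) -> dict:
    """Relatedness analysis for one patient's mutation data.

    Filters calls per sample, builds the union presence/absence matrix,
    applies deep-coverage rescue when enabled, classifies mutations, and
    infers the germline-rooted NJ tree.  Mean VAFs per category are computed
    over WES calls at cells that are present in the final matrix.
    """
    detected = {
        s: filter_high_quality(vs, thresholds) for s, vs in per_sample_variants.items()
    }
    matrix = build_binary_matrix(detected, patient_id=patient_id)
    if rescue_rule is not None and deep_counts is not None:
        matrix = rescue_genotype(matrix, deep_counts, rescue_rule)
    labels, summary = classify_mutations(matrix)
    dist = hamming_distance_matrix(matrix)
    tree = neighbor_joining(dist)
    present_calls = [
        v
        for vs in per_sample_variants.values()
        for v in vs
        if v.key in matrix.presence.index and matrix.presence.at[v.key, v.sample_id] == 1
    ]
    vaf_by_cat = mean_vaf_by_category(present_calls, labels)
    return {
        "matrix": matrix,
        "labels": labels,
        "summary": summary,
        "distances": dist,
        "tree": tree,
        "mean_vaf": vaf_by_cat,
    }


def run_relatedness(
    config: PipelineConfig, fixture_dir: str | Path, out_dir: str | Path
) -> dict:
    """Run the full relatedness workflow on a fixture directory.

    Patients with a single sample are skipped with a warning (a phylogeny is
    undefined).  Writes per-patient matrices, category tables, distance
    matrices and Newick trees (mutation and SCNA), plus a cohort summary.
    """
    fixture_dir, out_dir = Path(fixture_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    thresholds = config.qc.to_thresholds()
    rule = (
        RescueRule(config.rescue.min_alt, config.rescue.min_vaf)
        if config.rescue.enabled
        else None
    )
    deep_all = psio.read_deep_counts(fixture_dir / "deep_counts.tsv")

    # group sample MAFs by patient prefix recorded inside the files
    variants_by_patient: dict[str, dict] = {}
    for maf in sorted(fixture_dir.glob("*.maf.tsv")):
        calls = psio.read_maf(maf)
        if not calls:
            continue
        pid, sid = calls[0].patient_id, calls[0].sample_id
        variants_by_patient.setdefault(pid, {})[sid] = calls

    seg_profiles: dict[str, list] = {}
    for seg in sorted(fixture_dir.glob("*.seg")):
        for prof in psio.read_seg(seg):
            pid = next(
                (p for p, ss in variants_by_patient.items() if prof.sample_id in ss),
                prof.sample_id.rstrip("abcdefgh"),
            )
            seg_profiles.setdefault(pid, []).append(prof)

    summaries, mean_vafs = [], []
    for pid in sorted(variants_by_patient):
        samples = variants_by_patient[pid]
        if len(samples) < 2:
            log.warning("patient %s has a single sample; phylogeny skipped", pid)
            continue
        deep = deep_all[deep_all["patient"] == pid]
        res = analyze_patient_mutations(samples, deep, thresholds, rule, patient_id=pid)
        res["matrix"].presence.to_csv(out_dir / f"{pid}.matrix.tsv", sep="\t")
        res["matrix"].provenance.to_csv(out_dir / f"{pid}.provenance.tsv", sep="\t")
        res["labels"].to_csv(out_dir / f"{pid}.categories.tsv", sep="\t")
        res["distances"].to_csv(out_dir / f"{pid}.distances.tsv", sep="\t")
        (out_dir / f"{pid}.mutations.nwk").write_text(res["tree"].to_newick() + "\n")
        summaries.append(res["summary"])
        mean_vafs.append({"patient_id": pid, **res["mean_vaf"]})

        profs = seg_profiles.get(pid, [])
        if len(profs) >= 2 and all(p.has_tcn for p in profs):
            enc = segments_to_site_matrix(profs, scale="encoded", patient_id=pid)
            (out_dir / f"{pid}.scna.nwk").write_text(scna_tree(enc).to_newick() + "\n")
            logm = segments_to_site_matrix(profs, scale="log2", patient_id=pid)
            intersample_correlation(logm).to_csv(
                out_dir / f"{pid}.scna_correlation.tsv", sep="\t", index=False
            )

    trunk_fracs = [s["trunk_fraction"] for s in summaries]
    pooled_trunk = (
        sum(s["n_trunk"] for s in summaries) / sum(s["n_mutations"] for s in summaries)
        if summaries
        else float("nan")
    )
    cohort = {
        "n_patients": len(summaries),
        "per_patient": summaries,
        "mean_trunk_fraction": float(np.mean(trunk_fracs)) if trunk_fracs else float("nan"),
        "pooled_trunk_fraction": pooled_trunk,
        "mean_vaf_by_category": mean_vafs,
        "seed": config.seed,
    }
    (out_dir / "cohort_summary.json").write_text(json.dumps(cohort, indent=2))
    return cohort


def run_enrichment(
    config: PipelineConfig,
    ranked_table: pd.DataFrame,
    pathways: dict,
    de_table: pd.DataFrame,
    benchmark_sets: dict | None = None,
    drug_map: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """GSEA association + deregulation analysis with p-value combination.

    ``ranked_table`` carries network-association scores; deregulation scores
    each pathway against a ranked list derived from the DE table (genes ranked
    by log2 fold change).  Returns pathway results sorted by combined p,
    benchmark AUCs, and the prioritized drug-target table when a drug map is
    supplied.
    """
    enr = config.enrichment
    ranked = RankedGeneList(ranked_table)
    overlap = set(ranked.genes) & {g for gs in pathways.values() for g in gs}
    if not overlap:
        raise ValueError("no overlap between ranked genes and any pathway gene set")
    dereg_ranked = RankedGeneList(
        de_table.rename(columns={"log2fc": "score"})[["gene", "score"]]
    )
    rng = np.random.default_rng(config.seed)
    rows_a, rows_d = [], []
    for name, members in pathways.items():
        try:
            es_a, p_a = gsea_enrichment(
                ranked, members, n_perm=enr.n_perm,
                weight_exponent=enr.weight_exponent, rng=rng,
            )
            es_d, p_d = gsea_enrichment(
                dereg_ranked, members, n_perm=enr.n_perm,
                weight_exponent=enr.weight_exponent, rng=rng,
            )
        except ValueError:
            log.warning("pathway %s does not overlap a ranked list; skipped", name)
            continue
        rows_a.append({"pathway": name, "es": es_a, "p": p_a})
        rows_d.append({"pathway": name, "es": es_d, "p": p_d})
    pathway_table = combine_pathway_pvalues(
        pd.DataFrame(rows_a), pd.DataFrame(rows_d), tau=enr.tau
    )

    aucs, curves = {}, {}
    for name, members in (benchmark_sets or {}).items():
        auc, curve = roc_auc(ranked, members)
        aucs[name] = auc
        curves[name] = curve

    targets = None
    if drug_map is not None:
        targets = prioritize_drug_targets(
            ranked, drug_map, de_table,
            top_percentile=enr.top_percentile,
            p_cut=enr.de_p_cut, fc_cut=enr.de_fc_cut,
        )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pathway_table.to_csv(out_dir / "pathways.tsv", sep="\t", index=False)
        for name, curve in curves.items():
            curve.to_csv(out_dir / f"roc_{name}.tsv", sep="\t", index=False)
        if aucs:
            (out_dir / "benchmark_auc.json").write_text(json.dumps(aucs, indent=2))
        if targets is not None:
            targets.to_csv(out_dir / "drug_targets.tsv", sep="\t", index=False)

    return {"pathways": pathway_table, "auc": aucs, "drug_targets": targets}
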