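"""Readers and writers for the pipeline's tabular formats.

All genomic coordinates are 1-based inclusive.  Formats:

* MAF-like TSV — one somatic call per row (schema in :mod:`phylosite.qc`);
* VCF v4.2 — minimal per-sample somatic VCF with paired TUMOR/NORMAL
  genotype columns carrying DP and AD, written and read through pysam;
* SEG — tab-separated segments (sample, chrom, start, end, num_mark,
  seg_mean[, tcn]);
* GMT — gene sets, one per line (name, description, members);
* deep read-count TSV — (patient, mutation, sample, depth, alt).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .genome import chromosome_lengths
from .qc import VariantCall, frame_to_variants, variants_to_frame
from .scna import SegmentProfile

MAF_COLUMNS = [
    "patient", "sample", "chrom", "pos", "ref", "alt",
    "t_depth", "t_alt", "n_depth", "n_alt",
    "consequence", "gene", "maf_esp6500", "maf_1000g",
]

SEG_COLUMNS = ["sample", "chrom", "start", "end", "num_mark", "seg_mean", "tcn"]


def write_maf(variants: Sequence[VariantCall], path: str | Path) -> None:
    variants_to_frame(variants).to_csv(path, sep="\t", index=False)


def read_maf(path: str | Path, cancer_genes: frozenset[str] | None = None) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"MAF-like TSV {path} lacks columns: {missing}")
    return frame_to_variants(df, cancer_genes=cancer_genes)


def write_vcf(variants: Sequence[VariantCall], path: str | Path) -> None:
    """Minimal VCF v4.2 for one sample's somatic calls (TUMOR + NORMAL columns)."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">'
    )
    for chrom, length in chromosome_lengths().items():
        header.contigs.add(chrom, length=length)
    header.add_sample("TUMOR")
    header.add_sample("NORMAL")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos,
                alleles=(v.ref, v.alt), id=".",
            )
            rec.samples["TUMOR"]["DP"] = v.t_depth
            rec.samples["TUMOR"]["AD"] = (v.t_depth - v.t_alt, v.t_alt)
            rec.samples["NORMAL"]["DP"] = v.n_depth
            rec.samples["NORMAL"]["AD"] = (v.n_depth - v.n_alt, v.n_alt)
            out.write(rec)


def read_vcf(path: str | Path, patient_id: str = "", sample_id: str = "") -> list[VariantCall]:
    """Read a minimal paired somatic VCF back into variant calls."""
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            t, n = rec.samples["TUMOR"], rec.samples["NORMAL"]
            out.append(
                VariantCall(
                    patient_id=patient_id,
                    sample_id=sample_id,
                    chrom=rec.contig,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    t_depth=int(t["DP"]),
                    t_alt=int(t["AD"][1]),
                    n_depth=int(n["DP"]),
                    n_alt=int(n["AD"][1]),
                )
            )
    return out


def write_seg(profile: SegmentProfile, path: str | Path) -> None:
    df = profile.segments
    out = pd.DataFrame(
        {
            "sample": [profile.sample_id] * len(df),
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "num_mark": df["num_mark"].astype(int) if "num_mark" in df.columns else 0,
            "seg_mean": df["log2"] if "log2" in df.columns else np.nan,
        }
    )
    if "tcn" in df.columns:
        out["tcn"] = df["tcn"].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_seg(path: str | Path) -> list[SegmentProfile]:
    """Read a SEG file into one profile per sample (coordinates 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    profiles = []
    for sample, grp in df.groupby("sample", sort=True):
        segs = (
            grp.rename(columns={"seg_mean": "log2"})[["chrom", "start", "end", "log2"]]
            .reset_index(drop=True)
        )
        if "tcn" in grp.columns:
            segs["tcn"] = grp["tcn"].to_numpy()
        profiles.append(SegmentProfile(sample_id=str(sample), segments=segs))
    return profiles


def write_gmt(gene_sets: dict, path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in gene_sets:
            members = "\t".join(str(g) for g in gene_sets[name])
            fh.write(f"{name}\t{description}\t{members}\n")


def read_gmt(path: str | Path) -> dict:
    """Parse a GMT file into {set name: [genes]}; names must be unique."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            name, _desc, members = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in sets:
                raise ValueError(f"duplicate gene-set name in {path}: {name}")
            if not members:
                raise ValueError(f"empty gene set in {path}: {name}")
            sets[name] = members
    return sets


def write_deep_counts(deep: pd.DataFrame, path: str | Path) -> None:
    deep.to_csv(path, sep="\t", index=False)


def read_deep_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"mutation": str, "sample": str})


def write_fixtures(cohort, out_dir: str | Path) -> dict:
    """Write a simulated cohort to disk as plain-text fixtures.

    Per sample: MAF-like TSV, minimal VCF, SEG.  Per cohort: truth TSV, deep
    read-count TSV, DE table TSV, planted gene sets GMT.  File ordering is
    deterministic; returns a manifest of written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, list[str] | str] = {"maf": [], "vcf": [], "seg": [], "deep": [], }
    truth_rows, deep_frames = [], []
    for patient in cohort.patients:
        by_sample: dict[str, list[VariantCall]] = {s: [] for s in patient.sites}
        for v in patient.wes_calls:
            by_sample[v.sample_id].append(v)
        for s in sorted(by_sample):
            maf_path = out_dir / f"{s}.maf.tsv"
            vcf_path = out_dir / f"{s}.vcf"
            write_maf(by_sample[s], maf_path)
            write_vcf(by_sample[s], vcf_path)
            manifest["maf"].append(str(maf_path))
            manifest["vcf"].append(str(vcf_path))
        for prof in patient.scna_profiles:
            seg_path = out_dir / f"{prof.sample_id}.seg"
            write_seg(prof, seg_path)
            manifest["seg"].append(str(seg_path))
        deep_frames.append(patient.deep_counts)
        for t in patient.truth:
            truth_rows.append(
                {
                    "patient": t.patient_id,
                    "mutation": t.mutation_id,
                    "category": t.true_category,
                    "sites_present": ",".join(t.sites_present),
                    "vaf_per_site": ",".join(
                        f"{s}={v:.6g}" for s, v in sorted(t.true_vaf_per_site.items())
                    ),
                }
            )
    truth_cols = ["patient", "mutation", "category", "sites_present", "vaf_per_site"]
    pd.DataFrame(truth_rows, columns=truth_cols).to_csv(
        out_dir / "truth.tsv", sep="\t", index=False
    )
    deep_all = (
        pd.concat(deep_frames, ignore_index=True)
        if deep_frames
        else pd.DataFrame(columns=["patient", "mutation", "sample", "depth", "alt"])
    )
    write_deep_counts(deep_all, out_dir / "deep_counts.tsv")
    cohort.expression.to_csv(out_dir / "expression_de.tsv", sep="\t", index=False)
    if cohort.gene_sets:
        write_gmt(cohort.gene_sets, out_dir / "planted_sets.gmt")
        manifest["gmt"] = str(out_dir / "planted_sets.gmt")
    else:
        (out_dir / "planted_sets.gmt").write_text("")
        manifest["gmt"] = str(out_dir / "planted_sets.gmt")
    manifest["truth"] = str(out_dir / "truth.tsv")
    manifest["deep"] = [str(out_dir / "deep_counts.tsv")]
    manifest["expression"] = str(out_dir / "expression_de.tsv")
    return manifest
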