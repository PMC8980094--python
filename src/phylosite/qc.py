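"""High-quality variant filtering, driver-mutation classification, mutation rate.

A somatic call is *high quality* when the tumor locus is covered by at least
30 reads, the matched normal by at least 15, the tumor variant allele fraction
(VAF) is at least 0.05 and the normal VAF at most 0.01 — the standard paired
tumor/normal post-calling filter for exome data.  A *driver* candidate is a
non-silent high-quality call in a known cancer gene that is essentially absent
from population databases (MAF < 0.01 in both ESP6500 and 1000 Genomes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONSEQUENCES = frozenset(
    {"nonsynonymous", "stopgain", "stoploss", "splicing", "synonymous", "other"}
)
DEFAULT_NONSILENT = frozenset({"nonsynonymous", "stopgain", "stoploss", "splicing"})


@dataclass(frozen=True)
class VariantCall:
    """One somatic variant observed in one tumor sample (with matched normal)."""

    patient_id: str
    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    t_depth: int
    t_alt: int
    n_depth: int
    n_alt: int
    consequence: str = "nonsynonymous"
    gene: str = ""
    maf_esp6500: float | None = None
    maf_1000g: float | None = None
    is_cancer_gene: bool = False

    def __post_init__(self) -> None:
        if min(self.t_depth, self.t_alt, self.n_depth, self.n_alt) < 0:
            raise ValueError(f"negative read counts in {self.key}")
        if self.t_alt > self.t_depth or self.n_alt > self.n_depth:
            raise ValueError(f"alt count exceeds depth in {self.key}")

    @property
    def key(self) -> str:
        """Canonical variant key ``chrom:pos:ref:alt``."""
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def t_vaf(self) -> float:
        if self.t_depth == 0:
            raise ValueError(f"tumor VAF undefined at zero depth for {self.key}")
        return self.t_alt / self.t_depth

    @property
    def n_vaf(self) -> float:
        # no normal coverage ⇒ no normal evidence of the allele
        return self.n_alt / self.n_depth if self.n_depth > 0 else 0.0


@dataclass(frozen=True)
class QCThresholds:
    """Detection / driver thresholds. Depth and VAF bounds are inclusive."""

    min_t_depth: int = 30
    min_n_depth: int = 15
    min_t_vaf: float = 0.05
    max_n_vaf: float = 0.01
    driver_max_maf: float = 0.01  # strict '<' per driver criterion
    nonsilent_classes: frozenset[str] = DEFAULT_NONSILENT

    def __post_init__(self) -> None:
        if min(self.min_t_depth, self.min_n_depth, self.min_t_vaf, self.max_n_vaf) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.min_t_vaf <= self.max_n_vaf:
            raise ValueError("min_t_vaf must exceed max_n_vaf")
        unknown = frozenset(self.nonsilent_classes) - CONSEQUENCES
        if unknown:
            raise ValueError(f"unknown consequence classes: {sorted(unknown)}")


def passes_quality(v: VariantCall, thr: QCThresholds) -> bool:
    """Whether a single call clears the paired tumor/normal quality filter."""
    if v.t_depth < thr.min_t_depth or v.n_depth < thr.min_n_depth:
        return False
    return v.t_vaf >= thr.min_t_vaf and v.n_vaf <= thr.max_n_vaf


def filter_high_quality(
    variants: Iterable[VariantCall], thr: QCThresholds = QCThresholds()
) -> list[VariantCall]:
    """Keep calls with t_depth≥30, n_depth≥15, tumor VAF≥0.05, normal VAF≤0.01.

    Boundaries are inclusive; input order is preserved.
    """
    return [v for v in variants if passes_quality(v, thr)]


def classify_driver(v: VariantCall, thr: QCThresholds = QCThresholds()) -> bool:
    """Driver candidate: rare in populations, non-silent, in a known cancer gene.

    Missing population MAFs are treated as 0 (a variant absent from the
    databases is novel and passes the rarity criterion).
    """
    if v.consequence not in CONSEQUENCES:
        raise ValueError(f"unknown consequence token: {v.consequence!r}")
    esp = v.maf_esp6500 if v.maf_esp6500 is not None else 0.0
    kg = v.maf_1000g if v.maf_1000g is not None else 0.0
    rare = esp < thr.driver_max_maf and kg < thr.driver_max_maf
    return rare and v.consequence in thr.nonsilent_classes and v.is_cancer_gene


def mutation_rate_per_mb(nonsilent_count: int, capture_size_mb: float) -> float:
    """Non-silent mutations per megabase of captured territory."""
    if capture_size_mb <= 0:
        raise ValueError("capture_size_mb must be positive")
    if nonsilent_count < 0:
        raise ValueError("mutation count must be non-negative")
    return nonsilent_count / capture_size_mb


def cohort_mutation_rates(
    per_sample_counts: dict[str, int], capture_size_mb: float
) -> tuple[pd.Series, float]:
    """Per-sample non-silent mutation rates and their cohort median."""
    rates = pd.Series(
        {s: mutation_rate_per_mb(c, capture_size_mb) for s, c in per_sample_counts.items()},
        dtype=float,
    )
    return rates, float(rates.median()) if len(rates) else float("nan")


def variants_to_frame(variants: Sequence[VariantCall]) -> pd.DataFrame:
    """Tabulate calls into the MAF-like schema (one row per call)."""
    cols = [
        "patient",
        "sample",
        "chrom",
        "pos",
        "ref",
        "alt",
        "t_depth",
        "t_alt",
        "n_depth",
        "n_alt",
        "consequence",
        "gene",
        "maf_esp6500",
        "maf_1000g",
    ]
    rows = [
        (
            v.patient_id,
            v.sample_id,
            v.chrom,
            v.pos,
            v.ref,
            v.alt,
            v.t_depth,
            v.t_alt,
            v.n_depth,
            v.n_alt,
            v.consequence,
            v.gene,
            v.maf_esp6500,
            v.maf_1000g,
        )
        for v in variants
    ]
    return pd.DataFrame(rows, columns=cols)


def frame_to_variants(
    df: pd.DataFrame, cancer_genes: frozenset[str] | None = None
) -> list[VariantCall]:
    """Inverse of :func:`variants_to_frame`; optional cancer-gene flagging."""
    out = []
    for row in df.itertuples(index=False):
        for f in ("t_depth", "t_alt", "n_depth", "n_alt"):
            val = getattr(row, f)
            if val is None or (isinstance(val, float) and np.isnan(val)):
                raise ValueError(
                    f"missing {f} for record {row.chrom}:{row.pos}:{row.ref}:{row.alt}"
                )
        out.append(
            VariantCall(
                patient_id=str(row.patient),
                sample_id=str(row.sample),
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                t_depth=int(row.t_depth),
                t_alt=int(row.t_alt),
                n_depth=int(row.n_depth),
                n_alt=int(row.n_alt),
                consequence=str(row.consequence),
                gene=str(row.gene),
                maf_esp6500=None if pd.isna(row.maf_esp6500) else float(row.maf_esp6500),
                maf_1000g=None if pd.isna(row.maf_1000g) else float(row.maf_1000g),
                is_cancer_gene=(
                    str(row.gene) in cancer_genes if cancer_genes is not None else False
                ),
            )
        )
    return out
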