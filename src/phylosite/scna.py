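"""Somatic copy-number segment merging, encoding, site matrices and recurrence.

Coordinates are 1-based inclusive throughout (SEG convention).  Integer total
copy number (tCN) is encoded on a five-level scale:

    tCN 0 → −2,  1 → −1,  2 → 0,  3 → +1,  ≥4 → +2

Patient-level merging aligns segments across a patient's samples on the
breakpoint union and assigns each overlap interval the unweighted mean of the
log2 ratios of the samples covering it; sample-specific intervals keep their
own value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import genomic_sort_key

# log2 ratio assigned to homozygous deletion (tCN = 0), where log2(tCN/2) diverges
LOG2_FLOOR = -3.0

_ENCODE = {0: -2, 1: -1, 2: 0, 3: 1}


def encode_tcn(tcn: int) -> int:
    """Five-level encoding of integer total copy number (−2..+2)."""
    if isinstance(tcn, (bool, float)) and not float(tcn).is_integer():
        raise ValueError(f"tcn must be an integer, got {tcn!r}")
    t = int(tcn)
    if t != tcn:
        raise ValueError(f"tcn must be an integer, got {tcn!r}")
    if t < 0:
        raise ValueError(f"tcn must be non-negative, got {t}")
    return _ENCODE.get(t, 2)


def encode_tcn_array(tcn) -> np.ndarray:
    arr = np.asarray(tcn)
    if np.any(arr < 0):
        raise ValueError("tcn must be non-negative")
    return np.clip(arr - 2, -2, 2).astype(int)


@dataclass
class SegmentProfile:
    """Ordered copy-number segments for one sample.

    ``segments`` columns: chrom, start, end, log2 and optionally tcn (then
    encoded is derived via the five-level map).  Segments must be sorted and
    non-overlapping within each chromosome.
    """

    sample_id: str
    segments: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        df = self.segments
        if len(df) == 0:
            self.segments = pd.DataFrame(columns=["chrom", "start", "end", "log2"])
            return
        df = df.copy()
        df["chrom"] = df["chrom"].astype(str)
        if (df["start"] > df["end"]).any():
            raise ValueError(f"segment with start > end in sample {self.sample_id}")
        df = df.sort_values(
            by=["chrom", "start"],
            key=lambda col: (
                col.map(lambda c: genomic_sort_key(c, 0)[:2]) if col.name == "chrom" else col
            ),
            ignore_index=True,
        )
        for _, grp in df.groupby("chrom", sort=False):
            if (grp["start"].to_numpy()[1:] <= grp["end"].to_numpy()[:-1]).any():
                raise ValueError(
                    f"overlapping segments within sample {self.sample_id} on chr {grp['chrom'].iloc[0]}"
                )
        if "tcn" in df.columns and df["tcn"].notna().all():
            df["encoded"] = encode_tcn_array(df["tcn"].astype(int))
        self.segments = df

    @property
    def has_tcn(self) -> bool:
        return "tcn" in self.segments.columns and self.segments["tcn"].notna().all()


def _breakpoint_union(profiles: list[SegmentProfile]) -> pd.DataFrame:
    """Disjoint intervals tiling the union footprint of all input segments.

    Within each chromosome, every input start/end becomes a breakpoint; the
    resulting atomic intervals are kept iff covered by at least one sample.
    """
    chroms: dict[str, list[tuple[int, int]]] = {}
    for p in profiles:
        for row in p.segments.itertuples(index=False):
            chroms.setdefault(str(row.chrom), []).append((int(row.start), int(row.end)))
    out = []
    for chrom in sorted(chroms, key=lambda c: genomic_sort_key(c, 0)[:2]):
        segs = chroms[chrom]
        # half-open breakpoints: [start, end+1)
        bps = sorted({s for s, _ in segs} | {e + 1 for _, e in segs})
        starts = np.array([s for s, _ in segs])
        ends = np.array([e for _, e in segs])
        for a, b in zip(bps[:-1], bps[1:]):
            if np.any((starts <= a) & (ends >= b - 1)):
                out.append({"chrom": chrom, "start": a, "end": b - 1})
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def _interval_values(
    profile: SegmentProfile, intervals: pd.DataFrame, column: str
) -> np.ndarray:
    """Value of the unique covering segment per interval (NaN where uncovered)."""
    vals = np.full(len(intervals), np.nan)
    segs = profile.segments
    for chrom, grp in segs.groupby("chrom", sort=False):
        mask = intervals["chrom"].to_numpy() == chrom
        if not mask.any():
            continue
        ivs = intervals.loc[mask]
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        v = grp[column].to_numpy(dtype=float)
        idx = np.searchsorted(starts, ivs["start"].to_numpy(), side="right") - 1
        ok = (idx >= 0) & (ends[np.clip(idx, 0, None)] >= ivs["end"].to_numpy())
        out = np.full(len(ivs), np.nan)
        out[ok] = v[idx[ok]]
        vals[mask] = out
    return vals


def merge_patient_segments(profiles: list[SegmentProfile]) -> SegmentProfile:
    """Merge a patient's per-sample profiles into one log2 profile.

    Each breakpoint-union interval receives the unweighted mean of the log2
    values of the samples covering it; intervals covered by a single sample
    keep that sample's value unchanged.
    """
    if not profiles:
        raise ValueError("at least one profile required")
    intervals = _breakpoint_union(profiles)
    if len(intervals) == 0:
        return SegmentProfile(sample_id="merged", segments=pd.DataFrame())
    values = np.vstack([_interval_values(p, intervals, "log2") for p in profiles])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(values, axis=0)
    out = intervals.copy()
    out["log2"] = mean
    return SegmentProfile(sample_id="merged", segments=out)


@dataclass
class SiteBySampleMatrix:
    """Breakpoint-union intervals × samples matrix of copy-number values."""

    patient_id: str
    intervals: pd.DataFrame  # chrom, start, end
    values: pd.DataFrame  # rows aligned to intervals, columns = samples
    scale: str  # 'encoded' | 'log2'


def segments_to_site_matrix(
    profiles: list[SegmentProfile], scale: str = "encoded", patient_id: str = ""
) -> SiteBySampleMatrix:
    """Overlap a patient's segment profiles into a site-by-sample matrix.

    Entries are the covering segment's encoded status (or log2 ratio); NaN
    marks intervals a sample does not cover.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two sample profiles")
    if scale not in ("encoded", "log2"):
        raise ValueError(f"unknown scale {scale!r}")
    if scale == "encoded":
        for p in profiles:
            if not p.has_tcn:
                raise ValueError(f"sample {p.sample_id} lacks integer tCN; encode first")
    intervals = _breakpoint_union(profiles)
    col = "encoded" if scale == "encoded" else "log2"
    values = pd.DataFrame(
        {p.sample_id: _interval_values(p, intervals, col) for p in profiles}
    )
    return SiteBySampleMatrix(patient_id, intervals, values, scale)


def scna_tree(matrix: SiteBySampleMatrix):
    """Neighbor-joining tree over encoded SCNA profiles, germline-rooted.

    The germline ancestor carries no copy-number alterations (all-zero encoded
    column); distances are hamming counts of intervals whose encoded status
    differs.  Missing coverage is treated as diploid (encoded 0).
    """
    from .phylogeny import hamming_distance_matrix, neighbor_joining

    if matrix.scale != "encoded":
        raise ValueError("SCNA trees require the encoded scale; encode tCN first")
    filled = matrix.values.fillna(0.0).astype(int)
    dist = hamming_distance_matrix(filled)
    return neighbor_joining(dist)


def gene_level_log2(
    merged: SegmentProfile, gene_table: pd.DataFrame, mode: str = "midpoint"
) -> pd.Series:
    """Map genes onto a merged profile: each gene takes its segment's log2.

    ``midpoint`` (default) assigns the segment containing the gene midpoint;
    ``any_overlap`` assigns the mean over all overlapping segments.
    """
    if mode not in ("midpoint", "any_overlap"):
        raise ValueError(f"unknown assignment mode {mode!r}")
    out = pd.Series(np.nan, index=gene_table["gene"], name="log2")
    segs = merged.segments
    for chrom, grp in segs.groupby("chrom", sort=False):
        g = gene_table[gene_table["chrom"].astype(str) == str(chrom)]
        if len(g) == 0:
            continue
        starts, ends = grp["start"].to_numpy(), grp["end"].to_numpy()
        vals = grp["log2"].to_numpy(dtype=float)
        if mode == "midpoint":
            mid = ((g["start"] + g["end"]) // 2).to_numpy()
            idx = np.searchsorted(starts, mid, side="right") - 1
            ok = (idx >= 0) & (ends[np.clip(idx, 0, None)] >= mid)
            out.loc[g["gene"].to_numpy()[ok]] = vals[idx[ok]]
        else:
            for gene, gs, ge in zip(g["gene"], g["start"], g["end"]):
                hit = (starts <= ge) & (ends >= gs)
                if hit.any():
                    out.loc[gene] = float(vals[hit].mean())
    return out


def recurrent_scna_genes(
    per_patient_gene_log2: pd.DataFrame,
    cutoff: float = 0.25,
    min_patients: int = 4,
) -> pd.DataFrame:
    """Recurrently altered genes: |log2| past the cutoff in ≥ min_patients.

    Input is a patients × genes table of gene-level log2 ratios.  A gene is a
    recurrent gain iff log2 ≥ +cutoff in at least ``min_patients`` patients,
    a recurrent loss iff log2 ≤ −cutoff likewise; a gene crossing both
    thresholds in disjoint patient sets is reported in both and flagged.
    """
    if per_patient_gene_log2.isna().all().all():
        raise ValueError("no gene-level log2 values (missing gene annotation?)")
    vals = per_patient_gene_log2
    n_gain = (vals >= cutoff).sum(axis=0)
    n_loss = (vals <= -cutoff).sum(axis=0)
    rows = []
    for gene in vals.columns:
        g, l = int(n_gain[gene]), int(n_loss[gene])
        if g >= min_patients:
            rows.append({"gene": gene, "direction": "gain", "n_patients": g,
                         "both_directions": l >= min_patients})
        if l >= min_patients:
            rows.append({"gene": gene, "direction": "loss", "n_patients": l,
                         "both_directions": g >= min_patients})
    return pd.DataFrame(rows, columns=["gene", "direction", "n_patients", "both_directions"])


def integrate_with_expression(
    recurrent: pd.DataFrame,
    de_table: pd.DataFrame,
    p_cut: float = 0.05,
    fc_cut: float = 1.5,
) -> pd.DataFrame:
    """Intersect recurrent SCNA genes with concordant differential expression.

    Retains recurrent gains that are significantly up-regulated (p < p_cut and
    linear fold change > fc_cut) and recurrent losses significantly
    down-regulated (fold change > fc_cut downward); only direction-concordant
    classes are emitted.
    """
    if de_table["gene"].duplicated().any():
        dups = de_table.loc[de_table["gene"].duplicated(), "gene"].tolist()[:5]
        raise ValueError(f"duplicate genes in differential-expression table: {dups}")
    log2_cut = float(np.log2(fc_cut))
    de = de_table.set_index("gene")
    rows = []
    for r in recurrent.itertuples(index=False):
        if r.gene not in de.index:
            continue
        l2fc, p = float(de.loc[r.gene, "log2fc"]), float(de.loc[r.gene, "p"])
        if p >= p_cut:
            continue
        if r.direction == "gain" and l2fc > log2_cut:
            rows.append({"gene": r.gene, "class": "upregulated_with_gain",
                         "log2fc": l2fc, "p": p, "n_patients": r.n_patients})
        elif r.direction == "loss" and l2fc < -log2_cut:
            rows.append({"gene": r.gene, "class": "downregulated_with_loss",
                         "log2fc": l2fc, "p": p, "n_patients": r.n_patients})
    return pd.DataFrame(rows, columns=["gene", "class", "log2fc", "p", "n_patients"])


def intersample_correlation(matrix: SiteBySampleMatrix) -> pd.DataFrame:
    """Pairwise Pearson correlation of samples over interval log2 values."""
    if matrix.scale != "log2":
        raise ValueError("intersample correlation is defined on the log2 scale")
    if len(matrix.intervals) < 3:
        raise ValueError("need at least three intervals")
    cols = list(matrix.values.columns)
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            a = matrix.values[cols[i]].to_numpy(dtype=float)
            b = matrix.values[cols[j]].to_numpy(dtype=float)
            ok = ~(np.isnan(a) | np.isnan(b))
            r_val, p_val = np.nan, np.nan
            if ok.sum() >= 3 and np.std(a[ok]) > 0 and np.std(b[ok]) > 0:
                r_val, p_val = stats.pearsonr(a[ok], b[ok])
            rows.append({"sample_a": cols[i], "sample_b": cols[j],
                         "r": r_val, "p": p_val, "n": int(ok.sum())})
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "r", "p", "n"])
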