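"""Packaged toy genome: hg19 autosome arm boundaries and a synthetic gene annotation.

The arm table carries real hg19 chromosome lengths and approximate centromere
midpoints (p arm = 1..centromere, q arm = centromere+1..length, 1-based
inclusive).  The gene annotation is synthetic: ``N_TOY_GENES`` genes named
``G0001``.. are spread across arms proportionally to arm length, so arm-level
copy-number events translate into gene-level dosage exactly as in real data
while the whole table stays desk-scale.
"""

from __future__ import annotations

import functools

import numpy as np
import pandas as pd

# (length, centromere midpoint), hg19, autosomes only
_HG19 = {
    "1": (249250621, 125000000),
    "2": (243199373, 93300000),
    "3": (198022430, 91000000),
    "4": (191154276, 50400000),
    "5": (180915260, 48400000),
    "6": (171115067, 61000000),
    "7": (159138663, 59900000),
    "8": (146364022, 45600000),
    "9": (141213431, 49000000),
    "10": (135534747, 40200000),
    "11": (135006516, 53700000),
    "12": (133851895, 35800000),
    "13": (115169878, 17900000),
    "14": (107349540, 17600000),
    "15": (102531392, 19000000),
    "16": (90354753, 36600000),
    "17": (81195210, 24000000),
    "18": (78077248, 17200000),
    "19": (59128983, 26500000),
    "20": (63025520, 27500000),
    "21": (48129895, 13200000),
    "22": (51304566, 14700000),
}

CHROMOSOMES = list(_HG19)

N_TOY_GENES = 2000
# every 20th toy gene is flagged as a known cancer gene (Census-like annotation)
CANCER_GENE_STRIDE = 20


@functools.lru_cache(maxsize=1)
def arm_table() -> pd.DataFrame:
    """Chromosome-arm template: one row per arm with 1-based inclusive bounds."""
    rows = []
    for chrom, (length, cen) in _HG19.items():
        rows.append({"chrom": chrom, "arm": f"{chrom}p", "start": 1, "end": cen})
        rows.append({"chrom": chrom, "arm": f"{chrom}q", "start": cen + 1, "end": length})
    return pd.DataFrame(rows)


def chromosome_lengths() -> dict[str, int]:
    return {c: v[0] for c, v in _HG19.items()}


@functools.lru_cache(maxsize=1)
def toy_gene_table() -> pd.DataFrame:
    """Synthetic gene annotation (gene, chrom, start, end, arm, is_cancer_gene).

    Genes are laid out deterministically: arms receive genes proportionally to
    their length, and genes are evenly spaced within each arm.  Coordinates are
    1-based inclusive; every gene spans 10 kb.
    """
    arms = arm_table()
    arm_len = (arms["end"] - arms["start"] + 1).to_numpy(dtype=float)
    raw = arm_len / arm_len.sum() * N_TOY_GENES
    counts = np.floor(raw).astype(int)
    # distribute the remainder to the arms with the largest fractional part
    rem = N_TOY_GENES - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1

    rows = []
    gidx = 0
    for (_, arm), n in zip(arms.iterrows(), counts):
        if n == 0:
            continue
        span = arm["end"] - arm["start"] + 1
        starts = arm["start"] + (np.arange(n) + 0.5) / n * span
        for s in starts.astype(int):
            gidx += 1
            rows.append(
                {
                    "gene": f"G{gidx:04d}",
                    "chrom": arm["chrom"],
                    "start": int(s),
                    "end": int(s) + 9999,
                    "arm": arm["arm"],
                    "is_cancer_gene": gidx % CANCER_GENE_STRIDE == 0,
                }
            )
    return pd.DataFrame(rows)


def genomic_sort_key(chrom: str, pos: int) -> tuple[int, str, int]:
    """Sort key placing chromosomes in natural order (1..22, X, Y, then others)."""
    name = chrom.removeprefix("chr")
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if name.isdigit():
        return (int(name), "", pos)
    if name in special:
        return (special[name], "", pos)
    return (1000, name, pos)
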