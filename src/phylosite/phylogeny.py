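"""Multi-site mutation matrices, deep-coverage rescue, and NJ phylogenies.

The presence/absence matrix has one row per somatic mutation (keyed
``chrom:pos:ref:alt``) and one column per tumor site.  Rows are classified:

* **trunk** — present in every site (all entries 1);
* **private** — present in exactly one site;
* **branch** — anything in between.

Deep-targeted *rescue* re-genotypes every union mutation at high coverage
(~3700X) and flips absent cells to present when the deep alt count and VAF
clear a configurable rule; presence can only grow, so the trunk fraction is
non-decreasing under rescue.

Trees are inferred with classical Saitou–Nei neighbor joining on hamming
distances, with an all-zero germline profile appended as the ancestor and used
to root the tree.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

from .genome import genomic_sort_key
from .qc import VariantCall

GERMLINE = "germline"

WES_DETECTED = "wes_detected"
DEEP_RESCUED = "deep_rescued"
ABSENT = "absent"


def _key_sort(keys: Iterable[str]) -> list[str]:
    def k(key: str):
        chrom, pos, ref, alt = key.split(":", 3)
        return (*genomic_sort_key(chrom, int(pos)), ref, alt)

    return sorted(keys, key=k)


@dataclass
class SiteMutationMatrix:
    """Per-patient mutations × samples presence/absence matrix with provenance."""

    patient_id: str
    presence: pd.DataFrame  # 0/1, index = mutation keys, columns = samples
    provenance: pd.DataFrame  # aligned, entries in {wes_detected, deep_rescued, absent}

    def __post_init__(self) -> None:
        if (self.presence.sum(axis=1) == 0).any():
            bad = self.presence.index[self.presence.sum(axis=1) == 0].tolist()
            raise ValueError(f"all-zero mutation rows violate the union invariant: {bad}")

    @property
    def samples(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def categories(self) -> pd.Series:
        """Row label: trunk (all 1), private (exactly one 1), branch otherwise."""
        n = self.presence.shape[1]
        counts = self.presence.sum(axis=1)
        lab = np.where(counts == n, "trunk", np.where(counts == 1, "private", "branch"))
        return pd.Series(lab, index=self.presence.index, name="category")

    @property
    def trunk_fraction(self) -> float:
        cats = self.categories
        return float((cats == "trunk").mean())


def build_binary_matrix(
    per_sample_variants: Mapping[str, Iterable[VariantCall]], patient_id: str = ""
) -> SiteMutationMatrix:
    """Union all detected mutations over a patient's samples into a 0/1 matrix.

    Row order is genomic; entry 1 iff the variant key was detected in that
    sample.  Requires at least two samples.
    """
    samples = list(per_sample_variants)
    if len(samples) < 2:
        raise ValueError("a phylogeny needs at least two samples")
    key_sets: dict[str, set[str]] = {}
    for s in samples:
        keys = [v.key if isinstance(v, VariantCall) else str(v) for v in per_sample_variants[s]]
        if len(keys) != len(set(keys)):
            dup = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate variant keys in sample {s}: {dup}")
        key_sets[s] = set(keys)
    union = _key_sort(set().union(*key_sets.values()))
    pres = pd.DataFrame(
        {s: [1 if k in key_sets[s] else 0 for k in union] for s in samples},
        index=pd.Index(union, name="mutation"),
        dtype=int,
    )
    prov = pres.map(lambda x: WES_DETECTED if x else ABSENT)
    return SiteMutationMatrix(patient_id, pres, prov)


@dataclass(frozen=True)
class RescueRule:
    """Deep-tier presence rule: alt reads ≥ min_alt and VAF ≥ min_vaf."""

    min_alt: int = 5
    min_vaf: float = 0.01


def rescue_genotype(
    matrix: SiteMutationMatrix, deep_counts: pd.DataFrame, rule: RescueRule = RescueRule()
) -> SiteMutationMatrix:
    """Flip absent cells to present where deep re-genotyping finds the allele.

    ``deep_counts`` columns: mutation, sample, depth, alt.  Present cells never
    flip back; cells without deep coverage are warned about and left as is.
    """
    deep = deep_counts.set_index(["mutation", "sample"])
    pres = matrix.presence.copy()
    prov = matrix.provenance.copy()
    for key in pres.index:
        for s in pres.columns:
            if pres.at[key, s] == 1:
                continue
            try:
                rec = deep.loc[(key, s)]
            except KeyError:
                warnings.warn(
                    f"no deep coverage for {key} in {s}; cell left unrescued",
                    stacklevel=2,
                )
                continue
            depth, alt = int(rec["depth"]), int(rec["alt"])
            if depth > 0 and alt >= rule.min_alt and alt / depth >= rule.min_vaf:
                pres.at[key, s] = 1
                prov.at[key, s] = DEEP_RESCUED
    return SiteMutationMatrix(matrix.patient_id, pres, prov)


def classify_mutations(matrix: SiteMutationMatrix) -> tuple[pd.Series, dict]:
    """Per-row trunk/branch/private labels plus a per-patient summary."""
    cats = matrix.categories
    counts = cats.value_counts().reindex(["trunk", "branch", "private"], fill_value=0)
    summary = {
        "patient_id": matrix.patient_id,
        "n_mutations": int(len(cats)),
        "n_trunk": int(counts["trunk"]),
        "n_branch": int(counts["branch"]),
        "n_private": int(counts["private"]),
        "trunk_fraction": float(counts["trunk"] / len(cats)),
    }
    return cats, summary


def hamming_distance_matrix(matrix, germline: str = GERMLINE) -> pd.DataFrame:
    """Pairwise hamming distances between sample columns, plus a germline.

    Accepts a :class:`SiteMutationMatrix` or a plain rows × samples DataFrame
    (binary or encoded integers).  An all-zero germline column is appended
    before computation, so a sample's distance to germline is its number of
    non-zero entries.
    """
    df = matrix.presence if isinstance(matrix, SiteMutationMatrix) else matrix
    if df.shape[1] < 2:
        raise ValueError("need at least two samples")
    data = df.to_numpy()
    cols = list(df.columns) + [germline]
    data = np.column_stack([data, np.zeros(len(df), dtype=data.dtype)])
    n = len(cols)
    out = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.sum(data[:, i] != data[:, j]))
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=cols, columns=cols)


@dataclass
class PhyloTree:
    """A germline-rooted tree over one patient's samples.

    Branch lengths are in alteration counts (real-valued after NJ estimation,
    clamped at 0).  Serializes to/from Newick losslessly.
    """

    tree: TreeNode

    @property
    def leaf_names(self) -> set[str]:
        return {t.name for t in self.tree.tips()}

    def to_newick(self) -> str:
        buf = _io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        return cls(TreeNode.read(_io.StringIO(newick), format="newick"))

    def leaf_distance(self, a: str, b: str) -> float:
        """Path length between two leaves."""
        return float(self.tree.find(a).distance(self.tree.find(b)))

    def root_to_leaf_lengths(self) -> dict[str, float]:
        return {t.name: float(t.accumulate_to_ancestor(self.tree)) for t in self.tree.tips()}


def neighbor_joining(dist: pd.DataFrame, root_at: str | None = GERMLINE) -> PhyloTree:
    """Classical Saitou–Nei neighbor joining with deterministic tie-breaking.

    The Q criterion Q(i,j) = (n−2)·d(i,j) − r(i) − r(j) is minimized at each
    agglomeration step; ties are broken by lexicographic order of the joined
    leaf-name pairs.  Negative branch-length estimates are clamped to 0.  If
    ``root_at`` names a leaf present in the matrix (the germline by default),
    the returned tree is rooted with that leaf as outgroup.
    """
    d = dist.to_numpy(dtype=float)
    names = [str(c) for c in dist.columns]
    if list(dist.index) != list(dist.columns):
        raise ValueError("distance matrix index and columns must match")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    n = len(names)
    if n < 2:
        raise ValueError("need at least two taxa")

    nodes = [TreeNode(name=nm) for nm in names]
    # min-name per subtree for lexicographic tie-breaking
    labels = list(names)
    d = d.copy()

    while len(nodes) > 2:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair = tuple(sorted((labels[i], labels[j])))
                cand = (q, pair, i, j)
                if best is None or (q < best[0] - 1e-12) or (
                    abs(q - best[0]) <= 1e-12 and pair < best[1]
                ):
                    best = cand
        _, _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = float(li), float(lj)
        parent = TreeNode(children=[child_i, child_j])
        new_d = np.array([(d[i, k] + d[j, k] - d[i, j]) / 2 for k in range(m)])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((len(keep) + 1, len(keep) + 1))
        d2[: len(keep), : len(keep)] = d[np.ix_(keep, keep)]
        d2[-1, : len(keep)] = d2[: len(keep), -1] = np.maximum(new_d[keep], 0.0)
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]

    # final join: attach the remaining edge length to the lexicographically
    # later subtree; any split preserves all leaf-to-leaf path lengths
    a, b = nodes
    if labels[0] <= labels[1]:
        a.length, b.length = 0.0, float(max(d[0, 1], 0.0))
    else:
        a.length, b.length = float(max(d[0, 1], 0.0)), 0.0
    tree = TreeNode(children=[a, b])

    if root_at is not None and root_at in names:
        tree = tree.root_by_outgroup([root_at])
    return PhyloTree(tree)


def mean_vaf_by_category(
    variants: Iterable[VariantCall], labels: pd.Series
) -> dict[str, float]:
    """Mean tumor VAF over present (mutation, sample) cells, per category.

    ``labels`` maps mutation keys to trunk/branch/private.  Only calls whose
    key is labeled contribute; categories with no present cells are omitted
    from the result rather than reported as 0.
    """
    acc: dict[str, list[float]] = {}
    for v in variants:
        if v.key not in labels.index:
            continue
        acc.setdefault(str(labels[v.key]), []).append(v.t_vaf)
    return {cat: float(np.mean(vals)) for cat, vals in acc.items()}
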