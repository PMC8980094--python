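"""Synthetic multi-site tumor cohorts with known clonal truth.

Each simulated patient carries 2–5 tumor sites.  Somatic mutations partition
into three clonal categories:

* **trunk** — present in every site, carried by the founding clone
  (cancer cell fraction, CCF, of 1.0 in every site);
* **branch** — present in more than one but not all sites, carried by a
  subclone with CCF drawn uniformly from a configurable range;
* **private** — present in exactly one site, likewise subclonal.

The expected variant allele fraction of a mutation in a site where it is
present is ``0.5 × purity × CCF`` (heterozygous, diploid locus).  Read counts
are generated at two coverage tiers: exome-like (depth ~ Poisson(228)) and
deep targeted (depth ~ Poisson(3700)); alt counts are Binomial(depth, VAF)
where the mutation is present and Binomial(depth, error_rate) where absent.

Arm-level copy-number events are either shared by all sites (trunk events) or
private to one site; expression log2 fold changes are generated as a linear
function of gene-level encoded copy-number dosage plus Gaussian noise.

A patient with only two sites cannot host a "more than one but not all sites"
subclone, so for such patients the branch probability mass is folded into the
private category; the trunk proportion is unaffected, which keeps the cohort
trunk fraction interpretable regardless of the site-count mix.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import genome
from .qc import QCThresholds, VariantCall

CATEGORIES = ("trunk", "branch", "private")

_BASES = np.array(list("ACGT"))

_CONSEQUENCE_PROBS = {
    "nonsynonymous": 0.60,
    "synonymous": 0.25,
    "stopgain": 0.05,
    "splicing": 0.05,
    "stoploss": 0.02,
    "other": 0.03,
}


@dataclass(frozen=True)
class ScnaEventRates:
    """Per-arm probabilities of shared (trunk) and private copy-number events."""

    shared_gain: float = 0.15
    shared_loss: float = 0.10
    private_gain: float = 0.03
    private_loss: float = 0.03
    per_arm: dict = field(default_factory=dict)  # arm -> {field: rate} overrides

    def __post_init__(self) -> None:
        for f in ("shared_gain", "shared_loss", "private_gain", "private_loss"):
            r = getattr(self, f)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"event rate {f}={r} outside [0, 1]")
        for arm, over in self.per_arm.items():
            for f, r in over.items():
                if not 0.0 <= r <= 1.0:
                    raise ValueError(f"event rate {f}={r} for arm {arm} outside [0, 1]")

    def rate(self, arm: str, which: str) -> float:
        return self.per_arm.get(arm, {}).get(which, getattr(self, which))


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of a synthetic multi-site cohort."""

    n_patients: int = 14
    sites_per_patient: tuple[int, int] = (2, 5)  # inclusive range, drawn uniformly
    n_mutations_per_patient: int = 40
    clone_fractions: tuple[float, float, float] = (0.60, 0.25, 0.15)  # trunk/branch/private
    subclone_ccf_range: tuple[float, float] = (0.3, 0.8)
    tumor_purity: float = 0.4
    depth_wes: float = 228.0
    depth_deep: float = 3700.0
    sequencing_error: float = 0.001
    detection_thresholds: QCThresholds = field(default_factory=QCThresholds)
    scna_event_rates: ScnaEventRates = field(default_factory=ScnaEventRates)
    expression_cn_slope: float = 1.0
    expression_noise_sd: float = 0.25
    # explicit per-patient site counts (entries in [1, 5]); single-site
    # patients are legal here and are skipped by the relatedness workflow
    site_counts: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        cf = np.asarray(self.clone_fractions, dtype=float)
        if cf.min() < 0 or abs(cf.sum() - 1.0) > 1e-9:
            raise ValueError("clone_fractions must be non-negative and sum to 1")
        lo, hi = self.sites_per_patient
        if not (2 <= lo <= hi <= 5):
            raise ValueError("sites_per_patient must lie within [2, 5]")
        if self.site_counts is not None:
            if len(self.site_counts) != self.n_patients:
                raise ValueError("site_counts must list one count per patient")
            if any(not 1 <= int(c) <= 5 for c in self.site_counts):
                raise ValueError("site_counts entries must lie within [1, 5]")
        if self.depth_wes <= 0 or self.depth_deep <= 0:
            raise ValueError("coverage depths must be strictly positive")
        if not 0.0 < self.tumor_purity <= 1.0:
            raise ValueError("tumor_purity must be in (0, 1]")
        if self.n_mutations_per_patient <= 0:
            raise ValueError("n_mutations_per_patient must be positive")
        if not 0.0 <= self.sequencing_error < 0.5:
            raise ValueError("sequencing_error must be a small per-base rate")


def study_like_config(seed: int = 0) -> SimulationConfig:
    """A 14-patient cohort mirroring a typical multi-site study design.

    Four patients carry multiple specimens (2, 2, 3 and 5 tumor sites); the
    remaining ten have a single specimen and are skipped by the per-patient
    phylogeny (which needs at least two sites).
    """
    return SimulationConfig(
        n_patients=14, site_counts=(2, 2, 3, 5) + (1,) * 10, seed=seed
    )


def deep_validation_config(seed: int = 0, n_patients: int = 20) -> SimulationConfig:
    """The packaged deep-validation scenario.

    Trunk/branch/private proportions 0.60/0.25/0.15, exome coverage 228X,
    deep-targeted re-genotyping at 3700X, purity 0.4 — the regime in which
    deep re-genotyping recovers the true 60% trunk proportion.
    """
    return SimulationConfig(n_patients=n_patients, seed=seed)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated mutation in one patient."""

    patient_id: str
    mutation_id: str  # chrom:pos:ref:alt
    true_category: str
    sites_present: tuple[str, ...]
    true_vaf_per_site: dict  # sample_id -> VAF (0.0 where absent)


@dataclass(frozen=True)
class ScnaTruthEvent:
    patient_id: str
    arm: str
    kind: str  # gain | loss
    shared: bool
    sites: tuple[str, ...]
    tcn: int


@dataclass
class SimulatedPatient:
    patient_id: str
    sites: list[str]
    truth: list[TruthRecord]
    wes_calls: list[VariantCall]
    deep_counts: pd.DataFrame  # patient, mutation, sample, depth, alt
    scna_profiles: list  # SegmentProfile, one per site
    scna_truth: list[ScnaTruthEvent]


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    patients: list[SimulatedPatient]
    expression: pd.DataFrame  # gene, log2fc, p
    gene_sets: dict  # name -> list of genes

    @property
    def truth(self) -> list[TruthRecord]:
        return [t for p in self.patients for t in p.truth]


def _draw_categories(rng: np.random.Generator, n: int, fractions, n_sites: int) -> np.ndarray:
    """Draw trunk/branch/private labels; with <3 sites branch mass goes private."""
    p = np.asarray(fractions, dtype=float)
    if n_sites <= 2:
        p = np.array([p[0], 0.0, p[1] + p[2]])
    return rng.choice(np.array(CATEGORIES), size=n, p=p)


def _draw_mutation_loci(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Sample n distinct loci from the toy annotation with ref/alt alleles."""
    genes = genome.toy_gene_table()
    idx = rng.choice(len(genes), size=n, replace=n > len(genes))
    rows = genes.iloc[idx].reset_index(drop=True)
    offsets = rng.integers(0, rows["end"] - rows["start"] + 1)
    pos = (rows["start"] + offsets).to_numpy()
    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
    out = pd.DataFrame(
        {
            "chrom": rows["chrom"].to_numpy(),
            "pos": pos,
            "ref": _BASES[ref_i],
            "alt": _BASES[alt_i],
            "gene": rows["gene"].to_numpy(),
            "is_cancer_gene": rows["is_cancer_gene"].to_numpy(),
        }
    )
    out = out.drop_duplicates(subset=["chrom", "pos"]).reset_index(drop=True)
    while len(out) < n:  # rare collision: top up
        extra = _draw_mutation_loci(rng, n - len(out))
        out = (
            pd.concat([out, extra])
            .drop_duplicates(subset=["chrom", "pos"])
            .reset_index(drop=True)
        )
    return out.iloc[:n]


def simulate_patient(
    config: SimulationConfig,
    patient_id: str,
    rng: np.random.Generator,
    n_sites: int | None = None,
) -> tuple[list[TruthRecord], list[VariantCall], pd.DataFrame]:
    """Simulate one patient's mutations at both coverage tiers.

    Returns truth records, exome-tier variant calls (one per mutation × site,
    including error-only records at sites where the mutation is absent), and
    the deep-targeted read-count table covering every (mutation, site) pair.
    ``n_sites`` overrides the random draw (used for fixed study designs).
    """
    if n_sites is None:
        n_sites = int(
            rng.integers(config.sites_per_patient[0], config.sites_per_patient[1] + 1)
        )
    sites = [f"{patient_id}{chr(ord('a') + i)}" for i in range(n_sites)]
    n_mut = config.n_mutations_per_patient

    loci = _draw_mutation_loci(rng, n_mut)
    cats = _draw_categories(rng, n_mut, config.clone_fractions, n_sites)

    consequences = rng.choice(
        list(_CONSEQUENCE_PROBS), size=n_mut, p=list(_CONSEQUENCE_PROBS.values())
    )
    # most variants are novel; a few carry a small population frequency
    pop_maf = np.where(rng.random(n_mut) < 0.05, rng.uniform(0.0, 0.05, n_mut), 0.0)

    truth: list[TruthRecord] = []
    wes_calls: list[VariantCall] = []
    deep_rows = []
    lo, hi = config.subclone_ccf_range

    for i in range(n_mut):
        cat = str(cats[i])
        if cat == "trunk":
            present = list(sites)
            ccf = 1.0
        elif cat == "private":
            present = [sites[int(rng.integers(n_sites))]]
            ccf = float(rng.uniform(lo, hi))
        else:  # branch: 1 < k < n_sites
            k = int(rng.integers(2, n_sites))
            present = sorted(rng.choice(sites, size=k, replace=False))
            ccf = float(rng.uniform(lo, hi))
        vaf = 0.5 * config.tumor_purity * ccf
        mut_id = f"{loci.chrom[i]}:{loci.pos[i]}:{loci.ref[i]}:{loci.alt[i]}"
        vaf_per_site = {s: (vaf if s in present else 0.0) for s in sites}
        truth.append(
            TruthRecord(patient_id, mut_id, cat, tuple(sorted(present)), vaf_per_site)
        )
        for s in sites:
            p_alt = vaf_per_site[s] if vaf_per_site[s] > 0 else config.sequencing_error
            t_depth = max(1, int(rng.poisson(config.depth_wes)))
            t_alt = int(rng.binomial(t_depth, p_alt))
            n_depth = max(1, int(rng.poisson(config.depth_wes)))
            n_alt = int(rng.binomial(n_depth, config.sequencing_error))
            wes_calls.append(
                VariantCall(
                    patient_id=patient_id,
                    sample_id=s,
                    chrom=str(loci.chrom[i]),
                    pos=int(loci.pos[i]),
                    ref=str(loci.ref[i]),
                    alt=str(loci.alt[i]),
                    t_depth=t_depth,
                    t_alt=t_alt,
                    n_depth=n_depth,
                    n_alt=n_alt,
                    consequence=str(consequences[i]),
                    gene=str(loci.gene[i]),
                    maf_esp6500=float(pop_maf[i]),
                    maf_1000g=float(pop_maf[i]),
                    is_cancer_gene=bool(loci.is_cancer_gene[i]),
                )
            )
            d_depth = max(1, int(rng.poisson(config.depth_deep)))
            d_alt = int(rng.binomial(d_depth, p_alt))
            deep_rows.append((patient_id, mut_id, s, d_depth, d_alt))

    deep = pd.DataFrame(deep_rows, columns=["patient", "mutation", "sample", "depth", "alt"])
    return truth, wes_calls, deep


def simulate_scna_profiles(
    config: SimulationConfig, patient_id: str, sites: list[str], rng: np.random.Generator
):
    """Arm-level copy-number profiles for each site plus the truth event list.

    Shared (trunk) events hit every site; private events hit exactly one.
    Each profile tiles every autosome arm exactly once (whole-arm events), with
    integer total copy number and log2 ratio (log2(tCN/2), tCN 0 floored).
    """
    from .scna import LOG2_FLOOR, SegmentProfile, encode_tcn

    arms = genome.arm_table()
    rates = config.scna_event_rates
    # tcn per (arm, site); start diploid
    tcn = {arm: {s: 2 for s in sites} for arm in arms["arm"]}
    events: list[ScnaTruthEvent] = []

    for arm in arms["arm"]:
        u = rng.random()
        if u < rates.rate(arm, "shared_gain"):
            cn = int(rng.choice([3, 4], p=[0.7, 0.3]))
            for s in sites:
                tcn[arm][s] = cn
            events.append(ScnaTruthEvent(patient_id, arm, "gain", True, tuple(sites), cn))
        elif u < rates.rate(arm, "shared_gain") + rates.rate(arm, "shared_loss"):
            cn = int(rng.choice([1, 0], p=[0.9, 0.1]))
            for s in sites:
                tcn[arm][s] = cn
            events.append(ScnaTruthEvent(patient_id, arm, "loss", True, tuple(sites), cn))
        else:
            v = rng.random()
            if v < rates.rate(arm, "private_gain"):
                s = sites[int(rng.integers(len(sites)))]
                tcn[arm][s] = 3
                events.append(ScnaTruthEvent(patient_id, arm, "gain", False, (s,), 3))
            elif v < rates.rate(arm, "private_gain") + rates.rate(arm, "private_loss"):
                s = sites[int(rng.integers(len(sites)))]
                tcn[arm][s] = 1
                events.append(ScnaTruthEvent(patient_id, arm, "loss", False, (s,), 1))

    profiles = []
    for s in sites:
        rows = []
        for _, a in arms.iterrows():
            cn = tcn[a["arm"]][s]
            log2 = float(np.log2(cn / 2)) if cn > 0 else LOG2_FLOOR
            rows.append(
                {
                    "chrom": a["chrom"],
                    "start": int(a["start"]),
                    "end": int(a["end"]),
                    "log2": log2,
                    "tcn": cn,
                    "encoded": encode_tcn(cn),
                }
            )
        profiles.append(SegmentProfile(sample_id=s, segments=pd.DataFrame(rows)))
    return profiles, events


def simulate_expression_table(
    config: SimulationConfig,
    scna_truth: list[ScnaTruthEvent],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Differential-expression table concordant with cohort copy-number dosage.

    Each gene's log2 fold change is ``slope × mean encoded status`` of its arm
    across patients (shared events only — they define the cohort-level dosage)
    plus Normal(0, noise_sd).  The p-value is a deterministic monotone map of
    the fold change: the two-sided normal tail probability of log2FC under the
    noise distribution, so larger |log2FC| ⇒ smaller p.
    """
    from .scna import encode_tcn

    genes = genome.toy_gene_table()
    patients = sorted({e.patient_id for e in scna_truth}) or ["none"]
    arm_dosage = {}
    for arm in genome.arm_table()["arm"]:
        enc = {p: 0 for p in patients}
        for e in scna_truth:
            if e.arm == arm and e.shared:
                enc[e.patient_id] = encode_tcn(e.tcn)
        arm_dosage[arm] = float(np.mean(list(enc.values())))

    dosage = genes["arm"].map(arm_dosage).to_numpy()
    noise = (
        rng.normal(0.0, config.expression_noise_sd, len(genes))
        if config.expression_noise_sd > 0
        else np.zeros(len(genes))
    )
    log2fc = config.expression_cn_slope * dosage + noise
    sd = config.expression_noise_sd if config.expression_noise_sd > 0 else 1.0
    p = np.clip(2.0 * stats.norm.sf(np.abs(log2fc) / sd), 1e-300, 1.0)
    return pd.DataFrame({"gene": genes["gene"], "log2fc": log2fc, "p": p})


def simulate_ranked_list(
    genes: pd.Series | list[str],
    planted_sets: dict,
    planted_names: list[str],
    rng: np.random.Generator,
    boost: float = 2.0,
) -> pd.DataFrame:
    """Fusion-association scores with the named planted sets shifted upward."""
    genes = pd.Series(list(genes), name="gene")
    score = rng.normal(0.0, 1.0, len(genes))
    planted = set()
    for name in planted_names:
        planted |= set(planted_sets.get(name, []))
    score = score + boost * genes.isin(planted).to_numpy()
    return pd.DataFrame({"gene": genes, "score": score}).sort_values(
        "score", ascending=False, ignore_index=True
    )


def _plant_gene_sets(rng: np.random.Generator, n_sets: int = 8, set_size: int = 25) -> dict:
    genes = genome.toy_gene_table()["gene"].to_numpy()
    sets = {}
    for i in range(n_sets):
        members = sorted(rng.choice(genes, size=set_size, replace=False))
        sets[f"PLANTED_SET_{i + 1}"] = members
    return sets


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Simulate a full cohort: mutations, SCNA profiles, expression, gene sets.

    All randomness descends from ``config.seed`` via spawned child generators,
    so identical configs yield byte-identical cohorts.
    """
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_patients + 2)
    patients = []
    all_events: list[ScnaTruthEvent] = []
    for i in range(config.n_patients):
        rng = np.random.default_rng(children[i])
        pid = f"P{i + 1:02d}"
        fixed = config.site_counts[i] if config.site_counts is not None else None
        truth, wes, deep = simulate_patient(config, pid, rng, n_sites=fixed)
        sites = sorted({v.sample_id for v in wes}) or [f"{pid}a", f"{pid}b"]
        profiles, events = simulate_scna_profiles(config, pid, sites, rng)
        all_events.extend(events)
        patients.append(SimulatedPatient(pid, sites, truth, wes, deep, profiles, events))

    expr_rng = np.random.default_rng(children[config.n_patients])
    expression = simulate_expression_table(config, all_events, expr_rng)
    sets_rng = np.random.default_rng(children[config.n_patients + 1])
    gene_sets = _plant_gene_sets(sets_rng)
    return SimulatedCohort(config, patients, expression, gene_sets)
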