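"""Synthetic data generators with known ground truth.

Each generator emulates the statistical structure of one input of the
pipeline at desk scale — an EPIC-style beta matrix with donor random
effects and planted delta-beta shifts, a paired negative-binomial RNA-seq
count matrix with planted fold changes, a four-condition LPS re-stimulation
time course with planted tolerized genes, and a toy contig with CpG
positions, motif occurrences, peaks and TSSs concentrated near target
CpGs. Every generator is a pure function of its parameters including the
seed, and returns the planted truth alongside the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BASES, GeneSetCollection, GenomicInterval, PWM, SampleSheet
from .methylation import beta_to_m, m_to_beta


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset: parameters plus planted effects."""

    kind: str
    params: dict
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "kind": self.kind,
            "params": self.params,
            "tables": {k: v.to_dict(orient="list") for k, v in self.tables.items()},
        }
        return json.dumps(payload, indent=1, default=str)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        payload = json.loads(text)
        tables = {k: pd.DataFrame(v) for k, v in payload["tables"].items()}
        return cls(payload["kind"], payload["params"], tables)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "SimTruth":
        with open(path) as fh:
            return cls.from_json(fh.read())


def derive_seed(seed: int, stream: str) -> int:
    """Deterministic per-stream child seed (< 2**31) from one master seed."""
    import zlib

    return (int(seed) ^ zlib.crc32(stream.encode())) % (2**31)


# ---------------------------------------------------------------------------
# methylome

def simulate_methylome(
    n_probes: int = 20_000,
    n_dmp: int = 300,
    n_donors: int = 3,
    conditions: tuple[str, str] = ("untreated", "lps"),
    delta_beta: float = -0.3,
    donor_sd: float = 0.3,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, SampleSheet, SimTruth]:
    """Paired beta matrix: one sample per condition per donor.

    Baseline M-values follow a bimodal mixture (arrays are mostly near 0 or
    fully methylated). Donor offsets are probe-specific Normal(0, donor_sd)
    on the M scale, shared by both conditions of that donor (a paired random
    effect). Planted probes take baseline betas in a range where the target
    treated-minus-reference beta difference fits inside [0, 1].
    """
    if not 0 <= n_dmp < n_probes:
        raise ValueError("need 0 <= n_dmp < n_probes")
    if n_donors < 2:
        raise ValueError("need >=2 donors")
    if not -1 < delta_beta < 1 or delta_beta == 0 and n_dmp > 0:
        if n_dmp > 0:
            raise ValueError("delta_beta must be nonzero in (-1, 1) when planting probes")
    rng = np.random.default_rng(seed)
    reference, treated = conditions[0], conditions[1]

    probes = np.array([f"cg{i:08d}" for i in range(n_probes)])
    comp = rng.choice(3, size=n_probes, p=[0.45, 0.45, 0.10])
    base_m = np.where(
        comp == 0,
        rng.normal(-3.0, 0.8, n_probes),
        np.where(comp == 1, rng.normal(3.0, 0.8, n_probes), rng.normal(0.0, 1.5, n_probes)),
    )
    planted = rng.choice(n_probes, size=n_dmp, replace=False) if n_dmp else np.array([], dtype=int)
    m_ref = base_m.copy()
    m_trt = base_m.copy()
    if n_dmp:
        # reference beta drawn so beta_ref + delta stays well inside [0, 1]
        margin = 0.05
        lo = max(margin, margin - delta_beta)
        hi = min(1 - margin, 1 - margin - delta_beta)
        beta_ref = rng.uniform(lo, hi, n_dmp)
        beta_trt = beta_ref + delta_beta
        m_ref[planted] = beta_to_m(beta_ref)
        m_trt[planted] = beta_to_m(beta_trt)

    samples, cond_labels, donor_labels = [], [], []
    cols = []
    donor_offsets = rng.normal(0.0, donor_sd, size=(n_probes, n_donors))
    for d in range(n_donors):
        for cond, mu in ((reference, m_ref), (treated, m_trt)):
            samples.append(f"D{d + 1}_{cond}")
            cond_labels.append(cond)
            donor_labels.append(f"D{d + 1}")
            noise = rng.normal(0.0, noise_sd, n_probes)
            cols.append(mu + donor_offsets[:, d] + noise)
    betas = pd.DataFrame(
        np.clip(m_to_beta(np.column_stack(cols)), 0.0, 1.0), index=probes, columns=samples
    )
    sheet = SampleSheet(
        pd.DataFrame({"sample": samples, "condition": cond_labels, "donor": donor_labels})
    )
    truth = SimTruth(
        "methylome",
        {
            "n_probes": n_probes, "n_dmp": n_dmp, "n_donors": n_donors,
            "conditions": list(conditions), "delta_beta": delta_beta,
            "donor_sd": donor_sd, "noise_sd": noise_sd, "seed": seed,
        },
        {"dmps": pd.DataFrame({"probe": probes[planted], "true_delta_beta": delta_beta})},
    )
    return betas, sheet, truth


# ---------------------------------------------------------------------------
# counts

def simulate_counts(
    n_genes: int = 5_000,
    n_de: int = 200,
    lfc: float = 2.0,
    dispersion: float = 0.1,
    n_donors: int = 3,
    conditions: tuple[str, str] = ("untreated", "lps"),
    mean_log: float = 5.0,
    sd_log: float = 1.5,
    lib_size_sd: float = 0.2,
    donor_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, SampleSheet, SimTruth]:
    """Paired negative-binomial count matrix with planted fold changes.

    Gene means are log-normal; counts are NB with variance mu + dispersion
    * mu^2, multiplied by per-sample library factors and per-gene donor
    factors. Planted genes (half up, half down) are scaled by 2^(+/-lfc)
    in the treated condition.
    """
    if not 0 <= n_de < n_genes:
        raise ValueError("need 0 <= n_de < n_genes")
    rng = np.random.default_rng(seed)
    reference, treated = conditions
    genes = np.array([f"G{i:05d}" for i in range(n_genes)])
    mu0 = np.exp(rng.normal(mean_log, sd_log, n_genes))
    planted = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    true_lfc = np.zeros(n_genes)
    if n_de:
        signs = np.ones(n_de)
        signs[n_de // 2 :] = -1.0
        true_lfc[planted] = lfc * signs

    samples, cond_labels, donor_labels, cols = [], [], [], []
    donor_factor = np.exp(rng.normal(0.0, donor_sd, size=(n_genes, n_donors)))
    for d in range(n_donors):
        for cond in (reference, treated):
            samples.append(f"D{d + 1}_{cond}")
            cond_labels.append(cond)
            donor_labels.append(f"D{d + 1}")
            lib = np.exp(rng.normal(0.0, lib_size_sd))
            mu = mu0 * donor_factor[:, d] * lib
            if cond == treated:
                mu = mu * 2.0**true_lfc
            if dispersion > 0:
                r = 1.0 / dispersion
                counts = rng.negative_binomial(r, r / (r + mu))
            else:
                counts = rng.poisson(mu)
            cols.append(counts)
    counts = pd.DataFrame(np.column_stack(cols), index=genes, columns=samples)
    sheet = SampleSheet(
        pd.DataFrame({"sample": samples, "condition": cond_labels, "donor": donor_labels})
    )
    truth = SimTruth(
        "counts",
        {
            "n_genes": n_genes, "n_de": n_de, "lfc": lfc, "dispersion": dispersion,
            "n_donors": n_donors, "conditions": list(conditions), "mean_log": mean_log,
            "sd_log": sd_log, "lib_size_sd": lib_size_sd, "donor_sd": donor_sd, "seed": seed,
        },
        {"degs": pd.DataFrame({"gene": genes[planted], "true_lfc": true_lfc[planted]})},
    )
    return counts, sheet, truth


# ---------------------------------------------------------------------------
# tolerance time course

def simulate_tolerance_timecourse(
    n_genes: int = 5_000,
    n_tolerized: int = 150,
    effect: float = 2.0,
    noise_sd: float = 0.5,
    n_reps: int = 6,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str], SimTruth]:
    """Four-condition log2 expression table with planted tolerized genes.

    Every gene has a baseline, a first-exposure effect in the LPS arm and a
    re-exposure response shared by both arms; tolerized genes respond by
    ``effect`` less in the pre-exposed (LPS) arm, so their noise-free score
    is exactly ``effect`` and every other gene scores exactly 0. Each
    condition has ``n_reps`` replicate columns (donor replicates) with
    additive Normal(0, noise_sd) noise per entry; scoring averages
    replicates per condition.
    """
    if not 0 <= n_tolerized < n_genes:
        raise ValueError("need 0 <= n_tolerized < n_genes")
    rng = np.random.default_rng(seed)
    genes = np.array([f"G{i:05d}" for i in range(n_genes)])
    baseline = rng.normal(5.0, 2.0, n_genes)
    first = rng.normal(0.0, 1.0, n_genes)       # LPS-arm first-exposure shift
    response = rng.normal(2.0, 1.0, n_genes)    # shared re-exposure response
    planted = rng.choice(n_genes, size=n_tolerized, replace=False) if n_tolerized else np.array([], dtype=int)
    tol = np.zeros(n_genes)
    tol[planted] = effect

    cond_means = {
        "untreated": baseline,
        "untreated_reexposure": baseline + response,
        "lps": baseline + first,
        "lps_reexposure": baseline + first + response - tol,
    }
    cols, cond_map = {}, {}
    for cond, mu in cond_means.items():
        for r in range(n_reps):
            col = f"{cond}_r{r + 1}" if n_reps > 1 else cond
            cond_map[col] = cond
            cols[col] = mu + (rng.normal(0.0, noise_sd, n_genes) if noise_sd > 0 else 0.0)
    expr = pd.DataFrame(cols, index=genes)
    truth = SimTruth(
        "timecourse",
        {
            "n_genes": n_genes, "n_tolerized": n_tolerized, "effect": effect,
            "noise_sd": noise_sd, "n_reps": n_reps, "seed": seed,
        },
        {"tolerized": pd.DataFrame({"gene": genes[planted], "true_effect": effect})},
    )
    return expr, cond_map, truth


# ---------------------------------------------------------------------------
# regions: sequence, CpGs, peaks, TSS

DEFAULT_MOTIF = PWM(
    "SIM_STAT_LIKE",
    # sharp 9-mer, consensus TTCCGGGAA (palindromic GAS-like site)
    np.array(
        [
            [0, 0, 0, 0, 0, 0, 0, 20, 20],
            [0, 0, 20, 20, 0, 0, 0, 0, 0],
            [0, 0, 0, 0, 20, 20, 20, 0, 0],
            [20, 20, 0, 0, 0, 0, 0, 0, 0],
        ],
        dtype=float,
    ),
)


def simulate_regions(
    n_target_cpgs: int = 200,
    n_background_cpgs: int = 2_000,
    contig_length: int = 5_000_000,
    motif: PWM = DEFAULT_MOTIF,
    motif_rate_target: float = 0.6,
    motif_rate_background: float = 0.05,
    peak_halfwidth: int = 100,
    peak_rate_target: float = 1.0,
    n_tss: int = 200,
    flank: int = 250,
    seed: int = 0,
    contig: str = "chrS",
) -> tuple[str, pd.DataFrame, list[GenomicInterval], list[GenomicInterval], SimTruth]:
    """Toy contig with CpGs, planted motifs, peaks near targets, and TSSs.

    Returns (sequence, cpg annotation frame, peaks, tss, truth). The CpG
    annotation carries target/background status plus genomic-feature and
    CpG-island-context labels with distinct distributions for targets
    (mostly intergenic/intronic, open sea) versus background. Motif
    consensus copies are written into the sequence within +/-flank of a
    CpG at the given per-CpG rates; peaks of the given halfwidth are
    centered near target CpGs.
    """
    n_cpgs = n_target_cpgs + n_background_cpgs
    margin = 4000
    step = contig_length // (n_cpgs + 1)
    if step < 2 * flank + motif.length + 2 or contig_length < 4 * margin:
        raise ValueError("contig too small for requested CpG count; increase contig_length")
    rng = np.random.default_rng(seed)
    seq = rng.choice(list(BASES), size=contig_length, p=[0.25] * 4)

    # CpG positions: unique, separated by >= 2*flank so motif windows do not overlap
    jitter = min(step // 3, 1000)
    positions = np.arange(1, n_cpgs + 1) * step + rng.integers(-jitter, jitter + 1, n_cpgs)
    positions = np.clip(positions, margin, contig_length - margin)
    order = rng.permutation(n_cpgs)
    target_idx = np.sort(order[:n_target_cpgs])
    is_target = np.zeros(n_cpgs, dtype=bool)
    is_target[target_idx] = True
    for p in positions:  # make an actual CpG dinucleotide at each position
        seq[p] = "C"
        seq[p + 1] = "G"

    motif_len = motif.length
    consensus = list(motif.consensus)
    planted_motif = np.zeros(n_cpgs, dtype=bool)
    for i, p in enumerate(positions):
        rate = motif_rate_target if is_target[i] else motif_rate_background
        if rng.random() < rate:
            off = int(rng.integers(-flank, flank - motif_len + 1))
            start = p + off
            seq[start : start + motif_len] = consensus
            planted_motif[i] = True

    peaks: list[GenomicInterval] = []
    peak_cpgs = []
    for i in target_idx:
        if rng.random() < peak_rate_target:
            center = int(positions[i] + rng.integers(-peak_halfwidth // 2, peak_halfwidth // 2 + 1))
            peaks.append(
                GenomicInterval(contig, max(0, center - peak_halfwidth), center + peak_halfwidth,
                                name=f"peak_{len(peaks)}")
            )
            peak_cpgs.append(i)

    features = ["intergenic", "intron", "promoter", "exon"]
    islands = ["open_sea", "shore", "island"]
    feat = np.where(
        is_target,
        rng.choice(features, n_cpgs, p=[0.45, 0.35, 0.10, 0.10]),
        rng.choice(features, n_cpgs, p=[0.25, 0.25, 0.30, 0.20]),
    )
    isl = np.where(
        is_target,
        rng.choice(islands, n_cpgs, p=[0.70, 0.20, 0.10]),
        rng.choice(islands, n_cpgs, p=[0.40, 0.25, 0.35]),
    )

    tss_pos = np.sort(rng.choice(contig_length - 2 * margin, size=n_tss, replace=False) + margin)
    strands = rng.choice(["+", "-"], n_tss)
    tss = [
        GenomicInterval(contig, int(p), int(p) + 1, strand=s, name=f"TSSG{i:04d}")
        for i, (p, s) in enumerate(zip(tss_pos, strands))
    ]

    annot = pd.DataFrame(
        {
            "probe": [f"cg{i:08d}" for i in range(n_cpgs)],
            "chrom": contig,
            "pos": positions,
            "is_target": is_target,
            "feature": feat,
            "island_context": isl,
        }
    )
    truth = SimTruth(
        "regions",
        {
            "n_target_cpgs": n_target_cpgs, "n_background_cpgs": n_background_cpgs,
            "contig_length": contig_length, "motif": motif.name,
            "motif_rate_target": motif_rate_target, "motif_rate_background": motif_rate_background,
            "peak_halfwidth": peak_halfwidth, "n_tss": n_tss, "flank": flank, "seed": seed,
        },
        {
            "motif_carriers": pd.DataFrame({"probe": annot["probe"][planted_motif]}),
            "peak_cpgs": pd.DataFrame({"probe": annot["probe"].iloc[peak_cpgs]}),
        },
    )
    return "".join(seq), annot, peaks, tss, truth


def cpg_intervals(annot: pd.DataFrame, targets_only: bool | None = None) -> list[GenomicInterval]:
    """1-bp CpG intervals from an annotation frame (optionally target subset)."""
    frame = annot
    if targets_only is True:
        frame = annot.loc[annot["is_target"]]
    elif targets_only is False:
        frame = annot.loc[~annot["is_target"]]
    return [
        GenomicInterval(r.chrom, int(r.pos), int(r.pos) + 1, name=r.probe)
        for r in frame.itertuples()
    ]


def simulate_ranked_list(
    n_genes: int = 1_000,
    set_size: int = 50,
    top_decile: bool = True,
    seed: int = 0,
) -> tuple[pd.Series, GeneSetCollection]:
    """Synthetic ranked list plus a gene set drawn from its top decile
    (signal) or uniformly (null)."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    scores = np.sort(rng.normal(0.0, 2.0, n_genes))[::-1]
    ranked = pd.Series(scores, index=genes)
    if top_decile:
        pool = np.arange(max(set_size, n_genes // 10))
    else:
        pool = np.arange(n_genes)
    members = rng.choice(pool, size=set_size, replace=False)
    label = "planted_top_decile" if top_decile else "null_set"
    sets = GeneSetCollection({label: [genes[i] for i in members]})
    return ranked, sets
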