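"""Synthetic transcriptomes and pulsed-SILAC quantity tables with known truth.

The generator emulates the study design the pipeline targets: two conditions
("A"/"B", analogous to two cell-line strains) of six samples each, labeling
time points 0/1/4.5/11 h, replicate injections, multi-isoform genes whose
protein sequences share constitutive tryptic segments (producing shared
peptides) and carry isoform-specific segments (producing unique peptides),
multiplicative lognormal measurement noise, missingness, and a programmable
fraction of "buffered" genes whose per-sample k_loss tracks their mRNA
deviation (log2 k = log2 k_base + alpha * dlog2 mRNA + noise).

Channel kinetics are the exact steady-state inversion of the decay model:
light L(t) = T exp(-k t) and heavy H(t) = T (1 - exp(-k t)) for a precursor
of steady-state total intensity T, so L + H = T at every time point and no
heavy signal exists at t = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .peptide_mapping import DigestConfig, digest

# residues for random proteins; K/R handled separately at segment boundaries
_BODY_AA = "ACDEFGHILMNQSTVWY"  # no K/R (cleavage sites), no P (rule exception)
_AA_EXTRA = "ACDEFGHILMNPQSTVWY"  # body positions may contain P


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth generator settings (defaults mirror the study design)."""

    n_genes: int = 300
    isoform_count_distribution: tuple[tuple[int, float], ...] = (
        (1, 0.35),
        (2, 0.35),
        (3, 0.20),
        (4, 0.10),
    )
    n_samples_per_condition: int = 6
    n_replicates: int = 3
    time_points_h: tuple[float, ...] = (0.0, 1.0, 4.5, 11.0)
    noise_cv: float = 0.1
    missing_rate: float = 0.02
    buffered_fraction: float = 0.5
    buffering_alpha: float = 0.8
    buffering_noise_sd: float = 0.2  # log2 residual around the coupled rate
    independent_noise_sd: float = 0.15  # log2 jitter of unbuffered rates
    retained_intron_fraction: float = 0.2  # among non-dominant isoforms
    kloss_range: tuple[float, float] = (0.02, 0.6)  # per hour, log-uniform
    dominant_fraction: float = 0.7  # mRNA share of the major isoform
    mrna_log2_sd: float = 0.7  # per-sample biological deviation
    condition_log2_sd: float = 0.8  # gene-level A-vs-B expression shift
    expression_replicate_cv: float = 0.1
    fpkm_log_mean: float = 3.0  # natural-log lognormal parameters
    fpkm_log_sd: float = 1.0
    peptide_log_mean: float = math.log(1e5)
    peptide_log_sd: float = 0.8
    max_shared_peptides: int = 6
    max_unique_peptides: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [p for _, p in self.isoform_count_distribution]
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("isoform_count_distribution must be a probability vector")
        times = list(self.time_points_h)
        if any(t < 0 for t in times) or sorted(set(times)) != times:
            raise ValueError("time_points_h must be strictly increasing and >= 0")
        for name in ("noise_cv", "missing_rate", "buffered_fraction"):
            v = getattr(self, name)
            if v < 0 or (name != "noise_cv" and v > 1):
                raise ValueError(f"{name} out of range: {v}")
        if not (0 < self.kloss_range[0] < self.kloss_range[1]):
            raise ValueError("kloss_range must be positive and increasing")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth behind one simulated data set."""

    transcripts: pd.DataFrame
    fpkm: pd.DataFrame  # transcript x sample, noiseless
    gene_kloss: pd.DataFrame  # gene x sample, per hour
    samples: tuple[str, ...]
    condition_of: dict[str, str]
    peptide_transcripts: dict[str, frozenset] = field(default_factory=dict)
    peptide_gene: dict[str, str] = field(default_factory=dict)
    buffered_genes: frozenset = frozenset()


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with the given coefficient of variation, mean 1."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _random_tryptic_peptide(rng: np.random.Generator, length: int) -> str:
    """A peptide ending in K/R, not starting with P, no internal K/R."""
    body = "".join(rng.choice(list(_AA_EXTRA), size=length - 1))
    if body[0] == "P":
        body = rng.choice(list(_BODY_AA)) + body[1:]
    return body + rng.choice(["K", "R"])


def _segment(rng: np.random.Generator, n_peptides: int) -> str:
    return "".join(
        _random_tryptic_peptide(rng, int(rng.integers(7, 15)))
        for _ in range(n_peptides)
    )


def simulate_transcriptome(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate transcript annotation, an FPKM matrix and the ground truth.

    Every gene has one dominant protein-coding isoform; additional isoforms
    are retained_intron with probability ``retained_intron_fraction`` (no
    protein sequence) and protein-coding otherwise.  Coding isoforms of one
    gene share constitutive sequence segments and each carries an
    isoform-specific segment.
    """
    rng = _rng(config, 1)
    conditions = ("A", "B")
    samples = tuple(
        f"{c}{i + 1}" for c in conditions for i in range(config.n_samples_per_condition)
    )
    condition_of = {s: s[0] for s in samples}

    iso_counts = [n for n, _ in config.isoform_count_distribution]
    iso_probs = [p for _, p in config.isoform_count_distribution]

    t_rows: list[tuple] = []
    fpkm_rows: dict[str, np.ndarray] = {}
    gene_k: dict[str, np.ndarray] = {}
    n_samples = len(samples)
    is_b = np.array([condition_of[s] == "B" for s in samples], dtype=float)

    for gi in range(config.n_genes):
        gene = f"G{gi + 1:04d}"
        n_iso = int(rng.choice(iso_counts, p=iso_probs))

        prefix = _segment(rng, 3)
        suffix = _segment(rng, 2)

        base = rng.lognormal(config.fpkm_log_mean, config.fpkm_log_sd)
        shift = rng.normal(0.0, config.condition_log2_sd)
        dev = rng.normal(0.0, config.mrna_log2_sd, size=n_samples)
        gene_fpkm = base * 2.0 ** (shift * is_b + dev)

        if n_iso == 1:
            fracs = np.array([1.0])
        else:
            rest = rng.dirichlet(np.ones(n_iso - 1)) * (1.0 - config.dominant_fraction)
            fracs = np.concatenate([[config.dominant_fraction], rest])

        for ii in range(n_iso):
            tid = f"{gene}.T{ii + 1}"
            if ii == 0 or rng.random() >= config.retained_intron_fraction:
                biotype = "protein_coding"
                seq = prefix + _segment(rng, 2) + suffix
            else:
                biotype = "retained_intron"
                seq = ""
            t_rows.append((gene, tid, biotype, seq))
            fpkm_rows[tid] = gene_fpkm * fracs[ii]

        k_base = math.exp(
            rng.uniform(math.log(config.kloss_range[0]), math.log(config.kloss_range[1]))
        )
        gene_k[gene] = np.full(n_samples, k_base)

    transcripts = pd.DataFrame(
        t_rows, columns=["gene_id", "transcript_id", "biotype", "protein_sequence"]
    )
    fpkm = pd.DataFrame.from_dict(fpkm_rows, orient="index", columns=list(samples))
    fpkm.index.name = "transcript_id"
    gene_kloss = pd.DataFrame.from_dict(gene_k, orient="index", columns=list(samples))
    gene_kloss.index.name = "gene_id"

    # replicate-level expression matrix with injection noise
    rep_cols = pd.MultiIndex.from_product(
        [list(samples), range(1, config.n_replicates + 1)],
        names=["sample", "replicate"],
    )
    reps = np.repeat(fpkm.to_numpy(), config.n_replicates, axis=1)
    reps = reps * _lognormal_noise(rng, config.expression_replicate_cv, reps.shape)
    expression = pd.DataFrame(reps, index=fpkm.index, columns=rep_cols)

    truth = SimTruth(
        transcripts=transcripts,
        fpkm=fpkm,
        gene_kloss=gene_kloss,
        samples=samples,
        condition_of=condition_of,
    )
    return transcripts, expression, truth


def plant_buffering(truth: SimTruth, config: SimConfig) -> SimTruth:
    """Couple per-sample k_loss to mRNA deviations for a fraction of genes.

    For buffered genes, log2 k_loss in sample s equals log2 k_base +
    alpha * (log2 gene FPKM in s - gene mean) + Gaussian noise; the rest get
    independent per-sample jitter.  Membership is recorded in the truth.
    """
    if not (0.0 <= config.buffered_fraction <= 1.0):
        raise ValueError("buffered_fraction must be in [0, 1]")
    if len(set(truth.condition_of.values())) < 2:
        raise ValueError("plant_buffering requires a two-condition design")
    rng = _rng(config, 2)
    genes = list(truth.gene_kloss.index)
    n_buf = int(round(config.buffered_fraction * len(genes)))
    buffered = set(rng.choice(genes, size=n_buf, replace=False)) if n_buf else set()

    gene_fpkm = truth.fpkm.groupby(
        truth.transcripts.set_index("transcript_id")["gene_id"]
    ).sum()
    log2_fpkm = np.log2(gene_fpkm)
    dev = log2_fpkm.sub(log2_fpkm.mean(axis=1), axis=0)

    new_k = truth.gene_kloss.copy()
    n_samples = new_k.shape[1]
    for gene in genes:
        base = math.log2(truth.gene_kloss.loc[gene].iloc[0])
        if gene in buffered:
            log2k = (
                base
                + config.buffering_alpha * dev.loc[gene].to_numpy()
                + rng.normal(0.0, config.buffering_noise_sd, n_samples)
            )
        else:
            log2k = base + rng.normal(0.0, config.independent_noise_sd, n_samples)
        new_k.loc[gene] = 2.0 ** log2k
    return replace(truth, gene_kloss=new_k, buffered_genes=frozenset(buffered))


def light_heavy(total, k, t):
    """Noiseless channel kinetics: L = T e^(-k t), H = T - L."""
    total = np.asarray(total, dtype=float)
    light = total * np.exp(-np.asarray(k, dtype=float) * np.asarray(t, dtype=float))
    return light, total - light


def _choose_peptides(truth: SimTruth, config: SimConfig, rng) -> SimTruth:
    """Digest coding isoforms and pick the detectable peptide panel."""
    digest_cfg = DigestConfig(missed_cleavages=0)
    pep_tids: dict[str, set[str]] = {}
    pep_genes: dict[str, set[str]] = {}
    for row in truth.transcripts.itertuples(index=False):
        if not row.protein_sequence:
            continue
        for pep in digest(row.protein_sequence, digest_cfg):
            pep_tids.setdefault(pep, set()).add(row.transcript_id)
            pep_genes.setdefault(pep, set()).add(row.gene_id)

    chosen_t: dict[str, frozenset] = {}
    chosen_g: dict[str, str] = {}
    by_gene: dict[str, list[str]] = {}
    for pep, genes in pep_genes.items():
        if len(genes) > 1:
            continue  # cross-gene collisions are not planted as detectable
        by_gene.setdefault(next(iter(genes)), []).append(pep)

    coding_per_gene = (
        truth.transcripts[truth.transcripts["protein_sequence"] != ""]
        .groupby("gene_id")["transcript_id"]
        .nunique()
    )
    for gene in sorted(by_gene):
        peps = sorted(by_gene[gene])
        rng.shuffle(peps)
        n_coding = int(coding_per_gene.get(gene, 1))
        shared = [p for p in peps if len(pep_tids[p]) == n_coding > 1]
        unique = [p for p in peps if len(pep_tids[p]) == 1]
        other = [p for p in peps if p not in set(shared) | set(unique)]
        picked = shared[: config.max_shared_peptides]
        per_iso: dict[str, int] = {}
        for p in unique:
            (tid,) = pep_tids[p]
            if per_iso.get(tid, 0) < config.max_unique_peptides:
                per_iso[tid] = per_iso.get(tid, 0) + 1
                picked.append(p)
        if len(shared) <= 1 and n_coding == 1:
            # single-isoform gene: everything is "unique"; keep a panel wide
            # enough for a quantifiable group
            picked = unique[: config.max_shared_peptides]
        picked.extend(other[:1])
        for p in picked:
            chosen_t[p] = frozenset(pep_tids[p])
            chosen_g[p] = gene
    return replace(truth, peptide_transcripts=chosen_t, peptide_gene=chosen_g)


def simulate_psilac(truth: SimTruth, config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Generate the long-format precursor quantity table.

    Returns (table, truth) where the returned truth carries the realized
    peptide -> transcript mapping.  Heavy intensity at t = 0 is exactly 0
    before noise; dropped observations are removed from the table.
    """
    rng = _rng(config, 3)
    if not truth.peptide_transcripts:
        truth = _choose_peptides(truth, config, rng)

    peptides = sorted(truth.peptide_transcripts)
    n_pep = len(peptides)
    samples = list(truth.samples)
    n_s = len(samples)
    reps = list(range(1, config.n_replicates + 1))
    times = np.array(config.time_points_h, dtype=float)

    base = np.exp(rng.normal(config.peptide_log_mean, config.peptide_log_sd, n_pep))
    abund = np.zeros((n_pep, n_s))
    k = np.zeros((n_pep, n_s))
    for i, pep in enumerate(peptides):
        tids = truth.peptide_transcripts[pep]
        abund[i] = truth.fpkm.loc[sorted(tids), samples].sum(axis=0).to_numpy()
        k[i] = truth.gene_kloss.loc[truth.peptide_gene[pep], samples].to_numpy()
    total = base[:, None] * abund / 10.0  # scale FPKM into intensity units

    # broadcast to (pep, sample, replicate, time)
    shape = (n_pep, n_s, len(reps), len(times))
    T = np.broadcast_to(total[:, :, None, None], shape)
    K = np.broadcast_to(k[:, :, None, None], shape)
    tt = np.broadcast_to(times[None, None, None, :], shape)
    L0, H0 = light_heavy(T, K, tt)

    L = L0 * _lognormal_noise(rng, config.noise_cv, shape)
    H = H0 * _lognormal_noise(rng, config.noise_cv, shape)  # H0 = 0 stays 0

    frame = pd.DataFrame(
        {
            "sample": np.repeat(samples, len(reps) * len(times)).tolist() * n_pep,
            "replicate": np.tile(np.repeat(reps, len(times)), n_s * n_pep),
            "time_h": np.tile(times, n_s * len(reps) * n_pep),
            "peptide": np.repeat(peptides, n_s * len(reps) * len(times)),
        }
    )
    frame["charge"] = 2
    light = frame.copy()
    light["channel"] = "light"
    light["intensity"] = L.ravel()
    heavy = frame.copy()
    heavy["channel"] = "heavy"
    heavy["intensity"] = H.ravel()
    table = pd.concat([light, heavy], ignore_index=True)

    if config.missing_rate > 0:
        keep = rng.random(len(table)) >= config.missing_rate
        table = table[keep].reset_index(drop=True)
    table = table[
        ["sample", "replicate", "time_h", "peptide", "charge", "channel", "intensity"]
    ]
    return table, truth


def simulate_dataset(config: SimConfig):
    """Convenience wrapper: transcriptome + buffering + pSILAC table.

    Returns (transcripts, expression, precursors, truth).
    """
    transcripts, expression, truth = simulate_transcriptome(config)
    truth = plant_buffering(truth, config)
    precursors, truth = simulate_psilac(truth, config)
    return transcripts, expression, precursors, truth


# ---------------------------------------------------------------------------
# splicing-switch fixture
# ---------------------------------------------------------------------------

def simulate_switch_dataset(
    n_genes: int = 100,
    n_switch: int = 20,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two-condition expression matrix with planted major-isoform switches.

    Each gene has a protein-coding and a retained-intron isoform.  For
    ``n_switch`` genes the major isoform flips between conditions A and B
    (half RI->coding, half coding->RI by biotype of the majors); the rest
    keep a stable major.  All planted FPKMs clear the default prefilter.

    Returns (transcripts, expression, planted events) where planted events
    has columns gene_id, major_A, major_B, class.
    """
    rng = np.random.default_rng(seed)
    samples = [f"A{i+1}" for i in range(n_replicates)] + [
        f"B{i+1}" for i in range(n_replicates)
    ]
    cols = pd.MultiIndex.from_tuples(
        [(s, 1) for s in samples], names=["sample", "replicate"]
    )
    t_rows, e_rows, events = [], {}, []
    for gi in range(n_genes):
        gene = f"SG{gi + 1:04d}"
        t_cod, t_ri = f"{gene}.T1", f"{gene}.T2"
        t_rows.append((gene, t_cod, "protein_coding", "M" + "A" * 8 + "K"))
        t_rows.append((gene, t_ri, "retained_intron", ""))
        hi = float(rng.uniform(20, 60))
        lo = float(rng.uniform(4, 9))
        if gi < n_switch:
            ri_to_coding = gi % 2 == 0
            # majors flip between conditions
            major_a, major_b = (t_ri, t_cod) if ri_to_coding else (t_cod, t_ri)
            cls = "RI_to_coding" if ri_to_coding else "coding_to_RI"
            a_major, a_minor, b_major, b_minor = hi, lo, hi, lo
            e_rows[major_a] = [a_major] * n_replicates + [b_minor] * n_replicates
            e_rows[major_b] = [a_minor] * n_replicates + [b_major] * n_replicates
            events.append((gene, major_a, major_b, cls))
        else:
            e_rows[t_cod] = [hi] * (2 * n_replicates)
            e_rows[t_ri] = [lo] * (2 * n_replicates)
    transcripts = pd.DataFrame(
        t_rows, columns=["gene_id", "transcript_id", "biotype", "protein_sequence"]
    )
    expression = pd.DataFrame.from_dict(e_rows, orient="index")
    expression.columns = cols
    expression.index.name = "transcript_id"
    noise = 1.0 + 0.02 * rng.standard_normal(expression.shape)
    expression = expression * noise
    planted = pd.DataFrame(events, columns=["gene_id", "major_A", "major_B", "class"])
    return transcripts, expression, planted
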