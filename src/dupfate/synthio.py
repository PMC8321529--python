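"""Synthetic inputs with the statistical structure the analyses assume.

Three generators cover the pipeline end to end: duplicated gene families with
known expression fates, read sets from near-identical duplicated sequences
with known true origins, and peak landscapes with controlled depletion inside
duplicated intervals.  Every generator takes its own RNG stream derived from
the config seed plus a stage tag, so stages are individually reproducible.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dupfate.emalloc import Candidate, MultiMapping
from dupfate.quantdiv import ExpressionMatrix, GeneFamily
from dupfate.sdperm import GenomicInterval, Genome

FATES = ("conserved", "pseudogenized", "neofunctionalized", "subfunctionalized")
_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    n_families: int = 30
    paralogs_min: int = 2
    paralogs_max: int = 4
    n_tissues: int = 7
    n_replicates: int = 3
    fate_mix: dict = field(
        default_factory=lambda: {
            "conserved": 0.25,
            "pseudogenized": 0.25,
            "neofunctionalized": 0.25,
            "subfunctionalized": 0.25,
        }
    )
    expression_noise_sd: float = 0.25
    #: log2 TPM baseline distribution for ortholog profiles
    log2_tpm_mean: float = 4.0
    log2_tpm_sd: float = 1.0
    #: scale of the independent reduced profile of derived genes (conserved fate)
    derived_scale: float = 0.3
    #: subfunctionalized families are resampled until every individual paralog
    #: correlates with the ortholog at most this much at zero noise, so the
    #: summed profile is the best-correlated by a guaranteed margin
    subfun_max_individual_r: float = 0.85
    pseudocount: float = 1e-4
    # --- duplicated-read simulation ---
    psv_rate: float = 0.005
    duplicon_length: int = 5000
    read_length: int = 100
    n_reads: int = 2000
    #: probability a read originates from locus A (asymmetry knob)
    origin_prob_a: float = 0.5
    # --- CN genotypes ---
    cn_mean: float = 2.0
    cn_sd: float = 0.5
    # --- peak landscape ---
    genome_length: int = 1_000_000
    n_sd_intervals: int = 10
    sd_length: int = 10_000
    peak_density: float = 1e-4  # expected peaks per bp
    peak_length: int = 200
    depletion: float = 1.0  # 1 = calibrated null, 0 = total depletion in SDs
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.fate_mix.values()) - 1.0) > 1e-9:
            raise ValueError("fate_mix must sum to 1")
        if set(self.fate_mix) - set(FATES):
            raise ValueError(f"unknown fates: {set(self.fate_mix) - set(FATES)}")
        for name in ("n_families", "n_tissues", "n_replicates", "duplicon_length",
                     "read_length", "n_reads", "genome_length", "peak_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (2 <= self.paralogs_min <= self.paralogs_max <= 4):
            raise ValueError("paralogs per family must lie in 2..4")
        if not (0 <= self.psv_rate < 1):
            raise ValueError("psv_rate must be in [0, 1)")
        if not (0 <= self.depletion <= 1):
            raise ValueError("depletion must be in [0, 1]")

    def rng(self, stage: str) -> np.random.Generator:
        """Stage-scoped RNG: seeded from the config seed plus the stage name."""
        return np.random.default_rng([self.seed, zlib.crc32(stage.encode())])


@dataclass
class SimulatedTruth:
    """Ground-truth records for every simulated entity."""

    family_fates: dict = field(default_factory=dict)  # family -> fate
    gene_profiles: dict = field(default_factory=dict)  # gene -> true TPM per tissue
    read_origins: dict = field(default_factory=dict)  # read_id -> locus name
    psv_positions: np.ndarray | None = None
    peak_states: pd.DataFrame | None = None  # candidate peaks with accepted flag
    depletion: float | None = None


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _partition_weights(n_paralogs: int, n_tissues: int) -> np.ndarray:
    """Per-tissue partition weights (paralogs x tissues) summing to 1.

    Two paralogs get complementary sigmoids across the tissue axis; larger
    families get normalized Gaussian bumps with evenly spaced centers, which
    reduces to a similar soft partition at k=2.
    """
    t = np.arange(n_tissues, dtype=float)
    if n_paralogs == 2:
        w = _sigmoid(2.0 * (t - (n_tissues - 1) / 2.0))
        return np.vstack([1.0 - w, w])
    centers = np.linspace(0, n_tissues - 1, n_paralogs)
    sigma = (n_tissues - 1) / (2.0 * n_paralogs)
    raw = np.exp(-((t[None, :] - centers[:, None]) ** 2) / (2 * sigma**2))
    return raw / raw.sum(axis=0, keepdims=True)


def _apply_noise(tpm: np.ndarray, sd: float, pc: float, rng) -> np.ndarray:
    """Additive Gaussian noise on log2(TPM + pc), mapped back to TPM scale."""
    if sd == 0:
        return tpm.copy()
    noisy = 2.0 ** (np.log2(tpm + pc) + rng.normal(0.0, sd, size=tpm.shape)) - pc
    return np.clip(noisy, 0.0, None)


def simulate_families(config: SimulationConfig):
    """Generate ortholog/human expression with known per-family fates.

    Returns (human ExpressionMatrix, ortholog ExpressionMatrix, families,
    SimulatedTruth).  At zero noise the fate signatures hold exactly:
    conserved ancestral profiles equal the ortholog, pseudogenized derived
    genes are silent, and subfunctionalized paralogs partition the ortholog
    profile so their sum reproduces it.
    """
    rng = config.rng("families")
    T = config.n_tissues
    tissues = [f"tissue{i+1}" for i in range(T)]
    fates = rng.choice(
        list(config.fate_mix), size=config.n_families, p=list(config.fate_mix.values())
    )
    truth = SimulatedTruth()
    families = []
    human_rows = {}
    ortho_rows = {}
    for i, fate in enumerate(fates):
        fam_id = f"fam{i+1:03d}"
        k = int(rng.integers(config.paralogs_min, config.paralogs_max + 1))
        ortho = 2.0 ** rng.normal(config.log2_tpm_mean, config.log2_tpm_sd, size=T)
        anc_gene = f"{fam_id}_A"
        der_genes = tuple(f"{fam_id}_D{j}" for j in range(1, k))
        ortho_gene = f"{fam_id}_ORT"
        families.append(GeneFamily(fam_id, anc_gene, der_genes, ortho_gene))
        truth.family_fates[fam_id] = str(fate)

        profiles = {}
        if fate == "conserved":
            profiles[anc_gene] = ortho.copy()
            for g in der_genes:
                profiles[g] = config.derived_scale * 2.0 ** rng.normal(
                    config.log2_tpm_mean, config.log2_tpm_sd, size=T
                )
        elif fate == "pseudogenized":
            profiles[anc_gene] = ortho.copy()
            for g in der_genes:
                profiles[g] = np.zeros(T)
        elif fate == "neofunctionalized":
            profiles[anc_gene] = ortho.copy()
            for g in der_genes:
                profiles[g] = 2.0 ** rng.normal(
                    config.log2_tpm_mean, config.log2_tpm_sd, size=T
                )
        else:  # subfunctionalized
            weights = _partition_weights(k, T)
            # identifiability by construction: redraw the ortholog profile
            # until no single paralog tracks it too closely at zero noise
            for _ in range(1000):
                corrs = [
                    np.corrcoef(w * ortho, ortho)[0, 1] for w in weights
                ]
                if max(corrs) <= config.subfun_max_individual_r:
                    break
                ortho = 2.0 ** rng.normal(
                    config.log2_tpm_mean, config.log2_tpm_sd, size=T
                )
            for w, g in zip(weights, (anc_gene,) + der_genes):
                profiles[g] = w * ortho

        truth.gene_profiles[ortho_gene] = ortho
        truth.gene_profiles.update({g: p.copy() for g, p in profiles.items()})
        ortho_rows[ortho_gene] = ortho
        human_rows.update(profiles)

    samples = [f"s{t+1}_{r+1}" for t in range(T) for r in range(config.n_replicates)]
    tissue_of = pd.Series(
        [tissues[t] for t in range(T) for _ in range(config.n_replicates)],
        index=samples,
    )

    def expand(rows: dict) -> pd.DataFrame:
        genes = list(rows)
        base = np.vstack([rows[g] for g in genes])  # genes x tissues
        reps = np.repeat(base, config.n_replicates, axis=1)
        noisy = _apply_noise(
            reps, config.expression_noise_sd, config.pseudocount, rng
        )
        return pd.DataFrame(noisy, index=genes, columns=samples)

    human = ExpressionMatrix(expand(human_rows), tissue_of)
    ortholog = ExpressionMatrix(expand(ortho_rows), tissue_of)
    return human, ortholog, families, truth


def simulate_cn(config: SimulationConfig, genes, n_samples: int) -> pd.DataFrame:
    """Continuous per-paralog CN genotypes: Gaussian truncated at 0 around the
    configured mean (samples x genes)."""
    rng = config.rng("cn")
    cn = rng.normal(config.cn_mean, config.cn_sd, size=(n_samples, len(genes)))
    return pd.DataFrame(
        np.clip(cn, 0.0, None),
        index=[f"ind{i+1}" for i in range(n_samples)],
        columns=list(genes),
    )


def simulate_duplicated_reads(config: SimulationConfig):
    """Two near-identical paralogous sequences plus reads with known origins.

    PSV count is Poisson(psv_rate * duplicon_length); positions are uniform
    without replacement.  A read is multi-mapping iff it covers no PSV, in
    which case both loci are listed as candidates at the same offset.

    Returns ((seq_a, seq_b), reads, truth).
    """
    if config.duplicon_length <= config.read_length:
        raise ValueError("duplicon_length must exceed read_length")
    rng = config.rng("reads")
    L, R = config.duplicon_length, config.read_length
    seq_a = rng.choice(_BASES, size=L)
    seq_b = seq_a.copy()
    n_psv = min(int(rng.poisson(config.psv_rate * L)), L)
    psv_pos = np.sort(rng.choice(L, size=n_psv, replace=False))
    for p in psv_pos:
        alts = [b for b in "ACGT" if b != seq_a[p]]
        seq_b[p] = alts[rng.integers(0, 3)]

    psv_set = set(int(p) for p in psv_pos)
    reads = []
    truth = SimulatedTruth(psv_positions=psv_pos)
    n_multi = 0
    for i in range(config.n_reads):
        origin = "locusA" if rng.random() < config.origin_prob_a else "locusB"
        start = int(rng.integers(0, L - R + 1))
        covers_psv = any(start <= p < start + R for p in psv_set)
        read_id = f"read{i+1:06d}"
        truth.read_origins[read_id] = origin
        if covers_psv:
            cands = [Candidate(origin, start)]
        else:
            cands = [Candidate("locusA", start), Candidate("locusB", start)]
            n_multi += 1
        reads.append(MultiMapping(read_id=read_id, candidates=cands))
    if n_multi == 0:
        warnings.warn("psv_rate so high that no multi-mapping reads were produced")
    return ("".join(seq_a), "".join(seq_b)), reads, truth


def simulate_peak_landscape(config: SimulationConfig):
    """Peak set over a one-chromosome genome with controlled SD depletion.

    Candidate peaks arrive as a Poisson process along the chromosome;
    candidates overlapping an SD interval are kept with probability
    ``config.depletion`` (1 keeps everything, giving a calibrated null; 0
    leaves SDs peak-free).

    Returns (Genome, peaks, sd_intervals, truth).
    """
    rng = config.rng("peaks")
    L = config.genome_length
    total_sd = config.n_sd_intervals * config.sd_length
    if total_sd * 2 > L:
        raise ValueError("genome too small for the requested SD intervals")
    genome = Genome({"chr1": L})

    # evenly strided SD placement with random jitter keeps intervals disjoint
    stride = L // config.n_sd_intervals
    sds = []
    for i in range(config.n_sd_intervals):
        slack = stride - config.sd_length
        start = i * stride + int(rng.integers(0, max(slack, 1)))
        sds.append(GenomicInterval("chr1", start, start + config.sd_length))

    n_candidates = rng.poisson(config.peak_density * L)
    starts = np.sort(rng.integers(0, max(L - config.peak_length, 1), size=n_candidates))
    sd_starts = np.array([iv.start for iv in sds])
    sd_ends = np.array([iv.end for iv in sds])
    peaks = []
    records = []
    for s in starts:
        e = s + config.peak_length
        in_sd = bool(np.any((s < sd_ends) & (e > sd_starts)))
        keep = (not in_sd) or (rng.random() < config.depletion)
        records.append({"start": int(s), "end": int(e), "in_sd": in_sd, "kept": keep})
        if keep:
            peaks.append(GenomicInterval("chr1", int(s), int(e)))
    truth = SimulatedTruth(
        peak_states=pd.DataFrame(records, columns=["start", "end", "in_sd", "kept"]),
        depletion=config.depletion,
    )
    return genome, peaks, sds, truth
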