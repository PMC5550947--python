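"""Synthetic base-level read-start counts with known ground truth.

The generative model mirrors the estimation model: per position, a total
depth t is drawn from a (optionally sequence-modulated) log-normal/Poisson
depth model, the overdispersion rate theta is computed from the chosen
variant using the drawn total as the depth covariate, and the sample-1
count n is drawn beta-binomially with the gene's proportion p_i, m = t-n.

Replicate sets are generated through a shared gamma-Poisson construction:
each sample's count at a position is Poisson with rate proportional to a
Gamma(a_j)-distributed per-sample factor, a_j = 1/(2 theta_j), which makes
every unordered pair's conditional split exactly beta-binomial with the
target theta (the pair-total covariate is the expected total; realized
pair totals fluctuate around it).

Sequence-modulated depth emulates priming bias: each of the first four
downstream bases of a position's window multiplies the start rate by a
per-base factor (defaults 4^(1/4) for G and 4^(-1/4) for A when enabled,
so GGGG starts ~4x more reads and AAAA ~4x fewer).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .basecounts import (ANTISENSE, BaseStartCounts, ConfigError, GeneModel,
                         PairedCounts, SENSE, STRANDS, context_windows,
                         write_counts_table, write_fasta)

#: per-base start-rate multipliers applied over window offsets +1..+4
DEFAULT_START_MULTIPLIERS = {"G": 4.0 ** 0.25, "A": 4.0 ** -0.25}

THETA_VARIANTS = ("full", "primer_free", "depth_free", "constant", "binomial")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic comparison.

    Defaults emulate a deep spike-in style replicate experiment: 100 genes
    of 500 nt, per-position pair totals log-normal around a median of 300,
    overdispersion following the depth-dependent (primer-free) law with
    D = 1 and gamma = -0.8, which puts theta between ~10^-1 at depth 10
    and ~10^-3 at depth 3000 — the magnitude range observed in deep
    replicate data.
    """

    seed: int
    G: int = 100
    gene_length: int | tuple[int, int] = 500
    median_depth: float = 300.0
    depth_sigma: float = 0.8
    start_multipliers: Mapping[str, float] | None = None
    p_n: float = 0.5
    de_fraction: float = 0.0
    de_p: float = 0.8
    variant: str = "primer_free"
    D: float = 1.0
    gamma: float = -0.8
    beta: Mapping[tuple[int, str], float] = field(default_factory=dict)
    tail_inflation: float = 1.0
    tail_length: int = 200
    strand: str = ANTISENSE
    K: int = 80
    base_composition: tuple[float, float, float, float] | None = None
    read_length: int = 50

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.variant not in THETA_VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}")
        if not 0.0 < self.p_n < 1.0:
            raise ConfigError("p_n must be in (0,1)")
        if not 0.0 < self.de_p < 1.0:
            raise ConfigError("de_p must be in (0,1)")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigError("de_fraction must be in [0,1]")
        if self.median_depth <= 0 or self.depth_sigma < 0:
            raise ConfigError("depth parameters must be positive")
        if self.D < 0:
            raise ConfigError("D must be >= 0")
        if self.tail_inflation <= 0 or self.tail_length < 0:
            raise ConfigError("invalid tail parameters")
        if self.strand not in STRANDS:
            raise ConfigError(f"bad strand {self.strand!r}")
        if self.K <= 0 or self.K % 2:
            raise ConfigError("K must be a positive even integer")


@dataclass
class SimulationTruth:
    """Ground truth aligned to the emitted counts."""

    p_i: dict[str, float]
    de_genes: frozenset[str]
    theta: dict[str, np.ndarray]
    expected_depth: dict[str, np.ndarray]
    config: SimulationConfig
    jitter_sigma: dict[str, float] = field(default_factory=dict)


@dataclass
class PairSimulation:
    genes: dict[str, GeneModel]
    paired: list[PairedCounts]
    truth: SimulationTruth


@dataclass
class ReplicateSimulation:
    genes: dict[str, GeneModel]
    counts: dict[tuple[str, str, str], BaseStartCounts]
    sample_ids: list[str]
    truth: SimulationTruth


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def draw_beta_binomial(rng: np.random.Generator, t, p: float, theta) -> np.ndarray:
    """n ~ BetaBinomial(t; p, theta) drawn as Binomial(t, q), q ~ Beta."""
    t = np.asarray(t, dtype=np.int64)
    theta = np.broadcast_to(np.asarray(theta, dtype=float), t.shape)
    if (theta < 0).any():
        raise ConfigError("negative theta in simulation")
    q = np.full(t.shape, p, dtype=float)
    pos = theta > 0
    if pos.any():
        q[pos] = rng.beta(p / theta[pos], (1.0 - p) / theta[pos])
    return rng.binomial(t, q)


def _gene_lengths(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(cfg.gene_length, int):
        return np.full(cfg.G, cfg.gene_length, dtype=np.int64)
    lo, hi = cfg.gene_length
    return rng.integers(lo, hi + 1, size=cfg.G)


def _random_sequence(rng: np.random.Generator, L: int,
                     composition: tuple[float, ...] | None) -> str:
    probs = np.full(4, 0.25) if composition is None else np.asarray(composition)
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=L, p=probs / probs.sum())])


def _depth_multiplier(sequence: str, L: int,
                      mult: Mapping[str, float] | None) -> np.ndarray:
    """Product of per-base rate multipliers over window offsets +1..+4."""
    out = np.ones(L, dtype=float)
    if not mult:
        return out
    for off in range(1, 5):
        bases = np.array(list(sequence[off:off + L].ljust(L, "N")))
        for h, f in mult.items():
            out[bases == h] *= f
    return out


def _sequence_effect(cfg: SimulationConfig, contexts: np.ndarray) -> np.ndarray:
    """sum of true beta over each window (0 for missing windows)."""
    if not cfg.beta or cfg.variant not in ("full", "depth_free"):
        return np.zeros(len(contexts))
    out = np.zeros(len(contexts))
    for i, c in enumerate(contexts):
        if len(c) != cfg.K:
            continue
        out[i] = sum(v for (k, h), v in cfg.beta.items() if c[k - 1] == h)
    return out


def _theta_from_depth(cfg: SimulationConfig, t: np.ndarray,
                      seq_eff: np.ndarray, L_full: int,
                      positions: np.ndarray) -> np.ndarray:
    """Eq.-style overdispersion: log theta = log D + seq + gamma*log t,
    with optional tail inflation over the last tail_length nt."""
    if cfg.variant == "binomial":
        return np.zeros(len(t))
    log_theta = np.full(len(t), np.log(cfg.D) if cfg.D > 0 else -np.inf)
    if cfg.variant in ("full", "primer_free"):
        with np.errstate(divide="ignore"):
            log_theta = log_theta + cfg.gamma * np.log(np.maximum(t, 1))
    if cfg.variant in ("full", "depth_free"):
        log_theta = log_theta + seq_eff
    theta = np.exp(log_theta)
    if cfg.tail_inflation != 1.0 and cfg.tail_length > 0:
        tail = (L_full - 1 - positions) < cfg.tail_length
        theta[tail] *= cfg.tail_inflation
    return theta


# ---------------------------------------------------------------------------
# sample-pair simulation
# ---------------------------------------------------------------------------

def simulate_pair(cfg: SimulationConfig,
                  rng: np.random.Generator | None = None) -> PairSimulation:
    """Counts for one two-sample comparison with known truth.

    Per position: expected depth (log-normal, sequence-modulated), total
    t ~ Poisson, theta from the drawn total, n ~ BB(t; p_i, theta).
    A de_fraction of genes get proportion de_p instead of p_n (exact
    count, labels recorded in the truth).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    lengths = _gene_lengths(cfg, rng)
    n_de = int(round(cfg.de_fraction * cfg.G))
    de_idx = set(rng.choice(cfg.G, size=n_de, replace=False).tolist())

    genes: dict[str, GeneModel] = {}
    paired: list[PairedCounts] = []
    truth = SimulationTruth(p_i={}, de_genes=frozenset(), theta={},
                            expected_depth={}, config=cfg)
    de_names = []
    for gi in range(cfg.G):
        gid = f"g{gi + 1:04d}"
        L = int(lengths[gi])
        seq = _random_sequence(rng, L, cfg.base_composition)
        genes[gid] = GeneModel(gene_id=gid, sequence=seq, strand=SENSE)
        lam = cfg.median_depth * np.exp(cfg.depth_sigma * rng.standard_normal(L))
        lam *= _depth_multiplier(seq, L, cfg.start_multipliers)
        t = rng.poisson(lam)
        ctx = context_windows(seq, L, cfg.K)
        pos = np.arange(L)
        theta = _theta_from_depth(cfg, t, _sequence_effect(cfg, ctx), L, pos)
        p_i = cfg.de_p if gi in de_idx else cfg.p_n
        if gi in de_idx:
            de_names.append(gid)
        n = draw_beta_binomial(rng, t, p_i, theta)
        paired.append(PairedCounts(gene_id=gid, strand=cfg.strand,
                                   positions=pos, n=n, m=t - n, context=ctx))
        truth.p_i[gid] = p_i
        truth.theta[gid] = theta
        truth.expected_depth[gid] = lam
    truth.de_genes = frozenset(de_names)
    return PairSimulation(genes=genes, paired=paired, truth=truth)


# ---------------------------------------------------------------------------
# replicate-set simulation
# ---------------------------------------------------------------------------

def simulate_replicates(cfg: SimulationConfig, n_samples: int,
                        jitter: float = 0.0,
                        rng: np.random.Generator | None = None,
                        ) -> ReplicateSimulation:
    """n_samples replicates sharing p_i = p_n, pairwise beta-binomial.

    theta is computed from the expected pair total (the depth covariate of
    the regression); ``jitter`` > 0 adds an extra per-sample log-normal
    rate noise with sample-specific sigma ~ U(0, jitter), emulating a
    library effect that makes the effective dispersion pair-specific.
    With jitter = 0 every pair shares the configured theta law exactly.
    """
    if n_samples < 2:
        raise ConfigError("need at least 2 replicate samples")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    lengths = _gene_lengths(cfg, rng)
    sample_ids = [f"s{i + 1}" for i in range(n_samples)]
    tau = {s: (rng.uniform(0.0, jitter) if jitter > 0 else 0.0)
           for s in sample_ids}

    genes: dict[str, GeneModel] = {}
    counts: dict[tuple[str, str, str], BaseStartCounts] = {}
    truth = SimulationTruth(p_i={}, de_genes=frozenset(), theta={},
                            expected_depth={}, config=cfg,
                            jitter_sigma=dict(tau))
    for gi in range(cfg.G):
        gid = f"g{gi + 1:04d}"
        L = int(lengths[gi])
        seq = _random_sequence(rng, L, cfg.base_composition)
        genes[gid] = GeneModel(gene_id=gid, sequence=seq, strand=SENSE)
        lam_pair = cfg.median_depth * np.exp(cfg.depth_sigma * rng.standard_normal(L))
        lam_pair *= _depth_multiplier(seq, L, cfg.start_multipliers)
        ctx = context_windows(seq, L, cfg.K)
        pos = np.arange(L)
        theta = _theta_from_depth(cfg, np.maximum(lam_pair, 1.0),
                                  _sequence_effect(cfg, ctx), L, pos)
        # replicates of one sample at equal depth: every pair's neutral
        # proportion is 1/2, and Gamma(a)/Gamma(a) splits give Beta(a, a)
        # pair proportions with theta = 1/(2a)
        truth.p_i[gid] = 0.5
        truth.theta[gid] = theta
        truth.expected_depth[gid] = lam_pair
        a = np.where(theta > 0, 0.5 / np.maximum(theta, 1e-300), np.inf)
        for s in sample_ids:
            g = np.ones(L)
            fin = np.isfinite(a)
            if fin.any():
                g[fin] = rng.gamma(a[fin], 1.0 / a[fin])
            if tau[s] > 0:
                g *= np.exp(tau[s] * rng.standard_normal(L) - tau[s] ** 2 / 2)
            c = rng.poisson(lam_pair / 2.0 * g)
            counts[(gid, s, cfg.strand)] = BaseStartCounts(gid, s, cfg.strand, c)
    return ReplicateSimulation(genes=genes, counts=counts,
                               sample_ids=sample_ids, truth=truth)


# ---------------------------------------------------------------------------
# fixture emission
# ---------------------------------------------------------------------------

def emit_fixtures(genes: Mapping[str, GeneModel],
                  counts: Mapping[tuple[str, str, str], BaseStartCounts],
                  outdir,
                  sample_groups: Mapping[str, str] | None = None,
                  bam: bool = False,
                  read_length: int = 50) -> dict[str, str]:
    """Write FASTA + counts table + sample sheet (+ optional minimal BAM).

    Files round-trip through the I/O layer to the in-memory objects.  BAM
    emission writes one forward-strand single-end read per count unit in
    coordinate order, so unstranded re-extraction reproduces the track on
    the sense strand.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {"fasta": os.path.join(outdir, "genes.fa"),
             "counts": os.path.join(outdir, "counts.tsv"),
             "samples": os.path.join(outdir, "samples.tsv")}
    write_fasta(genes, paths["fasta"])
    write_counts_table(counts.values(), paths["counts"])
    samples = sorted({s for (_, s, _) in counts})
    with open(paths["samples"], "w") as fh:
        fh.write("sample_id\tgroup\n")
        for s in samples:
            grp = sample_groups.get(s, "a") if sample_groups else "a"
            fh.write(f"{s}\t{grp}\n")
    if bam:
        paths.update(_emit_bam(genes, counts, outdir, read_length))
    return paths


def _emit_bam(genes, counts, outdir, read_length) -> dict[str, str]:
    import os
    import pysam

    gene_ids = sorted(genes)
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": g, "LN": genes[g].length} for g in gene_ids]}
    by_sample: dict[str, list] = {}
    for (gid, sid, strand), track in counts.items():
        by_sample.setdefault(sid, []).append((gid, track))
    paths = {}
    for sid, tracks in sorted(by_sample.items()):
        path = os.path.join(outdir, f"{sid}.bam")
        with pysam.AlignmentFile(path, "wb", header=header) as bf:
            for ref_id, gid in enumerate(gene_ids):
                L = genes[gid].length
                combined = np.zeros(L, dtype=np.int64)
                for tgid, track in tracks:
                    if tgid == gid:
                        combined[:len(track.counts)] += track.counts
                k = 0
                for pos in np.nonzero(combined)[0]:
                    rl = int(min(read_length, L - pos))
                    for _ in range(int(combined[pos])):
                        a = pysam.AlignedSegment()
                        a.query_name = f"{sid}_{gid}_{pos}_{k}"
                        k += 1
                        a.reference_id = ref_id
                        a.reference_start = int(pos)
                        a.mapping_quality = 60
                        a.cigarstring = f"{rl}M"
                        a.query_sequence = genes[gid].sequence[pos:pos + rl] \
                            if genes[gid].sequence else "N" * rl
                        a.flag = 0
                        bf.write(a)
        pysam.index(path)
        paths[f"bam:{sid}"] = path
    return paths
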