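"""Method-of-moments overdispersion estimation from replicate pairs.

For replicates nothing is differentially expressed, so each pair's
per-position proportion fluctuates around that pair's neutral proportion
p_nr.  Writing sigma_r for the squared deviation of the observed
proportion from p_nr and t_r for the pair's total depth at the position,
the per-position overdispersion rate is estimated across R pairs as

    theta_hat = mean_r[ sigma_r / (p_nr (1-p_nr)) - 1/t_r ]
                / (1 - mean_r[ sigma_r / (p_nr (1-p_nr)) ])

(the moment identity Var(p_hat|t) = p(1-p)(1/t + theta(1-1/t)) solved for
theta).  Sampling noise can make the estimate negative or the denominator
non-positive; such records are flagged, floored for bookkeeping, and by
default excluded from the downstream regression.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .basecounts import (EstimationError, FilterConfig, GeneModel,
                         MISSING_CONTEXT, PairedCounts)

THETA_FLOOR = 1e-6

OBS_COLUMNS = ["gene_id", "position", "strand", "theta_hat", "depth",
               "context", "floored", "invalid"]


@dataclass(frozen=True)
class ReplicatePairSet:
    """Unordered replicate pairs with their per-pair neutral proportions."""

    pairs: tuple[tuple[str, str], ...]
    p_nr: Mapping[tuple[str, str], float]

    def __post_init__(self):
        if len(self.pairs) < 1:
            raise EstimationError("need at least one replicate pair")
        for pr in self.pairs:
            v = self.p_nr[pr]
            if not 0.0 < v < 1.0:
                raise EstimationError(f"p_nr for {pr} not inside (0,1): {v}")

    @property
    def R(self) -> int:
        return len(self.pairs)


@dataclass
class ThetaObservations:
    """Per-position theta estimates with depth and context features."""

    df: pd.DataFrame

    def __post_init__(self):
        missing = set(OBS_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"missing columns {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.df)

    def subset_strand(self, strand: str) -> "ThetaObservations":
        return ThetaObservations(self.df[self.df["strand"] == strand].reset_index(drop=True))

    @property
    def strands(self) -> list[str]:
        return sorted(self.df["strand"].unique())

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ThetaObservations":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "context": str})
        return cls(df)


# ---------------------------------------------------------------------------
# proportions
# ---------------------------------------------------------------------------

def neutral_proportion(paired: Iterable[PairedCounts]) -> float:
    """Genome-wide sample-1 count fraction over all genes and positions."""
    tot_n = 0
    tot_m = 0
    for pc in paired:
        tot_n += int(pc.n.sum())
        tot_m += int(pc.m.sum())
    if tot_n + tot_m == 0:
        raise EstimationError("zero grand total; cannot estimate neutral proportion")
    return tot_n / (tot_n + tot_m)


def gene_proportion(pc: PairedCounts) -> float:
    """Per-gene count fraction; NaN for an all-zero gene (untestable)."""
    tot = int(pc.n.sum() + pc.m.sum())
    if tot == 0:
        return float("nan")
    return int(pc.n.sum()) / tot


# ---------------------------------------------------------------------------
# moment estimator
# ---------------------------------------------------------------------------

def estimate_theta(n, m, p_nr) -> tuple[np.ndarray, np.ndarray]:
    """Per-position overdispersion estimate across R replicate pairs.

    Parameters
    ----------
    n, m : arrays of shape (R,) or (R, J)
        Counts for the two members of each pair; every entry must have
        total depth n+m >= 1.
    p_nr : array of shape (R,)
        Neutral proportion of each pair.

    Returns
    -------
    theta_hat : array of shape () or (J,)
        May be negative (sampling noise); the caller decides flooring.
    valid : boolean array, same shape
        False where the denominator is <= 0 (estimate undefined).
    """
    n = np.asarray(n, dtype=float)
    m = np.asarray(m, dtype=float)
    p = np.asarray(p_nr, dtype=float)
    scalar = n.ndim == 1
    if scalar:
        n = n[:, None]
        m = m[:, None]
    t = n + m
    if (t < 1).any():
        raise EstimationError("zero-depth pair at a position passed to estimate_theta")
    if not ((p > 0) & (p < 1)).all():
        raise EstimationError("p_nr outside (0,1)")
    phat = n / t
    sigma = (phat - p[:, None]) ** 2
    A = sigma / (p * (1.0 - p))[:, None]
    num = (A - 1.0 / t).mean(axis=0)
    den = 1.0 - A.mean(axis=0)
    valid = den > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(valid, num / np.where(valid, den, 1.0), np.nan)
    if scalar:
        return theta[0], valid[0]
    return theta, valid


def build_theta_observations(paired_by_pair: Mapping[tuple, Sequence[PairedCounts]],
                             p_nr: Mapping[tuple, float],
                             cfg: FilterConfig = FilterConfig(),
                             floor: float = THETA_FLOOR,
                             ) -> ThetaObservations:
    """Assemble the regression dataset: one record per retained position.

    A position is retained when every replicate pair has total depth >=
    max(cfg.min_depth, 1) there.  Non-positive or undefined estimates are
    floored at ``floor`` and flagged (floored / invalid), not silently
    dropped.  The depth feature is the mean pair total across pairs.
    """
    pairs = list(paired_by_pair)
    if not pairs:
        raise EstimationError("no replicate pairs")
    min_depth = max(cfg.min_depth, 1)

    # index each pair's genes
    by_gene: dict[tuple[str, str], list[PairedCounts]] = {}
    for pr in pairs:
        for pc in paired_by_pair[pr]:
            by_gene.setdefault((pc.gene_id, pc.strand), []).append(pc)

    frames = []
    p_arr = np.array([p_nr[pr] for pr in pairs], dtype=float)
    for (gid, strand), pcs in sorted(by_gene.items()):
        if len(pcs) != len(pairs):
            continue  # gene must be present in every pair
        N = np.stack([pc.n for pc in pcs])
        M = np.stack([pc.m for pc in pcs])
        T = N + M
        keep = (T >= min_depth).all(axis=0)
        if not keep.any():
            continue
        theta, valid = estimate_theta(N[:, keep], M[:, keep], p_arr)
        depth = T[:, keep].mean(axis=0)
        invalid = ~valid
        floored = invalid | (theta <= 0)
        theta = np.where(floored, floor, theta)
        frames.append(pd.DataFrame({
            "gene_id": gid,
            "position": pcs[0].positions[keep],
            "strand": strand,
            "theta_hat": theta,
            "depth": depth,
            "context": pcs[0].context[keep],
            "floored": floored,
            "invalid": invalid,
        }))
    if not frames:
        return ThetaObservations(pd.DataFrame(columns=OBS_COLUMNS))
    return ThetaObservations(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def _start_motif(contexts: pd.Series) -> pd.Series:
    """First four downstream bases of each window (the priming site)."""
    ctx = contexts.astype(str)
    half = ctx.str.len() // 2
    out = pd.Series([c[h:h + 4] if c != MISSING_CONTEXT and len(c) >= h + 4 else ""
                     for c, h in zip(ctx, half)], index=contexts.index)
    return out


def depth_dispersion_profile(obs: ThetaObservations, n_bins: int = 20) -> pd.DataFrame:
    """Mean log10 theta by log10-depth bin, with GGGG/AAAA context subsets.

    Equal-width bins in log10 depth over the observed range; per bin the
    mean of log10 theta_hat, the record count, and the same aggregates for
    positions whose window starts (downstream) with GGGG or AAAA.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    df = obs.df[~obs.df["invalid"] & ~obs.df["floored"]].copy()
    if df.empty:
        raise EstimationError("no usable theta observations")
    ld = np.log10(df["depth"].to_numpy(dtype=float))
    lt = np.log10(df["theta_hat"].to_numpy(dtype=float))
    edges = np.linspace(ld.min(), ld.max() + 1e-9, n_bins + 1)
    idx = np.clip(np.digitize(ld, edges) - 1, 0, n_bins - 1)
    motif = _start_motif(df["context"]).to_numpy()
    rows = []
    for b in range(n_bins):
        sel = idx == b
        row = {"bin_mid_log10_depth": 0.5 * (edges[b] + edges[b + 1]),
               "mean_log10_theta": lt[sel].mean() if sel.any() else np.nan,
               "count": int(sel.sum())}
        for mo in ("GGGG", "AAAA"):
            ms = sel & (motif == mo)
            row[f"mean_log10_theta_{mo.lower()}"] = lt[ms].mean() if ms.any() else np.nan
            row[f"count_{mo.lower()}"] = int(ms.sum())
        rows.append(row)
    return pd.DataFrame(rows)


def positional_profile(obs: ThetaObservations,
                       genes: Mapping[str, GeneModel],
                       n_parts: int = 10) -> pd.DataFrame:
    """Mean theta by distance-to-gene-end category.

    Positions are ranked by distance to the 3' end of their gene (in
    transcript orientation, using the full gene length) and split into
    ``n_parts`` categories with equal numbers of data points; part 1 is the
    gene tail, part ``n_parts`` the gene start.
    """
    df = obs.df[~obs.df["invalid"]]
    if len(df) < n_parts:
        raise EstimationError(f"fewer positions ({len(df)}) than parts ({n_parts})")
    lengths = df["gene_id"].map(lambda g: genes[g].length).to_numpy()
    dist = lengths - 1 - df["position"].to_numpy()
    theta = df["theta_hat"].to_numpy(dtype=float)
    order = np.argsort(dist, kind="stable")
    chunks = np.array_split(order, n_parts)
    return pd.DataFrame({
        "part": np.arange(1, n_parts + 1),
        "mean_theta": [theta[c].mean() for c in chunks],
        "count": [len(c) for c in chunks],
    })
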