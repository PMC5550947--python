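"""Log-linear overdispersion models fitted by ordinary least squares.

The linearized model for position j of gene i is

    log(theta_ij) = log(D) + sum_k sum_h beta_kh I(b_ijk = h)
                           + gamma * log(n_ij + m_ij)

with the window of K bases around the read start (K/2 before, K/2 after,
the start base itself excluded), indicator coding against a reference base
(default G, so coefficients exist for A, T and C only: 3K sequence terms).

Four nested variants are supported:

    full        depth + sequence          (3K + 2 parameters)
    primer_free depth only                (2 parameters)
    depth_free  sequence only             (3K + 1 parameters)
    constant    intercept only            (1 parameter)
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .basecounts import ConfigError, MISSING_CONTEXT
from .dispersion import ThetaObservations

VARIANTS = ("full", "primer_free", "depth_free", "constant")

LSTSQ_RCOND = 1e-10


@dataclass(frozen=True)
class DesignSpec:
    """Shape of the linearized design."""

    K: int = 80
    reference_base: str = "G"
    include_depth: bool = True
    include_sequence: bool = True

    def __post_init__(self):
        if self.K <= 0 or self.K % 2:
            raise ConfigError("K must be a positive even integer")
        if self.reference_base not in "ACGT":
            raise ConfigError("reference_base must be one of A, C, G, T")

    @property
    def coded_bases(self) -> tuple[str, str, str]:
        return tuple(b for b in "ATCG" if b != self.reference_base)[:3]

    def for_variant(self, variant: str) -> "DesignSpec":
        if variant not in VARIANTS:
            raise ConfigError(f"unknown variant {variant!r}")
        return replace(self,
                       include_depth=variant in ("full", "primer_free"),
                       include_sequence=variant in ("full", "depth_free"))


@dataclass
class DesignMatrix:
    X: np.ndarray
    y: np.ndarray
    columns: list[str]
    gene_id: np.ndarray
    position: np.ndarray
    spec: DesignSpec

    def __len__(self) -> int:
        return len(self.y)


@dataclass
class OverdispersionModel:
    """Fitted (log D, gamma, beta) for one model variant on one strand."""

    variant: str
    logD: float
    gamma: float = 0.0
    beta: np.ndarray | None = None      # (K, 3), column order = coded_bases
    K: int = 80
    reference_base: str = "G"
    strand: str | None = None
    n_obs: int = 0
    resid_var: float = float("nan")
    r_squared: float = float("nan")
    rank_deficient: bool = False

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}")
        if self.variant in ("primer_free", "constant") and self.beta is not None \
                and np.any(self.beta != 0):
            raise ConfigError(f"{self.variant} model must have beta = 0")
        if self.variant in ("depth_free", "constant") and self.gamma != 0.0:
            raise ConfigError(f"{self.variant} model must have gamma = 0")
        if self.beta is not None:
            self.beta = np.asarray(self.beta, dtype=float)
            if self.beta.shape != (self.K, 3):
                raise ConfigError(f"beta must be ({self.K}, 3)")

    @property
    def coded_bases(self) -> tuple[str, str, str]:
        return tuple(b for b in "ATCG" if b != self.reference_base)[:3]

    # -- prediction -------------------------------------------------------

    def sequence_effect(self, contexts) -> np.ndarray:
        """Per-position sum of beta over the window; 0 where the window is
        missing/incomplete (those positions still enter the likelihood)."""
        contexts = np.asarray(contexts)
        out = np.zeros(len(contexts), dtype=float)
        if self.beta is None or not np.any(self.beta):
            return out
        valid = np.array([len(c) == self.K and "N" not in c and c != MISSING_CONTEXT
                          for c in contexts])
        if not valid.any():
            return out
        chars = np.asarray(contexts[valid], dtype=f"U{self.K}") \
            .view("U1").reshape(-1, self.K)
        eff = np.zeros(chars.shape[0], dtype=float)
        for col, h in enumerate(self.coded_bases):
            eff += ((chars == h) * self.beta[:, col]).sum(axis=1)
        out[valid] = eff
        return out

    def base_log_theta(self, depth, contexts=None) -> np.ndarray:
        """Linear predictor without intercept: gamma*log(depth) + seq effect."""
        depth = np.asarray(depth, dtype=float)
        out = np.zeros(depth.shape, dtype=float)
        if self.gamma != 0.0:
            out = out + self.gamma * np.log(depth)
        if contexts is not None:
            out = out + self.sequence_effect(contexts)
        return out

    def log_theta(self, depth, contexts=None, logD: float | None = None) -> np.ndarray:
        d = self.logD if logD is None else logD
        return d + self.base_log_theta(depth, contexts)

    def theta(self, depth, contexts=None, D: float | None = None) -> np.ndarray:
        logD = None if D is None else float(np.log(D))
        return np.exp(self.log_theta(depth, contexts, logD=logD))

    # -- serialization ----------------------------------------------------

    def to_tsv(self, path) -> None:
        rows = [("__variant__", 0, ".", 0.0, self.variant),
                ("__K__", self.K, ".", 0.0, ""),
                ("__reference_base__", 0, self.reference_base, 0.0, ""),
                ("__strand__", 0, ".", 0.0, self.strand or ""),
                ("logD", 0, ".", self.logD, ""),
                ("gamma", 0, ".", self.gamma, "")]
        if self.beta is not None:
            prof = coefficient_profile(self)
            for r in prof.itertuples():
                rows.append(("beta", r.offset, r.base, r.coefficient, ""))
        pd.DataFrame(rows, columns=["term", "position_offset", "base",
                                    "estimate", "note"]) \
            .to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "OverdispersionModel":
        df = pd.read_csv(path, sep="\t", dtype={"base": str, "note": str},
                         keep_default_na=False)
        meta = {r.term: r for r in df.itertuples()}
        variant = meta["__variant__"].note
        K = int(meta["__K__"].position_offset)
        ref = meta["__reference_base__"].base
        strand = meta["__strand__"].note or None
        logD = float(meta["logD"].estimate)
        gamma = float(meta["gamma"].estimate)
        beta = None
        brows = df[df["term"] == "beta"]
        if len(brows):
            coded = tuple(b for b in "ATCG" if b != ref)[:3]
            beta = np.zeros((K, 3))
            for r in brows.itertuples():
                k = _offset_to_k(int(r.position_offset), K)
                beta[k - 1, coded.index(r.base)] = float(r.estimate)
        return cls(variant=variant, logD=logD, gamma=gamma, beta=beta, K=K,
                   reference_base=ref, strand=strand)


@dataclass
class CVResult:
    """Repeated 5-fold cross-validation R-squared for one variant.

    ``r_squared`` is the mean over all folds x repeats of the held-out
    regression sum of squares over the total sum of squares
    (SSR/SST); ``r_squared_pred`` is the conventional 1 - SSE/SST on the
    same held-out data.
    """

    variant: str
    r_squared: float
    r_squared_pred: float
    per_round: np.ndarray
    per_round_pred: np.ndarray


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _k_to_offset(k: int, K: int) -> int:
    """Window index k (1..K) to signed offset around the read start."""
    half = K // 2
    return k - half - 1 if k <= half else k - half


def _offset_to_k(offset: int, K: int) -> int:
    half = K // 2
    return offset + half + 1 if offset < 0 else offset + half


def build_design(obs: ThetaObservations, spec: DesignSpec,
                 drop_flagged: bool = True) -> DesignMatrix:
    """Feature table: response log theta_hat, predictors per the spec.

    Rows with flagged (floored / invalid) estimates are excluded by
    default: the floor value is a bookkeeping artifact whose logarithm
    would badly distort the fit.  When sequence terms are requested, rows
    with a missing or N-containing window are excluded as well.
    """
    df = obs.df
    keep = ~df["invalid"].to_numpy(dtype=bool)
    if drop_flagged:
        keep &= ~df["floored"].to_numpy(dtype=bool)
    keep &= df["theta_hat"].to_numpy(dtype=float) > 0
    ctx = df["context"].to_numpy(dtype=str)
    if spec.include_sequence:
        nonmissing = ctx != MISSING_CONTEXT
        lens = np.char.str_len(ctx)
        if (lens[nonmissing] != spec.K).any():
            raise ConfigError("context length does not match spec.K")
        keep &= nonmissing & (np.char.find(ctx, "N") < 0)
    if not keep.any():
        raise ConfigError("no usable rows for the design")
    sub = df[keep]
    y = np.log(sub["theta_hat"].to_numpy(dtype=float))
    cols: list[np.ndarray] = [np.ones(len(sub))]
    names = ["intercept"]
    if spec.include_depth:
        cols.append(np.log(sub["depth"].to_numpy(dtype=float)))
        names.append("log_depth")
    if spec.include_sequence:
        chars = np.asarray(sub["context"].to_numpy(), dtype=f"U{spec.K}") \
            .view("U1").reshape(-1, spec.K)
        for k in range(spec.K):
            for h in spec.coded_bases:
                cols.append((chars[:, k] == h).astype(float))
                names.append(f"b{k + 1}_{h}")
    X = np.column_stack(cols)
    return DesignMatrix(X=X, y=y, columns=names,
                        gene_id=sub["gene_id"].to_numpy(),
                        position=sub["position"].to_numpy(),
                        spec=spec)


def _variant_columns(design: DesignMatrix, variant: str) -> np.ndarray:
    want_depth = variant in ("full", "primer_free")
    want_seq = variant in ("full", "depth_free")
    sel = []
    for i, c in enumerate(design.columns):
        if c == "intercept":
            sel.append(i)
        elif c == "log_depth":
            if want_depth:
                sel.append(i)
        elif want_seq:
            sel.append(i)
    if want_depth and "log_depth" not in design.columns:
        raise ConfigError("variant needs a depth column the design lacks")
    if want_seq and not any(c.startswith("b") for c in design.columns):
        raise ConfigError("variant needs sequence columns the design lacks")
    return np.array(sel, dtype=int)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_theta_model(design: DesignMatrix, variant: str = "full",
                    strand: str | None = None) -> OverdispersionModel:
    """OLS on log theta_hat; coefficients mapped into an OverdispersionModel."""
    if variant not in VARIANTS:
        raise ConfigError(f"unknown variant {variant!r}")
    sel = _variant_columns(design, variant)
    X = design.X[:, sel]
    y = design.y
    if X.shape[0] < X.shape[1]:
        raise ConfigError(f"fewer rows ({X.shape[0]}) than columns ({X.shape[1]})")
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=LSTSQ_RCOND)
    rank_deficient = rank < X.shape[1]
    resid = y - X @ coef
    dof = max(X.shape[0] - rank, 1)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / sst if sst > 0 else float("nan")
    names = [design.columns[i] for i in sel]
    logD = float(coef[names.index("intercept")])
    gamma = float(coef[names.index("log_depth")]) if "log_depth" in names else 0.0
    beta = None
    if variant in ("full", "depth_free"):
        spec = design.spec
        beta = np.zeros((spec.K, 3))
        for i, name in enumerate(names):
            if name.startswith("b") and "_" in name:
                k, h = name[1:].split("_")
                beta[int(k) - 1, spec.coded_bases.index(h)] = coef[i]
    return OverdispersionModel(
        variant=variant, logD=logD, gamma=gamma, beta=beta,
        K=design.spec.K, reference_base=design.spec.reference_base,
        strand=strand, n_obs=X.shape[0],
        resid_var=float((resid ** 2).sum()) / dof, r_squared=r2,
        rank_deficient=bool(rank_deficient))


def cross_validated_r2(obs: ThetaObservations, spec: DesignSpec,
                       variant: str = "full", folds: int = 5,
                       repeats: int = 10, seed: int | None = None,
                       drop_flagged: bool = True) -> CVResult:
    """Repeated k-fold CV: fit on k-1 folds, score R-squared on the rest.

    Positions are split at random, ignoring gene structure.  Deterministic
    given ``seed``.
    """
    design = build_design(obs, spec.for_variant(variant), drop_flagged=drop_flagged)
    sel = _variant_columns(design, variant)
    X = design.X[:, sel]
    y = design.y
    n = len(y)
    if n < folds * X.shape[1]:
        raise ConfigError(f"insufficient rows ({n}) for {folds}-fold CV "
                          f"with {X.shape[1]} columns")
    rng = np.random.default_rng(seed)
    ssr_sst, one_m_sse = [], []
    for _ in range(repeats):
        perm = rng.permutation(n)
        for fold in np.array_split(perm, folds):
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            coef, *_ = np.linalg.lstsq(X[mask], y[mask], rcond=LSTSQ_RCOND)
            yhat = X[~mask] @ coef
            yt = y[~mask]
            sst = float(((yt - yt.mean()) ** 2).sum())
            ssr = float(((yhat - yt.mean()) ** 2).sum())
            sse = float(((yt - yhat) ** 2).sum())
            ssr_sst.append(ssr / sst)
            one_m_sse.append(1.0 - sse / sst)
    ssr_sst = np.array(ssr_sst)
    one_m_sse = np.array(one_m_sse)
    return CVResult(variant=variant,
                    r_squared=float(ssr_sst.mean()),
                    r_squared_pred=float(one_m_sse.mean()),
                    per_round=ssr_sst, per_round_pred=one_m_sse)


def coefficient_profile(model: OverdispersionModel) -> pd.DataFrame:
    """Sequence coefficients indexed by signed offset around the read start.

    Offsets run -K/2..-1 then +1..+K/2 (the read-start base, offset 0, is
    excluded from the window).
    """
    if model.beta is None:
        raise ConfigError(f"{model.variant} model has no sequence coefficients")
    rows = []
    for k in range(1, model.K + 1):
        off = _k_to_offset(k, model.K)
        for col, h in enumerate(model.coded_bases):
            rows.append((off, h, model.beta[k - 1, col]))
    return pd.DataFrame(rows, columns=["offset", "base", "coefficient"])
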