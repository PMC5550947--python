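"""Two-stage fitting, likelihood-ratio testing and model comparison.

Stage 1 (training): on replicate pairs with no expected biological
difference, estimate the neutral proportion, the per-position
overdispersion rates (method of moments), and regress log theta on depth
and local sequence to obtain gamma and beta.

Stage 2 (testing): on a test sample pair, hold gamma/beta at their trained
values and alternate (a) the pair-specific scale D by 1-D likelihood
maximization and (b) per-gene proportion updates, until the deviance
(-2 log L) decreases by less than the convergence threshold (default 1%).
When comparing replicates the proportion stays at the neutral value and a
single D fit is performed.

The per-gene test statistic for a pair is -2 log L(p_n) + 2 log L(p_hat_i)
~ chi-square with 1 df; with groups of replicates the pairwise statistics
over all cross-group pairs are summed, with df equal to the number of
pairs.

Model comparison names follow the nesting chain
    bi < bb_D < bb_D_g < bb_D_g_coe
(binomial; constant theta = D; depth-dependent theta; depth + sequence),
which maps onto the regression variants None / constant / primer_free /
full.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .basecounts import (BaseStartCounts, ConfigError, EstimationError,
                         FilterConfig, GeneModel, PairedCounts, build_pairs,
                         replicate_pairs)
from .core import fit_pair_D, gene_loglik, update_p
from .dispersion import (ThetaObservations, build_theta_observations,
                         gene_proportion, neutral_proportion)
from .regression import (DesignSpec, OverdispersionModel, build_design,
                         fit_theta_model)

#: comparison-chain name -> regression variant (None = binomial, theta = 0)
MODEL_VARIANTS: dict[str, str | None] = {
    "bi": None,
    "bb_D": "constant",
    "bb_D_g": "primer_free",
    "bb_D_g_coe": "full",
}
NESTED_ORDER = ("bi", "bb_D", "bb_D_g", "bb_D_g_coe")


def k_parameters(name: str, K: int) -> tuple[int, int]:
    """(total, per-pair) free-parameter counts for AIC.

    "total" counts every parameter of the theta law (D, gamma, the 3K
    sequence coefficients); "per-pair" counts only what is free when a
    test pair is fitted with gamma/beta trained upstream (D alone).
    """
    total = {"bi": 0, "bb_D": 1, "bb_D_g": 2, "bb_D_g_coe": 2 + 3 * K}[name]
    pair = 0 if name == "bi" else 1
    return total, pair


@dataclass(frozen=True)
class PipelineConfig:
    model: str = "bb_D_g"
    K: int = 80
    filters: FilterConfig = field(default_factory=FilterConfig)
    theta_floor: float = 1e-6
    convergence: float = 0.01
    max_iter: int = 50
    seed: int | None = None
    mt_method: str = "bh"

    def __post_init__(self):
        if self.model not in MODEL_VARIANTS:
            raise ConfigError(f"unknown model {self.model!r}")
        if not 0.0 < self.convergence <= 1.0:
            raise ConfigError("convergence threshold must be in (0,1]")


class ConvergenceError(RuntimeError):
    """Deviance increased beyond tolerance during iterative fitting."""


@dataclass
class FitState:
    """Result of fitting one sample pair."""

    pair: tuple[str, str] | None
    model_name: str
    p_n: float
    D: float | None
    p_hat: dict[str, float]
    loglik_pn: dict[str, float]
    loglik_phat: dict[str, float]
    deviance_history: list[float]
    n_iter: int
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def loglik(self) -> float:
        return float(sum(self.loglik_phat.values()))

    @property
    def deviance(self) -> float:
        return self.deviance_history[-1]


@dataclass
class TrainResult:
    """Trained overdispersion models (per strand) plus the regression data."""

    models: dict[str, OverdispersionModel]
    obs: ThetaObservations
    p_nr: dict[tuple[str, str], float]

    @property
    def model(self) -> OverdispersionModel:
        if len(self.models) != 1:
            raise ConfigError(f"{len(self.models)} strands fitted; pick one explicitly")
        return next(iter(self.models.values()))


# ---------------------------------------------------------------------------
# stage 1: training
# ---------------------------------------------------------------------------

def train(counts: Mapping[tuple[str, str, str], BaseStartCounts],
          genes: Mapping[str, GeneModel],
          sample_ids: Sequence[str],
          spec: DesignSpec = DesignSpec(),
          variant: str = "full",
          filters: FilterConfig = FilterConfig(),
          floor: float = 1e-6,
          drop_flagged: bool = True) -> TrainResult:
    """Estimate gamma and beta from replicate pairs.

    Runs neutral-proportion estimation, per-position moment estimation of
    theta across all unordered replicate pairs, and the linearized OLS fit
    of the requested variant, separately per strand.  D is left at the
    fitted intercept but is refit pair-specifically downstream.
    """
    pairs = replicate_pairs(sample_ids)
    if not pairs:
        raise EstimationError("need at least two replicate samples to train")
    spec = spec.for_variant(variant)
    paired_by_pair: dict[tuple[str, str], list[PairedCounts]] = {}
    p_nr: dict[tuple[str, str], float] = {}
    for pr in pairs:
        paired = build_pairs(counts, genes, pr[0], pr[1], K=spec.K, filters=filters)
        if not paired:
            raise EstimationError(f"no shared genes for replicate pair {pr}")
        paired_by_pair[pr] = paired
        p_nr[pr] = neutral_proportion(paired)
    obs = build_theta_observations(paired_by_pair, p_nr, filters, floor=floor)
    models: dict[str, OverdispersionModel] = {}
    for strand in obs.strands:
        design = build_design(obs.subset_strand(strand), spec,
                              drop_flagged=drop_flagged)
        models[strand] = fit_theta_model(design, variant, strand=strand)
    if not models:
        raise EstimationError("no usable theta observations on any strand")
    return TrainResult(models=models, obs=obs, p_nr=p_nr)


def constant_model(logD: float = 0.0) -> OverdispersionModel:
    """Intercept-only theta law (the bb_D comparison model)."""
    return OverdispersionModel(variant="constant", logD=logD)


def _model_for_strand(model, strand: str) -> OverdispersionModel:
    if isinstance(model, OverdispersionModel):
        return model
    if isinstance(model, TrainResult):
        model = model.models
    if strand in model:
        return model[strand]
    raise ConfigError(f"no trained model for strand {strand!r}")


# ---------------------------------------------------------------------------
# stage 2: per-pair fitting
# ---------------------------------------------------------------------------

def _theta_vectors(paired, model, D) -> dict[str, np.ndarray]:
    out = {}
    for pc in paired:
        if model is None:
            out[pc.gene_id] = np.zeros(len(pc))
        else:
            mdl = _model_for_strand(model, pc.strand)
            out[pc.gene_id] = D * np.exp(mdl.base_log_theta(
                np.maximum(pc.depth, 1), pc.context))
    return out


def _total_loglik(paired, theta_by_gene, p_by_gene) -> tuple[float, dict, float]:
    """(total, per-gene dict) log-likelihood at the given proportions."""
    per_gene = {}
    for pc in paired:
        pg = p_by_gene[pc.gene_id]
        if not np.isfinite(pg):
            per_gene[pc.gene_id] = 0.0
            continue
        per_gene[pc.gene_id] = gene_loglik(pc.n, pc.m, pg, theta_by_gene[pc.gene_id])
    tot = float(sum(per_gene.values()))
    return tot, per_gene, -2.0 * tot


def fit_test_pair(paired: Sequence[PairedCounts],
                  model,
                  cfg: PipelineConfig = PipelineConfig(),
                  mode: str = "comparison",
                  pair: tuple[str, str] | None = None) -> FitState:
    """Iterative D / p fitting for one sample pair.

    mode="replicate": the proportion is held at the neutral value and a
    single D optimization is performed (model-comparison protocol).
    mode="comparison": alternate pair-specific D estimation and per-gene
    proportion updates until the relative deviance decrease drops below
    cfg.convergence.  The deviance trajectory must be non-increasing (up
    to numerical tolerance); an increase aborts with diagnostics.
    """
    if mode not in ("replicate", "comparison"):
        raise ConfigError(f"unknown mode {mode!r}")
    if isinstance(model, TrainResult):
        model = model.models if len(model.models) > 1 else model.model
    model_name = "bi" if model is None else cfg.model
    p_n = neutral_proportion(paired)
    p: dict[str, float] = {}
    testable: dict[str, bool] = {}
    for pc in paired:
        gp = gene_proportion(pc)
        testable[pc.gene_id] = np.isfinite(gp)
        p[pc.gene_id] = p_n if np.isfinite(gp) else float("nan")

    flags = {"flat_D": False}

    def d_step(p_cur):
        if model is None:
            return None, _theta_vectors(paired, None, 0.0)
        res = fit_pair_D(paired, model, p_cur)
        flags["flat_D"] = flags["flat_D"] or res.flat
        return res.D, _theta_vectors(paired, model, res.D)

    D, theta = d_step(p)
    _, per_gene_pn, dev = _total_loglik(paired, theta, p)
    history = [dev]
    n_iter = 0
    tol = 1e-9

    if mode == "comparison":
        for n_iter in range(1, cfg.max_iter + 1):
            # p update given theta
            for pc in paired:
                if testable[pc.gene_id]:
                    p[pc.gene_id] = update_p(pc.n, pc.m, theta[pc.gene_id])
            _, _, dev_p = _total_loglik(paired, theta, p)
            if dev_p > history[-1] * (1 + np.sign(history[-1]) * tol) + tol:
                raise ConvergenceError(
                    f"deviance increased at iteration {n_iter}: "
                    f"{history[-1]:.6f} -> {dev_p:.6f}")
            # D refit given p
            if model is not None:
                D, theta = d_step(p)
            _, _, dev_new = _total_loglik(paired, theta, p)
            if dev_new > dev_p * (1 + np.sign(dev_p) * tol) + tol:
                raise ConvergenceError(
                    f"deviance increased after D refit at iteration {n_iter}: "
                    f"{dev_p:.6f} -> {dev_new:.6f}")
            prev = history[-1]
            history.append(dev_new)
            if abs(prev - dev_new) < cfg.convergence * abs(prev):
                break

    # final likelihoods under the final theta
    p_null = {g: (p_n if testable[g] else float("nan")) for g in p}
    _, ll_pn, _ = _total_loglik(paired, theta, p_null)
    _, ll_ph, _ = _total_loglik(paired, theta, p)
    return FitState(pair=pair, model_name=model_name, p_n=p_n, D=D,
                    p_hat=dict(p), loglik_pn=ll_pn, loglik_phat=ll_ph,
                    deviance_history=history, n_iter=n_iter, flags=flags)


# ---------------------------------------------------------------------------
# likelihood-ratio test
# ---------------------------------------------------------------------------

def lrt_genes(states: Sequence[FitState]) -> pd.DataFrame:
    """Per-gene LRT summed over cross-group pairs.

    chi2 = sum over pairs of max(0, 2[log L(p_hat_i) - log L(p_n)]), df =
    number of pairs, p-value from the upper chi-square tail.  Genes absent
    from any pair raise; all-zero genes are flagged untestable.
    """
    if not states:
        raise EstimationError("no fitted pairs")
    gene_sets = [set(s.loglik_phat) for s in states]
    common = set.intersection(*gene_sets)
    union = set.union(*gene_sets)
    if union - common:
        raise EstimationError(f"genes missing from some pairs: {sorted(union - common)[:5]}")
    rows = []
    df_total = len(states)
    for g in sorted(common):
        ph = [s.p_hat[g] for s in states]
        testable = all(np.isfinite(v) for v in ph)
        chi2 = sum(max(0.0, 2.0 * (s.loglik_phat[g] - s.loglik_pn[g]))
                   for s in states)
        if testable:
            pval = float(stats.chi2.sf(chi2, df_total)) if chi2 > 0 else 1.0
        else:
            pval = float("nan")
        rows.append({"gene_id": g,
                     "p_hat": float(np.mean(ph)) if testable else float("nan"),
                     "chi2": chi2, "df": df_total, "pvalue": pval,
                     "n_pairs": len(states), "testable": testable})
    return pd.DataFrame(rows)


def adjust_pvalues(pvalues, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment (Benjamini-Hochberg by default)."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = stats.false_discovery_control(p[ok], method=method)
    return q


def run_de_test(counts: Mapping[tuple[str, str, str], BaseStartCounts],
                genes: Mapping[str, GeneModel],
                groups: Mapping[str, str],
                model,
                cfg: PipelineConfig = PipelineConfig()) -> pd.DataFrame:
    """Full DE comparison of two groups: all cross-group pairs, summed LRT."""
    names = sorted(set(groups.values()))
    if len(names) != 2:
        raise ConfigError(f"need exactly two groups, got {names}")
    g1 = sorted(s for s, g in groups.items() if g == names[0])
    g2 = sorted(s for s, g in groups.items() if g == names[1])
    states = []
    for a, b in itertools.product(g1, g2):
        paired = build_pairs(counts, genes, a, b, K=cfg.K, filters=cfg.filters)
        if not paired:
            raise EstimationError(f"no shared genes for pair ({a}, {b})")
        states.append(fit_test_pair(paired, model, cfg, mode="comparison",
                                    pair=(a, b)))
    res = lrt_genes(states)
    res["qvalue"] = adjust_pvalues(res["pvalue"].to_numpy(), cfg.mt_method)
    return res


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def compare_models(paired_by_pair: Mapping[tuple, Sequence[PairedCounts]],
                   models: Mapping[str, object | None],
                   K: int = 80,
                   chain: Sequence[str] = NESTED_ORDER,
                   cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Goodness of fit of the nested model chain on replicate pairs.

    Every variant is fitted on identical data with the proportion fixed at
    each pair's neutral value (replicate protocol, single D fit).  Reports
    mean log-likelihood, mean AIC under both parameter-count conventions,
    mean percent likelihood change vs. the nested predecessor, and the
    nested chi-square test (statistics summed over pairs, df = pairs x
    parameter difference under the total convention).
    """
    if cfg is None:
        cfg = PipelineConfig(K=K)
    pair_keys = list(paired_by_pair)
    if not pair_keys:
        raise EstimationError("no replicate pairs to compare on")
    loglik: dict[str, list[float]] = {}
    for name in chain:
        if name not in MODEL_VARIANTS:
            raise ConfigError(f"unknown model {name!r}")
        mdl = models.get(name)
        if mdl is None and name != "bi":
            if name == "bb_D":
                mdl = constant_model()
            else:
                raise ConfigError(f"model {name!r} requires a trained model")
        lls = []
        for pk in pair_keys:
            st = fit_test_pair(paired_by_pair[pk], mdl,
                               cfg=PipelineConfig(model=name, K=K,
                                                  filters=cfg.filters,
                                                  convergence=cfg.convergence),
                               mode="replicate", pair=pk if isinstance(pk, tuple) else None)
            lls.append(st.loglik)
        loglik[name] = lls
    rows = []
    for i, name in enumerate(chain):
        lls = np.array(loglik[name])
        k_tot, k_pair = k_parameters(name, K)
        row = {"model": name, "n_pairs": len(pair_keys),
               "mean_loglik": float(lls.mean()),
               "mean_aic": float((2 * k_tot - 2 * lls).mean()),
               "mean_aic_pair_params": float((2 * k_pair - 2 * lls).mean()),
               "k_total": k_tot, "k_pair": k_pair}
        if i > 0:
            prev = np.array(loglik[chain[i - 1]])
            with np.errstate(divide="ignore", invalid="ignore"):
                row["pct_likelihood_change"] = float(
                    np.mean(100.0 * (lls - prev) / np.abs(prev)))
            chi2 = float(np.maximum(2.0 * (lls - prev), 0.0).sum())
            dk = k_tot - k_parameters(chain[i - 1], K)[0]
            df = max(dk, 0) * len(pair_keys)
            row["nested_chi2"] = chi2
            row["nested_df"] = df
            row["nested_pvalue"] = float(stats.chi2.sf(chi2, df)) if df > 0 \
                else float("nan")
        else:
            row.update({"pct_likelihood_change": float("nan"),
                        "nested_chi2": float("nan"), "nested_df": 0,
                        "nested_pvalue": float("nan")})
        rows.append(row)
    return pd.DataFrame(rows)
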