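"""Mixed-model inference on block-level PSC with permutation FWER control.

Each condition is coded by three binary stimulus-content parameters —
auditory (AP), visual (VP), speech (SP) — and block-level percent signal
change is modeled per subregion as

    psc ~ AP + VP + SP + (1 + AP + VP + SP | subject) + error,

fit by REML after within-subject/subregion predictor standardization and
robust (median/MAD) outlier exclusion. Family-wise error across subregions
is controlled with a max-t / min-t permutation test: condition labels are
reshuffled within subject, identically for the three parameters and for all
subregions, the models are refit, and the extrema of the t-scores across
subregions form the null distributions.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

__all__ = [
    "CONDITION_CODING",
    "EFFECTS",
    "code_conditions",
    "add_condition_coding",
    "outlier_cutoff",
    "detect_outliers",
    "exclude_outliers",
    "scale_predictors",
    "MixedFitResult",
    "fit_glmm",
    "subject_ols_tscores",
    "PermutationResult",
    "permutation_fwer",
    "min_t_conjunction",
]

EFFECTS = ("AP", "VP", "SP")

# (AP, VP, SP): AP=1 for A/AV/R, VP=1 for V/AV/G, SP=1 for A/V/AV.
CONDITION_CODING = {
    "A": (1, 0, 1),
    "V": (0, 1, 1),
    "AV": (1, 1, 1),
    "R": (1, 0, 0),
    "G": (0, 1, 0),
}


def code_conditions(labels: Sequence[str]) -> pd.DataFrame:
    """AP/VP/SP coding table for a list of condition labels."""
    rows = []
    for lab in labels:
        if lab not in CONDITION_CODING:
            raise ValueError(f"unknown condition label {lab!r}")
        rows.append(CONDITION_CODING[lab])
    return pd.DataFrame(rows, columns=list(EFFECTS), index=list(labels))


def add_condition_coding(table: pd.DataFrame) -> pd.DataFrame:
    """Attach AP/VP/SP columns derived from the ``condition`` column."""
    coding = code_conditions(table["condition"].tolist())
    out = table.copy()
    for e in EFFECTS:
        out[e] = coding[e].to_numpy(dtype=float)
    return out


# ---------------------------------------------------------------------------
# Robust outlier exclusion (median/MAD cutoff)
# ---------------------------------------------------------------------------

def outlier_cutoff(n: int, constant: float = math.pi / 2, p: float = 0.001) -> float:
    """Quantile multiplier alpha = Phi^-1(1 - p/N), as used in the cutoff
    C = alpha * constant * MAD."""
    if n < 2:
        raise ValueError("need N >= 2")
    return float(norm.ppf(1 - p / n))


def detect_outliers(
    psc: Sequence[float], constant: float = math.pi / 2, p: float = 0.001
) -> np.ndarray:
    """Keep mask for one subject's block vector.

    A value is flagged when its absolute deviation from the median exceeds
    C = Phi^-1(1 - p/N) * constant * MAD, with MAD the (unscaled) median
    absolute deviation. With degenerate data (MAD = 0) every point off the
    median is flagged.
    """
    x = np.asarray(psc, dtype=float)
    alpha = outlier_cutoff(x.size, constant=constant, p=p)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    cutoff = alpha * constant * mad
    return np.abs(x - med) <= cutoff


def exclude_outliers(
    table: pd.DataFrame,
    by: Sequence[str] = ("subject_id",),
    constant: float = math.pi / 2,
    p: float = 0.001,
) -> pd.DataFrame:
    """Drop extreme-psc rows, applying the cutoff separately per subject."""
    keep = np.ones(len(table), dtype=bool)
    for _, idx in table.groupby(list(by)).groups.items():
        sub = table.loc[idx, "psc"].to_numpy()
        keep[table.index.get_indexer(idx)] = detect_outliers(sub, constant=constant, p=p)
    return table.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Predictor scaling
# ---------------------------------------------------------------------------

def scale_predictors(
    table: pd.DataFrame,
    cols: Sequence[str] = EFFECTS,
    by: Sequence[str] = ("subject_id", "subregion_id"),
    ddof: int = 1,
) -> pd.DataFrame:
    """Standardize predictor columns to mean 0, sd 1 within each stratum."""
    out = table.copy()
    grouped = out.groupby(list(by), sort=False)
    for c in cols:
        mean = grouped[c].transform("mean")
        sd = grouped[c].transform("std", ddof=ddof)
        if (sd <= 0).any() or sd.isna().any():
            bad = out.loc[(sd <= 0) | sd.isna(), list(by)].drop_duplicates()
            raise ValueError(
                f"zero-variance predictor {c!r} in strata:\n{bad.to_string(index=False)}"
            )
        out[c] = (out[c] - mean) / sd
    return out


# ---------------------------------------------------------------------------
# Mixed-model fit
# ---------------------------------------------------------------------------

_FALLBACK_CHAIN = (
    "full",          # random intercept + slopes, free correlations
    "uncorrelated",  # independent variance components for intercept + slopes
    "drop_SP",
    "drop_VP",
    "drop_AP",       # random intercept only
    "ols",           # no random effects at all
)


@dataclass
class MixedFitResult:
    """Fixed-effect estimates and Wald t-scores for one subregion."""

    subregion_id: object
    estimates: dict[str, float]
    stderrs: dict[str, float]
    tscores: dict[str, float]
    converged: bool
    fallback: str
    random_effect_var: Optional[dict[str, float]] = None

    def tvector(self, effects: Sequence[str] = EFFECTS) -> np.ndarray:
        return np.array([self.tscores[e] for e in effects])


def _try_mixedlm(data: pd.DataFrame, mode: str):
    kwargs: dict = {"groups": data["subject_id"]}
    if mode == "full":
        kwargs["re_formula"] = "~AP+VP+SP"
    elif mode == "uncorrelated":
        kwargs["re_formula"] = "~1"
        kwargs["vc_formula"] = {"AP": "0+AP", "VP": "0+VP", "SP": "0+SP"}
    elif mode == "drop_SP":
        kwargs["re_formula"] = "~1"
        kwargs["vc_formula"] = {"AP": "0+AP", "VP": "0+VP"}
    elif mode == "drop_VP":
        kwargs["re_formula"] = "~1"
        kwargs["vc_formula"] = {"AP": "0+AP"}
    elif mode == "drop_AP":
        kwargs["re_formula"] = "~1"
    else:
        raise ValueError(mode)
    model = smf.mixedlm("psc ~ AP + VP + SP", data, **kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True, method=["lbfgs", "cg"])
    return res


def _ols_fit(data: pd.DataFrame):
    res = smf.ols("psc ~ AP + VP + SP", data).fit()
    return res


def fit_glmm(table: pd.DataFrame, subregion: object | None = None) -> MixedFitResult:
    """REML linear mixed model psc ~ AP+VP+SP with by-subject random
    intercept and slopes; Wald t = estimate / stderr.

    On non-convergence the random structure is simplified step by step
    (drop slope correlations, then slopes SP, VP, AP, then all random terms),
    logging each step.
    """
    data = table if subregion is None else table[table["subregion_id"] == subregion]
    if subregion is None and "subregion_id" in table.columns:
        ids = table["subregion_id"].unique()
        if len(ids) > 1:
            raise ValueError("table holds several subregions; pass `subregion`")
    data = data.reset_index(drop=True)
    if data["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects")

    last_exc: Exception | None = None
    for mode in _FALLBACK_CHAIN:
        try:
            if mode == "ols":
                res = _ols_fit(data)
                ok = True
            else:
                res = _try_mixedlm(data, mode)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    bse = res.bse_fe.loc[["Intercept", "AP", "VP", "SP"]]
                ok = bool(getattr(res, "converged", True)) and np.all(np.isfinite(bse))
        except Exception as exc:  # noqa: BLE001 - solver failures trigger fallback
            last_exc = exc
            ok = False
        if ok:
            if mode != "full":
                logger.warning("mixed-model fallback engaged: %s", mode)
            names = ["Intercept", "AP", "VP", "SP"]
            if mode == "ols":
                params, bse = res.params, res.bse
                re_var = None
            else:
                params, bse = res.fe_params, res.bse_fe
                try:
                    diag = np.atleast_1d(np.asarray(res.cov_re).diagonal())
                    re_var = {f"re{i}": float(v) for i, v in enumerate(diag)}
                except Exception:  # pragma: no cover - informational only
                    re_var = None
            return MixedFitResult(
                subregion_id=subregion,
                estimates={n: float(params[n]) for n in names},
                stderrs={n: float(bse[n]) for n in names},
                tscores={n: float(params[n] / bse[n]) if bse[n] > 0 else float("nan")
                         for n in names},
                converged=mode == "full",
                fallback=mode,
                random_effect_var=re_var,
            )
    raise RuntimeError(f"all mixed-model fallbacks failed: {last_exc}")


# ---------------------------------------------------------------------------
# Fast within-subject score (summary-statistics path)
# ---------------------------------------------------------------------------

def subject_ols_tscores(
    table: pd.DataFrame, effects: Sequence[str] = EFFECTS
) -> dict[str, float]:
    """One-sample t across subjects of per-subject OLS coefficients.

    Each subject's psc is regressed on (1, AP, VP, SP); the group t for an
    effect is mean(beta_s) / SEM over subjects. For balanced designs this
    summary-statistics score tracks the mixed-model Wald t and is orders of
    magnitude faster, which makes dense permutation schedules practical.
    """
    betas = []
    for _, sub in table.groupby("subject_id", sort=False):
        X = np.column_stack(
            [np.ones(len(sub))] + [sub[e].to_numpy(dtype=float) for e in effects]
        )
        b, *_ = np.linalg.lstsq(X, sub["psc"].to_numpy(dtype=float), rcond=None)
        betas.append(b[1:])
    B = np.asarray(betas)
    n = B.shape[0]
    t = B.mean(axis=0) / (B.std(axis=0, ddof=1) / np.sqrt(n))
    return dict(zip(effects, t.tolist()))


# ---------------------------------------------------------------------------
# Permutation FWER across subregions
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Observed t-scores, max-t/min-t null distributions, and p-values."""

    observed: pd.DataFrame          # index: subregion, columns: effects
    pvalues: pd.DataFrame           # same shape, one-tailed FWER-corrected
    significant: pd.DataFrame       # pvalues < alpha
    max_t: pd.DataFrame             # n_permutations x effects
    min_t: pd.DataFrame
    n_permutations: int
    seed: Optional[int]
    method: str
    alpha: float = 0.05
    exhaustive: bool = False

    def provenance(self) -> dict:
        return {
            "seed": self.seed,
            "n_permutations": self.n_permutations,
            "method": self.method,
            "alpha": self.alpha,
            "exhaustive": self.exhaustive,
        }


def _aligned_layout(table: pd.DataFrame):
    """Sort so every subregion presents each subject's rows in the same order."""
    df = add_condition_coding(table)
    df = df.sort_values(
        ["subregion_id", "subject_id", "run_id", "condition", "block_index"],
        kind="mergesort",
    ).reset_index(drop=True)
    df = scale_predictors(df)
    subregions = list(pd.unique(df["subregion_id"]))
    subjects = list(pd.unique(df["subject_id"]))
    # verify identical within-subject row structure across subregions
    key_cols = ["subject_id", "run_id", "condition", "block_index"]
    ref = None
    for sr in subregions:
        keys = df.loc[df["subregion_id"] == sr, key_cols].reset_index(drop=True)
        if ref is None:
            ref = keys
        elif not keys.equals(ref):
            raise ValueError("subregions do not share an identical block structure")
    return df, subregions, subjects


def _refit_tmatrix_mixed(df: pd.DataFrame, subregions) -> np.ndarray:
    t = np.empty((len(subregions), len(EFFECTS)))
    for i, sr in enumerate(subregions):
        fit = fit_glmm(df, subregion=sr)
        t[i] = [fit.tscores[e] for e in EFFECTS]
    return t


def permutation_fwer(
    table: pd.DataFrame,
    n_permutations: int = 10000,
    seed: Optional[int] = None,
    method: str = "mixed",
    alpha: float = 0.05,
    exhaustive: bool = False,
    max_exhaustive: int = 1_000_000,
) -> PermutationResult:
    """Max-t / min-t permutation FWER correction across subregions.

    Per permutation, each subject's condition-label assignment is shuffled
    (the same shuffle for AP, VP and SP and for every subregion; the
    dependent variable is never reordered), the per-subregion t-scores are
    recomputed, and their extrema across subregions recorded. One-tailed
    p-values compare each observed t to the max-t distribution (positive t)
    or the min-t distribution (negative t); p < alpha controls family-wise
    error across subregions for that effect.

    method ``"mixed"`` refits the full mixed model per permutation (slow);
    ``"subject_ols"`` uses the validated within-subject OLS summary score.
    Random mode uses the add-one p-value (b+1)/(n+1); ``exhaustive=True``
    enumerates every within-subject shuffle combination (the identity is
    part of the null) and returns exact proportions.
    """
    if method not in ("mixed", "subject_ols"):
        raise ValueError(f"unknown method {method!r}")
    if not exhaustive:
        if seed is None:
            raise ValueError("a seed is mandatory for reproducible permutations")
        if n_permutations < 100:
            logger.warning("n_permutations=%d is very small", n_permutations)

    df, subregions, subjects = _aligned_layout(table)

    # per (subregion, subject) blocks, identically ordered across subregions
    y: dict[tuple, np.ndarray] = {}
    X: dict[tuple, np.ndarray] = {}
    pinv: dict[tuple, np.ndarray] = {}
    m: dict = {}
    for sr in subregions:
        for s in subjects:
            sel = df[(df["subregion_id"] == sr) & (df["subject_id"] == s)]
            Xs = np.column_stack(
                [np.ones(len(sel))] + [sel[e].to_numpy(dtype=float) for e in EFFECTS]
            )
            y[(sr, s)] = sel["psc"].to_numpy(dtype=float)
            X[(sr, s)] = Xs
            pinv[(sr, s)] = np.linalg.pinv(Xs)
            m[s] = len(sel)

    def fast_tmatrix(inv_perms: dict) -> np.ndarray:
        t = np.empty((len(subregions), len(EFFECTS)))
        for i, sr in enumerate(subregions):
            betas = np.empty((len(subjects), len(EFFECTS)))
            for j, s in enumerate(subjects):
                ys = y[(sr, s)]
                if inv_perms is not None:
                    ys = ys[inv_perms[s]]
                betas[j] = (pinv[(sr, s)] @ ys)[1:]
            n = len(subjects)
            t[i] = betas.mean(axis=0) / (betas.std(axis=0, ddof=1) / np.sqrt(n))
        return t

    def permuted_table(perms: dict) -> pd.DataFrame:
        out = df.copy()
        for sr in subregions:
            for s in subjects:
                mask = (out["subregion_id"] == sr) & (out["subject_id"] == s)
                idx = out.index[mask]
                vals = out.loc[idx, list(EFFECTS)].to_numpy()
                out.loc[idx, list(EFFECTS)] = vals[perms[s]]
        return out

    # observed statistics (identity permutation)
    if method == "subject_ols":
        t_obs = fast_tmatrix(None)
    else:
        t_obs = _refit_tmatrix_mixed(df, subregions)

    # permutation schedule
    if exhaustive:
        per_subj = [list(itertools.permutations(range(m[s]))) for s in subjects]
        total = int(np.prod([len(p) for p in per_subj]))
        if total > max_exhaustive:
            raise ValueError(
                f"exhaustive enumeration would need {total} shuffles (> {max_exhaustive})"
            )
        schedule = itertools.product(*per_subj)
        n_total = total
    else:
        rng = np.random.default_rng(seed)
        def _random_schedule():
            for _ in range(n_permutations):
                yield tuple(rng.permutation(m[s]) for s in subjects)
        schedule = _random_schedule()
        n_total = n_permutations

    max_t = np.empty((n_total, len(EFFECTS)))
    min_t = np.empty((n_total, len(EFFECTS)))
    for k, perms_tuple in enumerate(schedule):
        perms = {s: np.asarray(p) for s, p in zip(subjects, perms_tuple)}
        if method == "subject_ols":
            inv = {s: np.argsort(p) for s, p in perms.items()}
            t = fast_tmatrix(inv)
        else:
            t = _refit_tmatrix_mixed(permuted_table(perms), subregions)
        max_t[k] = t.max(axis=0)
        min_t[k] = t.min(axis=0)

    # One-tailed p-values against the family extrema. Null values tied with
    # the observed statistic (to within tie_tol) count toward the exceedance,
    # so mathematically exact ties resolve identically regardless of
    # floating-point evaluation order.
    tie_tol = 1e-8
    pv = np.empty_like(t_obs)
    for i in range(t_obs.shape[0]):
        for j in range(t_obs.shape[1]):
            t0 = t_obs[i, j]
            if t0 >= 0:
                b = int((max_t[:, j] >= t0 - tie_tol).sum())
            else:
                b = int((min_t[:, j] <= t0 + tie_tol).sum())
            pv[i, j] = b / n_total if exhaustive else (b + 1) / (n_total + 1)

    obs_df = pd.DataFrame(t_obs, index=subregions, columns=list(EFFECTS))
    pv_df = pd.DataFrame(pv, index=subregions, columns=list(EFFECTS))
    return PermutationResult(
        observed=obs_df,
        pvalues=pv_df,
        significant=pv_df < alpha,
        max_t=pd.DataFrame(max_t, columns=list(EFFECTS)),
        min_t=pd.DataFrame(min_t, columns=list(EFFECTS)),
        n_permutations=n_total,
        seed=seed,
        method=method,
        alpha=alpha,
        exhaustive=exhaustive,
    )


def min_t_conjunction(tmap_a: np.ndarray, tmap_b: np.ndarray) -> np.ndarray:
    """Voxelwise minimum of two aligned statistic maps (conjunction null)."""
    a = np.asarray(tmap_a, dtype=float)
    b = np.asarray(tmap_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"statistic maps are not aligned: {a.shape} vs {b.shape}")
    return np.minimum(a, b)
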