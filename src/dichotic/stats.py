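"""Behavioural preprocessing and state/trait mixed-effects models.

Listening success is analysed with the conventions of large-sample
psycholinguistic mixed modelling: deviation-coded categorical predictors,
z-scored continuous covariates, a within/between (state/trait)
decomposition of trial-level neural measures, binomial-logit models for
single-trial accuracy and Gaussian models for response speed (1/RT,
correct trials only), Wald tests, Benjamini-Hochberg FDR correction, and
likelihood-ratio tests for random-slope selection.

Model fitting is delegated to lme4 (via an ``Rscript`` subprocess), the
standard estimator for crossed random effects; results come back as tidy
coefficient tables.
"""

from __future__ import annotations

import json
import logging
import subprocess
import tempfile
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "preprocess_behaviour",
    "error_breakdown",
    "decompose_within_between",
    "fit_mixed_model",
    "fit_mixed_models",
    "fit_accuracy_model",
    "fit_speed_model",
    "lrt_random_slopes",
    "fdr_correct",
    "FitResult",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess_behaviour(trials: pd.DataFrame,
                         response_window_s: float = 4.0,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a trial table into accuracy and speed analysis tables.

    Trials without a response inside the response window (timeouts) are
    excluded from the accuracy table; the speed table holds 1/RT for
    correct trials only.
    """
    t = trials.copy()
    timeout = (t["accuracy"] == "timeout") | (t["rt"] >= response_window_s)
    acc = t[~timeout].copy()
    acc["correct"] = acc["correct"].astype(int)
    speed = acc[acc["correct"] == 1].copy()
    speed["speed"] = 1.0 / speed["rt"]
    if speed.empty:
        logger.warning("no correct trials: speed table is empty")
    return acc, speed


def _adjusted_logit(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Logit of (k + 0.5)/(n + 1): finite for zero and full counts."""
    p = (k + 0.5) / (n + 1.0)
    return np.log(p / (1.0 - p))


def error_breakdown(trials: pd.DataFrame) -> dict:
    """Per-subject error proportions and a paired test on their logits.

    Compares the proportion of spatial stream confusions (choosing the
    to-be-ignored stream's final word) against random errors across
    subjects, via a paired t test on small-sample-adjusted logits.
    """
    t = trials[trials["accuracy"] != "timeout"]
    g = t.groupby("subject")
    n = g.size().to_numpy().astype(float)
    conf = g.apply(lambda d: (d["accuracy"] == "spatial_confusion").sum(),
                   include_groups=False).to_numpy().astype(float)
    rand = g.apply(lambda d: (d["accuracy"] == "random_error").sum(),
                   include_groups=False).to_numpy().astype(float)
    lc, lr = _adjusted_logit(conf, n), _adjusted_logit(rand, n)
    diff = lc - lr
    if np.std(diff, ddof=1) <= 1e-12 * max(1.0, float(np.abs(diff).max())):
        # degenerate case: identical paired differences across subjects
        tstat = 0.0 if np.mean(diff) == 0 else np.sign(np.mean(diff)) * np.inf
        p = 1.0 if tstat == 0.0 else 0.0
    else:
        tstat, p = sps.ttest_rel(lc, lr)
    return {
        "prop_confusion": conf / n,
        "prop_random": rand / n,
        "t": float(tstat),
        "p": float(p),
        "df": len(n) - 1,
    }


def decompose_within_between(values: np.ndarray, subjects: np.ndarray,
                             z_between: bool = True, z_within: bool = True,
                             ) -> tuple[np.ndarray, np.ndarray]:
    """State/trait split of a trial-level measure into two regressors.

    The between-subject (trait) regressor is the subject mean, z-scored
    across subjects (n-1 denominator) and broadcast back to trials; the
    within-subject (state) regressor is the trial deviation from the
    subject mean (zero-sum within every subject), z-scored globally.
    """
    values = np.asarray(values, dtype=float)
    subjects = np.asarray(subjects)
    df = pd.DataFrame({"v": values, "s": subjects})
    means = df.groupby("s")["v"].transform("mean").to_numpy()
    within = values - means
    between = means
    if z_between:
        uniq = df.groupby("s")["v"].mean()
        sd = uniq.std(ddof=1)
        mu = uniq.mean()
        between = (means - mu) / (sd if sd > 0 else 1.0)
    if z_within:
        sd = np.std(within, ddof=1)
        if sd > 0:
            within = within / sd
    return within, between


# ---------------------------------------------------------------------------
# lme4 bridge
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Tidy mixed-model result.

    ``table`` columns: term, estimate, se, statistic, p, p_fdr and, for
    binomial models, odds_ratio (exp(estimate)).
    """

    table: pd.DataFrame
    family: str
    loglik: float
    df: int
    nobs: int
    converged: bool
    random_effects: dict = field(default_factory=dict)
    formula: str = ""
    messages: list = field(default_factory=list)

    def coef(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "se"])

    def ci(self, term: str, level: float = 0.95) -> tuple[float, float]:
        z = sps.norm.ppf(0.5 + level / 2)
        e, s = self.coef(term), self.se(term)
        return e - z * s, e + z * s


def _runner_path() -> str:
    return str(resources.files("dichotic").joinpath("lme4_runner.R"))


def fit_mixed_models(jobs: list[dict], q: float = 0.05) -> dict[str, FitResult]:
    """Fit a batch of lme4 models in one R subprocess.

    Each job dict needs ``name``, ``data`` (DataFrame), ``formula`` (lme4
    syntax) and ``family``; optional ``reml`` (Gaussian only, default
    False so nested models are LRT-comparable).  FDR correction is applied
    within each model across its non-intercept terms.
    """
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        spec = []
        for i, job in enumerate(jobs):
            csv = tmp / f"data_{i}.csv"
            cols = _columns_in_formula(job["formula"], job["data"].columns)
            job["data"][cols].to_csv(csv, index=False)
            spec.append({
                "name": job["name"],
                "data": str(csv),
                "formula": job["formula"],
                "family": job["family"],
                "reml": bool(job.get("reml", False)),
            })
        jobs_json = tmp / "jobs.json"
        out_json = tmp / "out.json"
        jobs_json.write_text(json.dumps({"jobs": spec}))
        proc = subprocess.run(
            ["Rscript", "--vanilla", _runner_path(), str(jobs_json), str(out_json)],
            capture_output=True, text=True)
        if proc.returncode != 0 or not out_json.exists():
            raise RuntimeError(
                f"lme4 runner failed (exit {proc.returncode}):\n{proc.stderr[-2000:]}"
            )
        raw = json.loads(out_json.read_text())

    results = {}
    for job in jobs:
        r = raw[job["name"]]
        if "error" in r:
            raise RuntimeError(f"model {job['name']!r} failed: {r['error']}")
        tab = pd.DataFrame({
            "term": _aslist(r["terms"]),
            "estimate": _aslist(r["estimate"], float),
            "se": _aslist(r["se"], float),
            "statistic": _aslist(r["statistic"], float),
            "p": _aslist(r["p"], float),
        })
        non_int = tab["term"] != "(Intercept)"
        tab["p_fdr"] = tab["p"]
        if non_int.sum() > 0:
            tab.loc[non_int, "p_fdr"] = fdr_correct(
                tab.loc[non_int, "p"].to_numpy(), q=q)
        if job["family"] == "binomial":
            tab["odds_ratio"] = np.exp(tab["estimate"])
        re = dict(zip(_aslist(r.get("vc_group", [])),
                      _aslist(r.get("vc_sd", []), float)))
        if not r.get("converged", True):
            logger.warning("model %s: convergence messages: %s",
                           job["name"], r.get("messages"))
        results[job["name"]] = FitResult(
            table=tab, family=job["family"], loglik=float(r["loglik"]),
            df=int(r["df"]), nobs=int(r["nobs"]),
            converged=bool(r.get("converged", True)),
            random_effects=re, formula=job["formula"],
            messages=list(r.get("messages", []) or []))
    return results


def _aslist(x, cast=None):
    if not isinstance(x, list):
        x = [x]
    return [cast(v) for v in x] if cast else x


def _columns_in_formula(formula: str, columns) -> list[str]:
    import re
    toks = set(re.findall(r"[A-Za-z_][A-Za-z0-9_.]*", formula))
    return [c for c in columns if c in toks]


def fit_mixed_model(data: pd.DataFrame, formula: str, family: str,
                    reml: bool = False, q: float = 0.05) -> FitResult:
    """Fit one mixed model (see :func:`fit_mixed_models`)."""
    return fit_mixed_models([{"name": "m", "data": data, "formula": formula,
                              "family": family, "reml": reml}], q=q)["m"]


def fit_accuracy_model(accuracy_table: pd.DataFrame, formula: str,
                       q: float = 0.05) -> FitResult:
    """Binomial-logit mixed model of single-trial accuracy.

    The outcome must be binary (0/1); coefficients are reported as odds
    ratios alongside Wald z statistics and FDR-corrected p values.
    """
    return fit_mixed_model(accuracy_table, formula, "binomial", q=q)


def fit_speed_model(speed_table: pd.DataFrame, formula: str,
                    q: float = 0.05, reml: bool = False,
                    zscore_outcome: bool = True) -> FitResult:
    """Gaussian mixed model of (z-scored) response speed.

    The outcome named on the left of ``formula`` is z-scored in place when
    ``zscore_outcome`` is set (n-1 denominator, after exclusions), so
    slopes are standardized betas.
    """
    outcome = formula.split("~")[0].strip()
    d = speed_table.copy()
    if zscore_outcome:
        v = d[outcome].to_numpy(dtype=float)
        sd = v.std(ddof=1)
        d[outcome] = (v - v.mean()) / (sd if sd > 0 else 1.0)
    return fit_mixed_model(d, formula, "gaussian", reml=reml, q=q)


def lrt_random_slopes(base: FitResult, extended: FitResult,
                      alpha: float = 0.05) -> dict:
    """Likelihood-ratio test between nested (ML-fitted) mixed models.

    Returns the chi-square statistic, degrees of freedom, p value and the
    adopt/retain decision (adopt the extension only on significant
    improvement).
    """
    if extended.df < base.df:
        raise ValueError("models are not nested: extension must not drop parameters")
    if extended.nobs != base.nobs:
        raise ValueError("models fitted on different data")
    stat = max(2.0 * (extended.loglik - base.loglik), 0.0)
    df = extended.df - base.df
    p = float(sps.chi2.sf(stat, df)) if stat > 0 and df > 0 else 1.0
    return {"statistic": float(stat), "df": int(df), "p": p,
            "adopt_extension": bool(p < alpha)}


def fdr_correct(pvalues, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values (step-up, monotone in ranks)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, alpha=q, method="fdr_bh")[1]
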