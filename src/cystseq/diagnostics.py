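"""Cohort-level diagnostic statistics.

Covers the statistics used to evaluate mutation detection in cyst fluid as a
surgical triage marker: per-class detection fractions with exact
(Clopper-Pearson) binomial confidence intervals, pooled sensitivity over the
classes requiring surgery (borderline, type I, type II) and specificity over
those that do not, per-class mutant-allele-fraction summaries, replicate
concordance, a Wilcoxon rank-sum comparison of cyst DNA yields, and a
multivariate Firth penalized-likelihood logistic regression of the need for
surgery on mutation status, log10 DNA amount, and indicators for normal serum
CA-125 (<35 U/mL) and HE4 (<92 / <121 pmol/L pre-/post-menopause).

The Firth fit maximizes the Jeffreys-penalized log-likelihood
``l*(b) = l(b) + 0.5 log det I(b)`` by Newton iteration on the adjusted score
``U*_j = sum_i (y_i - pi_i + h_i (1/2 - pi_i)) x_ij`` (``h_i`` the hat-matrix
diagonals), which keeps every coefficient finite under complete separation.
Per-predictor p-values are penalized likelihood-ratio tests (refit without the
predictor; 2*delta l* against chi-square with 1 df) — Wald tests are
anti-conservative under separation and cannot produce the small p-values a
perfectly separating predictor deserves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CA125_CUTOFF = 35.0      # U/mL
HE4_CUTOFF_PRE = 92.0    # pmol/L, pre-menopausal
HE4_CUTOFF_POST = 121.0  # pmol/L, post-menopausal

SURGERY_CLASSES = frozenset({"borderline", "type1", "type2"})
CANCER_CLASSES = frozenset({"type1", "type2"})
EARLY_STAGES = frozenset({"I", "II"})
LATE_STAGES = frozenset({"III", "IV"})


def needs_surgery(cyst_class: str) -> bool:
    """Surgical label: borderline tumors and type I/II cancers require surgery."""
    return cyst_class in SURGERY_CLASSES


# ---------------------------------------------------------------------------
# exact binomial interval
# ---------------------------------------------------------------------------

def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) two-sided binomial confidence interval.

    ``lower = BetaInv(alpha/2; k, n-k+1)`` (0 when k = 0) and
    ``upper = BetaInv(1-alpha/2; k+1, n-k)`` (1 when k = n).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


def round_percent(x: float) -> int:
    """Round a fraction to whole percent, half away from zero (display rule)."""
    return int(math.floor(100 * x + 0.5))


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    """Per-group detection fractions with exact CIs and MAF summaries."""

    table: pd.DataFrame
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]


def _group_row(label: str, sub: pd.DataFrame, alpha: float) -> dict:
    n = len(sub)
    k = int(sub["positive"].sum())
    lo, hi = clopper_pearson(k, n, alpha)
    pos = sub.loc[sub["positive"], "max_maf"]
    if len(pos):
        med = float(pos.median())
        q1, q3 = (float(pos.quantile(q)) for q in (0.25, 0.75))
    else:
        med = q1 = q3 = 0.0
    return {
        "group": label, "n": n, "n_detected": k, "fraction": k / n,
        "ci_low": lo, "ci_high": hi,
        "pct": round_percent(k / n),
        "ci_low_pct": round_percent(lo), "ci_high_pct": round_percent(hi),
        "median_maf": med, "maf_q1": q1, "maf_q3": q3,
    }


def diagnostic_summary(samples: pd.DataFrame, alpha: float = 0.05) -> CohortSummary:
    """Detection-rate summary over classes, cancer stage strata and surgery label.

    ``samples`` needs columns ``cyst_class``, ``positive`` (bool) and
    ``max_maf`` (fraction; 0 when negative), plus ``stage`` for the stage
    strata.  MAF medians/IQRs are over mutation-positive samples of the group
    (0 when none are positive).  Empty groups are omitted with a warning.
    """
    rows = []
    for cls in ("non_neoplastic", "benign", "borderline", "type1", "type2"):
        sub = samples[samples["cyst_class"] == cls]
        if len(sub) == 0:
            warnings.warn(f"class {cls!r} is empty; omitted from summary")
            continue
        rows.append(_group_row(cls, sub, alpha))

    if "stage" in samples.columns:
        cancers = samples[samples["cyst_class"].isin(CANCER_CLASSES)]
        early = cancers[cancers["stage"].isin(EARLY_STAGES)]
        late = cancers[cancers["stage"].isin(LATE_STAGES)]
        for label, sub in (("early_stage", early), ("late_stage", late)):
            if len(sub):
                rows.append(_group_row(label, sub, alpha))

    surgery = samples[samples["cyst_class"].map(needs_surgery)]
    no_surgery = samples[~samples["cyst_class"].map(needs_surgery)]
    sens_row = spec_row = None
    if len(no_surgery):
        spec_row = _group_row("surgery_no", no_surgery, alpha)
        rows.append(spec_row)
    if len(surgery):
        sens_row = _group_row("surgery_yes", surgery, alpha)
        rows.append(sens_row)

    sensitivity = sens_row["fraction"] if sens_row else float("nan")
    sens_ci = (sens_row["ci_low"], sens_row["ci_high"]) if sens_row else (float("nan"),) * 2
    if spec_row:
        k_neg = spec_row["n"] - spec_row["n_detected"]
        specificity = k_neg / spec_row["n"]
        spec_ci = clopper_pearson(k_neg, spec_row["n"], alpha)
    else:
        specificity, spec_ci = float("nan"), (float("nan"),) * 2
    return CohortSummary(
        table=pd.DataFrame(rows),
        sensitivity=sensitivity, sensitivity_ci=sens_ci,
        specificity=specificity, specificity_ci=spec_ci,
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact p by enumeration when ``len(x) + len(y) <= 12`` and the data are
    untied; otherwise the normal approximation with tie and continuity
    corrections.  Returns ``(U, p)``; identical pooled values give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        u = len(x) * len(y) / 2
        return float(u), 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# Firth penalized logistic regression
# ---------------------------------------------------------------------------

@dataclass
class FirthResult:
    """Fitted Firth logistic model; coefficients include the intercept first."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float            # penalized log-likelihood at the optimum
    p_lrt: dict[str, float]  # per-predictor penalized likelihood-ratio p-values
    n_iter: int
    converged: bool


def _firth_penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    pi = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-12
    ll = float(y @ np.log(pi + eps) + (1 - y) @ np.log(1 - pi + eps))
    W = pi * (1 - pi)
    info = X.T @ (X * W[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def _firth_fit_core(
    X: np.ndarray,
    y: np.ndarray,
    free: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    """Maximize the Jeffreys-penalized likelihood of the design ``X``.

    ``free`` marks the coefficients being estimated; the rest stay fixed at
    zero, which gives the *profile* penalized likelihood used by the
    penalized likelihood-ratio test — the penalty is always computed from
    the full design's information matrix, so constrained and unconstrained
    optima are directly comparable.
    """
    n, p = X.shape
    if free is None:
        free = np.ones(p, dtype=bool)
    beta = np.zeros(p)
    ll = _firth_penalized_loglik(X, y, beta)
    it = 0
    converged = p == 0 or not free.any()
    for it in range(1, max_iter + 1):
        if converged:
            break
        eta = X @ beta
        pi = 1.0 / (1.0 + np.exp(-eta))
        W = pi * (1 - pi)
        info = X.T @ (X * W[:, None])
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError("singular information matrix") from err
        # hat diagonals h_i = w_i * x_i' I^{-1} x_i from the full design
        h = W * np.einsum("ij,jk,ik->i", X, info_inv, X)
        adj = y - pi + h * (0.5 - pi)
        score = X[:, free].T @ adj
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        info_free = info[np.ix_(free, free)]
        step_free = np.linalg.solve(info_free, score)
        step = np.zeros(p)
        step[free] = step_free
        # step-halving on the penalized likelihood
        new_ll = _firth_penalized_loglik(X, y, beta + step)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step /= 2
            halvings += 1
            new_ll = _firth_penalized_loglik(X, y, beta + step)
        beta = beta + step
        # secondary criterion for quasi-separation ridges: the gradient is
        # tiny but decays geometrically while the penalized likelihood is
        # already stationary to working precision
        if abs(new_ll - ll) < 1e-10 and np.max(np.abs(score)) < 1e-4:
            converged = True
            ll = new_ll
            break
        ll = new_ll
    if p:
        eta = X @ beta
        pi = 1.0 / (1.0 + np.exp(-eta))
        W = pi * (1 - pi)
        info = X.T @ (X * W[:, None])
        se = np.sqrt(np.diag(np.linalg.inv(info)))
    else:
        se = np.zeros(0)
    return beta, se, _firth_penalized_loglik(X, y, beta), it, converged


def firth_logistic(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    names: list[str] | None = None,
    add_intercept: bool = True,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> FirthResult:
    """Fit a Firth penalized-likelihood logistic regression.

    ``X`` holds the predictors (no intercept column; one is added unless
    ``add_intercept=False``).  Collinear designs raise a ``ValueError`` naming
    the offending columns.  Per-predictor p-values come from penalized
    likelihood-ratio tests against the refit without that predictor.
    """
    if isinstance(X, pd.DataFrame):
        names = names or list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and X.shape[1] > 1 and names and len(names) == X.shape[0]:
            X = X.T
        names = names or [f"x{j + 1}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("predictors must be finite")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")

    cols = [np.ones(len(y))] + [X[:, j] for j in range(X.shape[1])]
    full = np.column_stack(cols)
    if np.linalg.matrix_rank(full) < full.shape[1]:
        bad = []
        for j in range(1, full.shape[1]):
            sub = np.delete(full, j, axis=1)
            if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(full):
                bad.append(names[j - 1])
        raise ValueError(f"collinear design; offending columns: {bad or names}")

    beta, se, ll_full, n_iter, conv = _firth_fit_core(full, y, None, tol, max_iter)
    if not conv:
        raise RuntimeError(f"Firth fit did not converge after {max_iter} iterations")

    p_lrt: dict[str, float] = {}
    for j, name in enumerate(names, start=1):
        free = np.ones(full.shape[1], dtype=bool)
        free[j] = False  # profile fit: coefficient constrained to zero
        _, _, ll_red, _, conv_r = _firth_fit_core(full, y, free, tol, max_iter)
        if not conv_r:
            raise RuntimeError(f"Firth refit without {name!r} did not converge")
        lr = max(0.0, 2.0 * (ll_full - ll_red))
        p_lrt[name] = float(stats.chi2.sf(lr, df=1))

    return FirthResult(
        names=["intercept"] + list(names), coef=beta, se=se,
        loglik=ll_full, p_lrt=p_lrt, n_iter=n_iter, converged=conv,
    )


# ---------------------------------------------------------------------------
# replicate concordance
# ---------------------------------------------------------------------------

def replicate_concordance(pairs) -> tuple[float, tuple[float, float]]:
    """Median relative difference (and IQR) between replicate MAF measurements.

    The relative difference of a pair is ``|a - b| / ((a + b) / 2)``; pairs
    with both members zero are excluded with a warning.
    """
    diffs = []
    n_skipped = 0
    for a, b in pairs:
        if a == 0 and b == 0:
            n_skipped += 1
            continue
        diffs.append(abs(a - b) / ((a + b) / 2))
    if n_skipped:
        warnings.warn(f"excluded {n_skipped} all-zero replicate pair(s)")
    if not diffs:
        raise ValueError("no scorable replicate pairs")
    arr = np.asarray(diffs)
    return float(np.median(arr)), (float(np.quantile(arr, 0.25)), float(np.quantile(arr, 0.75)))


# ---------------------------------------------------------------------------
# multivariate marker report
# ---------------------------------------------------------------------------

@dataclass
class MarkerReport:
    """Multivariate marker analysis plus per-group scatter data for plotting."""

    pvalues: dict[str, float]
    fit: FirthResult
    table: pd.DataFrame                 # criterion / p-value rows
    figure_data: dict[str, pd.DataFrame] = field(default_factory=dict)
    n_dropped: int = 0


def he4_normal(he4: float, menopause: str) -> bool:
    cutoff = HE4_CUTOFF_PRE if menopause == "pre" else HE4_CUTOFF_POST
    return he4 < cutoff


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.2f}"


def marker_report(samples: pd.DataFrame) -> MarkerReport:
    """Firth multivariate analysis of the need for surgery.

    Predictors: mutation presence, log10 cyst DNA (ng), and indicators for
    normal CA-125 (<35 U/mL) and normal HE4 (<92 / <121 pmol/L for pre-/post-
    menopausal women).  Rows with missing covariates are dropped with a log
    entry.  Also emits per-group scatter data tables (MAF by class and stage;
    DNA, CA-125 and HE4 by surgery label).
    """
    required = ["cyst_class", "positive", "max_maf", "dna_ng", "ca125", "he4", "menopause"]
    df = samples.copy()
    complete = df[required].notna().all(axis=1) & (df["dna_ng"] > 0)
    n_dropped = int((~complete).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} sample(s) with missing covariates")
    df = df[complete]

    y = df["cyst_class"].map(needs_surgery).astype(float).to_numpy()
    design = pd.DataFrame({
        "mutation_present": df["positive"].astype(float),
        "log10_dna_ng": np.log10(df["dna_ng"].astype(float)),
        "ca125_normal": (df["ca125"] < CA125_CUTOFF).astype(float),
        "he4_normal": [
            float(he4_normal(h, m)) for h, m in zip(df["he4"], df["menopause"])
        ],
    }, index=df.index)
    constant = [c for c in design.columns if design[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping constant predictor(s): {constant}")
        design = design.drop(columns=constant)
    fit = firth_logistic(design, y)
    for c in constant:
        fit.p_lrt[c] = float("nan")

    display_names = {
        "mutation_present": "Mutation present",
        "ca125_normal": "Serum CA-125 normal",
        "he4_normal": "HE4 normal",
        "log10_dna_ng": "Cyst DNA amount (log10 ng)",
    }
    order = ["mutation_present", "ca125_normal", "he4_normal", "log10_dna_ng"]
    table = pd.DataFrame({
        "criterion": [display_names[k] for k in order],
        "p_value": [_fmt_p(fit.p_lrt[k]) for k in order],
        "p_numeric": [fit.p_lrt[k] for k in order],
    })

    surgery_lab = df["cyst_class"].map(lambda c: "yes" if needs_surgery(c) else "no")
    figure_data = {
        "maf_by_class": df.loc[df["positive"], ["sample_id", "cyst_class", "stage", "max_maf"]]
        if "sample_id" in df else df.loc[df["positive"], ["cyst_class", "stage", "max_maf"]],
        "markers_by_surgery": pd.DataFrame({
            "needs_surgery": surgery_lab,
            "dna_ng": df["dna_ng"].astype(float),
            "ca125": df["ca125"].astype(float),
            "he4": df["he4"].astype(float),
        }),
    }
    return MarkerReport(
        pvalues=dict(fit.p_lrt), fit=fit, table=table,
        figure_data=figure_data, n_dropped=n_dropped,
    )
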