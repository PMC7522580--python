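"""Univariate Cox screening, linear risk score and survival comparison.

The Cox engine maximizes the Breslow partial likelihood for a single
covariate by Newton-Raphson with step halving.  The risk score is the
linear combination of designated lncRNAs' expression weighted by their
univariate Cox coefficients; the median training score is the cutoff
between high- and low-risk groups (the boundary itself is low-risk, since
high risk means exceeding the cutoff).  Group survival is compared with
the Kaplan-Meier product-limit estimator and the two-sample log-rank
chi-square test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import ClinicalTable, ExpressionMatrix


@dataclass
class CoxResult:
    covariate_id: str
    coef: float
    hr: float
    se: float
    z: float
    p: float
    converged: bool
    n_iter: int
    message: str = ""


@dataclass
class RiskModel:
    terms: list[tuple[str, float]]       # (lncRNA id, Cox coefficient)
    cutoff: float                        # median training risk score
    training_sample_ids: list[str]

    def score(self, expr: ExpressionMatrix, samples: list[str] | None = None) -> pd.Series:
        samples = samples if samples is not None else expr.sample_ids
        total = np.zeros(len(samples))
        for lnc, coef in self.terms:
            if lnc not in expr.data.index:
                raise KeyError(f"risk lncRNA {lnc!r} absent from expression matrix")
            total = total + coef * expr.data.loc[lnc, samples].to_numpy(dtype=float)
        return pd.Series(total, index=samples, name="risk_score")


@dataclass
class SurvivalComparison:
    labels: pd.Series                    # "high" / "low" per sample
    km_curves: dict[str, pd.DataFrame]
    logrank_chi2: float
    logrank_p: float
    group_sizes: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Cox partial likelihood (Breslow ties)


def _breslow_loglik_parts(beta: float, time: np.ndarray, event: np.ndarray, x: np.ndarray):
    """Log-likelihood, gradient and information at beta (Breslow ties)."""
    order = np.argsort(-time, kind="mergesort")
    t, e, xv = time[order], event[order], x[order]
    eta = beta * xv
    w = np.exp(eta - eta.max())  # stabilized; constants cancel in ratios
    cw = np.cumsum(w)
    cwx = np.cumsum(w * xv)
    cwx2 = np.cumsum(w * xv * xv)
    loglik = grad = info = 0.0
    log_shift = eta.max()
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        # risk set for time t[i] = all subjects with time >= t[i] = indices 0..j-1
        d_idx = [idx for idx in range(i, j) if e[idx] == 1]
        d = len(d_idx)
        if d > 0:
            S0, S1, S2 = cw[j - 1], cwx[j - 1], cwx2[j - 1]
            loglik += beta * xv[d_idx].sum() - d * (np.log(S0) + log_shift)
            grad += xv[d_idx].sum() - d * S1 / S0
            info += d * (S2 / S0 - (S1 / S0) ** 2)
        i = j
    return loglik, grad, info


def cox_univariate(
    time,
    event,
    covariate,
    covariate_id: str = "x",
    max_iter: int = 100,
    tol: float = 1e-10,
) -> CoxResult:
    """Fit a one-covariate Cox proportional-hazards model.

    Newton-Raphson on the Breslow partial likelihood with step halving;
    the standard error comes from the observed information at the
    maximum, giving a Wald z and two-sided p.  Monotone likelihoods
    (coefficient running away) are reported as non-converged.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(covariate, dtype=float)
    if not (time.shape == event.shape == x.shape) or time.ndim != 1:
        raise ValueError("time, event and covariate must be equal-length vectors")
    if event.sum() < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    if np.ptp(x) == 0:
        raise ValueError("covariate has zero variance")

    beta = 0.0
    loglik, grad, info = _breslow_loglik_parts(beta, time, event, x)
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        if info <= 0:
            message = "non-positive information"
            break
        step = grad / info
        new_beta = beta + step
        new_ll, new_grad, new_info = _breslow_loglik_parts(new_beta, time, event, x)
        halvings = 0
        while new_ll < loglik and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = _breslow_loglik_parts(new_beta, time, event, x)
            halvings += 1
        beta, loglik, grad, info = new_beta, new_ll, new_grad, new_info
        if abs(beta) > 50:
            message = "monotone likelihood: coefficient diverges"
            break
        if abs(step) < tol or abs(grad) < tol:
            converged = True
            break
    if not converged and not message:
        message = f"no convergence in {max_iter} iterations"
    if converged and abs(beta) > 10:
        # a hazard ratio beyond e^10 per unit is a separation artefact
        converged = False
        message = "coefficient diverges (likely monotone likelihood)"

    se = 1.0 / np.sqrt(info) if info > 0 else float("nan")
    z = beta / se if se and np.isfinite(se) else float("nan")
    p = 2.0 * sps.norm.sf(abs(z)) if np.isfinite(z) else float("nan")
    return CoxResult(
        covariate_id=covariate_id,
        coef=float(beta),
        hr=float(np.exp(beta)),
        se=float(se),
        z=float(z),
        p=float(p),
        converged=converged,
        n_iter=it,
        message=message,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


def kaplan_meier(time, event) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct event time with the number at risk, the
    events, and the stepped survival probability.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="mergesort")
    t, e = time[order], event[order]
    n = len(t)
    rows = []
    surv = 1.0
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())
        at_risk = n - i
        if d > 0:
            surv *= 1.0 - d / at_risk
            rows.append({"time": t[i], "n_at_risk": at_risk, "n_events": d, "survival": surv})
        i = j
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-sample log-rank chi-square (1 df) and p-value.

    At each distinct event time the observed events in group 1 are
    compared with the hypergeometric expectation given the pooled risk
    set; the squared standardized sum of O - E over times is chi-square
    with one degree of freedom.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {labels.size}")
    g1 = group == labels[0]
    order = np.argsort(time, kind="mergesort")
    t, e, g = time[order], event[order], g1[order]
    n = len(t)
    o_minus_e = 0.0
    var = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())
        if d > 0:
            at_risk = n - i
            n1 = int(g[i:].sum())
            d1 = int((e[i:j] & g[i:j]).sum())
            expected = d * n1 / at_risk
            o_minus_e += d1 - expected
            if at_risk > 1:
                var += d * (n1 / at_risk) * (1 - n1 / at_risk) * (at_risk - d) / (at_risk - 1)
        i = j
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# cohort handling


def split_train_test(
    clinical: ClinicalTable | pd.DataFrame,
    train_frac: float = 0.7,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Random train/test partition of tumor samples, stratified by event.

    The total training size is round(train_frac * n); it is allocated
    across the event strata by largest remainder so the overall fraction
    is hit exactly.  Falls back to an unstratified split (with a warning)
    when a stratum is too small.
    """
    df = clinical.tumor() if isinstance(clinical, ClinicalTable) else pd.DataFrame(clinical)
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    ids = df["sample_id"].to_numpy()
    events = df["event"].to_numpy()
    n_train = int(round(train_frac * len(ids)))
    strata = [ids[events == v] for v in (0, 1)]
    if any(len(s) < 2 for s in strata):
        warnings.warn("a stratum has < 2 samples; splitting without stratification", stacklevel=2)
        strata = [ids]
    quotas = [train_frac * len(s) for s in strata]
    base = [int(np.floor(q)) for q in quotas]
    remainder = n_train - sum(base)
    frac_order = np.argsort([-(q - b) for q, b in zip(quotas, base)], kind="mergesort")
    for idx in frac_order[: max(0, remainder)]:
        base[idx] += 1
    train: list[str] = []
    test: list[str] = []
    for s, n_take in zip(strata, base):
        perm = rng.permutation(len(s))
        train.extend(s[perm[:n_take]])
        test.extend(s[perm[n_take:]])
    return sorted(train), sorted(test)


def build_risk_model(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    lnc_ids: list[str],
    train_ids: list[str],
) -> tuple[RiskModel, list[CoxResult]]:
    """Univariate Cox coefficients on training samples and the median cutoff."""
    clin = clinical.tumor().set_index("sample_id").loc[train_ids]
    terms: list[tuple[str, float]] = []
    fits: list[CoxResult] = []
    for lnc in lnc_ids:
        if lnc not in expr.data.index:
            raise KeyError(f"lncRNA {lnc!r} absent from expression matrix")
        res = cox_univariate(
            clin["time"], clin["event"], expr.data.loc[lnc, train_ids], covariate_id=lnc
        )
        if not res.converged:
            raise RuntimeError(f"Cox fit failed for {lnc!r}: {res.message}")
        fits.append(res)
        terms.append((lnc, res.coef))
    model = RiskModel(terms=terms, cutoff=0.0, training_sample_ids=list(train_ids))
    scores = model.score(expr, list(train_ids))
    model.cutoff = float(scores.median())
    return model, fits


def score_and_stratify(
    model: RiskModel,
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    sample_ids: list[str] | None = None,
) -> SurvivalComparison:
    """Score samples, split at the cutoff, and compare group survival.

    Samples scoring strictly above the cutoff are high-risk.  Raises when
    either group is empty (the split carries no information).
    """
    clin = clinical.tumor()
    if sample_ids is None:
        sample_ids = [s for s in clin["sample_id"] if s in expr.data.columns]
    clin = clin.set_index("sample_id").loc[sample_ids]
    scores = model.score(expr, list(sample_ids))
    labels = pd.Series(
        np.where(scores > model.cutoff, "high", "low"), index=scores.index, name="risk_group"
    )
    sizes = labels.value_counts().to_dict()
    if sizes.get("high", 0) == 0 or sizes.get("low", 0) == 0:
        raise ValueError("risk stratification produced an empty group")
    chi2, p = logrank_test(clin["time"], clin["event"], labels.to_numpy())
    curves = {
        grp: kaplan_meier(clin.loc[labels == grp, "time"], clin.loc[labels == grp, "event"])
        for grp in ("high", "low")
    }
    return SurvivalComparison(
        labels=labels, km_curves=curves, logrank_chi2=chi2, logrank_p=p, group_sizes=sizes
    )


def compare_expression_groups(
    expr: ExpressionMatrix,
    labels: pd.Series,
    rna_id: str,
) -> tuple[float, float, dict]:
    """Two-sided Wilcoxon rank-sum of one RNA's expression between groups."""
    if rna_id not in expr.data.index:
        raise KeyError(f"{rna_id!r} absent from expression matrix")
    groups = labels.dropna()
    names = sorted(groups.unique())
    if len(names) != 2:
        raise ValueError(f"need exactly 2 groups, got {names}")
    vals = [
        expr.data.loc[rna_id, groups[groups == name].index].to_numpy(dtype=float)
        for name in names
    ]
    if any(v.size == 0 for v in vals):
        raise ValueError("both groups must be non-empty")
    res = sps.mannwhitneyu(vals[0], vals[1], alternative="two-sided", method="auto")
    medians = {name: float(np.median(v)) for name, v in zip(names, vals)}
    return float(res.statistic), float(res.pvalue), medians
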