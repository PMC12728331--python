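"""Statistical chain for the dyadic neurofeedback analysis.

Group comparisons use a Levene-gated t-test (classical Levene with the mean
as center; Welch with Satterthwaite degrees of freedom when the gate
rejects equal variances at p < 0.05). Frequency-wise group differences in
the coupling spectrum are tested per 1-Hz bin and corrected with
Benjamini-Hochberg FDR. Pre/post questionnaire outcomes go through a 2x2
mixed ANOVA (Group between dyads, Time within), with partial eta squared
F*df1/(F*df1 + df2) and pooled-error simple effects with Bonferroni
adjustment. The serial three-mediator model (coupling -> joint control ->
delta shared intentionality -> delta perceived similarity -> delta social
connectedness) is estimated by nested OLS on z-scored variables with a
dyad-level percentile bootstrap over all seven indirect paths; no
correction is applied across the seven paths (each is reported with its
own bootstrap CI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .offline import CouplingSpectrum

LEVENE_GATE_P = 0.05


# ---------------------------------------------------------------- t tests

def levene(x, y, center: str = "mean") -> tuple[float, float]:
    """Classical Levene test of equal variances (center = mean)."""
    W, p = sps.levene(np.asarray(x), np.asarray(y), center=center)
    return float(W), float(p)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    d: float  # Cohen's d = t * sqrt(1/n1 + 1/n2)
    variant: str  # student | welch
    levene_W: float
    levene_p: float
    n1: int = 0
    n2: int = 0


def cohens_d_from_t(t: float, n1: int, n2: int) -> float:
    """Two-sample Cohen's d recovered from the t statistic."""
    return float(t * np.sqrt(1.0 / n1 + 1.0 / n2))


def t_test_auto(x, y, gate_p: float = LEVENE_GATE_P) -> TTestResult:
    """Independent-samples t-test with a Levene gate.

    Pooled-variance Student test when Levene's p >= ``gate_p``; otherwise
    Welch's test with adjusted degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two observations per group")
    if x.std() == 0 and y.std() == 0:
        raise ValueError("degenerate zero-variance inputs")
    W, lp = levene(x, y)
    equal_var = lp >= gate_p
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    df = float(res.df)
    t = float(res.statistic)
    return TTestResult(t=t, df=df, p=float(res.pvalue),
                       d=cohens_d_from_t(t, len(x), len(y)),
                       variant="student" if equal_var else "welch",
                       levene_W=W, levene_p=lp, n1=len(x), n2=len(y))


def freqwise_tests(spectra_real: list[CouplingSpectrum] | np.ndarray,
                   spectra_sham: list[CouplingSpectrum] | np.ndarray,
                   gate_p: float = LEVENE_GATE_P) -> list[TTestResult]:
    """Independent-samples test per frequency bin (real vs sham dyads)."""
    def as_matrix(spectra):
        if isinstance(spectra, np.ndarray):
            return spectra
        return np.vstack([s.values for s in spectra])

    a = as_matrix(spectra_real)
    b = as_matrix(spectra_sham)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least two dyads per group")
    if a.shape[1] != b.shape[1]:
        raise ValueError("frequency grids differ between groups")
    return [t_test_auto(a[:, j], b[:, j], gate_p=gate_p)
            for j in range(a.shape[1])]


def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


# ------------------------------------------------------------ mixed ANOVA

def partial_eta_sq(F: float, df1: float, df2: float) -> float:
    """Partial eta squared from an F ratio: F*df1 / (F*df1 + df2)."""
    return float(F * df1 / (F * df1 + df2))


@dataclass(frozen=True)
class Effect:
    F: float
    df1: float
    df2: float
    p: float
    partial_eta_sq: float


@dataclass(frozen=True)
class AnovaResult:
    """2x2 mixed ANOVA effects keyed 'group', 'time', 'interaction'."""
    effects: dict[str, Effect]
    outcome: str
    group_levels: tuple[str, str]


def _pre_post(scores: pd.DataFrame, outcome: str):
    pre = scores[f"{outcome}_pre"].to_numpy(dtype=float)
    post = scores[f"{outcome}_post"].to_numpy(dtype=float)
    groups = scores["group"].to_numpy()
    levels = tuple(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    return pre, post, groups, levels


def mixed_anova_2x2(scores: pd.DataFrame, outcome: str) -> AnovaResult:
    """Group (between) x Time (within) ANOVA on one pre/post outcome.

    Uses the exact 2x2 decomposition: between effects live on the dyad
    means m = (pre+post)/2, within effects on the differences d = post-pre.
    The interaction F equals the squared pooled t comparing d between
    groups; the Group F equals the squared pooled t on m; the Time F tests
    the unweighted grand mean of d against the same pooled within error.
    All three are F(1, N-2).
    """
    pre, post, groups, levels = _pre_post(scores, outcome)
    d = post - pre
    m = 0.5 * (post + pre)
    g1, g2 = (groups == levels[0]), (groups == levels[1])
    n1, n2 = int(g1.sum()), int(g2.sum())
    if min(n1, n2) < 2:
        raise ValueError("need at least two dyads per group")
    df2 = n1 + n2 - 2

    def pooled_var(v):
        return (((n1 - 1) * np.var(v[g1], ddof=1)
                 + (n2 - 1) * np.var(v[g2], ddof=1)) / df2)

    def eff(F):
        F = float(max(F, 0.0))
        p = float(sps.f.sf(F, 1, df2))
        return Effect(F, 1.0, float(df2), p, partial_eta_sq(F, 1, df2))

    # Group: pooled two-sample t on dyad means.
    s2m = pooled_var(m)
    t_group = ((m[g1].mean() - m[g2].mean())
               / np.sqrt(s2m * (1 / n1 + 1 / n2))) if s2m > 0 else 0.0
    # Interaction: pooled two-sample t on difference scores.
    s2d = pooled_var(d)
    t_int = ((d[g1].mean() - d[g2].mean())
             / np.sqrt(s2d * (1 / n1 + 1 / n2))) if s2d > 0 else 0.0
    # Time: unweighted mean of the group means of d (Type III) against the
    # same pooled error.
    theta = 0.5 * (d[g1].mean() + d[g2].mean())
    se_theta = np.sqrt(s2d * (1 / n1 + 1 / n2)) / 2 if s2d > 0 else 0.0
    t_time = theta / se_theta if se_theta > 0 else 0.0

    effects = {"group": eff(t_group ** 2),
               "time": eff(t_time ** 2),
               "interaction": eff(t_int ** 2)}
    return AnovaResult(effects, outcome, (str(levels[0]), str(levels[1])))


def simple_effects(scores: pd.DataFrame, outcome: str,
                   bonferroni: int = 2) -> dict[str, Effect]:
    """Per-group post-vs-pre contrast using the omnibus pooled error term.

    Each contrast is F(1, N-2) with the pooled variance of the difference
    scores as error; p-values are Bonferroni-multiplied by the number of
    contrasts (capped at 1).
    """
    pre, post, groups, levels = _pre_post(scores, outcome)
    d = post - pre
    g1, g2 = (groups == levels[0]), (groups == levels[1])
    n1, n2 = int(g1.sum()), int(g2.sum())
    df2 = n1 + n2 - 2
    s2d = (((n1 - 1) * np.var(d[g1], ddof=1)
            + (n2 - 1) * np.var(d[g2], ddof=1)) / df2)
    out = {}
    for lev, g, n in ((levels[0], g1, n1), (levels[1], g2, n2)):
        t = d[g].mean() / np.sqrt(s2d / n) if s2d > 0 else 0.0
        F = float(t ** 2)
        p = min(1.0, float(sps.f.sf(F, 1, df2)) * bonferroni)
        out[str(lev)] = Effect(F, 1.0, float(df2), p,
                               partial_eta_sq(F, 1, df2))
    return out


# --------------------------------------------------- simple descriptives

def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation with two-tailed t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least three observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def cronbach_alpha(items: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha of a respondents x items score matrix."""
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 items and 2 respondents")
    k = X.shape[1]
    item_vars = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero variance of item sums")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


# ------------------------------------------------------- serial mediation

#: The seven indirect paths of the serial three-mediator model, as tuples
#: of the chained variables between X and Y.
INDIRECT_PATHS: tuple[tuple[str, ...], ...] = (
    ("M1",), ("M2",), ("M3",),
    ("M1", "M2"), ("M1", "M3"), ("M2", "M3"),
    ("M1", "M2", "M3"),
)


@dataclass
class MediationResult:
    paths: dict[str, float]  # a1..a3, d21, d31, d32, b1..b3, c, c_prime
    indirect: pd.DataFrame  # label, estimate, boot_se, ci_low, ci_high
    n: int
    n_boot: int
    seed: int
    ci_level: float = 0.95

    @property
    def total_indirect(self) -> float:
        return float(self.indirect["estimate"].sum())


def _fit_paths(X, M1, M2, M3, Y) -> dict[str, float]:
    """Nested OLS coefficient estimates (variables already standardized)."""
    def ols(y, *cols):
        A = np.column_stack([np.ones_like(y), *cols])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        return beta[1:]

    a1 = ols(M1, X)[0]
    a2, d21 = ols(M2, X, M1)
    a3, d31, d32 = ols(M3, X, M1, M2)
    c_prime, b1, b2, b3 = ols(Y, X, M1, M2, M3)
    c = ols(Y, X)[0]
    return dict(a1=a1, a2=a2, a3=a3, d21=d21, d31=d31, d32=d32,
                b1=b1, b2=b2, b3=b3, c=c, c_prime=c_prime)


def _indirect_from_paths(p: dict[str, float]) -> np.ndarray:
    a = {"M1": p["a1"], "M2": p["a2"], "M3": p["a3"]}
    d = {("M1", "M2"): p["d21"], ("M1", "M3"): p["d31"],
         ("M2", "M3"): p["d32"]}
    b = {"M1": p["b1"], "M2": p["b2"], "M3": p["b3"]}
    out = []
    for chain in INDIRECT_PATHS:
        v = a[chain[0]]
        for u, w in zip(chain, chain[1:]):
            v *= d[(u, w)]
        v *= b[chain[-1]]
        out.append(v)
    return np.array(out)


def _batched_indirects(V: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Indirect effects for many bootstrap resamples at once.

    ``V``: (n, 5) columns (X, M1, M2, M3, Y); ``idx``: (B, n) resample
    indices. Solves the four nested regressions per resample via batched
    normal equations. Returns (B, 7).
    """
    B, n = idx.shape
    Vb = V[idx]  # (B, n, 5)
    ones = np.ones((B, n, 1))

    def ols(y_col: int, x_cols: list[int]) -> np.ndarray:
        A = np.concatenate([ones, Vb[:, :, x_cols]], axis=2)  # (B, n, k)
        At = A.transpose(0, 2, 1)
        G = At @ A
        h = At @ Vb[:, :, y_col:y_col + 1]  # (B, k, 1)
        try:
            beta = np.linalg.solve(G, h)[:, :, 0]
        except np.linalg.LinAlgError:
            beta = (np.linalg.pinv(G) @ h)[:, :, 0]
        return beta[:, 1:]  # drop intercept

    a1 = ols(1, [0])[:, 0]
    m2 = ols(2, [0, 1])
    a2, d21 = m2[:, 0], m2[:, 1]
    m3 = ols(3, [0, 1, 2])
    a3, d31, d32 = m3[:, 0], m3[:, 1], m3[:, 2]
    yy = ols(4, [0, 1, 2, 3])
    b1, b2, b3 = yy[:, 1], yy[:, 2], yy[:, 3]
    return np.column_stack([
        a1 * b1, a2 * b2, a3 * b3,
        a1 * d21 * b2, a1 * d31 * b3, a2 * d32 * b3,
        a1 * d21 * d32 * b3,
    ])


def path_label(chain: tuple[str, ...],
               names: dict[str, str] | None = None) -> str:
    names = names or {}
    parts = ["X", *chain, "Y"]
    return " -> ".join(names.get(p, p) for p in parts)


def serial_mediation(X, M1, M2, M3, Y, n_boot: int = 5000, seed: int = 0,
                     standardize: bool = True, ci_level: float = 0.95,
                     names: dict[str, str] | None = None) -> MediationResult:
    """Serial three-mediator model with a dyad-level percentile bootstrap.

    Variables are z-scored once on the full sample (resamples reuse the
    full-sample standardization). Point estimates come from the nested OLS
    equations; the seven indirect effects are products of path
    coefficients along the chains M1, M2, M3, M1->M2, M1->M3, M2->M3 and
    M1->M2->M3, each with a percentile bootstrap CI over ``n_boot``
    resamples of dyads with replacement. The OLS identity
    c = c' + sum(indirect) holds exactly.
    """
    cols = [np.asarray(v, dtype=float) for v in (X, M1, M2, M3, Y)]
    n = len(cols[0])
    if any(len(c) != n for c in cols):
        raise ValueError("variables must have equal length")
    mask = np.all(np.isfinite(np.column_stack(cols)), axis=1)
    if not mask.all():
        warnings.warn(f"dropping {int((~mask).sum())} incomplete dyads")
        cols = [c[mask] for c in cols]
        n = int(mask.sum())
    if n < 10:
        raise ValueError("need at least 10 complete dyads")
    if n_boot < 1000:
        warnings.warn("n_boot < 1000 gives unstable percentile CIs")

    V = np.column_stack(cols)
    if standardize:
        V = (V - V.mean(axis=0)) / V.std(axis=0, ddof=1)
    paths = _fit_paths(*(V[:, j] for j in range(5)))
    point = _indirect_from_paths(paths)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = _batched_indirects(V, idx)  # (n_boot, 7)
    alpha = (1.0 - ci_level) / 2.0
    lo = np.quantile(boot, alpha, axis=0)
    hi = np.quantile(boot, 1.0 - alpha, axis=0)
    se = boot.std(axis=0, ddof=1)

    indirect = pd.DataFrame({
        "label": [path_label(c, names) for c in INDIRECT_PATHS],
        "estimate": point,
        "boot_se": se,
        "ci_low": lo,
        "ci_high": hi,
    })
    return MediationResult(paths={k: float(v) for k, v in paths.items()},
                           indirect=indirect, n=n, n_boot=n_boot, seed=seed,
                           ci_level=ci_level)
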