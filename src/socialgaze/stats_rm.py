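"""Within-subject inferential statistics.

Paired t-tests with Cohen's d for paired data, one- and two-way
repeated-measures ANOVA (univariate sums-of-squares approach, participant x
factor interactions as error strata) with Huynh-Feldt sphericity
correction and partial eta squared, and Bonferroni-corrected post hoc
pairwise tests.

The Huynh-Feldt epsilon is derived from the Greenhouse-Geisser estimate of
the condition-difference covariance structure:

    eps_hf = (n * m * eps_gg - 2) / (m * (n - 1 - m * eps_gg))

with m the effect's numerator df, clamped to [1/m, 1]. A factor with two
levels has eps = 1 by definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "paired_t",
    "cohens_d",
    "rm_anova_oneway",
    "rm_anova_twoway",
    "rm_anova",
    "bonferroni_posthoc",
]


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    epsilon_hf: float
    p_uncorrected: float
    p_corrected: float
    eta_sq_partial: float


def cohens_d(a, b, *, kind: str = "paired") -> float:
    """Cohen's d: 'paired' (d_z = mean diff / SD of diffs) or 'two_sample'.

    The paired default divides the mean difference by the standard
    deviation of the differences; the pooled-SD two-sample form is the
    classic independent-groups measure.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if kind == "paired":
        d = a - b
        sd = d.std(ddof=1)
        if sd == 0:
            return 0.0 if d.mean() == 0 else float(np.sign(d.mean()) * np.inf)
        return float(d.mean() / sd)
    if kind == "two_sample":
        na, nb = len(a), len(b)
        pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
        if pooled == 0:
            return 0.0 if a.mean() == b.mean() else float(np.sign(a.mean() - b.mean()) * np.inf)
        return float((a.mean() - b.mean()) / pooled)
    raise ValueError(f"kind must be 'paired' or 'two_sample', got {kind!r}")


def paired_t(a, b, *, tails: int = 2) -> tuple[float, int, float, float]:
    """Paired t-test with Cohen's d for paired data.

    Returns (t, df, p, d_paired). A zero-variance nonzero mean difference
    yields an infinite t with p = 0 (flagged by a warning).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("paired_t needs two equal-length 1-D samples, n >= 3")
    d = a - b
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, n - 1, 1.0, 0.0
        warnings.warn("zero variance of differences with nonzero mean: infinite t")
        t = float(np.sign(d.mean()) * np.inf)
        return t, n - 1, 0.0, cohens_d(a, b, kind="paired")
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(stats.t.sf(abs(t), n - 1) * (2 if tails == 2 else 1))
    return t, n - 1, p, cohens_d(a, b, kind="paired")


def _eps_from_contrast(S: np.ndarray, C: np.ndarray, n: int) -> tuple[float, float]:
    """(eps_gg, eps_hf) for an effect with orthonormal contrast rows C."""
    m = C.shape[0]
    if m == 1:
        return 1.0, 1.0
    M = C @ S @ C.T
    tr = np.trace(M)
    gg = tr**2 / (m * np.sum(M * M))
    lo = 1.0 / m
    gg = min(max(gg, lo), 1.0)
    denom = m * (n - 1 - m * gg)
    if denom <= 0:
        warnings.warn("too few participants to estimate epsilon; clamped to lower bound")
        return gg, lo
    hf = (n * m * gg - 2.0) / denom
    return gg, float(min(max(hf, lo), 1.0))


def _orthonormal_contrast(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows spanning the space orthogonal to 1."""
    q, _ = np.linalg.qr(np.column_stack([np.ones(k), np.eye(k)[:, : k - 1]]))
    return q[:, 1:].T


def rm_anova_oneway(data, *, factor: str = "condition") -> list[AnovaResult]:
    """One-way repeated-measures ANOVA on an (n_participants x k) table."""
    Y = np.asarray(data, dtype=float)
    if Y.ndim != 2:
        raise ValueError("expected a participants x conditions matrix")
    n, k = Y.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 participants and >= 2 conditions")
    gm = Y.mean()
    ss_cond = n * np.sum((Y.mean(axis=0) - gm) ** 2)
    ss_subj = k * np.sum((Y.mean(axis=1) - gm) ** 2)
    ss_tot = np.sum((Y - gm) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    F = (ss_cond / df1) / (ss_err / df2)
    C = _orthonormal_contrast(k)
    _, hf = _eps_from_contrast(np.cov(Y, rowvar=False, ddof=1), C, n)
    p_unc = float(stats.f.sf(F, df1, df2))
    p_cor = float(stats.f.sf(F, df1 * hf, df2 * hf)) if df1 > 1 else p_unc
    return [
        AnovaResult(
            effect=factor,
            F=float(F),
            df_num=df1,
            df_den=df2,
            epsilon_hf=hf,
            p_uncorrected=p_unc,
            p_corrected=p_cor,
            eta_sq_partial=float(ss_cond / (ss_cond + ss_err)),
        )
    ]


def rm_anova_twoway(data, *, factors: tuple[str, str] = ("A", "B")) -> list[AnovaResult]:
    """Two-way fully-within ANOVA on an (n x a x b) array.

    Error strata are the participant x effect interactions, the univariate
    approach: effect A is tested against subject x A, B against subject x B,
    and A x B against the three-way residual.
    """
    Y = np.asarray(data, dtype=float)
    if Y.ndim != 3:
        raise ValueError("expected an (n_participants, a, b) array")
    n, a, b = Y.shape
    gm = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_sa = Y.mean(axis=2)
    m_sb = Y.mean(axis=1)
    m_ab = Y.mean(axis=0)

    ss_a = n * b * np.sum((m_a - gm) ** 2)
    ss_b = n * a * np.sum((m_b - gm) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2)
    ss_sa = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + gm) ** 2)
    ss_sb = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + gm) ** 2)
    resid = (
        Y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - gm
    )
    ss_res = np.sum(resid**2)

    S_full = np.cov(Y.reshape(n, a * b), rowvar=False, ddof=1)
    Ca = _orthonormal_contrast(a)
    Cb = _orthonormal_contrast(b)
    one_a = np.full((1, a), 1.0 / np.sqrt(a))
    one_b = np.full((1, b), 1.0 / np.sqrt(b))

    out = []
    specs = [
        (factors[0], ss_a, a - 1, ss_sa, (n - 1) * (a - 1), np.kron(Ca, one_b)),
        (factors[1], ss_b, b - 1, ss_sb, (n - 1) * (b - 1), np.kron(one_a, Cb)),
        (
            f"{factors[0]} x {factors[1]}",
            ss_ab,
            (a - 1) * (b - 1),
            ss_res,
            (n - 1) * (a - 1) * (b - 1),
            np.kron(Ca, Cb),
        ),
    ]
    for name, ss_eff, df1, ss_err, df2, C in specs:
        F = (ss_eff / df1) / (ss_err / df2)
        _, hf = _eps_from_contrast(S_full, C, n)
        p_unc = float(stats.f.sf(F, df1, df2))
        p_cor = float(stats.f.sf(F, df1 * hf, df2 * hf)) if df1 > 1 else p_unc
        out.append(
            AnovaResult(
                effect=name,
                F=float(F),
                df_num=df1,
                df_den=df2,
                epsilon_hf=hf,
                p_uncorrected=p_unc,
                p_corrected=p_cor,
                eta_sq_partial=float(ss_eff / (ss_eff + ss_err)),
            )
        )
    return out


def rm_anova(data, *, factors=None) -> list[AnovaResult]:
    """Dispatch: 2-D input -> one-way; 3-D input -> two-way within design."""
    Y = np.asarray(data, dtype=float)
    if Y.ndim == 2:
        return rm_anova_oneway(Y, factor=factors if isinstance(factors, str) else "condition")
    if Y.ndim == 3:
        return rm_anova_twoway(Y, factors=tuple(factors) if factors else ("A", "B"))
    raise ValueError("data must be 2-D (one factor) or 3-D (two factors)")


def bonferroni_posthoc(data, condition_names=None, *, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise paired t-tests with a Bonferroni-corrected threshold.

    ``data`` is an (n x k) table; significance is judged at alpha / m with
    m the number of pairs.
    """
    Y = np.asarray(data, dtype=float)
    n, k = Y.shape
    names = list(condition_names) if condition_names is not None else [str(i) for i in range(k)]
    pairs = list(combinations(range(k), 2))
    m = len(pairs)
    thresh = alpha / m
    rows = []
    for i, j in pairs:
        t, df, p, d = paired_t(Y[:, i], Y[:, j])
        rows.append(
            {
                "a": names[i],
                "b": names[j],
                "t": t,
                "df": df,
                "p": p,
                "d_paired": d,
                "threshold": thresh,
                "significant": p < thresh,
            }
        )
    return pd.DataFrame(rows)
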