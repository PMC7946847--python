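"""Repeated-measures inference for attention-window thresholds.

Implements the two-way fully-within-subject ANOVA used to compare
thresholds across task conditions and meridians: sum-of-squares partition
into subject, the two main effects, their interaction and the matching
subject-interaction error strata; Mauchly's sphericity test and the
Greenhouse–Geisser ε̂ from the orthonormal-contrast covariance; partial
η² = SS_effect / (SS_effect + SS_error); Bonferroni-corrected pairwise
follow-ups on subject-level marginal means; and percent-reduction effect
summaries. p-values use exact F / χ² / t reference distributions.

For an effect with numerator degrees of freedom ≥ 2 the Greenhouse–Geisser
correction is applied (df and p rescaled by ε̂) whenever Mauchly's test
rejects at 0.05 — the conventional reporting rule — and the
unconditionally corrected values are emitted alongside for comparison.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "rm_anova_2way",
    "rm_anova_2way_array",
    "mauchly_gg",
    "pairwise_bonferroni",
    "percent_reduction",
]

MAUCHLY_ALPHA = 0.05


@dataclass
class AnovaResult:
    """Effect table plus sphericity diagnostics for a 2-way within design."""

    effects: pd.DataFrame  # index: A, B, A x B
    sphericity: pd.DataFrame  # per effect with >=3 numerator levels
    factors: tuple[str, str]
    n_subjects: int

    def to_text(self) -> str:
        lines = []
        for name, row in self.effects.iterrows():
            lines.append(
                f"{name}: F({row.df_num:g}, {row.df_den:g}) = {row.F:.3f}, "
                f"p = {row.p:.3f}, partial eta^2 = {row.partial_eta_sq:.3f}"
                + (
                    f"  [GG: F({row.df_num_gg:.3f}, {row.df_den_gg:.3f}), "
                    f"p = {row.p_gg:.3f}, eps = {row.eps_gg:.3f}"
                    + (", applied" if row.gg_applied else "")
                    + "]"
                    if np.isfinite(row.get("eps_gg", np.nan))
                    else ""
                )
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "factors": list(self.factors),
            "n_subjects": self.n_subjects,
            "effects": self.effects.reset_index(names="effect").to_dict(orient="records"),
            "sphericity": self.sphericity.reset_index(names="effect").to_dict(orient="records"),
        }


def _orthonormal_contrasts(p: int) -> np.ndarray:
    """(p−1) × p orthonormal contrast matrix (rows sum to zero)."""
    h = np.zeros((p - 1, p))
    for i in range(p - 1):
        h[i, : i + 1] = 1.0
        h[i, i + 1] = -(i + 1.0)
        h[i] /= np.linalg.norm(h[i])
    return h


def mauchly_gg(contrast_cov: np.ndarray, n: int) -> tuple[float, float, float, float]:
    """Mauchly's W, its χ² approximation and p, and Greenhouse–Geisser ε̂.

    ``contrast_cov`` is the k×k sample covariance of the data projected onto
    k = p−1 orthonormal contrasts of a p-level within factor; ``n`` is the
    number of subjects. For k = 1 (a 2-level factor) sphericity holds
    trivially: W = 1, χ² = 0, p = 1, ε̂ = 1.
    """
    s = np.atleast_2d(np.asarray(contrast_cov, dtype=float))
    k = s.shape[0]
    if s.shape != (k, k):
        raise ValueError("contrast covariance must be square")
    if k == 1:
        return 1.0, 0.0, 1.0, 1.0
    eig = np.linalg.eigvalsh(s)
    tr = float(eig.sum())
    if tr <= 0 or np.any(eig <= 0):
        raise ValueError("singular contrast covariance: Mauchly's W is 0 (ln W undefined)")
    w = float(np.prod(eig) / (tr / k) ** k)
    d = 1.0 - (2.0 * k * k + k + 2.0) / (6.0 * k * (n - 1.0))
    chi2 = -(n - 1.0) * d * math.log(w)
    df = k * (k + 1) / 2.0 - 1.0
    p = float(sps.chi2.sf(chi2, df))
    eps = tr**2 / (k * float((eig**2).sum()))
    return w, float(chi2), p, float(eps)


def rm_anova_2way_array(y: np.ndarray) -> dict:
    """Core SS partition on an (n_subjects, a, b) array; returns raw pieces.

    Each effect is tested against its own subject-interaction error stratum:
    F_A = MS_A / MS_{A×S}, etc.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 3:
        raise ValueError("expected an (n_subjects, a_levels, b_levels) array")
    if np.isnan(y).any():
        raise ValueError("missing cells are not supported in a within design")
    n, a, b = y.shape
    if n < 2:
        raise ValueError("need at least 2 subjects (no error stratum otherwise)")
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    ss_subj = a * b * float(((m_s - grand) ** 2).sum())
    ss_a = n * b * float(((m_a - grand) ** 2).sum())
    ss_b = n * a * float(((m_b - grand) ** 2).sum())
    ss_ab = n * float(((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum())
    ss_as = b * float(((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum())
    ss_bs = a * float(((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_abs = ss_total - (ss_subj + ss_a + ss_b + ss_ab + ss_as + ss_bs)
    out = {
        "n": n, "a": a, "b": b,
        "ss": {
            "subject": ss_subj, "A": ss_a, "B": ss_b, "A x B": ss_ab,
            "A error": ss_as, "B error": ss_bs, "A x B error": ss_abs,
            "total": ss_total,
        },
        "df": {
            "A": (a - 1, (n - 1) * (a - 1)),
            "B": (b - 1, (n - 1) * (b - 1)),
            "A x B": ((a - 1) * (b - 1), (n - 1) * (a - 1) * (b - 1)),
        },
    }
    f = {}
    for eff, ss_eff, ss_err in (("A", ss_a, ss_as), ("B", ss_b, ss_bs), ("A x B", ss_ab, ss_abs)):
        dfn, dfd = out["df"][eff]
        ms_eff = ss_eff / dfn
        ms_err = ss_err / dfd if dfd > 0 else np.nan
        f[eff] = ms_eff / ms_err if ms_err and ms_err > 0 else 0.0
    out["F"] = f
    return out


def _effect_contrast_cov(y: np.ndarray, effect: str) -> np.ndarray:
    """Sample covariance of the effect's orthonormal-contrast scores."""
    n, a, b = y.shape
    ca = _orthonormal_contrasts(a)
    cb = _orthonormal_contrasts(b)
    flat = y.reshape(n, a * b)
    if effect == "A":
        m = np.kron(ca, np.full((1, b), 1.0 / b))
    elif effect == "B":
        m = np.kron(np.full((1, a), 1.0 / a), cb)
    else:
        m = np.kron(ca, cb)
    # re-orthonormalise rows (averaging shrinks their norm)
    m = m / np.linalg.norm(m, axis=1, keepdims=True)
    scores = flat @ m.T
    return np.cov(scores, rowvar=False).reshape(m.shape[0], m.shape[0])


def rm_anova_2way(
    data: pd.DataFrame | np.ndarray,
    dv: str = "threshold_deg",
    within: Sequence[str] = ("condition", "meridian_class"),
    subject: str = "subject",
) -> AnovaResult:
    """Two-way fully-within-subject ANOVA with sphericity diagnostics.

    ``data`` is a complete, balanced long-format table (one value per
    subject × A × B cell; replicate rows within a cell are averaged first)
    or an (n, a, b) array. Factor levels are ordered by first appearance.
    """
    if isinstance(data, np.ndarray):
        y = data
        within = ("A", "B")
    else:
        fa, fb = within
        for col in (subject, fa, fb, dv):
            if col not in data.columns:
                raise ValueError(f"missing column: {col}")
        a_levels = list(pd.unique(data[fa]))
        b_levels = list(pd.unique(data[fb]))
        subjects = list(pd.unique(data[subject]))
        cell = data.groupby([subject, fa, fb], observed=True, sort=False)[dv].mean()
        try:
            y = np.array(
                [[[cell[s, ai, bi] for bi in b_levels] for ai in a_levels] for s in subjects]
            )
        except KeyError as exc:
            raise ValueError(f"incomplete design: missing cell {exc.args[0]!r}") from exc
    core = rm_anova_2way_array(y)
    n = core["n"]
    rows = {}
    sph_rows = {}
    for eff in ("A", "B", "A x B"):
        dfn, dfd = core["df"][eff]
        fval = core["F"][eff]
        ss_eff = core["ss"][eff]
        ss_err = core["ss"][f"{eff} error"]
        p = float(sps.f.sf(fval, dfn, dfd)) if fval > 0 else 1.0
        peta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        row = {
            "df_num": dfn, "df_den": dfd, "F": fval, "p": p,
            "partial_eta_sq": peta, "SS": ss_eff, "SS_error": ss_err,
            "eps_gg": np.nan, "df_num_gg": np.nan, "df_den_gg": np.nan,
            "p_gg": np.nan, "gg_applied": False,
        }
        if dfn >= 2:
            cov = _effect_contrast_cov(y, eff)
            try:
                w, chi2, p_m, eps = mauchly_gg(cov, n)
            except ValueError:
                w, chi2, p_m, eps = 0.0, np.inf, 0.0, 1.0 / dfn
            sph_rows[_effect_name(eff, within)] = {
                "mauchly_W": w, "chi2": chi2,
                "df": cov.shape[0] * (cov.shape[0] + 1) / 2.0 - 1.0,
                "p": p_m, "eps_gg": eps,
            }
            row["eps_gg"] = eps
            row["df_num_gg"] = eps * dfn
            row["df_den_gg"] = eps * dfd
            row["p_gg"] = float(sps.f.sf(fval, eps * dfn, eps * dfd)) if fval > 0 else 1.0
            if p_m < MAUCHLY_ALPHA:
                row["gg_applied"] = True
                row["p"] = row["p_gg"]
                row["df_num"] = row["df_num_gg"]
                row["df_den"] = row["df_den_gg"]
        rows[_effect_name(eff, within)] = row
    effects = pd.DataFrame(rows).T
    sphericity = pd.DataFrame(sph_rows).T if sph_rows else pd.DataFrame(
        columns=["mauchly_W", "chi2", "df", "p", "eps_gg"]
    )
    return AnovaResult(effects=effects, sphericity=sphericity,
                       factors=tuple(within), n_subjects=n)


def _effect_name(eff: str, within: Sequence[str]) -> str:
    fa, fb = (within[0], within[1]) if len(within) == 2 else ("A", "B")
    return {"A": fa, "B": fb, "A x B": f"{fa} x {fb}"}[eff]


def pairwise_bonferroni(
    data: pd.DataFrame,
    dv: str = "threshold_deg",
    factor: str = "meridian_class",
    subject: str = "subject",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired-t follow-ups on subject-level marginal means, Bonferroni-corrected.

    Marginal means collapse over any other within factors by averaging.
    With k levels there are k(k−1)/2 comparisons and the adjusted α is
    alpha / n_comparisons (0.05/3 ≈ 0.017 for a 3-level factor).
    """
    levels = list(pd.unique(data[factor]))
    if len(levels) < 2:
        raise ValueError("pairwise comparisons need at least 2 levels")
    marg = data.groupby([subject, factor], observed=True, sort=False)[dv].mean().unstack(factor)
    pairs = list(itertools.combinations(levels, 2))
    k = len(pairs)
    adj_alpha = alpha / k
    rows = []
    for l1, l2 in pairs:
        x, yv = marg[l1].to_numpy(), marg[l2].to_numpy()
        diff = x - yv
        if np.allclose(diff, diff[0]) and np.isclose(diff.std(), 0):
            t, p = (0.0, 1.0) if np.isclose(diff.mean(), 0) else (np.inf, 0.0)
        else:
            t, p = sps.ttest_rel(x, yv)
        rows.append({
            "level_1": l1, "level_2": l2,
            "mean_diff": float(diff.mean()),
            "t": float(t), "p": float(p),
            "p_bonferroni": min(1.0, float(p) * k),
            "adjusted_alpha": adj_alpha,
            "significant": float(p) < adj_alpha,
        })
    return pd.DataFrame(rows)


def percent_reduction(mean_ref: float, mean_cmp: float) -> float:
    """Percent decrease of ``mean_cmp`` relative to ``mean_ref`` (reference > 0)."""
    if mean_ref <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * (mean_ref - mean_cmp) / mean_ref
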