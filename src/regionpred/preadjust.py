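"""Phenotype preadjustment for a many-level random systematic factor.

Fits the one-way random-intercept model

    y_il = mu + s_l + e_il,   s_l ~ N(0, sigma2_s),  e_il ~ N(0, sigma2_e)

by EM-REML and returns residuals y_R = y - mu_hat - s_hat(level) as the
preadjusted phenotype. Treating the factor as random is essential here:
most levels are observed once or twice, so fixed-effect adjustment would
delete nearly all information, whereas BLUPs shrink sparse levels toward 0
by the factor n_l sigma2_s / (n_l sigma2_s + sigma2_e).

The genetic signal is absorbed into the residual at this stage, as in any
two-step (preadjust, then predict) procedure; the resulting shrinkage bias
is a documented property, not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RandomEffectFit", "fit_random_intercept", "preadjust"]


@dataclass
class RandomEffectFit:
    mu: float
    level_effects: dict[str, float]       # BLUPs per level
    sigma2_level: float
    sigma2_resid: float                   # residual-plus-genetic variance
    converged: bool
    n_iter: int
    history: np.ndarray | None = None     # (iter, sigma2_level, sigma2_resid)


def fit_random_intercept(
    phenotypes: pd.DataFrame,
    y_col: str = "y",
    level_col: str = "level",
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> RandomEffectFit:
    """EM-REML for the one-way random-intercept model.

    The E step computes GLS mean, level BLUPs and their prediction-error
    variances from the mixed-model equations (exploiting their arrow
    structure, so each iteration is O(L)); the M step applies the standard
    EM-REML variance updates. Variance iterates are non-negative by
    construction and the sequence is monotone in the REML objective.
    """
    y = phenotypes[y_col].to_numpy(dtype=float)
    lev = phenotypes[level_col].to_numpy()
    levels, lev_idx = np.unique(lev, return_inverse=True)
    L, n = len(levels), len(y)
    if L < 2:
        raise ValueError(
            "only one systematic level: level variance is undefined; "
            "subtract the mean instead of fitting a random-effects model")
    n_l = np.bincount(lev_idx).astype(float)
    if (n_l < 2).all():
        raise ValueError("variance estimation needs at least one level with >=2 records")
    sum_l = np.bincount(lev_idx, weights=y)
    ybar_l = sum_l / n_l
    yty = float(y @ y)
    sy = float(y.sum())

    ssw = yty - float(n_l @ ybar_l**2)  # within-level sum of squares

    def reml_ll(s2s: float, s2e: float) -> float:
        vl = s2e + n_l * s2s
        w = n_l / vl
        mu = float((w * ybar_l).sum() / w.sum())
        return -0.5 * (float(((n_l - 1) * np.log(s2e)).sum())
                       + float(np.log(vl).sum())
                       + np.log(float(w.sum()))
                       + ssw / s2e
                       + float((n_l * (ybar_l - mu) ** 2 / vl).sum()))

    s2s = max(np.var(y) / 2.0, 1e-8)
    s2e = max(np.var(y) / 2.0, 1e-8)
    hist = []
    snaps: list[tuple[float, float]] = []
    converged = False
    for it in range(1, max_iter + 1):
        lam = s2e / s2s
        d = n_l + lam
        # GLS mean: weights 1 / (sigma2_s + sigma2_e / n_l)
        w = n_l / (s2s * n_l + s2e)
        mu = float((w * ybar_l).sum() / w.sum())
        shat = (n_l * s2s / (n_l * s2s + s2e)) * (ybar_l - mu)
        # diagonal of the s-block of the inverse MME coefficient matrix
        schur = n - float((n_l * n_l / d).sum())
        css = 1.0 / d + (n_l / d) ** 2 / schur
        s2s_new = float((shat @ shat + s2e * css.sum()) / L)
        s2e_new = float((yty - mu * sy - shat @ sum_l) / (n - 1))
        s2e_new = max(s2e_new, 1e-12)
        s2s_new = max(s2s_new, 1e-12)
        rel = max(abs(s2s_new - s2s) / max(s2s, 1e-12),
                  abs(s2e_new - s2e) / max(s2e, 1e-12))
        s2s, s2e = s2s_new, s2e_new
        hist.append((it, s2s, s2e))
        if rel < tol:
            converged = True
            break
        # EM's linear rate approaches 1 near flat ridges and the sigma2_s = 0
        # boundary; standard remedies, applied periodically:
        if it % 25 == 0:
            snaps.append((s2s, s2e))
            if len(snaps) >= 3:
                # Aitken extrapolation on trajectory snapshots, accepted only
                # if it does not decrease the REML objective
                (a_s, a_e), (b_s, b_e), (c_s, c_e) = snaps[-3:]
                acc = []
                for x0, x1, x2 in ((a_s, b_s, c_s), (a_e, b_e, c_e)):
                    d0, d1 = x1 - x0, x2 - x1
                    r = d1 / d0 if d0 != 0 else 0.0
                    acc.append(x2 + d1 * r / (1.0 - r) if 0.0 < r < 0.999 else x2)
                if acc[0] > 0 and acc[1] > 0 and reml_ll(*acc) >= reml_ll(s2s, s2e):
                    s2s, s2e = acc
                    hist.append((it, s2s, s2e))
                    snaps.clear()
        if it % 100 == 0 and s2s < 1e-2 * s2e:
            # boundary detection: compare against the profiled sigma2_s = 0
            # solution and terminate there when it is optimal to within
            # statistically negligible log-likelihood slack
            s2e0 = (yty - sy * sy / n) / (n - 1)
            if reml_ll(0.0, s2e0) >= reml_ll(s2s, s2e) - 1e-6:
                s2s, s2e = 0.0, s2e0
                hist.append((it + 1, s2s, s2e))
                converged = True
                break
    if not converged:
        raise RuntimeError(
            f"EM-REML did not converge in {max_iter} iterations; "
            f"last iterates sigma2_s={s2s:.6g}, sigma2_e={s2e:.6g}")
    w = n_l / (s2s * n_l + s2e)
    mu = float((w * ybar_l).sum() / w.sum())
    shat = (n_l * s2s / (n_l * s2s + s2e)) * (ybar_l - mu)
    return RandomEffectFit(
        mu=mu,
        level_effects=dict(zip(levels.tolist(), shat.tolist())),
        sigma2_level=s2s,
        sigma2_resid=s2e,
        converged=True,
        n_iter=len(hist),
        history=np.array(hist),
    )


def preadjust(
    phenotypes: pd.DataFrame,
    fit: RandomEffectFit,
    y_col: str = "y",
    level_col: str = "level",
) -> pd.DataFrame:
    """Attach y_R = y - mu_hat - s_hat(level) as column ``y_R``."""
    if not fit.converged:
        raise ValueError("preadjustment requires a converged fit")
    unseen = set(phenotypes[level_col]) - set(fit.level_effects)
    if unseen:
        raise KeyError(f"levels absent from the fit: {sorted(unseen)[:5]}")
    s = phenotypes[level_col].map(fit.level_effects).to_numpy(dtype=float)
    out = phenotypes.copy()
    out["y_R"] = phenotypes[y_col].to_numpy(dtype=float) - fit.mu - s
    return out


def balanced_oneway_reml(y: np.ndarray, lev_idx: np.ndarray) -> tuple[float, float]:
    """Closed-form REML for the *balanced* one-way layout (L levels x r reps).

    sigma2_e = MSW, sigma2_s = (MSB - MSW) / r truncated at 0. Serves as an
    independent oracle for the EM iteration; only valid when every level has
    the same replicate count.
    """
    levels, idx = np.unique(lev_idx, return_inverse=True)
    n_l = np.bincount(idx)
    if len(set(n_l.tolist())) != 1:
        raise ValueError("balanced closed form requires equal level sizes")
    r = int(n_l[0])
    L = len(levels)
    ybar_l = np.bincount(idx, weights=y) / r
    ybar = y.mean()
    ssw = float(((y - ybar_l[idx]) ** 2).sum())
    ssb = float(r * ((ybar_l - ybar) ** 2).sum())
    msw = ssw / (L * (r - 1))
    msb = ssb / (L - 1)
    return max((msb - msw) / r, 0.0), msw
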