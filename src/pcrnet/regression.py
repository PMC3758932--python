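"""Moderation, mediation, and moderated-mediation with percentile bootstrap.

Three regression designs link symptom-frequency composites and PCR composites:

* **Moderation** — OLS of y on mean-centered x, w and their product; the
  interaction is judged by the Delta-R^2 F test and probed with simple slopes
  of x at chosen moderator values (default mean +/- 1 SD).
* **Mediation** — the indirect effect a*b from m ~ x and y ~ x + m, with a
  nonparametric case-resampling bootstrap percentile CI (the total effect
  decomposes exactly as c = c' + a*b in OLS with complete data).
* **Moderated mediation** — w moderates the x -> m path and v the m -> y
  path; conditional indirect effects (a1 + a3*w0)(b1 + b3*v0) are evaluated
  on a probe grid (default: 25th/50th/75th percentiles of each moderator)
  with bootstrap CIs sharing one set of resamples across cells.

Headline fits use statsmodels OLS; bootstrap inner loops are closed-form
normal-equation solves vectorized over resamples.  Missing data is handled
listwise per model.  CI level defaults to 95%; pass 0.9833 for the
Bonferroni-corrected variant used when three model families are tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

_MIN_CASES = 10


class CollinearityError(ValueError):
    """Singular design matrix; names the offending columns."""


def _complete(*arrays: Sequence[float]) -> list[np.ndarray]:
    cols = [np.asarray(a, dtype=float) for a in arrays]
    n = {len(c) for c in cols}
    if len(n) != 1:
        raise ValueError("all variables must have the same length")
    mask = np.ones(n.pop(), dtype=bool)
    for c in cols:
        mask &= np.isfinite(c)
    kept = [c[mask] for c in cols]
    if len(kept[0]) < _MIN_CASES:
        raise ValueError(
            f"need at least {_MIN_CASES} complete cases, got {len(kept[0])}"
        )
    return kept


def _check_design(X: np.ndarray, names: Sequence[str]) -> None:
    """Raise CollinearityError naming degenerate or collinear columns."""
    bad = [
        names[j]
        for j in range(X.shape[1])
        if names[j] != "const" and np.std(X[:, j]) == 0
    ]
    if bad:
        raise CollinearityError(f"constant column(s): {', '.join(bad)}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        centered = X - X.mean(axis=0)
        pairs = []
        for j in range(X.shape[1]):
            for k in range(j + 1, X.shape[1]):
                sj, sk = np.std(centered[:, j]), np.std(centered[:, k])
                if sj > 0 and sk > 0:
                    r = np.corrcoef(centered[:, j], centered[:, k])[0, 1]
                    if abs(r) > 1 - 1e-10:
                        pairs.append(f"{names[j]}~{names[k]}")
        detail = f" ({', '.join(pairs)})" if pairs else ""
        raise CollinearityError(f"singular design matrix{detail}")


# ---------------------------------------------------------------------------
# moderation
# ---------------------------------------------------------------------------

@dataclass
class SimpleSlope:
    """Slope of x on y at one moderator value (delta-method SE)."""

    probe: float  # moderator value, original scale
    slope: float
    se: float
    t: float
    p: float


@dataclass
class ModerationResult:
    coefficients: dict[str, float]  # b0 const, b1 x, b2 w, b3 x:w (centered)
    se: dict[str, float]
    n: int
    r2_full: float
    r2_reduced: float
    delta_r2: float
    f: float
    f_p: float
    df_denom: int
    simple_slopes: list[SimpleSlope]
    resid_sd: float
    x_mean: float
    x_sd: float
    w_mean: float
    w_sd: float
    level: float


def fit_moderation(
    x: Sequence[float],
    w: Sequence[float],
    y: Sequence[float],
    probes: Sequence[float] | None = None,
    level: float = 0.95,
) -> ModerationResult:
    """OLS moderation with the Delta-R^2 interaction test and simple slopes.

    x and w are mean-centered before forming the product, so the x coefficient
    is the slope at the moderator mean and probes at mean +/- 1 SD are
    directly interpretable.  Probe values are on the original moderator scale.
    """
    x, w, y = _complete(x, w, y)
    n = len(y)
    x_mean, w_mean = float(x.mean()), float(w.mean())
    x_sd = float(x.std(ddof=1))
    w_sd = float(w.std(ddof=1))
    xc, wc = x - x_mean, w - w_mean
    X_full = np.column_stack([np.ones(n), xc, wc, xc * wc])
    names = ["const", "x", "w", "x:w"]
    _check_design(X_full, names)

    full = sm.OLS(y, X_full).fit()
    reduced = sm.OLS(y, X_full[:, :3]).fit()
    delta_r2 = float(full.rsquared - reduced.rsquared)
    df_denom = n - 4
    f = (delta_r2 / 1.0) / ((1.0 - full.rsquared) / df_denom)
    f_p = float(stats.f.sf(f, 1, df_denom))

    cov = full.cov_params()
    b = full.params
    if probes is None:
        probes = [w_mean - w_sd, w_mean + w_sd]
    slopes = []
    for probe in probes:
        w0 = probe - w_mean
        slope = float(b[1] + b[3] * w0)
        var = cov[1, 1] + w0 * w0 * cov[3, 3] + 2 * w0 * cov[1, 3]
        se = float(np.sqrt(var))
        t = slope / se
        slopes.append(
            SimpleSlope(
                probe=float(probe),
                slope=slope,
                se=se,
                t=t,
                p=float(2 * stats.t.sf(abs(t), df_denom)),
            )
        )
    return ModerationResult(
        coefficients=dict(zip(names, map(float, b))),
        se=dict(zip(names, map(float, full.bse))),
        n=n,
        r2_full=float(full.rsquared),
        r2_reduced=float(reduced.rsquared),
        delta_r2=delta_r2,
        f=float(f),
        f_p=f_p,
        df_denom=df_denom,
        simple_slopes=slopes,
        resid_sd=float(np.sqrt(full.mse_resid)),
        x_mean=x_mean,
        x_sd=x_sd,
        w_mean=w_mean,
        w_sd=w_sd,
        level=level,
    )


def simple_slope_contrast_d(
    model: ModerationResult,
    x_probe: float | None = None,
    w_hi: float | None = None,
    w_lo: float | None = None,
) -> float:
    """Interaction-attributable group contrast in residual-SD units.

    At a fixed predictor value x_probe (default mean + 1 SD), the difference
    between model-implied outcomes at w_hi versus w_lo (defaults mean +/- 1
    SD) *net of the moderator's main effect* — i.e. the difference in
    differences against x at its mean — is b3 * (x_probe - x_mean) *
    (w_hi - w_lo); dividing by the residual SD gives a d-type effect size.
    Zero interaction gives d = 0 at any probe, and d is linear in b3.
    """
    if x_probe is None:
        x_probe = model.x_mean + model.x_sd
    if w_hi is None:
        w_hi = model.w_mean + model.w_sd
    if w_lo is None:
        w_lo = model.w_mean - model.w_sd
    b3 = model.coefficients["x:w"]
    return float(b3 * (x_probe - model.x_mean) * (w_hi - w_lo) / model.resid_sd)


# ---------------------------------------------------------------------------
# incremental regression
# ---------------------------------------------------------------------------

@dataclass
class IncrementalResult:
    delta_r2: float
    f: float
    p: float
    n: int
    r2_full: float
    r2_reduced: float


def incremental_regression(
    x: Sequence[float], z: Sequence[float], y: Sequence[float]
) -> IncrementalResult:
    """Does z increment the prediction of y beyond x?  Hierarchical OLS."""
    x, z, y = _complete(x, z, y)
    n = len(y)
    X_full = np.column_stack([np.ones(n), x, z])
    _check_design(X_full, ["const", "x", "z"])
    full = sm.OLS(y, X_full).fit()
    reduced = sm.OLS(y, X_full[:, :2]).fit()
    delta_r2 = float(full.rsquared - reduced.rsquared)
    df_denom = n - 3
    if full.rsquared >= 1.0 - 1e-14:
        f, p = float("inf"), 0.0
    else:
        f = (delta_r2 / 1.0) / ((1.0 - full.rsquared) / df_denom)
        p = float(stats.f.sf(f, 1, df_denom))
    return IncrementalResult(
        delta_r2=delta_r2,
        f=float(f),
        p=p,
        n=n,
        r2_full=float(full.rsquared),
        r2_reduced=float(reduced.rsquared),
    )


# ---------------------------------------------------------------------------
# mediation
# ---------------------------------------------------------------------------

def _percentile_ci(draws: np.ndarray, level: float) -> tuple[float, float]:
    lo = 100 * (1 - level) / 2
    return (
        float(np.percentile(draws, lo)),
        float(np.percentile(draws, 100 - lo)),
    )


def _boot_rows_two_reg(
    x: np.ndarray, m: np.ndarray, y: np.ndarray, idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-resample a, b, c' and a validity mask, via closed-form OLS sums."""
    xs, ms, ys = x[idx], m[idx], y[idx]
    xs = xs - xs.mean(axis=1, keepdims=True)
    ms_c = ms - ms.mean(axis=1, keepdims=True)
    ys_c = ys - ys.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", xs, xs)
    smm = np.einsum("ij,ij->i", ms_c, ms_c)
    sxm = np.einsum("ij,ij->i", xs, ms_c)
    sxy = np.einsum("ij,ij->i", xs, ys_c)
    smy = np.einsum("ij,ij->i", ms_c, ys_c)
    det = sxx * smm - sxm**2
    ok = (sxx > 0) & (det > 1e-12 * np.maximum(sxx * smm, 1e-300))
    with np.errstate(divide="ignore", invalid="ignore"):
        a = sxm / sxx
        c_prime = (smm * sxy - sxm * smy) / det
        b = (sxx * smy - sxm * sxy) / det
    return a, b, c_prime, ok


@dataclass
class MediationResult:
    a: float
    b: float
    c: float  # total effect, y ~ x
    c_prime: float  # direct effect, y ~ x + m
    indirect: float  # a * b
    indirect_se: float  # bootstrap SD
    indirect_ci: tuple[float, float]
    ratio: float  # indirect / direct
    ratio_se: float
    ratio_ci: tuple[float, float]
    proportion_mediated: float  # a*b / c
    proportion_mediated_alt: float  # a*b / (a*b + c')
    n: int
    n_boot: int
    level: float
    n_redrawn: int  # degenerate resamples replaced


def fit_mediation(
    x: Sequence[float],
    m: Sequence[float],
    y: Sequence[float],
    n_boot: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
) -> MediationResult:
    """Simple mediation with case-resampling percentile bootstrap.

    Zero-variance (degenerate) resamples are redrawn and counted; the same
    resamples feed the indirect effect and the indirect/direct ratio.
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    x, m, y = _complete(x, m, y)
    n = len(y)
    X2 = np.column_stack([np.ones(n), x, m])
    _check_design(X2, ["const", "x", "m"])
    fit_m = sm.OLS(m, np.column_stack([np.ones(n), x])).fit()
    fit_y = sm.OLS(y, X2).fit()
    fit_tot = sm.OLS(y, np.column_stack([np.ones(n), x])).fit()
    a, b, c_prime = float(fit_m.params[1]), float(fit_y.params[2]), float(fit_y.params[1])
    c = float(fit_tot.params[1])
    indirect = a * b

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    a_b, b_b, cp_b, ok = _boot_rows_two_reg(x, m, y, idx)
    n_redrawn = 0
    while not ok.all():
        bad = np.flatnonzero(~ok)
        n_redrawn += len(bad)
        idx[bad] = rng.integers(0, n, size=(len(bad), n))
        a2, b2, cp2, ok2 = _boot_rows_two_reg(x, m, y, idx[bad])
        a_b[bad], b_b[bad], cp_b[bad] = a2, b2, cp2
        ok[bad] = ok2
    if n_redrawn:
        logger.info("mediation bootstrap: redrew %d degenerate resamples", n_redrawn)

    ind_draws = a_b * b_b
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_draws = ind_draws / cp_b
    ratio_draws = ratio_draws[np.isfinite(ratio_draws)]
    if ratio_draws.size == 0:  # direct effect identically zero in every resample
        ratio_ci = (float("nan"), float("nan"))
    else:
        ratio_ci = _percentile_ci(ratio_draws, level)
    return MediationResult(
        a=a,
        b=b,
        c=c,
        c_prime=c_prime,
        indirect=indirect,
        indirect_se=float(ind_draws.std(ddof=1)),
        indirect_ci=_percentile_ci(ind_draws, level),
        ratio=indirect / c_prime if c_prime != 0 else float("nan"),
        ratio_se=float(ratio_draws.std(ddof=1)) if ratio_draws.size > 1 else float("nan"),
        ratio_ci=ratio_ci,
        proportion_mediated=indirect / c if c != 0 else float("nan"),
        proportion_mediated_alt=(
            indirect / (indirect + c_prime) if indirect + c_prime != 0 else float("nan")
        ),
        n=n,
        n_boot=n_boot,
        level=level,
        n_redrawn=n_redrawn,
    )


# ---------------------------------------------------------------------------
# moderated mediation
# ---------------------------------------------------------------------------

@dataclass
class ConditionalIndirect:
    """Indirect effect of x on y through m at one (w, v) probe cell."""

    w_probe: float  # original scale
    v_probe: float
    effect: float  # (a1 + a3*w0)(b1 + b3*v0)
    se: float
    ci: tuple[float, float]
    excludes_zero: bool


@dataclass
class ModeratedMediationResult:
    a_coefficients: dict[str, float]  # m ~ const + x + w + x:w (centered)
    a_se: dict[str, float]
    y_coefficients: dict[str, float]  # y ~ const + x + m + v + m:v (centered)
    y_se: dict[str, float]
    conditional: list[ConditionalIndirect]
    n: int
    n_boot: int
    level: float
    n_redrawn: int
    dropped_w: bool  # moderator had zero variance; its columns were dropped
    dropped_v: bool
    pcr_interaction_variant: dict[str, float] = field(default_factory=dict)


def _batched_ols(X: np.ndarray, Y: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients for Y ~ X per bootstrap row; returns (betas, ok mask)."""
    n_boot = idx.shape[0]
    p = X.shape[1]
    betas = np.empty((n_boot, p))
    ok = np.ones(n_boot, dtype=bool)
    chunk = max(1, 2_000_000 // (idx.shape[1] * p))
    for start in range(0, n_boot, chunk):
        sl = slice(start, min(start + chunk, n_boot))
        Xb = X[idx[sl]]  # (B, n, p)
        Yb = Y[idx[sl]]  # (B, n)
        G = np.einsum("bij,bik->bjk", Xb, Xb)
        h = np.einsum("bij,bi->bj", Xb, Yb)
        dets = np.linalg.det(G)
        good = np.abs(dets) > 1e-10
        sol = np.full((Xb.shape[0], p), np.nan)
        if good.any():
            sol[good] = np.linalg.solve(G[good], h[good][..., None])[..., 0]
        betas[sl] = sol
        ok[sl] = good
    return betas, ok


def fit_moderated_mediation(
    x: Sequence[float],
    w: Sequence[float],
    m: Sequence[float],
    v: Sequence[float],
    y: Sequence[float],
    n_boot: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
    probes: tuple[Sequence[float], Sequence[float]] | None = None,
) -> ModeratedMediationResult:
    """First- and second-stage moderated mediation with a shared bootstrap.

    w moderates x -> m and v moderates m -> y.  A zero-variance moderator is
    dropped (with a flag) so the model degrades gracefully to plain mediation.
    Probe cells default to the 25th/50th/75th percentiles of each moderator;
    every cell's CI comes from the same resamples.  A secondary, clearly
    labeled variant of the y-model adds w*v and m*(w*v) terms, exposing the
    coefficient of the moderator-product interaction.
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    x, w, m, v, y = _complete(x, w, m, v, y)
    n = len(y)
    means = {k: float(arr.mean()) for k, arr in zip("xwmv", (x, w, m, v))}
    xc, wc, mc, vc = (arr - arr.mean() for arr in (x, w, m, v))
    dropped_w = float(np.std(wc)) == 0.0
    dropped_v = float(np.std(vc)) == 0.0

    a_cols, a_names = [np.ones(n), xc], ["const", "x"]
    if not dropped_w:
        a_cols += [wc, xc * wc]
        a_names += ["w", "x:w"]
    Xa = np.column_stack(a_cols)
    _check_design(Xa, a_names)

    y_cols, y_names = [np.ones(n), xc, mc], ["const", "x", "m"]
    if not dropped_v:
        y_cols += [vc, mc * vc]
        y_names += ["v", "m:v"]
    Xy = np.column_stack(y_cols)
    _check_design(Xy, y_names)

    fit_a = sm.OLS(m, Xa).fit()
    fit_y = sm.OLS(y, Xy).fit()
    a_coef = dict(zip(a_names, map(float, fit_a.params)))
    y_coef = dict(zip(y_names, map(float, fit_y.params)))

    if probes is None:
        w_probes = [means["w"]] if dropped_w else list(np.percentile(w, [25, 50, 75]))
        v_probes = [means["v"]] if dropped_v else list(np.percentile(v, [25, 50, 75]))
    else:
        w_probes, v_probes = list(probes[0]), list(probes[1])

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    betas_a, ok_a = _batched_ols(Xa, m, idx)
    betas_y, ok_y = _batched_ols(Xy, y, idx)
    ok = ok_a & ok_y
    n_redrawn = 0
    while not ok.all():
        bad = np.flatnonzero(~ok)
        n_redrawn += len(bad)
        idx[bad] = rng.integers(0, n, size=(len(bad), n))
        ba, oa = _batched_ols(Xa, m, idx[bad])
        by, oy = _batched_ols(Xy, y, idx[bad])
        betas_a[bad], betas_y[bad] = ba, by
        ok[bad] = oa & oy
    if n_redrawn:
        logger.info("moderated-mediation bootstrap: redrew %d resamples", n_redrawn)

    ia1 = a_names.index("x")
    ia3 = a_names.index("x:w") if "x:w" in a_names else None
    ib1 = y_names.index("m")
    ib3 = y_names.index("m:v") if "m:v" in y_names else None

    def conditional_draws(betas_a_, betas_y_, w0c, v0c):
        a_path = betas_a_[:, ia1] + (betas_a_[:, ia3] * w0c if ia3 is not None else 0.0)
        b_path = betas_y_[:, ib1] + (betas_y_[:, ib3] * v0c if ib3 is not None else 0.0)
        return a_path * b_path

    cells = []
    for w0 in w_probes:
        for v0 in v_probes:
            w0c, v0c = w0 - means["w"], v0 - means["v"]
            a_pt = a_coef["x"] + (a_coef.get("x:w", 0.0) * w0c)
            b_pt = y_coef["m"] + (y_coef.get("m:v", 0.0) * v0c)
            draws = conditional_draws(betas_a, betas_y, w0c, v0c)
            ci = _percentile_ci(draws, level)
            cells.append(
                ConditionalIndirect(
                    w_probe=float(w0),
                    v_probe=float(v0),
                    effect=float(a_pt * b_pt),
                    se=float(draws.std(ddof=1)),
                    ci=ci,
                    excludes_zero=not (ci[0] <= 0.0 <= ci[1]),
                )
            )

    # documented variant: the y-model augmented with w*v and m*(w*v), whose
    # m:(w:v) coefficient mirrors a reported moderator-product interaction
    variant: dict[str, float] = {}
    if not dropped_w and not dropped_v:
        wv = wc * vc
        Xv = np.column_stack([Xy, wv, mc * wv])
        v_names = y_names + ["w:v", "m:w:v"]
        if np.linalg.matrix_rank(Xv) == Xv.shape[1]:
            fit_v = sm.OLS(y, Xv).fit()
            j = v_names.index("m:w:v")
            t_stat = float(fit_v.tvalues[j])
            variant = {
                "b": float(fit_v.params[j]),
                "se": float(fit_v.bse[j]),
                "t": t_stat,
                "p": float(fit_v.pvalues[j]),
                "df": int(fit_v.df_resid),
            }

    return ModeratedMediationResult(
        a_coefficients=a_coef,
        a_se=dict(zip(a_names, map(float, fit_a.bse))),
        y_coefficients=y_coef,
        y_se=dict(zip(y_names, map(float, fit_y.bse))),
        conditional=cells,
        n=n,
        n_boot=n_boot,
        level=level,
        n_redrawn=n_redrawn,
        dropped_w=dropped_w,
        dropped_v=dropped_v,
        pcr_interaction_variant=variant,
    )
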