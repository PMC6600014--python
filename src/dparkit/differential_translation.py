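"""Negative-binomial GLM engine for the diet x fraction contrasts.

Each gene's counts over the 16-sample design (2 diets x 2 fractions x 4
replicates) are modelled as NB(mu, phi) with log link,

    log mu = beta0 + beta1*[diet=DR] + beta2*[fraction=TR]
             + beta3*[diet=DR][fraction=TR] + log(effective library size),

so the interaction coefficient beta3 is the DPAR — the log ratio of
(TR/TO under DR) to (TR/TO under AL).  Dispersion is estimated by
maximising the Cox-Reid adjusted profile likelihood (APL), first pooled
across genes (common phi) and then per gene with empirical-Bayes shrinkage
towards the common curve.  Contrasts are tested by likelihood-ratio tests
(refit under the single-df constraint, chi-square with 1 df), with BH
correction within each contrast family.

All fitting is vectorised across genes (stacked IRLS), which keeps a
10,000-gene analysis in seconds on one core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import null_space
from scipy.special import gammaln

from .counts_pipeline import CountMatrix, SampleDesign, cpm_matrix, tmm_factors
from .stats_core import bh_fdr

__all__ = [
    "DispersionEstimates",
    "build_design_matrix",
    "contrast_vector",
    "estimate_dispersions",
    "fit_nb_glm",
    "test_contrast",
    "run_dpar_analysis",
    "classify_regulation",
    "significant_set",
]

CONTRASTS = {
    # coefficients: [intercept, diet_DR, fraction_TR, diet_DR:fraction_TR]
    "transcription": np.array([0.0, 1.0, 0.0, 0.0]),
    "translation_AL": np.array([0.0, 0.0, 1.0, 0.0]),
    "translation_DR": np.array([0.0, 0.0, 1.0, 1.0]),
    "dpar": np.array([0.0, 0.0, 0.0, 1.0]),
}

_ETA_CLIP = 50.0
_MU_FLOOR = 1e-10


@dataclass
class DispersionEstimates:
    """Common and tagwise (per-gene) NB dispersions.

    ``prior_df`` controls how strongly tagwise values shrink towards the
    common APL curve (prior degrees of freedom of the shared likelihood).
    """

    common: float
    tagwise: pd.Series
    prior_df: float

    def __post_init__(self) -> None:
        if self.common < 0 or (self.tagwise < 0).any():
            raise ValueError("dispersions must be nonnegative")
        if not np.isfinite(self.tagwise).all():
            raise ValueError("tagwise dispersions must be finite")


def build_design_matrix(design: SampleDesign) -> pd.DataFrame:
    """Full-rank treatment-coded design matrix, samples in design order."""
    t = design.table
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "diet_DR": (t["diet"] == "DR").astype(float).values,
            "fraction_TR": (t["fraction"] == "TR").astype(float).values,
            "diet_DR:fraction_TR": (
                (t["diet"] == "DR") & (t["fraction"] == "TR")
            ).astype(float).values,
        },
        index=t["sample"].values,
    )
    if np.linalg.matrix_rank(X.values) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X


def contrast_vector(name_or_vec) -> np.ndarray:
    if isinstance(name_or_vec, str):
        try:
            return CONTRASTS[name_or_vec].copy()
        except KeyError:
            raise ValueError(f"unknown contrast {name_or_vec!r}") from None
    c = np.asarray(name_or_vec, dtype=float)
    if c.shape != (4,):
        raise ValueError("contrast vector must have length 4")
    return c


# ----------------------------------------------------------------------
# vectorised NB IRLS


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB log-likelihood summed over samples; phi broadcastable (G,1)."""
    mu = np.maximum(mu, _MU_FLOOR)
    out = np.empty(y.shape[0])
    phi = np.broadcast_to(phi, (y.shape[0], 1))
    pois = (phi[:, 0] <= 0)
    if pois.any():
        yp, mp = y[pois], mu[pois]
        out[pois] = np.sum(yp * np.log(mp) - mp - gammaln(yp + 1), axis=1)
    nb = ~pois
    if nb.any():
        r = 1.0 / phi[nb]
        yn, mn = y[nb], mu[nb]
        out[nb] = np.sum(
            gammaln(yn + r) - gammaln(r) - gammaln(yn + 1)
            + r * np.log(r / (r + mn)) + yn * np.log(mn / (r + mn)),
            axis=1,
        )
    return out


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    mu = np.maximum(mu, _MU_FLOOR)
    phi = np.broadcast_to(phi, (y.shape[0], 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(np.maximum(y, _MU_FLOOR) / mu), 0.0)
        pois_part = 2.0 * (ylogy - (y - mu))
        nb_part = 2.0 * (
            ylogy - (y + 1.0 / np.maximum(phi, _MU_FLOOR))
            * np.log((1.0 + phi * y) / (1.0 + phi * mu))
        )
    dev = np.where(phi <= 0, pois_part, nb_part)
    return dev.sum(axis=1)


def _irls(
    y: np.ndarray,
    X: np.ndarray,
    phi: np.ndarray,
    offset: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
):
    """Stacked IRLS fit of the NB log-link GLM for all genes at once.

    Returns (beta (G,P), mu (G,S), deviance (G,), converged (G,),
    XtWX (G,P,P) at the final iterate).
    """
    G, S = y.shape
    P = X.shape[1]
    phi = np.asarray(phi, dtype=float).reshape(-1, 1)
    if phi.shape[0] == 1:
        phi = np.broadcast_to(phi, (G, 1)).copy()
    off = np.broadcast_to(offset, (G, S))

    # initialise from a log-linear least-squares fit on shifted counts
    z0 = np.log(np.maximum(y, 0.5)) - off
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T  # (G, P)

    eta = np.clip(beta @ X.T + off, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    dev = _nb_deviance(y, mu, phi)
    converged = np.zeros(G, dtype=bool)
    XtWX = np.empty((G, P, P))

    for _ in range(max_iter):
        w = mu / (1.0 + phi * mu)
        z = (eta - off) + (y - mu) / np.maximum(mu, _MU_FLOOR)
        XtWX = np.einsum("sp,gs,sq->gpq", X, w, X, optimize=True)
        XtWz = np.einsum("sp,gs,gs->gp", X, w, z, optimize=True)
        # ridge-stabilise near-singular systems (all-zero cells)
        XtWX_s = XtWX + 1e-10 * np.eye(P)
        beta_new = np.linalg.solve(XtWX_s, XtWz[..., None])[..., 0]
        eta = np.clip(beta_new @ X.T + off, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        dev_new = _nb_deviance(y, mu, phi)
        rel = np.abs(dev_new - dev) / (np.abs(dev) + 1.0)
        newly = rel < tol
        beta = beta_new
        dev = dev_new
        converged = newly
        if newly.all():
            break

    w = mu / (1.0 + phi * mu)
    XtWX = np.einsum("sp,gs,sq->gpq", X, w, X, optimize=True)
    return beta, mu, dev, converged, XtWX


def fit_nb_glm(counts_g, design_matrix, phi: float, offsets):
    """Fit one gene's NB GLM; convenience wrapper over the stacked fitter.

    Returns a dict with natural-log-scale ``coef``, ``deviance``,
    ``converged`` and fitted ``mu``.  All-zero genes are rejected;
    non-convergence is flagged, not raised.
    """
    y = np.asarray(counts_g, dtype=float).reshape(1, -1)
    if y.sum() == 0:
        raise ValueError("all-zero gene cannot be fit")
    X = np.asarray(design_matrix, dtype=float)
    beta, mu, dev, conv, _ = _irls(y, X, np.array([phi]), np.asarray(offsets, dtype=float))
    return {
        "coef": beta[0],
        "deviance": float(dev[0]),
        "converged": bool(conv[0]),
        "mu": mu[0],
    }


# ----------------------------------------------------------------------
# dispersion estimation (Cox-Reid adjusted profile likelihood)


def _apl_matrix(y, X, offset, grid):
    """APL(g, phi) over a dispersion grid: loglik - 0.5 logdet(X'WX)."""
    G = y.shape[0]
    apl = np.empty((G, grid.size))
    for j, phi in enumerate(grid):
        phi_arr = np.full(G, phi)
        beta, mu, dev, conv, XtWX = _irls(y, X, phi_arr, offset, max_iter=30, tol=1e-6)
        ll = _nb_loglik(y, mu, phi_arr.reshape(-1, 1))
        sign, logdet = np.linalg.slogdet(XtWX + 1e-10 * np.eye(X.shape[1]))
        apl[:, j] = ll - 0.5 * logdet
    return apl


def _argmax_interp(xlog: np.ndarray, yvals: np.ndarray) -> float:
    """Quadratic-interpolated argmax of a curve sampled on a log grid."""
    i = int(np.argmax(yvals))
    if i == 0 or i == len(xlog) - 1:
        return float(np.exp(xlog[i]))
    x0, x1, x2 = xlog[i - 1], xlog[i], xlog[i + 1]
    y0, y1, y2 = yvals[i - 1], yvals[i], yvals[i + 1]
    denom = (y0 - y1) * (x1 - x2) - (y1 - y2) * (x0 - x1)
    if denom == 0:
        return float(np.exp(x1))
    xs = x1 - 0.5 * ((x1 - x0) ** 2 * (y1 - y2) - (x1 - x2) ** 2 * (y1 - y0)) / (
        (x1 - x0) * (y1 - y2) - (x1 - x2) * (y1 - y0)
    )
    xs = float(np.clip(xs, x0, x2))
    return float(np.exp(xs))


def estimate_dispersions(
    cm: CountMatrix,
    factors: pd.Series | None = None,
    prior_df: float = 10.0,
    grid: np.ndarray | None = None,
) -> DispersionEstimates:
    """Common and tagwise NB dispersions by Cox-Reid APL maximisation.

    The common dispersion maximises the mean APL across genes; tagwise
    values maximise ``APL_g + prior_n * mean-APL`` where
    ``prior_n = prior_df / residual df``, shrinking noisy per-gene
    estimates towards the shared curve.
    """
    X = build_design_matrix(cm.design)
    if grid is None:
        grid = np.logspace(-4, np.log10(3.0), 25)
    y = cm.counts.values.astype(float)
    if (y.sum(axis=1) == 0).any():
        raise ValueError("remove all-zero genes before dispersion estimation")
    lib = cm.library_sizes.astype(float)
    if factors is not None:
        lib = lib * factors[cm.counts.columns]
    offset = np.log(lib.values)

    apl = _apl_matrix(y, X.values, offset, grid)
    xlog = np.log(grid)
    mean_apl = apl.mean(axis=0)
    common = _argmax_interp(xlog, mean_apl)

    df_res = y.shape[1] - X.shape[1]
    prior_n = prior_df / max(df_res, 1)
    obj = apl + prior_n * mean_apl[None, :]
    tagwise = np.array([_argmax_interp(xlog, obj[g]) for g in range(y.shape[0])])
    return DispersionEstimates(
        common=common,
        tagwise=pd.Series(tagwise, index=cm.genes),
        prior_df=prior_df,
    )


# ----------------------------------------------------------------------
# contrast testing


def test_contrast(
    cm: CountMatrix,
    dispersions: DispersionEstimates | float,
    contrast,
    factors: pd.Series | None = None,
    label: str | None = None,
) -> pd.DataFrame:
    """Likelihood-ratio test of a single-df contrast for every gene.

    The full interaction model is fit per gene, then refit with the
    contrast constrained to zero; the deviance difference is referred to
    chi-square(1).  Output columns: logFC (log2 scale), logCPM, PValue,
    FDR, converged.
    """
    c = contrast_vector(contrast)
    if label is None:
        label = contrast if isinstance(contrast, str) else "custom"
    X = build_design_matrix(cm.design)
    # reduced design spans the null space of the contrast
    N = null_space(c[None, :])
    X_red = X.values @ N
    if np.linalg.matrix_rank(X_red) != X.shape[1] - 1:
        raise ValueError("contrast is not in the span of the design")

    y = cm.counts.values.astype(float)
    nonzero = y.sum(axis=1) > 0
    lib = cm.library_sizes.astype(float)
    if factors is not None:
        lib = lib * factors[cm.counts.columns]
    offset = np.log(lib.values)

    if isinstance(dispersions, DispersionEstimates):
        phi = dispersions.tagwise.reindex(cm.genes).values
    else:
        phi = np.full(y.shape[0], float(dispersions))

    yf = y[nonzero]
    phif = phi[nonzero]
    beta, mu, dev_full, conv_full, _ = _irls(yf, X.values, phif, offset)
    _, _, dev_red, conv_red, _ = _irls(yf, X_red, phif, offset)

    lr = np.maximum(dev_red - dev_full, 0.0)
    p = stats.chi2.sf(lr, df=1)
    logfc = (beta @ c) / np.log(2.0)
    log_cpm = np.log2(cpm_matrix(cm.counts, factors=factors) + 0.25).mean(axis=1)

    out = pd.DataFrame(
        {
            "contrast": label,
            "logFC": np.nan,
            "logCPM": log_cpm,
            "PValue": np.nan,
            "FDR": np.nan,
            "converged": False,
        },
        index=cm.genes,
    )
    idx = cm.genes[nonzero]
    out.loc[idx, "logFC"] = logfc
    out.loc[idx, "PValue"] = p
    out.loc[idx, "converged"] = conv_full & conv_red
    out.loc[idx, "FDR"] = bh_fdr(p)
    return out


def run_dpar_analysis(
    cm: CountMatrix,
    dispersions: DispersionEstimates | float | None = None,
    factors: pd.Series | None = None,
    contrasts: tuple[str, ...] = ("transcription", "translation_AL", "translation_DR", "dpar"),
) -> dict[str, pd.DataFrame]:
    """Convenience driver: TMM factors, dispersion, all standard contrasts."""
    if factors is None:
        factors = tmm_factors(cm.counts)
    if dispersions is None:
        dispersions = estimate_dispersions(cm, factors=factors)
    return {
        name: test_contrast(cm, dispersions, name, factors=factors) for name in contrasts
    }


def significant_set(
    result: pd.DataFrame, lfc: float = 1.0, fdr: float = 0.05, direction: str | None = None
) -> pd.Index:
    """Genes passing |log2FC| >= lfc and FDR < fdr (optionally one direction)."""
    m = (result["FDR"] < fdr) & result["logFC"].abs().ge(lfc) & result["converged"]
    if direction == "up":
        m &= result["logFC"] > 0
    elif direction == "down":
        m &= result["logFC"] < 0
    elif direction is not None:
        raise ValueError("direction must be 'up', 'down' or None")
    return result.index[m]


def classify_regulation(
    transcriptional: pd.DataFrame,
    dpar: pd.DataFrame,
    lfc: float = 1.0,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Cross-classify DPAR-regulated genes by their transcriptional status.

    DPAR class: promoted / repressed / unchanged at |log2FC| >= lfc and
    FDR < fdr.  For promoted/repressed genes the transcriptional change is
    labelled same-direction, opposite, or not significant under the same
    thresholds.
    """
    if not transcriptional.index.equals(dpar.index):
        raise ValueError("gene universes of the two tables differ")
    dpar_sig = (dpar["FDR"] < fdr) & dpar["logFC"].abs().ge(lfc) & dpar["converged"]
    dpar_class = pd.Series("unchanged", index=dpar.index)
    dpar_class[dpar_sig & (dpar["logFC"] > 0)] = "promoted"
    dpar_class[dpar_sig & (dpar["logFC"] < 0)] = "repressed"

    tx_sig = (
        (transcriptional["FDR"] < fdr)
        & transcriptional["logFC"].abs().ge(lfc)
        & transcriptional["converged"]
    )
    tx_dir = np.sign(transcriptional["logFC"])

    status = pd.Series("", index=dpar.index)
    regulated = dpar_class != "unchanged"
    dpar_dir = np.sign(dpar["logFC"])
    same = regulated & tx_sig & (tx_dir == dpar_dir)
    opp = regulated & tx_sig & (tx_dir == -dpar_dir)
    ns = regulated & ~tx_sig
    status[same] = "same_direction"
    status[opp] = "opposite"
    status[ns] = "not_significant"

    return pd.DataFrame(
        {
            "dpar_class": dpar_class,
            "dpar_logFC": dpar["logFC"],
            "transcription_logFC": transcriptional["logFC"],
            "transcription_status": status,
        }
    )
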