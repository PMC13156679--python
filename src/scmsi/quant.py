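"""Per-cell feature matrices, empirical-Bayes batch correction, scaling, PCA.

The batch model is the parametric ComBat location/scale model: after
standardizing log intensities per feature (preserving covariate effects),
per-batch location shifts get a normal prior and per-batch scale factors
an inverse-gamma prior, with method-of-moments hyperparameters and
iterated posterior (EB) estimates; corrected data are back-transformed
with covariates restored.  Batches are matrix-application pairs
(``pair_id``); treatment is protected as a covariate by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import PeakTable, mean_spectrum
from .segment import CellAssignment, DISPERSED, COHESIVE

logger = logging.getLogger(__name__)

__all__ = [
    "CellFeatureMatrix",
    "CombatModel",
    "extract_units",
    "combat_correct",
    "zscore_scale",
    "pca_embed",
]


@dataclass
class CellFeatureMatrix:
    """Observational units (cells / pooled regions / samples) x lipid features.

    ``values`` rows are units, columns m/z-labeled features; ``obs``
    carries sample_id, treatment, pair_id (matrix-application batch) and
    organization per row.
    """

    values: pd.DataFrame
    obs: pd.DataFrame
    scaled: bool = False

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("missing values in feature matrix")
        if not self.values.index.equals(self.obs.index):
            raise ValueError("values and obs must share an index")
        if self.values.columns.duplicated().any():
            raise ValueError("feature labels must be unique")

    @property
    def n_units(self) -> int:
        return len(self.values)

    def to_tsv(self, path, annotations_path=None) -> None:
        self.values.to_csv(path, sep="\t")
        if annotations_path is not None:
            self.obs.to_csv(annotations_path, sep="\t")


@dataclass
class CombatModel:
    """Fitted parameters of the parametric EB batch model."""

    alpha_hat: np.ndarray  # per-feature grand mean (standardization)
    beta_hat: np.ndarray  # covariate effects (n_cov x features)
    sigma_hat: np.ndarray  # per-feature pooled SD
    gamma_star: np.ndarray  # batches x features EB location adjustments
    delta_star: np.ndarray  # batches x features EB scale adjustments (SD ratio)
    gamma_bar: np.ndarray
    tau2: np.ndarray
    a_prior: np.ndarray
    b_prior: np.ndarray
    batches: list
    log_eps: float


def extract_units(
    pt: PeakTable,
    ca: CellAssignment,
    feature_idx: np.ndarray,
    mode: str = "single_cell",
    sample_id: str | None = None,
    treatment: str = "CTR",
    pair_id: str = "P1",
) -> CellFeatureMatrix:
    """Mean spectra per observational unit, restricted to cell-specific features.

    ``sample_mean``: one row per sample over all cell pixels.
    ``organization_mean``: up to two rows per sample (cohesive and
    dispersed pools; an empty pool is omitted with a warning).
    ``single_cell``: one row per dispersed cell id.
    """
    sid = sample_id or ca.sample_id
    feature_idx = np.asarray(feature_idx)
    cols = [f"mz_{m:.4f}" for m in pt.features[feature_idx]]
    coord_to_row = {tuple(c): i for i, c in enumerate(pt.coords)}

    def pixel_rows(mask2d: np.ndarray) -> np.ndarray:
        rr, cc = np.nonzero(mask2d)
        return np.array([coord_to_row[(r, c)] for r, c in zip(rr, cc) if (r, c) in coord_to_row])

    recs, names, orgs = [], [], []
    if mode == "sample_mean":
        idx = pixel_rows(ca.is_cell)
        recs.append(mean_spectrum(pt, idx)[feature_idx])
        names.append(sid)
        orgs.append("all")
    elif mode == "organization_mean":
        for org in (COHESIVE, DISPERSED):
            sel = ca.organization == org
            if not sel.any():
                warnings.warn(f"sample {sid}: no {org} pixels, pool omitted")
                logger.warning("sample %s: no %s pixels, pool omitted", sid, org)
                continue
            recs.append(mean_spectrum(pt, pixel_rows(sel))[feature_idx])
            names.append(f"{sid}_{org}")
            orgs.append(org)
    elif mode == "single_cell":
        for cid in np.unique(ca.cell_id[ca.cell_id > 0]):
            sel = (ca.cell_id == cid) & (ca.organization == DISPERSED)
            if not sel.any():
                continue
            recs.append(mean_spectrum(pt, pixel_rows(sel))[feature_idx])
            names.append(f"{sid}_cell{int(cid)}")
            orgs.append(DISPERSED)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not recs:
        raise ValueError(f"sample {sid}: no units extracted in mode {mode!r}")
    values = pd.DataFrame(np.vstack(recs), index=names, columns=cols)
    obs = pd.DataFrame(
        {
            "sample_id": sid,
            "treatment": treatment,
            "pair_id": pair_id,
            "organization": orgs,
        },
        index=names,
    )
    return CellFeatureMatrix(values=values, obs=obs)


# ---------------------------------------------------------------------------
# ComBat


def _design_matrix(obs: pd.DataFrame, batch_key: str, covariate_keys) -> tuple[np.ndarray, np.ndarray, list]:
    batches = list(pd.unique(obs[batch_key]))
    B = np.stack([(obs[batch_key] == b).to_numpy(float) for b in batches], axis=1)
    cov_cols = []
    for key in covariate_keys:
        levels = list(pd.unique(obs[key]))
        for lev in levels[1:]:  # drop first level (absorbed in batch means)
            cov_cols.append((obs[key] == lev).to_numpy(float))
    C = np.stack(cov_cols, axis=1) if cov_cols else np.empty((len(obs), 0))
    return B, C, batches


def combat_correct(
    m: CellFeatureMatrix,
    batch_key: str = "pair_id",
    covariate_keys: tuple[str, ...] = ("treatment",),
    log_transform: bool = True,
    conv: float = 1e-6,
    max_iter: int = 500,
) -> tuple[CellFeatureMatrix, CombatModel | None]:
    """Parametric empirical-Bayes batch correction (ComBat model).

    Operates on log(x + eps) with eps = half the smallest positive value
    in the matrix; covariate (treatment) effects are estimated jointly,
    held out of the standardized data, and restored on back-transform.
    With a single batch the input is returned unchanged.  A batch with a
    single unit gets a location-only correction (scale left at 1) with a
    warning.
    """
    obs = m.obs
    X = m.values.to_numpy(float)
    B, C, batches = _design_matrix(obs, batch_key, covariate_keys)
    n, g = X.shape
    n_batch = len(batches)
    if n_batch == 1:
        return replace(m, values=m.values.copy()), None
    n_per_batch = B.sum(axis=0)
    if (n_per_batch < 1).any():
        raise ValueError("every batch needs at least one unit")

    if log_transform:
        pos = X[X > 0]
        eps = 0.5 * float(pos.min()) if pos.size else 1e-12
        Y = np.log(X + eps)
    else:
        eps = 0.0
        Y = X.copy()

    D = np.hstack([B, C])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("confounded design: batch and covariates are collinear")
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    batch_eff = beta[:n_batch]  # per-batch intercepts
    cov_eff = beta[n_batch:]
    alpha = (n_per_batch / n) @ batch_eff  # grand mean, batch-size weighted
    fitted = D @ beta
    sigma2 = ((Y - fitted) ** 2).sum(axis=0) / n  # pooled, divide by n
    sigma = np.sqrt(np.maximum(sigma2, 1e-300))

    stand = (Y - alpha[None, :] - C @ cov_eff) / sigma[None, :]

    gamma_hat = np.stack([stand[B[:, i] > 0].mean(axis=0) for i in range(n_batch)])
    delta_hat = np.ones((n_batch, g))
    single = np.zeros(n_batch, dtype=bool)
    for i in range(n_batch):
        sel = B[:, i] > 0
        if sel.sum() >= 2:
            delta_hat[i] = stand[sel].var(axis=0, ddof=1)
        else:
            single[i] = True
            warnings.warn(
                f"batch {batches[i]!r} has a single unit: location-only correction"
            )

    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    # inverse-gamma method-of-moments hyperparameters
    m_d = delta_hat.mean(axis=1)
    s2_d = delta_hat.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_prior = (2 * s2_d + m_d**2) / s2_d
        b_prior = (m_d * s2_d + m_d**3) / s2_d

    gamma_star = gamma_hat.copy()
    delta_star = delta_hat.copy()
    for i in range(n_batch):
        if single[i]:
            gamma_star[i] = (
                gamma_hat[i] if not np.isfinite(tau2[i]) or tau2[i] == 0 else gamma_hat[i]
            )
            delta_star[i] = 1.0
            continue
        ni = n_per_batch[i]
        sel = B[:, i] > 0
        g_new = gamma_hat[i].copy()
        d_new = delta_hat[i].copy()
        for _ in range(max_iter):
            g_old, d_old = g_new, d_new
            g_new = (ni * tau2[i] * gamma_hat[i] + d_old * gamma_bar[i]) / (
                ni * tau2[i] + d_old
            )
            ssq = ((stand[sel] - g_new[None, :]) ** 2).sum(axis=0)
            d_new = (b_prior[i] + 0.5 * ssq) / (ni / 2.0 + a_prior[i] - 1.0)
            if max(np.abs(g_new - g_old).max(), np.abs(d_new - d_old).max()) < conv:
                break
        gamma_star[i] = g_new
        delta_star[i] = d_new

    adj = stand.copy()
    for i in range(n_batch):
        sel = B[:, i] > 0
        adj[sel] = (stand[sel] - gamma_star[i][None, :]) / np.sqrt(delta_star[i])[None, :]
    Y_adj = adj * sigma[None, :] + alpha[None, :] + C @ cov_eff
    X_adj = np.maximum(np.exp(Y_adj) - eps, 0.0) if log_transform else Y_adj

    model = CombatModel(
        alpha_hat=alpha,
        beta_hat=cov_eff,
        sigma_hat=sigma,
        gamma_star=gamma_star,
        delta_star=np.sqrt(delta_star),
        gamma_bar=gamma_bar,
        tau2=tau2,
        a_prior=a_prior,
        b_prior=b_prior,
        batches=batches,
        log_eps=eps,
    )
    out = replace(m, values=pd.DataFrame(X_adj, index=m.values.index, columns=m.values.columns))
    return out, model


# ---------------------------------------------------------------------------


def zscore_scale(m: CellFeatureMatrix) -> CellFeatureMatrix:
    """Scale each feature to mean 0, SD 1 (ddof=1); zero-SD features dropped."""
    if m.n_units < 2:
        raise ValueError("need >= 2 units to scale")
    X = m.values.to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance features")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    return replace(
        m,
        values=pd.DataFrame(Z, index=m.values.index, columns=m.values.columns[keep]),
        scaled=True,
    )


def pca_embed(m: CellFeatureMatrix, n_components: int = 10):
    """PCA scores and explained variance with deterministic orientation.

    Each component's sign is fixed so its largest-magnitude loading is
    positive.  Returns ``(scores, explained_variance_ratio, loadings)``.
    """
    from sklearn.decomposition import PCA

    X = m.values.to_numpy(float)
    max_nc = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_nc:
        raise ValueError(f"n_components must be <= {max_nc}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_
    flip = np.sign(loadings[np.arange(n_components), np.abs(loadings).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return scores * flip, pca.explained_variance_ratio_, loadings * flip[:, None]
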