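"""Used-habitat-calibration (UHC) validation of step-selection fits.

A UHC plot compares, per covariate, the distribution of values at the
actually chosen endpoints of held-out strata against the envelope of
distributions predicted by the fitted model: for each resample a
coefficient vector beta* is drawn from N(beta_hat, V_hat), one endpoint
per test stratum is sampled with probability proportional to
exp(beta* . x), and the covariate density of those "predicted used"
endpoints is accumulated.  A well-calibrated model keeps the observed
density inside the pointwise 2.5-97.5% envelope; a model missing a
selected covariate lets the observed density escape it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import ModelFit, _stratum_structure

GRID_SIZE_DEFAULT = 100


@dataclass
class UHCResult:
    predictor: str
    grid: np.ndarray
    observed: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    coverage: float
    is_binary: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"grid": self.grid, "observed": self.observed,
                             "lo": self.lo, "hi": self.hi})


def _silverman_bw(x):
    n = x.size
    sd = np.std(x, ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale == 0:
        scale = max(abs(x).max(), 1.0) * 0.01
    return 0.9 * scale * n ** (-0.2)


def _kde(values, grid, bw):
    z = (grid[:, None] - values[None, :]) / bw
    return np.exp(-0.5 * z * z).sum(axis=1) / (values.size * bw * np.sqrt(2 * np.pi))


def _binary_density(values):
    v = np.asarray(values, dtype=float)
    return np.array([(v == 0).mean(), (v == 1).mean()])


def train_test_split_strata(strata: pd.DataFrame, test_frac: float = 0.3,
                            seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split strata by individual (strata within a bird are dependent)."""
    rng = np.random.default_rng(seed)
    inds = strata["individual"].unique()
    inds = rng.permutation(inds)
    n_test = max(1, int(round(test_frac * inds.size)))
    test_inds = set(inds[:n_test])
    is_test = strata["individual"].isin(test_inds)
    return strata[~is_test].copy(), strata[is_test].copy()


def uhc_validate(fit: ModelFit, test_strata: pd.DataFrame,
                 eval_predictors: list | None = None,
                 n_resamples: int = 1000, seed: int = 0,
                 grid_size: int = GRID_SIZE_DEFAULT) -> dict[str, UHCResult]:
    """Run the UHC resampling check on held-out strata.

    ``eval_predictors`` may include covariates absent from the model
    (that is the point of the check: a missing selected covariate shows
    up as poor calibration).  Continuous covariates are summarised by a
    Gaussian KDE (Silverman bandwidth from the observed used values) on
    a ``grid_size``-point grid; binary covariates by their two-cell
    proportion vector.  Coverage is the fraction of grid points where
    the observed density lies inside the 2.5-97.5% envelope.
    """
    if n_resamples < 100:
        warnings.warn("n_resamples < 100 gives a rough envelope", stacklevel=2)
    eval_predictors = list(eval_predictors or fit.predictors)
    rng = np.random.default_rng(seed)
    df, codes, starts = _stratum_structure(test_strata)
    counts = np.diff(np.r_[starts, len(df)])
    y = df["case"].to_numpy()

    beta = fit.params.to_numpy(dtype=float)
    if beta.size:
        V = fit.vcov if fit.vcov is not None else np.diag(fit.se.to_numpy() ** 2)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError as e:
            raise ValueError("singular coefficient covariance; cannot resample beta") from e
        Xfit = df[fit.predictors].to_numpy(dtype=float)
    else:
        L = None
        Xfit = np.zeros((len(df), 0))

    Xeval = {p: df[p].to_numpy(dtype=float) for p in eval_predictors}
    observed_vals = {p: Xeval[p][y == 1] for p in eval_predictors}
    is_binary = {p: set(np.unique(Xeval[p])) <= {0.0, 1.0} for p in eval_predictors}

    grids, obs_dens, bws = {}, {}, {}
    for p in eval_predictors:
        if is_binary[p]:
            grids[p] = np.array([0.0, 1.0])
            obs_dens[p] = _binary_density(observed_vals[p])
        else:
            lo, hi = Xeval[p].min(), Xeval[p].max()
            pad = 0.1 * (hi - lo if hi > lo else 1.0)
            grids[p] = np.linspace(lo - pad, hi + pad, grid_size)
            bws[p] = _silverman_bw(observed_vals[p])
            obs_dens[p] = _kde(observed_vals[p], grids[p], bws[p])

    pred = {p: np.empty((n_resamples, grids[p].size)) for p in eval_predictors}
    for r in range(n_resamples):
        bstar = beta + L @ rng.standard_normal(beta.size) if L is not None else beta
        eta = Xfit @ bstar if beta.size else np.zeros(len(df))
        mx = np.repeat(np.maximum.reduceat(eta, starts), counts)
        w = np.exp(eta - mx)
        cum = np.cumsum(w)
        tot = np.add.reduceat(w, starts)
        # sample one endpoint per stratum by its softmax weight
        base = np.r_[0.0, cum[starts[1:] - 1]]
        u = rng.random(starts.size) * tot + base
        pick = np.searchsorted(cum, u, side="left")
        pick = np.clip(pick, starts, starts + counts - 1)
        for p in eval_predictors:
            vals = Xeval[p][pick]
            pred[p][r] = _binary_density(vals) if is_binary[p] else _kde(vals, grids[p], bws[p])

    out = {}
    for p in eval_predictors:
        lo = np.percentile(pred[p], 2.5, axis=0)
        hi = np.percentile(pred[p], 97.5, axis=0)
        cover = float(np.mean((obs_dens[p] >= lo) & (obs_dens[p] <= hi)))
        out[p] = UHCResult(p, grids[p], obs_dens[p], lo, hi, cover, is_binary[p])
    return out


def plot_uhc(results: dict[str, UHCResult], path=None):
    """Simple diagnostic UHC panels (one per covariate)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, axes = plt.subplots(1, len(results), figsize=(4 * len(results), 3.2), squeeze=False)
    for ax, (name, r) in zip(axes[0], results.items()):
        if r.is_binary:
            ax.bar(r.grid - 0.12, r.observed, width=0.22, label="observed")
            ax.bar(r.grid + 0.12, (r.lo + r.hi) / 2, width=0.22,
                   yerr=np.vstack([(r.lo + r.hi) / 2 - r.lo, r.hi - (r.lo + r.hi) / 2]),
                   label="predicted")
        else:
            ax.fill_between(r.grid, r.lo, r.hi, alpha=0.3, label="predicted 95%")
            ax.plot(r.grid, r.observed, lw=1.5, label="observed")
        ax.set_title(f"{name} (coverage {r.coverage:.2f})")
        ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
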