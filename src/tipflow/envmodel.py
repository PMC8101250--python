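"""Genotype + environment + GxE models of transposition and climate forecasting.

Very-recent insertion counts per accession are modeled with a log-link Poisson
GLM on kinship principal components, the modifier allele, z-scored bio-climatic
variables and modifier x bio-variable interactions.  Variance explained (PVE)
is the deviance pseudo-R^2, 1 - D_res / D_null.  Bio-variables enter by greedy
forward selection, stopping when no candidate adds more than 1% PVE.  Family-
level environmental associations use a partial (kinship-restricted) Mantel
test; climate space is summarized by PCA into climatic envelopes (CEs); shifts
of gene-carrier sets in CE space are tested with binomial GLMs under BH-FDR;
and the fitted Poisson model is projected onto future climates z-scored with
current-epoch statistics, holding the genetic terms fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .synth import BIO_VARS

STEPWISE_STOP = 0.01


def zscore_climate(climate: pd.DataFrame, reference_epoch: str = "current",
                   bio_vars=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize bio-variables using the reference (current) epoch only.

    Future columns are transformed with current means/SDs so the fitted model's
    covariate scale carries over.  Returns the z-scored table and the
    reference statistics (mean, sd per variable).
    """
    bio_vars = list(bio_vars) if bio_vars is not None else \
        [c for c in BIO_VARS if c in climate.columns]
    ref = climate.loc[climate["epoch"] == reference_epoch]
    if ref.empty:
        raise ValueError(f"reference epoch {reference_epoch!r} not present")
    mean = ref[bio_vars].mean()
    sd = ref[bio_vars].std(ddof=0)
    zero = sd.index[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance bio-variable(s): {', '.join(zero)}")
    out = climate.copy()
    out[bio_vars] = (climate[bio_vars] - mean) / sd
    stats = pd.DataFrame({"mean": mean, "sd": sd})
    return out, stats


def build_design(data: pd.DataFrame, terms) -> pd.DataFrame:
    """Design matrix with intercept; 'a:b' terms are elementwise products."""
    X = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
    for t in terms:
        if ":" in t:
            a, b = t.split(":", 1)
            X[t] = data[a].to_numpy() * data[b].to_numpy()
        else:
            X[t] = data[t].to_numpy()
    return X


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    r = np.linalg.matrix_rank(mat)
    if r < mat.shape[1]:
        collinear = [
            c for i, c in enumerate(X.columns)
            if np.linalg.matrix_rank(np.delete(mat, i, axis=1)) == r
        ]
        raise ValueError(f"rank-deficient design; collinear terms: {collinear}")


@dataclass
class GlmFit:
    """A fitted GLM with its term list, coefficients, deviances and PVE."""

    family: str
    terms: list[str]
    params: pd.Series
    bse: pd.Series
    deviance: float
    null_deviance: float
    pve: float
    result: object = field(repr=False, default=None)

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        X = build_design(data, self.terms)
        return np.asarray(self.result.predict(X))

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        X = build_design(data, self.terms)
        return X.to_numpy(dtype=float) @ self.params.to_numpy()


def _fit_glm(y, data, terms, family_obj, family_name) -> GlmFit:
    X = build_design(data, list(terms))
    _check_rank(X)
    y = np.asarray(y, dtype=float)
    model = sm.GLM(y, X, family=family_obj)
    try:
        res = model.fit()
    except Exception as err:  # non-convergence surfaces with the trace
        raise RuntimeError(f"GLM failed to converge: {err}") from err
    if not getattr(res, "converged", True):
        niter = res.fit_history.get("iteration", "?") if hasattr(res, "fit_history") else "?"
        raise RuntimeError(f"GLM did not converge after {niter} IRLS iterations")
    pve = 1.0 - res.deviance / res.null_deviance if res.null_deviance > 0 else 0.0
    return GlmFit(
        family=family_name, terms=list(terms),
        params=res.params, bse=res.bse,
        deviance=float(res.deviance), null_deviance=float(res.null_deviance),
        pve=float(pve), result=res,
    )


def fit_poisson_glm(counts, data: pd.DataFrame, terms) -> GlmFit:
    """Log-link Poisson GLM of per-accession counts; PVE = 1 - D_res/D_null."""
    counts = np.asarray(counts)
    if np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    return _fit_glm(counts, data, terms, sm.families.Poisson(), "poisson-log")


def fit_binomial_glm(y, data: pd.DataFrame, terms) -> GlmFit:
    """Logit-link binomial GLM (carrier status on covariates)."""
    return _fit_glm(y, data, terms, sm.families.Binomial(), "binomial-logit")


def stepwise_select(counts, data: pd.DataFrame, base_terms, candidates,
                    modifier_col: str = "modifier", allow_gxe: bool = True,
                    stop: float = STEPWISE_STOP):
    """Greedy forward selection of bio-variables (fixed and GxE terms).

    Candidate moves are each bio-variable as a fixed effect and, when
    ``allow_gxe``, as a modifier interaction (entering jointly with its main
    effect).  At each round the move with the largest PVE gain is added; the
    search stops when the best gain is <= ``stop`` (strictly more than 1% is
    required by default).  Ties break deterministically by candidate name.
    Returns the final fit and the addition trace.
    """
    terms = list(base_terms)
    fit = fit_poisson_glm(counts, data, terms)
    trace = []
    remaining = sorted(candidates)
    while True:
        best = None
        for b in remaining:
            moves = [("fixed", b, [b])]
            if allow_gxe:
                inter = f"{modifier_col}:{b}"
                add = ([inter] if b in terms else [b, inter])
                moves.append(("gxe", b, add))
            for kind, name, add in moves:
                new_terms = terms + [t for t in add if t not in terms]
                if len(new_terms) == len(terms):
                    continue
                try:
                    cand_fit = fit_poisson_glm(counts, data, new_terms)
                except (ValueError, RuntimeError):
                    continue
                delta = cand_fit.pve - fit.pve
                if best is None or delta > best[0]:
                    best = (delta, kind, name, new_terms, cand_fit)
        if best is None or best[0] <= stop:
            if best is not None:
                trace.append({"candidate": best[2], "kind": best[1],
                              "delta_pve": best[0], "added": False})
            break
        delta, kind, name, new_terms, cand_fit = best
        trace.append({"candidate": name, "kind": kind,
                      "delta_pve": delta, "added": True})
        terms, fit = new_terms, cand_fit
    return fit, trace


@dataclass
class HoldoutResult:
    per_accession: pd.DataFrame      # mean prediction error etc. for the primary design
    outliers: list
    predictive_variance: dict        # design name -> variance of mean errors
    error_sd: float


def holdout_validation(counts, data: pd.DataFrame, designs: dict,
                       n_sets: int = 100, set_size: int = 100,
                       outlier_sd: float = 4.0, seed=None) -> HoldoutResult:
    """Repeated random hold-out validation of competing GLM designs.

    For each of ``n_sets`` draws a ``set_size`` testing set is held out, each
    design is fitted on the remainder and used to predict the held-out counts.
    Per accession, predictions are averaged over the draws containing it; an
    accession is an outlier when its mean error exceeds ``outlier_sd`` times
    the across-accession error SD (under the first design).  The predictive
    variance per design is the variance of per-accession mean errors.
    """
    counts = np.asarray(counts, dtype=float)
    n = len(counts)
    if set_size >= n:
        raise ValueError("set_size must be smaller than the panel")
    rng = np.random.default_rng(seed)
    names = list(designs)
    sums = {d: np.zeros(n) for d in names}
    cnts = {d: np.zeros(n) for d in names}
    for _ in range(n_sets):
        test = rng.choice(n, size=set_size, replace=False)
        train = np.setdiff1d(np.arange(n), test)
        for d in names:
            fit = fit_poisson_glm(counts[train], data.iloc[train], designs[d])
            pred = fit.predict(data.iloc[test])
            sums[d][test] += pred
            cnts[d][test] += 1
    pv = {}
    per_acc = None
    for d in names:
        seen = cnts[d] > 0
        mean_pred = np.full(n, np.nan)
        mean_pred[seen] = sums[d][seen] / cnts[d][seen]
        err = mean_pred - counts
        pv[d] = float(np.nanvar(err, ddof=1))
        if d == names[0]:
            per_acc = pd.DataFrame({
                "accession": data.index if data.index.dtype == object else np.arange(n),
                "observed": counts, "mean_pred": mean_pred,
                "mean_error": err, "n_predictions": cnts[d],
            })
    esd = float(np.nanstd(per_acc["mean_error"], ddof=1))
    out_mask = np.abs(per_acc["mean_error"]) > outlier_sd * esd
    outliers = list(per_acc.loc[out_mask.fillna(False), "accession"])
    return HoldoutResult(per_accession=per_acc, outliers=outliers,
                         predictive_variance=pv, error_sd=esd)


def _condense(D: np.ndarray) -> np.ndarray:
    return squareform(D, checks=False)


def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def restricted_mantel(counts, bio, kinship: np.ndarray, n_perm: int = 1000,
                      seed=None) -> tuple[float, float]:
    """Partial Mantel test of count vs bio-variable distances given kinship.

    Both distance matrices are residualized on the kinship distance
    (1 - normalized kinship); the statistic is the Pearson correlation of the
    residuals.  Significance comes from ``n_perm`` row/column-coherent
    permutations of the count matrix, p = (1 + #(r_perm >= r_obs)) / (n_perm + 1).
    """
    kinship = np.asarray(kinship, dtype=float)
    if kinship.ndim != 2 or kinship.shape[0] != kinship.shape[1] \
            or not np.allclose(kinship, kinship.T):
        raise ValueError("kinship must be a square symmetric matrix")
    counts = np.asarray(counts, dtype=float)
    bio = np.asarray(bio, dtype=float)
    n = len(counts)
    Dc = np.abs(counts[:, None] - counts[None, :])
    Db = np.abs(bio[:, None] - bio[None, :])
    diag = np.mean(np.diag(kinship))
    Dk = 1.0 - kinship / (diag if diag != 0 else 1.0)
    dc, db, dk = _condense(Dc), _condense(Db), _condense(Dk)
    rb = _residualize(db, dk)
    rc = _residualize(dc, dk)
    r_obs = float(np.corrcoef(rc, rb)[0, 1])
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    count_ge = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        dcp = Dc[np.ix_(p, p)][iu]
        rcp = _residualize(dcp, dk)
        if float(np.corrcoef(rcp, rb)[0, 1]) >= r_obs:
            count_ge += 1
    pval = (1 + count_ge) / (n_perm + 1)
    return r_obs, pval


@dataclass
class ClimaticEnvelope:
    loadings: pd.DataFrame          # bio-variables x CEs
    scores: pd.DataFrame            # accessions x CEs
    variance_fractions: np.ndarray


def climatic_envelopes(z_climate: pd.DataFrame,
                       n_components: int = 3) -> ClimaticEnvelope:
    """PCA of z-scored bio-variables into climatic envelopes (CE1..).

    Deterministic sign convention: the largest-magnitude loading of each
    component is positive.
    """
    from sklearn.decomposition import PCA

    X = z_climate.to_numpy(dtype=float)
    nondeg = int(np.sum(X.std(axis=0) > 0))
    if nondeg < n_components:
        raise ValueError(
            f"only {nondeg} non-degenerate variables for {n_components} components")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T.copy()
    for j in range(n_components):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    ces = [f"CE{j + 1}" for j in range(n_components)]
    return ClimaticEnvelope(
        loadings=pd.DataFrame(loadings, index=z_climate.columns, columns=ces),
        scores=pd.DataFrame(scores, index=z_climate.index, columns=ces),
        variance_fractions=pca.explained_variance_ratio_.copy(),
    )


def ce_shift_association(carrier_sets: dict, ce_scores: pd.DataFrame,
                         kinship_pcs: pd.DataFrame, fdr: float = 0.05,
                         permute_env: bool = False, seed=None,
                         min_carriers: int = 3) -> pd.DataFrame:
    """Per-gene climatic-envelope shift tests with BH-FDR.

    For every gene with >= ``min_carriers`` carriers, carrier status is
    regressed (binomial GLM, logit link) on each CE score with kinship PCs as
    covariates.  Delta-CE is the carrier mean CE minus the panel mean.  With
    ``permute_env`` the environment (CE scores) is shuffled across accessions
    once before testing, as a negative control.
    """
    scores = ce_scores.copy()
    if permute_env:
        rng = np.random.default_rng(seed)
        scores = pd.DataFrame(scores.to_numpy()[rng.permutation(len(scores))],
                              index=scores.index, columns=scores.columns)
    rows = []
    panel_mean = scores.mean()
    for gene, carriers in carrier_sets.items():
        y = np.asarray(carriers, dtype=float)
        if np.nansum(y) < min_carriers:
            warnings.warn(f"{gene}: fewer than {min_carriers} carriers, skipped")
            continue
        for ce in scores.columns:
            data = kinship_pcs.copy()
            data[ce] = scores[ce].to_numpy()
            try:
                fit = fit_binomial_glm(y, data, list(kinship_pcs.columns) + [ce])
                p = float(fit.result.pvalues[ce])
            except (ValueError, RuntimeError):
                continue
            delta = float(scores.loc[y == 1.0, ce].mean() - panel_mean[ce])
            rows.append({"gene_id": gene, "ce": ce, "delta_ce": delta, "p": p})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["q"] = np.nan
    for ce in df["ce"].unique():
        m = df["ce"] == ce
        df.loc[m, "q"] = multipletests(df.loc[m, "p"], method="fdr_bh")[1]
    df["significant"] = df["q"] <= fdr
    return df


@dataclass
class ForecastResult:
    per_accession: pd.DataFrame
    by_group: pd.DataFrame
    by_modifier: pd.DataFrame


def forecast_transposition(fit: GlmFit, panel_data: pd.DataFrame,
                           climate_current_z: pd.DataFrame,
                           climate_future_z: pd.DataFrame,
                           group_col: str = "group",
                           modifier_col: str = "modifier") -> ForecastResult:
    """Predicted very-recent insertion counts under current vs future climate.

    Genetic terms (kinship PCs, modifier allele, groups) are held fixed; only
    the bio-variable columns change between epochs.  Future z-scores must use
    current-epoch statistics (see :func:`zscore_climate`).
    """
    bio_terms = set()
    for t in fit.terms:
        for part in t.split(":"):
            if part in climate_current_z.columns:
                bio_terms.add(part)
    missing = [b for b in bio_terms if b not in climate_future_z.columns]
    if missing:
        raise ValueError(f"future climate missing model bio-variable(s): {missing}")

    def predict(clim):
        data = panel_data.copy()
        for b in bio_terms:
            data[b] = clim[b].to_numpy()
        return fit.predict(data)

    cur = predict(climate_current_z)
    fut = predict(climate_future_z)
    per = pd.DataFrame({
        "accession": panel_data.index,
        "group": panel_data[group_col].to_numpy(),
        "modifier": panel_data[modifier_col].to_numpy(),
        "pred_current": cur, "pred_future": fut,
        "delta": fut - cur,
    })
    per["pct_change"] = 100.0 * per["delta"] / per["pred_current"]

    def agg(col):
        g = per.groupby(col)["delta"]
        out = g.agg(["mean", "std", "count"]).rename(
            columns={"mean": "delta_mean", "std": "delta_sd", "count": "n"})
        out["delta_se"] = out["delta_sd"] / np.sqrt(out["n"])
        return out.reset_index()

    return ForecastResult(per_accession=per, by_group=agg("group"),
                          by_modifier=agg("modifier"))
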