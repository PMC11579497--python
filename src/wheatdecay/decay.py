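"""Maximum-likelihood mRNA decay-rate estimation from transcription-arrest
time courses.

The observation model: after transcription is blocked at t=0, the relative
abundance of a transcript follows either

* ``const_rate``:    m(t) = exp(-alpha * t)
* ``decaying_rate``: m(t) = exp(-(alpha/beta) * (1 - exp(-beta * t)))

with alpha the initial decay rate (per minute) and beta the rate at which the
decay rate itself relaxes.  Residuals are Gaussian on the log of the relative
abundance by default (multiplicative noise); parameters are estimated by
maximum likelihood and the model is selected by the corrected Akaike
criterion AICc = -2 logL + 2k + 2k(k+1)/(n-k-1), counting the residual scale
sigma among the k free parameters.  Half-life is ln(2)/alpha.

Profiles are first corrected for total-RNA-pool drift using "decay factor"
genes (highly expressed, stable) and scaled to their own t=0 value, so every
profile starts at exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

LN2 = float(np.log(2.0))

#: alpha in [ln2 / 72 h, ln2 / 1 min] per minute: spans the observed
#: half-life range (minutes to >24 h) with margin.
DEFAULT_RATE_BOUNDS = (LN2 / (72.0 * 60.0), LN2 / 1.0)
#: beta above 1/(first sampling interval) is unidentifiable on the default
#: grid (the rate decay would complete before the first observation).
DEFAULT_BETA_BOUNDS = (1e-6, 1.0 / 15.0)
DEFAULT_MODELS = ("const_rate", "decaying_rate")
RELATIVE_FLOOR = 1e-3  # pseudo-abundance admitting zeros on the log scale


@dataclass
class NormalizedProfile:
    """Relative abundance of one gene, drift-corrected and scaled to t0 = 1."""

    gene_id: str
    times: np.ndarray  # minutes
    relative_abundance: np.ndarray  # time x replicate, == 1 at t=0
    correction_factors: np.ndarray  # time x replicate pool-drift factors


@dataclass
class DecayFit:
    """Fitted decay model for one gene."""

    gene_id: str
    model: str
    alpha: float  # per minute
    beta: float  # per minute (decaying_rate only, else NaN)
    sigma: float
    logL: float
    aicc: float
    flag: str = "ok"

    @property
    def half_life_minutes(self) -> float:
        return LN2 / self.alpha


def half_life(fit_or_alpha, unit="hours"):
    """t1/2 = ln(2)/rate; ``unit`` is ``hours`` or ``minutes``."""
    alpha = getattr(fit_or_alpha, "alpha", fit_or_alpha)
    if not alpha > 0:
        raise ValueError("half-life requires alpha > 0")
    minutes = LN2 / alpha
    return minutes / 60.0 if unit == "hours" else minutes


def format_half_life(hours, max_horizon_h=72.0):
    """Human-readable half-life, reporting beyond-horizon values as bounds."""
    if hours > max_horizon_h:
        return f"> {max_horizon_h:g} h"
    return f"{hours:.2f} h"


# ---------------------------------------------------------------------------
# decay-factor selection and normalization
# ---------------------------------------------------------------------------

def select_decay_factor_genes(table, n):
    """Pick the n best normalization genes: highly expressed and stable.

    Library-depth drift common to all genes is first removed by dividing
    each sample by the geometric mean over genes of y(g,t,r)/y(g,0,r); each
    gene's stability is then measured as the least-squares slope of its
    drift-corrected log profile (the most stable genes have the largest
    slope, since the correction is anchored on the transcriptome average,
    which itself decays).  Genes are ranked by t0 abundance (descending) and
    by that stability slope (descending); the two ranks are summed and the n
    lowest-scoring genes are returned.  Ties break by gene id, so the choice
    is deterministic given the table.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if table.n_genes < n:
        raise ValueError("table has fewer genes than requested")
    y = table.abundance  # gene x time x replicate
    t = table.times
    t0 = y[:, 0, :].mean(axis=1)
    positive = np.all(y > 0, axis=(1, 2))
    if positive.any():
        rel = y[positive] / y[positive, 0:1, :]
        pool = np.exp(np.log(rel).mean(axis=0))  # time x replicate drift proxy
    else:
        pool = np.ones((len(t), y.shape[2]))
    with np.errstate(invalid="ignore", divide="ignore"):
        logrel = np.log(np.maximum(y / pool[None, :, :], 1e-12))
    logrel = logrel - logrel[:, 0:1, :]  # anchor each replicate at t0
    # least-squares slope through the origin of log relative abundance vs t
    tt = np.broadcast_to(t[None, :, None], logrel.shape)
    slope = (tt * logrel).sum(axis=(1, 2)) / (tt * tt).sum(axis=(1, 2))
    frame = pd.DataFrame({"gene": table.genes, "t0": t0, "slope": slope})
    frame["rank_expr"] = frame["t0"].rank(ascending=False, method="min")
    frame["rank_stable"] = frame["slope"].rank(ascending=False, method="min")
    frame["score"] = frame["rank_expr"] + frame["rank_stable"]
    frame = frame.sort_values(["score", "gene"], kind="mergesort")
    return frame["gene"].head(n).tolist()


def normalize_profiles(table, decay_factors):
    """Drift-correct every profile and scale it to its own t0 value.

    The correction factor for sample (t, r) is the geometric mean over
    decay-factor genes of RPM(g, t, r) / RPM(g, 0, r): since those genes are
    stable, any departure from 1 measures total-pool / depth drift.  Factor
    genes with a zero abundance anywhere are excluded with a warning.
    """
    usable = []
    for g in decay_factors:
        prof = table.gene_profile(g)
        if np.all(prof > 0):
            usable.append(g)
        else:
            warnings.warn(f"decay factor gene {g} has zero abundance; excluded")
    if not usable:
        raise ValueError("no usable decay-factor genes")
    ratios = np.stack(
        [table.gene_profile(g) / table.gene_profile(g)[0] for g in usable]
    )  # factor-gene x time x replicate
    factors = np.exp(np.log(ratios).mean(axis=0))  # time x replicate

    profiles = {}
    for g in table.genes:
        corrected = table.gene_profile(g) / factors
        t0 = corrected[0]
        if np.any(t0 <= 0):
            rel = np.full_like(corrected, np.nan)
            rel[0] = 1.0
        else:
            rel = corrected / t0
        profiles[g] = NormalizedProfile(g, table.times.copy(), rel, factors)
    return profiles


# ---------------------------------------------------------------------------
# per-gene ML fitting
# ---------------------------------------------------------------------------

def _log_model(model, t, alpha, beta=None):
    if model == "const_rate":
        return -alpha * t
    return -(alpha / beta) * (1.0 - np.exp(-beta * t))


def _gaussian_ml(residuals):
    n = residuals.size
    rss = float(np.dot(residuals, residuals))
    sigma2 = max(rss / n, 1e-300)
    logL = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    return np.sqrt(sigma2), logL


def _aicc(logL, k, n):
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * logL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_decay(
    profile: NormalizedProfile,
    bounds=DEFAULT_RATE_BOUNDS,
    models=DEFAULT_MODELS,
    log_scale=True,
    beta_bounds=DEFAULT_BETA_BOUNDS,
    floor=RELATIVE_FLOOR,
    n_starts=5,
):
    """ML fit of the decay models to one normalized profile; min-AICc wins.

    Only t > 0 observations enter the likelihood (the t=0 values are exactly
    1 by construction).  Requires >= 4 time points with at least one finite
    replicate value each.
    """
    t_all = profile.times
    y = profile.relative_abundance
    mask_t = t_all > 0
    t_obs, y_obs = [], []
    for ti in np.where(mask_t)[0]:
        vals = y[ti][np.isfinite(y[ti])]
        t_obs.extend([t_all[ti]] * len(vals))
        y_obs.extend(vals)
    t_arr = np.asarray(t_obs, dtype=float)
    y_arr = np.asarray(y_obs, dtype=float)
    n_points = len(np.unique(t_arr)) + 1  # + t0
    if n_points < 4:
        raise ValueError(f"{profile.gene_id}: need >= 4 informative time points")
    if np.all(y_arr <= 0):
        raise ValueError(f"{profile.gene_id}: profile is all zero")

    if log_scale:
        log_floor = np.log(floor)
        target = np.log(np.maximum(y_arr, floor))

        def residuals(model, params):
            # the floor censors both data and prediction, so values below
            # the detection floor carry no signal instead of biasing alpha
            pred = np.maximum(_log_model(model, t_arr, *params), log_floor)
            return target - pred

    else:

        def residuals(model, params):
            return y_arr - np.exp(_log_model(model, t_arr, *params))

    n = y_arr.size
    lo, hi = bounds
    alpha_grid = np.exp(np.linspace(np.log(lo), np.log(hi), n_starts))
    fits = []
    for model in models:
        if model == "const_rate":
            k = 2
            if log_scale:
                # closed-form least squares through the origin, then clip
                denom = float(np.dot(t_arr, t_arr))
                a_hat = float(np.dot(t_arr, -target)) / denom if denom else lo
                starts = [np.clip(a_hat, lo, hi)]
            else:
                starts = list(alpha_grid)
            best = None
            for a0 in starts:
                res = optimize.minimize(
                    lambda p: float(np.sum(residuals(model, p) ** 2)),
                    x0=[a0],
                    bounds=[(lo, hi)],
                    method="L-BFGS-B",
                )
                if best is None or res.fun < best.fun:
                    best = res
            params = (float(best.x[0]), np.nan)
        else:
            k = 3
            best = None
            for a0 in alpha_grid:
                res = optimize.minimize(
                    lambda p: float(np.sum(residuals(model, p) ** 2)),
                    x0=[a0, 1e-2],
                    bounds=[(lo, hi), beta_bounds],
                    method="L-BFGS-B",
                )
                if best is None or res.fun < best.fun:
                    best = res
            params = (float(best.x[0]), float(best.x[1]))
        if best is None or not np.isfinite(best.fun):
            continue
        sigma, logL = _gaussian_ml(residuals(model, [p for p in params if np.isfinite(p)]))
        fits.append(
            DecayFit(
                gene_id=profile.gene_id,
                model=model,
                alpha=params[0],
                beta=params[1],
                sigma=sigma,
                logL=logL,
                aicc=_aicc(logL, k, n),
            )
        )
    if not fits:
        return DecayFit(profile.gene_id, "none", np.nan, np.nan, np.nan, np.nan,
                        np.inf, flag="failed")
    # min AICc; tie-break by lower alpha
    fits.sort(key=lambda f: (f.aicc, f.alpha))
    return fits[0]


# ---------------------------------------------------------------------------
# curve comparison and correlations
# ---------------------------------------------------------------------------

def compare_decay_curves(profile_a: NormalizedProfile, profile_b: NormalizedProfile,
                         hypothesis="a_faster"):
    """One-sided repeated-measures comparison of two decay curves.

    Mixed ANOVA with time as the within-subject factor (subjects are the
    replicate profiles) and gene as the between factor; the gene x time
    interaction F is converted to a one-sided p for the directional
    hypothesis that the nominated gene decays faster (lower relative
    abundance at t > 0).
    """
    import pingouin as pg

    if not np.array_equal(profile_a.times, profile_b.times):
        raise ValueError("time grids differ")
    if profile_a.relative_abundance.shape != profile_b.relative_abundance.shape:
        raise ValueError("replicate counts differ")
    n_rep = profile_a.relative_abundance.shape[1]
    if n_rep < 2:
        raise ValueError("repeated-measures comparison needs >= 2 replicates")

    rows = []
    for label, prof in (("a", profile_a), ("b", profile_b)):
        for r in range(n_rep):
            for ti, t in enumerate(prof.times):
                rows.append(
                    {
                        "subject": f"{label}_rep{r}",
                        "gene": label,
                        "time": float(t),
                        "abundance": prof.relative_abundance[ti, r],
                    }
                )
    long = pd.DataFrame(rows)

    mask = long["time"] > 0
    mean_a = long.loc[(long["gene"] == "a") & mask, "abundance"].mean()
    mean_b = long.loc[(long["gene"] == "b") & mask, "abundance"].mean()
    faster = "a" if mean_a < mean_b else ("b" if mean_b < mean_a else None)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(
            data=long, dv="abundance", within="time", between="gene",
            subject="subject",
        )
    inter = aov.loc[aov["Source"] == "Interaction"].iloc[0]
    f_stat = float(inter["F"])
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    p_two = float(inter[p_col])
    if not np.isfinite(f_stat):  # degenerate: zero residual variance
        f_stat, p_two = 0.0, 1.0
    nominated = hypothesis.split("_")[0]
    if faster is None:
        p_one = 0.5
    elif faster == nominated:
        p_one = p_two / 2.0
    else:
        p_one = 1.0 - p_two / 2.0
    return f_stat, p_one


def decay_abundance_correlation(fits: pd.DataFrame, abundance: pd.Series,
                                categories=None, log_abundance=True):
    """Pearson correlation of decay rate against (log) steady-state abundance.

    Returns ``(r, p)``; with a gene -> category map, also a per-category
    table as a second element ``(overall, per_category_frame)``.
    """
    merged = pd.DataFrame({"alpha": fits.set_index("gene")["alpha_per_min"]})
    merged["abundance"] = abundance
    merged = merged.dropna()
    merged = merged[merged["abundance"] > 0] if log_abundance else merged
    if len(merged) < 3:
        raise ValueError("need >= 3 paired observations")
    x = np.log10(merged["abundance"]) if log_abundance else merged["abundance"]
    if np.std(x) == 0 or np.std(merged["alpha"]) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(merged["alpha"], x)
    if categories is None:
        return float(r), float(p)
    rows = []
    cat = pd.Series(categories)
    for name, genes in cat.groupby(cat).groups.items():
        sub = merged.loc[merged.index.intersection(genes)]
        if len(sub) < 3:
            continue
        xs = np.log10(sub["abundance"]) if log_abundance else sub["abundance"]
        rc, pc = stats.pearsonr(sub["alpha"], xs)
        rows.append({"category": name, "r": rc, "p": pc, "n": len(sub)})
    return (float(r), float(p)), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class DecayModel:
    """Exponential decay model for a transcription-arrest time course.

    Parameters
    ----------
    table : TimeCourseTable
        Gene x time x replicate RPM abundances.
    decay_factors : 'auto' or list of gene ids
        Normalization genes; ``'auto'`` selects ``n_factors`` genes that are
        highly expressed and stable.
    models : subset of {'const_rate', 'decaying_rate'}
    log_scale : bool
        Gaussian likelihood on log relative abundance (default) or raw scale.
    """

    def __init__(self, table, decay_factors="auto", n_factors=30,
                 models=DEFAULT_MODELS, log_scale=True,
                 bounds=DEFAULT_RATE_BOUNDS):
        self.table = table
        if decay_factors == "auto":
            decay_factors = select_decay_factor_genes(
                table, min(n_factors, table.n_genes)
            )
        self.decay_factors = list(decay_factors)
        self.models = tuple(models)
        self.log_scale = log_scale
        self.bounds = bounds
        self.profiles = normalize_profiles(table, self.decay_factors)

    def fit(self, genes=None) -> "DecayResults":
        genes = list(genes) if genes is not None else self.table.genes
        fits = []
        for g in genes:
            try:
                fits.append(
                    fit_decay(self.profiles[g], bounds=self.bounds,
                              models=self.models, log_scale=self.log_scale)
                )
            except ValueError:
                fits.append(DecayFit(g, "none", np.nan, np.nan, np.nan,
                                     np.nan, np.inf, flag="failed"))
        return DecayResults(self, fits)

    def fit_per_replicate(self, genes=None) -> pd.DataFrame:
        """Fit each replicate's profile separately (const_rate model).

        Returns a gene x replicate table of alpha estimates; these replicate
        rates feed the homoeolog-pair t-tests.
        """
        genes = list(genes) if genes is not None else self.table.genes
        n_rep = self.table.n_replicates
        out = np.full((len(genes), n_rep), np.nan)
        for gi, g in enumerate(genes):
            prof = self.profiles[g]
            for r in range(n_rep):
                single = NormalizedProfile(
                    g, prof.times, prof.relative_abundance[:, r : r + 1],
                    prof.correction_factors[:, r : r + 1],
                )
                try:
                    fit = fit_decay(single, bounds=self.bounds,
                                    models=("const_rate",),
                                    log_scale=self.log_scale)
                    out[gi, r] = fit.alpha
                except ValueError:
                    pass
        return pd.DataFrame(
            out, index=genes, columns=[f"rep{r + 1}" for r in range(n_rep)]
        )


class DecayResults:
    """Per-gene decay fits with model-selection diagnostics."""

    def __init__(self, model: DecayModel, fits):
        self.model = model
        self.fit_objects = {f.gene_id: f for f in fits}
        rows = []
        for f in fits:
            hl_min = LN2 / f.alpha if f.alpha and f.alpha > 0 else np.nan
            rows.append(
                {
                    "gene": f.gene_id,
                    "model": f.model,
                    "alpha_per_min": f.alpha,
                    "beta_per_min": f.beta,
                    "sigma": f.sigma,
                    "logL": f.logL,
                    "aicc": f.aicc,
                    "half_life_min": hl_min,
                    "half_life_h": hl_min / 60.0 if np.isfinite(hl_min) else np.nan,
                    "flag": f.flag,
                }
            )
        self.fits = pd.DataFrame(rows)

    @property
    def rates(self) -> pd.Series:
        return self.fits.set_index("gene")["alpha_per_min"]

    def half_lives(self, unit="hours") -> pd.Series:
        col = "half_life_h" if unit == "hours" else "half_life_min"
        return self.fits.set_index("gene")[col]

    def rate_deciles(self) -> pd.Series:
        """Decile of decay rate per gene (1 = slowest/most stable); strict
        deciles with ties broken by gene id."""
        ok = self.fits.dropna(subset=["alpha_per_min"]).sort_values(
            ["alpha_per_min", "gene"], kind="mergesort"
        )
        n = len(ok)
        sizes = [n // 10 + (1 if i < n % 10 else 0) for i in range(10)]
        labels = np.repeat(np.arange(1, 11), sizes)
        return pd.Series(labels, index=ok["gene"].to_numpy(), name="decile")

    def decay_abundance_correlation(self, abundance=None, categories=None):
        if abundance is None:
            abundance = self.model.table.t0_abundance()
        return decay_abundance_correlation(self.fits, abundance,
                                           categories=categories)

    def summary(self) -> str:
        ok = self.fits[self.fits["flag"] == "ok"]
        lines = [
            "Decay model results",
            "===================",
            f"genes fitted:        {len(ok)} / {len(self.fits)}",
            f"models:              {', '.join(self.model.models)}"
            f" (scale: {'log' if self.model.log_scale else 'raw'})",
            f"decay-factor genes:  {len(self.model.decay_factors)}",
        ]
        if len(ok):
            counts = ok["model"].value_counts().to_dict()
            lines.append(f"model selection:     {counts}")
            lines.append(
                f"median half-life:    {ok['half_life_h'].median():.2f} h"
            )
            lines.append(
                f"mean half-life:      {ok['half_life_h'].mean():.2f} h"
            )
        return "\n".join(lines)

    def write_tsv(self, path):
        self.fits.to_csv(path, sep="\t", index=False, na_rep="NA")

    def plot_half_life_distribution(self, ax=None, bins=50, max_h=24):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        hl = self.half_lives().dropna().clip(upper=max_h)
        ax.hist(hl, bins=bins)
        ax.set_xlabel("half-life (h)")
        ax.set_ylabel("mRNAs")
        return ax

    def plot_profiles(self, genes, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for g in genes:
            prof = self.model.profiles[g]
            mean = prof.relative_abundance.mean(axis=1)
            ax.plot(prof.times, mean, marker="o", label=g)
        ax.set_xlabel("minutes after arrest")
        ax.set_ylabel("relative abundance")
        ax.legend()
        return ax
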