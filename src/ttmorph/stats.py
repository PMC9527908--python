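"""Hierarchical statistics for clustered morphometry tables.

Repeated per-tubule measurements are clustered within cells, and cells
within animals; treating them as independent inflates type-I error.  The
regional contrast (control / MI-remote / MI-border) is therefore fit as a
linear mixed model with a fixed region effect and random intercepts for
animal and for cell nested in animal, estimated by maximum likelihood.
Metrics failing a normality screen are transformed (log10, then sqrt)
before modelling; per-region mean ± s.e. summaries are always reported on
the original scale.  A paired t-test serves the before/after ejection-
fraction comparison.

Boundary policy: a random-effect variance estimated at (numerically) zero
is dropped and the model refit without it, cascading down to ordinary
least squares — in that collapsed limit the contrast p-value coincides
with a two-sample t-test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.diagnostic import kstest_normal

from .errors import DegenerateDataError, MeasurementError

logger = logging.getLogger(__name__)

__all__ = [
    "GroupComparison",
    "test_normality",
    "choose_transform",
    "fit_region_contrast",
    "paired_t",
    "summarize_mean_se",
    "recompute_printed_summaries",
    "simulate_clustered",
]

_TRANSFORMS = {
    "identity": lambda v: v,
    "log10": np.log10,
    "sqrt": np.sqrt,
}


@dataclass
class GroupComparison:
    """Result of one regional contrast on one metric."""

    metric: str
    regions: tuple[str, str]
    transform: str
    estimate: float          # fixed-effect difference (region[1] − region[0]) on analysis scale
    std_error: float
    p_value: float
    group_means: dict        # region -> (mean, se) on the original scale
    n_observations: dict
    n_cells: dict
    n_animals: dict
    model_structure: str = "animal+cell"
    residual_normality_p: float | None = None
    warnings: list[str] = field(default_factory=list)


def test_normality(values, method: str = "shapiro") -> tuple[float, float]:
    """Shapiro–Wilk or (Lilliefors-corrected) Kolmogorov–Smirnov normality test.

    Returns ``(statistic, p_value)`` for the null that the sample is
    normal.  Constant input is degenerate (normality is undefined).
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 3:
        raise DegenerateDataError(f"need at least 3 values, got {len(v)}")
    if np.ptp(v) == 0:
        raise DegenerateDataError("constant input: normality test undefined")
    if method == "shapiro":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sps.shapiro(v)
        return float(res.statistic), float(res.pvalue)
    if method == "ks":
        stat, p = kstest_normal(v, dist="norm")
        return float(stat), float(p)
    raise MeasurementError(f"unknown normality method {method!r}")


def choose_transform(values, alpha: float = 0.05, method: str = "shapiro") -> str:
    """Pick the analysis-scale transform: identity, else log10, else sqrt.

    The identity is kept whenever normality is not rejected at ``alpha``;
    otherwise the first of (log10, sqrt) whose transformed values pass the
    test is used; if none passes, log10 is used with a warning (or sqrt /
    identity when positivity rules log10 out).  The decision is logged.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    _, p = test_normality(v, method=method)
    if p > alpha:
        logger.info("transform decision: identity (normality p=%.3g)", p)
        return "identity"
    candidates = []
    if np.all(v > 0):
        candidates.append("log10")
    else:
        logger.info("log10 skipped: non-positive values present")
    if np.all(v >= 0):
        candidates.append("sqrt")
    else:
        logger.info("sqrt skipped: negative values present")
    for name in candidates:
        _, pt = test_normality(_TRANSFORMS[name](v), method=method)
        if pt > alpha:
            logger.info("transform decision: %s (normality p=%.3g)", name, pt)
            return name
    fallback = candidates[0] if candidates else "identity"
    logger.warning("no transform restored normality; falling back to %s", fallback)
    return fallback


def _fit_mixed_cascade(df: pd.DataFrame) -> tuple[float, float, float, np.ndarray, str, list[str]]:
    """ML mixed-model fit with boundary-variance drop-and-refit cascade.

    ``df`` needs columns ``y`` (analysis scale), ``g`` (0/1 region code),
    ``animal``, ``cell`` (globally unique).  Returns
    ``(estimate, se, p, residuals, structure, warnings)``.

    The contrast p-value uses a t reference with containment-style
    denominator degrees of freedom: the region effect varies between
    animals, so the effective replication is the animal count, not the
    observation count — ``df = n_animals − 2`` when an animal intercept is
    in the model (``n_cells − 2`` for the cell-only model).  A normal
    (Wald z) reference with 3 animals per arm roughly doubles the nominal
    type-I error.
    """
    notes: list[str] = []
    obs_per_cell = df.groupby("cell", observed=True).size()
    want_cell = bool((obs_per_cell > 1).any())
    n_animals = df["animal"].nunique()
    min_animals = df.groupby("g", observed=True)["animal"].nunique().min()
    want_animal = n_animals > 1 and min_animals >= 2
    if not want_animal:
        notes.append("fewer than 2 animals in a region: animal random effect dropped "
                     "(cell-level intercept only)")

    structures = []
    if want_animal and want_cell:
        structures.append("animal+cell")
    if want_animal:
        structures.append("animal")
    if want_cell:
        structures.append("cell")
    structures.append("ols")

    X = sm.add_constant(df["g"].to_numpy(dtype=float))
    y = df["y"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise DegenerateDataError("all response values identical")

    for structure in structures:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if structure == "ols":
                    res = sm.OLS(y, X).fit()
                    return (float(np.asarray(res.params)[1]), float(np.asarray(res.bse)[1]),
                            float(np.asarray(res.pvalues)[1]), np.asarray(res.resid),
                            structure, notes)
                if structure == "animal+cell":
                    md = sm.MixedLM.from_formula(
                        "y ~ g", data=df, groups="animal", re_formula="1",
                        vc_formula={"cell": "0 + C(cell)"})
                elif structure == "animal":
                    md = sm.MixedLM.from_formula("y ~ g", data=df,
                                                 groups="animal", re_formula="1")
                else:  # cell
                    md = sm.MixedLM.from_formula("y ~ g", data=df,
                                                 groups="cell", re_formula="1")
                res = md.fit(reml=False, method="lbfgs", maxiter=200)
            if not np.isfinite(res.bse_fe.iloc[1]):
                raise ValueError("non-finite standard error")
            # boundary check: variance components at ~0 -> simpler structure
            tol = 1e-6 * res.scale
            boundary = False
            if structure in ("animal+cell", "animal") and float(res.cov_re.iloc[0, 0]) < tol:
                boundary = True
            if structure == "animal+cell" and res.vcomp.size and float(res.vcomp[0]) < tol:
                boundary = True
            if structure == "cell" and float(res.cov_re.iloc[0, 0]) < tol:
                boundary = True
            if boundary:
                notes.append(f"random-effect variance at boundary in '{structure}'; refitting simpler model")
                continue
            est = float(res.fe_params.iloc[1])
            se = float(res.bse_fe.iloc[1])
            if structure in ("animal+cell", "animal"):
                ddf = df["animal"].nunique() - 2
            else:
                ddf = df["cell"].nunique() - 2
            ddf = max(ddf, 1)
            p = float(2.0 * sps.t.sf(abs(est / se), ddf))
            return (est, se, p, np.asarray(res.resid), structure, notes)
        except DegenerateDataError:
            raise
        except Exception as exc:  # convergence/singularity: fall through the cascade
            notes.append(f"fit with structure '{structure}' failed ({exc}); simplifying")
            continue
    raise MeasurementError("all model structures failed")  # pragma: no cover


def fit_region_contrast(table: pd.DataFrame, metric: str | None = None,
                        region_pair: tuple[str, str] = ("control", "border"),
                        alpha: float = 0.05,
                        transform: str | None = None) -> GroupComparison:
    """Mixed-model contrast of one metric between two regions.

    ``table`` is tidy: columns ``value``, ``region``, ``animal_id``,
    ``cell_id`` (and optionally ``metric``).  The fixed effect is the
    region difference (second minus first of ``region_pair``) on the
    analysis scale chosen by :func:`choose_transform` unless ``transform``
    is forced.  Per-region mean ± s.e. are reported on the original scale.
    """
    df = table.copy()
    if metric is not None and "metric" in df.columns:
        df = df[df["metric"] == metric]
    df = df[df["region"].isin(region_pair)].dropna(subset=["value"])
    if df["region"].nunique() < 2:
        raise DegenerateDataError(f"need observations in both of {region_pair}")

    values = df["value"].to_numpy(dtype=float)
    if transform is None:
        try:
            transform = choose_transform(values, alpha=alpha)
        except DegenerateDataError:
            transform = "identity"
    if transform != "identity" and not np.all(
            values > 0 if transform == "log10" else values >= 0):
        logger.warning("transform %s invalid for data range; using identity", transform)
        transform = "identity"

    work = pd.DataFrame({
        "y": _TRANSFORMS[transform](values),
        "g": (df["region"] == region_pair[1]).astype(float).to_numpy(),
        "animal": df["animal_id"].astype(str).to_numpy(),
    })
    work["cell"] = (df["animal_id"].astype(str) + "/" + df["cell_id"].astype(str)).to_numpy()

    est, se, p, resid, structure, notes = _fit_mixed_cascade(work)

    try:
        _, p_resid = test_normality(resid)
    except DegenerateDataError:
        p_resid = None

    means, n_obs, n_cells, n_animals = {}, {}, {}, {}
    for r in region_pair:
        sub = df[df["region"] == r]
        means[r] = summarize_mean_se(sub["value"])
        n_obs[r] = int(len(sub))
        n_cells[r] = int(sub.groupby(["animal_id", "cell_id"]).ngroups)
        n_animals[r] = int(sub["animal_id"].nunique())

    return GroupComparison(
        metric=metric or (df["metric"].iloc[0] if "metric" in df.columns and len(df) else ""),
        regions=region_pair,
        transform=transform,
        estimate=est, std_error=se, p_value=p,
        group_means=means, n_observations=n_obs,
        n_cells=n_cells, n_animals=n_animals,
        model_structure=structure,
        residual_normality_p=p_resid,
        warnings=notes,
    )


def paired_t(before, after) -> tuple[float, float]:
    """Paired t-test; returns (mean difference before − after, two-sided p).

    A zero-variance difference vector is handled directly: p = 1 when the
    common difference is 0, else p → 0.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise MeasurementError(f"length mismatch: {b.shape} vs {a.shape}")
    if b.size < 2:
        raise MeasurementError("need at least 2 pairs")
    d = b - a
    md = float(d.mean())
    if np.ptp(d) == 0:
        return md, 1.0 if md == 0 else 0.0
    res = sps.ttest_rel(b, a)
    return md, float(res.pvalue)


def summarize_mean_se(values) -> tuple[float, float | None]:
    """Arithmetic mean and standard error (sd/√n); s.e. is None for n = 1."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise MeasurementError("empty input")
    mean = float(v.mean())
    if v.size == 1:
        return mean, None
    return mean, float(v.std(ddof=1) / np.sqrt(v.size))


def recompute_printed_summaries(per_tubule: pd.DataFrame,
                                metrics: list[str] | None = None) -> pd.DataFrame:
    """Per-region mean ± s.e. recomputed from a per-tubule measurement list.

    ``per_tubule`` must carry a ``region`` column plus one numeric column
    per metric (e.g. ``diameter_nm``, ``length_fraction``, ``volume_um3``,
    ``surface_area_um2``).  This is the entry point for checking published
    summary statistics against a released per-tubule list.
    """
    if "region" not in per_tubule.columns:
        raise MeasurementError("per-tubule table needs a 'region' column")
    if metrics is None:
        metrics = [c for c in per_tubule.columns
                   if c != "region" and pd.api.types.is_numeric_dtype(per_tubule[c])]
    rows = []
    for region, sub in per_tubule.groupby("region"):
        for m in metrics:
            vals = sub[m].dropna()
            if not len(vals):
                continue
            mean, se = summarize_mean_se(vals)
            rows.append({"region": region, "metric": m, "mean": mean,
                         "se": se, "n": int(len(vals))})
    return pd.DataFrame(rows)


def simulate_clustered(n_animals: int = 3, n_cells: int = 3, n_obs: int = 15,
                       sd_animal: float = 0.3, sd_cell: float = 0.2,
                       sd_residual: float = 1.0, delta: float = 0.0,
                       regions: tuple[str, str] = ("control", "border"),
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Two-arm clustered Gaussian data for model calibration studies.

    Each arm has ``n_animals`` animals × ``n_cells`` cells × ``n_obs``
    observations; ``delta`` is added to the second arm.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    rows = []
    for gi, region in enumerate(regions):
        for ai in range(n_animals):
            a_eff = rng.normal(0.0, sd_animal)
            for ci in range(n_cells):
                c_eff = rng.normal(0.0, sd_cell)
                eps = rng.normal(0.0, sd_residual, size=n_obs)
                for v in gi * delta + a_eff + c_eff + eps:
                    rows.append({"value": v, "region": region,
                                 "animal_id": f"{region}_a{ai}",
                                 "cell_id": f"c{ci}"})
    return pd.DataFrame(rows)
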